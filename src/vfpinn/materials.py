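"""Transversely isotropic elasticity for the two-layer (body--cover) vocal fold.

Each layer is linear elastic and transversely isotropic, with the plane of
isotropy perpendicular to the anterior--posterior (AP) axis.  The AP axis is
the domain z-axis throughout the package (see :mod:`vfpinn.geometry`), so the
stiffness matrix is written directly in domain coordinates and no rotation
machinery is needed.

Voigt convention (used everywhere in this package): component order
(11, 22, 33, 23, 13, 12) with *engineering* shear strains
``gamma_ij = 2 eps_ij``, so that ``sigma_voigt = C_voigt @ eps_voigt`` and
``eps^T C eps`` equals the full contraction ``eps : C : eps``.

The free material parameters of a configuration are the transverse Young's
modulus ``Et`` (shared by both layers) and the AP shear moduli ``GAP`` of the
body and cover; the AP Young's modulus is tied to the shear modulus by
``E_AP = 4 GAP``.  The remaining constants of the transversely isotropic law
(in-plane Poisson ratio, AP Poisson ratio) are not determined by those three
numbers; they live in :class:`AuxiliaryElasticParams` with near-incompressible
in-plane behaviour as the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VOIGT_ORDER",
    "AuxiliaryElasticParams",
    "MaterialConfig",
    "LayerElasticity",
    "MaterialGridError",
    "transversely_isotropic_stiffness",
    "isotropic_stiffness",
    "build_layer_elasticity",
    "voigt_to_full",
    "full_to_voigt",
]

#: Voigt index pairs, fixed package-wide: (11, 22, 33, 23, 13, 12).
VOIGT_ORDER = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))

AP_AXIS = np.array([0.0, 0.0, 1.0])

#: Default tissue density, kg/m^3.
DEFAULT_DENSITY = 1030.0


class MaterialGridError(ValueError):
    """Raised for non-physical material parameters or an indefinite stiffness."""


@dataclass(frozen=True)
class AuxiliaryElasticParams:
    """Constants of the transversely isotropic law not fixed by (Et, GAP).

    nu_t : in-plane Poisson ratio (default 0.499, nearly incompressible in
        the transverse plane).
    nu_ap : Poisson ratio coupling AP stress to transverse strain
        (default 0: axial stretch produces no lateral contraction).
    eap_factor : ratio E_AP / G_AP (default 4).
    """

    nu_t: float = 0.499
    nu_ap: float = 0.0
    eap_factor: float = 4.0


@dataclass(frozen=True)
class MaterialConfig:
    """One body--cover material configuration.

    Free parameters: transverse Young's modulus ``Et`` (Pa, shared by both
    layers) and AP shear moduli ``gap_body`` / ``gap_cover`` (Pa).  The AP
    Young's moduli are derived as ``eap = 4 * gap`` per layer.
    """

    Et: float
    gap_body: float
    gap_cover: float
    density: float = DEFAULT_DENSITY
    aux: AuxiliaryElasticParams = field(default_factory=AuxiliaryElasticParams)

    def __post_init__(self) -> None:
        for name in ("Et", "gap_body", "gap_cover", "density"):
            if getattr(self, name) <= 0.0:
                raise MaterialGridError(f"{name} must be strictly positive")

    @property
    def eap_body(self) -> float:
        return self.aux.eap_factor * self.gap_body

    @property
    def eap_cover(self) -> float:
        return self.aux.eap_factor * self.gap_cover

    def as_vector(self) -> np.ndarray:
        """Free parameters (Et, gap_body, gap_cover) as an array, Pa."""
        return np.array([self.Et, self.gap_body, self.gap_cover])

    def layer_elasticity(self, layer: str) -> "LayerElasticity":
        gap = {"body": self.gap_body, "cover": self.gap_cover}[layer]
        return build_layer_elasticity(self.Et, gap, self.aux, layer=layer)


@dataclass(frozen=True)
class LayerElasticity:
    """6x6 Voigt stiffness of one layer, Pa, with its layer tag."""

    C_voigt: np.ndarray
    layer: str
    isotropy_axis: np.ndarray = field(default_factory=lambda: AP_AXIS.copy())

    @property
    def C_full(self) -> np.ndarray:
        return voigt_to_full(self.C_voigt)


def transversely_isotropic_stiffness(
    Et: float, Eap: float, Gap: float, nu_t: float, nu_ap: float
) -> np.ndarray:
    """Voigt stiffness of a transversely isotropic solid, symmetry axis = z.

    Built by inverting the compliance matrix; ``Gt = Et / (2 (1 + nu_t))``
    closes the in-plane isotropy.  Raises :class:`MaterialGridError` if the
    parameter set is not materially stable (stiffness not positive definite).
    """
    if min(Et, Eap, Gap) <= 0.0:
        raise MaterialGridError("all moduli must be strictly positive")
    Gt = Et / (2.0 * (1.0 + nu_t))
    S = np.zeros((6, 6))
    S[0, 0] = S[1, 1] = 1.0 / Et
    S[2, 2] = 1.0 / Eap
    S[0, 1] = S[1, 0] = -nu_t / Et
    S[0, 2] = S[2, 0] = S[1, 2] = S[2, 1] = -nu_ap / Eap
    S[3, 3] = S[4, 4] = 1.0 / Gap
    S[5, 5] = 1.0 / Gt
    C = np.linalg.inv(S)
    C = 0.5 * (C + C.T)
    if np.linalg.eigvalsh(C).min() <= 0.0:
        raise MaterialGridError(
            "stiffness matrix not positive definite; "
            "inconsistent auxiliary elastic parameters"
        )
    return C


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """Isotropic Lame stiffness matrix in the package Voigt convention."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2.0 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def build_layer_elasticity(
    Et: float,
    gap: float,
    aux: AuxiliaryElasticParams | None = None,
    layer: str = "cover",
) -> LayerElasticity:
    """Layer stiffness from the free parameters (Et, GAP); E_AP = 4*GAP applied."""
    aux = aux or AuxiliaryElasticParams()
    if Et <= 0.0 or gap <= 0.0:
        raise MaterialGridError("Et and gap must be strictly positive")
    C = transversely_isotropic_stiffness(
        Et, aux.eap_factor * gap, gap, aux.nu_t, aux.nu_ap
    )
    return LayerElasticity(C_voigt=C, layer=layer)


def voigt_to_full(C_voigt: np.ndarray) -> np.ndarray:
    """Expand a symmetric 6x6 Voigt stiffness to the full 3x3x3x3 tensor."""
    C_voigt = np.asarray(C_voigt, dtype=float)
    if C_voigt.shape != (6, 6) or not np.allclose(C_voigt, C_voigt.T):
        raise ValueError("C_voigt must be a symmetric 6x6 matrix")
    full = np.zeros((3, 3, 3, 3))
    for I, (i, j) in enumerate(VOIGT_ORDER):
        for J, (k, l) in enumerate(VOIGT_ORDER):
            v = C_voigt[I, J]
            full[i, j, k, l] = v
            full[j, i, k, l] = v
            full[i, j, l, k] = v
            full[j, i, l, k] = v
    return full


def full_to_voigt(C_full: np.ndarray) -> np.ndarray:
    """Contract a fully symmetric 3x3x3x3 stiffness back to 6x6 Voigt."""
    C_full = np.asarray(C_full, dtype=float)
    out = np.empty((6, 6))
    for I, (i, j) in enumerate(VOIGT_ORDER):
        for J, (k, l) in enumerate(VOIGT_ORDER):
            out[I, J] = C_full[i, j, k, l]
    return out


def strain_to_voigt(eps: np.ndarray) -> np.ndarray:
    """Symmetric 3x3 strain -> engineering Voigt 6-vector (batched ok)."""
    eps = np.asarray(eps, dtype=float)
    idx = (..., [0, 1, 2, 1, 0, 0], [0, 1, 2, 2, 2, 1])
    v = eps[idx].copy()
    v[..., 3:] *= 2.0
    return v
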