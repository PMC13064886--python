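"""Composite loss of the eigenmode network and the Rayleigh-quotient estimate.

The total loss is the unweighted (by default) sum of

* physics terms — the Navier--Cauchy residual at interior collocation
  points, zero displacement on the fixed faces (Dirichlet), zero traction on
  the free faces (Neumann), and displacement/traction continuity at the
  body--cover interface; and
* data terms — the normalized squared discrepancy between the
  Rayleigh-quotient eigenvalue of the predicted field and the reference
  eigenvalue, and ``1 - cos`` between predicted and reference mode shapes.

All functions accept either :class:`vfpinn.autodiff.Tensor` inputs (during
training, gradients flow through every term including the Rayleigh quotient)
or plain ndarrays (oracle checks, stub fields).

Nondimensionalization: displacements are nondimensional (mode shapes carry
no physical scale), so residual and traction terms are scaled to be
comparable with the O(1) displacement terms — tractions by a reference
stress over the coordinate-normalization length (``traction_scale``), the
residual by a reference inertial force density (``scale``, typically
``rho * lambda_true``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import value

__all__ = [
    "LossBreakdown",
    "RayleighEstimate",
    "DegenerateFieldError",
    "strain_voigt",
    "traction",
    "rayleigh_quotient",
    "pde_residual_loss",
    "dirichlet_loss",
    "neumann_loss",
    "interface_loss",
    "eigenvalue_loss",
    "cosine_loss",
    "total_loss",
]


class DegenerateFieldError(ValueError):
    """Raised when a loss is evaluated on an identically zero field."""


#: (6, 3, 3) map between Voigt slots and tensor index pairs.  Contracting a
#: displacement Jacobian with it yields the engineering-strain Voigt vector
#: (shear slots sum both off-diagonal entries); expanding a stress Voigt
#: vector with it yields the full symmetric stress tensor.
VOIGT_MAP = np.zeros((6, 3, 3))
for _k, (_i, _j) in enumerate(((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))):
    VOIGT_MAP[_k, _i, _j] = 1.0
    VOIGT_MAP[_k, _j, _i] = 1.0
for _k in range(3):
    VOIGT_MAP[_k, _k, _k] = 1.0  # diagonal slots must not double


LOSS_TERMS = ("pde", "dirichlet", "neumann", "interface", "eigenvalue", "cosine")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-term loss values (floats) of one training step."""

    pde: float
    dirichlet: float
    neumann: float
    interface: float
    eigenvalue: float
    cosine: float
    total: float
    weights: dict

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in LOSS_TERMS}
        d["total"] = self.total
        return d


@dataclass
class RayleighEstimate:
    """Rayleigh-quotient eigenvalue estimate of a displacement field.

    lambda_rq = V / T in rad^2/s^2; V is the strain energy and T the kinetic
    energy density (before the omega^2 factor) of the unit-scale field.
    """

    lambda_rq: object  # Tensor or float
    strain_energy: object
    kinetic_density: object
    n_points: dict

    @property
    def value(self) -> float:
        return float(value(self.lambda_rq))


def strain_voigt(J):
    """Engineering-strain Voigt vector from a displacement Jacobian (B,3,3)."""
    return ad.einsum("kij,bij->bk", VOIGT_MAP, J)


def traction(J, C_voigt_pts, normals):
    """Traction sigma(u).n at each point; C_voigt_pts is (B, 6, 6)."""
    eps = strain_voigt(J)
    sig = ad.einsum("bkl,bl->bk", C_voigt_pts, eps)
    sig_full = ad.einsum("kij,bk->bij", VOIGT_MAP, sig)
    return ad.einsum("bij,bj->bi", sig_full, normals)


def rayleigh_quotient(u, J, C_voigt_pts, density, weights, layer_tags=None):
    """Rayleigh quotient over weighted interior collocation points.

    ``V = sum_b w_b eps_b^T C_b eps_b``, ``T = sum_b w_b rho |u_b|^2``,
    ``lambda_rq = V / T``; the per-point stiffness carries the layer
    dependence, the weights carry the volume-consistent layer quadrature.
    """
    eps = strain_voigt(J)
    sig = ad.einsum("bkl,bl->bk", C_voigt_pts, eps)
    V = ad.tsum(ad.mul(weights, ad.einsum("bk,bk->b", eps, sig)))
    T = ad.tsum(ad.mul(weights, ad.mul(density, ad.einsum("bc,bc->b", u, u))))
    if float(value(T)) <= 0.0:
        raise DegenerateFieldError("kinetic energy is zero: field vanishes on sample")
    counts = {}
    if layer_tags is not None:
        tags, cnt = np.unique(np.asarray(layer_tags), return_counts=True)
        counts = dict(zip(tags.tolist(), cnt.tolist()))
    return RayleighEstimate(
        lambda_rq=ad.div(V, T), strain_energy=V, kinetic_density=T, n_points=counts
    )


def pde_residual_loss(u, H, C_full_pts, density, lam, scale: float = 1.0):
    """Mean squared Navier--Cauchy residual at interior points.

    ``R_i = d_j sigma_ij + rho lambda u_i`` with the stress divergence taken
    from the field Hessian and the per-point full stiffness (B, 3, 3, 3, 3).
    ``scale`` divides the residual (use ``rho * lambda_ref`` to make the
    term dimensionless and O(1)).
    """
    div_sig = ad.einsum("bijkl,bkjl->bi", C_full_pts, H)
    R = ad.add(div_sig, ad.mul(ad.mul(lam, density), u))
    return ad.tmean(ad.power(ad.mul(R, 1.0 / scale), 2))


def dirichlet_loss(u_fixed):
    """Mean squared displacement magnitude on fixed-face points."""
    return ad.tmean(ad.tsum(ad.power(u_fixed, 2), axis=1))


def neumann_loss(J_free, C_voigt_pts, normals, traction_scale: float = 1.0):
    """Mean squared (nondimensionalized) traction on free-face points."""
    t = traction(J_free, C_voigt_pts, normals)
    return ad.tmean(ad.tsum(ad.power(ad.mul(t, 1.0 / traction_scale), 2), axis=1))


def interface_loss(
    u_cover,
    u_body,
    J_cover,
    J_body,
    C_cover_pts,
    C_body_pts,
    normal,
    traction_scale: float = 1.0,
):
    """Displacement and traction jump across the body--cover plane.

    The shared normal points from cover into body; each side's traction uses
    its own stiffness.  For a single continuous network the displacement
    jump is identically zero (same field both sides) and is still computed
    so the invariant can be asserted.
    """
    B = value(u_cover).shape[0]
    normals = np.broadcast_to(np.asarray(normal, dtype=float), (B, 3))
    jump_u = ad.tmean(ad.tsum(ad.power(ad.add(u_body, ad.mul(u_cover, -1.0)), 2), axis=1))
    t_b = traction(J_body, C_body_pts, normals)
    t_c = traction(J_cover, C_cover_pts, normals)
    jump_t = ad.tmean(
        ad.tsum(
            ad.power(ad.mul(ad.add(t_b, ad.mul(t_c, -1.0)), 1.0 / traction_scale), 2),
            axis=1,
        )
    )
    return ad.add(jump_u, jump_t)


def eigenvalue_loss(lam_rq, lam_true: float):
    """Normalized squared eigenvalue discrepancy ((l_rq - l_true)/l_true)^2."""
    if lam_true <= 0.0:
        raise ValueError("lam_true must be strictly positive")
    return ad.power(ad.mul(ad.add(lam_rq, -lam_true), 1.0 / lam_true), 2)


def cosine_loss(u_pred, u_true):
    """1 - cosine correlation between stacked displacement vectors.

    Signed (no absolute value) as in the training objective; evaluation
    metrics use |cos| separately.  In [0, 2].
    """
    up = ad.reshape(u_pred, (-1,))
    ut = np.asarray(value(u_true), dtype=float).ravel()
    nt = np.linalg.norm(ut)
    dot = ad.tsum(ad.mul(up, ut))
    norm_p = ad.power(ad.tsum(ad.power(up, 2)), 0.5)
    if nt == 0.0 or float(value(norm_p)) == 0.0:
        raise DegenerateFieldError("zero-norm field in cosine loss")
    return ad.add(1.0, ad.mul(ad.div(dot, ad.mul(norm_p, nt)), -1.0))


def total_loss(terms: dict, weights: dict | None = None):
    """Weighted sum of the loss terms.

    ``terms`` maps term names (subset of pde/dirichlet/neumann/interface/
    eigenvalue/cosine) to Tensor or float values; missing terms count as 0.
    Default weights are all 1 (the plain unweighted sum).  Returns
    ``(total, LossBreakdown)`` where ``total`` keeps the autodiff graph.
    """
    weights = dict(weights or {})
    full_w = {k: float(weights.get(k, 1.0)) for k in LOSS_TERMS}
    if any(w < 0 for w in full_w.values()):
        raise ValueError("loss weights must be non-negative")
    total = 0.0
    vals = {}
    for k in LOSS_TERMS:
        term = terms.get(k, 0.0)
        vals[k] = float(value(term))
        total = ad.add(total, ad.mul(term, full_w[k]))
    breakdown = LossBreakdown(
        **vals, total=float(value(total)), weights=full_w
    )
    return total, breakdown
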