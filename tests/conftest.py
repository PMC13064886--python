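"""Shared fixtures: FEM reference solves and stub displacement fields.

The expensive FEM artifacts (reference solve on a fine mesh, the coarse
9-configuration dataset, the full material-grid dataset) are session-scoped
so the whole suite pays for each of them once.
"""

import numpy as np
import pytest

from vfpinn.fem import (
    MaterialGrid,
    assemble_km,
    build_mesh,
    fixed_dof_indices,
    generate_dataset,
    match_modes,
    solve_modes,
)
from vfpinn.geometry import RESCALED_PROFILE
from vfpinn.materials import MaterialConfig


@pytest.fixture(scope="session")
def geom():
    return RESCALED_PROFILE


@pytest.fixture(scope="session")
def t3_material():
    """The tabulated reference configuration: Et=2, GAP_body=20, GAP_cover=10 kPa."""
    return MaterialConfig(Et=2e3, gap_body=20e3, gap_cover=10e3)


@pytest.fixture(scope="session")
def medium_reference(geom, t3_material):
    """Two lowest eigenpairs of the reference configuration on a 16x12x16 mesh."""
    mesh = build_mesh(geom, (16, 12, 16))
    K, M = assemble_km(
        mesh,
        t3_material.layer_elasticity("body").C_voigt,
        t3_material.layer_elasticity("cover").C_voigt,
        t3_material.density,
    )
    lams, modes = solve_modes(K, M, fixed_dof_indices(mesh), 2)
    return {"mesh": mesh, "config": t3_material, "lams": lams, "modes": modes,
            "K": K, "M": M}


@pytest.fixture(scope="session")
def medium_dataset(medium_reference, t3_material):
    """Single-configuration ModalDataset on the 16x12x16 reference mesh."""
    from vfpinn.fem import ModalDataset

    lams = medium_reference["lams"]
    return ModalDataset(
        mesh=medium_reference["mesh"],
        configs=[t3_material],
        frequencies_hz=(np.sqrt(lams) / (2 * np.pi))[None, :],
        modes=medium_reference["modes"][None, :, :],
        split=np.array(["validation"]),
        grid={"et": (t3_material.Et,), "gap_body": (t3_material.gap_body,),
              "gap_cover": (t3_material.gap_cover,)},
        seed=0,
    )


@pytest.fixture(scope="session")
def coarse_dataset(geom):
    """Nine-configuration (1x3x3 subgrid) dataset on a 6x4x6 mesh, mode-matched."""
    grid = MaterialGrid(
        et=(2e3,), gap_body=(10e3, 20e3, 30e3), gap_cover=(10e3, 20e3, 30e3)
    )
    ds = generate_dataset(grid, geom, (6, 4, 6), n_modes=3, split_seed=7)
    ds, _ = match_modes(ds, anchor_idx=0)
    return ds


@pytest.fixture(scope="session")
def full_grid_dataset(geom):
    """The full 3x5x5 material grid (75 configurations), 10 modes, coarse mesh."""
    from vfpinn.fem import REFERENCE_GRID

    ds = generate_dataset(REFERENCE_GRID, geom, (8, 6, 8), n_modes=10, split_seed=11)
    ds, _ = match_modes(ds, anchor_idx=0)
    return ds


class PolynomialField:
    """Stub field evaluator u(x) = a + B x + quadratic terms (exact derivatives).

    ``u_c(x) = a_c + sum_j B_cj x_j + sum_jk Q_cjk x_j x_k`` with symmetric Q.
    """

    def __init__(self, a=None, B=None, Q=None):
        self.a = np.zeros(3) if a is None else np.asarray(a, dtype=float)
        self.B = np.zeros((3, 3)) if B is None else np.asarray(B, dtype=float)
        Q = np.zeros((3, 3, 3)) if Q is None else np.asarray(Q, dtype=float)
        self.Q = 0.5 * (Q + Q.transpose(0, 2, 1))

    def evaluate(self, pts):
        pts = np.atleast_2d(pts)
        u = (
            self.a
            + pts @ self.B.T
            + np.einsum("cjk,pj,pk->pc", self.Q, pts, pts)
        )
        J = self.B + 2.0 * np.einsum("cjk,pk->pcj", self.Q, pts)
        H = np.broadcast_to(2.0 * self.Q, (len(pts), 3, 3, 3)).copy()
        return u, J, H

    def displacement_and_jacobian(self, pts):
        u, J, _ = self.evaluate(pts)
        return u, J


@pytest.fixture
def polynomial_field_cls():
    return PolynomialField
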