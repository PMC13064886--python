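"""Finite-element modal analysis of the body--cover prism.

Structured 8-node (trilinear) hexahedral mesh with the body--cover interface
on a mesh plane, consistent mass, full 2x2x2 Gauss quadrature, and a sparse
shift-invert generalized eigensolve ``K u = lambda M u`` for the lowest
modes.  This module generates the reference eigenfrequencies and eigenmodes
(``lambda_true``, ``u_true``) that supervise the network, and the
cross-configuration mode statistics.

Because the mesh is axis-aligned and each layer has a single element shape,
only two distinct element (stiffness, mass) pairs exist per configuration;
assembly is a vectorised scatter of those two blocks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import FACE_NORMALS, GeometrySpec
from .materials import AuxiliaryElasticParams, MaterialConfig

__all__ = [
    "HexMesh",
    "ReferenceSolution",
    "ModalDataset",
    "MaterialGrid",
    "REFERENCE_GRID",
    "build_mesh",
    "brick_stiffness",
    "brick_mass",
    "assemble_km",
    "fixed_dof_indices",
    "solve_modes",
    "generate_dataset",
    "match_modes",
    "cross_config_cosine_stats",
]

# 2-point Gauss rule on [-1, 1]
_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
# local corner signs, standard hex ordering (counter-clockwise bottom, then top)
_CORNERS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


class MeshError(ValueError):
    pass


class EigenSolveError(RuntimeError):
    pass


@dataclass(frozen=True)
class HexMesh:
    """Structured hex mesh of the prism; interface at x = Dc is a mesh plane."""

    geom: GeometrySpec
    xs: np.ndarray  # depth-node coordinates, cover nodes first
    ys: np.ndarray
    zs: np.ndarray
    n_cover_elems_x: int
    nodes: np.ndarray  # (n_nodes, 3)
    elems: np.ndarray  # (n_elems, 8) node indices
    elem_layers: np.ndarray  # (n_elems,) 'body'/'cover'
    face_nodes: dict = field(repr=False)
    interface_nodes: np.ndarray = field(repr=False)

    @property
    def shape(self):
        return (len(self.xs) - 1, len(self.ys) - 1, len(self.zs) - 1)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes

    def node_index(self, ix, iy, iz):
        ny1, nz1 = len(self.ys), len(self.zs)
        return (ix * ny1 + iy) * nz1 + iz

    def grid_values(self, nodal: np.ndarray) -> np.ndarray:
        """Reshape per-node values (n_nodes, ...) to (nx+1, ny+1, nz+1, ...)."""
        return nodal.reshape(len(self.xs), len(self.ys), len(self.zs), -1)


def build_mesh(geom: GeometrySpec, resolution) -> HexMesh:
    """Structured mesh with ``resolution = (nx, ny, nz)`` elements per axis.

    The depth count nx is split between the layers proportionally to their
    depths (at least 1 cover and 2 body element columns), so the interface
    plane x = Dc coincides with a mesh plane and no element straddles layers.
    """
    nx, ny, nz = (int(v) for v in resolution)
    ncx = max(1, int(round(nx * geom.cover_depth / geom.depth)))
    nbx = nx - ncx
    if ncx < 1 or nbx < 2:
        raise MeshError(
            f"resolution {resolution} too coarse to separate layers "
            f"(need >=1 cover and >=2 body element columns, got {ncx}/{nbx})"
        )
    xs = np.concatenate(
        [
            np.linspace(0.0, geom.cover_depth, ncx + 1),
            np.linspace(geom.cover_depth, geom.depth, nbx + 1)[1:],
        ]
    )
    ys = np.linspace(0.0, geom.thickness, ny + 1)
    zs = np.linspace(0.0, geom.length, nz + 1)

    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    ny1, nz1 = ny + 1, nz + 1

    def nid(ix, iy, iz):
        return (ix * ny1 + iy) * nz1 + iz

    elems, layers = [], []
    for ex in range(nx):
        tag = "cover" if ex < ncx else "body"
        for ey in range(ny):
            for ez in range(nz):
                n000 = nid(ex, ey, ez)
                n100 = nid(ex + 1, ey, ez)
                n010 = nid(ex, ey + 1, ez)
                n110 = nid(ex + 1, ey + 1, ez)
                elems.append(
                    [
                        n000,
                        n100,
                        n110,
                        n010,
                        n000 + 1,
                        n100 + 1,
                        n110 + 1,
                        n010 + 1,
                    ]
                )
                layers.append(tag)

    ix_all = np.arange(nx + 1)
    iy_all = np.arange(ny + 1)
    iz_all = np.arange(nz + 1)

    def plane(ix=None, iy=None, iz=None):
        axes = [
            [ix] if ix is not None else ix_all,
            [iy] if iy is not None else iy_all,
            [iz] if iz is not None else iz_all,
        ]
        out = [
            nid(a, b, c)
            for a in axes[0]
            for b in axes[1]
            for c in axes[2]
        ]
        return np.array(sorted(out))

    face_nodes = {
        "medial": plane(ix=0),
        "lateral": plane(ix=nx),
        "inferior": plane(iy=0),
        "superior": plane(iy=ny),
        "anterior": plane(iz=0),
        "posterior": plane(iz=nz),
    }
    interface_nodes = plane(ix=ncx)

    return HexMesh(
        geom=geom,
        xs=xs,
        ys=ys,
        zs=zs,
        n_cover_elems_x=ncx,
        nodes=nodes,
        elems=np.array(elems, dtype=np.int64),
        elem_layers=np.array(layers),
        face_nodes=face_nodes,
        interface_nodes=interface_nodes,
    )


def _shape_gradients(hx, hy, hz):
    """dN/dx (8 Gauss pts, 8 nodes, 3) and shape values (8, 8) on a brick."""
    scale = np.array([2.0 / hx, 2.0 / hy, 2.0 / hz])
    grads = np.empty((8, 8, 3))
    vals = np.empty((8, 8))
    g = 0
    for gx, gy, gz in itertools.product(_GP, _GP, _GP):
        xi = np.array([gx, gy, gz])
        for a in range(8):
            s = _CORNERS[a]
            f = 0.125 * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2])
            vals[g, a] = f
            grads[g, a, 0] = 0.125 * s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) * scale[0]
            grads[g, a, 1] = 0.125 * (1 + s[0] * xi[0]) * s[1] * (1 + s[2] * xi[2]) * scale[1]
            grads[g, a, 2] = 0.125 * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * s[2] * scale[2]
        g += 1
    detJ = hx * hy * hz / 8.0
    return vals, grads, detJ


def brick_stiffness(hx, hy, hz, C_voigt) -> np.ndarray:
    """24x24 element stiffness of an axis-aligned brick, full Gauss quadrature."""
    _, grads, detJ = _shape_gradients(hx, hy, hz)
    K = np.zeros((24, 24))
    for g in range(8):
        B = np.zeros((6, 24))
        d = grads[g]  # (8, 3)
        for a in range(8):
            c = 3 * a
            B[0, c + 0] = d[a, 0]
            B[1, c + 1] = d[a, 1]
            B[2, c + 2] = d[a, 2]
            B[3, c + 1] = d[a, 2]
            B[3, c + 2] = d[a, 1]
            B[4, c + 0] = d[a, 2]
            B[4, c + 2] = d[a, 0]
            B[5, c + 0] = d[a, 1]
            B[5, c + 1] = d[a, 0]
        K += detJ * (B.T @ C_voigt @ B)
    return 0.5 * (K + K.T)


def brick_mass(hx, hy, hz, density) -> np.ndarray:
    """24x24 consistent element mass of an axis-aligned brick."""
    vals, _, detJ = _shape_gradients(hx, hy, hz)
    Mn = density * detJ * (vals.T @ vals)  # (8, 8)
    M = np.zeros((24, 24))
    for i in range(3):
        M[i::3, i::3] = Mn
    return M


def assemble_km(mesh: HexMesh, C_body, C_cover, density):
    """Global sparse symmetric stiffness and consistent mass matrices."""
    hy = mesh.ys[1] - mesh.ys[0]
    hz = mesh.zs[1] - mesh.zs[0]
    hx_cover = mesh.xs[1] - mesh.xs[0]
    hx_body = mesh.xs[-1] - mesh.xs[-2]

    blocks = {
        "cover": (
            brick_stiffness(hx_cover, hy, hz, C_cover),
            brick_mass(hx_cover, hy, hz, density),
        ),
        "body": (
            brick_stiffness(hx_body, hy, hz, C_body),
            brick_mass(hx_body, hy, hz, density),
        ),
    }

    ndof = mesh.n_dofs
    rows_all, cols_all, kv_all, mv_all = [], [], [], []
    for layer, (Ke, Me) in blocks.items():
        sel = mesh.elem_layers == layer
        conn = mesh.elems[sel]  # (ne, 8)
        edofs = (3 * conn[:, :, None] + np.arange(3)).reshape(len(conn), 24)
        rows = np.repeat(edofs, 24, axis=1).ravel()
        cols = np.tile(edofs, (1, 24)).ravel()
        rows_all.append(rows)
        cols_all.append(cols)
        kv_all.append(np.tile(Ke.ravel(), len(conn)))
        mv_all.append(np.tile(Me.ravel(), len(conn)))

    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    K = sp.coo_matrix((np.concatenate(kv_all), (rows, cols)), shape=(ndof, ndof)).tocsr()
    M = sp.coo_matrix((np.concatenate(mv_all), (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K, M


def fixed_dof_indices(mesh: HexMesh, faces=("lateral", "anterior", "posterior")):
    """All 3 displacement DOFs of every node on the given faces."""
    nodes = np.unique(np.concatenate([mesh.face_nodes[f] for f in faces]))
    return (3 * nodes[:, None] + np.arange(3)).ravel()


def solve_modes(K, M, fixed_dofs, n_modes):
    """Lowest generalized eigenpairs of the Dirichlet-constrained system.

    Constraints are imposed by row/column elimination.  Returns
    ``(lambdas, modes)`` with lambdas ascending (rad^2/s^2) and modes as
    full-length unit-norm vectors (zeros on fixed DOFs), sign-fixed so the
    largest-magnitude component is positive.
    """
    ndof = K.shape[0]
    free = np.setdiff1d(np.arange(ndof), np.asarray(fixed_dofs, dtype=np.int64))
    if not 1 <= n_modes <= len(free):
        raise ValueError("n_modes must be in [1, number of free DOFs]")
    Kff = K[free][:, free].tocsc()
    Mff = M[free][:, free].tocsc()
    try:
        lams, vecs = spla.eigsh(Kff, k=n_modes, M=Mff, sigma=0.0, which="LM")
    except Exception as exc:  # pragma: no cover - solver failure path
        raise EigenSolveError(f"shift-invert eigensolve failed: {exc}") from exc
    order = np.argsort(lams)
    lams = lams[order]
    vecs = vecs[:, order]
    modes = np.zeros((n_modes, ndof))
    for k in range(n_modes):
        v = np.zeros(ndof)
        v[free] = vecs[:, k]
        v /= np.linalg.norm(v)
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        modes[k] = v
    if np.any(lams <= 0):
        raise EigenSolveError("non-positive eigenvalue; check constraints")
    return lams, modes


@dataclass(frozen=True)
class ReferenceSolution:
    """One reference eigenpair of one material configuration."""

    config: MaterialConfig
    mode_index: int  # 1-based
    frequency_hz: float
    lambda_true: float  # (2 pi f)^2, rad^2/s^2
    nodal_displacements: np.ndarray  # (n_dofs,) unit norm

    def __post_init__(self):
        assert self.frequency_hz > 0


@dataclass
class ModalDataset:
    """Reference modes for a set of configurations on one shared mesh."""

    mesh: HexMesh
    configs: list  # list[MaterialConfig]
    frequencies_hz: np.ndarray  # (n_cfg, n_modes)
    modes: np.ndarray  # (n_cfg, n_modes, n_dofs)
    split: np.ndarray  # (n_cfg,) 'train'/'validation'
    grid: dict
    seed: int
    matched_to: int | None = None

    @property
    def n_configs(self) -> int:
        return len(self.configs)

    @property
    def n_modes(self) -> int:
        return self.frequencies_hz.shape[1]

    def lambdas(self) -> np.ndarray:
        return (2.0 * np.pi * self.frequencies_hz) ** 2

    def split_indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == split)

    def solution(self, cfg_idx: int, mode_index: int) -> ReferenceSolution:
        f = float(self.frequencies_hz[cfg_idx, mode_index - 1])
        return ReferenceSolution(
            config=self.configs[cfg_idx],
            mode_index=mode_index,
            frequency_hz=f,
            lambda_true=(2.0 * np.pi * f) ** 2,
            nodal_displacements=self.modes[cfg_idx, mode_index - 1],
        )

    def save_npz(self, path) -> None:
        g = self.mesh.geom
        np.savez_compressed(
            path,
            geom=np.array([g.thickness, g.body_depth, g.cover_depth, g.length]),
            resolution=np.array(self.mesh.shape),
            config_params=np.array([c.as_vector() for c in self.configs]),
            density=np.array([c.density for c in self.configs]),
            aux=np.array(
                [
                    [c.aux.nu_t, c.aux.nu_ap, c.aux.eap_factor]
                    for c in self.configs
                ]
            ),
            frequencies_hz=self.frequencies_hz,
            modes=self.modes,
            split=self.split,
            seed=np.array(self.seed),
            matched_to=np.array(-1 if self.matched_to is None else self.matched_to),
            et_values=np.asarray(self.grid["et"]),
            gap_body_values=np.asarray(self.grid["gap_body"]),
            gap_cover_values=np.asarray(self.grid["gap_cover"]),
        )

    @staticmethod
    def load_npz(path) -> "ModalDataset":
        d = np.load(path, allow_pickle=False)
        t, db, dc, ln = d["geom"]
        geom = GeometrySpec(t, db, dc, ln)
        mesh = build_mesh(geom, tuple(int(v) for v in d["resolution"]))
        configs = [
            MaterialConfig(
                Et=p[0],
                gap_body=p[1],
                gap_cover=p[2],
                density=float(rho),
                aux=AuxiliaryElasticParams(nu_t=a[0], nu_ap=a[1], eap_factor=a[2]),
            )
            for p, rho, a in zip(d["config_params"], d["density"], d["aux"])
        ]
        matched = int(d["matched_to"])
        return ModalDataset(
            mesh=mesh,
            configs=configs,
            frequencies_hz=d["frequencies_hz"],
            modes=d["modes"],
            split=d["split"],
            grid={
                "et": d["et_values"],
                "gap_body": d["gap_body_values"],
                "gap_cover": d["gap_cover_values"],
            },
            seed=int(d["seed"]),
            matched_to=None if matched < 0 else matched,
        )


@dataclass(frozen=True)
class MaterialGrid:
    """Cartesian grid of free material parameters (Pa)."""

    et: tuple
    gap_body: tuple
    gap_cover: tuple

    def configs(self, density=1030.0, aux=None):
        aux = aux or AuxiliaryElasticParams()
        return [
            MaterialConfig(Et=e, gap_body=gb, gap_cover=gc, density=density, aux=aux)
            for e, gb, gc in itertools.product(self.et, self.gap_body, self.gap_cover)
        ]

    @property
    def size(self) -> int:
        return len(self.et) * len(self.gap_body) * len(self.gap_cover)


#: The reference material grid: Et in {1, 2, 4} kPa, GAP in {1, 10, 20, 30, 40} kPa per layer.
REFERENCE_GRID = MaterialGrid(
    et=(1e3, 2e3, 4e3),
    gap_body=(1e3, 10e3, 20e3, 30e3, 40e3),
    gap_cover=(1e3, 10e3, 20e3, 30e3, 40e3),
)


def generate_dataset(
    grid: MaterialGrid,
    geom: GeometrySpec,
    resolution,
    n_modes: int = 10,
    split_seed: int = 0,
    density: float = 1030.0,
    aux: AuxiliaryElasticParams | None = None,
    train_fraction: float = 0.8,
) -> ModalDataset:
    """One FEM modal solve per grid configuration, split by configuration.

    The split is a seeded shuffle of configurations at ``train_fraction``
    (80/20 by default); modes are returned in ascending frequency order per
    configuration (run :func:`match_modes` to align mode identities).
    """
    configs = grid.configs(density=density, aux=aux)
    if not configs:
        raise ValueError("empty material grid")
    mesh = build_mesh(geom, resolution)
    fixed = fixed_dof_indices(mesh)
    freqs = np.empty((len(configs), n_modes))
    modes = np.empty((len(configs), n_modes, mesh.n_dofs))
    for i, cfg in enumerate(configs):
        try:
            K, M = assemble_km(
                mesh,
                cfg.layer_elasticity("body").C_voigt,
                cfg.layer_elasticity("cover").C_voigt,
                cfg.density,
            )
            lams, vecs = solve_modes(K, M, fixed, n_modes)
        except Exception as exc:
            raise EigenSolveError(
                f"modal solve failed for configuration {i} "
                f"(Et={cfg.Et}, gap_body={cfg.gap_body}, gap_cover={cfg.gap_cover}): {exc}"
            ) from exc
        freqs[i] = np.sqrt(lams) / (2.0 * np.pi)
        modes[i] = vecs

    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(configs))
    n_train = max(1, int(round(train_fraction * len(configs))))
    split = np.array(["validation"] * len(configs), dtype=object)
    split[order[:n_train]] = "train"
    split = split.astype(str)

    return ModalDataset(
        mesh=mesh,
        configs=configs,
        frequencies_hz=freqs,
        modes=modes,
        split=split,
        grid={"et": grid.et, "gap_body": grid.gap_body, "gap_cover": grid.gap_cover},
        seed=split_seed,
    )


def modal_frequencies(config: MaterialConfig, geom: GeometrySpec, resolution,
                      n_modes: int = 2):
    """Eigenfrequencies (Hz) of one configuration at one resolution."""
    mesh = build_mesh(geom, resolution)
    K, M = assemble_km(
        mesh,
        config.layer_elasticity("body").C_voigt,
        config.layer_elasticity("cover").C_voigt,
        config.density,
    )
    lams, _ = solve_modes(K, M, fixed_dof_indices(mesh), n_modes)
    return np.sqrt(lams) / (2.0 * np.pi)


def converged_frequencies(config: MaterialConfig, geom: GeometrySpec,
                          resolutions, n_modes: int = 2):
    """Mesh-converged eigenfrequencies via an h^2 Richardson fit.

    Solves at each resolution of the ladder (coarse to fine) and fits
    ``f(h) = f0 + c h^2`` with ``h ~ 1/nx`` by least squares; trilinear
    elements converge at second order, so ``f0`` is the mesh-limit
    estimate.  Returns ``(f0, ladder)`` with ``ladder`` of shape
    ``(n_resolutions, n_modes)``; the ladder should be monotone (or move
    < 0.5% per step) if the meshes are in the asymptotic range.
    """
    ladder = np.array(
        [modal_frequencies(config, geom, r, n_modes) for r in resolutions]
    )
    h2 = np.array([1.0 / r[0] ** 2 for r in resolutions])
    A = np.column_stack([np.ones_like(h2), h2])
    coef, *_ = np.linalg.lstsq(A, ladder, rcond=None)
    return coef[0], ladder


def mac(u: np.ndarray, v: np.ndarray) -> float:
    """Modal assurance criterion (u.v)^2 / (|u|^2 |v|^2), in [0, 1]."""
    return float((u @ v) ** 2 / ((u @ u) * (v @ v)))


def match_modes(dataset: ModalDataset, anchor_idx: int = 0):
    """Align mode identities across configurations against an anchor.

    Eigenvalue ordering can swap between configurations as material
    parameters vary; modes of every configuration are permuted to maximise
    the MAC against the anchor configuration's modes, greedily in anchor-mode
    order (mode 1 has highest priority), ties broken by ascending frequency.
    Returns ``(matched_dataset, mac_tables)`` where ``mac_tables`` is the
    (n_cfg, n_modes, n_modes) array of MAC values used for the assignment.
    """
    K = dataset.n_modes
    anchor = dataset.modes[anchor_idx]
    tables = np.empty((dataset.n_configs, K, K))
    new_modes = np.empty_like(dataset.modes)
    new_freqs = np.empty_like(dataset.frequencies_hz)
    for c in range(dataset.n_configs):
        U = dataset.modes[c]
        G = (anchor @ U.T) ** 2  # unit-norm modes: MAC directly
        tables[c] = G
        taken = np.zeros(K, dtype=bool)
        for k in range(K):
            row = np.where(taken, -np.inf, G[k])
            # argmax returns the lowest index on ties = ascending frequency
            j = int(np.argmax(row))
            taken[j] = True
            new_modes[c, k] = U[j]
            new_freqs[c, k] = dataset.frequencies_hz[c, j]
    out = ModalDataset(
        mesh=dataset.mesh,
        configs=dataset.configs,
        frequencies_hz=new_freqs,
        modes=new_modes,
        split=dataset.split,
        grid=dataset.grid,
        seed=dataset.seed,
        matched_to=anchor_idx,
    )
    return out, tables


def cross_config_cosine_stats(
    dataset: ModalDataset,
    mode_index: int,
    dof_subset: np.ndarray | None = None,
    split: str = "train",
):
    """Median/mean |cosine| of one reference mode across configuration pairs.

    Absolute cosine correlation (sign-invariant) over all unordered pairs of
    configurations in the given split, optionally restricted to a DOF subset
    (e.g. surface DOFs).  Quantifies how structurally stable the mode shape
    is under material variation.
    """
    idx = dataset.split_indices(split)
    if len(idx) < 2:
        raise ValueError("need at least two configurations in the split")
    U = dataset.modes[idx, mode_index - 1]
    if dof_subset is not None:
        if len(dof_subset) == 0:
            raise ValueError("empty DOF subset")
        U = U[:, dof_subset]
    norms = np.linalg.norm(U, axis=1)
    G = np.abs(U @ U.T) / np.outer(norms, norms)
    iu = np.triu_indices(len(idx), k=1)
    vals = G[iu]
    return {"median": float(np.median(vals)), "mean": float(np.mean(vals))}


def surface_dof_indices(mesh: HexMesh, faces=("medial", "superior", "inferior")):
    """DOFs of all nodes on the given (by default free) faces."""
    nodes = np.unique(np.concatenate([mesh.face_nodes[f] for f in faces]))
    return (3 * nodes[:, None] + np.arange(3)).ravel()


def export_vtk(mesh: HexMesh, path, point_data: dict | None = None) -> None:
    """Write the mesh (+ per-node vector fields) as legacy ASCII VTK."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvfpinn mode shape\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        ne = len(mesh.elems)
        fh.write(f"CELLS {ne} {9 * ne}\n")
        for e in mesh.elems:
            fh.write("8 " + " ".join(str(int(n)) for n in e) + "\n")
        fh.write(f"CELL_TYPES {ne}\n")
        fh.write("\n".join(["12"] * ne) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                vec = np.asarray(arr).reshape(mesh.n_nodes, 3)
                fh.write(f"VECTORS {name} double\n")
                for v in vec:
                    fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
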