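"""Per-mode training loop, evaluation metrics, and report tables.

One network is trained per vibration mode (independent training avoids mode
mixing); the objective is the composite loss summed over the training
configurations, with the Rayleigh-quotient eigenvalue of the predicted field
coupled into the residual term (gradients flow through it unless detached).

Evaluation reports, per configuration: the predicted
eigenfrequency ``f_pred = sqrt(lambda_RQ) / 2 pi`` from a fresh dense
collocation draw, relative frequency error in percent, and the absolute
cosine correlation between predicted and reference mode shapes on the
free-surface nodes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import losses as lo
from .autodiff import Adam, value
from .fem import MaterialGrid, ModalDataset, cross_config_cosine_stats
from .geometry import FIXED_FACES, FREE_FACES, sample_collocation
from .interpolate import SplineModeField
from .materials import voigt_to_full
from .network import DisplacementNet, NetworkSpec, Normalization

__all__ = ["TrainConfig", "TrainingError", "train_mode", "evaluate", "report_tables"]


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Training hyperparameters; every randomized component is seeded."""

    mode_index: int = 1
    epochs: int = 3000
    lr: float = 1e-4
    lr_schedule: str = "cosine"  # or "constant"
    n_interior: int = 512
    n_per_face: int = 64
    n_interface: int = 64
    resample_each_epoch: bool = False
    init_seed: int = 0
    sample_seed: int = 0
    loss_weights: dict = field(default_factory=dict)
    detach_lambda: bool = False
    interp_order: int = 1  # supervision-mode interpolation (1 = trilinear)
    cosine_volumetric: bool = False
    network: NetworkSpec = field(default_factory=NetworkSpec)

    def __post_init__(self):
        if self.epochs < 1 or self.mode_index < 1:
            raise ValueError("epochs and mode_index must be >= 1")

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return {
            "config": d,
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seeds": {"init": self.init_seed, "sampling": self.sample_seed},
        }


def _material_grid(dataset: ModalDataset) -> MaterialGrid:
    g = dataset.grid
    return MaterialGrid(
        et=tuple(np.atleast_1d(g["et"]).tolist()),
        gap_body=tuple(np.atleast_1d(g["gap_body"]).tolist()),
        gap_cover=tuple(np.atleast_1d(g["gap_cover"]).tolist()),
    )


def _lr_at(cfg: TrainConfig, epoch: int) -> float:
    if cfg.lr_schedule == "constant":
        return cfg.lr
    # cosine decay to a 10% floor
    frac = epoch / max(1, cfg.epochs - 1)
    return cfg.lr * (0.1 + 0.9 * 0.5 * (1.0 + np.cos(np.pi * frac)))


@dataclass
class _ConfigBundle:
    """Per-configuration constants precomputed before the epoch loop."""

    m_norm: np.ndarray
    lam_true: float
    C6_int: np.ndarray
    Cfull_int: np.ndarray
    C6_free: np.ndarray
    C6_iface_cover: np.ndarray
    C6_iface_body: np.ndarray
    u_true_cos: np.ndarray
    traction_scale: float


def _bundle(dataset, colloc, cfg_idx, mode_index, norm, fld, cosine_volumetric):
    """Per-configuration constants for one collocation draw.

    ``fld`` is the (point-independent) reference-mode interpolant, built
    once per configuration and reused across resampled draws.
    """
    cfg = dataset.configs[cfg_idx]
    Cb = cfg.layer_elasticity("body").C_voigt
    Cc = cfg.layer_elasticity("cover").C_voigt
    geom = colloc.geom
    is_cover = colloc.interior_layers == "cover"
    C6_int = np.where(is_cover[:, None, None], Cc, Cb)
    Cfull_int = np.where(
        is_cover[:, None, None, None, None], voigt_to_full(Cc), voigt_to_full(Cb)
    )
    free = colloc.surface_mask(FREE_FACES)
    pf = colloc.surface_points[free]
    C6_free = np.where((pf[:, 0] <= geom.cover_depth)[:, None, None], Cc, Cb)
    n_if = len(colloc.interface_points)
    sol = dataset.solution(cfg_idx, mode_index)
    cos_pts = (
        np.vstack([colloc.interior_points, pf]) if cosine_volumetric else pf
    )
    u_true = fld.evaluate(cos_pts)[0]
    L_char = max(geom.depth, geom.thickness, geom.length) / 2.0
    return _ConfigBundle(
        m_norm=norm.normalize_m(cfg.as_vector()),
        lam_true=sol.lambda_true,
        C6_int=C6_int,
        Cfull_int=Cfull_int,
        C6_free=C6_free,
        C6_iface_cover=np.broadcast_to(Cc, (n_if, 6, 6)).copy(),
        C6_iface_body=np.broadcast_to(Cb, (n_if, 6, 6)).copy(),
        u_true_cos=u_true,
        traction_scale=cfg.Et / L_char,
    )


def _config_loss(net, colloc, b: _ConfigBundle, cfg, weights, detach_lambda,
                 cosine_volumetric):
    """Total loss of one configuration (autodiff graph kept)."""
    free = colloc.surface_mask(FREE_FACES)
    fixed = colloc.surface_mask(FIXED_FACES)
    n_free = int(free.sum())

    # Hessians only where the residual needs them; values only on fixed faces
    u_int, J_int, H_int = net.evaluate(
        colloc.interior_points, b.m_norm, tape=True, order=2
    )
    srf = np.vstack([colloc.surface_points[free], colloc.interface_points])
    u_srf, J_srf, _ = net.evaluate(srf, b.m_norm, tape=True, order=1)
    u_free = ad.narrow(u_srf, 0, n_free)
    J_free = ad.narrow(J_srf, 0, n_free)
    u_if = ad.narrow(u_srf, n_free, len(srf))
    J_if = ad.narrow(J_srf, n_free, len(srf))
    u_fix, _, _ = net.evaluate(
        colloc.surface_points[fixed], b.m_norm, tape=True, order=0
    )

    rq = lo.rayleigh_quotient(
        u_int, J_int, b.C6_int, cfg.density, colloc.interior_weights
    )
    lam = rq.lambda_rq.detach() if detach_lambda else rq.lambda_rq
    terms = {
        "pde": lo.pde_residual_loss(
            u_int, H_int, b.Cfull_int, cfg.density, lam,
            scale=cfg.density * b.lam_true,
        ),
        "dirichlet": lo.dirichlet_loss(u_fix),
        "neumann": lo.neumann_loss(
            J_free, b.C6_free, colloc.surface_normals[free],
            traction_scale=b.traction_scale,
        ),
        "interface": lo.interface_loss(
            u_if, u_if, J_if, J_if, b.C6_iface_cover, b.C6_iface_body,
            colloc.interface_normal, traction_scale=b.traction_scale,
        ),
        "eigenvalue": lo.eigenvalue_loss(rq.lambda_rq, b.lam_true),
        "cosine": lo.cosine_loss(
            ad.concat([u_int, u_free], axis=0) if cosine_volumetric else u_free,
            b.u_true_cos,
        ),
    }
    return lo.total_loss(terms, weights)


def train_mode(dataset: ModalDataset, cfg: TrainConfig):
    """Train one network for ``cfg.mode_index`` on the dataset's train split.

    Returns ``(net, history)``; ``history`` is a list of per-epoch dicts
    (mean loss breakdown across training configurations plus the summed
    total actually minimized).  Raises :class:`TrainingError` on a
    non-finite loss, reporting the epoch reached.
    """
    if cfg.mode_index > dataset.n_modes:
        raise ValueError("dataset does not contain the requested mode")
    geom = dataset.mesh.geom
    norm = Normalization.from_geometry_and_grid(geom, _material_grid(dataset))
    spec = dataclasses.replace(cfg.network, seed=cfg.init_seed)
    net = DisplacementNet(spec, norm)
    opt = Adam(net.parameters(), lr=cfg.lr)

    train_idx = dataset.split_indices("train")
    colloc = sample_collocation(
        geom, cfg.n_interior, cfg.n_per_face, cfg.n_interface, cfg.sample_seed
    )
    flds = {
        i: SplineModeField(
            dataset.mesh,
            dataset.solution(i, cfg.mode_index).nodal_displacements,
            order=cfg.interp_order,
        )
        for i in train_idx
    }
    bundles = {
        i: _bundle(dataset, colloc, i, cfg.mode_index, norm,
                   flds[i], cfg.cosine_volumetric)
        for i in train_idx
    }

    history = []
    for epoch in range(cfg.epochs):
        if cfg.resample_each_epoch and epoch > 0:
            colloc = sample_collocation(
                geom, cfg.n_interior, cfg.n_per_face, cfg.n_interface,
                cfg.sample_seed + epoch,
            )
            bundles = {
                i: _bundle(dataset, colloc, i, cfg.mode_index, norm,
                           flds[i], cfg.cosine_volumetric)
                for i in train_idx
            }
        opt.zero_grad()
        total = 0.0
        sums = dict.fromkeys(lo.LOSS_TERMS, 0.0)
        for i in train_idx:
            t, bd = _config_loss(
                net, colloc, bundles[i], dataset.configs[i],
                cfg.loss_weights, cfg.detach_lambda, cfg.cosine_volumetric,
            )
            total = ad.add(total, t)
            for k in lo.LOSS_TERMS:
                sums[k] += getattr(bd, k)
        total_val = float(value(total))
        if not np.isfinite(total_val):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        total.backward()
        opt.step(lr=_lr_at(cfg, epoch))
        if not net.finite():
            raise TrainingError(f"non-finite weights after epoch {epoch}")
        row = {k: v / len(train_idx) for k, v in sums.items()}
        row.update(epoch=epoch, total=total_val)
        history.append(row)
    return net, history


class _NetField:
    """Binds a network to one configuration's normalized materials."""

    def __init__(self, net: DisplacementNet, m_norm: np.ndarray):
        self.net = net
        self.m_norm = m_norm

    def displacement_and_jacobian(self, pts):
        return self.net.displacement_and_jacobian(pts, self.m_norm)


def network_fields(net: DisplacementNet, dataset: ModalDataset):
    """field_for_config factory for :func:`evaluate` from a trained network."""
    norm = net.norm

    def factory(cfg_idx: int):
        return _NetField(net, norm.normalize_m(dataset.configs[cfg_idx].as_vector()))

    return factory


def evaluate(
    field_for_config,
    dataset: ModalDataset,
    mode_index: int,
    split: str = "validation",
    n_interior: int = 20000,
    seed: int = 0,
):
    """Frequency and mode-shape metrics of a predictor on one split.

    ``field_for_config(cfg_idx)`` must return an object with
    ``displacement_and_jacobian(points) -> (u, J)``; both trained networks
    (:func:`network_fields`) and reference-mode interpolants satisfy the
    protocol.  The eigenfrequency comes from the Rayleigh quotient on a
    fresh seeded stratified draw of ``n_interior`` points; the cosine metric
    is |cos| between predicted and reference displacements on the
    free-surface mesh nodes.

    Returns ``(records, summary)``: a DataFrame with one row per
    configuration and a dict with the split means.
    """
    idx = dataset.split_indices(split)
    if len(idx) == 0:
        raise ValueError(f"split {split!r} is empty")
    geom = dataset.mesh.geom
    colloc = sample_collocation(geom, n_interior, 8, 8, seed)
    is_cover = colloc.interior_layers == "cover"

    # free-surface nodes, excluding nodes on the Dirichlet boundary (their
    # reference displacement is identically zero and only biases the norm)
    mesh = dataset.mesh
    free_nodes = np.unique(
        np.concatenate([mesh.face_nodes[f] for f in FREE_FACES])
    )
    fixed_nodes = np.unique(
        np.concatenate([mesh.face_nodes[f] for f in FIXED_FACES])
    )
    surf_nodes = np.setdiff1d(free_nodes, fixed_nodes)
    surf_dofs = (3 * surf_nodes[:, None] + np.arange(3)).ravel()
    surf_pts = mesh.nodes[surf_nodes]

    rows = []
    for i in idx:
        cfg = dataset.configs[i]
        fld = field_for_config(i)
        Cb = cfg.layer_elasticity("body").C_voigt
        Cc = cfg.layer_elasticity("cover").C_voigt
        C6 = np.where(is_cover[:, None, None], Cc, Cb)
        u, J = fld.displacement_and_jacobian(colloc.interior_points)
        rq = lo.rayleigh_quotient(u, J, C6, cfg.density, colloc.interior_weights)
        f_pred = float(np.sqrt(rq.value) / (2.0 * np.pi))
        f_true = float(dataset.frequencies_hz[i, mode_index - 1])
        u_surf, _ = fld.displacement_and_jacobian(surf_pts)
        ref = dataset.modes[i, mode_index - 1][surf_dofs].reshape(-1, 3)
        num = abs(float(np.sum(u_surf * ref)))
        den = np.linalg.norm(u_surf) * np.linalg.norm(ref)
        cosine = num / den if den > 0 else 0.0
        rows.append(
            {
                "config": int(i),
                "mode": mode_index,
                "f_true_hz": f_true,
                "f_pred_hz": f_pred,
                "rel_error_pct": 100.0 * abs(f_pred - f_true) / f_true,
                "cosine": cosine,
            }
        )
    records = pd.DataFrame(rows)
    summary = {
        "mean_rel_error_pct": float(records["rel_error_pct"].mean()),
        "mean_cosine": float(records["cosine"].mean()),
    }
    return records, summary


def report_tables(dataset: ModalDataset, records_by_mode: dict):
    """Per-mode metric table and cross-configuration cosine statistics.

    ``records_by_mode`` maps mode index -> records DataFrame from
    :func:`evaluate`.  The first table reports, per mode, the first
    configuration's metrics plus split means; the second reports the
    median/mean |cosine| of the *reference* modes across training
    configuration pairs (n/a when fewer than two).
    """
    rows1, rows2 = [], []
    for mode, rec in sorted(records_by_mode.items()):
        first = rec.iloc[0]
        rows1.append(
            {
                "mode": mode,
                "case1_f_true_hz": first["f_true_hz"],
                "case1_f_pred_hz": first["f_pred_hz"],
                "case1_rel_error_pct": first["rel_error_pct"],
                "case1_cosine": first["cosine"],
                "mean_rel_error_pct": rec["rel_error_pct"].mean(),
                "mean_cosine": rec["cosine"].mean(),
            }
        )
        try:
            stats = cross_config_cosine_stats(dataset, mode)
            rows2.append({"mode": mode, **stats})
        except ValueError:
            rows2.append({"mode": mode, "median": np.nan, "mean": np.nan})
    return pd.DataFrame(rows1), pd.DataFrame(rows2)
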