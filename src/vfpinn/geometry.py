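"""Body--cover prism geometry, point classification, and collocation sampling.

Coordinate convention (fixed package-wide):

* ``x`` — depth, medial (0) to lateral (Dc + Db); the cover occupies
  ``x <= Dc`` (superficial layer at the medial surface), the body the rest,
  with a planar interface at ``x = Dc``;
* ``y`` — inferior (0) to superior (T, the medial-surface thickness);
* ``z`` — anterior (0) to posterior (L, the AP length).

Fixed (zero-displacement) faces: lateral, anterior, posterior.  Free
(traction-free) faces: medial, superior, inferior.

Interior collocation sampling is stratified by layer: point counts are split
in proportion to the layer volumes and each point carries the quadrature
weight (stratum volume / stratum count), so Monte Carlo sums over the set
partition the prism volume exactly — this is what keeps the Rayleigh-quotient
quadrature volume-consistent between body and cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometrySpec",
    "CollocationSet",
    "PRINTED_PROFILE",
    "RESCALED_PROFILE",
    "FIXED_FACES",
    "FREE_FACES",
    "FACE_NORMALS",
    "classify_point",
    "classify_points",
    "face_normal",
    "sample_collocation",
]


class DomainError(ValueError):
    """Raised when a point lies outside the prism or a face tag is unknown."""


@dataclass(frozen=True)
class GeometrySpec:
    """Prism dimensions in metres.

    thickness : inferior--superior medial-surface thickness T
    body_depth / cover_depth : layer depths Db, Dc (total depth D = Db + Dc)
    length : anterior--posterior length L
    """

    thickness: float
    body_depth: float
    cover_depth: float
    length: float

    def __post_init__(self) -> None:
        for name in ("thickness", "body_depth", "cover_depth", "length"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def depth(self) -> float:
        return self.body_depth + self.cover_depth

    @property
    def volume(self) -> float:
        return self.thickness * self.length * self.depth

    @property
    def body_volume(self) -> float:
        return self.thickness * self.length * self.body_depth

    @property
    def cover_volume(self) -> float:
        return self.thickness * self.length * self.cover_depth

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of lower/upper corner, metres."""
        return np.array(
            [[0.0, 0.0, 0.0], [self.depth, self.thickness, self.length]]
        )


#: Dimensions as printed in the source model description (Db = 60 mm).
PRINTED_PROFILE = GeometrySpec(
    thickness=4.5e-3, body_depth=60e-3, cover_depth=15e-3, length=17e-3
)
#: Depths rescaled by 1/10 (Db = 6.0 mm), the physiologically plausible reading.
RESCALED_PROFILE = GeometrySpec(
    thickness=4.5e-3, body_depth=6.0e-3, cover_depth=1.5e-3, length=17e-3
)

FACE_NORMALS = {
    "medial": np.array([-1.0, 0.0, 0.0]),
    "lateral": np.array([1.0, 0.0, 0.0]),
    "inferior": np.array([0.0, -1.0, 0.0]),
    "superior": np.array([0.0, 1.0, 0.0]),
    "anterior": np.array([0.0, 0.0, -1.0]),
    "posterior": np.array([0.0, 0.0, 1.0]),
}

FIXED_FACES = ("lateral", "anterior", "posterior")
FREE_FACES = ("medial", "superior", "inferior")

#: Unit normal of the body--cover interface, pointing from cover into body.
INTERFACE_NORMAL = np.array([1.0, 0.0, 0.0])


def face_normal(face: str) -> np.ndarray:
    """Outward unit normal of a prism face."""
    try:
        return FACE_NORMALS[face].copy()
    except KeyError:
        raise DomainError(f"unknown face tag {face!r}") from None


def classify_points(points: np.ndarray, geom: GeometrySpec) -> np.ndarray:
    """Vectorised layer classification; returns an array of 'body'/'cover'.

    The interface plane x = Dc is assigned to the cover.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    lo, hi = geom.bounds
    tol = 1e-12 * max(geom.depth, geom.thickness, geom.length)
    if np.any(points < lo - tol) or np.any(points > hi + tol):
        raise DomainError("point outside the prism")
    return np.where(points[:, 0] <= geom.cover_depth, "cover", "body")


def classify_point(p: np.ndarray, geom: GeometrySpec) -> str:
    """Layer tag ('cover' iff depth coordinate <= Dc) for a single point."""
    return str(classify_points(np.asarray(p)[None, :], geom)[0])


@dataclass(frozen=True)
class CollocationSet:
    """Interior / surface / interface point sets with quadrature weights.

    interior_points : (Ni, 3) m; interior_layers : (Ni,) 'body'/'cover';
    interior_weights : (Ni,) m^3, summing exactly to the prism volume (and
    per-layer to the layer volume).  surface_* carry face tags and outward
    unit normals; interface points lie on x = Dc with the cover->body normal.
    """

    geom: GeometrySpec
    interior_points: np.ndarray
    interior_layers: np.ndarray
    interior_weights: np.ndarray
    surface_points: np.ndarray
    surface_faces: np.ndarray
    surface_normals: np.ndarray
    interface_points: np.ndarray
    interface_normal: np.ndarray
    seed: int

    def layer_mask(self, layer: str) -> np.ndarray:
        return self.interior_layers == layer

    def surface_mask(self, faces) -> np.ndarray:
        return np.isin(self.surface_faces, list(faces))

    def save_npz(self, path) -> None:
        np.savez(
            path,
            geom=np.array(
                [
                    self.geom.thickness,
                    self.geom.body_depth,
                    self.geom.cover_depth,
                    self.geom.length,
                ]
            ),
            interior_points=self.interior_points,
            interior_layers=self.interior_layers,
            interior_weights=self.interior_weights,
            surface_points=self.surface_points,
            surface_faces=self.surface_faces,
            surface_normals=self.surface_normals,
            interface_points=self.interface_points,
            interface_normal=self.interface_normal,
            seed=np.array(self.seed),
        )

    @staticmethod
    def load_npz(path) -> "CollocationSet":
        d = np.load(path, allow_pickle=False)
        t, db, dc, ln = d["geom"]
        return CollocationSet(
            geom=GeometrySpec(t, db, dc, ln),
            interior_points=d["interior_points"],
            interior_layers=d["interior_layers"],
            interior_weights=d["interior_weights"],
            surface_points=d["surface_points"],
            surface_faces=d["surface_faces"],
            surface_normals=d["surface_normals"],
            interface_points=d["interface_points"],
            interface_normal=d["interface_normal"],
            seed=int(d["seed"]),
        )


def _uniform_in_box(rng, n, lo, hi):
    return lo + (hi - lo) * rng.random((n, 3))


def sample_collocation(
    geom: GeometrySpec,
    n_interior: int,
    n_per_face: int,
    n_interface: int,
    seed: int,
) -> CollocationSet:
    """Stratified collocation draw, deterministic for a fixed seed.

    Interior counts are split between layers proportionally to layer volume
    (rounded, remainder to the body); each stratum is sampled uniformly and
    weighted by stratum volume / stratum count.  Surface points are uniform
    per face; interface points are uniform on the x = Dc plane.
    """
    if min(n_interior, n_per_face, n_interface) <= 0:
        raise ValueError("all point counts must be positive")
    rng = np.random.default_rng(seed)
    D, T, L, Dc = geom.depth, geom.thickness, geom.length, geom.cover_depth

    n_cover = int(round(n_interior * geom.cover_volume / geom.volume))
    n_cover = min(max(n_cover, 1), n_interior - 1)
    n_body = n_interior - n_cover

    cov_lo = np.array([0.0, 0.0, 0.0])
    cov_hi = np.array([Dc, T, L])
    bod_lo = np.array([Dc, 0.0, 0.0])
    bod_hi = np.array([D, T, L])
    pts_c = _uniform_in_box(rng, n_cover, cov_lo, cov_hi)
    pts_b = _uniform_in_box(rng, n_body, bod_lo, bod_hi)
    interior = np.vstack([pts_c, pts_b])
    layers = np.array(["cover"] * n_cover + ["body"] * n_body)
    weights = np.concatenate(
        [
            np.full(n_cover, geom.cover_volume / n_cover),
            np.full(n_body, geom.body_volume / n_body),
        ]
    )

    face_pts, face_tags, face_nrm = [], [], []
    spans = {
        "medial": (np.array([0.0, 0.0, 0.0]), np.array([0.0, T, L])),
        "lateral": (np.array([D, 0.0, 0.0]), np.array([D, T, L])),
        "inferior": (np.array([0.0, 0.0, 0.0]), np.array([D, 0.0, L])),
        "superior": (np.array([0.0, T, 0.0]), np.array([D, T, L])),
        "anterior": (np.array([0.0, 0.0, 0.0]), np.array([D, T, 0.0])),
        "posterior": (np.array([0.0, 0.0, L]), np.array([D, T, L])),
    }
    for face, (lo, hi) in spans.items():
        pts = _uniform_in_box(rng, n_per_face, lo, hi)
        face_pts.append(pts)
        face_tags.extend([face] * n_per_face)
        face_nrm.append(np.tile(FACE_NORMALS[face], (n_per_face, 1)))

    iface = _uniform_in_box(
        rng, n_interface, np.array([Dc, 0.0, 0.0]), np.array([Dc, T, L])
    )

    return CollocationSet(
        geom=geom,
        interior_points=interior,
        interior_layers=layers,
        interior_weights=weights,
        surface_points=np.vstack(face_pts),
        surface_faces=np.array(face_tags),
        surface_normals=np.vstack(face_nrm),
        interface_points=iface,
        interface_normal=INTERFACE_NORMAL.copy(),
        seed=seed,
    )
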