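"""Displacement-field network: SiLU material encoder + SIREN backbone.

The network maps a spatial point ``x`` (normalized to [-1, 1]^3) and an
encoded material vector to a 3-component nondimensional displacement.
Material parameters (Et, GAP_body, GAP_cover) are min--max normalized over
the training grid and passed through two SiLU-activated dense layers; the
encoding is concatenated with the normalized coordinates and fed to a SIREN
(sinusoidal layers ``sin(omega0 (W h + b))``) whose smoothness makes the
second spatial derivatives needed by the governing-equation residual exact
and well-behaved.

Spatial first and second derivatives are produced alongside the value by
explicit layerwise chain-rule propagation (exact, identical to nested
automatic differentiation); the whole computation is expressed in
:mod:`vfpinn.autodiff` ops, so one reverse pass yields parameter gradients
of any loss built on the value, Jacobian, or Hessian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, value

__all__ = ["NetworkSpec", "Normalization", "DisplacementNet"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    The reference setting is a 4x128 SIREN backbone with omega0 = 5 and a
    2-layer SiLU encoder; width/depth are configurable for scaled-down runs.
    """

    encoder_width: int = 64
    encoder_layers: int = 2
    hidden_width: int = 128
    hidden_layers: int = 4
    omega0: float = 5.0
    n_materials: int = 3
    n_outputs: int = 3
    seed: int = 0

    @staticmethod
    def reference(seed: int = 0) -> "NetworkSpec":
        """The full-scale architecture (4x128 SIREN, 64-wide encoder)."""
        return NetworkSpec(seed=seed)


@dataclass(frozen=True)
class Normalization:
    """Affine input maps stored with the weights (self-contained inference).

    Spatial coordinates map to [-1, 1]^3 (the SIREN's natural range);
    material parameters map to [0, 1] by min--max over the training grid
    (a degenerate axis, max == min, maps to the constant 0.5).
    """

    x_lo: np.ndarray
    x_hi: np.ndarray
    m_lo: np.ndarray
    m_hi: np.ndarray

    def normalize_x(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (x - self.x_lo) / (self.x_hi - self.x_lo) - 1.0

    @property
    def x_scale(self) -> np.ndarray:
        """d(x_norm)/d(x_phys), per axis (1/m)."""
        return 2.0 / (self.x_hi - self.x_lo)

    def normalize_m(self, m: np.ndarray) -> np.ndarray:
        span = self.m_hi - self.m_lo
        out = np.where(span > 0, (m - self.m_lo) / np.where(span > 0, span, 1.0), 0.5)
        return out

    @staticmethod
    def from_geometry_and_grid(geom, grid) -> "Normalization":
        lo, hi = geom.bounds
        pts = np.array(
            [
                [min(grid.et), min(grid.gap_body), min(grid.gap_cover)],
                [max(grid.et), max(grid.gap_body), max(grid.gap_cover)],
            ]
        )
        return Normalization(x_lo=lo, x_hi=hi, m_lo=pts[0], m_hi=pts[1])


def _uniform(rng, lo, hi, shape):
    return rng.uniform(lo, hi, size=shape)


class DisplacementNet:
    """SiLU encoder + SIREN displacement field with exact spatial derivatives."""

    def __init__(self, spec: NetworkSpec, norm: Normalization):
        self.spec = spec
        self.norm = norm
        self.params: dict[str, Tensor] = {}
        self._init_weights()

    # -- initialization -----------------------------------------------------
    def _param(self, name, arr):
        t = Tensor(arr)
        t.requires_grad = True
        self.params[name] = t
        return t

    def _init_weights(self):
        rng = np.random.default_rng(self.spec.seed)
        s = self.spec
        # encoder: SiLU dense layers, Kaiming-uniform style init
        fan = s.n_materials
        for i in range(s.encoder_layers):
            bound = np.sqrt(1.0 / fan)
            self._param(f"enc_W{i}", _uniform(rng, -bound, bound, (s.encoder_width, fan)))
            self._param(f"enc_b{i}", _uniform(rng, -bound, bound, (s.encoder_width,)))
            fan = s.encoder_width
        # SIREN backbone: uniform ranges of the sinusoidal-network scheme
        fan = 3 + s.encoder_width
        for i in range(s.hidden_layers):
            if i == 0:
                bound = 1.0 / fan
            else:
                bound = np.sqrt(6.0 / fan) / s.omega0
            self._param(f"sir_W{i}", _uniform(rng, -bound, bound, (s.hidden_width, fan)))
            self._param(f"sir_b{i}", _uniform(rng, -bound, bound, (s.hidden_width,)))
            fan = s.hidden_width
        bound = np.sqrt(6.0 / fan) / s.omega0
        self._param("out_W", _uniform(rng, -bound, bound, (s.n_outputs, fan)))
        self._param("out_b", np.zeros(s.n_outputs))

    def parameters(self):
        return list(self.params.values())

    def finite(self) -> bool:
        return all(np.all(np.isfinite(p.data)) for p in self.params.values())

    # -- forward ------------------------------------------------------------
    def encode(self, m_norm: np.ndarray, tape: bool = True):
        """Encoded material vector for one configuration (shape (E,))."""
        h = np.asarray(m_norm, dtype=float)
        outside = np.any((h < -1e-9) | (h > 1.0 + 1e-9))
        if outside:
            import warnings

            warnings.warn(
                "material parameters outside the normalized training range; "
                "the encoder is extrapolating",
                stacklevel=2,
            )
        for i in range(self.spec.encoder_layers):
            W = self.params[f"enc_W{i}"]
            b = self.params[f"enc_b{i}"]
            if not tape:
                W, b = W.data, b.data
            h = ad.add(ad.einsum("oi,i->o", W, h), b)
            h = ad.silu(h)
        return h

    def evaluate(
        self,
        x_phys: np.ndarray,
        m_norm: np.ndarray,
        tape: bool = True,
        order: int = 2,
    ):
        """Value, Jacobian, and Hessian of u at physical points.

        Returns ``(u, J, H)`` with shapes (N, 3), (N, 3, 3), (N, 3, 3, 3):
        ``J[p, c, j] = d u_c / d x_j`` and ``H[p, c, j, k] = d^2 u_c /
        (d x_j d x_k)``, derivatives with respect to physical metres (the
        chain rule through the coordinate normalization is applied).
        As :class:`autodiff.Tensor` when ``tape``, else plain ndarrays.
        ``order`` < 2 skips the Hessian (returned as None), ``order`` = 0
        also the Jacobian — derivative propagation dominates the cost, so
        callers that need values only should say so.
        """
        x_phys = np.atleast_2d(np.asarray(x_phys, dtype=float))
        B = x_phys.shape[0]
        s = self.spec
        xn = self.norm.normalize_x(x_phys)  # (B, 3)

        e = self.encode(m_norm, tape=tape)  # (E,)
        ones = np.ones((B, 1))
        e_b = ad.mul(ad.reshape(e, (1, s.encoder_width)), ones)  # (B, E)
        z = ad.concat([xn if not tape else Tensor(xn), e_b], axis=1)

        d_in = 3 + s.encoder_width
        J = H = None
        if order >= 1:
            J = np.zeros((B, d_in, 3))
            J[:, 0, 0] = J[:, 1, 1] = J[:, 2, 2] = 1.0
            J = Tensor(J) if tape else J
        if order >= 2:
            H = np.zeros((B, d_in, 3, 3))
            H = Tensor(H) if tape else H

        w0 = s.omega0

        def linear(Wname, bname, z, J, H):
            """Affine layer applied to value/Jacobian/Hessian (BLAS matmuls)."""
            W = self.params[Wname]
            b = self.params[bname]
            if not tape:
                W, b = W.data, b.data
            n_out, n_in = value(W).shape
            W1 = ad.reshape(W, (1, n_out, n_in))
            zc = ad.reshape(ad.matmul(W1, ad.reshape(z, (B, -1, 1))), (B, n_out))
            z = ad.add(zc, b)
            if J is not None:
                J = ad.matmul(W1, J)
            if H is not None:
                H = ad.reshape(
                    ad.matmul(W1, ad.reshape(H, (B, n_in, 9))), (B, n_out, 3, 3)
                )
            return z, J, H

        for i in range(s.hidden_layers):
            pre, Jp, Hp = linear(f"sir_W{i}", f"sir_b{i}", z, J, H)
            sin_p = ad.sin(ad.mul(pre, w0))
            z = sin_p
            if order >= 1:
                cos_p = ad.cos(ad.mul(pre, w0))
                c3 = ad.reshape(cos_p, (B, -1, 1))
                J = ad.mul(ad.mul(c3, w0), Jp)
                if order >= 2:
                    outer = ad.mul(
                        ad.reshape(Jp, (B, -1, 3, 1)), ad.reshape(Jp, (B, -1, 1, 3))
                    )
                    c4 = ad.reshape(cos_p, (B, -1, 1, 1))
                    s4 = ad.reshape(sin_p, (B, -1, 1, 1))
                    H = ad.add(
                        ad.mul(ad.mul(s4, -(w0**2)), outer),
                        ad.mul(ad.mul(c4, w0), Hp),
                    )

        u, J, H = linear("out_W", "out_b", z, J, H)
        sc = self.norm.x_scale  # chain rule: d x_norm / d x_phys
        if order >= 1:
            J = ad.mul(J, sc[None, None, :])
        if order >= 2:
            H = ad.mul(H, sc[None, None, :, None] * sc[None, None, None, :])
        return u, J, H

    def predict_displacement(self, x_phys, m_norm, chunk: int = 4096) -> np.ndarray:
        """Displacement values only, numpy fast path, chunked."""
        x_phys = np.atleast_2d(np.asarray(x_phys, dtype=float))
        out = np.empty((x_phys.shape[0], self.spec.n_outputs))
        for i in range(0, x_phys.shape[0], chunk):
            u, _, _ = self.evaluate(x_phys[i : i + chunk], m_norm, tape=False, order=0)
            out[i : i + chunk] = u
        return out

    def displacement_and_jacobian(self, x_phys, m_norm, chunk: int = 4096):
        """(u, J) numpy fast path, chunked — the field-evaluator protocol."""
        x_phys = np.atleast_2d(np.asarray(x_phys, dtype=float))
        N = x_phys.shape[0]
        u = np.empty((N, 3))
        J = np.empty((N, 3, 3))
        for i in range(0, N, chunk):
            ui, Ji, _ = self.evaluate(x_phys[i : i + chunk], m_norm, tape=False, order=1)
            u[i : i + chunk] = ui
            J[i : i + chunk] = Ji
        return u, J

    # -- persistence ---------------------------------------------------------
    def save(self, path, metadata: dict | None = None) -> None:
        """Single-file checkpoint: weights + spec + normalization (+ metadata)."""
        meta = {
            "spec": self.spec.__dict__,
            "metadata": metadata or {},
        }
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            x_lo=self.norm.x_lo,
            x_hi=self.norm.x_hi,
            m_lo=self.norm.m_lo,
            m_hi=self.norm.m_hi,
            **arrays,
        )

    @staticmethod
    def load(path) -> tuple["DisplacementNet", dict]:
        d = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(d["__meta__"]).decode())
        spec = NetworkSpec(**meta["spec"])
        norm = Normalization(
            x_lo=d["x_lo"], x_hi=d["x_hi"], m_lo=d["m_lo"], m_hi=d["m_hi"]
        )
        net = DisplacementNet(spec, norm)
        for k in net.params:
            net.params[k].data = d[k].copy()
        return net, meta["metadata"]
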