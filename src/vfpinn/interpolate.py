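"""Evaluate FEM reference modes at arbitrary points, with derivatives.

Reference eigenmodes live on the structured hex mesh.  To use them inside
the loss stack (Rayleigh quotient, residual checks, cosine supervision) they
must be evaluated at arbitrary collocation points together with exact first
and second derivatives of the interpolant.  A tensor-product B-spline is
built per displacement component *per layer*: the true mode has a strain
kink at the body--cover interface (traction, not strain, is continuous
there), so interpolating each layer separately preserves the kink while
keeping the field smooth within a layer.  Order 1 reproduces the FEM's own
trilinear field; order 3 gives a twice-differentiable representation whose
Hessian converges to the true mode's.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline

from .fem import HexMesh

__all__ = ["SplineModeField"]


class _TensorSpline:
    """Tensor-product B-spline on one layer's node grid, (nx, ny, nz, 3) data."""

    def __init__(self, xs, ys, zs, values, order):
        self.axes = (xs, ys, zs)
        c = np.asarray(values, dtype=float)
        self.ks, self.ts = [], []
        # interpolate along axis 0 and rotate, so after three passes the
        # coefficient tensor is (ncoef_x, ncoef_y, ncoef_z, 3)
        for grid in self.axes:
            k = min(order, len(grid) - 1)
            spl = make_interp_spline(grid, c, k=k, axis=0)
            self.ks.append(k)
            self.ts.append(spl.t)
            c = np.moveaxis(spl.c, 0, 2)
        self.coef = c  # (ncx, ncy, ncz, 3)

    def _basis(self, pts_1d, axis, deriv):
        t, k = self.ts[axis], self.ks[axis]
        n = len(t) - k - 1
        if deriv > k:  # e.g. pure second derivative of a trilinear interpolant
            return np.zeros((len(np.atleast_1d(pts_1d)), n))
        b = BSpline(t, np.eye(n), k)
        if deriv:
            b = b.derivative(deriv)
        lo, hi = self.axes[axis][0], self.axes[axis][-1]
        return b(np.clip(pts_1d, lo, hi))  # (P, n)

    def evaluate(self, pts):
        """(u, J, H) at pts (P, 3): values, physical-coordinate derivatives."""
        pts = np.atleast_2d(pts)
        B = [
            [self._basis(pts[:, ax], ax, d) for d in range(3)] for ax in range(3)
        ]

        def contract(dx, dy, dz):
            return np.einsum(
                "pi,pj,pk,ijkc->pc",
                B[0][dx],
                B[1][dy],
                B[2][dz],
                self.coef,
                optimize=True,
            )

        u = contract(0, 0, 0)
        P = pts.shape[0]
        J = np.empty((P, 3, 3))
        J[:, :, 0] = contract(1, 0, 0)
        J[:, :, 1] = contract(0, 1, 0)
        J[:, :, 2] = contract(0, 0, 1)
        H = np.empty((P, 3, 3, 3))
        orders = {
            (0, 0): (2, 0, 0),
            (1, 1): (0, 2, 0),
            (2, 2): (0, 0, 2),
            (0, 1): (1, 1, 0),
            (0, 2): (1, 0, 1),
            (1, 2): (0, 1, 1),
        }
        for (a, b), o in orders.items():
            val = contract(*o)
            H[:, :, a, b] = val
            H[:, :, b, a] = val
        return u, J, H


class SplineModeField:
    """Per-layer spline evaluator for one reference eigenmode.

    order = 1 is the trilinear (FEM-native) interpolant; order = 3 a cubic
    tensor spline.  Points with depth coordinate <= Dc evaluate on the cover
    spline, the rest on the body spline; :meth:`evaluate_side` forces a side
    (used for one-sided traction at the interface).
    """

    def __init__(self, mesh: HexMesh, nodal_displacements: np.ndarray, order: int = 3):
        vals = mesh.grid_values(np.asarray(nodal_displacements, dtype=float))
        ncx = mesh.n_cover_elems_x
        self.mesh = mesh
        self.order = order
        self.split_x = mesh.geom.cover_depth
        self._cover = _TensorSpline(
            mesh.xs[: ncx + 1], mesh.ys, mesh.zs, vals[: ncx + 1], order
        )
        self._body = _TensorSpline(
            mesh.xs[ncx:], mesh.ys, mesh.zs, vals[ncx:], order
        )

    def evaluate_side(self, pts, side: str):
        spl = {"cover": self._cover, "body": self._body}[side]
        return spl.evaluate(pts)

    def evaluate(self, pts):
        """(u, J, H) at arbitrary points, routed to the containing layer."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        in_cover = pts[:, 0] <= self.split_x
        P = pts.shape[0]
        u = np.empty((P, 3))
        J = np.empty((P, 3, 3))
        H = np.empty((P, 3, 3, 3))
        for side, mask in (("cover", in_cover), ("body", ~in_cover)):
            if mask.any():
                ui, Ji, Hi = self.evaluate_side(pts[mask], side)
                u[mask], J[mask], H[mask] = ui, Ji, Hi
        return u, J, H

    def displacement_and_jacobian(self, pts, m_norm=None, chunk=None):
        """Field-evaluator protocol (matches DisplacementNet's signature)."""
        u, J, _ = self.evaluate(pts)
        return u, J
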