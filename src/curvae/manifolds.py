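"""Constant-curvature space primitives.

Three geometries are supported, matching the latent subspaces of the
model:

* Euclidean space ``E^d`` (curvature ``K = 0``), points stored as
  ``d``-vectors;
* the hypersphere ``S_K^d = {x : <x,x>_2 = 1/K}``, ``K > 0``, points in
  ambient ``R^{d+1}``;
* hyperbolic space in the Lorentz (hyperboloid) model
  ``H_K^d = {x : <x,x>_L = 1/K, x_0 > 0}``, ``K < 0``, points in ambient
  ``R^{d+1}`` under the Minkowski inner product
  ``<x,y>_L = -x_0 y_0 + sum_i x_i y_i``.

All maps (exp/log, parallel transport, projections, gyro-operations on
the Poincaré ball) are batched over leading axes and accept either
``ndarray`` or autodiff :class:`~curvae.autodiff.Tensor` inputs, so the
same code runs inside the training graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .config import TOLERANCES

_EPS = 1e-12


@dataclass(frozen=True)
class CurvatureSpace:
    """A constant-curvature manifold: its kind, curvature K and dimension d.

    Ambient dimension is ``d`` for Euclidean space and ``d + 1`` for the
    curved spaces.
    """

    kind: str
    K: float
    d: int

    def __post_init__(self):
        if self.kind not in ("euclidean", "hyperspherical", "hyperbolic"):
            raise ValueError(f"unknown space kind {self.kind!r}")
        if self.kind == "euclidean" and self.K != 0:
            raise ValueError("euclidean space requires K = 0")
        if self.kind == "hyperspherical" and not self.K > 0:
            raise ValueError("hyperspherical space requires K > 0")
        if self.kind == "hyperbolic" and not self.K < 0:
            raise ValueError("hyperbolic space requires K < 0")
        if self.d < 1:
            raise ValueError("dimension must be >= 1")

    @property
    def curved(self) -> bool:
        return self.kind != "euclidean"

    @property
    def ambient_dim(self) -> int:
        return self.d if self.kind == "euclidean" else self.d + 1

    @property
    def radius(self) -> float:
        """1/sqrt(|K|); the Poincaré-ball radius for hyperbolic spaces."""
        if not self.curved:
            raise ValueError("flat space has no radius")
        return 1.0 / np.sqrt(abs(self.K))

    @property
    def origin(self) -> np.ndarray:
        """mu_0: zero for E^d, (1/sqrt(|K|), 0, ..., 0) for curved spaces."""
        if self.kind == "euclidean":
            return np.zeros(self.d)
        mu0 = np.zeros(self.d + 1)
        mu0[0] = self.radius
        return mu0


def euclidean(d: int) -> CurvatureSpace:
    return CurvatureSpace("euclidean", 0.0, d)


def hypersphere(d: int, K: float = 1.0) -> CurvatureSpace:
    return CurvatureSpace("hyperspherical", K, d)


def hyperbolic(d: int, K: float = -1.0) -> CurvatureSpace:
    return CurvatureSpace("hyperbolic", K, d)


@dataclass
class ManifoldPoint:
    """A point in ambient coordinates together with its space."""

    coords: np.ndarray
    space: CurvatureSpace

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        check_on_manifold(self.coords, self.space)


@dataclass
class TangentVector:
    """A tangent vector at a base point (ambient coordinates)."""

    coords: np.ndarray
    base: ManifoldPoint

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        sp = self.base.space
        if sp.curved:
            ip = inner(self.base.coords, self.coords, sp)
            if np.any(np.abs(ip) > TOLERANCES.tangency):
                raise ValueError("vector is not tangent at its base point")


# ---------------------------------------------------------------------------
# inner products and constraints
# ---------------------------------------------------------------------------

def lorentz_inner(a, b):
    """Minkowski form <a,b>_L = -a0*b0 + sum_{i>=1} ai*bi over the last axis."""
    av, bv = ad.value(a), ad.value(b)
    if av.shape[-1] != bv.shape[-1] or av.shape[-1] < 2:
        raise ValueError("ambient dimension mismatch or < 2")
    s = ad.sum(ad.mul(a, b), axis=-1)
    return ad.add(s, ad.mul(ad.mul(ad.take(a, (..., 0)), ad.take(b, (..., 0))), -2.0))


def inner(a, b, space: CurvatureSpace):
    """The ambient inner product belonging to `space`."""
    if space.kind == "hyperbolic":
        return lorentz_inner(a, b)
    return ad.sum(ad.mul(a, b), axis=-1)


def constraint_residual(x, space: CurvatureSpace) -> np.ndarray:
    """|<x,x> - 1/K| (zero for Euclidean points)."""
    xv = ad.value(x)
    if space.kind == "euclidean":
        return np.zeros(xv.shape[:-1])
    return np.abs(ad.value(inner(xv, xv, space)) - 1.0 / space.K)


def check_on_manifold(x, space: CurvatureSpace, tol: float | None = None) -> np.ndarray:
    """Validate (and lightly re-project) ambient points; numpy path only.

    Residuals below ``TOLERANCES.reproject`` are renormalised back onto the
    manifold (float drift guard); larger residuals raise.
    """
    xv = np.asarray(ad.value(x), dtype=np.float64)
    if not np.all(np.isfinite(xv)):
        raise ValueError("non-finite coordinates")
    if space.kind == "euclidean":
        if xv.shape[-1] != space.d:
            raise ValueError("wrong dimension for euclidean point")
        return xv
    if xv.shape[-1] != space.d + 1:
        raise ValueError("wrong ambient dimension")
    res = constraint_residual(xv, space)
    tol = TOLERANCES.on_manifold if tol is None else tol
    if np.any(res > TOLERANCES.reproject):
        raise ValueError(
            f"point off the manifold (max residual {res.max():.3g})")
    if np.any(res > tol):
        xv = project_to_manifold(xv, space)
    if space.kind == "hyperbolic" and np.any(xv[..., 0] <= 0):
        raise ValueError("hyperbolic point must have positive first coordinate")
    return xv


def project_to_manifold(x: np.ndarray, space: CurvatureSpace) -> np.ndarray:
    """Exact renormalisation onto the constraint set (numpy only)."""
    x = np.asarray(x, dtype=np.float64)
    if space.kind == "euclidean":
        return x
    if space.kind == "hyperspherical":
        n = np.linalg.norm(x, axis=-1, keepdims=True)
        return x / np.maximum(n, _EPS) * space.radius
    # hyperbolic: solve x0 from the spatial part
    sp = x[..., 1:]
    x0 = np.sqrt(1.0 / abs(space.K) + np.sum(sp * sp, axis=-1, keepdims=True))
    return np.concatenate([x0, sp], axis=-1)


def _prepend_zero(v):
    vv = ad.value(v)
    zeros = np.zeros(vv.shape[:-1] + (1,))
    return ad.concat([zeros, v], axis=-1)


# ---------------------------------------------------------------------------
# exp / log / transport (unified over the three geometries)
# ---------------------------------------------------------------------------

def exp_map(base, u, space: CurvatureSpace):
    """Exponential map: follow the geodesic from `base` with velocity `u`.

    ``u`` must be tangent at ``base``; the geodesic distance travelled is
    the tangent norm of ``u``.
    """
    if space.kind == "euclidean":
        return ad.add(base, u)
    sk = np.sqrt(abs(space.K))
    nrm_sq = inner(u, u, space)
    nrm = ad.sqrt(ad.maximum(nrm_sq, _EPS * _EPS))
    theta = ad.mul(nrm, sk)
    if space.kind == "hyperbolic":
        c1, c2 = ad.cosh(theta), ad.mul(ad.sinh(theta), ad.power(ad.mul(nrm, sk), -1.0))
    else:
        c1, c2 = ad.cos(theta), ad.mul(ad.sin(theta), ad.power(ad.mul(nrm, sk), -1.0))
    c1 = ad.reshape(c1, ad.value(c1).shape + (1,))
    c2 = ad.reshape(c2, ad.value(c2).shape + (1,))
    return ad.add(ad.mul(c1, base), ad.mul(c2, u))


def log_map(base, target, space: CurvatureSpace):
    """Inverse of :func:`exp_map`: the tangent vector at `base` reaching `target`."""
    if space.kind == "euclidean":
        return ad.add(target, ad.mul(base, -1.0))
    K = space.K
    alpha = ad.mul(inner(base, target, space), K)
    if space.kind == "hyperbolic":
        alpha = ad.maximum(alpha, 1.0)
        theta = ad.arccosh(ad.add(alpha, _EPS))
        denom = ad.sinh(theta)
    else:
        av = ad.value(alpha)
        if np.any(av < -1.0 + 1e-9):
            raise ValueError("antipodal points: logarithmic map is degenerate")
        alpha = ad.clip(alpha, -1.0, 1.0)
        theta = ad.arccos(alpha)
        denom = ad.sin(theta)
    factor = ad.mul(theta, ad.power(ad.maximum(denom, _EPS), -1.0))
    factor = ad.reshape(factor, ad.value(factor).shape + (1,))
    alpha_e = ad.reshape(alpha, ad.value(alpha).shape + (1,))
    diff = ad.add(target, ad.mul(ad.mul(alpha_e, base), -1.0))
    return ad.mul(factor, diff)


def parallel_transport(src, dst, v, space: CurvatureSpace, check: bool = True):
    """Transport tangent vector `v` from T_src to T_dst along the geodesic.

    An isometry of tangent spaces: inner products are preserved.
    """
    if space.kind == "euclidean":
        return v
    if check and not ad._is_tensor(v):
        ip = np.abs(ad.value(inner(src, v, space)))
        if np.any(ip > TOLERANCES.tangency):
            raise ValueError("v is not tangent at the source point")
    K = space.K
    qv = inner(dst, v, space)
    pq = inner(src, dst, space)
    coef = ad.mul(ad.mul(qv, -K), ad.power(ad.add(ad.mul(pq, K), 1.0), -1.0))
    coef = ad.reshape(coef, ad.value(coef).shape + (1,))
    return ad.add(v, ad.mul(coef, ad.add(src, dst)))


def distance(x, y, space: CurvatureSpace):
    """Geodesic distance."""
    if space.kind == "euclidean":
        d = ad.add(x, ad.mul(y, -1.0))
        return ad.sqrt(ad.maximum(ad.sum(ad.mul(d, d), axis=-1), 0.0))
    sk = np.sqrt(abs(space.K))
    alpha = ad.mul(inner(x, y, space), space.K)
    if space.kind == "hyperbolic":
        return ad.mul(ad.arccosh(ad.maximum(alpha, 1.0)), 1.0 / sk)
    return ad.mul(ad.arccos(ad.clip(alpha, -1.0, 1.0)), 1.0 / sk)


def tangent_lift(v_spatial, space: CurvatureSpace):
    """Map an unconstrained R^d vector onto the manifold through exp at mu0.

    Used as the posterior-location head for curved latent components.
    """
    if space.kind == "euclidean":
        return v_spatial
    v = _prepend_zero(v_spatial)
    base = np.broadcast_to(space.origin, ad.value(v).shape)
    return exp_map(base, v, space)


# ---------------------------------------------------------------------------
# Poincaré ball
# ---------------------------------------------------------------------------

def lorentz_to_poincare(x, space: CurvatureSpace):
    """Project Lorentz coordinates to the Poincaré ball of radius 1/sqrt(|K|).

    ``(x_1, ..., x_d) / (1 + sqrt(|K|) x_0)``.
    """
    if space.kind != "hyperbolic":
        raise ValueError("Poincaré projection is defined for hyperbolic spaces")
    sk = np.sqrt(abs(space.K))
    x0 = ad.take(x, (..., slice(0, 1)))
    denom = ad.add(ad.mul(x0, sk), 1.0)
    return ad.mul(ad.take(x, (..., slice(1, None))), ad.power(denom, -1.0))


def poincare_to_lorentz(p, space: CurvatureSpace):
    """Inverse lift of :func:`lorentz_to_poincare`."""
    if space.kind != "hyperbolic":
        raise ValueError("Poincaré lift is defined for hyperbolic spaces")
    aK = abs(space.K)
    s = ad.sum(ad.mul(p, p), axis=-1, keepdims=True)
    denom = ad.power(ad.add(ad.mul(s, -aK), 1.0), -1.0)
    x0 = ad.mul(ad.mul(ad.add(ad.mul(s, aK), 1.0), denom), 1.0 / np.sqrt(aK))
    sp = ad.mul(ad.mul(p, 2.0), denom)
    return ad.concat([x0, sp], axis=-1)


def _check_in_ball(p: np.ndarray, K: float):
    R = 1.0 / np.sqrt(abs(K))
    n = np.linalg.norm(np.asarray(p, dtype=np.float64), axis=-1)
    if np.any(n >= R):
        raise ValueError("point on or outside the Poincaré ball boundary")


def mobius_add(x, y, K: float):
    """Möbius (gyrovector) addition on the Poincaré ball of curvature K < 0.

    x (+)_K y = [(1 - 2K<x,y> - K|y|^2) x + (1 + K|x|^2) y]
                / (1 - 2K<x,y> + K^2 |x|^2 |y|^2)
    """
    if not K < 0:
        raise ValueError("Möbius addition requires K < 0")
    _check_in_ball(ad.value(x), K)
    _check_in_ball(ad.value(y), K)
    xy = ad.sum(ad.mul(x, y), axis=-1, keepdims=True)
    nx = ad.sum(ad.mul(x, x), axis=-1, keepdims=True)
    ny = ad.sum(ad.mul(y, y), axis=-1, keepdims=True)
    a = ad.add(ad.add(ad.mul(xy, -2.0 * K), ad.mul(ny, -K)), 1.0)
    b = ad.add(ad.mul(nx, K), 1.0)
    denom = ad.add(ad.add(ad.mul(xy, -2.0 * K), ad.mul(ad.mul(nx, ny), K * K)), 1.0)
    num = ad.add(ad.mul(a, x), ad.mul(b, y))
    return ad.mul(num, ad.power(denom, -1.0))


def recenter(points, new_origin, K: float):
    """Gyro-translate the ball so that `new_origin` maps to 0.

    Implemented as left translation ``(-new_origin) (+)_K p`` for each
    point; a hyperbolic isometry, so pairwise gyro-distances are
    preserved.
    """
    o = ad.mul(new_origin, -1.0)
    ov = ad.value(o)
    pv = ad.value(points)
    o_b = np.broadcast_to(ov, pv.shape) if not ad._is_tensor(o) else o
    return mobius_add(o_b, points, K)


def poincare_distance(x, y, K: float):
    """Geodesic distance between Poincaré-ball points of curvature K < 0."""
    aK = abs(K)
    d = np.asarray(ad.value(x)) - np.asarray(ad.value(y))
    nd = np.sum(d * d, axis=-1)
    nx = np.sum(np.asarray(ad.value(x)) ** 2, axis=-1)
    ny = np.sum(np.asarray(ad.value(y)) ** 2, axis=-1)
    arg = 1.0 + 2.0 * aK * nd / np.maximum((1 - aK * nx) * (1 - aK * ny), _EPS)
    return np.arccosh(np.maximum(arg, 1.0)) / np.sqrt(aK)


def estimate_cycling_center(cycling_points) -> np.ndarray:
    """Midpoint of the axis-aligned bounding box of the cycling cells'
    Poincaré coordinates: p_c = [x_l + (x_r - x_l)/2, y_b + (y_t - y_b)/2]."""
    pts = np.asarray(ad.value(cycling_points), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("need an (n, 2) array with n >= 1")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    return lo + (hi - lo) / 2.0


def suggest_new_origin(p_c: np.ndarray, K: float, r: float | None = None) -> np.ndarray:
    """Advisory new origin diagonally across from the cycling center,
    near the edge of the disk: -r * p_c / ||p_c||, default r = 0.9/sqrt(|K|)."""
    p_c = np.asarray(p_c, dtype=np.float64)
    R = 1.0 / np.sqrt(abs(K))
    if r is None:
        r = 0.9 * R
    n = np.linalg.norm(p_c)
    if n < _EPS:
        return np.zeros_like(p_c)
    return -r * p_c / n
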