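"""Wrapped normal distributions on constant-curvature spaces, and RoWN.

The wrapped normal ``WN(mu, Sigma)`` is built by the usual wrapping
construction: draw ``v~ ~ N(0, Sigma)`` in ``R^d``, prepend a zero
coordinate (curved spaces) so the result is tangent at the origin
``mu_0``, parallel-transport to ``mu`` and apply the exponential map.
Its density follows by running the construction backwards and
subtracting the log-determinant of the Jacobian of
``f = exp_mu o PT_{mu0 -> mu}``, which for the Lorentz model is

    log det = (d - 1) * log( sinh(sqrt(|K|) r) / (sqrt(|K|) r) ),

with ``r`` the tangent norm of ``log_mu(z)`` (the ``sin`` analogue on the
sphere, zero in flat space).

The rotated variant (RoWN) replaces the diagonal covariance by
``Sigma_hat = R Sigma R^T`` where ``R`` rotates the first standard basis
vector onto the radial direction of ``mu``, so that the leading
principal axis of the noise points radially — off-circle variation then
models non-phase factors instead of smearing the phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import manifolds as mf
from .manifolds import CurvatureSpace

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class WrappedNormalParams:
    """Location on the manifold + diagonal tangent standard deviations.

    With ``rown=True`` the covariance is rotated by the RoWN rule before
    sampling and density evaluation.
    """

    mu: np.ndarray
    sigma: np.ndarray
    rown: bool = False

    def __post_init__(self):
        if np.any(ad.value(self.sigma) <= 0):
            raise ValueError("sigma must be strictly positive")


def standard_prior(space: CurvatureSpace) -> WrappedNormalParams:
    """Wrapped standard normal at the origin (sigma = 1 per dimension)."""
    return WrappedNormalParams(mu=space.origin, sigma=np.ones(space.d))


# ---------------------------------------------------------------------------
# RoWN rotation
# ---------------------------------------------------------------------------

def rown_rotation(mu, space: CurvatureSpace):
    """Rotation R aligning x = [s, 0, ..., 0] with the radial direction y.

    ``y`` is the normalised spatial part of ``mu`` and ``s`` the sign of
    its first spatial coordinate (so ``1 + <x, y> >= 1``).  Built from
    ``A = y^T x - x^T y`` as ``R = I + A + A^2 / (1 + <x, y>)``.  For a
    location at the origin (zero spatial part) the identity is returned.
    Batched over leading axes; differentiable in ``mu``.
    """
    d = space.d
    spatial = ad.take(mu, (..., slice(1, None)))
    sv = ad.value(spatial)
    norm = ad.sqrt(ad.maximum(ad.sum(ad.mul(spatial, spatial), axis=-1, keepdims=True), 1e-24))
    y = ad.mul(spatial, ad.power(norm, -1.0))
    sign = np.where(sv[..., 0] >= 0, 1.0, -1.0)  # constant w.r.t. the tape
    x = np.zeros(sv.shape)
    x[..., 0] = sign
    # A = outer(y, x) - outer(x, y)
    y_col = ad.reshape(y, ad.value(y).shape + (1,))
    y_row = ad.reshape(y, ad.value(y).shape[:-1] + (1, d))
    x_col = x[..., :, None]
    x_row = x[..., None, :]
    A = ad.add(ad.mul(y_col, x_row), ad.mul(ad.mul(x_col, y_row), -1.0))
    c = ad.sum(ad.mul(y, x), axis=-1)  # <x, y> in [0, 1]
    coef = ad.power(ad.add(c, 1.0), -1.0)
    coef = ad.reshape(coef, ad.value(coef).shape + (1, 1))
    R = ad.add(ad.add(np.broadcast_to(np.eye(d), sv.shape + (d,)), A),
               ad.mul(ad.matmul(A, A), coef))
    # degenerate location exactly at the origin: identity
    at_origin = np.linalg.norm(sv, axis=-1) < 1e-12
    if np.any(at_origin):
        R = ad.where_const(at_origin[..., None, None],
                           np.broadcast_to(np.eye(d), sv.shape + (d,)), R)
    return R


def _maybe_rotate(v_spatial, params: WrappedNormalParams, space: CurvatureSpace,
                  transpose: bool):
    """Apply R (or R^T) to spatial tangent coordinates when rown is set."""
    if not params.rown or space.kind == "euclidean" or space.d < 2:
        return v_spatial
    R = rown_rotation(params.mu, space)
    if transpose:
        R = _transpose_last2(R)
    col = ad.reshape(v_spatial, ad.value(v_spatial).shape + (1,))
    out = ad.matmul(R, col)
    return ad.reshape(out, ad.value(out).shape[:-1])


def _transpose_last2(R):
    if ad._is_tensor(R):
        Rv = ad.value(R)
        perm = tuple(range(Rv.ndim - 2)) + (Rv.ndim - 1, Rv.ndim - 2)
        # implement transpose via take with swapped index grid
        idx = np.transpose(np.arange(Rv.size).reshape(Rv.shape), perm)
        flat = ad.reshape(R, (-1,))
        return ad.reshape(ad.take(flat, (idx.reshape(-1),)), idx.shape)
    return np.swapaxes(R, -1, -2)


# ---------------------------------------------------------------------------
# sampling and density
# ---------------------------------------------------------------------------

def sample_wrapped_normal(params: WrappedNormalParams, space: CurvatureSpace,
                          n: int | None = None, rng: np.random.Generator | None = None,
                          eps=None):
    """Sample by wrapping: v~ ~ N(0, Sigma); transport mu0 -> mu; exp map.

    Either pass ``rng`` (and optionally ``n``) for numpy sampling, or a
    pre-drawn standard-normal ``eps`` for reparameterised sampling on the
    autodiff tape.
    """
    mu, sigma = params.mu, params.sigma
    d = space.d
    if eps is None:
        if rng is None:
            raise ValueError("provide rng or eps")
        shape = (ad.value(mu).shape[:-1] if n is None else (n,)) + (d,)
        eps = rng.standard_normal(shape)
    vt = ad.mul(sigma, eps)                       # ~ N(0, Sigma), diagonal
    vt = _maybe_rotate(vt, params, space, transpose=False)   # RoWN: v = R (sigma*eps)
    if space.kind == "euclidean":
        return ad.add(mu, vt)
    v = mf._prepend_zero(vt)
    mu_b = _broadcast_like(mu, ad.value(v).shape)
    origin = np.broadcast_to(space.origin, ad.value(v).shape)
    u = mf.parallel_transport(origin, mu_b, v, space, check=False)
    return mf.exp_map(mu_b, u, space)


def _broadcast_like(mu, shape):
    if ad._is_tensor(mu):
        if ad.value(mu).shape == shape:
            return mu
        return ad.add(mu, np.zeros(shape))
    return np.broadcast_to(np.asarray(mu, dtype=np.float64), shape)


def _diag_gauss_logpdf(v, sigma):
    """log N(v; 0, diag(sigma^2)), summed over the last axis."""
    z = ad.mul(v, ad.power(sigma, -1.0))
    quad = ad.sum(ad.mul(z, z), axis=-1)
    logdet = ad.sum(ad.log(sigma), axis=-1)
    dd = ad.value(v).shape[-1]
    return ad.add(ad.mul(ad.add(quad, dd * _LOG2PI), -0.5), ad.mul(logdet, -1.0))


def log_prob_wrapped_normal(z, params: WrappedNormalParams, space: CurvatureSpace):
    """Density by the reverse construction: pull z back to the tangent
    space at the origin and correct by the wrapping Jacobian."""
    mu, sigma = params.mu, params.sigma
    if space.kind == "euclidean":
        diff = ad.add(z, ad.mul(mu, -1.0))
        return _diag_gauss_logpdf(diff, sigma)
    mu_b = _broadcast_like(mu, ad.value(z).shape)
    origin = np.broadcast_to(space.origin, ad.value(z).shape)
    u = mf.log_map(mu_b, z, space)
    v = mf.parallel_transport(mu_b, origin, u, space, check=False)
    vt = ad.take(v, (..., slice(1, None)))
    vt = _maybe_rotate(vt, params, space, transpose=True)    # undo RoWN rotation
    base = _diag_gauss_logpdf(vt, sigma)
    # log|det df/dv| with r the tangent norm of u
    sk = np.sqrt(abs(space.K))
    rr = ad.sqrt(ad.maximum(mf.inner(u, u, space), 1e-30))
    theta = ad.mul(rr, sk)
    if space.kind == "hyperbolic":
        ratio = ad.mul(ad.sinh(theta), ad.power(ad.maximum(theta, 1e-15), -1.0))
    else:
        ratio = ad.mul(ad.sin(theta), ad.power(ad.maximum(theta, 1e-15), -1.0))
    logdet = ad.mul(ad.log(ad.maximum(ratio, 1e-300)), float(space.d - 1))
    return ad.add(base, ad.mul(logdet, -1.0))


def kl_monte_carlo(q: WrappedNormalParams, p: WrappedNormalParams,
                   space: CurvatureSpace, n_samples: int = 1,
                   rng: np.random.Generator | None = None, eps=None):
    """Unbiased Monte-Carlo estimate of KL(q || p): mean_z[log q(z) - log p(z)]."""
    if eps is None:
        if rng is None:
            raise ValueError("provide rng or eps")
        eps = rng.standard_normal((n_samples,) + ad.value(q.mu).shape[:-1] + (space.d,))
    z = sample_wrapped_normal(q, space, eps=eps)
    lq = log_prob_wrapped_normal(z, q, space)
    lp = log_prob_wrapped_normal(z, p, space)
    diff = ad.add(lq, ad.mul(lp, -1.0))
    return ad.mean(diff, axis=0)


def gaussian_kl_closed_form(mu_q, sigma_q, mu_p=None, sigma_p=None):
    """KL between diagonal Gaussians; standard-normal p by default.
    Summed over the last axis."""
    if mu_p is None:
        quad = ad.sum(ad.mul(mu_q, mu_q), axis=-1)
        s2 = ad.mul(sigma_q, sigma_q)
        tr = ad.sum(s2, axis=-1)
        logdet = ad.mul(ad.sum(ad.log(s2), axis=-1), -1.0)
        d = ad.value(mu_q).shape[-1]
        return ad.mul(ad.add(ad.add(tr, quad), ad.add(logdet, -float(d))), 0.5)
    dm = ad.add(mu_q, ad.mul(mu_p, -1.0))
    r2 = ad.mul(ad.mul(sigma_q, sigma_q), ad.power(ad.mul(sigma_p, sigma_p), -1.0))
    quad = ad.sum(ad.mul(ad.mul(dm, dm), ad.power(ad.mul(sigma_p, sigma_p), -1.0)), axis=-1)
    tr = ad.sum(r2, axis=-1)
    logdet = ad.mul(ad.sum(ad.log(r2), axis=-1), -1.0)
    d = ad.value(mu_q).shape[-1]
    return ad.mul(ad.add(ad.add(tr, quad), ad.add(logdet, -float(d))), 0.5)
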