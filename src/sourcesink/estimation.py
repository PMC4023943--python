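"""Penalized constrained least squares for source-sink reconstruction.

Model: for region i and year t,

    y[i, t] = sum_j w[j] * theta[j, i] * sum_d f[j, d] * G[j, d, i, t] + eps

with theta[j, :] >= 0 summing to 1, f[j, :] = Phi @ b[j] >= 0 summing to 1,
w[j] >= 0, and eps uncorrelated mean-zero constant-variance noise.

Internally the model is fit in unnormalized bilinear form: with the design
tensor Z[j, k, i, t] = sum_d Phi[d, k] * G[j, d, i, t] the mean response is

    sum_j sum_k u[j, i] * v[j, k] * Z[j, k, i, t],

and the objective adds, per source, an adaptive-lasso-style penalty on the
weighted outer product of (u[j, :], v[j, :]):

    Q(u, v) = sum_obs (y - yhat)^2
              + sum_j lam[j] * sum_{i,k} omega[j, i, k] * u[j, i] * v[j, k]

minimized over u, v >= 0 by cyclic block relaxation: each block update is
a non-negative L1-penalized least squares with a closed-form non-negative
soft-threshold solution per coordinate.  Sink effects whose exposure is
identically zero across the data are structurally fixed at zero.  After
convergence the parameters are normalized to the interpretable
(w, theta, f) scale.  Tuning is by AIC over a lambda grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .basis import SplineBasis
from .data_model import AbundanceMatrix, ExposureTensor

logger = logging.getLogger(__name__)

_WEIGHT_FLOOR = 1e-6
_ROUND = 1e-10  # serialization rounding for normalized outputs


@dataclass
class FitOptions:
    tol: float = 1e-8
    max_iter: int = 500
    n_restarts: int = 3
    seed: int = 0
    debug_monotone: bool = False
    polish: bool = True  # quasi-Newton refinement after block relaxation
    polish_ftol: float = 1e-15
    polish_gtol: float = 1e-12
    polish_maxiter: int = 2000


@dataclass
class ModelFit:
    """Fitted source-sink model, normalized and unnormalized forms."""

    w: np.ndarray            # (J,) productivity multipliers
    theta: np.ndarray        # (J, I) sink effects, rows of active sources sum to 1
    f: np.ndarray            # (J, D) release-time probability masses
    b: np.ndarray            # (J, K) spline coefficients >= 0
    u: np.ndarray            # (J, I) unnormalized sink block
    v: np.ndarray            # (J, K) unnormalized spline block
    lam: np.ndarray          # (J,) tuning parameters
    omega: np.ndarray        # (J, I, K) adaptive penalty weights
    fixed_zero_mask: np.ndarray  # (J, I) structural zeros
    rss: float
    df: int
    aic: float
    objective: float
    objective_trace: np.ndarray
    converged: bool
    n_obs: int
    seed: int = 0
    tuning_path: list = field(default_factory=list)  # (lam, aic, df) triples

    @property
    def active(self) -> np.ndarray:
        """(J,) boolean: sources with positive productivity."""
        return self.w > 0


# ---------------------------------------------------------------------------
# Design pieces
# ---------------------------------------------------------------------------


def structural_zero_mask(G: ExposureTensor) -> np.ndarray:
    """(J, I) boolean; True where exposure is identically zero over (d, t).

    Such sink effects are fixed at zero — the asterisk cells of the
    reconstruction tables.
    """
    return G.G.sum(axis=(1, 3)) == 0


def precompute_design(G: ExposureTensor, basis: SplineBasis) -> np.ndarray:
    """Collapse the release axis: Z[j, k, i, t] = sum_d Phi[d, k] G[j, d, i, t]."""
    if basis.n_events != G.G.shape[1]:
        raise ValueError(
            f"basis rows ({basis.n_events}) != release axis of G ({G.G.shape[1]})"
        )
    return np.einsum("dk,jdit->jkit", basis.Phi, G.G)


def _predict_uv(u: np.ndarray, v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    return np.einsum("ji,jk,jkit->it", u, v, Z)


def _objective_uv(
    y: np.ndarray,
    obs: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    Z: np.ndarray,
    lam: np.ndarray,
    omega_f: np.ndarray,
) -> float:
    resid = (y - _predict_uv(u, v, Z))[obs]
    pen = float(np.sum(lam[:, None, None] * omega_f * u[:, :, None] * v[:, None, :]))
    return float(resid @ resid) + pen


def adaptive_weights(
    Y: AbundanceMatrix,
    Z: np.ndarray,
    mask: np.ndarray,
    opts: FitOptions | None = None,
) -> np.ndarray:
    """Data-driven penalty weights from an unpenalized pilot fit.

    omega[j, i, k] = 1 / (|u0[j, i] * v0[j, k]| + 1e-6) from the pilot
    (lambda = 0, constraints on); structurally masked (j, i) get +inf.
    A degenerate all-zero pilot falls back to uniform weights.
    """
    J, K, I, T = Z.shape
    opts = opts or FitOptions()
    pilot = _fit_uv(Y, Z, np.zeros(J), np.ones((J, I, K)), mask, opts)
    return _weights_from_pilot(pilot.u, pilot.v, mask)


def _weights_from_pilot(u0: np.ndarray, v0: np.ndarray, mask: np.ndarray) -> np.ndarray:
    outer = np.abs(u0[:, :, None] * v0[:, None, :])
    if not outer.any():
        logger.warning("adaptive weights: degenerate all-zero pilot; uniform weights")
        omega = np.ones(outer.shape)
    else:
        omega = 1.0 / (outer + _WEIGHT_FLOOR)
    return np.where(mask[:, :, None], np.inf, omega)


# ---------------------------------------------------------------------------
# Core solver
# ---------------------------------------------------------------------------


def _nn_soft_threshold(a: float, b: float, pen: float) -> float:
    """argmin over x >= 0 of  a*x^2 - 2*b*x + pen*x  (a > 0)."""
    return max(0.0, (b - 0.5 * pen) / a)


@dataclass
class _RawFit:
    u: np.ndarray
    v: np.ndarray
    objective: float
    trace: np.ndarray
    converged: bool


def _init_uv(
    y: np.ndarray,
    obs: np.ndarray,
    Z: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal non-negative regression init for u; uniform v; optional jitter."""
    J, K, I, T = Z.shape
    v = np.full((J, K), 1.0 / K)
    u = np.zeros((J, I))
    for j in range(J):
        x = np.einsum("k,kit->it", v[j], Z[j])  # aggregate covariate
        for i in range(I):
            if mask[j, i]:
                continue
            o = obs[i]
            denom = float(x[i, o] @ x[i, o])
            u[j, i] = max(0.0, float(y[i, o] @ x[i, o]) / denom) if denom > 0 else 0.0
    if rng is not None:
        u *= rng.uniform(0.5, 1.5, size=u.shape)
        v *= rng.uniform(0.5, 1.5, size=v.shape)
    return u, v


def _fit_uv(
    Y: AbundanceMatrix,
    Z: np.ndarray,
    lam: np.ndarray,
    omega: np.ndarray,
    mask: np.ndarray,
    opts: FitOptions,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> _RawFit:
    """Cyclic block relaxation on the bilinear penalized objective.

    Per cycle and source j: (a) solve each u[j, i] in closed form (u[j, i]
    enters only region i's residuals, so the u block is exactly separable);
    (b) one coordinate-descent sweep over v[j, :].  Restarts (seeded) guard
    against poor local minima of the non-convex objective; the best
    objective wins.
    """
    y, obs = Y.y, Y.observed
    J, K, I, T = Z.shape
    omega_f = np.where(mask[:, :, None], 0.0, omega)  # masked u are pinned to 0

    starts: list[tuple[np.ndarray, np.ndarray]] = []
    if warm is not None:
        starts.append((warm[0].copy(), warm[1].copy()))
    starts.append(_init_uv(y, obs, Z, mask, None))
    rng = np.random.default_rng(opts.seed)
    for _ in range(max(0, opts.n_restarts - 1)):
        starts.append(_init_uv(y, obs, Z, mask, rng))

    best: _RawFit | None = None
    for u0, v0 in starts:
        raw = _relax(y, obs, Z, lam, omega_f, mask, u0, v0, opts)
        if best is None or raw.objective < best.objective - 1e-15:
            best = raw
    return best


def _relax(
    y: np.ndarray,
    obs: np.ndarray,
    Z: np.ndarray,
    lam: np.ndarray,
    omega_f: np.ndarray,
    mask: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    opts: FitOptions,
) -> _RawFit:
    J, K, I, T = Z.shape
    u = np.where(mask, 0.0, u)
    yhat = _predict_uv(u, v, Z)
    q = _objective_uv(y, obs, u, v, Z, lam, omega_f)
    trace = [q]
    converged = False
    for _ in range(opts.max_iter):
        for j in range(J):
            # ---- u[j, :] update (exact, separable over regions) ----
            contrib_j = np.einsum("i,k,kit->it", u[j], v[j], Z[j])
            r = y - (yhat - contrib_j)  # partial residual incl. only source j... r = y - others
            c = np.einsum("k,kit->it", v[j], Z[j])
            pen_u = lam[j] * (omega_f[j] @ v[j])  # (I,)
            for i in range(I):
                if mask[j, i]:
                    u[j, i] = 0.0
                    continue
                o = obs[i]
                a = float(c[i, o] @ c[i, o])
                if a <= 0.0:
                    u[j, i] = 0.0
                    continue
                bq = float(r[i, o] @ c[i, o])
                u[j, i] = _nn_soft_threshold(a, bq, pen_u[i])
            yhat = (y - r) + np.einsum("i,k,kit->it", u[j], v[j], Z[j])

            # ---- v[j, :] update (one coordinate sweep) ----
            pen_v = lam[j] * (u[j] @ omega_f[j])  # (K,)
            for k in range(K):
                m = u[j][:, None] * Z[j, k]  # (I, T)
                contrib_k = v[j, k] * m
                rk = y - (yhat - contrib_k)
                a = float((m[obs] ** 2).sum())
                if a <= 0.0:
                    new = 0.0
                else:
                    bq = float((rk[obs] * m[obs]).sum())
                    new = _nn_soft_threshold(a, bq, pen_v[k])
                if new != v[j, k]:
                    yhat = yhat + (new - v[j, k]) * m
                    v[j, k] = new
        q_new = _objective_uv(y, obs, u, v, Z, lam, omega_f)
        if opts.debug_monotone and q_new > q + 1e-7 * max(1.0, abs(q)):
            raise RuntimeError(f"objective increased: {q} -> {q_new}")
        trace.append(q_new)
        if q - q_new < opts.tol * max(1.0, abs(q)):
            converged = True
            q = q_new
            break
        q = q_new
    if opts.polish:
        u, v, q_pol = _polish(y, obs, Z, lam, omega_f, mask, u, v,
                              ftol=opts.polish_ftol, gtol=opts.polish_gtol,
                              maxiter=opts.polish_maxiter)
        if q_pol <= q:
            q = q_pol
            trace.append(q)
            converged = True
    return _RawFit(u=u, v=v, objective=q, trace=np.asarray(trace), converged=converged)


def _polish(
    y: np.ndarray,
    obs: np.ndarray,
    Z: np.ndarray,
    lam: np.ndarray,
    omega_f: np.ndarray,
    mask: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    ftol: float = 1e-15,
    gtol: float = 1e-12,
    maxiter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bound-constrained quasi-Newton refinement of the block-relaxation
    solution.

    On the non-negative orthant the penalty sum lam*omega*u*v is smooth
    (no absolute values are active), so the whole objective is
    differentiable and L-BFGS-B applies; structural zeros are pinned by
    (0, 0) bounds.  This removes the slow tail of coordinate descent on
    ill-conditioned bilinear problems while keeping exact zeros (active
    bounds) intact.
    """
    from scipy.optimize import minimize

    J, K, I, T = Z.shape
    nu = J * I
    obs_f = obs.astype(float)
    lam_om = lam[:, None, None] * omega_f  # (J, I, K), zero at masked cells

    def unpack(x):
        return x[:nu].reshape(J, I), x[nu:].reshape(J, K)

    def fun(x):
        uu, vv = unpack(x)
        # cv[j] = v_j-weighted design, shape (J, I, T)
        cv = np.matmul(vv[:, None, :], Z.reshape(J, K, I * T))[:, 0, :].reshape(J, I, T)
        yhat = (uu[:, :, None] * cv).sum(axis=0)
        r = (y - yhat) * obs_f
        gu = -2.0 * (cv * r[None]).sum(axis=2) + np.matmul(
            lam_om, vv[:, :, None]
        )[:, :, 0]
        ru = uu[:, :, None] * r[None]  # (J, I, T)
        gv = -2.0 * np.matmul(
            Z.reshape(J, K, I * T), ru.reshape(J, I * T, 1)
        )[:, :, 0] + np.matmul(lam_om.transpose(0, 2, 1), uu[:, :, None])[:, :, 0]
        gu[mask] = 0.0
        pen = float((np.matmul(lam_om, vv[:, :, None])[:, :, 0] * uu).sum())
        return float((r * r).sum()) + pen, np.concatenate([gu.ravel(), gv.ravel()])

    bounds = [(0.0, 0.0) if mask.ravel()[n] else (0.0, None) for n in range(nu)]
    bounds += [(0.0, None)] * (J * K)
    x0 = np.concatenate([u.ravel(), v.ravel()])
    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
    )
    uu, vv = unpack(res.x)
    return uu, vv, float(res.fun)


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


def _normalize(
    u: np.ndarray, v: np.ndarray, Phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(u, v) -> (w, theta, f, b) on the interpretable scale."""
    J, I = u.shape
    D = Phi.shape[0]
    fv = v @ Phi.T  # (J, D) unnormalized curves
    su = u.sum(axis=1)
    sf = fv.sum(axis=1)
    w = su * sf
    theta = np.zeros_like(u)
    f = np.zeros_like(fv)
    b = np.zeros_like(v)
    for j in range(J):
        if w[j] > 0:
            theta[j] = u[j] / su[j]
            f[j] = fv[j] / sf[j]
            b[j] = v[j] / sf[j]
    w = np.round(w / _ROUND) * _ROUND
    theta = np.round(theta / _ROUND) * _ROUND
    f = np.round(f / _ROUND) * _ROUND
    return w, theta, f, b


def _dof(u: np.ndarray, v: np.ndarray) -> int:
    """Effective parameter count: nonzero entries minus the two
    normalization constraints absorbed per active source."""
    active = (u.sum(axis=1) > 0) & (v.sum(axis=1) > 0)
    return int((u > 0).sum() + (v > 0).sum() - 2 * active.sum())


def aic(rss: float, n_obs: int, df: int) -> float:
    """Gaussian working-likelihood AIC with variance profiled out."""
    if rss <= 0:
        logger.warning("aic: zero rss (degenerate interpolation); returning -inf")
        return -np.inf
    return n_obs * np.log(rss / n_obs) + 2 * df


def fit(
    Y: AbundanceMatrix,
    G: ExposureTensor,
    basis: SplineBasis,
    lam: float | np.ndarray = 0.0,
    omega: np.ndarray | None = None,
    opts: FitOptions | None = None,
    mask: np.ndarray | None = None,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    Z: np.ndarray | None = None,
) -> ModelFit:
    """Fit the source-sink model at fixed tuning parameter(s).

    ``lam`` may be a scalar (shared across sources) or a (J,) vector.
    ``omega`` defaults to adaptive weights from an unpenalized pilot fit
    (uniform weights when lam is identically zero, where they are inert).
    ``Z`` may carry a precomputed design tensor (resampling loops).
    """
    opts = opts or FitOptions()
    if Z is None:
        Z = precompute_design(G, basis)
    J, K, I, T = Z.shape
    if Y.y.shape != (I, T):
        raise ValueError(f"Y shape {Y.y.shape} does not match G's (I, T)=({I}, {T})")
    lam = np.broadcast_to(np.atleast_1d(np.asarray(lam, dtype=float)), (J,)).copy()
    if (lam < 0).any():
        raise ValueError("tuning parameters must be non-negative")
    if mask is None:
        mask = structural_zero_mask(G)
    if omega is None:
        if lam.any():
            omega = adaptive_weights(Y, Z, mask, opts)
        else:
            omega = np.where(mask[:, :, None], np.inf, np.ones((J, I, K)))
    raw = _fit_uv(Y, Z, lam, omega, mask, opts, warm=warm)
    w, theta, f, b = _normalize(raw.u, raw.v, basis.Phi)
    resid = (Y.y - _predict_uv(raw.u, raw.v, Z))[Y.observed]
    rss = float(resid @ resid)
    n_obs = int(Y.observed.sum())
    df = _dof(raw.u, raw.v)
    for j in range(J):
        if mask[j].all():
            logger.warning("source %d fully masked; productivity fixed at 0", j + 1)
    return ModelFit(
        w=w, theta=theta, f=f, b=b, u=raw.u, v=raw.v, lam=lam, omega=omega,
        fixed_zero_mask=mask, rss=rss, df=df, aic=aic(rss, n_obs, df),
        objective=raw.objective, objective_trace=raw.trace,
        converged=raw.converged, n_obs=n_obs, seed=opts.seed,
    )


def tune(
    Y: AbundanceMatrix,
    G: ExposureTensor,
    basis: SplineBasis,
    lambda_grid: np.ndarray,
    omega: np.ndarray | None = None,
    opts: FitOptions | None = None,
    Z: np.ndarray | None = None,
) -> ModelFit:
    """Fit each lambda in the grid (shared across sources) and return the
    AIC-minimizing fit; the (lam, aic, df) path is attached to the result.

    A single unpenalized pilot fit supplies both the adaptive penalty
    weights and the warm start for the smallest grid value; subsequent
    grid values are warm-started pathwise in increasing order.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    if (lambda_grid < 0).any():
        raise ValueError("tuning parameters must be non-negative")
    opts = opts or FitOptions()
    if Z is None:
        Z = precompute_design(G, basis)
    J, K, I, T = Z.shape
    mask = structural_zero_mask(G)
    warm = None
    if (lambda_grid != 0).any():
        pilot = _fit_uv(Y, Z, np.zeros(J), np.ones((J, I, K)), mask, opts)
        warm = (pilot.u, pilot.v)
        if omega is None:
            omega = _weights_from_pilot(pilot.u, pilot.v, mask)
    elif omega is None:
        omega = np.where(mask[:, :, None], np.inf, np.ones((J, I, K)))
    best: ModelFit | None = None
    path = []
    for lam in np.sort(lambda_grid):
        m = fit(Y, G, basis, lam=lam, omega=omega, opts=opts, mask=mask, warm=warm, Z=Z)
        warm = (m.u, m.v)
        path.append((float(lam), m.aic, m.df))
        if best is None or m.aic < best.aic:
            best = m
    best.tuning_path = path
    return best


def predict(fit_: ModelFit, G: ExposureTensor, basis: SplineBasis | None = None) -> np.ndarray:
    """Model mean sum_j w[j] theta[j, i] sum_d f[j, d] G[j, d, i, t]."""
    J, D, I, T = G.G.shape
    if fit_.theta.shape[0] != J or fit_.theta.shape[1] != I or fit_.f.shape[1] != D:
        raise ValueError(
            f"fit dims (J={fit_.theta.shape[0]}, I={fit_.theta.shape[1]}, "
            f"D={fit_.f.shape[1]}) do not match G {G.G.shape}"
        )
    return np.einsum("j,ji,jd,jdit->it", fit_.w, fit_.theta, fit_.f, G.G)


def source_productivity(fit_: ModelFit) -> np.ndarray:
    """Per-source annual production index w (response scale)."""
    return fit_.w.copy()
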