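"""Uncertainty quantification: residual bootstrap, structural-change
permutation test, and changepoint estimation.

The bootstrap resamples centered fit residuals, refits with the original
tuning parameter and adaptive weights held fixed, and summarizes the
replicate distribution of each normalized parameter by its probability of
being exactly zero and a 90% interval (percentile, with the lower end
pinned at zero when the zero-probability reaches 5%).

The permutation test probes for a change in the source-sink parameters at
a split year t0: the statistic is the sum of the two per-period AICs, and
year labels are permuted jointly across the response and the exposure
covariates.  Small p-values indicate change (lower tail of the statistic);
see the note in ``permutation_test`` on the tail direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .basis import SplineBasis
from .data_model import AbundanceMatrix, ExposureTensor
from .estimation import FitOptions, ModelFit, fit, predict, tune

logger = logging.getLogger(__name__)

PI0_PIN_THRESHOLD = 0.05  # zero-probability at/above which the CI lower end pins to 0


@dataclass
class BootstrapResult:
    B: int
    seed: int
    w_pi0: np.ndarray          # (J,)
    w_ci: np.ndarray           # (J, 2)
    theta_pi0: np.ndarray      # (J, I)
    theta_ci: np.ndarray       # (J, I, 2)
    f_lo: np.ndarray           # (J, D) point-wise 5th percentile of curves
    f_hi: np.ndarray           # (J, D) point-wise 95th percentile
    n_dropped: int = 0
    draws: dict = field(default_factory=dict)  # optional replicate arrays


@dataclass
class PermutationResult:
    t0: int
    observed_stat: float
    permuted_stats: np.ndarray
    p_value: float
    B: int
    seed: int


@dataclass
class ChangepointResult:
    year: int
    profile: list  # (candidate year, AIC_pre + AIC_post)


def _interval(draws: np.ndarray, pi0: float) -> tuple[float, float]:
    """90% interval: [0, q95) when pi0 >= threshold, else (q05, q95)."""
    q05, q95 = np.percentile(draws, [5, 95])
    if pi0 >= PI0_PIN_THRESHOLD:
        return 0.0, float(q95)
    return float(q05), float(q95)


def residual_bootstrap(
    fit_: ModelFit,
    Y: AbundanceMatrix,
    G: ExposureTensor,
    basis: SplineBasis,
    B: int = 400,
    seed: int = 0,
    opts: FitOptions | None = None,
    keep_draws: bool = False,
) -> BootstrapResult:
    """Residual bootstrap of the penalized fit (lambda, omega held fixed)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    opts = opts or FitOptions(seed=seed)
    yhat = predict(fit_, G)
    obs = Y.observed
    resid = (Y.y - yhat)[obs]
    resid = resid - resid.mean()
    rng = np.random.default_rng(seed)
    from .estimation import precompute_design

    Z = precompute_design(G, basis)

    J, I = fit_.theta.shape
    D = fit_.f.shape[1]
    ws, thetas, fs = [], [], []
    n_dropped = 0
    for _ in range(B):
        e_star = rng.choice(resid, size=resid.size, replace=True)
        y_star = Y.y.copy()
        y_star[obs] = yhat[obs] + e_star
        Y_star = AbundanceMatrix(
            y=y_star, n_obs=Y.n_obs, years=list(Y.years), mask=Y.mask
        )
        m = fit(
            Y_star, G, basis, lam=fit_.lam, omega=fit_.omega, opts=opts,
            mask=fit_.fixed_zero_mask, warm=(fit_.u, fit_.v), Z=Z,
        )
        if not m.converged:
            n_dropped += 1
            continue
        ws.append(m.w)
        thetas.append(m.theta)
        fs.append(m.f)
    if n_dropped > 0.1 * B:
        logger.warning("residual_bootstrap: %d/%d replicates dropped", n_dropped, B)
    if not ws:
        raise RuntimeError("all bootstrap replicates failed to converge")
    W = np.asarray(ws)        # (B', J)
    TH = np.asarray(thetas)   # (B', J, I)
    F = np.asarray(fs)        # (B', J, D)

    w_pi0 = (W == 0).mean(axis=0)
    theta_pi0 = (TH == 0).mean(axis=0)
    w_ci = np.array([_interval(W[:, j], w_pi0[j]) for j in range(J)])
    theta_ci = np.array(
        [[_interval(TH[:, j, i], theta_pi0[j, i]) for i in range(I)] for j in range(J)]
    )
    f_lo = np.percentile(F, 5, axis=0)
    f_hi = np.percentile(F, 95, axis=0)
    draws = {"w": W, "theta": TH, "f": F} if keep_draws else {}
    return BootstrapResult(
        B=B, seed=seed, w_pi0=w_pi0, w_ci=w_ci, theta_pi0=theta_pi0,
        theta_ci=theta_ci, f_lo=f_lo, f_hi=f_hi, n_dropped=n_dropped, draws=draws,
    )


def _slice_years(
    Y: AbundanceMatrix, G: ExposureTensor, idx: np.ndarray
) -> tuple[AbundanceMatrix, ExposureTensor]:
    years = [Y.years[t] for t in idx]
    Ys = AbundanceMatrix(
        y=Y.y[:, idx], n_obs=Y.n_obs[:, idx], years=years, mask=Y.mask[:, idx]
    )
    Gs = ExposureTensor(G=G.G[:, :, :, idx], years=years)
    return Ys, Gs


def _two_period_stat(
    Y: AbundanceMatrix,
    G: ExposureTensor,
    basis: SplineBasis,
    n_pre: int,
    order: np.ndarray,
    lambda_grid: np.ndarray,
    opts: FitOptions,
    Z: np.ndarray | None = None,
) -> float:
    """AIC(fit on first n_pre year-slices of `order`) + AIC(fit on the rest),
    each period tuned independently over the grid."""
    pre, post = order[:n_pre], order[n_pre:]
    stat = 0.0
    for idx in (pre, post):
        sel = np.sort(idx)
        Ys, Gs = _slice_years(Y, G, sel)
        m = tune(Ys, Gs, basis, lambda_grid, opts=opts,
                 Z=None if Z is None else Z[:, :, :, sel])
        stat += m.aic
    return stat


def permutation_test(
    Y: AbundanceMatrix,
    G: ExposureTensor,
    basis: SplineBasis,
    t0: int,
    B: int = 500,
    seed: int = 0,
    lambda_grid: np.ndarray | float = 0.0,
    min_years: int = 4,
    opts: FitOptions | None = None,
) -> PermutationResult:
    """Permutation test for a structural change at split year ``t0``.

    Whole year-slices of (Y, G) are exchanged, preserving within-year
    spatial structure; each permuted dataset is re-split at the same
    pre/post sizes and both periods refit.  The p-value is the lower-tail
    fraction (1 + #{permuted <= observed}) / (B + 1): a strong change makes
    the observed two-period AIC sum unusually small, so small p indicates
    change.  (A literal upper-tail reading of the test description would
    invert this; the lower tail is the direction under which the observed
    split is favored when the dynamics genuinely differ.)
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    opts = opts or FitOptions(seed=seed)
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    years = np.asarray(Y.years)
    n_pre = int((years <= t0).sum())
    n_post = len(years) - n_pre
    if n_pre < min_years or n_post < min_years:
        raise ValueError(
            f"split at {t0} leaves {n_pre}/{n_post} years; need >= {min_years} each"
        )
    from .estimation import precompute_design

    Z = precompute_design(G, basis)
    ident = np.arange(len(years))
    observed = _two_period_stat(Y, G, basis, n_pre, ident, lambda_grid, opts, Z=Z)
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    for b in range(B):
        perm = rng.permutation(len(years))
        stats[b] = _two_period_stat(Y, G, basis, n_pre, perm, lambda_grid, opts, Z=Z)
    p = (1.0 + float((stats <= observed).sum())) / (B + 1.0)
    return PermutationResult(
        t0=t0, observed_stat=observed, permuted_stats=stats, p_value=p, B=B, seed=seed
    )


def estimate_changepoint(
    Y: AbundanceMatrix,
    G: ExposureTensor,
    basis: SplineBasis,
    candidates: list[int],
    min_years: int = 4,
    lambda_grid: np.ndarray | float = 0.0,
    opts: FitOptions | None = None,
) -> ChangepointResult:
    """Changepoint = candidate year minimizing AIC_pre + AIC_post, subject
    to at least ``min_years`` years in both periods."""
    opts = opts or FitOptions()
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    years = np.asarray(Y.years)
    ident = np.arange(len(years))
    profile = []
    for t0 in candidates:
        n_pre = int((years <= t0).sum())
        if n_pre < min_years or len(years) - n_pre < min_years:
            continue
        stat = _two_period_stat(Y, G, basis, n_pre, ident, lambda_grid, opts)
        profile.append((int(t0), float(stat)))
    if not profile:
        raise ValueError("no admissible changepoint candidates")
    best = min(profile, key=lambda x: x[1])
    return ChangepointResult(year=best[0], profile=profile)
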