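"""Percentile-bootstrap inference for the mediated effect.

Subjects (entire rows: exposure, mediator, full event sequence) are
resampled with replacement; the mediation model is refit on each resample
and the 95% asymmetric confidence limits are the empirical 2.5th and
97.5th quantiles of the resampled estimates.  The effect is declared
significant when the interval excludes zero.

Two refitting engines produce identical draws from the same resample
indices: a reference loop that calls :func:`dtsmed.estimators.fit_dtsm`
per resample, and a vectorized engine that runs all Newton iterations for
every resample simultaneously (the constant-baseline hazard likelihood
collapses to one binomial observation per subject, so each resample is a
three-parameter logistic fit on ``n`` rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit

from .estimators import SEPARATION_BOUND, fit_dtsm
from .simulator import SimulatedDataset, risk_summaries

__all__ = [
    "BootstrapResult",
    "bootstrap_resample",
    "percentile_bootstrap_ci",
    "bootstrap_mediation",
    "percentile_interval",
]

#: Fraction of failed resamples beyond which inference is flagged unreliable.
MAX_FAILURE_FRACTION = 0.20


@dataclass
class BootstrapResult:
    """Percentile-bootstrap confidence limits for one mediated-effect statistic."""

    estimate: float
    lower: float
    upper: float
    n_draws: int
    n_failed: int
    significant: bool
    alpha: float
    statistic: str = "ab"
    unreliable: bool = False
    #: Quantile convention applied to the stored draws (numpy ``method=``).
    quantile_method: str = "linear"
    draws: Optional[np.ndarray] = field(default=None, repr=False)


def percentile_interval(draws: np.ndarray, alpha: float) -> tuple[float, float]:
    """Asymmetric confidence limits: the alpha/2 and 1-alpha/2 empirical
    quantiles of the bootstrap draws (order statistics with linear
    interpolation).  A zero-variance set of draws collapses to a point."""
    draws = np.asarray(draws, float)
    if draws.size == 0:
        return float("nan"), float("nan")
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi)


def bootstrap_resample(
    data: SimulatedDataset, rng: np.random.Generator
) -> SimulatedDataset:
    """One nonparametric resample of subjects, with replacement, of size n."""
    idx = rng.integers(0, data.n, size=data.n)
    return SimulatedDataset(
        x=np.asarray(data.x)[idx],
        m=np.asarray(data.m)[idx],
        events=np.asarray(data.events)[idx],
        params=data.params,
    )


def _batched_constant_fit(
    x: np.ndarray,
    m: np.ndarray,
    trials: np.ndarray,
    successes: np.ndarray,
    idx: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton MLE of (beta02, c', b) for every resample simultaneously.

    ``idx`` is a ``(B, n)`` matrix of subject indices.  Returns the ``(B, 3)``
    coefficient array and a converged mask; resamples whose coefficients
    leave the separation bound or fail to converge are masked out.
    """
    xb = x[idx].astype(float)  # (B, n)
    mb = m[idx].astype(float)
    tb = trials[idx].astype(float)
    db = successes[idx].astype(float)
    B = idx.shape[0]

    beta = np.zeros((B, 3))
    rate = db.sum(axis=1) / tb.sum(axis=1)
    rate = np.clip(rate, 1e-12, 1 - 1e-12)
    beta[:, 0] = np.log(rate / (1.0 - rate))

    active = np.ones(B, dtype=bool)
    converged = np.zeros(B, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = beta[:, [0]] + beta[:, [1]] * xb + beta[:, [2]] * mb
        mu = expit(eta)
        r = db - tb * mu  # (B, n) score residuals
        s0 = r.sum(axis=1)
        s1 = (xb * r).sum(axis=1)
        s2 = (mb * r).sum(axis=1)
        score = np.stack([s0, s1, s2], axis=1)
        newly = np.abs(score).max(axis=1) <= tol
        converged |= newly & active
        active &= ~newly
        if not active.any():
            break
        w = tb * mu * (1.0 - mu)
        h00 = w.sum(axis=1)
        h01 = (w * xb).sum(axis=1)
        h02 = (w * mb).sum(axis=1)
        h11 = (w * xb * xb).sum(axis=1)
        h12 = (w * xb * mb).sum(axis=1)
        h22 = (w * mb * mb).sum(axis=1)
        H = np.empty((B, 3, 3))
        H[:, 0, 0] = h00
        H[:, 0, 1] = H[:, 1, 0] = h01
        H[:, 0, 2] = H[:, 2, 0] = h02
        H[:, 1, 1] = h11
        H[:, 1, 2] = H[:, 2, 1] = h12
        H[:, 2, 2] = h22
        try:
            step = np.linalg.solve(H[active], score[active][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            # fall back to per-resample solves; singular ones take a zero
            # step here and are deactivated below
            act_idx = np.flatnonzero(active)
            step = np.zeros((act_idx.size, 3))
            singular = np.zeros(act_idx.size, dtype=bool)
            for k, b_i in enumerate(act_idx):
                try:
                    step[k] = np.linalg.solve(H[b_i], score[b_i])
                except np.linalg.LinAlgError:
                    singular[k] = True
            active[act_idx[singular]] = False
            step = step[~singular]
        # damp very large steps instead of halving per resample
        norms = np.linalg.norm(step, axis=1)
        scale = np.where(norms > 5.0, 5.0 / norms, 1.0)
        beta[active] += step * scale[:, None]
        blown = np.abs(beta).max(axis=1) > SEPARATION_BOUND
        active &= ~blown
    bad = ~np.isfinite(beta).all(axis=1)
    converged &= ~bad
    return beta, converged


def _batched_mediator_fit(
    x: np.ndarray, m: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS slope/intercept/residual SD for every resample; flags constant-x."""
    xb = x[idx].astype(float)
    mb = m[idx].astype(float)
    n = idx.shape[1]
    xbar = xb.mean(axis=1, keepdims=True)
    mbar = mb.mean(axis=1, keepdims=True)
    sxx = ((xb - xbar) ** 2).sum(axis=1)
    ok = sxx > 0
    sxx_safe = np.where(ok, sxx, 1.0)
    a = ((xb - xbar) * (mb - mbar)).sum(axis=1) / sxx_safe
    b0 = mbar[:, 0] - a * xbar[:, 0]
    resid = mb - b0[:, None] - a[:, None] * xb
    sigma = np.sqrt((resid**2).sum(axis=1) / max(n - 2, 1))
    return a, b0, sigma, ok


def _quadrature_acme(
    a: np.ndarray,
    beta01: np.ndarray,
    sigma: np.ndarray,
    beta02: np.ndarray,
    cprime: np.ndarray,
    b: np.ndarray,
    t: int = 1,
    n_nodes: int = 64,
) -> np.ndarray:
    """Vectorized Gauss–Hermite ACME over resamples (logit scale)."""
    z, w = hermegauss(n_nodes)
    wn = w / w.sum()
    # E[eta(t, M(x))] = beta02 + cprime*t + b * sum_k wn_k (mu_x + sigma z_k)
    mz = sigma[:, None] * z[None, :]
    e1 = beta02 + cprime * t + b * (((beta01 + a)[:, None] + mz) @ wn)
    e0 = beta02 + cprime * t + b * ((beta01[:, None] + mz) @ wn)
    return e1 - e0


def bootstrap_mediation(
    data: SimulatedDataset,
    n_draws: int = 1000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    engine: str = "vectorized",
    return_draws: bool = False,
    base_fit=None,
) -> dict[str, BootstrapResult]:
    """Percentile-bootstrap intervals for ``ab`` and the ACME from shared resamples.

    Every resample is refit once; both statistics are read off the same
    refit, mirroring how the two estimators are compared replication by
    replication.  Non-converged refits are dropped and counted in
    ``n_failed``; when more than 20% fail the result is flagged unreliable.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if rng is None:
        raise ValueError("an explicit rng is required for reproducibility")
    if base_fit is None:
        base_fit = fit_dtsm(data)
    if not base_fit.converged:
        raise ValueError("base fit did not converge; bootstrap not run")

    n = data.n
    idx = rng.integers(0, n, size=(n_draws, n))

    if engine == "vectorized":
        x = np.asarray(data.x)
        m = np.asarray(data.m)
        trials, successes = risk_summaries(data.events)
        beta, hz_ok = _batched_constant_fit(x, m, trials, successes, idx)
        a, b0, sigma, med_ok = _batched_mediator_fit(x, m, idx)
        ok = hz_ok & med_ok
        ab = a * beta[:, 2]
        acme = _quadrature_acme(a, b0, sigma, beta[:, 0], beta[:, 1], beta[:, 2])
    elif engine == "loop":
        ab = np.full(n_draws, np.nan)
        acme = np.full(n_draws, np.nan)
        ok = np.zeros(n_draws, dtype=bool)
        for r in range(n_draws):
            sample = SimulatedDataset(
                x=np.asarray(data.x)[idx[r]],
                m=np.asarray(data.m)[idx[r]],
                events=np.asarray(data.events)[idx[r]],
                params=data.params,
            )
            try:
                fit = fit_dtsm(sample, validate=False)
            except ValueError:
                continue
            if fit.converged:
                ok[r] = True
                ab[r] = fit.ab_hat
                acme[r] = fit.acme_hat
    else:
        raise ValueError("engine must be 'vectorized' or 'loop'")

    n_failed = int(n_draws - ok.sum())
    unreliable = n_failed > MAX_FAILURE_FRACTION * n_draws

    results: dict[str, BootstrapResult] = {}
    for name, draws, estimate in (
        ("ab", ab, base_fit.ab_hat),
        ("acme", acme, base_fit.acme_hat),
    ):
        good = np.asarray(draws)[ok]
        lower, upper = percentile_interval(good, alpha)
        significant = bool(good.size) and bool(0.0 < lower or 0.0 > upper)
        results[name] = BootstrapResult(
            estimate=float(estimate),
            lower=float(lower),
            upper=float(upper),
            n_draws=n_draws,
            n_failed=n_failed,
            significant=significant,
            alpha=alpha,
            statistic=name,
            unreliable=unreliable,
            draws=good if return_draws else None,
        )
    return results


def percentile_bootstrap_ci(
    data: SimulatedDataset,
    n_draws: int = 1000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    statistic: str = "ab",
    engine: str = "vectorized",
    return_draws: bool = False,
) -> BootstrapResult:
    """Percentile-bootstrap CI for one statistic (``"ab"`` or ``"acme"``)."""
    if statistic not in ("ab", "acme"):
        raise ValueError("statistic must be 'ab' or 'acme'")
    return bootstrap_mediation(
        data, n_draws=n_draws, alpha=alpha, rng=rng, engine=engine,
        return_draws=return_draws,
    )[statistic]
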