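"""Maximum-likelihood estimation of the discrete-time survival mediation model.

Two fits are combined: an ordinary least-squares regression of the mediator
on the exposure, and a logistic regression of the person-period event
indicators on exposure and mediator under proportional hazard odds.  The
mediated effect is reported two ways that coincide under this model: the
product of coefficients ``a*b`` and the average causal mediation effect
(ACME) obtained by integrating the fitted linear predictor over the two
counterfactual mediator distributions.

Subjects contribute one Bernoulli likelihood term per interval they enter
event-free; post-event (missing) intervals contribute nothing, which under
administrative, non-informative censoring is the full-information maximum
likelihood treatment of the censored event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit

from .simulator import MISSING, SimulatedDataset, risk_summaries

__all__ = [
    "FitResult",
    "expand_person_period",
    "fit_mediator_model",
    "fit_hazard_model",
    "product_of_coefficients",
    "acme_mediation_formula",
    "fit_dtsm",
    "newton_logistic",
]

#: Convergence: max absolute score component at the solution.
SCORE_TOL = 1e-8
#: Alternative convergence: Newton step norm below this.
STEP_TOL = 1e-10
MAX_ITER = 100
#: |coefficient| beyond which a non-converged fit is flagged as separated.
SEPARATION_BOUND = 15.0


@dataclass
class FitResult:
    """Joint fit of the mediator and hazard models plus mediated effects."""

    a_hat: float
    beta01_hat: float
    sigma_hat: float
    b_hat: float
    cprime_hat: float
    beta02_hat: np.ndarray  # scalar array (constant) or length-J (per interval)
    converged: bool
    n_subjects: int
    n_person_periods: int
    acme_hat: Optional[float] = None
    se_a: Optional[float] = None
    se_b: Optional[float] = None
    se_cprime: Optional[float] = None
    loglik: Optional[float] = None
    n_iter: Optional[int] = None
    message: str = ""
    loglik_path: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def ab_hat(self) -> float:
        """Product-of-coefficients mediated effect, exactly ``a_hat * b_hat``."""
        return self.a_hat * self.b_hat


def expand_person_period(data: SimulatedDataset) -> pd.DataFrame:
    """Long-format person-period table: one row per subject-interval at risk.

    Columns are ``id, j, event, x, m`` with intervals ``j`` starting at 1.
    Missing (post-event) entries produce no rows, so each subject
    contributes ``min(first event interval, J)`` rows and ``event = 1``
    appears only in a subject's final row.
    """
    data.validate()
    trials, d = risk_summaries(data.events)
    n = data.n
    ids = np.repeat(np.arange(n), trials)
    j = np.concatenate([np.arange(1, t + 1) for t in trials])
    event = np.zeros(trials.sum(), dtype=np.int8)
    last = np.cumsum(trials) - 1
    event[last[d == 1]] = 1
    return pd.DataFrame(
        {
            "id": ids,
            "j": j,
            "event": event,
            "x": np.repeat(np.asarray(data.x, dtype=np.int8), trials),
            "m": np.repeat(np.asarray(data.m, dtype=float), trials),
        }
    )


def fit_mediator_model(data) -> tuple[float, float, float]:
    """OLS fit of ``m = beta01 + a x + eps``.

    Accepts a :class:`SimulatedDataset` or an ``(x, m)`` pair.  Returns
    ``(a_hat, beta01_hat, sigma_hat)`` where ``sigma_hat`` is the residual
    standard deviation (denominator ``n - 2``).
    """
    if isinstance(data, SimulatedDataset):
        x, m = np.asarray(data.x, float), np.asarray(data.m, float)
    else:
        x, m = (np.asarray(v, float) for v in data)
    if np.all(x == x[0]):
        raise ValueError("exposure has no variation; mediator slope not identified")
    xbar, mbar = x.mean(), m.mean()
    sxx = np.sum((x - xbar) ** 2)
    a_hat = float(np.sum((x - xbar) * (m - mbar)) / sxx)
    beta01_hat = float(mbar - a_hat * xbar)
    resid = m - beta01_hat - a_hat * x
    n = x.shape[0]
    dof = max(n - 2, 1)
    sigma_hat = float(np.sqrt(np.sum(resid**2) / dof))
    return a_hat, beta01_hat, sigma_hat


def newton_logistic(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    *,
    tol: float = SCORE_TOL,
    step_tol: float = STEP_TOL,
    max_iter: int = MAX_ITER,
) -> dict:
    """Newton–Raphson MLE for binomial-logit data with step halving.

    Maximizes ``sum_i [ y_i * eta_i - t_i * log(1 + exp(eta_i)) ]`` over
    ``beta`` with ``eta = X @ beta``.  Step halving enforces a non-decreasing
    log-likelihood across iterations.  Separation is flagged when the
    optimizer fails to converge while a coefficient has drifted beyond
    ``SEPARATION_BOUND``.
    """
    X = np.asarray(X, float)
    y = np.asarray(successes, float)
    t = np.asarray(trials, float)
    n, p = X.shape

    def loglik(beta: np.ndarray) -> float:
        eta = X @ beta
        # -log(1+exp(eta)) computed stably
        return float(y @ eta - t @ np.logaddexp(0.0, eta))

    beta = np.zeros(p)
    # intercept warm start at the pooled event rate keeps early steps small
    rate = y.sum() / t.sum()
    if 0.0 < rate < 1.0:
        beta[0] = np.log(rate / (1.0 - rate))

    ll = loglik(beta)
    path = [ll]
    converged = False
    message = "max iterations reached"
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (y - t * mu)
        if np.max(np.abs(score)) <= tol:
            converged = True
            message = "score within tolerance"
            break
        w = t * mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # halve until the log-likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        ll = max(ll, ll_new)
        path.append(ll)
        if np.linalg.norm(factor * step) <= step_tol:
            converged = np.max(np.abs(X.T @ (y - t * expit(X @ beta)))) <= 1e-4
            message = "step below tolerance"
            break
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            message = "coefficient diverged (possible separation)"
            break

    separated = (not converged) and np.max(np.abs(beta)) > SEPARATION_BOUND
    if separated:
        message = "separation detected: a coefficient diverged"

    cov = None
    if converged:
        mu = expit(X @ beta)
        w = t * mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
    return {
        "beta": beta,
        "converged": converged,
        "separated": separated,
        "loglik": ll,
        "loglik_path": np.asarray(path),
        "cov": cov,
        "n_iter": it,
        "message": message,
    }


def _hazard_design(table: pd.DataFrame, baseline: str):
    """Design matrix, successes and trials for the hazard logistic fit.

    With a constant baseline and time-invariant covariates the person-period
    rows of a subject share one linear predictor, so they collapse to a
    single binomial observation (intervals at risk, event count); the
    likelihood is identical to the row-level one.  Per-interval baselines
    keep the rows and add one intercept per interval.
    """
    if baseline == "constant":
        grouped = table.groupby("id", sort=True).agg(
            trials=("event", "size"),
            successes=("event", "sum"),
            x=("x", "first"),
            m=("m", "first"),
        )
        X = np.column_stack(
            [
                np.ones(len(grouped)),
                grouped["x"].to_numpy(float),
                grouped["m"].to_numpy(float),
            ]
        )
        return X, grouped["successes"].to_numpy(float), grouped["trials"].to_numpy(float)
    if baseline == "per-interval":
        js = np.sort(table["j"].unique())
        dummies = (table["j"].to_numpy()[:, None] == js[None, :]).astype(float)
        X = np.column_stack(
            [dummies, table["x"].to_numpy(float), table["m"].to_numpy(float)]
        )
        return X, table["event"].to_numpy(float), np.ones(len(table))
    raise ValueError("baseline must be 'constant' or 'per-interval'")


def fit_hazard_model(table: pd.DataFrame, baseline: str = "constant") -> dict:
    """Fit the discrete-time hazard logistic model on a person-period table.

    Returns a dict with ``b_hat`` (mediator log-odds coefficient),
    ``cprime_hat`` (exposure log-odds coefficient), ``beta02_hat``
    (intercept, or per-interval intercepts), convergence information and
    asymptotic standard errors.
    """
    if len(table) == 0:
        raise ValueError("person-period table is empty")
    events = table["event"].to_numpy()
    if events.sum() == 0 or events.sum() == len(events):
        raise ValueError("hazard model needs at least one event and one non-event")

    X, y, t = _hazard_design(table, baseline)
    res = newton_logistic(X, y, t)
    k = X.shape[1] - 2  # number of intercepts
    beta = res["beta"]
    cov = res["cov"]
    se = np.sqrt(np.diag(cov)) if cov is not None else np.full(X.shape[1], np.nan)
    return {
        "b_hat": float(beta[k + 1]),
        "cprime_hat": float(beta[k]),
        "beta02_hat": np.atleast_1d(beta[:k]),
        "converged": bool(res["converged"]),
        "separated": bool(res["separated"]),
        "se_b": float(se[k + 1]),
        "se_cprime": float(se[k]),
        "loglik": res["loglik"],
        "loglik_path": res["loglik_path"],
        "n_iter": res["n_iter"],
        "message": res["message"],
    }


def product_of_coefficients(a_hat: float, b_hat: float) -> float:
    """Mediated effect as the product of the two path coefficients."""
    if not (np.isfinite(a_hat) and np.isfinite(b_hat)):
        raise ValueError("path coefficients must be finite")
    return a_hat * b_hat


def acme_mediation_formula(
    fit: FitResult,
    t: int = 1,
    integration: str = "quadrature",
    n_nodes: int = 64,
    n_draws: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Average causal mediation effect on the logit (linear-predictor) scale.

    Computes ``E[eta(t, M(1))] - E[eta(t, M(0))]`` where ``M(x)`` is normal
    with mean ``beta01_hat + a_hat * x`` and SD ``sigma_hat``, and ``eta``
    is the fitted logit-hazard linear predictor held at exposure ``t``.
    Under the linear mediator model and logit hazard with no exposure ×
    mediator interaction this equals ``a_hat * b_hat`` for either ``t``.

    ``integration`` is ``"quadrature"`` (Gauss–Hermite, default) or
    ``"monte-carlo"`` (requires ``rng``).
    """
    if not fit.converged:
        raise ValueError("ACME requires a converged hazard-model fit")
    if t not in (0, 1):
        raise ValueError("t must be 0 or 1")
    beta02 = float(np.mean(fit.beta02_hat))
    mu1 = fit.beta01_hat + fit.a_hat * 1.0
    mu0 = fit.beta01_hat
    sd = fit.sigma_hat

    def mean_eta(mu: float) -> float:
        if integration == "quadrature":
            z, w = hermegauss(n_nodes)  # weights for exp(-z^2/2), sum = sqrt(2*pi)
            mvals = mu + sd * z
            eta = beta02 + fit.cprime_hat * t + fit.b_hat * mvals
            return float((w @ eta) / w.sum())
        if integration == "monte-carlo":
            if rng is None:
                raise ValueError("monte-carlo integration requires rng")
            mvals = rng.normal(mu, sd, size=n_draws)
            eta = beta02 + fit.cprime_hat * t + fit.b_hat * mvals
            return float(eta.mean())
        raise ValueError("integration must be 'quadrature' or 'monte-carlo'")

    return mean_eta(mu1) - mean_eta(mu0)


def fit_dtsm(
    data: SimulatedDataset,
    baseline: str = "constant",
    compute_acme: bool = True,
    validate: bool = True,
) -> FitResult:
    """Fit both component models and assemble the mediated-effect estimates.

    Convergence failures of the hazard model (e.g. separation) yield a
    ``FitResult`` with ``converged = False`` rather than an exception.
    """
    if validate:
        data.validate()
    a_hat, beta01_hat, sigma_hat = fit_mediator_model(data)
    se_a = sigma_hat / np.sqrt(
        np.sum((np.asarray(data.x, float) - np.mean(data.x)) ** 2)
    )
    if baseline == "constant":
        # the person-period rows of a subject share one linear predictor,
        # so the likelihood collapses to one binomial term per subject and
        # the long-format expansion can be skipped
        trials, successes = risk_summaries(data.events)
        if successes.sum() == 0 or (successes == trials).all():
            raise ValueError(
                "hazard model needs at least one event and one non-event"
            )
        X = np.column_stack(
            [np.ones(data.n), np.asarray(data.x, float), np.asarray(data.m, float)]
        )
        res = newton_logistic(X, successes.astype(float), trials.astype(float))
        se = (
            np.sqrt(np.diag(res["cov"]))
            if res["cov"] is not None
            else np.full(3, np.nan)
        )
        hz = {
            "b_hat": float(res["beta"][2]),
            "cprime_hat": float(res["beta"][1]),
            "beta02_hat": np.atleast_1d(res["beta"][0]),
            "converged": bool(res["converged"]),
            "se_b": float(se[2]),
            "se_cprime": float(se[1]),
            "loglik": res["loglik"],
            "loglik_path": res["loglik_path"],
            "n_iter": res["n_iter"],
            "message": res["message"],
        }
        n_pp = int(trials.sum())
    else:
        table = expand_person_period(data)
        hz = fit_hazard_model(table, baseline=baseline)
        n_pp = len(table)
    fit = FitResult(
        a_hat=a_hat,
        beta01_hat=beta01_hat,
        sigma_hat=sigma_hat,
        b_hat=hz["b_hat"],
        cprime_hat=hz["cprime_hat"],
        beta02_hat=hz["beta02_hat"],
        converged=hz["converged"],
        n_subjects=data.n,
        n_person_periods=n_pp,
        se_a=float(se_a),
        se_b=hz["se_b"],
        se_cprime=hz["se_cprime"],
        loglik=hz["loglik"],
        n_iter=hz["n_iter"],
        message=hz["message"],
        loglik_path=hz["loglik_path"],
    )
    if compute_acme and fit.converged:
        fit.acme_hat = acme_mediation_formula(fit, t=1)
    return fit
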