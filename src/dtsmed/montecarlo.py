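"""Factorial Monte Carlo evaluation of the discrete-time survival mediation model.

The study crosses six design factors — number of intervals J, sample size
n, exposure->mediator slope a, mediator->hazard odds ratio b, direct-effect
odds ratio c', and baseline hazard probability — in a full factorial, 384
cells with the default levels.  Each cell is replicated: simulate a
dataset, fit the model, optionally run the percentile bootstrap, and
aggregate accuracy (relative and raw bias), precision (MSE and its
variance + bias^2 decomposition) and rejection rates (power when the
population mediated effect is nonzero, Type I error when it is zero).
A cell-level factorial ANOVA with an eta-squared screen summarizes which
factors drive each outcome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import fit_dtsm
from .inference import bootstrap_mediation
from .simulator import MediationParams, baseline_logit, simulate_dataset

__all__ = [
    "TABLE1_FACTORS",
    "DEFAULT_REPLICATIONS",
    "DEFAULT_BOOTSTRAP_DRAWS",
    "DesignCondition",
    "ConditionSummary",
    "build_design",
    "population_ab",
    "relative_bias",
    "raw_bias",
    "mse",
    "rejection_rate",
    "run_condition",
    "run_cells",
    "summaries_frame",
    "stratified_nonnull_cells",
    "stratified_null_cells",
    "factorial_anova_eta2",
]

#: Default factor levels of the full factorial design (384 cells).
TABLE1_FACTORS: dict[str, tuple] = {
    "J": (4, 8),
    "n": (250, 500, 1000),
    "a": (0.0, 0.14, 0.39, 0.59),
    "b_or": (1.0, 1.5, 2.0, 4.0),
    "c_or": (1.0, 1.5),
    "h0": (0.05, 0.2),
}

#: Replications per cell and bootstrap draws per replication in the
#: full-scale study design.
DEFAULT_REPLICATIONS = 500
DEFAULT_BOOTSTRAP_DRAWS = 1000

FACTOR_ORDER = ("J", "n", "a", "b_or", "c_or", "h0")


@dataclass(frozen=True)
class DesignCondition:
    """One cell of the factorial design."""

    id: int
    J: int
    n: int
    a: float
    b_or: float
    c_or: float
    h0: float

    @property
    def params(self) -> MediationParams:
        """Generating parameters: beta01 = 0, sigma_m = 1, p_x = 0.5, and the
        hazard intercept set to ``logit(h0)`` at full precision."""
        return MediationParams(
            a=self.a,
            b_or=self.b_or,
            c_or=self.c_or,
            beta02=baseline_logit(self.h0),
            beta01=0.0,
            sigma_m=1.0,
            J=self.J,
            p_x=0.5,
        )

    @property
    def is_null(self) -> bool:
        """True when the population mediated effect is zero."""
        return self.a == 0.0 or self.b_or == 1.0


@dataclass
class ConditionSummary:
    """Aggregated outcomes for one design cell."""

    condition_id: int
    theta: float
    mean_estimate: float
    relative_bias: Optional[float]
    raw_bias: float
    mse: float
    variance: float
    rejection_rate_ab: Optional[float]
    rejection_rate_acme: Optional[float]
    R_completed: int
    R_failed: int


def build_design(factors: Optional[dict[str, Sequence]] = None) -> list[DesignCondition]:
    """Full Cartesian product of the factor levels, deterministic order,
    sequential ids starting at 1."""
    factors = dict(TABLE1_FACTORS if factors is None else factors)
    for name in FACTOR_ORDER:
        if name not in factors or len(factors[name]) == 0:
            raise ValueError(f"factor {name!r} needs at least one level")
    cells = []
    for i, (J, n, a, b_or, c_or, h0) in enumerate(
        itertools.product(*(factors[f] for f in FACTOR_ORDER)), start=1
    ):
        cells.append(
            DesignCondition(
                id=i, J=int(J), n=int(n), a=float(a), b_or=float(b_or),
                c_or=float(c_or), h0=float(h0),
            )
        )
    return cells


def population_ab(condition: DesignCondition) -> float:
    """Population mediated effect on the log-odds scale, ``a * ln(b_or)``."""
    return condition.a * float(np.log(condition.b_or))


def relative_bias(estimates: Iterable[float], theta: float) -> float:
    """(mean estimate - theta) / theta; undefined when theta is zero."""
    est = np.asarray(list(estimates), float)
    if est.size == 0:
        raise ValueError("no estimates supplied")
    if theta == 0.0:
        raise ValueError(
            "relative bias is undefined at theta = 0; use raw_bias instead"
        )
    return float((est.mean() - theta) / theta)


def raw_bias(estimates: Iterable[float], theta: float) -> float:
    """Unstandardized bias, mean estimate minus the population value."""
    est = np.asarray(list(estimates), float)
    if est.size == 0:
        raise ValueError("no estimates supplied")
    return float(est.mean() - theta)


def mse(estimates: Iterable[float], theta: float) -> tuple[float, float]:
    """Mean squared error about theta and the (1/R) sampling variance.

    Satisfies ``mse = variance + raw_bias**2`` exactly (both moments use
    the 1/R denominator).
    """
    est = np.asarray(list(estimates), float)
    if est.size == 0:
        raise ValueError("no estimates supplied")
    m = float(np.mean((est - theta) ** 2))
    v = float(np.mean((est - est.mean()) ** 2))
    return m, v


def rejection_rate(results: Sequence) -> float:
    """Fraction of bootstrap results whose CI excludes zero.

    Interpreted as power when the population mediated effect is nonzero and
    as Type I error when it is zero.  Accepts BootstrapResult objects or
    plain booleans.
    """
    if len(results) == 0:
        raise ValueError("no bootstrap results supplied")
    flags = [bool(getattr(r, "significant", r)) for r in results]
    return float(np.mean(flags))


def run_condition(
    condition: DesignCondition,
    R: int,
    master_seed: int,
    n_draws: int = 0,
    alpha: float = 0.05,
    engine: str = "vectorized",
    compute_acme: bool = True,
) -> tuple[pd.DataFrame, ConditionSummary]:
    """Replicate one design cell R times and aggregate the outcomes.

    Each replication simulates a dataset, fits the mediation model and —
    when ``n_draws > 0`` — runs the percentile bootstrap for both the
    product-of-coefficients and ACME statistics.  All randomness derives
    from the key ``(master_seed, condition id, replication)``, so results
    are reproducible cell by cell.  Replications whose base fit fails are
    recorded and excluded from the aggregates.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    records = []
    for r in range(1, R + 1):
        ss = np.random.SeedSequence([int(master_seed), int(condition.id), int(r)])
        ss_sim, ss_boot = ss.spawn(2)
        data = simulate_dataset(condition, ss_sim)
        rec = {
            "condition_id": condition.id,
            "rep": r,
            "converged": False,
            "a_hat": np.nan,
            "b_hat": np.nan,
            "ab_hat": np.nan,
            "acme_hat": np.nan,
            "lower": np.nan,
            "upper": np.nan,
            "significant": np.nan,
            "significant_acme": np.nan,
        }
        try:
            fit = fit_dtsm(data, compute_acme=compute_acme, validate=False)
        except ValueError:
            records.append(rec)
            continue
        rec["converged"] = fit.converged
        if fit.converged:
            rec.update(
                a_hat=fit.a_hat, b_hat=fit.b_hat, ab_hat=fit.ab_hat,
                acme_hat=fit.acme_hat,
            )
            if n_draws > 0:
                boot_rng = np.random.Generator(np.random.PCG64(ss_boot))
                res = bootstrap_mediation(
                    data, n_draws=n_draws, alpha=alpha, rng=boot_rng,
                    engine=engine, base_fit=fit,
                )
                rec.update(
                    lower=res["ab"].lower,
                    upper=res["ab"].upper,
                    significant=float(res["ab"].significant),
                    significant_acme=float(res["acme"].significant),
                )
        records.append(rec)

    df = pd.DataFrame.from_records(records)
    theta = population_ab(condition)
    good = df[df["converged"] == True]  # noqa: E712
    est = good["ab_hat"].to_numpy(float)
    R_completed = len(good)
    R_failed = R - R_completed
    if R_completed == 0:
        summary = ConditionSummary(
            condition.id, theta, np.nan, None, np.nan, np.nan, np.nan,
            None, None, 0, R_failed,
        )
        return df, summary

    mse_val, var_val = mse(est, theta)
    rej_ab = rej_acme = None
    if n_draws > 0:
        rej_ab = float(good["significant"].mean())
        rej_acme = float(good["significant_acme"].mean())
    summary = ConditionSummary(
        condition_id=condition.id,
        theta=theta,
        mean_estimate=float(est.mean()),
        relative_bias=relative_bias(est, theta) if theta != 0.0 else None,
        raw_bias=raw_bias(est, theta),
        mse=mse_val,
        variance=var_val,
        rejection_rate_ab=rej_ab,
        rejection_rate_acme=rej_acme,
        R_completed=R_completed,
        R_failed=R_failed,
    )
    return df, summary


def run_cells(
    conditions: Sequence[DesignCondition],
    R: int,
    master_seed: int,
    n_draws: int = 0,
    alpha: float = 0.05,
    engine: str = "vectorized",
    keep_records: bool = False,
    progress: Optional[callable] = None,
) -> tuple[Optional[pd.DataFrame], pd.DataFrame]:
    """Run several cells; returns (per-replication records, summary frame)."""
    summaries, frames = [], []
    for cond in conditions:
        df, summ = run_condition(
            cond, R=R, master_seed=master_seed, n_draws=n_draws,
            alpha=alpha, engine=engine,
        )
        summaries.append((cond, summ))
        if keep_records:
            frames.append(df)
        if progress is not None:
            progress(cond, summ)
    records = pd.concat(frames, ignore_index=True) if keep_records else None
    return records, summaries_frame(summaries)


def summaries_frame(summaries: Sequence[tuple[DesignCondition, ConditionSummary]]) -> pd.DataFrame:
    """Flatten (condition, summary) pairs into one tidy frame."""
    rows = []
    for cond, s in summaries:
        rows.append(
            {
                "condition_id": cond.id,
                "J": cond.J, "n": cond.n, "a": cond.a, "b_or": cond.b_or,
                "c_or": cond.c_or, "h0": cond.h0,
                "theta": s.theta,
                "mean_estimate": s.mean_estimate,
                "relative_bias": np.nan if s.relative_bias is None else s.relative_bias,
                "raw_bias": s.raw_bias,
                "mse": s.mse,
                "variance": s.variance,
                "rejection_rate_ab": np.nan if s.rejection_rate_ab is None else s.rejection_rate_ab,
                "rejection_rate_acme": np.nan if s.rejection_rate_acme is None else s.rejection_rate_acme,
                "R_completed": s.R_completed,
                "R_failed": s.R_failed,
            }
        )
    return pd.DataFrame(rows)


def stratified_nonnull_cells(
    design: Optional[Sequence[DesignCondition]] = None, per_stratum: int = 4
) -> list[DesignCondition]:
    """Deterministic stratified subsample of cells with a nonzero mediated effect.

    Strata are the 24 combinations of (J, n, c', h0); within each stratum
    ``per_stratum`` of the nine nonzero (a, b) pairs are taken, rotating the
    pair list across strata so every effect-size pair appears with near-equal
    frequency.  The default yields 96 cells covering every factor level.
    """
    design = build_design() if design is None else list(design)
    nonnull = [c for c in design if not c.is_null]
    ab_pairs = sorted({(c.a, c.b_or) for c in nonnull})
    strata: dict[tuple, list[DesignCondition]] = {}
    for c in nonnull:
        strata.setdefault((c.J, c.n, c.c_or, c.h0), []).append(c)
    chosen = []
    for s_idx, key in enumerate(sorted(strata)):
        cells = {(c.a, c.b_or): c for c in strata[key]}
        for k in range(per_stratum):
            pair = ab_pairs[(s_idx * per_stratum + k) % len(ab_pairs)]
            chosen.append(cells[pair])
    return chosen


def stratified_null_cells(
    design: Optional[Sequence[DesignCondition]] = None, k: int = 6
) -> list[DesignCondition]:
    """Deterministic sample of k >= 6 null cells spanning both baseline
    hazards and all sample sizes, alternating J, c' and the null type
    (a = 0 versus b odds ratio = 1)."""
    design = build_design() if design is None else list(design)
    null = {
        (c.J, c.n, c.a, c.b_or, c.c_or, c.h0): c for c in design if c.is_null
    }
    combos = list(itertools.product((250, 500, 1000), (0.05, 0.2)))
    chosen = []
    for i in range(max(k, 6)):
        n, h0 = combos[i % len(combos)]
        J = (4, 8)[i % 2]
        c_or = (1.0, 1.5)[(i // 2) % 2]
        if i % 2 == 0:
            a, b_or = 0.0, 2.0  # null through the a path
        else:
            a, b_or = 0.39, 1.0  # null through the b path
        chosen.append(null[(J, n, a, b_or, c_or, h0)])
    return chosen


def factorial_anova_eta2(
    cell_outcomes: pd.DataFrame,
    factors: Sequence[str],
    outcome: str,
    screen: float = 0.01,
) -> pd.DataFrame:
    """Complete sums-of-squares decomposition of cell means in a full factorial.

    With one outcome value per design cell, the balanced-design decomposition
    assigns every main effect and interaction a sum of squares via the
    inclusion-exclusion of conditional means; there is no residual, so the
    effect sums of squares add up to the total.  Returns one row per effect
    with ``ss``, ``eta2 = ss / ss_total`` and a practical-significance flag
    at the ``screen`` threshold.
    """
    df = cell_outcomes.reset_index(drop=True)
    missing = df[outcome].isna()
    if missing.any():
        raise ValueError("outcome contains missing cells")
    sizes = [df[f].nunique() for f in factors]
    if len(df) != int(np.prod(sizes)) or df.duplicated(subset=list(factors)).any():
        raise ValueError("need exactly one outcome value per factorial cell")

    y = df[outcome].to_numpy(float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    # conditional means aligned with the cell rows, for every factor subset
    cond_means: dict[frozenset, np.ndarray] = {frozenset(): np.full(len(df), grand)}
    rows = []
    for size in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, size):
            key = frozenset(subset)
            cond_means[key] = (
                df.groupby(list(subset), sort=False)[outcome].transform("mean").to_numpy()
            )
            effect = np.zeros(len(df))
            for r in range(size + 1):
                for sub in itertools.combinations(subset, r):
                    sign = (-1) ** (size - r)
                    effect += sign * cond_means[frozenset(sub)]
            ss = float(np.sum(effect**2))
            eta2 = ss / ss_total if ss_total > 0 else 0.0
            rows.append(
                {
                    "effect": ":".join(subset),
                    "order": size,
                    "ss": ss,
                    "eta2": eta2,
                    "practically_significant": eta2 >= screen,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["ss_total"] = ss_total
    return out
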