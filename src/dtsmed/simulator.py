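"""Data-generating process for discrete-time survival mediation studies.

The generator follows a two-equation structural model.  A binary exposure
``X ~ Bernoulli(p_x)`` affects a continuous mediator through a linear
regression,

    M = beta01 + a * X + sigma_m * eps,     eps ~ N(0, 1),

and the mediator and exposure jointly drive a discrete-time hazard with a
constant baseline under proportional hazard odds,

    logit Pr(event in interval j | event-free at j) = beta02 + ln(c_or)*X
                                                              + ln(b_or)*M.

Event indicators are drawn interval by interval from independent standard
logistic thresholds; once a subject experiences the event, the remaining
indicators are recoded as missing, which yields non-informative
administrative right-censoring at the end of interval ``J`` for subjects
who never experience the event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "MISSING",
    "MediationParams",
    "SimulatedDataset",
    "baseline_logit",
    "hazard_probability",
    "draw_exposure",
    "draw_mediator",
    "draw_event_history",
    "apply_missing_coding",
    "simulate_dataset",
    "risk_summaries",
]

#: Sentinel for post-event (recoded) entries of the event matrix.  Kept
#: distinct from the 0/1 outcome codes; serialized as an empty CSV cell.
MISSING: int = -1

RandomState = Union[int, np.random.SeedSequence, np.random.Generator]


def _as_seedseq(rng: RandomState) -> Optional[np.random.SeedSequence]:
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, (int, np.integer)):
        return np.random.SeedSequence(int(rng))
    return None


def _as_generator(rng: RandomState) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    ss = _as_seedseq(rng)
    if ss is None:
        raise TypeError(f"cannot interpret {rng!r} as a random stream")
    return np.random.Generator(np.random.PCG64(ss))


@dataclass(frozen=True)
class MediationParams:
    """Generating parameters of the discrete-time survival mediation model.

    Parameters
    ----------
    a : float
        Exposure -> mediator regression coefficient (raw scale).
    b_or : float
        Mediator -> hazard odds ratio per one-unit increase in M
        (``b_or = 1`` means no mediator effect on the hazard).
    c_or : float
        Exposure -> hazard odds ratio (the direct effect).
    beta02 : float
        Hazard-model intercept on the logit scale; ``expit(beta02)`` is the
        baseline hazard probability for a subject with ``X = 0, M = 0``.
    beta01 : float
        Mediator-model intercept.
    sigma_m : float
        Residual standard deviation of the mediator.
    J : int
        Number of discrete time intervals.
    p_x : float
        Exposure probability, ``X ~ Bernoulli(p_x)``.
    """

    a: float
    b_or: float
    c_or: float
    beta02: float
    beta01: float = 0.0
    sigma_m: float = 1.0
    J: int = 4
    p_x: float = 0.5

    def __post_init__(self) -> None:
        if self.b_or <= 0 or self.c_or <= 0:
            raise ValueError("b_or and c_or are odds ratios and must be > 0")
        if self.sigma_m < 0:
            raise ValueError("sigma_m must be >= 0")
        if int(self.J) != self.J or self.J < 1:
            raise ValueError("J must be a positive integer")
        if not 0.0 <= self.p_x <= 1.0:
            raise ValueError("p_x must lie in [0, 1]")

    @property
    def b_log(self) -> float:
        """Mediator effect on the log-odds scale, ``ln(b_or)``."""
        return math.log(self.b_or)

    @property
    def c_log(self) -> float:
        """Direct exposure effect on the log-odds scale, ``ln(c_or)``."""
        return math.log(self.c_or)


@dataclass
class SimulatedDataset:
    """Per-subject exposure, mediator and event-history matrix.

    ``events`` is an ``n x J`` integer matrix with entries in
    ``{0, 1, MISSING}``.  Each row contains at most one ``1``; every entry
    after the first ``1`` is ``MISSING``; rows without a ``1`` are fully
    observed (administratively censored at ``J``).
    """

    x: np.ndarray
    m: np.ndarray
    events: np.ndarray
    params: Optional[MediationParams] = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.events.shape[0]

    @property
    def J(self) -> int:
        return self.events.shape[1]

    def validate(self) -> None:
        """Raise ``ValueError`` (naming the first offending row) if any
        structural invariant is violated."""
        x = np.asarray(self.x)
        m = np.asarray(self.m)
        e = np.asarray(self.events)
        if e.ndim != 2:
            raise ValueError("events must be a 2-D matrix")
        n, J = e.shape
        if x.shape != (n,) or m.shape != (n,):
            raise ValueError("x, m and events have inconsistent lengths")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("x entries must be 0 or 1")
        if not np.isfinite(m).all():
            raise ValueError("m entries must be finite")
        valid = np.isin(e, (0, 1, MISSING))
        if not valid.all():
            row = int(np.argwhere(~valid)[0, 0])
            raise ValueError(f"row {row}: event entries must be 0, 1 or missing")
        for i in range(n):
            row = e[i]
            ones = np.flatnonzero(row == 1)
            miss = np.flatnonzero(row == MISSING)
            if ones.size > 1:
                raise ValueError(f"row {i}: more than one event indicator set")
            if ones.size == 0:
                if miss.size:
                    raise ValueError(
                        f"row {i}: missing entries without a preceding event"
                    )
            else:
                j = ones[0]
                expected = np.arange(j + 1, J)
                if miss.size != expected.size or not np.array_equal(miss, expected):
                    raise ValueError(
                        f"row {i}: entries after the first event must all be "
                        "missing and none before it"
                    )


def baseline_logit(h0: float) -> float:
    """Hazard-model intercept producing baseline hazard probability ``h0``.

    Inverse of :func:`hazard_probability` at ``x = 0, m = 0``:
    ``expit(baseline_logit(h0)) == h0``.
    """
    if not 0.0 < h0 < 1.0:
        raise ValueError("baseline hazard probability must lie in (0, 1)")
    return float(logit(h0))


def hazard_probability(x_i, m_i, params: MediationParams):
    """Conditional event probability for one interval given ``(x, m)``.

    The baseline hazard is constant across intervals, so this value applies
    to every interval the subject enters event-free.
    """
    eta = params.beta02 + params.c_log * np.asarray(x_i) + params.b_log * np.asarray(m_i)
    return expit(eta)


def draw_exposure(n: int, p_x: float, rng: RandomState) -> np.ndarray:
    """Draw ``n`` independent Bernoulli(``p_x``) exposure indicators."""
    if int(n) != n or n < 1:
        raise ValueError("n must be a positive integer")
    if not 0.0 <= p_x <= 1.0:
        raise ValueError("p_x must lie in [0, 1]")
    gen = _as_generator(rng)
    return (gen.random(int(n)) < p_x).astype(np.int8)


def draw_mediator(x: np.ndarray, params: MediationParams, rng: RandomState) -> np.ndarray:
    """Draw the mediator ``m_i = beta01 + a*x_i + sigma_m*z_i``."""
    x = np.asarray(x)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("x entries must be 0 or 1")
    gen = _as_generator(rng)
    z = gen.standard_normal(x.shape[0])
    return params.beta01 + params.a * x.astype(float) + params.sigma_m * z


def draw_event_history(
    x: np.ndarray, m: np.ndarray, params: MediationParams, rng: RandomState
) -> np.ndarray:
    """Draw the raw ``n x J`` 0/1 event matrix (before missingness coding).

    For each interval an independent standard-logistic threshold ``y_ij``
    is drawn; the indicator is 1 iff ``y_ij > -(beta02 + ln(c_or) x_i +
    ln(b_or) m_i)``, which is Bernoulli with the interval hazard
    probability.  When ``rng`` is a seed or ``SeedSequence``, each interval
    uses its own spawned sub-stream, so interval draws come from
    independent streams.
    """
    x = np.asarray(x)
    m = np.asarray(m)
    if x.shape[0] != m.shape[0]:
        raise ValueError("x and m must have the same length")
    n = x.shape[0]
    J = params.J
    thresh = -(params.beta02 + params.c_log * x.astype(float) + params.b_log * m)

    ss = _as_seedseq(rng)
    raw = np.empty((n, J), dtype=np.int8)
    if ss is not None:
        streams = [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(J)]
        for j in range(J):
            y = streams[j].logistic(size=n)
            raw[:, j] = y > thresh
    else:
        gen = _as_generator(rng)
        for j in range(J):
            y = gen.logistic(size=n)
            raw[:, j] = y > thresh
    return raw


def apply_missing_coding(raw: np.ndarray) -> np.ndarray:
    """Recode all entries after each row's first event as missing.

    Idempotent; rows without an event are returned unchanged (right-censored
    at the final interval).  Accepts matrices that already contain the
    missing sentinel.
    """
    raw = np.asarray(raw)
    if not np.isin(raw, (0, 1, MISSING)).all():
        raise ValueError("event matrix entries must be 0, 1 or missing")
    coded = raw.astype(np.int8, copy=True)
    n, J = coded.shape
    is_event = coded == 1
    has_event = is_event.any(axis=1)
    first = np.where(has_event, is_event.argmax(axis=1), J)
    after = np.arange(J)[None, :] > first[:, None]
    coded[after] = MISSING
    return coded


def simulate_dataset(
    condition, rng: RandomState, n: Optional[int] = None
) -> SimulatedDataset:
    """Generate one dataset from the full data-generating process.

    Parameters
    ----------
    condition
        Either a :class:`MediationParams` (then ``n`` is required) or any
        object exposing ``params`` and ``n`` attributes (e.g. a design
        condition from the Monte Carlo module).
    rng
        Seed, ``SeedSequence`` or ``Generator``.  Seeds and seed sequences
        are split into independent sub-streams for the exposure, the
        mediator and each event interval, making datasets reproducible from
        a ``(master seed, condition, replication)`` key alone.
    """
    if isinstance(condition, MediationParams):
        params = condition
        if n is None:
            raise ValueError("n is required when passing MediationParams directly")
    else:
        params = condition.params
        n = condition.n if n is None else n

    ss = _as_seedseq(rng)
    if ss is not None:
        s_x, s_m, s_e = ss.spawn(3)
    else:
        gen = _as_generator(rng)
        s_x = s_m = s_e = gen

    x = draw_exposure(n, params.p_x, s_x)
    m = draw_mediator(x, params, s_m)
    raw = draw_event_history(x, m, params, s_e)
    events = apply_missing_coding(raw)
    return SimulatedDataset(x=x, m=m, events=events, params=params)


def risk_summaries(events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (intervals at risk, event indicator) from the coded matrix.

    A subject contributes ``min(first event interval, J)`` risk intervals;
    with a constant baseline hazard and time-invariant covariates these two
    numbers are sufficient for the hazard-model likelihood.
    """
    e = np.asarray(events)
    n, J = e.shape
    is_event = e == 1
    d = is_event.any(axis=1)
    trials = np.where(d, is_event.argmax(axis=1) + 1, J)
    return trials.astype(np.int64), d.astype(np.int64)
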