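"""Sample-size and power calculations for the trial's hypotheses.

Time-to-event comparisons are sized in two steps, as is conventional for
log-rank/Cox analyses: first the number of *events* needed to detect a given
hazard ratio (Schoenfeld or Freedman formula), then the number of
*participants* needed to observe those events given exponential survival,
uniform accrual, a minimum follow-up period and administrative dropout.
Binary (MRD-negativity) comparisons use the normal-approximation power of the
two-sample proportion z-test, with a Monte-Carlo variant as a check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EventSizeResult",
    "BinaryPowerResult",
    "required_events",
    "event_probability",
    "required_n",
    "binary_power",
]

#: events beyond which a design is treated as unpowerable (hr too close to 1)
EVENT_CAP = 10_000_000


@dataclass(frozen=True)
class EventSizeResult:
    """Required events and participants for a time-to-event hypothesis."""

    required_events: int
    required_n_per_arm: tuple[int, ...]
    required_n_total: int
    event_prob_control: float
    event_prob_experimental: float
    dropout_inflation: float
    gsd_inflation: float
    method: str


@dataclass(frozen=True)
class BinaryPowerResult:
    """Power of a two-sample proportion comparison at a fixed per-arm n."""

    power: float
    n_per_arm: int
    p0: float
    p1: float
    alpha_two_sided: float
    test: str
    null_case: bool = False
    mc_se: float | None = None


def required_events(hr: float, alpha_two_sided: float = 0.05, power: float = 0.80,
                    method: str = "schoenfeld", gsd_inflation: float = 1.0) -> int:
    """Number of events for a log-rank test of a superiority hazard ratio.

    Schoenfeld: ``d = 4 (z_{1-a/2} + z_pow)^2 / (ln hr)^2``.
    Freedman:   ``d = ((1+hr)/(1-hr))^2 (z_{1-a/2} + z_pow)^2``.
    The result is multiplied by ``gsd_inflation`` (maximum-information
    inflation of a group-sequential plan; 1.0 for a fixed design) and rounded
    up.  Freedman exceeds Schoenfeld for hr < 1.
    """
    if not (0 < hr < 1):
        if hr >= 1:
            raise ValueError(f"no superiority effect: hr must be < 1, got {hr}")
        raise ValueError(f"hr must be in (0, 1), got {hr}")
    if not (0 < alpha_two_sided < 1 and 0 < power < 1):
        raise ValueError("alpha_two_sided and power must be in (0, 1)")
    if gsd_inflation < 1:
        raise ValueError("gsd_inflation must be >= 1")
    z = stats.norm.ppf(1 - alpha_two_sided / 2) + stats.norm.ppf(power)
    if method == "schoenfeld":
        d = 4 * z**2 / math.log(hr) ** 2
    elif method == "freedman":
        d = ((1 + hr) / (1 - hr)) ** 2 * z**2
    else:
        raise ValueError(f"unknown method {method!r}")
    d *= gsd_inflation
    if d > EVENT_CAP:
        raise ValueError(f"required events {d:.0f} exceed cap {EVENT_CAP}; "
                         "effect size too small to power")
    return math.ceil(d)


def event_probability(median_years: float, accrual_years: float,
                      min_followup_years: float) -> float:
    """P(event observed by the final analysis) for one arm.

    Assumes exponential event times with the given median, entry uniform over
    the accrual period ``A`` and analysis at ``A + F`` (so individual
    follow-up ranges from ``F`` to ``F + A``):

        ``P = 1 - (1 / (lam A)) (exp(-lam F) - exp(-lam (F + A)))``

    with ``lam = ln 2 / median``.
    """
    if median_years <= 0 or accrual_years <= 0 or min_followup_years <= 0:
        raise ValueError("median, accrual and follow-up must all be > 0")
    lam = math.log(2) / median_years
    a, f = accrual_years, min_followup_years
    # stable form: 1 - exp(-lam f) * (1 - exp(-lam a)) / (lam a); the
    # expm1 factor avoids cancellation when lam a is tiny
    g = -math.expm1(-lam * a) / (lam * a)
    return 1.0 - math.exp(-lam * f) * g


def required_n(events: int, event_prob_control: float, event_prob_experimental: float,
               dropout_prob: float = 0.0, allocation: tuple[int, int] = (1, 1),
               gsd_inflation: float = 1.0, method: str = "schoenfeld") -> EventSizeResult:
    """Participants needed for a target event count, with dropout inflation.

    The expected per-patient event probability is averaged over arms with
    allocation weights; total n is that quotient inflated by ``1/(1-dropout)``
    and rounded up to a whole multiple of the allocation ratio so the per-arm
    counts are integers in ratio.
    """
    if events < 1:
        raise ValueError("events must be >= 1")
    if not (0 <= dropout_prob < 1):
        raise ValueError("dropout_prob must be in [0, 1)")
    for p in (event_prob_control, event_prob_experimental):
        if not (0 < p <= 1):
            raise ValueError(f"event probabilities must be in (0, 1], got {p}")
    w = np.asarray(allocation, dtype=float)
    if w.size != 2 or (w <= 0).any():
        raise ValueError("allocation must be two positive weights (control, experimental)")
    probs = np.array([event_prob_control, event_prob_experimental])
    mean_prob = float((w * probs).sum() / w.sum())
    raw_total = events / mean_prob / (1.0 - dropout_prob)
    # round up to a whole block of the allocation ratio
    block = int(w.sum())
    n_blocks = math.ceil(raw_total / block)
    per_arm = tuple(int(round(n_blocks * wi)) for wi in w)
    return EventSizeResult(
        required_events=int(events),
        required_n_per_arm=per_arm,
        required_n_total=int(sum(per_arm)),
        event_prob_control=event_prob_control,
        event_prob_experimental=event_prob_experimental,
        dropout_inflation=1.0 / (1.0 - dropout_prob),
        gsd_inflation=gsd_inflation,
        method=method,
    )


def size_time_to_event(hr: float | None = None, control_median: float | None = None,
                       experimental_median: float | None = None,
                       alpha_two_sided: float = 0.05, power: float = 0.80,
                       accrual_years: float = 4.0, min_followup_years: float = 4.0,
                       dropout_prob: float = 0.05, method: str = "schoenfeld",
                       gsd_inflation: float = 1.0) -> EventSizeResult:
    """One-call sizing: events via :func:`required_events`, n via :func:`required_n`."""
    if hr is None:
        if control_median is None or experimental_median is None:
            raise ValueError("give either hr or both medians")
        hr = control_median / experimental_median
    if control_median is None or experimental_median is None:
        raise ValueError("medians are needed to convert events to participants")
    d = required_events(hr, alpha_two_sided, power, method, gsd_inflation)
    p0 = event_probability(control_median, accrual_years, min_followup_years)
    p1 = event_probability(experimental_median, accrual_years, min_followup_years)
    return required_n(d, p0, p1, dropout_prob, gsd_inflation=gsd_inflation, method=method)


def binary_power(n_per_arm: int, p0: float, p1: float, alpha_two_sided: float = 0.05,
                 test: str = "pooled_z", reps: int = 100_000,
                 seed: int | None = None) -> BinaryPowerResult:
    """Power of the two-sample proportion z-test at ``n_per_arm`` per group.

    ``pooled_z`` / ``unpooled_z`` give the normal-approximation power with the
    null variance pooled (as in the test statistic) or not; ``exact_enum``
    computes the exact power of the pooled z-test by enumerating the joint
    binomial distribution; ``exact_sim`` estimates the same quantity by Monte
    Carlo of binomial draws.  The normal approximation typically understates
    the exact power by a few parts per thousand at design-sized n.
    ``p0 == p1`` is the null case: the returned "power" is the test size,
    flagged via ``null_case``.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    for p in (p0, p1):
        if not (0 < p < 1):
            raise ValueError("p0 and p1 must be in (0, 1)")
    if not (0 < alpha_two_sided < 1):
        raise ValueError("alpha_two_sided must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha_two_sided / 2)
    n = n_per_arm
    delta = abs(p1 - p0)
    null_case = delta == 0.0
    mc_se = None
    if test in ("pooled_z", "unpooled_z"):
        sd_alt = math.sqrt(p0 * (1 - p0) + p1 * (1 - p1))
        if test == "pooled_z":
            pbar = (p0 + p1) / 2
            sd_null = math.sqrt(2 * pbar * (1 - pbar))
        else:
            sd_null = sd_alt
        # two-sided rejection probability under the alternative
        upper = stats.norm.sf((z_a * sd_null - delta * math.sqrt(n)) / sd_alt)
        lower = stats.norm.cdf((-z_a * sd_null - delta * math.sqrt(n)) / sd_alt)
        power = float(upper + lower)
    elif test == "exact_enum":
        x0 = np.arange(n + 1)
        x1 = np.arange(n + 1)
        pmf0 = stats.binom.pmf(x0, n, p0)
        pmf1 = stats.binom.pmf(x1, n, p1)
        diff = (x1[None, :] - x0[:, None]) / n
        pbar = (x0[:, None] + x1[None, :]) / (2 * n)
        var = 2 * pbar * (1 - pbar) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, diff / np.sqrt(var), 0.0)
        rej = np.abs(z) > z_a
        power = float(pmf0 @ rej @ pmf1)
    elif test == "exact_sim":
        rng = np.random.default_rng(seed)
        x0 = rng.binomial(n, p0, size=reps)
        x1 = rng.binomial(n, p1, size=reps)
        phat0, phat1 = x0 / n, x1 / n
        pbar = (x0 + x1) / (2 * n)
        var = 2 * pbar * (1 - pbar) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, (phat1 - phat0) / np.sqrt(var), 0.0)
        rej = np.abs(z) > z_a
        power = float(rej.mean())
        mc_se = float(math.sqrt(power * (1 - power) / reps))
    else:
        raise ValueError(f"unknown test {test!r}")
    return BinaryPowerResult(power=power, n_per_arm=n_per_arm, p0=p0, p1=p1,
                             alpha_two_sided=alpha_two_sided, test=test,
                             null_case=null_case, mc_se=mc_se)
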