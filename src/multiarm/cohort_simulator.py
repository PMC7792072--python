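"""Synthetic participants with the statistical structure the design assumes.

Entry times follow a homogeneous Poisson process at the configured accrual
rate; stratification-factor levels are drawn independently per factor;
progression-free survival is exponential with each arm's median; dropout is
an independent exponential censoring process calibrated so the probability
of dropping out within a configured horizon equals the design's dropout
allowance; MRD negativity at 24 months is Bernoulli with the arm's assumed
rate, independent of the survival time.

Randomness is split into named substreams (entry, profiles, assignment,
outcomes) spawned deterministically from a master seed.  Outcome uniforms
are indexed by patient position, so the latent outcome of patient *i* does
not change when arms are added or allocation differs — only the inverse
transform applied to it does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .design_model import Arm

__all__ = ["Patient", "draw_profile", "draw_profiles", "draw_outcomes",
           "dropout_rate", "outcome_streams"]

# substream labels appended to the master seed when spawning generators
STREAM_ENTRY, STREAM_PROFILE, STREAM_ASSIGN, STREAM_OUTCOME = 1, 2, 3, 4


@dataclass
class Patient:
    """One simulated participant."""

    id: int
    entry_time: float  # years from trial start
    stage_at_entry: int
    profile: tuple[int, ...]  # level index per stratification factor
    arm: str
    pfs_time: float  # latent progression/death time from entry
    dropout_time: float  # latent censoring time from entry (inf if none)
    observed_time: float
    event_flag: bool
    mrd_negative: bool


def outcome_streams(seed) -> dict[str, np.random.Generator]:
    """Named, independent generators derived from one master seed.

    ``seed`` may be an int or a sequence of ints (e.g. ``[master, replicate]``).
    """
    base = [int(seed)] if np.isscalar(seed) else [int(s) for s in seed]
    return {
        "entry": np.random.default_rng(base + [STREAM_ENTRY]),
        "profile": np.random.default_rng(base + [STREAM_PROFILE]),
        "assign": np.random.default_rng(base + [STREAM_ASSIGN]),
        "outcome": np.random.default_rng(base + [STREAM_OUTCOME]),
    }


def _check_distribution(factor_distribution) -> list[np.ndarray]:
    dists = []
    for i, probs in enumerate(factor_distribution):
        p = np.asarray(probs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"factor {i}: level probabilities must be >= 0 and sum to 1")
        dists.append(p)
    return dists


def draw_profile(factor_distribution, rng: np.random.Generator,
                 correlated: bool = False) -> tuple[int, ...]:
    """One stratification profile: an independent categorical draw per factor."""
    if correlated:
        raise NotImplementedError("correlated factor draws are not supported")
    dists = _check_distribution(factor_distribution)
    return tuple(int(rng.choice(len(p), p=p)) for p in dists)


def draw_profiles(factor_distribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """``(n, n_factors)`` array of level indices, factors independent."""
    dists = _check_distribution(factor_distribution)
    out = np.empty((n, len(dists)), dtype=np.int64)
    for f, p in enumerate(dists):
        out[:, f] = rng.choice(len(p), size=n, p=p)
    return out


def dropout_rate(dropout_prob: float, horizon_years: float) -> float:
    """Exponential dropout rate with P(dropout <= horizon) = dropout_prob."""
    if horizon_years <= 0:
        raise ValueError("horizon must be > 0")
    if not (0 <= dropout_prob < 1):
        raise ValueError("dropout_prob must be in [0, 1)")
    if dropout_prob == 0:
        return 0.0
    return -math.log1p(-dropout_prob) / horizon_years


def draw_outcomes(arm: Arm, dropout_prob: float, horizon_years: float,
                  rng: np.random.Generator, n: int = 1,
                  median_override: float | None = None,
                  mrd_override: float | None = None):
    """Latent outcomes for ``n`` patients on ``arm``.

    Returns ``(pfs_time, dropout_time, mrd_negative)`` arrays.  PFS is
    exponential with rate ``ln 2 / median``; dropout is exponential with the
    rate from :func:`dropout_rate` (``+inf`` when the dropout probability is
    zero); MRD negativity is Bernoulli with the arm's rate (``False``
    when the arm declares none).
    """
    median = median_override if median_override is not None else arm.median_pfs
    if median is None or median <= 0:
        raise ValueError(f"arm {arm.name!r}: positive median_pfs required")
    lam = math.log(2) / median
    u = rng.random((3, n))
    pfs = -np.log(u[0]) / lam
    lam_d = dropout_rate(dropout_prob, horizon_years)
    drop = -np.log(u[1]) / lam_d if lam_d > 0 else np.full(n, np.inf)
    p_mrd = mrd_override if mrd_override is not None else arm.mrd_neg_prob
    mrd = u[2] < p_mrd if p_mrd is not None else np.zeros(n, dtype=bool)
    return pfs, drop, mrd


def transform_uniforms(u: np.ndarray, median: float, dropout_prob: float,
                       horizon_years: float, mrd_prob: float | None):
    """Inverse-CDF transform of pre-drawn ``(n, 3)`` uniforms to outcomes.

    Used by the trial engine so that each patient's latent randomness is
    fixed by their position in the entry sequence regardless of arm.
    """
    lam = math.log(2) / median
    pfs = -np.log(u[:, 0]) / lam
    lam_d = dropout_rate(dropout_prob, horizon_years)
    drop = -np.log(u[:, 1]) / lam_d if lam_d > 0 else np.full(len(u), np.inf)
    mrd = u[:, 2] < mrd_prob if mrd_prob is not None else np.zeros(len(u), dtype=bool)
    return pfs, drop, mrd
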