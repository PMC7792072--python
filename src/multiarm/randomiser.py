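"""Minimisation randomisation with a random element, plus simple randomisation.

Minimisation (Pocock–Simon style, range variant) assigns each incoming
patient to the arm that minimises covariate imbalance: for every candidate
arm the score is the summed count, across stratification factors, of already
randomised patients who share the patient's factor level and would sit in
that arm after the assignment, each count normalised by the arm's allocation
weight.  The minimising arm is then chosen with probability ``p`` (the
"random element", > 0.5) and one of the remaining arms uniformly otherwise,
so allocation stays unpredictable.  In a staged platform design the
algorithm is reset whenever the active-arm set changes, because a newly
added arm would otherwise start with zero counts and soak up patients.

The module keeps per-(factor, level, arm) counts only — it never needs the
patient history — so state is tiny and assignment is O(factors × arms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_model import Stage

__all__ = [
    "FactorProfile",
    "MinimisationState",
    "assign",
    "assign_simple",
    "reset_for_stage",
    "balance_report",
]

# A patient's stratification profile is one level index per factor, in the
# declared factor order.
FactorProfile = tuple[int, ...]


@dataclass
class MinimisationState:
    """Running state of the minimisation algorithm for one design stage."""

    active_arms: list[str]
    allocation_ratio: list[int]
    n_levels: list[int]  # levels per stratification factor
    random_element: float = 0.8
    counts: list[list[list[int]]] = field(default=None)  # [factor][level][arm]
    n_assigned: int = 0

    def __post_init__(self):
        if len(self.active_arms) < 2:
            raise ValueError("minimisation needs at least 2 active arms")
        if len(self.allocation_ratio) != len(self.active_arms):
            raise ValueError("allocation_ratio must match active_arms")
        if not (0.5 < self.random_element <= 1.0):
            raise ValueError("random_element must be in (0.5, 1]")
        if self.counts is None:
            self.counts = [[[0] * len(self.active_arms) for _ in range(nl)]
                           for nl in self.n_levels]

    def copy(self) -> "MinimisationState":
        return MinimisationState(
            active_arms=list(self.active_arms),
            allocation_ratio=list(self.allocation_ratio),
            n_levels=list(self.n_levels),
            random_element=self.random_element,
            counts=[[row[:] for row in fac] for fac in self.counts],
            n_assigned=self.n_assigned,
        )


def imbalance_scores(state: MinimisationState, profile: FactorProfile) -> list[float]:
    """Per-arm hypothetical imbalance score for a new patient with ``profile``.

    Score of arm ``a`` = sum over factors of ``(count[f][level_f][a] + 1) / w_a``:
    the weight-normalised count the patient would bring that arm to, within
    their own factor levels.
    """
    n_arms = len(state.active_arms)
    weights = state.allocation_ratio
    scores = [0.0] * n_arms
    counts = state.counts
    for f, lev in enumerate(profile):
        row = counts[f][lev]
        for a in range(n_arms):
            scores[a] += (row[a] + 1) / weights[a]
    return scores


def assign(state: MinimisationState, profile: FactorProfile,
           rng: np.random.Generator) -> int:
    """Assign one patient by minimisation with a random element; update state.

    Ties among minimum-score arms are broken uniformly first; the resulting
    candidate is kept with probability ``random_element`` and otherwise
    replaced by one of the other arms uniformly.  Returns the arm index
    within ``state.active_arms``.
    """
    n_arms = len(state.active_arms)
    scores = imbalance_scores(state, profile)
    m = min(scores)
    minima = [a for a in range(n_arms) if scores[a] <= m + 1e-12]
    if len(minima) == 1:
        cand = minima[0]
    else:
        cand = minima[int(rng.random() * len(minima))]
    p = state.random_element
    if p < 1.0 and rng.random() >= p:
        others = [a for a in range(n_arms) if a != cand]
        cand = others[int(rng.random() * len(others))]
    counts = state.counts
    for f, lev in enumerate(profile):
        counts[f][lev][cand] += 1
    state.n_assigned += 1
    return cand


def assign_simple(state: MinimisationState, profile: FactorProfile,
                  rng: np.random.Generator) -> int:
    """Ratio-weighted simple randomisation (comparator for minimisation)."""
    w = np.asarray(state.allocation_ratio, dtype=float)
    cand = int(rng.choice(len(w), p=w / w.sum()))
    for f, lev in enumerate(profile):
        state.counts[f][lev][cand] += 1
    state.n_assigned += 1
    return cand


def reset_for_stage(state: MinimisationState | None, stage: Stage,
                    n_levels: list[int], random_element: float | None = None) -> MinimisationState:
    """Fresh zeroed minimisation state for a new stage.

    All counts are zeroed and the active arms and allocation ratio replaced —
    the reset-at-each-stage rule of the staged design.  Idempotent: resetting
    an already-fresh state yields an equal state.
    """
    p = random_element if random_element is not None else (
        state.random_element if state is not None else 0.8)
    return MinimisationState(
        active_arms=list(stage.active_arms),
        allocation_ratio=list(stage.allocation_ratio),
        n_levels=list(n_levels),
        random_element=p,
    )


def balance_report(assignments, profiles, arm_names, factor_names=None,
                   level_names=None) -> pd.DataFrame:
    """Per-factor-level arm counts with the max pairwise imbalance.

    Returns a tidy frame with one row per (factor, level) plus an overall
    row, columns ``n_<arm>`` for each arm and ``max_abs_diff`` for the
    largest pairwise absolute count difference.  Empty input yields an empty
    frame.
    """
    assignments = list(assignments)
    profiles = list(profiles)
    if len(assignments) != len(profiles):
        raise ValueError("assignments and profiles must have equal length")
    n_arms = len(arm_names)
    cols = [f"n_{a}" for a in arm_names]
    if not assignments:
        return pd.DataFrame(columns=["factor", "level", *cols, "max_abs_diff"])
    n_factors = len(profiles[0])
    if factor_names is None:
        factor_names = [f"factor_{f}" for f in range(n_factors)]
    rows = []
    for f in range(n_factors):
        levels = sorted({p[f] for p in profiles})
        for lev in levels:
            counts = [0] * n_arms
            for a, p in zip(assignments, profiles):
                if p[f] == lev:
                    counts[a] += 1
            name = (level_names[f][lev] if level_names is not None else lev)
            rows.append({"factor": factor_names[f], "level": name,
                         **dict(zip(cols, counts)),
                         "max_abs_diff": max(counts) - min(counts)})
    overall = [0] * n_arms
    for a in assignments:
        overall[a] += 1
    rows.append({"factor": "<overall>", "level": "", **dict(zip(cols, overall)),
                 "max_abs_diff": max(overall) - min(overall)})
    return pd.DataFrame(rows)
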