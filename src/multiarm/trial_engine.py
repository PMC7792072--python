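"""End-to-end execution of a staged platform trial on synthetic patients.

``run_trial`` recruits patients as a Poisson stream, randomises each within
the stage open at their entry using minimisation with a random element,
fires stage transitions the first time a stage's exit trigger holds
(checked after every randomisation), resets the minimisation state at each
transition, and finally books each patient into the *concurrent* analysis
set of every hypothesis whose two arms were both open when the patient was
randomised.  Control patients appearing in more than one concurrent set are
the design's shared controls.

``analysis_dataset`` then cuts an analysis table for one hypothesis at an
event-count or calendar cutoff, administratively censoring everyone at the
cutoff date — the pooled-over-stages dataset the comparative analyses use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from . import cohort_simulator as cs
from . import randomiser as rnd
from .design_model import DesignSpec, Hypothesis, Stage

__all__ = ["TrialRun", "run_trial", "analysis_dataset"]

_BLOCK = 512  # pre-draw block size for entries/profiles/outcome uniforms

#: age in years at which the binary MRD endpoint is assessed
MRD_ASSESSMENT_YEARS = 2.0


@dataclass
class TrialRun:
    """Result of one simulated execution of a platform-trial design.

    Patient-level data are stored as flat arrays (fast path for Monte-Carlo
    use); ``patients`` materialises them as a DataFrame on demand.
    """

    spec: DesignSpec
    seed: int
    entry_time: np.ndarray
    stage: np.ndarray  # stage index per patient
    arm_index: np.ndarray  # index into spec.arms
    levels: np.ndarray  # (n, n_factors) stratification level indices
    pfs_time: np.ndarray
    dropout_time: np.ndarray
    mrd_negative: np.ndarray
    stage_boundaries: list[dict] = field(default_factory=list)
    concurrent_sets: dict[str, np.ndarray] = field(default_factory=dict)
    shared_control_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_patients(self) -> int:
        return len(self.entry_time)

    @property
    def arm_names(self) -> np.ndarray:
        names = np.array([a.name for a in self.spec.arms])
        return names[self.arm_index]

    @cached_property
    def patients(self) -> pd.DataFrame:
        cols = {
            "id": np.arange(self.n_patients, dtype=np.int64),
            "entry_time": np.round(self.entry_time, 6),
            "stage": self.stage,
            "arm": self.arm_names,
        }
        for f, (fname, _) in enumerate(self.spec.stratification_factors):
            cols[fname] = self.levels[:, f]
        cols["pfs_time"] = np.round(self.pfs_time, 6)
        cols["dropout_time"] = np.round(self.dropout_time, 6)
        cols["mrd_negative"] = self.mrd_negative
        return pd.DataFrame(cols)

    def arm_totals(self) -> dict[str, int]:
        names = [a.name for a in self.spec.arms]
        counts = np.bincount(self.arm_index, minlength=len(names))
        return dict(zip(names, counts.tolist()))


def _trigger_fired(trigger, per_stage_counts: np.ndarray, stage_of, entry_time: float,
                   arm_index_of: dict[str, int]) -> bool:
    if trigger.kind == "calendar":
        return entry_time >= trigger.years
    a = arm_index_of[trigger.arm]
    total = int(per_stage_counts[trigger.since_stage - 1:, a].sum())
    return total >= trigger.count


def run_trial(spec: DesignSpec, seed: int, scenario: dict | None = None,
              factor_distribution=None, max_patients: int = 100_000) -> TrialRun:
    """Simulate one complete run of the staged design.

    Parameters
    ----------
    spec
        Validated design.
    seed
        Master seed; identical seeds reproduce the run exactly.
    scenario
        Optional per-arm overrides ``{arm_name: {"median_pfs": ..,
        "mrd_neg_prob": ..}}`` for evaluating operating characteristics under
        true-parameter configurations other than the design assumptions.
    factor_distribution
        Level probabilities per stratification factor; uniform by default.
    max_patients
        Safety horizon; exceeded means a stage trigger can never fire.
    """
    spec.check()
    if scenario:
        unknown = set(scenario) - {a.name for a in spec.arms}
        if unknown:
            raise ValueError(f"scenario references unknown arms: {sorted(unknown)}")
    arm_names = [a.name for a in spec.arms]
    arm_index_of = {a: i for i, a in enumerate(arm_names)}
    n_factors = len(spec.stratification_factors)
    n_levels = [len(levels) for _, levels in spec.stratification_factors]
    if factor_distribution is None:
        factor_distribution = [np.full(nl, 1.0 / nl) for nl in n_levels]

    streams = cs.outcome_streams(seed)
    rng_entry, rng_prof, rng_assign = streams["entry"], streams["profile"], streams["assign"]

    entry, stage_ix, arm_ix = [], [], []
    levels_blocks: list[np.ndarray] = []
    per_stage_counts = np.zeros((len(spec.stages), len(arm_names)), dtype=np.int64)
    stage_boundaries: list[dict] = []

    stage_pos = 0
    stage = spec.stages[0]
    state = rnd.reset_for_stage(None, stage, n_levels, spec.minimisation_random_element)
    local_to_global = [arm_index_of[a] for a in stage.active_arms]
    stage_boundaries.append({"stage": 1, "start_time": 0.0, "start_index": 0})

    t = 0.0
    i = 0
    gaps = profs = None
    done = False
    while not done:
        if i % _BLOCK == 0:
            gaps = rng_entry.exponential(1.0 / spec.accrual_rate, size=_BLOCK)
            profs = cs.draw_profiles(factor_distribution, _BLOCK, rng_prof)
            levels_blocks.append(profs)
            prof_list = profs.tolist()
        if i >= max_patients:
            raise RuntimeError(
                f"stage {stage.index} exit trigger never fired within {max_patients} patients")
        t += gaps[i % _BLOCK]
        # calendar triggers can fire between randomisations
        while (stage.exit_trigger.kind == "calendar"
               and t >= stage.exit_trigger.years and stage_pos + 1 < len(spec.stages)):
            stage_pos += 1
            stage = spec.stages[stage_pos]
            state = rnd.reset_for_stage(state, stage, n_levels)
            local_to_global = [arm_index_of[a] for a in stage.active_arms]
            stage_boundaries.append({"stage": stage.index, "start_time": t, "start_index": i})
        if stage.exit_trigger.kind == "calendar" and t >= stage.exit_trigger.years:
            break  # final stage closed by calendar before this patient entered
        profile = tuple(prof_list[i % _BLOCK])
        local = rnd.assign(state, profile, rng_assign)
        g = local_to_global[local]
        entry.append(t)
        stage_ix.append(stage.index)
        arm_ix.append(g)
        per_stage_counts[stage_pos, g] += 1
        i += 1
        if _trigger_fired(stage.exit_trigger, per_stage_counts, stage_pos, t, arm_index_of):
            if stage_pos + 1 < len(spec.stages):
                stage_pos += 1
                stage = spec.stages[stage_pos]
                state = rnd.reset_for_stage(state, stage, n_levels)
                local_to_global = [arm_index_of[a] for a in stage.active_arms]
                stage_boundaries.append({"stage": stage.index, "start_time": t, "start_index": i})
            else:
                done = True

    n = i
    entry = np.asarray(entry)
    stage_ix = np.asarray(stage_ix, dtype=np.int64)
    arm_ix = np.asarray(arm_ix, dtype=np.int64)
    levels = np.concatenate(levels_blocks, axis=0)[:n]
    for j, b in enumerate(stage_boundaries):
        b["end_index"] = stage_boundaries[j + 1]["start_index"] if j + 1 < len(stage_boundaries) else n
        b["end_time"] = float(entry[b["end_index"] - 1]) if b["end_index"] > 0 else 0.0

    # latent outcomes: per-patient uniform rows, arm-specific inverse transform
    u = streams["outcome"].random((n, 3))
    pfs = np.empty(n)
    drop = np.empty(n)
    mrd = np.zeros(n, dtype=bool)
    for g, arm in enumerate(spec.arms):
        mask = arm_ix == g
        if not mask.any():
            continue
        over = (scenario or {}).get(arm.name, {})
        p, d, m = cs.transform_uniforms(
            u[mask],
            median=over.get("median_pfs", arm.median_pfs),
            dropout_prob=spec.dropout_prob,
            horizon_years=spec.dropout_horizon_years,
            mrd_prob=over.get("mrd_neg_prob", arm.mrd_neg_prob),
        )
        pfs[mask], drop[mask], mrd[mask] = p, d, m

    run = TrialRun(spec=spec, seed=seed, entry_time=entry, stage=stage_ix,
                   arm_index=arm_ix, levels=levels, pfs_time=pfs, dropout_time=drop,
                   mrd_negative=mrd, stage_boundaries=stage_boundaries)
    _book_concurrent_sets(run)
    return run


def _book_concurrent_sets(run: TrialRun) -> None:
    spec = run.spec
    arm_index_of = {a.name: i for i, a in enumerate(spec.arms)}
    controls = {i for i, a in enumerate(spec.arms) if a.role == "control"}
    membership = np.zeros(run.n_patients, dtype=np.int64)
    for h in spec.hypotheses:
        stages = spec.concurrent_stages(h)
        in_stage = np.isin(run.stage, stages)
        in_arms = np.isin(run.arm_index, [arm_index_of[h.experimental_arm],
                                          arm_index_of[h.control_arm]])
        ids = np.nonzero(in_stage & in_arms)[0]
        run.concurrent_sets[h.label] = ids
        membership[ids] += 1
    is_control = np.isin(run.arm_index, list(controls))
    run.shared_control_ids = np.nonzero((membership >= 2) & is_control)[0]


def _event_calendar_times(run: TrialRun, ids: np.ndarray) -> np.ndarray:
    """Sorted calendar times of true (non-dropout) events among ``ids``."""
    pfs = run.pfs_time[ids]
    drop = run.dropout_time[ids]
    ev = pfs <= drop
    return np.sort(run.entry_time[ids][ev] + pfs[ev])


def analysis_dataset(run: TrialRun, hypothesis: Hypothesis | str,
                     cutoff_events: int | None = None,
                     cutoff_years: float | None = None,
                     exclude_factors: tuple[str, ...] = ("centre",)) -> pd.DataFrame:
    """Analysis table for one hypothesis at a cutoff, concurrent patients only.

    For a time-to-event hypothesis the table has ``arm`` (1 = experimental),
    ``time``, ``event``, ``stage`` and the stratification-factor levels
    (centre excluded by default, matching the planned analysis covariates).
    When ``cutoff_events`` is given, the cutoff calendar date is the time of
    that event among the hypothesis's own concurrent patients.  For a binary
    hypothesis the table has ``arm``, ``mrd_negative`` and ``evaluable``
    (no dropout before the 24-month assessment).
    """
    spec = run.spec
    if isinstance(hypothesis, str):
        hypothesis = spec.hypothesis(hypothesis)
    h = hypothesis
    if h.label not in run.concurrent_sets:
        raise KeyError(f"hypothesis {h.label!r} not booked in this run")
    ids = run.concurrent_sets[h.label]
    arm_index_of = {a.name: i for i, a in enumerate(spec.arms)}
    exp_ix = arm_index_of[h.experimental_arm]

    if h.endpoint == "binary":
        sub_ids = ids
        cols = {
            "id": sub_ids,
            "arm": (run.arm_index[sub_ids] == exp_ix).astype(np.int64),
            "mrd_negative": run.mrd_negative[sub_ids].astype(np.int64),
            "evaluable": (run.dropout_time[sub_ids] > MRD_ASSESSMENT_YEARS),
            "stage": run.stage[sub_ids],
        }
    else:
        if cutoff_events is not None:
            times = _event_calendar_times(run, ids)
            if cutoff_events < 1 or cutoff_events > len(times):
                raise ValueError(
                    f"cutoff of {cutoff_events} events unreachable: only {len(times)} "
                    f"events ever occur among concurrent patients")
            cutoff = float(times[cutoff_events - 1])
        elif cutoff_years is not None:
            cutoff = float(cutoff_years)
        else:
            cutoff = float("inf")
        sub_ids = ids[run.entry_time[ids] < cutoff]
        if len(sub_ids) == 0:
            import warnings
            warnings.warn("cutoff precedes the first concurrent entry; table is empty")
        followup = cutoff - run.entry_time[sub_ids]
        pfs = run.pfs_time[sub_ids]
        drop = run.dropout_time[sub_ids]
        obs = np.minimum(np.minimum(pfs, drop), followup)
        # the admin comparison runs on the calendar scale so an event-count
        # cutoff includes exactly its defining event
        event = (pfs <= drop) & (run.entry_time[sub_ids] + pfs <= cutoff)
        cols = {
            "id": sub_ids,
            "arm": (run.arm_index[sub_ids] == exp_ix).astype(np.int64),
            "time": obs,
            "event": event.astype(np.int64),
            "stage": run.stage[sub_ids],
        }
    for f, (fname, _) in enumerate(spec.stratification_factors):
        if fname in exclude_factors:
            continue
        cols[fname] = run.levels[sub_ids, f]
    return pd.DataFrame(cols)
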