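"""Domain types for staged multi-arm platform-trial designs.

A platform trial runs several experimental arms against one or more shared
control arms under a single protocol, with arms added and dropped in stages.
The types here describe such a design declaratively: the arms and their
assumed outcome distributions, the stages with their active-arm sets and
stage-exit triggers, and the hypotheses (pairwise comparisons) the trial is
powered for.  Designs round-trip through a YAML config (see
:func:`load_design` / :func:`save_design`; schema documented in
``docs/config_schema.md``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "Arm",
    "StageTrigger",
    "Stage",
    "Hypothesis",
    "DesignSpec",
    "DesignValidationError",
    "load_design",
    "save_design",
    "flair_design",
]

#: tolerance for the hazard-ratio / median-ratio consistency check
_HR_TOL = 1e-9


class DesignValidationError(ValueError):
    """Raised when a design violates its structural invariants.

    Carries the full list of failures in ``errors`` so a config author sees
    every problem at once rather than one per run.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid design:\n" + "\n".join(f"  - {e}" for e in self.errors))


@dataclass(frozen=True)
class Arm:
    """A treatment arm with the outcome parameters the design assumes.

    ``median_pfs`` is the assumed median progression-free survival in years
    under an exponential model; ``mrd_neg_prob`` is the assumed probability of
    minimal-residual-disease negativity at 24 months (binary endpoint),
    optional for arms without a binary hypothesis.
    """

    name: str
    role: str  # "control" | "experimental"
    median_pfs: float
    mrd_neg_prob: float | None = None

    def validate(self) -> list[str]:
        errs = []
        if self.role not in ("control", "experimental"):
            errs.append(f"arm {self.name!r}: role must be 'control' or 'experimental', got {self.role!r}")
        if not (self.median_pfs > 0):
            errs.append(f"arm {self.name!r}: median_pfs must be > 0, got {self.median_pfs}")
        if self.mrd_neg_prob is not None and not (0.0 <= self.mrd_neg_prob <= 1.0):
            errs.append(f"arm {self.name!r}: mrd_neg_prob must be in [0, 1], got {self.mrd_neg_prob}")
        return errs


@dataclass(frozen=True)
class StageTrigger:
    """Condition on the trial state that ends a stage.

    Two kinds are supported:

    * ``kind="arm_recruitment"``: the stage ends once cumulative recruitment
      to ``arm`` (counted from the start of stage ``since_stage``, default 1)
      reaches ``count`` participants.
    * ``kind="calendar"``: the stage ends at ``years`` after trial start.
    """

    kind: str  # "arm_recruitment" | "calendar"
    arm: str | None = None
    count: int | None = None
    since_stage: int = 1
    years: float | None = None

    def validate(self, label: str) -> list[str]:
        errs = []
        if self.kind == "arm_recruitment":
            if self.arm is None or self.count is None:
                errs.append(f"{label}: arm_recruitment trigger needs 'arm' and 'count'")
            elif self.count < 1:
                errs.append(f"{label}: trigger count must be >= 1, got {self.count}")
        elif self.kind == "calendar":
            if self.years is None or self.years <= 0:
                errs.append(f"{label}: calendar trigger needs 'years' > 0")
        else:
            errs.append(f"{label}: unknown trigger kind {self.kind!r}")
        return errs


@dataclass(frozen=True)
class Stage:
    """One design stage: which arms are open and when the stage ends."""

    index: int
    active_arms: tuple[str, ...]
    allocation_ratio: tuple[int, ...]
    exit_trigger: StageTrigger

    def validate(self) -> list[str]:
        errs = []
        label = f"stage {self.index}"
        if self.index < 1:
            errs.append(f"{label}: index must be >= 1")
        if len(self.active_arms) < 2:
            errs.append(f"{label}: needs at least 2 active arms")
        if len(set(self.active_arms)) != len(self.active_arms):
            errs.append(f"{label}: duplicate arm names")
        if len(self.allocation_ratio) != len(self.active_arms):
            errs.append(f"{label}: allocation_ratio length {len(self.allocation_ratio)} "
                        f"!= number of active arms {len(self.active_arms)}")
        if any(w < 1 or int(w) != w for w in self.allocation_ratio):
            errs.append(f"{label}: allocation weights must be positive integers")
        errs.extend(self.exit_trigger.validate(label))
        return errs


@dataclass(frozen=True)
class Hypothesis:
    """A powered pairwise comparison between an experimental and a control arm.

    For ``endpoint="time_to_event"`` the design quantities are a superiority
    hazard ratio (``target_hr``, derived from the two exponential medians when
    not given) plus accrual and minimum-follow-up durations.  For
    ``endpoint="binary"`` they are the two assumed success probabilities.
    ``interim_fractions`` are the information fractions of the planned
    analyses, ending at 1 (the final analysis).
    """

    label: str
    experimental_arm: str
    control_arm: str
    endpoint: str  # "time_to_event" | "binary"
    alpha_two_sided: float = 0.05
    power: float = 0.80
    target_hr: float | None = None
    control_median: float | None = None
    experimental_median: float | None = None
    p_control: float | None = None
    p_experimental: float | None = None
    accrual_years: float | None = None
    min_followup_years: float | None = None
    dropout_prob: float = 0.0
    interim_fractions: tuple[float, ...] = (1.0,)

    @property
    def hazard_ratio(self) -> float:
        """Design hazard ratio, derived from medians if not given explicitly."""
        if self.target_hr is not None:
            return self.target_hr
        if self.control_median is not None and self.experimental_median is not None:
            return self.control_median / self.experimental_median
        raise ValueError(f"hypothesis {self.label!r}: no hazard ratio available")

    def validate(self) -> list[str]:
        errs = []
        label = f"hypothesis {self.label!r}"
        if self.endpoint not in ("time_to_event", "binary"):
            errs.append(f"{label}: endpoint must be 'time_to_event' or 'binary'")
        if not (0 < self.alpha_two_sided < 1):
            errs.append(f"{label}: alpha_two_sided must be in (0, 1)")
        if not (0 < self.power < 1):
            errs.append(f"{label}: power must be in (0, 1)")
        if not (0 <= self.dropout_prob < 1):
            errs.append(f"{label}: dropout_prob must be in [0, 1)")
        if self.endpoint == "time_to_event":
            if (self.target_hr is not None
                    and self.control_median is not None
                    and self.experimental_median is not None):
                implied = self.control_median / self.experimental_median
                if abs(implied - self.target_hr) > _HR_TOL:
                    errs.append(
                        f"{label}: target_hr {self.target_hr} inconsistent with medians "
                        f"{self.control_median}/{self.experimental_median} (implied {implied!r}); "
                        f"omit target_hr to derive it from the medians")
            if self.target_hr is not None and not (0 < self.target_hr < 1):
                errs.append(f"{label}: target_hr must be in (0, 1) for superiority")
        if self.endpoint == "binary":
            for nm, p in (("p_control", self.p_control), ("p_experimental", self.p_experimental)):
                if p is None or not (0 < p < 1):
                    errs.append(f"{label}: {nm} must be given in (0, 1) for a binary endpoint")
        fr = self.interim_fractions
        if not fr or abs(fr[-1] - 1.0) > 1e-12:
            errs.append(f"{label}: interim_fractions must end at 1.0")
        if any(not (0 < f <= 1) for f in fr) or any(b <= a for a, b in zip(fr, fr[1:])):
            errs.append(f"{label}: interim_fractions must be strictly increasing within (0, 1]")
        return errs


@dataclass(frozen=True)
class DesignSpec:
    """Complete declarative description of a staged platform trial."""

    name: str
    arms: tuple[Arm, ...]
    stages: tuple[Stage, ...]
    hypotheses: tuple[Hypothesis, ...]
    stratification_factors: tuple[tuple[str, tuple[str, ...]], ...]
    minimisation_random_element: float = 0.8
    accrual_rate: float = 250.0  # patients per year
    dropout_prob: float = 0.05
    dropout_horizon_years: float = 8.0
    notes: str = ""

    def arm(self, name: str) -> Arm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)

    def hypothesis(self, label: str) -> Hypothesis:
        for h in self.hypotheses:
            if h.label == label:
                return h
        raise KeyError(label)

    def stage(self, index: int) -> Stage:
        for s in self.stages:
            if s.index == index:
                return s
        raise KeyError(index)

    def validate(self) -> list[str]:
        errs: list[str] = []
        if not self.arms:
            errs.append("design has no arms")
        if not self.stages:
            errs.append("design has no stages")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            errs.append("duplicate arm names")
        for a in self.arms:
            errs.extend(a.validate())
        for s in self.stages:
            errs.extend(s.validate())
            for nm in s.active_arms:
                if nm not in names:
                    errs.append(f"stage {s.index}: undeclared arm {nm!r}")
            if (s.exit_trigger.kind == "arm_recruitment"
                    and s.exit_trigger.arm is not None
                    and s.exit_trigger.arm not in names):
                errs.append(f"stage {s.index}: trigger references undeclared arm "
                            f"{s.exit_trigger.arm!r}")
        idx = [s.index for s in self.stages]
        if idx != list(range(1, len(idx) + 1)):
            errs.append(f"stage indices must be 1..K consecutive, got {idx}")
        controls = {a.name for a in self.arms if a.role == "control"}
        for prev, nxt in zip(self.stages, self.stages[1:]):
            shared = set(prev.active_arms) & set(nxt.active_arms) & controls
            if not shared:
                errs.append(f"stages {prev.index} and {nxt.index} share no control arm")
        for h in self.hypotheses:
            errs.extend(h.validate())
            for nm in (h.experimental_arm, h.control_arm):
                if nm not in names:
                    errs.append(f"hypothesis {h.label!r}: undeclared arm {nm!r}")
            else:
                both = [s.index for s in self.stages
                        if h.experimental_arm in s.active_arms and h.control_arm in s.active_arms]
                if {h.experimental_arm, h.control_arm} <= set(names) and not both:
                    errs.append(f"hypothesis {h.label!r}: arms never simultaneously active")
        labels = [h.label for h in self.hypotheses]
        if len(set(labels)) != len(labels):
            errs.append("duplicate hypothesis labels")
        for fname, levels in self.stratification_factors:
            if len(levels) < 2:
                errs.append(f"stratification factor {fname!r} needs >= 2 levels")
            if len(set(levels)) != len(levels):
                errs.append(f"stratification factor {fname!r} has duplicate levels")
        if not (0.5 < self.minimisation_random_element <= 1.0):
            errs.append("minimisation_random_element must be in (0.5, 1]")
        if not (self.accrual_rate > 0):
            errs.append("accrual_rate must be > 0")
        if not (0 <= self.dropout_prob < 1):
            errs.append("dropout_prob must be in [0, 1)")
        return errs

    def check(self) -> "DesignSpec":
        errs = self.validate()
        if errs:
            raise DesignValidationError(errs)
        return self

    def concurrent_stages(self, h: Hypothesis) -> tuple[int, ...]:
        """Stage indices in which both of a hypothesis's arms are open."""
        return tuple(s.index for s in self.stages
                     if h.experimental_arm in s.active_arms and h.control_arm in s.active_arms)


# ---------------------------------------------------------------------------
# config (de)serialisation


def _trigger_to_dict(t: StageTrigger) -> dict:
    if t.kind == "arm_recruitment":
        d = {"arm": t.arm, "count": t.count}
        if t.since_stage != 1:
            d["since_stage"] = t.since_stage
        return d
    return {"years": t.years}


def _trigger_from_dict(d: dict, label: str) -> StageTrigger:
    if "arm" in d or "count" in d:
        return StageTrigger(kind="arm_recruitment", arm=d.get("arm"),
                            count=d.get("count"), since_stage=int(d.get("since_stage", 1)))
    if "years" in d:
        return StageTrigger(kind="calendar", years=float(d["years"]))
    raise DesignValidationError([f"{label}: exit trigger needs either arm/count or years"])


def _opt(v):
    return None if v is None else float(v)


def spec_to_dict(spec: DesignSpec) -> dict:
    """Plain-dict form of a design, suitable for YAML/JSON dumping."""
    d: dict = {
        "name": spec.name,
        "accrual_rate": spec.accrual_rate,
        "minimisation_random_element": spec.minimisation_random_element,
        "dropout": {"prob": spec.dropout_prob, "horizon_years": spec.dropout_horizon_years},
        "arms": [
            {k: v for k, v in (("name", a.name), ("role", a.role),
                               ("median_pfs", a.median_pfs), ("mrd_neg_prob", a.mrd_neg_prob))
             if v is not None}
            for a in spec.arms
        ],
        "stages": [
            {"index": s.index, "arms": list(s.active_arms),
             "ratio": list(s.allocation_ratio), "exit": _trigger_to_dict(s.exit_trigger)}
            for s in spec.stages
        ],
        "hypotheses": [],
        "stratification": [{"name": f, "levels": list(levels)}
                           for f, levels in spec.stratification_factors],
    }
    if spec.notes:
        d["notes"] = spec.notes
    for h in spec.hypotheses:
        hd = {"label": h.label, "experimental_arm": h.experimental_arm,
              "control_arm": h.control_arm, "endpoint": h.endpoint,
              "alpha_two_sided": h.alpha_two_sided, "power": h.power,
              "dropout_prob": h.dropout_prob,
              "interim_fractions": list(h.interim_fractions)}
        for k in ("target_hr", "control_median", "experimental_median",
                  "p_control", "p_experimental", "accrual_years", "min_followup_years"):
            v = getattr(h, k)
            if v is not None:
                hd[k] = v
        d["hypotheses"].append(hd)
    return d


def spec_from_dict(d: dict) -> DesignSpec:
    """Build and validate a :class:`DesignSpec` from its plain-dict form."""
    try:
        arms = tuple(
            Arm(name=str(a["name"]), role=str(a.get("role", "experimental")),
                median_pfs=float(a["median_pfs"]), mrd_neg_prob=_opt(a.get("mrd_neg_prob")))
            for a in d.get("arms", ())
        )
        stages = tuple(
            Stage(index=int(s["index"]), active_arms=tuple(s["arms"]),
                  allocation_ratio=tuple(int(w) for w in s["ratio"]),
                  exit_trigger=_trigger_from_dict(s["exit"], f"stage {s.get('index')}"))
            for s in d.get("stages", ())
        )
        hyps = []
        for h in d.get("hypotheses", ()):
            hyps.append(Hypothesis(
                label=str(h["label"]),
                experimental_arm=str(h["experimental_arm"]),
                control_arm=str(h["control_arm"]),
                endpoint=str(h["endpoint"]),
                alpha_two_sided=float(h.get("alpha_two_sided", 0.05)),
                power=float(h.get("power", 0.80)),
                target_hr=_opt(h.get("target_hr")),
                control_median=_opt(h.get("control_median")),
                experimental_median=_opt(h.get("experimental_median")),
                p_control=_opt(h.get("p_control")),
                p_experimental=_opt(h.get("p_experimental")),
                accrual_years=_opt(h.get("accrual_years")),
                min_followup_years=_opt(h.get("min_followup_years")),
                dropout_prob=float(h.get("dropout_prob", 0.0)),
                interim_fractions=tuple(float(f) for f in h.get("interim_fractions", (1.0,))),
            ))
        strat = []
        for f in d.get("stratification", ()):
            levels = f["levels"]
            if isinstance(levels, int):
                # shorthand: integer level count expands to generated labels
                width = len(str(levels))
                levels = [f"{f['name']}{i + 1:0{width}d}" for i in range(levels)]
            strat.append((str(f["name"]), tuple(str(x) for x in levels)))
        dropout = d.get("dropout", {})
        spec = DesignSpec(
            name=str(d.get("name", "design")),
            arms=arms, stages=stages, hypotheses=tuple(hyps),
            stratification_factors=tuple(strat),
            minimisation_random_element=float(d.get("minimisation_random_element", 0.8)),
            accrual_rate=float(d.get("accrual_rate", 250.0)),
            dropout_prob=float(dropout.get("prob", 0.05)),
            dropout_horizon_years=float(dropout.get("horizon_years", 8.0)),
            notes=str(d.get("notes", "")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, DesignValidationError):
            raise
        raise DesignValidationError([f"schema violation: {exc!r}"]) from exc
    return spec.check()


def load_design(path: str | Path) -> DesignSpec:
    """Read and validate a design config (YAML, of which JSON is a subset)."""
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise DesignValidationError([f"cannot parse {path}: {exc}"]) from exc
    if not isinstance(d, dict):
        raise DesignValidationError([f"{path}: top level must be a mapping"])
    return spec_from_dict(d)


def save_design(spec: DesignSpec, path: str | Path) -> None:
    """Validate and write a design config; ``load_design`` inverts it exactly."""
    spec.check()
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False, default_flow_style=None)


def flair_design() -> DesignSpec:
    """The bundled three-stage CLL platform-trial design used throughout the docs.

    Four arms — chemo-immunotherapy control (FCR), ibrutinib+rituximab (IR),
    ibrutinib monotherapy (I, second control) and ibrutinib+venetoclax (I+V) —
    over three stages, with IR dropped in stage 3.
    """
    with resources.files("multiarm.data").joinpath("flair.yaml").open() as fh:
        return spec_from_dict(yaml.safe_load(fh))
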