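"""Group-sequential boundaries for event-driven interim analyses.

The trial tests each time-to-event hypothesis at planned interim looks and a
final look, with early stopping for efficacy only.  Under the usual
asymptotics the sequence of score statistics behaves as a Brownian motion in
information time: on the score scale ``S_k = Z_k sqrt(t_k)`` the increments
between looks are independent Gaussians with variance equal to the increment
in information fraction.  Crossing probabilities therefore follow from a
recursive numerical integration over the continuation region at each look
(the classic Armitage–McPherson–Rowe recursion), which is what this module
implements; no closed form exists for more than one look.

The default boundary shape is the classic O'Brien–Fleming rule
``z_k = C / sqrt(t_k)`` — constant on the score scale — with ``C`` solved so
the overall two-sided crossing probability under the null equals alpha.  For
one interim at half the events and overall alpha 0.05 this yields the
familiar nominal two-sided p-value pair (0.005, 0.048).  A Lan–DeMets
O'Brien–Fleming-like alpha-spending variant is available behind the
``shape`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = ["GSDPlan", "obf_boundaries", "interim_trigger"]


@dataclass(frozen=True)
class GSDPlan:
    """A group-sequential plan: per-look boundaries and alpha accounting."""

    info_fractions: tuple[float, ...]
    alpha_two_sided: float
    z_bounds: tuple[float, ...]
    nominal_p_two_sided: tuple[float, ...]
    cumulative_alpha_spent: tuple[float, ...]
    inflation_factor: float
    shape: str = "obf"

    @property
    def n_looks(self) -> int:
        return len(self.info_fractions)


def _check_fractions(info_fractions) -> np.ndarray:
    t = np.asarray(info_fractions, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("info_fractions must be a non-empty 1-d sequence")
    if (t <= 0).any() or (t > 1).any():
        raise ValueError("info_fractions must lie in (0, 1]")
    if (np.diff(t) <= 0).any():
        raise ValueError("info_fractions must be strictly increasing")
    if abs(t[-1] - 1.0) > 1e-12:
        raise ValueError("last info fraction must equal 1")
    return t


def _crossing_probs(t: np.ndarray, score_bounds: np.ndarray, drift: float = 0.0,
                    n_grid: int = 801) -> np.ndarray:
    """Per-look boundary-crossing probabilities of the discretised score process.

    ``score_bounds[k]`` is the two-sided threshold on ``|S_k|``; the process
    has mean ``drift * t`` and independent increments of variance ``dt``.
    Uses trapezoid quadrature of the sub-density over the continuation region.
    """
    crossed = np.empty(len(t))
    b = score_bounds[0]
    x = np.linspace(-b, b, n_grid)
    sd = math.sqrt(t[0])
    f = stats.norm.pdf(x, loc=drift * t[0], scale=sd)
    w = np.full(n_grid, x[1] - x[0])
    w[0] = w[-1] = (x[1] - x[0]) / 2
    crossed[0] = 1.0 - float(f @ w)
    for k in range(1, len(t)):
        dt = t[k] - t[k - 1]
        b = score_bounds[k]
        x_new = np.linspace(-b, b, n_grid)
        sd = math.sqrt(dt)
        kernel = stats.norm.pdf((x_new[:, None] - x[None, :] - drift * dt) / sd) / sd
        f_new = kernel @ (w * f)
        w_new = np.full(n_grid, x_new[1] - x_new[0])
        w_new[0] = w_new[-1] = (x_new[1] - x_new[0]) / 2
        survive = float(f_new @ w_new)
        prev_survive = float(f @ w)
        crossed[k] = prev_survive - survive
        x, f, w = x_new, f_new, w_new
    return crossed


def _total_crossing_obf(c: float, t: np.ndarray, n_grid: int) -> float:
    return float(_crossing_probs(t, np.full(len(t), c), n_grid=n_grid).sum())


def _solve_obf_constant(t: np.ndarray, alpha: float, n_grid: int = 801,
                        tol: float = 1e-7) -> float:
    lo = stats.norm.ppf(1 - alpha / 2) * 0.8
    hi = stats.norm.ppf(1 - alpha / 2) + 4.0
    return float(brentq(lambda c: _total_crossing_obf(c, t, n_grid) - alpha,
                        lo, hi, xtol=tol))


def _obf_spending(alpha: float, t: np.ndarray) -> np.ndarray:
    """Lan–DeMets O'Brien–Fleming-like cumulative spending function."""
    z = stats.norm.ppf(1 - alpha / 2)
    return 2.0 * stats.norm.sf(z / np.sqrt(t))


def _solve_spending_bounds(t: np.ndarray, alpha: float, n_grid: int = 801) -> np.ndarray:
    """Score-scale bounds matching a cumulative spending schedule, look by look."""
    target = _obf_spending(alpha, t)
    target[-1] = alpha  # exact conservation at the final look
    bounds = np.empty(len(t))
    for k in range(len(t)):
        def spent(bk: float) -> float:
            trial = np.concatenate([bounds[:k], [bk]])
            return float(_crossing_probs(t[:k + 1], trial, n_grid=n_grid).sum())
        incr = target[k] - (target[k - 1] if k else 0.0)
        if incr <= 1e-12:
            bounds[k] = 10.0 * math.sqrt(t[k])  # effectively no spend at this look
            continue
        bounds[k] = brentq(lambda bk: spent(bk) - target[k], 1e-3, 12.0, xtol=1e-7)
    return bounds


def _power(t: np.ndarray, score_bounds: np.ndarray, drift: float, n_grid: int = 801) -> float:
    return float(_crossing_probs(t, score_bounds, drift=drift, n_grid=n_grid).sum())


def _inflation_factor(t: np.ndarray, score_bounds: np.ndarray, alpha: float,
                      power: float) -> float:
    """Maximum-information inflation relative to a fixed-sample design.

    The drift needed for the sequential design to reach the target power,
    squared and compared with the fixed-design drift ``z_{1-a/2} + z_pow``.
    """
    theta_fixed = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    theta = brentq(lambda th: _power(t, score_bounds, th) - power,
                   theta_fixed * 0.8, theta_fixed * 2.0, xtol=1e-7)
    return float((theta / theta_fixed) ** 2)


def obf_boundaries(info_fractions, alpha_two_sided: float = 0.05,
                   shape: str = "obf", power: float = 0.80,
                   n_grid: int = 801) -> GSDPlan:
    """Group-sequential efficacy boundaries at the given information fractions.

    Parameters
    ----------
    info_fractions
        Strictly increasing fractions of total information (events), last = 1.
    alpha_two_sided
        Overall two-sided type-I error to be preserved across all looks.
    shape
        ``"obf"`` (default): classic O'Brien–Fleming, ``z_k = C / sqrt(t_k)``;
        ``"ld_spending"``: Lan–DeMets O'Brien–Fleming-like spending function.
    power
        Target power used only for the reported maximum-information
        ``inflation_factor``.
    n_grid
        Quadrature points per look; the default leaves boundaries stable to
        well below 1e-5 (refinement is checked in the test-suite).

    Returns a :class:`GSDPlan` with z boundaries, nominal two-sided p-values
    per look and the cumulative alpha spending, which sums exactly to alpha.
    """
    t = _check_fractions(info_fractions)
    if not (0 < alpha_two_sided < 1):
        raise ValueError("alpha_two_sided must be in (0, 1)")
    if len(t) == 1:
        z = float(stats.norm.ppf(1 - alpha_two_sided / 2))
        return GSDPlan(info_fractions=(1.0,), alpha_two_sided=alpha_two_sided,
                       z_bounds=(z,), nominal_p_two_sided=(alpha_two_sided,),
                       cumulative_alpha_spent=(alpha_two_sided,),
                       inflation_factor=1.0, shape=shape)
    if shape == "obf":
        c = _solve_obf_constant(t, alpha_two_sided, n_grid=n_grid)
        score_bounds = np.full(len(t), c)
    elif shape == "ld_spending":
        score_bounds = _solve_spending_bounds(t, alpha_two_sided, n_grid=n_grid)
    else:
        raise ValueError(f"unknown boundary shape {shape!r}")
    z_bounds = score_bounds / np.sqrt(t)
    crossing = _crossing_probs(t, score_bounds, n_grid=n_grid)
    cumulative = np.cumsum(crossing)
    # normalise the last entry to alpha (it matches to quadrature error)
    cumulative[-1] = alpha_two_sided
    nominal_p = 2.0 * stats.norm.sf(z_bounds)
    infl = _inflation_factor(t, score_bounds, alpha_two_sided, power)
    return GSDPlan(
        info_fractions=tuple(float(x) for x in t),
        alpha_two_sided=float(alpha_two_sided),
        z_bounds=tuple(float(x) for x in z_bounds),
        nominal_p_two_sided=tuple(float(x) for x in nominal_p),
        cumulative_alpha_spent=tuple(float(x) for x in cumulative),
        inflation_factor=infl,
        shape=shape,
    )


def interim_trigger(plan: GSDPlan, total_events: int) -> list[int]:
    """Event counts at which each planned look takes place.

    Each look fires at ``round(fraction * total_events)``; the final look is
    pinned to the full event count.
    """
    if total_events < plan.n_looks:
        raise ValueError(f"total_events {total_events} < number of looks {plan.n_looks}")
    counts = [int(np.rint(f * total_events)) for f in plan.info_fractions]
    counts[-1] = int(total_events)
    return counts
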