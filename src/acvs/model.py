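"""Adaptation-curve model of target choice.

Observers see two always-present targets (a star and a pentagon) and freely
choose which to report.  The probability of choosing the star target is
modelled as a sigmoid read-out of the (lagged) objective distractor
composition:

    p_star(t) = logistic( 2 G tau (q(t - delta) - 1/2) - beta )

where ``q`` is the proportion of pentagon distractors at schedule position
``t`` (piecewise linear over the plateau/transition cycle, evaluated with
linear interpolation and clamped at block boundaries), and

* ``tau >= 0`` scales how strongly choice tracks the objective ratio:
  0 means random choice, large values approach the perfect small-subset
  discriminator;
* ``delta`` (trials) lags the read-out horizontally — the delay with which
  attentional control settings follow the environment;
* ``beta`` shifts the curve vertically on the log-odds scale toward
  pentagon choices (positive beta = pentagon preference).

The gain constant ``G = 6`` fixes the parameter scale: at ``tau = 1`` the
log-odds sweep from -6 to +6 — logistic saturation — over one full
transition, i.e. a tau of one corresponds to an adaptation curve that just
about fully reaches the plateaus, and tau around 10 to near-perfect
discrimination.  Because the distractor ratio is piecewise linear in trial
position, the resulting curve is a chain of connected sigmoids: rising and
falling ramps through the transitions joined by flat plateau segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import PENTAGON, STAR

#: log-odds half-span of one transition at tau = 1
GAIN = 6.0

#: numerical floor keeping curve probabilities strictly inside (0, 1)
_EPS = 1e-9

__all__ = [
    "GAIN", "AdaptationParams", "ChoiceDataset", "objective_proportion",
    "adaptation_curve", "curve_function", "unique_target_probability",
    "plateau_unique_selection", "log_likelihood",
]


@dataclass(frozen=True)
class AdaptationParams:
    """One observer's (or the group-level) adaptation parameters.

    Attributes
    ----------
    tau : float
        Adaptation strength, non-negative.
    delta : float
        Horizontal shift of the curve, in trials (may be negative).
    beta : float
        Vertical bias toward pentagon choices, on the log-odds scale.
    """

    tau: float
    delta: float = 0.0
    beta: float = 0.0

    def __post_init__(self):
        if not self.tau >= 0:
            raise ValueError(f"tau must be non-negative, got {self.tau}")


@dataclass
class ChoiceDataset:
    """Trial records linked to the full design schedule they were drawn on.

    ``trials`` may be a filtered subset (rows removed by preprocessing) but
    every row must keep its ``block`` / ``trial_in_block`` coordinates;
    ``schedule`` is the complete session schedule, optionally with a
    ``participant`` column when participants ran different schedules
    (e.g. counterbalanced starting plateaus).
    """

    trials: pd.DataFrame
    schedule: pd.DataFrame

    def schedule_for(self, participant) -> pd.DataFrame:
        if "participant" in self.schedule.columns:
            sched = self.schedule[self.schedule["participant"] == participant]
            if sched.empty:
                raise ValueError(f"no schedule for participant {participant!r}")
            return sched
        return self.schedule

    def participants(self):
        if "participant" in self.trials.columns:
            return list(pd.unique(self.trials["participant"]))
        return [None]


def objective_proportion(schedule: pd.DataFrame) -> np.ndarray:
    """Per-trial objective proportion of pentagon distractors, in [0, 1]."""
    n_star = schedule["n_star_distractors"].to_numpy(float)
    n_pent = schedule["n_pentagon_distractors"].to_numpy(float)
    return n_pent / (n_star + n_pent)


def schedule_lag_arrays(schedule: pd.DataFrame):
    """Precompute arrays for lagged, block-clamped evaluation of q.

    Returns ``(q, t, lo, hi)``: the pentagon proportion, 1-based global
    positions, and each trial's block-boundary positions.  The lag never
    reads across a block boundary — blocks were separated by breaks, so the
    adaptation state is anchored within the block.
    """
    q = objective_proportion(schedule)
    t = np.arange(1, len(schedule) + 1, dtype=float)
    if "block" in schedule.columns:
        blocks = schedule["block"].to_numpy()
    else:
        blocks = np.zeros(len(schedule), dtype=int)
    lo = np.empty_like(t)
    hi = np.empty_like(t)
    for b in np.unique(blocks):
        mask = blocks == b
        lo[mask] = t[mask].min()
        hi[mask] = t[mask].max()
    return q, t, lo, hi


def lagged_proportion(q, t, lo, hi, delta):
    """Evaluate q at positions ``t - delta`` by linear interpolation.

    ``delta`` may be a scalar or an array broadcastable against ``t`` (e.g.
    shape ``(n_participants, 1)``), enabling vectorised evaluation across
    observers that share a schedule.
    """
    u = np.clip(t - np.asarray(delta), lo, hi)
    i0 = np.clip(np.floor(u).astype(int), lo.astype(int),
                 np.maximum(hi.astype(int) - 1, lo.astype(int)))
    frac = u - i0
    return q[i0 - 1] * (1.0 - frac) + q[np.minimum(i0, len(q) - 1)] * frac


def adaptation_curve(params: AdaptationParams,
                     schedule: pd.DataFrame) -> np.ndarray:
    """Per-trial probability of choosing the *star* target.

    Values are strictly inside (0, 1) for finite parameters.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    q, t, lo, hi = schedule_lag_arrays(schedule)
    qlag = lagged_proportion(q, t, lo, hi, params.delta)
    z = 2.0 * GAIN * params.tau * (qlag - 0.5) - params.beta
    # keep probabilities strictly inside (0, 1) even where expit saturates
    return np.clip(expit(z), _EPS, 1.0 - _EPS)


def curve_function(params: AdaptationParams, schedule: pd.DataFrame):
    """Continuous-position version of the curve for a single-block schedule.

    Returns a callable ``p(pos)`` of real-valued schedule position, useful
    for inspecting the horizontal-shift semantics of ``delta`` on a dense
    grid.
    """
    q, t, lo, hi = schedule_lag_arrays(schedule)
    if not (lo == lo[0]).all():
        raise ValueError("curve_function expects a single-block schedule")

    def p(pos):
        pos = np.asarray(pos, dtype=float)
        u = np.clip(pos - params.delta, lo[0], hi[0])
        qlag = np.interp(u, t, q)
        z = 2.0 * GAIN * params.tau * (qlag - 0.5) - params.beta
        return np.clip(expit(z), _EPS, 1.0 - _EPS)

    return p


def unique_target_probability(p_star: np.ndarray,
                              schedule: pd.DataFrame) -> np.ndarray:
    """Probability of choosing the target from the smaller shape subset.

    On trials where both subsets are equal (transition centre) there is no
    unique target and the value is NaN.
    """
    n_star = schedule["n_star_distractors"].to_numpy(float)
    n_pent = schedule["n_pentagon_distractors"].to_numpy(float)
    out = np.full(len(schedule), np.nan)
    # fewer star distractors -> star target is (more) unique
    star_unique = n_star < n_pent
    pent_unique = n_pent < n_star
    out[star_unique] = p_star[star_unique]
    out[pent_unique] = 1.0 - p_star[pent_unique]
    return out


def plateau_unique_selection(params: AdaptationParams,
                             schedule: pd.DataFrame) -> pd.Series:
    """Mean predicted unique-target selection on plateau trials, by state.

    Returns a Series indexed by the plateau's shape state (``"star"`` for
    all-star-distractor plateaus, where the pentagon target is unique, and
    vice versa).  With a positive pentagon bias the star-plateau mean
    exceeds the pentagon-plateau mean.
    """
    p_star = adaptation_curve(params, schedule)
    p_unique = unique_target_probability(p_star, schedule)
    mask = schedule["phase_type"].to_numpy() == "plateau"
    state = schedule["plateau_state"].to_numpy()
    return pd.Series({
        s: float(np.nanmean(p_unique[mask & (state == s)]))
        for s in (STAR, PENTAGON)
    })


def _star_indicator(choices: pd.Series) -> np.ndarray:
    vals = choices.to_numpy()
    bad = ~np.isin(vals, [STAR, PENTAGON])
    if bad.any():
        raise ValueError(f"invalid choice labels: {set(vals[bad])!r}")
    return (vals == STAR).astype(float)


def log_likelihood(params: AdaptationParams, dataset: ChoiceDataset) -> float:
    """Bernoulli log-likelihood of the recorded choices under the curve.

    Each trial contributes ``log p_star`` for a star choice and
    ``log (1 - p_star)`` for a pentagon choice, with the curve evaluated on
    the participant's full schedule (so the lag sees the true trial
    positions even when intervening trials were filtered out).
    """
    total = 0.0
    trials = dataset.trials
    if "choice" not in trials.columns:
        raise ValueError("trials must have a 'choice' column")
    for pid in dataset.participants():
        sub = trials if pid is None else trials[trials["participant"] == pid]
        sched = dataset.schedule_for(pid)
        p_star = adaptation_curve(params, sched)
        key = sched.reset_index()[["block", "trial_in_block"]]
        lookup = pd.Series(
            np.arange(len(sched)),
            index=pd.MultiIndex.from_frame(key),
        )
        try:
            rows = lookup.loc[list(zip(sub["block"], sub["trial_in_block"]))].to_numpy()
        except KeyError as err:
            raise ValueError(
                "trial not present in the linked schedule") from err
        y = _star_indicator(sub["choice"])
        p = np.clip(p_star[rows], 1e-12, 1 - 1e-12)
        total += float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    return total
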