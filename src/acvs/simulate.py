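"""Synthetic studies with the statistical structure the analyses assume.

The generator emulates a complete experiment: counterbalanced session
schedules, participant heterogeneity in the adaptation parameters, Bernoulli
choices from the adaptation curve, lognormal response times that are slower
during transitions than plateaus, contamination (wrong-digit reports,
timeouts, chance-level participants) to exercise the exclusion filters, and
item-level fixation sequences from a simple two-state agent that tends to
stay within the currently inspected shape subset until it finds the
eventually chosen target.

The fixation agent is a test harness with transparent parameters, not a
cognitive claim.  All randomness flows from one root seed through named
substreams (cohort, choices, response times, contamination, displays,
fixations), so every generated study is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import design
from .design import PENTAGON, STAR, TARGET_DIGITS, DISTRACTOR_DIGITS
from .model import AdaptationParams, ChoiceDataset, adaptation_curve

__all__ = ["SimulationConfig", "SimulatedStudy", "draw_participants",
           "simulate_study"]


@dataclass
class SimulationConfig:
    """Study-level settings for :func:`simulate_study`.

    Defaults emulate the online experiment's scale (four main blocks) with
    group-level parameters in the empirically observed range: adaptation
    around 0.1, a lag slightly above one trial, and a mild pentagon bias.
    Response times are lognormal with arithmetic phase means of 950 ms
    (plateau) and 950 + 60 ms (transition), matching the observed
    plateau/transition contrast magnitude.
    """

    n_participants: int = 30
    n_practice: int = 2
    n_main: int = 4
    cycles_per_practice: int = 1
    cycles_per_main: int = 3

    tau_mean: float = 0.1
    tau_sd: float = 0.04
    delta_mean: float = 1.2
    delta_sd: float = 0.6
    beta_mean: float = 0.15
    beta_sd: float = 0.25

    rt_plateau_mean_ms: float = 950.0
    rt_transition_offset_ms: float = 60.0
    rt_sigma: float = 0.25          # lognormal shape parameter

    wrong_digit_rate: float = 0.025
    timeout_rate: float = 0.001
    rt_timeout_ms: float = 5000.0
    n_chance_participants: int = 0

    fixations: bool = True
    p_stay: float = 0.8
    p_first_on_target: float | object = 0.125   # scalar or f(pos_in_cycle)
    #: False = stay-with-subset agent; True or "item" = every fixation
    #: uniform over the 16 items (chance-level reference for normalized
    #: proportions); "shape" = shape class drawn fairly each fixation,
    #: independent of the eventual choice (null for chosen-shape excess)
    uniform_fixations: bool | str = False
    max_fixations: int = 12
    fixation_jitter_px: float = 8.0

    seed: int = 0

    def __post_init__(self):
        for name in ("wrong_digit_rate", "timeout_rate", "p_stay"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("tau_sd", "delta_sd", "beta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau_mean < 0:
            raise ValueError("tau_mean must be non-negative")


@dataclass
class SimulatedStudy:
    """A generated study plus the ground truth that produced it."""

    dataset: ChoiceDataset
    fixations: pd.DataFrame | None
    items: pd.DataFrame | None
    manifest: dict


def draw_participants(config: SimulationConfig,
                      rng=None) -> pd.DataFrame:
    """Draw per-participant adaptation parameters from the group model.

    tau is lognormal, moment-matched to (tau_mean, tau_sd) on the natural
    scale — the same family the hierarchical model assumes — so the
    configured mean is the recoverable group-level quantity; delta and beta
    are normal.  Zero SDs collapse to the group means; the last
    ``n_chance_participants`` are flagged chance-level responders.
    """
    rng = np.random.default_rng(
        rng if rng is not None else np.random.SeedSequence(config.seed))
    n = config.n_participants
    if config.tau_mean == 0 or config.tau_sd == 0:
        tau = np.full(n, config.tau_mean, dtype=float)
    else:
        s2 = np.log1p((config.tau_sd / config.tau_mean) ** 2)
        mu = np.log(config.tau_mean) - s2 / 2
        tau = rng.lognormal(mu, np.sqrt(s2), size=n)
    delta = config.delta_mean + config.delta_sd * rng.normal(size=n)
    beta = config.beta_mean + config.beta_sd * rng.normal(size=n)
    ids = [f"p{i + 1:03d}" for i in range(n)]
    chance = np.zeros(n, dtype=bool)
    if config.n_chance_participants:
        chance[n - config.n_chance_participants:] = True
    return pd.DataFrame({"participant": ids, "tau": tau, "delta": delta,
                         "beta": beta, "chance_level": chance})


def _simulate_fixation_trial(rng, shapes, roles, chosen_idx, pos_in_cycle,
                             config):
    """Item-index fixation sequence for one trial."""
    n_items = len(shapes)
    if config.uniform_fixations:
        n_fix = int(rng.integers(3, 8))
        if config.uniform_fixations == "shape":
            out = []
            for _ in range(n_fix):
                s = STAR if rng.uniform() < 0.5 else PENTAGON
                out.append(int(rng.choice(np.flatnonzero(shapes == s))))
            return out
        return list(rng.integers(0, n_items, size=n_fix))
    p_first = config.p_first_on_target
    if callable(p_first):
        p_first = float(p_first(pos_in_cycle))
    targets = np.flatnonzero(roles == "target")
    if rng.uniform() < p_first:
        current = int(rng.choice(targets))
    else:
        current = int(rng.integers(0, n_items))
    seq = [current]
    shape = shapes[current]
    for _ in range(config.max_fixations - 1):
        if seq[-1] == chosen_idx:
            return seq
        if rng.uniform() >= config.p_stay:
            shape = PENTAGON if shape == STAR else STAR
        pool = np.flatnonzero(shapes == shape)
        seq.append(int(rng.choice(pool)))
    if seq[-1] != chosen_idx:
        seq.append(int(chosen_idx))   # the chosen target ends the search
    return seq


def simulate_study(config: SimulationConfig,
                   seed: int | None = None) -> SimulatedStudy:
    """Generate a full synthetic study.

    Returns trials (with schedule context and behavioral outcomes), the
    per-participant schedules, and — unless ``config.fixations`` is off —
    display items and fixation tables, plus a manifest recording all ground
    truth for recovery tests.
    """
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    s_cohort, s_choice, s_rt, s_contam, s_display, s_fix = root.spawn(6)
    cohort = draw_participants(config, s_cohort)
    rng_choice = np.random.default_rng(s_choice)
    rng_rt = np.random.default_rng(s_rt)
    rng_contam = np.random.default_rng(s_contam)
    rng_display = np.random.default_rng(s_display)
    rng_fix = np.random.default_rng(s_fix)

    trial_frames, schedule_frames = [], []
    item_rows, fix_rows = [], []
    centers = design.grid_pixel_centers()

    for i, prow in cohort.iterrows():
        pid = prow["participant"]
        start = STAR if i % 2 == 0 else PENTAGON
        sched = design.build_session(
            config.n_practice, config.n_main, config.cycles_per_practice,
            config.cycles_per_main, first_block_start=start)
        sched_p = sched.copy()
        sched_p.insert(0, "participant", pid)
        schedule_frames.append(sched_p)

        n_trials = len(sched)
        params = AdaptationParams(tau=prow["tau"], delta=prow["delta"],
                                  beta=prow["beta"])
        p_star = adaptation_curve(params, sched)
        if prow["chance_level"]:
            p_star = np.full(n_trials, 0.5)
        star_choice = rng_choice.uniform(size=n_trials) < p_star

        # response times: lognormal with phase-dependent arithmetic mean
        mean_ms = np.where(
            sched["phase_type"] == "transition",
            config.rt_plateau_mean_ms + config.rt_transition_offset_ms,
            config.rt_plateau_mean_ms)
        mu = np.log(mean_ms) - config.rt_sigma ** 2 / 2
        rt = rng_rt.lognormal(mu, config.rt_sigma)
        timeout = rng_contam.uniform(size=n_trials) < config.timeout_rate
        rt[timeout] = (config.rt_timeout_ms + 1.0
                       + rng_contam.exponential(300.0, size=timeout.sum()))

        # target digits; the reported digit is the chosen target's digit,
        # a non-displayed key for wrong-digit lapses, or uniform for
        # chance-level responders
        digits = np.array([rng_display.choice(TARGET_DIGITS, size=2,
                                              replace=False)
                           for _ in range(n_trials)])
        d_star, d_pent = digits[:, 0], digits[:, 1]
        reported = np.where(star_choice, d_star, d_pent)
        wrong = rng_contam.uniform(size=n_trials) < config.wrong_digit_rate
        if wrong.any():
            others = np.array([
                rng_contam.choice(np.setdiff1d(TARGET_DIGITS, row))
                for row in digits[wrong]])
            reported = reported.copy()
            reported[wrong] = others
        if prow["chance_level"]:
            reported = rng_contam.choice(TARGET_DIGITS, size=n_trials)

        trials = sched.copy()
        trials.insert(0, "participant", pid)
        trials["choice"] = np.where(star_choice, STAR, PENTAGON)
        trials["target_digit_star"] = d_star
        trials["target_digit_pentagon"] = d_pent
        trials["reported_digit"] = reported
        trials["correct"] = (reported == d_star) | (reported == d_pent)
        trials["rt_ms"] = rt
        trial_frames.append(trials)

        if config.fixations:
            for j in range(n_trials):
                srow = sched.iloc[j]
                n_star = int(srow["n_star_distractors"])
                n_pent = int(srow["n_pentagon_distractors"])
                n_items = n_star + n_pent + 2
                cells = rng_display.choice(35, size=n_items, replace=False)
                rows_, cols_ = np.divmod(cells, design.GRID_COLS)
                shapes = np.array([STAR, PENTAGON] + [STAR] * n_star
                                  + [PENTAGON] * n_pent)
                roles = np.array(["target", "target"]
                                 + ["distractor"] * (n_items - 2))
                item_digits = np.concatenate(
                    [digits[j], rng_display.choice(DISTRACTOR_DIGITS,
                                                   size=n_items - 2)])
                x = centers[rows_, cols_, 0]
                y = centers[rows_, cols_, 1]
                tnum = int(srow["trial"])
                for k in range(n_items):
                    item_rows.append((pid, tnum, k, int(rows_[k]),
                                      int(cols_[k]), roles[k], shapes[k],
                                      int(item_digits[k]), x[k], y[k]))
                chosen_idx = 0 if star_choice[j] else 1
                seq = _simulate_fixation_trial(
                    rng_fix, shapes, roles, chosen_idx,
                    int(srow["pos_in_cycle"]), config)
                onset = 150.0
                for fi, item in enumerate(seq):
                    dur = float(rng_fix.lognormal(np.log(200.0), 0.2))
                    fix_rows.append((
                        pid, tnum, fi + 1,
                        x[item] + rng_fix.normal(0, config.fixation_jitter_px),
                        y[item] + rng_fix.normal(0, config.fixation_jitter_px),
                        onset, dur))
                    onset += dur + 30.0

    trials = pd.concat(trial_frames, ignore_index=True)
    schedule = pd.concat(schedule_frames, ignore_index=True)
    items = fixes = None
    if config.fixations:
        items = pd.DataFrame(
            item_rows, columns=["participant", "trial", "item", "row", "col",
                                "role", "shape", "digit", "x_px", "y_px"])
        fixes = pd.DataFrame(
            fix_rows, columns=["participant", "trial", "fix_index", "x_px",
                               "y_px", "onset_ms", "duration_ms"])

    manifest = {
        "config": asdict(config),
        "seed": int(seed if seed is not None else config.seed),
        "group": {"tau": config.tau_mean, "delta": config.delta_mean,
                  "beta": config.beta_mean},
        "participants": cohort.to_dict(orient="records"),
        "chance_participants": cohort.loc[cohort["chance_level"],
                                          "participant"].tolist(),
        "rt": {"plateau_mean_ms": config.rt_plateau_mean_ms,
               "transition_offset_ms": config.rt_transition_offset_ms},
    }
    manifest["config"]["p_first_on_target"] = (
        None if callable(config.p_first_on_target)
        else config.p_first_on_target)
    dataset = ChoiceDataset(trials=trials, schedule=schedule)
    return SimulatedStudy(dataset=dataset, fixations=fixes, items=items,
                          manifest=manifest)
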