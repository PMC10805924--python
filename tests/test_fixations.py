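"""Fixation assignment and the normalized fixation-proportion statistics."""

import numpy as np
import pandas as pd
import pytest

from acvs.fixations import (assign_fixations, chosen_vs_nonchosen_plateau,
                            first_fixation_on_target_by_position,
                            normalized_shape_proportions)
from acvs.preprocessing import exclude_invalid_trials
from acvs.simulate import SimulationConfig, simulate_study


def plateau_display(participant="a", trial=1):
    """16-item pentagon-plateau display on a simple pixel grid."""
    rows = []
    for k in range(16):
        shape = "star" if k == 0 else "pentagon"
        role = "target" if k in (0, 1) else "distractor"
        rows.append({"participant": participant, "trial": trial, "item": k,
                     "role": role, "shape": shape,
                     "x_px": 100.0 * (k % 8), "y_px": 100.0 * (k // 8)})
    return pd.DataFrame(rows)


def plateau_trial_row(participant="a", trial=1, choice="star"):
    return {"participant": participant, "trial": trial,
            "n_star_distractors": 0, "n_pentagon_distractors": 14,
            "cycle_start": "pentagon", "pos_in_cycle": 1,
            "phase_type": "plateau", "plateau_state": "pentagon",
            "choice": choice}


def fixation_row(participant, trial, fix_index, x, y):
    return {"participant": participant, "trial": trial,
            "fix_index": fix_index, "x_px": x, "y_px": y,
            "onset_ms": 100.0 * fix_index, "duration_ms": 200.0}


class TestAssignFixations:
    def test_center_hit_assigns_that_item(self):
        items = plateau_display()
        fix = pd.DataFrame([fixation_row("a", 1, 1, 300.0, 100.0)])
        out = assign_fixations(fix, items)
        assert out["assigned_item"].iloc[0] == 11   # (x=300, y=100)
        assert not out["tie"].iloc[0]

    def test_equidistant_tie_takes_lowest_index_and_flags(self):
        items = plateau_display()
        fix = pd.DataFrame([fixation_row("a", 1, 1, 50.0, 0.0)])
        out = assign_fixations(fix, items)
        assert out["assigned_item"].iloc[0] == 0
        assert out["tie"].iloc[0]

    def test_matches_exhaustive_distance_scan(self):
        rng = np.random.default_rng(8)
        items = plateau_display()
        fix = pd.DataFrame([
            fixation_row("a", 1, i + 1, rng.uniform(-50, 800),
                         rng.uniform(-50, 250))
            for i in range(200)])
        out = assign_fixations(fix, items)
        for _, f in out.iterrows():
            dists = [np.hypot(f["x_px"] - it["x_px"], f["y_px"] - it["y_px"])
                     for _, it in items.iterrows()]
            assert f["assigned_item"] == int(np.argmin(dists))

    def test_missing_display_raises(self):
        fix = pd.DataFrame([fixation_row("a", 99, 1, 0.0, 0.0)])
        with pytest.raises(ValueError, match="no display"):
            assign_fixations(fix, plateau_display())


class TestNormalizedShapeProportions:
    def test_uniform_single_fixation_gives_chance_for_both_shapes(self):
        """One fixation per trial, cycled over all 16 items: the mean
        normalized proportion is exactly 1/16 for both shape classes."""
        items = pd.concat([plateau_display(trial=t) for t in range(1, 17)],
                          ignore_index=True)
        trials = pd.DataFrame([plateau_trial_row(trial=t)
                               for t in range(1, 17)])
        fix = pd.DataFrame([
            fixation_row("a", t, 1, 100.0 * ((t - 1) % 8),
                         100.0 * ((t - 1) // 8))
            for t in range(1, 17)])
        table = assign_fixations(fix, items)
        props = normalized_shape_proportions(table, trials, which="first")
        for shape in ("star", "pentagon"):
            val = props.loc[props["shape"] == shape, "mean"].iloc[0]
            assert val == pytest.approx(1 / 16)

    def test_all_first_fixations_on_the_unique_item(self):
        items = pd.concat([plateau_display(trial=t) for t in (1, 2)],
                          ignore_index=True)
        trials = pd.DataFrame([plateau_trial_row(trial=t) for t in (1, 2)])
        fix = pd.DataFrame([fixation_row("a", t, 1, 0.0, 0.0)
                            for t in (1, 2)])   # item 0 = unique star target
        table = assign_fixations(fix, items)
        props = normalized_shape_proportions(table, trials, which="first")
        star = props.loc[props["shape"] == "star", "mean"].iloc[0]
        pent = props.loc[props["shape"] == "pentagon", "mean"].iloc[0]
        assert star == pytest.approx(1.0)
        assert pent == pytest.approx(0.0)

    def test_equal_count_trials_rescale_raw_proportions(self):
        # at the transition centre both shapes have 8 items (7 distractors
        # + target): normalized = raw / 8, so ordering is preserved
        items = plateau_display()
        items.loc[2:8, "shape"] = "star"   # now 8 star, 8 pentagon
        trials = pd.DataFrame([{**plateau_trial_row(),
                                "n_star_distractors": 7,
                                "n_pentagon_distractors": 7,
                                "phase_type": "transition",
                                "plateau_state": ""}])
        fix = pd.DataFrame([fixation_row("a", 1, i + 1, 100.0 * i, 0.0)
                            for i in range(5)])
        table = assign_fixations(fix, items)
        props = normalized_shape_proportions(table, trials, which="total")
        raw_star = (table["assigned_shape"] == "star").mean()
        star = props.loc[props["shape"] == "star", "mean"].iloc[0]
        assert star == pytest.approx(raw_star / 8)


class TestChosenVsNonchosen:
    def _study_tables(self, seed, p_stay, uniform=False, n_boot=1500,
                      n_participants=8):
        cfg = SimulationConfig(n_participants=n_participants, n_practice=0,
                               n_main=2,
                               fixations=True, p_stay=p_stay,
                               uniform_fixations=uniform, seed=seed)
        study = simulate_study(cfg)
        trials, _ = exclude_invalid_trials(study.dataset.trials)
        table = assign_fixations(study.fixations, study.items)
        return chosen_vs_nonchosen_plateau(table, trials, n_boot=n_boot,
                                           seed=seed)

    def test_pure_chosen_shape_agent_gives_proportion_one(self):
        items = pd.concat([plateau_display(trial=t) for t in (1, 2)],
                          ignore_index=True)
        trials = pd.DataFrame([plateau_trial_row(trial=t, choice="pentagon")
                               for t in (1, 2)])
        # every fixation on pentagon items (the chosen shape)
        fix = pd.DataFrame([fixation_row("a", t, i + 1, 100.0 * (i + 2), 0.0)
                            for t in (1, 2) for i in range(3)])
        table = assign_fixations(fix, items)
        out = chosen_vs_nonchosen_plateau(table, trials, n_boot=200, seed=0)
        df = out["nonunique_chosen"]
        assert df.loc["chosen", "total"] == pytest.approx(1.0)
        assert df.loc["difference", "total"] == pytest.approx(1.0)

    def test_shape_fair_agent_difference_straddles_zero(self):
        # fixated shape drawn fairly each fixation, independent of choice
        out = self._study_tables(seed=31, p_stay=0.5, uniform="shape",
                                 n_participants=16)
        for df in out.values():
            assert (df.loc["difference", "first_hdi_low"] <= 0
                    <= df.loc["difference", "first_hdi_high"])

    def test_subset_agent_last_exceeds_first_difference(self):
        out = self._study_tables(seed=32, p_stay=0.9)
        for df in out.values():
            assert (df.loc["difference", "last"]
                    > df.loc["difference", "first"])
            assert df.loc["difference", "last"] > 0


class TestFirstFixationOnTarget:
    def test_always_on_target_agent(self):
        items = plateau_display()
        trials = pd.DataFrame([plateau_trial_row()])
        fix = pd.DataFrame([fixation_row("a", 1, 1, 0.0, 0.0)])
        table = assign_fixations(fix, items)
        out = first_fixation_on_target_by_position(table, trials)
        assert out["prop"].iloc[0] == 1.0

    def test_uniform_first_fixations_land_on_targets_at_two_sixteenths(self):
        items = pd.concat([plateau_display(trial=t) for t in range(1, 17)],
                          ignore_index=True)
        trials = pd.DataFrame([plateau_trial_row(trial=t)
                               for t in range(1, 17)])
        fix = pd.DataFrame([
            fixation_row("a", t, 1, 100.0 * ((t - 1) % 8),
                         100.0 * ((t - 1) // 8))
            for t in range(1, 17)])
        table = assign_fixations(fix, items)
        out = first_fixation_on_target_by_position(table, trials)
        assert out["prop"].iloc[0] == pytest.approx(2 / 16)

    def test_cycle_modulated_target_probability_is_recovered(self):
        mod = lambda pos: 0.6 if pos <= 3 else 0.1
        cfg = SimulationConfig(n_participants=8, n_practice=0, n_main=2,
                               fixations=True, p_first_on_target=mod,
                               seed=33)
        study = simulate_study(cfg)
        table = assign_fixations(study.fixations, study.items)
        out = first_fixation_on_target_by_position(
            table, study.dataset.trials)
        plateau = out[out["pos_in_cycle"] <= 3]["prop"].mean()
        transition = out[out["pos_in_cycle"] > 3]["prop"].mean()
        # baseline uniform fixations add ~2/16 on top of the planted rates
        assert plateau > transition + 0.2
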