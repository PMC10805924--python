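"""Schedule and display construction: structural invariants of the paradigm."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acvs.design import (PENTAGON, STAR, ScheduleConfigError, build_cycle,
                         build_session, render_display, validate_schedule)


class TestBuildCycle:
    def test_default_cycle_structure(self):
        cyc = build_cycle(STAR)
        assert len(cyc) == 32
        # opening star plateau: no pentagon distractors
        assert (cyc["n_pentagon_distractors"].iloc[:3] == 0).all()
        # counts always sum to 14
        total = cyc["n_star_distractors"] + cyc["n_pentagon_distractors"]
        assert (total == 14).all()
        # transition centre has equal shape counts
        t7 = cyc[cyc["phase"] == "T7"]
        assert (t7["n_star_distractors"] == 7).all()
        assert (t7["n_pentagon_distractors"] == 7).all()

    def test_transitions_step_by_one(self):
        cyc = build_cycle(PENTAGON)
        diffs = np.diff(cyc["n_star_distractors"].to_numpy())
        trans = cyc["phase_type"].to_numpy() == "transition"
        within = trans[1:] & trans[:-1]
        assert set(np.abs(diffs[within])) == {1}

    def test_smallest_legal_cycle(self):
        cyc = build_cycle(STAR, plateau_len=1, transition_len=1,
                          n_distractors=2)
        got = list(zip(cyc["n_pentagon_distractors"],
                       cyc["n_star_distractors"]))
        assert got == [(0, 2), (1, 1), (2, 0), (1, 1)]

    @pytest.mark.parametrize("kwargs", [
        dict(plateau_len=0), dict(transition_len=0),
        dict(transition_len=5, n_distractors=4),
    ])
    def test_invalid_lengths_raise(self, kwargs):
        with pytest.raises(ScheduleConfigError):
            build_cycle(STAR, **kwargs)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(plateau_len=st.integers(1, 4), transition_len=st.integers(1, 13),
           extra=st.integers(0, 6),
           start=st.sampled_from([STAR, PENTAGON]))
    def test_cycle_invariants_hold_generally(self, plateau_len,
                                             transition_len, extra, start):
        n_distractors = transition_len + extra
        cyc = build_cycle(start, plateau_len, transition_len, n_distractors)
        assert len(cyc) == 2 * (plateau_len + transition_len)
        total = cyc["n_star_distractors"] + cyc["n_pentagon_distractors"]
        assert (total == n_distractors).all()
        plateaus = cyc[cyc["phase_type"] == "plateau"]
        assert (plateaus[["n_star_distractors",
                          "n_pentagon_distractors"]].min(axis=1) == 0).all()


class TestBuildSession:
    @pytest.mark.parametrize("n_main,expected", [(4, 466), (8, 862)])
    def test_published_session_lengths(self, n_main, expected):
        session = build_session(2, n_main)
        assert len(session) == expected
        # practice 35 trials, main 99
        sizes = session.groupby("block").size()
        types = session.drop_duplicates("block").set_index("block")["block_type"]
        assert (sizes[types == "practice"] == 35).all()
        assert (sizes[types == "main"] == 99).all()
        validate_schedule(session)

    def test_first_plateau_alternates_between_blocks(self):
        session = build_session(2, 4, first_block_start=PENTAGON)
        firsts = session.drop_duplicates("block")["block_first_plateau"].tolist()
        assert firsts[0] == PENTAGON
        assert all(a != b for a, b in zip(firsts, firsts[1:]))

    def test_empty_session(self):
        assert len(build_session(0, 0)) == 0

    def test_objective_proportion_is_piecewise_linear_with_plateaus(self):
        session = build_session(0, 1)
        q = session["n_pentagon_distractors"].to_numpy() / 14
        phases = session["phase_type"].to_numpy()
        # plateau values pinned at 0 or 1
        assert set(q[phases == "plateau"]) <= {0.0, 1.0}
        # second differences vanish inside transitions (linearity)
        d2 = np.diff(q, 2)
        interior = (phases[1:-1] == "transition") & \
            (phases[:-2] == "transition") & (phases[2:] == "transition")
        assert np.allclose(d2[interior], 0.0)


class TestRenderDisplay:
    @pytest.fixture
    def trial(self):
        return build_cycle(PENTAGON).iloc[0]   # pentagon plateau trial

    def test_item_composition(self, trial):
        disp = render_display(trial, rng=1)
        assert len(disp) == 16
        assert (disp["color"] == "black").sum() == 14
        assert (disp["color"] == "blue").sum() == 2
        targets = disp[disp["role"] == "target"]
        assert set(targets["shape"]) == {STAR, PENTAGON}
        # digits: targets distinct in 1-4, distractors in 5-8
        assert set(targets["digit"]) <= {1, 2, 3, 4}
        assert targets["digit"].nunique() == 2
        assert set(disp.loc[disp["role"] == "distractor", "digit"]) <= {5, 6, 7, 8}

    def test_unique_shape_on_pentagon_plateau_is_the_star_target(self, trial):
        disp = render_display(trial, rng=2)
        stars = disp[disp["shape"] == STAR]
        assert len(stars) == 1
        assert stars.iloc[0]["role"] == "target"

    def test_positions_distinct_and_match_schedule(self, trial):
        disp = render_display(trial, rng=3)
        assert not disp.duplicated(["row", "col"]).any()
        assert (disp["shape"] == PENTAGON).sum() == \
            trial["n_pentagon_distractors"] + 1

    def test_deterministic_given_seed(self, trial):
        a = render_display(trial, rng=11)
        b = render_display(trial, rng=11)
        pd.testing.assert_frame_equal(a, b)
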