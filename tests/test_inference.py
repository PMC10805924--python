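"""Posterior summaries (mode, HDI, contrasts) and the hierarchical fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import arviz as az

from acvs.inference import (HierarchicalSpec, contrast, fit_hierarchical,
                            hdi, posterior_mode)
from acvs.model import AdaptationParams, ChoiceDataset, log_likelihood
from acvs.simulate import SimulationConfig, simulate_study


def hdi_bruteforce(x, mass=0.95):
    """Exhaustive scan over every window of ceil(mass*n) sorted draws."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    k = int(np.ceil(mass * n))
    best = (np.inf, None)
    for j in range(n - k + 1):
        width = x[j + k - 1] - x[j]
        if width < best[0]:
            best = (width, (x[j], x[j + k - 1]))
    return best[1]


class TestHdi:
    def test_point_mass(self):
        assert hdi(np.full(200, 3.5)) == (3.5, 3.5)

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100_000)
        low, high = hdi(x, 0.95)
        assert low == pytest.approx(-1.96, abs=0.05)
        assert high == pytest.approx(1.96, abs=0.05)

    def test_mass_validation(self):
        with pytest.raises(ValueError):
            hdi(np.arange(100), mass=1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(100, 400),
           mass=st.sampled_from([0.5, 0.8, 0.95]))
    def test_matches_exhaustive_window_scan(self, seed, n, mass):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 1.0, size=n)   # skewed, to exercise asymmetry
        assert hdi(x, mass) == hdi_bruteforce(x, mass)

    def test_agrees_with_arviz_on_large_samples(self):
        # independent implementation cross-check (conventions differ by
        # one order statistic at most, so compare loosely)
        rng = np.random.default_rng(4)
        x = rng.gamma(3.0, 2.0, size=50_000)
        ours = hdi(x)
        theirs = az.hdi(x, hdi_prob=0.95)
        assert ours[0] == pytest.approx(theirs[0], abs=0.05)
        assert ours[1] == pytest.approx(theirs[1], abs=0.05)


class TestPosteriorMode:
    def test_degenerate_sample(self):
        assert posterior_mode(np.full(150, 2.0)) == 2.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            posterior_mode([])

    def test_standard_normal_mode_near_zero(self):
        # precision is bandwidth-limited: Silverman bw ~ 0.11 at n = 1e5
        rng = np.random.default_rng(2)
        assert abs(posterior_mode(rng.standard_normal(100_000))) < 0.1

    def test_right_skew_puts_mode_below_mean(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50_000) ** 2
        assert posterior_mode(x) < x.mean()


class TestContrast:
    def test_identical_samples(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=2000)
        c = contrast(a, a.copy())
        assert c.mode == pytest.approx(0.0)
        assert c.hdi_low <= 0 <= c.hdi_high

    def test_unit_shift(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=5000)
        c = contrast(a, a + 1.0)
        assert c.mode == pytest.approx(-1.0, abs=0.05)
        assert c.frac_below_zero == 1.0

    def test_length_mismatch_truncates(self):
        c = contrast(np.zeros(500), np.zeros(300))
        assert c.mode == 0.0


@pytest.fixture(scope="module")
def fitted(behavioral_study):
    spec = HierarchicalSpec(chains=2, draws=400, tune=400, seed=9)
    return fit_hierarchical(behavioral_study.dataset, spec)


class TestFitHierarchical:
    def test_summary_layout_and_hdi_mass(self, fitted):
        for name in ("tau", "delta", "beta"):
            row = fitted.summaries.loc[name]
            assert row["hdi_low"] <= row["mode"] <= row["hdi_high"]
        assert fitted.draws["tau"].shape == (2, 400)
        assert (fitted.draws["tau"] > 0).all()

    def test_same_seed_reproduces_summaries(self, behavioral_study):
        spec = HierarchicalSpec(chains=1, draws=150, tune=150, seed=21)
        a = fit_hierarchical(behavioral_study.dataset, spec)
        b = fit_hierarchical(behavioral_study.dataset, spec)
        pd.testing.assert_frame_equal(a.summaries, b.summaries)

    def test_practice_blocks_excluded_by_default(self, behavioral_study,
                                                 fitted):
        trials = behavioral_study.dataset.trials
        assert (trials["block_type"] == "practice").any()
        # stacking with practice included must see more trials
        from acvs.inference import _StackedData
        with_p = _StackedData(behavioral_study.dataset, True)
        without_p = _StackedData(behavioral_study.dataset, False)
        assert len(with_p.y) > len(without_p.y)

    def test_shrinkage_toward_group_mean(self):
        """Partial pooling: participant posterior means sit between the
        no-pooling maximum-likelihood estimate and the group mean (with a
        small pad absorbing Monte-Carlo and optimiser noise)."""
        from scipy.optimize import minimize
        cfg = SimulationConfig(n_participants=15, n_practice=0, n_main=2,
                               fixations=False, seed=42)
        study = simulate_study(cfg)
        fitted = fit_hierarchical(
            study.dataset, HierarchicalSpec(chains=2, draws=500, tune=500,
                                            seed=9))
        ds = study.dataset
        trials = ds.trials
        inside = 0
        checks = 0
        for pname, col in (("tau", 0), ("delta", 1), ("beta", 2)):
            group_mean = fitted.flat(pname).mean()
            part = fitted.flat(f"{pname}_participant").mean(axis=0)
            for i, pid in enumerate(fitted.participants):
                sub = ChoiceDataset(
                    trials[trials["participant"] == pid],
                    ds.schedule_for(pid))

                def nll(x):
                    return -log_likelihood(
                        AdaptationParams(np.exp(x[0]), x[1], x[2]), sub)

                x_mle = minimize(nll, [-2.3, 1.0, 0.0],
                                 method="Nelder-Mead").x
                mle = np.exp(x_mle[0]) if col == 0 else x_mle[col]
                lo, hi = sorted([mle, group_mean])
                pad = 0.05 * (hi - lo) + 0.02
                checks += 1
                inside += lo - pad <= part[i] <= hi + pad
        assert inside / checks >= 0.9
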