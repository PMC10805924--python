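"""Response-time analysis: phase-wise means and Bayesian two-group comparison.

Searching is easiest when one target is a shape singleton, so plateau trials
should be answered faster than transition trials.  The comparison follows
the BEST procedure (Kruschke's Bayesian alternative to the two-sample t
test): each group is modelled with a Student-t distribution, with
data-scaled vague priors on the group means and scales and a
shifted-exponential prior on the shared normality parameter nu.

The plateau-vs-transition comparison treats the two per-participant mean
vectors as independent groups, mirroring the two-sample framing of the
original analyses even though the samples are paired; pass the difference
vector to :func:`best_compare` against zeros (or use ``paired=True`` in
:func:`plateau_transition_best`) for a paired variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import hdi, posterior_mode

__all__ = ["BESTResult", "mean_rt_by_phase", "best_compare",
           "plateau_transition_best"]


@dataclass
class BESTResult:
    """Posterior summaries from the two-group Student-t comparison."""

    mean_a_mode: float
    mean_a_hdi: tuple
    mean_b_mode: float
    mean_b_hdi: tuple
    diff_mode: float
    diff_hdi: tuple
    frac_diff_above_zero: float
    frac_diff_below_zero: float
    draws: dict


def mean_rt_by_phase(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean RT (ms) on plateau and transition trials.

    Participants lacking trials in either phase are dropped with a warning.
    Expects preprocessed trials with ``phase_type`` and ``rt_ms`` columns.
    """
    means = (trials.groupby(["participant", "phase_type"])["rt_ms"]
             .mean().unstack("phase_type"))
    means = means.rename(columns={"plateau": "plateau_mean_ms",
                                  "transition": "transition_mean_ms"})
    for col in ("plateau_mean_ms", "transition_mean_ms"):
        if col not in means:
            means[col] = np.nan
    incomplete = means.index[means.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"participants without trials in both phases dropped: "
            f"{list(incomplete)}")
        means = means.dropna()
    return means[["plateau_mean_ms", "transition_mean_ms"]]


def _best_loglik(params, a, b):
    mu1, mu2, ls1, ls2, lnu = params
    nu = 1.0 + np.exp(lnu)
    return (stats.t.logpdf(a, nu, mu1, np.exp(ls1)).sum()
            + stats.t.logpdf(b, nu, mu2, np.exp(ls2)).sum())


def best_compare(group_a, group_b, n_draws: int = 4000, tune: int = 1000,
                 chains: int = 2, seed: int = 0) -> BESTResult:
    """Bayesian estimation of the difference between two groups' means.

    Kruschke's published defaults: ``mu_k ~ N(pooled mean, 1000 * pooled
    sd)``, ``sigma_k ~ Uniform(pooled sd / 1000, pooled sd * 1000)``,
    ``nu - 1 ~ Exponential(1/29)``.  Sampled with a seeded adaptive
    random-walk Metropolis chain on (mu1, mu2, log sigma1, log sigma2,
    log(nu - 1)).
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    psd = pooled.std(ddof=1)
    if psd == 0:
        raise ValueError("zero-variance input: BEST priors are data-scaled")
    pm = pooled.mean()
    lsd_lo, lsd_hi = np.log(psd / 1000), np.log(psd * 1000)

    def logpost(params):
        mu1, mu2, ls1, ls2, lnu = params
        if not (lsd_lo <= ls1 <= lsd_hi and lsd_lo <= ls2 <= lsd_hi):
            return -np.inf
        lp = (-0.5 * ((mu1 - pm) / (1000 * psd)) ** 2
              - 0.5 * ((mu2 - pm) / (1000 * psd)) ** 2
              - np.exp(lnu) / 29.0 + lnu)   # Exp(1/29) on nu-1 + Jacobian
        return lp + _best_loglik(params, a, b)

    seeds = np.random.SeedSequence(seed).spawn(chains)
    all_draws = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        x = np.array([a.mean(), b.mean(),
                      np.clip(np.log(a.std(ddof=1) + 1e-9), lsd_lo, lsd_hi),
                      np.clip(np.log(b.std(ddof=1) + 1e-9), lsd_lo, lsd_hi),
                      np.log(29.0)])
        scale = np.array([a.std(ddof=1) / np.sqrt(a.size),
                          b.std(ddof=1) / np.sqrt(b.size), 0.15, 0.15, 0.5])
        lp = logpost(x)
        acc = 0
        out = np.empty((n_draws, 5))
        for it in range(tune + n_draws):
            x_new = x + scale * rng.normal(size=5)
            lp_new = logpost(x_new)
            if np.log(rng.uniform()) < lp_new - lp:
                x, lp = x_new, lp_new
                acc += 1
            if it < tune and (it + 1) % 50 == 0:
                scale *= np.exp((acc / 50 - 0.25) * 0.7)
                acc = 0
            if it >= tune:
                out[it - tune] = x
        all_draws.append(out)
    draws = np.concatenate(all_draws)
    mu1, mu2 = draws[:, 0], draws[:, 1]
    diff = mu1 - mu2
    return BESTResult(
        mean_a_mode=posterior_mode(mu1), mean_a_hdi=hdi(mu1),
        mean_b_mode=posterior_mode(mu2), mean_b_hdi=hdi(mu2),
        diff_mode=posterior_mode(diff), diff_hdi=hdi(diff),
        frac_diff_above_zero=float(np.mean(diff > 0)),
        frac_diff_below_zero=float(np.mean(diff < 0)),
        draws={"mean_a": mu1, "mean_b": mu2, "diff": diff,
               "sigma_a": np.exp(draws[:, 2]), "sigma_b": np.exp(draws[:, 3]),
               "nu": 1.0 + np.exp(draws[:, 4])},
    )


def plateau_transition_best(trials: pd.DataFrame, paired: bool = False,
                            seed: int = 0, **kwargs) -> BESTResult:
    """BEST comparison of plateau vs transition per-participant mean RTs.

    The reported difference is transition minus plateau (positive = slower
    transitions).  ``paired=True`` compares the within-participant
    difference vector against a zero-centred reference instead.
    """
    means = mean_rt_by_phase(trials)
    if paired:
        d = (means["transition_mean_ms"] - means["plateau_mean_ms"]).to_numpy()
        zeros = np.zeros_like(d)
        return best_compare(d, zeros, seed=seed, **kwargs)
    return best_compare(means["transition_mean_ms"].to_numpy(),
                        means["plateau_mean_ms"].to_numpy(),
                        seed=seed, **kwargs)
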