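"""Exclusion filters for behavioral and fixation data.

Filter order follows the published sequencing: whole blocks with accuracy
below 75% are dropped first (block accuracy is computed on the raw, unfiltered
trials), then incorrect-report trials and over-long response times; a
stricter minimum-RT filter applies only to fixation analyses.

Boundary semantics are literal: "longer than 5,000 ms" removes strictly
greater, "faster than 100 ms" strictly smaller, "less than 75%" strictly
smaller.  "Incorrect" means the reported digit is not among the two target
digits of that display (the four response keys cover only target digits, so
distractor digits cannot be reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ExclusionReport", "block_accuracy", "exclude_low_accuracy_blocks",
    "exclude_invalid_trials", "exclude_fast_fixation_trials", "is_correct",
]


@dataclass
class ExclusionReport:
    """What a filter removed, in counts and fractions of its input."""

    n_input: int
    n_removed: int
    details: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    @property
    def frac_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def is_correct(trials: pd.DataFrame) -> pd.Series:
    """Whether the reported digit matches either target digit of the display."""
    return (trials["reported_digit"] == trials["target_digit_star"]) | (
        trials["reported_digit"] == trials["target_digit_pentagon"])


def block_accuracy(trials: pd.DataFrame) -> pd.Series:
    """Accuracy per (participant, block), computed before any trial removal."""
    correct = is_correct(trials)
    return correct.groupby(
        [trials["participant"], trials["block"]]).mean()


def exclude_low_accuracy_blocks(
        trials: pd.DataFrame, threshold: float = 0.75,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove whole blocks whose average accuracy is strictly below threshold.

    The report lists removed blocks, the removed-trial fraction, and
    participants excluded entirely (all their blocks below threshold).
    """
    acc = block_accuracy(trials)
    bad = acc[acc < threshold]
    key = pd.MultiIndex.from_frame(trials[["participant", "block"]])
    mask = key.isin(bad.index)
    kept = trials[~mask]
    all_participants = set(trials["participant"])
    fully_excluded = sorted(all_participants - set(kept["participant"]),
                            key=str)
    report = ExclusionReport(
        n_input=len(trials), n_removed=int(mask.sum()),
        details={
            "removed_blocks": sorted(map(tuple, bad.index), key=str),
            "block_accuracy": acc.to_dict(),
            "fully_excluded_participants": fully_excluded,
        })
    return kept.reset_index(drop=True), report


def exclude_invalid_trials(
        trials: pd.DataFrame, rt_max_ms: float = 5000.0,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop incorrect-report trials, then trials with RT strictly > rt_max_ms.

    Run after the block-accuracy filter.  The report gives both fractions
    the way results sections quote them: incorrect relative to this filter's
    input, slow relative to the correct remainder ("another x%").
    """
    correct = is_correct(trials)
    n_incorrect = int((~correct).sum())
    kept = trials[correct]
    slow = kept["rt_ms"] > rt_max_ms
    n_slow = int(slow.sum())
    out = kept[~slow]
    report = ExclusionReport(
        n_input=len(trials), n_removed=n_incorrect + n_slow,
        details={
            "n_incorrect": n_incorrect,
            "frac_incorrect": n_incorrect / len(trials) if len(trials) else 0.0,
            "n_slow": n_slow,
            "frac_slow": n_slow / len(kept) if len(kept) else 0.0,
            "rt_max_ms": rt_max_ms,
        })
    return out.reset_index(drop=True), report


def exclude_fast_fixation_trials(
        trials: pd.DataFrame, rt_min_ms: float = 100.0,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop trials with RT strictly below rt_min_ms (fixation analyses only)."""
    fast = trials["rt_ms"] < rt_min_ms
    report = ExclusionReport(
        n_input=len(trials), n_removed=int(fast.sum()),
        details={"rt_min_ms": rt_min_ms})
    return trials[~fast].reset_index(drop=True), report
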