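"""Fixation-to-item assignment and fixation-proportion statistics.

Fixations recorded during the search display are assigned to the nearest
item by Euclidean distance to the item centers (ties break to the lowest
item index and are flagged).  From the assignments three statistics mirror
the standard analyses for this paradigm:

* normalized shape proportions — the proportion of first / last / all
  fixations landing on items of a shape class, divided by the number of
  displayed items of that class, so that chance is 1/16 for both classes
  regardless of the subset split;
* chosen vs non-chosen plateau tables — on plateau trials, proportions of
  first and last fixations (and mean per-trial counts of total fixations)
  on the unique versus non-unique shape class, split by whether the unique
  target was eventually chosen, with bootstrap HDIs on the differences;
* first fixation on target — the proportion of first fixations landing on
  either blue target, by position in the distractor cycle.

Aggregation is per-participant means first, then the group mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import hdi

__all__ = [
    "assign_fixations", "normalized_shape_proportions",
    "chosen_vs_nonchosen_plateau", "first_fixation_on_target_by_position",
    "read_fixation_report",
]

FIXATION_COLUMNS = ["participant", "trial", "fix_index", "x_px", "y_px",
                    "onset_ms", "duration_ms"]


def assign_fixations(fixations: pd.DataFrame,
                     items: pd.DataFrame) -> pd.DataFrame:
    """Assign each fixation to the closest display item.

    Parameters
    ----------
    fixations
        One row per fixation with :data:`FIXATION_COLUMNS`.
    items
        Long frame of display items with ``participant``, ``trial``,
        ``item``, ``x_px``, ``y_px``, ``shape``, ``role``.

    Returns a copy of ``fixations`` with ``assigned_item``,
    ``assigned_shape``, ``assigned_role``, ``tie`` (equidistant to several
    items; lowest index was taken) and ``off_canvas`` is not flagged here —
    any position is simply mapped to its nearest item.
    """
    out = fixations.copy()
    out["assigned_item"] = -1
    out["assigned_shape"] = ""
    out["assigned_role"] = ""
    out["tie"] = False
    grouped_items = dict(tuple(items.groupby(["participant", "trial"])))
    for key, fix in out.groupby(["participant", "trial"]):
        disp = grouped_items.get(key)
        if disp is None:
            raise ValueError(f"no display items for participant/trial {key}")
        disp = disp.sort_values("item")
        dx = fix["x_px"].to_numpy()[:, None] - disp["x_px"].to_numpy()[None, :]
        dy = fix["y_px"].to_numpy()[:, None] - disp["y_px"].to_numpy()[None, :]
        d2 = dx ** 2 + dy ** 2
        nearest = np.argmin(d2, axis=1)     # first minimum = lowest index
        tie = (d2 == d2[np.arange(len(fix)), nearest][:, None]).sum(axis=1) > 1
        out.loc[fix.index, "assigned_item"] = disp["item"].to_numpy()[nearest]
        out.loc[fix.index, "assigned_shape"] = disp["shape"].to_numpy()[nearest]
        out.loc[fix.index, "assigned_role"] = disp["role"].to_numpy()[nearest]
        out.loc[fix.index, "tie"] = tie
    return out


def _restrict(table: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Keep only fixations from trials present in the (filtered) trial frame."""
    keep = pd.MultiIndex.from_frame(trials[["participant", "trial"]])
    mask = pd.MultiIndex.from_frame(table[["participant", "trial"]]).isin(keep)
    return table[mask]


def _select_fixations(table: pd.DataFrame, which: str) -> pd.DataFrame:
    if which == "total":
        return table
    idx = table.groupby(["participant", "trial"])["fix_index"]
    if which == "first":
        return table.loc[idx.idxmin()]
    if which == "last":
        return table.loc[idx.idxmax()]
    raise ValueError(f"which must be first|last|total, got {which!r}")


def _shape_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Displayed items per shape class: distractors plus the matching target."""
    return pd.DataFrame({
        "star": trials["n_star_distractors"].to_numpy() + 1,
        "pentagon": trials["n_pentagon_distractors"].to_numpy() + 1,
    }, index=pd.MultiIndex.from_frame(trials[["participant", "trial"]]))


def normalized_shape_proportions(table: pd.DataFrame, trials: pd.DataFrame,
                                 which: str = "first") -> pd.DataFrame:
    """Normalized fixation proportions per shape class and cycle position.

    For each trial the proportion of the selected fixation set (first, last
    or all fixations) on each shape class is divided by the number of
    displayed items of that class; trial values are averaged within
    participant at each cycle position and condition (cycle starting
    plateau), then across participants.

    Returns a tidy frame with columns ``cycle_start``, ``pos_in_cycle``,
    ``shape``, ``mean``, ``se``, ``n_participants``.
    """
    sel = _select_fixations(_restrict(table, trials), which)
    trial_info = trials.set_index(["participant", "trial"])
    counts = _shape_counts(trials)
    per_trial = (sel.groupby(["participant", "trial"])["assigned_shape"]
                 .value_counts(normalize=True)
                 .unstack(fill_value=0.0)
                 .reindex(columns=["star", "pentagon"], fill_value=0.0))
    per_trial = per_trial.div(counts.loc[per_trial.index])
    per_trial = per_trial.join(
        trial_info[["cycle_start", "pos_in_cycle"]], how="left")
    long = per_trial.reset_index().melt(
        id_vars=["participant", "trial", "cycle_start", "pos_in_cycle"],
        value_vars=["star", "pentagon"], var_name="shape",
        value_name="norm_prop")
    per_participant = (long.groupby(
        ["cycle_start", "pos_in_cycle", "shape", "participant"])
        ["norm_prop"].mean())
    grp = per_participant.groupby(["cycle_start", "pos_in_cycle", "shape"])
    out = grp.agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v))
                  if len(v) > 1 else np.nan, n_participants="count")
    return out.reset_index()


_PLATEAU_MEASURES = ("first", "last", "total", "total_count")


def _plateau_table(table, trials, chosen_unique: bool):
    """Per-participant chosen-shape fixation statistics on plateau trials.

    Returns a frame indexed by participant with, per measure, the
    chosen-shape and non-chosen-shape values: proportions of first / last /
    all fixations, and mean per-trial fixation counts (``total_count``).
    """
    info = trials.set_index(["participant", "trial"])
    t = _restrict(table, trials).join(
        info[["phase_type", "plateau_state", "choice"]],
        on=["participant", "trial"])
    t = t[t["phase_type"] == "plateau"].copy()
    if t.empty:
        raise ValueError("no plateau trials with fixations")
    # unique shape = the one the plateau's distractors do NOT share
    t["unique_shape"] = np.where(t["plateau_state"] == "star",
                                 "pentagon", "star")
    t = t[(t["choice"] == t["unique_shape"]) == chosen_unique]
    if t.empty:
        return None
    t["on_chosen"] = t["assigned_shape"] == t["choice"]

    rows = {}
    for which in ("first", "last", "total"):
        sel = _select_fixations(t, which)
        per_part = sel.groupby("participant")["on_chosen"].mean()
        rows[(which, "chosen")] = per_part
        rows[(which, "nonchosen")] = 1.0 - per_part
    cnt = (t.groupby(["participant", "trial"])["on_chosen"]
           .agg(chosen="sum", n="count"))
    cnt["nonchosen"] = cnt["n"] - cnt["chosen"]
    per_cnt = cnt.groupby("participant")[["chosen", "nonchosen"]].mean()
    rows[("total_count", "chosen")] = per_cnt["chosen"]
    rows[("total_count", "nonchosen")] = per_cnt["nonchosen"]
    return pd.DataFrame(rows)


def chosen_vs_nonchosen_plateau(table: pd.DataFrame, trials: pd.DataFrame,
                                n_boot: int = 10_000,
                                seed: int = 0) -> dict:
    """Plateau fixations on the chosen vs non-chosen target's shape class.

    Trials are split by whether the eventually chosen target was the unique
    one; within each split, fixations are classified by whether they landed
    on items sharing the chosen target's shape.  Returns
    ``{"unique_chosen": df, "nonunique_chosen": df}``; each frame is indexed
    by ``chosen`` / ``nonchosen`` / ``difference`` with columns ``first``,
    ``last``, ``total`` (proportions of those fixation sets) and
    ``total_count`` (mean per-trial fixation counts), plus ``*_hdi_low`` /
    ``*_hdi_high`` on the difference row from a seeded nonparametric
    bootstrap over participants.

    Aggregation is per-participant means, then the group mean.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for label, chosen_unique in (("unique_chosen", True),
                                 ("nonunique_chosen", False)):
        per_part = _plateau_table(table, trials, chosen_unique)
        if per_part is None:       # no trials fell into this category
            out[label] = None
            continue
        n = len(per_part)
        rows = {}
        for which in _PLATEAU_MEASURES:
            u = per_part[(which, "chosen")].to_numpy()
            v = per_part[(which, "nonchosen")].to_numpy()
            diff = u - v
            idx = rng.integers(0, n, size=(n_boot, n))
            boot = diff[idx].mean(axis=1)
            low, high = hdi(boot)
            rows[which] = {"chosen": u.mean(), "nonchosen": v.mean(),
                           "difference": diff.mean(),
                           "hdi_low": low, "hdi_high": high}
        df = pd.DataFrame({
            w: [rows[w]["chosen"], rows[w]["nonchosen"],
                rows[w]["difference"]]
            for w in _PLATEAU_MEASURES},
            index=["chosen", "nonchosen", "difference"])
        for w in _PLATEAU_MEASURES:
            df.loc["difference", f"{w}_hdi_low"] = rows[w]["hdi_low"]
            df.loc["difference", f"{w}_hdi_high"] = rows[w]["hdi_high"]
        out[label] = df
    return out


def first_fixation_on_target_by_position(table: pd.DataFrame,
                                         trials: pd.DataFrame) -> pd.DataFrame:
    """Proportion of first fixations landing on either blue target.

    Grouped by position in the distractor cycle; per-participant means then
    group mean with standard error across participants.
    """
    first = _select_fixations(_restrict(table, trials), "first")
    info = trials.set_index(["participant", "trial"])
    first = first.join(info[["pos_in_cycle"]], on=["participant", "trial"])
    first["on_target"] = first["assigned_role"] == "target"
    per_part = (first.groupby(["pos_in_cycle", "participant"])
                ["on_target"].mean())
    grp = per_part.groupby("pos_in_cycle")
    out = grp.agg(prop="mean",
                  se=lambda v: v.std(ddof=1) / np.sqrt(len(v))
                  if len(v) > 1 else np.nan,
                  n_participants="count")
    return out.reset_index()


def read_fixation_report(path) -> pd.DataFrame:
    """Read a columnar fixation report (CSV with :data:`FIXATION_COLUMNS`).

    A thin import shim for fixation tables exported from eye-tracker
    software; columns beyond the required set pass through untouched.
    """
    df = pd.read_csv(path)
    missing = set(FIXATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation report missing columns: {sorted(missing)}")
    return df
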