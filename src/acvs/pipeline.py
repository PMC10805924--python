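"""End-to-end orchestration: simulate/load -> preprocess -> fit -> RT -> fixations.

Each stage failure is re-raised tagged with the stage name.  All artifacts
land in ``config.outdir``: trial and fixation CSVs, posterior draws (CSV,
one column per scalar parameter plus chain/draw indices), a JSON exclusion
report, a JSON summary with parameter modes and HDIs (rounded to the
configured significant figures; draws keep raw precision), and a run log.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, read_csv, round_sig, write_csv, write_json
from .fixations import (assign_fixations, chosen_vs_nonchosen_plateau,
                        first_fixation_on_target_by_position,
                        normalized_shape_proportions)
from .inference import HierarchicalSpec, fit_hierarchical
from .model import ChoiceDataset
from .preprocessing import (exclude_fast_fixation_trials,
                            exclude_invalid_trials,
                            exclude_low_accuracy_blocks)
from .rt import plateau_transition_best
from .simulate import SimulationConfig, simulate_study

log = logging.getLogger("acvs")


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:
                raise StageError(name, err) from err
        return wrapped
    return deco


@_stage("input")
def _obtain_data(config: RunConfig):
    if config.simulate:
        sim = SimulationConfig(**config.simulation.model_dump(),
                               seed=config.seed)
        study = simulate_study(sim)
        return study.dataset, study.fixations, study.items, study.manifest
    data = config.data
    trials = read_csv(data.trials_path)
    schedule = read_csv(data.schedule_path)
    fixes = read_csv(data.fixations_path) if data.fixations_path else None
    items = read_csv(data.items_path) if data.items_path else None
    return ChoiceDataset(trials, schedule), fixes, items, None


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis pipeline; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("acvs %s, python %s, numpy %s, config %s", __version__,
                 platform.python_version(), np.__version__, chash)
        dataset, fixes, items, manifest = _obtain_data(config)
        write_csv(dataset.trials, outdir / "trials.csv", chash)
        write_csv(dataset.schedule, outdir / "schedule.csv", chash)
        if manifest is not None:
            write_json({"manifest": manifest}, outdir / "manifest.json", chash)

        summary = {"seed": config.seed}
        sig = config.report.sig_figs

        # --- preprocessing ---
        trials, rep_blocks = _preprocess_blocks(dataset.trials, config)
        trials, rep_trials = _preprocess_trials(trials, config)
        exclusions = {
            "low_accuracy_blocks": {
                "frac_removed": rep_blocks.frac_removed,
                "fully_excluded_participants":
                    rep_blocks.details["fully_excluded_participants"],
            },
            "invalid_trials": rep_trials.details,
        }
        write_json({"exclusions": exclusions},
                   outdir / "exclusions.json", chash)
        write_csv(trials, outdir / "trials_clean.csv", chash)
        clean = ChoiceDataset(trials, dataset.schedule)
        log.info("preprocessing: %.2f%% of trials in low-accuracy blocks, "
                 "%.2f%% incorrect, %.2f%% slow",
                 100 * rep_blocks.frac_removed,
                 100 * rep_trials.details["frac_incorrect"],
                 100 * rep_trials.details["frac_slow"])

        # --- hierarchical fit ---
        result = _fit(clean, config)
        draws_df = _draws_frame(result)
        write_csv(draws_df, outdir / "draws.csv", chash)
        fit_summary = {}
        for name in ("tau", "delta", "beta"):
            row = result.summaries.loc[name]
            fit_summary[name] = {
                "mode": round_sig(row["mode"], sig),
                "hdi95": [round_sig(row["hdi_low"], sig),
                          round_sig(row["hdi_high"], sig)],
            }
        summary["adaptation"] = fit_summary
        summary["diagnostics"] = {
            "max_rhat": float(result.diagnostics["rhat"].max()),
            "min_ess_bulk": float(result.diagnostics["ess_bulk"].min()),
            "warnings": result.warnings,
        }
        for w in result.warnings:
            log.warning("fit: %s", w)

        # --- response times ---
        best = _rt(trials, config)
        summary["rt"] = {
            "plateau_mean_mode_ms": round_sig(best.mean_b_mode, 4),
            "transition_mean_mode_ms": round_sig(best.mean_a_mode, 4),
            "diff_mode_ms": round_sig(best.diff_mode, sig),
            "diff_hdi95_ms": [round_sig(best.diff_hdi[0], sig),
                              round_sig(best.diff_hdi[1], sig)],
        }

        # --- fixations ---
        if fixes is not None and items is not None:
            fx = _fixation_stage(trials, fixes, items, config,
                                 outdir, chash)
            summary["fixations"] = fx

        write_json({"summary": summary}, outdir / "summary.json", chash)
        log.info("pipeline complete")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


@_stage("preprocess")
def _preprocess_blocks(trials, config):
    return exclude_low_accuracy_blocks(
        trials, threshold=config.filters.accuracy_threshold)


@_stage("preprocess")
def _preprocess_trials(trials, config):
    return exclude_invalid_trials(trials, rt_max_ms=config.filters.rt_max_ms)


@_stage("fit")
def _fit(dataset, config):
    s = config.sampler
    spec = HierarchicalSpec(chains=s.chains, draws=s.draws, tune=s.tune,
                            seed=config.seed, full_scale=s.full_scale,
                            include_practice=s.include_practice,
                            priors=dict(s.priors))
    return fit_hierarchical(dataset, spec)


@_stage("rt")
def _rt(trials, config):
    return plateau_transition_best(trials, seed=config.seed)


@_stage("fixations")
def _fixation_stage(trials, fixes, items, config, outdir, chash):
    trials_fx, rep_fast = exclude_fast_fixation_trials(
        trials, rt_min_ms=config.filters.rt_min_ms)
    key = pd.MultiIndex.from_frame(trials_fx[["participant", "trial"]])
    fixes = fixes[pd.MultiIndex.from_frame(
        fixes[["participant", "trial"]]).isin(key)]
    table = assign_fixations(fixes, items)
    out = {"frac_fast_removed": rep_fast.frac_removed}
    for which in ("first", "last", "total"):
        props = normalized_shape_proportions(table, trials_fx, which=which)
        write_csv(props, outdir / f"fixations_{which}.csv", chash)
    tables = chosen_vs_nonchosen_plateau(
        table, trials_fx, n_boot=config.report.n_boot, seed=config.seed)
    for label, df in tables.items():
        if df is None:
            out[label] = None
            continue
        write_csv(df.reset_index(names="shape_role"),
                  outdir / f"plateau_{label}.csv", chash)
        out[label] = {
            w: {"difference": round_sig(float(df.loc["difference", w]), 2)}
            for w in ("first", "last", "total")
        }
    ontarget = first_fixation_on_target_by_position(table, trials_fx)
    write_csv(ontarget, outdir / "first_fixation_on_target.csv", chash)
    return out


def _draws_frame(result) -> pd.DataFrame:
    names = ["tau", "delta", "beta", "mu_log_tau", "sigma_log_tau",
             "sigma_delta", "sigma_beta"]
    chains, ndraws = result.draws["tau"].shape
    base = {
        "chain": np.repeat(np.arange(chains), ndraws),
        "draw": np.tile(np.arange(ndraws), chains),
    }
    for name in names:
        base[name] = result.draws[name].ravel()
    for pname in ("tau", "delta", "beta"):
        arr = result.draws[f"{pname}_participant"]
        for i, pid in enumerate(result.participants):
            base[f"{pname}[{pid}]"] = arr[:, :, i].ravel()
    return pd.DataFrame(base)
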