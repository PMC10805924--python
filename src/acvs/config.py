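"""Run configuration: YAML-backed, schema-validated, hash-stamped.

Configs are plain YAML mapping onto :class:`RunConfig`; unknown keys are
rejected so typos fail loudly.  Every artifact a run writes declares the
SHA-256 hash of the canonical config JSON that produced it (JSON outputs in
a ``config_hash`` field, CSV outputs in a leading ``#`` comment line).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSettings(_Strict):
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
    rt_sigma: float = 0.25
    wrong_digit_rate: float = 0.025
    timeout_rate: float = 0.001
    n_chance_participants: int = 0
    fixations: bool = True
    p_stay: float = 0.8
    p_first_on_target: float = 0.125
    uniform_fixations: bool = False


class SamplerSettings(_Strict):
    chains: int = 4
    draws: int = 1000
    tune: int = 1000
    full_scale: bool = False
    include_practice: bool = False   # published fits use main blocks only
    priors: dict = Field(default_factory=dict)


class FilterSettings(_Strict):
    accuracy_threshold: float = 0.75
    rt_max_ms: float = 5000.0
    rt_min_ms: float = 100.0


class DataPaths(_Strict):
    trials_path: str | None = None
    schedule_path: str | None = None
    fixations_path: str | None = None
    items_path: str | None = None


class ReportSettings(_Strict):
    n_boot: int = 10_000
    sig_figs: int = 2


class RunConfig(_Strict):
    """Top-level pipeline configuration."""

    seed: int = 0
    outdir: str = "acvs_run"
    simulate: bool = True
    data: DataPaths | None = None
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    sampler: SamplerSettings = Field(default_factory=SamplerSettings)
    filters: FilterSettings = Field(default_factory=FilterSettings)
    report: ReportSettings = Field(default_factory=ReportSettings)

    @model_validator(mode="after")
    def _check_data(self):
        if not self.simulate:
            if self.data is None or self.data.trials_path is None:
                raise ValueError(
                    "data.trials_path is required when simulate is false")
            if self.data.schedule_path is None:
                raise ValueError(
                    "data.schedule_path is required when simulate is false")
        return self

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def write_csv(df: pd.DataFrame, path, config_hash: str) -> None:
    """CSV with a leading comment line declaring the producing config."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj, path, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    import numpy as np
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting layer only)."""
    import math
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
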