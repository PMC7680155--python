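"""Trial-table and configuration I/O.

The single on-disk trial format is a UTF-8 CSV with header
``subject_id,condition,phase,trial_index,stimulus_deg,response_deg,
reference_deg``; the reference column is empty for control (no-reference)
rows.  Run configurations are flat YAML key/value files mirroring
:class:`RunConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ExperimentDesign
from .observer import TRIAL_COLUMNS, TrialDataset

__all__ = ["TrialTableError", "RunConfig", "read_trials", "write_trials",
           "load_config"]


class TrialTableError(ValueError):
    """Malformed trial table (schema, value or range problem)."""


def write_trials(dataset: TrialDataset, path) -> None:
    df = dataset.records.loc[:, list(TRIAL_COLUMNS)]
    df.to_csv(path, index=False)


def read_trials(path, design: ExperimentDesign | None = None) -> TrialDataset:
    """Load and validate a trial CSV.

    Responses must be numeric orientations in [0, 180); offending rows are
    reported by (0-based data) row number.  Control rows may leave
    ``reference_deg`` empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"trial table {path} is missing columns {missing}")
    for col in ("stimulus_deg", "response_deg", "trial_index"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            bad = bad or df.index[coerced.isna()].tolist()
            raise TrialTableError(f"non-numeric {col} at rows {bad[:10]}")
        df[col] = coerced
    df["reference_deg"] = pd.to_numeric(df["reference_deg"], errors="coerce")
    out_of_range = df.index[(df["response_deg"] < 0) | (df["response_deg"] >= 180)]
    if len(out_of_range):
        raise TrialTableError(
            f"response_deg outside [0, 180) at rows {out_of_range.tolist()[:10]}")
    if design is None:
        design = ExperimentDesign()
    return TrialDataset(df.loc[:, list(TRIAL_COLUMNS)], design,
                        {"source": "empirical", "path": str(path)})


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults reproduce the standard design."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    model: str = "bls_vp"
    lam: float | None = None
    grid_min: float | None = None
    grid_max: float | None = None
    grid_step: float = 0.01
    n_mc: int = 800
    n_reps: int = 32
    seed: int = 0
    smoothing: float | None = None

    def grid(self) -> np.ndarray | None:
        if self.grid_min is None or self.grid_max is None:
            return None
        return np.round(np.arange(self.grid_min, self.grid_max + self.grid_step / 2,
                                  self.grid_step), 10)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        design = ExperimentDesign.from_dict(d.pop("design")) if "design" in d \
            else ExperimentDesign()
        known = {f for f in cls.__dataclass_fields__ if f != "design"}
        unknown = set(d) - known
        if unknown:
            raise TrialTableError(f"unknown config keys {sorted(unknown)}")
        return cls(design=design, **d)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
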