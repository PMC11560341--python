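"""CSV readers and writers for the pipeline's external interfaces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signal import CAPTrace

__all__ = ["read_trace", "read_force_table", "read_cohort_meta", "read_fiber_angles"]


def _require(path: Path, stage: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{stage}: required input file {path} is missing")
    return path


def read_trace(trace_csv, stims_csv) -> CAPTrace:
    """Load a two-column trace (time_s, voltage_mV) and its stimulus onsets."""
    tr = pd.read_csv(_require(trace_csv, "trace loading"))
    st = pd.read_csv(_require(stims_csv, "stimulus-onset loading"))
    t = tr["time_s"].to_numpy()
    v = tr["voltage_mV"].to_numpy()
    if t.size < 2:
        raise ValueError(f"trace {trace_csv} has fewer than 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return CAPTrace(t=t, v=v, fs=fs, stim_onsets=st["stim_onset_s"].to_numpy())


def read_force_table(path) -> pd.DataFrame:
    """Load a (stretch, force_N) table sorted by stretch."""
    df = pd.read_csv(_require(path, "force-table loading"))
    if not {"stretch", "force_N"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'stretch' and 'force_N'")
    return df.sort_values("stretch").reset_index(drop=True)


def read_cohort_meta(path) -> pd.DataFrame:
    """Load per-specimen metadata (id, sex, side, L0_mm, d0_mm)."""
    df = pd.read_csv(_require(path, "metadata loading"))
    need = {"id", "sex", "side", "L0_mm", "d0_mm"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicated specimen ids")
    return df


def read_fiber_angles(path) -> pd.DataFrame:
    """Load fiber angles (specimen_id, group, section, angle_deg)."""
    df = pd.read_csv(_require(path, "fiber-angle loading"))
    need = {"specimen_id", "group", "section", "angle_deg"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df
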