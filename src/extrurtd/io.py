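"""CSV/JSON plumbing shared by the CLI and tests."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .rtd_core import RTDCurves, TracerSeries

TRACER_COLUMNS = ("time_s", "concentration_mg_per_g")


def read_tracer_csv(path, run_label: str | None = None) -> TracerSeries:
    """Read one run: columns time_s, concentration_mg_per_g, optional header."""
    path = Path(path)
    try:
        with open(path, newline="") as fh:
            sample = fh.read(2048)
        has_header = csv.Sniffer().has_header(sample) if sample.strip() else False
    except csv.Error:
        has_header = False
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, concentration)")
    if has_header:
        cols = [c.strip().lower() for c in map(str, df.columns)]
        df.columns = cols
        time_col = TRACER_COLUMNS[0] if TRACER_COLUMNS[0] in cols else cols[0]
        conc_col = TRACER_COLUMNS[1] if TRACER_COLUMNS[1] in cols else cols[1]
    else:
        time_col, conc_col = df.columns[0], df.columns[1]
    times = pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=float)
    conc = pd.to_numeric(df[conc_col], errors="raise").to_numpy(dtype=float)
    return TracerSeries(times, conc, run_label=run_label or path.stem)


def write_tracer_csv(series: TracerSeries, path) -> None:
    pd.DataFrame(
        {TRACER_COLUMNS[0]: series.times, TRACER_COLUMNS[1]: series.concentrations}
    ).to_csv(path, index=False)


def write_curves_csv(curves: RTDCurves, path) -> None:
    cols = {"time_s": curves.times, "E": curves.E}
    for name, arr in (
        ("F", curves.F),
        ("theta", curves.theta),
        ("E_theta", curves.E_theta),
        ("F_theta", curves.F_theta),
    ):
        if arr is not None:
            cols[name] = arr
    pd.DataFrame(cols).to_csv(path, index=False)


def read_standards_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Standards table: concentration_mg_per_g, feature_value."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in map(str, df.columns)]
    df.columns = cols
    conc_col = "concentration_mg_per_g" if "concentration_mg_per_g" in cols else cols[0]
    feat_col = "feature_value" if "feature_value" in cols else cols[1]
    return (
        df[conc_col].to_numpy(dtype=float),
        df[feat_col].to_numpy(dtype=float),
    )
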