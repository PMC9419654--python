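"""File formats and run configuration.

Panels travel as long-format CSV with columns path_id, time, value (one
row per observation), which supports ragged per-path grids.  Fit reports
and FPT summaries are flat key-value text; every run can write its
resolved configuration next to its outputs so results are reproducible
from the emitted files alone.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SamplePanel

PANEL_COLUMNS = ("path_id", "time", "value")


def read_panel(path, normalize: str | None = None) -> SamplePanel:
    """Read a long-format CSV panel, validating row by row.

    ``normalize="max"`` divides each path by its maximum value (useful
    for case-count data interpreted as a fraction of the final size).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("time", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric {col!r} at line {row}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df[["time", "value"]].isna().any().any():
        row = int(df.index[df[["time", "value"]].isna().any(axis=1)][0]) + 2
        raise ValueError(f"{path}: missing time/value at line {row}")
    nonpos = df["value"] <= 0
    if nonpos.any():
        row = int(df.index[nonpos][0]) + 2
        raise ValueError(f"{path}: non-positive value at line {row}")
    if normalize == "max":
        df["value"] = df.groupby("path_id")["value"].transform(
            lambda s: s / s.max())
    elif normalize is not None:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    try:
        return SamplePanel.from_frame(df, metadata=str(path))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_panel(panel: SamplePanel, path) -> None:
    panel.to_frame().to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    """Flat key-value report, one `key = value` line per entry."""
    with open(path, "w") as fh:
        for key, val in report.items():
            fh.write(f"{key} = {val!r}\n" if isinstance(val, str)
                     else f"{key} = {val:.12g}\n")


def write_run_config(config: dict, out_path) -> None:
    """Record the resolved options of a run next to its outputs."""
    out_path = Path(out_path)
    cfg_path = out_path.with_suffix(out_path.suffix + ".config")
    with open(cfg_path, "w") as fh:
        for key, val in sorted(config.items()):
            fh.write(f"{key} = {val}\n")
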