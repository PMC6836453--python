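"""Delimited text formats for recordings, events, matrices and fixtures.

sEMG format: UTF-8 CSV with a first line ``# fs_hz=<rate>``, a header row of
muscle labels, and one row of channel values per sample. Event tables carry
one stride per row with the five event times in seconds. Matrices are CSV
with a labeled header row and a label column.
"""

from __future__ import annotations

import importlib.resources
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_prep import EVENT_NAMES, EmgRecording, EnvelopeMatrix, GaitEvents

__all__ = [
    "read_emg",
    "write_emg",
    "read_events",
    "write_events",
    "read_matrix",
    "write_matrix",
    "read_envelope",
    "write_envelope",
    "load_table1",
    "summarize_table1",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (matching printed one-decimal conventions)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# sEMG recordings
# ---------------------------------------------------------------------------


def write_emg(path, rec: EmgRecording, fmt: str = "%.9g") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# fs_hz={rec.fs:g}\n")
        fh.write(",".join(rec.muscle_labels) + "\n")
        np.savetxt(fh, rec.samples.T, delimiter=",", fmt=fmt)


def read_emg(path, expected_muscles: int | None = None) -> EmgRecording:
    """Parse the delimited sEMG format, validating structure line by line."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# fs_hz="):
            raise ValueError(f"{path}, line 1: missing '# fs_hz=' header")
        try:
            fs = float(first.strip().split("=", 1)[1])
        except ValueError as exc:
            raise ValueError(f"{path}, line 1: invalid sampling rate") from exc
        labels = [s.strip() for s in fh.readline().strip().split(",")]
        if not labels or labels == [""]:
            raise ValueError(f"{path}, line 2: missing muscle label header")
        if expected_muscles is not None and len(labels) != expected_muscles:
            raise ValueError(
                f"{path}, line 2: {len(labels)} channels, expected {expected_muscles}"
            )
        rows = []
        for ln, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(labels):
                raise ValueError(
                    f"{path}, line {ln}: {len(cells)} columns, expected {len(labels)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path}, line {ln}: non-numeric cell") from exc
    if not rows:
        raise ValueError(f"{path}: no sample rows")
    return EmgRecording(tuple(labels), np.asarray(rows).T, fs)


# ---------------------------------------------------------------------------
# Gait events
# ---------------------------------------------------------------------------

_EVENT_HEADER = ("stride_id",) + EVENT_NAMES


def write_events(path, events: GaitEvents) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(",".join(_EVENT_HEADER) + "\n")
        for k, row in enumerate(events.times):
            fh.write(f"{k}," + ",".join(f"{t:.6f}" for t in row) + "\n")


def read_events(path) -> GaitEvents:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header != list(_EVENT_HEADER):
            raise ValueError(f"{path}, line 1: expected header {','.join(_EVENT_HEADER)}")
        rows = []
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != 6:
                raise ValueError(f"{path}, line {ln}: expected 6 columns")
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}, line {ln}: non-numeric cell") from exc
    if not rows:
        raise ValueError(f"{path}: no stride rows")
    return GaitEvents(np.asarray(rows))


# ---------------------------------------------------------------------------
# Labeled matrices and envelopes
# ---------------------------------------------------------------------------


def write_matrix(path, values, row_labels=None, col_labels=None, fmt: str = "%.12g") -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    r, c = values.shape
    row_labels = [f"r{i}" for i in range(r)] if row_labels is None else list(row_labels)
    col_labels = [f"c{j}" for j in range(c)] if col_labels is None else list(col_labels)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("label," + ",".join(map(str, col_labels)) + "\n")
        for lab, row in zip(row_labels, values):
            fh.write(str(lab) + "," + ",".join(fmt % v for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str))


def write_envelope(path, env: EnvelopeMatrix) -> None:
    """Envelope matrix plus a sidecar ``<path>.strides.csv`` boundary table."""
    labels = env.muscle_labels or tuple(f"ch{i}" for i in range(env.values.shape[0]))
    write_matrix(path, env.values, row_labels=labels)
    sidecar = Path(str(path) + ".strides.csv")
    with sidecar.open("w", encoding="utf-8") as fh:
        fh.write("boundary_sample\n")
        for b in env.stride_boundaries:
            fh.write(f"{int(b)}\n")


def read_envelope(path) -> EnvelopeMatrix:
    values, labels, _ = read_matrix(path)
    sidecar = Path(str(path) + ".strides.csv")
    bounds = None
    if sidecar.exists():
        bounds = np.loadtxt(sidecar, skiprows=1, dtype=int, ndmin=1)
    return EnvelopeMatrix(values, bounds, tuple(labels))


# ---------------------------------------------------------------------------
# Table 1 fixture (subject descriptors transcribed from the study table)
# ---------------------------------------------------------------------------


def load_table1(path=None) -> pd.DataFrame:
    if path is None:
        ref = importlib.resources.files("synergait").joinpath("data/table1.csv")
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def summarize_table1(path=None) -> pd.DataFrame:
    """Per-group descriptive statistics, rounded half-up to one decimal.

    The SD of a single-row group is reported as missing (NaN), never as zero.
    """
    df = load_table1(path)
    numeric = ["age_y", "height_cm", "weight_kg", "speed_m_s"]
    missing = [c for c in numeric + ["group"] if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
    rows = []
    for group, sub in df.groupby("group", sort=False):
        row: dict = {"group": group, "n": len(sub)}
        for col in numeric:
            vals = sub[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = round_half_up(float(np.mean(vals)))
            row[f"{col}_sd"] = (
                round_half_up(float(np.std(vals, ddof=1))) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
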