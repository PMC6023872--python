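"""Readers and writers for the plain-text and TIFF formats the pipeline
shares: two-column spectra/decays, localization CSV, wide trace CSV, ROI
tables, 16-bit TIFF stacks, and JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_two_column",
    "write_two_column",
    "read_stack",
    "write_stack",
    "read_localizations",
    "write_localizations",
    "read_traces_csv",
    "write_traces_csv",
    "read_json",
    "write_json",
]


def read_two_column(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column numeric text file (whitespace-, tab- or
    comma-separated; lines starting with # ignored)."""
    text = Path(path).read_text()
    delimiter = "," if ("," in text.splitlines()[0] if text.splitlines() else False) else None
    data = np.loadtxt(path, delimiter=delimiter, comments="#")
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns")
    return data[:, 0], data[:, 1]


def write_two_column(path, col1, col2, header: str = ""):
    arr = np.column_stack([np.asarray(col1, float), np.asarray(col2, float)])
    np.savetxt(path, arr, delimiter="\t", header=header, comments="# ")


def read_stack(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_stack(path, stack: np.ndarray):
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")


def read_localizations(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_localizations(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def write_traces_csv(traces, path, rois_path=None):
    """Write traces as a wide CSV (one column per molecule) and,
    optionally, the ROI table (id, row, col)."""
    data = {f"molecule_{i}": t.values for i, t in enumerate(traces)}
    pd.DataFrame(data).to_csv(path, index=False)
    if rois_path is not None:
        rows = [
            {
                "id": i,
                "row": (t.center[0] if t.center is not None else -1),
                "col": (t.center[1] if t.center is not None else -1),
            }
            for i, t in enumerate(traces)
        ]
        pd.DataFrame(rows).to_csv(rois_path, index=False)


def read_traces_csv(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    return [df[c].to_numpy(dtype=float) for c in df.columns]


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
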