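"""Reading and writing datasets as delimited text (TSV/CSV) or HDF5.

A dataset is a flat mapping from names to numeric arrays: 1-D stimulus /
label vectors and trials x (grid...) response arrays.  Delimited text holds
one column per 1-D variable (multi-column variables are split into
``name__0``, ``name__1``, ... and rejoined on read); HDF5 stores arrays of
any shape under their names.  Floats are written at 17 significant digits so
that a text round trip is lossless.
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["read_dataset", "write_dataset"]

_SPLIT = re.compile(r"^(?P<name>.+)__(?P<idx>\d+)$")


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def read_dataset(path: str | Path) -> dict[str, np.ndarray]:
    """Read a named collection of numeric arrays from TSV/CSV or HDF5.

    Delimited files must have a header row and fully numeric cells; a
    non-numeric cell is reported with its line number.  Columns named
    ``name__<i>`` are reassembled into a 2-D array ``name``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_hdf5(path):
        out: dict[str, np.ndarray] = {}
        with h5py.File(path, "r") as fh:
            def collect(name, obj):
                if isinstance(obj, h5py.Dataset):
                    out[name] = obj[()]
            fh.visititems(collect)
        return out
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        col = bad[0]
        numeric = pd.to_numeric(df[col], errors="coerce")
        row = int(numeric.index[numeric.isna() & df[col].notna()][0])
        raise ValueError(
            f"non-numeric cell in column {col!r} at data line {row + 2} of {path}"
        )
    groups: dict[str, list[tuple[int, str]]] = {}
    out = {}
    for col in df.columns:
        m = _SPLIT.match(col)
        if m:
            groups.setdefault(m["name"], []).append((int(m["idx"]), col))
        else:
            arr = df[col].to_numpy()
            if np.allclose(arr, np.round(arr)) and np.abs(arr).max(initial=0) < 2**31:
                as_int = arr.astype(np.int64)
                if np.array_equal(as_int, arr):
                    arr = as_int
            out[col] = arr
    for name, cols in groups.items():
        cols.sort()
        out[name] = np.column_stack([df[c].to_numpy() for _, c in cols])
    return out


def write_dataset(path: str | Path, arrays: dict[str, np.ndarray]) -> Path:
    """Write a named collection of arrays; format chosen by file extension.

    TSV/CSV accepts 1-D and 2-D arrays sharing a first axis; HDF5 accepts
    any shapes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {k: np.asarray(v) for k, v in arrays.items()}
    if _is_hdf5(path):
        with h5py.File(path, "w") as fh:
            for name, arr in arrays.items():
                fh.create_dataset(name, data=arr)
        return path
    cols: dict[str, np.ndarray] = {}
    for name, arr in arrays.items():
        if arr.ndim == 1:
            cols[name] = arr
        elif arr.ndim == 2:
            for j in range(arr.shape[1]):
                cols[f"{name}__{j}"] = arr[:, j]
        else:
            raise ValueError(
                f"array {name!r} has {arr.ndim} dimensions; use an HDF5 path "
                "for arrays beyond 2-D"
            )
    lengths = {v.shape[0] for v in cols.values()}
    if len(lengths) > 1:
        raise ValueError(f"columns disagree on sample count: {sorted(lengths)}")
    df = pd.DataFrame(cols)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path
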