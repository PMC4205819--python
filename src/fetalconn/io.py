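"""File formats: TSV tables with '#' metadata headers, FSL-style .par traces.

All tabular outputs are tab-separated text with optional leading comment
lines (``# key: value``); motion traces follow the FSL ``.par`` dialect
(whitespace-delimited, per row 3 rotations in radians then 3 translations
in mm). Numeric round-trips are lossless at 10 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiAtlas

__all__ = [
    "FormatError",
    "read_timeseries",
    "write_timeseries",
    "read_motion_par",
    "write_motion_par",
    "read_matrix",
    "write_matrix",
    "read_atlas",
    "write_atlas",
    "write_json",
    "read_json",
]

FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells, wrong shape)."""


def _meta_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_timeseries(path, data: np.ndarray, region_names, meta: dict | None = None) -> None:
    """Frames x regions TSV with a region-name header row."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(region_names):
        raise FormatError(
            f"data shape {data.shape} does not match {len(region_names)} region names"
        )
    df = pd.DataFrame(data, columns=list(region_names))
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty input file") from exc
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty input file")
    return df


def read_timeseries(path, expect_regions=None) -> tuple[np.ndarray, list]:
    """Read a frames x regions TSV; returns (matrix, region names)."""
    df = _read_tsv(path)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else -1
            raise FormatError(f"{path}: non-numeric cell in column {col!r}, row {row}")
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise FormatError(f"{path}: missing value in column {col!r}, row {row} (ragged row?)")
    names = [str(c) for c in df.columns]
    if expect_regions is not None and list(expect_regions) != names:
        extra = set(names) ^ set(expect_regions)
        raise FormatError(f"{path}: region header mismatch, offending column(s): {sorted(extra)}")
    return df.to_numpy(dtype=float), names


def write_motion_par(path, motion: np.ndarray) -> None:
    np.savetxt(path, np.asarray(motion, dtype=float), fmt="%.10g")


def read_motion_par(path) -> np.ndarray:
    """FSL .par dialect: 6 whitespace-delimited columns per frame."""
    try:
        arr = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse motion file: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"{path}: empty motion file")
    if arr.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 columns, found {arr.shape[1]}")
    return arr


def write_matrix(path, mat: np.ndarray, region_names, meta: dict | None = None) -> None:
    """Square symmetric matrix TSV with region-name header (row order = header)."""
    write_timeseries(path, mat, region_names, meta=meta)


def read_matrix(path) -> tuple[np.ndarray, list]:
    mat, names = read_timeseries(path)
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path}: matrix is {mat.shape}, expected square")
    return mat, names


def write_atlas(path, atlas: RoiAtlas, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        atlas.to_frame().to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_atlas(path) -> RoiAtlas:
    return RoiAtlas.from_frame(_read_tsv(path))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
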