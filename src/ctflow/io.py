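"""Readers and writers for all tabular artifacts.

Conventions
-----------
* Dialect is inferred from the extension: ``.csv`` is comma-separated,
  anything else is tab-separated. Files are UTF-8.
* CT matrices are assays in rows, samples in columns (array-export layout);
  the first column holds the assay id, the header row the sample ids.
* Missing values are encoded as empty cells. Undetected CT cells that still
  carry a magnitude (post-censoring) are serialized with a sidecar
  ``<path>.mask`` 0/1 table so masks survive round trips.
* Identifiers are case-sensitive exact strings; no spelling normalization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .types import (
    SHEET_KNOWN_COLUMNS,
    AnalytePanel,
    CtMatrix,
    SampleSheet,
)

DEFAULT_UNDETECTED_TOKENS = ("Undetermined",)


def _sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _mask_path(path: Path) -> Path:
    return Path(str(path) + ".mask")


def read_ct_table(
    path,
    undetected_tokens=DEFAULT_UNDETECTED_TOKENS,
    stage: str = "raw",
) -> CtMatrix:
    """Read a CT matrix from a delimited text file.

    Blank cells and cells equal to one of ``undetected_tokens`` are marked
    undetected. If a sidecar ``<path>.mask`` file exists (written by
    :func:`write_ct_table` for censored/normalized matrices) it overrides
    the detection mask so masked-but-valued cells survive a round trip.
    """
    path = Path(path)
    header = path.open(encoding="utf-8").readline().rstrip("\n").split(_sep(path))[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"{path}: duplicate sample id(s) {dup}")
    raw = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False, index_col=0)
    raw.index.name = None
    raw.columns.name = None
    _no_duplicates(raw, path)
    tokens = set(undetected_tokens)

    ct = np.full(raw.shape, np.nan)
    detected = np.zeros(raw.shape, dtype=bool)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col].to_numpy()):
            cell = cell.strip()
            if cell == "" or cell in tokens:
                continue
            try:
                ct[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at assay "
                    f"{raw.index[i]!r}, sample {col!r}"
                ) from None
            detected[i, j] = True

    mask_file = _mask_path(path)
    if mask_file.exists():
        mask = pd.read_csv(mask_file, sep=_sep(path), index_col=0)
        mask.index.name = None
        if not mask.index.equals(raw.index) or list(mask.columns) != list(raw.columns):
            raise ValidationError(f"{mask_file}: mask does not match {path}")
        detected = mask.to_numpy().astype(bool)

    return CtMatrix(
        pd.DataFrame(ct, index=raw.index, columns=raw.columns),
        pd.DataFrame(detected, index=raw.index, columns=raw.columns),
        stage=stage,
    )


def _no_duplicates(frame: pd.DataFrame, path: Path) -> None:
    idx = frame.index
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate assay id(s) {dup}")
    cols = pd.Index(frame.columns)
    if cols.has_duplicates:
        dup = cols[cols.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample id(s) {dup}")


def write_ct_table(ct: CtMatrix, path) -> Path:
    """Write a CT matrix; undetected cells without a value become blanks.

    When any undetected cell still carries a finite value the full detection
    mask is written to ``<path>.mask`` so that reading reproduces the matrix
    exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = ct.ct.copy()
    needs_mask = bool((~ct.detected & np.isfinite(ct.ct)).any().any())
    if not needs_mask:
        out = out.where(ct.detected)
    out.to_csv(path, sep=_sep(path), index_label="assay_id")
    mask_file = _mask_path(path)
    if needs_mask:
        ct.detected.astype(int).to_csv(mask_file, sep=_sep(path), index_label="assay_id")
    elif mask_file.exists():
        mask_file.unlink()
    return path


def read_sample_sheet(path) -> SampleSheet:
    """Read a sample sheet; unknown extra columns become binary flags.

    Required columns: ``sample_id`` (first or named) and ``cohort``. Extra
    columns are accepted only when their values are within {0, 1, blank}.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'sample_id'")
    if "cohort" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'cohort'")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate sample id(s) {dup}")
    df = df.set_index("sample_id")

    flags = []
    for col in df.columns:
        if col in SHEET_KNOWN_COLUMNS:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        ok = vals.dropna().isin([0, 1]).all() and not (vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")).any()
        if not ok:
            raise ValidationError(
                f"{path}: column {col!r} is neither a known covariate nor a 0/1 flag"
            )
        df[col] = vals
        flags.append(col)
    for col in ("pain_nrs", "crps_type", "duration_years", "bmi"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleSheet(df, flags=flags)


def write_sample_sheet(sheet: SampleSheet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sheet.data.to_csv(path, sep=_sep(path), index_label="sample_id")
    return path


def read_analyte_panel(path) -> AnalytePanel:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric analyte value ({exc})") from None
    return AnalytePanel(df)


def write_analyte_panel(panel: AnalytePanel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    panel.data.to_csv(path, sep=_sep(path), index_label="sample_id")
    return path


def write_result_table(table: pd.DataFrame, path) -> Path:
    """Write any downstream result table with stable column order and
    full-precision numerics (Python float repr round-trips exactly)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_sep(path), index=False)
    return path


def read_result_table(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep(path))


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
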