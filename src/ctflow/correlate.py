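"""Pairwise Spearman correlation screening across miRNAs, analytes and
clinical covariates, with per-family BH adjustment and link-table export.

Variables are namespaced ``mirna:``, ``analyte:`` and ``clinical:``. miRNA
expression enters as -ΔCT (monotone in abundance, rank-equivalent to any
2^-ΔCT transform under Spearman). Binary flags are coded 0/1 and CRPS type
as 1/2. Missing data is handled by pairwise-complete deletion with a
minimum pair count.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .types import AnalytePanel, DeltaCtMatrix, SampleSheet

log = logging.getLogger(__name__)

DEFAULT_MIN_N = 5

#: namespace pairs tested, in output order
FAMILIES = (
    ("mirna", "clinical"),
    ("mirna", "analyte"),
    ("analyte", "clinical"),
    ("clinical", "clinical"),
)

LINK_COLUMNS = ["var1", "var2", "rho", "q", "sign"]


def spearman(x, y, min_n: int = DEFAULT_MIN_N):
    """Tie-corrected (average-rank) Spearman correlation.

    Returns ``(rho, p, n)`` where n is the number of complete pairs after
    pairwise deletion. p comes from the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) with n-2 df, two-tailed; |rho| = 1
    yields p = 0. Raises on fewer than ``min_n`` complete pairs or on a
    constant input (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n:
        raise ValidationError(f"only {n} complete pairs; minimum is {min_n}")
    rx = stats.rankdata(x[mask])
    ry = stats.rankdata(y[mask])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("constant input; Spearman rho undefined")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    return rho, _rho_pvalue(rho, n), n


def _rho_pvalue(rho: float, n: int) -> float:
    if 1.0 - rho * rho <= 1e-15:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def assemble_variables(
    sheet: SampleSheet,
    dct: DeltaCtMatrix | None = None,
    panel: AnalytePanel | None = None,
) -> dict[str, pd.DataFrame]:
    """Build per-namespace samples x variables frames aligned to the sheet."""
    index = pd.Index(sheet.sample_ids)
    frames: dict[str, pd.DataFrame] = {}
    if dct is not None:
        frames["mirna"] = (-dct.masked()).T.reindex(index)
    if panel is not None:
        frames["analyte"] = panel.data.reindex(index)
    clinical_cols = ["pain_nrs", "crps_type", "duration_years", "bmi"] + list(sheet.flags)
    clin = sheet.data[clinical_cols].astype(float).reindex(index)
    # drop covariates with no observations at all (e.g. flags never set)
    frames["clinical"] = clin.loc[:, clin.notna().any()]
    return frames


def _rank_z(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized column ranks for complete columns.

    Returns (z, complete, constant): z holds centered unit-norm ranks for
    columns without missing values; ``complete`` and ``constant`` are
    boolean column masks.
    """
    arr = frame.to_numpy(float)
    n, m = arr.shape
    complete = np.isfinite(arr).all(axis=0)
    constant = np.zeros(m, dtype=bool)
    z = np.zeros((n, m))
    for j in range(m):
        if not complete[j]:
            continue
        r = stats.rankdata(arr[:, j])
        if np.ptp(r) == 0:
            constant[j] = True
            continue
        r = r - r.mean()
        z[:, j] = r / np.sqrt(np.dot(r, r))
    return z, complete, constant


def _family_table(
    name1: str,
    frame1: pd.DataFrame,
    name2: str,
    frame2: pd.DataFrame,
    samples: list[str],
    min_n: int,
) -> pd.DataFrame:
    """All pairs for one namespace family restricted to ``samples``.

    Pairs where both columns are complete go through one rank matrix
    product; pairs touching a column with missing values fall back to the
    scalar pairwise-complete path.
    """
    f1 = frame1.loc[samples]
    f2 = frame2.loc[samples]
    within = name1 == name2 and frame1 is frame2
    family = f"{name1}x{name2}"
    n_full = len(samples)

    z1, comp1, const1 = _rank_z(f1)
    z2, comp2, const2 = (z1, comp1, const1) if within else _rank_z(f2)
    fast1 = comp1 & ~const1
    fast2 = comp2 & ~const2
    idx1 = np.flatnonzero(fast1)
    idx2 = np.flatnonzero(fast2)

    frames: list[pd.DataFrame] = []
    if len(idx1) and len(idx2):
        rho_block = np.clip(z1[:, idx1].T @ z2[:, idx2], -1.0, 1.0)
        ii, jj = np.meshgrid(idx1, idx2, indexing="ij")
        if within:
            keep = ii < jj
        else:
            keep = np.ones_like(ii, dtype=bool)
        rho = rho_block[keep]
        with np.errstate(divide="ignore"):
            denom = 1.0 - rho * rho
            t = rho * np.sqrt((n_full - 2) / np.where(denom <= 1e-15, np.nan, denom))
            p = 2.0 * stats.t.sf(np.abs(t), n_full - 2)
        p = np.where(denom <= 1e-15, 0.0, p)
        frames.append(
            pd.DataFrame(
                {
                    "var1": [f"{name1}:{c}" for c in f1.columns[ii[keep]]],
                    "var2": [f"{name2}:{c}" for c in f2.columns[jj[keep]]],
                    "rho": rho,
                    "n": n_full,
                    "p_raw": p,
                    "family": family,
                    "note": "",
                }
            )
        )

    # slow path: any pair touching an incomplete or constant column
    slow: list[dict] = []
    for i in range(f1.shape[1]):
        j_range = range(i + 1, f2.shape[1]) if within else range(f2.shape[1])
        for j in j_range:
            if fast1[i] and fast2[j]:
                continue
            rec = {
                "var1": f"{name1}:{f1.columns[i]}",
                "var2": f"{name2}:{f2.columns[j]}",
                "rho": np.nan,
                "n": np.nan,
                "p_raw": np.nan,
                "family": family,
                "note": "",
            }
            if const1[i] or const2[j]:
                rec["note"] = "constant"
            else:
                try:
                    rho_s, p_s, n_s = spearman(
                        f1.iloc[:, i].to_numpy(float),
                        f2.iloc[:, j].to_numpy(float),
                        min_n=min_n,
                    )
                except ValidationError as exc:
                    rec["note"] = "constant" if "constant" in str(exc) else "n_lt_min"
                else:
                    rec.update(rho=rho_s, n=n_s, p_raw=p_s)
            slow.append(rec)
    if slow:
        frames.append(pd.DataFrame.from_records(slow))
    if not frames:
        return pd.DataFrame(
            columns=["var1", "var2", "rho", "n", "p_raw", "family", "note"]
        )
    return pd.concat(frames, ignore_index=True)


def correlation_screen(
    sheet: SampleSheet,
    dct: DeltaCtMatrix | None = None,
    panel: AnalytePanel | None = None,
    alpha: float = 0.01,
    min_n: int = DEFAULT_MIN_N,
    scope: str = "auto",
) -> pd.DataFrame:
    """Spearman screen over all cross-namespace pairs plus clinical-clinical.

    BH adjustment is applied within each namespace-pair family; ``kept`` is
    q < alpha. ``scope`` picks the samples entering each family: ``auto``
    uses patients only for families involving clinical covariates and all
    samples otherwise; ``patients``/``all`` force one choice globally.
    """
    from .differential import bh_adjust  # local import to avoid cycle

    if scope not in ("auto", "patients", "all"):
        raise ValidationError(f"unknown scope {scope!r}")
    frames = assemble_variables(sheet, dct=dct, panel=panel)
    parts: list[pd.DataFrame] = []
    for ns1, ns2 in FAMILIES:
        if ns1 not in frames or ns2 not in frames:
            continue
        if scope == "patients":
            samples = sheet.patients
        elif scope == "all":
            samples = sheet.sample_ids
        else:
            samples = sheet.patients if "clinical" in (ns1, ns2) else sheet.sample_ids
        parts.append(_family_table(ns1, frames[ns1], ns2, frames[ns2], samples, min_n))

    table = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["var1", "var2", "rho", "n", "p_raw", "family", "note"]
    )
    table["q"] = np.nan
    for family, idx in table.groupby("family").groups.items():
        sub = table.loc[idx]
        valid = sub["p_raw"].notna()
        if valid.any():
            table.loc[sub.index[valid], "q"] = bh_adjust(sub.loc[valid, "p_raw"].to_numpy())
    table["kept"] = table["q"].notna() & (table["q"] < alpha)
    table = table[["var1", "var2", "family", "rho", "n", "p_raw", "q", "kept", "note"]]
    n_skipped = int((table["note"] != "").sum())
    if n_skipped:
        log.info("correlation screen skipped %d pair(s)", n_skipped)
    return table


def export_links(table: pd.DataFrame, path) -> pd.DataFrame:
    """Write the kept pairs as a circular-plot link table.

    Columns: var1, var2, rho, q, sign (``pos``/``neg``), sorted by |rho|
    descending. Returns the exported frame.
    """
    from .io import write_result_table

    kept = table[table["kept"]].copy()
    kept["sign"] = np.where(kept["rho"] >= 0, "pos", "neg")
    kept = kept.sort_values(
        "rho", key=lambda c: c.abs(), ascending=False, kind="stable"
    )[LINK_COLUMNS].reset_index(drop=True)
    write_result_table(kept, path)
    return kept
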