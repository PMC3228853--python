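"""Differential expression on ΔCT values and analyte concentrations.

Fold changes follow the 2^-ΔΔCT convention with the signed-ratio report
(ratios below 1 become the negative reciprocal, so every magnitude is >= 1
and sign(fold change) = -sign(ΔΔCT)). Group tests are two-tailed
independent-samples t-tests (pooled variance by default, Welch optional)
with Benjamini-Hochberg step-up adjustment across features.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .types import AnalytePanel, DeltaCtMatrix, SampleSheet

MIN_PER_GROUP = 2

TABLE_COLUMNS = [
    "feature",
    "delta_delta_ct",
    "fold_change",
    "p_raw",
    "q",
    "n_a",
    "n_b",
    "tested",
    "significant",
]


def fold_change_from_ddct(ddct):
    """Signed fold change from ΔΔCT: r = 2^-ΔΔCT, reported as r if r >= 1
    else -1/r. Scalar in, scalar out; arrays map elementwise."""
    arr = np.asarray(ddct, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("ΔΔCT must be finite")
    r = np.power(2.0, -arr)
    out = np.where(r >= 1.0, r, -1.0 / r)
    if np.isscalar(ddct) or np.ndim(ddct) == 0:
        return float(out)
    return out


def two_sample_test(values_a, values_b, variant: str = "student"):
    """Two-tailed independent-samples t-test; returns (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < MIN_PER_GROUP or len(b) < MIN_PER_GROUP:
        raise ValidationError("each group needs >= 2 values")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(k) = min_{j >= k} p_(j) * m / j, capped at 1, in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return np.empty(0)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@contextmanager
def _quiet():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        with np.errstate(all="ignore"):
            yield


def _vectorized_ttest(a: np.ndarray, b: np.ndarray, variant: str):
    """Row-wise t-test with NaN exclusion; a, b are features x samples."""
    na = np.sum(np.isfinite(a), axis=1)
    nb = np.sum(np.isfinite(b), axis=1)
    with _quiet():
        ma = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
        mb = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
        va = np.nanvar(np.where(np.isfinite(a), a, np.nan), axis=1, ddof=1)
        vb = np.nanvar(np.where(np.isfinite(b), b, np.nan), axis=1, ddof=1)
        if variant == "student":
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = (na + nb - 2).astype(float)
        else:
            se = np.sqrt(va / na + vb / nb)
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        t = (ma - mb) / se
        # zero-variance rows: equal means -> t=0, p=1; unequal -> p=0
        zero_se = se == 0
        t = np.where(zero_se & (ma == mb), 0.0, t)
        t = np.where(zero_se & (ma != mb), np.inf * np.sign(ma - mb), t)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isinf(t), 0.0, p)
        p = np.where(zero_se & (ma == mb), 1.0, p)
    return t, p, na, nb, ma, mb


def _resolve_groups(sheet: SampleSheet, groups) -> tuple[list[str], list[str]]:
    if len(groups) != 2:
        raise ValidationError("groups must name exactly two groups")
    out = []
    for g in groups:
        if isinstance(g, str):
            members = sheet.cohort_samples(g)  # raises on unknown label
            if not members:
                raise ValidationError(f"group {g!r} is empty")
            out.append(members)
        else:
            members = list(g)
            if not members:
                raise ValidationError("explicit sample group is empty")
            unknown = set(members) - set(sheet.sample_ids)
            if unknown:
                raise ValidationError(f"unknown sample id(s) in group: {sorted(unknown)}")
            out.append(members)
    return out[0], out[1]


def differential_table(
    dct: DeltaCtMatrix,
    sheet: SampleSheet,
    groups: Sequence = ("patient", "control"),
    *,
    fc_dct: DeltaCtMatrix | None = None,
    q_threshold: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-assay ΔΔCT, signed fold change, raw and BH-adjusted p.

    ``groups`` may be two cohort labels or two explicit sample-id lists
    (group A first). Tests run on ``dct``; ΔΔCT and the fold change are
    taken from ``fc_dct`` when given (e.g. ΔCT on censored raw CT), else
    from ``dct``. Features with fewer than two detected values in either
    group are flagged untested (p, q = NaN) rather than failing the run.
    Rows are sorted by q ascending, then |fold change| descending.
    """
    samples_a, samples_b = _resolve_groups(sheet, groups)
    fc_src = fc_dct if fc_dct is not None else dct
    if list(fc_src.assay_ids) != list(dct.assay_ids):
        fc_view = fc_src.masked().reindex(index=dct.delta_ct.index)
    else:
        fc_view = fc_src.masked()

    vals = dct.masked()
    a = vals[samples_a].to_numpy(float)
    b = vals[samples_b].to_numpy(float)
    t, p, na, nb, _, _ = _vectorized_ttest(a, b, variant)

    fa = fc_view[[s for s in samples_a if s in fc_view.columns]].to_numpy(float)
    fb = fc_view[[s for s in samples_b if s in fc_view.columns]].to_numpy(float)
    with _quiet():
        ddct = np.nanmean(fa, axis=1) - np.nanmean(fb, axis=1)
        r = np.power(2.0, -ddct)
        fc = np.where(r >= 1.0, r, -1.0 / r)

    tested = (na >= MIN_PER_GROUP) & (nb >= MIN_PER_GROUP) & np.isfinite(p)
    q = np.full(len(p), np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    table = pd.DataFrame(
        {
            "feature": dct.assay_ids,
            "delta_delta_ct": ddct,
            "fold_change": fc,
            "p_raw": np.where(tested, p, np.nan),
            "q": q,
            "n_a": na,
            "n_b": nb,
            "tested": tested,
            "significant": tested & (q < q_threshold),
        }
    )
    table = table.sort_values(
        ["q", "fold_change"],
        key=lambda col: col.abs() if col.name == "fold_change" else col,
        ascending=[True, False],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    table.attrs["comparison"] = f"{_group_name(groups[0])}_vs_{_group_name(groups[1])}"
    table.attrs["q_threshold"] = q_threshold
    table.attrs["variant"] = variant
    return table


def _group_name(g) -> str:
    return g if isinstance(g, str) else f"set{len(list(g))}"


def analyte_differential(
    panel: AnalytePanel,
    sheet: SampleSheet,
    log_transform: bool = False,
    *,
    q_threshold: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Patient-vs-control tests on analyte concentrations.

    The fold change is the unsigned patient/control mean ratio (these are
    concentrations, not CT cycles). With ``log_transform`` the t-test runs
    on log-concentrations; the ratio is always reported on the raw scale.
    """
    patients = [s for s in sheet.patients if s in panel.data.index]
    controls = [s for s in sheet.controls if s in panel.data.index]
    if len(patients) < MIN_PER_GROUP or len(controls) < MIN_PER_GROUP:
        raise ValidationError("need >= 2 patients and >= 2 controls with analyte data")

    values = panel.data.T  # analytes x samples
    a = values[patients].to_numpy(float)
    b = values[controls].to_numpy(float)
    if log_transform:
        with _quiet():
            ta, tb = np.log(a), np.log(b)
    else:
        ta, tb = a, b
    t, p, na, nb, _, _ = _vectorized_ttest(ta, tb, variant)
    with _quiet():
        ratio = np.nanmean(a, axis=1) / np.nanmean(b, axis=1)

    tested = (na >= MIN_PER_GROUP) & (nb >= MIN_PER_GROUP) & np.isfinite(p)
    q = np.full(len(p), np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    table = pd.DataFrame(
        {
            "feature": list(values.index),
            "delta_delta_ct": np.nan,
            "fold_change": ratio,
            "p_raw": np.where(tested, p, np.nan),
            "q": q,
            "n_a": na,
            "n_b": nb,
            "tested": tested,
            "significant": tested & (q < q_threshold),
        }
    )
    table = table.sort_values(["q", "p_raw"], na_position="last", kind="stable").reset_index(
        drop=True
    )
    table.attrs["comparison"] = "patient_vs_control_analytes"
    table.attrs["q_threshold"] = q_threshold
    return table
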