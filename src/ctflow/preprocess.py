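"""CT preprocessing: censoring, detection filtering, quantile normalization,
endogenous-control selection and ΔCT computation.

Undetected cells are excluded from every statistic in this module; censored
magnitudes are retained but masked, so censoring only ever grows the mask.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .types import COHORTS, CtMatrix, DeltaCtMatrix, ReferenceSet, SampleSheet

log = logging.getLogger(__name__)


def censor_undetected(ct: CtMatrix, threshold: float = 32.0) -> CtMatrix:
    """Mark cells with CT >= ``threshold`` as undetected (values retained).

    Idempotent; accepts raw or already-censored input. The boundary is
    inclusive: a CT of exactly ``threshold`` is undetected.
    """
    if threshold <= 0:
        raise ConfigError(f"censor threshold must be positive, got {threshold}")
    if ct.stage == "normalized":
        raise ConfigError("cannot censor a normalized matrix")
    detected = ct.detected & ~(ct.ct >= threshold)
    n_new = int((ct.detected & ~detected).sum().sum())
    log.info("censoring at %.3g cycles masked %d additional cell(s)", threshold, n_new)
    return CtMatrix(ct.ct.copy(), detected, stage="censored")


def filter_assays(
    ct: CtMatrix, sheet: SampleSheet, min_det_frac: float = 0.5
) -> CtMatrix:
    """Keep assays detected in at least ``min_det_frac`` of samples within
    each cohort."""
    if not 0 <= min_det_frac <= 1:
        raise ConfigError(f"min_det_frac must be in [0,1], got {min_det_frac}")
    sheet.check_matches(ct)
    keep = pd.Series(True, index=ct.ct.index)
    for cohort in COHORTS:
        members = [s for s in sheet.cohort_samples(cohort) if s in ct.ct.columns]
        if not members:
            raise ValidationError(f"cohort {cohort!r} has no samples in the CT matrix")
        frac = ct.detected[members].mean(axis=1)
        keep &= frac >= min_det_frac
    dropped = int((~keep).sum())
    log.info("detection filter dropped %d of %d assays", dropped, len(keep))
    return CtMatrix(ct.ct.loc[keep], ct.detected.loc[keep], stage=ct.stage)


def quantile_normalize(ct: CtMatrix) -> CtMatrix:
    """Force all samples onto a common distribution of detected CT values.

    The target distribution is the across-sample mean of within-sample order
    statistics mapped onto a common quantile grid; a within-sample rank r of
    n maps to quantile (r - 0.5)/n, with linear interpolation when samples
    differ in detected count. Ties receive the average of their target
    values. Undetected cells are untouched. With equal detected counts the
    result is exactly the mean of sorted columns.
    """
    if ct.stage not in ("raw", "censored"):
        raise ConfigError("quantile_normalize expects a raw or censored matrix")
    det = ct.detected.to_numpy()
    vals = np.where(det, ct.ct.to_numpy(float), np.nan)
    n_samples = vals.shape[1]
    counts = det.sum(axis=0)
    for j, sid in enumerate(ct.sample_ids):
        if counts[j] < 2:
            raise ValidationError(
                f"sample {sid!r} has {counts[j]} detected value(s); need >= 2"
            )

    n_max = int(counts.max())
    grid = (np.arange(n_max) + 0.5) / n_max
    curves = np.empty((n_samples, n_max))
    for j in range(n_samples):
        v = np.sort(vals[det[:, j], j])
        q = (np.arange(len(v)) + 0.5) / len(v)
        curves[j] = np.interp(grid, q, v)
    target = curves.mean(axis=0)

    out = ct.ct.to_numpy(float).copy()
    for j in range(n_samples):
        idx = np.flatnonzero(det[:, j])
        v = vals[idx, j]
        order = np.argsort(v, kind="stable")
        q = (np.arange(len(v)) + 0.5) / len(v)
        mapped = np.interp(q, grid, target)
        sv = v[order]
        uniq, inverse = np.unique(sv, return_inverse=True)
        sums = np.bincount(inverse, weights=mapped)
        cnts = np.bincount(inverse)
        out[idx[order], j] = (sums / cnts)[inverse]

    return CtMatrix(
        pd.DataFrame(out, index=ct.ct.index, columns=ct.ct.columns),
        ct.detected.copy(),
        stage="normalized",
    )


def select_reference(
    ct: CtMatrix, size: int = 10, allow_fewer: bool = False
) -> ReferenceSet:
    """Select the ``size`` assays with the lowest across-sample standard
    deviation among assays detected in every sample.

    Ties are broken by assay id (lexicographic) so selection is deterministic
    and invariant to input row order. ``per_sample_mean`` is the mean CT of
    the selected assays within each sample.
    """
    if size < 1:
        raise ConfigError(f"reference size must be >= 1, got {size}")
    fully = ct.detected.all(axis=1)
    candidates = ct.ct.loc[fully]
    if len(candidates) < size:
        if not allow_fewer:
            raise ValidationError(
                f"only {len(candidates)} fully-detected assays available; "
                f"{size} requested (set allow_fewer to relax)"
            )
        log.warning(
            "only %d fully-detected assays; using all of them as reference",
            len(candidates),
        )
        size = len(candidates)
    if size == 0:
        raise ValidationError("no fully-detected assays; cannot build a reference set")
    sd = candidates.std(axis=1, ddof=1)
    ranking = pd.DataFrame({"sd": sd, "assay": sd.index.astype(str)})
    ranking = ranking.sort_values(["sd", "assay"], kind="stable")
    members = list(ranking.index[:size])
    return ReferenceSet(
        assay_ids=members,
        per_sample_mean=candidates.loc[members].mean(axis=0),
        selection_sd=sd.loc[members],
    )


def reference_on(ct: CtMatrix, assay_ids: list[str]) -> ReferenceSet:
    """Rebuild a reference set (means + SDs) for the same assays on another
    stage of the matrix (e.g. censored-raw instead of normalized)."""
    missing = [a for a in assay_ids if a not in ct.ct.index]
    if missing:
        raise ValidationError(f"reference assay(s) missing from matrix: {missing}")
    sub = ct.ct.loc[list(assay_ids)]
    if not ct.detected.loc[list(assay_ids)].all(axis=None):
        raise ValidationError("reference assays must be detected in all samples")
    return ReferenceSet(
        assay_ids=list(assay_ids),
        per_sample_mean=sub.mean(axis=0),
        selection_sd=sub.std(axis=1, ddof=1),
    )


def compute_delta_ct(ct: CtMatrix, ref: ReferenceSet) -> DeltaCtMatrix:
    """ΔCT(i, s) = CT(i, s) - reference mean(s), defined on detected cells."""
    missing = [a for a in ref.assay_ids if a not in ct.ct.index]
    if missing:
        raise ValidationError(f"reference assay(s) missing from matrix: {missing}")
    extra = set(ct.sample_ids) - set(ref.per_sample_mean.index)
    if extra:
        raise ValidationError(f"reference means missing for sample(s): {sorted(extra)}")
    delta = ct.ct.sub(ref.per_sample_mean.reindex(ct.ct.columns), axis=1)
    return DeltaCtMatrix(delta, ct.detected.copy(), ref)
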