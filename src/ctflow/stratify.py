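"""Cluster-based patient stratification.

Builds the per-sample log2 relative-expression matrix over the significant
assays, hierarchically clusters samples into k groups, reports group
composition (flagging patient-only groups) and re-runs differential testing
for a chosen subgroup against all other samples.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .differential import differential_table
from .errors import ConfigError, ValidationError
from .types import ClusterResult, DeltaCtMatrix, SampleSheet

log = logging.getLogger(__name__)


def relative_expression(
    dct: DeltaCtMatrix, sheet: SampleSheet, significant_assays: Sequence[str]
) -> pd.DataFrame:
    """Per-sample log2 relative expression vs. the control mean.

    rel(i, s) = -(ΔCT(i, s) - mean over controls of ΔCT(i, .)), so positive
    values mean higher expression than the control average. NaN where the
    underlying ΔCT is undetected. Control samples average to 0 per assay.
    """
    assays = list(significant_assays)
    if not assays:
        raise ValidationError("significant_assays must be nonempty")
    missing = [a for a in assays if a not in dct.delta_ct.index]
    if missing:
        raise ValidationError(f"assay(s) absent from ΔCT matrix: {missing}")
    controls = [s for s in sheet.controls if s in dct.delta_ct.columns]
    if not controls:
        raise ValidationError("control cohort is empty")
    vals = dct.masked().loc[assays]
    control_mean = vals[controls].mean(axis=1)
    if control_mean.isna().any():
        bad = list(control_mean.index[control_mean.isna()])
        raise ValidationError(f"no detected control values for assay(s): {bad}")
    return -(vals.sub(control_mean, axis=0))


def cluster_samples(
    rel: pd.DataFrame,
    k: int = 3,
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of samples on the relative-expression matrix.

    Missing cells are imputed as 0 (the "no change" point of the centered
    scale) for distance computation only. The tree is cut to k groups; group
    ids are renumbered 1..k in order of first appearance along the input
    sample order, which makes labels deterministic. The assay dendrogram is
    computed the same way to provide the heatmap row order.
    """
    n = rel.shape[1]
    if k < 2 or k > n:
        raise ConfigError(f"k must be in [2, {n}], got {k}")
    filled = rel.fillna(0.0)

    x_samples = filled.T.to_numpy(float)
    z_samples = hierarchy.linkage(pdist(x_samples, metric=metric), method=linkage)
    raw_labels = hierarchy.fcluster(z_samples, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw_labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    if len(remap) != k:
        log.warning("maxclust cut produced %d group(s) instead of %d", len(remap), k)

    if rel.shape[0] >= 2:
        x_assays = filled.to_numpy(float)
        z_assays = hierarchy.linkage(pdist(x_assays, metric=metric), method=linkage)
        assay_order = [rel.index[i] for i in hierarchy.leaves_list(z_assays)]
    else:  # a single assay has no dendrogram
        z_assays = np.empty((0, 4))
        assay_order = list(rel.index)

    sample_order = [rel.columns[i] for i in hierarchy.leaves_list(z_samples)]
    return ClusterResult(
        k=len(remap),
        labels=pd.Series(labels, index=rel.columns, name="group"),
        sample_order=sample_order,
        assay_order=assay_order,
        sample_linkage=z_samples,
        assay_linkage=z_assays,
    )


def heatmap_matrix(rel: pd.DataFrame, clusters: ClusterResult) -> pd.DataFrame:
    """Relative-expression matrix reordered by the dendrogram leaf orders
    (missing values kept missing); ready for external rendering."""
    return rel.loc[clusters.assay_order, clusters.sample_order]


def group_composition(clusters: ClusterResult, sheet: SampleSheet) -> pd.DataFrame:
    """Per-group patient/control counts and the fraction of all patients."""
    patients = set(sheet.patients)
    controls = set(sheet.controls)
    n_patients_total = len(patients)
    rows = []
    for group in sorted(set(int(v) for v in clusters.labels)):
        members = clusters.members(group)
        n_p = sum(1 for s in members if s in patients)
        n_c = sum(1 for s in members if s in controls)
        rows.append(
            {
                "group": group,
                "n_samples": len(members),
                "n_patients": n_p,
                "n_controls": n_c,
                "patient_fraction": n_p / n_patients_total if n_patients_total else 0.0,
                "patient_only": n_p > 0 and n_c == 0,
            }
        )
    return pd.DataFrame(rows)


def identify_signature_group(composition: pd.DataFrame) -> int | None:
    """Pick the patient-only group with the largest patient fraction, or
    None when no patient-only group exists (ambiguous stratification)."""
    pure = composition[composition["patient_only"]]
    if pure.empty:
        return None
    best = pure.sort_values(["patient_fraction", "group"], ascending=[False, True])
    return int(best.iloc[0]["group"])


def subgroup_differential(
    dct: DeltaCtMatrix,
    sheet: SampleSheet,
    clusters: ClusterResult,
    target_group: int,
    **kwargs,
) -> pd.DataFrame:
    """Differential table for one cluster vs. all other samples (controls
    included in the complement)."""
    members = clusters.members(target_group)  # raises on unknown group
    complement = [s for s in clusters.labels.index if s not in set(members)]
    if not complement:
        raise ValidationError(f"group {target_group} covers all samples; empty complement")
    table = differential_table(dct, sheet, groups=(members, complement), **kwargs)
    table.attrs["comparison"] = f"group{target_group}_vs_rest"
    return table
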