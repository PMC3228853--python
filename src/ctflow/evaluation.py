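"""Recovery and calibration experiments against synthetic ground truth.

These drive the validation story for the whole pipeline: planted-effect
recovery (sensitivity / false-discovery proportion / fold-change accuracy),
cluster recovery of the signature subgroup, the subgroup-only-marker
phenomenon, pain-analyte correlation recovery, and null calibration of the
differential and correlation stages.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .correlate import spearman
from .pipeline import analyze_cohort
from .simulate import SimulationConfig, simulate_cohort, simulate_null


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (closed form from
    the pair-counting contingency table)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = len(a)
    cats_a, inv_a = np.unique(a, return_inverse=True)
    cats_b, inv_b = np.unique(b, return_inverse=True)
    contingency = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    np.add.at(contingency, (inv_a, inv_b), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def recovery_metrics(seed: int, config: SimulationConfig | None = None) -> dict:
    """Run the full pipeline on one planted cohort and score it vs. truth."""
    cfg = replace(config or SimulationConfig(), seed=seed)
    ct, sheet, panel, truth = simulate_cohort(cfg)
    res = analyze_cohort(ct, sheet, panel)

    de = set(truth.de_shifts)
    planted = truth.planted_assays
    sig_all = set(res.diff.loc[res.diff["significant"], "feature"])

    out = {
        "seed": seed,
        "sens_all_patients": len(sig_all & de) / len(de) if de else np.nan,
        "has_patient_only_group": bool(
            res.composition is not None and res.composition["patient_only"].any()
        ),
        "signature_found": res.signature_group is not None,
    }

    if res.signature_group is not None:
        comp = res.composition.set_index("group")
        out["signature_patient_fraction"] = float(
            comp.loc[res.signature_group, "patient_fraction"]
        )
        truth_member = np.array(
            [s in set(truth.signature_samples) for s in res.clusters.labels.index]
        )
        predicted = res.clusters.labels.to_numpy() == res.signature_group
        out["ari_signature"] = adjusted_rand_index(truth_member, predicted)
    else:
        out["signature_patient_fraction"] = np.nan
        out["ari_signature"] = np.nan

    if res.subgroup_diff is not None:
        sub = res.subgroup_diff.set_index("feature")
        sig_sub = set(sub.index[sub["significant"]])
        out["sens_subgroup"] = len(sig_sub & de) / len(de) if de else np.nan
        out["fdp_subgroup"] = (
            len(sig_sub - planted) / len(sig_sub) if sig_sub else 0.0
        )
        recovered = [a for a in de if a in sig_sub]
        fcs = sub.loc[recovered, "fold_change"]
        out["fc_abs_mean"] = float(fcs.abs().mean()) if len(fcs) else np.nan
        out["fc_sign_ok_frac"] = (
            float(
                np.mean(
                    [np.sign(fcs[a]) == -np.sign(truth.de_shifts[a]) for a in recovered]
                )
            )
            if recovered
            else np.nan
        )
        markers = set(truth.subgroup_markers)
        out["markers_all_in_subgroup"] = markers <= sig_sub
        out["markers_add_discovery"] = bool(markers & (sig_sub - sig_all))
    else:
        for key in ("sens_subgroup", "fdp_subgroup", "fc_abs_mean", "fc_sign_ok_frac"):
            out[key] = np.nan
        out["markers_all_in_subgroup"] = False
        out["markers_add_discovery"] = False

    pain = sheet.data.loc[sheet.patients, "pain_nrs"].to_numpy(float)
    rhos = []
    for analyte in truth.pain_corr_targets:
        vals = panel.data.loc[sheet.patients, analyte].to_numpy(float)
        rhos.append(spearman(pain, vals)[0])
    out["pain_rho_mean"] = float(np.mean(rhos)) if rhos else np.nan

    analyte_sig = set(
        res.analyte_diff.loc[res.analyte_diff["significant"], "feature"]
    )
    out["analytes_recovered"] = set(truth.analyte_shifts) <= analyte_sig
    return out


def null_metrics(seed: int, config: SimulationConfig | None = None) -> dict:
    """Run the pipeline on one null cohort; all discoveries are false."""
    cfg = replace(config or SimulationConfig(), seed=seed)
    ct, sheet, panel, _ = simulate_null(cfg)
    res = analyze_cohort(ct, sheet, panel)
    n_disc = int(res.diff["significant"].sum())
    corr = res.correlations
    kept = corr[corr["kept"]]
    return {
        "seed": seed,
        "n_discoveries": n_disc,
        "fdp": 1.0 if n_disc > 0 else 0.0,
        "n_tested": int(res.diff["tested"].sum()),
        "kept_pairs": len(kept),
        "families_with_kept": int(kept["family"].nunique()),
        "n_families": int(corr["family"].nunique()),
    }
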