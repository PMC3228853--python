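"""End-to-end orchestration: simulate/load -> preprocess -> differential ->
stratify -> correlate -> report, with a seeded run manifest.

The library entry points (:func:`preprocess_cohort`, :func:`analyze_cohort`,
:func:`run_all`) are shared by the CLI, the test suite and the acceptance
script so every consumer exercises the same code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import io
from .correlate import correlation_screen, export_links
from .differential import analyte_differential, differential_table
from .errors import ConfigError, CtflowError
from .preprocess import (
    censor_undetected,
    compute_delta_ct,
    filter_assays,
    quantile_normalize,
    reference_on,
    select_reference,
)
from .simulate import AnalyteSpec, SimulationConfig, simulate_cohort
from .stratify import (
    cluster_samples,
    group_composition,
    heatmap_matrix,
    identify_signature_group,
    relative_expression,
    subgroup_differential,
)
from .types import AnalytePanel, CtMatrix, DeltaCtMatrix, SampleSheet

log = logging.getLogger(__name__)

DEFAULTS = {
    "censor_threshold": 32.0,
    "min_det_frac": 0.5,
    "ref_size": 10,
    "ref_stage": "normalized",  # or "censored"
    "fc_source": "raw",  # ΔΔCT from censored-raw CT ("raw") or "normalized"
    "q_threshold": 0.05,
    "t_variant": "student",
    "analyte_log": False,
    "k": 3,
    "metric": "euclidean",
    "linkage": "average",
    "alpha": 0.01,
    "min_corr_n": 5,
    "corr_scope": "auto",
}


@dataclass
class PreprocessResult:
    censored: CtMatrix
    filtered: CtMatrix
    normalized: CtMatrix
    reference: object
    dct: DeltaCtMatrix  # ΔCT on normalized CT (used for testing)
    dct_raw: DeltaCtMatrix  # ΔCT on censored raw CT (fold-change source)


@dataclass
class CohortResult:
    pre: PreprocessResult
    diff: pd.DataFrame
    analyte_diff: pd.DataFrame | None
    rel: pd.DataFrame | None
    clusters: object | None
    composition: pd.DataFrame | None
    signature_group: int | None
    subgroup_diff: pd.DataFrame | None
    correlations: pd.DataFrame | None


def preprocess_cohort(ct: CtMatrix, sheet: SampleSheet, params: dict | None = None) -> PreprocessResult:
    """Censor, filter, quantile-normalize, select reference, compute ΔCT."""
    p = {**DEFAULTS, **(params or {})}
    sheet.check_matches(ct)
    censored = censor_undetected(ct, threshold=p["censor_threshold"])
    filtered = filter_assays(censored, sheet, min_det_frac=p["min_det_frac"])
    normalized = quantile_normalize(filtered)
    ref_matrix = normalized if p["ref_stage"] == "normalized" else filtered
    reference = select_reference(ref_matrix, size=p["ref_size"])
    dct = compute_delta_ct(normalized, reference)
    dct_raw = compute_delta_ct(filtered, reference_on(filtered, reference.assay_ids))
    return PreprocessResult(censored, filtered, normalized, reference, dct, dct_raw)


def analyze_cohort(
    ct: CtMatrix,
    sheet: SampleSheet,
    panel: AnalytePanel | None = None,
    params: dict | None = None,
) -> CohortResult:
    """Full analysis of one cohort from a raw CT matrix."""
    p = {**DEFAULTS, **(params or {})}
    pre = preprocess_cohort(ct, sheet, p)
    fc_dct = pre.dct_raw if p["fc_source"] == "raw" else None
    diff = differential_table(
        pre.dct,
        sheet,
        groups=("patient", "control"),
        fc_dct=fc_dct,
        q_threshold=p["q_threshold"],
        variant=p["t_variant"],
    )
    analyte_diff = (
        analyte_differential(
            panel, sheet, log_transform=p["analyte_log"], q_threshold=p["q_threshold"]
        )
        if panel is not None
        else None
    )

    significant = diff.loc[diff["significant"], "feature"].tolist()
    rel = clusters = composition = subgroup = None
    signature_group = None
    if significant:
        rel = relative_expression(pre.dct, sheet, significant)
        k = min(p["k"], rel.shape[1])
        clusters = cluster_samples(rel, k=k, metric=p["metric"], linkage=p["linkage"])
        composition = group_composition(clusters, sheet)
        signature_group = identify_signature_group(composition)
        if signature_group is not None:
            subgroup = subgroup_differential(
                pre.dct,
                sheet,
                clusters,
                signature_group,
                fc_dct=fc_dct,
                q_threshold=p["q_threshold"],
                variant=p["t_variant"],
            )

    correlations = correlation_screen(
        sheet,
        dct=pre.dct,
        panel=panel,
        alpha=p["alpha"],
        min_n=p["min_corr_n"],
        scope=p["corr_scope"],
    )
    return CohortResult(
        pre, diff, analyte_diff, rel, clusters, composition, signature_group,
        subgroup, correlations,
    )


# ---------------------------------------------------------------------------
# file-level orchestration


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sim_config_from_dict(block: dict) -> SimulationConfig:
    block = dict(block)
    if "analytes" in block:
        block["analytes"] = {
            name: AnalyteSpec(**spec) for name, spec in block["analytes"].items()
        }
    for key in ("baseline_ct_range", "pain_corr_analytes"):
        if key in block:
            block[key] = tuple(block[key])
    if "comorbidity_links" in block:
        block["comorbidity_links"] = tuple(tuple(x) for x in block["comorbidity_links"])
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown simulate key(s): {sorted(unknown)}")
    return SimulationConfig(**block)


def run_all(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute every stage from one configuration mapping.

    ``config`` keys: optional ``simulate`` block (:class:`SimulationConfig`
    fields), optional ``inputs`` block with ``ct``/``samples``/``analytes``
    paths, optional ``seed``, plus any :data:`DEFAULTS` override. Returns
    the run manifest (also written to ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = {k: config[k] for k in DEFAULTS if k in config}
    unknown = set(config) - set(DEFAULTS) - {"simulate", "inputs", "seed"}
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    effective = {**DEFAULTS, **params}
    seed = seed if seed is not None else config.get("seed", 0)

    outputs: dict[str, Path] = {}

    def stage(name):
        log.info("stage: %s", name)

    truth = None
    if "simulate" in config:
        stage("simulate")
        sim_cfg = _sim_config_from_dict({**config["simulate"], "seed": seed})
        ct, sheet, panel, truth = simulate_cohort(sim_cfg)
        outputs["ct"] = io.write_ct_table(ct, out_dir / "ct.tsv")
        outputs["samples"] = io.write_sample_sheet(sheet, out_dir / "samples.tsv")
        outputs["analytes"] = io.write_analyte_panel(panel, out_dir / "analytes.tsv")
        outputs["truth"] = truth.to_json(out_dir / "truth.json")
    elif "inputs" in config:
        inputs = config["inputs"]
        if "ct" not in inputs or "samples" not in inputs:
            raise ConfigError("inputs block requires 'ct' and 'samples' paths")
        ct = io.read_ct_table(inputs["ct"])
        sheet = io.read_sample_sheet(inputs["samples"])
        panel = io.read_analyte_panel(inputs["analytes"]) if "analytes" in inputs else None
    else:
        raise ConfigError("config needs a 'simulate' or an 'inputs' block")

    try:
        stage("preprocess")
        result = analyze_cohort(ct, sheet, panel, effective)
    except CtflowError as exc:
        raise type(exc)(f"[analysis] {exc}") from exc

    pre = result.pre
    outputs["normalized_ct"] = io.write_ct_table(pre.normalized, out_dir / "normalized_ct.tsv")
    ref_report = pd.DataFrame(
        {
            "assay": pre.reference.assay_ids,
            "selection_sd": pre.reference.selection_sd.loc[pre.reference.assay_ids].to_numpy(),
        }
    )
    outputs["reference_set"] = io.write_result_table(ref_report, out_dir / "reference_set.tsv")
    dct_frame = pre.dct.masked().reset_index(names="assay_id")
    outputs["delta_ct"] = io.write_result_table(dct_frame, out_dir / "delta_ct.tsv")

    stage("differential")
    outputs["differential"] = io.write_result_table(result.diff, out_dir / "differential.tsv")
    if result.analyte_diff is not None:
        outputs["analyte_differential"] = io.write_result_table(
            result.analyte_diff, out_dir / "analyte_differential.tsv"
        )

    stage("stratify")
    if result.clusters is not None:
        labels = result.clusters.labels.rename_axis("sample_id").reset_index(name="group")
        outputs["cluster_labels"] = io.write_result_table(labels, out_dir / "cluster_labels.tsv")
        outputs["composition"] = io.write_result_table(
            result.composition, out_dir / "composition.tsv"
        )
        heat = heatmap_matrix(result.rel, result.clusters).reset_index(names="assay_id")
        outputs["heatmap_matrix"] = io.write_result_table(heat, out_dir / "heatmap_matrix.tsv")
        if result.subgroup_diff is not None:
            outputs["subgroup_differential"] = io.write_result_table(
                result.subgroup_diff, out_dir / "subgroup_differential.tsv"
            )

    stage("correlate")
    outputs["correlations"] = io.write_result_table(
        result.correlations, out_dir / "correlations.tsv"
    )
    links_path = out_dir / "links.tsv"
    export_links(result.correlations, links_path)
    outputs["links"] = links_path

    stage("report")
    report_text = build_report(result, sheet)
    report_path = out_dir / "report.md"
    report_path.write_text(report_text)
    outputs["report"] = report_path

    manifest = {
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "simulate"},
        "simulate": config.get("simulate", None) and dict(config["simulate"]),
        "thresholds": effective,
        "outputs": {name: {"path": str(p.name), "sha256": _sha256(p)} for name, p in outputs.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    io.write_json(manifest, out_dir / "manifest.json")
    return manifest


def build_report(result: CohortResult, sheet: SampleSheet) -> str:
    """Human-readable markdown summary of one analysis run."""
    lines = ["# Run summary", ""]
    lines.append(
        f"Cohort: {len(sheet.patients)} patients, {len(sheet.controls)} controls."
    )
    pre = result.pre
    lines.append(
        f"Assays tested: {len(pre.dct.assay_ids)} "
        f"(of {len(pre.censored.assay_ids)} after censoring)."
    )
    lines.append(
        "Reference set: " + ", ".join(pre.reference.assay_ids)
    )
    n_sig = int(result.diff["significant"].sum())
    lines.append(f"Significant assays (patient vs control): {n_sig}.")
    top = result.diff[result.diff["significant"]].head(10)
    if len(top):
        lines.append("")
        lines.append("Top differential assays (by q):")
        for _, row in top.iterrows():
            lines.append(
                f"- {row['feature']}: fold change {row['fold_change']:.3g}, q = {row['q']:.3g}"
            )
    else:
        lines.append("No significant differential features at the configured threshold.")
    if result.composition is not None:
        lines.append("")
        lines.append("Cluster composition:")
        for _, row in result.composition.iterrows():
            tag = " (patient-only)" if row["patient_only"] else ""
            lines.append(
                f"- group {int(row['group'])}: {int(row['n_patients'])} patients, "
                f"{int(row['n_controls'])} controls "
                f"({100 * row['patient_fraction']:.0f}% of patients){tag}"
            )
        if result.signature_group is not None:
            frac = result.composition.loc[
                result.composition["group"] == result.signature_group, "patient_fraction"
            ].iloc[0]
            lines.append(
                f"Signature group: group {result.signature_group} "
                f"({100 * frac:.0f}% of patients, no controls)."
            )
        else:
            lines.append("Signature group: ambiguous (no patient-only group).")
    if result.subgroup_diff is not None:
        extra = set(
            result.subgroup_diff.loc[result.subgroup_diff["significant"], "feature"]
        ) - set(result.diff.loc[result.diff["significant"], "feature"])
        lines.append(
            f"Subgroup comparison: {int(result.subgroup_diff['significant'].sum())} "
            f"significant assays, {len(extra)} beyond the all-patients comparison."
        )
    if result.analyte_diff is not None:
        sig_analytes = result.analyte_diff.loc[
            result.analyte_diff["significant"], "feature"
        ].tolist()
        lines.append(f"Significant analytes: {', '.join(sig_analytes) or 'none'}.")
    if result.correlations is not None:
        kept = result.correlations[result.correlations["kept"]]
        lines.append(f"Kept correlation pairs: {len(kept)}.")
        for _, row in kept.head(10).iterrows():
            lines.append(
                f"- {row['var1']} ~ {row['var2']}: rho = {row['rho']:.3f}, q = {row['q']:.3g}"
            )
    lines.append("")
    return "\n".join(lines)


def regenerate_report(out_dir) -> str:
    """Rebuild report.md from the artifacts of a completed run."""
    out_dir = Path(out_dir)
    required = ["differential.tsv", "correlations.tsv", "samples.tsv"]
    missing = [f for f in required if not (out_dir / f).exists()]
    if missing:
        raise CtflowError(f"incomplete run in {out_dir}: missing {missing}")
    # Rebuild a lightweight summary straight from the written tables.
    sheet = io.read_sample_sheet(out_dir / "samples.tsv")
    diff = io.read_result_table(out_dir / "differential.tsv")
    corr = io.read_result_table(out_dir / "correlations.tsv")
    lines = ["# Run summary (regenerated)", ""]
    lines.append(f"Cohort: {len(sheet.patients)} patients, {len(sheet.controls)} controls.")
    lines.append(f"Assays tested: {len(diff)}.")
    lines.append(f"Significant assays (patient vs control): {int(diff['significant'].sum())}.")
    comp_path = out_dir / "composition.tsv"
    if comp_path.exists():
        comp = io.read_result_table(comp_path)
        for _, row in comp.iterrows():
            tag = " (patient-only)" if row["patient_only"] else ""
            lines.append(
                f"- group {int(row['group'])}: {int(row['n_patients'])} patients, "
                f"{int(row['n_controls'])} controls{tag}"
            )
    lines.append(f"Kept correlation pairs: {int(corr['kept'].sum())}.")
    lines.append("")
    text = "\n".join(lines)
    (out_dir / "report.md").write_text(text)
    return text
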