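"""Seeded synthetic cohort generator with a recorded ground truth.

Generates a CT matrix (assays x samples), a sample sheet and an analyte
panel whose statistical structure matches the targeted study design: a
mostly-downregulated differential signature confined to a subgroup of
patients, a handful of near-constant reference-like assays, elevated
analytes of which some track a latent pain severity, and comorbidity-linked
assays disjoint from the signature.

Generative model (CT scale, Gaussian noise):

    CT(i, s) = baseline_i
               + shift_i * 1[s in signature] * 1[i in DE or subgroup markers]
               + link_shift * flag(s)        for comorbidity-linked assays
               + Normal(0, sd_i)

with sd_i = noise_sd for regular assays and noise_sd/10 for reference-like
assays. Cells at or above the censor threshold are undetected. Analytes are
log-normal with multiplicative patient shifts; the pain score is an
integerized latent severity coupled to the pain-correlated analytes through
a Gaussian copula calibrated so the *Spearman* correlation hits its target
(r_latent = 2 sin(pi * rho_s / 6)).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .types import AnalytePanel, CtMatrix, SampleSheet


@dataclass(frozen=True)
class AnalyteSpec:
    """Control-group log-normal parameters and the patient mean ratio."""

    mean: float  # control mean concentration, pg/mL
    cv: float  # coefficient of variation
    patient_shift: float = 1.0  # multiplicative shift in patients


def default_analytes() -> dict[str, AnalyteSpec]:
    """20-analyte inflammatory panel; three elevated two-fold in patients."""
    elevated = {"VEGF": 220.0, "IL1Ra": 350.0, "MCP1": 180.0}
    flat = {
        "IFNg": 12.0, "IL1b": 2.5, "IL2": 4.0, "IL4": 9.0, "IL5": 2.0,
        "IL6": 5.0, "IL7": 6.5, "IL8": 14.0, "IL10": 3.5, "TNFa": 8.0,
        "sgp130": 250000.0, "sIL2Ra": 1600.0, "sIL4R": 900.0, "sIL6R": 28000.0,
        "sTNFRI": 1300.0, "sTNFRII": 2400.0, "sRAGE": 1100.0,
    }
    spec = {name: AnalyteSpec(mean, 0.4, 2.0) for name, mean in elevated.items()}
    spec.update({name: AnalyteSpec(mean, 0.4, 1.0) for name, mean in flat.items()})
    return spec


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 41
    n_controls: int = 20
    n_assays: int = 758
    n_de_assays: int = 18
    frac_down: float = 0.9
    signature_frac: float = 0.60
    de_shift_cycles: float = 2.0
    noise_sd_cycles: float = 0.5
    n_reference_like: int = 20
    censor_threshold: float = 32.0
    baseline_ct_range: tuple[float, float] = (20.0, 31.0)
    analytes: dict[str, AnalyteSpec] = field(default_factory=default_analytes)
    pain_corr_analytes: tuple[str, ...] = ("VEGF", "IL1Ra")
    pain_target_rho: float = 0.6
    n_subgroup_markers: int = 5
    subgroup_shift_frac: float = 0.5  # marker shift as a fraction of de_shift
    comorbidity_links: tuple[tuple[str, float], ...] = (
        ("thyroid_disorder", 1.5),
        ("narcotics", -1.5),
    )
    flag_prevalence_patient: float = 0.3
    flag_prevalence_control: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ConfigError("need at least 2 patients and 2 controls")
        for name, val in (
            ("frac_down", self.frac_down),
            ("signature_frac", self.signature_frac),
        ):
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1], got {val}")
        if not np.isfinite(self.de_shift_cycles):
            raise ConfigError("de_shift_cycles must be finite")
        n_special = (
            self.n_de_assays + self.n_reference_like + self.n_subgroup_markers
            + len(self.comorbidity_links)
        )
        if n_special > self.n_assays:
            raise ConfigError(
                f"{n_special} special assays exceed n_assays={self.n_assays}"
            )
        if self.baseline_ct_range[0] >= self.baseline_ct_range[1]:
            raise ConfigError("baseline_ct_range must be (low, high) with low < high")
        if self.noise_sd_cycles <= 0:
            raise ConfigError("noise_sd_cycles must be positive")
        unknown = set(self.pain_corr_analytes) - set(self.analytes)
        if unknown:
            raise ConfigError(f"pain_corr_analytes not in panel: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for the planted structure of one cohort."""

    de_shifts: dict[str, float]  # assay -> planted CT shift (signature only)
    signature_samples: list[str]
    subgroup_markers: dict[str, float]  # assay -> planted CT shift (half effect)
    reference_like: list[str]
    analyte_shifts: dict[str, float]  # analyte -> patient mean ratio (!= 1 only)
    pain_corr_targets: dict[str, float]  # analyte -> target Spearman rho
    comorbidity_links: list[tuple[str, str, float]]  # (flag, assay, shift)
    seed: int

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["comorbidity_links"] = [tuple(x) for x in d["comorbidity_links"]]
        return cls(**d)

    @property
    def planted_assays(self) -> set[str]:
        return set(self.de_shifts) | set(self.subgroup_markers)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CtMatrix, SampleSheet, AnalytePanel, SyntheticTruth]:
    """Generate one cohort; byte-identical outputs for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    controls = [f"C{i + 1:03d}" for i in range(config.n_controls)]
    samples = patients + controls
    assays = [f"miR-{i + 1:04d}" for i in range(config.n_assays)]

    # --- role assignment (disjoint) ---------------------------------------
    n_special = (
        config.n_reference_like + config.n_de_assays + config.n_subgroup_markers
        + len(config.comorbidity_links)
    )
    special = rng.choice(config.n_assays, size=n_special, replace=False)
    cursor = 0

    def take(n):
        nonlocal cursor
        out = [assays[i] for i in special[cursor : cursor + n]]
        cursor += n
        return out

    reference_like = take(config.n_reference_like)
    de_assays = take(config.n_de_assays)
    subgroup_assays = take(config.n_subgroup_markers)
    comorbid_assays = take(len(config.comorbidity_links))

    n_signature = round(config.signature_frac * config.n_patients)
    signature = sorted(
        rng.choice(patients, size=n_signature, replace=False).tolist()
    )

    down = rng.random(config.n_de_assays) < config.frac_down
    de_shifts = {
        a: (config.de_shift_cycles if d else -config.de_shift_cycles)
        for a, d in zip(de_assays, down)
    }
    marker_shift = config.subgroup_shift_frac * config.de_shift_cycles
    down_m = rng.random(config.n_subgroup_markers) < config.frac_down
    subgroup_shifts = {
        a: (marker_shift if d else -marker_shift)
        for a, d in zip(subgroup_assays, down_m)
    }

    # --- clinical covariates ----------------------------------------------
    flags = {}
    for (flag_name, _), _assay in zip(config.comorbidity_links, comorbid_assays):
        f = np.concatenate(
            [
                (rng.random(config.n_patients) < config.flag_prevalence_patient),
                (rng.random(config.n_controls) < config.flag_prevalence_control),
            ]
        ).astype(int)
        flags[flag_name] = f
    links = [
        (flag_name, assay, shift)
        for (flag_name, shift), assay in zip(config.comorbidity_links, comorbid_assays)
    ]

    severity = rng.normal(size=config.n_patients)  # latent pain severity
    pain = np.clip(np.rint(10.0 * stats.norm.cdf(severity)), 0, 10).astype(int)
    crps_type = np.where(rng.random(config.n_patients) < 0.8, 1, 2)
    duration = np.round(np.exp(rng.normal(1.3, 0.6, size=config.n_patients)), 1)
    bmi_p = np.round(np.clip(rng.normal(28.6, 4.5, size=config.n_patients), 16, None), 1)
    bmi_c = np.round(np.clip(rng.normal(24.1, 3.2, size=config.n_controls), 16, None), 1)

    sheet_df = pd.DataFrame(
        {
            "cohort": ["patient"] * config.n_patients + ["control"] * config.n_controls,
            "pain_nrs": list(pain) + [np.nan] * config.n_controls,
            "crps_type": list(crps_type) + [np.nan] * config.n_controls,
            "duration_years": list(duration) + [np.nan] * config.n_controls,
            "bmi": list(bmi_p) + list(bmi_c),
            **{name: vals for name, vals in flags.items()},
        },
        index=pd.Index(samples, name="sample_id"),
    )
    sheet = SampleSheet(sheet_df, flags=list(flags))

    # --- CT matrix ---------------------------------------------------------
    lo, hi = config.baseline_ct_range
    baseline = rng.uniform(lo, hi, size=config.n_assays)
    sd = np.full(config.n_assays, config.noise_sd_cycles)
    ref_idx = [assays.index(a) for a in reference_like]
    sd[ref_idx] = config.noise_sd_cycles / 10.0

    ct = baseline[:, None] + rng.normal(size=(config.n_assays, len(samples))) * sd[:, None]

    sig_cols = np.array([s in set(signature) for s in samples])
    for shifts in (de_shifts, subgroup_shifts):
        for assay, shift in shifts.items():
            if shift != 0.0:
                ct[assays.index(assay), sig_cols] += shift
    for flag_name, assay, shift in links:
        if shift != 0.0:
            carrier = sheet_df[flag_name].to_numpy() == 1
            ct[assays.index(assay), carrier] += shift

    detected = ct < config.censor_threshold
    ct_values = np.where(detected, ct, np.nan)
    ct_matrix = CtMatrix(
        pd.DataFrame(ct_values, index=assays, columns=samples),
        pd.DataFrame(detected, index=assays, columns=samples),
        stage="raw",
    )

    # --- analytes ----------------------------------------------------------
    r_latent = 2.0 * np.sin(np.pi * config.pain_target_rho / 6.0)
    panel = {}
    analyte_shifts = {}
    for name, spec_ in sorted(config.analytes.items()):
        sigma = np.sqrt(np.log(1.0 + spec_.cv**2))
        eps_p = rng.normal(size=config.n_patients)
        eps_c = rng.normal(size=config.n_controls)
        if name in config.pain_corr_analytes and config.pain_target_rho != 0.0:
            latent_p = r_latent * severity + np.sqrt(1.0 - r_latent**2) * eps_p
        else:
            latent_p = eps_p
        conc_p = spec_.mean * spec_.patient_shift * np.exp(
            sigma * latent_p - sigma**2 / 2.0
        )
        conc_c = spec_.mean * np.exp(sigma * eps_c - sigma**2 / 2.0)
        panel[name] = np.concatenate([conc_p, conc_c])
        if spec_.patient_shift != 1.0:
            analyte_shifts[name] = spec_.patient_shift
    panel_df = pd.DataFrame(panel, index=pd.Index(samples, name="sample_id"))
    analyte_panel = AnalytePanel(panel_df)

    truth = SyntheticTruth(
        de_shifts={a: s for a, s in de_shifts.items() if s != 0.0},
        signature_samples=signature,
        subgroup_markers={a: s for a, s in subgroup_shifts.items() if s != 0.0},
        reference_like=reference_like,
        analyte_shifts=analyte_shifts,
        pain_corr_targets=(
            {a: config.pain_target_rho for a in config.pain_corr_analytes}
            if config.pain_target_rho != 0.0
            else {}
        ),
        comorbidity_links=[l for l in links if l[2] != 0.0],
        seed=config.seed,
    )
    return ct_matrix, sheet, analyte_panel, truth


def null_config(config: SimulationConfig) -> SimulationConfig:
    """Copy of ``config`` with every planted effect zeroed."""
    analytes = {
        name: AnalyteSpec(spec_.mean, spec_.cv, 1.0)
        for name, spec_ in config.analytes.items()
    }
    return replace(
        config,
        de_shift_cycles=0.0,
        subgroup_shift_frac=0.0,
        analytes=analytes,
        pain_target_rho=0.0,
        comorbidity_links=tuple((f, 0.0) for f, _ in config.comorbidity_links),
    )


def simulate_null(
    config: SimulationConfig,
) -> tuple[CtMatrix, SampleSheet, AnalytePanel, SyntheticTruth]:
    """Cohort with the same structure but no planted effects anywhere."""
    return simulate_cohort(null_config(config))
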