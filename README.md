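# ctflow

Analysis pipeline for low-density-array qPCR (TLDA-style) profiling of a
patient/control cohort, with an emphasis on patient stratification:

* **I/O** — strict readers/writers for CT matrices (assays × samples),
  sample sheets (cohort, pain 0–10 NRS, clinical covariates, binary flags)
  and analyte concentration panels; delimited text, mask-preserving round
  trips.
* **Preprocessing** — censoring of CT values at a detection threshold
  (default: CT ≥ 32 is undetected), per-cohort detection filtering,
  quantile normalization of detected CT values (rank → common quantile grid
  with linear interpolation, tie-averaged), endogenous-control selection
  (the 10 fully-detected assays with the lowest across-sample SD) and ΔCT
  computation.
* **Differential expression** — two-tailed independent-samples t-tests on
  ΔCT (pooled variance by default, Welch optional), 2^−ΔΔCT signed fold
  changes (magnitudes always ≥ 1; sign opposes ΔΔCT), Benjamini–Hochberg
  adjustment; the same machinery handles analyte panels (unsigned
  patient/control mean ratios).
* **Stratification** — per-sample log2 relative-expression matrix over the
  significant assays, hierarchical clustering (euclidean/average by
  default) cut to k groups, composition reporting with patient-only-group
  ("signature group") identification, and subgroup-vs-rest re-testing.
* **Correlation networks** — tie-corrected Spearman screening across miRNA
  (−ΔCT), analyte and clinical namespaces with per-family BH adjustment and
  a Circos-style link-table export.
* **Synthetic cohorts** — a seeded generator planting a known differential
  signature (default: 18 assays, mostly down-regulated, 2-cycle shift
  confined to a 60% patient subgroup over 758 assays, 41 patients / 20
  controls), subgroup-only markers, elevated analytes, pain-correlated
  analytes (Gaussian-copula rank targeting) and comorbidity-linked assays,
  with a complete JSON ground-truth ledger for recovery testing.

## CLI

Every stage is a verb of the `ctflow` command (exit codes: 0 ok,
2 validation/config error, 3 runtime error):

```sh
ctflow simulate --seed 17 --out-dir fixtures/
ctflow preprocess --ct fixtures/ct.tsv --samples fixtures/samples.tsv --out-dir out/
ctflow diff --dct out/delta_ct.tsv --samples fixtures/samples.tsv \
    --fc-dct out/delta_ct_raw.tsv --out out/differential.tsv
ctflow stratify --dct out/delta_ct.tsv --diff out/differential.tsv \
    --samples fixtures/samples.tsv --k 3 --out-dir out/
ctflow correlate --dct out/delta_ct.tsv --samples fixtures/samples.tsv \
    --analytes fixtures/analytes.tsv --out out/links.tsv
```

or run everything from one YAML config (all thresholds land in
`manifest.json`, which digests every output for bit-reproducibility):

```sh
cat > run.yaml <<'EOF'
seed: 7
simulate: {}          # default paper-shaped cohort; or an `inputs:` block
q_threshold: 0.05
k: 3
alpha: 0.01
EOF
ctflow run-all --config run.yaml --out-dir out/
cat out/report.md
```

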