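# evmir

Analysis pipeline for serum **extracellular-vesicle (EV) miRNomes** in
multiple-sclerosis staging studies. Starting from a miRNA × sample table of
UMI-deduplicated small-RNA-seq counts and a sample sheet (groups: healthy
controls, hospitalized neurological controls, CIS-remission, RRMS-relapse,
viral inflammatory CNS controls), it provides:

- **QC** — background-noise filtering (count < 10 in ≥ 50% of samples),
  outlier-subject exclusion by Spearman correlation against the group mean
  profile, and a reads-vs-UMIs amplification-bias check;
- **Normalization** — TMM scaling factors implemented from first principles
  (verified to 1e-6 against the reference Bioconductor implementation) and
  prior-augmented counts-per-million;
- **Differential expression** — per-miRNA negative-binomial GLMs
  (Var = μ + φμ²) with Cox–Reid dispersion estimation, an empirical-Bayes
  moderated quasi-likelihood F-test (default) or conditional exact test,
  BH adjustment, and calling at raw p < 0.01 with |log2FC| ≥ 1;
- **Stage-specific set logic** — the double dissociation
  (CIS-specific-down = down vs HealthCtl ∧ down vs RRMS;
  RRMS-specific-up = up vs HealthCtl ∧ up vs CIS) plus the directional Venn
  partition across patient groups;
- **Biomarker panels** — z-scored ROC analysis (AUC = Mann–Whitney
  concordance, tie-corrected normal p), greedy panel growth with a
  strict-improvement stop rule, panel t-tests, and normality-gated
  EDSS correlation;
- **Pathway over-representation** — hypergeometric ORA of validated miRNA
  targets against GMT pathway sets (adjusted p < 0.01, ≥ 3 contributing
  miRNAs);
- **Serum–CSF comparison** — two-population split of the log mean-expression
  plane and within-population / per-miRNA correlations;
- **RT-qPCR validation** — replicate QC, Delta Cq (target minus UniSp6
  spike-in), group t-tests, and cross-platform Spearman correlation;
- a **synthetic-data generator** that emulates the study design (group sizes
  18/22/18/16/11, ~5 M reads/sample, NB dispersion 0.2, planted 6 CIS-down /
  9 RRMS-up miRNAs at |log2FC| = 2, matched serum/CSF pairs, qPCR plates)
  with a complete ground-truth ledger, so the whole pipeline is testable
  end-to-end without access to patient data.

See `docs/methods.md` for the statistical details and design rationale.

## Worked example

Run the demo pipeline (simulated data, all stages) from Python:

```python
from evmir.pipeline import run_pipeline
run_pipeline({"out_dir": "demo", "seed": 42})
```

or from the shell: `evmir run --config demo.yaml` after
`evmir simulate --out-dir demo --seed 42`. With seed 42 this prints/writes:

- `qc.json` — 2000 simulated miRNAs filtered to **1392**; the six injected
  outlier subjects (`S003_HealthCtl, S042_CIS, S051_CIS, S064_RRMS,
  S071_RRMS, S080_VI`) are exactly the six excluded ones.
- `de_RRMS_vs_HealthCtl.tsv` — **27 up- and 11 down-regulated** miRNAs at
  raw p < 0.01 and |log2FC| ≥ 1 (the planted 9 RRMS-up plus the shared
  inflammation signature, with expected sampling scatter).
- `specific_sets.json` — the derived CIS-specific-down and RRMS-specific-up
  sets equal the planted truth exactly (6 and 9 IDs).
- `panel.json` — the top-ranked marker already separates CIS from RRMS
  perfectly (panel AUC 1.0, so the stop rule selects a single marker);
  the group test on panel scores gives t(28) = 7.82, p = 1.6e-08.
- `compartment.json` — the serum–CSF split labels 37 paired miRNAs
  high-serum and 1274 similar, with within-population Spearman r = 0.92 and
  0.99 (the high-serum population shrinks after CSF background filtering:
  dividing counts by 10² pushes many below the detection filter, as in real
  CSF).
- `qpcr.json` — for the two top RRMS-specific targets, Delta Cq is lower in
  RRMS than CIS (t ≈ −8.1 and −7.2; lower Delta Cq = higher expression) and
  Delta Cq vs normalized counts gives Spearman rho ≈ −0.98.

Every output file is listed with a SHA-256 hash in `manifest.json`;
re-running with the same seed reproduces all files byte-for-byte.

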