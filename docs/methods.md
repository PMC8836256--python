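# Methods

`evmir` implements the statistical pipeline used in serum extracellular-vesicle
(EV) miRNome studies of multiple sclerosis stages: small-RNA UMI counts from
five subject groups (healthy controls, hospitalized neurological controls,
CIS-remission, RRMS-relapse, and viral inflammatory CNS controls) are
quality-controlled, TMM-normalized, tested for pairwise differential
expression under a negative-binomial model, reduced to stage-specific marker
sets by double dissociation, and followed up with ROC biomarker panels,
pathway over-representation, serum–CSF comparison, and RT-qPCR Delta-Cq
validation. Because such datasets are rarely public, the package ships a
first-class synthetic-data generator with planted ground truth; every claim
the test suite makes is a recovery or calibration statement about that
generator.

## Count model and synthetic data

Counts are negative binomial with mean–dispersion parameterization
Var(Y) = μ + φμ², matching the downstream GLM. The generator
(`evmir.synthetic`) draws:

- **Baseline abundances** log-uniform over `baseline_logmean_range`
  (default 0–5 on log10), normalized to relative proportions. Real EV miRNA
  abundance distributions are not published for this design; the log-uniform
  is a deliberate stand-in, exposed in the configuration. The range was
  pilot-calibrated once so that at the default depth the per-sample number
  of detected miRNAs (count ≥ 1) falls in the 731–2407 band reported for
  serum EV sequencing at ~5 million reads/sample (the simulation averages
  ≈1820 of 2000 simulated miRNAs).
- **Library sizes** lognormal with mean 5×10⁶ and CV 0.25 (default);
  group sizes default to 18/22/18/16/11 (HealthCtl/HospCtl/CIS/RRMS/VI).
- **Dispersion** φ = 0.2 by default, constant across miRNAs; an optional
  gamma model gives per-miRNA dispersions.
- **Planted effects**: 6 miRNAs down-regulated only in CIS and 9 up-regulated
  only in RRMS at |log2FC| = 2 (the stage-specific double dissociation), plus
  a shared "inflammation signature" of 18 up- and 11 down-regulated miRNAs
  applied equally to CIS, RRMS, and VI. Applying the shared signature to all
  three patient groups keeps it out of the RRMS-vs-CIS contrast, so the
  stage-specific truth sets stay exactly the 6+9 planted IDs; a
  `shared_cis_fraction` parameter lets users attenuate the CIS component and
  populate RRMS∩VI-only overlap regions instead (at the cost of leakage into
  the stage-specific sets near the calling thresholds). Planted effects are
  placed only on miRNAs whose expected baseline count is ≥ 50, so the effect
  is observable after background filtering; with ~2800 expected counts per
  detected miRNA this excludes only the detection-limit tail.
- **Outlier subjects** are corrupted by rank-shuffling a `severity` fraction
  of a subject's counts within the column, which preserves the library size
  but destroys the correlation with the group profile.
- **Matched CSF** samples copy the serum counts of one group, divide a
  randomly chosen "high-serum" population (default fraction 128/2151) by
  10^2, and multiply every miRNA by lognormal noise (sd 0.15 on log10).
  Real CSF is not a noisy copy of serum — this emulates only the two-cluster
  structure and within-population coupling that the compartment module is
  meant to recover.
- **qPCR plates**: triplicate Cq = intercept − slope·log2(CPM+1) + N(0, sd)
  per target, duplicate UniSp6 spike-in at a fixed level, and optional
  displaced replicates (≥ 2 cycles) recorded in the truth ledger.

What passing tests do **not** show about real data: the generator has no
batch effects, no GC/length bias, no compositional coupling between planted
effects, no heavy-tailed abundance distribution, and its outliers are
maximally detached. Recovery rates here are upper bounds on field behavior.

## QC

Background noise: a miRNA is discarded iff the fraction of samples with
count < 10 reaches 50% (both thresholds configurable). The filter is
idempotent and order-preserving.

Outlier subjects: each subject is scored by the Spearman correlation of its
count profile against the arithmetic mean profile of its group (subject
included; a leave-one-out option exists). Flagging offers two rules on the
pooled rho distribution: the literal `quartile` rule (below the 25th
percentile — which by construction removes ~25% of subjects and is kept only
for comparison) and the default `tukey` rule, rho < Q1 − max(1.5·IQR, 0.05).
The absolute 0.05 floor exists because in a homogeneous cohort the rho
distribution is nearly degenerate (IQR of order 10⁻³ at this depth) and a
pure IQR fence flags sampling noise; a genuinely corrupted profile sits
several tenths below the bulk. `run_qc` applies the rule iteratively
(`detect_outliers`): the lowest-rho subject below threshold is removed, group
means are recomputed over the remaining subjects, and the procedure repeats
until stable. The iteration matters when several corrupted subjects land in
one group — they drag the group mean down and, in a single pass, the entire
group can cross the fence.

Amplification bias: Spearman rho of per-sample total reads vs total UMIs,
with a warning below 0.99.

## Normalization

TMM scaling factors follow the published trimmed-mean-of-M-values algorithm:
reference sample = the one whose 75th count-percentile proportion is closest
to the mean; per sample, M and A values over miRNAs nonzero in both sample
and reference; double trimming (30% on M, 5% on A, rank-based with average
ties); inverse-variance (delta-method binomial) weighting; factors rescaled
to geometric mean 1. All-zero miRNAs are removed first. The implementation
is tested to 10⁻⁶ agreement against the reference Bioconductor
implementation on composition-biased fixtures; reproducing that agreement
requires computing M as a single `log2((obs/N_obs)/(ref/N_ref))` so exact
ties remain exactly tied under rank trimming.

CPM: value = (count + prior_i)/(library·factor)·10⁶ with the prior scaled
per effective library (`prior_i = prior_count·L_i/mean(L)`); prior 0.5 by
default so downstream logs are defined, 0 gives plain CPM.

## Differential expression

Per miRNA, a one-way NB GLM with log link and effective-library-size offsets.
Dispersion: common φ maximizes the Cox–Reid adjusted profile likelihood
(APL = profile log-likelihood − ½·Σ_groups log Fisher information) summed
over non-zero miRNAs; per-miRNA values maximize APL_g + w·mean-APL on a
log-spaced grid around the common value with weight w = prior_df/residual_df
(prior_df = 10) — a weighted-likelihood shrinkage toward the shared profile.

- **QL engine (default)**: full (two group means) and null (one mean) fits at
  the shrunk dispersion; quasi-dispersion s² = residual deviance / (n−2),
  moderated across miRNAs by an empirical-Bayes scaled inverse-chi-square fit
  (moment matching on log s², trigamma-inverse solved by Newton); the
  deviance difference divided by the moderated s² is referred to
  F(1, d₀ + n − 2). Empirical type-I error at raw p < 0.01 on null
  simulations is ≈ 0.008–0.017 (inside the [0.005, 0.02] calibration band).
- **Exact engine**: conditional NB exact test at the common dispersion on
  counts scaled (and rounded) to the geometric-mean effective library; the
  conditional distribution of the group-A sum given the total is enumerated
  over a ±20-conditional-SD window and the two-sided p sums probabilities no
  larger than the observed one. This is a simplification of
  quantile-adjusted-pseudo-count exact testing; its p-values agree with the
  QL engine at rank correlation ≥ 0.95 on filtered data.

log2FC comes from prior-augmented TMM-CPM group means, not the GLM
coefficient (configurable through `prior_count`); miRNAs all-zero in a
contrast are skipped (p = 1, log2FC = 0). Calling uses raw p < 0.01 together
with |log2FC| ≥ 1 (boundary inclusive); BH-adjusted p-values are reported
alongside but do not gate the calls, since the stage-specific set logic is
defined at the raw threshold. BH is the textbook step-up with enforced
monotonicity.

Stage-specific sets: CIS-specific-down = down in CIS vs HealthCtl AND down
in CIS vs RRMS; RRMS-specific-up = up in RRMS vs HealthCtl AND up in RRMS vs
CIS. The Venn partition over the three vs-HealthCtl contrasts retains
direction; concordant calls versus HospCtl are annotated when those
contrasts are available.

## Biomarker panels

Normalized expression is z-scored per miRNA across exactly the two compared
groups, using the sample (n−1) standard deviation. AUC is the Mann–Whitney
U statistic scaled to [0,1] with ties counted ½; its two-sided p-value uses
the normal approximation with tie and continuity correction (equivalent to
the common ROC software behavior, and verified against exhaustive
enumeration on small fixtures). Markers are oriented so AUC ≥ 0.5
(orientation recorded), ranked by AUC, ties broken by smaller p then
lexicographic ID. Panels average the oriented z-scores of the top-k markers;
k grows while the panel AUC strictly improves, and the selected panel is the
prefix achieving the maximum — which by construction is at least the best
single marker. Panel scores are compared between groups with the classical
pooled-variance t-test. Correlation with a clinical covariate (EDSS) uses
Pearson when both marginals pass the D'Agostino–Pearson K² normality test at
α = 0.05 and Spearman otherwise (both marginals are tested because the
published procedure does not say which one was); 95% CIs by Fisher
transform, with the 1.06/(n−3) variance for rank correlations.

## Pathway over-representation

The gene universe is the union of all pathway genes in the supplied GMT —
reproducible from inputs, and the convention of the common ORA services.
raw p = upper-tail hypergeometric P(X ≥ k) for overlap k, pathway size K,
query size n, universe N; BH across all pathways tested. Significant
pathways require adjusted p < 0.01 AND ≥ 3 query miRNAs each contributing at
least one target gene to the overlap. Live database access (miRWalk,
Reactome, MSigDB) is out of scope: the package reads user-supplied exports
and, in the demo pipeline, a synthetic target-map/pathway fixture with one
planted enriched pathway.

## Serum–CSF comparison

Per-miRNA compartment means are computed over matched subjects, restricted
to miRNAs detected (post background filter) in both compartments — this
restriction matters, since miRNAs with all-zero CSF counts cannot be placed
on the log-log plane. The log10 serum−CSF difference is split into two
populations by a deterministic 1-D 2-means (centers initialized at the
10th/90th percentiles; the higher cluster is "high-serum"; the threshold is
reported). The published split was explicitly qualitative; 2-means on the
log-difference is the smallest reproducible assumption that yields a
separating line parallel to the identity. Within-population serum–CSF
correlations default to Spearman (the stated methods choice; the
corresponding figure caption says Pearson — the pipeline reports both and
labels Spearman primary). Per-miRNA between-subject correlations use the
same normality-gated rule as the panel module.

## RT-qPCR

Delta Cq = mean target Cq (over unflagged replicates) − mean UniSp6 Cq;
lower means higher expression. Replicate QC aligns the replicate columns of
each assay on their across-sample medians (a robust one-parameter quantile
alignment) and flags replicates deviating from the well median by more than
`max_dev` = 0.5 cycles after alignment. A full sorted-profile quantile
mapping was rejected: rank mapping erases the magnitude of a displaced
replicate (making it undetectable), and with several outliers on a plate the
extreme-rank profile itself becomes contaminated. Wells whose replicates are
all flagged are reported missing. Group comparisons use the pooled-variance
t-test per target; cross-platform consistency is the Spearman correlation of
Delta Cq against normalized sequencing counts, expected negative.

## Pipeline, seeds, determinism

`evmir run --config cfg.yaml` executes simulate → QC → normalize → DE (7
pairwise contrasts) → stage-specific sets → panel → enrichment → CSF → qPCR,
writing TSV/JSON artifacts plus a manifest with parameters and SHA-256
hashes of every output. A single global seed fans out to per-stage seeds by
hashing the stage name, so identical config + seed give byte-identical
outputs and stages are independently reproducible.

## Problem sizes

The test suite and the reproduction script use the study-design scale
throughout: 2000 simulated miRNAs (2151 for the compartment analysis),
85 subjects in five groups, 5×10⁶ reads/sample. Multi-seed recovery checks
use 20 seeds (stage-specific sets, panels) and 50 seeds (outlier recovery);
calibration checks use one null simulation of 2000 miRNAs with 16 vs 18
subjects. These sizes keep a full run in a few minutes on one CPU while
leaving the binomial uncertainty of the reported rates well inside the
asserted bands.

## Known limitations

- The exact-test engine rounds scaled counts; at very unequal library sizes
  its conditioning is approximate.
- QL moderation assumes a common quasi-dispersion prior across miRNAs;
  strongly heteroskedastic dispersion (e.g. the gamma option with small
  shape) will make the F-test conservative.
- The normality gate is applied to both marginals; with n ≈ 15 per group the
  K² test has limited power, so near-normal heavy-tailed data will often be
  routed to Pearson.
- The compartment split assumes exactly two populations; more structure ends
  up absorbed into the nearer cluster.
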