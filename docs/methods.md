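# Methods

`methylodyn` implements an n-of-1 longitudinal analysis of cell-free DNA
(cfDNA) methylomes: per-sample cell-of-origin deconvolution, per-subject
temporal variability, therapy-window methylation-shift detection, and
differential methylation calling driven by tumour (prostate) content. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic cohort does and does not emulate.

## Data model

A cohort is a probes × samples matrix of β-values (methylation fractions in
[0, 1], missing allowed), a sample sheet (subject, timepoint label, months
since baseline, PSA, cfDNA concentration), a therapy timeline (windows of
LHRH / taxane / AR-inhibitor / radioisotope administration in months), a
probe annotation exploded to (probe, gene, region) triples with the closed
region vocabulary TSS1500/TSS200/5UTR/BODY/3UTR/INTERGENIC, and a reference
methylation atlas (cell types × marker probes). "5′ regulatory" means
TSS1500, TSS200 or 5′UTR for at least one gene. Months are the time axis
throughout; timepoint labels (BL, FU1, …) are display-only.

## Cell-of-origin deconvolution

Each sample's β vector over the atlas marker probes is decomposed by
non-negative least squares, min‖Aᵀf − b‖₂ s.t. f ≥ 0, over the sample's
non-missing markers (missing markers are dropped, never imputed — NNLS
tolerates subset fitting and imputation would invent signal). Fractions are
renormalised to sum to one; the RMS residual is reported. The prostate
fraction classifies the sample:

- `NPC` below the detectable threshold (default 0.03 — an explicit operating
  point, configurable and surfaced in every report),
- `PC_DETECTABLE` in [0.03, 0.10),
- `PC_SUBSTANTIAL` at ≥ 0.10 (the standard "substantial content" cut).

No downstream statistic is adjusted for cell composition: generic cell-type
adjustment methods are built for cross-sectional blood panels, and applying
them to n-of-1 tumour-fraction series risks erroneous corrections, so the
longitudinal results deliberately describe total cfDNA.

## Temporal variability and MVPs

Per subject, each probe's temporal variability is the sample standard
deviation (n−1 denominator; configurable in principle, but the sample SD is
the natural default for 4–6 observations) over that subject's timepoints,
requiring ≥ 3 non-missing values. The most-variable probes (MVPs) are the
top ⌈0.05·n⌉ by SD — selection happens over *all* eligible probes first and
the 5′-regulatory filter is applied second, so the regulatory subset is
"regulatory probes within the top 5%". Ties break by probe-ID lexicographic
order, making the selection invariant to input order. The stability summary
is the fraction of probes with SD strictly below 0.1.

PCA (probe-centred SVD, per-probe mean imputation for missing values) is a
cohort-level QC view only; imputed values never feed any other stage.

## Trajectory clustering and gene envelopes

Regulatory-MVP trajectories (raw β vectors over the subject's timepoints)
are clustered by average-linkage agglomerative clustering on euclidean
distances. Raw β rather than z-scores is the default so clusters separate
by both level and shape; a standardisation flag exists. The cluster count
is chosen as the k in [2, 8] maximising the mean silhouette width (ties go
to the smaller k; k_max covers the 2–7 range seen in practice, and the
silhouette rule is a deterministic stand-in since no canonical selection
rule exists for this design). If all pairwise distances vanish the
degenerate single-cluster partition is returned. For each (cluster, gene)
with ≥ 2 member probes, per-timepoint mean/min/max envelopes are emitted;
single-probe genes are omitted (the "≥ 2 dynamic CpGs" convention — all
cluster members count as dynamic).

## Therapy-window shifts

For a subject × therapy window: baseline is the last sample at or before
the window start; on-therapy samples are all samples within [start, end];
the probe's Δβ is the signed on-minus-baseline change of maximal magnitude
(this captures within-window extremes rather than privileging one
timepoint; a single pre/post pair is the special case of a one-sample
window). A probe is *shifted* when |Δβ| ≥ 0.1, hyper- or hypomethylated by
sign. When a post-cessation sample exists, the shift is *transient* iff
|β_post − β_baseline| < 0.1 (the same threshold reused as the reversion
band; configurable); without a post-cessation sample transience is
undefined, not false. Windows of distinct therapy classes that overlap in
months raise a simultaneous-therapies flag, since attribution to either
drug is then impossible. No causal claims attach to any shift.

Gene-set enrichment of shifted genes is a one-sided hypergeometric tail
P(X ≥ overlap) per GMT set (sets intersected with the universe), BH-adjusted
across sets, significant at q < 0.05. The foreground is genes with ≥ 1
shifted regulatory MVP; the universe is genes with ≥ 1 regulatory MVP for
that subject. Probe-number bias correction for GO testing is intentionally
out of scope.

## DMG calling

Gene-level β is the mean over a gene's regulatory probes (per-probe calling
with ≥ 2-probe gene support exists as an alternative convention; gene-level
means are the default because the 0.1 threshold is defined on promoter
methylation). For each discovery subject with ≥ 2 `PC_SUBSTANTIAL` samples
(single-PC subjects are excluded with a logged warning — two-group
statistics are undefined otherwise), candidate genes are those hit by the
subject's regulatory MVPs. The **pooled** comparison — subject's PC samples
vs all NPC samples cohort-wide — defines DMG status at |Δβ| ≥ 0.1 and BH
q < 0.05, with BH applied within subject across its candidate genes (a
per-subject family matches the n-of-1 discovery design; a global family is
a one-line change). The within-subject PC-vs-own-NPC comparison is reported
descriptively. Direction is the sign of (PC mean − NPC mean). Union
summaries count distinct called genes per direction and the fraction unique
to a single subject.

Two-group testing auto-selects Welch's t when both groups have n ≥ 4 and
pass Shapiro–Wilk at α = 0.05, otherwise the two-sided Mann–Whitney U
(exact when min(n) ≤ 8 with no ties, tie-corrected normal approximation
otherwise; all-identical input returns p = 1). The Welch gate requires
n ≥ 4 rather than 3 because Shapiro–Wilk has essentially no power at n = 3
— the normality check is vacuous there — and Welch's Satterthwaite df
collapses to ≈ 2 in such groups, capping attainable significance near
5×10⁻³ even under complete separation; the exact rank test is both better
calibrated and better powered for the smallest groups. Benjamini–Hochberg
is the in-package step-up implementation (cross-checked against an
independent reference implementation in the tests).

Validation re-tests each discovery (gene, direction) in an independent
PC/NPC-labelled cohort under the same thresholds, requiring the same
direction; external gene lists (e.g. a user-supplied cancer-methylation
list) are reported as overlap fractions of the validated genes. Stage-wise
comparisons across ≥ 3 histological groups use Kruskal–Wallis (tie-corrected;
chi-square approximation by default, exact permutation enumeration
available for ≤ 12 observations) with Dunn's z post hoc BH-adjusted across
pairs.

## Synthetic cohort

The generator reproduces the statistical structure the analysis assumes,
with full ground truth. Defaults are the study conditions: 9 subjects at
4–6 timepoints every 4 months (5×6 + 2×5 + 2×4 = 48 samples), 20,000
probes (desk-scale; the EPIC-scale probe count is a preprocessing outcome,
not a method parameter), 8 cell types (prostate + 7 hematopoietic
lineages) with 200 marker probes each (own type β ≈ 0.1, all others ≈ 0.9),
and beta-distributed measurement noise: observed β ~ Beta(μν, (1−μ)ν) with
precision ν = 50, which keeps draws on [0, 1] without clipping artefacts
(SD ≈ 0.066 at μ = 0.5, ≈ 0.03 near the support edges — the magnitude of
array-replicate noise).

Each sample's expected β is the fraction-weighted mixture of cell-type
profiles. Non-tumour composition is a Dirichlet draw (concentration 100)
around a fixed neutrophil-dominated hematopoietic base; the per-sample
prostate fraction follows a curated default schedule that reproduces the
reference composition — 16/48 samples with detectable content across 6
subjects, 10 substantial (≥ 0.10) across 4, maximum 0.49.

Planted effects:

- **Therapy shifts** (default 300 probes, Δ = 0.2, transient): additive on
  the mixture mean inside the assigned window (pulse archetype) or from the
  window start onward (step archetype), then clipped. Gain-of-methylation
  shifts are planted on near-unmethylated baselines U(0.05, 0.15) and
  losses on near-methylated U(0.85, 0.95) — the canonical promoter
  patterns, and the regime where beta noise is tight enough for the
  single-post-sample transience call to be reliable (at mid-range baselines
  the |Δ| < 0.1 reversion band has a ~25% false-exceedance rate under
  ν = 50, and transience accuracy sits near 0.9 rather than above it).
- **Tumour DMGs** (default 100 hyper + 100 hypo, Δ = 0.3, 3 regulatory
  probes per gene): planted in the *prostate profile only*, so the
  observable PC-vs-NPC contrast scales with tumour fraction. At the default
  schedule's 0.15–0.49 fractions a 0.3 profile-level difference attenuates
  to ≈ 0.05–0.15 at the sample level, so the end-to-end pipeline calls only
  the strongest planted genes — an honest property of mixture-mediated
  signal, and the reason full-scale (0 → 1) tumour-vs-blood differences
  dominate real DMG lists. The focused DMG benchmark therefore plants Δβ
  directly as the PC-group contrast (3 PC vs 30 NPC samples) when measuring
  calling error rates.

All randomness flows from one seed through named `SeedSequence` streams
(atlas, design, planting, noise, gene sets); a paired cohort generated with
a different `noise_seed` shares every design and planting choice and
differs only in measurement noise — the construction used for validation.

What the generator does **not** emulate: array chemistry, batch and
position effects, detection p-values, probe cross-reactivity, realistic
genomic probe spacing, correlated probes within CpG islands, or clinical
covariate structure (PSA and cfDNA concentrations are decorative draws).
Passing recovery tests therefore demonstrates correctness of the analysis
under the stated mixture-plus-beta-noise model, not robustness to array
artefacts — which the upstream preprocessing (out of scope here) is
responsible for removing.

## Problem sizes and numerical notes

The test-suite and acceptance-script runs use the default 20,000-probe,
48-sample cohort for end-to-end checks; the focused benchmarks use a
3,000-probe single-subject cohort for shifts (300 planted), 2,000 genes ×
33 samples for DMG calling (aggregated over multiple seeds), and 60
trajectories for cluster recovery — sizes chosen so every property is
measured on hundreds-to-thousands of decisions while a full run stays in
the tens of seconds on one CPU.

Numerical conventions: mixture means are clipped to [1e-3, 1−1e-3] before
beta sampling; NNLS residuals are reported as RMS over used markers; BH
uses a stable mergesort so equal p-values keep input order; cluster labels
are renumbered by first appearance so clustering output is reproducible;
β TSVs are written at %.10g so write∘read round-trips within 1e-9. All
stage outputs at a fixed seed are byte-identical across runs; the manifest
(which carries wall-clock timestamps) is the only non-reproducible file.

## Known limitations

- The detectable-content threshold (0.03) is an assumed operating point;
  published deconvolution work reports "detectable" without a number.
- Transience is judged from a single post-cessation sample; with 4-monthly
  sampling a shift can dissipate and recur unseen, and the ~0.9 accuracy
  ceiling under realistic noise is intrinsic to the single-sample rule.
- DMG discovery power depends multiplicatively on tumour fraction; subjects
  whose PC samples sit near the 10% cut contribute little.
- The asymptotic Kruskal–Wallis p is anticonservative for very small
  groups; use the permutation mode there.
- Gene-set enrichment ignores per-gene probe counts, so probe-rich genes
  are slightly favoured in the foreground; a bias-corrected GO test is a
  deliberate non-goal.
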