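# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Differential accessibility (`sexregulome.diffacc`)

**Model.** For each OCR, log-CPM values
`y = log2((count + 0.5) / (libsize + 1) * 1e6)` are modelled as

    y ~ X beta + Z u + e,   u ~ N(0, sigma_u^2 per individual),
    e ~ N(0, sigma^2 / w)   (w = per-observation precision weight)

with fixed covariates X (sex, diagnosis, brain region, technical
covariates; categorical covariates are reference-coded so the sex
coefficient is a male-vs-female log2 fold change) and one random intercept
per individual to absorb the repeated-measures correlation of two regions
(and optionally two cell fractions) per donor.

**Precision weights.** A per-OCR OLS fit yields residual standard
deviations; lowess of sqrt(residual sd) on mean log-count gives a
mean-variance trend, and each observation's weight is the trend value at
its fitted log-count to the inverse fourth power — the voom convention.
Pseudocounts 0.5 (count) and 1.0 (library) are fixed; they only matter at
very low counts.

**Fitting.** Because the random structure is a single grouped intercept
over diagonal weights, the marginal covariance is block-diagonal with
blocks `D_g + lambda * 1 1'` whose inverse and determinant have closed
Sherman–Morrison forms. The REML criterion is therefore profiled to one
dimension in `lambda = sigma_u^2 / sigma^2` and maximized by a log-spaced
grid (17 points, 10^-2.5..10^2, plus lambda = 0) refined by 20
golden-section iterations — all vectorised across OCRs, so fitting 2,000
OCRs x 80 samples takes ~3 s on one CPU. When every individual contributes
exactly one sample the intercept variance is unidentifiable and the fit
short-circuits to weighted least squares (lambda = 0).

**Inference.** Wald t on the contrast coefficient with conservative
degrees of freedom `df = n_individuals - n_fixed_coefficients`, floored at
2; this is deliberately simpler than a Satterthwaite approximation and
errs toward fewer false positives. BH adjustment runs across all retained
OCRs. Labels: FDR < 0.05 and log2FC > 0 male-specific, < 0
female-specific; an exactly zero log2FC stays `ns`.

**Stratification.** Chromosome classes come from names (chrX/X, chrY/Y,
else autosome; mitochondrial names are rejected since chrM reads are
removed upstream of any such analysis). Whole-number percentages use
round-half-away-from-zero and need not sum to 100; note that 84/5,327 is
reported as 2% under this convention.

## CRD calling and testing (`sexregulome.crd`)

Calling operates on the covariate-corrected matrix (residuals of a
regression on all nuisance covariates, never including sex). A contiguous
segment of OCRs is an admissible domain when it has >= 2 members
(`min_members`), every gap between consecutive member midpoints is <=
250 kb (`max_pair_distance_bp`), and its mean pairwise |Pearson r| is >=
0.3 (`min_mean_abs_corr`). Among all contiguous segmentations of a
chromosome the caller returns, by dynamic programming, the one maximizing
(1) OCRs covered by admissible segments, (2) fewest segments, (3) total
mean |r|. An exact optimizer was chosen over greedy agglomeration because
its output is reproducible, order-independent, and provably optimal for
the stated emission criterion — a greedy average-linkage merge can
fragment a correlated block or depend on tie order. Key (2) is what keeps
a fully correlated block as a single domain rather than a chain of pairs.
Defaults (250 kb, 0.3, 2) are tunable; Pearson (not Spearman) correlation
is used because the input is already on the linear-model residual scale.

**Stage-wise sex test.** Stage 1 screens domains by the Simes combination
of member OCR p-values (valid under the positive dependence expected of
correlated members), with BH across domains at alpha = 0.05. Stage 2
refits the same mixed model on the domain's per-sample mean score and
Wald-tests the sex coefficient. A domain is called sex-specific when it
passes screening and stage2_p < 0.05; the stage-wise adjusted level
`alpha * n_screened / n_domains` is reported alongside
(`confirmed_adjusted`) for users who prefer the stricter convention.
Direction is the sign of the unweighted mean member log2FC; testing each
member OCR instead of the domain mean is available by using the per-OCR
results directly.

## TRD clustering (`sexregulome.trd`)

Sex-specific CRD scores are correlated across samples; hierarchical
clustering (average linkage, matching the CRD module) runs on the signed
dissimilarity 1 − r so anti-correlated domains separate. The tree is cut
at every k in 2..20 (truncated with a warning when there are fewer than
k_max + 1 domains) and the Baker–Hubert Gamma index picks k: over all
pairs of a within-cluster dissimilarity w and a between-cluster
dissimilarity b, s+ counts w < b and s− counts w > b, ties count in
neither (the classical definition), and Γ = (s+ − s−)/(s+ + s−).
Γ is computed exactly by sorted counting (no sampling), is invariant to
cluster relabelling and to any strictly increasing transform of the
dissimilarities, and ties across k resolve to the smallest k. When every
candidate pair ties, Γ is undefined and reported as NaN.

Per-TRD summaries count female/male-specific member CRDs and OCRs and
report the Spearman correlation between member-OCR sex log2FC and SCZ
log2FC twice — over all member OCRs and over sex-specific members only —
because either universe is defensible; TRDs with fewer than 3 qualifying
OCRs get NaN rather than an error.

## ABC links (`sexregulome.abc_model`)

Activity is the geometric mean of ATAC and H3K27ac signal (the original
ABC convention). Contacts are binned at a configurable resolution
(`bin = floor(pos / resolution)`), symmetric, with pseudocount 0.01 added
at lookup so unobserved bins rank below observed ones without producing
zero denominators. Candidates for a gene are elements whose midpoint lies
within 5 Mb of the TSS; the element midpoint (not the full interval)
determines both the bin and the signed distance, which keeps results
resolution-independent and deterministic. Pre-threshold scores of a gene
sum to exactly 1 whenever the activity-contact mass is positive; links are
kept at score >= 0.02 and ubiquitously expressed genes (a caller-provided
flag) yield no links. Sex comparison reports the shared fraction
(intersection over the mean set size) plus the Jaccard index, and Spearman
score correlations over both the union (absent links scored 0) and the
intersection. Chromatin-state composition assigns each linked element the
state of maximal overlap; a state absent from one partition receives
pseudo-frequency 0.5/n so log2 ratios stay finite.

## Enrichment (`sexregulome.enrich`)

All enrichment reduces to a 2x2 table over an explicit universe with
Fisher's exact test, two-sided by default. The odds ratio is ad/bc with
the Haldane–Anscombe +0.5 applied to every cell when any cell is zero.
The exact p of a discrete test is conservative and lumpy, so
`EnrichmentResult` also carries the one-sided mid-p
(P(X > a) + P(X = a)/2), the standard calibrated variant, which is what
null-uniformity diagnostics should use. Gene-set enrichment intersects GMT
sets with the universe, keeps sets of 10–1000 genes, and controls FDR by
BH across retained sets (BH output is deterministic and monotone in the
p-value order; re-adjusting already-adjusted values is not a no-op and is
never done). Gene identifiers are harmonized by case-folding only — alias
resolution would require external databases. XCI-escape overlap is pure
set arithmetic per cell type. The OCR-to-gene map for gene-level analyses
uses ABC links when available, otherwise the nearest TSS.

## Synthetic studies (`sexregulome.synth`)

The generator emulates the statistical structure the pipeline is built
for, not the sequence content of real data:

* **Counts**: negative binomial (dispersion 0.1) whose log2 mean is
  baseline + planted effects + region offset + latent noise; expected
  column sums are scaled to a library size drawn uniformly from
  30k–80k reads. These are desk-scale libraries; the dispersion and the
  biological log2 sd of 1.0 were chosen so that biological variation
  dominates count noise, as it does in deeply sequenced bulk ATAC data.
* **Correlation structure**: a Gaussian-copula latent layer with shared
  factors per CRD block and per TRD group
  (`z = sqrt(r_t) g + sqrt(r_w - r_t) f + sqrt(1 - r_w) e`), which
  requires the nesting `r_within >= r_trans` and rejects configurations
  violating it. The latent layer has two components with identical
  correlation structure: one drawn per individual (sd 0.5, reused by all
  of that donor's samples — this is the repeated-measures signal, ICC ~
  0.2 on log-CPM) and one per sample (sd 1.0).
* **Effects**: affected OCRs carry sex effects of fixed magnitude with
  random signs, forced negative (female-biased) on chrX; chrY OCRs are
  male-only structurally, with females receiving Poisson(0.1) residual
  noise so the low-count filter is exercised (mirroring pseudoautosomal
  bleed-through). Diagnosis effects share the affected set with a sign
  that agrees with the sex sign with probability (1 + rho)/2, giving the
  two effect vectors Pearson correlation rho.
* **Covariates**: two synthetic technical covariates (FRiP-like,
  GC-like) with correlation 0.1 to sex, so covariate adjustment is
  exercised under mild confounding; covariate *selection* is out of scope
  and the covariate list is taken as given.
* **Replicates**: `resample_seed` redraws all sampling noise while
  keeping the layout, cohort and planted truth of `seed`, which is what
  replicate-concordance analyses need.
* **ABC inputs**: a power-law contact kernel `(|Δbin| + 1)^-1` with a 10x
  contact and 10x activity boost on one planted element per gene (the
  nearest unused element to the TSS, so the planted product provably
  outranks decoys); sex-specific genes have the boost in one sex and
  near-zero activity in the other.

Not emulated: read-level data, fragment-size structure, peak calling,
realistic Hi-C distance decay beyond the power law, GC/mappability bias,
population structure. Passing tests therefore demonstrate correctness of
the statistics under the stated noise model, not robustness to artifacts
peculiar to real sequencing data.

## Problem sizes and calibration experiments

The shipped experiments use 40–100 individuals, 60–2,000 OCRs and 20-seed
replications — sizes at which every stage's behaviour (FDR control below
5%, effect recovery within ±0.1 of a planted log2FC of 1.0, block
recovery at ARI ≥ 0.8, planted-k recovery ≥ 90%) is measurable in about a
minute of CPU; they are scaled-down analogues of a cohort study, chosen as
the smallest sizes with stable statistics. The headline numbers of any
specific real dataset (total counts of sex-specific OCRs or domains)
depend on that dataset's sample size and noise and are not reproduced by
simulation; what the experiments establish is the calibration and
recovery behaviour of the machinery itself.

## Known limitations

* The mixed model supports a single random intercept; crossed or nested
  random effects (e.g. batch within donor) are not implemented.
* Conservative df makes the per-OCR test slightly underpowered relative
  to a Satterthwaite approximation at small n.
* CRD calling is exact per chromosome but O(n * L) in the number of OCRs
  times the maximum segment length (`max_members`, default 50); very
  dense OCR maps may need a smaller cap.
* The two-sided Fisher p uses the "sum of less-probable tables"
  convention (scipy); other conventions (doubling the one-sided p) give
  different values for asymmetric margins.
* Hi-C normalization (KR/ICE), promoter-activity rescaling and external
  H3K27ac processing are upstream of this package and assumed done.
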