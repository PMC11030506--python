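"""Simulate a sex-stratified chromatin accessibility study with known truth.

Builds a small cohort (60 individuals, two brain regions each) with planted
sex effects (female-biased on chrX, male-only chrY baseline), correlated OCR
blocks, and negative-binomial counts, then prints what was planted.
"""

from sexregulome import SimConfig, simulate_study

config = SimConfig(
    n_individuals=60,
    sex_effect_log2fc=1.0,           # |log2FC| of planted male-vs-female effects
    scz_effect_log2fc=0.6,
    sex_scz_effect_correlation=0.5,  # planted rho between the two effect vectors
    crd_blocks=(("chr1", 6, 0.75), ("chrX", 5, 0.75)),
    sex_effect_block_ids=(0, 1),
    seed=0,
)
study = simulate_study(config)

print(f"counts matrix: {study.counts.shape[0]} OCRs x {study.counts.shape[1]} samples")
print(f"individuals: {study.sample_table['individual'].nunique()} "
      f"({(study.sample_table['sex'] == 'female').mean():.0%} of samples female)")
affected = study.truth[study.truth["sex_log2fc"] != 0]
print(f"OCRs with a planted sex effect: {len(affected)}")
print("per chromosome class:")
print(affected.groupby("chrom_class", observed=True)["sex_log2fc"].agg(["count", "mean"]))
# chrX effects are negative (female-biased) by construction; chrY OCRs are
# male-only at the baseline level rather than via a planted log2FC.
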