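"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a sex-stratified brain ATAC-seq study:
negative-binomial counts with library-size variation, per-individual repeated
measures across brain regions (and optionally cell types), planted sex
effects concentrated on chrX (female-biased) and chrY (male-only), planted
diagnosis effects correlated with the sex effects at a configurable rho,
genomically local correlated OCR blocks (CRDs), and trans-correlated block
groups (TRDs). A companion generator produces toy activity + contact inputs
with planted enhancer-promoter links for the ABC model.

The count model is negative binomial over a Gaussian-copula latent layer:
block / group correlation is imposed on a unit-variance Gaussian field which
enters the NB log-mean, so the planted correlation lives on the log scale
where every downstream statistic operates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from sexregulome.fileio import chrom_class, read_bed, read_counts, read_table, write_bed, write_counts, write_table

AUTOSOMES = [f"chr{i}" for i in range(1, 8)]


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    CRD blocks are ``(chromosome, n_member_ocrs, within_block_correlation)``
    triples; TRD groups are ``(member_block_ids, trans_correlation)`` pairs.
    Correlations are nested: every block's within-correlation must be at
    least the trans-correlation of any group containing it, otherwise the
    implied OCR-level correlation matrix is not positive semidefinite.
    """

    n_individuals: int = 80
    female_fraction: float = 0.4
    scz_fraction: float = 0.33
    regions: tuple[str, ...] = ("ACC", "DLPFC")
    cell_types: tuple[str, ...] = ("neuronal",)
    n_ocrs_autosome: int = 600
    n_ocrs_X: int = 150
    n_ocrs_Y: int = 30
    crd_blocks: tuple[tuple[str, int, float], ...] = ()
    trd_groups: tuple[tuple[tuple[int, ...], float], ...] = ()
    sex_effect_log2fc: float = 0.0
    scz_effect_log2fc: float = 0.0
    sex_scz_effect_correlation: float = 0.0
    frac_affected_autosome: float = 0.05
    frac_affected_X: float = 0.5
    sex_effect_block_ids: tuple[int, ...] = ()
    nb_dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (30_000.0, 80_000.0)
    individual_sd: float = 0.5
    residual_sd: float = 1.0
    region_effect_sd: float = 0.2
    baseline_log2_sd: float = 1.0
    chry_female_mean: float = 0.1
    # toy ABC inputs
    abc_n_elements: int = 40
    abc_n_genes: int = 6
    abc_resolution: int = 10_000
    abc_sex_specific_fraction: float = 0.2
    seed: int = 0
    # replicate support: when set, the study keeps the layout, individuals and
    # planted truth of `seed` but redraws all sampling noise from this seed
    resample_seed: int | None = None

    def validate(self) -> None:
        for name in ("female_fraction", "scz_fraction", "frac_affected_autosome", "frac_affected_X"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.sex_scz_effect_correlation <= 1.0:
            raise ValueError("sex_scz_effect_correlation outside [-1, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[0] > self.lib_size_range[1]:
            raise ValueError("lib_size_range must be positive and ordered")
        per_chrom = {"chrX": self.n_ocrs_X, "chrY": self.n_ocrs_Y}
        for c in AUTOSOMES:
            per_chrom[c] = self.n_ocrs_autosome  # upper bound per autosome
        used: dict[str, int] = {}
        for bid, (chrom, n, r) in enumerate(self.crd_blocks):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"block {bid}: correlation {r} outside [0, 1]")
            if n < 2:
                raise ValueError(f"block {bid}: needs >= 2 member OCRs")
            used[chrom] = used.get(chrom, 0) + n
            if chrom not in per_chrom or used[chrom] > per_chrom[chrom]:
                raise ValueError(f"block {bid}: members do not fit on {chrom}")
        for gid, (members, r_t) in enumerate(self.trd_groups):
            if not 0.0 <= r_t <= 1.0:
                raise ValueError(f"group {gid}: trans correlation {r_t} outside [0, 1]")
            for bid in members:
                if bid >= len(self.crd_blocks):
                    raise ValueError(f"group {gid}: unknown block id {bid}")
                if self.crd_blocks[bid][2] < r_t:
                    raise ValueError(
                        f"group {gid}: trans correlation {r_t} exceeds within-block "
                        f"correlation {self.crd_blocks[bid][2]} of block {bid}; the "
                        "implied correlation matrix is not positive semidefinite"
                    )
        seen: set[int] = set()
        for members, _ in self.trd_groups:
            for bid in members:
                if bid in seen:
                    raise ValueError(f"block {bid} appears in more than one TRD group")
                seen.add(bid)


@dataclass
class SimulatedStudy:
    counts: pd.DataFrame          # OCR x sample, integer
    sample_table: pd.DataFrame    # per-sample metadata
    ocr_bed: pd.DataFrame         # chrom, start, end, name, chrom_class
    truth: pd.DataFrame           # per-OCR planted effects and block/group ids
    config: SimConfig


@dataclass
class SimulatedABCInputs:
    elements: pd.DataFrame        # chrom, start, end, element_id, activity_female, activity_male
    genes: pd.DataFrame           # gene_id, chrom, tss, strand, ubiquitous
    contacts: pd.DataFrame        # chrom, bin_i, bin_j, freq (symmetric)
    resolution: int
    truth_links: dict[str, set[tuple[str, str]]]


def _layout_ocrs(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place OCRs on chromosomes; CRD-block members are adjacent intervals."""
    rows = []
    block_of: list[int] = []
    # blocks grouped by chromosome so their members stay contiguous
    blocks_by_chrom: dict[str, list[int]] = {}
    for bid, (chrom, _, _) in enumerate(config.crd_blocks):
        blocks_by_chrom.setdefault(chrom, []).append(bid)

    counts_per_chrom = {c: 0 for c in AUTOSOMES + ["chrX", "chrY"]}
    n_auto_left = config.n_ocrs_autosome
    for chrom, bids in blocks_by_chrom.items():
        for bid in bids:
            n = config.crd_blocks[bid][1]
            counts_per_chrom[chrom] += n
            if chrom == "chrX":
                pass
            elif chrom == "chrY":
                pass
            elif chrom in AUTOSOMES:
                n_auto_left -= n
    if n_auto_left < 0:
        raise ValueError("CRD blocks exceed the autosomal OCR budget")
    free_x = config.n_ocrs_X - sum(
        config.crd_blocks[b][1] for b in blocks_by_chrom.get("chrX", []))
    free_y = config.n_ocrs_Y - sum(
        config.crd_blocks[b][1] for b in blocks_by_chrom.get("chrY", []))

    def emit(chrom: str, bid: int, pos: int) -> int:
        width = int(rng.integers(200, 1000))
        rows.append((chrom, pos, pos + width))
        block_of.append(bid)
        return pos + width

    for chrom in AUTOSOMES + ["chrX", "chrY"]:
        pos = int(rng.integers(10_000, 50_000))
        for bid in blocks_by_chrom.get(chrom, []):
            n = config.crd_blocks[bid][1]
            for _ in range(n):
                pos = emit(chrom, bid, pos)
                pos += int(rng.integers(1_000, 8_000))   # inside a block: short gaps
            pos += 500_000                                # blocks well separated
        if chrom in AUTOSOMES:
            n_free = n_auto_left // len(AUTOSOMES)
            if chrom == AUTOSOMES[-1]:
                n_free = n_auto_left - n_free * (len(AUTOSOMES) - 1)
        elif chrom == "chrX":
            n_free = free_x
        else:
            n_free = free_y
        for _ in range(n_free):
            pos = emit(chrom, bid=-1, pos=pos)
            pos += int(rng.integers(300_000, 600_000))    # background OCRs uncorrelated & far apart

    bed = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bed["name"] = [f"ocr_{i:05d}" for i in range(len(bed))]
    bed["chrom_class"] = [chrom_class(c) for c in bed["chrom"]]
    bed["crd_block"] = block_of
    return bed


def _plant_effects(config: SimConfig, bed: pd.DataFrame, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Signed per-OCR sex and diagnosis log2FC vectors.

    Affected OCRs carry effects of fixed magnitude with random signs; chrX
    effects are forced female-biased (negative under male-vs-female coding).
    The diagnosis sign matches the sex sign with probability (1 + rho) / 2,
    which gives the two +/-1 sign vectors expected Pearson correlation rho.
    """
    g = len(bed)
    sex = np.zeros(g)
    scz = np.zeros(g)
    if config.sex_effect_log2fc == 0.0 and config.scz_effect_log2fc == 0.0:
        return sex, scz
    is_x = (bed["chrom_class"] == "X").to_numpy()
    is_y = (bed["chrom_class"] == "Y").to_numpy()
    in_forced_block = bed["crd_block"].isin(config.sex_effect_block_ids).to_numpy()
    u = rng.random(g)
    affected = in_forced_block.copy()
    affected |= is_x & ~in_forced_block & (u < config.frac_affected_X)
    affected |= (~is_x & ~is_y & ~in_forced_block) & (u < config.frac_affected_autosome)
    affected &= ~is_y  # chrY sex bias is structural (male-only baseline), not a planted log2FC

    idx = np.flatnonzero(affected)
    sign_sex = np.where(is_x[idx], -1.0, rng.choice([-1.0, 1.0], size=idx.size))
    # a forced block carries one coherent sign so the domain has a clear direction
    block_sign = {bid: (-1.0 if config.crd_blocks[bid][0] == "chrX"
                        else float(rng.choice([-1.0, 1.0])))
                  for bid in config.sex_effect_block_ids}
    blocks_at_idx = bed["crd_block"].to_numpy()[idx]
    for k, bid in enumerate(blocks_at_idx):
        if bid in block_sign:
            sign_sex[k] = block_sign[bid]
    agree = rng.random(idx.size) < (1.0 + config.sex_scz_effect_correlation) / 2.0
    sign_scz = np.where(agree, sign_sex, -sign_sex)
    sex[idx] = config.sex_effect_log2fc * sign_sex
    scz[idx] = config.scz_effect_log2fc * sign_scz
    if config.scz_effect_log2fc == 0.0:
        scz[:] = 0.0
    if config.sex_effect_log2fc == 0.0:
        sex[:] = 0.0
    return sex, scz


def _latent_noise(config: SimConfig, bed: pd.DataFrame, n_samples: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian field with nested block/group correlation.

    For OCR i in block b of group t:
        z_i = sqrt(r_t) * g_t + sqrt(r_w - r_t) * f_b + sqrt(1 - r_w) * e_i
    so corr within a block is r_w and across blocks of one group is r_t.
    """
    g = len(bed)
    z = rng.standard_normal((g, n_samples))
    if not config.crd_blocks:
        return z
    group_of_block = {}
    trans_r = {}
    for gid, (members, r_t) in enumerate(config.trd_groups):
        for bid in members:
            group_of_block[bid] = gid
            trans_r[bid] = r_t
    group_factors = rng.standard_normal((max(len(config.trd_groups), 1), n_samples))
    block_factors = rng.standard_normal((len(config.crd_blocks), n_samples))
    block_ids = bed["crd_block"].to_numpy()
    for bid, (_, _, r_w) in enumerate(config.crd_blocks):
        members = np.flatnonzero(block_ids == bid)
        if members.size == 0:
            continue
        r_t = trans_r.get(bid, 0.0)
        shared = np.zeros(n_samples)
        if bid in group_of_block:
            shared += math.sqrt(r_t) * group_factors[group_of_block[bid]]
        shared += math.sqrt(max(r_w - r_t, 0.0)) * block_factors[bid]
        z[members] = shared + math.sqrt(max(1.0 - r_w, 0.0)) * rng.standard_normal(
            (members.size, n_samples))
    return z


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Draw one complete synthetic study; the seed fully determines output."""
    config.validate()
    if config.n_ocrs_autosome + config.n_ocrs_X + config.n_ocrs_Y == 0:
        raise ValueError("study must contain at least one OCR")
    rng = np.random.default_rng(config.seed)
    noise_seed = config.seed if config.resample_seed is None else config.resample_seed
    rng_noise = np.random.default_rng([noise_seed, 17])

    bed = _layout_ocrs(config, rng)
    g = len(bed)

    # individuals and samples
    n = config.n_individuals
    n_female = int(round(config.female_fraction * n))
    sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sexes)
    dx = np.where(rng.random(n) < config.scz_fraction, "SCZ", "control")

    samples = []
    for i in range(n):
        for region in config.regions:
            for ct in config.cell_types:
                samples.append((f"ind_{i:04d}", sexes[i], dx[i], region, ct, i))
    st = pd.DataFrame(samples, columns=["individual", "sex", "diagnosis", "region",
                                        "cell_type", "_ind_idx"])
    s = len(st)
    st.index = [f"samp_{j:05d}" for j in range(s)]
    st["lib_size"] = rng_noise.uniform(*config.lib_size_range, size=s)
    # two technical covariates with mild confounding to sex (r ~ 0.1)
    male = (st["sex"] == "male").to_numpy(float)
    male_z = (male - male.mean()) / (male.std() + 1e-12)
    for cov, base, scale in (("frip", 0.30, 0.04), ("gc_content", 0.45, 0.03)):
        st[cov] = base + scale * (0.1 * male_z
                                  + math.sqrt(1 - 0.01) * rng_noise.standard_normal(s))

    sex_lfc, scz_lfc = _plant_effects(config, bed, rng)
    region_coef = rng.normal(0.0, config.region_effect_sd, size=g)
    baseline = rng.normal(0.0, config.baseline_log2_sd, size=g)

    is_scz = (st["diagnosis"] == "SCZ").to_numpy(float)
    is_region2 = (st["region"] == config.regions[-1]).to_numpy(float) if len(config.regions) > 1 else np.zeros(s)

    # Repeated-measures correlation is per (OCR, individual): a per-individual
    # latent field re-used by all of that individual's samples, plus a
    # per-sample field. Both carry the nested block/group correlation, so
    # within-block correlation of the summed noise stays at the planted level.
    ind_idx = st["_ind_idx"].to_numpy()
    z_ind = _latent_noise(config, bed, n, rng_noise)[:, ind_idx]
    z_samp = _latent_noise(config, bed, s, rng_noise)
    log2_mu = (baseline[:, None]
               + np.outer(sex_lfc, male)
               + np.outer(scz_lfc, is_scz)
               + np.outer(region_coef, is_region2)
               + config.individual_sd * z_ind
               + config.residual_sd * z_samp)

    rel = np.exp2(log2_mu)
    is_y = (bed["chrom_class"] == "Y").to_numpy()
    female_col = (st["sex"] == "female").to_numpy()
    rel[np.ix_(is_y, female_col)] = 0.0
    lib = st["lib_size"].to_numpy()
    mean = lib[None, :] * rel / rel.sum(axis=0, keepdims=True)

    alpha = config.nb_dispersion
    counts = rng_noise.negative_binomial(n=1.0 / alpha, p=1.0 / (1.0 + alpha * mean))
    # residual chrY noise in females (pseudoautosomal bleed-through), exercises filtering
    if is_y.any() and female_col.any():
        counts[np.ix_(is_y, female_col)] = rng_noise.poisson(
            config.chry_female_mean, size=(is_y.sum(), female_col.sum()))

    counts_df = pd.DataFrame(counts, index=bed["name"].to_numpy(), columns=st.index)
    counts_df.index.name = "ocr_id"
    truth = pd.DataFrame({
        "ocr_id": bed["name"],
        "chrom": bed["chrom"],
        "chrom_class": bed["chrom_class"],
        "sex_log2fc": sex_lfc,
        "scz_log2fc": scz_lfc,
        "crd_block": bed["crd_block"],
        "trd_group": [_group_of(config, b) for b in bed["crd_block"]],
        "male_only": bed["chrom_class"] == "Y",
    }).set_index("ocr_id", drop=False)

    sample_table = st.drop(columns=["_ind_idx"]).reset_index(names="sample_id")
    return SimulatedStudy(counts=counts_df, sample_table=sample_table,
                          ocr_bed=bed, truth=truth, config=config)


def _group_of(config: SimConfig, block_id: int) -> int:
    if block_id < 0:
        return -1
    for gid, (members, _) in enumerate(config.trd_groups):
        if block_id in members:
            return gid
    return -1


def simulate_abc_inputs(config: SimConfig) -> SimulatedABCInputs:
    """Toy enhancer activity + contact inputs with planted E-P links.

    One planted element per gene gets a 10x activity boost and a 5x contact
    boost toward the gene's TSS, so it attains the top activity-by-contact
    product among that gene's candidates. Sex-specific genes have the boost
    applied in one sex only; in the other sex the element is near-silent.
    Contacts follow a power-law distance kernel at the configured resolution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    ne, ng = config.abc_n_elements, config.abc_n_genes
    if ne == 0 or ng == 0:
        raise ValueError("ABC inputs need at least one element and one gene")
    res = config.abc_resolution
    chrom = "chr1"
    spacing = 50_000
    starts = np.arange(ne) * spacing + rng.integers(0, 10_000, size=ne)
    elements = pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": starts + 500,
        "element_id": [f"elem_{i:03d}" for i in range(ne)],
    })
    base = np.exp(rng.normal(0.0, 0.5, size=ne))
    tss = np.sort(rng.choice(np.arange(ne) * spacing + 25_000, size=ng, replace=False))
    genes = pd.DataFrame({
        "gene_id": [f"gene_{j:02d}" for j in range(ng)],
        "chrom": chrom,
        "tss": tss,
        "strand": rng.choice(["+", "-"], size=ng),
        "ubiquitous": False,
    })
    genes.loc[genes.index[-1], "ubiquitous"] = True  # one housekeeping-style decoy

    span_bins = int(np.ceil((max(starts.max() + 500, tss.max()) + 1) / res))
    act = {"female": base.copy(), "male": base.copy()}
    boost: dict[tuple[int, int], float] = {}
    truth: dict[str, set[tuple[str, str]]] = {"female": set(), "male": set()}
    n_sex_specific = int(round(config.abc_sex_specific_fraction * ng))
    mid = elements["start"].to_numpy() + 250
    used: set[int] = set()
    for j in range(ng):
        if bool(genes.loc[j, "ubiquitous"]):
            continue
        dist = np.abs(mid - tss[j]).astype(float)
        dist[list(used)] = np.inf
        e = int(np.argmin(dist))  # nearest unused element: boosted activity x
        used.add(e)               # boosted contact dominates every decoy product
        b_e, b_t = int(mid[e] // res), int(tss[j] // res)
        boost[(min(b_e, b_t), max(b_e, b_t))] = 10.0
        eid, gid = elements.loc[e, "element_id"], genes.loc[j, "gene_id"]
        if j < n_sex_specific:
            on = "female" if j % 2 == 0 else "male"
            off = "male" if on == "female" else "female"
            act[on][e] = base[e] * 10.0
            act[off][e] = 1e-3
            truth[on].add((eid, gid))
        else:
            act["female"][e] = act["male"][e] = base[e] * 10.0
            truth["female"].add((eid, gid))
            truth["male"].add((eid, gid))
    elements["activity_female"] = act["female"]
    elements["activity_male"] = act["male"]

    rows = []
    for i in range(span_bins):
        for j in range(i, span_bins):
            freq = (abs(j - i) + 1.0) ** -1.0
            freq *= boost.get((i, j), 1.0)
            rows.append((chrom, i, j, freq))
    contacts = pd.DataFrame(rows, columns=["chrom", "bin_i", "bin_j", "freq"])
    return SimulatedABCInputs(elements=elements, genes=genes, contacts=contacts,
                              resolution=res, truth_links=truth)


FIXTURE_FILES = {
    "counts": "counts.tsv",
    "samples": "samples.tsv",
    "bed": "ocrs.bed",
    "truth": "truth_ocr.tsv",
}


def write_fixture(study: SimulatedStudy, directory: str | Path) -> dict[str, Path]:
    """Write a study to TSV/BED files; a round-trip read is exact."""
    if len(study.counts) == 0:
        raise ValueError("refusing to write a study with zero OCRs")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}
    try:
        write_counts(study.counts, paths["counts"])
        write_table(study.sample_table, paths["samples"])
        write_bed(study.ocr_bed, paths["bed"])
        write_table(study.truth.reset_index(drop=True), paths["truth"])
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths


def read_fixture(directory: str | Path) -> SimulatedStudy:
    directory = Path(directory)
    counts = read_counts(directory / FIXTURE_FILES["counts"])
    samples = read_table(directory / FIXTURE_FILES["samples"])
    bed = read_bed(directory / FIXTURE_FILES["bed"])
    bed["chrom_class"] = [chrom_class(c) for c in bed["chrom"]]
    truth = read_table(directory / FIXTURE_FILES["truth"]).set_index("ocr_id", drop=False)
    return SimulatedStudy(counts=counts, sample_table=samples, ocr_bed=bed,
                          truth=truth, config=None)
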