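"""Activity-by-contact (ABC) enhancer-promoter linking and landscape statistics.

For a gene g and a candidate element e, the ABC score is

    ABC(e, g) = A(e) * C(e, g) / sum over candidates e' of A(e') * C(e', g)

where A is element activity (geometric mean of ATAC and H3K27ac signal) and
C the Hi-C contact frequency between the element's bin and the TSS bin plus
a small pseudocount. Candidates are elements whose midpoint lies within a
window of the TSS (default 5 Mb); links are kept when the normalized score
reaches the threshold (default 0.02). Links to ubiquitously expressed genes
are removed by rule. Running the model separately per sex yields link sets
whose sharing, score correlation, distance structure and chromatin-state
composition are summarized here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sexregulome.fileio import chrom_class


@dataclass
class GenePromoter:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    ubiquitous: bool = False


@dataclass
class ContactMap:
    """Symmetric binned contact frequencies; ``bin = floor(pos / resolution)``."""

    resolution: int
    freq: dict[tuple[str, int, int], float]
    pseudocount: float = 0.01

    @classmethod
    def from_table(cls, contacts: pd.DataFrame, resolution: int,
                   pseudocount: float = 0.01) -> "ContactMap":
        if (contacts["freq"] < 0).any():
            raise ValueError("contact frequencies must be non-negative")
        freq: dict[tuple[str, int, int], float] = {}
        for chrom, bi, bj, f in contacts[["chrom", "bin_i", "bin_j", "freq"]].itertuples(index=False):
            key = (chrom, min(int(bi), int(bj)), max(int(bi), int(bj)))
            freq[key] = max(freq.get(key, 0.0), float(f))
        return cls(resolution=resolution, freq=freq, pseudocount=pseudocount)

    def contact(self, chrom: str, pos_a: int, pos_b: int) -> float:
        ba, bb = pos_a // self.resolution, pos_b // self.resolution
        key = (chrom, min(ba, bb), max(ba, bb))
        return self.freq.get(key, 0.0) + self.pseudocount


def element_activity(atac_signal, h3k27ac_signal):
    """Combined activity A = sqrt(ATAC x H3K27ac), elementwise."""
    a = np.asarray(atac_signal, float)
    h = np.asarray(h3k27ac_signal, float)
    if (a < 0).any() or (h < 0).any():
        raise ValueError("activity signals must be non-negative")
    return np.sqrt(a * h)


def abc_scores(elements: pd.DataFrame, gene: GenePromoter, contacts: ContactMap,
               window: float = 5e6, threshold: float = 0.02,
               activity_col: str = "activity") -> pd.DataFrame:
    """Score all candidate elements for one gene; keep links >= threshold.

    ``elements`` needs columns (chrom, start, end, element_id, <activity_col>)
    sorted by position. Ubiquitous genes yield no links by rule. Candidate
    selection and binning use the element midpoint. Before thresholding the
    scores of a gene sum to exactly 1 whenever sum(A*C) > 0.
    """
    cols = ["chrom", "start", "end", "element_id", activity_col, "gene_id",
            "A", "C", "abc_score", "distance_to_tss"]
    if gene.ubiquitous:
        return pd.DataFrame(columns=cols)
    mid = ((elements["start"] + elements["end"]) // 2).to_numpy()
    cand = elements.loc[(elements["chrom"] == gene.chrom)
                        & (np.abs(mid - gene.tss) <= window)].copy()
    if cand.empty:
        return pd.DataFrame(columns=cols)
    cmid = ((cand["start"] + cand["end"]) // 2).to_numpy()
    A = cand[activity_col].to_numpy(float)
    if (A < 0).any():
        raise ValueError("element activity must be non-negative")
    C = np.array([contacts.contact(gene.chrom, int(m), gene.tss) for m in cmid])
    prod = A * C
    total = prod.sum()
    if total <= 0:
        return pd.DataFrame(columns=cols)  # flagged by emptiness, not an error
    cand["gene_id"] = gene.gene_id
    cand["A"] = A
    cand["C"] = C
    cand["abc_score"] = prod / total
    cand["distance_to_tss"] = cmid - gene.tss
    out = cand[cand["abc_score"] >= threshold]
    return out[cols].reset_index(drop=True)


def abc_all_genes(elements: pd.DataFrame, genes: list[GenePromoter],
                  contacts: ContactMap, window: float = 5e6,
                  threshold: float = 0.02, activity_col: str = "activity") -> pd.DataFrame:
    """Run the ABC model for every gene and annotate nearest-gene status."""
    frames = [abc_scores(elements, g, contacts, window, threshold, activity_col)
              for g in genes]
    links = pd.concat([f for f in frames if not f.empty], ignore_index=True) \
        if any(not f.empty for f in frames) else pd.DataFrame(
            columns=frames[0].columns if frames else [])
    if links.empty:
        return links
    return annotate_nearest_gene(links, genes)


def annotate_nearest_gene(links: pd.DataFrame, genes: list[GenePromoter]) -> pd.DataFrame:
    """Flag links whose gene is the nearest TSS to the element midpoint."""
    links = links.copy()
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    nearest = []
    for chrom, start, end, gid in links[["chrom", "start", "end", "gene_id"]].itertuples(index=False):
        mid = (start + end) // 2
        cands = tss_by_chrom.get(chrom, [])
        best = min(cands, key=lambda t: (abs(t[0] - mid), t[1]))[1] if cands else None
        nearest.append(gid == best)
    links["is_nearest_gene"] = nearest
    return links


def compare_sex_links(links_female: pd.DataFrame, links_male: pd.DataFrame) -> dict:
    """Sharing and score-correlation report between the two per-sex link sets.

    Shared fraction = |intersection| / mean(|F|, |M|) over (element, gene)
    keys; the Jaccard index is reported alongside. Spearman correlation of
    ABC scores is computed over the union (absent links scored 0) and over
    the intersection.
    """
    if links_female.empty and links_male.empty:
        raise ValueError("both link sets are empty")

    def keyed(links):
        return {(e, g): s for e, g, s in
                links[["element_id", "gene_id", "abc_score"]].itertuples(index=False)}

    f, m = keyed(links_female), keyed(links_male)
    inter = sorted(set(f) & set(m))
    union = sorted(set(f) | set(m))
    mean_size = (len(f) + len(m)) / 2.0
    fu = np.array([f.get(k, 0.0) for k in union])
    mu = np.array([m.get(k, 0.0) for k in union])
    rho_union = stats.spearmanr(fu, mu)[0] if len(union) >= 3 else float("nan")
    rho_inter = (stats.spearmanr([f[k] for k in inter], [m[k] for k in inter])[0]
                 if len(inter) >= 3 else float("nan"))

    def chrom_partition(links, keys):
        sub = links[[tuple(k) in keys for k in
                     links[["element_id", "gene_id"]].itertuples(index=False)]]
        elems = sub.drop_duplicates("element_id")
        cls = pd.Series([chrom_class(c) for c in elems["chrom"]])
        n = max(len(cls), 1)
        return {"autosome": float((cls == "autosome").sum() / n),
                "X": float((cls == "X").sum() / n)}

    female_only = set(f) - set(m)
    male_only = set(m) - set(f)
    return {
        "n_female": len(f),
        "n_male": len(m),
        "n_shared": len(inter),
        "shared_fraction": len(inter) / mean_size if mean_size else 0.0,
        "jaccard": len(inter) / len(union) if union else 0.0,
        "spearman_union": float(rho_union),
        "spearman_intersection": float(rho_inter),
        "female_specific": female_only,
        "male_specific": male_only,
        "female_specific_chrom": chrom_partition(links_female, female_only),
        "male_specific_chrom": chrom_partition(links_male, male_only),
    }


def landscape_stats(links: pd.DataFrame, near_tss_bp: int = 100_000) -> dict:
    """Distance / multiplicity / nearest-gene summary of a link set."""
    if links.empty:
        raise ValueError("no links to summarize")
    genes_per_element = links.groupby("element_id")["gene_id"].nunique()
    elements_per_gene = links.groupby("gene_id")["element_id"].nunique()
    return {
        "n_links": len(links),
        "genes_per_element": dict(genes_per_element.value_counts().sort_index()),
        "elements_per_gene": dict(elements_per_gene.value_counts().sort_index()),
        "frac_multigene_elements": float((genes_per_element >= 2).mean()),
        "frac_multielement_genes": float((elements_per_gene >= 2).mean()),
        "frac_nearest_gene": float(links["is_nearest_gene"].mean())
            if "is_nearest_gene" in links.columns else float("nan"),
        "frac_within_100kb": float((links["distance_to_tss"].abs() <= near_tss_bp).mean()),
    }


def _max_overlap_state(chrom: str, start: int, end: int, states: pd.DataFrame) -> str | None:
    sub = states[(states["chrom"] == chrom) & (states["start"] < end) & (states["end"] > start)]
    if sub.empty:
        return None
    ov = np.minimum(sub["end"], end) - np.maximum(sub["start"], start)
    return str(sub["name"].iloc[int(np.argmax(ov.to_numpy()))])


def state_overlap_ratio(links_x: pd.DataFrame, links_auto: pd.DataFrame,
                        state_bed: pd.DataFrame) -> dict[str, float]:
    """Per-state log2 ratio of state frequencies: X-linked vs autosomal elements.

    Each linked element is assigned the chromatin state of maximal overlap;
    a state absent from one partition gets pseudo-frequency 0.5 / n_elements
    for that partition so the ratio stays finite.
    """
    if links_x.empty or links_auto.empty:
        raise ValueError("both partitions must be non-empty")

    def freqs(links):
        elems = links.drop_duplicates("element_id")
        assigned = [
            _max_overlap_state(c, s, e, state_bed)
            for c, s, e in elems[["chrom", "start", "end"]].itertuples(index=False)]
        assigned = [a for a in assigned if a is not None]
        n = len(assigned)
        if n == 0:
            raise ValueError("no linked element overlaps the state segmentation")
        counts = pd.Series(assigned).value_counts()
        return counts, n

    cx, nx = freqs(links_x)
    ca, na = freqs(links_auto)
    out = {}
    for state in sorted(set(cx.index) | set(ca.index)):
        fx = cx.get(state, 0.0) / nx or 0.5 / nx
        fa = ca.get(state, 0.0) / na or 0.5 / na
        out[state] = float(np.log2(fx / fa))
    return out
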