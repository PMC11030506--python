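"""Fisher-exact enrichment, gene-set tests, XCI-list overlap and concordance.

All enrichment statistics are built on one primitive: a 2x2 contingency
table over a common universe, tested with Fisher's exact test (two-sided by
default) and summarized by the sample odds ratio ad/bc, with the
Haldane-Anscombe 0.5 correction applied to every cell whenever any cell is
zero. Benjamini-Hochberg controls the FDR across gene-set terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ContingencyTable:
    a: int  # in A and in B
    b: int  # in A, not B
    c: int  # not A, in B
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


@dataclass
class EnrichmentResult:
    term_id: str
    table: ContingencyTable
    odds_ratio: float
    p: float
    fdr: float = float("nan")
    # one-sided (enrichment) mid-p: P(X > a) + P(X = a)/2 under the
    # hypergeometric null. The exact p of a discrete test is conservative and
    # lumpy by construction; the mid-p is the standard calibrated variant and
    # is what null-uniformity diagnostics should look at.
    midp_greater: float = float("nan")


@dataclass
class ConcordanceResult:
    n_features: int
    spearman_rho: float
    p: float


def fisher_enrichment(set_a_flags, set_b_flags, term_id: str = "",
                      alternative: str = "two-sided") -> EnrichmentResult:
    """Fisher's exact test of association between two flag vectors."""
    a_fl = np.asarray(set_a_flags, bool)
    b_fl = np.asarray(set_b_flags, bool)
    if a_fl.size == 0 or a_fl.shape != b_fl.shape:
        raise ValueError("flags must be non-empty and over the same universe")
    table = ContingencyTable(
        a=int((a_fl & b_fl).sum()), b=int((a_fl & ~b_fl).sum()),
        c=int((~a_fl & b_fl).sum()), d=int((~a_fl & ~b_fl).sum()))
    _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]],
                              alternative=alternative)
    rv = stats.hypergeom(table.n, table.a + table.b, table.a + table.c)
    midp = float(rv.sf(table.a) + 0.5 * rv.pmf(table.a))
    return EnrichmentResult(term_id=term_id, table=table,
                            odds_ratio=table.odds_ratio(), p=float(p),
                            midp_greater=midp)


def ocr_in_crd_enrichment(sex_specific_flags: pd.Series,
                          crd_membership: pd.Series,
                          sex_specific_crd_ids: set[str]) -> EnrichmentResult:
    """Are sex-specific OCRs over-represented inside sex-specific CRDs?

    ``crd_membership`` maps every OCR id to a CRD id or None/NaN.
    """
    universe = sex_specific_flags.index
    member = crd_membership.reindex(universe)
    if member.dropna().empty:
        raise ValueError("no OCR lies inside any CRD")
    in_sex_crd = member.isin(sex_specific_crd_ids).to_numpy()
    return fisher_enrichment(sex_specific_flags.to_numpy(bool), in_sex_crd,
                             term_id="sex_ocr_in_sex_crd")


def gene_set_enrichment(target_genes: set[str], universe_genes: set[str],
                        gmt_sets: dict[str, set[str]],
                        size_bounds: tuple[int, int] = (10, 1000),
                        fdr_threshold: float = 0.05) -> list[EnrichmentResult]:
    """Fisher enrichment of a target gene list against GMT sets.

    Sets are intersected with the universe, then filtered to the size
    bounds; BH FDR runs across retained sets.
    """
    universe = {g.casefold() for g in universe_genes}
    if not universe:
        raise ValueError("empty gene universe")
    targets = {g.casefold() for g in target_genes} & universe
    results: list[EnrichmentResult] = []
    uni = sorted(universe)
    t_flags = np.array([g in targets for g in uni])
    retained = []
    for name, genes in gmt_sets.items():
        gset = {g.casefold() for g in genes} & universe
        if not size_bounds[0] <= len(gset) <= size_bounds[1]:
            continue
        retained.append((name, gset))
    if not retained:
        raise ValueError("no gene set survives the size bounds within the universe")
    for name, gset in retained:
        s_flags = np.array([g in gset for g in uni])
        results.append(fisher_enrichment(t_flags, s_flags, term_id=name))
    _, fdr, _, _ = multipletests([r.p for r in results], method="fdr_bh")
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    return sorted(results, key=lambda r: r.p)


def xci_overlap(regulated_genes_by_celltype: dict[str, set[str]],
                xci_escape_list: list[str]) -> dict:
    """Overlap of sex-specific-OCR-regulated genes with an XCI escape list.

    Pure set arithmetic after case-folding; reports per-cell-type overlap
    counts and the genes shared across all cell types.
    """
    if not xci_escape_list:
        raise ValueError("empty XCI escape list")
    escape = {g.casefold() for g in xci_escape_list}
    per_ct = {ct: escape & {g.casefold() for g in genes}
              for ct, genes in regulated_genes_by_celltype.items()}
    shared = set.intersection(*per_ct.values()) if per_ct else set()
    return {
        "n_escape_genes": len(escape),
        "overlap_counts": {ct: len(v) for ct, v in per_ct.items()},
        "overlap_genes": per_ct,
        "n_shared": len(shared),
        "shared_genes": shared,
    }


def concordance(tstats_a: pd.Series, tstats_b: pd.Series) -> ConcordanceResult:
    """Spearman concordance of two per-feature statistics matched on id."""
    joined = pd.concat([tstats_a.rename("a"), tstats_b.rename("b")],
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 matched features")
    rho, p = stats.spearmanr(joined["a"], joined["b"])
    return ConcordanceResult(n_features=len(joined), spearman_rho=float(rho), p=float(p))


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term_id": r.term_id, "a": r.table.a, "b": r.table.b, "c": r.table.c,
        "d": r.table.d, "odds_ratio": r.odds_ratio, "p": r.p, "fdr": r.fdr,
    } for r in results])
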