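"""Activity-by-contact scoring, sex comparison and landscape statistics."""

import numpy as np
import pandas as pd
import pytest

from sexregulome.abc_model import (ContactMap, GenePromoter, abc_all_genes,
                                   abc_scores, annotate_nearest_gene,
                                   compare_sex_links, element_activity,
                                   landscape_stats, state_overlap_ratio)
from sexregulome.synth import SimConfig, simulate_abc_inputs


def _elements(activities, spacing=100_000, chrom="chr1"):
    starts = np.arange(len(activities)) * spacing
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + 500,
                         "element_id": [f"e{i}" for i in range(len(activities))],
                         "activity": activities})


def _uniform_contacts(n_bins=400, chrom="chr1"):
    rows = [(chrom, i, j, 1.0) for i in range(n_bins) for j in range(i, n_bins)]
    return ContactMap.from_table(
        pd.DataFrame(rows, columns=["chrom", "bin_i", "bin_j", "freq"]),
        resolution=10_000, pseudocount=0.0)


class TestActivity:
    def test_geometric_mean_closed_forms(self):
        assert element_activity(4.0, 9.0) == pytest.approx(6.0)
        assert element_activity(7.0, 7.0) == pytest.approx(7.0)
        assert element_activity(0.0, 5.0) == 0.0

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            element_activity(-1.0, 4.0)


class TestAbcScores:
    def test_single_candidate_scores_one(self):
        gene = GenePromoter("g", "chr1", 50_000)
        links = abc_scores(_elements([3.0]), gene, _uniform_contacts())
        assert len(links) == 1 and links["abc_score"].iloc[0] == pytest.approx(1.0)

    def test_equal_products_split_evenly(self):
        gene = GenePromoter("g", "chr1", 50_000)
        links = abc_scores(_elements([2.0, 2.0]), gene, _uniform_contacts())
        np.testing.assert_allclose(links["abc_score"], [0.5, 0.5])

    def test_three_candidate_arithmetic(self):
        # A=(2,1,1), uniform C -> scores (1/2, 1/4, 1/4); with planted C
        # ratios (0.5, 0.25, 0.25) -> A*C = (1, 0.25, 0.25) -> (2/3, 1/6, 1/6)
        gene = GenePromoter("g", "chr1", 250)
        rows = [("chr1", 0, b, f) for b, f in [(0, 0.5), (10, 0.25), (20, 0.25)]]
        cmap = ContactMap.from_table(
            pd.DataFrame(rows, columns=["chrom", "bin_i", "bin_j", "freq"]),
            resolution=10_000, pseudocount=0.0)
        links = abc_scores(_elements([2.0, 1.0, 1.0]), gene, cmap)
        np.testing.assert_allclose(sorted(links["abc_score"], reverse=True),
                                   [2 / 3, 1 / 6, 1 / 6], atol=1e-12)

    def test_ubiquitous_gene_yields_no_links(self):
        gene = GenePromoter("g", "chr1", 50_000, ubiquitous=True)
        assert abc_scores(_elements([10.0, 10.0]), gene, _uniform_contacts()).empty

    def test_window_excludes_distant_elements(self):
        gene = GenePromoter("g", "chr1", 0)
        elements = _elements([1.0, 1.0], spacing=6_000_000)
        links = abc_scores(elements, gene, _uniform_contacts(1000))
        assert links["element_id"].tolist() == ["e0"]

    def test_prethreshold_normalization_sums_to_one(self, rng):
        gene = GenePromoter("g", "chr1", 500_000)
        elements = _elements(rng.random(30) * 5)
        links = abc_scores(elements, gene, _uniform_contacts(), threshold=0.0)
        assert links["abc_score"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_raising_threshold_never_adds_links(self, rng):
        gene = GenePromoter("g", "chr1", 500_000)
        elements = _elements(rng.random(30) * 5)
        cmap = _uniform_contacts()
        low = abc_scores(elements, gene, cmap, threshold=0.01)
        high = abc_scores(elements, gene, cmap, threshold=0.05)
        assert set(high["element_id"]) <= set(low["element_id"])

    def test_matches_brute_force_double_loop(self, rng):
        # 50 elements x 5 genes vs a hand-written O(E*G) reference
        elements = _elements(rng.random(50) * 4, spacing=80_000)
        genes = [GenePromoter(f"g{j}", "chr1", int(tss))
                 for j, tss in enumerate(rng.integers(0, 4_000_000, size=5))]
        cmap = ContactMap.from_table(pd.DataFrame(
            [("chr1", i, j, float(1.0 / (abs(i - j) + 1)))
             for i in range(420) for j in range(i, 420)],
            columns=["chrom", "bin_i", "bin_j", "freq"]), resolution=10_000)
        links = abc_all_genes(elements, genes, cmap, threshold=0.0)
        mids = (elements["start"] + elements["end"]) // 2
        for g in genes:
            prods = {}
            for i in range(len(elements)):
                if abs(mids[i] - g.tss) > 5e6:
                    continue
                bi, bt = mids[i] // 10_000, g.tss // 10_000
                c = 1.0 / (abs(bi - bt) + 1) + 0.01
                prods[elements["element_id"][i]] = elements["activity"][i] * c
            total = sum(prods.values())
            sub = links[links["gene_id"] == g.gene_id].set_index("element_id")
            for eid, prod in prods.items():
                assert sub.loc[eid, "abc_score"] == pytest.approx(prod / total, abs=1e-12)

    def test_planted_links_outrank_decoys(self, abc_inputs):
        cmap = ContactMap.from_table(abc_inputs.contacts, abc_inputs.resolution)
        genes = [GenePromoter(r.gene_id, r.chrom, int(r.tss), r.strand,
                              bool(r.ubiquitous))
                 for r in abc_inputs.genes.itertuples(index=False)]
        for sex in ("female", "male"):
            elems = abc_inputs.elements.rename(columns={f"activity_{sex}": "activity"})
            links = abc_all_genes(elems, genes, cmap)
            for eid, gid in abc_inputs.truth_links[sex]:
                sub = links[links["gene_id"] == gid].sort_values(
                    "abc_score", ascending=False)
                assert sub.iloc[0]["element_id"] == eid


class TestCompareSexLinks:
    def _links(self, pairs_scores, chrom="chr1"):
        return pd.DataFrame([
            {"chrom": chrom, "start": 0, "end": 500, "element_id": e,
             "gene_id": g, "abc_score": s} for (e, g), s in pairs_scores.items()])

    def test_identical_sets_fully_shared(self):
        d = {("e1", "g1"): 0.5, ("e2", "g1"): 0.3, ("e3", "g2"): 0.9}
        rep = compare_sex_links(self._links(d), self._links(d))
        assert rep["shared_fraction"] == pytest.approx(1.0)
        assert rep["spearman_union"] == pytest.approx(1.0)

    def test_disjoint_sets_share_nothing(self):
        a = self._links({("e1", "g1"): 0.5})
        b = self._links({("e2", "g2"): 0.5})
        rep = compare_sex_links(a, b)
        assert rep["shared_fraction"] == 0.0 and rep["n_shared"] == 0

    def test_both_empty_rejected(self):
        empty = self._links({})
        with pytest.raises(ValueError):
            compare_sex_links(empty, empty)

    def test_planted_sex_specific_fraction_recovered(self):
        # 40% of genes sex-specific by construction -> sharing known
        ab = simulate_abc_inputs(SimConfig(seed=9, abc_n_genes=11,
                                           abc_sex_specific_fraction=0.4))
        cmap = ContactMap.from_table(ab.contacts, ab.resolution)
        genes = [GenePromoter(r.gene_id, r.chrom, int(r.tss), r.strand,
                              bool(r.ubiquitous))
                 for r in ab.genes.itertuples(index=False)]
        links = {s: abc_all_genes(ab.elements.rename(
            columns={f"activity_{s}": "activity"}), genes, cmap)
            for s in ("female", "male")}
        rep = compare_sex_links(links["female"], links["male"])
        truth_female_only = ab.truth_links["female"] - ab.truth_links["male"]
        truth_male_only = ab.truth_links["male"] - ab.truth_links["female"]
        assert truth_female_only <= rep["female_specific"]
        assert truth_male_only <= rep["male_specific"]


class TestLandscape:
    def test_nearest_gene_fraction_one_when_only_nearest_linked(self):
        genes = [GenePromoter("g1", "chr1", 1_000), GenePromoter("g2", "chr1", 900_000)]
        links = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 500, "element_id": "e1",
             "gene_id": "g1", "abc_score": 1.0, "distance_to_tss": -750}])
        out = annotate_nearest_gene(links, genes)
        assert landscape_stats(out)["frac_nearest_gene"] == 1.0

    def test_multigene_element_distribution(self):
        links = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 500, "element_id": "e1",
             "gene_id": g, "abc_score": 0.5, "distance_to_tss": d,
             "is_nearest_gene": g == "g1"} for g, d in [("g1", 10), ("g2", 200_000)]])
        stats = landscape_stats(links)
        assert stats["genes_per_element"] == {2: 1}
        assert stats["frac_within_100kb"] == 0.5

    def test_hand_counted_toy(self):
        rows = []
        for i in range(10):
            rows.append({"chrom": "chr1", "start": i * 1000, "end": i * 1000 + 500,
                         "element_id": f"e{i}", "gene_id": f"g{i % 3}",
                         "abc_score": 0.1,
                         "distance_to_tss": 50_000 if i < 7 else 400_000,
                         "is_nearest_gene": i < 4})
        stats = landscape_stats(pd.DataFrame(rows))
        assert stats["frac_within_100kb"] == pytest.approx(0.7)
        assert stats["frac_nearest_gene"] == pytest.approx(0.4)


class TestStateOverlap:
    def _links(self, chrom, n):
        return pd.DataFrame([
            {"chrom": chrom, "start": i * 1000, "end": i * 1000 + 500,
             "element_id": f"{chrom}_e{i}", "gene_id": "g", "abc_score": 0.5}
            for i in range(n)])

    def test_identical_composition_gives_zero_ratios(self):
        states = pd.DataFrame({"chrom": ["chr1", "chrX"], "start": [0, 0],
                               "end": [100_000, 100_000], "name": ["EnhA", "EnhA"]})
        ratios = state_overlap_ratio(self._links("chrX", 5), self._links("chr1", 5),
                                     states)
        assert ratios["EnhA"] == pytest.approx(0.0)

    def test_repressed_state_enriched_on_x(self):
        states = pd.DataFrame({"chrom": ["chrX", "chr1"], "start": [0, 0],
                               "end": [100_000, 100_000],
                               "name": ["ReprPC", "EnhA"]})
        ratios = state_overlap_ratio(self._links("chrX", 5), self._links("chr1", 5),
                                     states)
        assert ratios["ReprPC"] > 0 and ratios["EnhA"] < 0

    def test_known_overlap_counting(self):
        # X: 3 EnhA + 1 TssA; autosome: 2 EnhA + 2 TssA
        states = pd.DataFrame({
            "chrom": ["chrX", "chrX", "chr1", "chr1"],
            "start": [0, 3000, 0, 2000],
            "end": [3000, 10_000, 2000, 10_000],
            "name": ["EnhA", "TssA", "EnhA", "TssA"]})
        ratios = state_overlap_ratio(self._links("chrX", 4), self._links("chr1", 4),
                                     states)
        assert ratios["EnhA"] == pytest.approx(np.log2((3 / 4) / (2 / 4)))
        assert ratios["TssA"] == pytest.approx(np.log2((1 / 4) / (2 / 4)))

    def test_empty_partition_rejected(self):
        states = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                               "name": ["EnhA"]})
        with pytest.raises(ValueError):
            state_overlap_ratio(self._links("chrX", 0), self._links("chr1", 3), states)
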