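"""CRD calling, quantification and stage-wise sex-specificity testing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sexregulome.crd import (CRD, call_crds, crd_directionality, quantify_crd,
                             residualize_covariates, simes_p, stagewise_test)
from sexregulome.diffacc import (DesignSpec, estimate_precision_weights,
                                 fit_per_feature_model, normalize_log_cpm)
from sexregulome.synth import SimConfig, simulate_study


def _bed(n, chrom="chr1", gap=5_000, width=500):
    starts = np.arange(n) * (gap + width) + 1_000
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width,
                         "name": [f"o{i}" for i in range(n)]})


class TestResidualize:
    def test_no_covariates_equals_centering(self, rng):
        Y = pd.DataFrame(rng.standard_normal((5, 12)))
        st = pd.DataFrame({"individual": [f"i{j}" for j in range(12)]})
        out = residualize_covariates(Y, st, ())
        np.testing.assert_allclose(out.to_numpy(),
                                   Y.to_numpy() - Y.to_numpy().mean(1, keepdims=True),
                                   atol=1e-10)

    def test_perfect_covariate_yields_zero_residuals(self, rng):
        x = rng.standard_normal(15)
        Y = pd.DataFrame(np.tile(3 * x + 1, (4, 1)))
        st = pd.DataFrame({"cov": x})
        out = residualize_covariates(
            Y, st, ("cov",),
            design=DesignSpec(fixed_covariates=("cov",), contrast="cov", categorical=()))
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-8)

    def test_region_offset_removed(self, planted_study, planted_logcpm):
        design = DesignSpec(
            fixed_covariates=("sex", "diagnosis", "region", "frip", "gc_content"),
            contrast="sex")
        corrected = residualize_covariates(
            planted_logcpm, planted_study.sample_table,
            ("diagnosis", "region", "frip", "gc_content"), design=design)
        region = planted_study.sample_table["region"].to_numpy()
        pre = planted_logcpm.to_numpy()
        post = corrected.to_numpy()
        gap_pre = np.abs(pre[:, region == "ACC"].mean(1) - pre[:, region == "DLPFC"].mean(1))
        gap_post = np.abs(post[:, region == "ACC"].mean(1) - post[:, region == "DLPFC"].mean(1))
        assert gap_post.mean() < 0.05 * gap_pre.mean()

    def test_sex_cannot_be_a_nuisance_covariate(self, rng):
        Y = pd.DataFrame(rng.standard_normal((3, 6)))
        st = pd.DataFrame({"sex": ["male", "female"] * 3})
        with pytest.raises(ValueError, match="sex"):
            residualize_covariates(Y, st, ("sex",))


def _brute_force_segmentation(vals, bed, max_gap, min_corr, min_members):
    """Exhaustive enumeration of all contiguous segmentations (independent oracle)."""
    n = vals.shape[0]
    r = np.abs(np.nan_to_num(np.corrcoef(vals)))
    mids = ((bed["start"] + bed["end"]) // 2).to_numpy()

    def admissible(i, j):
        m = j - i + 1
        if m < min_members:
            return None
        if (np.diff(mids[i:j + 1]) > max_gap).any():
            return None
        pairs = [(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
        mean_r = np.mean([r[a, b] for a, b in pairs])
        return mean_r if mean_r >= min_corr else None

    best_val, best_segs = (0, 0, 0.0), []

    def recurse(pos, segs, covered, score):
        nonlocal best_val, best_segs
        if pos == n:
            val = (covered, -len(segs), score)
            if val > best_val:
                best_val, best_segs = val, list(segs)
            return
        recurse(pos + 1, segs, covered, score)          # skip this OCR
        for j in range(pos + min_members - 1, n):
            sc = admissible(pos, j)
            if sc is not None:
                segs.append((pos, j))
                recurse(j + 1, segs, covered + (j - pos + 1), score + sc)
                segs.pop()

    recurse(0, [], 0, 0.0)
    return best_segs


class TestCallCrds:
    def test_two_perfectly_correlated_neighbours_form_one_crd(self, rng):
        x = rng.standard_normal(30)
        vals = pd.DataFrame(np.vstack([x, x]), index=["o0", "o1"])
        crds = call_crds(vals, _bed(2), min_mean_abs_corr=0.5)
        assert len(crds) == 1 and crds[0].member_ocr_ids == ["o0", "o1"]

    def test_independent_ocrs_rarely_produce_crds(self):
        hits = 0
        for seed in range(20):
            vals = pd.DataFrame(np.random.default_rng(seed).standard_normal((8, 200)),
                                index=[f"o{i}" for i in range(8)])
            hits += bool(call_crds(vals, _bed(8), min_mean_abs_corr=0.3))
        assert hits <= 1  # null calling in >= 95% of runs

    def test_planted_blocks_recovered_with_high_ari(self, planted_study, planted_logcpm):
        from sklearn.metrics import adjusted_rand_score
        design = DesignSpec(
            fixed_covariates=("sex", "diagnosis", "region", "frip", "gc_content"),
            contrast="sex")
        corrected = residualize_covariates(
            planted_logcpm, planted_study.sample_table,
            ("diagnosis", "region", "frip", "gc_content"), design=design)
        bed = planted_study.ocr_bed[
            planted_study.ocr_bed["name"].isin(corrected.index)]
        crds = call_crds(corrected, bed)
        truth = planted_study.truth.loc[bed["name"], "crd_block"].to_numpy()
        called = {o: k + 1 for k, c in enumerate(crds) for o in c.member_ocr_ids}
        labels = np.array([called.get(o, 0) for o in bed["name"]])
        mask = truth >= 0
        assert adjusted_rand_score(truth[mask], labels[mask]) >= 0.8

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_segmentation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        # random mixture of correlated pairs/triples and noise
        base = rng.standard_normal((3, 60))
        rows = [base[rng.integers(0, 3)] + 0.7 * rng.standard_normal(60) for _ in range(n)]
        vals = pd.DataFrame(np.vstack(rows), index=[f"o{i}" for i in range(n)])
        bed = _bed(n)
        crds = call_crds(vals, bed, max_pair_distance_bp=250_000,
                         min_mean_abs_corr=0.3, min_members=2)
        oracle = _brute_force_segmentation(vals.to_numpy(), bed, 250_000, 0.3, 2)
        got = [(bed.index[bed["name"] == c.member_ocr_ids[0]][0],
                bed.index[bed["name"] == c.member_ocr_ids[-1]][0]) for c in crds]
        assert got == oracle

    def test_unsorted_bed_rejected(self, rng):
        vals = pd.DataFrame(rng.standard_normal((3, 10)), index=["o0", "o1", "o2"])
        bed = _bed(3).iloc[[1, 0, 2]].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            call_crds(vals, bed)

    def test_partition_invariants(self, planted_study, planted_logcpm):
        bed = planted_study.ocr_bed[
            planted_study.ocr_bed["name"].isin(planted_logcpm.index)]
        crds = call_crds(planted_logcpm, bed)
        seen = [o for c in crds for o in c.member_ocr_ids]
        assert len(seen) == len(set(seen)) <= len(bed)
        order = {o: i for i, o in enumerate(bed["name"])}
        for c in crds:
            idx = [order[o] for o in c.member_ocr_ids]
            assert idx == list(range(idx[0], idx[-1] + 1))  # contiguity


class TestQuantifyAndSimes:
    def test_identical_members_score_equals_row(self, rng):
        x = rng.standard_normal(10)
        vals = pd.DataFrame(np.vstack([x, x]), index=["a", "b"])
        c = CRD("c1", "chr1", 0, 10, ["a", "b"], 1.0)
        np.testing.assert_allclose(quantify_crd(vals, c), x)

    def test_opposite_members_cancel(self, rng):
        x = rng.standard_normal(10)
        vals = pd.DataFrame(np.vstack([x, -x]), index=["a", "b"])
        c = CRD("c1", "chr1", 0, 10, ["a", "b"], 1.0)
        np.testing.assert_allclose(quantify_crd(vals, c), 0.0, atol=1e-12)

    def test_five_member_mean_by_hand(self):
        vals = pd.DataFrame(np.arange(15.0).reshape(5, 3), index=list("abcde"))
        c = CRD("c1", "chr1", 0, 10, list("abcde"), 1.0)
        np.testing.assert_allclose(quantify_crd(vals, c), [6.0, 7.0, 8.0])

    def test_missing_member_rejected(self, rng):
        vals = pd.DataFrame(rng.standard_normal((1, 5)), index=["a"])
        with pytest.raises(ValueError, match="missing"):
            quantify_crd(vals, CRD("c1", "chr1", 0, 10, ["a", "zzz"], 1.0))

    def test_simes_formula(self):
        assert simes_p(np.array([0.001, 0.5])) == pytest.approx(0.002)
        assert simes_p(np.array([1.0, 1.0, 1.0])) == 1.0
        # enumeration oracle: min over ordered p of m*p_(k)/k
        p = np.array([0.03, 0.2, 0.011, 0.8])
        m = len(p)
        oracle = min(m * pk / (k + 1) for k, pk in enumerate(sorted(p)))
        assert simes_p(p) == pytest.approx(oracle)


class TestStagewise:
    def _fit(self, study, logcpm, design):
        X, _, _ = design.build_matrix(study.sample_table)
        w = estimate_precision_weights(logcpm, X)
        return fit_per_feature_model(logcpm, w, study.sample_table, design,
                                     ocr_bed=study.ocr_bed)

    def test_all_member_p_one_screens_nothing(self, rng):
        vals = pd.DataFrame(rng.standard_normal((4, 20)),
                            index=["a", "b", "c", "d"],
                            columns=[f"s{i}" for i in range(20)])
        res = pd.DataFrame({"p": [1.0] * 4, "log2FC": [0.1] * 4},
                           index=["a", "b", "c", "d"])
        crds = [CRD("c1", "chr1", 0, 10, ["a", "b"], 1.0),
                CRD("c2", "chr1", 20, 30, ["c", "d"], 1.0)]
        st = pd.DataFrame({"individual": [f"i{j}" for j in range(20)],
                           "sex": ["male", "female"] * 10})
        design = DesignSpec(fixed_covariates=("sex",), contrast="sex")
        out = stagewise_test(res, crds, vals, st, design)
        assert out.screened_ids == []
        assert all(c.sex_label == "ns" for c in crds)

    def test_planted_sex_blocks_confirmed(self, planted_study, planted_logcpm,
                                          sex_design):
        res = self._fit(planted_study, planted_logcpm, sex_design)
        corrected = residualize_covariates(
            planted_logcpm, planted_study.sample_table,
            ("diagnosis", "region", "frip", "gc_content"),
            design=DesignSpec(
                fixed_covariates=("sex", "diagnosis", "region", "frip", "gc_content"),
                contrast="sex"))
        bed = planted_study.ocr_bed[
            planted_study.ocr_bed["name"].isin(corrected.index)]
        crds = call_crds(corrected, bed)
        out = stagewise_test(res, crds, corrected, planted_study.sample_table,
                             sex_design)
        truth = planted_study.truth
        # recall of truly sex-specific blocks
        effect_blocks = set(planted_study.config.sex_effect_block_ids)
        called_blocks = set()
        for c in crds:
            if c.sex_label != "ns":
                blocks = truth.loc[c.member_ocr_ids, "crd_block"]
                called_blocks.update(b for b in blocks if b in effect_blocks)
        assert len(called_blocks) / len(effect_blocks) >= 0.8
        assert out.alpha_adjusted <= out.alpha
        for cid, dec in out.decisions.items():
            if dec:
                assert cid in out.screened_ids

    def test_null_study_calls_few_sex_specific_crds(self, null_study):
        lc = normalize_log_cpm(null_study.counts)
        design = DesignSpec(fixed_covariates=("sex", "diagnosis"), contrast="sex")
        res = fit_per_feature_model(lc, None, null_study.sample_table, design)
        bed = null_study.ocr_bed
        # force domains from genomic adjacency despite weak correlation
        crds = call_crds(lc, bed, max_pair_distance_bp=10_000_000,
                         min_mean_abs_corr=0.0)
        out = stagewise_test(res, crds, lc, null_study.sample_table, design)
        frac = sum(out.decisions.values()) / max(len(crds), 1)
        assert frac <= 0.05 + 0.02

    def test_empty_crd_set_gives_empty_result(self):
        out = stagewise_test(pd.DataFrame({"p": []}), [], pd.DataFrame(),
                             pd.DataFrame(), None)
        assert out.screened_ids == [] and out.decisions == {}


class TestDirectionality:
    def _crd(self, members):
        return CRD("c1", "chr1", 0, 100, members, 1.0)

    def test_positive_mean_is_male_specific(self):
        res = pd.DataFrame({"log2FC": [1.0, 2.0, 3.0]}, index=list("abc"))
        c = self._crd(list("abc"))
        assert crd_directionality(c, res, significant=True) == "male-specific"
        assert c.mean_log2FC == pytest.approx(2.0)

    def test_negative_members_female_specific(self):
        res = pd.DataFrame({"log2FC": [-1.0, -1.0]}, index=list("ab"))
        assert crd_directionality(self._crd(list("ab")), res,
                                  significant=True) == "female-specific"

    def test_mixed_signs_follow_the_mean(self):
        res = pd.DataFrame({"log2FC": [-2.0, 1.0]}, index=list("ab"))
        c = self._crd(list("ab"))
        assert crd_directionality(c, res, significant=True) == "female-specific"
        assert c.mean_log2FC == pytest.approx(-0.5)

    def test_not_significant_stays_ns(self):
        res = pd.DataFrame({"log2FC": [5.0, 5.0]}, index=list("ab"))
        assert crd_directionality(self._crd(list("ab")), res,
                                  significant=False) == "ns"
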