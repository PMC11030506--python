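"""Cis-regulatory domains: calling, quantification and stage-wise sex testing.

A CRD is a genomically contiguous run of locally correlated OCRs treated as
one regulatory unit. Calling works per chromosome on covariate-corrected
log-CPM: a contiguous segment is admissible when it has at least
``min_members`` OCRs, mean pairwise |Pearson r| at least ``min_mean_abs_corr``,
and no gap between consecutive member midpoints larger than
``max_pair_distance_bp``. Among all contiguous segmentations, the caller
returns the one maximizing, lexicographically, (number of OCRs covered by
admissible segments, fewest segments, total mean |r| of the segments) by
exact dynamic programming; preferring fewer segments keeps a correlated
block as one domain instead of a chain of fragments. The optimum is exact
rather than dependent on a greedy merge order.

Sex specificity is assessed stage-wise: a screening stage combines member
OCR p-values per CRD with Simes' method and applies Benjamini-Hochberg
across CRDs; a confirmation stage refits the repeated-measures model on the
CRD per-sample mean score and Wald-tests the sex coefficient. A CRD is
called sex-specific when it passes screening and its confirmation p-value
is below 0.05; the stage-wise adjusted level (alpha x screened / total) is
reported alongside. Directionality follows the mean member log2FC
(males vs females): positive = male-specific, negative = female-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from sexregulome.diffacc import DesignSpec, fit_per_feature_model


@dataclass
class CRD:
    crd_id: str
    chrom: str
    start: int
    end: int
    member_ocr_ids: list[str]
    mean_abs_corr: float
    per_sample_score: np.ndarray | None = None
    mean_log2FC: float = float("nan")
    stage1_p: float = float("nan")
    stage1_fdr: float = float("nan")
    stage2_p: float = float("nan")
    sex_label: str = "ns"

    @property
    def n_members(self) -> int:
        return len(self.member_ocr_ids)


@dataclass
class StagewiseResult:
    alpha: float
    alpha_adjusted: float
    screened_ids: list[str]
    decisions: dict[str, bool] = field(default_factory=dict)
    confirmed_adjusted: dict[str, bool] = field(default_factory=dict)


def residualize_covariates(logcpm: pd.DataFrame, sample_table: pd.DataFrame,
                           nuisance_covariates: tuple[str, ...],
                           design: DesignSpec | None = None,
                           weights: np.ndarray | None = None) -> pd.DataFrame:
    """Residuals of a per-OCR (weighted) regression on nuisance covariates.

    The nuisance design must exclude the sex term so the sex signal survives
    correction; an intercept is always included, so with no covariates the
    output is the row-centred input.
    """
    if design is None:
        design = DesignSpec(fixed_covariates=tuple(nuisance_covariates) + ("_dummy",),
                            contrast="_dummy")
        sample_table = sample_table.assign(_dummy=np.arange(len(sample_table), dtype=float))
    if "sex" in nuisance_covariates:
        raise ValueError("nuisance covariates must exclude the sex term")
    X, names, _ = design.build_matrix(sample_table)
    keep = [i for i, nm in enumerate(names)
            if nm == "intercept" or any(nm == c or nm.startswith(f"{c}[")
                                        for c in nuisance_covariates)]
    Xn = X[:, keep]
    if np.linalg.matrix_rank(Xn) < Xn.shape[1]:
        raise ValueError("singular nuisance design")
    Y = logcpm.to_numpy(float)
    if weights is None:
        beta, *_ = np.linalg.lstsq(Xn, Y.T, rcond=None)
        resid = Y - (Xn @ beta).T
    else:
        resid = np.empty_like(Y)
        for i in range(Y.shape[0]):
            w = weights[i]
            Xw = Xn * w[:, None]
            beta_i = np.linalg.solve(Xn.T @ Xw, Xw.T @ Y[i])
            resid[i] = Y[i] - Xn @ beta_i
    return pd.DataFrame(resid, index=logcpm.index, columns=logcpm.columns)


def _segment_stats(vals: np.ndarray) -> np.ndarray:
    """Cumulative pairwise |r| sums; S[i, j] = sum of |r| over pairs in i..j."""
    n = vals.shape[0]
    r = np.corrcoef(vals)
    r = np.nan_to_num(r, nan=0.0)
    a = np.abs(r)
    np.fill_diagonal(a, 0.0)
    # recurrence over the upper triangle: S[i, j] = S[i+1, j] + sum(a[i, i+1..j])
    S = np.zeros((n, n))
    for i in range(n - 1, -1, -1):
        row = np.cumsum(a[i, i + 1:]) if i + 1 < n else np.array([])
        for j in range(i + 1, n):
            S[i, j] = S[i + 1, j] + row[j - i - 1]
    return S


def call_crds(corrected: pd.DataFrame, ocr_bed: pd.DataFrame,
              max_pair_distance_bp: int = 250_000,
              min_mean_abs_corr: float = 0.3,
              min_members: int = 2,
              max_members: int = 50) -> list[CRD]:
    """Exact segmentation of each chromosome into non-overlapping CRDs.

    ``ocr_bed`` must be sorted by (chrom, start); every OCR ends up in at
    most one CRD.
    """
    bed = ocr_bed.reset_index(drop=True)
    key = list(zip(bed["chrom"], bed["start"]))
    if key != sorted(key):
        raise ValueError("OCR BED must be sorted by (chrom, start)")
    missing = [nm for nm in bed["name"] if nm not in corrected.index]
    if missing:
        raise ValueError(f"OCRs missing from the corrected matrix: {missing[:5]}")

    crds: list[CRD] = []
    for chrom, sub in bed.groupby("chrom", sort=False):
        n = len(sub)
        if n < 2:
            continue
        ids = sub["name"].tolist()
        vals = corrected.loc[ids].to_numpy(float)
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        S = _segment_stats(vals)
        gap_ok = np.diff(mids) <= max_pair_distance_bp

        # admissible segment (i..j): length, distance and correlation criteria
        def seg_score(i: int, j: int) -> float | None:
            m = j - i + 1
            if m < min_members or m > max_members:
                return None
            if not gap_ok[i:j].all():
                return None
            mean_r = S[i, j] / (m * (m - 1) / 2)
            return mean_r if mean_r >= min_mean_abs_corr else None

        # DP over prefixes maximizing (covered OCRs, -n segments, total mean |r|)
        best: list[tuple[int, int, float]] = [(0, 0, 0.0)] * (n + 1)
        choice: list[tuple[int, float] | None] = [None] * (n + 1)
        for j in range(1, n + 1):
            best[j], choice[j] = best[j - 1], None
            lo = max(0, j - max_members)
            for i in range(lo, j - min_members + 1):
                sc = seg_score(i, j - 1)
                if sc is None:
                    continue
                cand = (best[i][0] + (j - i), best[i][1] - 1, best[i][2] + sc)
                if cand > best[j]:
                    best[j], choice[j] = cand, (i, sc)
        # backtrack
        j = n
        segs: list[tuple[int, int, float]] = []
        while j > 0:
            if choice[j] is None:
                j -= 1
            else:
                i, sc = choice[j]
                segs.append((i, j - 1, sc))
                j = i
        for i, jj, sc in reversed(segs):
            members = ids[i:jj + 1]
            crds.append(CRD(
                crd_id=f"crd_{len(crds):04d}",
                chrom=chrom,
                start=int(sub["start"].iloc[i]),
                end=int(sub["end"].iloc[jj]),
                member_ocr_ids=members,
                mean_abs_corr=float(sc),
                per_sample_score=vals[i:jj + 1].mean(axis=0),
            ))
    return crds


def quantify_crd(corrected: pd.DataFrame, crd: CRD) -> np.ndarray:
    """Per-sample CRD score: unweighted mean of member rows."""
    missing = [m for m in crd.member_ocr_ids if m not in corrected.index]
    if missing:
        raise ValueError(f"CRD {crd.crd_id} members missing from matrix: {missing}")
    return corrected.loc[crd.member_ocr_ids].to_numpy(float).mean(axis=0)


def simes_p(pvals: np.ndarray) -> float:
    """Simes combination: min over ordered p of m * p_(k) / k."""
    p = np.sort(np.asarray(pvals, float))
    m = p.size
    return float(min(1.0, (m * p / np.arange(1, m + 1)).min()))


def stagewise_test(ocr_results: pd.DataFrame, crds: list[CRD],
                   corrected: pd.DataFrame, sample_table: pd.DataFrame,
                   design: DesignSpec, alpha: float = 0.05) -> StagewiseResult:
    """Two-stage screening / confirmation test for sex-specific CRDs.

    Mutates the CRDs in place (stage1_p, stage1_fdr, stage2_p, mean_log2FC,
    sex_label) and returns the stage-wise bookkeeping.
    """
    if not crds:
        return StagewiseResult(alpha=alpha, alpha_adjusted=0.0, screened_ids=[])
    stage1 = np.array([simes_p(ocr_results.loc[c.member_ocr_ids, "p"].to_numpy())
                       for c in crds])
    _, fdr1, _, _ = multipletests(stage1, method="fdr_bh")
    screened = fdr1 < alpha

    scores = pd.DataFrame(
        np.vstack([quantify_crd(corrected, c) for c in crds]),
        index=[c.crd_id for c in crds], columns=corrected.columns)
    stage2_res = fit_per_feature_model(scores, None, sample_table, design)
    stage2 = stage2_res["p"].to_numpy()

    n_scr = int(screened.sum())
    alpha_adj = alpha * n_scr / len(crds)
    result = StagewiseResult(alpha=alpha, alpha_adjusted=alpha_adj,
                             screened_ids=[c.crd_id for c, s in zip(crds, screened) if s])
    for c, p1, f1, p2, scr in zip(crds, stage1, fdr1, stage2, screened):
        c.stage1_p, c.stage1_fdr, c.stage2_p = float(p1), float(f1), float(p2)
        significant = bool(scr and p2 < alpha)
        result.decisions[c.crd_id] = significant
        result.confirmed_adjusted[c.crd_id] = bool(scr and p2 < alpha_adj)
        crd_directionality(c, ocr_results, significant=significant)
    return result


def crd_directionality(crd: CRD, ocr_results: pd.DataFrame,
                       significant: bool | None = None) -> str:
    """Assign male-/female-specific by the sign of the mean member log2FC."""
    lfc = ocr_results.loc[crd.member_ocr_ids, "log2FC"].to_numpy(float)
    crd.mean_log2FC = float(lfc.mean())
    if significant is None:
        significant = crd.sex_label != "ns"
    if not significant or crd.mean_log2FC == 0.0:
        crd.sex_label = "ns"
    elif crd.mean_log2FC > 0:
        crd.sex_label = "male-specific"
    else:
        crd.sex_label = "female-specific"
    return crd.sex_label


def crds_to_table(crds: list[CRD]) -> pd.DataFrame:
    return pd.DataFrame([{
        "crd_id": c.crd_id, "chrom": c.chrom, "start": c.start, "end": c.end,
        "n_members": c.n_members, "members": ";".join(c.member_ocr_ids),
        "mean_abs_corr": c.mean_abs_corr, "mean_log2FC": c.mean_log2FC,
        "stage1_p": c.stage1_p, "stage1_fdr": c.stage1_fdr,
        "stage2_p": c.stage2_p, "sex_label": c.sex_label,
    } for c in crds])
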