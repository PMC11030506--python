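"""Trans-regulatory domains: clustering sex-specific CRDs across samples.

CRD per-sample scores are correlated across samples; hierarchical clustering
(average linkage) on the dissimilarity 1 - r groups CRDs into TRDs. The
number of clusters k is chosen over a range (default 2..20) by the
Baker-Hubert Gamma index

    Gamma = (s+ - s-) / (s+ + s-)

where, over all pairs (w, b) of a within-cluster dissimilarity w and a
between-cluster dissimilarity b, s+ counts w < b (concordant) and s- counts
w > b (discordant); exact ties count in neither. Gamma is 1 when every
within-cluster distance is smaller than every between-cluster distance.
The signed dissimilarity 1 - r (not 1 - |r|) is used so anti-correlated
CRDs land in different TRDs.

Each TRD is summarized against per-OCR sex and disease effects: counts of
female-/male-specific member CRDs and OCRs, and the Spearman correlation
between member OCR sex log2FC and SCZ log2FC (computed both over all member
OCRs and over sex-specific members only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from sexregulome.crd import CRD


@dataclass
class GammaScore:
    k: int
    s_plus: int
    s_minus: int

    @property
    def gamma(self) -> float:
        tot = self.s_plus + self.s_minus
        return float("nan") if tot == 0 else (self.s_plus - self.s_minus) / tot


@dataclass
class TRDAssignment:
    labels: dict[str, int]            # CRD id -> TRD id (1..k)
    k_selected: int
    gamma_trace: list[GammaScore]
    linkage_record: np.ndarray


@dataclass
class TRDSummary:
    trd_id: int
    n_crds_female: int
    n_crds_male: int
    n_sex_ocrs_female: int
    n_sex_ocrs_male: int
    spearman_rho_all: float
    spearman_p_all: float
    spearman_rho_sex: float
    spearman_p_sex: float
    direction_note: float             # fraction of sex-specific OCRs with SCZ log2FC > 0


def crd_correlation_matrix(crd_scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-sample CRD scores (CRDs as rows)."""
    if crd_scores.shape[0] < 2 or crd_scores.shape[1] < 3:
        raise ValueError("need >= 2 CRDs and >= 3 samples")
    vals = crd_scores.to_numpy(float)
    sd = vals.std(axis=1)
    flat = [crd_scores.index[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise ValueError(f"zero-variance CRD scores: {flat}")
    corr = np.corrcoef(vals)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=crd_scores.index, columns=crd_scores.index)


def gamma_index(dissimilarity: np.ndarray, labels: np.ndarray) -> GammaScore:
    """Baker-Hubert Gamma for one flat clustering.

    ``dissimilarity`` is a square symmetric matrix; ``labels`` an integer
    vector. Requires at least one within-cluster and one between-cluster
    pair. s+ and s- are computed exactly (sorted counting, no sampling).
    """
    D = np.asarray(dissimilarity, float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if D.shape != (n, n) or labels.shape != (n,):
        raise ValueError("dissimilarity must be square and labels match its size")
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    within = D[iu][same]
    between = D[iu][~same]
    if within.size == 0 or between.size == 0:
        raise ValueError("gamma needs both within- and between-cluster pairs")
    b_sorted = np.sort(between)
    # for each within-distance w: #(b > w) concordant, #(b < w) discordant
    s_plus = int((between.size - np.searchsorted(b_sorted, within, side="right")).sum())
    s_minus = int(np.searchsorted(b_sorted, within, side="left").sum())
    return GammaScore(k=int(len(np.unique(labels))), s_plus=s_plus, s_minus=s_minus)


def select_k(corr: pd.DataFrame, k_min: int = 2, k_max: int = 20,
             method: str = "average") -> TRDAssignment:
    """Cut an average-linkage tree at each k and keep the Gamma-optimal cut.

    Ties in Gamma resolve to the smallest k. With fewer than k_max + 1 CRDs
    the range is truncated (with a warning); fewer than 3 CRDs is an error.
    """
    n = corr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 CRDs to cluster")
    if n < k_max + 1:
        warnings.warn(f"only {n} CRDs; truncating k range to 2..{n - 1}")
        k_max = n - 1
    D = 1.0 - corr.to_numpy(float)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method=method)
    cuts = cut_tree(Z, n_clusters=list(range(k_min, k_max + 1)))
    trace: list[GammaScore] = []
    for col, k in enumerate(range(k_min, k_max + 1)):
        trace.append(gamma_index(D, cuts[:, col]))
    gammas = np.array([g.gamma for g in trace])
    best = int(np.nanargmax(gammas))      # np.nanargmax returns the first maximum
    k_sel = k_min + best
    labels = {crd_id: int(lab) + 1 for crd_id, lab in zip(corr.index, cuts[:, best])}
    return TRDAssignment(labels=labels, k_selected=k_sel, gamma_trace=trace,
                         linkage_record=Z)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 3:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def assign_and_summarize(assignment: TRDAssignment, crds: list[CRD],
                         ocr_results_sex: pd.DataFrame,
                         ocr_results_scz: pd.DataFrame) -> list[TRDSummary]:
    """Per-TRD composition counts and Spearman of sex vs SCZ effect sizes.

    Both contrasts must cover the same OCR universe. TRDs without any
    sex-specific member OCR get NaN correlations (they are excluded from
    correlation reporting, not an error).
    """
    by_id = {c.crd_id: c for c in crds}
    out: list[TRDSummary] = []
    for trd_id in sorted(set(assignment.labels.values())):
        members = [by_id[cid] for cid, t in assignment.labels.items() if t == trd_id]
        ocrs = [o for c in members for o in c.member_ocr_ids]
        sex = ocr_results_sex.loc[ocrs]
        scz = ocr_results_scz.loc[ocrs]
        sex_mask = (sex["sex_label"] != "ns").to_numpy()
        rho_all, p_all = _spearman(sex["log2FC"].to_numpy(), scz["log2FC"].to_numpy())
        rho_s, p_s = _spearman(sex["log2FC"].to_numpy()[sex_mask],
                               scz["log2FC"].to_numpy()[sex_mask])
        n_sex = int(sex_mask.sum())
        frac_up = (float((scz["log2FC"].to_numpy()[sex_mask] > 0).mean())
                   if n_sex else float("nan"))
        out.append(TRDSummary(
            trd_id=trd_id,
            n_crds_female=sum(c.sex_label == "female-specific" for c in members),
            n_crds_male=sum(c.sex_label == "male-specific" for c in members),
            n_sex_ocrs_female=int((sex["sex_label"] == "female-specific").sum()),
            n_sex_ocrs_male=int((sex["sex_label"] == "male-specific").sum()),
            spearman_rho_all=rho_all, spearman_p_all=p_all,
            spearman_rho_sex=rho_s, spearman_p_sex=p_s,
            direction_note=frac_up,
        ))
    return out


def gamma_trace_table(assignment: TRDAssignment, k_min: int = 2) -> pd.DataFrame:
    return pd.DataFrame([{
        "k": g.k, "s_plus": g.s_plus, "s_minus": g.s_minus, "gamma": g.gamma,
    } for g in assignment.gamma_trace])
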