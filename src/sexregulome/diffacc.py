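"""Per-OCR differential chromatin accessibility between sexes (or diagnoses).

The workflow mirrors precision-weighted repeated-measures modelling of bulk
count data: low-accessibility filtering on CPM, log-CPM transformation,
voom-style precision weights from a lowess mean-variance trend, then a
weighted linear mixed model with one random intercept per individual fitted
by profiled REML. Because the random structure is a single grouped
intercept with diagonal observation weights, the covariance inverse has a
closed Sherman-Morrison form per individual and the REML criterion can be
profiled down to a one-dimensional search over the variance ratio
``lambda = var(individual) / var(residual)``; that search is a coarse
log-grid refined by golden-section, vectorised across all OCRs at once.

Degrees of freedom for the Wald t-test are conservative:
``df = n_individuals - n_fixed_coefficients`` floored at 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from sexregulome.fileio import chrom_class

LOG2E6 = np.log2(1e6)


@dataclass
class DesignSpec:
    """Fixed-effect design plus the tested contrast and the grouping column.

    ``levels`` pins the level order of categorical covariates (first level =
    reference), so e.g. ``{"sex": ("female", "male")}`` makes the sex
    coefficient a male-vs-female log2 fold change.
    """

    fixed_covariates: tuple[str, ...]
    contrast: str
    grouping: str = "individual"
    categorical: tuple[str, ...] = ("sex", "diagnosis", "region", "cell_type")
    levels: dict[str, tuple[str, ...]] = field(default_factory=lambda: {
        "sex": ("female", "male"),
        "diagnosis": ("control", "SCZ"),
    })

    def __post_init__(self) -> None:
        if self.contrast not in self.fixed_covariates:
            raise ValueError(f"contrast {self.contrast!r} not among fixed covariates")

    def build_matrix(self, sample_table: pd.DataFrame) -> tuple[np.ndarray, list[str], int]:
        """Return (X, column names, index of the contrast coefficient)."""
        cols: list[np.ndarray] = [np.ones(len(sample_table))]
        names = ["intercept"]
        for cov in self.fixed_covariates:
            if cov not in sample_table.columns:
                raise ValueError(f"covariate {cov!r} missing from sample table")
            vals = sample_table[cov]
            if cov in self.categorical or vals.dtype == object:
                levels = list(self.levels.get(cov) or sorted(pd.unique(vals.astype(str))))
                observed = set(vals.astype(str))
                unknown = observed - set(levels)
                if unknown:
                    raise ValueError(f"covariate {cov!r} has unexpected levels {sorted(unknown)}")
                for lev in levels[1:]:
                    cols.append((vals.astype(str) == lev).to_numpy(float))
                    names.append(f"{cov}[{lev}]")
            else:
                cols.append(vals.to_numpy(float))
                names.append(cov)
        X = np.column_stack(cols)
        contrast_cols = [i for i, nm in enumerate(names)
                         if nm == self.contrast or nm.startswith(f"{self.contrast}[")]
        if len(contrast_cols) != 1:
            raise ValueError(
                f"contrast {self.contrast!r} must map to exactly one coefficient, "
                f"got {[names[i] for i in contrast_cols]}")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            aliased = _aliased_columns(X, names)
            raise ValueError(f"singular design matrix; aliased columns: {aliased}")
        return X, names, contrast_cols[0]


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    small = np.abs(np.diag(r)) < 1e-8 * max(np.abs(np.diag(r)).max(), 1.0)
    return [names[i] for i in np.flatnonzero(small)]


@dataclass
class WeightMatrix:
    """Per-observation precision weights plus the fitted mean-variance trend."""

    weights: np.ndarray                      # OCR x sample, positive
    trend: list[tuple[float, float]]         # (mean log-count, sqrt residual sd) knots

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and positive")


def filter_low_accessibility(counts: pd.DataFrame, min_cpm: float = 1.0,
                             min_sample_fraction: float = 0.5) -> list[str]:
    """OCR ids retained iff CPM >= min_cpm in >= min_sample_fraction of samples."""
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    lib = vals.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    cpm = vals / lib[None, :] * 1e6
    keep = (cpm >= min_cpm).mean(axis=1) >= min_sample_fraction
    retained = [ocr for ocr, k in zip(counts.index, keep) if k]
    if not retained:
        raise ValueError("filtering removed every OCR; lower min_cpm or the sample fraction")
    return retained


def normalize_log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2((count + 0.5) / (library size + 1) * 1e6)."""
    vals = counts.to_numpy(float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    lib = vals.sum(axis=0)
    logcpm = np.log2(vals + 0.5) - np.log2(lib + 1.0)[None, :] + LOG2E6
    return pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)


def estimate_precision_weights(logcpm: pd.DataFrame, X: np.ndarray,
                               lowess_frac: float = 0.5) -> WeightMatrix:
    """Voom-style inverse-variance weights from a lowess mean-variance trend.

    An OLS fit per OCR on the fixed covariates yields residual standard
    deviations; lowess of sqrt(residual sd) against mean log-count gives the
    trend, and each observation's weight is the predicted sqrt-sd at its
    fitted log-count raised to the inverse fourth power.
    """
    Y = logcpm.to_numpy(float)
    g, n = Y.shape
    if g < 10:
        raise ValueError("need >= 10 OCRs to fit a mean-variance trend")
    p = X.shape[1]
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T                             # g x n
    resid = Y - fitted
    sd = np.sqrt((resid ** 2).sum(axis=1) / max(n - p, 1))
    sqrt_sd = np.sqrt(np.maximum(sd, 1e-8))
    mean_log = Y.mean(axis=1)
    smoothed = lowess(sqrt_sd, mean_log, frac=lowess_frac, return_sorted=True)
    xs, ys = smoothed[:, 0], np.maximum(smoothed[:, 1], 1e-4)
    pred = np.interp(fitted, xs, ys)                  # clamped at the trend ends
    weights = pred ** -4.0
    return WeightMatrix(weights=weights, trend=list(zip(xs.tolist(), ys.tolist())))


# ---------------------------------------------------------------------------
# profiled-REML weighted mixed model with one random intercept
# ---------------------------------------------------------------------------

def _group_codes(sample_table: pd.DataFrame, grouping: str) -> tuple[np.ndarray, np.ndarray, int]:
    codes, uniques = pd.factorize(sample_table[grouping])
    order = np.argsort(codes, kind="stable")
    starts = np.flatnonzero(np.r_[1, np.diff(codes[order])])
    return order, starts, len(uniques)


def _reml_pieces(Y, W, X, starts, lam):
    """REML criterion and GLS pieces for per-OCR variance ratios ``lam``.

    Y, W: (g, n) response and weights, samples sorted so groups are
    contiguous with row offsets ``starts``. V = diag(1/w) + lam * ZZ', whose
    inverse is Sherman-Morrison per group. Returns the (g,) REML
    log-likelihood (additive constants dropped), per-OCR beta (g, p),
    normal-equation matrices A = X'V^-1X (g, p, p) and sigma2 (g,).
    """
    g, n = Y.shape
    p = X.shape[1]
    lam = np.asarray(lam, float).reshape(-1)

    s_g = np.add.reduceat(W, starts, axis=1)                      # g x m
    denom = 1.0 + lam[:, None] * s_g                              # g x m
    n_per = np.diff(np.r_[starts, n])

    def vinv_dot(M):  # M: g x n x k  ->  V^-1 M, rowwise per OCR
        WM = W[:, :, None] * M
        gs = np.add.reduceat(WM, starts, axis=1)                  # g x m x k
        corr = gs * (lam[:, None] / denom)[:, :, None]
        corr_full = np.repeat(corr, n_per, axis=1)                # g x n x k
        return WM - W[:, :, None] * corr_full

    Xb = np.broadcast_to(X, (g, n, p))
    VinvX = vinv_dot(Xb)                                          # g x n x p
    Viy = vinv_dot(Y[:, :, None])[:, :, 0]                        # g x n
    A = np.einsum("np,gnq->gpq", X, VinvX)
    b = np.einsum("np,gn->gp", X, Viy)
    beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    yVy = np.einsum("gn,gn->g", Y, Viy)
    quad = np.maximum(yVy - np.einsum("gp,gp->g", b, beta), 1e-300)
    logdetV = -np.log(W).sum(axis=1) + np.log(denom).sum(axis=1)
    sign, logdetA = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    reml = -0.5 * (logdetV + logdetA + (n - p) * np.log(quad))
    sigma2 = quad / (n - p)
    return reml, beta, A, sigma2


def fit_per_feature_model(logcpm: pd.DataFrame, weights: WeightMatrix | None,
                          sample_table: pd.DataFrame, design: DesignSpec,
                          fdr_threshold: float = 0.05,
                          ocr_bed: pd.DataFrame | None = None,
                          n_grid: int = 17, n_golden: int = 20) -> pd.DataFrame:
    """Fit the weighted mixed model per OCR and test the contrast coefficient.

    Returns a DataFrame with columns (ocr_id, log2FC, se, t, df, p, fdr,
    lambda_ratio[, chrom, chrom_class, sex_label]) indexed by OCR id. The BH
    adjustment runs across all rows of ``logcpm``.
    """
    X, names, ci = design.build_matrix(sample_table)
    order, starts, n_ind = _group_codes(sample_table, design.grouping)
    Y = logcpm.to_numpy(float)[:, order]
    W = (weights.weights if weights is not None else np.ones_like(Y))[:, order]
    Xs = X[order]
    g, n = Y.shape
    p = Xs.shape[1]

    # singleton groups: the intercept variance is not separable from the
    # residual, so the model collapses to weighted least squares (lambda = 0)
    if n_ind == n:
        _, beta, A, sigma2 = _reml_pieces(Y, W, Xs, starts, np.zeros(g))
        return _wald_results(logcpm, design, beta, A, sigma2, np.zeros(g),
                             ci, n_ind, n, p, fdr_threshold, ocr_bed)

    lam_grid = np.r_[0.0, np.logspace(-2.5, 2.0, n_grid - 1)]
    crits = np.empty((len(lam_grid), g))
    for i, lam in enumerate(lam_grid):
        crits[i], *_ = _reml_pieces(Y, W, Xs, starts, np.full(g, lam))
    best = crits.argmax(axis=0)

    # golden-section refinement on log-lambda between the grid neighbours
    eps = 1e-4
    lo = np.log(np.maximum(lam_grid[np.maximum(best - 1, 0)], eps))
    hi = np.log(np.maximum(lam_grid[np.minimum(best + 1, len(lam_grid) - 1)], eps))
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - phi * (hi - lo)
    x2 = lo + phi * (hi - lo)
    f1, *_ = _reml_pieces(Y, W, Xs, starts, np.exp(x1))
    f2, *_ = _reml_pieces(Y, W, Xs, starts, np.exp(x2))
    for _ in range(n_golden):
        take_right = f1 < f2
        lo = np.where(take_right, x1, lo)
        hi = np.where(take_right, hi, x2)
        x1 = hi - phi * (hi - lo)
        x2 = lo + phi * (hi - lo)
        f1, *_ = _reml_pieces(Y, W, Xs, starts, np.exp(x1))
        f2, *_ = _reml_pieces(Y, W, Xs, starts, np.exp(x2))
    lam_ref = np.exp((lo + hi) / 2.0)
    crit_ref, *_ = _reml_pieces(Y, W, Xs, starts, lam_ref)
    crit0, *_ = _reml_pieces(Y, W, Xs, starts, np.zeros(g))
    lam_hat = np.where(crit0 >= crit_ref, 0.0, lam_ref)

    _, beta, A, sigma2 = _reml_pieces(Y, W, Xs, starts, lam_hat)
    return _wald_results(logcpm, design, beta, A, sigma2, lam_hat, ci, n_ind, n, p,
                         fdr_threshold, ocr_bed)


def _wald_results(logcpm, design, beta, A, sigma2, lam_hat, ci, n_ind, n, p,
                  fdr_threshold, ocr_bed) -> pd.DataFrame:
    Ainv = np.linalg.inv(A)
    se = np.sqrt(np.maximum(sigma2 * Ainv[:, ci, ci], 1e-300))
    log2fc = beta[:, ci]
    tstat = log2fc / se
    df = max(n_ind - p, 2)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    res = pd.DataFrame({
        "ocr_id": logcpm.index,
        "contrast": design.contrast,
        "log2FC": log2fc,
        "se": se,
        "t": tstat,
        "df": float(df),
        "p": pvals,
        "fdr": fdr,
        "lambda_ratio": lam_hat,
    }).set_index("ocr_id", drop=False)
    if ocr_bed is not None:
        bed = ocr_bed.set_index("name")
        res["chrom"] = bed["chrom"].reindex(res.index)
        res["chrom_class"] = [chrom_class(c) for c in res["chrom"]]
    return classify_sex_specific(res, fdr_threshold)


def classify_sex_specific(results: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Label each OCR male-specific / female-specific / ns by FDR and sign.

    Positive log2FC under male-vs-female coding means higher accessibility
    in males. A zero log2FC at significant FDR is labelled ns.
    """
    results = results.copy()
    sig = results["fdr"] < fdr_threshold
    label = np.where(sig & (results["log2FC"] > 0), "male-specific",
             np.where(sig & (results["log2FC"] < 0), "female-specific", "ns"))
    results["sex_label"] = label
    return results


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def stratification_from_counts(counts: dict[str, int]) -> dict:
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no significant OCRs to stratify")
    pct = {k: _round_half_away(100.0 * v / total) for k, v in counts.items()}
    return {"counts": dict(counts), "percentages": pct, "total": total}


def stratify_by_chromosome(labeled_results: pd.DataFrame,
                           ocr_bed: pd.DataFrame | None = None) -> dict:
    """Counts and whole-number percentages of significant OCRs per chromosome class.

    Percentages use round-half-away-from-zero and may not sum to exactly 100.
    """
    res = labeled_results
    if "chrom_class" not in res.columns:
        if ocr_bed is None:
            raise ValueError("need chrom_class column or an OCR BED")
        bed = ocr_bed.set_index("name")
        missing = [i for i in res.index if i not in bed.index]
        if missing:
            raise ValueError(f"OCRs missing from BED: {missing[:5]}")
        res = res.assign(chrom_class=[chrom_class(c) for c in bed["chrom"].reindex(res.index)])
    sig = res[res["sex_label"] != "ns"]
    counts = {cls: int((sig["chrom_class"] == cls).sum()) for cls in ("autosome", "X", "Y")}
    return stratification_from_counts(counts)
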