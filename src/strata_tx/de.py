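"""Negative-binomial Wald differential expression for stratified count data.

A desk-scale NB-GLM engine: median-of-ratios size factors, per-gene
method-of-moments dispersion (var = mu + alpha*mu^2) computed within
design cells with optional shrinkage toward the dispersion-mean trend,
and a per-gene log-linear NB fit (IRLS at fixed alpha, via statsmodels)
of ``count ~ Age + RIN + PMI + Diagnosis`` with a library-size offset.
The reported L2FC is the diagnosis coefficient on the log2 scale, with
positive values meaning higher expression in AD; the Wald p-value tests
that coefficient against the standard normal, and multiple testing is
controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .errors import ValidationError
from .io import CountMatrix, SampleMetadata
from .varpart import _design_columns

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # guards -log10(p) downstream
_MIN_ALPHA = 1e-8  # below this the model is fit as Poisson

DE_COLUMNS = ("baseMean", "log2FC", "stat", "pvalue", "padj", "dispersion", "flag")


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over genes nonzero in all samples of
    count_gj / geometric-mean_g(count).
    """
    values = counts.values.astype(float)
    all_nonzero = np.all(values > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValidationError(
            "no gene has nonzero counts in every sample; consider a "
            "pseudo-reference fallback (add a pseudocount or pre-filter samples)"
        )
    log_counts = np.log(values[all_nonzero])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    log_factors = np.median(log_counts - log_geomean, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.sample_ids, name="size_factor")


def _trend_shrink(alpha: np.ndarray, base_mean: np.ndarray, weight: float) -> np.ndarray:
    """Shrink log-dispersions toward a quadratic log-mean trend."""
    ok = (alpha > 0) & (base_mean > 0)
    if ok.sum() < 10:
        return alpha
    x = np.log(base_mean[ok])
    y = np.log(alpha[ok])
    coeffs = np.polyfit(x, y, deg=2)
    shrunk = alpha.copy()
    trend = np.polyval(coeffs, np.log(base_mean[ok]))
    shrunk[ok] = np.exp(weight * trend + (1.0 - weight) * y)
    return shrunk


def estimate_dispersion(
    counts: CountMatrix,
    size_factors: pd.Series,
    design_cells: pd.Series,
    shrink: bool = False,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion alpha >= 0 by method of moments.

    Within each design cell (e.g. diagnosis group) the normalized counts
    give alpha_c = (s^2 - mean)/mean^2; cells are combined with weights
    n_c - 1.  Degenerate genes (zero mean everywhere) get alpha = 0.
    """
    sf = size_factors.reindex(counts.sample_ids).to_numpy()
    q = counts.values / sf[None, :]
    cells = design_cells.reindex(counts.sample_ids)
    alpha_acc = np.zeros(q.shape[0])
    weight_acc = np.zeros(q.shape[0])
    for _, idx in cells.groupby(cells).groups.items():
        cols = [counts.sample_ids.index(s) for s in idx]
        if len(cols) < 2:
            continue
        sub = q[:, cols]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(mean > 0, (var - mean) / mean**2, 0.0)
        a = np.clip(np.nan_to_num(a, nan=0.0), 0.0, None)
        w = len(cols) - 1
        alpha_acc += w * a
        weight_acc += w
    alpha = np.where(weight_acc > 0, alpha_acc / np.maximum(weight_acc, 1), 0.0)
    if shrink:
        alpha = _trend_shrink(alpha, q.mean(axis=1), shrink_weight)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def _fit_gene(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float, max_iter: int
) -> tuple[float, float, bool, np.ndarray | None]:
    """One NB (or Poisson) log-linear IRLS fit; returns (coef, se, converged,
    fitted mean) for the last design column."""
    if alpha > _MIN_ALPHA:
        family = sm.families.NegativeBinomial(alpha=alpha)
    else:
        family = sm.families.Poisson()
    model = sm.GLM(y, X, family=family, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(maxiter=max_iter, tol=1e-8)
        except Exception:
            return np.nan, np.nan, False, None
    converged = bool(getattr(res, "converged", True))
    coef = float(res.params[-1])
    se = float(res.bse[-1])
    if not np.isfinite(coef) or not np.isfinite(se) or se <= 0:
        return np.nan, np.nan, False, None
    return coef, se, converged, np.asarray(res.mu)


def _residual_alpha(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Moment re-estimate of alpha under the fitted design: solve
    E[(y-mu)^2] = mu + alpha*mu^2 on the fit residuals, with a degrees-of-
    freedom correction for the fitted coefficients."""
    n = len(y)
    if n <= n_params:
        return 0.0
    correction = n / (n - n_params)
    num = np.sum((y - mu) ** 2 * correction - mu)
    den = np.sum(mu**2)
    if den <= 0:
        return 0.0
    return float(max(num / den, 0.0))


def wald_test(
    counts: CountMatrix,
    metadata: SampleMetadata,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    shrink_dispersion: bool = False,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Per-gene NB Wald test of the diagnosis effect, adjusting for
    Age, RIN and PMI.

    Returns a DataFrame indexed by gene id with columns baseMean, log2FC,
    stat, pvalue, padj, dispersion, flag.  Genes whose IRLS fit fails are
    flagged with missing p-values and excluded from the BH adjustment.
    """
    meta = metadata.aligned_to(counts)
    design = _design_columns(meta)  # validates PMI imputed, non-constant terms
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.reindex(counts.sample_ids).to_numpy()
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValidationError("size factors must be strictly positive")
    if dispersions is None:
        dispersions = estimate_dispersion(
            counts, size_factors, meta.table["diagnosis"], shrink=shrink_dispersion
        )
    alpha = dispersions.reindex(counts.gene_ids).to_numpy()

    nuisance = design[["Age", "RIN", "PMI"]].to_numpy()
    # standardize nuisance columns for IRLS conditioning; the diagnosis
    # coefficient and its SE are invariant to this rescaling
    centered = nuisance - nuisance.mean(axis=0)
    scales = centered.std(axis=0)
    scales[scales == 0] = 1.0
    X = np.column_stack(
        [np.ones(len(sf)), centered / scales, design["Diagnosis"].to_numpy()]
    )
    offset = np.log(sf)

    values = counts.values
    base_mean = (values / sf[None, :]).mean(axis=1)
    n_genes = values.shape[0]
    l2fc = np.full(n_genes, np.nan)
    stat = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    flags = np.array([""] * n_genes, dtype=object)

    ln2 = np.log(2.0)
    final_alpha = alpha.astype(float).copy()
    n_params = X.shape[1]
    for g in range(n_genes):
        y = values[g]
        if y.sum() == 0:
            flags[g] = "all_zero"
            l2fc[g] = 0.0
            continue
        coef, se, converged, mu = _fit_gene(y, X, offset, float(alpha[g]), max_iter)
        if converged and mu is not None:
            # refine alpha under the full design: the cell-based initial
            # estimate absorbs covariate-driven mean variation
            refined = _residual_alpha(y, mu, n_params)
            if abs(refined - alpha[g]) > 0.01 * max(refined, float(alpha[g]), 1e-6):
                coef, se, converged, mu = _fit_gene(y, X, offset, refined, max_iter)
                if converged:
                    final_alpha[g] = refined
        if not converged or not np.isfinite(coef):
            flags[g] = "no_converge"
            logger.warning("gene %s: IRLS did not converge", counts.gene_ids[g])
            continue
        l2fc[g] = coef / ln2
        stat[g] = coef / se
        pval[g] = max(2.0 * stats.norm.sf(abs(stat[g])), P_FLOOR)

    padj = adjust_bh(pd.Series(pval, index=counts.gene_ids)).to_numpy()
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": l2fc,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "dispersion": final_alpha,
            "flag": flags,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )


def adjust_bh(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; missing values pass through."""
    p = pvalues.to_numpy(dtype=float)
    mask = np.isfinite(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = np.full_like(p, np.nan)
    if mask.sum() > 0:
        adjusted[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return pd.Series(adjusted, index=pvalues.index, name="padj")


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene_id")
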