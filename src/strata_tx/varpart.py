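"""Per-gene variance partitioning across Age, RIN, PMI and Diagnosis.

Each gene's normalized log2 expression is fit with the fixed-effect linear
model ``expr ~ Age + RIN + PMI + Diagnosis`` and each term is attributed
its marginal delta-R^2 (full-model R^2 minus the R^2 of the model without
that term), rescaled so that term fractions sum to the full-model R^2 and
the residual fraction is 1 - R^2.  Genes with zero expression variance are
flagged and given residual 1.  The diagnosis fraction is then used to
filter genes whose variability is unrelated to phenotype before the
differential test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix, SampleMetadata

TERMS = ("Age", "RIN", "PMI", "Diagnosis")
FRACTION_COLUMNS = ("age_frac", "rin_frac", "pmi_frac", "dx_frac", "residual", "flagged")

_ZERO_VAR_TOL = 1e-12


def impute_pmi(metadata: SampleMetadata, value: float = -1.0) -> SampleMetadata:
    """Replace every missing PMI with a fixed sentinel (default -1 hours)."""
    table = metadata.table.copy()
    table["PMI"] = table["PMI"].fillna(value)
    return SampleMetadata(table)


def transform_counts(counts: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), genes x samples."""
    sf = size_factors.reindex(counts.sample_ids)
    if sf.isna().any() or (sf <= 0).any():
        raise ValidationError("size factors must be strictly positive for all samples")
    return np.log2(counts.counts / sf.to_numpy()[None, :] + 1.0)


def _design_columns(metadata: SampleMetadata) -> pd.DataFrame:
    table = metadata.table
    if table["PMI"].isna().any():
        raise ValidationError("PMI contains missing values; impute before modelling")
    design = pd.DataFrame(
        {
            "Age": table["Age"].astype(float),
            "RIN": table["RIN"].astype(float),
            "PMI": table["PMI"].astype(float),
            "Diagnosis": (table["diagnosis"] == "AD").astype(float),
        },
        index=table.index,
    )
    for term in TERMS:
        if design[term].nunique() < 2:
            raise ValidationError(f"covariate {term!r} is constant; design is rank-deficient")
    return design


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per gene (columns of Y) under OLS on X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.sum(resid**2, axis=0)


def partition_variance(
    expr_matrix: pd.DataFrame, metadata: SampleMetadata
) -> pd.DataFrame:
    """Fraction of each gene's variance attributed to every model term.

    Returns a DataFrame indexed by gene with columns age_frac, rin_frac,
    pmi_frac, dx_frac, residual, flagged; fractions sum to 1 for every
    non-flagged gene.
    """
    meta = metadata.subset(list(expr_matrix.columns))
    design = _design_columns(meta)
    n = design.shape[0]
    if (design["Diagnosis"] == 1).sum() < 2 or (design["Diagnosis"] == 0).sum() < 2:
        raise ValidationError("need >= 2 samples per diagnosis level")

    Y = expr_matrix.to_numpy(dtype=float).T  # samples x genes
    tss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    flagged = tss <= _ZERO_VAR_TOL

    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept, design.to_numpy()])
    rss_full = _rss(X_full, Y)

    with np.errstate(invalid="ignore", divide="ignore"):
        r2_full = np.where(flagged, 0.0, 1.0 - rss_full / tss)
    r2_full = np.clip(r2_full, 0.0, 1.0)

    delta = np.zeros((len(TERMS), Y.shape[1]))
    for i, term in enumerate(TERMS):
        keep = [t for t in TERMS if t != term]
        X_red = np.hstack([intercept, design[list(keep)].to_numpy()])
        rss_red = _rss(X_red, Y)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2_red = np.where(flagged, 0.0, 1.0 - rss_red / tss)
        delta[i] = np.clip(r2_full - np.clip(r2_red, 0.0, 1.0), 0.0, None)

    total_delta = delta.sum(axis=0)
    scale = np.where(total_delta > 0, r2_full / np.where(total_delta > 0, total_delta, 1.0), 0.0)
    fractions = delta * scale[None, :]
    fractions[:, flagged] = 0.0
    residual = 1.0 - fractions.sum(axis=0)

    out = pd.DataFrame(
        {
            "age_frac": fractions[0],
            "rin_frac": fractions[1],
            "pmi_frac": fractions[2],
            "dx_frac": fractions[3],
            "residual": residual,
            "flagged": flagged,
        },
        index=expr_matrix.index,
    )
    return out


def filter_genes(fractions: pd.DataFrame, min_diagnosis_fraction: float = 0.01) -> list[str]:
    """Genes whose diagnosis-attributed variance fraction meets the threshold.

    Flagged (zero-variance) genes are never retained; input order is kept.
    """
    if not 0.0 <= min_diagnosis_fraction <= 1.0:
        raise ValidationError("min_diagnosis_fraction must lie in [0, 1]")
    keep = (~fractions["flagged"]) & (fractions["dx_frac"] >= min_diagnosis_fraction)
    return list(fractions.index[keep])


def write_variance_fractions(fractions: pd.DataFrame, path) -> None:
    fractions.to_csv(path, sep="\t", index_label="gene_id")
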