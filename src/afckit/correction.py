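"""Expression normalization and two-step covariate correction.

Raw gene counts are scaled to a common library size (the median across
samples), floored with a pseudo-count of 1 and log2-transformed to
stabilize the variance for least-squares fitting.  Known confounders (PEER
factors, genotype PCs, platform, sex, ...) are consumed as a numeric
covariate matrix and removed in two steps: a joint regression selects
covariates with nominally significant coefficients (p < 0.01), and the
residuals of a second regression on the selected set become the corrected
expression vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from afckit.io_formats import CountMatrix


@dataclass
class CorrectedExpression:
    """Covariate-corrected log2 expression for one gene (zero-mean residuals)."""

    gene_id: str
    sample_ids: list[str]
    y: np.ndarray
    selected_covariates: list[str]


def normalize_log(counts: CountMatrix, pseudo_count: float = 1.0) -> pd.DataFrame:
    """log2(count * median_library / library + pseudo_count), genes x samples."""
    libs = counts.library_sizes.to_numpy(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    target = float(np.median(libs))
    scaled = counts.counts.to_numpy(float) * (target / libs)[None, :]
    return pd.DataFrame(
        np.log2(scaled + pseudo_count),
        index=counts.counts.index,
        columns=counts.counts.columns,
    )


def correct_covariates(
    y,
    covariates: pd.DataFrame | None,
    alpha_select: float = 0.01,
    gene_id: str = "",
) -> CorrectedExpression:
    """Two-step covariate correction of a log2 expression vector.

    Step 1 regresses ``y`` jointly on all covariates (plus intercept) and
    keeps those whose coefficient is nominally significant (two-sided t
    test, strict p < ``alpha_select``).  Step 2 regresses ``y`` on the kept
    set and returns the residuals.  With no covariates (or none selected)
    the result is the mean-centered vector.
    """
    if isinstance(y, pd.Series):
        sample_ids = list(y.index)
        yv = y.to_numpy(float)
    else:
        yv = np.asarray(y, float)
        sample_ids = list(covariates.index) if covariates is not None else [
            str(i) for i in range(len(yv))
        ]
    n = len(yv)

    if covariates is None or covariates.shape[1] == 0:
        return CorrectedExpression(gene_id, sample_ids, yv - yv.mean(), [])

    cov = covariates.loc[sample_ids] if isinstance(y, pd.Series) else covariates
    cov = cov.select_dtypes(include=[np.number])
    # drop constant columns: no estimable coefficient next to the intercept
    cov = cov.loc[:, cov.std(ddof=0) > 0]
    if cov.shape[1] >= n:
        raise ValueError(
            f"{cov.shape[1]} covariates for {n} samples; reduce the covariate "
            "matrix (e.g. fewer PEER factors) before correction"
        )
    if cov.shape[1] == 0:
        return CorrectedExpression(gene_id, sample_ids, yv - yv.mean(), [])

    X = sm.add_constant(cov.to_numpy(float))
    fit1 = sm.OLS(yv, X).fit()
    pvals = fit1.pvalues[1:]  # skip intercept
    selected = [c for c, p in zip(cov.columns, pvals) if p < alpha_select]

    if not selected:
        resid = yv - yv.mean()
    else:
        X2 = sm.add_constant(cov[selected].to_numpy(float))
        resid = sm.OLS(yv, X2).fit().resid
    return CorrectedExpression(gene_id, sample_ids, np.asarray(resid), selected)
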