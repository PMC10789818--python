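"""Joint maximum-likelihood estimation of log2 allelic fold changes.

A gene regulated in cis by N conditionally independent eQTLs is modelled
with a reference-haplotype expression e_R and one allelic fold change
(aFC) per eQTL.  On log2 scale, with s the vector of log2 aFCs and h1, h2
the binary alternative-allele indicators of the two phased haplotypes, the
total expression of an individual is

    log2 e_total = log2(2^(s.h1) + 2^(s.h2)) + log2 e_R

The noise is multiplicative (log-normal), so the model is fitted by
nonlinear least squares on log2-transformed, library-size-normalized
(optionally covariate-corrected) expression.  Estimates are initialized
from a linear fit on allele dosage and constrained to |s| <= log2(100);
95% confidence intervals come from the curvature at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from afckit.io_formats import HaplotypeDesign, IdentifiabilityError

AFC_BOUND = float(np.log2(100.0))  # clamp on |log2 aFC| to avoid outliers


@dataclass
class GeneModel:
    """Fitted effect sizes for one gene.

    ``s`` holds the per-eQTL log2 aFC of the alternative allele relative to
    the reference, in eQTL rank order; ``log2_e_ref`` is the log2
    expression of a haplotype carrying reference alleles at every eQTL.
    """

    gene_id: str
    variant_ids: list[str]
    s: np.ndarray
    log2_e_ref: float
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    converged: bool = True
    n_samples_used: int = 0
    fixed_zero: list[str] = field(default_factory=list)
    objective_init: float = np.nan
    objective_final: float = np.nan
    message: str = ""
    # curvature bookkeeping for confidence intervals
    _jac: np.ndarray | None = field(default=None, repr=False)
    _rss: float = field(default=np.nan, repr=False)
    _active: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_eqtls(self) -> int:
        return len(self.variant_ids)

    def ci_overlaps_zero(self) -> np.ndarray | None:
        """Boolean per eQTL: 95% CI includes zero (effect not resolved)."""
        if self.ci_low is None or self.ci_high is None:
            return None
        return (self.ci_low <= 0.0) & (self.ci_high >= 0.0)


def predict_log_total(s, log2_e_ref, h1, h2):
    """log2 total expression under the haplotypic aFC model.

    ``h1``/``h2`` may be single rows or (n_samples, N) matrices.  Uses
    log-sum-exp in base 2, so large |s| cannot overflow.
    """
    s = np.asarray(s, float)
    a = np.asarray(h1, float) @ s
    b = np.asarray(h2, float) @ s
    return np.logaddexp2(a, b) + log2_e_ref


def _coerce_y(design: HaplotypeDesign, y) -> np.ndarray:
    from afckit.correction import CorrectedExpression
    from afckit.io_formats import assert_sample_alignment

    if isinstance(y, CorrectedExpression):
        assert_sample_alignment(
            y.sample_ids, design.sample_ids, "expression vs genotype design"
        )
        return np.asarray(y.y, float)
    try:
        import pandas as pd

        if isinstance(y, pd.Series):
            return y.loc[design.sample_ids].to_numpy(float)
    except ImportError:  # pragma: no cover
        pass
    yv = np.asarray(y, float)
    if yv.shape[0] != design.n_samples:
        raise ValueError(
            f"expression length {yv.shape[0]} != design samples {design.n_samples}"
        )
    return yv


def _residual_and_jac(theta, H1, H2, y):
    """Residuals y - model and the model Jacobian for active parameters."""
    s, e_ref = theta[:-1], theta[-1]
    a = H1 @ s
    b = H2 @ s
    pred = np.logaddexp2(a, b) + e_ref
    resid = y - pred
    # weight of haplotype 1 in the total: 2^a / (2^a + 2^b), overflow-safe
    w = 1.0 / (1.0 + np.exp2(np.clip(b - a, -60, 60)))
    dpred_ds = w[:, None] * H1 + (1.0 - w)[:, None] * H2
    jac = -np.column_stack([dpred_ds, np.ones_like(y)])
    return resid, jac


def fit_afc(
    design: HaplotypeDesign,
    y,
    bound: float = AFC_BOUND,
    compute_ci: bool = True,
    level: float = 0.95,
    tol: float = 1e-8,
    max_nfev: int = 1000,
) -> GeneModel:
    """Fit log2 aFCs for all eQTLs of a gene simultaneously.

    Bounded trust-region nonlinear least squares on the log2 expression
    model, initialized from the linear regression of ``y`` on per-variant
    alternative-allele dosage (the intercept initializes ``log2_e_ref``).
    Monomorphic eQTLs in the sample subset get s fixed at 0 and are listed
    in ``fixed_zero`` instead of failing the gene.
    """
    yv = _coerce_y(design, y)
    n, N = design.n_samples, design.n_eqtls
    if n <= N + 1:
        raise ValueError(
            f"gene {design.gene_id}: {n} samples cannot identify {N} effects "
            "plus reference expression"
        )

    dosage = design.dosage()
    poly = dosage.std(axis=0) > 0
    active = np.where(poly)[0]
    fixed_zero = [design.variant_ids[j] for j in np.where(~poly)[0]]
    H1, H2 = design.H1[:, active].astype(float), design.H2[:, active].astype(float)
    k = len(active)

    X = np.column_stack([dosage[:, active], np.ones(n)])
    if np.linalg.matrix_rank(X) < k + 1:
        raise IdentifiabilityError(
            f"gene {design.gene_id}: dosage design rank-deficient after "
            "dropping monomorphic eQTLs"
        )
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    s0 = np.clip(beta[:-1], -bound * 0.999, bound * 0.999)
    theta0 = np.append(s0, beta[-1])

    lo = np.append(np.full(k, -bound), -np.inf)
    hi = np.append(np.full(k, bound), np.inf)
    res = optimize.least_squares(
        lambda t: _residual_and_jac(t, H1, H2, yv)[0],
        theta0,
        jac=lambda t: _residual_and_jac(t, H1, H2, yv)[1],
        bounds=(lo, hi),
        method="trf",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_nfev,
    )

    s_full = np.zeros(N)
    s_full[active] = res.x[:-1]
    obj0 = float(np.sum(_residual_and_jac(theta0, H1, H2, yv)[0] ** 2))
    model = GeneModel(
        gene_id=design.gene_id,
        variant_ids=list(design.variant_ids),
        s=s_full,
        log2_e_ref=float(res.x[-1]),
        converged=bool(res.success),
        n_samples_used=n,
        fixed_zero=fixed_zero,
        objective_init=obj0,
        objective_final=float(2 * res.cost),
        message=res.status if res.success else res.message,
        _jac=res.jac,
        _rss=float(2 * res.cost),
        _active=active,
    )
    if compute_ci and model.converged:
        confidence_intervals(model, level=level)
    return model


def confidence_intervals(model: GeneModel, level: float = 0.95) -> GeneModel:
    """Attach per-eQTL confidence intervals from the least-squares curvature.

    Uses the asymptotic covariance sigma^2 (J'J)^-1 with a Student-t
    quantile.  A singular curvature leaves the CI as NaN (unavailable)
    rather than fabricating one; eQTLs fixed at zero for monomorphism get
    NaN CIs as well.
    """
    if not model.converged:
        raise ValueError(f"gene {model.gene_id}: cannot compute CI, fit not converged")
    N = model.n_eqtls
    ci_low = np.full(N, np.nan)
    ci_high = np.full(N, np.nan)
    J, active = model._jac, model._active
    if J is not None and active is not None:
        p = J.shape[1]
        dof = model.n_samples_used - p
        if dof > 0:
            JtJ = J.T @ J
            sigma2 = model._rss / dof
            try:
                cov = sigma2 * np.linalg.inv(JtJ)
                se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))[:-1]
                tq = stats.t.ppf(0.5 + level / 2.0, dof)
                ci_low[active] = model.s[active] - tq * se
                ci_high[active] = model.s[active] + tq * se
            except np.linalg.LinAlgError:
                warnings.warn(
                    f"gene {model.gene_id}: singular curvature, CI unavailable",
                    stacklevel=2,
                )
    model.ci_low = ci_low
    model.ci_high = ci_high
    return model


def fit_afc_single(
    design: HaplotypeDesign,
    y,
    variant_index: int = 0,
    bound: float = AFC_BOUND,
) -> GeneModel:
    """Single-variant aFC estimate via one-dimensional profiling.

    For one eQTL the least-squares problem reduces to a scalar search: for
    any fixed s the optimal log2 e_R is the mean residual offset, so the
    profiled objective is minimized over s alone (bounded Brent).  This is
    the closed computation of the original single-eQTL aFC estimator; when
    ``design`` has several eQTLs it yields the marginal (per-variant)
    estimate that ignores the others.
    """
    sub = design.subset_variants([variant_index])
    yv = _coerce_y(sub, y)
    h1 = sub.H1[:, 0].astype(float)
    h2 = sub.H2[:, 0].astype(float)

    def profiled(s):
        g = np.logaddexp2(s * h1, s * h2)
        offset = np.mean(yv - g)
        return float(np.sum((yv - g - offset) ** 2))

    res = optimize.minimize_scalar(
        profiled, bounds=(-bound, bound), method="bounded",
        options={"xatol": 1e-10},
    )
    s_hat = float(res.x)
    g = np.logaddexp2(s_hat * h1, s_hat * h2)
    return GeneModel(
        gene_id=sub.gene_id,
        variant_ids=list(sub.variant_ids),
        s=np.array([s_hat]),
        log2_e_ref=float(np.mean(yv - g)),
        converged=bool(res.success),
        n_samples_used=sub.n_samples,
        objective_final=float(res.fun),
    )


@dataclass
class AncestryGeneModel:
    """Ancestry-stratified effect sizes for one gene.

    ``s_strat0``/``s_strat1`` are per-eQTL log2 aFCs for the indicator-0
    and indicator-1 strata (e.g. European- and African-American samples),
    fitted jointly with a shared log2 e_R.  ``stratified_selected`` is true
    per eQTL only where the strata's 95% CIs do not overlap; elsewhere the
    shared (pooled) estimate is the reported effect.
    """

    gene_id: str
    variant_ids: list[str]
    s_shared: np.ndarray
    s_strat0: np.ndarray
    s_strat1: np.ndarray
    ci0_low: np.ndarray | None
    ci0_high: np.ndarray | None
    ci1_low: np.ndarray | None
    ci1_high: np.ndarray | None
    log2_e_ref: float
    indicator_name: str
    stratified_selected: np.ndarray
    stratified_fit_performed: bool = True
    converged: bool = True
    message: str = ""

    def selected_s(self, indicator_value: int) -> np.ndarray:
        """Effect sizes to report for one stratum after CI-based selection."""
        strat = self.s_strat1 if indicator_value else self.s_strat0
        return np.where(self.stratified_selected, strat, self.s_shared)


def fit_ancestry_afc(
    design: HaplotypeDesign,
    y,
    indicator,
    indicator_name: str = "ancestry",
    bound: float = AFC_BOUND,
    level: float = 0.95,
    tol: float = 1e-8,
) -> AncestryGeneModel:
    """Fit stratum-specific log2 aFCs jointly with a shared reference level.

    Each sample's effective effect vector is s0*(1-I) + s1*I with I the
    per-sample stratum indicator; both strata share log2 e_R and are
    optimized in one bounded least-squares problem.  Per eQTL the
    stratified estimate is selected only where the two strata's CIs do not
    overlap; otherwise the pooled fit is reported.  A stratum with too few
    samples to identify the parameters refuses stratification and returns
    the pooled model with a warning.
    """
    yv = _coerce_y(design, y)
    I = np.asarray(indicator, float)
    if I.shape[0] != design.n_samples:
        raise ValueError("indicator length must match design samples")
    if not set(np.unique(I)) <= {0.0, 1.0}:
        raise ValueError("indicator must be binary (0/1)")
    if len(np.unique(I)) < 2:
        raise ValueError(
            f"gene {design.gene_id}: indicator '{indicator_name}' is constant; "
            "both strata must be non-empty"
        )

    shared = fit_afc(design, yv, bound=bound)
    N = design.n_eqtls
    n0, n1 = int((I == 0).sum()), int((I == 1).sum())
    if min(n0, n1) <= N + 1:
        warnings.warn(
            f"gene {design.gene_id}: stratum sizes ({n0}, {n1}) too small to "
            f"identify {N} effects; returning the pooled model",
            stacklevel=2,
        )
        return AncestryGeneModel(
            gene_id=design.gene_id,
            variant_ids=list(design.variant_ids),
            s_shared=shared.s,
            s_strat0=shared.s.copy(),
            s_strat1=shared.s.copy(),
            ci0_low=None, ci0_high=None, ci1_low=None, ci1_high=None,
            log2_e_ref=shared.log2_e_ref,
            indicator_name=indicator_name,
            stratified_selected=np.zeros(N, bool),
            stratified_fit_performed=False,
            converged=shared.converged,
            message="stratified fit refused: stratum too small",
        )

    H1, H2 = design.H1.astype(float), design.H2.astype(float)
    # effective per-sample design: columns for s0 scaled by (1-I), s1 by I
    A1 = np.hstack([(1 - I)[:, None] * H1, I[:, None] * H1])
    A2 = np.hstack([(1 - I)[:, None] * H2, I[:, None] * H2])

    theta0 = np.concatenate([shared.s, shared.s, [shared.log2_e_ref]])
    theta0[:-1] = np.clip(theta0[:-1], -bound * 0.999, bound * 0.999)
    lo = np.append(np.full(2 * N, -bound), -np.inf)
    hi = np.append(np.full(2 * N, bound), np.inf)
    res = optimize.least_squares(
        lambda t: _residual_and_jac(t, A1, A2, yv)[0],
        theta0,
        jac=lambda t: _residual_and_jac(t, A1, A2, yv)[1],
        bounds=(lo, hi),
        method="trf",
        xtol=tol, ftol=tol, gtol=tol,
    )
    s0_hat, s1_hat = res.x[:N], res.x[N:2 * N]

    ci0_low = np.full(N, np.nan); ci0_high = np.full(N, np.nan)
    ci1_low = np.full(N, np.nan); ci1_high = np.full(N, np.nan)
    dof = design.n_samples - (2 * N + 1)
    if dof > 0:
        try:
            cov = (2 * res.cost / dof) * np.linalg.inv(res.jac.T @ res.jac)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            tq = stats.t.ppf(0.5 + level / 2.0, dof)
            ci0_low, ci0_high = s0_hat - tq * se[:N], s0_hat + tq * se[:N]
            ci1_low = s1_hat - tq * se[N:2 * N]
            ci1_high = s1_hat + tq * se[N:2 * N]
        except np.linalg.LinAlgError:
            warnings.warn(
                f"gene {design.gene_id}: singular curvature in stratified fit",
                stacklevel=2,
            )
    disjoint = (ci0_high < ci1_low) | (ci1_high < ci0_low)
    disjoint = np.where(np.isnan(ci0_low) | np.isnan(ci1_low), False, disjoint)

    return AncestryGeneModel(
        gene_id=design.gene_id,
        variant_ids=list(design.variant_ids),
        s_shared=shared.s,
        s_strat0=s0_hat,
        s_strat1=s1_hat,
        ci0_low=ci0_low, ci0_high=ci0_high,
        ci1_low=ci1_low, ci1_high=ci1_high,
        log2_e_ref=float(res.x[-1]),
        indicator_name=indicator_name,
        stratified_selected=np.asarray(disjoint, bool),
        stratified_fit_performed=True,
        converged=bool(res.success) and shared.converged,
    )
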