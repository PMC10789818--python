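"""Synthetic cohorts for validating the estimator end to end.

The generator mirrors the noise structure of bulk RNA-seq eQTL data with
all biology held fixed: log2 effect sizes are drawn from Normal(0, sigma_s)
(sigma_s = 1 by default), phased genotypes are sampled at given minor
allele frequencies — independently, or for variant pairs from the
two-locus haplotype table solved for a target LD r^2 — expected haplotypic
expressions follow the aFC model, total gene counts are Poisson, and
haplotype counts are Binomial(total, r) at the true reference ratio
r = e_h1 / (e_h1 + e_h2).  No biological variation beyond genotype and
counting noise is added, so deviations of the fitted from the generating
effects isolate estimator error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from afckit.io_formats import (
    CountMatrix,
    EqtlAssignment,
    HaplotypeCountTable,
    HaplotypeDesign,
    PhasedGenotypeTable,
)


@dataclass
class SimParams:
    """Cohort-level simulation settings.

    mean_expression is the target average total read count per gene across
    the cohort (the reference-haplotype level e_R is solved from it, so the
    realized mean matches regardless of the drawn effect sizes).  ``maf``
    may be a scalar applied to every eQTL or None to draw per-eQTL MAFs
    uniformly from [0.05, 0.5].  ``n_eqtls`` may be an int or an inclusive
    (low, high) range sampled per gene.
    """

    n_individuals: int = 500
    n_eqtls: int | tuple[int, int] = 1
    sigma_s: float = 1.0
    maf: float | None = None
    ld_target: float = 0.0
    mean_expression: float = 500.0
    n_genes: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be non-negative")
        if self.maf is not None and not (0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if not (0 <= self.ld_target < 1):
            raise ValueError("ld_target r^2 must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ground truth that generated it."""

    genotypes: PhasedGenotypeTable
    assignment: EqtlAssignment
    counts: CountMatrix
    ase: HaplotypeCountTable
    true_s: dict[str, np.ndarray]
    true_log2_e_ref: dict[str, float]
    ref_ratio: dict[str, np.ndarray]  # per gene: per-sample r = e_h1/(e_h1+e_h2)
    params: SimParams = field(default=None)

    def design_for(self, gene_id: str) -> HaplotypeDesign:
        from afckit.io_formats import build_design

        return build_design(self.genotypes, self.assignment, gene_id)


def simulate_effects(n_eqtls: int, sigma_s: float = 1.0, seed=None) -> np.ndarray:
    """Draw i.i.d. Normal(0, sigma_s) log2 effect sizes."""
    if n_eqtls < 1:
        raise ValueError("n_eqtls must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(0.0, sigma_s, size=n_eqtls)


def simulate_haplotypes(n: int, mafs, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Independent phased haplotypes; columns carry the given alt frequencies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.atleast_1d(np.asarray(mafs, float))
    h1 = (rng.random((n, mafs.size)) < mafs).astype(np.int8)
    h2 = (rng.random((n, mafs.size)) < mafs).astype(np.int8)
    return h1, h2


def max_r_squared(maf_a: float, maf_b: float) -> float:
    """Largest achievable LD r^2 for two loci at the given alt frequencies.

    With positive D, D_max = min(p_a(1-p_b), p_b(1-p_a)); r^2_max follows
    from r = D / sqrt(p_a(1-p_a) p_b(1-p_b)).
    """
    pa, pb = float(maf_a), float(maf_b)
    d_max = min(pa * (1 - pb), pb * (1 - pa))
    return d_max**2 / (pa * (1 - pa) * pb * (1 - pb))


def simulate_haplotype_pair(
    maf_a: float,
    maf_b: float,
    ld_target: float,
    n: int,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Phased genotypes for two variants at a target LD r^2.

    Haplotypes are drawn from the two-locus haplotype frequency table
    (p_AB = p_a p_b + D with D solved from the target r^2, positive sign),
    so the empirical r^2 converges to ``ld_target`` as n grows.  An
    infeasible (MAF, r^2) combination raises with the feasible maximum.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pa, pb = float(maf_a), float(maf_b)
    r2max = max_r_squared(pa, pb)
    if ld_target > r2max + 1e-12:
        raise ValueError(
            f"ld_target r^2={ld_target:.3g} infeasible for MAFs "
            f"({pa}, {pb}); maximum achievable is {r2max:.4g}"
        )
    D = np.sqrt(ld_target * pa * (1 - pa) * pb * (1 - pb))
    # haplotype classes: (alt,alt), (alt,ref), (ref,alt), (ref,ref)
    freqs = np.array(
        [
            pa * pb + D,
            pa * (1 - pb) - D,
            (1 - pa) * pb - D,
            (1 - pa) * (1 - pb) + D,
        ]
    )
    freqs = np.clip(freqs, 0.0, None)
    freqs /= freqs.sum()
    alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
    draws = rng.choice(4, size=2 * n, p=freqs)
    haps = alleles[draws]
    return haps[:n], haps[n:]


def empirical_r_squared(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Squared Pearson correlation between two allele (or dosage) vectors."""
    c = np.corrcoef(np.asarray(g_a, float).ravel(), np.asarray(g_b, float).ravel())
    return float(c[0, 1] ** 2)


def simulate_counts(
    h1: np.ndarray,
    h2: np.ndarray,
    s: np.ndarray,
    log2_e_ref: float,
    seed=None,
    dispersion: float = 0.0,
):
    """Poisson totals and Binomial haplotype counts under the aFC model.

    Expected haplotypic expressions are e_h = e_R * 2^(s.h); the total read
    count is Poisson(e_h1 + e_h2), and reads are split Binomial(total, r)
    at the true reference ratio r = e_h1/(e_h1+e_h2).  ``dispersion`` > 0
    switches totals to a gamma-Poisson mixture (negative binomial with
    variance mu + dispersion*mu^2); the default keeps pure counting noise.

    Returns (total, hap1, hap2, r).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(s, float)
    e1 = np.exp2(log2_e_ref + np.asarray(h1, float) @ s)
    e2 = np.exp2(log2_e_ref + np.asarray(h2, float) @ s)
    mu = e1 + e2
    r = e1 / mu
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        total = rng.poisson(lam)
    else:
        total = rng.poisson(mu)
    hap1 = rng.binomial(total, r)
    return total, hap1, total - hap1, r


def simulate_cohort(params: SimParams) -> SyntheticCohort:
    """Generate a full multi-gene cohort with ground truth attached.

    One master seed fans out to named substreams (effects, haplotypes,
    counts) via numpy's SeedSequence, so each component is independently
    reproducible.  For 2-eQTL genes with ``ld_target`` > 0 the variant pair
    is drawn at the requested LD; otherwise variants are independent.
    Library sizes are uniform (library variation is not simulated).
    """
    ss = np.random.SeedSequence(params.seed).spawn(3)
    rng_eff = np.random.default_rng(ss[0])
    rng_hap = np.random.default_rng(ss[1])
    rng_cnt = np.random.default_rng(ss[2])

    n = params.n_individuals
    sample_ids = [f"S{i:04d}" for i in range(n)]
    variant_ids: list[str] = []
    h1_cols, h2_cols = [], []
    asn_rows, count_rows, ase_rows = [], [], []
    true_s, true_e_ref, ref_ratio = {}, {}, {}
    pos = 10_000

    for g in range(params.n_genes):
        gene = f"GENE{g:04d}"
        if isinstance(params.n_eqtls, tuple):
            lo, hi = params.n_eqtls
            N = int(rng_eff.integers(lo, hi + 1))
        else:
            N = int(params.n_eqtls)
        s = simulate_effects(N, params.sigma_s, rng_eff)

        if params.maf is None:
            mafs = rng_hap.uniform(0.05, 0.5, size=N)
        else:
            mafs = np.full(N, params.maf)
        if N == 2 and params.ld_target > 0:
            H1, H2 = simulate_haplotype_pair(
                mafs[0], mafs[1], params.ld_target, n, rng_hap
            )
        else:
            H1, H2 = simulate_haplotypes(n, mafs, rng_hap)

        # solve e_R so the cohort-average expected total hits mean_expression
        m = np.mean(
            np.exp2(H1.astype(float) @ s) + np.exp2(H2.astype(float) @ s)
        )
        log2_e_ref = float(np.log2(params.mean_expression / m))

        total, hap1, hap2, r = simulate_counts(H1, H2, s, log2_e_ref, rng_cnt)

        vids = []
        for k in range(N):
            vid = f"chr1_{pos}_A_G"
            pos += 1000
            vids.append(vid)
            variant_ids.append(vid)
            h1_cols.append(H1[:, k])
            h2_cols.append(H2[:, k])
            asn_rows.append({"gene_id": gene, "variant_id": vid, "rank": k + 1})
        true_s[gene] = s
        true_e_ref[gene] = log2_e_ref
        ref_ratio[gene] = r
        count_rows.append(pd.Series(total, index=sample_ids, name=gene))
        for i, sid in enumerate(sample_ids):
            ase_rows.append(
                {
                    "gene_id": gene,
                    "sample_id": sid,
                    "hap1_count": int(hap1[i]),
                    "hap2_count": int(hap2[i]),
                }
            )

    genotypes = PhasedGenotypeTable(
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        h1=np.stack(h1_cols, axis=1).astype(np.int8),
        h2=np.stack(h2_cols, axis=1).astype(np.int8),
    )
    counts = CountMatrix(
        counts=pd.DataFrame(count_rows),
        library_sizes=pd.Series(1.0, index=sample_ids),
    )
    return SyntheticCohort(
        genotypes=genotypes,
        assignment=EqtlAssignment(pd.DataFrame(asn_rows)),
        counts=counts,
        ase=HaplotypeCountTable(pd.DataFrame(ase_rows)),
        true_s=true_s,
        true_log2_e_ref=true_e_ref,
        ref_ratio=ref_ratio,
        params=params,
    )
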