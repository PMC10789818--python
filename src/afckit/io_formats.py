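"""Readers/writers for the external formats and the internal data model.

Conventions used throughout the package:

* Coordinates are 1-based (VCF convention); variant ids are normalized to
  ``chrom_pos_ref_alt``.
* Haplotype 1 is the LEFT allele of the phased GT field everywhere.  The
  haplotype-aggregated ASE counts must be keyed to the same phase frame —
  hap1 counts belong to the left allele of the VCF genotype.
* Missing or unphased calls are recorded and lead to per-gene sample
  exclusion, never to silent imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a call that could not be used


@dataclass
class PhasedGenotypeTable:
    """Phased bi-allelic genotype calls for a set of samples and variants.

    ``h1``/``h2`` hold the alternative-allele indicator of the left/right
    allele of the phased GT, shape (n_samples, n_variants), with entries in
    {0, 1} or ``MISSING`` (-1) where the call was absent or unphased.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    h1: np.ndarray
    h2: np.ndarray
    call_errors: list[tuple[str, str, str]] = field(default_factory=list)
    missing_variants: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._vidx = {v: i for i, v in enumerate(self.variant_ids)}
        self._sidx = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def variant_index(self, variant_id: str) -> int:
        return self._vidx[variant_id]


@dataclass
class CountMatrix:
    """Gene-level read counts (genes x samples) with per-sample library sizes."""

    counts: pd.DataFrame  # index gene_id, columns sample_ids, integer counts
    library_sizes: pd.Series  # index sample_ids, positive totals

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene_ids in count matrix: {dups}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts in count matrix")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.library_sizes <= 0).any() or self.library_sizes.isna().any():
            raise ValueError("library sizes must be positive for every sample")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CountMatrix":
        """Build with library sizes taken as the per-sample column totals."""
        return cls(counts=counts, library_sizes=counts.sum(axis=0))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class HaplotypeCountTable:
    """Haplotype-aggregated ASE read counts, one row per (gene, sample).

    hap1_count / hap2_count are reads assigned to haplotype 1 / 2 in the
    same phase frame as the genotypes (hap1 = left allele of the GT).
    """

    table: pd.DataFrame  # columns: gene_id, sample_id, hap1_count, hap2_count

    REQUIRED = ("gene_id", "sample_id", "hap1_count", "hap2_count")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"haplotype count table missing columns: {missing}")
        if (self.table[["hap1_count", "hap2_count"]].to_numpy() < 0).any():
            raise ValueError("negative haplotype counts")
        if self.table.duplicated(["gene_id", "sample_id"]).any():
            raise ValueError("duplicate (gene_id, sample_id) pairs in ASE table")


@dataclass
class EqtlAssignment:
    """Mapping of genes to their conditionally independent eQTLs.

    Ranks reflect the order in which signals were mapped by stepwise
    regression; within a gene they must be 1..N without gaps.
    """

    table: pd.DataFrame  # columns: gene_id, variant_id, rank

    def __post_init__(self):
        if self.table.duplicated(["gene_id", "variant_id"]).any():
            raise ValueError("duplicate (gene, variant) pairs in eQTL assignment")
        for gene, sub in self.table.groupby("gene_id"):
            ranks = sorted(sub["rank"].tolist())
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError(
                    f"gene {gene}: ranks must be 1..N without gaps, got {ranks}"
                )

    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))

    def variants_for(self, gene_id: str) -> list[str]:
        sub = self.table[self.table["gene_id"] == gene_id].sort_values("rank")
        if sub.empty:
            raise KeyError(f"gene {gene_id} not in eQTL assignment")
        return sub["variant_id"].tolist()

    def all_variants(self) -> list[str]:
        return list(dict.fromkeys(self.table["variant_id"]))


@dataclass
class HaplotypeDesign:
    """Phase-resolved allele-indicator design for one gene.

    H1, H2 are (n_samples, N) binary matrices over the gene's eQTLs in rank
    order; row i gives the alternative-allele indicators on each haplotype
    of sample i.
    """

    gene_id: str
    variant_ids: list[str]
    sample_ids: list[str]
    H1: np.ndarray
    H2: np.ndarray
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_eqtls(self) -> int:
        return len(self.variant_ids)

    def dosage(self) -> np.ndarray:
        """Per-variant alternative-allele dosage h1 + h2 (values 0/1/2)."""
        return self.H1 + self.H2

    def subset_variants(self, idx: list[int]) -> "HaplotypeDesign":
        return HaplotypeDesign(
            gene_id=self.gene_id,
            variant_ids=[self.variant_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            H1=self.H1[:, idx],
            H2=self.H2[:, idx],
            dropped_samples=list(self.dropped_samples),
        )


def normalize_variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}_{pos}_{ref}_{alt}"


def read_phased_vcf(path, variant_subset=None) -> PhasedGenotypeTable:
    """Read phased bi-allelic SNV genotypes from a VCF.

    Multi-allelic records are skipped with a warning.  Unphased ("/") or
    missing GT calls are recorded in ``call_errors`` rather than silently
    coerced; downstream design construction drops those samples per gene.
    If ``variant_subset`` is given, only those variant ids are retained and
    ids that never appear are listed in ``missing_variants``.
    """
    from cyvcf2 import VCF

    subset = set(variant_subset) if variant_subset is not None else None
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids: list[str] = []
    h1_rows, h2_rows = [], []
    call_errors: list[tuple[str, str, str]] = []

    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record at {rec.CHROM}:{rec.POS}",
                stacklevel=2,
            )
            continue
        vid = normalize_variant_id(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
        if subset is not None and vid not in subset:
            continue
        h1 = np.full(len(samples), MISSING, dtype=np.int8)
        h2 = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(rec.genotypes):  # [allele1, allele2, phased]
            a1, a2, phased = g[0], g[1], bool(g[-1])
            if a1 < 0 or a2 < 0:
                call_errors.append((vid, samples[i], "missing GT"))
            elif not phased and a1 != a2:
                # homozygous calls carry no phase ambiguity
                call_errors.append((vid, samples[i], "unphased heterozygous GT"))
            elif a1 > 1 or a2 > 1:
                call_errors.append((vid, samples[i], "non bi-allelic allele index"))
            else:
                h1[i], h2[i] = a1, a2
        variant_ids.append(vid)
        h1_rows.append(h1)
        h2_rows.append(h2)

    missing_variants = sorted(subset - set(variant_ids)) if subset else []
    n = len(samples)
    h1_mat = np.stack(h1_rows, axis=1) if h1_rows else np.zeros((n, 0), dtype=np.int8)
    h2_mat = np.stack(h2_rows, axis=1) if h2_rows else np.zeros((n, 0), dtype=np.int8)
    return PhasedGenotypeTable(
        sample_ids=samples,
        variant_ids=variant_ids,
        h1=h1_mat,
        h2=h2_mat,
        call_errors=call_errors,
        missing_variants=missing_variants,
    )


class IdentifiabilityError(ValueError):
    """Raised when a gene's genotype design cannot identify all effects."""


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns not independently identifiable (QR with pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def build_design(
    genotypes: PhasedGenotypeTable, assignment: EqtlAssignment, gene_id: str
) -> HaplotypeDesign:
    """Assemble the phase-resolved allele-indicator design for one gene.

    Columns follow eQTL rank order.  Samples with any missing/unphased call
    at the gene's eQTLs are dropped (and listed in ``dropped_samples``).
    Raises ``IdentifiabilityError`` when the combined genotype design is
    rank-deficient, naming the collinear variants.
    """
    variants = assignment.variants_for(gene_id)
    absent = [v for v in variants if v not in genotypes._vidx]
    if absent:
        raise KeyError(f"gene {gene_id}: variants absent from genotypes: {absent}")
    cols = [genotypes.variant_index(v) for v in variants]
    H1 = genotypes.h1[:, cols].astype(float)
    H2 = genotypes.h2[:, cols].astype(float)
    ok = (H1 != MISSING).all(axis=1) & (H2 != MISSING).all(axis=1)
    dropped = [s for s, keep in zip(genotypes.sample_ids, ok) if not keep]
    kept = [s for s, keep in zip(genotypes.sample_ids, ok) if keep]
    H1, H2 = H1[ok], H2[ok]

    # identifiability: allele indicators of both haplotypes, with intercept
    C = np.vstack([H1, H2])
    X = np.column_stack([np.ones(C.shape[0]), C])
    bad = _collinear_columns(X, ["<intercept>"] + variants)
    bad = [b for b in bad if b != "<intercept>"]
    if bad:
        raise IdentifiabilityError(
            f"gene {gene_id}: genotype design is rank-deficient; "
            f"collinear variant columns: {bad}"
        )
    return HaplotypeDesign(
        gene_id=gene_id,
        variant_ids=variants,
        sample_ids=kept,
        H1=H1,
        H2=H2,
        dropped_samples=dropped,
    )


# ---------------------------------------------------------------------------
# TSV readers / writers

def read_counts(path) -> CountMatrix:
    """Read a gene x sample count matrix TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_counts(df)


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_haplotype_counts(path) -> HaplotypeCountTable:
    return HaplotypeCountTable(pd.read_csv(path, sep="\t"))


def write_haplotype_counts(tab: HaplotypeCountTable, path) -> None:
    tab.table.to_csv(path, sep="\t", index=False)


def read_eqtl_assignment(path) -> EqtlAssignment:
    return EqtlAssignment(pd.read_csv(path, sep="\t"))


def write_eqtl_assignment(asn: EqtlAssignment, path) -> None:
    asn.table.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    """Covariate TSV: first column sample id, remaining columns numeric."""
    return pd.read_csv(path, sep="\t", index_col=0)


EFFECT_COLUMNS = [
    "gene_id",
    "variant_id",
    "rank",
    "log2_afc",
    "ci_low",
    "ci_high",
    "log2_e_ref",
    "n_samples",
    "converged",
]


def write_effect_sizes(models, path) -> None:
    """Write fitted gene models to a TSV, one row per (gene, eQTL)."""
    rows = []
    for m in models:
        for k, vid in enumerate(m.variant_ids):
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "variant_id": vid,
                    "rank": k + 1,
                    "log2_afc": m.s[k],
                    "ci_low": m.ci_low[k] if m.ci_low is not None else np.nan,
                    "ci_high": m.ci_high[k] if m.ci_high is not None else np.nan,
                    "log2_e_ref": m.log2_e_ref,
                    "n_samples": m.n_samples_used,
                    "converged": m.converged,
                }
            )
    pd.DataFrame(rows, columns=EFFECT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_effect_sizes(path) -> list:
    """Read an effect-size TSV back into GeneModel objects."""
    from afckit.model import GeneModel

    df = pd.read_csv(path, sep="\t")
    models = []
    for gene, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("rank")
        ci_low = sub["ci_low"].to_numpy(float)
        ci_high = sub["ci_high"].to_numpy(float)
        models.append(
            GeneModel(
                gene_id=gene,
                variant_ids=sub["variant_id"].tolist(),
                s=sub["log2_afc"].to_numpy(float),
                log2_e_ref=float(sub["log2_e_ref"].iloc[0]),
                ci_low=None if np.isnan(ci_low).all() else ci_low,
                ci_high=None if np.isnan(ci_high).all() else ci_high,
                converged=bool(sub["converged"].iloc[0]),
                n_samples_used=int(sub["n_samples"].iloc[0]),
            )
        )
    return models


def write_vcf(genotypes: PhasedGenotypeTable, path, chrom_pos_ref_alt=None) -> None:
    """Write phased genotypes as a minimal text VCF (phased GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.split("_")[0] for v in genotypes.variant_ids):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, vid in enumerate(genotypes.variant_ids):
            chrom, pos, ref, alt = vid.split("_")
            gts = [
                "./."
                if genotypes.h1[i, j] == MISSING or genotypes.h2[i, j] == MISSING
                else f"{genotypes.h1[i, j]}|{genotypes.h2[i, j]}"
                for i in range(genotypes.n_samples)
            ]
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def assert_sample_alignment(a: list[str], b: list[str], what: str) -> None:
    """Joining two tables requires identical sample ordering; never guess."""
    if list(a) != list(b):
        raise ValueError(
            f"sample ordering mismatch while joining {what}; "
            "re-index explicitly before combining tables"
        )
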