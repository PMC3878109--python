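"""Allelic read counting and allele-specific expression classification.

Reads overlapping parent-discriminating SNPs in an F1 sample are assigned to
the maternal or paternal allele by their nucleotide; per-gene maternal (M)
and paternal (P) totals sum the assignments over all gene-body SNPs. Genes
with at least ``min_reads`` informative reads (default 10) are classified:

* monoallelic — only one allele detected (minor-allele reads at most
  ``mono_max_minor_reads``, default 0);
* preferential — both alleles detected, ratio of major to minor above
  ``bias_fold`` (default 2, strict: a ratio of exactly 2 is biallelic);
* biallelic — both alleles within the fold bound.

A zero side is replaced by ``zero_substitute`` (default 0.001) before ratio
computation. The favored allele is reported by parental genotype (which
variety contributed it), not by maternal/paternal role: in reciprocal
crosses this is what distinguishes genotype-dependent expression from
imprinting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TrioDesign

__all__ = [
    "AseThresholds",
    "count_alleles",
    "allele_fraction",
    "classify_ase",
    "classify_ase_table",
    "parent_of_origin_balance",
]

ASE_CLASSES = ("monoallelic", "preferential", "biallelic", "unclassified")


@dataclass(frozen=True)
class AseThresholds:
    min_reads: int = 10
    bias_fold: float = 2.0
    zero_substitute: float = 0.001
    mono_max_minor_reads: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.bias_fold <= 1.0:
            raise ValueError("bias_fold must exceed 1")
        if self.zero_substitute <= 0:
            raise ValueError("zero_substitute must be positive")
        if self.mono_max_minor_reads < 0:
            raise ValueError("mono_max_minor_reads must be >= 0")


_BASE_COUNT_COLS = {"count_A", "count_C", "count_G", "count_T"}


def count_alleles(
    f1_pileup: pd.DataFrame,
    snps: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    cross: TrioDesign | None = None,
) -> pd.DataFrame:
    """Aggregate per-SNP allelic counts to per-gene maternal/paternal totals.

    Two input shapes are accepted:

    * allele-resolved: columns ``gene_id, count_maternal, count_paternal``
      (as emitted by the synthetic generator) — summed directly;
    * base-resolved: columns ``chrom, pos, count_A..count_T`` — each SNP's
      counts are mapped to alleles via the *snps* table (which must carry
      per-parent genotype columns ``gt_<parent>`` with ref/alt alleles) and
      the *cross* design, and SNPs are assigned to genes via the *genes*
      interval table. Bases matching neither parental allele are discarded
      and tallied in ``discarded``.

    Returns one row per gene with columns gene_id, M, P, n_snps, discarded,
    discordant (True when SNPs within the gene favor opposite alleles).
    Genes without informative SNPs are absent.
    """
    df = f1_pileup
    if not {"count_maternal", "count_paternal"} <= set(df.columns):
        if snps is None or cross is None:
            raise ValueError(
                "base-resolved pileup requires the SNP table and cross design"
            )
        df = assign_alleles(df, snps, cross, genes=genes)

    if "gene_id" not in df.columns:
        if genes is None:
            raise ValueError("pileup lacks gene_id and no gene table was given")
        df = _annotate_genes(df, genes)

    df = df.loc[df["gene_id"].notna() & (df["gene_id"] != "")]
    if "discarded" not in df.columns:
        df = df.assign(discarded=0)

    def _agg(grp: pd.DataFrame) -> pd.Series:
        m = int(grp["count_maternal"].sum())
        p = int(grp["count_paternal"].sum())
        covered = grp.loc[(grp["count_maternal"] + grp["count_paternal"]) > 0]
        direction = np.sign(covered["count_maternal"] - covered["count_paternal"])
        discordant = bool((direction > 0).any() and (direction < 0).any())
        return pd.Series(
            {
                "M": m,
                "P": p,
                "n_snps": len(grp),
                "discarded": int(grp["discarded"].sum()),
                "discordant": discordant,
            }
        )

    if len(df) == 0:
        return pd.DataFrame(columns=["gene_id", "M", "P", "n_snps", "discarded", "discordant"])
    out = df.groupby("gene_id", sort=True).apply(_agg, include_groups=False).reset_index()
    for col in ("M", "P", "n_snps", "discarded"):
        out[col] = out[col].astype(int)
    return out


def assign_alleles(
    pileup: pd.DataFrame,
    snps: pd.DataFrame,
    cross: TrioDesign,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Map per-base pileup counts at SNP sites to maternal/paternal alleles."""
    missing = _BASE_COUNT_COLS - set(pileup.columns)
    if missing:
        raise ValueError(f"base-resolved pileup missing columns: {sorted(missing)}")
    snp = snps.copy()
    for par in (cross.maternal, cross.paternal):
        if f"gt_{par}" not in snp.columns:
            raise ValueError(f"SNP table lacks genotypes for parent {par!r}")
    am = np.where(snp[f"gt_{cross.maternal}"] == "RR", snp["ref"], snp["alt"])
    ap = np.where(snp[f"gt_{cross.paternal}"] == "RR", snp["ref"], snp["alt"])
    if np.any(am == ap):
        raise ValueError(
            "SNP table contains sites whose alleles do not differ between the "
            "cross parents; filter to discriminating sites first"
        )
    snp["allele_maternal"] = am
    snp["allele_paternal"] = ap
    keep = ["chrom", "pos", "allele_maternal", "allele_paternal"]
    if "gene_id" in snp.columns:
        keep.append("gene_id")
    merged = pileup.merge(snp[keep], on=["chrom", "pos"], how="inner")

    base_counts = merged[[f"count_{b}" for b in "ACGT"]].to_numpy(int)
    base_index = {b: i for i, b in enumerate("ACGT")}
    mi = np.array([base_index[b] for b in merged["allele_maternal"]])
    pi = np.array([base_index[b] for b in merged["allele_paternal"]])
    rows = np.arange(len(merged))
    cm = base_counts[rows, mi]
    cp = base_counts[rows, pi]
    merged["count_maternal"] = cm
    merged["count_paternal"] = cp
    merged["discarded"] = base_counts.sum(axis=1) - cm - cp

    if "gene_id" not in merged.columns:
        if genes is None:
            raise ValueError("SNP table lacks gene_id and no gene table was given")
        merged = _annotate_genes(merged, genes)
    return merged


def _annotate_genes(df: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach gene_id to positions via 1-based closed gene intervals."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(
            int(g["start"]), int(g["end"]) + 1, g["gene_id"]
        )
    ids = []
    for chrom, pos in zip(df["chrom"], df["pos"]):
        hits = trees.get(chrom, IntervalTree())[int(pos)]
        ids.append(next(iter(hits)).data if hits else None)
    out = df.copy()
    out["gene_id"] = ids
    return out


def allele_fraction(
    M: int, P: int, thresholds: AseThresholds | None = None
) -> tuple[float, float]:
    """(maternal fraction, major/minor allele ratio) for one gene.

    The minor side is replaced by ``zero_substitute`` when zero. Raises on
    M + P == 0 (no informative reads — nothing to express).
    """
    thresholds = thresholds or AseThresholds()
    if M < 0 or P < 0:
        raise ValueError("allele counts must be non-negative")
    total = M + P
    if total == 0:
        raise ValueError("no informative reads (M + P = 0)")
    frac = M / total
    hi, lo = max(M, P), min(M, P)
    ratio = hi / (lo if lo > 0 else thresholds.zero_substitute)
    return frac, ratio


def classify_ase(
    M: int, P: int, thresholds: AseThresholds | None = None
) -> tuple[str, str | None]:
    """Classify one gene's allelic expression from its (M, P) read counts.

    Returns (class, favored role) with role in {"maternal", "paternal",
    None}. Monoallelic and preferential calls favor the major allele;
    biallelic and unclassified calls favor none.
    """
    thresholds = thresholds or AseThresholds()
    if M < 0 or P < 0:
        raise ValueError("allele counts must be non-negative")
    if M + P < thresholds.min_reads:
        return "unclassified", None
    major = "maternal" if M > P else "paternal"
    if min(M, P) <= thresholds.mono_max_minor_reads:
        return "monoallelic", major
    _, ratio = allele_fraction(M, P, thresholds)
    if ratio > thresholds.bias_fold:
        return "preferential", major
    return "biallelic", None


def classify_ase_table(
    counts: pd.DataFrame,
    thresholds: AseThresholds | None = None,
    cross: TrioDesign | None = None,
) -> pd.DataFrame:
    """Classify every gene in a (gene_id, M, P, ...) counts table.

    Adds maternal_fraction, ratio, ase_class, favored_role and — when a
    cross design is supplied — favored_genotype (the variety whose allele
    dominates, resolving maternal/paternal role through the cross).
    """
    thresholds = thresholds or AseThresholds()
    out = counts.copy()
    cls, role, frac, ratio = [], [], [], []
    for m, p in zip(out["M"].astype(int), out["P"].astype(int)):
        c, r = classify_ase(m, p, thresholds)
        cls.append(c)
        role.append(r)
        if m + p > 0:
            f, q = allele_fraction(m, p, thresholds)
        else:
            f, q = np.nan, np.nan
        frac.append(f)
        ratio.append(q)
    out["maternal_fraction"] = frac
    out["ratio"] = ratio
    out["ase_class"] = cls
    out["favored_role"] = role
    if cross is not None:
        out["favored_genotype"] = [
            (cross.maternal if r == "maternal" else cross.paternal) if r else None
            for r in role
        ]
    return out


def parent_of_origin_balance(counts: pd.DataFrame) -> tuple[float, float]:
    """Genome-wide maternal read fraction and a two-sided binomial test vs 0.5.

    Pools M and P over all genes in the table. Returns (fraction, p-value).
    """
    m = int(counts["M"].sum())
    p = int(counts["P"].sum())
    if m + p == 0:
        raise ValueError("no informative reads in any gene")
    res = stats.binomtest(m, m + p, 0.5, alternative="two-sided")
    return m / (m + p), res.pvalue
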