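"""Bayesian genotype calling and SNP reliability filtering.

Genotypes at candidate sites are called from pileup base observations with a
per-base Phred error model and a uniform prior over {RR, RA, AA}. Candidate
SNPs then pass through six reliability criteria (consensus quality, spacing,
supporting reads, depth cap, distance from intron–exon junctions, flanking
copy number) before parent-discriminating sets are formed from pairs of
inbred parents called as opposite homozygotes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PileupSite",
    "SnpFilterConfig",
    "GenotypeCall",
    "genotype_posterior",
    "apply_snp_filters",
    "parent_discriminating_snps",
    "filter_reads",
    "FILTER_CRITERIA",
]

GENOTYPES = ("RR", "RA", "AA")

#: Criterion keys, in the order the rejection tally reports them.
FILTER_CRITERIA = (
    "quality",
    "spacing",
    "min_reads",
    "max_depth",
    "junction",
    "copy_number",
)


@dataclass
class PileupSite:
    """Base observations at one candidate site.

    ``observations`` is a list of (base, Phred quality) pairs; ``depth`` is
    implied by its length. ``flank_copy_number`` is the approximate copy
    number of the flanking sequence (repeat proxy); ``dist_to_junction_bp``
    the distance to the nearest intron–exon boundary.
    """

    chrom: str
    pos: int
    ref_base: str
    observations: list[tuple[str, int]]
    flank_copy_number: float = 1.0
    dist_to_junction_bp: int = 10**9

    def __post_init__(self) -> None:
        if any(q < 0 for _, q in self.observations):
            raise ValueError("Phred qualities must be non-negative")

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class SnpFilterConfig:
    """The six SNP reliability thresholds.

    Defaults: consensus quality >= 20, candidate spacing >= 5 bp, >= 4
    supporting reads, depth < 10,000, > 5 bp from an intron-exon junction,
    flanking copy number < 4.
    """

    min_quality: int = 20
    min_spacing_bp: int = 5
    min_reads: int = 4
    max_depth: int = 10_000
    min_junction_dist_bp: int = 5
    max_copy_number: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "min_quality",
            "min_spacing_bp",
            "min_reads",
            "max_depth",
            "min_junction_dist_bp",
            "max_copy_number",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GenotypeCall:
    """Posterior over {RR, RA, AA} at one site, plus the consensus quality.

    ``quality`` is the Phred-scaled posterior probability that the best
    genotype is wrong, capped at 1000.
    """

    best: str
    posteriors: dict[str, float]
    alt_base: str
    quality: float
    depth: int

    @property
    def is_het(self) -> bool:
        return self.best == "RA"


def genotype_posterior(site: PileupSite) -> GenotypeCall | None:
    """Posterior genotype call at *site* under a per-base error model.

    Each read base contributes likelihood (1 - e) when it matches a genotype
    allele and e/3 otherwise, with e the Phred error probability of that
    base; a heterozygote emits each of its alleles with probability 1/2. The
    prior over {RR, RA, AA} is uniform. Returns ``None`` (no-call) at zero
    depth.
    """
    if site.depth == 0:
        return None
    ref = site.ref_base
    bases = [b for b, _ in site.observations]
    non_ref = [b for b in bases if b != ref]
    if non_ref:
        counts: dict[str, int] = {}
        for b in non_ref:
            counts[b] = counts.get(b, 0) + 1
        alt = min(counts, key=lambda b: (-counts[b], b))
    else:
        alt = next(b for b in "ACGT" if b != ref)

    loglik = {g: 0.0 for g in GENOTYPES}
    for b, q in site.observations:
        e = 10.0 ** (-q / 10.0)
        p_ref = (1.0 - e) if b == ref else e / 3.0
        p_alt = (1.0 - e) if b == alt else e / 3.0
        loglik["RR"] += math.log(p_ref)
        loglik["AA"] += math.log(p_alt)
        loglik["RA"] += math.log(0.5 * p_ref + 0.5 * p_alt)

    mx = max(loglik.values())
    w = {g: math.exp(v - mx) for g, v in loglik.items()}
    z = sum(w.values())
    post = {g: w[g] / z for g in GENOTYPES}
    best = max(GENOTYPES, key=lambda g: post[g])
    err = max(1.0 - post[best], 1e-100)
    quality = min(-10.0 * math.log10(err), 1000.0)
    return GenotypeCall(best=best, posteriors=post, alt_base=alt, quality=quality, depth=site.depth)


REQUIRED_CANDIDATE_COLUMNS = (
    "chrom",
    "pos",
    "quality",
    "supporting_reads",
    "depth",
    "dist_to_junction_bp",
    "flank_copy_number",
)


def apply_snp_filters(
    candidates: pd.DataFrame, config: SnpFilterConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the six reliability criteria; return (passing, rejection tally).

    A candidate passes iff

    1. ``quality >= min_quality``
    2. every other candidate on the same chromosome is at least
       ``min_spacing_bp`` away (both members of a close pair are rejected)
    3. ``supporting_reads >= min_reads``
    4. ``depth < max_depth``
    5. ``dist_to_junction_bp > min_junction_dist_bp``
    6. ``flank_copy_number < max_copy_number``

    The tally counts, per criterion, how many candidates violated it; a
    candidate violating several criteria increments each.

    *candidates* must be sorted by (chrom, pos) — the spacing check relies
    on adjacency.
    """
    config = config or SnpFilterConfig()
    missing = [c for c in REQUIRED_CANDIDATE_COLUMNS if c not in candidates.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    n = len(candidates)
    if n == 0:
        return candidates.copy(), {k: 0 for k in FILTER_CRITERIA}

    chrom = candidates["chrom"].to_numpy()
    pos = candidates["pos"].to_numpy()
    order_ok = all(
        (chrom[i] < chrom[i + 1]) or (chrom[i] == chrom[i + 1] and pos[i] <= pos[i + 1])
        for i in range(n - 1)
    )
    if not order_ok:
        raise ValueError("candidates must be sorted by (chrom, pos)")

    ok_quality = candidates["quality"].to_numpy() >= config.min_quality
    ok_reads = candidates["supporting_reads"].to_numpy() >= config.min_reads
    ok_depth = candidates["depth"].to_numpy() < config.max_depth
    ok_junction = candidates["dist_to_junction_bp"].to_numpy() > config.min_junction_dist_bp
    ok_copy = candidates["flank_copy_number"].to_numpy() < config.max_copy_number

    ok_spacing = np.ones(n, dtype=bool)
    same_prev = np.zeros(n, dtype=bool)
    same_prev[1:] = (chrom[1:] == chrom[:-1]) & (pos[1:] - pos[:-1] < config.min_spacing_bp)
    ok_spacing[1:] &= ~same_prev[1:]
    ok_spacing[:-1] &= ~same_prev[1:]

    tally = {
        "quality": int((~ok_quality).sum()),
        "spacing": int((~ok_spacing).sum()),
        "min_reads": int((~ok_reads).sum()),
        "max_depth": int((~ok_depth).sum()),
        "junction": int((~ok_junction).sum()),
        "copy_number": int((~ok_copy).sum()),
    }
    passing = candidates.loc[
        ok_quality & ok_spacing & ok_reads & ok_depth & ok_junction & ok_copy
    ].copy()
    return passing.reset_index(drop=True), tally


def parent_discriminating_snps(
    parent_a: pd.DataFrame, parent_b: pd.DataFrame
) -> pd.DataFrame:
    """Sites where two inbred parents are opposite homozygotes.

    Inputs are per-parent tables with columns (chrom, pos, ref, alt,
    genotype) where genotype is one of RR/RA/AA; heterozygous calls
    (residual heterozygosity, impossible in a true inbred) are dropped. The
    result carries ``gt_a`` / ``gt_b`` plus the allele each parent carries.
    """
    a = parent_a.loc[parent_a["genotype"].isin(("RR", "AA"))]
    b = parent_b.loc[parent_b["genotype"].isin(("RR", "AA"))]
    merged = a.merge(
        b[["chrom", "pos", "ref", "alt", "genotype"]],
        on=["chrom", "pos", "ref", "alt"],
        suffixes=("_a", "_b"),
    )
    disc = merged.loc[merged["genotype_a"] != merged["genotype_b"]].copy()
    disc = disc.rename(columns={"genotype_a": "gt_a", "genotype_b": "gt_b"})
    disc["allele_a"] = np.where(disc["gt_a"] == "RR", disc["ref"], disc["alt"])
    disc["allele_b"] = np.where(disc["gt_b"] == "RR", disc["ref"], disc["alt"])
    return disc.reset_index(drop=True)


def filter_reads(records, adaptors=(), *, max_n_fraction=0.10, min_quality=5, max_low_q_fraction=0.5):
    """Quality-filter FASTQ records (Biopython ``SeqRecord`` objects).

    A read is discarded iff it consists of adaptor sequence only, its
    fraction of unknown (N) bases exceeds ``max_n_fraction``, or more than
    ``max_low_q_fraction`` of its bases score below ``min_quality``. Yields
    the surviving records.
    """
    doubled = [a.upper() * 2 for a in adaptors if a]
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(seq):
            raise ValueError(f"record {rec.id}: sequence/quality length mismatch")
        if not seq:
            continue
        if any(seq in d for d in doubled):
            continue
        if seq.count("N") / len(seq) > max_n_fraction:
            continue
        low = sum(1 for q in quals if q < min_quality)
        if low / len(seq) > max_low_q_fraction:
            continue
        out.append(rec)
    return out
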