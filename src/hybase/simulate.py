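"""Synthetic F1 hybrid transcriptomes with known regulatory ground truth.

The generator emulates the statistical structure an allele-specific
expression (ASE) analysis of inbred-parent F1 hybrids assumes:

* inbred parental genotypes that are opposite homozygotes at gene-body SNPs;
* parental expression programs with log-scale divergence, including genes
  silent in exactly one parent;
* F1 allelic read counts produced under configurable regulatory
  architectures — *cis* (the F1 allelic ratio mirrors the parental
  expression ratio), *trans* (the F1 ratio is 1 despite parental
  divergence), and *genotype-dependent monoallelic* (only the allele from a
  fixed parental genotype is expressed, in both reciprocal orientations);
* biomass phenotypes with a tunable mid-parent heterosis level.

Counts are simulated directly at informative-SNP resolution: the analysis
consumes allele counts, not reads, so no read sequences or aligner are
involved. All draws come from seeded sub-streams keyed by (purpose, sample,
gene), so a fixed seed reproduces every table exactly and adding a cross
does not perturb another cross's counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DEFAULT_PARENTS, TrioDesign

__all__ = [
    "SimConfig",
    "ParentalData",
    "simulate_parents",
    "simulate_f1_counts",
    "simulate_phenotypes",
    "write_fixture_bundle",
]

LABELS = ("neutral", "cis", "trans", "genotype_dependent_mono", "parent_silent")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Expression is parameterised on the log2 RPKM scale; informative depth is
    the mean number of allele-assignable reads per gene in one F1 sample.
    ``frac_cis`` and ``frac_trans`` partition the genes that are neither
    parent-silent nor genotype-dependent-monoallelic; whatever probability
    mass remains is neutral (no parental divergence, balanced alleles).
    """

    n_genes: int = 2000
    snps_per_gene_mean: float = 4.0
    gene_length_bp: tuple[int, int] = (500, 3000)
    parental_log2_expression: tuple[float, float] = (4.0, 2.0)
    frac_parent_silent: float = 0.03
    frac_cis: float = 0.40
    frac_trans: float = 0.25
    frac_genotype_dependent_mono: float = 0.02
    depth_mean: float = 50.0
    overdispersion: float = 0.0
    mph_target: float = 20.0
    seed: int = 0
    # secondary knobs; defaults are part of the study conditions
    divergence_log2_sd: float = 1.5
    frac_nonadditive: float = 0.0
    nonadditive_fold: float = 8.0
    library_size: int = 5_000_000
    phenotype_noise_sd: float = 0.5
    phenotype_replicates: int = 30
    parents: tuple[str, ...] = DEFAULT_PARENTS

    def __post_init__(self) -> None:
        for name in (
            "frac_parent_silent",
            "frac_cis",
            "frac_trans",
            "frac_genotype_dependent_mono",
            "frac_nonadditive",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_cis + self.frac_trans > 1.0 + 1e-12:
            raise ValueError("frac_cis + frac_trans must not exceed 1")
        if self.frac_parent_silent + self.frac_genotype_dependent_mono > 1.0 + 1e-12:
            raise ValueError(
                "frac_parent_silent + frac_genotype_dependent_mono must not exceed 1"
            )
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must lie in [0, 1)")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if self.snps_per_gene_mean <= 0:
            raise ValueError("snps_per_gene_mean must be positive")
        lo, hi = self.gene_length_bp
        if lo < 1 or hi < lo:
            raise ValueError("gene_length_bp must be a non-empty positive range")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if len(self.parents) < 2:
            raise ValueError("need at least two parents")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_length_bp"] = list(self.gene_length_bp)
        d["parental_log2_expression"] = list(self.parental_log2_expression)
        d["parents"] = list(self.parents)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _rng(seed: int, *key: object) -> np.random.Generator:
    """Deterministic sub-stream keyed by (seed, *key)."""
    tag = zlib.crc32("/".join(str(k) for k in key).encode())
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag])


@dataclass
class ParentalData:
    """Everything :func:`simulate_parents` produces, plus the truth table."""

    config: SimConfig
    reference: dict[str, str]
    genes: pd.DataFrame  # gene_id, chrom, start, end, length
    snps: pd.DataFrame  # chrom, pos, gene_id, ref, alt, gt_<parent>...
    expression: pd.DataFrame  # gene_id, rpkm_<parent>, reads_<parent>
    truth: pd.DataFrame

    def discriminating_snps(self, cross: TrioDesign) -> pd.DataFrame:
        """Sites where the cross's two parents are opposite homozygotes.

        With inbred parents every genotype is homozygous, so a site
        discriminates exactly when the two parents carry different alleles.
        Adds ``allele_maternal`` / ``allele_paternal`` columns.
        """
        gm = self.snps[f"gt_{cross.maternal}"]
        gp = self.snps[f"gt_{cross.paternal}"]
        disc = self.snps.loc[gm.values != gp.values].copy()
        for role, col in (("maternal", gm), ("paternal", gp)):
            alleles = np.where(
                col.loc[disc.index].values == "RR", disc["ref"], disc["alt"]
            )
            disc[f"allele_{role}"] = alleles
        return disc.reset_index(drop=True)

    def true_maternal_fraction(self, cross: TrioDesign) -> pd.Series:
        """Ground-truth F1 maternal allele fraction per gene for *cross*."""
        return _true_fraction(self.truth, cross)


def _true_fraction(truth: pd.DataFrame, cross: TrioDesign) -> pd.Series:
    em = truth[f"expr_{cross.maternal}"].to_numpy(float)
    ep = truth[f"expr_{cross.paternal}"].to_numpy(float)
    label = truth["label"].to_numpy()
    frac = np.full(len(truth), 0.5)

    tot = em + ep
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_frac = np.where(tot > 0, em / np.where(tot > 0, tot, 1.0), np.nan)
    # cis genes: allelic ratio mirrors the parental expression ratio
    is_cis = label == "cis"
    frac[is_cis] = ratio_frac[is_cis]
    # parent-silent genes behave cis: the silent allele stays silent in F1
    silent = truth["silent_parent"].to_numpy(object)
    is_sil = label == "parent_silent"
    frac[is_sil & (silent == cross.maternal)] = 0.0
    frac[is_sil & (silent == cross.paternal)] = 1.0
    # genotype-dependent monoallelic: the source parent's allele, whichever
    # role that parent plays; crosses not carrying the source are balanced
    src = truth["gdm_source"].to_numpy(object)
    is_gdm = label == "genotype_dependent_mono"
    frac[is_gdm & (src == cross.maternal)] = 1.0
    frac[is_gdm & (src == cross.paternal)] = 0.0
    # genes with no expression in either parent have no defined fraction
    frac[tot == 0] = np.nan
    return pd.Series(frac, index=truth.index, name="true_maternal_fraction")


_BASES = np.array(list("ACGT"))


def simulate_parents(config: SimConfig) -> ParentalData:
    """Draw reference, gene models, parental SNPs, expression and truth.

    Gene models are non-overlapping, 1-based closed intervals laid tandem on
    one chromosome with fixed 200-bp spacers. Each gene receives a
    Poisson-distributed number of SNPs at distinct positions; each parent is
    homozygous ref or alt with probability 1/2 at every site independently
    (inbred lines from a shared ancestral pool).
    """
    cfg = config
    parents = list(cfg.parents)
    rng_layout = _rng(cfg.seed, "layout")

    n = cfg.n_genes
    lo, hi = cfg.gene_length_bp
    lengths = rng_layout.integers(lo, hi + 1, size=n)
    gap = 200
    starts = np.empty(n, dtype=np.int64)
    pos = 1
    for i, L in enumerate(lengths):
        starts[i] = pos
        pos += int(L) + gap
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(n)])
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chr1",
            "start": starts,
            "end": starts + lengths - 1,
            "length": lengths,
        }
    )

    total_len = int(pos - 1) if n else 0
    seq = rng_layout.choice(_BASES, size=total_len) if total_len else np.array([], dtype="<U1")
    reference = {"chr1": "".join(seq)}

    # SNPs
    rng_snp = _rng(cfg.seed, "snps")
    n_snps = rng_snp.poisson(cfg.snps_per_gene_mean, size=n)
    rows = []
    for i in range(n):
        k = min(int(n_snps[i]), int(lengths[i]))
        if k == 0:
            continue
        offs = np.sort(rng_snp.choice(int(lengths[i]), size=k, replace=False))
        for off in offs:
            p = int(starts[i]) + int(off)
            ref_base = reference["chr1"][p - 1]
            alt_base = rng_snp.choice([b for b in "ACGT" if b != ref_base])
            rows.append((("chr1"), p, gene_ids[i], ref_base, alt_base))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "ref", "alt"])
    for par in parents:
        gts = np.where(rng_snp.random(len(snps)) < 0.5, "RR", "AA")
        snps[f"gt_{par}"] = gts

    # generative labels
    rng_lab = _rng(cfg.seed, "labels")
    u = rng_lab.random(n)
    label = np.full(n, "neutral", dtype=object)
    p_sil = cfg.frac_parent_silent
    p_gdm = cfg.frac_genotype_dependent_mono
    label[u < p_sil] = "parent_silent"
    label[(u >= p_sil) & (u < p_sil + p_gdm)] = "genotype_dependent_mono"
    rest = u >= p_sil + p_gdm
    v = rng_lab.random(n)
    label[rest & (v < cfg.frac_cis)] = "cis"
    label[rest & (v >= cfg.frac_cis) & (v < cfg.frac_cis + cfg.frac_trans)] = "trans"

    silent_parent = np.full(n, "", dtype=object)
    idx_sil = np.flatnonzero(label == "parent_silent")
    silent_parent[idx_sil] = rng_lab.choice(parents, size=idx_sil.size)
    gdm_source = np.full(n, "", dtype=object)
    idx_gdm = np.flatnonzero(label == "genotype_dependent_mono")
    gdm_source[idx_gdm] = rng_lab.choice(parents, size=idx_gdm.size)

    nonadd = rng_lab.random(n) < cfg.frac_nonadditive

    # parental expression (RPKM scale, log-normal)
    rng_expr = _rng(cfg.seed, "expression")
    mu, sd = cfg.parental_log2_expression
    base = rng_expr.normal(mu, sd, size=n)
    expr = {}
    divergent = (label == "cis") | (label == "trans")
    for par in parents:
        delta = np.zeros(n)
        delta[divergent] = rng_expr.normal(0.0, cfg.divergence_log2_sd, size=int(divergent.sum()))
        level = np.power(2.0, base + delta)
        level[(label == "parent_silent") & (silent_parent == par)] = 0.0
        expr[par] = level

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "label": label,
            "silent_parent": silent_parent,
            "gdm_source": gdm_source,
            "nonadditive": nonadd,
            "length": lengths,
        }
    )
    for par in parents:
        truth[f"expr_{par}"] = expr[par]

    # parental read counts: Poisson around the RPKM-implied rate
    expression = pd.DataFrame({"gene_id": gene_ids})
    for par in parents:
        lam = expr[par] * (lengths / 1e3) * (cfg.library_size / 1e6)
        rng_cnt = _rng(cfg.seed, "counts", par)
        reads = rng_cnt.poisson(lam) if n else np.array([], dtype=np.int64)
        expression[f"reads_{par}"] = reads
        expression[f"rpkm_{par}"] = expr[par]
    expression["length"] = lengths

    return ParentalData(
        config=cfg,
        reference=reference,
        genes=genes,
        snps=snps,
        expression=expression,
        truth=truth,
    )


def _betabinom_draw(
    rng: np.random.Generator, depth: np.ndarray, frac: np.ndarray, rho: float
) -> np.ndarray:
    """Maternal counts: binomial when rho == 0, beta-binomial otherwise.

    rho is the beta-binomial intra-class correlation; fractions of exactly
    0 or 1 are degenerate and emit a single allele regardless of rho.
    """
    out = np.zeros(len(depth), dtype=np.int64)
    interior = (frac > 0.0) & (frac < 1.0) & (depth > 0)
    if rho <= 0.0:
        out[interior] = rng.binomial(depth[interior], frac[interior])
    else:
        conc = (1.0 - rho) / rho
        a = frac[interior] * conc
        b = (1.0 - frac[interior]) * conc
        out[interior] = stats.betabinom.rvs(
            depth[interior], a, b, random_state=rng
        )
    out[frac >= 1.0] = depth[frac >= 1.0]
    return out


def simulate_f1_counts(
    parents: ParentalData, config: SimConfig, cross: TrioDesign
) -> pd.DataFrame:
    """Per-SNP allelic read counts for one F1 sample (pileup-style table).

    Per gene, total informative depth is Poisson(depth_mean) split uniformly
    across the cross's discriminating SNPs; the maternal count at each SNP is
    binomial (or beta-binomial when ``overdispersion > 0``) around the gene's
    true maternal fraction. Genes without discriminating SNPs do not appear.

    Columns: chrom, pos, gene_id, allele_maternal, allele_paternal,
    count_maternal, count_paternal.
    """
    for par in (cross.maternal, cross.paternal):
        if f"gt_{par}" not in parents.snps.columns:
            raise ValueError(f"parent {par!r} not present in simulated SNP table")
    disc = parents.discriminating_snps(cross)
    truth = parents.truth.set_index("gene_id")
    frac_by_gene = _true_fraction(parents.truth, cross)
    frac_by_gene.index = parents.truth["gene_id"]

    rows = []
    rho = config.overdispersion
    for gene_id, grp in disc.groupby("gene_id", sort=True):
        f = frac_by_gene.get(gene_id, np.nan)
        if np.isnan(f):
            continue  # silent in both parents: no transcripts to sample
        rng = _rng(config.seed, "f1", cross.cross_id, gene_id)
        depth = rng.poisson(config.depth_mean)
        k = len(grp)
        split = rng.multinomial(depth, np.full(k, 1.0 / k))
        m = _betabinom_draw(rng, split, np.full(k, f), rho)
        for (_, snp), d_s, m_s in zip(grp.iterrows(), split, m):
            rows.append(
                (
                    snp["chrom"],
                    snp["pos"],
                    gene_id,
                    snp["allele_maternal"],
                    snp["allele_paternal"],
                    int(m_s),
                    int(d_s - m_s),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "gene_id",
            "allele_maternal",
            "allele_paternal",
            "count_maternal",
            "count_paternal",
        ],
    )


def simulate_f1_expression(
    parents: ParentalData, config: SimConfig, cross: TrioDesign
) -> pd.DataFrame:
    """Per-gene F1 total expression and read counts for one cross.

    F1 expression is additive (the mid-parent mean on the RPKM scale) except
    for genes flagged non-additive, whose level is multiplied by
    ``nonadditive_fold`` (upward; the direction is arbitrary but fixed).
    """
    t = parents.truth
    em = t[f"expr_{cross.maternal}"].to_numpy(float)
    ep = t[f"expr_{cross.paternal}"].to_numpy(float)
    f1 = 0.5 * (em + ep)
    f1 = np.where(t["nonadditive"].to_numpy(bool), f1 * config.nonadditive_fold, f1)
    lengths = t["length"].to_numpy(int)
    lam = f1 * (lengths / 1e3) * (config.library_size / 1e6)
    rng = _rng(config.seed, "counts", cross.f1_id)
    reads = rng.poisson(lam) if len(t) else np.array([], dtype=np.int64)
    return pd.DataFrame(
        {
            "gene_id": t["gene_id"],
            "length": lengths,
            "reads_f1": reads,
            "rpkm_f1": f1,
        }
    )


#: Baseline fresh-mass means (g/plant) for the stock parents; dry mass is a
#: fixed fraction typical of rice leaf tissue at the vegetative stage.
_PARENT_FRESH_G = {"GL": 9.0, "TQ": 12.0, "9311": 15.0}
_DRY_FRACTION = 0.22
_DEFAULT_FRESH_G = 10.0


def simulate_phenotypes(
    config: SimConfig, crosses: list[TrioDesign]
) -> pd.DataFrame:
    """Fresh/dry biomass replicates for parents and F1s.

    The F1 mean mass is (1 + mph_target/100) x the mid-parent mean;
    replicates add Gaussian noise with sd ``phenotype_noise_sd`` (grams).
    Negative masses are resampled. ``mph_target`` may be a scalar applied to
    every cross or a mapping ``cross_id -> percent``.
    """
    mph = config.mph_target
    mph_for = (lambda c: float(mph[c.cross_id])) if isinstance(mph, dict) else (
        lambda c: float(mph)
    )

    genotypes: dict[str, float] = {}
    for c in crosses:
        for par in (c.maternal, c.paternal):
            genotypes[par] = _PARENT_FRESH_G.get(par, _DEFAULT_FRESH_G)
    for c in crosses:
        mp = 0.5 * (genotypes[c.maternal] + genotypes[c.paternal])
        genotypes[c.f1_id] = (1.0 + mph_for(c) / 100.0) * mp

    rows = []
    for gid, fresh_mean in genotypes.items():
        rng = _rng(config.seed, "phenotype", gid)
        for rep in range(1, config.phenotype_replicates + 1):
            fresh = _positive_normal(rng, fresh_mean, config.phenotype_noise_sd)
            dry = _positive_normal(
                rng, fresh_mean * _DRY_FRACTION, config.phenotype_noise_sd * _DRY_FRACTION
            )
            rows.append((gid, rep, fresh, dry))
    return pd.DataFrame(rows, columns=["genotype", "replicate", "fresh_mass", "dry_mass"])


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0.0:
            return float(x)
    raise RuntimeError("could not draw a non-negative mass; sd too large for mean")


def write_fixture_bundle(
    parents: ParentalData,
    f1_counts: dict[str, pd.DataFrame],
    phenotypes: pd.DataFrame,
    outdir,
) -> dict:
    """Write one coherent fixture bundle to *outdir* and return the manifest.

    Files: reference.fasta, genes.gff3, snps_<A>_vs_<B>.vcf per parent pair,
    f1_counts_<cross>.tsv, parent_counts.tsv, phenotypes.tsv, truth.tsv,
    manifest.json. The bundle is staged in a temporary sibling directory and
    renamed into place, so a failed write leaves no partial bundle.
    """
    from . import io as hio  # deferred: io imports pysam

    return hio.write_bundle(parents, f1_counts, phenotypes, outdir)
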