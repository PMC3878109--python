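"""Integrative analyses over ASE calls, DEG calls, divergence classes and
phenotypes.

These operations combine the per-stage outputs into the headline hybrid
analyses: genotype-dependence of allelic expression across reciprocal
crosses, attribution of differentially expressed genes to ASE classes,
allelic complementary effects with mid-parent dosage checks, mid-parent
heterosis, and the parent-divergence versus F1-allelic-ratio correlation
that diagnoses cis regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import TrioDesign
from .expression import DegConfig, call_deg

__all__ = [
    "call_genotype_dependence",
    "genotype_dependence_table",
    "attribute_degs",
    "AttributionTable",
    "complementary_effects",
    "mid_parent_heterosis",
    "correlate_parent_f1",
    "correlate_deg_heterosis",
    "nonadditive_fraction",
]

_ASE_BIASED = ("monoallelic", "preferential")
FOLD_BINS = ("<4", "4-10", ">10")


def call_genotype_dependence(
    forward: tuple[str, str | None],
    reciprocal: tuple[str, str | None],
    forward_cross: TrioDesign,
    reciprocal_cross: TrioDesign,
) -> str:
    """Pattern of one gene's allelic bias across a reciprocal cross pair.

    *forward* / *reciprocal* are (ase_class, favored_genotype) pairs from the
    two orientations. Returns one of:

    * ``genotype-dependent`` — the favored allele comes from the same
      parental genotype in both orientations (cis-like, the common case);
    * ``parent-of-origin`` — the favored allele tracks the maternal (or
      paternal) role while the genotype flips (imprinting-like);
    * ``inconsistent`` — favored in both orientations but matching neither
      pattern (possible only with asymmetric thresholds) or favoring
      different genotypes without a role match;
    * ``untestable`` — either orientation is biallelic or unclassified.
    """
    if not forward_cross.is_reciprocal_of(reciprocal_cross):
        raise ValueError(
            f"{forward_cross.cross_id} and {reciprocal_cross.cross_id} are not "
            "a reciprocal pair"
        )
    (cls_f, gt_f), (cls_r, gt_r) = forward, reciprocal
    if cls_f not in _ASE_BIASED or cls_r not in _ASE_BIASED:
        return "untestable"
    if gt_f is None or gt_r is None:
        return "untestable"
    role_f = forward_cross.parent_role(gt_f)
    role_r = reciprocal_cross.parent_role(gt_r)
    if gt_f == gt_r:
        return "genotype-dependent"
    if role_f == role_r:
        return "parent-of-origin"
    return "inconsistent"


def genotype_dependence_table(
    forward_calls: pd.DataFrame,
    reciprocal_calls: pd.DataFrame,
    forward_cross: TrioDesign,
    reciprocal_cross: TrioDesign,
) -> pd.DataFrame:
    """Apply :func:`call_genotype_dependence` gene-by-gene.

    Inputs are classified tables (gene_id, ase_class, favored_genotype);
    genes present in only one orientation are untestable.
    """
    f = forward_calls.set_index("gene_id")
    r = reciprocal_calls.set_index("gene_id")
    all_genes = sorted(set(f.index) | set(r.index))
    rows = []
    for g in all_genes:
        if g in f.index and g in r.index:
            pattern = call_genotype_dependence(
                (f.at[g, "ase_class"], f.at[g, "favored_genotype"]),
                (r.at[g, "ase_class"], r.at[g, "favored_genotype"]),
                forward_cross,
                reciprocal_cross,
            )
            fwd = (f.at[g, "ase_class"], f.at[g, "favored_genotype"])
            rec = (r.at[g, "ase_class"], r.at[g, "favored_genotype"])
        else:
            pattern, fwd, rec = "untestable", (None, None), (None, None)
        rows.append((g, pattern, fwd[0], fwd[1], rec[0], rec[1]))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "pattern",
            "class_forward",
            "origin_forward",
            "class_reciprocal",
            "origin_reciprocal",
        ],
    )


@dataclass
class AttributionTable:
    """Cross-tabulation of ASE class x DEG status x fold-difference bin.

    ``by_class``: per ASE class, gene count, DEG count, percent DEG, and the
    class's share of all DEGs. ``fold_bins``: among DEGs of each class, the
    distribution over F1-vs-parent fold bins (<4, 4-10, >10). ``
    parent_silent``: per class, genes expressed in the F1 but silent in one
    parent (divergence class IV), and the share of those that are DEGs.
    """

    by_class: pd.DataFrame
    fold_bins: pd.DataFrame
    parent_silent: pd.DataFrame

    @property
    def n_classified(self) -> int:
        return int(self.by_class["n_genes"].sum())

    @property
    def n_deg(self) -> int:
        return int(self.by_class["n_deg"].sum())


def attribute_degs(
    ase_calls: pd.DataFrame,
    degs: pd.DataFrame,
    divergence: pd.DataFrame | None = None,
) -> AttributionTable:
    """Attribute DEGs to ASE classes, with fold-difference stratification.

    *ase_calls* needs (gene_id, ase_class); unclassified genes are excluded.
    *degs* needs (gene_id, is_deg, fold) where fold is the F1-vs-parent
    ratio in the direction of change (>= 1). *divergence* optionally carries
    (gene_id, divergence_class) to define the parent-silent stratum
    (class IV).
    """
    calls = ase_calls.loc[ase_calls["ase_class"] != "unclassified", ["gene_id", "ase_class"]]
    deg = degs[["gene_id", "is_deg", "fold"]].copy()
    deg["fold_dir"] = np.maximum(deg["fold"], 1.0 / deg["fold"])
    merged = calls.merge(deg, on="gene_id", how="left")
    merged["is_deg"] = merged["is_deg"].fillna(False).astype(bool)

    classes = ["monoallelic", "preferential", "biallelic"]
    total_deg = int(merged["is_deg"].sum())
    rows = []
    for c in classes:
        sub = merged.loc[merged["ase_class"] == c]
        n, nd = len(sub), int(sub["is_deg"].sum())
        rows.append(
            {
                "ase_class": c,
                "n_genes": n,
                "n_deg": nd,
                "pct_deg": 100.0 * nd / n if n else 0.0,
                "pct_of_total_genes": 100.0 * n / len(merged) if len(merged) else 0.0,
                "pct_of_degs": 100.0 * nd / total_deg if total_deg else 0.0,
            }
        )
    by_class = pd.DataFrame(rows)

    bins_rows = []
    for c in classes:
        sub = merged.loc[(merged["ase_class"] == c) & merged["is_deg"]]
        fd = sub["fold_dir"].to_numpy(float)
        n = len(sub)
        counts = {
            "<4": int((fd < 4.0).sum()),
            "4-10": int(((fd >= 4.0) & (fd <= 10.0)).sum()),
            ">10": int((fd > 10.0).sum()),
        }
        row = {"ase_class": c, "n_deg": n}
        for k, v in counts.items():
            row[f"n_{k}"] = v
            row[f"pct_{k}"] = 100.0 * v / n if n else 0.0
        bins_rows.append(row)
    fold_bins = pd.DataFrame(bins_rows)

    if divergence is not None:
        silent = divergence.loc[
            divergence["divergence_class"] == "IV", ["gene_id"]
        ].merge(merged, on="gene_id")
        ps_rows = []
        n_sil = len(silent)
        for c in classes:
            sub = silent.loc[silent["ase_class"] == c]
            ps_rows.append(
                {
                    "ase_class": c,
                    "n_genes": len(sub),
                    "pct_of_parent_silent": 100.0 * len(sub) / n_sil if n_sil else 0.0,
                    "n_deg": int(sub["is_deg"].sum()),
                }
            )
        parent_silent = pd.DataFrame(ps_rows)
    else:
        parent_silent = pd.DataFrame(
            columns=["ase_class", "n_genes", "pct_of_parent_silent", "n_deg"]
        )
    return AttributionTable(by_class=by_class, fold_bins=fold_bins, parent_silent=parent_silent)


def complementary_effects(
    ase_calls: pd.DataFrame,
    divergence: pd.DataFrame,
    expression: pd.DataFrame,
    *,
    dosage_tolerance_fold: float = 1.5,
    pseudo_value: float = 0.001,
) -> pd.DataFrame:
    """Allelic patterns of strongly divergent genes, with dosage checks.

    For genes in divergence classes III (>10-fold parental difference) and
    IV (expressed in one parent only) that received an ASE call, tallies the
    F1 allelic pattern and flags whether the F1 total expression lies within
    ``dosage_tolerance_fold`` of the mid-parent level — the dosage signature
    of complementation under cis control.

    *expression* needs (gene_id, rpkm_f1, rpkm_maternal, rpkm_paternal).
    Returns the per-gene table; aggregate with ``groupby`` as needed.
    """
    calls = ase_calls.loc[
        ase_calls["ase_class"].isin(("monoallelic", "preferential", "biallelic")),
        ["gene_id", "ase_class"],
    ]
    div = divergence.loc[
        divergence["divergence_class"].isin(("III", "IV")),
        ["gene_id", "divergence_class"],
    ]
    merged = div.merge(calls, on="gene_id").merge(expression, on="gene_id")
    mp = 0.5 * (merged["rpkm_maternal"] + merged["rpkm_paternal"])
    f1 = merged["rpkm_f1"].to_numpy(float)
    ratio = np.maximum(f1, pseudo_value) / np.maximum(mp.to_numpy(float), pseudo_value)
    dev = np.maximum(ratio, 1.0 / ratio)
    merged["mid_parent_rpkm"] = mp
    merged["dosage_consistent"] = dev <= dosage_tolerance_fold
    return merged


def mid_parent_heterosis(
    phenotypes: pd.DataFrame, cross: TrioDesign
) -> dict[str, float]:
    """Mid-parent heterosis percentages for fresh and dry mass.

    MPH = 100 x (mean_F1 - MP) / MP with MP the mean of the two parental
    means. Returns NaN for a trait whose mid-parent mean is zero.
    """
    means = phenotypes.groupby("genotype")[["fresh_mass", "dry_mass"]].mean()
    for gid in (cross.maternal, cross.paternal, cross.f1_id):
        if gid not in means.index:
            raise ValueError(f"phenotype table lacks genotype {gid!r}")
    out = {}
    for trait in ("fresh_mass", "dry_mass"):
        mp = 0.5 * (means.at[cross.maternal, trait] + means.at[cross.paternal, trait])
        f1 = means.at[cross.f1_id, trait]
        out[trait] = float("nan") if mp == 0 else 100.0 * (f1 - mp) / mp
    return out


def correlate_parent_f1(
    parental_log_ratio: np.ndarray,
    f1_allelic_log_ratio: np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation between parental expression divergence and F1
    allelic imbalance (both log-scale, zero-substituted upstream).

    Under pure cis regulation the two are equal gene-by-gene (r -> 1);
    under pure trans regulation the F1 ratio is 0 regardless of the
    parental ratio (r -> 0). Returns (r, p); (nan, nan) below 3 genes.
    """
    x = np.asarray(parental_log_ratio, float)
    y = np.asarray(f1_allelic_log_ratio, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def log_ratio(numer, denom, pseudo_value: float = 0.001) -> np.ndarray:
    """log2(numer/denom) with zero sides replaced by *pseudo_value*."""
    a = np.asarray(numer, float)
    b = np.asarray(denom, float)
    return np.log2(np.where(a > 0, a, pseudo_value) / np.where(b > 0, b, pseudo_value))


def correlate_deg_heterosis(
    deg_counts,
    mph_levels,
) -> tuple[float, float]:
    """Pearson r between per-cross DEG totals and per-cross MPH.

    With the usual three crosses this is an n=3 correlation: report it, but
    treat the p-value as descriptive only. Returns (nan, nan) below 3
    crosses.
    """
    x = np.asarray(deg_counts, float)
    y = np.asarray(mph_levels, float)
    if len(x) < 3 or len(x) != len(y):
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def nonadditive_fraction(
    f1: pd.DataFrame,
    parent_a: pd.DataFrame,
    parent_b: pd.DataFrame,
    config: DegConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of genes whose F1 expression deviates from the mid-parent
    expectation.

    A mid-parent pseudo-sample is constructed by scaling each parent's
    counts to the F1 library size and averaging; the F1 is then tested
    against it with the standard DEG machinery (exact test + BH-FDR + fold
    threshold). Inputs are per-gene (gene_id, length, reads) tables.
    Returns (fraction, per-gene DEG table).
    """
    config = config or DegConfig()
    a = parent_a.set_index("gene_id")
    b = parent_b.set_index("gene_id")
    f = f1.set_index("gene_id")
    if not (set(a.index) == set(b.index) == set(f.index)):
        raise ValueError("samples cover different gene universes")
    a = a.reindex(f.index)
    b = b.reindex(f.index)
    n_f1 = f["reads"].sum()
    na, nb = a["reads"].sum(), b["reads"].sum()
    if na == 0 or nb == 0:
        raise ValueError("parent library with zero total reads")
    mp_reads = np.rint(
        0.5 * (a["reads"] * n_f1 / na + b["reads"] * n_f1 / nb)
    ).astype(int)
    mp = pd.DataFrame(
        {"gene_id": f.index, "length": f["length"].to_numpy(), "reads": mp_reads.to_numpy()}
    )
    f1_tbl = pd.DataFrame(
        {"gene_id": f.index, "length": f["length"].to_numpy(), "reads": f["reads"].to_numpy()}
    )
    table = call_deg(f1_tbl, mp, config, total_a=int(n_f1), total_b=int(n_f1))
    frac = float(table["is_deg"].mean()) if len(table) else 0.0
    return frac, table
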