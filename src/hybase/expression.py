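"""Per-gene expression levels, differential expression, and divergence classes.

Expression is quantified as RPKM (reads per kilobase of gene model per
million mapped reads). Differential expression between two count libraries
uses the Audic–Claverie exact test: conditional on the summed count, the
second library's count follows a negative binomial whose tail probabilities
give the p-value; Benjamini–Hochberg controls the FDR across genes. A gene
is differentially expressed when its fold change exceeds the threshold
(default 2.0, strict) at FDR below 0.05. Parental divergence is stratified
into classes I (ratio < 2), II (2–10-fold, inclusive), III (> 10-fold) and
IV (expressed in only one parent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegConfig",
    "rpkm",
    "audic_claverie_pvalue",
    "call_deg",
    "classify_parental_divergence",
    "divergence_classes",
]


@dataclass(frozen=True)
class DegConfig:
    """Thresholds for differential-expression calls.

    ``pseudo_value`` replaces a zero expression level before fold-change
    computation so that ratios against silent genes remain finite.
    """

    fold_threshold: float = 2.0
    fdr_threshold: float = 0.05
    pseudo_value: float = 0.001

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or self.fdr_threshold <= 0 or self.pseudo_value <= 0:
            raise ValueError("all DegConfig thresholds must be positive")


def rpkm(reads, gene_length_bp, total_mapped) -> float | np.ndarray:
    """RPKM = 1e9 * reads / (total mapped reads * gene length in bp)."""
    reads = np.asarray(reads, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if np.any(length < 1):
        raise ValueError("gene length must be >= 1 bp")
    if np.any(total < 1):
        raise ValueError("total mapped reads must be >= 1")
    out = 1e9 * reads / (total * length)
    return float(out) if out.ndim == 0 else out


def audic_claverie_pvalue(x, y, n1, n2):
    """Two-sided Audic–Claverie p-value for counts x (library 1) vs y (library 2).

    Under the null of equal expression, the posterior predictive of *y*
    given *x* is negative binomial with ``r = x + 1`` successes and success
    probability ``n1 / (n1 + n2)``. The two-sided p-value doubles the
    smaller tail (capped at 1). Vectorised over x, y.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    p = float(n1) / (float(n1) + float(n2))
    lower = stats.nbinom.cdf(y, x + 1, p)
    upper = stats.nbinom.sf(y - 1, x + 1, p)
    pval = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(pval) if pval.ndim == 0 else pval


def call_deg(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    config: DegConfig | None = None,
    *,
    total_a: int | None = None,
    total_b: int | None = None,
) -> pd.DataFrame:
    """Differential expression between two samples over a shared gene universe.

    Inputs are per-gene tables with columns ``gene_id``, ``length`` and
    ``reads``; library sizes default to the column sums. Fold changes are
    computed on RPKM (zero side replaced by ``pseudo_value``); the exact
    test runs on the raw counts. Returns a table with rpkm_a, rpkm_b,
    fold (a over b, >= or < 1), log2fc, p, fdr, is_deg.
    """
    config = config or DegConfig()
    a = sample_a.set_index("gene_id")
    b = sample_b.set_index("gene_id")
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("samples cover different gene universes")
        b = b.reindex(a.index)
    if len(a) == 0:
        return pd.DataFrame(
            columns=["gene_id", "rpkm_a", "rpkm_b", "fold", "log2fc", "p", "fdr", "is_deg"]
        )
    if not np.array_equal(a["length"].to_numpy(), b["length"].to_numpy()):
        raise ValueError("gene lengths differ between samples")

    na = int(total_a if total_a is not None else a["reads"].sum())
    nb = int(total_b if total_b is not None else b["reads"].sum())
    rpkm_a = rpkm(a["reads"], a["length"], max(na, 1))
    rpkm_b = rpkm(b["reads"], b["length"], max(nb, 1))

    pa = np.where(rpkm_a > 0, rpkm_a, config.pseudo_value)
    pb = np.where(rpkm_b > 0, rpkm_b, config.pseudo_value)
    log2fc = np.log2(pa / pb)

    p = audic_claverie_pvalue(a["reads"].to_numpy(), b["reads"].to_numpy(), na, nb)
    p = np.atleast_1d(p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    is_deg = (np.abs(log2fc) > np.log2(config.fold_threshold)) & (
        fdr < config.fdr_threshold
    )
    return pd.DataFrame(
        {
            "gene_id": a.index,
            "rpkm_a": rpkm_a,
            "rpkm_b": rpkm_b,
            "fold": pa / pb,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "is_deg": is_deg,
        }
    ).reset_index(drop=True)


def _expressed(rpkm_value: np.ndarray, threshold: float) -> np.ndarray:
    # threshold 0 means "any signal at all" (raw reads >= 1 <=> RPKM > 0)
    if threshold <= 0:
        return np.asarray(rpkm_value) > 0
    return np.asarray(rpkm_value) >= threshold


def classify_parental_divergence(
    rpkm_a: float, rpkm_b: float, expressed_threshold: float = 0.0
) -> str | None:
    """Divergence class of one gene from its two parental RPKM values.

    Returns "I", "II", "III", "IV", or ``None`` when the gene is expressed
    in neither parent (excluded from divergence analysis).
    """
    out = divergence_classes(
        pd.DataFrame({"gene_id": ["g"], "rpkm_a": [rpkm_a], "rpkm_b": [rpkm_b]}),
        expressed_threshold,
    )
    cls = out["divergence_class"].iloc[0]
    return None if cls == "" else cls


def divergence_classes(
    table: pd.DataFrame, expressed_threshold: float = 0.0
) -> pd.DataFrame:
    """Vectorised divergence classification over (gene_id, rpkm_a, rpkm_b).

    Adds ``divergence_class`` (I/II/III/IV, "" when silent in both) and
    ``parental_ratio`` (larger over smaller RPKM; inf when one side is 0,
    NaN when both are).
    """
    ra = table["rpkm_a"].to_numpy(float)
    rb = table["rpkm_b"].to_numpy(float)
    ea = _expressed(ra, expressed_threshold)
    eb = _expressed(rb, expressed_threshold)

    hi = np.maximum(ra, rb)
    lo = np.minimum(ra, rb)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.inf)
    ratio = np.where(hi == 0, np.nan, ratio)

    cls = np.full(len(table), "", dtype=object)
    both = ea & eb
    cls[both & (ratio < 2.0)] = "I"
    cls[both & (ratio >= 2.0) & (ratio <= 10.0)] = "II"
    cls[both & (ratio > 10.0)] = "III"
    cls[ea ^ eb] = "IV"

    out = table.copy()
    out["divergence_class"] = cls
    out["parental_ratio"] = ratio
    return out
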