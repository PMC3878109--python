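"""End-to-end orchestration: simulate (or load), quantify, classify, integrate.

A :class:`PipelineConfig` fully determines a run: the simulation conditions,
the cross designs, and every stage threshold. ``run_pipeline`` executes the
stages in order and returns a :class:`PipelineResult` whose ``summary`` dict
(also written as ``summary.json``) holds per-cross ASE class proportions,
DEG counts, attribution tables, heterosis and the cis-diagnostic
correlations, both per cross and pooled. Outputs are written per stage
through a temp-file rename, so an interrupted run never leaves a truncated
table behind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ase import AseThresholds, classify_ase_table, count_alleles, parent_of_origin_balance
from .design import TrioDesign, default_designs, reciprocal_pairs
from .expression import DegConfig, call_deg, divergence_classes
from .integrate import (
    attribute_degs,
    complementary_effects,
    correlate_deg_heterosis,
    correlate_parent_f1,
    genotype_dependence_table,
    log_ratio,
    mid_parent_heterosis,
    nonadditive_fraction,
)
from .simulate import (
    ParentalData,
    SimConfig,
    simulate_f1_counts,
    simulate_f1_expression,
    simulate_parents,
    simulate_phenotypes,
)
from .variants import SnpFilterConfig

logger = logging.getLogger("hybase")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_summary"]


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    designs: list[TrioDesign] = field(default_factory=default_designs)
    ase_thresholds: AseThresholds = field(default_factory=AseThresholds)
    deg: DegConfig = field(default_factory=DegConfig)
    snp_filters: SnpFilterConfig = field(default_factory=SnpFilterConfig)

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "designs": [dataclasses.asdict(d) for d in self.designs],
            "ase_thresholds": dataclasses.asdict(self.ase_thresholds),
            "deg": dataclasses.asdict(self.deg),
            "snp_filters": dataclasses.asdict(self.snp_filters),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = d.get("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            for key in ("gene_length_bp", "parental_log2_expression", "parents"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        designs = [
            TrioDesign(**dd) if isinstance(dd, dict) else dd
            for dd in d.get("designs", default_designs())
        ]
        return cls(
            sim=sim,
            designs=designs,
            ase_thresholds=AseThresholds(**d.get("ase_thresholds", {})),
            deg=DegConfig(**d.get("deg", {})),
            snp_filters=SnpFilterConfig(**d.get("snp_filters", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    parents: ParentalData
    summary: dict
    tables: dict[str, pd.DataFrame]


def _atomic_write_text(text: str, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_table(df: pd.DataFrame, path: Path) -> None:
    _atomic_write_text(df.to_csv(sep="\t", index=False), path)


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Run the full synthetic analysis described by *config*.

    When *outdir* is given, per-stage TSV tables, ``summary.json``, a
    ``report.md`` and ``run.log`` are written there.
    """
    cfg = config
    sim = cfg.sim
    logger.info("simulating parents: %d genes, seed %d", sim.n_genes, sim.seed)
    parents = simulate_parents(sim)
    phenotypes = simulate_phenotypes(sim, cfg.designs)

    tables: dict[str, pd.DataFrame] = {"phenotypes": phenotypes, "truth": parents.truth}
    per_cross: dict[str, dict] = {}
    ase_by_cross: dict[str, pd.DataFrame] = {}
    pooled_counts = []
    pooled_degs = []
    pooled_div = []

    for cross in cfg.designs:
        logger.info("analysing cross %s", cross.cross_id)
        pileup = simulate_f1_counts(parents, sim, cross)
        counts = count_alleles(pileup)
        calls = classify_ase_table(counts, cfg.ase_thresholds, cross)
        ase_by_cross[cross.cross_id] = calls
        tables[f"ase_{cross.cross_id}"] = calls

        f1_expr = simulate_f1_expression(parents, sim, cross)
        f1_tbl = f1_expr.rename(columns={"reads_f1": "reads"})[["gene_id", "length", "reads"]]

        deg_vs_parent = {}
        for par in (cross.maternal, cross.paternal):
            p_tbl = parents.expression.rename(columns={f"reads_{par}": "reads"})[
                ["gene_id", "length", "reads"]
            ]
            deg_vs_parent[par] = call_deg(f1_tbl, p_tbl, cfg.deg)
        # a gene is a DEG when it differs from either parent; for fold-bin
        # reporting use the comparison with the larger |log2 fold|
        da = deg_vs_parent[cross.maternal]
        db = deg_vs_parent[cross.paternal]
        pick_a = np.abs(da["log2fc"]) >= np.abs(db["log2fc"])
        deg = pd.DataFrame(
            {
                "gene_id": da["gene_id"],
                "is_deg": da["is_deg"] | db["is_deg"],
                "fold": np.where(pick_a, da["fold"], db["fold"]),
                "log2fc": np.where(pick_a, da["log2fc"], db["log2fc"]),
            }
        )
        tables[f"deg_{cross.cross_id}"] = deg

        div = divergence_classes(
            parents.expression.rename(
                columns={f"rpkm_{cross.maternal}": "rpkm_a", f"rpkm_{cross.paternal}": "rpkm_b"}
            )[["gene_id", "rpkm_a", "rpkm_b"]]
        )
        tables[f"divergence_{cross.cross_id}"] = div

        attribution = attribute_degs(calls, deg, div)
        expr_cmp = pd.DataFrame(
            {
                "gene_id": parents.expression["gene_id"],
                "rpkm_f1": f1_expr["rpkm_f1"],
                "rpkm_maternal": parents.expression[f"rpkm_{cross.maternal}"],
                "rpkm_paternal": parents.expression[f"rpkm_{cross.paternal}"],
            }
        )
        comp = complementary_effects(calls, div, expr_cmp, pseudo_value=cfg.deg.pseudo_value)
        tables[f"complementary_{cross.cross_id}"] = comp

        # cis diagnostic: parental divergence vs F1 allelic imbalance
        joined = calls.merge(expr_cmp, on="gene_id")
        analyzable = joined.loc[joined["ase_class"] != "unclassified"]
        x = log_ratio(analyzable["rpkm_maternal"], analyzable["rpkm_paternal"], cfg.deg.pseudo_value)
        y = log_ratio(analyzable["M"], analyzable["P"], cfg.deg.pseudo_value)
        r_all, p_all = correlate_parent_f1(x, y)
        ase_only = analyzable["ase_class"].isin(("monoallelic", "preferential")).to_numpy()
        r_ase, _ = correlate_parent_f1(x[ase_only], y[ase_only])

        p1 = parents.expression.rename(columns={f"reads_{cross.maternal}": "reads"})[
            ["gene_id", "length", "reads"]
        ]
        p2 = parents.expression.rename(columns={f"reads_{cross.paternal}": "reads"})[
            ["gene_id", "length", "reads"]
        ]
        nonadd_frac, _ = nonadditive_fraction(f1_tbl, p1, p2, cfg.deg)

        mph = mid_parent_heterosis(phenotypes, cross)
        classified = calls.loc[calls["ase_class"] != "unclassified"]
        n_classified = len(classified)
        props = {
            c: (float((classified["ase_class"] == c).sum()) / n_classified if n_classified else 0.0)
            for c in ("monoallelic", "preferential", "biallelic")
        }
        balance_frac, balance_p = parent_of_origin_balance(counts) if len(counts) else (float("nan"), float("nan"))

        per_cross[cross.cross_id] = {
            "n_genes_with_counts": int(len(counts)),
            "n_analyzable": n_classified,
            "ase_proportions": props,
            "deg_count": int(deg["is_deg"].sum()),
            "attribution": {
                "by_class": attribution.by_class.to_dict(orient="records"),
                "fold_bins": attribution.fold_bins.to_dict(orient="records"),
                "parent_silent": attribution.parent_silent.to_dict(orient="records"),
            },
            "maternal_read_fraction": balance_frac,
            "parent_of_origin_p": balance_p,
            "parent_f1_r_all": r_all,
            "parent_f1_r_ase": r_ase,
            "nonadditive_fraction": nonadd_frac,
            "mph_fresh_pct": mph["fresh_mass"],
            "mph_dry_pct": mph["dry_mass"],
        }
        classified_counts = classified[["gene_id", "M", "P", "ase_class"]].copy()
        classified_counts["cross"] = cross.cross_id
        pooled_counts.append(classified_counts)
        deg2 = deg.copy()
        deg2["cross"] = cross.cross_id
        pooled_degs.append(deg2)
        div2 = div.copy()
        div2["cross"] = cross.cross_id
        pooled_div.append(div2)

    # reciprocal-cross genotype dependence
    genotype_dependence = {}
    by_id = {d.cross_id: d for d in cfg.designs}
    for fwd, rec in reciprocal_pairs(cfg.designs):
        gd = genotype_dependence_table(
            ase_by_cross[fwd.cross_id], ase_by_cross[rec.cross_id], fwd, rec
        )
        tables[f"genotype_dependence_{fwd.cross_id}"] = gd
        testable = gd.loc[gd["pattern"] != "untestable"]
        genotype_dependence[fwd.cross_id] = {
            "n_testable": int(len(testable)),
            "n_genotype_dependent": int((testable["pattern"] == "genotype-dependent").sum()),
            "n_parent_of_origin": int((testable["pattern"] == "parent-of-origin").sum()),
            "n_inconsistent": int((testable["pattern"] == "inconsistent").sum()),
        }

    # pooled statistics across crosses
    if pooled_counts:
        pool = pd.concat(pooled_counts, ignore_index=True)
        n_pool = len(pool)
        pooled_props = {
            c: float((pool["ase_class"] == c).sum()) / n_pool
            for c in ("monoallelic", "preferential", "biallelic")
        }
        deg_pool = pd.concat(pooled_degs, ignore_index=True)
        ase_pool = pool.rename(columns={"cross": "_cross"})
        merged = ase_pool.merge(
            deg_pool.rename(columns={"cross": "_cross"}), on=["gene_id", "_cross"], how="left"
        )
        merged["is_deg"] = merged["is_deg"].fillna(False).astype(bool)
        biased = merged["ase_class"].isin(("monoallelic", "preferential"))
        n_deg = int(merged["is_deg"].sum())
        pooled_summary = {
            "n_gene_cross_pairs": n_pool,
            "ase_proportions": pooled_props,
            "pct_ase_of_analyzable": 100.0 * float(biased.mean()),
            "pct_degs_from_ase": (
                100.0 * float(merged.loc[merged["is_deg"], "ase_class"].isin(_ASE_BIASED_CLASSES).mean())
                if n_deg
                else 0.0
            ),
        }
    else:
        pooled_summary = {
            "n_gene_cross_pairs": 0,
            "ase_proportions": {},
            "pct_ase_of_analyzable": 0.0,
            "pct_degs_from_ase": 0.0,
        }

    forward = [d for d in cfg.designs if _is_forward(d, by_id)]
    deg_counts = [per_cross[d.cross_id]["deg_count"] for d in forward]
    r_fresh, p_fresh = correlate_deg_heterosis(
        deg_counts, [per_cross[d.cross_id]["mph_fresh_pct"] for d in forward]
    )
    r_dry, p_dry = correlate_deg_heterosis(
        deg_counts, [per_cross[d.cross_id]["mph_dry_pct"] for d in forward]
    )

    summary = {
        "version": __version__,
        "seed": sim.seed,
        "config_hash": cfg.config_hash(),
        "crosses": per_cross,
        "pooled": pooled_summary,
        "genotype_dependence": genotype_dependence,
        "deg_heterosis_correlation": {
            "fresh": {"r": r_fresh, "p": p_fresh},
            "dry": {"r": r_dry, "p": p_dry},
        },
    }
    summary = _round_floats(summary)

    result = PipelineResult(config=cfg, parents=parents, summary=summary, tables=tables)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


_ASE_BIASED_CLASSES = ("monoallelic", "preferential")


def _is_forward(d: TrioDesign, by_id: dict) -> bool:
    # deduplicate reciprocal pairs: keep the lexicographically first id
    if not d.reciprocal_id or d.reciprocal_id not in by_id:
        return True
    return d.cross_id < d.reciprocal_id


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, ndigits) if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables.items():
        _write_table(df, outdir / f"{name}.tsv")
    _atomic_write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n", outdir / "summary.json"
    )
    _atomic_write_text(render_summary(result.summary), outdir / "report.md")
    log_lines = [
        f"hybase {__version__}",
        f"seed: {result.summary['seed']}",
        f"config_hash: {result.summary['config_hash']}",
        f"crosses: {', '.join(result.summary['crosses'])}",
    ]
    _atomic_write_text("\n".join(log_lines) + "\n", outdir / "run.log")


def _pct(x) -> str:
    return "n/a" if x is None else f"{100.0 * x:.1f}%"


def render_summary(summary: dict) -> str:
    """Render a pipeline summary as a human-readable markdown report.

    Every number shown is taken directly from the summary dict (percentages
    to one decimal place).
    """
    required = ("crosses", "pooled", "genotype_dependence")
    missing = [k for k in required if k not in summary]
    if missing:
        raise ValueError(f"summary is missing sections: {missing}")

    lines = ["# Allele-specific expression report", ""]
    lines.append(f"Seed {summary.get('seed')}, config {summary.get('config_hash')}.")
    lines.append("")
    for cross_id, s in summary["crosses"].items():
        lines.append(f"## Cross {cross_id}")
        lines.append("")
        props = s["ase_proportions"]
        lines.append(
            f"- analyzable genes: {s['n_analyzable']} "
            f"(of {s['n_genes_with_counts']} with informative reads)"
        )
        if props:
            lines.append(
                "- ASE classes: "
                + ", ".join(f"{c} {_pct(props[c])}" for c in props)
            )
        lines.append(f"- DEGs vs parents: {s['deg_count']}")
        lines.append(f"- maternal read fraction: {s['maternal_read_fraction']:.3f}")
        lines.append(
            f"- parent-vs-F1 allelic correlation r = {s['parent_f1_r_all']:.3f} "
            f"(ASE subset r = {s['parent_f1_r_ase']:.3f})"
        )
        lines.append(f"- non-additive expression fraction: {_pct(s['nonadditive_fraction'])}")
        lines.append(
            f"- mid-parent heterosis: fresh {s['mph_fresh_pct']:.1f}%, dry {s['mph_dry_pct']:.1f}%"
        )
        lines.append("")
    lines.append("## Pooled across crosses")
    lines.append("")
    pooled = summary["pooled"]
    if pooled.get("ase_proportions"):
        lines.append(
            "- ASE classes: "
            + ", ".join(f"{c} {_pct(v)}" for c, v in pooled["ase_proportions"].items())
        )
    lines.append(f"- ASE share of analyzable genes: {pooled['pct_ase_of_analyzable']:.1f}%")
    lines.append(f"- share of DEGs showing ASE: {pooled['pct_degs_from_ase']:.1f}%")
    lines.append("")
    if summary["genotype_dependence"]:
        lines.append("## Reciprocal-cross patterns")
        lines.append("")
        for pair, s in summary["genotype_dependence"].items():
            lines.append(
                f"- {pair}: {s['n_genotype_dependent']}/{s['n_testable']} testable genes "
                f"genotype-dependent, {s['n_parent_of_origin']} parent-of-origin, "
                f"{s['n_inconsistent']} inconsistent"
            )
        lines.append("")
    corr = summary.get("deg_heterosis_correlation", {})
    if corr:
        lines.append("## DEG count vs heterosis")
        lines.append("")
        for trait, s in corr.items():
            lines.append(f"- {trait} mass: r = {s['r']} (p = {s['p']})")
        lines.append("")
    return "\n".join(lines)
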