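"""Synthetic-data generator: marginals, determinism, ground-truth contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from hybase.design import TrioDesign
from hybase.io import read_bundle
from hybase.simulate import (
    SimConfig,
    simulate_f1_counts,
    simulate_parents,
    simulate_phenotypes,
    write_fixture_bundle,
)


def test_invalid_proportions_rejected():
    with pytest.raises(ValueError):
        SimConfig(frac_cis=0.7, frac_trans=0.4)
    with pytest.raises(ValueError):
        SimConfig(frac_parent_silent=-0.1)
    with pytest.raises(ValueError):
        SimConfig(overdispersion=1.0)


def test_empty_config_yields_empty_tables_with_headers():
    sim = simulate_parents(SimConfig(n_genes=0, seed=1))
    assert len(sim.genes) == 0 and list(sim.genes.columns)
    assert len(sim.snps) == 0
    assert len(sim.truth) == 0
    counts = simulate_f1_counts(sim, sim.config, TrioDesign("GLxTQ", "GL", "TQ"))
    assert len(counts) == 0 and "count_maternal" in counts.columns


def test_all_parent_silent_when_forced():
    cfg = SimConfig(
        n_genes=100, frac_parent_silent=1.0, frac_genotype_dependent_mono=0.0,
        frac_cis=0.0, seed=1,
    )
    sim = simulate_parents(cfg)
    expr = sim.truth[[f"expr_{p}" for p in cfg.parents]].to_numpy()
    n_silent = (expr == 0).sum(axis=1)
    assert (sim.truth["label"] == "parent_silent").all()
    assert (n_silent == 1).all(), "each gene silent in exactly one parent"


def test_snp_count_poisson_mean():
    cfg = SimConfig(n_genes=1000, snps_per_gene_mean=3, seed=7)
    sim = simulate_parents(cfg)
    per_gene = sim.snps.groupby("gene_id").size().reindex(
        sim.genes["gene_id"], fill_value=0
    )
    tol = 3 * math.sqrt(3 / 1000)
    assert abs(per_gene.mean() - 3) < tol


def test_gene_models_nonoverlapping_one_based(small_parents):
    g = small_parents.genes.sort_values("start")
    assert (g["start"] >= 1).all()
    assert (g["end"] - g["start"] + 1 == g["length"]).all()
    assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()


def test_snps_match_reference_base(small_parents):
    ref = small_parents.reference["chr1"]
    for _, s in small_parents.snps.head(50).iterrows():
        assert ref[s["pos"] - 1] == s["ref"]
        assert s["ref"] != s["alt"]


def test_determinism_and_seed_sensitivity(gl_tq):
    a = simulate_parents(SimConfig(n_genes=100, seed=5))
    b = simulate_parents(SimConfig(n_genes=100, seed=5))
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(
        simulate_f1_counts(a, a.config, gl_tq), simulate_f1_counts(b, b.config, gl_tq)
    )
    c = simulate_parents(SimConfig(n_genes=100, seed=6))
    assert not a.truth.equals(c.truth)


def test_counts_conserve_depth_and_stay_in_gene_bodies(small_parents, gl_tq):
    counts = simulate_f1_counts(small_parents, small_parents.config, gl_tq)
    assert (counts["count_maternal"] >= 0).all()
    assert (counts["count_paternal"] >= 0).all()
    genes = small_parents.genes.set_index("gene_id")
    starts = genes.loc[counts["gene_id"], "start"].to_numpy()
    ends = genes.loc[counts["gene_id"], "end"].to_numpy()
    assert ((counts["pos"] >= starts) & (counts["pos"] <= ends)).all()


def test_degenerate_fraction_emits_single_allele(gl_tq):
    cfg = SimConfig(
        n_genes=50, frac_genotype_dependent_mono=1.0, frac_parent_silent=0.0,
        seed=3, depth_mean=40, parents=("GL", "TQ"),
    )
    sim = simulate_parents(cfg)
    counts = simulate_f1_counts(sim, cfg, gl_tq)
    per_gene = counts.groupby("gene_id")[["count_maternal", "count_paternal"]].sum()
    assert (per_gene.min(axis=1) == 0).all(), "one allele only at fraction 0/1"


def test_balanced_gene_fraction_binomial_concentration(gl_tq):
    # single neutral gene at depth 10,000: fraction within 0.5 +/- 3 binomial sd
    cfg = SimConfig(
        n_genes=1, frac_cis=0.0, frac_trans=0.0, frac_parent_silent=0.0,
        frac_genotype_dependent_mono=0.0, depth_mean=10_000,
        snps_per_gene_mean=4.0, seed=21,
    )
    sim = simulate_parents(cfg)
    counts = simulate_f1_counts(sim, cfg, gl_tq)
    m = counts["count_maternal"].sum()
    tot = m + counts["count_paternal"].sum()
    assert tot > 9000
    assert abs(m / tot - 0.5) < 0.015


def test_genotype_dependent_mono_reciprocal_symmetry(tq_gl, gl_tq):
    cfg = SimConfig(n_genes=200, frac_genotype_dependent_mono=0.3, seed=9)
    sim = simulate_parents(cfg)
    fwd = simulate_f1_counts(sim, cfg, gl_tq).groupby("gene_id")[
        ["count_maternal", "count_paternal"]
    ].sum()
    rev = simulate_f1_counts(sim, cfg, tq_gl).groupby("gene_id")[
        ["count_maternal", "count_paternal"]
    ].sum()
    truth = sim.truth.set_index("gene_id")
    gdm = truth.loc[truth["label"] == "genotype_dependent_mono"]
    checked = 0
    for gene, row in gdm.iterrows():
        if row["gdm_source"] == "GL":
            if gene in fwd.index and fwd.loc[gene].sum() > 0:
                assert fwd.loc[gene, "count_paternal"] == 0  # GL maternal here
                checked += 1
            if gene in rev.index and rev.loc[gene].sum() > 0:
                assert rev.loc[gene, "count_maternal"] == 0  # GL paternal here
                checked += 1
    assert checked > 10


def test_overdispersion_inflates_fraction_variance(gl_tq):
    base = dict(
        n_genes=400, frac_cis=0.0, frac_trans=0.0, frac_parent_silent=0.0,
        frac_genotype_dependent_mono=0.0, depth_mean=100, seed=17,
    )
    sim0 = simulate_parents(SimConfig(**base))
    c0 = simulate_f1_counts(sim0, sim0.config, gl_tq)
    simr = simulate_parents(SimConfig(**base, overdispersion=0.3))
    cr = simulate_f1_counts(simr, simr.config, gl_tq)

    def gene_frac(c):
        g = c.groupby("gene_id")[["count_maternal", "count_paternal"]].sum()
        tot = g.sum(axis=1)
        return (g["count_maternal"] / tot).loc[tot > 20]

    assert gene_frac(cr).var() > 2 * gene_frac(c0).var()


def test_identical_parents_rejected():
    with pytest.raises(ValueError):
        TrioDesign("GLxGL", "GL", "GL")


def test_phenotype_arithmetic():
    cfg = SimConfig(mph_target=20.0, phenotype_noise_sd=0.0, phenotype_replicates=3, seed=1)
    crosses = [TrioDesign("GLxTQ", "GL", "TQ")]
    pheno = simulate_phenotypes(cfg, crosses)
    means = pheno.groupby("genotype")["fresh_mass"].mean()
    mp = 0.5 * (means["GL"] + means["TQ"])
    assert means["GLxTQ"] == pytest.approx(1.2 * mp)

    cfg0 = SimConfig(mph_target=0.0, phenotype_noise_sd=0.0, seed=1)
    pheno0 = simulate_phenotypes(cfg0, crosses)
    means0 = pheno0.groupby("genotype")["fresh_mass"].mean()
    assert means0["GLxTQ"] == pytest.approx(0.5 * (means0["GL"] + means0["TQ"]))
    assert (pheno["fresh_mass"] >= 0).all() and (pheno["dry_mass"] >= 0).all()


def test_bundle_roundtrip_and_atomicity(tmp_path, gl_tq):
    cfg = SimConfig(n_genes=30, seed=4)
    sim = simulate_parents(cfg)
    f1 = {"GLxTQ": simulate_f1_counts(sim, cfg, gl_tq)}
    pheno = simulate_phenotypes(cfg, [gl_tq])
    out = tmp_path / "bundle"
    manifest = write_fixture_bundle(sim, f1, pheno, out)

    manifest2, tables = read_bundle(out)
    assert manifest2["config_hash"] == manifest["config_hash"] == cfg.config_hash()
    assert tables["reference"] == sim.reference
    pd.testing.assert_frame_equal(tables["genes"], sim.genes, check_dtype=False)
    pd.testing.assert_frame_equal(tables["snps"], sim.snps, check_dtype=False, check_like=True)
    pd.testing.assert_frame_equal(tables["f1_counts"]["GLxTQ"], f1["GLxTQ"], check_dtype=False)

    # immutable: refuses to overwrite an existing bundle
    with pytest.raises(FileExistsError):
        write_fixture_bundle(sim, f1, pheno, out)

    # different seed changes the counts
    cfg2 = SimConfig(n_genes=30, seed=5)
    sim2 = simulate_parents(cfg2)
    f1b = simulate_f1_counts(sim2, cfg2, gl_tq)
    assert not f1b.equals(f1["GLxTQ"])
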