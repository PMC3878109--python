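"""Reciprocal-cross patterns, DEG attribution, complementation, heterosis."""

import math

import numpy as np
import pandas as pd
import pytest

from hybase.design import TrioDesign
from hybase.expression import DegConfig
from hybase.integrate import (
    attribute_degs,
    call_genotype_dependence,
    complementary_effects,
    correlate_deg_heterosis,
    correlate_parent_f1,
    genotype_dependence_table,
    log_ratio,
    mid_parent_heterosis,
    nonadditive_fraction,
)


@pytest.fixture
def pair(gl_tq, tq_gl):
    return gl_tq, tq_gl


@pytest.mark.parametrize(
    "fwd,rec,expected",
    [
        (("monoallelic", "GL"), ("monoallelic", "GL"), "genotype-dependent"),
        (("preferential", "TQ"), ("preferential", "TQ"), "genotype-dependent"),
        # maternal allele favored in both orientations = imprinting-like
        (("monoallelic", "GL"), ("monoallelic", "TQ"), "parent-of-origin"),
        (("biallelic", None), ("biallelic", None), "untestable"),
        (("monoallelic", "GL"), ("biallelic", None), "untestable"),
        (("monoallelic", "GL"), ("unclassified", None), "untestable"),
    ],
)
def test_genotype_dependence_patterns(pair, fwd, rec, expected):
    assert call_genotype_dependence(fwd, rec, *pair) == expected


def test_non_reciprocal_pair_rejected(gl_tq):
    other = TrioDesign("GLx9311", "GL", "9311")
    with pytest.raises(ValueError, match="reciprocal"):
        call_genotype_dependence(("monoallelic", "GL"), ("monoallelic", "GL"), gl_tq, other)


def test_genotype_dependence_table_handles_missing_genes(pair):
    fwd_calls = pd.DataFrame(
        {"gene_id": ["a", "b"], "ase_class": ["monoallelic", "preferential"],
         "favored_genotype": ["GL", "TQ"]}
    )
    rec_calls = pd.DataFrame(
        {"gene_id": ["a"], "ase_class": ["monoallelic"], "favored_genotype": ["GL"]}
    )
    out = genotype_dependence_table(fwd_calls, rec_calls, *pair).set_index("gene_id")
    assert out.at["a", "pattern"] == "genotype-dependent"
    assert out.at["b", "pattern"] == "untestable"


@pytest.mark.parametrize(
    "f1,p1,p2,expected",
    [(12.0, 10.0, 10.0, 20.0), (10.0, 10.0, 10.0, 0.0), (9.0, 10.0, 10.0, -10.0)],
)
def test_mph_arithmetic(gl_tq, f1, p1, p2, expected):
    pheno = pd.DataFrame(
        {
            "genotype": ["GL", "TQ", "GLxTQ"],
            "replicate": [1, 1, 1],
            "fresh_mass": [p1, p2, f1],
            "dry_mass": [p1, p2, f1],
        }
    )
    out = mid_parent_heterosis(pheno, gl_tq)
    assert out["fresh_mass"] == pytest.approx(expected)
    assert out["dry_mass"] == pytest.approx(expected)


def test_mph_zero_midparent_is_nan(gl_tq):
    pheno = pd.DataFrame(
        {
            "genotype": ["GL", "TQ", "GLxTQ"],
            "replicate": [1, 1, 1],
            "fresh_mass": [0.0, 0.0, 1.0],
            "dry_mass": [1.0, 1.0, 1.0],
        }
    )
    out = mid_parent_heterosis(pheno, gl_tq)
    assert math.isnan(out["fresh_mass"]) and out["dry_mass"] == 0.0


def test_perfect_cis_correlation_is_one():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 2, 100)
    r, p = correlate_parent_f1(x, x.copy())
    assert r == pytest.approx(1.0)
    assert p < 1e-10


def test_pure_trans_correlation_near_zero():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 2, 2000)
    # trans regulation: F1 allelic ratio is 1 regardless of parental ratio;
    # binomial counting noise at depth 50 keeps y finite but independent of x
    m = rng.binomial(50, 0.5, 2000)
    y = log_ratio(m, 50 - m)
    r, _ = correlate_parent_f1(x, y)
    assert abs(r) < 0.08


def test_correlation_needs_three_genes():
    r, p = correlate_parent_f1([1.0, 2.0], [1.0, 2.0])
    assert math.isnan(r) and math.isnan(p)


def test_deg_heterosis_correlation_cases():
    r, _ = correlate_deg_heterosis([100, 200, 300], [5.0, 10.0, 15.0])
    assert r == pytest.approx(1.0)
    r, _ = correlate_deg_heterosis([100, 200, 300], [15.0, 10.0, 5.0])
    assert r == pytest.approx(-1.0)
    r, p = correlate_deg_heterosis([100, 200], [5.0, 10.0])
    assert math.isnan(r)


def _hand_fixture():
    """10 genes with known classes, DEG status and folds."""
    ase = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "ase_class": [
                "monoallelic", "monoallelic", "preferential", "preferential",
                "preferential", "biallelic", "biallelic", "biallelic",
                "biallelic", "unclassified",
            ],
        }
    )
    degs = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "is_deg": [True, True, True, False, True, False, False, True, False, False],
            "fold": [20.0, 3.0, 5.0, 1.2, 0.2, 1.0, 1.1, 12.0, 1.0, 1.0],
        }
    )
    div = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "divergence_class": ["IV", "I", "II", "I", "III", "I", "I", "III", "I", "I"],
        }
    )
    return ase, degs, div


def test_attribution_matches_hand_computation():
    ase, degs, div = _hand_fixture()
    table = attribute_degs(ase, degs, div)
    by_class = table.by_class.set_index("ase_class")
    # monoallelic: 2 genes, 2 DEGs; preferential: 3 genes, 2 DEGs (fold 0.2
    # is a 5-fold change downward); biallelic: 4 genes, 1 DEG
    assert by_class.at["monoallelic", "n_genes"] == 2
    assert by_class.at["monoallelic", "n_deg"] == 2
    assert by_class.at["monoallelic", "pct_deg"] == pytest.approx(100.0)
    assert by_class.at["preferential", "n_deg"] == 2
    assert by_class.at["biallelic", "n_deg"] == 1
    assert by_class.at["monoallelic", "pct_of_degs"] == pytest.approx(40.0)
    # unclassified gene excluded from the 9-gene universe
    assert table.n_classified == 9 and table.n_deg == 5

    bins = table.fold_bins.set_index("ase_class")
    assert bins.at["monoallelic", "n_>10"] == 1  # fold 20
    assert bins.at["monoallelic", "n_<4"] == 1  # fold 3
    assert bins.at["preferential", "n_4-10"] == 2  # folds 5 and 1/0.2
    assert bins.at["biallelic", "n_>10"] == 1  # fold 12

    silent = table.parent_silent.set_index("ase_class")
    assert silent.at["monoallelic", "n_genes"] == 1
    assert silent.at["monoallelic", "pct_of_parent_silent"] == pytest.approx(100.0)


def test_attribution_margins_reconcile():
    ase, degs, div = _hand_fixture()
    t = attribute_degs(ase, degs, div)
    assert t.by_class["n_genes"].sum() == 9
    assert t.by_class["n_deg"].sum() == int(
        degs.merge(ase[ase.ase_class != "unclassified"], on="gene_id")["is_deg"].sum()
    )
    assert t.by_class["pct_of_degs"].sum() == pytest.approx(100.0)
    assert t.by_class["pct_of_total_genes"].sum() == pytest.approx(100.0)


def test_attribution_empty_case():
    ase = pd.DataFrame({"gene_id": ["a", "b"], "ase_class": ["biallelic", "biallelic"]})
    degs = pd.DataFrame({"gene_id": ["a", "b"], "is_deg": [False, False], "fold": [1.0, 1.0]})
    t = attribute_degs(ase, degs)
    assert t.n_deg == 0
    assert (t.fold_bins["n_deg"] == 0).all()


def test_complementary_class_iv_dosage():
    ase = pd.DataFrame(
        {"gene_id": ["g1", "g2", "g3"], "ase_class": ["monoallelic", "biallelic", "biallelic"]}
    )
    div = pd.DataFrame(
        {"gene_id": ["g1", "g2", "g3"], "divergence_class": ["IV", "I", "III"]}
    )
    expr = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "rpkm_f1": [5.0, 10.0, 40.0],
            "rpkm_maternal": [10.0, 10.0, 22.0],
            "rpkm_paternal": [0.0, 10.0, 2.0],
        }
    )
    out = complementary_effects(ase, div, expr).set_index("gene_id")
    # class I gene excluded entirely
    assert "g2" not in out.index
    # class IV monoallelic at exactly the mid-parent level: complementation
    assert out.at["g1", "dosage_consistent"]
    # class III gene at 40 vs mid-parent 12: >1.5-fold deviation
    assert not out.at["g3", "dosage_consistent"]


def _counts(reads):
    return pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(len(reads))], "length": 1000, "reads": reads}
    )


def test_nonadditive_fraction_zero_when_additive():
    rng = np.random.default_rng(2)
    p1 = rng.poisson(200, 200)
    p2 = rng.poisson(800, 200)
    f1 = np.rint(0.5 * (p1 + p2)).astype(int)
    frac, _ = nonadditive_fraction(_counts(f1), _counts(p1), _counts(p2))
    assert frac == 0.0


def test_nonadditive_fraction_recovers_deviant_subset():
    # 10% of genes deviate 8-fold upward from the mid-parent expectation
    rng = np.random.default_rng(3)
    p1 = rng.poisson(300, 500)
    p2 = rng.poisson(300, 500)
    mp = np.rint(0.5 * (p1 + p2)).astype(int)
    f1 = mp.copy()
    f1[:50] = 8 * mp[:50]
    frac, table = nonadditive_fraction(_counts(f1), _counts(p1), _counts(p2))
    assert abs(frac - 0.10) <= 0.03
    assert table.set_index("gene_id")["is_deg"].loc["g0"]


def test_uniform_shift_is_invisible_to_relative_counts():
    # counts carry relative abundance only: doubling every gene leaves the
    # composition unchanged, so no gene can be called non-additive
    rng = np.random.default_rng(4)
    p1 = rng.poisson(300, 200)
    p2 = rng.poisson(300, 200)
    f1 = 2 * np.rint(0.5 * (p1 + p2)).astype(int)
    frac, _ = nonadditive_fraction(_counts(f1), _counts(p1), _counts(p2))
    assert frac < 0.05
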