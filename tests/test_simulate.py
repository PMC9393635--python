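"""The synthetic study generator: determinism, truth structure, noise model."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from clonalai import (
    ConfigError,
    SimulationConfig,
    compute_ai,
    draw_gene_truth,
    simulate_study,
)
from clonalai.simulate import beta_binomial


def _cfg(**kw):
    base = dict(
        n_autosomal_genes=200,
        n_x_genes=60,
        n_monoclonal=3,
        n_polyclonal=2,
        n_unmanipulated=1,
        mean_gene_coverage=50.0,
        seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_same_seed_reproduces_study_exactly():
    a = simulate_study(_cfg(seed=7))
    b = simulate_study(_cfg(seed=7))
    pdt.assert_frame_equal(a.rna_counts, b.rna_counts)
    pdt.assert_frame_equal(a.wes_counts, b.wes_counts)
    pdt.assert_frame_equal(a.marker_counts, b.marker_counts)
    pdt.assert_frame_equal(a.truth.genes, b.truth.genes)


def test_different_seeds_differ_in_counts_not_class_counts():
    a = simulate_study(_cfg(seed=1, frac_stable_rme=0.05))
    b = simulate_study(_cfg(seed=2, frac_stable_rme=0.05))
    assert not a.rna_counts["maternal_count"].equals(b.rna_counts["maternal_count"])
    assert (
        a.truth.genes.ai_class.value_counts().to_dict()
        == b.truth.genes.ai_class.value_counts().to_dict()
    )


def test_class_counts_match_rounded_fractions():
    cfg = _cfg(frac_stable_rme=0.05, frac_imprinted=0.02, frac_loh=0.01, frac_escapee=0.1)
    study = simulate_study(cfg)
    counts = study.truth.genes.ai_class.value_counts()
    assert counts["stable_rme"] == round(0.05 * 200)
    assert counts["imprinted"] == round(0.02 * 200)
    assert counts["loh"] == round(0.01 * 200)
    assert counts["escapee"] == round(0.1 * 60)


def test_all_fracs_zero_gives_balanced_autosomes():
    cfg = _cfg(frac_stable_rme=0.0, frac_imprinted=0.0, frac_loh=0.0, frac_escapee=0.0)
    _, truth = draw_gene_truth(cfg, np.random.default_rng(0))
    auto = truth.genes.loc[truth.genes.chrom_class == "autosome"]
    assert (auto.ai_class == "balanced").all()
    auto_ai = truth.sample_ai.merge(auto[["gene_id"]], on="gene_id")
    assert np.allclose(auto_ai.pre_ai, 0.5)


def test_contamination_mixture_closed_form():
    """Observed AI of a fully skewed X gene is (1-c)*chi + c*q."""
    cfg = _cfg(frac_escapee=0.0, contamination=0.05, x_poly_ai=0.35)
    meta, truth = draw_gene_truth(cfg, np.random.default_rng(3))
    x_std = truth.genes.loc[truth.genes.ai_class == "x_standard", "gene_id"]
    sub = truth.sample_ai.loc[
        truth.sample_ai.gene_id.isin(x_std)
        & truth.sample_ai.sample_id.isin(truth.contamination)
    ]
    for sample_id, grp in sub.groupby("sample_id"):
        chi = truth.x_choice[sample_id.split("_")[0]]
        expected = 0.95 * chi + 0.05 * 0.35
        assert np.allclose(grp.true_ai, expected), sample_id
    if any(truth.x_choice[s.split("_")[0]] == 1 for s in truth.contamination):
        assert np.isclose(0.95 * 1 + 0.05 * 0.35, 0.9675)


def test_escapee_precontamination_ai_is_one_minus_f():
    cfg = _cfg(frac_escapee=0.2, contamination=0.0)
    _, truth = draw_gene_truth(cfg, np.random.default_rng(4))
    esc = truth.genes.loc[truth.genes.ai_class == "escapee"].set_index("gene_id")
    sub = truth.sample_ai.loc[
        truth.sample_ai.gene_id.isin(esc.index)
        & truth.sample_ai.sample_id.isin(truth.contamination)
    ]
    for _, row in sub.iterrows():
        f = esc.loc[row.gene_id, "xi_fraction"]
        chi = truth.x_choice[row.sample_id.split("_")[0]]
        expected = 1.0 - f if chi == 1 else f
        assert np.isclose(row.pre_ai, expected)


def test_fully_skewed_gene_has_zero_opposite_counts():
    cfg = _cfg(frac_escapee=0.0, contamination=0.0, rho_tech=0.0)
    study = simulate_study(cfg)
    x_std = study.truth.genes.loc[study.truth.genes.ai_class == "x_standard", "gene_id"]
    mono = study.metadata.loc[study.metadata.clonality == "monoclonal"]
    counts = study.rna_counts.loc[
        study.rna_counts.gene_id.isin(x_std)
        & study.rna_counts.sample_id.isin(mono.sample_id)
    ]
    for animal, chi in study.truth.x_choice.items():
        rows = counts.loc[counts.sample_id.str.startswith(animal + "_")]
        col = "paternal_count" if chi == 1 else "maternal_count"
        assert (rows[col] == 0).all()


def test_zero_coverage_gives_empty_table():
    study = simulate_study(_cfg(mean_gene_coverage=0.0))
    assert study.rna_counts.empty


def test_single_replicate_rejected():
    with pytest.raises(ConfigError, match="QCC"):
        _cfg(n_replicates=1)


def test_fraction_sum_above_one_rejected():
    with pytest.raises(ConfigError):
        _cfg(frac_stable_rme=0.5, frac_imprinted=0.4, frac_loh=0.2)


def test_binomial_replicate_variance_matches_closed_form(rng):
    """With rho_tech = 0 replicate AI differences have binomial variance."""
    n = np.full(20000, 100)
    p = np.full(20000, 0.4)
    m1 = beta_binomial(rng, n, p, 0.0)
    m2 = beta_binomial(rng, n, p, 0.0)
    d = m1 / n - m2 / n
    expected = 0.4 * 0.6 * (2 / 100)
    assert abs(d.var() / expected - 1) < 0.05


def test_beta_binomial_variance_inflation(rng):
    rho = 0.1
    n = np.full(50000, 100)
    p = np.full(50000, 0.5)
    m = beta_binomial(rng, n, p, rho)
    var = (m / 100).var()
    expected = 0.25 / 100 * (1 + 99 * rho)
    assert abs(var / expected - 1) < 0.05


def test_marker_counts_track_contamination():
    cfg = _cfg(contamination=0.0, marker_reads=10000)
    study = simulate_study(cfg)
    assert (study.marker_counts.recipient_allele_reads == 0).all()
    cfg2 = _cfg(contamination=0.5, marker_reads=10000, seed=9)
    study2 = simulate_study(cfg2)
    frac = study2.marker_counts.recipient_allele_reads / (
        study2.marker_counts.recipient_allele_reads
        + study2.marker_counts.donor_allele_reads
    )
    assert np.allclose(frac, 0.5, atol=0.02)
    cfg3 = _cfg(contamination=0.01, marker_reads=10000, seed=10)
    study3 = simulate_study(cfg3)
    frac3 = study3.marker_counts.recipient_allele_reads / 10000
    assert np.allclose(frac3, 0.01, atol=0.006)


def test_wes_balanced_genes_concentrate_and_loh_is_extreme():
    cfg = _cfg(frac_loh=0.05, wes_mean_coverage=200.0, seed=12)
    study = simulate_study(cfg)
    wes_ai = compute_ai(study.wes_counts)
    loh_genes = set(study.truth.genes.loc[study.truth.genes.ai_class == "loh", "gene_id"])
    balanced = wes_ai.loc[~wes_ai.gene_id.isin(loh_genes)]
    inside = ((balanced.ai >= 0.4) & (balanced.ai <= 0.6)).mean()
    assert inside > 0.98
    loh = wes_ai.loc[wes_ai.gene_id.isin(loh_genes)]
    assert ((loh.ai < 0.1) | (loh.ai > 0.9)).all()


def test_mixture_identity_at_high_coverage():
    """Mean X AI of a maternal-X clone converges to (1-c) + c*q."""
    cfg = _cfg(
        n_x_genes=150,
        frac_escapee=0.0,
        contamination=0.08,
        mean_gene_coverage=500.0,
        coverage_dispersion=0.0,
        seed=31,
    )
    study = simulate_study(cfg)
    ai = compute_ai(study.rna_counts)
    x_std = study.truth.genes.loc[
        study.truth.genes.ai_class == "x_standard", "gene_id"
    ]
    for sample_id, c in study.truth.contamination.items():
        chi = study.truth.x_choice[sample_id.split("_")[0]]
        expected = (1 - c) * chi + c * cfg.x_poly_ai
        observed = ai.loc[
            ai.sample_id.eq(sample_id) & ai.gene_id.isin(x_std), "ai"
        ].mean()
        assert abs(observed - expected) < 0.02
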