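"""SD-based stable-RME screen, signed-rank asymmetry, concordance,
DNA/RNA bootstrap and AI PCA."""

import numpy as np
import pandas as pd
import pytest

from clonalai import (
    ai_pca,
    bootstrap_dna_rna,
    cross_lineage_concordance,
    sd_analysis,
    wilcoxon_asymmetry,
)


def _meta(n_mono=5, n_poly=5):
    rows = []
    for i in range(1, n_mono + 1):
        rows.append((f"M{i}_B", "B", "monoclonal", "E1", f"M{i}"))
    for i in range(1, n_poly + 1):
        rows.append((f"P{i}_B", "B", "polyclonal", "E1", f"P{i}"))
    return pd.DataFrame(
        rows, columns=["sample_id", "tissue", "clonality", "experiment_id", "animal_id"]
    )


def _ai_frame(gene_values):
    """gene_values: {gene: {sample: ai}}."""
    rows = [
        (g, s, v, "chr1")
        for g, by_sample in gene_values.items()
        for s, v in by_sample.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "ai", "chrom"])


def test_sd_analysis_flags_dispersed_monoclonals():
    meta = _meta()
    mono_ais = [0.1, 0.9, 0.5, 0.5, 0.5]
    values = {
        "rme": {f"M{i+1}_B": mono_ais[i] for i in range(5)}
        | {f"P{i}_B": 0.5 for i in range(1, 6)},
        "flat": {s: 0.5 for s in meta.sample_id},
    }
    calls = sd_analysis(_ai_frame(values), meta)
    rme = calls.set_index("gene_id").loc["rme"]
    assert rme.sd_mono == pytest.approx(np.std(mono_ais, ddof=1))
    assert rme.sd_mono == pytest.approx(0.2828, abs=1e-3)
    assert rme.sd_poly == 0.0
    assert bool(rme.flagged)
    flat = calls.set_index("gene_id").loc["flat"]
    assert flat.sd_mono == 0.0 and not bool(flat.flagged)


def test_sd_analysis_prefilters_gate_flagging():
    meta = _meta()
    values = {
        "rme": {f"M{i}_B": v for i, v in zip(range(1, 6), [0.1, 0.9, 0.5, 0.5, 0.5])}
        | {f"P{i}_B": 0.5 for i in range(1, 6)},
    }
    calls = sd_analysis(_ai_frame(values), meta, candidate_genes=set())
    row = calls.set_index("gene_id").loc["rme"]
    assert bool(row.flagged_unfiltered) and not bool(row.flagged)


def test_sd_analysis_needs_three_per_group():
    meta = _meta(n_mono=2, n_poly=5)
    values = {"g": {s: 0.5 for s in meta.sample_id}}
    with pytest.raises(ValueError, match=">= 3"):
        sd_analysis(_ai_frame(values), meta)


def _calls(n, sd_mono=0.3, sd_poly=0.05):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "sd_mono": sd_mono,
            "sd_poly": sd_poly,
            "flagged": True,
        }
    )


def test_wilcoxon_all_positive_differences_is_two_to_minus_n():
    p = wilcoxon_asymmetry(_calls(14))
    assert p == pytest.approx(2.0**-14, rel=1e-9)


def test_wilcoxon_zero_differences_gives_one():
    p = wilcoxon_asymmetry(_calls(10, sd_mono=0.2, sd_poly=0.2))
    assert p == 1.0


def test_wilcoxon_minimum_flagged():
    with pytest.raises(ValueError, match=">= 5"):
        wilcoxon_asymmetry(_calls(1))


def _tissue_ai(sample, values):
    return pd.DataFrame(
        {
            "sample_id": sample,
            "gene_id": [f"g{i}" for i in range(len(values))],
            "ai": values,
        }
    )


def test_concordance_within_vs_swapped():
    rng = np.random.default_rng(0)
    a1 = rng.uniform(0.1, 0.9, 20)
    a2 = rng.uniform(0.1, 0.9, 20)
    ai_b = pd.concat([_tissue_ai("M1_B", a1), _tissue_ai("M2_B", a2)])
    ai_t = pd.concat([_tissue_ai("M1_T", a1), _tissue_ai("M2_T", a2)])
    animals = {"M1_B": "M1", "M1_T": "M1", "M2_B": "M2", "M2_T": "M2"}
    within, swapped = cross_lineage_concordance(
        ai_b, ai_t, animals, [f"g{i}" for i in range(20)]
    )
    assert within.pairing == "within_animal"
    assert within.pearson_r == pytest.approx(1.0)
    assert swapped.pearson_r < within.pearson_r


def test_concordance_identical_animals_degenerate_control():
    a = np.linspace(0.1, 0.9, 15)
    ai_b = pd.concat([_tissue_ai("M1_B", a), _tissue_ai("M2_B", a)])
    ai_t = pd.concat([_tissue_ai("M1_T", a), _tissue_ai("M2_T", a)])
    animals = {"M1_B": "M1", "M1_T": "M1", "M2_B": "M2", "M2_T": "M2"}
    within, swapped = cross_lineage_concordance(
        ai_b, ai_t, animals, [f"g{i}" for i in range(15)]
    )
    assert within.pearson_r == pytest.approx(swapped.pearson_r)


def _diff_series(rng, n=200):
    return pd.Series(
        rng.normal(0.0, 0.05, n), index=[f"g{i}" for i in range(n)]
    )


def test_bootstrap_extreme_set_hits_tail_bound(rng):
    diffs = _diff_series(rng)
    top = diffs.nlargest(10).index.tolist()
    res = bootstrap_dna_rna(
        diffs, top, n_replicates=999, rng=np.random.default_rng(1),
        statistics=("signed_mean",),
    )[0]
    assert res.p_value == pytest.approx(1.0 / 1000.0)


def test_bootstrap_deterministic_given_seed(rng):
    diffs = _diff_series(rng)
    flagged = diffs.index[:10].tolist()
    r1 = bootstrap_dna_rna(diffs, flagged, 2000, np.random.default_rng(5))
    r2 = bootstrap_dna_rna(diffs, flagged, 2000, np.random.default_rng(5))
    assert [b.p_value for b in r1] == [b.p_value for b in r2]


def test_bootstrap_p_monotone_in_observed(rng):
    diffs = _diff_series(rng)
    mid = diffs.sort_values().index[90:100].tolist()
    high = diffs.nlargest(10).index.tolist()
    p_mid = bootstrap_dna_rna(diffs, mid, 999, np.random.default_rng(2),
                              statistics=("signed_mean",))[0].p_value
    p_high = bootstrap_dna_rna(diffs, high, 999, np.random.default_rng(2),
                               statistics=("signed_mean",))[0].p_value
    assert p_high < p_mid


def test_bootstrap_pool_must_dominate_flagged(rng):
    diffs = _diff_series(rng, n=15)
    with pytest.raises(ValueError, match="twice"):
        bootstrap_dna_rna(diffs, diffs.index[:10].tolist(), 100, rng)


def test_pca_identical_samples_project_to_origin():
    wide = pd.DataFrame(
        {s: [0.2, 0.5, 0.8, 0.4] for s in ("A", "B", "C")},
        index=[f"g{i}" for i in range(4)],
    )
    scores, evr = ai_pca(wide)
    assert np.allclose(scores.to_numpy(), 0.0)


def test_pca_single_discordant_sample_is_extreme_on_pc1():
    rng = np.random.default_rng(4)
    base = rng.uniform(0.4, 0.6, 50)
    wide = pd.DataFrame(
        {
            "A": base,
            "B": base + rng.normal(0, 0.01, 50),
            "C": base + rng.normal(0, 0.01, 50),
            "D": 1.0 - base,  # discordant
        },
        index=[f"g{i}" for i in range(50)],
    )
    scores, _ = ai_pca(wide)
    dist = scores.PC1.abs()
    assert dist.idxmax() == "D"


def test_pca_separates_x_skew_clusters():
    """Samples expressing opposite X chromosomes split on PC1 when X genes
    are included."""
    rng = np.random.default_rng(6)
    auto = rng.uniform(0.45, 0.55, (40, 6))
    x_ai = np.array([[0.98] * 3 + [0.02] * 3] * 15)
    mat = np.vstack([auto, x_ai + rng.normal(0, 0.01, x_ai.shape)])
    wide = pd.DataFrame(mat, columns=[f"S{i}" for i in range(6)])
    scores, _ = ai_pca(wide)
    side = scores.PC1 > scores.PC1.median()
    assert side.iloc[:3].nunique() == 1 and side.iloc[3:].nunique() == 1
    assert side.iloc[0] != side.iloc[3]


def test_pca_sign_convention_is_deterministic():
    rng = np.random.default_rng(8)
    wide = pd.DataFrame(rng.uniform(0, 1, (30, 5)), columns=list("ABCDE"))
    s1, _ = ai_pca(wide)
    s2, _ = ai_pca(wide.copy())
    pd.testing.assert_frame_equal(s1, s2)
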