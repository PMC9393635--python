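"""Count-table I/O, SNP collapsing, AI point estimates and TMM."""

import io

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalai import (
    CountsFormatError,
    collapse_to_gene,
    compute_ai,
    read_counts,
    tmm_normalize,
    write_counts,
)

HEADER = "sample_id\treplicate_id\tgene_id\tchrom\tmaternal_count\tpaternal_count\tassay\n"


def _read(text, dialect="gene_level"):
    return read_counts(io.StringIO(text), dialect=dialect)


def test_round_trip_is_identity(small_study, tmp_path):
    path = tmp_path / "rna.tsv"
    write_counts(small_study.rna_counts, path)
    back = read_counts(path)
    pdt.assert_frame_equal(
        back.reset_index(drop=True), small_study.rna_counts.reset_index(drop=True)
    )


def test_empty_file_with_header_is_empty_table():
    table = _read(HEADER)
    assert table.empty


def test_negative_count_rejected_with_row_number():
    text = HEADER + "S1\tr1\tg1\tchr1\t-1\t5\tRNA\n"
    with pytest.raises(CountsFormatError, match="line 2"):
        _read(text)


def test_duplicate_key_rejected():
    row = "S1\tr1\tg1\tchr1\t3\t5\tRNA\n"
    with pytest.raises(CountsFormatError, match="duplicate"):
        _read(HEADER + row + row)


def test_missing_column_rejected():
    with pytest.raises(CountsFormatError, match="missing columns"):
        _read("sample_id\tgene_id\n")


def _snp_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "sample_id",
            "replicate_id",
            "gene_id",
            "chrom",
            "maternal_count",
            "paternal_count",
            "assay",
        ],
    )


def test_collapse_sums_snp_counts():
    snp = _snp_table(
        [
            ("s1", "S1", "r1", "gA", "chr1", 3, 1, "RNA"),
            ("s2", "S1", "r1", "gA", "chr1", 2, 2, "RNA"),
        ]
    )
    gene = collapse_to_gene(snp)
    assert len(gene) == 1
    assert gene.loc[0, "maternal_count"] == 5
    assert gene.loc[0, "paternal_count"] == 3


def test_multi_gene_snp_excluded_from_both():
    snp = _snp_table(
        [
            ("s1", "S1", "r1", "gA,gB", "chr1", 10, 10, "RNA"),
            ("s2", "S1", "r1", "gA", "chr1", 1, 1, "RNA"),
        ]
    )
    gene = collapse_to_gene(snp)
    assert set(gene.gene_id) == {"gA"}
    assert gene.loc[0, "maternal_count"] == 1


def test_unassigned_snp_dropped_and_reads_conserved():
    snp = _snp_table(
        [
            ("s1", "S1", "r1", "", "chr1", 4, 4, "RNA"),
            ("s2", "S1", "r1", "gA", "chr1", 2, 3, "RNA"),
            ("s3", "S1", "r1", "gB", "chr2", 7, 0, "RNA"),
        ]
    )
    gene = collapse_to_gene(snp)
    retained = snp.loc[snp.gene_id.isin(["gA", "gB"])]
    assert gene.maternal_count.sum() == retained.maternal_count.sum()
    assert gene.paternal_count.sum() == retained.paternal_count.sum()


@pytest.mark.parametrize(
    "maternal,paternal,expected",
    [(30, 10, 0.75), (5, 5, 0.5), (0, 7, 0.0), (7, 0, 1.0)],
)
def test_ai_point_estimate(maternal, paternal, expected):
    table = pd.DataFrame(
        {
            "sample_id": ["S1"],
            "replicate_id": ["r1"],
            "gene_id": ["g1"],
            "chrom": ["chr1"],
            "maternal_count": [maternal],
            "paternal_count": [paternal],
            "assay": ["RNA"],
        }
    )
    ai = compute_ai(table)
    assert ai.loc[0, "ai"] == pytest.approx(expected)


def test_pooling_sums_before_ratio_and_omits_zero_totals():
    table = pd.DataFrame(
        {
            "sample_id": ["S1"] * 2 + ["S1"],
            "replicate_id": ["r1", "r2", "r1"],
            "gene_id": ["g1", "g1", "g2"],
            "chrom": "chr1",
            "maternal_count": [10, 0, 0],
            "paternal_count": [0, 10, 0],
            "assay": "RNA",
        }
    )
    ai = compute_ai(table, pool_replicates=True)
    assert set(ai.gene_id) == {"g1"}  # zero-total gene omitted, not NaN
    assert ai.loc[0, "ai"] == pytest.approx(0.5)


@given(
    m1=st.integers(0, 50),
    p1=st.integers(0, 50),
    m2=st.integers(0, 50),
    p2=st.integers(0, 50),
)
@settings(max_examples=60, deadline=None)
def test_pooled_ai_between_replicate_ais(m1, p1, m2, p2):
    if m1 + p1 == 0 or m2 + p2 == 0:
        return
    table = pd.DataFrame(
        {
            "sample_id": "S1",
            "replicate_id": ["r1", "r2"],
            "gene_id": "g1",
            "chrom": "chr1",
            "maternal_count": [m1, m2],
            "paternal_count": [p1, p2],
            "assay": "RNA",
        }
    )
    per_rep = compute_ai(table, pool_replicates=False)["ai"]
    pooled = compute_ai(table, pool_replicates=True)["ai"].iloc[0]
    assert per_rep.min() - 1e-12 <= pooled <= per_rep.max() + 1e-12
    assert 0.0 <= pooled <= 1.0


# ---------------------------------------------------------------------------
# TMM


def _random_counts(rng, genes=300, libs=4):
    counts = rng.negative_binomial(5, 0.05, size=(genes, libs)).astype(float)
    return pd.DataFrame(counts, columns=[f"L{i}" for i in range(libs)])


def test_identical_libraries_have_unit_factors():
    counts = pd.DataFrame({"A": [10, 20, 30, 5], "B": [10, 20, 30, 5]}, dtype=float)
    factors, _ = tmm_normalize(counts)
    assert np.allclose(factors, 1.0)


def test_doubled_library_has_unit_factor_and_equal_normalized_counts():
    rng = np.random.default_rng(1)
    a = rng.poisson(100, 500).astype(float) + 1
    counts = pd.DataFrame({"A": a, "B": 2 * a})
    factors, abundance = tmm_normalize(counts)
    assert np.allclose(factors, 1.0)
    assert np.allclose(abundance["A"], abundance["B"], rtol=1e-9)


def test_factor_geometric_mean_is_one_for_random_inputs():
    rng = np.random.default_rng(2)
    counts = _random_counts(rng)
    factors, _ = tmm_normalize(counts)
    assert np.isclose(np.exp(np.log(factors).mean()), 1.0, atol=1e-12)


def test_factors_invariant_to_global_rescaling():
    rng = np.random.default_rng(3)
    counts = _random_counts(rng)
    f1, _ = tmm_normalize(counts)
    f2, _ = tmm_normalize(counts * 7.0)
    assert np.allclose(f1, f2)


def test_zero_total_library_rejected():
    counts = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]})
    with pytest.raises(ValueError, match="zero total"):
        tmm_normalize(counts)
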