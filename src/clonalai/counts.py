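"""Allele-count table I/O, SNP-to-gene collapsing, AI estimates and TMM.

Tables are plain TSV (UTF-8, tab-separated, '.' decimal; gzip-transparent
on read).  The in-memory container is a pandas DataFrame with one row per
(sample, replicate, gene) and integer maternal/paternal read counts.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_LEVEL_COLUMNS = [
    "sample_id",
    "replicate_id",
    "gene_id",
    "chrom",
    "maternal_count",
    "paternal_count",
    "assay",
]
SNP_LEVEL_COLUMNS = ["snp_id"] + GENE_LEVEL_COLUMNS
_KEY_COLUMNS = {
    "gene_level": ["sample_id", "replicate_id", "gene_id"],
    "snp_level": ["sample_id", "replicate_id", "snp_id"],
}
#: Separators accepted in a SNP row's gene assignment; a row listing more
#: than one gene sits in a region shared by multiple genes and is excluded.
_MULTI_GENE_SEPARATORS = (",", ";")


class CountsFormatError(ValueError):
    """A count table violates its schema; the message names the row."""


def read_counts(path, dialect: str = "gene_level") -> pd.DataFrame:
    """Read and validate an allele-count TSV.

    ``dialect`` is ``gene_level`` (unique per sample/replicate/gene) or
    ``snp_level`` (unique per sample/replicate/SNP, with a ``gene_id``
    assignment column that may be empty or list several genes).
    """
    if dialect not in _KEY_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, keep_default_na=False)
    required = SNP_LEVEL_COLUMNS if dialect == "snp_level" else GENE_LEVEL_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CountsFormatError(f"{path}: missing columns {missing}")
    return validate_counts(df, dialect=dialect, source=str(path))


def validate_counts(
    df: pd.DataFrame, dialect: str = "gene_level", source: str = "<table>"
) -> pd.DataFrame:
    """Check count types, signs and key uniqueness; returns the table."""
    df = df.copy()
    for col in ("maternal_count", "paternal_count"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values % 1 != 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise CountsFormatError(f"{source}: non-integer {col} at line {row}")
        neg = values < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0]) + 2
            raise CountsFormatError(f"{source}: negative {col} at line {row}")
        df[col] = values.astype(np.int64)
    keys = _KEY_COLUMNS[dialect]
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise CountsFormatError(
            f"{source}: duplicate {'/'.join(keys)} key at line {row}"
        )
    return df


def write_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "tissue", "clonality", "experiment_id", "animal_id"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise CountsFormatError(f"{path}: missing metadata columns {missing}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def collapse_to_gene(snp_table: pd.DataFrame) -> pd.DataFrame:
    """Sum SNP-level allelic counts into gene-level counts.

    SNP rows with an empty gene assignment are dropped (count logged);
    rows listing multiple genes lie in overlapping gene models and are
    excluded from every listed gene.
    """
    df = snp_table.copy()
    gene = df["gene_id"].fillna("").astype(str).str.strip()
    unassigned = gene == ""
    multi = gene.str.contains("|".join(map(_escape, _MULTI_GENE_SEPARATORS)))
    if unassigned.any():
        logger.info("collapse_to_gene: dropped %d SNP rows with no gene", int(unassigned.sum()))
    if multi.any():
        logger.info(
            "collapse_to_gene: excluded %d SNP rows overlapping multiple genes",
            int(multi.sum()),
        )
    df = df.loc[~(unassigned | multi)]
    grouped = (
        df.groupby(["sample_id", "replicate_id", "gene_id"], as_index=False)
        .agg(
            chrom=("chrom", "first"),
            maternal_count=("maternal_count", "sum"),
            paternal_count=("paternal_count", "sum"),
            assay=("assay", "first"),
        )
        .loc[:, GENE_LEVEL_COLUMNS]
    )
    return grouped


def _escape(s: str) -> str:
    import re

    return re.escape(s)


def compute_ai(table: pd.DataFrame, pool_replicates: bool = True) -> pd.DataFrame:
    """Allelic-imbalance point estimates: maternal / (maternal + paternal).

    With ``pool_replicates`` (the default) replicate counts are summed
    before the ratio.  Rows with zero total are omitted rather than
    propagated as NaN.
    """
    keys = ["sample_id", "gene_id"] if pool_replicates else [
        "sample_id",
        "replicate_id",
        "gene_id",
    ]
    grouped = table.groupby(keys, as_index=False).agg(
        chrom=("chrom", "first"),
        maternal=("maternal_count", "sum"),
        paternal=("paternal_count", "sum"),
    )
    grouped["total"] = grouped["maternal"] + grouped["paternal"]
    grouped = grouped.loc[grouped["total"] > 0].copy()
    grouped["ai"] = grouped["maternal"] / grouped["total"]
    return grouped.reset_index(drop=True)


def pooled_counts_matrix(
    table: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-pooled maternal and total counts as gene x sample frames."""
    ai = compute_ai(table, pool_replicates=True)
    maternal = ai.pivot(index="gene_id", columns="sample_id", values="maternal")
    total = ai.pivot(index="gene_id", columns="sample_id", values="total")
    return maternal, total


def tmm_normalize(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    scale: float = 1e6,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M-values normalization of a gene x library matrix.

    The reference library is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  For each library, log-ratios M and
    log-abundances A are computed over genes expressed in both the library
    and the reference; the most extreme 30% of M and 5% of A are trimmed
    two-sided; the factor is the precision-weighted mean of the remaining M
    (inverse asymptotic binomial variance weights).  Factors are rescaled
    to geometric mean 1.

    Returns ``(factors, abundance)`` where abundance holds
    ``count / (library_size * factor) * scale`` — counts per ``scale``
    effective library reads (the default ``1e6`` is a CPM-style unit; the
    expression threshold "10 TMM-normalized counts" is interpreted on this
    scale and is configurable).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 libraries")
    counts = counts.fillna(0.0)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0].tolist()
        raise ValueError(f"libraries with zero total counts: {bad}")
    frac = counts.div(libsize, axis=1)
    uq = frac.quantile(0.75)
    ref = (uq - uq.mean()).abs().idxmin()

    from scipy.stats import rankdata

    f_ref = frac[ref].to_numpy()
    n_ref = libsize[ref]
    y_ref = counts[ref].to_numpy()
    log2_factors = {}
    for lib in counts.columns:
        if lib == ref:
            log2_factors[lib] = 0.0
            continue
        y = counts[lib].to_numpy()
        shared = (y > 0) & (y_ref > 0)
        f = frac[lib].to_numpy()[shared]
        fr = f_ref[shared]
        m = np.log2(f / fr)
        a = 0.5 * np.log2(f * fr)
        w = (libsize[lib] - y[shared]) / (libsize[lib] * y[shared]) + (
            n_ref - y_ref[shared]
        ) / (n_ref * y_ref[shared])
        finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
        m, a, w = m[finite], a[finite], w[finite]
        n = m.size
        if n == 0:
            log2_factors[lib] = 0.0
            continue
        rm = rankdata(m)
        ra = rankdata(a)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            log2_factors[lib] = 0.0
        else:
            log2_factors[lib] = float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    f = pd.Series({lib: 2.0 ** v for lib, v in log2_factors.items()})
    f = f.loc[counts.columns]
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    abundance = counts.div(libsize * f, axis=1) * scale
    return f, abundance


def abundance_long(abundance: pd.DataFrame) -> pd.DataFrame:
    """Wide gene x sample abundance to long (sample_id, gene_id, tmm_count)."""
    long = abundance.stack().rename("tmm_count").reset_index()
    long.columns = ["gene_id", "sample_id", "tmm_count"]
    return long.loc[:, ["sample_id", "gene_id", "tmm_count"]]
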