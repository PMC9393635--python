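"""Gene inclusion/exclusion rules, each as a separately testable predicate.

Every filter is a pure function of immutable inputs returning the affected
gene set plus report rows, so the final retained set is independent of the
order in which filters are applied.  Boundary semantics are deliberately
literal and documented per filter: expression removal is strictly below
the threshold, the allelic-ratio bands remove genes strictly outside
(low, high) in *all* in-scope samples, and the exome rule excludes genes
with DNA totals strictly below the minimum or DNA AI strictly outside the
band in any assayed sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .config import FilterConfig

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-gene record of which filters removed it, with per-filter counts."""

    rows: List[Tuple[str, str, str, float]] = field(default_factory=list)

    def add(self, gene_id: str, filter_name: str, scope: str, value: float) -> None:
        self.rows.append((gene_id, filter_name, scope, value))

    def extend(self, other: "FilterReport") -> None:
        self.rows.extend(other.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["gene_id", "filter", "scope", "value"]
        )

    def counts(self) -> Dict[str, int]:
        df = self.to_frame()
        if df.empty:
            return {}
        return df.groupby("filter")["gene_id"].nunique().to_dict()

    def removed_genes(self) -> Set[str]:
        return {r[0] for r in self.rows}


def _ai_wide(ai: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    wide = ai.pivot(index="gene_id", columns="sample_id", values="ai")
    cols = [s for s in samples if s in wide.columns]
    return wide.loc[:, cols]


def expression_filter(
    abundance: pd.DataFrame,
    samples: Sequence[str],
    threshold: float = 10.0,
    scope: str = "all",
) -> Tuple[Set[str], FilterReport]:
    """Retain genes with abundance >= ``threshold`` in every in-scope sample.

    The boundary is inclusive: a gene at exactly the threshold everywhere
    is retained; removal is strictly below.  Genes lacking an abundance row
    for some sample count as unexpressed there.
    """
    report = FilterReport()
    wide = abundance.pivot(index="gene_id", columns="sample_id", values="tmm_count")
    cols = [s for s in samples if s in wide.columns]
    if not cols:
        return set(), report
    sub = wide.loc[:, cols].fillna(0.0)
    minimum = sub.min(axis=1)
    retained = set(minimum.index[minimum >= threshold])
    for gene, val in minimum.items():
        if gene not in retained:
            report.add(gene, "expression", scope, float(val))
    return retained, report


def nonrandom_bias_filter(
    ai: pd.DataFrame,
    samples: Sequence[str],
    low: float = 0.1,
    high: float = 0.9,
    scope: str = "tissue",
    filter_name: str = "nonrandom_bias",
) -> Tuple[Set[str], FilterReport]:
    """Remove genes with AI strictly below ``low`` in ALL in-scope samples,
    or strictly above ``high`` in ALL of them (imprint-like fixed bias).

    A gene missing an AI value in some in-scope sample cannot satisfy the
    "all samples" quantifier and is never removed by this rule (logged).
    """
    report = FilterReport()
    if low >= high:
        return set(), report  # degenerate band removes nothing
    wide = _ai_wide(ai, samples)
    if wide.empty:
        return set(), report
    complete = wide.notna().all(axis=1)
    incomplete = int((~complete).sum())
    if incomplete:
        logger.info(
            "%s: %d genes missing AI in some sample; not removable", filter_name, incomplete
        )
    sub = wide.loc[complete]
    all_low = (sub < low).all(axis=1)
    all_high = (sub > high).all(axis=1)
    removed = set(sub.index[all_low | all_high])
    means = sub.mean(axis=1)
    for gene in removed:
        report.add(gene, filter_name, scope, float(means.loc[gene]))
    return removed, report


def trans_deletion_filter(
    ai: pd.DataFrame,
    experiment_samples: Sequence[str],
    low: float = 0.25,
    high: float = 0.75,
    scope: str = "experiment",
) -> Tuple[Set[str], FilterReport]:
    """Wider-band fixed-bias removal restricted to one experiment's samples.

    Used when all samples of an experiment share a large deletion whose
    trans effects skew genome-wide AI; genes outside (low, high) in every
    sample of that experiment are removed.
    """
    return nonrandom_bias_filter(
        ai,
        experiment_samples,
        low=low,
        high=high,
        scope=scope,
        filter_name="trans_deletion",
    )


def loh_filter(
    wes_ai: pd.DataFrame,
    min_total: int = 10,
    band: Tuple[float, float] = (0.25, 0.75),
    all_genes: Optional[Iterable[str]] = None,
) -> Tuple[Set[str], FilterReport]:
    """Exclude genes whose exome data suggests loss of heterozygosity.

    ``wes_ai`` holds per-(sample, gene) DNA ``ai`` and ``total`` columns.
    A gene is excluded from the whole study if, in ANY assayed sample, its
    DNA total is strictly below ``min_total`` or its DNA AI is strictly
    outside ``band``.  Genes without any exome row are retained with a
    warning (the assay simply did not cover them).
    """
    report = FilterReport()
    low, high = band
    excluded: Set[str] = set()
    for _, row in wes_ai.iterrows():
        gene = row["gene_id"]
        if row["total"] < min_total:
            if gene not in excluded:
                report.add(gene, "loh", str(row["sample_id"]), float(row["total"]))
            excluded.add(gene)
        elif row["ai"] < low or row["ai"] > high:
            if gene not in excluded:
                report.add(gene, "loh", str(row["sample_id"]), float(row["ai"]))
            excluded.add(gene)
    if all_genes is not None:
        missing = set(all_genes) - set(wes_ai["gene_id"])
        if missing:
            logger.warning(
                "loh_filter: %d genes lack exome coverage; retained", len(missing)
            )
    return excluded, report


def imprint_screen(
    ai: pd.DataFrame,
    abundance: pd.DataFrame,
    tissue_samples: Sequence[str],
    threshold: float = 0.15,
    expression_min: float = 10.0,
    tissue: str = "B",
) -> pd.DataFrame:
    """Flag candidate nonrandom-bias (imprint-like) genes in one tissue.

    A gene is flagged iff it is robustly expressed (abundance >=
    ``expression_min``) in all samples of the tissue and its AI is <=
    ``threshold`` in all of them or >= 1 - ``threshold`` in all of them.
    Both boundaries are inclusive.  The screen only flags candidates; it
    cannot distinguish genomic imprinting from a genetic cis effect.
    """
    wide = _ai_wide(ai, tissue_samples)
    ab_wide = abundance.pivot(index="gene_id", columns="sample_id", values="tmm_count")
    ab_cols = [s for s in tissue_samples if s in ab_wide.columns]
    expressed = (
        ab_wide.loc[:, ab_cols].fillna(0.0).min(axis=1) >= expression_min
        if ab_cols
        else pd.Series(dtype=bool)
    )
    complete = wide.notna().all(axis=1)
    sub = wide.loc[complete]
    low_all = (sub <= threshold).all(axis=1)
    high_all = (sub >= 1.0 - threshold).all(axis=1)
    candidates = sub.index[(low_all | high_all)]
    flagged = [
        g for g in candidates if bool(expressed.get(g, False))
    ]
    out = pd.DataFrame(
        {
            "gene_id": flagged,
            "tissue": tissue,
            "mean_ai": [float(sub.loc[g].mean()) for g in flagged],
            "direction": [
                "low" if bool(low_all.get(g, False)) else "high" for g in flagged
            ],
        }
    )
    return out.sort_values("gene_id").reset_index(drop=True)


def apply_filters(
    ai: pd.DataFrame,
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    config: FilterConfig,
    wes_ai: Optional[pd.DataFrame] = None,
    trans_experiments: Sequence[str] = (),
    tissue: Optional[str] = None,
) -> Tuple[Set[str], FilterReport]:
    """Compose the standard filter battery; returns retained genes + report.

    Scope is the sample set of ``tissue`` (or all samples).  The exome
    (LOH) exclusion applies study-wide; the trans-deletion band applies to
    the samples of each experiment listed in ``trans_experiments``.
    """
    meta = metadata if tissue is None else metadata.loc[metadata.tissue == tissue]
    samples = meta["sample_id"].tolist()
    scope = tissue or "all"
    report = FilterReport()
    all_genes: Set[str] = set(ai.loc[ai.sample_id.isin(samples), "gene_id"])

    retained_expr, rep = expression_filter(
        abundance, samples, threshold=config.expression_min, scope=scope
    )
    report.extend(rep)
    removed = (all_genes - retained_expr)

    bias_removed, rep = nonrandom_bias_filter(
        ai, samples, low=config.bias_low, high=config.bias_high, scope=scope
    )
    report.extend(rep)
    removed |= bias_removed

    for exp in trans_experiments:
        exp_samples = metadata.loc[
            (metadata.experiment_id == exp) & metadata.sample_id.isin(samples),
            "sample_id",
        ].tolist()
        if not exp_samples:
            continue
        trans_removed, rep = trans_deletion_filter(
            ai, exp_samples, low=config.trans_low, high=config.trans_high, scope=exp
        )
        report.extend(rep)
        removed |= trans_removed

    if wes_ai is not None and not wes_ai.empty:
        loh_removed, rep = loh_filter(
            wes_ai,
            min_total=config.wes_min_total,
            band=config.wes_band,
            all_genes=all_genes,
        )
        report.extend(rep)
        removed |= loh_removed

    return all_genes - removed, report
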