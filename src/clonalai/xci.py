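"""X-chromosome inactivation analysis of clonal hematopoietic samples.

In a population derived from a single female HSC every cell has silenced
the same X chromosome, so X-linked allelic ratios collapse to ~1 (maternal
X active) or ~0 (paternal X active).  Contaminating recipient cells are a
polyclonal admixture with population X AI ``q``, shifting the observed
median to the mixture ``(1 - c) * chi + c * q`` with ``chi`` in {0, 1}.
Genes expressed from the inactive X (escapees) sit displaced from the
skewed median toward 0.5; their inactive-X expression fraction is
recovered after subtracting the contamination contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .simulate import X_CHROM


@dataclass
class ContaminationEstimate:
    sample_id: str
    c: float
    recipient_reads: int
    donor_reads: int
    ci: Tuple[float, float]


@dataclass
class XProfile:
    sample_id: str
    median_x_ai: float
    n_x_genes: int
    expressed_x: str  # maternal / paternal / mixed
    expected_median_given_c: float
    c: float


def estimate_contamination(
    recipient_reads: int, donor_reads: int, sample_id: str = "<sample>", level: float = 0.95
) -> ContaminationEstimate:
    """Recipient-cell fraction from marker-locus allele reads.

    c = recipient / (recipient + donor), with a Wilson binomial interval.
    """
    total = recipient_reads + donor_reads
    if total <= 0:
        raise ValueError("marker locus has zero reads")
    c = recipient_reads / total
    lo, hi = proportion_confint(recipient_reads, total, alpha=1 - level, method="wilson")
    lo, hi = min(float(lo), c), max(float(hi), c)  # guard float slop at 0/1
    return ContaminationEstimate(
        sample_id=sample_id,
        c=float(c),
        recipient_reads=int(recipient_reads),
        donor_reads=int(donor_reads),
        ci=(float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))),
    )


def estimate_contamination_all(marker: pd.DataFrame) -> Dict[str, ContaminationEstimate]:
    out = {}
    for _, row in marker.iterrows():
        out[str(row.sample_id)] = estimate_contamination(
            int(row.recipient_allele_reads),
            int(row.donor_allele_reads),
            sample_id=str(row.sample_id),
        )
    return out


def x_profile(
    sample_ai: pd.DataFrame,
    c: float = 0.0,
    q: float = 0.5,
    min_genes: int = 20,
    exclude_genes: Iterable[str] = (),
    x_chrom: str = X_CHROM,
) -> XProfile:
    """Median X-linked AI of one sample and the mixture-expected median.

    ``exclude_genes`` removes known inactive-X-expressed special cases
    (an Xist-like gene shows AI opposite to every other X gene and would
    distort the median).
    """
    sub = sample_ai.loc[
        (sample_ai["chrom"] == x_chrom) & ~sample_ai["gene_id"].isin(set(exclude_genes))
    ]
    if len(sub) < min_genes:
        raise ValueError(
            f"only {len(sub)} X-linked genes with AI; need >= {min_genes}"
        )
    med = float(sub["ai"].median())
    chi = 1.0 if med > 0.5 else 0.0
    sample_id = str(sub["sample_id"].iloc[0]) if "sample_id" in sub else "<sample>"
    return XProfile(
        sample_id=sample_id,
        median_x_ai=med,
        n_x_genes=int(len(sub)),
        expressed_x="maternal" if med > 0.5 else "paternal",
        expected_median_given_c=(1.0 - c) * chi + c * q,
        c=float(c),
    )


def classify_clonality(
    profile: XProfile, q: float = 0.5, tolerance: float = 0.05
) -> str:
    """Classify a sample from its X AI median.

    ``monoclonal-consistent`` if the median sits within ``tolerance`` of
    the contamination-corrected complete-skew expectation (with the skew
    direction chosen nearest the data); ``polyclonal-consistent`` if it
    sits within ``tolerance`` of the population AI ``q``; otherwise
    ``inconsistent`` (mixed injection or leaky inactivation).  If both
    expectations fit, the closer one wins.
    """
    med = profile.median_x_ai
    c = profile.c
    d_mono = min(abs(med - ((1 - c) * chi + c * q)) for chi in (0.0, 1.0))
    d_poly = abs(med - q)
    mono_ok = d_mono <= tolerance
    poly_ok = d_poly <= tolerance
    if mono_ok and poly_ok:
        return "monoclonal-consistent" if d_mono <= d_poly else "polyclonal-consistent"
    if mono_ok:
        return "monoclonal-consistent"
    if poly_ok:
        return "polyclonal-consistent"
    return "inconsistent"


def _binom_p(k: float, n: float, p0: float) -> float:
    """Two-sided binomial test on (rounded) effective counts."""
    k_i, n_i = int(round(k)), int(round(n))
    if n_i <= 0:
        return 1.0
    k_i = min(max(k_i, 0), n_i)
    p0 = float(min(max(p0, 0.0), 1.0))
    if p0 in (0.0, 1.0):
        observed_matches = (k_i == 0) if p0 == 0.0 else (k_i == n_i)
        return 1.0 if observed_matches else 0.0
    return float(sps.binomtest(k_i, n_i, p0).pvalue)


def call_escapees(
    mono_ai: pd.DataFrame,
    control_ai: pd.DataFrame,
    metadata: pd.DataFrame,
    qcc: Dict[str, float],
    contamination: Dict[str, float],
    abundance: pd.DataFrame,
    alpha: float = 0.05,
    displacement: float = 0.1,
    expression_min: float = 10.0,
    control_band: Tuple[float, float] = (0.3, 0.7),
    min_xi_fraction: float = 0.1,
    exclude_genes: Iterable[str] = (),
    x_chrom: str = X_CHROM,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Call X-inactivation escapees across monoclonal samples.

    Per sample, a gene supports escape if (criterion 1) its AI is displaced
    from the sample's all-X-gene median by at least ``displacement`` toward
    0.5 AND that displacement is significant under the QCC-corrected
    binomial test against the median, and (criterion 2) its abundance
    exceeds ``expression_min`` TMM-normalized counts.  At the gene level,
    (criterion 3) the median AI over control (polyclonal + unmanipulated)
    samples must be balanced, i.e. inside ``control_band``.

    The inactive-X expression fraction is corrected for recipient-cell
    contamination: f = (f_obs - c * f_control) / (1 - c), clipped to [0, 1].

    A gene is called an escapee when criteria hold in at least two samples
    of the same tissue or in at least one B and one T sample, and its mean
    corrected inactive-X fraction over supporting samples is at least
    ``min_xi_fraction``.

    Returns ``(calls, per_sample)``: gene-level calls and the per-sample
    evidence table.
    """
    exclude = set(exclude_genes)
    tissues = metadata.set_index("sample_id")["tissue"].to_dict()
    x_mono = mono_ai.loc[
        (mono_ai["chrom"] == x_chrom) & ~mono_ai["gene_id"].isin(exclude)
    ]
    x_ctrl = control_ai.loc[
        (control_ai["chrom"] == x_chrom) & ~control_ai["gene_id"].isin(exclude)
    ]
    ab = abundance.set_index(["sample_id", "gene_id"])["tmm_count"]

    ctrl_median = x_ctrl.groupby("gene_id")["ai"].median()
    lo, hi = control_band

    rows = []
    for sample_id, grp in x_mono.groupby("sample_id", sort=False):
        med = float(grp["ai"].median())
        maternal_active = med > 0.5
        q2 = qcc.get(sample_id, 1.0) ** 2
        c = float(contamination.get(sample_id, 0.0))
        for _, r in grp.iterrows():
            ai_val = float(r["ai"])
            if maternal_active:
                displaced = ai_val <= med - displacement
                f_obs = 1.0 - ai_val
            else:
                displaced = ai_val >= med + displacement
                f_obs = ai_val
            p_val = (
                _binom_p(r["maternal"] / q2, r["total"] / q2, med) if displaced else 1.0
            )
            crit1 = displaced and (p_val < alpha)
            tmm = float(ab.get((sample_id, r["gene_id"]), 0.0))
            crit2 = tmm > expression_min
            qg = ctrl_median.get(r["gene_id"], np.nan)
            if np.isnan(qg):
                f_ctrl = 0.0
            else:
                f_ctrl = 1.0 - float(qg) if maternal_active else float(qg)
            f_corr = float(np.clip((f_obs - c * f_ctrl) / (1.0 - c), 0.0, 1.0))
            rows.append(
                (
                    r["gene_id"],
                    sample_id,
                    tissues.get(sample_id, "other"),
                    ai_val,
                    med,
                    p_val,
                    crit1,
                    crit2,
                    tmm,
                    f_obs,
                    f_corr,
                )
            )
    per_sample = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "sample_id",
            "tissue",
            "ai",
            "sample_x_median",
            "p_value",
            "criterion1",
            "criterion2",
            "abundance",
            "xi_fraction_raw",
            "xi_fraction_corrected",
        ],
    )

    calls = []
    for gene_id, grp in per_sample.groupby("gene_id", sort=False):
        qg = ctrl_median.get(gene_id, np.nan)
        crit3 = bool(not np.isnan(qg) and lo <= qg <= hi)
        support = grp.loc[grp.criterion1 & grp.criterion2]
        tiss = support["tissue"].tolist()
        same_tissue = any(tiss.count(t) >= 2 for t in set(tiss))
        cross = ("B" in tiss) and ("T" in tiss)
        support_ok = same_tissue or cross
        f_mean = float(support["xi_fraction_corrected"].mean()) if len(support) else 0.0
        call = bool(support_ok and crit3 and f_mean >= min_xi_fraction)
        calls.append(
            (
                gene_id,
                len(support),
                ";".join(support["sample_id"]),
                crit3,
                float(qg) if not np.isnan(qg) else np.nan,
                f_mean,
                call,
            )
        )
    calls_df = pd.DataFrame(
        calls,
        columns=[
            "gene_id",
            "n_supporting",
            "supporting_samples",
            "criterion3",
            "control_median_ai",
            "corrected_xi_fraction",
            "call",
        ],
    )
    return calls_df.sort_values("gene_id").reset_index(drop=True), per_sample


def escapee_overlap(calls: pd.DataFrame, known_escapees: Iterable[str]) -> pd.DataFrame:
    """Set intersection of called escapees with a user-provided catalogue."""
    known = set(known_escapees)
    called = calls.loc[calls.call, "gene_id"]
    return pd.DataFrame(
        {
            "gene_id": called,
            "in_catalogue": [g in known for g in called],
        }
    ).reset_index(drop=True)
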