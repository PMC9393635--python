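"""Overdispersion-corrected allelic-imbalance statistics.

Technical replicates of the same RNA library are two draws from the same
cellular allelic ratio, so under pure binomial sampling the standardized
replicate AI differences

    z = (AI1 - AI2) / sqrt(p * (1 - p) * (1/n1 + 1/n2)),   p pooled,

have unit variance.  Library preparation inflates that variance by an
experiment-specific factor; the quality-control constant (QCC) is the
square root of that inflation, estimated robustly from the replicate pair,
and every downstream binomial test divides allelic counts by QCC**2
("effective counts") before testing.  Under a beta-binomial noise model
with intraclass correlation rho and coverage n the inflation is
1 + (n - 1) * rho, i.e. QCC = sqrt(1 + (n - 1) * rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint


class QCCError(ValueError):
    """QCC estimation prerequisites are not met."""


@dataclass
class QCCEstimate:
    sample_id: str
    qcc: float
    n_genes_used: int
    method: Dict[str, object] = field(default_factory=dict)


@dataclass
class AITestResult:
    gene_id: str
    sample_a: str
    sample_b: str
    ai1: float
    ai2: float
    effective_total1: float
    effective_total2: float
    p_value: float
    ci1: Tuple[float, float]
    ci2: Tuple[float, float]
    significant: bool


def _trimmed_chi2_mean(trim: float) -> float:
    """Mean of chi-square(1) after two-sided trimming at ``trim``.

    Uses the identity x * f_chi2_1(x) = f_chi2_3(x), so the trimmed mean is
    (F3(q_hi) - F3(q_lo)) / (1 - 2 * trim) with q the chi2(1) quantiles.
    The z**2 trimmed mean is divided by this constant so the estimator is
    consistent under the binomial null (analogous to the 1.4826 factor that
    calibrates the MAD against the normal).
    """
    q_lo = sps.chi2.ppf(trim, df=1)
    q_hi = sps.chi2.ppf(1.0 - trim, df=1)
    return float((sps.chi2.cdf(q_hi, df=3) - sps.chi2.cdf(q_lo, df=3)) / (1 - 2 * trim))


def replicate_z_scores(
    sample_table: pd.DataFrame, min_total: int = 10
) -> Tuple[np.ndarray, int]:
    """Standardized replicate AI differences for one sample's two replicates.

    Eligible genes have both replicate totals >= ``min_total`` and a pooled
    AI strictly inside (0, 1).
    """
    reps = sorted(sample_table["replicate_id"].unique())
    if len(reps) != 2:
        raise QCCError(
            f"QCC requires exactly 2 technical replicates, found {len(reps)}"
        )
    piv_m = sample_table.pivot_table(
        index="gene_id", columns="replicate_id", values="maternal_count", aggfunc="sum"
    )
    piv_t = sample_table.assign(
        total=sample_table.maternal_count + sample_table.paternal_count
    ).pivot_table(index="gene_id", columns="replicate_id", values="total", aggfunc="sum")
    m1 = piv_m[reps[0]].to_numpy(dtype=float)
    m2 = piv_m[reps[1]].to_numpy(dtype=float)
    n1 = piv_t[reps[0]].to_numpy(dtype=float)
    n2 = piv_t[reps[1]].to_numpy(dtype=float)
    ok = np.isfinite(n1) & np.isfinite(n2) & (n1 >= min_total) & (n2 >= min_total)
    m1, m2, n1, n2 = m1[ok], m2[ok], n1[ok], n2[ok]
    p = (m1 + m2) / (n1 + n2)
    inner = (p > 0) & (p < 1)
    m1, m2, n1, n2, p = m1[inner], m2[inner], n1[inner], n2[inner], p[inner]
    z = (m1 / n1 - m2 / n2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    return z, int(z.size)


def estimate_qcc(
    sample_table: pd.DataFrame,
    min_total: int = 10,
    trim: float = 0.1,
    sample_id: Optional[str] = None,
    min_genes: int = 50,
) -> QCCEstimate:
    """Estimate the per-sample quality-control constant from replicates.

    QCC is sqrt of the two-sided ``trim``-trimmed mean of z**2, divided by
    the matching trimmed mean of the reference chi-square(1) so that pure
    binomial replicates give QCC ~= 1, and clipped below at 1.
    """
    if sample_id is None:
        ids = sample_table["sample_id"].unique()
        sample_id = str(ids[0]) if ids.size else "<sample>"
    z, n_genes = replicate_z_scores(sample_table, min_total=min_total)
    if n_genes < min_genes:
        raise QCCError(
            f"sample {sample_id}: only {n_genes} genes with both replicate "
            f"totals >= {min_total}; at least {min_genes} are required. "
            "Consider calibrating QCC on simulated data with matched "
            "coverage instead."
        )
    kappa = _trimmed_chi2_mean(trim)
    raw = sps.trim_mean(z**2, trim) / kappa
    qcc = float(max(1.0, np.sqrt(max(raw, 0.0))))
    return QCCEstimate(
        sample_id=sample_id,
        qcc=qcc,
        n_genes_used=n_genes,
        method={
            "estimator": "trimmed-z2",
            "trim": trim,
            "min_total": min_total,
            "chi2_calibration": kappa,
            "uncorrected": float(np.sqrt(max(raw, 0.0))),
        },
    )


def estimate_qcc_all(
    table: pd.DataFrame,
    min_total: int = 10,
    trim: float = 0.1,
    autosomes_only: bool = True,
    x_chrom: str = "chrX",
) -> Dict[str, QCCEstimate]:
    """Per-sample QCC over a multi-sample RNA count table.

    By default only autosomal genes enter the estimate: in a monoclonal
    female sample the X is almost fully skewed and its near-degenerate
    allelic ratios violate the normal approximation behind z.
    """
    sub = table
    if autosomes_only and "chrom" in table.columns:
        sub = table.loc[table["chrom"] != x_chrom]
    out = {}
    for sample_id, grp in sub.groupby("sample_id", sort=False):
        out[str(sample_id)] = estimate_qcc(
            grp, min_total=min_total, trim=trim, sample_id=str(sample_id)
        )
    return out


def ai_confint(
    maternal: float,
    paternal: float,
    qcc: float = 1.0,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Wilson interval for the allelic ratio on QCC-effective counts."""
    total = maternal + paternal
    if total <= 0:
        raise ValueError("confidence interval undefined for zero total counts")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo, hi = proportion_confint(
        maternal / qcc**2, total / qcc**2, alpha=1.0 - level, method="wilson"
    )
    point = maternal / total
    lo, hi = min(float(lo), point), max(float(hi), point)  # guard float slop
    return (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))


def exact_two_proportion_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """Unconditional exact two-proportion test with the pooled plug-in null.

    Enumerates every outcome pair and sums the probability, under
    p0 = (x1 + x2) / (n1 + n2), of an absolute AI difference at least as
    large as observed.
    """
    p0 = (x1 + x2) / (n1 + n2)
    d = abs(x1 / n1 - x2 / n2)
    pi = sps.binom.pmf(np.arange(n1 + 1), n1, p0)
    pj = sps.binom.pmf(np.arange(n2 + 1), n2, p0)
    diff = np.abs(
        np.arange(n1 + 1)[:, None] / n1 - np.arange(n2 + 1)[None, :] / n2
    )
    mask = diff >= d - 1e-12
    return float(pi @ mask @ pj)


def _is_integral(x: np.ndarray) -> np.ndarray:
    return np.abs(x - np.round(x)) < 1e-9


def diff_ai_pvalues(
    m1: np.ndarray,
    n1: np.ndarray,
    m2: np.ndarray,
    n2: np.ndarray,
    qcc1: float | np.ndarray = 1.0,
    qcc2: float | np.ndarray = 1.0,
    exact_max_total: int = 100,
) -> np.ndarray:
    """Vectorized two-sided differential-AI p-values on effective counts.

    Counts on each side are divided by that side's QCC**2.  When both
    effective totals are integers no larger than ``exact_max_total`` the
    exact enumeration test is used; otherwise the pooled two-proportion
    z-test.  Degenerate pooled ratios (0 or 1, i.e. both sides at the same
    extreme) give p = 1.
    """
    m1 = np.asarray(m1, float)
    n1 = np.asarray(n1, float)
    m2 = np.asarray(m2, float)
    n2 = np.asarray(n2, float)
    q1sq = np.broadcast_to(np.asarray(qcc1, float) ** 2, m1.shape)
    q2sq = np.broadcast_to(np.asarray(qcc2, float) ** 2, m2.shape)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("differential AI test requires positive totals")
    em1, en1 = m1 / q1sq, n1 / q1sq
    em2, en2 = m2 / q2sq, n2 / q2sq
    ai1, ai2 = m1 / n1, m2 / n2
    pooled = (em1 + em2) / (en1 + en2)
    p = np.ones_like(pooled)
    live = (pooled > 0) & (pooled < 1)
    se = np.sqrt(
        np.where(live, pooled * (1 - pooled), 1.0) * (1 / en1 + 1 / en2)
    )
    z = np.where(live, (ai1 - ai2) / se, 0.0)
    p = np.where(live, 2.0 * sps.norm.sf(np.abs(z)), 1.0)
    p = np.minimum(p, 1.0)

    exact = (
        live
        & (en1 <= exact_max_total)
        & (en2 <= exact_max_total)
        & _is_integral(em1)
        & _is_integral(en1)
        & _is_integral(em2)
        & _is_integral(en2)
    )
    for idx in np.flatnonzero(exact):
        p.flat[idx] = exact_two_proportion_p(
            int(round(em1.flat[idx])),
            int(round(en1.flat[idx])),
            int(round(em2.flat[idx])),
            int(round(en2.flat[idx])),
        )
    return p


def diff_ai_test(
    maternal1: float,
    paternal1: float,
    maternal2: float,
    paternal2: float,
    qcc1: float = 1.0,
    qcc2: float = 1.0,
    alpha: float = 0.05,
    gene_id: str = "<gene>",
    sample_a: str = "A",
    sample_b: str = "B",
    level: float = 0.95,
    exact_max_total: int = 100,
) -> AITestResult:
    """QCC-corrected test of differential AI between two samples."""
    n1 = maternal1 + paternal1
    n2 = maternal2 + paternal2
    if n1 <= 0 or n2 <= 0:
        raise ValueError("differential AI test requires positive totals")
    p = float(
        diff_ai_pvalues(
            np.array([maternal1]),
            np.array([n1]),
            np.array([maternal2]),
            np.array([n2]),
            qcc1,
            qcc2,
            exact_max_total=exact_max_total,
        )[0]
    )
    return AITestResult(
        gene_id=gene_id,
        sample_a=sample_a,
        sample_b=sample_b,
        ai1=maternal1 / n1,
        ai2=maternal2 / n2,
        effective_total1=n1 / qcc1**2,
        effective_total2=n2 / qcc2**2,
        p_value=p,
        ci1=ai_confint(maternal1, paternal1, qcc1, level),
        ci2=ai_confint(maternal2, paternal2, qcc2, level),
        significant=p < alpha,
    )


@dataclass
class PairwiseResult:
    """Pairwise differential-AI summary over a sample set.

    ``n_significant`` and ``pearson_r`` are symmetric sample x sample
    frames; ``significant_genes`` maps an (a, b) pair (a < b) to the list
    of genes whose AI differs significantly after QCC correction.
    """

    n_significant: pd.DataFrame
    pearson_r: pd.DataFrame
    significant_genes: Dict[Tuple[str, str], list]
    n_shared: pd.DataFrame


def pairwise_significance(
    maternal: pd.DataFrame,
    total: pd.DataFrame,
    qcc: Dict[str, float],
    alpha: float = 0.05,
    genes: Optional[Iterable[str]] = None,
    min_shared: int = 3,
) -> PairwiseResult:
    """All-pairs QCC-corrected differential AI and AI correlation.

    ``maternal`` and ``total`` are replicate-pooled gene x sample count
    matrices (NaN where a gene was not measured).  Pearson r is computed on
    AI point estimates over the genes shared by each pair; pairs sharing
    fewer than ``min_shared`` genes get NaN.
    """
    if genes is not None:
        idx = maternal.index.intersection(pd.Index(genes))
        maternal, total = maternal.loc[idx], total.loc[idx]
    samples = list(maternal.columns)
    n = len(samples)
    n_sig = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    n_shared = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    r_mat = pd.DataFrame(np.nan, index=samples, columns=samples, dtype=float)
    sig_genes: Dict[Tuple[str, str], list] = {}
    ai = maternal / total
    for i in range(n):
        r_mat.iloc[i, i] = 1.0
        n_shared.iloc[i, i] = int(total.iloc[:, i].gt(0).sum())
    for i in range(n):
        for j in range(i + 1, n):
            a, b = samples[i], samples[j]
            shared = (total[a] > 0) & (total[b] > 0)
            shared &= total[a].notna() & total[b].notna()
            k = int(shared.sum())
            n_shared.loc[a, b] = n_shared.loc[b, a] = k
            if k == 0:
                sig_genes[(a, b)] = []
                continue
            pv = diff_ai_pvalues(
                maternal.loc[shared, a].to_numpy(),
                total.loc[shared, a].to_numpy(),
                maternal.loc[shared, b].to_numpy(),
                total.loc[shared, b].to_numpy(),
                qcc.get(a, 1.0),
                qcc.get(b, 1.0),
            )
            hits = maternal.index[shared][pv < alpha].tolist()
            sig_genes[(a, b)] = hits
            n_sig.loc[a, b] = n_sig.loc[b, a] = len(hits)
            if k >= min_shared:
                r = np.corrcoef(ai.loc[shared, a], ai.loc[shared, b])[0, 1]
                r_mat.loc[a, b] = r_mat.loc[b, a] = float(r)
    return PairwiseResult(
        n_significant=n_sig,
        pearson_r=r_mat,
        significant_genes=sig_genes,
        n_shared=n_shared,
    )
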