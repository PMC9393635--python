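"""Discovery of autosomal genes with mitotically stable clone-specific AI.

A gene under stable random monoallelic expression (RME) keeps a
clone-specific allelic ratio through expansion and differentiation, so
across a set of monoclonal samples its AI disperses while polyclonal
controls stay balanced.  The screen compares the AI standard deviation in
the monoclonal and polyclonal sample sets gene by gene, tests the
resulting asymmetry with an exact one-sided signed-rank test, checks
cross-lineage concordance (B vs T of the same animal against a
swapped-animal control), and guards against loss of heterozygosity with a
bootstrap of DNA-minus-RNA allelic differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ConcordanceResult:
    pairing: str  # within_animal | swapped_control
    pearson_r: float
    p_value: float
    n_genes: int


@dataclass
class BootstrapResult:
    sample_id: str
    statistic: str  # signed_mean | absolute_mean
    observed: float
    n_replicates: int
    p_value: float
    null_mean: float
    null_q05: float
    null_q95: float
    n_flagged: int


def sd_analysis(
    ai: pd.DataFrame,
    metadata: pd.DataFrame,
    candidate_genes: Optional[Iterable[str]] = None,
    expressed_genes: Optional[Iterable[str]] = None,
    threshold: float = 0.15,
    tissue: str = "B",
    x_chrom: str = "chrX",
    include_x: bool = False,
) -> pd.DataFrame:
    """Per-gene AI standard deviations in monoclonal vs polyclonal samples.

    ``candidate_genes`` is the prefilter of genes significant in at least
    one pairwise comparison; ``expressed_genes`` the prefilter of genes
    expressed in all samples.  Both are recorded as flags and combined with
    the dispersion rule (sample s.d., n-1 denominator) into ``flagged``:
    sd_mono >= threshold and sd_poly < threshold with both prefilters
    passed.  ``flagged_unfiltered`` applies the dispersion rule alone.
    Groups need at least 3 samples each.
    """
    meta = metadata.loc[metadata.tissue == tissue]
    mono = meta.loc[meta.clonality == "monoclonal", "sample_id"].tolist()
    poly = meta.loc[meta.clonality.isin(["polyclonal", "unmanipulated"]), "sample_id"].tolist()
    if len(mono) < 3 or len(poly) < 3:
        raise ValueError(
            f"sd_analysis needs >= 3 monoclonal and >= 3 control samples "
            f"(got {len(mono)} / {len(poly)})"
        )
    sub = ai if include_x else ai.loc[ai["chrom"] != x_chrom]
    wide = sub.pivot(index="gene_id", columns="sample_id", values="ai")
    mono_cols = [s for s in mono if s in wide.columns]
    poly_cols = [s for s in poly if s in wide.columns]
    complete = wide[mono_cols].notna().all(axis=1) & wide[poly_cols].notna().all(axis=1)
    wide = wide.loc[complete]
    out = pd.DataFrame(
        {
            "gene_id": wide.index,
            "sd_mono": wide[mono_cols].std(axis=1, ddof=1).to_numpy(),
            "sd_poly": wide[poly_cols].std(axis=1, ddof=1).to_numpy(),
            "n_mono": len(mono_cols),
            "n_poly": len(poly_cols),
        }
    ).reset_index(drop=True)
    cand = set(candidate_genes) if candidate_genes is not None else None
    expr = set(expressed_genes) if expressed_genes is not None else None
    out["significant_pairwise"] = (
        out.gene_id.isin(cand) if cand is not None else True
    )
    out["expressed_all"] = out.gene_id.isin(expr) if expr is not None else True
    disp = (out.sd_mono >= threshold) & (out.sd_poly < threshold)
    out["flagged_unfiltered"] = disp
    out["flagged"] = disp & out.significant_pairwise & out.expressed_all
    return out


def wilcoxon_asymmetry(calls: pd.DataFrame, min_flagged: int = 5) -> float:
    """Exact one-sided signed-rank p for sd_mono > sd_poly over flagged genes.

    Uses the exact null distribution for n <= 25, the normal approximation
    beyond.  Returns 1.0 when every paired difference is zero.
    """
    flagged = calls.loc[calls.flagged]
    n = len(flagged)
    if n < min_flagged:
        raise ValueError(f"wilcoxon_asymmetry needs >= {min_flagged} flagged genes, got {n}")
    d = flagged.sd_mono.to_numpy() - flagged.sd_poly.to_numpy()
    if np.all(d == 0):
        return 1.0
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(d, alternative="greater", method=method)
    return float(res.pvalue)


def cross_lineage_concordance(
    ai_b: pd.DataFrame,
    ai_t: pd.DataFrame,
    animals: Dict[str, str],
    genes: Iterable[str],
) -> Tuple[ConcordanceResult, ConcordanceResult]:
    """Pearson correlation of gene AI between B and T cells of each animal,
    against a control in which animals are deliberately mispaired.

    ``animals`` maps a B sample id and a T sample id to their animal; at
    least two animals must have both tissues.  The swapped control pairs
    each animal's B data with the next animal's T data (cyclic shift), on
    exactly the same gene set.
    """
    genes = list(genes)
    if len(genes) < 3:
        raise ValueError("concordance needs >= 3 genes")
    b_by_animal: Dict[str, pd.Series] = {}
    t_by_animal: Dict[str, pd.Series] = {}
    for df, store in ((ai_b, b_by_animal), (ai_t, t_by_animal)):
        for sample_id, grp in df.groupby("sample_id"):
            animal = animals.get(str(sample_id))
            if animal is None:
                continue
            store[animal] = grp.set_index("gene_id")["ai"]
    shared_animals = sorted(set(b_by_animal) & set(t_by_animal))
    if len(shared_animals) < 2:
        raise ValueError("concordance needs >= 2 animals with both tissues")

    def _stack(pairing: Sequence[Tuple[str, str]]) -> Tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for a_b, a_t in pairing:
            b = b_by_animal[a_b]
            t = t_by_animal[a_t]
            for g in genes:
                if g in b.index and g in t.index:
                    xs.append(float(b.loc[g]))
                    ys.append(float(t.loc[g]))
        return np.array(xs), np.array(ys)

    within_pairs = [(a, a) for a in shared_animals]
    swapped_pairs = [
        (shared_animals[i], shared_animals[(i + 1) % len(shared_animals)])
        for i in range(len(shared_animals))
    ]
    results = []
    for name, pairing in (
        ("within_animal", within_pairs),
        ("swapped_control", swapped_pairs),
    ):
        x, y = _stack(pairing)
        if x.size < 3:
            raise ValueError("concordance needs >= 3 paired gene values")
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = sps.pearsonr(x, y)
        results.append(
            ConcordanceResult(
                pairing=name, pearson_r=float(r), p_value=float(p), n_genes=int(x.size)
            )
        )
    return results[0], results[1]


def _sample_subset_means(
    values: np.ndarray,
    k: int,
    n_replicates: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Means of ``n_replicates`` random size-k subsets drawn without
    replacement (within a subset) from ``values``.

    Uses random-key top-k selection per replicate, chunked to bound memory.
    """
    n = values.size
    out = np.empty(n_replicates)
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[done : done + m] = values[idx].mean(axis=1)
        done += m
    return out


def bootstrap_dna_rna(
    diffs: pd.Series,
    flagged_genes: Iterable[str],
    n_replicates: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "<sample>",
    statistics: Sequence[str] = ("signed_mean", "absolute_mean"),
) -> List[BootstrapResult]:
    """Bootstrap the DNA-minus-RNA allelic difference of a flagged gene set.

    ``diffs`` holds AI_DNA - AI_RNA per eligible gene (expressed, with
    exome coverage), indexed by gene.  The observed statistic over the
    flagged subset is compared with the same statistic over random
    same-size subsets of the pool; the upper-tail p-value is
    (1 + #{null >= observed}) / (B + 1), never zero.  A genuine allelic
    loss shifts DNA away from 0.5 and yields a small p; an epigenetic
    clone-specific bias leaves DNA balanced and does not.
    """
    rng = rng if rng is not None else np.random.default_rng()
    flagged = [g for g in flagged_genes if g in diffs.index]
    k = len(flagged)
    pool = diffs.dropna()
    if k == 0:
        raise ValueError("no flagged genes with eligible DNA/RNA differences")
    if len(pool) < 2 * k:
        raise ValueError(
            f"eligible pool ({len(pool)} genes) must be at least twice the "
            f"flagged set ({k})"
        )
    results = []
    values = pool.to_numpy()
    flagged_vals = pool.loc[flagged].to_numpy()
    for stat in statistics:
        if stat == "signed_mean":
            observed = float(flagged_vals.mean())
            null = _sample_subset_means(values, k, n_replicates, rng)
        elif stat == "absolute_mean":
            observed = float(np.abs(flagged_vals).mean())
            null = _sample_subset_means(np.abs(values), k, n_replicates, rng)
        else:
            raise ValueError(f"unknown statistic {stat!r}")
        p = (1 + int(np.sum(null >= observed))) / (n_replicates + 1)
        results.append(
            BootstrapResult(
                sample_id=sample_id,
                statistic=stat,
                observed=observed,
                n_replicates=n_replicates,
                p_value=float(p),
                null_mean=float(null.mean()),
                null_q05=float(np.quantile(null, 0.05)),
                null_q95=float(np.quantile(null, 0.95)),
                n_flagged=k,
            )
        )
    return results


def ai_pca(ai_wide: pd.DataFrame, n_components: int = 2) -> Tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the gene x sample AI matrix.

    Complete-case genes only; the matrix is gene-centred and decomposed by
    SVD.  Each component's loading vector is oriented so that its
    largest-magnitude entry is positive, which makes the projection
    deterministic.  Returns (sample scores, explained variance ratio).
    """
    complete = ai_wide.dropna(axis=0)
    if complete.shape[0] < 3 or complete.shape[1] < 3:
        raise ValueError("PCA needs at least 3 complete-case genes and 3 samples")
    x = complete.to_numpy(dtype=float)
    centred = (x - x.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, s.size)
    for comp in range(k):
        j = int(np.argmax(np.abs(vt[comp])))
        if vt[comp, j] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    scores = u[:, :k] * s[:k]
    total_var = float(np.sum(s**2))
    evr = (s[:k] ** 2 / total_var) if total_var > 0 else np.zeros(k)
    frame = pd.DataFrame(
        scores,
        index=complete.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    frame.index.name = "sample_id"
    return frame, evr
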