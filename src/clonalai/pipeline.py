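"""End-to-end orchestration from count tables to the report bundle.

The run proceeds: TMM abundance -> per-sample QCC -> AI point estimates ->
filters -> contamination + X profiles + clonality -> escapee calls ->
pairwise differential-AI matrices -> SD-based stable-RME screen (with
signed-rank asymmetry test) -> cross-lineage concordance -> DNA/RNA
bootstrap -> AI PCA.  Every intermediate is a plain TSV/JSON artifact so a
run can be inspected and resumed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import counts as cio
from . import filters as flt
from . import rme as rme_mod
from . import stats as ai_stats
from . import xci as xci_mod
from .config import PipelineConfig
from .simulate import DNA_ASSAY, RNA_ASSAY, X_CHROM, SimulatedStudy, simulate_study

logger = logging.getLogger(__name__)


def write_study(study: SimulatedStudy, outdir) -> Dict[str, Path]:
    """Write a simulated study's tables (and truth) as TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rna_counts": outdir / "rna_counts.tsv",
        "wes_counts": outdir / "wes_counts.tsv",
        "marker_counts": outdir / "marker_counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_sample_ai": outdir / "truth_sample_ai.tsv",
        "truth_contamination": outdir / "truth_contamination.tsv",
    }
    cio.write_counts(study.rna_counts, paths["rna_counts"])
    cio.write_counts(study.wes_counts, paths["wes_counts"])
    study.marker_counts.to_csv(paths["marker_counts"], sep="\t", index=False)
    cio.write_metadata(study.metadata, paths["metadata"])
    study.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    study.truth.sample_ai.to_csv(paths["truth_sample_ai"], sep="\t", index=False)
    pd.DataFrame(
        [
            (s, c, study.truth.x_choice.get(s.split("_")[0], ""))
            for s, c in study.truth.contamination.items()
        ],
        columns=["sample_id", "contamination", "maternal_x_active"],
    ).to_csv(paths["truth_contamination"], sep="\t", index=False)
    return paths


def load_inputs(inputs: Dict[str, str]):
    rna = cio.read_counts(inputs["rna_counts"])
    meta = cio.read_metadata(inputs["metadata"])
    wes = (
        cio.read_counts(inputs["wes_counts"])
        if inputs.get("wes_counts")
        else None
    )
    marker = (
        pd.read_csv(inputs["marker_counts"], sep="\t")
        if inputs.get("marker_counts")
        else None
    )
    return rna, meta, wes, marker


def run_pipeline(
    config: PipelineConfig,
    study: Optional[SimulatedStudy] = None,
    outdir: Optional[str] = None,
) -> Dict[str, object]:
    """Run the full analysis; returns (and optionally writes) the bundle."""
    t0 = time.time()
    if study is None and config.simulation is not None:
        study = simulate_study(config.simulation)
    if study is not None:
        rna, meta = study.rna_counts, study.metadata
        wes, marker = study.wes_counts, study.marker_counts
    else:
        rna, meta, wes, marker = load_inputs(config.inputs or {})

    n_reps = rna.groupby("sample_id")["replicate_id"].nunique()
    if (n_reps < 2).any():
        bad = n_reps.index[n_reps < 2].tolist()
        raise ValueError(
            f"samples {bad} have fewer than 2 technical replicates; the "
            "replicate-overdispersion constant (QCC) cannot be estimated"
        )

    bundle: Dict[str, object] = {}
    fcfg = config.filters

    # Abundance (TMM) from replicate-pooled totals.
    maternal, total = cio.pooled_counts_matrix(rna)
    factors, abundance_wide = cio.tmm_normalize(total.fillna(0.0))
    abundance = cio.abundance_long(abundance_wide)
    bundle["tmm_factors"] = factors
    logger.info("TMM factors computed for %d libraries", len(factors))

    # Per-sample QCC from technical replicates (autosomal genes).
    qcc_est = ai_stats.estimate_qcc_all(rna, min_total=config.qcc_min_total)
    qcc = {s: e.qcc for s, e in qcc_est.items()}
    bundle["qcc"] = qcc_est

    # AI point estimates on pooled replicates.
    ai = cio.compute_ai(rna, pool_replicates=True)
    bundle["ai"] = ai

    # Contamination per monoclonal sample.
    contamination: Dict[str, float] = {}
    if marker is not None and len(marker):
        cont = xci_mod.estimate_contamination_all(marker)
        contamination = {s: e.c for s, e in cont.items()}
        bundle["contamination"] = cont

    # WES AI for the LOH exclusion and the bootstrap.
    wes_ai = None
    if wes is not None and len(wes):
        wes_ai = cio.compute_ai(wes, pool_replicates=True)
        bundle["wes_ai"] = wes_ai

    # Filters per tissue.
    retained: Dict[str, set] = {}
    report = flt.FilterReport()
    for tissue in sorted(meta.tissue.unique()):
        kept, rep = flt.apply_filters(
            ai, abundance, meta, fcfg, wes_ai=wes_ai, tissue=tissue
        )
        retained[tissue] = kept
        report.extend(rep)
        logger.info("tissue %s: %d genes retained", tissue, len(kept))
    bundle["retained"] = retained
    bundle["filter_report"] = report

    # X profiles and clonality, using controls to anchor the population AI.
    ctrl_samples = meta.loc[
        meta.clonality.isin(["polyclonal", "unmanipulated"]), "sample_id"
    ]
    ctrl_ai = ai.loc[ai.sample_id.isin(ctrl_samples)]
    x_ctrl = ctrl_ai.loc[ctrl_ai.chrom == X_CHROM]
    q = float(x_ctrl["ai"].median()) if len(x_ctrl) else 0.5
    bundle["x_population_ai"] = q
    profiles = {}
    clonality_calls = {}
    for sample_id, grp in ai.groupby("sample_id"):
        c = contamination.get(str(sample_id), 0.0)
        try:
            prof = xci_mod.x_profile(grp, c=c, q=q)
        except ValueError:
            continue
        profiles[str(sample_id)] = prof
        clonality_calls[str(sample_id)] = xci_mod.classify_clonality(
            prof, q=q, tolerance=config.clonality_tolerance
        )
    bundle["x_profiles"] = profiles
    bundle["clonality"] = clonality_calls

    # Escapee calls over monoclonal samples.
    mono_samples = meta.loc[meta.clonality == "monoclonal", "sample_id"]
    mono_ai = ai.loc[ai.sample_id.isin(mono_samples)]
    if len(mono_ai) and len(ctrl_ai):
        esc_calls, esc_detail = xci_mod.call_escapees(
            mono_ai,
            ctrl_ai,
            meta,
            qcc,
            contamination,
            abundance,
            alpha=config.alpha,
            displacement=config.escapee_displacement,
            expression_min=fcfg.expression_min,
            control_band=config.escapee_control_band,
            min_xi_fraction=config.escapee_min_xi_fraction,
        )
        bundle["escapees"] = esc_calls
        bundle["escapee_detail"] = esc_detail

    # Pairwise differential AI per tissue (autosomal, filtered genes).
    pairwise = {}
    for tissue, kept in retained.items():
        t_samples = meta.loc[meta.tissue == tissue, "sample_id"].tolist()
        cols = [s for s in t_samples if s in maternal.columns]
        if len(cols) < 2:
            continue
        auto_genes = set(ai.loc[ai.chrom != X_CHROM, "gene_id"]) & kept
        pairwise[tissue] = ai_stats.pairwise_significance(
            maternal[cols], total[cols], qcc, alpha=config.alpha, genes=auto_genes
        )
    bundle["pairwise"] = pairwise

    # SD-based stable-RME screen in B cells.
    rng = np.random.default_rng(config.seed)
    if "B" in pairwise:
        b_meta = meta.loc[meta.tissue == "B"]
        sig_union = set()
        for genes_list in pairwise["B"].significant_genes.values():
            sig_union.update(genes_list)
        b_samples = b_meta["sample_id"].tolist()
        expr_all, _ = flt.expression_filter(
            abundance, b_samples, threshold=fcfg.expression_min
        )
        try:
            calls = rme_mod.sd_analysis(
                ai.loc[ai.sample_id.isin(b_samples)],
                meta,
                candidate_genes=sig_union & retained["B"],
                expressed_genes=expr_all,
                threshold=config.sd_threshold,
                tissue="B",
            )
            bundle["stable_rme"] = calls
            flagged = calls.loc[calls.flagged]
            if len(flagged) >= 5:
                bundle["wilcoxon_p"] = rme_mod.wilcoxon_asymmetry(calls)
        except ValueError as exc:
            logger.info("stable-RME screen skipped: %s", exc)

    # Cross-lineage concordance for animals with both tissues.
    animals = meta.set_index("sample_id")["animal_id"].to_dict()
    mono_meta = meta.loc[meta.clonality == "monoclonal"]
    both = (
        mono_meta.groupby("animal_id")["tissue"].nunique().pipe(lambda s: s[s >= 2])
    )
    if len(both) >= 2 and "stable_rme" in bundle:
        flagged_genes = bundle["stable_rme"].loc[
            bundle["stable_rme"].flagged, "gene_id"
        ].tolist()
        if len(flagged_genes) >= 3:
            ai_b = ai.loc[
                ai.sample_id.isin(mono_meta.loc[mono_meta.tissue == "B", "sample_id"])
            ]
            ai_t = ai.loc[
                ai.sample_id.isin(mono_meta.loc[mono_meta.tissue == "T", "sample_id"])
            ]
            try:
                within, swapped = rme_mod.cross_lineage_concordance(
                    ai_b, ai_t, animals, flagged_genes
                )
                bundle["concordance"] = (within, swapped)
            except ValueError as exc:
                logger.info("concordance skipped: %s", exc)

    # DNA/RNA bootstrap per WES-assayed sample.
    if wes_ai is not None and "stable_rme" in bundle:
        flagged_genes = bundle["stable_rme"].loc[
            bundle["stable_rme"].flagged, "gene_id"
        ].tolist()
        boots = []
        if flagged_genes:
            for sample_id in wes_ai.sample_id.unique():
                if sample_id not in set(ai.sample_id):
                    continue
                rna_s = ai.loc[ai.sample_id == sample_id].set_index("gene_id")["ai"]
                dna_s = wes_ai.loc[wes_ai.sample_id == sample_id].set_index("gene_id")["ai"]
                expr_s = abundance.loc[
                    (abundance.sample_id == sample_id)
                    & (abundance.tmm_count > fcfg.expression_min),
                    "gene_id",
                ]
                pool_genes = (
                    set(rna_s.index) & set(dna_s.index) & set(expr_s)
                )
                pool_genes &= set(
                    ai.loc[ai.chrom != X_CHROM, "gene_id"]
                )
                diffs = (dna_s - rna_s).loc[sorted(pool_genes)]
                usable = [g for g in flagged_genes if g in diffs.index]
                if len(usable) < 2 or len(diffs) < 2 * len(usable):
                    continue
                boots.extend(
                    rme_mod.bootstrap_dna_rna(
                        diffs,
                        usable,
                        n_replicates=config.bootstrap_replicates,
                        rng=rng,
                        sample_id=str(sample_id),
                    )
                )
        bundle["bootstrap"] = boots

    # AI PCA over autosomal genes of all samples.
    auto_ai = ai.loc[ai.chrom != X_CHROM]
    wide = auto_ai.pivot(index="gene_id", columns="sample_id", values="ai")
    try:
        scores, evr = rme_mod.ai_pca(wide)
        bundle["pca_scores"] = scores
        bundle["pca_explained"] = evr
    except ValueError as exc:
        logger.info("PCA skipped: %s", exc)

    logger.info("pipeline finished in %.1f s", time.time() - t0)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(x).items()}
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_bundle(bundle: Dict[str, object], outdir) -> None:
    """Serialize the report bundle as TSV/JSON artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if "ai" in bundle:
        bundle["ai"].to_csv(out / "ai_estimates.tsv", sep="\t", index=False)
    if "tmm_factors" in bundle:
        bundle["tmm_factors"].rename("tmm_factor").to_csv(
            out / "tmm_factors.tsv", sep="\t", header=True
        )
    if "qcc" in bundle:
        pd.DataFrame(
            [
                (s, e.qcc, e.n_genes_used)
                for s, e in bundle["qcc"].items()
            ],
            columns=["sample_id", "qcc", "n_genes_used"],
        ).to_csv(out / "qcc.tsv", sep="\t", index=False)
    if "filter_report" in bundle:
        bundle["filter_report"].to_frame().to_csv(
            out / "filter_report.tsv", sep="\t", index=False
        )
    if "escapees" in bundle:
        bundle["escapees"].to_csv(out / "escapee_calls.tsv", sep="\t", index=False)
        bundle["escapee_detail"].to_csv(
            out / "escapee_detail.tsv", sep="\t", index=False
        )
    if "stable_rme" in bundle:
        bundle["stable_rme"].to_csv(out / "stable_rme.tsv", sep="\t", index=False)
    if "pairwise" in bundle:
        for tissue, res in bundle["pairwise"].items():
            res.n_significant.to_csv(out / f"pairwise_nsig_{tissue}.tsv", sep="\t")
            res.pearson_r.to_csv(out / f"pairwise_r_{tissue}.tsv", sep="\t")
    if "pca_scores" in bundle:
        bundle["pca_scores"].to_csv(out / "pca_scores.tsv", sep="\t")
    summary = {}
    for key in (
        "clonality",
        "x_population_ai",
        "wilcoxon_p",
    ):
        if key in bundle:
            summary[key] = _jsonable(bundle[key])
    if "x_profiles" in bundle:
        summary["x_profiles"] = _jsonable(bundle["x_profiles"])
    if "contamination" in bundle:
        summary["contamination"] = _jsonable(bundle["contamination"])
    if "bootstrap" in bundle:
        summary["bootstrap"] = _jsonable(bundle["bootstrap"])
    if "concordance" in bundle:
        summary["concordance"] = _jsonable(bundle["concordance"])
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
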