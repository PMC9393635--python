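"""Synthetic clonal/polyclonal allele-specific studies with known truth.

The generator produces the full set of tables the analysis consumes — RNA
allelic counts with technical replicates, whole-exome allelic counts, a
donor/recipient marker-locus count table and sample metadata — together
with a ground-truth table, so that every downstream stage (overdispersion
estimation, filters, XCI escapee calling, stable-RME discovery) can be
validated against a study whose answers are known.

Noise model
-----------
Per-replicate total allelic reads are negative binomial around the mean
gene coverage; maternal reads are beta-binomial with intraclass correlation
``rho_tech``, the minimal overdispersion model whose variance inflation
``1 + (n - 1) * rho`` is exactly what the replicate-based quality-control
constant (QCC) is designed to absorb.  Recipient-cell contamination acts as
a linear mixture on the allelic ratio: a monoclonal sample with
contamination ``c`` observes ``(1 - c) * AI_clone + c * AI_population``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig

RNA_ASSAY = "RNA"
DNA_ASSAY = "DNA"
X_CHROM = "chrX"

#: Autosomal chromosome labels cycled over autosomal genes.
_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 20))


def beta_binomial(
    rng: np.random.Generator,
    n: np.ndarray,
    p: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Draw beta-binomial counts with intraclass correlation ``rho``.

    ``rho = 0`` reduces exactly to the binomial; ``p`` of 0 or 1 is
    degenerate and returns 0 or ``n``.
    """
    n = np.asarray(n, dtype=np.int64)
    p = np.asarray(p, dtype=float)
    n, p = np.broadcast_arrays(n, p)
    if rho == 0.0:
        return rng.binomial(n, p)
    degenerate = (p <= 0.0) | (p >= 1.0)
    a = np.where(degenerate, 1.0, p * (1.0 - rho) / rho)
    b = np.where(degenerate, 1.0, (1.0 - p) * (1.0 - rho) / rho)
    q = rng.beta(a, b)
    x = rng.binomial(n, q)
    return np.where(degenerate, np.round(n * p).astype(np.int64), x)


def _negative_binomial_totals(
    rng: np.random.Generator, mean: float, alpha: float, size: int
) -> np.ndarray:
    """Totals with variance mu * (1 + alpha * mu); alpha = 0 is Poisson."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if alpha == 0.0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / alpha
    return rng.negative_binomial(shape, shape / (shape + mean), size=size)


@dataclass
class StudyTruth:
    """Ground truth of a simulated study.

    Attributes
    ----------
    genes:
        One row per gene: ``gene_id, chrom, chrom_class, ai_class, dna_ai,
        xi_fraction`` (xi_fraction is NaN for non-escapees).
    sample_ai:
        One row per (gene, sample): pre-contamination AI, the AI of the
        contaminating population, and the observed (post-mixture) AI.
    contamination:
        True recipient-cell fraction per monoclonal sample.
    x_choice:
        Maternal-X indicator (1 maternal active, 0 paternal) per monoclonal
        animal.
    """

    genes: pd.DataFrame
    sample_ai: pd.DataFrame
    contamination: Dict[str, float] = field(default_factory=dict)
    x_choice: Dict[str, int] = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    rna_counts: pd.DataFrame
    wes_counts: pd.DataFrame
    marker_counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: StudyTruth
    config: SimulationConfig


def _make_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i, tissues in enumerate(config.monoclonal_design(), start=1):
        animal = f"M{i}"
        for t in tissues:
            rows.append((f"{animal}_{t}", t, "monoclonal", "E1", animal))
    for i in range(1, config.n_polyclonal + 1):
        rows.append((f"P{i}_B", "B", "polyclonal", "E1", f"P{i}"))
    for i in range(1, config.n_unmanipulated + 1):
        animal = f"U{i}"
        for t in ("B", "T"):
            rows.append((f"{animal}_{t}", t, "unmanipulated", "E1", animal))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "tissue", "clonality", "experiment_id", "animal_id"]
    )
    meta["expressed_x"] = "unknown"
    return meta


def _class_counts(n: int, fracs: Dict[str, float]) -> Dict[str, int]:
    counts = {name: int(round(f * n)) for name, f in fracs.items()}
    if sum(counts.values()) > n:
        raise ConfigError("special-class fractions exceed the gene count")
    return counts


def draw_gene_truth(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, StudyTruth]:
    """Assign gene classes and per-sample true allelic ratios.

    Returns the sample metadata and a :class:`StudyTruth`.  Observed AI for
    a monoclonal sample with contamination ``c`` is the mixture
    ``(1 - c) * AI_clone + c * AI_population``.
    """
    config.validate()
    meta = _make_metadata(config)

    n_auto, n_x = config.n_autosomal_genes, config.n_x_genes
    auto_counts = _class_counts(
        n_auto,
        {
            "stable_rme": config.frac_stable_rme,
            "imprinted": config.frac_imprinted,
            "loh": config.frac_loh,
        },
    )
    n_escapee = int(round(config.frac_escapee * n_x))
    if n_escapee > n_x:
        raise ConfigError("frac_escapee exceeds the X gene count")

    auto_classes = np.array(
        ["stable_rme"] * auto_counts["stable_rme"]
        + ["imprinted"] * auto_counts["imprinted"]
        + ["loh"] * auto_counts["loh"]
        + ["balanced"] * (n_auto - sum(auto_counts.values()))
    )
    rng.shuffle(auto_classes)
    x_classes = np.array(["escapee"] * n_escapee + ["x_standard"] * (n_x - n_escapee))
    rng.shuffle(x_classes)

    gene_ids = np.array(
        [f"gene{i:05d}" for i in range(1, n_auto + 1)]
        + [f"xgene{i:04d}" for i in range(1, n_x + 1)]
    )
    chroms = np.array(
        [_AUTOSOMES[i % len(_AUTOSOMES)] for i in range(n_auto)] + [X_CHROM] * n_x
    )
    classes = np.concatenate([auto_classes, x_classes])
    chrom_class = np.where(chroms == X_CHROM, "X", "autosome")

    # Gene-level latent values.
    dna_ai = np.full(len(gene_ids), 0.5)
    loh_mask = classes == "loh"
    loh_side = rng.random(loh_mask.sum()) < 0.5
    dna_ai[loh_mask] = np.where(
        loh_side,
        rng.uniform(0.97, 1.0, loh_mask.sum()),
        rng.uniform(0.0, 0.03, loh_mask.sum()),
    )
    imp_mask = classes == "imprinted"
    imp_side = rng.random(imp_mask.sum()) < 0.5
    imprint_ai = np.where(
        imp_side,
        rng.uniform(0.97, 1.0, imp_mask.sum()),
        rng.uniform(0.0, 0.03, imp_mask.sum()),
    )
    esc_mask = classes == "escapee"
    f_lo, f_hi = config.escapee_xi_fraction_range
    xi_fraction = np.full(len(gene_ids), np.nan)
    xi_fraction[esc_mask] = rng.uniform(f_lo, f_hi, esc_mask.sum())

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "chrom_class": chrom_class,
            "ai_class": classes,
            "dna_ai": dna_ai,
            "xi_fraction": xi_fraction,
        }
    )

    # Per-animal latent values.
    mono_animals = [f"M{i}" for i in range(1, config.n_monoclonal + 1)]
    x_choice = {a: int(rng.random() < 0.5) for a in mono_animals}
    rme_idx = np.flatnonzero(classes == "stable_rme")
    rme_draws = {
        a: rng.choice(config.rme_ai_choices, size=rme_idx.size) for a in mono_animals
    }

    # Contamination per monoclonal sample, cycling the configured sequence.
    mono_samples = meta.loc[meta.clonality == "monoclonal", "sample_id"].tolist()
    cseq = config.contamination_sequence()
    contamination = {s: cseq[i % len(cseq)] for i, s in enumerate(mono_samples)}

    q = config.x_poly_ai
    # Population (polyclonal) AI per gene: the AI of the contaminating cells
    # and of the polyclonal/unmanipulated samples themselves.
    pop_ai = np.full(len(gene_ids), 0.5)
    pop_ai[imp_mask] = imprint_ai
    pop_ai[loh_mask] = dna_ai[loh_mask]  # shared genetic loss (deletion scenario)
    x_std_mask = classes == "x_standard"
    pop_ai[x_std_mask] = q
    pop_ai[esc_mask] = q * (1.0 - xi_fraction[esc_mask]) + (1.0 - q) * xi_fraction[
        esc_mask
    ]

    records = []
    for _, row in meta.iterrows():
        s, animal, clonality = row.sample_id, row.animal_id, row.clonality
        pre = pop_ai.copy()
        if clonality == "monoclonal":
            chi = x_choice[animal]
            pre[x_std_mask] = float(chi)
            pre[esc_mask] = np.where(
                chi == 1, 1.0 - xi_fraction[esc_mask], xi_fraction[esc_mask]
            )
            pre[rme_idx] = rme_draws[animal]
        if config.rho_bio > 0:
            auto_free = (chrom_class == "autosome") & ~loh_mask & ~imp_mask
            jitter = rng.normal(0.0, config.rho_bio, auto_free.sum())
            pre[auto_free] = np.clip(pre[auto_free] + jitter, 0.0, 1.0)
        c = contamination.get(s, 0.0)
        observed = (1.0 - c) * pre + c * pop_ai if c > 0 else pre
        records.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "sample_id": s,
                    "pre_ai": pre,
                    "contaminant_ai": pop_ai,
                    "true_ai": observed,
                }
            )
        )
    sample_ai = pd.concat(records, ignore_index=True)

    meta = meta.copy()
    expressed = {
        a: ("maternal" if chi == 1 else "paternal") for a, chi in x_choice.items()
    }
    meta["expressed_x"] = [
        expressed.get(an, "mixed") if cl == "monoclonal" else "mixed"
        for an, cl in zip(meta.animal_id, meta.clonality)
    ]

    truth = StudyTruth(
        genes=genes, sample_ai=sample_ai, contamination=contamination, x_choice=x_choice
    )
    return meta, truth


def simulate_rna_counts(
    truth: StudyTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    metadata: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Draw RNA allelic counts for every (sample, replicate, gene).

    Replicates share the sample's true AI but draw totals and maternal
    counts independently; rows whose total is zero are omitted.
    """
    if config.mean_gene_coverage <= 0:
        return _empty_counts()
    gene_info = truth.genes.set_index("gene_id")["chrom"]
    frames = []
    for sample_id, grp in truth.sample_ai.groupby("sample_id", sort=False):
        ai = grp["true_ai"].to_numpy()
        gids = grp["gene_id"].to_numpy()
        for r in range(1, config.n_replicates + 1):
            totals = _negative_binomial_totals(
                rng, config.mean_gene_coverage, config.coverage_dispersion, ai.size
            )
            maternal = beta_binomial(rng, totals, ai, config.rho_tech)
            keep = totals > 0
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "replicate_id": f"r{r}",
                        "gene_id": gids[keep],
                        "chrom": gene_info.loc[gids[keep]].to_numpy(),
                        "maternal_count": maternal[keep],
                        "paternal_count": totals[keep] - maternal[keep],
                        "assay": RNA_ASSAY,
                    }
                )
            )
    if not frames:
        return _empty_counts()
    return pd.concat(frames, ignore_index=True)


def _empty_counts() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "sample_id",
            "replicate_id",
            "gene_id",
            "chrom",
            "maternal_count",
            "paternal_count",
            "assay",
        ]
    )


def default_wes_samples(metadata: pd.DataFrame) -> list[str]:
    """One polyclonal sample plus one sample from each of the last two
    monoclonal animals — the minimal design that lets the DNA/RNA bootstrap
    contrast a control against two independent clones."""
    poly = metadata.loc[metadata.clonality == "polyclonal", "sample_id"].tolist()
    mono = metadata.loc[metadata.clonality == "monoclonal"]
    picks = []
    if poly:
        picks.append(poly[0])
    animals = mono.animal_id.unique().tolist()
    for animal in animals[-2:]:
        picks.append(mono.loc[mono.animal_id == animal, "sample_id"].iloc[0])
    return picks


def simulate_wes_counts(
    truth: StudyTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Draw whole-exome allelic counts for the configured WES samples.

    DNA maternal counts are binomial around the gene's DNA allelic ratio
    (0.5 except for genes carrying an allelic loss); totals are Poisson.
    """
    samples = (
        list(config.wes_samples)
        if config.wes_samples is not None
        else default_wes_samples(metadata)
    )
    if config.wes_mean_coverage <= 0 or not samples:
        return _empty_counts()
    genes = truth.genes
    frames = []
    for sample_id in samples:
        totals = rng.poisson(config.wes_mean_coverage, size=len(genes))
        maternal = rng.binomial(totals, genes["dna_ai"].to_numpy())
        keep = totals > 0
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "replicate_id": "r1",
                    "gene_id": genes["gene_id"].to_numpy()[keep],
                    "chrom": genes["chrom"].to_numpy()[keep],
                    "maternal_count": maternal[keep],
                    "paternal_count": totals[keep] - maternal[keep],
                    "assay": DNA_ASSAY,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_marker_counts(
    truth: StudyTruth, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Donor/recipient marker-locus reads per monoclonal sample.

    Recipient reads are Poisson(lambda * c) and donor reads
    Poisson(lambda * (1 - c)), with lambda the expected marker coverage.
    """
    rows = []
    lam = config.marker_reads
    for sample_id, c in truth.contamination.items():
        recipient = int(rng.poisson(lam * c))
        donor = int(rng.poisson(lam * (1.0 - c)))
        rows.append((sample_id, donor, recipient))
    return pd.DataFrame(
        rows, columns=["sample_id", "donor_allele_reads", "recipient_allele_reads"]
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a complete study from a single seeded random stream."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    metadata, truth = draw_gene_truth(config, rng)
    rna = simulate_rna_counts(truth, config, rng, metadata)
    wes = simulate_wes_counts(truth, config, rng, metadata)
    marker = simulate_marker_counts(truth, config, rng)
    return SimulatedStudy(
        rna_counts=rna,
        wes_counts=wes,
        marker_counts=marker,
        metadata=metadata,
        truth=truth,
        config=config,
    )
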