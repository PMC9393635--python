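"""Configuration objects for simulation, filtering and end-to-end runs.

All tunable thresholds of the analysis live here so that every stage of the
pipeline (filters, escapee calling, stable-RME discovery) can be driven from
a single YAML file and every default is visible in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its declared invariants."""


# Default tissue design for monoclonal animals: five single-HSC animals,
# three assayed in B cells only and two assayed in both B and T cells, so
# that cross-lineage concordance has two animals with both tissues.
_DEFAULT_MONO_TISSUES: Tuple[Tuple[str, ...], ...] = (
    ("B",),
    ("B",),
    ("B",),
    ("B", "T"),
    ("B", "T"),
)

# Per-monoclonal-sample recipient-cell contamination fractions, cycled over
# samples in order.  The spread mimics a cohort in which most sorts are very
# clean (~1%), some carry a few percent of recipient cells and the worst
# carry 5-10%.
_DEFAULT_CONTAMINATION: Tuple[float, ...] = (0.01, 0.01, 0.025, 0.05, 0.075)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic clonal/polyclonal allele-specific study.

    The defaults emulate the statistical structure of a single-HSC
    reconstitution experiment: ~8,000 autosomal genes with allelic counts,
    ~500 informative X-linked genes, five monoclonal animals (complete XCI
    skew) plus five polyclonal controls and one unmanipulated control, two
    technical replicates per RNA library, low-percent recipient-cell
    contamination, and rare autosomal gene classes (stable RME, imprinted,
    LOH) at the frequencies such a study reports.

    Attributes
    ----------
    n_autosomal_genes, n_x_genes:
        Number of autosomal / X-linked genes with measurable allelic counts.
    n_monoclonal, n_polyclonal, n_unmanipulated:
        Number of animals per clonality class.  Monoclonal animals contribute
        samples for the tissues in ``monoclonal_tissues``; polyclonal animals
        contribute one B-cell sample each; unmanipulated animals contribute
        one B and one T sample.
    n_replicates:
        Technical replicates per RNA library (>= 2; the replicate-based
        overdispersion constant is undefined otherwise).
    frac_stable_rme, frac_imprinted, frac_loh:
        Fractions of autosomal genes in each special class; the remainder is
        balanced (AI = 0.5).
    frac_escapee:
        Fraction of X-linked genes escaping XCI.
    contamination:
        Recipient-cell fraction per monoclonal sample.  A scalar applies to
        every sample; a sequence is cycled over monoclonal samples in order.
    mean_gene_coverage:
        Expected total allelic RNA reads per gene per technical replicate.
    coverage_dispersion:
        Negative-binomial dispersion alpha of per-replicate totals
        (variance = mu * (1 + alpha * mu); alpha = 0 gives Poisson).
    wes_mean_coverage:
        Expected total allelic DNA (exome) reads per gene (Poisson).
    rho_tech:
        Beta-binomial intraclass correlation of allelic counts within a
        technical replicate; inflates binomial variance by 1 + (n - 1) * rho.
    rho_bio:
        Optional between-sample jitter (s.d. of a truncated normal) applied
        to autosomal pre-contamination AI; 0 disables it.
    x_poly_ai:
        Population maternal-X AI of polyclonal/unmanipulated samples.  The
        default 0.35 mimics the off-centre X AI of a B-cell control carrying
        an Xist polymorphism.
    escapee_xi_fraction_range:
        Range of the inactive-X expression fraction f for escapee genes.
    rme_ai_choices:
        Support of the per-clone AI draw for stable-RME genes.
    marker_reads:
        Expected total reads over the donor/recipient marker locus.
    wes_samples:
        Sample ids with exome data; ``None`` selects one polyclonal sample
        and one sample from each of the last two monoclonal animals.
    seed:
        Seed of the single random stream driving the whole study.
    """

    n_autosomal_genes: int = 8000
    n_x_genes: int = 500
    n_monoclonal: int = 5
    n_polyclonal: int = 5
    n_unmanipulated: int = 1
    n_replicates: int = 2
    frac_stable_rme: float = 14 / 8000
    frac_imprinted: float = 0.0005
    frac_loh: float = 0.00075
    frac_escapee: float = 8 / 500
    contamination: float | Sequence[float] = _DEFAULT_CONTAMINATION
    mean_gene_coverage: float = 100.0
    coverage_dispersion: float = 0.2
    wes_mean_coverage: float = 40.0
    rho_tech: float = 0.02
    rho_bio: float = 0.0
    x_poly_ai: float = 0.35
    escapee_xi_fraction_range: Tuple[float, float] = (0.15, 0.5)
    rme_ai_choices: Tuple[float, ...] = (0.1, 0.5, 0.9)
    marker_reads: float = 10_000.0
    monoclonal_tissues: Optional[Sequence[Sequence[str]]] = None
    wes_samples: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fracs = {
            "frac_stable_rme": self.frac_stable_rme,
            "frac_imprinted": self.frac_imprinted,
            "frac_loh": self.frac_loh,
            "frac_escapee": self.frac_escapee,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        auto_sum = self.frac_stable_rme + self.frac_imprinted + self.frac_loh
        if auto_sum > 1.0 + 1e-12:
            raise ConfigError(
                "frac_stable_rme + frac_imprinted + frac_loh must not exceed 1 "
                f"(got {auto_sum})"
            )
        if self.n_replicates < 2:
            raise ConfigError(
                "n_replicates must be >= 2: the replicate-overdispersion "
                "constant (QCC) requires technical replicate pairs"
            )
        for c in self.contamination_sequence():
            if not 0.0 <= c < 1.0:
                raise ConfigError(f"contamination fractions must be in [0, 1), got {c}")
        if not 0.0 <= self.rho_tech < 1.0:
            raise ConfigError(f"rho_tech must be in [0, 1), got {self.rho_tech}")
        if not 0.0 <= self.rho_bio < 0.5:
            raise ConfigError(f"rho_bio must be in [0, 0.5), got {self.rho_bio}")
        if not 0.0 <= self.x_poly_ai <= 1.0:
            raise ConfigError(f"x_poly_ai must be in [0, 1], got {self.x_poly_ai}")
        lo, hi = self.escapee_xi_fraction_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(
                f"escapee_xi_fraction_range must lie within (0, 0.5], got {(lo, hi)}"
            )
        if self.mean_gene_coverage < 0 or self.wes_mean_coverage < 0:
            raise ConfigError("mean coverages must be non-negative")
        if self.coverage_dispersion < 0:
            raise ConfigError("coverage_dispersion must be non-negative")
        if self.monoclonal_tissues is not None:
            if len(self.monoclonal_tissues) != self.n_monoclonal:
                raise ConfigError(
                    "monoclonal_tissues must list one tissue tuple per "
                    "monoclonal animal"
                )

    def contamination_sequence(self) -> Tuple[float, ...]:
        c = self.contamination
        if isinstance(c, (int, float)):
            return (float(c),)
        return tuple(float(x) for x in c)

    def monoclonal_design(self) -> Tuple[Tuple[str, ...], ...]:
        """Tissues assayed per monoclonal animal."""
        if self.monoclonal_tissues is not None:
            return tuple(tuple(t) for t in self.monoclonal_tissues)
        base = _DEFAULT_MONO_TISSUES
        return tuple(base[i % len(base)] for i in range(self.n_monoclonal))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("escapee_xi_fraction_range", "rme_ai_choices"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class FilterConfig:
    """Thresholds of the gene inclusion/exclusion rules.

    Boundary semantics follow the wording of the rules they implement
    literally: expression is kept at >= ``expression_min`` (removal is
    strictly below), the nonrandom-bias and trans-deletion bands remove
    genes strictly outside (low, high) in *all* in-scope samples, and the
    exome (LOH) rule excludes genes with DNA totals strictly below
    ``wes_min_total`` or DNA AI strictly outside ``wes_band``.
    """

    expression_min: float = 10.0
    bias_low: float = 0.1
    bias_high: float = 0.9
    trans_low: float = 0.25
    trans_high: float = 0.75
    wes_min_total: int = 10
    wes_band: Tuple[float, float] = (0.25, 0.75)
    imprint_threshold: float = 0.15

    def __post_init__(self) -> None:
        for low, high, name in (
            (self.bias_low, self.bias_high, "bias"),
            (self.trans_low, self.trans_high, "trans"),
            (self.wes_band[0], self.wes_band[1], "wes_band"),
        ):
            if not (0.0 <= low < high <= 1.0):
                raise ConfigError(f"{name} band must satisfy 0 <= low < high <= 1")
        if not 0.0 < self.imprint_threshold < 0.5:
            raise ConfigError("imprint_threshold must be in (0, 0.5)")

    @classmethod
    def abelson(cls) -> "FilterConfig":
        """The exome-band dialect used for immortalized clone collections."""
        return cls(wes_band=(0.3, 0.7))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        d = dict(d)
        if "wes_band" in d:
            d["wes_band"] = tuple(d["wes_band"])
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end run configuration: either real input tables or a simulation.

    Exactly one of ``inputs`` (paths to RNA counts, metadata, marker and WES
    tables) or ``simulation`` must be provided.
    """

    simulation: Optional[SimulationConfig] = None
    inputs: Optional[dict] = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    sd_threshold: float = 0.15
    escapee_displacement: float = 0.1
    escapee_min_xi_fraction: float = 0.1
    escapee_control_band: Tuple[float, float] = (0.3, 0.7)
    clonality_tolerance: float = 0.05
    bootstrap_replicates: int = 100_000
    qcc_min_total: int = 10
    seed: int = 0
    output_dir: str = "clonalai_out"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of 'simulation' or 'inputs' must be specified"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        filt = raw.pop("filters", None)
        kwargs = dict(raw)
        if sim is not None:
            kwargs["simulation"] = SimulationConfig.from_dict(sim)
        if filt is not None:
            kwargs["filters"] = FilterConfig.from_dict(filt)
        for key in ("escapee_control_band",):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        d: dict = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("simulation", "filters")
        }
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        if self.inputs is None:
            d.pop("inputs", None)
        d["filters"] = self.filters.to_dict()
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
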