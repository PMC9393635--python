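import numpy as np
import pandas as pd
import pytest

from clonalai import PipelineConfig, SimulationConfig, simulate_study
from clonalai.pipeline import run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config():
    """A modest study exercising every gene class and both tissues."""
    return SimulationConfig(
        n_autosomal_genes=600,
        n_x_genes=80,
        n_monoclonal=5,
        n_polyclonal=3,
        n_unmanipulated=1,
        frac_stable_rme=0.02,
        frac_imprinted=0.01,
        frac_loh=0.01,
        frac_escapee=0.05,
        contamination=(0.01, 0.02, 0.03, 0.05, 0.01),
        mean_gene_coverage=100.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, small_study):
    cfg = PipelineConfig(simulation=small_config, seed=42, bootstrap_replicates=2000)
    return run_pipeline(cfg, study=small_study)


def make_replicate_table(
    rng, n_genes, coverage, rho, p_low=0.3, p_high=0.7, sample_id="S1"
):
    """Two technical replicates with fixed coverage and beta-binomial noise."""
    from clonalai.simulate import beta_binomial

    p = rng.uniform(p_low, p_high, n_genes)
    frames = []
    for r in (1, 2):
        n = np.full(n_genes, coverage)
        m = beta_binomial(rng, n, p, rho)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "replicate_id": f"r{r}",
                    "gene_id": [f"g{i:05d}" for i in range(n_genes)],
                    "chrom": "chr1",
                    "maternal_count": m,
                    "paternal_count": n - m,
                    "assay": "RNA",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
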