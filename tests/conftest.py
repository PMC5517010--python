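import numpy as np
import pandas as pd
import pytest

from nutrinet.network import CoexpressionNetwork
from nutrinet.preprocess import compute_fpkm, filter_network_genes, log_transform
from nutrinet.simulate import (
    SimulationConfig,
    generate_counts,
    generate_design,
    planted_module_genes,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-size study: 800 genes, two planted diet modules."""
    from nutrinet.simulate import ModuleSpec

    return SimulationConfig(
        n_genes=800,
        module_specs=(ModuleSpec(60, 0.8, 0.0), ModuleSpec(60, -0.8, 0.0)),
        seed=5,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    design = generate_design(small_config)
    counts, lengths, libs = generate_counts(design, small_config)
    return design, counts, lengths, libs


@pytest.fixture(scope="session")
def recovery_fit():
    """Default-config network fit on the selected-strain liver cohort,
    shared across tests because it is the most expensive computation."""
    cfg = SimulationConfig(seed=0)
    design = generate_design(cfg)
    counts, lengths, libs = generate_counts(design, cfg)
    fpkm = compute_fpkm(counts, lengths, libs)
    sub = design[(design["strain"] == "selected") & (design["tissue"] == "liver")]
    expr = log_transform(filter_network_genes(fpkm[list(sub["sample_id"])])).T
    model = CoexpressionNetwork().fit(expr)
    traits = pd.DataFrame(
        {
            "diet": (sub["diet"] == "PM").astype(float).to_numpy(),
            "hsi": sub["hsi"].to_numpy(),
        },
        index=pd.Index(sub["sample_id"]),
    )
    return {
        "config": cfg,
        "expr": expr,
        "model": model,
        "traits": traits,
        "truth": planted_module_genes(cfg),
    }


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """One small end-to-end pipeline run shared across tests."""
    from nutrinet.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(
        seed=3,
        simulation={
            "n_genes": 900,
            "module_specs": [(60, 0.8, 0.0), (60, -0.8, 0.0)],
        },
    )
    run_pipeline(cfg, out)
    return cfg, out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
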