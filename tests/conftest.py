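import logging
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from npcrosstalk.bundle import ExpressionBundle
from npcrosstalk.pipeline import PipelineConfig, make_demo, run_pipeline
from npcrosstalk.synthetic import CohortConfig, SyntheticConfig

logging.getLogger("npcrosstalk").setLevel(logging.WARNING)


def two_group_bundle(matrix: np.ndarray, n_case: int, n_control: int,
                     genes=None, batches=None, disease="T") -> ExpressionBundle:
    """Small helper to wrap a raw array as a case/control bundle."""
    n = n_case + n_control
    assert matrix.shape[1] == n
    samples = [f"s{i}" for i in range(n)]
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    meta = pd.DataFrame(
        {
            "group": ["case"] * n_case + ["control"] * n_control,
            "batch": batches or ["b1"] * n,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionBundle(
        matrix=pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=samples),
        metadata=meta,
        disease=disease,
    )


def small_config(seed=0, **overrides) -> SyntheticConfig:
    """Scaled-down synthetic study for fast pipeline-level tests."""
    defaults = dict(
        seed=seed,
        n_genes=400,
        n_neuropeptides=30,
        diseases={
            "MDD": CohortConfig(n_case=20, n_control=20, n_batches=2),
            "PD": CohortConfig(n_case=40, n_control=30, n_batches=2),
        },
        n_de_up=8,
        n_de_down=4,
        n_crosstalk_planted=10,
        n_drl_pairs=3,
        n_predictive_np=2,
        ppi_n_nodes=120,
        n_planted_bridges=5,
        n_pathways=10,
        n_mixed_sets=3,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo pipeline run at the study-sized defaults, shared across
    tests that inspect its outputs."""
    outdir = tmp_path_factory.mktemp("demo")
    config_path = make_demo(outdir, seed=11)
    config = PipelineConfig.from_yaml(config_path)
    config.make_plots = False
    manifest = run_pipeline(config)
    return SimpleNamespace(outdir=outdir, config=config, manifest=manifest)
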