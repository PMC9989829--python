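"""Shared fixtures: small simulated bundles and pipeline runs.

Everything is generated programmatically at test time; the small bundle
and its pipeline run are session-scoped because several module tests
only need read access to them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from editome.pipeline import PipelineConfig, run_pipeline
from editome.simulate import SimulationRecipe, write_bundle


def small_recipe(seed: int = 11, **kw) -> SimulationRecipe:
    r = SimulationRecipe(
        seed=seed,
        genome_length=80_000,
        n_samples=2,
        n_genes=8,
        antisense_pairs=1,
        isolated_sites=40,
        het_snps=60,
        hom_diffs=20,
        recoding_sites=4,
    )
    r.clusters.count = 8
    r.hyper.count = 2
    for k, v in kw.items():
        setattr(r, k, v)
    return r


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    manifest = write_bundle(small_recipe(), str(out))
    return manifest


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("results")
    result = run_pipeline(small_bundle["dir"], str(out), PipelineConfig(seed=5))
    return result, small_bundle, str(out)


@pytest.fixture(scope="session")
def truth_sites(small_bundle) -> pd.DataFrame:
    df = small_bundle["truth"].site_frame().copy()
    df["pos"] = df["pos_1based"] - 1
    return df


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
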