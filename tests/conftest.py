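import shutil
from pathlib import Path

import numpy as np
import pytest

import crisprtile as ct
from crisprtile.config import RunConfig
from crisprtile.pipeline import run_pipeline

EXAMPLES = Path(__file__).resolve().parents[1] / "examples"


@pytest.fixture(scope="session")
def example_config_path() -> Path:
    return EXAMPLES / "small_screen.yaml"


@pytest.fixture
def tiny_library():
    """A 12-guide library on a 6 kb region: 8 tiling + 3 NT + 1 nonexpressed."""
    return ct.build_library((0, 6000), 8, 3, 1, seed=42, jitter=0)


def simulate_screen(
    effect_elements,
    seed_key,
    region=(0, 50_000),
    n_tiling=1000,
    n_nontargeting=200,
    n_nonexpressed=100,
    n_cells=200_000,
    depth_per_bin=2_000_000,
    expr_cv=0.3,
    prefix="g",
):
    """One simulated screen: (library, normalized CountTable, elements)."""
    ss = np.random.SeedSequence(seed_key).spawn(3)
    lib = ct.build_library(region, n_tiling, n_nontargeting, n_nonexpressed, seed=ss[0])
    els = [ct.PlantedElement("chr3", s, e, eff) for s, e, eff in effect_elements]
    pop = ct.simulate_cells(lib, els, n_cells, expr_cv, seed=ss[1])
    table = ct.sequence_bins(ct.sort_cells(pop), depth_per_bin, seed=ss[2], sample_prefix=prefix)
    return lib, ct.normalize_counts(table), els


@pytest.fixture(scope="session")
def pipeline_runs(example_config_path, tmp_path_factory):
    """The bundled example screen run twice with the same config and seed."""
    base = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig.from_yaml(example_config_path)
    res1 = run_pipeline(cfg, base / "run1")
    res2 = run_pipeline(RunConfig.from_yaml(example_config_path), base / "run2")
    yield res1, res2
    shutil.rmtree(base, ignore_errors=True)
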