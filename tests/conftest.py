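import numpy as np
import pytest

from thsspipe.pipeline import config_for_dataset, run_pipeline
from thsspipe.synth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard-conditions synthetic dataset used for recovery tests."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """Full pipeline run over the standard dataset: (dataset, report, out)."""
    root = tmp_path_factory.mktemp("fullrun")
    data = root / "data"
    out = root / "out"
    default_dataset.write(data)
    cfg = config_for_dataset(data, out)
    report = run_pipeline(cfg)
    return default_dataset, report, out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def small_config(**overrides) -> SyntheticConfig:
    """A fast desk-scale configuration for unit-level pipeline tests."""
    base = dict(
        seed=3,
        n_chroms=2,
        chrom_length=200_000,
        decoy_length=30_000,
        n_genes=30,
        n_peaks=120,
        n_decoy_peaks=6,
        n_background_fragments=3_000,
        n_motifs=6,
        n_stages=1,
        n_enhancers_random=20,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    root = tmp_path_factory.mktemp("smallrun")
    ds = generate_dataset(small_config())
    ds.write(root / "data")
    cfg = config_for_dataset(root / "data", root / "out")
    report = run_pipeline(cfg)
    return ds, cfg, report
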