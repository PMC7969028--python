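"""Shared fixtures: small and full-size simulated datasets.

Everything is generated programmatically at test time; session scope
keeps the expensive full-size simulation to a single run.
"""

from __future__ import annotations

import pytest

from epimap.simulate import SimulationConfig, simulate_all


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A 1-chrom / 1-Mb configuration that keeps unit tests fast."""
    defaults = dict(
        seed=seed,
        n_chroms=1,
        chrom_length=1_000_000,
        n_genes=50,
        reads_per_sample=20_000,
        n_icrs=2,
        site_spacing=200,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(annotation, truth, readsets, callsets, expression) for the small config."""
    return simulate_all(small_cfg)


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    """The reference study conditions: 2 chroms × 5 Mb, 500 genes,
    8 ChIP samples at 200k reads, seed 1."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_sim(default_cfg):
    return simulate_all(default_cfg)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_cfg, small_sim):
    """The small dataset written out as an on-disk fixture bundle."""
    from epimap.simulate import write_fixture_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    annotation, truth, readsets, callsets, expression = small_sim
    write_fixture_bundle(outdir, small_cfg, annotation, truth, readsets, callsets, expression)
    return outdir
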