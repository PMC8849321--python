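"""Shared fixtures: a small fast dataset and one full-size reference run."""

from __future__ import annotations

import pytest

import pioneerkit as pk


def small_config(seed: int = 5, **overrides) -> pk.SimConfig:
    """A scaled-down simulation for fast pipeline tests."""
    params = dict(
        seed=seed,
        chrom_sizes={"chr1": 400_000, "chr2": 400_000},
        site_counts={
            "foxa1_accessible": 10,
            "foxa1_inaccessible": 20,
            "hnf4a_accessible": 10,
            "hnf4a_inaccessible": 20,
            "FP": 15,
            "HP": 20,
            "BOTH": 20,
            "CB": 12,
            "background": 10,
        },
        n_genes=300,
        n_activated=20,
        tissue_set_sizes={"liver": 60, "intestine": 30},
    )
    params.update(overrides)
    return pk.SimConfig(**params)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full-size noise-free simulate + analyze, shared across tests.

    Returns (dataset, analysis results, data dir, out dir).
    """
    root = tmp_path_factory.mktemp("default_run")
    cfg = pk.SimConfig(seed=11).noise_free()
    ds = pk.simulate_dataset(cfg)
    from pioneerkit.pipeline import write_dataset

    write_dataset(ds, root / "data")
    run = pk.RunConfig(data_dir=str(root / "data"), out_dir=str(root / "out"), seed=211)
    res = pk.cmd_analyze(run)
    return ds, res, root / "data", root / "out"


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Small noise-free simulate + analyze for cheap structural tests."""
    root = tmp_path_factory.mktemp("small_run")
    cfg = small_config().noise_free()
    pk.cmd_simulate(cfg, root / "data")
    run = pk.RunConfig(data_dir=str(root / "data"), out_dir=str(root / "out"), seed=7)
    res = pk.cmd_analyze(run)
    return cfg, res, root / "data", root / "out"
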