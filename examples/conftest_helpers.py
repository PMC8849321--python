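"""Shared small configuration for the example scripts."""

import pioneerkit as pk


def small_demo_config(seed: int = 0) -> pk.SimConfig:
    return pk.SimConfig(
        seed=seed,
        chrom_sizes={"chr1": 600_000, "chr2": 600_000},
        site_counts={
            "foxa1_accessible": 20, "foxa1_inaccessible": 40,
            "hnf4a_accessible": 20, "hnf4a_inaccessible": 40,
            "FP": 30, "HP": 50, "BOTH": 55, "CB": 30, "background": 25,
        },
        n_genes=500, n_activated=30,
        tissue_set_sizes={"liver": 80, "intestine": 40},
    )
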