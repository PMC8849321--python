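"""Generate a synthetic dataset with planted ground truth and inspect it.

The generator writes a toy genome in which every transcription-factor
binding site is planted deliberately: its 500-bp window, its class (bound
alone or co-bound, accessible or not), and the number of motif instances
written into the sequence are all recorded in a ledger, so downstream
classification can be scored against exact truth.
"""

from pathlib import Path

import pioneerkit as pk

cfg = pk.SimConfig(
    seed=1,
    chrom_sizes={"chr1": 600_000, "chr2": 600_000},
    site_counts={
        "foxa1_accessible": 20, "foxa1_inaccessible": 40,
        "hnf4a_accessible": 20, "hnf4a_inaccessible": 40,
        "FP": 30, "HP": 50, "BOTH": 55, "CB": 30, "background": 25,
    },
    n_genes=500, n_activated=30,
    tissue_set_sizes={"liver": 80, "intestine": 40},
)
out = Path("scratch/example_dataset")
manifest = pk.cmd_simulate(cfg, out, force=True)

ds = pk.simulate_dataset(cfg)  # same seed -> same dataset, now in memory
print(f"wrote {len(manifest['files'])} files to {out}")
print("\nplanted site classes:")
print(ds.plan.table["cls"].value_counts().to_string())
print("\nmean planted motif multiplicities per co-bound class:")
print(ds.plan.of_class("FP", "HP", "BOTH", "CB")
      .groupby("cls")[["n_foxa1", "n_hnf4a"]].mean().round(2).to_string())
# FP sites carry several FOXA1 motifs but at most one HNF4A motif (and vice
# versa for HP); cooperative (CB) sites carry almost none of either --
# that asymmetry is the ground truth the affinity model later has to detect.
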