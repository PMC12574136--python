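"""Extract per-island fragmentation odds ratios from an alignment file.

Simulates a small genome with CpG islands and methylation-biased break
events, writes them as a coordinate-sorted SAM, then runs the standard
featurization path (read filtering -> 5'-end break dinucleotides -> rho).
"""

import tempfile
from pathlib import Path

from fragmeth import FragilityModel, SimulationConfig, featurize, simulate_sample
from fragmeth.simulate import write_events_sam

config = SimulationConfig(n_islands=12, mean_events_per_island=2000, seed=11)
sample = simulate_sample(config, FragilityModel(meth_cpg_multiplier=1.3))

with tempfile.TemporaryDirectory() as tmp:
    sam = Path(tmp) / "reads.sam"
    write_events_sam(sample.genome, sample.events, sam,
                     read_length=config.read_length)
    table = featurize(sam, sample.genome, sample.islands)

table["methylated"] = table["island_id"].map(sample.true_states)
print(table[["island_id", "N", "rho_CG", "rho_GC", "rho_AT", "methylated"]]
      .to_string(index=False, float_format="%.3f"))
print()
print("mean rho_CG  methylated islands:",
      round(table.loc[table.methylated == 1, "rho_CG"].mean(), 3))
print("mean rho_CG unmethylated islands:",
      round(table.loc[table.methylated == 0, "rho_CG"].mean(), 3))
print()
print("rho_CG > 1 in every island (CpGs are ~1.5x more fragile than other "
      "dinucleotides), and it is visibly higher in methylated islands — the "
      "signal the classifier exploits. Other dinucleotides hover near 1.")
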