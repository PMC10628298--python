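"""Generate a complete synthetic fixture: barcodes, reads, counts, flow.

Emulates a lineage-barcoding experiment: a WSN-patterned barcode library,
noisy barcode reads (anchor + barcode, per-base substitution errors), a
two-state negative-binomial count matrix with primed/susceptible marker
genes, and a lognormal flow-intensity table.
"""

import numpy as np

import lineagemem as lm

cfg = lm.SynthConfig(n_cells=500, n_genes=200, primed_fraction=0.02, seed=1)
lib = lm.gen_barcode_library(80, length=100, seed=1)
print(f"library: {len(lib)} unique {lib.length}-nt WSN barcodes")
print(f"  first: {lib.sequences[0][:30]}...")

cells = [f"cell{i:04d}" for i in range(cfg.n_cells)]
assignment = lm.assign_barcodes(cells, lib, infected_fraction=cfg.infected_fraction, seed=2)
reads = lm.gen_reads(lib, assignment, reads_per_cell=8, config=cfg, seed=3)
print(f"reads: {len(reads)} from {len(assignment)} barcoded cells "
      f"(~{100 * cfg.infected_fraction:.0f}% transduction)")

rng = np.random.default_rng(4)
states = {c: ("P" if rng.random() < cfg.primed_fraction else "S") for c in cells}
counts = lm.gen_counts(states, cfg, seed=5)
print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} cells, "
      f"{sum(s == 'P' for s in states.values())} latent primed cells")

flow = lm.gen_flow(10_000, primed_fraction=0.02, shift=3.0, seed=6)
print(f"flow: {len(flow)} events, primed intensities shifted 3 log-units up")
# The numbers above are the raw material every other example builds on:
# known ground truth lets each downstream step be scored exactly.
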