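"""Simulate a small cross-species study and translate it into human-ortholog space.

Ten species (4 resilient to LPS, 6 sensitive) are simulated with many-to-many
orthology against a shared human gene universe; each species' TPM matrix is
then redistributed onto human orthologs by the sum/n rule and merged.
"""

import numpy as np

from xlps import SimulationConfig, simulate_transcriptome
from xlps.orthologs import build_components, translate

cfg = SimulationConfig(n_human_orthologs=500, individuals_per_species=3,
                       doses=(0.0, 10.0), times=(2.0,), seed=1)
sim = simulate_transcriptome(cfg)

mouse = sim.species_matrices["mouse"]
omap = sim.ortholog_maps["mouse"]
comps = build_components(omap)
sizes = {}
for c in comps:
    key = f"{len(c.species_genes)}:{len(c.human_genes)}"
    sizes[key] = sizes.get(key, 0) + 1
print(f"mouse: {len(mouse.gene_ids)} genes in {len(comps)} orthology components {sizes}")

human_mouse = translate(mouse, omap, sim.human_universe)
total_in = mouse.values.sum(axis=0)
total_out = np.where(human_mouse.missing_mask, 0, human_mouse.values).sum(axis=0)
print(f"mass conservation: max |out-in|/in = {np.max(np.abs(total_out - total_in) / total_in):.2e}")
# the sum/n rule moves every TPM unit to the human side, so this is ~1e-15

merged = sim.to_human_space()
missing_frac = merged.missing_mask.mean()
print(f"merged study matrix: {merged.values.shape[0]} orthologs x {merged.values.shape[1]} samples, "
      f"{100 * missing_frac:.1f}% cells missing")
# missing cells are genes without an annotated ortholog in that sample's species
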