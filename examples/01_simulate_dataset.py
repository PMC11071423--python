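"""Generate the default synthetic paired-multiome scenario and write it out.

The scenario mimics a skin-draining lymph-node nucleus suspension: ~2,000
cells over five types, a tdRFP reporter transcript marking RAG-experienced
cells, and planted gene-peak couplings whose activity depends on fate-map
and disease state.
"""

from fmm.scenarios import default_study_scenario
from fmm.simulate import emit_dataset, simulate_multiome

cfg = default_study_scenario(seed=0)
ds, truth = simulate_multiome(cfg)
emit_dataset(ds, truth, "scratch/example_dataset")

print(f"cells:            {ds.n_cells}")
print(f"genes x peaks:    {cfg.n_genes} x {cfg.n_peaks}")
print(f"fragments:        {len(ds.fragments)}")
print(f"planted links:    {len(truth.links)} "
      f"({(truth.links.kind == 'program').sum()} naive-only ILC2 program, "
      f"{truth.links.kind.isin(['induced', 'th2_induced']).sum()} disease-induced)")
print("cell composition:")
print(truth.labels.groupby(['cell_type', 'fate_map']).size().unstack())
# Counts per (type, fate map): the ILC2 pool is split evenly between
# RAG-naive and RAG-experienced, each further split by disease state.
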