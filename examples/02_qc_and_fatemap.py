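"""Per-cell QC, the strict filter cascade, lineage purge, and reporter-based
fate-map assignment on a simulated dataset."""

import numpy as np

from fmm import qc
from fmm.scenarios import default_study_scenario
from fmm.simulate import simulate_multiome

ds, truth = simulate_multiome(default_study_scenario(seed=0))

rna_qc = qc.compute_rna_qc(ds.rna)
atac_qc = qc.compute_atac_qc(ds.fragments, ds.genes, ds.rna.barcodes)
table = qc.combine_qc(rna_qc, atac_qc)
kept = qc.apply_qc_filters(table, qc.QCThresholds())
print(f"QC: kept {len(kept)} of {ds.n_cells} cells "
      f"(median TSS enrichment {table.tss_enrichment.median():.1f}, "
      f"median nucleosome signal {table.nucleosome_signal.median():.2f})")

purged = qc.purge_lineage_cells(ds.rna)
print(f"lineage purge: {len(purged)} cells without Cd3/Cd4/Cd19/Cd8a/Itgam transcripts")

fate = qc.assign_fatemap(ds.rna)
truth_exp = (truth.labels.fate_map == "exp").to_numpy()
called_exp = (fate.label == qc.RAG_EXP).to_numpy()
print(f"fate map: {called_exp.sum()} cells called RAG-experienced; "
      f"recall among truly experienced {called_exp[truth_exp].mean():.2f} "
      f"(reporter dropout 0.10), false calls on naive cells: "
      f"{int(called_exp[~truth_exp].sum())}")
# Recall below 1 reflects reporter transcript dropout only; a naive cell can
# never show reporter counts, so the false-call count is structurally zero.
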