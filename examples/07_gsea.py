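"""Fate-map differential gene ranking within ILC2 cells and preranked GSEA
against the scenario's planted gene programs."""

from fmm import embed, gsea
from fmm.qc import RAG_EXP, RAG_NAIVE
from fmm.scenarios import default_gene_sets, default_study_scenario
from fmm.simulate import simulate_multiome

cfg = default_study_scenario(seed=0)
ds, truth = simulate_multiome(cfg)
norm = embed.normalize_rna(ds.rna)
is_ilc2 = (truth.labels.cell_type == "ILC2").to_numpy()
fate = truth.labels.fate_map.map({"exp": RAG_EXP, "naive": RAG_NAIVE}).to_numpy()

ranked = gsea.rank_fatemap_degs(norm, fate, cluster_mask=is_ilc2)
print(f"ranked list: {len(ranked)} genes passing the permissive gates "
      f"(min.pct 0.1, logFC 0.1)")
print("most experienced-biased:", ", ".join(ranked.gene.head(3)),
      "| most naive-biased:", ", ".join(ranked.gene.tail(3)))

sets = default_gene_sets(cfg, seed=0)
res = gsea.gsea_preranked(ranked, sets, min_size=50, max_size=500, n_perm=1000, seed=0)
print("\nGSEA results (gene-label permutation, BH-corrected):")
print(res.table[["set", "size", "es", "nes", "p_value", "p_adj"]].to_string(index=False))
# The planted experienced-biased program scores a strongly positive NES and
# the naive-biased program a negative one; decoy sets are size-gated out or
# non-significant.
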