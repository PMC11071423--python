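"""End-to-end orchestration of the fate-mapped multiome analysis on a
simulated (or re-read) dataset: QC and fate mapping, joint embedding and
clustering, tri-assay markers and the multiomic signature, per-condition
gene-peak link regulomes, motif analyses, and preranked GSEA.

Cells failing QC are removed first; clustering runs on every QC-passing
cell, while the lineage purge defines the lymphoid subset used for the
fate-map analyses.  Every stage derives its randomness from the single run
seed, making the whole pipeline bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import embed, gsea, io as fio, links as lk, markers as mk, motifs as mo, qc
from .dataset import PairedMultiomeDataset
from .scenarios import (
    default_gene_sets,
    default_motif_gene_map,
    default_motif_set,
    default_study_scenario,
)
from .simulate import SimConfig, TruthTables, simulate_multiome

ILC2_SCORE_GENES = ["Gata3", "Il1rl1", "Icos"]


@dataclass
class PipelineResult:
    dataset: PairedMultiomeDataset
    truth: TruthTables | None
    qc_table: pd.DataFrame
    kept_barcodes: np.ndarray
    purged_barcodes: np.ndarray
    fatemap: pd.DataFrame
    clusters: embed.ClusterAssignment
    ilc2_cluster: int
    gex_markers: pd.DataFrame
    ga_markers: pd.DataFrame
    da_peaks: pd.DataFrame
    signature: mk.SignatureSet
    fate_links: dict
    cond_links: dict
    regulome: pd.DataFrame
    intersections: pd.DataFrame
    induced_ranking: pd.DataFrame
    th2: lk.Th2Report
    motif_hits: pd.DataFrame
    deviations: mo.DeviationResult
    enrichment: pd.DataFrame
    crossref: pd.DataFrame
    ranked_degs: pd.DataFrame
    gsea_result: gsea.GseaResult
    extras: dict = field(default_factory=dict)


def _pick_ilc2_cluster(norm: embed.NormalizedMatrix, labels: np.ndarray) -> int:
    """The cluster with the highest mean expression of canonical ILC2 genes."""
    fidx = {f: i for i, f in enumerate(norm.feature_ids)}
    rows = [fidx[g] for g in ILC2_SCORE_GENES if g in fidx]
    if not rows:
        return 0
    score = norm.values[rows].mean(axis=0)
    best, best_val = 0, -np.inf
    for c in np.unique(labels):
        v = score[labels == c].mean()
        if v > best_val:
            best, best_val = int(c), v
    return best


def run_all(
    cfg: fio.RunConfig,
    sim_config: SimConfig | None = None,
    dataset: PairedMultiomeDataset | None = None,
    truth: TruthTables | None = None,
    outdir: str | Path | None = None,
    gene_sets: dict | None = None,
    pfms: list | None = None,
    motif_gene_map: dict | None = None,
) -> PipelineResult:
    seed = cfg.seed
    if dataset is None:
        if sim_config is None:
            sim_config = default_study_scenario(seed)
        dataset, truth = simulate_multiome(sim_config)
    if gene_sets is None and sim_config is not None:
        gene_sets = default_gene_sets(sim_config, seed=seed)
    if pfms is None:
        pfms = default_motif_set()
    if motif_gene_map is None:
        motif_gene_map = default_motif_gene_map()

    # ---------------- QC and fate mapping --------------------------------
    rna_qc = qc.compute_rna_qc(dataset.rna)
    atac_qc = qc.compute_atac_qc(dataset.fragments, dataset.genes, dataset.rna.barcodes)
    qc_table = qc.combine_qc(rna_qc, atac_qc)
    kept = qc.apply_qc_filters(qc_table, qc.QCThresholds.from_config(cfg))
    kept_mask = np.isin(np.asarray(dataset.rna.barcodes, dtype=object), kept)
    ds = dataset.subset_cells(kept_mask)
    purged_kept = qc.purge_lineage_cells(ds.rna)
    fatemap = qc.assign_fatemap(ds.rna, cfg.reporter_gene, cfg.reporter_min_count)
    qc_table = qc_table.assign(kept=np.isin(qc_table["barcode"], kept))

    # ---------------- embedding and clustering ---------------------------
    norm_rna = embed.normalize_rna(ds.rna)
    tfidf = embed.run_tfidf(ds.atac)
    pca = embed.run_pca(norm_rna, cfg.n_pcs)
    lsi = embed.run_lsi(tfidf, max(cfg.lsi_dims))
    ga = embed.gene_activity(ds.fragments, ds.genes, ds.rna.barcodes)
    graph = embed.joint_neighbor_graph(pca, lsi, ds.rna.barcodes, k=cfg.n_neighbors)
    clusters = embed.cluster_graph(graph, cfg.cluster_resolution, seed)
    labels = clusters.labels
    ilc2_cluster = _pick_ilc2_cluster(norm_rna, labels)

    # ---------------- tri-assay markers and signature --------------------
    gex_markers = mk.find_all_markers(
        norm_rna, labels, min_pct=cfg.marker_min_pct, logfc_min=cfg.marker_logfc
    )
    # GA normalized like RNA (library-size log1p)
    ga_nonzero = np.asarray(ga.values.sum(axis=0)).ravel() > 0
    ga_norm_vals = np.zeros((ga.shape[0], ga.shape[1]))
    if ga_nonzero.any():
        sub = fio.CountMatrix(
            ga.values[:, np.flatnonzero(ga_nonzero)], ga.feature_ids,
            np.asarray(ga.barcodes)[ga_nonzero], fio.GENE_ACTIVITY,
        )
        ga_norm_vals[:, ga_nonzero] = embed.normalize_rna(sub).values
    ga_norm = embed.NormalizedMatrix(ga_norm_vals, ga.feature_ids, ga.barcodes, embed.LOG_CP10K)
    ga_markers = mk.find_all_markers(
        ga_norm, labels, min_pct=cfg.marker_min_pct, logfc_min=cfg.marker_logfc
    )
    n_atac_latent = qc_table.set_index("barcode").loc[list(ds.rna.barcodes), "n_atac"].to_numpy()
    da_peaks = mk.find_da_peaks(
        tfidf, labels, ilc2_cluster, latent=n_atac_latent.astype(float),
        min_pct=cfg.da_min_pct,
    )
    nearest = mk.assign_nearest_gene(ds.peaks, ds.genes, cfg.nearest_gene_max_dist)
    da_annot = da_peaks.merge(nearest, on="peak", how="inner")
    da_pos = da_annot[da_annot["log_fc"] > 0]
    signature = mk.build_signature(
        gex_markers[gex_markers["cluster"] == ilc2_cluster],
        ga_markers[ga_markers["cluster"] == ilc2_cluster],
        da_pos,
        top_n=cfg.signature_top_n,
    )

    # ---------------- fate-map link regulomes ----------------------------
    # restrict to the ILC2 cluster within the lineage-purged cells
    purged_mask = np.isin(np.asarray(ds.rna.barcodes, dtype=object), purged_kept)
    ilc2_mask = (labels == ilc2_cluster) & purged_mask
    ilc2 = ds.subset_cells(ilc2_mask)
    fate_obs = fatemap.loc[ilc2_mask.nonzero()[0], "label"].to_numpy()
    fate_short = qc.fatemap_to_condition(fate_obs)
    ld = lk.LinkData.from_dataset(ilc2)
    link_kw = dict(
        window=cfg.link_window, min_cells=cfg.link_min_cells,
        n_background=cfg.link_n_background, p_cutoff=cfg.link_p_cutoff,
        score_cutoff=cfg.link_score_cutoff,
    )
    gene_set = [g for g in signature.union if g in set(ds.genes["gene"])]
    fate_links = lk.links_by_condition(
        ld, fate_short, gene_subset=gene_set or None,
        min_condition_cells=cfg.condition_min_cells, seed=seed, **link_kw,
    )
    empty = pd.DataFrame(columns=lk.LINK_COLUMNS)
    regulome = lk.regulome_counts(
        fate_links.get("naive", empty), fate_links.get("exp", empty), gene_set or None
    )
    disease = ilc2.obs["disease"].to_numpy()
    cond_tags = np.array([f"{f}:{d}" for f, d in zip(fate_short, disease)])
    cond_links = lk.links_by_condition(
        ld, cond_tags, gene_subset=gene_set or None,
        min_condition_cells=cfg.condition_min_cells, seed=seed, **link_kw,
    )
    for c in lk.FOUR_CONDITIONS:
        cond_links.setdefault(c, empty)
    system = lk.peak_set_system({c: cond_links[c] for c in lk.FOUR_CONDITIONS})
    intersections = lk.exclusive_intersections(system)
    induced_ranking = lk.induced_peak_genes(system, cond_links)
    th2 = lk.th2_locus_report(
        ld, fate_short, cond_tags, min_condition_cells=cfg.condition_min_cells,
        seed=seed, **link_kw,
    )

    # ---------------- motifs ---------------------------------------------
    hits = mo.scan_motifs(
        ds.peak_sequences or [], pfms, cfg.motif_threshold_fraction, cfg.motif_pseudocount
    )
    peak_gc = ld.peak_gc
    deviations = mo.motif_deviations(
        ilc2.atac if ilc2.n_cells else ds.atac, hits, peak_gc,
        n_bg=cfg.motif_n_background, seed=seed,
    )
    naive_only = sorted(
        set(lk.dedup_peaks(fate_links.get("naive", empty)))
        - set(lk.dedup_peaks(fate_links.get("exp", empty)))
    )
    if naive_only:
        enrichment = mo.enrich_motifs(
            naive_only, list(ds.peaks["name"]), hits, peak_gc, seed=seed
        )
    else:
        enrichment = pd.DataFrame(
            columns=["motif", "n_fg_with", "n_fg", "n_bg_with", "n_bg",
                     "fold_enrichment", "p_value", "p_adj"]
        )
    ilc2_norm = embed.NormalizedMatrix(
        norm_rna.values[:, ilc2_mask], norm_rna.feature_ids,
        np.asarray(norm_rna.barcodes)[ilc2_mask], norm_rna.method,
    )
    crossref = mo.crossref_expression(enrichment, ilc2_norm, motif_gene_map)

    # ---------------- preranked GSEA -------------------------------------
    fate_full = fatemap["label"].to_numpy()
    ranked = gsea.rank_fatemap_degs(
        norm_rna, fate_full, cluster_mask=ilc2_mask,
        min_pct=cfg.deg_min_pct, logfc_min=cfg.deg_logfc,
    )
    if len(ranked) and gene_sets:
        gsea_result = gsea.gsea_preranked(
            ranked, gene_sets, cfg.gsea_min_size, cfg.gsea_max_size,
            cfg.gsea_n_perm, p_cutoff=cfg.gsea_p_cutoff, seed=seed,
        )
    else:
        emptyg = pd.DataFrame(
            columns=["set", "size", "es", "nes", "p_value", "leading_edge", "p_adj"]
        )
        gsea_result = gsea.GseaResult(table=emptyg, significant=emptyg)

    result = PipelineResult(
        dataset=dataset, truth=truth, qc_table=qc_table, kept_barcodes=kept,
        purged_barcodes=purged_kept, fatemap=fatemap, clusters=clusters,
        ilc2_cluster=ilc2_cluster, gex_markers=gex_markers, ga_markers=ga_markers,
        da_peaks=da_annot, signature=signature, fate_links=fate_links,
        cond_links=cond_links, regulome=regulome, intersections=intersections,
        induced_ranking=induced_ranking, th2=th2, motif_hits=hits,
        deviations=deviations, enrichment=enrichment, crossref=crossref,
        ranked_degs=ranked, gsea_result=gsea_result,
        extras={"pca": pca, "lsi": lsi, "ga": ga, "norm_rna": norm_rna, "tfidf": tfidf,
                "ilc2_mask": ilc2_mask, "link_data": ld},
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(res: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.qc_table.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    res.fatemap.to_csv(outdir / "fatemap.tsv", sep="\t", index=False)
    pd.DataFrame({"barcode": res.clusters.barcodes, "cluster": res.clusters.labels}).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )
    res.gex_markers.to_csv(outdir / "markers_gex.tsv", sep="\t", index=False)
    res.ga_markers.to_csv(outdir / "markers_ga.tsv", sep="\t", index=False)
    res.da_peaks.to_csv(outdir / "markers_da.tsv", sep="\t", index=False)
    (outdir / "signature.json").write_text(json.dumps(res.signature.to_json_dict(), indent=2))
    for cond, df in {**res.fate_links, **res.cond_links}.items():
        df.to_csv(outdir / f"links_{cond.replace(':', '_')}.tsv", sep="\t", index=False)
    res.regulome.to_csv(outdir / "regulome_counts.tsv", sep="\t", index=False)
    inter = res.intersections.copy()
    inter["members"] = inter["members"].map(lambda m: ",".join(m))
    inter.to_csv(outdir / "peak_intersections.tsv", sep="\t", index=False)
    res.induced_ranking.to_csv(outdir / "induced_peak_genes.tsv", sep="\t", index=False)
    res.th2.regulome.to_csv(outdir / "th2_regulome.tsv", sep="\t", index=False)
    th2i = res.th2.intersections.copy()
    th2i["members"] = th2i["members"].map(lambda m: ",".join(m))
    th2i.to_csv(outdir / "th2_intersections.tsv", sep="\t", index=False)
    res.th2.induced_ranking.to_csv(outdir / "th2_induced.tsv", sep="\t", index=False)
    res.motif_hits.astype(int).to_csv(outdir / "motif_hits.tsv", sep="\t")
    dev = pd.DataFrame(res.deviations.z, index=res.deviations.motif_names,
                       columns=res.deviations.barcodes)
    dev.to_csv(outdir / "motif_deviation_z.tsv", sep="\t")
    res.enrichment.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
    res.crossref.to_csv(outdir / "motif_expression_crossref.tsv", sep="\t", index=False)
    res.ranked_degs.to_csv(outdir / "fatemap_ranked_degs.tsv", sep="\t", index=False)
    tbl = res.gsea_result.table.copy()
    if len(tbl):
        tbl["leading_edge"] = tbl["leading_edge"].map(lambda g: ",".join(g))
    tbl.to_csv(outdir / "gsea.tsv", sep="\t", index=False)
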