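"""Ready-made simulation scenarios.

``default_study_scenario`` emulates the study conditions the pipeline was
built for: a skin-draining lymph-node mixture of five cell types (~2,000
cells after filtering), a Cre-activated tdRFP reporter marking the
RAG-experienced subpopulation, and planted gene-peak couplings whose
activity depends on fate-map and disease state — including a clustered
Th2-locus block (Il4, Il13, Rad50, Il5) with cross-gene links.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as fio
from .dataset import DISEASE_AD, DISEASE_SS, FATE_EXP, FATE_NAIVE
from .simulate import (
    ALL_STATES,
    INDUCED_STATES,
    LINEAGE_PANEL,
    NAIVE_STATES,
    TH2_LOCUS,
    DEFAULT_CELL_TYPES,
    PlantedLink,
    SimConfig,
)

GATA_CONSENSUS = "AGATAAGA"
TBOX_CONSENSUS = "AGGTGTGA"
KLF_CONSENSUS = "GGGGCGGGGC"
RORA_CONSENSUS = "TAGGTCAA"

TILE = 2_000_000
GENE_OFFSET = 900_000  # gene placed here inside its tile
GENE_LEN = 10_000


def _tile_layout(tiled_genes: list[str], per_chrom: int = 40):
    """One gene per 2-Mb tile; distal peaks live on a gene-free chromosome."""
    rows = []
    for i, g in enumerate(tiled_genes):
        chrom = f"chr{i // per_chrom + 1}"
        t0 = (i % per_chrom) * TILE
        start = t0 + GENE_OFFSET
        strand = "+" if i % 2 == 0 else "-"
        rows.append((g, chrom, start, start + GENE_LEN, strand))
    n_chroms = (len(tiled_genes) - 1) // per_chrom + 1
    genome = {f"chr{c + 1}": per_chrom * TILE for c in range(n_chroms)}
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"]), genome


def default_study_scenario(seed: int = 0) -> SimConfig:
    """The study-scale scenario: ~2,000 cells, 5 types x 2 fate-map x 2 disease.

    Plants 90 ILC2-program links active only in RAG-naive states, 20
    disease-induced links (active everywhere except RAG-experienced steady
    state), 15 constitutive links, and a Th2-locus block with naive-only and
    induced links including cross-gene peaks.
    """
    rng = np.random.default_rng(seed + 7)

    ilc2_named = ["Gata3", "Il1rl1", "Icos", "Tox", "Maf", "Il18r1", "Arg1", "Klrg1", "Areg", "Bcl11b"]
    ilc2_genes = ilc2_named + [f"g_ilc2_{i:02d}" for i in range(35)]
    induced_genes = ["Ccr6", "Rora"] + [f"g_ind_{i:02d}" for i in range(18)]
    t_markers = ["Lck", "Ccl5", "Cd2"] + [f"g_t_{i:02d}" for i in range(12)]
    b_markers = ["Ms4a1", "Ebf1", "Pax5"] + [f"g_b_{i:02d}" for i in range(12)]
    nk_markers = ["Eomes", "Tbx21", "Ncr1"] + [f"g_nk_{i:02d}" for i in range(12)]
    dc_markers = ["Flt3", "Batf3", "Zbtb46"] + [f"g_dc_{i:02d}" for i in range(12)]
    hk = [f"hk_{i:03d}" for i in range(150)]
    # fate- and disease-modulated genes live inside the housekeeping block
    hk[0], hk[1], hk[2] = "Klf2", "Klf6", "Klf12"  # higher in RAG-experienced
    hk[60] = "Klf7"  # higher in RAG-naive
    fate_up = hk[:60]
    fate_down = hk[60:120]
    disease_up = hk[120:135]
    const_genes = hk[135:150]
    mito = ["mt-Co1", "mt-Co2", "mt-Nd1", "mt-Nd2", "mt-Cytb"]
    ribo = ["Rps6", "Rps19", "Rpl13a", "Rpl32", "Rps29", "Rpl11", "Rps3", "Rpl5"]

    tiled = ilc2_genes + induced_genes + t_markers + b_markers + nk_markers + dc_markers + hk + LINEAGE_PANEL
    genes, genome = _tile_layout(tiled)

    # Th2 locus: four genes inside one 200-kb window on a dedicated chromosome
    th2_chrom = "chrTh2"
    t0 = 500_000
    th2_rows = [
        ("Il4", th2_chrom, t0, t0 + 8_000, "-"),
        ("Il13", th2_chrom, t0 + 25_000, t0 + 30_000, "-"),
        ("Rad50", th2_chrom, t0 + 60_000, t0 + 140_000, "+"),
        ("Il5", th2_chrom, t0 + 180_000, t0 + 185_000, "-"),
    ]
    genome[th2_chrom] = 4_000_000
    genome["chrM"] = 20_000
    genome["chrTg"] = 10_000
    genome["chrU"] = 10_000_000
    extra = pd.DataFrame(th2_rows, columns=["gene", "chrom", "start", "end", "strand"])
    mito_rows = [(m, "chrM", 1_000 + 3_000 * i, 3_000 + 3_000 * i, "+") for i, m in enumerate(mito)]
    ribo_rows = []
    genes = pd.concat(
        [
            genes,
            extra,
            pd.DataFrame(mito_rows, columns=genes.columns[:5]),
            pd.DataFrame([("tdRFP", "chrTg", 2_000, 4_000, "+")], columns=genes.columns[:5]),
        ],
        ignore_index=True,
    )
    # ribosomal genes share ordinary tiles appended at the end of chr1 layout:
    # place them on chrU-free chromosome tail positions of the last tile chrom
    ribo_rows = [
        (r, "chrTh2", 2_400_000 + 60_000 * i, 2_410_000 + 60_000 * i, "+")
        for i, r in enumerate(ribo)
    ]
    genes = pd.concat([genes, pd.DataFrame(ribo_rows, columns=genes.columns[:5])], ignore_index=True)

    gene_pos = genes.set_index("gene")

    # ------------------------------------------------------------------ peaks
    peak_rows = []  # (chrom, start, end, name)
    peak_meta = {}  # name -> dict(role=..., type=...)

    def add_peak(chrom, start, width, role, ptype=None):
        start = int(start)
        name = fio.peak_name(chrom, start, start + width)
        if name not in peak_meta:
            peak_rows.append((chrom, start, start + width, name))
            peak_meta[name] = {"role": role, "type": ptype}
        return name

    def tss_of(g):
        row = gene_pos.loc[g]
        return row.chrom, int(row.start if row.strand == "+" else row.end - 1)

    # promoter peaks for non-ILC2 marker genes, lineage genes and some
    # housekeeping genes (type-specific accessibility drives the LSI signal)
    promoter_of = {}
    for ctype, markers in (
        ("Tcell", t_markers),
        ("Bcell", b_markers),
        ("NK", nk_markers),
        ("DC", dc_markers),
    ):
        for g in markers:
            chrom, tss = tss_of(g)
            promoter_of[g] = add_peak(chrom, tss - 200, 500, "promoter", ctype)
    for g, t in zip(LINEAGE_PANEL, ["Tcell", "Tcell", "Tcell", "Tcell", "Bcell", "Tcell", "DC"]):
        chrom, tss = tss_of(g)
        promoter_of[g] = add_peak(chrom, tss - 200, 500, "promoter", t)
    for g in hk[:40]:
        chrom, tss = tss_of(g)
        promoter_of[g] = add_peak(chrom, tss - 200, 500, "promoter", None)

    links: list[PlantedLink] = []

    # ILC2-program links: two distal peaks per gene, active in naive states only
    for g in ilc2_genes:
        chrom, tss = tss_of(g)
        for off in (int(rng.integers(-450_000, -30_000)), int(rng.integers(30_000, 450_000))):
            w = int(rng.integers(400, 701))
            name = add_peak(chrom, tss + off, w, "ilc2_link", "ILC2")
            links.append(PlantedLink(g, name, 1.2, 1.2, NAIVE_STATES, "program"))

    # induced links: present in naive states and in experienced+disease cells
    for g in induced_genes:
        chrom, tss = tss_of(g)
        off = int(rng.integers(100_000, 400_000)) * int(rng.choice([-1, 1]))
        name = add_peak(chrom, tss + off, int(rng.integers(400, 701)), "induced_link", "ILC2")
        links.append(PlantedLink(g, name, 1.5, 1.5, INDUCED_STATES, "induced"))

    # constitutive links on housekeeping genes, active in every state
    for g in const_genes:
        chrom, tss = tss_of(g)
        off = int(rng.integers(40_000, 250_000)) * int(rng.choice([-1, 1]))
        name = add_peak(chrom, tss + off, int(rng.integers(400, 701)), "const_link", None)
        links.append(PlantedLink(g, name, 1.0, 1.0, ALL_STATES, "constitutive"))

    # Th2 block: 14 clustered peaks, naive-only and induced links, cross-gene
    th2_peaks = []
    for i in range(14):
        start = t0 - 40_000 + i * 20_000 + int(rng.integers(0, 8_000))
        th2_peaks.append(add_peak(th2_chrom, start, int(rng.integers(400, 701)), "th2", "ILC2"))
    th2_naive = [
        ("Il4", 0), ("Il4", 1),
        ("Il13", 2), ("Il13", 3), ("Il13", 4),
        ("Rad50", 5), ("Rad50", 6),
        ("Il5", 7), ("Il5", 8), ("Il5", 9),
        ("Il5", 2),  # cross-gene links within the locus
        ("Il13", 8),
        ("Il4", 3),
        ("Rad50", 4),
    ]
    for g, k in th2_naive:
        links.append(PlantedLink(g, th2_peaks[k], 1.2, 1.2, NAIVE_STATES, "th2"))
    for g, k in (("Il13", 10), ("Il13", 11), ("Il13", 12), ("Il4", 13)):
        links.append(PlantedLink(g, th2_peaks[k], 1.5, 1.5, INDUCED_STATES, "th2_induced"))

    # distal peaks on a gene-free chromosome: a type-specific program per
    # non-ILC2 type (real cell types differ over many distal elements), plus
    # shared background
    distal_types = ["Tcell", "Bcell", "NK", "DC"]
    for i in range(150):
        ptype = distal_types[i // 20] if i < 80 else None
        add_peak("chrU", 20_000 + i * 60_000 + int(rng.integers(0, 20_000)),
                 int(rng.integers(300, 801)), "distal", ptype)

    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])

    # ------------------------------------------------------------- weights
    gene_base = {g: 1.0 for g in genes["gene"]}
    type_gene_fold: dict = {t: {} for t in DEFAULT_CELL_TYPES}
    for g in ilc2_genes:
        gene_base[g] = 0.35
        type_gene_fold["ILC2"][g] = 6.0
    for g in induced_genes:
        gene_base[g] = 0.5
        type_gene_fold["ILC2"][g] = 6.0
    for g in TH2_LOCUS:
        gene_base[g] = 0.25
        type_gene_fold["ILC2"][g] = 6.0
    for ctype, markers in (
        ("Tcell", t_markers), ("Bcell", b_markers), ("NK", nk_markers), ("DC", dc_markers)
    ):
        for g in markers:
            gene_base[g] = 0.6
            type_gene_fold[ctype][g] = 6.0
    lineage_type = dict(zip(LINEAGE_PANEL, ["Tcell"] * 4 + ["Bcell", "Tcell", "DC"]))
    for g, t in lineage_type.items():
        gene_base[g] = 1.5
        for ct in DEFAULT_CELL_TYPES:
            type_gene_fold[ct][g] = 4.0 if ct == t else (1.0 if ct in (t,) else 0.0)
        type_gene_fold[t][g] = 4.0
    # mitochondrial ~2% and ribosomal ~5% of counts
    approx_z = 330.0
    for g in mito:
        gene_base[g] = 0.02 * approx_z / (0.93 * len(mito))
    for g in ribo:
        gene_base[g] = 0.05 * approx_z / (0.93 * len(ribo))
    gene_base["tdRFP"] = 0.0

    fate_gene_fold = {g: 1.7 for g in fate_up}
    fate_gene_fold.update({g: 1 / 1.7 for g in fate_down})
    disease_gene_fold = {g: 1.6 for g in disease_up}

    peak_base = {p: 1.0 for p in peaks["name"]}
    type_peak_fold: dict = {t: {} for t in DEFAULT_CELL_TYPES}
    peak_motif = {}
    for name, meta in peak_meta.items():
        if meta["role"] in ("ilc2_link", "induced_link", "th2"):
            peak_base[name] = 0.7
            type_peak_fold["ILC2"][name] = 4.0
        elif meta["role"] == "const_link":
            peak_base[name] = 0.8
        elif meta["role"] in ("promoter", "distal") and meta["type"] is not None:
            type_peak_fold[meta["type"]][name] = 4.0
        if meta["role"] in ("ilc2_link", "th2"):
            peak_motif[name] = GATA_CONSENSUS
        elif meta["role"] == "induced_link":
            peak_motif[name] = RORA_CONSENSUS
        elif meta["role"] == "const_link":
            peak_motif[name] = KLF_CONSENSUS
        elif meta["role"] == "promoter" and meta["type"] == "NK":
            peak_motif[name] = TBOX_CONSENSUS

    peak_gc = {p: float(np.clip(rng.beta(8, 8), 0.25, 0.75)) for p in peaks["name"]}

    n_cells = {}
    for fate in (FATE_NAIVE, FATE_EXP):
        for disease in (DISEASE_SS, DISEASE_AD):
            n_cells[("ILC2", fate, disease)] = 250
            for t in ("Tcell", "Bcell", "NK", "DC"):
                n_cells[(t, fate, disease)] = 62 if (fate, disease) != (FATE_NAIVE, DISEASE_SS) else 64

    return SimConfig(
        n_cells_per_group=n_cells,
        cell_types=list(DEFAULT_CELL_TYPES),
        genome=genome,
        genes=genes,
        peaks=peaks,
        linked_pairs=links,
        gene_base_weight=gene_base,
        type_gene_fold=type_gene_fold,
        fate_gene_fold=fate_gene_fold,
        disease_gene_fold=disease_gene_fold,
        peak_base_weight=peak_base,
        type_peak_fold=type_peak_fold,
        peak_gc=peak_gc,
        peak_motif=peak_motif,
        seed=seed,
    )


def null_calibration_config(
    n_cells: int = 500, n_genes: int = 100, peaks_per_gene: int = 10, seed: int = 0
) -> SimConfig:
    """A single-population scenario with ~n_genes*peaks_per_gene candidate
    gene-peak pairs and no planted links, for permutation-null calibration."""
    rng = np.random.default_rng(seed + 11)
    names = [f"g{i:03d}" for i in range(n_genes)]
    genes, genome = _tile_layout(names, per_chrom=50)
    peak_rows = []
    for i, g in enumerate(names):
        chrom = genes.loc[i, "chrom"]
        tss = int(genes.loc[i, "start"])
        for j in range(peaks_per_gene):
            off = int(rng.integers(-600_000, 600_000))
            start = int(np.clip(tss + off, 0, genome[chrom] - 1_000))
            width = int(rng.integers(300, 701))
            name = fio.peak_name(chrom, start, start + width)
            if name not in {r[3] for r in peak_rows}:
                peak_rows.append((chrom, start, start + width, name))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])
    n_map = {("ILC2", FATE_NAIVE, DISEASE_SS): n_cells}
    return SimConfig(
        n_cells_per_group=n_map,
        cell_types=["ILC2"],
        genome=genome,
        genes=genes,
        peaks=peaks,
        linked_pairs=[],
        make_fragments=False,
        make_sequences=True,
        peak_gc={p: float(np.clip(rng.beta(8, 8), 0.25, 0.75)) for p in peaks["name"]},
        seed=seed,
    )


def two_state_link_config(
    beta: float = 1.0,
    cells_per_state: int = 500,
    n_decoy_genes: int = 20,
    active_in=frozenset({(FATE_NAIVE, DISEASE_SS)}),
    make_fragments: bool = False,
    seed: int = 0,
) -> SimConfig:
    """Minimal scenario: one linked pair active in selected states only."""
    names = ["glink"] + [f"gd{i:02d}" for i in range(n_decoy_genes)]
    genes, genome = _tile_layout(names, per_chrom=50)
    genome["chrTg"] = 10_000
    genes = pd.concat(
        [genes, pd.DataFrame([("tdRFP", "chrTg", 2_000, 4_000, "+")], columns=genes.columns[:5])],
        ignore_index=True,
    )
    tss = int(genes.loc[0, "start"])
    chrom = genes.loc[0, "chrom"]
    rows = [(chrom, tss + 100_000, tss + 100_500, fio.peak_name(chrom, tss + 100_000, tss + 100_500))]
    for i in range(1, len(names)):
        c, t = genes.loc[i, "chrom"], int(genes.loc[i, "start"])
        rows.append((c, t + 80_000, t + 80_500, fio.peak_name(c, t + 80_000, t + 80_500)))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    planted = (
        [PlantedLink("glink", rows[0][3], beta, beta, frozenset(active_in), "program")]
        if beta > 0
        else []
    )
    n_map = {
        ("ILC2", f, d): cells_per_state
        for f in (FATE_NAIVE, FATE_EXP)
        for d in (DISEASE_SS, DISEASE_AD)
    }
    gene_base = {g: 1.0 for g in genes["gene"]}
    gene_base["glink"] = 3.0
    gene_base["tdRFP"] = 0.0
    return SimConfig(
        n_cells_per_group=n_map,
        cell_types=["ILC2"],
        genome=genome,
        genes=genes,
        peaks=peaks,
        linked_pairs=planted,
        gene_base_weight=gene_base,
        peak_base_weight={rows[0][3]: 2.0},
        make_fragments=make_fragments,
        make_sequences=True,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# motif and gene-set fixtures matched to the default scenario


def _consensus_pfm(mid: str, name: str, consensus: str, strength: int = 85) -> fio.PFM:
    counts = np.full((4, len(consensus)), 5.0)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, b in enumerate(consensus):
        if b == "N":
            counts[:, j] = 25.0  # uninformative column
        else:
            counts[idx[b], j] = strength
    return fio.PFM(id=mid, name=name, counts=counts)


def default_motif_set() -> list[fio.PFM]:
    """Synthetic PFMs matching the motifs the default scenario embeds, plus decoys."""
    return [
        _consensus_pfm("M001", "GATA3", GATA_CONSENSUS),
        _consensus_pfm("M002", "EOMES", TBOX_CONSENSUS),
        _consensus_pfm("M003", "KLF2", KLF_CONSENSUS),
        _consensus_pfm("M004", "RORA", RORA_CONSENSUS),
        _consensus_pfm("M005", "RORC", RORA_CONSENSUS),  # same half-site, gene absent
        _consensus_pfm("M006", "IRF8", "AANTGAAA"),
    ]


def default_motif_gene_map() -> dict[str, str]:
    return {
        "GATA3": "Gata3",
        "EOMES": "Eomes",
        "KLF2": "Klf2",
        "RORA": "Rora",
        "RORC": "Rorc",  # not present in the expression data
        "IRF8": "Irf8",
    }


def default_gene_sets(config: SimConfig, n_decoy: int = 8, seed: int = 0) -> dict[str, list[str]]:
    """GMT-style collection: the two fate-modulated programs plus random decoys."""
    rng = np.random.default_rng(seed + 13)
    up = [g for g, f in config.fate_gene_fold.items() if f > 1]
    down = [g for g, f in config.fate_gene_fold.items() if f < 1]
    universe = [g for g in config.genes["gene"] if g != config.reporter_gene]
    sets = {"FATE_EXP_UP": sorted(up), "FATE_NAIVE_UP": sorted(down)}
    for i in range(n_decoy):
        sets[f"DECOY_{i:02d}"] = sorted(rng.choice(universe, size=55, replace=False))
    return sets
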