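"""Synthetic paired RNA+ATAC multiome generator with planted ground truth.

The generative model is a gamma-Poisson hierarchy.  Every cell draws a
lognormal size factor per modality; gene and peak rates are type-, fate- and
disease-dependent relative weights normalized to the configured depth.  Each
planted gene-peak link carries a per-cell gamma latent activity ``a`` (mean
1): in cell states where the link is active the gene rate is multiplied by
``exp(beta_rna*(a-1))`` and the peak rate by ``exp(beta_atac*(a-1))`` with the
*same* draw of ``a``; in inactive states gene and peak receive *independent*
draws.  Both multipliers are divided by their analytic mean, so the marginal
rate of every feature is identical across states and only the gene-peak
correlation carries the planted signal.

Fragments are synthesized inside peaks (one record per counted peak-cell
pair), at transcription start sites in proportion to the cell's expression
program, and as a uniform genomic background; lengths come from a
sub-nucleosomal / mono-nucleosomal two-component mixture so the nucleosome
signal is controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as fio
from .dataset import (
    DISEASE_AD,
    DISEASE_SS,
    FATE_EXP,
    FATE_NAIVE,
    PairedMultiomeDataset,
    write_peak_fasta,
)

LINEAGE_PANEL = ["Cd3d", "Cd3e", "Cd3g", "Cd4", "Cd19", "Cd8a", "Itgam"]
TH2_LOCUS = ["Il4", "Il13", "Rad50", "Il5"]
DEFAULT_CELL_TYPES = ["ILC2", "Tcell", "Bcell", "NK", "DC"]

ALL_STATES = frozenset(
    {(FATE_NAIVE, DISEASE_SS), (FATE_NAIVE, DISEASE_AD), (FATE_EXP, DISEASE_SS), (FATE_EXP, DISEASE_AD)}
)
NAIVE_STATES = frozenset({(FATE_NAIVE, DISEASE_SS), (FATE_NAIVE, DISEASE_AD)})
INDUCED_STATES = frozenset(
    {(FATE_NAIVE, DISEASE_SS), (FATE_NAIVE, DISEASE_AD), (FATE_EXP, DISEASE_AD)}
)


@dataclass(frozen=True)
class PlantedLink:
    """A gene-peak coupling through a shared latent activity."""

    gene: str
    peak: str
    beta_rna: float = 1.2
    beta_atac: float = 1.2
    active_in: frozenset = NAIVE_STATES
    kind: str = "program"

    def __post_init__(self):
        if self.beta_rna <= 0 or self.beta_atac <= 0:
            raise ValueError("link effect sizes must be positive")
        if not self.active_in:
            raise ValueError("active_in must be non-empty")


@dataclass
class SimConfig:
    """Full specification of a synthetic paired-multiome experiment."""

    n_cells_per_group: dict  # (cell_type, fate, disease) -> count
    cell_types: list
    genome: dict  # chrom -> length
    genes: pd.DataFrame  # gene, chrom, start, end, strand
    peaks: pd.DataFrame  # chrom, start, end, name
    linked_pairs: list = field(default_factory=list)
    gene_base_weight: dict = field(default_factory=dict)
    type_gene_fold: dict = field(default_factory=dict)  # type -> {gene: fold}
    fate_gene_fold: dict = field(default_factory=dict)  # gene -> fold in EXP cells
    disease_gene_fold: dict = field(default_factory=dict)  # gene -> fold in AD cells
    peak_base_weight: dict = field(default_factory=dict)
    type_peak_fold: dict = field(default_factory=dict)  # type -> {peak: fold}
    peak_gc: dict = field(default_factory=dict)  # peak -> target GC fraction
    peak_motif: dict = field(default_factory=dict)  # peak -> consensus to embed
    rna_depth_mean: float = 2500.0
    atac_depth_mean: float = 1000.0
    depth_sigma: float = 0.25
    atac_depth_sigma: float = 0.65
    dropout_tdrfp: float = 0.1
    dispersion: float = 2.0
    reporter_gene: str = "tdRFP"
    frag_peak_frac: float = 0.6
    frag_tss_frac: float = 0.2
    frag_background_frac: float = 0.2
    long_frag_frac: float = 0.3
    make_fragments: bool = True
    make_sequences: bool = True
    link_window: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        self.genes = fio.validate_gene_model(self.genes, source="sim genes")
        self.validate()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def validate(self) -> None:
        if any(v <= 0 for v in self.n_cells_per_group.values()):
            raise ValueError("group cell counts must be positive")
        if not 0 <= self.dropout_tdrfp <= 1:
            raise ValueError("dropout_tdrfp must be a probability")
        gene_pos = self.genes.set_index("gene")
        peak_pos = self.peaks.set_index("name")
        for chrom, s, e in zip(self.peaks.chrom, self.peaks.start, self.peaks.end):
            if chrom not in self.genome or e > self.genome[chrom] or s < 0:
                raise ValueError(f"peak {chrom}:{s}-{e} outside configured genome")
        for link in self.linked_pairs:
            if link.gene not in gene_pos.index:
                raise ValueError(f"link references unknown gene {link.gene!r}")
            if link.peak not in peak_pos.index:
                raise ValueError(f"link references unknown peak {link.peak!r}")
            if max(link.beta_rna, link.beta_atac) >= self.dispersion:
                raise ValueError("link beta must be < dispersion (finite latent mean)")
            g = gene_pos.loc[link.gene]
            p = peak_pos.loc[link.peak]
            center = (p.start + p.end) // 2
            if p.chrom != g.chrom or abs(center - g.tss) > self.link_window:
                raise ValueError(
                    f"link {link.gene}<->{link.peak} outside {self.link_window} bp window"
                )


@dataclass
class TruthTables:
    """Planted ground truth: cell labels, the link registry, expected deltas."""

    labels: pd.DataFrame  # barcode, cell_type, fate_map, disease
    links: pd.DataFrame  # gene, peak, beta_rna, beta_atac, active_in, kind
    gpl_delta: pd.DataFrame  # gene, n_links_naive, n_links_exp, delta


def _latent_mean(beta: float, shape: float) -> float:
    """E[exp(beta*(a-1))] for a ~ Gamma(shape, 1/shape)."""
    return float(np.exp(-beta) * (1.0 - beta / shape) ** (-shape))


def _serialize_states(states) -> str:
    return "|".join(sorted(f"{f}:{d}" for f, d in states))


def parse_states(s: str) -> frozenset:
    return frozenset(tuple(part.split(":")) for part in s.split("|") if part)


def simulate_multiome(config: SimConfig) -> tuple[PairedMultiomeDataset, TruthTables]:
    """Draw one paired multiome dataset plus its truth tables."""
    rng = np.random.default_rng(config.seed)
    genes = config.genes.reset_index(drop=True)
    peaks = config.peaks.reset_index(drop=True)
    gene_names = genes["gene"].to_numpy()
    peak_names = peaks["name"].to_numpy()
    gi = {g: i for i, g in enumerate(gene_names)}
    pi = {p: i for i, p in enumerate(peak_names)}

    # --- cell table ------------------------------------------------------
    groups = sorted(config.n_cells_per_group.items())
    rows = []
    for (ctype, fate, disease), n in groups:
        rows += [(ctype, fate, disease)] * n
    obs = pd.DataFrame(rows, columns=["cell_type", "fate_map", "disease"])
    n_cells = len(obs)
    obs.insert(0, "barcode", [f"BC{i:06d}" for i in range(n_cells)])

    # --- relative weight matrices (features x groups) --------------------
    group_keys = [k for k, _ in groups]
    gene_w = np.zeros((len(genes), len(group_keys)))
    peak_w = np.zeros((len(peaks), len(group_keys)))
    base_g = np.array([config.gene_base_weight.get(g, 1.0) for g in gene_names])
    base_p = np.array([config.peak_base_weight.get(p, 1.0) for p in peak_names])
    for j, (ctype, fate, disease) in enumerate(group_keys):
        wg = base_g.copy()
        tf = config.type_gene_fold.get(ctype, {})
        for g, f in tf.items():
            wg[gi[g]] *= f
        if fate == FATE_EXP:
            for g, f in config.fate_gene_fold.items():
                wg[gi[g]] *= f
        if disease == DISEASE_AD:
            for g, f in config.disease_gene_fold.items():
                wg[gi[g]] *= f
        gene_w[:, j] = wg
        wp = base_p.copy()
        for p, f in config.type_peak_fold.get(ctype, {}).items():
            wp[pi[p]] *= f
        peak_w[:, j] = wp
    reporter_idx = gi.get(config.reporter_gene)
    if reporter_idx is not None:
        gene_w[reporter_idx, :] = 0.0  # reporter counts are drawn structurally

    group_of_cell = np.repeat(np.arange(len(group_keys)), [n for _, n in groups])

    # --- per-cell size factors ------------------------------------------
    sig = config.depth_sigma
    sig_a = config.atac_depth_sigma
    s_rna = rng.lognormal(-0.5 * sig**2, sig, size=n_cells)
    s_atac = rng.lognormal(-0.5 * sig_a**2, sig_a, size=n_cells)

    # --- link latents ----------------------------------------------------
    # Links of one gene sharing an activity pattern model a single regulatory
    # program: they share one latent, so the gene carries one multiplier per
    # program and its peaks are co-accessible, as in real regulomes.
    shape = config.dispersion
    gene_mult = np.ones((len(genes), n_cells))
    peak_mult = np.ones((len(peaks), n_cells))
    state_of_cell = list(zip(obs["fate_map"], obs["disease"]))
    programs: dict[tuple, list[PlantedLink]] = {}
    for link in config.linked_pairs:
        programs.setdefault((link.gene, link.active_in), []).append(link)
    for (gene, active_in), members in programs.items():
        active = np.array([st in active_in for st in state_of_cell])
        a_shared = rng.gamma(shape, 1.0 / shape, size=n_cells)
        beta_rna = members[0].beta_rna
        a_g = np.where(active, a_shared, rng.gamma(shape, 1.0 / shape, size=n_cells))
        gene_mult[gi[gene]] *= np.exp(beta_rna * (a_g - 1.0)) / _latent_mean(beta_rna, shape)
        for link in members:
            a_p = np.where(active, a_shared, rng.gamma(shape, 1.0 / shape, size=n_cells))
            peak_mult[pi[link.peak]] *= np.exp(link.beta_atac * (a_p - 1.0)) / _latent_mean(
                link.beta_atac, shape
            )

    # --- RNA counts ------------------------------------------------------
    gw_cells = gene_w[:, group_of_cell]
    gene_rates = gw_cells / gw_cells.sum(axis=0, keepdims=True)
    gene_rates *= config.rna_depth_mean * s_rna[None, :]
    gene_rates *= gene_mult
    rna_counts = rng.poisson(gene_rates).astype(np.int64)
    if reporter_idx is not None:
        exp_mask = (obs["fate_map"] == FATE_EXP).to_numpy()
        rep = np.zeros(n_cells, dtype=np.int64)
        detected = exp_mask & (rng.random(n_cells) >= config.dropout_tdrfp)
        rep[detected] = 1 + rng.poisson(0.7, size=int(detected.sum()))
        rna_counts[reporter_idx] = rep

    # --- ATAC peak counts ------------------------------------------------
    pw_cells = peak_w[:, group_of_cell]
    peak_rates = pw_cells / pw_cells.sum(axis=0, keepdims=True)
    peak_rates *= config.atac_depth_mean * config.frag_peak_frac * s_atac[None, :]
    peak_rates *= peak_mult
    atac_counts = rng.poisson(peak_rates).astype(np.int64)

    rna = fio.CountMatrix(sp.csr_matrix(rna_counts), gene_names, obs["barcode"].to_numpy(), fio.RNA)
    atac = fio.CountMatrix(
        sp.csr_matrix(atac_counts), peak_names, obs["barcode"].to_numpy(), fio.ATAC_PEAKS
    )

    # --- fragments -------------------------------------------------------
    if config.make_fragments:
        fragments = _synthesize_fragments(
            config, rng, obs, atac_counts, peaks, genes, gene_w, group_of_cell, s_atac
        )
    else:
        fragments = pd.DataFrame(columns=fio.FRAGMENT_COLUMNS)

    # --- peak sequences --------------------------------------------------
    sequences = None
    if config.make_sequences:
        sequences = _synthesize_sequences(config, rng, peaks)

    ds = PairedMultiomeDataset(
        rna=rna,
        atac=atac,
        fragments=fragments,
        peaks=peaks,
        genes=genes,
        obs=obs,
        peak_sequences=sequences,
    )
    truth = _build_truth(config, obs)
    fio.log.info(
        "simulated %d cells, %d genes, %d peaks, %d fragments, %d planted links",
        n_cells,
        len(genes),
        len(peaks),
        len(fragments),
        len(config.linked_pairs),
    )
    return ds, truth


def _frag_lengths(rng, n, long_frac):
    is_long = rng.random(n) < long_frac
    lens = np.where(
        is_long, rng.integers(147, 295, size=n), rng.integers(60, 147, size=n)
    )
    return lens


def _synthesize_fragments(config, rng, obs, atac_counts, peaks, genes, gene_w, group_of_cell, s_atac):
    n_cells = len(obs)
    barcodes = obs["barcode"].to_numpy()
    frames = []

    # fragments inside counted peaks: one record per (peak, cell) pair, the
    # count field carrying PCR duplicates
    coo = sp.coo_matrix(atac_counts)
    if coo.nnz:
        p_idx, c_idx, counts = coo.row, coo.col, coo.data
        widths = (peaks["end"].to_numpy() - peaks["start"].to_numpy())[p_idx]
        lens = np.minimum(_frag_lengths(rng, len(p_idx), config.long_frag_frac), widths - 1)
        lens = np.maximum(lens, 1)
        offs = (rng.random(len(p_idx)) * (widths - lens)).astype(np.int64)
        starts = peaks["start"].to_numpy()[p_idx] + offs
        frames.append(
            pd.DataFrame(
                {
                    "chrom": peaks["chrom"].to_numpy()[p_idx],
                    "start": starts,
                    "end": starts + lens,
                    "barcode": barcodes[c_idx],
                    "count": counts.astype(np.int64),
                }
            )
        )

    # TSS-proximal fragments in proportion to each cell's expression program
    n_tss = rng.poisson(config.frag_tss_frac * config.atac_depth_mean * s_atac)
    tss = genes["tss"].to_numpy()
    gene_chrom = genes["chrom"].to_numpy()
    probs_by_group = gene_w / np.maximum(gene_w.sum(axis=0, keepdims=True), 1e-12)
    cell_rows, gene_rows, count_rows = [], [], []
    for c in range(n_cells):
        if n_tss[c] == 0:
            continue
        cnts = rng.multinomial(n_tss[c], probs_by_group[:, group_of_cell[c]])
        nz = np.flatnonzero(cnts)
        cell_rows.append(np.full(len(nz), c))
        gene_rows.append(nz)
        count_rows.append(cnts[nz])
    if cell_rows:
        c_idx = np.concatenate(cell_rows)
        g_idx = np.concatenate(gene_rows)
        cnts = np.concatenate(count_rows)
        lens = rng.integers(60, 140, size=len(g_idx))
        # most promoter insertions are tight around the TSS; a minority spread
        # into the kilobase neighborhood so enrichment ratios stay finite
        tight = rng.random(len(g_idx)) < 0.7
        centers = tss[g_idx] + np.where(
            tight,
            rng.integers(-40, 41, size=len(g_idx)),
            rng.integers(-1200, 1201, size=len(g_idx)),
        )
        starts = np.maximum(centers - lens // 2, 0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": gene_chrom[g_idx],
                    "start": starts,
                    "end": starts + lens,
                    "barcode": barcodes[c_idx],
                    "count": cnts.astype(np.int64),
                }
            )
        )

    # uniform genomic background
    n_bg = rng.poisson(config.frag_background_frac * config.atac_depth_mean * s_atac)
    total_bg = int(n_bg.sum())
    if total_bg:
        chroms = list(config.genome)
        lengths = np.array([config.genome[c] for c in chroms], dtype=np.int64)
        cum = np.cumsum(lengths)
        pos = (rng.random(total_bg) * cum[-1]).astype(np.int64)
        which = np.searchsorted(cum, pos, side="right")
        local = pos - (cum[which] - lengths[which])
        lens = _frag_lengths(rng, total_bg, config.long_frag_frac)
        starts = np.minimum(local, lengths[which] - lens - 1)
        starts = np.maximum(starts, 0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": np.array(chroms, dtype=object)[which],
                    "start": starts,
                    "end": starts + lens,
                    "barcode": np.repeat(barcodes, n_bg),
                    "count": np.ones(total_bg, dtype=np.int64),
                }
            )
        )

    if not frames:
        return pd.DataFrame(columns=fio.FRAGMENT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return fio.validate_fragments(out, source="simulated fragments")


_BASE_ORDER = np.array(list("ACGT"))


def _synthesize_sequences(config, rng, peaks) -> list[str]:
    seqs = []
    for chrom, start, end, name in zip(peaks.chrom, peaks.start, peaks.end, peaks.name):
        width = end - start
        gc = config.peak_gc.get(name, 0.5)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes = rng.choice(4, size=width, p=p)
        seq = _BASE_ORDER[codes]
        motif = config.peak_motif.get(name)
        if motif and len(motif) <= width:
            at = (width - len(motif)) // 2
            seq[at : at + len(motif)] = list(motif)
        seqs.append("".join(seq))
    return seqs


def _build_truth(config: SimConfig, obs: pd.DataFrame) -> TruthTables:
    links = pd.DataFrame(
        {
            "gene": [l.gene for l in config.linked_pairs],
            "peak": [l.peak for l in config.linked_pairs],
            "beta_rna": [l.beta_rna for l in config.linked_pairs],
            "beta_atac": [l.beta_atac for l in config.linked_pairs],
            "active_in": [_serialize_states(l.active_in) for l in config.linked_pairs],
            "kind": [l.kind for l in config.linked_pairs],
        }
    )
    rows = []
    for gene, sub in links.groupby("gene"):
        states = [parse_states(s) for s in sub["active_in"]]
        n_naive = sum(any(f == FATE_NAIVE for f, _ in st) for st in states)
        n_exp = sum(any(f == FATE_EXP for f, _ in st) for st in states)
        rows.append((gene, n_naive, n_exp, n_naive - n_exp))
    gpl = pd.DataFrame(rows, columns=["gene", "n_links_naive", "n_links_exp", "delta"])
    labels = obs[["barcode", "cell_type", "fate_map", "disease"]].copy()
    return TruthTables(labels=labels, links=links, gpl_delta=gpl)


# ---------------------------------------------------------------------------
# dataset emission / round trip


def emit_dataset(ds: PairedMultiomeDataset, truth: TruthTables | None, outdir) -> None:
    """Write a dataset (and optional truth tables) in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fio.write_count_matrix(
        ds.rna, outdir / "rna.mtx", outdir / "rna_features.tsv", outdir / "barcodes.tsv"
    )
    fio.write_count_matrix(
        ds.atac, outdir / "atac.mtx", outdir / "atac_features.tsv", outdir / "barcodes.tsv"
    )
    fio.write_fragments(ds.fragments, outdir / "fragments.tsv")
    fio.write_bed(ds.peaks, outdir / "peaks.bed")
    fio.write_gene_model(ds.genes, outdir / "genes.tsv")
    ds.obs.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    if ds.peak_sequences is not None:
        write_peak_fasta(ds.peaks, ds.peak_sequences, outdir / "peaks.fa")
    if truth is not None:
        tdir = outdir / "truth"
        tdir.mkdir(exist_ok=True)
        truth.labels.to_csv(tdir / "labels.tsv", sep="\t", index=False)
        truth.links.to_csv(tdir / "links.tsv", sep="\t", index=False)
        truth.gpl_delta.to_csv(tdir / "gpl_delta.tsv", sep="\t", index=False)


def read_dataset(outdir) -> PairedMultiomeDataset:
    """Re-read a dataset written by :func:`emit_dataset`."""
    outdir = Path(outdir)
    rna = fio.read_count_matrix(
        outdir / "rna.mtx", outdir / "rna_features.tsv", outdir / "barcodes.tsv", fio.RNA
    )
    atac = fio.read_count_matrix(
        outdir / "atac.mtx", outdir / "atac_features.tsv", outdir / "barcodes.tsv", fio.ATAC_PEAKS
    )
    fragments = fio.read_fragments(outdir / "fragments.tsv")
    peaks = fio.read_bed(outdir / "peaks.bed")
    genes = fio.read_gene_model(outdir / "genes.tsv")
    obs = pd.read_csv(outdir / "cells.tsv", sep="\t", dtype=str)
    sequences = None
    fa = outdir / "peaks.fa"
    if fa.exists():
        from .dataset import read_peak_fasta

        seq_map = read_peak_fasta(fa)
        sequences = [seq_map[n] for n in peaks["name"]]
    return PairedMultiomeDataset(
        rna=rna, atac=atac, fragments=fragments, peaks=peaks, genes=genes, obs=obs,
        peak_sequences=sequences,
    )


def read_truth(outdir) -> TruthTables:
    tdir = Path(outdir) / "truth"
    return TruthTables(
        labels=pd.read_csv(tdir / "labels.tsv", sep="\t", dtype=str),
        links=pd.read_csv(tdir / "links.tsv", sep="\t"),
        gpl_delta=pd.read_csv(tdir / "gpl_delta.tsv", sep="\t"),
    )
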