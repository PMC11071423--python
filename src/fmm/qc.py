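"""Per-cell quality control, the filter cascade, lineage purge and
reporter-based fate-map assignment.

The filter is a conjunction of six strict inequalities (nucleosome signal,
TSS enrichment, RNA and ATAC totals, mitochondrial and ribosomal count
percentages); cells carrying any detectable lineage-panel transcript are
purged afterwards, and remaining cells are labelled RAG-experienced when the
reporter transcript (tdRFP) is detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as fio
from .dataset import FATE_EXP, FATE_NAIVE
from .simulate import LINEAGE_PANEL

RAG_EXP = "RAG_EXP"
RAG_NAIVE = "RAG_NAIVE"

TSS_CENTER_HALF = 100  # +-100 bp window around the TSS
TSS_FLANK_CENTER = 950  # 100-bp flanks centered at +-950 bp
TSS_FLANK_HALF = 50
TSS_PSEUDOCOUNT = 1e-9
MONO_NUC_MIN = 147  # mono-nucleosomal fragment length range
MONO_NUC_MAX = 294


@dataclass
class QCThresholds:
    """Strict-inequality bounds of the filter cascade."""

    ns_max: float = 1.5
    tss_min: float = 1.0
    rna_max: int = 15000
    rna_min: int = 1000
    atac_max: int = 75000
    atac_min: int = 100
    mito_max: float = 5.0
    ribo_max: float = 10.0

    @classmethod
    def from_config(cls, cfg: fio.RunConfig) -> "QCThresholds":
        return cls(
            ns_max=cfg.ns_max, tss_min=cfg.tss_min, rna_max=cfg.rna_max, rna_min=cfg.rna_min,
            atac_max=cfg.atac_max, atac_min=cfg.atac_min, mito_max=cfg.mito_max,
            ribo_max=cfg.ribo_max,
        )


QC_METRICS = [
    "n_rna", "n_atac", "pct_mito", "pct_ribo", "tss_enrichment", "nucleosome_signal",
]


def compute_atac_qc(fragments: pd.DataFrame, gene_model: pd.DataFrame, barcodes) -> pd.DataFrame:
    """Per-cell ATAC QC: TSS enrichment, nucleosome signal and fragment totals.

    Nucleosome signal is the count-weighted ratio of mono-nucleosomal
    (147-294 bp) to sub-nucleosomal (<147 bp) fragments (+inf when the
    denominator is zero).  TSS enrichment compares mean per-base insertion
    coverage within +-100 bp of the nearest TSS against two 100-bp flanks
    centered +-950 bp away; both fragment ends count as insertions.
    """
    barcodes = np.asarray(barcodes, dtype=object)
    bc_index = {b: i for i, b in enumerate(barcodes)}
    n = len(barcodes)
    genes = fio.validate_gene_model(gene_model)

    n_atac = np.zeros(n, dtype=np.int64)
    short = np.zeros(n, dtype=np.int64)
    mono = np.zeros(n, dtype=np.int64)
    center = np.zeros(n, dtype=np.int64)
    flank = np.zeros(n, dtype=np.int64)

    if len(fragments):
        keep = fragments["barcode"].isin(bc_index).to_numpy()
        frag = fragments.loc[keep]
        cidx = frag["barcode"].map(bc_index).to_numpy()
        counts = frag["count"].to_numpy()
        lengths = (frag["end"] - frag["start"]).to_numpy()
        np.add.at(n_atac, cidx, counts)
        np.add.at(short, cidx[lengths < MONO_NUC_MIN], counts[lengths < MONO_NUC_MIN])
        mono_mask = (lengths >= MONO_NUC_MIN) & (lengths <= MONO_NUC_MAX)
        np.add.at(mono, cidx[mono_mask], counts[mono_mask])

        tss_by_chrom = {
            c: np.sort(sub["tss"].to_numpy()) for c, sub in genes.groupby("chrom")
        }
        frag_chroms = set(frag["chrom"].unique())
        if not frag_chroms & set(tss_by_chrom):
            warnings.warn("no TSS on any fragment chromosome; TSS enrichment set to 0")
        else:
            for chrom, sub_idx in frag.groupby("chrom", sort=False).indices.items():
                tss = tss_by_chrom.get(chrom)
                if tss is None or len(tss) == 0:
                    continue
                starts = frag["start"].to_numpy()[sub_idx]
                ends = frag["end"].to_numpy()[sub_idx] - 1  # insertion at last covered base
                cnt = counts[sub_idx]
                cells = cidx[sub_idx]
                for pos in (starts, ends):
                    j = np.searchsorted(tss, pos)
                    left = tss[np.clip(j - 1, 0, len(tss) - 1)]
                    right = tss[np.clip(j, 0, len(tss) - 1)]
                    dist = np.minimum(np.abs(pos - left), np.abs(pos - right))
                    in_center = dist <= TSS_CENTER_HALF
                    in_flank = np.abs(dist - TSS_FLANK_CENTER) <= TSS_FLANK_HALF
                    np.add.at(center, cells[in_center], cnt[in_center])
                    np.add.at(flank, cells[in_flank], cnt[in_flank])

    with np.errstate(divide="ignore", invalid="ignore"):
        ns = np.where(short > 0, mono / np.maximum(short, 1), np.inf)
        ns = np.where((short == 0) & (mono == 0), 0.0, ns)
    center_width = 2 * TSS_CENTER_HALF + 1
    # two flanks at unsigned distance 900..1000: each distance maps to two
    # genomic positions, so 202 bases in total
    flank_width = 2 * (2 * TSS_FLANK_HALF + 1)
    tss_e = (center / center_width) / (flank / flank_width + TSS_PSEUDOCOUNT)
    tss_e[(center == 0) & (flank == 0)] = 0.0
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "n_atac": n_atac,
            "tss_enrichment": tss_e,
            "nucleosome_signal": ns,
        }
    )


def compute_rna_qc(rna: fio.CountMatrix) -> pd.DataFrame:
    """Per-cell RNA totals and mitochondrial / ribosomal count percentages.

    Classification is prefix-based on gene symbols: ``mt-`` (case-insensitive)
    and ``Rps`` / ``Rpl``.  All-zero cells get defined 0 percentages.
    """
    feats = [str(f) for f in rna.feature_ids]
    mito_mask = np.array([f.lower().startswith("mt-") for f in feats])
    ribo_mask = np.array([f.startswith("Rps") or f.startswith("Rpl") for f in feats])
    totals = rna.cell_totals().astype(float)
    mito = np.asarray(rna.values[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros_like(totals)
    ribo = np.asarray(rna.values[ribo_mask].sum(axis=0)).ravel() if ribo_mask.any() else np.zeros_like(totals)
    safe = np.maximum(totals, 1.0)
    return pd.DataFrame(
        {
            "barcode": rna.barcodes,
            "n_rna": totals.astype(np.int64),
            "pct_mito": 100.0 * mito / safe,
            "pct_ribo": 100.0 * ribo / safe,
        }
    )


def combine_qc(rna_qc: pd.DataFrame, atac_qc: pd.DataFrame) -> pd.DataFrame:
    return rna_qc.merge(atac_qc, on="barcode", validate="one_to_one")


def apply_qc_filters(qc: pd.DataFrame, thresholds: QCThresholds) -> np.ndarray:
    """Barcodes kept by the six-way conjunction of strict inequalities."""
    missing = [m for m in QC_METRICS if m not in qc.columns]
    if missing:
        raise ValueError(f"QC table missing metrics {missing}")
    for m in QC_METRICS:
        if qc[m].isna().any():
            raise ValueError(f"QC metric {m} contains missing values")
    t = thresholds
    keep = (
        (qc["nucleosome_signal"] < t.ns_max)
        & (qc["tss_enrichment"] > t.tss_min)
        & (qc["n_rna"] < t.rna_max)
        & (qc["n_rna"] > t.rna_min)
        & (qc["n_atac"] < t.atac_max)
        & (qc["n_atac"] > t.atac_min)
        & (qc["pct_mito"] < t.mito_max)
        & (qc["pct_ribo"] < t.ribo_max)
    )
    kept = qc.loc[keep, "barcode"].to_numpy()
    fio.log.info("QC filters: kept %d of %d cells", len(kept), len(qc))
    return kept


def purge_lineage_cells(rna: fio.CountMatrix, panel: list[str] | None = None) -> np.ndarray:
    """Remove every cell with a detectable transcript (count > 0) for any
    lineage-panel gene; returns the kept barcodes."""
    if panel is None:
        panel = list(LINEAGE_PANEL)
    fidx = rna.feature_index()
    present = [g for g in panel if g in fidx]
    missing = [g for g in panel if g not in fidx]
    if missing:
        warnings.warn(f"lineage panel genes absent from features, skipped: {missing}")
    if not present:
        return np.asarray(rna.barcodes, dtype=object)
    rows = [fidx[g] for g in present]
    hits = np.asarray((rna.values[rows] > 0).sum(axis=0)).ravel()
    kept = np.asarray(rna.barcodes, dtype=object)[hits == 0]
    fio.log.info("lineage purge (%d panel genes): kept %d of %d cells",
                 len(present), len(kept), rna.shape[1])
    return kept


def assign_fatemap(
    rna: fio.CountMatrix, reporter: str = "tdRFP", min_count: int = 1
) -> pd.DataFrame:
    """Label each cell RAG_EXP when the reporter transcript is detected
    (count >= min_count), RAG_NAIVE otherwise."""
    fidx = rna.feature_index()
    if reporter not in fidx:
        raise ValueError(f"reporter gene {reporter!r} absent from features")
    counts = np.asarray(rna.values[fidx[reporter]].todense()).ravel()
    labels = np.where(counts >= min_count, RAG_EXP, RAG_NAIVE)
    return pd.DataFrame({"barcode": rna.barcodes, "label": labels, "reporter_count": counts})


def fatemap_to_condition(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Map RAG_EXP / RAG_NAIVE labels onto the short condition tags."""
    arr = np.asarray(labels)
    return np.where(arr == RAG_EXP, FATE_EXP, FATE_NAIVE)
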