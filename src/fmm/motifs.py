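"""Motif scanning over peak sequences, chromVAR-style per-cell motif
deviation z-scores, motif enrichment in peak sets, and cross-referencing
motif accessibility with TF gene expression.

PFMs become log-odds matrices with a total pseudocount of 0.8 against a
uniform base background; a peak is a hit when the best score over both
strands and all offsets reaches a fraction (default 0.8) of the motif's
maximum attainable score.  Deviations compare observed per-cell motif-peak
counts with depth-scaled expectations and z-score them against GC- and
accessibility-matched background peak sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from . import io as fio
from ._stats import bh_adjust
from .embed import NormalizedMatrix

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def pfm_to_log_odds(pfm: fio.PFM, pseudocount: float = 0.8) -> np.ndarray:
    """4 x width log2-odds matrix vs uniform background."""
    counts = pfm.counts
    colsum = counts.sum(axis=0, keepdims=True)
    prob = (counts + pseudocount / 4.0) / (colsum + pseudocount)
    return np.log2(prob / 0.25)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in seq.upper()), dtype=np.int8, count=len(seq))


def _scan_one(codes: np.ndarray, lo_ext: np.ndarray) -> float:
    """Best window score of one strand's extended (5-row) log-odds matrix."""
    w = lo_ext.shape[1]
    L = len(codes)
    if L < w:
        return -np.inf
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = lo_ext[windows, np.arange(w)[None, :]].sum(axis=1)
    return float(scores.max())


def scan_motifs(
    sequences: list[str],
    pfms: list[fio.PFM],
    threshold_fraction: float = 0.8,
    pseudocount: float = 0.8,
) -> pd.DataFrame:
    """Boolean motifs x peaks hit matrix; N bases score as background (0)."""
    n_m, n_p = len(pfms), len(sequences)
    hits = np.zeros((n_m, n_p), dtype=bool)
    coded = [_encode(s) for s in sequences]
    for mi, pfm in enumerate(pfms):
        lo = pfm_to_log_odds(pfm, pseudocount)
        max_score = lo.max(axis=0).sum()
        thresh = threshold_fraction * max_score
        lo_ext = np.vstack([lo, np.zeros((1, lo.shape[1]))])  # N row
        rc = lo[::-1, ::-1]  # reverse complement (ACGT order)
        rc_ext = np.vstack([rc, np.zeros((1, rc.shape[1]))])
        for pi_, codes in enumerate(coded):
            best = max(_scan_one(codes, lo_ext), _scan_one(codes, rc_ext))
            hits[mi, pi_] = best >= thresh
    return pd.DataFrame(hits, index=[p.name for p in pfms])


@dataclass
class DeviationResult:
    raw: np.ndarray  # motifs x cells
    z: np.ndarray
    motif_names: list
    barcodes: np.ndarray
    n_background: int


def _gc_accessibility_bins(peak_gc: np.ndarray, mean_acc: np.ndarray, n_bins: int = 10):
    def _bin(v):
        ranks = sps.rankdata(v, method="average") / (len(v) + 1)
        return np.minimum((ranks * n_bins).astype(int), n_bins - 1)

    return _bin(peak_gc) * n_bins + _bin(mean_acc)


def motif_deviations(
    peak_counts: fio.CountMatrix,
    hits: pd.DataFrame,
    peak_gc: np.ndarray,
    n_bg: int = 50,
    seed: int = 0,
) -> DeviationResult:
    """chromVAR-style bias-corrected motif accessibility deviations.

    raw = (observed - expected)/expected with expected = cell total x the
    all-cell fraction of counts in the motif's peaks; z scores raw against
    ``n_bg`` GC/accessibility-matched background peak resamplings.
    """
    X = np.asarray(peak_counts.values.todense(), dtype=float)
    M = hits.to_numpy(dtype=float)
    if M.shape[1] != X.shape[0]:
        raise ValueError("hit matrix and peak counts are misaligned")
    cell_tot = X.sum(axis=0)
    peak_tot = X.sum(axis=1)
    grand = peak_tot.sum()

    def deviations(Mmat, Xrows):
        obs = Mmat @ Xrows
        frac = (Mmat @ Xrows.sum(axis=1)) / grand
        E = frac[:, None] * cell_tot[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            return (obs - E) / E

    raw = deviations(M, X)
    empty = ~(M.sum(axis=1) > 0) | np.isnan(raw).all(axis=1)
    if empty.any():
        warnings.warn(
            f"motifs hitting zero peaks, deviations undefined: "
            f"{[hits.index[i] for i in np.flatnonzero(empty)]}"
        )

    rng = np.random.default_rng(seed)
    bins = _gc_accessibility_bins(np.asarray(peak_gc), X.mean(axis=1))
    bin_members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    n_peaks = X.shape[0]
    bg_devs = np.empty((n_bg,) + raw.shape)
    for t in range(n_bg):
        repl = np.empty(n_peaks, dtype=np.int64)
        for b, members in bin_members.items():
            sel = bins == b
            repl[sel] = rng.choice(members, size=int(sel.sum()), replace=True)
        bg_devs[t] = deviations(M, X[repl])
    mu = bg_devs.mean(axis=0)
    sd = bg_devs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (raw - mu) / sd
    return DeviationResult(
        raw=raw, z=z, motif_names=list(hits.index), barcodes=peak_counts.barcodes,
        n_background=n_bg,
    )


def enrich_motifs(
    fg_peaks: list[str] | np.ndarray,
    all_peaks: list[str] | np.ndarray,
    hits: pd.DataFrame,
    peak_gc: np.ndarray,
    n_bg_sample: int = 40000,
    seed: int = 0,
) -> pd.DataFrame:
    """Hypergeometric motif enrichment of a foreground peak set against a
    GC-binned background sample of the remaining peaks (BH-corrected)."""
    all_peaks = list(all_peaks)
    pos = {p: i for i, p in enumerate(all_peaks)}
    fg = [p for p in fg_peaks]
    if not fg:
        raise ValueError("empty foreground peak set")
    unknown = [p for p in fg if p not in pos]
    if unknown:
        raise ValueError(f"foreground peaks not in peak universe: {unknown[:5]}")
    fg_idx = np.array([pos[p] for p in fg])
    non_fg = np.setdiff1d(np.arange(len(all_peaks)), fg_idx)
    rng = np.random.default_rng(seed)
    gc = np.asarray(peak_gc)
    if len(non_fg) == 0:
        bg_idx = np.arange(len(all_peaks))
    elif len(non_fg) <= n_bg_sample:
        bg_idx = non_fg
    else:
        # GC-binned sample matching the foreground GC distribution
        bins = np.minimum((sps.rankdata(gc, method="average") / (len(gc) + 1) * 10).astype(int), 9)
        per_fg = max(1, n_bg_sample // len(fg_idx))
        chosen = []
        for b in np.unique(bins[fg_idx]):
            pool = non_fg[bins[non_fg] == b]
            want = per_fg * int((bins[fg_idx] == b).sum())
            if len(pool):
                chosen.append(rng.choice(pool, size=min(want, len(pool)), replace=False))
        bg_idx = np.unique(np.concatenate(chosen)) if chosen else non_fg

    H = hits.to_numpy(dtype=bool)
    n_fg, n_bg = len(fg_idx), len(bg_idx)
    rows = []
    for mi, name in enumerate(hits.index):
        fg_with = int(H[mi, fg_idx].sum())
        bg_with = int(H[mi, bg_idx].sum())
        N = n_fg + n_bg
        K = fg_with + bg_with
        p = float(sps.hypergeom.sf(fg_with - 1, N, K, n_fg))
        fg_rate = fg_with / n_fg
        bg_rate = bg_with / n_bg if n_bg else np.nan
        fold = fg_rate / bg_rate if bg_rate else (np.inf if fg_rate > 0 else 1.0)
        rows.append((name, fg_with, n_fg, bg_with, n_bg, fold, p))
    out = pd.DataFrame(
        rows,
        columns=["motif", "n_fg_with", "n_fg", "n_bg_with", "n_bg", "fold_enrichment", "p_value"],
    )
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "motif"], kind="stable").reset_index(drop=True)


def crossref_expression(
    enrichments: pd.DataFrame,
    norm_rna: NormalizedMatrix,
    motif_to_gene: dict[str, str],
    group_mask: np.ndarray | None = None,
    detect_floor: float = 0.1,
    enriched_p_adj: float = 0.05,
) -> pd.DataFrame:
    """Join motif-level statistics with the detection fraction and mean
    normalized expression of the corresponding TF gene; a motif is concordant
    when it is enriched and its TF is detected above the floor."""
    X = norm_rna.values
    if group_mask is not None:
        X = X[:, np.asarray(group_mask, dtype=bool)]
    fidx = {f: i for i, f in enumerate(norm_rna.feature_ids)}
    rows = []
    for _, rec in enrichments.iterrows():
        motif = rec["motif"]
        gene = motif_to_gene.get(motif, motif if motif in fidx else None)
        mapped = gene is not None
        if mapped and gene in fidx:
            row = X[fidx[gene]]
            pct = float((row > 0).mean())
            mean_expr = float(row.mean())
            in_data = True
        else:
            pct, mean_expr, in_data = 0.0, 0.0, False
        enriched = bool(rec.get("p_adj", 1.0) < enriched_p_adj)
        rows.append(
            (
                motif, rec.get("p_adj", np.nan), rec.get("fold_enrichment", np.nan),
                gene if mapped else "", in_data, pct, mean_expr,
                enriched and pct >= detect_floor,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "motif", "p_adj", "fold_enrichment", "tf_gene", "gene_in_data",
            "pct_detected", "mean_expression", "concordant",
        ],
    )
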