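"""Fate-map differential gene ranking and preranked gene-set enrichment.

The enrichment score is the maximum deviation of the weighted
Kolmogorov-Smirnov running sum (hit increments proportional to
|metric|^weight, miss decrements uniform); significance comes from seeded
gene-label permutations, with NES normalized by the mean |ES| of same-sign
permutations and BH correction across reported sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as fio
from ._stats import bh_adjust
from .embed import NormalizedMatrix
from .markers import find_markers
from .qc import RAG_EXP, RAG_NAIVE


def rank_fatemap_degs(
    norm: NormalizedMatrix,
    fatemap_labels: np.ndarray,
    cluster_mask: np.ndarray | None = None,
    min_pct: float = 0.1,
    logfc_min: float = 0.1,
) -> pd.DataFrame:
    """Ranked differential genes between fate-map states (within a cluster
    mask): metric = natural-log fold change, positive = higher in RAG_EXP.
    Sorted descending by metric; ties broken by smaller p then gene name."""
    labels = np.asarray(fatemap_labels)
    if cluster_mask is None:
        cluster_mask = np.ones(len(labels), dtype=bool)
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    sub_labels = labels[cluster_mask]
    for lab in (RAG_EXP, RAG_NAIVE):
        if not (sub_labels == lab).any():
            raise ValueError(f"label {lab} absent within the cluster mask")
    sub = NormalizedMatrix(
        norm.values[:, cluster_mask], norm.feature_ids,
        np.asarray(norm.barcodes)[cluster_mask], norm.method,
    )
    recs = find_markers(sub, sub_labels, RAG_EXP, min_pct=min_pct, logfc_min=logfc_min)
    if not len(recs):
        return pd.DataFrame(columns=["gene", "metric", "p_value"])
    out = recs.rename(columns={"feature": "gene", "log_fc": "metric"})[
        ["gene", "metric", "p_value"]
    ]
    out = out.sort_values(
        ["metric", "p_value", "gene"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return out


def enrichment_score(metrics: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0):
    """Weighted KS enrichment score of one gene set on a descending-sorted
    metric vector.  Returns (ES, running sum, index of the extremum)."""
    metrics = np.asarray(metrics, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = len(metrics)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a proper subset of the ranked list")
    w = np.abs(metrics) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit metrics are zero: fall back to unweighted steps
        hit_w = hit_mask.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit_mask) / (n - n_hit)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    i_ext = i_max if running[i_max] >= -running[i_min] else i_min
    return float(es), running, i_ext


@dataclass
class GseaResult:
    table: pd.DataFrame  # set, size, es, nes, p_value, p_adj, leading_edge
    significant: pd.DataFrame  # filtered at p_adj < cutoff


def gsea_preranked(
    ranked: pd.DataFrame,
    sets: dict[str, list[str]],
    min_size: int = 50,
    max_size: int = 500,
    n_perm: int = 1000,
    weight: float = 1.0,
    p_cutoff: float = 0.05,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA with gene-label permutation significance.

    ``ranked`` must have columns gene, metric, sorted descending by metric.
    p = (1 + #{same-sign perm, |ES_perm| >= |ES|}) / (1 + #{same-sign perm}),
    the usual sign-conditional convention (keeping null p-values uniform);
    NES = ES / mean(|ES_perm| of same sign).
    """
    if not len(ranked):
        raise ValueError("ranked list is empty")
    genes = ranked["gene"].to_numpy()
    metrics = ranked["metric"].to_numpy(dtype=float)
    gpos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets.items():
        idx = sorted({gpos[g] for g in members if g in gpos})
        size = len(idx)
        if size < min_size or size > max_size or size == n:
            fio.log.info("gene set %s size %d outside [%d, %d]; skipped",
                         name, size, min_size, max_size)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, running, i_ext = enrichment_score(metrics, mask, weight)
        # leading edge: hits at or before (after) the extremum for positive
        # (negative) ES
        if es >= 0:
            le = [genes[i] for i in idx if i <= i_ext]
        else:
            le = [genes[i] for i in idx if i >= i_ext]
        perm_es = np.empty(n_perm)
        for t in range(n_perm):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=size, replace=False)] = True
            perm_es[t] = enrichment_score(metrics, pmask, weight)[0]
        same_sign = perm_es * np.sign(es) >= 0 if es != 0 else np.ones(n_perm, bool)
        n_extreme = int((same_sign & (np.abs(perm_es) >= abs(es))).sum())
        p = (1 + n_extreme) / (1 + int(same_sign.sum()))
        denom = np.abs(perm_es[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        rows.append((name, size, es, nes, p, le))
    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p_value", "leading_edge"])
    if len(table):
        table["p_adj"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(["p_value", "set"], kind="stable").reset_index(drop=True)
    else:
        table["p_adj"] = []
    sig = table[table["p_adj"] < p_cutoff].reset_index(drop=True) if len(table) else table
    return GseaResult(table=table, significant=sig)
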