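"""Per-cluster differential tests for the three assays (gene expression,
gene activity, differential accessibility), nearest-gene assignment for
peaks, and the three-way top-marker multiomic signature.

GEX/GA markers use a one-vs-rest Wilcoxon rank-sum on normalized values with
detection and fold-change gates; DA peaks use a likelihood-ratio test between
logistic regressions of cluster membership on {peak value, latent depth} vs
{latent depth} alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as fio
from ._stats import bonferroni_adjust, logistic_lr_test, ranksum_matrix
from .embed import NormalizedMatrix

MARKER_COLUMNS = ["feature", "cluster", "log_fc", "pct_in", "pct_out", "p_value", "p_adj"]


def _log_fold_change(vals_in: np.ndarray, vals_out: np.ndarray) -> np.ndarray:
    """Natural-log fold change of mean back-transformed expression,
    ln((mean(expm1 x_in)+1) / (mean(expm1 x_out)+1)), rowwise."""
    m_in = np.expm1(vals_in).mean(axis=1)
    m_out = np.expm1(vals_out).mean(axis=1)
    return np.log((m_in + 1.0) / (m_out + 1.0))


def find_markers(
    norm: NormalizedMatrix,
    clusters: np.ndarray,
    target,
    min_pct: float = 0.20,
    logfc_min: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers for ``target`` cluster.

    A feature is tested only when max(pct_in, pct_out) >= min_pct and
    |log_fc| >= logfc_min; p-values are Bonferroni-adjusted over the tested
    features.  Records are sorted by p then descending |log_fc|.
    """
    clusters = np.asarray(clusters)
    in_mask = clusters == target
    if not in_mask.any():
        raise ValueError(f"unknown cluster id {target!r}")
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError("need >= 2 cells in target and in rest")
    X = norm.values
    pct_in = (X[:, in_mask] > 0).mean(axis=1)
    pct_out = (X[:, ~in_mask] > 0).mean(axis=1)
    log_fc = _log_fold_change(X[:, in_mask], X[:, ~in_mask])
    tested = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(log_fc) >= logfc_min)
    idx = np.flatnonzero(tested)
    if len(idx) == 0:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    p = ranksum_matrix(X[idx], in_mask)
    out = pd.DataFrame(
        {
            "feature": np.asarray(norm.feature_ids)[idx],
            "cluster": target,
            "log_fc": log_fc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p_value": p,
            "p_adj": bonferroni_adjust(p, m=len(idx)),
        }
    )
    out = out.sort_values(
        ["p_value", "log_fc"], key=lambda s: s if s.name == "p_value" else -s.abs(),
        kind="stable",
    ).reset_index(drop=True)
    return out


def find_all_markers(norm: NormalizedMatrix, clusters: np.ndarray, **kw) -> pd.DataFrame:
    frames = [find_markers(norm, clusters, c, **kw) for c in np.unique(clusters)]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def find_da_peaks(
    peak_norm: NormalizedMatrix,
    clusters: np.ndarray,
    target,
    latent: np.ndarray | None = None,
    min_pct: float = 0.02,
) -> pd.DataFrame:
    """Differentially accessible peaks for ``target`` cluster by logistic-
    regression likelihood-ratio test with the latent depth covariate."""
    clusters = np.asarray(clusters)
    in_mask = clusters == target
    if not in_mask.any():
        raise ValueError(f"unknown cluster id {target!r}")
    X = peak_norm.values
    y = in_mask.astype(float)
    pct_in = (X[:, in_mask] > 0).mean(axis=1)
    pct_out = (X[:, ~in_mask] > 0).mean(axis=1)
    log_fc = _log_fold_change(X[:, in_mask], X[:, ~in_mask])
    tested = np.maximum(pct_in, pct_out) >= min_pct
    idx = np.flatnonzero(tested)
    stats = np.empty(len(idx))
    pvals = np.empty(len(idx))
    for k, i in enumerate(idx):
        stats[k], pvals[k] = logistic_lr_test(X[i], y, latent)
    out = pd.DataFrame(
        {
            "peak": np.asarray(peak_norm.feature_ids)[idx],
            "cluster": target,
            "log_fc": log_fc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "lr_stat": stats,
            "p_value": pvals,
            "p_adj": bonferroni_adjust(pvals, m=len(idx)),
        }
    )
    return out.sort_values(["p_value", "log_fc"], key=lambda s: s if s.name == "p_value" else -s.abs(),
                           kind="stable").reset_index(drop=True)


def assign_nearest_gene(
    peaks: pd.DataFrame, gene_model: pd.DataFrame, max_dist: int = 100_000
) -> pd.DataFrame:
    """Nearest gene per peak: distance 0 on gene-body overlap, else the bp gap
    to the closest gene boundary; ties resolved by smaller gene start then
    lexicographic name.  Peaks farther than ``max_dist`` (or on chromosomes
    without genes) are dropped."""
    genes = fio.validate_gene_model(gene_model)
    rows = []
    no_gene_chroms = set()
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in genes.groupby("chrom")}
    for chrom, ps, pe, name in zip(peaks["chrom"], peaks["start"], peaks["end"], peaks["name"]):
        sub = by_chrom.get(chrom)
        if sub is None or len(sub) == 0:
            no_gene_chroms.add(chrom)
            continue
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        # gap convention: 0 on overlap, else bp between the closest boundaries
        dist = np.where(
            (gs < pe) & (ge > ps), 0, np.maximum(np.where(ge <= ps, ps - ge, gs - pe), 0)
        )
        best = np.min(dist)
        if best > max_dist:
            continue
        cand = np.flatnonzero(dist == best)
        order = sorted(cand, key=lambda i: (gs[i], sub["gene"].iloc[i]))
        g = order[0]
        rows.append((name, sub["gene"].iloc[g], int(best)))
    if no_gene_chroms:
        warnings.warn(f"peaks on chromosomes without genes dropped: {sorted(no_gene_chroms)}")
    return pd.DataFrame(rows, columns=["peak", "nearest_gene", "distance"])


@dataclass
class SignatureSet:
    """Top-marker overlap across the three assays."""

    gex_top: list
    ga_top: list
    da_top: list
    union: list
    overlap_counts: dict  # 7 Venn regions keyed e.g. 'gex&ga'

    def to_json_dict(self) -> dict:
        return {
            "gex_top": self.gex_top,
            "ga_top": self.ga_top,
            "da_top": self.da_top,
            "union": self.union,
            "overlap_counts": self.overlap_counts,
        }


def _top_features(markers: pd.DataFrame, top_n: int, positive_only: bool = True) -> list:
    sub = markers
    if positive_only and len(sub):
        sub = sub[sub["log_fc"] > 0]
    feats = list(dict.fromkeys(sub["feature"]))
    if len(feats) < top_n:
        fio.log.warning("marker list shorter than top_n (%d < %d); using full list",
                        len(feats), top_n)
    return feats[:top_n]


def build_signature(
    gex_markers: pd.DataFrame,
    ga_markers: pd.DataFrame,
    da_records: pd.DataFrame,
    top_n: int = 100,
) -> SignatureSet:
    """Top-``top_n`` features per assay and their 7-region Venn decomposition.

    DA records must carry ``nearest_gene``; the DA list is deduplicated to
    genes (best-p order preserved) before truncation.
    """
    gex = _top_features(gex_markers, top_n)
    ga = _top_features(ga_markers, top_n)
    da_genes = list(dict.fromkeys(da_records["nearest_gene"]))
    if len(da_genes) < top_n:
        fio.log.warning("DA gene list shorter than top_n (%d < %d)", len(da_genes), top_n)
    da = da_genes[:top_n]
    s_gex, s_ga, s_da = set(gex), set(ga), set(da)
    union = sorted(s_gex | s_ga | s_da)
    counts = {
        "gex_only": len(s_gex - s_ga - s_da),
        "ga_only": len(s_ga - s_gex - s_da),
        "da_only": len(s_da - s_gex - s_ga),
        "gex&ga": len((s_gex & s_ga) - s_da),
        "gex&da": len((s_gex & s_da) - s_ga),
        "ga&da": len((s_ga & s_da) - s_gex),
        "gex&ga&da": len(s_gex & s_ga & s_da),
    }
    return SignatureSet(gex, ga, da, union, counts)
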