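"""Gene-peak links (GPLs) with a matched-background null, per-condition
regulome counts, peak deduplication, exclusive four-set intersections, and
disease-induced-peak gene ranking.

A candidate pair is any (gene, peak) with the peak center within a window
(default 1 Mb) of the gene TSS, both detected in at least ``min_cells``
cells.  The link score is the Pearson correlation between the normalized
peak and gene vectors across cells; its null is the score distribution over
background peaks matched to the candidate peak on GC content, total
accessibility and width, giving a z-score and two-sided normal p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.neighbors import NearestNeighbors

from . import io as fio
from .dataset import DISEASE_AD, DISEASE_SS, FATE_EXP, FATE_NAIVE, PairedMultiomeDataset
from .embed import NormalizedMatrix, normalize_rna, run_tfidf

TH2_LOCUS = ["Il4", "Il13", "Rad50", "Il5"]

LINK_COLUMNS = ["gene", "peak", "score", "z", "p_value", "condition"]

FOUR_CONDITIONS = [
    f"{FATE_NAIVE}:{DISEASE_SS}",
    f"{FATE_NAIVE}:{DISEASE_AD}",
    f"{FATE_EXP}:{DISEASE_SS}",
    f"{FATE_EXP}:{DISEASE_AD}",
]
INDUCED_REQUIRED = [FOUR_CONDITIONS[0], FOUR_CONDITIONS[1], FOUR_CONDITIONS[3]]
INDUCED_EXCLUDED = FOUR_CONDITIONS[2]


def gc_content(sequences: list[str]) -> np.ndarray:
    out = np.empty(len(sequences))
    for i, s in enumerate(sequences):
        su = s.upper()
        acgt = sum(su.count(b) for b in "ACGT")
        out[i] = (su.count("G") + su.count("C")) / max(acgt, 1)
    return out


@dataclass
class LinkData:
    """Normalized matrices plus peak metadata, ready for link calling.

    Normalization is computed once on the full cell set; per-condition runs
    subset the columns, keeping values comparable across conditions.
    """

    rna: fio.CountMatrix
    atac: fio.CountMatrix
    norm_rna: np.ndarray
    norm_atac: np.ndarray
    genes: pd.DataFrame
    peaks: pd.DataFrame
    peak_gc: np.ndarray

    @classmethod
    def from_dataset(cls, ds: PairedMultiomeDataset) -> "LinkData":
        if ds.peak_sequences is None:
            gc = np.full(len(ds.peaks), 0.5)
        else:
            gc = gc_content(ds.peak_sequences)
        return cls(
            rna=ds.rna,
            atac=ds.atac,
            norm_rna=normalize_rna(ds.rna).values,
            norm_atac=run_tfidf(ds.atac).values,
            genes=fio.validate_gene_model(ds.genes),
            peaks=ds.peaks.reset_index(drop=True),
            peak_gc=gc,
        )


def background_peak_indices(
    data: LinkData, n_background: int = 200, seed: int = 0
) -> np.ndarray:
    """For every peak, ``n_background`` background peaks matched on
    (GC, log total accessibility, log width) by nearest-neighbor search in
    standardized 3-feature space; sampled (seeded) from the 2x nearest pool."""
    n_peaks = len(data.peaks)
    width = (data.peaks["end"] - data.peaks["start"]).to_numpy(dtype=float)
    total = np.asarray(data.atac.values.sum(axis=1)).ravel().astype(float)
    feats = np.column_stack([data.peak_gc, np.log1p(total), np.log(width)])
    feats = (feats - feats.mean(axis=0)) / np.maximum(feats.std(axis=0), 1e-12)
    rng = np.random.default_rng(seed)
    if n_peaks <= n_background:
        warnings.warn("fewer peaks than n_background; sampling with replacement")
        out = np.empty((n_peaks, n_background), dtype=np.int64)
        for i in range(n_peaks):
            pool = np.delete(np.arange(n_peaks), i)
            out[i] = rng.choice(pool, size=n_background, replace=True) if len(pool) else i
        return out
    pool_size = min(2 * n_background + 1, n_peaks)
    nn = NearestNeighbors(n_neighbors=pool_size).fit(feats)
    _, idx = nn.kneighbors(feats)
    out = np.empty((n_peaks, n_background), dtype=np.int64)
    for i in range(n_peaks):
        pool = idx[i][idx[i] != i]
        out[i] = rng.choice(pool, size=n_background, replace=len(pool) < n_background)
    return out


def candidate_pairs(
    genes: pd.DataFrame, peaks: pd.DataFrame, window: int = 1_000_000,
    gene_subset=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (gene_idx, peak_idx) of all pairs with the peak center
    within ``window`` bp of the gene TSS."""
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    gsel = np.arange(len(genes))
    if gene_subset is not None:
        wanted = set(gene_subset)
        gsel = np.flatnonzero(genes["gene"].isin(wanted).to_numpy())
    gi_out, pi_out = [], []
    for chrom in genes["chrom"].unique():
        p_idx = np.flatnonzero((peaks["chrom"] == chrom).to_numpy())
        if len(p_idx) == 0:
            continue
        order = np.argsort(centers[p_idx], kind="stable")
        p_idx = p_idx[order]
        cen = centers[p_idx]
        for g in gsel[(genes["chrom"].to_numpy()[gsel] == chrom)]:
            tss = genes["tss"].iat[g]
            lo = np.searchsorted(cen, tss - window, side="left")
            hi = np.searchsorted(cen, tss + window, side="right")
            if hi > lo:
                gi_out.append(np.full(hi - lo, g))
                pi_out.append(p_idx[lo:hi])
    if not gi_out:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(gi_out), np.concatenate(pi_out)


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    ok = sd > 0
    Z = (X - mu) / np.maximum(sd, 1e-300)[:, None]
    Z[~ok] = 0.0
    return Z, ok


def compute_links(
    data: LinkData,
    cells: np.ndarray | None = None,
    gene_subset=None,
    window: int = 1_000_000,
    min_cells: int = 2,
    n_background: int = 200,
    p_cutoff: float = 0.05,
    score_cutoff: float = 0.05,
    seed: int = 0,
    bg_indices: np.ndarray | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Call gene-peak links on the selected cells.

    Returns the retained links (p < p_cutoff and |score| >= score_cutoff) as
    a DataFrame with score, background z and two-sided normal p.
    """
    if cells is None:
        cells = np.ones(len(data.rna.barcodes), dtype=bool)
    cells = np.asarray(cells, dtype=bool)
    n = int(cells.sum())
    if n < max(min_cells, 3):
        raise ValueError(f"condition {condition!r}: only {n} cells")
    if bg_indices is None:
        bg_indices = background_peak_indices(data, n_background, seed)

    gidx, pidx = candidate_pairs(data.genes, data.peaks, window, gene_subset)
    if len(gidx) == 0:
        return pd.DataFrame(columns=LINK_COLUMNS)

    raw_g = (data.rna.values[:, np.flatnonzero(cells)] > 0).sum(axis=1)
    raw_p = (data.atac.values[:, np.flatnonzero(cells)] > 0).sum(axis=1)
    det_g = np.asarray(raw_g).ravel() >= min_cells
    det_p = np.asarray(raw_p).ravel() >= min_cells

    G, ok_g = _standardize_rows(data.norm_rna[:, cells])
    P, ok_p = _standardize_rows(data.norm_atac[:, cells])
    keep = det_g[gidx] & det_p[pidx] & ok_g[gidx] & ok_p[pidx]
    gidx, pidx = gidx[keep], pidx[keep]
    if len(gidx) == 0:
        return pd.DataFrame(columns=LINK_COLUMNS)

    R = (G @ P.T) / n  # genes x peaks correlation matrix
    r = R[gidx, pidx]
    bg = bg_indices[pidx]  # (n_cand, n_bg)
    r_bg = R[gidx[:, None], bg]
    mu_bg = r_bg.mean(axis=1)
    sd_bg = r_bg.std(axis=1, ddof=1)
    sd_bg = np.maximum(sd_bg, 1e-12)
    z = (r - mu_bg) / sd_bg
    p = 2.0 * sps.norm.sf(np.abs(z))
    retained = (p < p_cutoff) & (np.abs(r) >= score_cutoff)
    out = pd.DataFrame(
        {
            "gene": data.genes["gene"].to_numpy()[gidx[retained]],
            "peak": data.peaks["name"].to_numpy()[pidx[retained]],
            "score": r[retained],
            "z": z[retained],
            "p_value": p[retained],
            "condition": condition,
        }
    )
    fio.log.info(
        "links%s: %d candidates, %d retained (n=%d cells)",
        f" [{condition}]" if condition else "", len(gidx), len(out), n,
    )
    return out.sort_values(["p_value", "gene", "peak"], kind="stable").reset_index(drop=True)


def permutation_null_retention(
    data: LinkData,
    n_perm: int = 200,
    seed: int = 0,
    **link_kw,
) -> np.ndarray:
    """Fraction of candidate pairs retained per permutation of gene
    expression across cells (a calibration check of the link null)."""
    rng = np.random.default_rng(seed)
    n_cells = len(data.rna.barcodes)
    bg = background_peak_indices(data, link_kw.get("n_background", 200), seed)
    gidx, pidx = candidate_pairs(data.genes, data.peaks, link_kw.get("window", 1_000_000))
    n_cand = max(len(gidx), 1)
    out = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n_cells)
        permuted = LinkData(
            rna=fio.CountMatrix(
                data.rna.values[:, perm], data.rna.feature_ids, data.rna.barcodes,
                data.rna.modality,
            ),
            atac=data.atac,
            norm_rna=data.norm_rna[:, perm],
            norm_atac=data.norm_atac,
            genes=data.genes,
            peaks=data.peaks,
            peak_gc=data.peak_gc,
        )
        links = compute_links(permuted, seed=seed, bg_indices=bg, **link_kw)
        out[t] = len(links) / n_cand
    return out


def links_by_condition(
    data: LinkData,
    labels: pd.Series | np.ndarray,
    gene_subset=None,
    min_condition_cells: int = 30,
    seed: int = 0,
    **link_kw,
) -> dict[str, pd.DataFrame]:
    """Run :func:`compute_links` independently per condition label.

    The background sampling seed is shared across conditions so their nulls
    are comparable.
    """
    labels = np.asarray(labels)
    bg = background_peak_indices(data, link_kw.get("n_background", 200), seed)
    out = {}
    for cond in pd.unique(labels):
        mask = labels == cond
        if mask.sum() == 0:
            raise ValueError(f"condition {cond!r} has no cells")
        if mask.sum() < min_condition_cells:
            raise ValueError(
                f"condition {cond!r} has {int(mask.sum())} cells "
                f"(< floor {min_condition_cells})"
            )
        out[str(cond)] = compute_links(
            data, cells=mask, gene_subset=gene_subset, seed=seed, bg_indices=bg,
            condition=str(cond), **link_kw,
        )
    return out


def regulome_counts(
    links_naive: pd.DataFrame, links_exp: pd.DataFrame, gene_set=None
) -> pd.DataFrame:
    """Per-gene GPL counts in each fate-map population and their difference,
    sorted by delta descending (ties by gene name)."""
    genes = set(links_naive["gene"]) | set(links_exp["gene"])
    if gene_set is not None:
        genes = set(gene_set)
    n_naive = links_naive[links_naive["gene"].isin(genes)].groupby("gene").size()
    n_exp = links_exp[links_exp["gene"].isin(genes)].groupby("gene").size()
    rows = []
    for g in sorted(genes):
        a = int(n_naive.get(g, 0))
        b = int(n_exp.get(g, 0))
        rows.append((g, a, b, a - b))
    out = pd.DataFrame(rows, columns=["gene", "n_links_naive", "n_links_exp", "delta"])
    return out.sort_values(["delta", "gene"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def dedup_peaks(links: pd.DataFrame) -> list[str]:
    """Unique peaks of a link table (a peak linked to several genes counts once)."""
    return sorted(set(links["peak"])) if len(links) else []


def exclusive_intersections(sets: dict[str, set]) -> pd.DataFrame:
    """UpSet-style exclusive intersections: every element is assigned to the
    exact combination of sets containing it; sizes over all 2^k - 1 nonempty
    combinations sum to |union|."""
    names = list(sets)
    sets = {k: set(v) for k, v in sets.items()}
    union = sorted(set().union(*sets.values())) if sets else []
    member_of: dict[tuple, list] = {}
    for el in union:
        combo = tuple(k for k in names if el in sets[k])
        member_of.setdefault(combo, []).append(el)
    rows = []
    # enumerate all nonempty combinations in a stable order
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            members = member_of.get(combo, [])
            rows.append(("&".join(combo), r, len(members), members))
    return pd.DataFrame(rows, columns=["combination", "degree", "size", "members"])


def peak_set_system(cond_links: dict[str, pd.DataFrame]) -> dict[str, set]:
    """Deduplicated peak sets per condition, the UpSet input."""
    return {cond: set(dedup_peaks(df)) for cond, df in cond_links.items()}


def induced_peaks(system: dict[str, set]) -> set:
    """Peaks shared by both RAG-naive conditions and RAG-experienced disease
    cells but absent from RAG-experienced steady state."""
    missing = [c for c in FOUR_CONDITIONS if c not in system]
    if missing:
        raise ValueError(f"peak set system missing conditions {missing}")
    req = [system[c] for c in INDUCED_REQUIRED]
    return (req[0] & req[1] & req[2]) - system[INDUCED_EXCLUDED]


def induced_peak_genes(
    system: dict[str, set], cond_links: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Rank genes by their number of distinct disease-induced linked peaks."""
    ind = induced_peaks(system)
    gene_peaks: dict[str, set] = {}
    for df in cond_links.values():
        sub = df[df["peak"].isin(ind)]
        for g, p in zip(sub["gene"], sub["peak"]):
            gene_peaks.setdefault(g, set()).add(p)
    rows = [(g, len(ps)) for g, ps in gene_peaks.items()]
    out = pd.DataFrame(rows, columns=["gene", "n_induced_peaks"])
    return out.sort_values(["n_induced_peaks", "gene"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)


@dataclass
class Th2Report:
    regulome: pd.DataFrame  # per-gene naive/exp counts and delta (fate split)
    intersections: pd.DataFrame  # UpSet table over the four-way split
    induced_ranking: pd.DataFrame
    cond_links: dict = field(default_factory=dict)


def th2_locus_report(
    data: LinkData,
    fate_labels,
    condition_labels,
    locus: list[str] | None = None,
    min_condition_cells: int = 30,
    seed: int = 0,
    **link_kw,
) -> Th2Report:
    """Regulome counts, four-way peak intersections and induced-peak ranking
    restricted to the Th2 locus genes; cross-gene links within the locus are
    retained."""
    locus = list(locus) if locus is not None else list(TH2_LOCUS)
    missing = set(locus) - set(data.genes["gene"])
    if missing:
        raise ValueError(f"Th2 locus genes missing from annotation: {sorted(missing)}")
    fate_runs = links_by_condition(
        data, fate_labels, gene_subset=locus, min_condition_cells=min_condition_cells,
        seed=seed, **link_kw,
    )
    reg = regulome_counts(
        fate_runs.get(FATE_NAIVE, pd.DataFrame(columns=LINK_COLUMNS)),
        fate_runs.get(FATE_EXP, pd.DataFrame(columns=LINK_COLUMNS)),
        gene_set=locus,
    )
    cond_runs = links_by_condition(
        data, condition_labels, gene_subset=locus,
        min_condition_cells=min_condition_cells, seed=seed, **link_kw,
    )
    for c in FOUR_CONDITIONS:
        cond_runs.setdefault(c, pd.DataFrame(columns=LINK_COLUMNS))
    system = peak_set_system({c: cond_runs[c] for c in FOUR_CONDITIONS})
    inter = exclusive_intersections(system)
    ranking = induced_peak_genes(system, cond_runs)
    return Th2Report(reg, inter, ranking, cond_runs)
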