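"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open, uniformly: BED and fragment
files are consumed as-is, and the gene-model TSV is declared to use the same
convention.  Count matrices travel as MatrixMarket triplets with one-ID-per-line
feature/barcode sidecars.
"""

from __future__ import annotations

import io as _stdio
import json
import logging
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from Bio import motifs as _bio_motifs

log = logging.getLogger("fmm")

RNA = "RNA"
ATAC_PEAKS = "ATAC_PEAKS"
GENE_ACTIVITY = "GENE_ACTIVITY"
MODALITIES = (RNA, ATAC_PEAKS, GENE_ACTIVITY)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


class FormatError(ValueError):
    """A file violated the dialect contract of its format."""


def setup_logging(level: int = logging.INFO) -> None:
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(level)


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountMatrix:
    """Features x cells non-negative integer counts for one modality."""

    values: sp.csr_matrix
    feature_ids: np.ndarray
    barcodes: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.values = sp.csr_matrix(self.values)
        self.validate()

    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}")
        n_feat, n_cell = self.values.shape
        if n_feat != len(self.feature_ids) or n_cell != len(self.barcodes):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match sidecars "
                f"({len(self.feature_ids)} features, {len(self.barcodes)} barcodes)"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative count entry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def subset_cells(self, mask_or_barcodes) -> "CountMatrix":
        if isinstance(mask_or_barcodes, np.ndarray) and mask_or_barcodes.dtype == bool:
            idx = np.flatnonzero(mask_or_barcodes)
        else:
            pos = {b: i for i, b in enumerate(self.barcodes)}
            idx = np.array([pos[b] for b in mask_or_barcodes], dtype=int)
        return CountMatrix(
            self.values[:, idx], self.feature_ids, self.barcodes[idx], self.modality
        )


def read_count_matrix(matrix_path, features_path, barcodes_path, modality) -> CountMatrix:
    """Read a MatrixMarket triplet file plus its two one-ID-per-line sidecars."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises assorted types on malformed input
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    features = _read_id_lines(features_path)
    barcodes = _read_id_lines(barcodes_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"{matrix_path}: header declares {mat.shape}, sidecars give "
            f"({len(features)}, {len(barcodes)})"
        )
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{matrix_path}: negative entry")
    if not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{matrix_path}: non-integer entry")
    mat.data = np.round(mat.data).astype(np.int64)
    cm = CountMatrix(mat, features, barcodes, modality)
    log.info("read %s matrix %s: %d features x %d cells", modality, matrix_path, *cm.shape)
    return cm


def write_count_matrix(cm: CountMatrix, matrix_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(cm.values), field="integer")
    Path(features_path).write_text("".join(f"{f}\n" for f in cm.feature_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in cm.barcodes))


def _read_id_lines(path) -> list[str]:
    out = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not out:
        raise FormatError(f"{path}: empty sidecar")
    return out


# ---------------------------------------------------------------------------
# fragments


def read_fragments(path) -> pd.DataFrame:
    """Read 5-column BED-like ATAC fragments (chrom, start, end, barcode, count).

    Records are returned in file order; coordinates are 0-based half-open.
    The file may be gzip-compressed (suffix .gz).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=FRAGMENT_COLUMNS,
            dtype={"chrom": str, "barcode": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return validate_fragments(df, source=str(path))


def validate_fragments(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    if list(df.columns) != FRAGMENT_COLUMNS:
        raise FormatError(f"{source}: expected columns {FRAGMENT_COLUMNS}")
    if len(df) == 0:
        return df
    for col in ("start", "end", "count"):
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError(f"{source}: non-integer values in column {col!r}")
    if (df["end"].to_numpy() <= df["start"].to_numpy()).any():
        raise FormatError(f"{source}: fragment with end <= start")
    if (df["count"].to_numpy() < 1).any():
        raise FormatError(f"{source}: fragment with count < 1")
    return df


def write_fragments(df: pd.DataFrame, path) -> None:
    validate_fragments(df).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# intervals (peaks) and gene models


def peak_name(chrom, start, end) -> str:
    return f"{chrom}:{start}-{end}"


def read_bed(path) -> pd.DataFrame:
    """Read a 3+-column BED file of intervals; a 4th column supplies names."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs >= 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["chrom"] = out["chrom"].astype(str)
    for col in ("start", "end"):
        if not np.issubdtype(out[col].to_numpy().dtype, np.integer):
            raise FormatError(f"{path}: non-integer coordinate in column {col!r}")
    if (out["end"].to_numpy() <= out["start"].to_numpy()).any():
        raise FormatError(f"{path}: interval with end <= start")
    if df.shape[1] >= 4:
        out["name"] = df.iloc[:, 3].astype(str)
    else:
        out["name"] = [peak_name(c, s, e) for c, s, e in zip(out.chrom, out.start, out.end)]
    return out


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gene_model(path) -> pd.DataFrame:
    """Read the gene-model TSV (gene, chrom, start, end, strand; 0-based half-open).

    Adds a ``tss`` column: ``start`` on the + strand, ``end - 1`` on the - strand.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    required = ["gene", "chrom", "start", "end", "strand"]
    if list(df.columns[: len(required)]) != required:
        raise FormatError(f"{path}: expected columns {required}")
    return validate_gene_model(df, source=str(path))


def validate_gene_model(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    df = df.copy()
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise FormatError(f"{source}: duplicate gene names {dups}")
    bad = set(df["strand"]) - {"+", "-"}
    if bad:
        raise FormatError(f"{source}: unknown strand symbols {sorted(bad)}")
    if (df["end"].to_numpy() <= df["start"].to_numpy()).any():
        raise FormatError(f"{source}: gene with end <= start")
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def write_gene_model(df: pd.DataFrame, path) -> None:
    df[["gene", "chrom", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# position frequency matrices (JASPAR text) and GMT gene sets

_BASES = "ACGT"


@dataclass
class PFM:
    """A position frequency matrix: 4 (A,C,G,T) x width non-negative counts."""

    id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.ndim != 2:
            raise FormatError(f"motif {self.id}: counts must be 4 x width")
        if self.counts.shape[1] < 1:
            raise FormatError(f"motif {self.id}: empty matrix")
        if (self.counts < 0).any():
            raise FormatError(f"motif {self.id}: negative count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


def read_pfm_set(path) -> list[PFM]:
    """Parse a JASPAR-format text file of position frequency matrices."""
    text = Path(path).read_text()
    _precheck_jaspar(text, source=str(path))
    try:
        parsed = _bio_motifs.parse(_stdio.StringIO(text), "jaspar")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in _BASES], dtype=float)
        out.append(PFM(id=m.matrix_id or m.name, name=m.name, counts=counts))
    return out


def _precheck_jaspar(text: str, source: str) -> None:
    # biopython silently tolerates records with missing base rows; enforce the
    # 4-row A/C/G/T record structure before handing over.
    rows: list[str] = []
    header_seen = False

    def _flush():
        if header_seen and sorted(rows) != list(_BASES):
            raise FormatError(f"{source}: record must have exactly A/C/G/T rows, got {rows}")

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            header_seen = True
            rows = []
        else:
            base = line.split()[0].upper()
            if base not in _BASES:
                raise FormatError(f"{source}: unexpected row label {base!r}")
            rows.append(base)
    _flush()
    if not header_seen:
        raise FormatError(f"{source}: no motif records found")


def write_pfm_set(pfms: list[PFM], path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.id} {p.name}\n")
            for i, b in enumerate(_BASES):
                vals = " ".join(f"{v:.0f}" if v == int(v) else f"{v}" for v in p.counts[i])
                fh.write(f"{b} [ {vals} ]\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: GMT line needs name, description, >=1 gene")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise FormatError(f"{path}: duplicate gene set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All pipeline tunables, with the study defaults.

    QC bounds are strict inequalities applied as a conjunction; dimension and
    gate defaults follow the published workflow settings.
    """

    # QC thresholds
    ns_max: float = 1.5
    tss_min: float = 1.0
    rna_max: int = 15000
    rna_min: int = 1000
    atac_max: int = 75000
    atac_min: int = 100
    mito_max: float = 5.0
    ribo_max: float = 10.0
    # embedding / clustering
    n_pcs: int = 25
    lsi_dims: tuple = tuple(range(2, 26))
    n_neighbors: int = 20
    cluster_resolution: float = 0.1
    # markers
    marker_min_pct: float = 0.20
    marker_logfc: float = 0.25
    da_min_pct: float = 0.02
    nearest_gene_max_dist: int = 100_000
    signature_top_n: int = 100
    # linkage
    link_window: int = 1_000_000
    link_min_cells: int = 2
    link_n_background: int = 200
    link_p_cutoff: float = 0.05
    link_score_cutoff: float = 0.05
    condition_min_cells: int = 30
    # gsea
    gsea_min_size: int = 50
    gsea_max_size: int = 500
    gsea_p_cutoff: float = 0.05
    gsea_n_perm: int = 1000
    deg_min_pct: float = 0.1
    deg_logfc: float = 0.1
    # motifs
    motif_pseudocount: float = 0.8
    motif_threshold_fraction: float = 0.8
    motif_n_background: int = 50
    # fate map
    reporter_gene: str = "tdRFP"
    reporter_min_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.lsi_dims = tuple(int(d) for d in self.lsi_dims)
        self.validate()

    def validate(self) -> None:
        for f in _dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if f.name != "seed" and v <= 0:
                    raise ValueError(f"config field {f.name} must be positive, got {v}")
        if 1 in self.lsi_dims:
            raise ValueError("lsi_dims must exclude component 1 (depth component)")
        for lo, hi in (("rna_min", "rna_max"), ("atac_min", "atac_max")):
            if getattr(self, lo) >= getattr(self, hi):
                raise ValueError(f"{lo} must be < {hi}")


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (or JSON); unknown keys are an error."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f.name for f in _dc_fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    data = {f.name: getattr(cfg, f.name) for f in _dc_fields(cfg)}
    data["lsi_dims"] = list(cfg.lsi_dims)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# small interval helper shared by several stages


def interval_overlap_weights(
    starts: np.ndarray, ends: np.ndarray, q_start: int, q_end: int
) -> np.ndarray:
    """Boolean mask of intervals [starts, ends) overlapping [q_start, q_end)."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    return (starts < q_end) & (ends > q_start)
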