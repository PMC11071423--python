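"""The paired-multiome in-memory container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio

# canonical condition labels
FATE_NAIVE = "naive"
FATE_EXP = "exp"
DISEASE_SS = "SS"
DISEASE_AD = "AD"


@dataclass
class PairedMultiomeDataset:
    """Aligned per-cell RNA counts, ATAC peak counts, fragments and metadata.

    ``rna`` and ``atac`` share the same barcodes in the same order; ``obs``
    carries one row per barcode (cell_type, fate_map, disease).  ``peaks`` and
    ``genes`` are 0-based half-open interval tables; ``peak_sequences`` (one
    string per peak, same order) backs motif scanning.
    """

    rna: fio.CountMatrix
    atac: fio.CountMatrix
    fragments: pd.DataFrame
    peaks: pd.DataFrame
    genes: pd.DataFrame
    obs: pd.DataFrame
    peak_sequences: list[str] | None = None

    def __post_init__(self) -> None:
        if not np.array_equal(self.rna.barcodes, self.atac.barcodes):
            raise ValueError("RNA and ATAC barcodes differ")
        if list(self.obs["barcode"]) != list(self.rna.barcodes):
            raise ValueError("obs rows must match barcode order")
        if self.peak_sequences is not None and len(self.peak_sequences) != len(self.peaks):
            raise ValueError("one sequence per peak required")

    @property
    def n_cells(self) -> int:
        return len(self.rna.barcodes)

    def subset_cells(self, mask: np.ndarray) -> "PairedMultiomeDataset":
        mask = np.asarray(mask, dtype=bool)
        keep = set(np.asarray(self.rna.barcodes)[mask])
        frags = self.fragments[self.fragments["barcode"].isin(keep)].reset_index(drop=True)
        return PairedMultiomeDataset(
            rna=self.rna.subset_cells(mask),
            atac=self.atac.subset_cells(mask),
            fragments=frags,
            peaks=self.peaks,
            genes=self.genes,
            obs=self.obs.loc[mask].reset_index(drop=True),
            peak_sequences=self.peak_sequences,
        )

    def condition_labels(self, split_disease: bool = True) -> pd.Series:
        """Per-cell condition tags, e.g. ``naive:SS`` (or just ``naive``)."""
        if split_disease:
            return self.obs["fate_map"] + ":" + self.obs["disease"]
        return self.obs["fate_map"].copy()


def write_peak_fasta(peaks: pd.DataFrame, sequences: list[str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(peaks["name"], sequences):
            fh.write(f">{name}\n{seq}\n")


def read_peak_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for ln in Path(path).read_text().splitlines():
        if ln.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = ln[1:].split()[0]
            chunks = []
        elif ln.strip():
            chunks.append(ln.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
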