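"""Epigenomic feature acquisition and bin aggregation.

Feature matrices are ``n_tracks x 896`` with 128-bp bins spanning the
central 114,688 bp of a 196,608-bp window centered on the TSS. The default
aggregation averages the central four bins (1-based 447-450) into a
per-gene feature vector.

Backends are pluggable: the built-in ``oracle`` backend personalizes
matrices from the synthetic ground truth; an ``enformer``-style external
predictor can be plugged in through :class:`CallableBackend` by supplying a
function that maps ``{interval, substitutions}`` requests to matrices.
Coordinates are 0-based half-open internally; 1-based only at I/O
boundaries (annotation TSV, VCF).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .simulate import (BIN_WIDTH, CENTRAL_BINS, N_BINS, GenotypePanel,
                       GroundTruth, epigenome_oracle, oracle_feature_vector)

ENFORMER_WINDOW = 196_608
CENTRAL_WINDOW = N_BINS * BIN_WIDTH  # 114,688 bp

__all__ = [
    "GeneAnnotation",
    "extract_window",
    "aggregate_bins",
    "backend_predict",
    "backend_feature_vector",
    "OracleBackend",
    "CallableBackend",
    "read_gene_annotation",
    "write_features_hdf5",
    "read_features_hdf5",
]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    tss: int  # 1-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1, got {self.tss}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return [GeneAnnotation(r.gene_id, r.chromosome, int(r.tss), r.strand)
            for r in df.itertuples(index=False)]


def extract_window(gene: GeneAnnotation, length: int = ENFORMER_WINDOW,
                   contig_lengths: dict[str, int] | None = None,
                   ) -> tuple[str, int, int, bool]:
    """Half-open 0-based interval of ``length`` bp with the TSS at offset
    ``length/2``. Returns (chromosome, start, end, truncated).

    Strand is ignored: windows are centered on the TSS regardless of gene
    orientation.
    """
    if length % 2 != 0:
        raise ValueError("window length must be even")
    if contig_lengths is not None and gene.chromosome not in contig_lengths:
        raise KeyError(f"gene {gene.gene_id} lies on unknown contig {gene.chromosome}")
    t0 = gene.tss - 1
    start = t0 - length // 2
    end = t0 + length // 2
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if contig_lengths is not None:
        clen = contig_lengths[gene.chromosome]
        if end > clen:
            end, truncated = clen, True
    return gene.chromosome, start, end, truncated


def aggregate_bins(matrix: np.ndarray, bins: tuple[int, int] = CENTRAL_BINS,
                   ) -> np.ndarray:
    """Per-track mean over a 1-based inclusive bin range (default 447-450)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != N_BINS:
        raise ValueError(f"expected (n_tracks, {N_BINS}) matrix, got {matrix.shape}")
    lo, hi = bins
    if not (1 <= lo <= hi <= N_BINS):
        raise ValueError(f"bin range {bins} outside 1..{N_BINS} or empty")
    return matrix[:, lo - 1:hi].mean(axis=1)


class EpigenomeBackend(Protocol):
    """Adapter contract: produce a feature matrix for (gene, individual)."""

    def matrix(self, gene_id: str, individual_id: str | None) -> np.ndarray: ...


class OracleBackend:
    """Personalizes matrices from the synthetic ground truth and a panel."""

    name = "oracle"

    def __init__(self, truth: GroundTruth, panel: GenotypePanel):
        self.truth = truth
        self.panel = panel
        self._ind_row = {ind: i for i, ind in enumerate(panel.individuals)}

    def _cis(self, gene_id: str, individual_id: str | None) -> np.ndarray:
        idx = self.panel.cis_indices(gene_id)
        if individual_id is None:
            return np.zeros(idx.size)
        if individual_id not in self._ind_row:
            raise KeyError(f"individual {individual_id} not in panel")
        return self.panel.dosages[self._ind_row[individual_id], idx].astype(float)

    def matrix(self, gene_id: str, individual_id: str | None = None) -> np.ndarray:
        return epigenome_oracle(self._cis(gene_id, individual_id), gene_id, self.truth)

    def feature_vector(self, gene_id: str, individual_id: str | None = None) -> np.ndarray:
        # fast path: identical to aggregate_bins(matrix(...)) by construction
        return oracle_feature_vector(self._cis(gene_id, individual_id), gene_id, self.truth)


class CallableBackend:
    """Wraps an external predictor.

    The callable receives a request dict
    ``{"interval": (chrom, start, end), "substitutions": [(pos, ref, alt,
    dosage), ...]}`` and must return an ``n_tracks x 896`` matrix. If no
    callable is supplied, any use raises an error spelling out the contract.
    """

    name = "external"

    def __init__(self, fn: Callable[[dict], np.ndarray] | None = None,
                 annotation: dict[str, GeneAnnotation] | None = None,
                 substitutions: Callable[[str, str | None], list] | None = None):
        self.fn = fn
        self.annotation = annotation or {}
        self.substitutions = substitutions

    def matrix(self, gene_id: str, individual_id: str | None = None) -> np.ndarray:
        if self.fn is None:
            raise RuntimeError(
                "external epigenome backend unavailable: supply a callable "
                "mapping {'interval': (chrom, start, end), 'substitutions': "
                "[(pos, ref, alt, dosage), ...]} -> (n_tracks, 896) array"
            )
        gene = self.annotation[gene_id]
        chrom, start, end, _ = extract_window(gene)
        subs = self.substitutions(gene_id, individual_id) if self.substitutions else []
        return np.asarray(self.fn({"interval": (chrom, start, end), "substitutions": subs}))


_CACHE: dict[tuple[int, str, str | None], np.ndarray] = {}


def backend_predict(gene_id: str, individual_id: str | None,
                    backend: EpigenomeBackend) -> np.ndarray:
    """Feature matrix for (gene, individual); reference when individual is
    None. Results are cached per (backend, gene, individual)."""
    key = (id(backend), gene_id, individual_id)
    if key not in _CACHE:
        _CACHE[key] = backend.matrix(gene_id, individual_id)
    return _CACHE[key]


def backend_feature_vector(gene_id: str, individual_id: str | None,
                           backend: EpigenomeBackend,
                           bins: tuple[int, int] = CENTRAL_BINS) -> np.ndarray:
    """Aggregated feature vector; uses a backend fast path when available."""
    if bins == CENTRAL_BINS and hasattr(backend, "feature_vector"):
        return backend.feature_vector(gene_id, individual_id)
    return aggregate_bins(backend_predict(gene_id, individual_id, backend), bins)


def clear_cache() -> None:
    _CACHE.clear()


# --------------------------------------------------------------------------
# feature I/O
# --------------------------------------------------------------------------

def _h5_key(gene_id: str, individual_id: str | None) -> str:
    return f"{gene_id}/{individual_id if individual_id is not None else 'ref'}"


def write_features_hdf5(path: str | Path,
                        items: dict[tuple[str, str | None], np.ndarray]) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for (gene_id, individual_id), arr in items.items():
            fh.create_dataset(_h5_key(gene_id, individual_id), data=np.asarray(arr))


def read_features_hdf5(path: str | Path) -> dict[tuple[str, str | None], np.ndarray]:
    import h5py

    out: dict[tuple[str, str | None], np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        for gene_id in fh:
            for ind in fh[gene_id]:
                key = (gene_id, None if ind == "ref" else ind)
                out[key] = fh[gene_id][ind][()]
    return out


def write_features_tsv(path: str | Path,
                       items: dict[tuple[str, str | None], np.ndarray]) -> None:
    """Delimited fallback: one row per (gene, individual) feature vector."""
    rows = {}
    for (gene_id, individual_id), arr in items.items():
        arr = np.asarray(arr)
        if arr.ndim != 1:
            raise ValueError("TSV fallback stores aggregated vectors only")
        rows[_h5_key(gene_id, individual_id)] = arr
    pd.DataFrame.from_dict(rows, orient="index").to_csv(path, sep="\t", header=False)


def read_features_tsv(path: str | Path) -> dict[tuple[str, str | None], np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    out = {}
    for key, row in df.iterrows():
        gene_id, ind = key.rsplit("/", 1)
        out[(gene_id, None if ind == "ref" else ind)] = row.to_numpy(dtype=float)
    return out
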