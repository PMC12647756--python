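"""Read-library resampling to remove count and length-distribution bias.

Two libraries sequenced separately differ in total read number and read
length distribution, which biases any downstream SV-count comparison (more
and longer reads capture more breakpoints). Before comparison both libraries
are therefore subsampled to a per-length-bin minimum: within every length
bin, each library keeps exactly ``min(count_A, count_B)`` reads, drawn
uniformly without replacement. The binned length distributions of the two
resampled libraries are then identical by construction, and total read
counts are equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignments import AlignmentSet

__all__ = [
    "ReadLibrary",
    "LengthHistogram",
    "ResampleReport",
    "length_histogram",
    "default_bin_edges",
    "match_libraries",
    "subset_alignments",
]


@dataclass
class ReadLibrary:
    """A labelled set of (read_id, length) pairs."""

    label: str
    read_ids: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.read_ids = np.asarray(self.read_ids, dtype=object)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if len(self.read_ids) != len(self.lengths):
            raise ValueError("read_ids and lengths must have equal length")

    @property
    def total_reads(self) -> int:
        return len(self.read_ids)

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())

    @classmethod
    def from_alignments(cls, aln: AlignmentSet) -> "ReadLibrary":
        ids, lens = [], []
        for rec in aln.primaries():
            ids.append(rec.read_id)
            lens.append(rec.query_length)
        return cls(aln.label, np.array(ids, dtype=object), np.array(lens))


@dataclass
class LengthHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)


def length_histogram(lib: ReadLibrary, bin_edges) -> LengthHistogram:
    """Bin read lengths into half-open bins [e_i, e_{i+1}); last bin closed.

    Raises if any read is longer than the last edge, instructing the caller
    to extend the edges.
    """
    edges = np.asarray(bin_edges, dtype=np.int64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    if lib.total_reads:
        if lib.lengths.max() > edges[-1]:
            raise ValueError(
                f"library {lib.label!r} has reads up to {lib.lengths.max()} bp, "
                f"beyond the last edge {edges[-1]}; extend bin_edges"
            )
        if lib.lengths.min() < edges[0]:
            raise ValueError(
                f"library {lib.label!r} has reads down to {lib.lengths.min()} bp, "
                f"below the first edge {edges[0]}; extend bin_edges"
            )
    counts, _ = np.histogram(lib.lengths, bins=edges)
    return LengthHistogram(edges, counts)


def default_bin_edges(
    libs: list[ReadLibrary], n_bins: int = 20, anchor: int = 500
) -> np.ndarray:
    """Log-spaced edges from min(anchor, shortest read) to the pooled 99.9th
    percentile, with a final overflow edge at the pooled maximum."""
    pooled = np.concatenate([l.lengths for l in libs if l.total_reads])
    if pooled.size == 0:
        raise ValueError("all libraries are empty")
    lo = min(anchor, int(pooled.min()))
    p999 = max(int(np.percentile(pooled, 99.9)), lo + 1)
    edges = np.unique(
        np.round(np.geomspace(lo, p999, n_bins + 1)).astype(np.int64)
    )
    top = int(pooled.max())
    if top > edges[-1]:
        edges = np.append(edges, top)
    return edges


@dataclass
class ResampleReport:
    """Per-bin retention bookkeeping plus before/after KS distances."""

    table: pd.DataFrame
    ks_before: float
    ks_after: float
    bin_edges: np.ndarray

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    return float(sps.ks_2samp(a, b).statistic)


def match_libraries(
    libA: ReadLibrary,
    libB: ReadLibrary,
    bin_edges=None,
    seed: int = 0,
) -> tuple[ReadLibrary, ReadLibrary, ResampleReport]:
    """Subsample both libraries to the per-bin minimum read count.

    Returns the two resampled libraries (equal totals, identical binned
    length distributions) and a report with per-bin retention fractions and
    the two-sample Kolmogorov–Smirnov distance before and after.
    """
    if libA.total_reads == 0 or libB.total_reads == 0:
        raise ValueError("both libraries must be non-empty")
    if bin_edges is None:
        bin_edges = default_bin_edges([libA, libB])
    edges = np.asarray(bin_edges, dtype=np.int64)
    hA = length_histogram(libA, edges)
    hB = length_histogram(libB, edges)

    rng = np.random.default_rng(seed)
    binA = np.clip(np.searchsorted(edges, libA.lengths, side="right") - 1, 0, len(edges) - 2)
    binB = np.clip(np.searchsorted(edges, libB.lengths, side="right") - 1, 0, len(edges) - 2)

    keepA, keepB, rows = [], [], []
    for b in range(len(edges) - 1):
        ia = np.flatnonzero(binA == b)
        ib = np.flatnonzero(binB == b)
        k = min(len(ia), len(ib))
        if k:
            keepA.append(rng.choice(ia, size=k, replace=False))
            keepB.append(rng.choice(ib, size=k, replace=False))
        rows.append(
            {
                "bin_lo": int(edges[b]),
                "bin_hi": int(edges[b + 1]),
                "count_a": len(ia),
                "count_b": len(ib),
                "retained": k,
                "retention_a": k / len(ia) if len(ia) else np.nan,
                "retention_b": k / len(ib) if len(ib) else np.nan,
            }
        )

    idxA = np.sort(np.concatenate(keepA)) if keepA else np.array([], dtype=int)
    idxB = np.sort(np.concatenate(keepB)) if keepB else np.array([], dtype=int)
    libA2 = ReadLibrary(libA.label, libA.read_ids[idxA], libA.lengths[idxA])
    libB2 = ReadLibrary(libB.label, libB.read_ids[idxB], libB.lengths[idxB])

    report = ResampleReport(
        table=pd.DataFrame(rows),
        ks_before=_ks_distance(libA.lengths, libB.lengths),
        ks_after=_ks_distance(libA2.lengths, libB2.lengths),
        bin_edges=edges,
    )
    return libA2, libB2, report


def subset_alignments(aln: AlignmentSet, lib: ReadLibrary) -> AlignmentSet:
    """Keep only the primary and supplementary records of retained reads."""
    return aln.subset(lib.read_ids)
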