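"""Breakpoint flanking-repeat and junction-microhomology scanning.

Rearrangements produced by homology-driven mechanisms (NAHR, MMEJ) leave
sequence fingerprints: direct or inverted repeats in the breakpoint flanks,
or short identical runs across the junction. This module scans each call's
flanks for the longest shared substring (exact matching only — determinism
and a clean random-sequence null) and walks the junction for microhomology,
then compares the observed repeat-length distribution against a
permuted-breakpoint null on the same genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .caller import SVCall, SVCallSet
from .genome import ReferenceGenome

__all__ = [
    "RepeatScanResult",
    "extract_flanks",
    "longest_shared_repeat",
    "junction_microhomology",
    "scan_callset",
    "permuted_breakpoint_null",
    "compare_to_null",
]

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def extract_flanks(
    ref: ReferenceGenome, call: SVCall, flank_len: int
) -> tuple[str, str, bool]:
    """Reference sequence immediately left of ``start`` and right of ``end``.

    Returns (left, right, truncated); flanks shorter than ``flank_len``
    because of chromosome boundaries set the truncated flag.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    if call.chrom not in ref:
        raise ValueError(f"unknown chromosome {call.chrom!r}")
    seq = ref.sequence(call.chrom)
    left = seq[max(call.start - flank_len, 0) : call.start]
    right = seq[call.end : call.end + flank_len]
    truncated = len(left) < flank_len or len(right) < flank_len
    return left, right, truncated


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def longest_shared_repeat(a: str, b: str, mode: str = "direct") -> tuple[int, str]:
    """Longest common substring of ``a`` and ``b`` (direct) or of ``a`` and
    reverse-complement(``b``) (inverted); ties break to the leftmost
    occurrence in ``a``. Empty inputs give (0, "")."""
    if mode not in ("direct", "inverted"):
        raise ValueError("mode must be 'direct' or 'inverted'")
    bb = revcomp(b) if mode == "inverted" else b
    if not a or not bb:
        return 0, ""
    ea, eb = _encode(a), _encode(bb)
    prev = np.zeros(len(eb), dtype=np.int32)
    best, best_end = 0, 0
    for i, ca in enumerate(ea):
        cur = np.zeros(len(eb), dtype=np.int32)
        match = eb == ca
        cur[match] = 1
        cur[1:][match[1:]] += prev[:-1][match[1:]]
        m = int(cur.max())
        if m > best:  # strict: earliest i wins ties -> leftmost in a
            best = m
            best_end = i + 1
        prev = cur
    return best, a[best_end - best : best_end]


def junction_microhomology(
    ref: ReferenceGenome, call: SVCall, max_len: int = 25
) -> int | None:
    """Microhomology length at a DEL/DUP junction, capped at ``max_len``.

    Counts identical bases reading right from the two breakends (the
    standard deletion-microhomology walk: sequence just inside one breakend
    equals sequence just outside the other). Returns None for call types
    without two same-chromosome breakends (explicit unsupported-type
    result).
    """
    if call.sv_type not in ("DEL", "DUP"):
        return None
    if call.chrom not in ref:
        raise ValueError(f"unknown chromosome {call.chrom!r}")
    seq = ref.sequence(call.chrom)
    n = len(seq)
    k = 0
    while (
        k < max_len
        and call.start + k < n
        and call.end + k < n
        and seq[call.start + k] == seq[call.end + k]
    ):
        k += 1
    return k


@dataclass
class RepeatScanResult:
    """Per-callset repeat scan as a table plus the parameters used."""

    table: pd.DataFrame
    flank_len: int
    max_microhomology: int
    notable_threshold: int

    def notable(self) -> pd.DataFrame:
        t = self.table
        return t[
            (t.longest_direct_repeat >= self.notable_threshold)
            | (t.longest_inverted_repeat >= self.notable_threshold)
        ]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def scan_callset(
    ref: ReferenceGenome,
    cs: SVCallSet,
    flank_len: int = 200,
    max_microhomology: int = 25,
    notable_threshold: int = 10,
) -> RepeatScanResult:
    """Scan every non-BND call's flanks for repeats and microhomology."""
    rows = []
    for c in cs.calls:
        if c.sv_type == "BND":
            continue
        left, right, truncated = extract_flanks(ref, c, flank_len)
        dlen, dseq = longest_shared_repeat(left, right, "direct")
        ilen, iseq = longest_shared_repeat(left, right, "inverted")
        mh = junction_microhomology(ref, c, max_microhomology)
        rows.append(
            {
                "chrom": c.chrom, "start": c.start, "end": c.end,
                "sv_type": c.sv_type, "svlen": c.svlen,
                "flank_truncated": truncated,
                "longest_direct_repeat": dlen,
                "direct_repeat_seq": dseq,
                "longest_inverted_repeat": ilen,
                "inverted_repeat_seq": iseq,
                "microhomology_len": -1 if mh is None else mh,
            }
        )
    return RepeatScanResult(
        pd.DataFrame(rows), flank_len, max_microhomology, notable_threshold
    )


def permuted_breakpoint_null(
    ref: ReferenceGenome,
    cs: SVCallSet,
    seed: int,
    flank_len: int = 200,
    max_microhomology: int = 25,
) -> RepeatScanResult:
    """Re-scan with each call moved to a uniform random breakpoint of the
    same length on the same genome — the 'no specific repeats' null."""
    rng = np.random.default_rng(seed)
    lengths = np.asarray(ref.lengths)
    total = lengths.sum()
    permuted = []
    for c in cs.calls:
        if c.sv_type == "BND":
            continue
        span = min(c.end - c.start, int(lengths.max()) - 1)
        while True:
            g = int(rng.integers(0, total))
            ci = int(np.searchsorted(np.cumsum(lengths), g, side="right"))
            start = g - int(np.concatenate([[0], np.cumsum(lengths)])[ci])
            if start + span < lengths[ci]:
                break
        permuted.append(
            SVCall(
                c.sv_type, ref.names[ci], start, start + span,
                c.svlen, c.support, c.supporting_reads,
            )
        )
    return scan_callset(
        ref, SVCallSet(permuted), flank_len, max_microhomology
    )


def compare_to_null(
    observed: RepeatScanResult, null: RepeatScanResult
) -> dict:
    """KS comparison of observed vs permuted-null repeat length distributions."""
    out = {}
    for col in ("longest_direct_repeat", "longest_inverted_repeat",
                "microhomology_len"):
        a = observed.table[col].to_numpy()
        b = null.table[col].to_numpy()
        a, b = a[a >= 0], b[b >= 0]
        if len(a) == 0 or len(b) == 0:
            out[col] = {"ks_stat": float("nan"), "p_value": float("nan")}
            continue
        res = sps.ks_2samp(a, b, method="asymp")  # heavy ties: exact unstable
        out[col] = {"ks_stat": float(res.statistic), "p_value": float(res.pvalue)}
    return out
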