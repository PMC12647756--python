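"""Signature-based SV calling from long-read alignments.

Two evidence classes are extracted per primary alignment:

* in-CIGAR runs — ``D`` ops become DEL signatures, ``I`` ops become INS
  signatures; adjacent same-type ops separated by short matched stretches
  are merged (summed length), since single indel events are routinely
  fragmented by aligners;
* split pairs — the primary segment plus each SA-linked supplementary is
  classified by geometry: strand flip -> INV, different chromosome -> BND,
  same chromosome/strand re-covering reference -> DUP, skipping reference ->
  DEL.

Signatures of the same type are then single-linkage clustered within
(type, chromosome): two signatures join when their starts differ by at most
``position_window`` bp and their length ratio is at least ``size_ratio_min``.
Each cluster becomes one call whose coordinates are signature medians and
whose support counts distinct reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignments import (
    AlignmentRecord,
    AlignmentSet,
    MalformedAlignmentError,
    cigar_query_length,
    cigar_ref_length,
)

__all__ = [
    "SVSignature",
    "SVCall",
    "SVCallSet",
    "extract_signatures",
    "cluster_signatures",
    "call_svs",
]


@dataclass(frozen=True)
class SVSignature:
    """One read's evidence for one SV."""

    sv_type: str
    chrom: str
    start: int
    length: int
    read_id: str
    evidence: str  # {"cigar", "split"}
    mate_chrom: str | None = None
    mate_pos: int | None = None


@dataclass(frozen=True)
class SVCall:
    """A clustered, typed SV call with per-call read support."""

    sv_type: str
    chrom: str
    start: int
    end: int
    svlen: int
    support: int
    supporting_reads: frozenset[str]
    mate_chrom: str | None = None
    mate_pos: int | None = None

    def __post_init__(self) -> None:
        if self.support != len(self.supporting_reads):
            raise ValueError("support must equal |supporting_reads|")


@dataclass
class SVCallSet:
    """Calls sorted by (chrom, start) plus run provenance."""

    calls: list[SVCall]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = sorted(
            self.calls, key=lambda c: (c.chrom, c.start, c.sv_type, c.svlen)
        )

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def by_type(self) -> dict[str, list[SVCall]]:
        out: dict[str, list[SVCall]] = {}
        for c in self.calls:
            out.setdefault(c.sv_type, []).append(c)
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [c.chrom for c in self.calls],
                "start": [c.start for c in self.calls],
                "end": [c.end for c in self.calls],
                "sv_type": [c.sv_type for c in self.calls],
                "svlen": [c.svlen for c in self.calls],
                "support": [c.support for c in self.calls],
            }
        )


def _cigar_signatures(
    read_id: str,
    chrom: str,
    pos: int,
    cigar,
    min_signature_len: int,
    merge_gap: int,
) -> list[SVSignature]:
    runs: list[tuple[str, int, int]] = []  # (op, ref_start, length)
    r = pos
    for op, n in cigar:
        if op == "D":
            runs.append(("D", r, n))
            r += n
        elif op == "I":
            runs.append(("I", r, n))
        elif op in "M=XN":
            r += n
    # merge same-type runs separated by <= merge_gap matched bases
    merged: list[list] = []
    for op, start, n in runs:
        if merged and merged[-1][0] == op:
            prev_end = merged[-1][1] + (merged[-1][2] if op == "D" else 0)
            if start - prev_end <= merge_gap:
                merged[-1][2] += n
                continue
        merged.append([op, start, n])
    out = []
    for op, start, n in merged:
        if n >= min_signature_len:
            out.append(
                SVSignature(
                    "DEL" if op == "D" else "INS",
                    chrom, start, n, read_id, "cigar",
                )
            )
    return out


def _segment(chrom: str, pos: int, strand: str, cigar) -> tuple:
    cig = list(cigar)
    lead = cig[0][1] if cig[0][0] in "SH" else 0
    trail = cig[-1][1] if cig[-1][0] in "SH" else 0
    total = cigar_query_length(cig) + sum(n for op, n in cig if op == "H")
    qs, qe = (lead, total - trail) if strand == "+" else (trail, total - lead)
    return (chrom, pos, pos + cigar_ref_length(cig), strand, qs, qe, total)


def _split_signatures(
    rec: AlignmentRecord, min_signature_len: int
) -> list[SVSignature]:
    segs = [_segment(rec.chrom, rec.pos, rec.strand, rec.cigar)]
    for link in rec.sa_links:
        segs.append(_segment(link.chrom, link.pos, link.strand, link.cigar))
    totals = {s[6] for s in segs}
    if len(totals) != 1:
        raise MalformedAlignmentError(
            f"inconsistent query lengths across split segments of read "
            f"{rec.read_id}: {sorted(totals)}"
        )
    segs.sort(key=lambda s: s[4])  # order along the read
    out = []
    for a, b in zip(segs, segs[1:]):
        ch1, b1, e1, s1, *_ = a
        ch2, b2, e2, s2, *_ = b
        if ch1 != ch2:
            end1 = (ch1, e1 if s1 == "+" else b1)
            end2 = (ch2, b2 if s2 == "+" else e2)
            lo, hi = sorted([end1, end2])
            out.append(
                SVSignature(
                    "BND", lo[0], lo[1], 0, rec.read_id, "split",
                    mate_chrom=hi[0], mate_pos=hi[1],
                )
            )
        elif s1 != s2:
            # +,- is an inversion's left junction; -,+ its right junction:
            # both delimit the same inverted interval.
            lo, hi = (e1, e2) if s1 == "+" else (b1, b2)
            if hi - lo >= min_signature_len:
                out.append(
                    SVSignature("INV", ch1, lo, hi - lo, rec.read_id, "split")
                )
        else:
            head_end, next_start = (e1, b2) if s1 == "+" else (e2, b1)
            gap = next_start - head_end
            if gap >= min_signature_len:
                out.append(
                    SVSignature(
                        "DEL", ch1, head_end, gap, rec.read_id, "split"
                    )
                )
            elif -gap >= min_signature_len:
                out.append(
                    SVSignature(
                        "DUP", ch1, next_start, -gap, rec.read_id, "split"
                    )
                )
    return out


def extract_signatures(
    rec: AlignmentRecord,
    min_signature_len: int = 30,
    merge_gap: int = 100,
) -> list[SVSignature]:
    """Extract SV signatures from one primary alignment record.

    Supplementary records are reached through ``rec.sa_links``; calling this
    on a supplementary record returns nothing (its evidence is owned by the
    primary, avoiding double counting).
    """
    if rec.is_supplementary:
        return []
    sigs = _cigar_signatures(
        rec.read_id, rec.chrom, rec.pos, rec.cigar,
        min_signature_len, merge_gap,
    )
    for link in rec.sa_links:
        # in-CIGAR evidence carried by supplementary segments (a SAM CIGAR
        # is reference-ordered for either strand, so the same walk applies)
        sigs += _cigar_signatures(
            rec.read_id, link.chrom, link.pos, list(link.cigar),
            min_signature_len, merge_gap,
        )
    if rec.sa_links:
        sigs += _split_signatures(rec, min_signature_len)
    return sigs


def _median_low(values: list[int]) -> int:
    """Median with even-count ties resolved to the lower value."""
    vs = sorted(values)
    return vs[(len(vs) - 1) // 2]


def cluster_signatures(
    signatures: list[SVSignature],
    position_window: int = 500,
    size_ratio_min: float = 0.7,
    provenance: dict | None = None,
) -> SVCallSet:
    """Single-linkage clustering of signatures into calls.

    Signatures of the same type on the same chromosome merge when their
    starts differ by at most ``position_window`` and min/max length ratio is
    at least ``size_ratio_min`` (BND signatures have no length; they merge on
    breakend proximity, requiring mate chromosome equality and mate position
    within the window). Call coordinates are medians over signatures, ties
    to the lower coordinate; support counts distinct read ids.
    """
    if not 0 < size_ratio_min <= 1:
        raise ValueError("size_ratio_min must be in (0, 1]")
    if position_window <= 0:
        raise ValueError("position_window must be > 0")

    groups: dict[tuple, list[SVSignature]] = {}
    for sig in signatures:
        groups.setdefault((sig.sv_type, sig.chrom, sig.mate_chrom), []).append(sig)

    calls: list[SVCall] = []
    for (sv_type, chrom, mate_chrom), sigs in groups.items():
        sigs.sort(key=lambda s: (s.start, s.length, s.read_id))
        n = len(sigs)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if sigs[j].start - sigs[i].start > position_window:
                    break
                if sv_type == "BND":
                    if abs(sigs[j].mate_pos - sigs[i].mate_pos) > position_window:
                        continue
                else:
                    lo = min(sigs[i].length, sigs[j].length)
                    hi = max(sigs[i].length, sigs[j].length)
                    if hi == 0 or lo / hi < size_ratio_min:
                        continue
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

        clusters: dict[int, list[SVSignature]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(sigs[i])

        for members in clusters.values():
            start = _median_low([s.start for s in members])
            reads = frozenset(s.read_id for s in members)
            if sv_type == "BND":
                mate_pos = _median_low([s.mate_pos for s in members])
                calls.append(
                    SVCall(
                        "BND", chrom, start, start, 0,
                        len(reads), reads,
                        mate_chrom=mate_chrom, mate_pos=mate_pos,
                    )
                )
            else:
                svlen = _median_low([s.length for s in members])
                end = start if sv_type == "INS" else start + svlen
                calls.append(
                    SVCall(sv_type, chrom, start, end, svlen, len(reads), reads)
                )

    return SVCallSet(calls, provenance or {})


def call_svs(
    aln: AlignmentSet,
    min_signature_len: int = 30,
    merge_gap: int = 100,
    position_window: int = 500,
    size_ratio_min: float = 0.7,
    min_mapq: int = 0,
) -> SVCallSet:
    """Extract and cluster signatures over a whole alignment set."""
    sigs: list[SVSignature] = []
    for rec in aln.primaries():
        if rec.mapq < min_mapq:
            continue
        sigs.extend(extract_signatures(rec, min_signature_len, merge_gap))
    return cluster_signatures(
        sigs,
        position_window,
        size_ratio_min,
        provenance={
            "library": aln.label,
            "n_primary_reads": len(aln.primaries()),
            "n_signatures": len(sigs),
            "min_signature_len": min_signature_len,
            "merge_gap": merge_gap,
            "position_window": position_window,
            "size_ratio_min": size_ratio_min,
        },
    )
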