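"""Alignment records, CIGAR utilities, and SAM reading/writing.

Internal coordinates are 0-based half-open; SAM is emitted 1-based per the
standard. Split reads are represented as a primary record plus supplementary
records linked through ``sa_links`` (the SA tag on disk). Sequences are
emitted as ``*``: the pipeline's evidence lives entirely in CIGARs and
split-alignment geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

__all__ = [
    "Cigar",
    "AlignmentRecord",
    "AlignmentSet",
    "SALink",
    "cigar_query_length",
    "cigar_ref_length",
    "parse_cigar",
    "format_cigar",
    "MalformedAlignmentError",
]

Cigar = list[tuple[str, int]]

_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MD=XN")
_VALID_OPS = frozenset("MIDNSHP=X")


class MalformedAlignmentError(ValueError):
    """An alignment record (or linked split pair) is internally inconsistent."""


def parse_cigar(text: str) -> Cigar:
    ops: Cigar = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        elif ch in _VALID_OPS:
            if not num:
                raise MalformedAlignmentError(f"bad CIGAR {text!r}")
            ops.append((ch, int(num)))
            num = ""
        else:
            raise MalformedAlignmentError(f"bad CIGAR op {ch!r} in {text!r}")
    if num:
        raise MalformedAlignmentError(f"bad CIGAR {text!r}")
    return ops


def format_cigar(ops: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def cigar_query_length(ops: Cigar) -> int:
    """Query bases consumed, counting soft (not hard) clips."""
    return sum(n for op, n in ops if op in _QUERY_OPS)


def cigar_ref_length(ops: Cigar) -> int:
    return sum(n for op, n in ops if op in _REF_OPS)


def simplify_cigar(ops: Cigar) -> Cigar:
    """Drop zero-length ops and merge adjacent ops of the same kind."""
    out: Cigar = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


@dataclass(frozen=True)
class SALink:
    """One linked split-alignment segment (the SA-tag tuple)."""

    chrom: str
    pos: int  # 0-based
    strand: str
    cigar: tuple[tuple[str, int], ...]

    @property
    def ref_end(self) -> int:
        return self.pos + cigar_ref_length(list(self.cigar))


@dataclass
class AlignmentRecord:
    """One read alignment (primary or supplementary)."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    strand: str
    cigar: Cigar
    is_supplementary: bool = False
    sa_links: list[SALink] = field(default_factory=list)
    mapq: int = 60

    def __post_init__(self) -> None:
        if not self.cigar:
            raise MalformedAlignmentError(f"empty CIGAR for read {self.read_id}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def query_length(self) -> int:
        return cigar_query_length(self.cigar)

    @property
    def ref_end(self) -> int:
        return self.pos + cigar_ref_length(self.cigar)

    def query_interval(self) -> tuple[int, int]:
        """Aligned interval on the original (forward) read, half-open."""
        lead = self.cigar[0][1] if self.cigar[0][0] in "SH" else 0
        trail = self.cigar[-1][1] if self.cigar[-1][0] in "SH" else 0
        total = self.query_length + sum(
            n for op, n in self.cigar if op == "H"
        )
        if self.strand == "+":
            return lead, total - trail
        return trail, total - lead

    def as_sa_link(self) -> SALink:
        return SALink(self.chrom, self.pos, self.strand, tuple(self.cigar))


@dataclass
class AlignmentSet:
    """A library of alignment records against one reference.

    ``records`` holds primaries and supplementaries; ``truth`` optionally
    carries the simulator's record of which (event, read) pairs were encoded.
    """

    chrom_lengths: dict[str, int]
    records: list[AlignmentRecord]
    label: str = "library"
    truth: object | None = None

    def primaries(self) -> list[AlignmentRecord]:
        return [r for r in self.records if not r.is_supplementary]

    def read_ids(self) -> list[str]:
        seen, out = set(), []
        for r in self.records:
            if not r.is_supplementary and r.read_id not in seen:
                seen.add(r.read_id)
                out.append(r.read_id)
        return out

    def subset(self, keep_ids) -> "AlignmentSet":
        keep = set(keep_ids)
        missing = keep - {r.read_id for r in self.records}
        if missing:
            raise KeyError(
                "read ids absent from alignment set: "
                + ", ".join(sorted(missing)[:10])
            )
        recs = [r for r in self.records if r.read_id in keep]
        return AlignmentSet(dict(self.chrom_lengths), recs, self.label)

    # ------------------------------------------------------------------ SAM
    def to_sam(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for name, ln in self.chrom_lengths.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
            fh.write("@PG\tID:raresv\tPN:raresv\n")
            for rec in self.records:
                flag = 0
                if rec.strand == "-":
                    flag |= 16
                if rec.is_supplementary:
                    flag |= 2048
                fields = [
                    rec.read_id,
                    str(flag),
                    rec.chrom,
                    str(rec.pos + 1),
                    str(rec.mapq),
                    format_cigar(rec.cigar),
                    "*", "0", "0", "*", "*",
                ]
                if rec.sa_links:
                    sa = "".join(
                        f"{l.chrom},{l.pos + 1},{l.strand},"
                        f"{format_cigar(list(l.cigar))},60,0;"
                        for l in rec.sa_links
                    )
                    fields.append(f"SA:Z:{sa}")
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def from_sam(cls, path, label: str | None = None) -> "AlignmentSet":
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            chrom_lengths = dict(zip(sam.references, sam.lengths))
            records = []
            for aln in sam:
                if aln.is_unmapped:
                    continue
                links = []
                if aln.has_tag("SA"):
                    for part in aln.get_tag("SA").rstrip(";").split(";"):
                        c, p, st, cg = part.split(",")[:4]
                        links.append(
                            SALink(c, int(p) - 1, st, tuple(parse_cigar(cg)))
                        )
                records.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        chrom=aln.reference_name,
                        pos=aln.reference_start,
                        strand="-" if aln.is_reverse else "+",
                        cigar=[
                            ("MIDNSHP=XB"[op], ln)
                            for op, ln in aln.cigartuples
                        ],
                        is_supplementary=aln.is_supplementary,
                        sa_links=links,
                        mapq=aln.mapping_quality,
                    )
                )
        return cls(chrom_lengths, records, label or str(path))
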