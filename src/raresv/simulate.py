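"""Pooled-nucleus long-read alignment simulation.

Emulates sequencing a pool of thousands of embryo nuclei at modest coverage:
each read is drawn from one randomly chosen nucleus, so a private SV of one
nucleus is captured by very few reads (support 1, rarely 2) — the regime the
rare-variant burden comparison is built for. Reads are emitted pre-aligned
(perfect mapping) with the alignment signature each spanned SV would leave:

* DEL -> in-CIGAR ``D`` op, or a split pair skipping the deleted interval
  (representation chosen per signature for deletions above a size threshold);
* INS -> in-CIGAR ``I`` op (only insertions that fit inside the read);
* INV -> split pair with a strand flip;
* DUP -> split pair whose second segment re-covers already-covered reference;
* BND -> split pair across chromosomes.

Platform noise is modeled as spurious short insertions/deletions scattered
through the CIGAR at a per-bp rate, mimicking the dominant nanopore error
mode. Base-level realism (homopolymer bias, quality strings) is out of scope;
SEQ is emitted as ``*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignments import AlignmentRecord, AlignmentSet, simplify_cigar
from .events import NucleusSVTable, SVEvent
from .genome import ReferenceGenome

__all__ = [
    "ReadLengthModel",
    "ErrorModel",
    "CaptureTruth",
    "simulate_alignments",
]


@dataclass(frozen=True)
class ReadLengthModel:
    """Read length distribution: log-normal or an empirical length list.

    Defaults approximate a genomic nanopore library with ~9-10 kb mean reads.
    Sampled lengths are clipped from below at ``min_length``.
    """

    family: str = "lognormal"
    mean_log: float = 9.0
    sd_log: float = 0.5
    lengths: tuple[int, ...] | None = None
    min_length: int = 500

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "empirical"):
            raise ValueError("family must be 'lognormal' or 'empirical'")
        if self.family == "empirical" and not self.lengths:
            raise ValueError("empirical model needs a non-empty length list")

    def mean_length(self) -> float:
        if self.family == "empirical":
            return float(np.mean(self.lengths))
        return float(np.exp(self.mean_log + self.sd_log**2 / 2))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "empirical":
            out = rng.choice(np.asarray(self.lengths, dtype=np.int64), size=n)
        else:
            out = np.exp(
                rng.normal(self.mean_log, self.sd_log, size=n)
            ).astype(np.int64)
        return np.maximum(out, self.min_length)


@dataclass(frozen=True)
class ErrorModel:
    """Spurious short-indel noise model (the dominant ONT error mode).

    ``small_indel_rate`` is the expected number of spurious indel events per
    aligned bp; each event is an insertion or deletion (equal odds) of length
    uniform on [1, small_indel_max_len].
    """

    small_indel_rate: float = 5e-5
    small_indel_max_len: int = 50
    mismatch_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.small_indel_rate, self.mismatch_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")
        if self.small_indel_max_len < 1:
            raise ValueError("small_indel_max_len must be >= 1")


NO_ERRORS = ErrorModel(small_indel_rate=0.0, mismatch_rate=0.0)


@dataclass
class CaptureTruth:
    """Ground-truth record of which planted events each read encoded."""

    table: NucleusSVTable
    captured: list[tuple[SVEvent, str]]

    def support_counts(self) -> dict[SVEvent, int]:
        out: dict[SVEvent, int] = {}
        for ev, _ in self.captured:
            out[ev] = out.get(ev, 0) + 1
        return out

    def captured_events(self) -> list[SVEvent]:
        return sorted(set(ev for ev, _ in self.captured),
                      key=lambda e: (e.chrom, e.start, e.sv_type))


def _inject_error_indels(
    ops: list[tuple[str, int]],
    rng: np.random.Generator,
    err: ErrorModel,
    read_len: int,
) -> list[tuple[str, int]]:
    """Scatter spurious short I/D events into M runs, conserving query length."""
    n_err = rng.poisson(err.small_indel_rate * read_len)
    for _ in range(n_err):
        m_positions = [i for i, (op, n) in enumerate(ops) if op == "M" and n >= 3]
        if not m_positions:
            break
        i = m_positions[rng.integers(len(m_positions))]
        op, n = ops[i]
        elen = int(rng.integers(1, err.small_indel_max_len + 1))
        if rng.random() < 0.5:  # deletion: query conserved, ref extends
            cut = int(rng.integers(1, n))
            ops[i : i + 1] = [("M", cut), ("D", elen), ("M", n - cut)]
        else:  # insertion: replace part of the M run, query conserved
            elen = min(elen, n - 2)
            cut = int(rng.integers(1, n - elen))
            ops[i : i + 1] = [("M", cut), ("I", elen), ("M", n - cut - elen)]
    return ops


def _build_read(
    chrom: str,
    p: int,
    L: int,
    donor_events,
    nlen: dict[str, int],
    rng: np.random.Generator,
    margin: int,
    split_del_prob: float,
    del_cigar_max: int,
):
    """Trace one read through its donor nucleus's derived genome.

    Returns travel-ordered alignment segments
    ``(chrom, ref_start, strand, q0, q1, ops)`` (ops in travel order, '+'
    segments reference-ordered) plus the list of events the read captured.
    A read chains through any number of junctions: after a split deletion or
    a tandem-duplication junction it continues on the same chromosome, after
    a translocation junction on the mate chromosome, and through an
    inversion it emits a reverse-strand segment and resumes forward past the
    right breakpoint.
    """
    by_chrom: dict[str, list] = {}
    for ev in donor_events:
        by_chrom.setdefault(ev.chrom, []).append(ev)

    segments = []
    seen: list = []
    used: set[int] = set()
    cur_chrom, seg_start, q0 = chrom, p, 0
    ops: list[tuple[str, int]] = []
    q, r = 0, p

    guard = 0
    while q < L and guard < 1000:
        guard += 1
        nxt = None
        for ev in by_chrom.get(cur_chrom, ()):
            bp = ev.breakpoint
            if id(ev) in used or bp < r + margin:
                continue
            if bp > r + (L - q) - margin:
                break
            nxt = ev
            break
        if nxt is None:
            break
        ev = nxt
        used.add(id(ev))
        gap = ev.breakpoint - r
        ops.append(("M", gap))
        q += gap
        r = ev.breakpoint

        if ev.sv_type == "DEL" and (
            ev.length <= del_cigar_max or rng.random() >= split_del_prob
        ):
            ops.append(("D", ev.length))
            r = ev.end
            seen.append(ev)
        elif ev.sv_type == "INS":
            if q + ev.length + margin > L:
                continue  # insertion does not fit inside the read
            ops.append(("I", ev.length))
            q += ev.length
            seen.append(ev)
        elif ev.sv_type == "INV":
            segments.append((cur_chrom, seg_start, "+", q0, q, ops))
            q2e = min(L - q, ev.length)
            segments.append(
                (cur_chrom, ev.end - q2e, "-", q, q + q2e, [("M", q2e)])
            )
            seen.append(ev)
            q += q2e
            seg_start, q0, ops, r = ev.end, q, [], ev.end
        else:  # split DEL, DUP junction, or BND junction
            segments.append((cur_chrom, seg_start, "+", q0, q, ops))
            seen.append(ev)
            if ev.sv_type == "DEL":
                seg_start = ev.end
            elif ev.sv_type == "DUP":
                seg_start = ev.start
            else:  # BND
                cur_chrom = ev.mate_chrom
                seg_start = min(ev.mate_pos, nlen[cur_chrom] - 1)
            q0, ops, r = q, [], seg_start

    # close the final forward segment with plain matches
    rem = min(L - q, nlen[cur_chrom] - r)
    if rem > 0:
        ops.append(("M", rem))
        q += rem
    if ops or not segments:
        segments.append((cur_chrom, seg_start, "+", q0, q, ops or [("M", 0)]))
    return segments, seen


def simulate_alignments(
    ref: ReferenceGenome,
    table: NucleusSVTable,
    coverage: float,
    read_model: ReadLengthModel | None = None,
    err: ErrorModel | None = None,
    seed: int = 0,
    *,
    margin: int = 100,
    split_del_prob: float = 0.5,
    del_cigar_max: int = 100,
    label: str = "library",
) -> AlignmentSet:
    """Simulate a pooled long-read library as pre-aligned SAM records.

    The number of reads is ``coverage * genome_length / mean_read_length``;
    each read's donor nucleus is uniform over ``table.n_nuclei``. A read
    captures a donor event when the event's breakpoint lies at least
    ``margin`` bp inside the read; captured events are encoded as the
    corresponding alignment signature and recorded in ``result.truth``.

    Deletions longer than ``del_cigar_max`` are encoded in-CIGAR or as a
    split pair with probability ``split_del_prob``, so callers must handle
    both evidence classes. A read carries at most one split-type signature;
    once a split is emitted the rest of the read is soft-clipped.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    read_model = read_model or ReadLengthModel()
    err = err if err is not None else ErrorModel()
    rng = np.random.default_rng(seed)

    chrom_len = np.asarray(ref.lengths, dtype=np.int64)
    max_chrom = int(chrom_len.max())
    total = int(chrom_len.sum())
    n_reads = max(1, int(round(coverage * total / read_model.mean_length())))

    lengths = read_model.sample(rng, n_reads)
    if int(lengths.max()) > max_chrom:
        raise ValueError(
            "read length model produced reads longer than the longest chromosome"
        )
    ci = rng.choice(len(chrom_len), size=n_reads, p=chrom_len / total)
    lengths = np.minimum(lengths, chrom_len[ci])  # read cannot exceed its chromosome
    starts = (rng.random(n_reads) * (chrom_len[ci] - lengths + 1)).astype(np.int64)
    donors = rng.integers(0, table.n_nuclei, size=n_reads)

    by_nucleus = table.by_nucleus()
    names = ref.names
    nlen = {n: int(l) for n, l in zip(names, chrom_len)}

    records: list[AlignmentRecord] = []
    captured: list[tuple[SVEvent, str]] = []
    width = max(6, len(str(n_reads)))

    for i in range(n_reads):
        read_id = f"{label}_read{i:0{width}d}"
        segments, seen = _build_read(
            names[ci[i]], int(starts[i]), int(lengths[i]),
            by_nucleus.get(int(donors[i]), ()), nlen, rng,
            margin, split_del_prob, del_cigar_max,
        )
        captured.extend((ev, read_id) for ev in seen)
        L = int(lengths[i])
        recs = []
        for si, (seg_chrom, seg_pos, strand, q0, q1, ops) in enumerate(segments):
            if strand == "+":
                cig = [("S", q0)] + ops + [("S", L - q1)]
            else:  # SAM CIGAR is reference-ordered: reverse the travel ops
                cig = [("S", L - q1)] + ops[::-1] + [("S", q0)]
            cig = simplify_cigar(cig)
            if si == 0 and err.small_indel_rate > 0:
                cig = simplify_cigar(_inject_error_indels(cig, rng, err, L))
            recs.append(
                AlignmentRecord(
                    read_id, seg_chrom, seg_pos, strand, cig,
                    is_supplementary=si > 0,
                )
            )
        for rec in recs:
            rec.sa_links = [r.as_sa_link() for r in recs if r is not rec]
        records.extend(recs)

    aln = AlignmentSet(ref.chrom_lengths(), records, label)
    aln.truth = CaptureTruth(table, captured)
    return aln
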