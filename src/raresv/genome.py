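"""Reference genome container and synthetic reference generation.

The synthetic reference stands in for a small multi-chromosome assembly:
chromosomes are named like *C. elegans* linkage groups (``LGI``, ``LGII``, ...)
and carry i.i.d. uniform base composition, which is the appropriate null for
the flanking-repeat analysis (no real repeat families are planted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = ["ReferenceGenome", "generate_reference"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _roman(n: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
        (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
        (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class ReferenceGenome:
    """Ordered named chromosome sequences.

    Parameters
    ----------
    names
        Unique chromosome names, in genome order.
    sequences
        DNA strings over {A, C, G, T}, one per name, all non-empty.
    """

    names: tuple[str, ...]
    sequences: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(len(s) == 0 for s in self.sequences):
            raise ValueError("every chromosome sequence must be non-empty")
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.names)}
        )

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.sequences)

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def chrom_lengths(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def sequence(self, name: str) -> str:
        return self.sequences[self._index[name]]

    def length(self, name: str) -> int:
        return len(self.sequences[self._index[name]])

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.sequences):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if not names:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(tuple(names), tuple(seqs))

    def to_fai(self, path) -> None:
        """Write a chromosome-length table in samtools .fai column order."""
        offset = 0
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.sequences):
                offset += len(name) + 2
                fh.write(f"{name}\t{len(seq)}\t{offset}\t70\t71\n")
                offset += len(seq) + len(seq) // 70 + 1


def generate_reference(chrom_lengths, seed: int) -> ReferenceGenome:
    """Generate a reproducible random reference genome.

    Chromosomes are named ``LGI``, ``LGII``, ... in input order and filled
    with i.i.d. uniform bases.

    Parameters
    ----------
    chrom_lengths
        Chromosome lengths in bp; each must be >= 10_000.
    seed
        Seed for the pseudo-random base stream; identical seeds give
        byte-identical sequences.
    """
    lengths = list(chrom_lengths)
    if not lengths:
        raise ValueError("chrom_lengths must be non-empty")
    if any(int(n) <= 0 for n in lengths):
        raise ValueError("chromosome lengths must be positive")
    if any(int(n) < 10_000 for n in lengths):
        raise ValueError("chromosome lengths must be >= 10000 bp")
    rng = np.random.default_rng(seed)
    names = tuple(f"LG{_roman(i + 1)}" for i in range(len(lengths)))
    seqs = tuple(
        _BASES[rng.integers(0, 4, size=int(n))].tobytes().decode()
        for n in lengths
    )
    return ReferenceGenome(names, seqs)
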