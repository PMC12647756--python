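"""Per-nucleus de novo SV event tables.

Each germline nucleus in the simulated pool carries its own private set of
structural variants; events arise independently per nucleus with per-type
Poisson rates, and events of one nucleus never overlap each other on the
reference (each nucleus is a single haplotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ReferenceGenome

__all__ = [
    "SV_TYPES",
    "SVEvent",
    "LogUniformSizeModel",
    "NucleusSVTable",
    "PlacementError",
    "plant_sv_events",
]

SV_TYPES = ("DEL", "DUP", "INS", "INV", "BND")


class PlacementError(RuntimeError):
    """Raised when non-overlapping event placement fails within the retry budget."""


@dataclass(frozen=True)
class SVEvent:
    """One planted de novo structural variant, private to one nucleus.

    ``start`` is 0-based on the reference; ``length`` is the affected span
    (for INS, the inserted length). BND events additionally carry a mate
    locus on a possibly different chromosome.
    """

    sv_type: str
    chrom: str
    start: int
    length: int
    nucleus_id: int
    mate_chrom: str | None = None
    mate_pos: int | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if (self.sv_type == "BND") != (self.mate_chrom is not None):
            raise ValueError("mate locus present iff sv_type is BND")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def breakpoint(self) -> int:
        """The reference position a read must span to capture this event.

        For a tandem duplication the detectable junction sits at the end of
        the duplicated interval (where the copy restarts); for every other
        type it is the event start.
        """
        return self.end if self.sv_type == "DUP" else self.start


@dataclass(frozen=True)
class LogUniformSizeModel:
    """Event lengths log-uniform on [min_len, max_len]."""

    min_len: int = 1_000
    max_len: int = 100_000

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = np.log(self.min_len), np.log(self.max_len)
        return np.exp(rng.uniform(lo, hi, size=n)).astype(np.int64)

    def bin_log_measure(self, lo: int, hi: int) -> float:
        """Probability mass of [lo, hi) under the model (closed form)."""
        a = np.clip(np.log(max(lo, self.min_len)), np.log(self.min_len), np.log(self.max_len))
        b = np.clip(np.log(min(hi, self.max_len)), np.log(self.min_len), np.log(self.max_len))
        return float(max(b - a, 0.0) / (np.log(self.max_len) - np.log(self.min_len)))


@dataclass
class NucleusSVTable:
    """Ground-truth table of planted events for a pool of nuclei."""

    n_nuclei: int
    events: list[SVEvent]
    rates: dict[str, float]
    size_model: object
    _by_nucleus: dict | None = field(default=None, repr=False, compare=False)

    def by_nucleus(self) -> dict[int, list[SVEvent]]:
        if self._by_nucleus is None:
            grouped: dict[int, list[SVEvent]] = {}
            for ev in self.events:
                grouped.setdefault(ev.nucleus_id, []).append(ev)
            for evs in grouped.values():
                evs.sort(key=lambda e: (e.chrom, e.breakpoint))
            self._by_nucleus = grouped
        return self._by_nucleus

    def counts_by_type(self) -> dict[str, int]:
        out = {t: 0 for t in SV_TYPES}
        for ev in self.events:
            out[ev.sv_type] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [e.chrom for e in self.events],
                "start": [e.start for e in self.events],
                "length": [e.length for e in self.events],
                "sv_type": [e.sv_type for e in self.events],
                "nucleus_id": [e.nucleus_id for e in self.events],
                "mate_chrom": [e.mate_chrom for e in self.events],
                "mate_pos": [e.mate_pos for e in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _normalize_size_models(size_model) -> dict[str, LogUniformSizeModel]:
    if isinstance(size_model, dict):
        models = dict(size_model)
        default = models.get("default", LogUniformSizeModel())
        return {t: models.get(t, default) for t in SV_TYPES}
    return {t: size_model for t in SV_TYPES}


def plant_sv_events(
    ref: ReferenceGenome,
    rates: dict[str, float],
    size_model,
    n_nuclei: int,
    seed: int,
    max_rounds: int = 200,
) -> NucleusSVTable:
    """Plant independent per-nucleus SV events on a reference genome.

    Per nucleus, the number of events of each type is Poisson with the given
    rate; positions are uniform on the genome, lengths come from
    ``size_model`` (a single model or a per-type mapping, truncated at the
    chromosome end), and events of one nucleus are re-drawn until they do
    not overlap each other. BND breakends are treated as 1-bp loci for the
    overlap rule.

    Raises
    ------
    PlacementError
        If non-overlap placement does not converge within ``max_rounds``
        redraw rounds (rates too high for the genome).
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    for t, r in rates.items():
        if t not in SV_TYPES:
            raise ValueError(f"unknown sv_type {t!r} in rates")
        if r < 0:
            raise ValueError("rates must be >= 0")
    models = _normalize_size_models(size_model)
    rng = np.random.default_rng(seed)

    chrom_len = np.asarray(ref.lengths, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(chrom_len)])
    total = int(offsets[-1])

    type_arr, nuc_arr, len_arr = [], [], []
    for t in SV_TYPES:
        rate = float(rates.get(t, 0.0))
        if rate == 0.0:
            continue
        counts = rng.poisson(rate, size=n_nuclei)
        k = int(counts.sum())
        if k == 0:
            continue
        nuc_arr.append(np.repeat(np.arange(n_nuclei), counts))
        type_arr.append(np.full(k, SV_TYPES.index(t), dtype=np.int8))
        if t == "BND":
            len_arr.append(np.ones(k, dtype=np.int64))
        else:
            len_arr.append(models[t].sample(rng, k))

    if not type_arr:
        return NucleusSVTable(n_nuclei, [], dict(rates), size_model)

    tcode = np.concatenate(type_arr)
    nuc = np.concatenate(nuc_arr)
    want_len = np.concatenate(len_arr)
    k = len(tcode)

    def draw_positions(m: int):
        g = rng.integers(0, total, size=m)
        ci = np.searchsorted(offsets, g, side="right") - 1
        return ci, g - offsets[ci]

    ci, start = draw_positions(k)
    length = np.minimum(want_len, chrom_len[ci] - start)

    bnd = tcode == SV_TYPES.index("BND")
    if bnd.any() and len(chrom_len) < 2:
        raise ValueError(
            "BND (translocation) events need at least two chromosomes"
        )

    # Iteratively redraw positions of events that overlap an earlier event of
    # the same nucleus until the pool is overlap-free.
    for _ in range(max_rounds):
        order = np.lexsort((start, ci, nuc))
        s, e = start[order], start[order] + length[order]
        same = (nuc[order][1:] == nuc[order][:-1]) & (ci[order][1:] == ci[order][:-1])
        # adjacent-pair screen: a sorted group with no adjacent overlap has
        # no overlap at all, so only groups with an adjacent clash need the
        # exact greedy sweep (keep earliest-start, flag every conflict).
        adj = same & (s[1:] < e[:-1])
        if not adj.any():
            break
        gid = np.cumsum(np.concatenate([[True], ~same])) - 1
        dirty = np.zeros(gid[-1] + 1, dtype=bool)
        dirty[gid[1:][adj]] = True
        idx = np.flatnonzero(dirty[gid])
        clash = np.zeros(k, dtype=bool)
        run_gid, run_end = -1, -1
        for i in idx:
            g = gid[i]
            if g != run_gid:
                run_gid, run_end = g, e[i]
            elif s[i] < run_end:
                clash[i] = True
            else:
                run_end = e[i]
        if not clash.any():
            break
        bad = order[clash]
        nci, nstart = draw_positions(len(bad))
        ci[bad], start[bad] = nci, nstart
        length[bad] = np.minimum(want_len[bad], chrom_len[nci] - nstart)
    else:
        raise PlacementError(
            f"non-overlapping placement failed after {max_rounds} rounds; "
            "rates too high for this genome/size model"
        )

    # translocation mates always sit on a different chromosome
    mate_ci = np.full(k, -1, dtype=np.int64)
    mate_pos = np.full(k, -1, dtype=np.int64)
    if bnd.any():
        m = int(bnd.sum())
        mci, mpos = draw_positions(m)
        own = ci[bnd]
        while (mci == own).any():
            clash = mci == own
            nci, npos = draw_positions(int(clash.sum()))
            mci[clash], mpos[clash] = nci, npos
        mate_ci[bnd], mate_pos[bnd] = mci, mpos

    names = ref.names
    events = [
        SVEvent(
            sv_type=SV_TYPES[tcode[i]],
            chrom=names[ci[i]],
            start=int(start[i]),
            length=int(length[i]),
            nucleus_id=int(nuc[i]),
            mate_chrom=names[mate_ci[i]] if bnd[i] else None,
            mate_pos=int(mate_pos[i]) if bnd[i] else None,
        )
        for i in range(k)
    ]
    events.sort(key=lambda e: (e.nucleus_id, e.chrom, e.start))
    return NucleusSVTable(n_nuclei, events, dict(rates), size_model)
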