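"""Rare large-SV burden comparison between two conditions.

The quantitative core of the pipeline: from two size-matched callsets,

1. keep rare large calls — support in {1, 2} (each germline nucleus
   contributes privately, so at pool-scale coverage a true de novo SV is
   seen by at most a couple of reads) and |svlen| above 1000 bp (spurious
   nanopore indel signatures are short);
2. tabulate counts per type and per size bin (1-10 kb, 10-50 kb, 50-100 kb);
3. report fold enrichment treatment/control per cell and per type overall;
4. tile the genome into non-overlapping 300-kb windows, count calls per
   window and type, and test each window's proportion between conditions
   with a two-proportion z test, Holm–Šídák corrected across the windows of
   each type.

Translocation (BND) calls carry no length: they bypass the length filter and
enter only the per-type overall comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import SVCallSet
from .events import SV_TYPES
from .stats import holm_sidak, two_proportion_test

__all__ = [
    "BurdenConfig",
    "CountTable",
    "WindowCountTrack",
    "EnrichmentReport",
    "filter_rare_large",
    "tabulate",
    "fold_enrichment",
    "window_counts",
    "window_enrichment",
    "compare_callsets",
]

DEFAULT_SIZE_BINS = ((1_000, 10_000), (10_000, 50_000), (50_000, 100_000))


@dataclass(frozen=True)
class BurdenConfig:
    """Parameters of the rare large-SV burden comparison.

    ``min_len`` is strict (svlen > min_len); ``size_bins`` are half-open
    [lo, hi) with the first edge inclusive, independently configurable from
    ``min_len``.
    """

    min_len: int = 1_000
    support_set: frozenset[int] = frozenset({1, 2})
    size_bins: tuple[tuple[int, int], ...] = DEFAULT_SIZE_BINS
    window_size: int = 300_000
    alpha: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "support_set", frozenset(self.support_set))
        bins = tuple(tuple(b) for b in self.size_bins)
        object.__setattr__(self, "size_bins", bins)
        for (lo, hi), (lo2, _) in zip(bins, bins[1:]):
            if hi > lo2:
                raise ValueError("size_bins must be disjoint and increasing")
        if any(lo >= hi for lo, hi in bins):
            raise ValueError("each size bin must satisfy lo < hi")
        if bins and self.min_len > bins[0][0]:
            raise ValueError("min_len must be <= first bin lower edge")
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def bin_labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.size_bins]


def filter_rare_large(cs: SVCallSet, cfg: BurdenConfig) -> SVCallSet:
    """Retain rare (support in support_set) large (|svlen| > min_len) calls.

    BND calls have no length and pass the length criterion by decision.
    Removal counts per criterion are recorded in provenance.
    """
    kept, removed_len, removed_support = [], 0, 0
    for c in cs.calls:
        if c.sv_type != "BND" and abs(c.svlen) <= cfg.min_len:
            removed_len += 1
            continue
        if c.support not in cfg.support_set:
            removed_support += 1
            continue
        kept.append(c)
    prov = dict(cs.provenance)
    prov.update(
        {
            "n_input_calls": len(cs.calls),
            "removed_by_length": removed_len,
            "removed_by_support": removed_support,
            "min_len": cfg.min_len,
            "support_set": sorted(cfg.support_set),
        }
    )
    return SVCallSet(kept, prov)


@dataclass
class CountTable:
    """Counts per (sv_type, size_bin) with per-type totals and out-of-range
    remainder (calls at or above the last bin edge)."""

    bins: pd.DataFrame  # index sv_type, columns bin labels
    overflow: pd.Series
    totals: pd.Series

    def count(self, sv_type: str, bin_label: str) -> int:
        return int(self.bins.loc[sv_type, bin_label])


def tabulate(cs: SVCallSet, cfg: BurdenConfig) -> CountTable:
    """Assign each (already filtered) call to its half-open size bin.

    Calls at or beyond the last bin edge count toward the out-of-range
    remainder; BND calls appear in totals only.
    """
    labels = cfg.bin_labels()
    bins = pd.DataFrame(0, index=list(SV_TYPES), columns=labels, dtype=int)
    overflow = pd.Series(0, index=list(SV_TYPES), dtype=int)
    totals = pd.Series(0, index=list(SV_TYPES), dtype=int)
    for c in cs.calls:
        totals[c.sv_type] += 1
        if c.sv_type == "BND":
            continue
        size = abs(c.svlen)
        placed = False
        for (lo, hi), lab in zip(cfg.size_bins, labels):
            if lo <= size < hi:
                bins.loc[c.sv_type, lab] += 1
                placed = True
                break
        if not placed and cfg.size_bins and size >= cfg.size_bins[-1][1]:
            overflow[c.sv_type] += 1
    return CountTable(bins, overflow, totals)


def fold_enrichment(
    treat: CountTable, ctrl: CountTable, cfg: BurdenConfig
) -> pd.DataFrame:
    """Per-cell and per-type-overall fold change treatment/control.

    The pseudocount enters only when the control cell is zero, and such
    cells are marked in the output; raw counts are always reported.
    """
    rows = []

    def fold(ct: int, cc: int) -> tuple[float, bool]:
        if cc > 0:
            return ct / cc, False
        if cfg.pseudocount > 0:
            return (ct + cfg.pseudocount) / cfg.pseudocount, True
        return float("nan"), True

    for t in SV_TYPES:
        for lab in cfg.bin_labels():
            ct, cc = treat.count(t, lab), ctrl.count(t, lab)
            f, used = fold(ct, cc)
            rows.append(
                {"sv_type": t, "size_bin": lab, "count_treat": ct,
                 "count_ctrl": cc, "fold": f, "pseudocount_used": used}
            )
        ct, cc = int(treat.totals[t]), int(ctrl.totals[t])
        f, used = fold(ct, cc)
        rows.append(
            {"sv_type": t, "size_bin": "overall", "count_treat": ct,
             "count_ctrl": cc, "fold": f, "pseudocount_used": used}
        )
    return pd.DataFrame(rows)


@dataclass
class WindowCountTrack:
    """SV counts in non-overlapping genomic windows (BND excluded)."""

    windows: pd.DataFrame  # chrom, start, end + one column per sv_type
    window_size: int

    def tiling(self) -> pd.DataFrame:
        return self.windows[["chrom", "start", "end"]]


def tile_genome(chrom_lengths: dict[str, int], window_size: int) -> pd.DataFrame:
    rows = []
    for chrom, ln in chrom_lengths.items():
        for s in range(0, ln, window_size):
            rows.append({"chrom": chrom, "start": s, "end": min(s + window_size, ln)})
    return pd.DataFrame(rows)


def window_counts(
    cs: SVCallSet, chrom_lengths: dict[str, int], cfg: BurdenConfig
) -> WindowCountTrack:
    """Count calls per 0-based half-open window; a call belongs to the single
    window containing its start coordinate."""
    win = tile_genome(chrom_lengths, cfg.window_size)
    types = [t for t in SV_TYPES if t != "BND"]
    for t in types:
        win[t] = 0
    index = {
        (row.chrom, row.start // cfg.window_size): i
        for i, row in win.iterrows()
    }
    for c in cs.calls:
        if c.sv_type == "BND":
            continue
        if c.chrom not in chrom_lengths:
            raise ValueError(f"call on unknown chromosome {c.chrom!r}")
        if not 0 <= c.start < chrom_lengths[c.chrom]:
            raise ValueError(f"call start {c.start} outside {c.chrom}")
        win.loc[index[(c.chrom, c.start // cfg.window_size)], c.sv_type] += 1
    return WindowCountTrack(win, cfg.window_size)


def window_enrichment(
    treat: WindowCountTrack, ctrl: WindowCountTrack, cfg: BurdenConfig
) -> pd.DataFrame:
    """Per-window, per-type two-proportion test between conditions.

    Each window's count is tested against the genome-wide total of that type
    in its condition; p-values are Holm–Šídák adjusted across the windows of
    each type, flagged significant at ``cfg.alpha``.
    """
    if not treat.tiling().equals(ctrl.tiling()):
        raise ValueError("window tilings differ between conditions")
    types = [c for c in treat.windows.columns if c in SV_TYPES]
    out = []
    for t in types:
        xt = treat.windows[t].to_numpy()
        xc = ctrl.windows[t].to_numpy()
        nt, nc = int(xt.sum()), int(xc.sum())
        raw = np.array(
            [two_proportion_test(int(a), nt, int(b), nc) for a, b in zip(xt, xc)]
        )
        adj, reject = holm_sidak(raw, cfg.alpha)
        for i, row in treat.tiling().iterrows():
            out.append(
                {
                    "chrom": row.chrom, "start": row.start, "end": row.end,
                    "sv_type": t,
                    "count_treat": int(xt[i]), "count_ctrl": int(xc[i]),
                    "total_treat": nt, "total_ctrl": nc,
                    "raw_p": raw[i], "adj_p": adj[i],
                    "significant": bool(reject[i]),
                }
            )
    return pd.DataFrame(out)


@dataclass
class EnrichmentReport:
    """Full burden-comparison result: fold table, window tests, metadata."""

    fold_table: pd.DataFrame
    window_table: pd.DataFrame
    config: BurdenConfig
    metadata: dict = field(default_factory=dict)

    def overall_fold(self, sv_type: str) -> float:
        sel = self.fold_table.query(
            "sv_type == @sv_type and size_bin == 'overall'"
        )
        return float(sel["fold"].iloc[0])

    def significant_windows(self) -> pd.DataFrame:
        return self.window_table[self.window_table["significant"]]

    def summary(self) -> str:
        lines = ["Rare large-SV burden comparison", "=" * 34]
        lines.append(
            f"filter: svlen > {self.config.min_len} bp, "
            f"support in {sorted(self.config.support_set)}"
        )
        overall = self.fold_table[self.fold_table.size_bin == "overall"]
        for _, r in overall.iterrows():
            mark = " (pseudocount)" if r.pseudocount_used else ""
            lines.append(
                f"  {r.sv_type:>3}: {r.count_treat:>5} vs {r.count_ctrl:>5}"
                f"  fold = {r.fold:.2f}{mark}"
            )
        nsig = int(self.window_table["significant"].sum()) if len(self.window_table) else 0
        lines.append(
            f"windows ({self.config.window_size} bp): "
            f"{nsig} significant at alpha = {self.config.alpha}"
        )
        return "\n".join(lines)

    def to_tsv(self, fold_path, window_path) -> None:
        self.fold_table.to_csv(fold_path, sep="\t", index=False)
        self.window_table.to_csv(window_path, sep="\t", index=False)

    def to_json_summary(self) -> str:
        overall = {
            r.sv_type: {
                "count_treat": int(r.count_treat),
                "count_ctrl": int(r.count_ctrl),
                "fold": None if np.isnan(r.fold) else round(float(r.fold), 4),
            }
            for _, r in self.fold_table[
                self.fold_table.size_bin == "overall"
            ].iterrows()
        }
        payload = {
            "overall": overall,
            "n_significant_windows": int(self.window_table["significant"].sum())
            if len(self.window_table)
            else 0,
            "config": {
                "min_len": self.config.min_len,
                "support_set": sorted(self.config.support_set),
                "size_bins": [list(b) for b in self.config.size_bins],
                "window_size": self.config.window_size,
                "alpha": self.config.alpha,
            },
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def compare_callsets(
    treat: SVCallSet,
    ctrl: SVCallSet,
    chrom_lengths: dict[str, int],
    cfg: BurdenConfig | None = None,
    metadata: dict | None = None,
) -> EnrichmentReport:
    """Run the full burden comparison on two (resampled) callsets."""
    cfg = cfg or BurdenConfig()
    ft = filter_rare_large(treat, cfg)
    fc = filter_rare_large(ctrl, cfg)
    folds = fold_enrichment(tabulate(ft, cfg), tabulate(fc, cfg), cfg)
    wt = window_counts(ft, chrom_lengths, cfg)
    wc = window_counts(fc, chrom_lengths, cfg)
    windows = window_enrichment(wt, wc, cfg)
    meta = dict(metadata or {})
    meta.update(
        {
            "treat_filter": {k: ft.provenance.get(k) for k in
                             ("n_input_calls", "removed_by_length", "removed_by_support")},
            "ctrl_filter": {k: fc.provenance.get(k) for k in
                            ("n_input_calls", "removed_by_length", "removed_by_support")},
        }
    )
    return EnrichmentReport(folds, windows, cfg, meta)
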