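"""Canned desk-scale synthetic studies.

These wrap the full pipeline at problem sizes a laptop handles in seconds to
minutes, emulating the pooled-embryo design: thousands of nuclei carrying
private SVs, ~30x coverage so each captured SV is supported by one or two
reads, treatment multiplying DEL/DUP rates. The desk-scale genome (2 Mb vs
a ~100 Mb animal genome) forces proportionally smaller event sizes so that
each nucleus's events still fit without overlap; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .burden import BurdenConfig, EnrichmentReport, compare_callsets, filter_rare_large
from .caller import call_svs
from .events import LogUniformSizeModel, plant_sv_events
from .genome import generate_reference
from .pipeline import stage_seed
from .repeats import compare_to_null, permuted_breakpoint_null, scan_callset
from .resample import ReadLibrary, match_libraries, subset_alignments
from .simulate import ErrorModel, ReadLengthModel, simulate_alignments

__all__ = [
    "BurdenStudyDesign",
    "BurdenStudyResult",
    "run_burden_study",
    "caller_oracle_study",
    "error_filter_study",
    "resampling_study",
    "repeat_null_study",
]


@dataclass(frozen=True)
class BurdenStudyDesign:
    """Study conditions for one two-arm synthetic burden comparison.

    Defaults are the desk-scale enrichment-recovery design: 5000 nuclei,
    two 1-Mb chromosomes, 30x coverage, treatment doubling the deletion
    rate and tripling the duplication rate.
    """

    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000)
    n_nuclei: int = 5_000
    coverage: float = 30.0
    base_rate: float = 20.0
    del_mult: float = 2.0
    dup_mult: float = 3.0
    bnd_rate: float = 0.5
    size_range: tuple[int, int] = (1_000, 20_000)
    ins_size_range: tuple[int, int] = (1_000, 8_000)
    read_model: ReadLengthModel = field(default_factory=ReadLengthModel)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    burden: BurdenConfig = field(default_factory=BurdenConfig)

    def size_models(self) -> dict:
        return {
            "default": LogUniformSizeModel(*self.size_range),
            "INS": LogUniformSizeModel(*self.ins_size_range),
        }

    def control_rates(self) -> dict[str, float]:
        r = self.base_rate
        return {"DEL": r, "DUP": r, "INS": r, "INV": r, "BND": self.bnd_rate}

    def treatment_rates(self) -> dict[str, float]:
        rates = self.control_rates()
        rates["DEL"] *= self.del_mult
        rates["DUP"] *= self.dup_mult
        return rates


@dataclass
class BurdenStudyResult:
    report: EnrichmentReport
    captured: dict[str, dict[str, int]]  # arm -> sv_type -> captured events
    library_sizes: dict[str, int]
    ks_after: float

    def overall_fold(self, sv_type: str) -> float:
        return self.report.overall_fold(sv_type)


def run_burden_study(seed: int, design: BurdenStudyDesign | None = None) -> BurdenStudyResult:
    """Simulate both arms, resample, call, and compare — the full loop."""
    d = design or BurdenStudyDesign()
    ref = generate_reference(d.chrom_lengths, stage_seed(seed, "ref"))
    arms = {}
    captured = {}
    for label, rates in (
        ("treat", d.treatment_rates()),
        ("ctrl", d.control_rates()),
    ):
        table = plant_sv_events(
            ref, rates, d.size_models(), d.n_nuclei,
            seed=stage_seed(seed, f"plant:{label}"),
        )
        aln = simulate_alignments(
            ref, table, d.coverage, d.read_model, d.error_model,
            seed=stage_seed(seed, f"reads:{label}"), label=label,
        )
        arms[label] = aln
        counts: dict[str, int] = {}
        for ev in aln.truth.captured_events():
            counts[ev.sv_type] = counts.get(ev.sv_type, 0) + 1
        captured[label] = counts

    libs = {k: ReadLibrary.from_alignments(a) for k, a in arms.items()}
    lt, lc, rep = match_libraries(
        libs["treat"], libs["ctrl"], seed=stage_seed(seed, "resample")
    )
    cs_treat = call_svs(subset_alignments(arms["treat"], lt))
    cs_ctrl = call_svs(subset_alignments(arms["ctrl"], lc))
    report = compare_callsets(
        cs_treat, cs_ctrl, ref.chrom_lengths(), d.burden,
        metadata={"seed": seed},
    )
    return BurdenStudyResult(
        report, captured,
        {"treat": lt.total_reads, "ctrl": lc.total_reads},
        rep.ks_after,
    )


def null_study_design() -> BurdenStudyDesign:
    """Equal-rate two-arm design small enough for hundreds of replicates.

    Four 300-kb windows; ~150 captured events per type per arm, ~37 per
    window, keeping the two-proportion normal approximation comfortable.
    """
    return BurdenStudyDesign(
        chrom_lengths=(600_000, 600_000),
        n_nuclei=300,
        coverage=15.0,
        base_rate=10.0,
        del_mult=1.0,
        dup_mult=1.0,
        bnd_rate=0.0,
        size_range=(1_000, 10_000),
        ins_size_range=(1_000, 5_000),
        read_model=ReadLengthModel(mean_log=8.4, sd_log=0.4),
    )


def caller_oracle_study(seed: int) -> dict:
    """Noise-free sparse simulation scored one-to-one against the truth."""
    ref = generate_reference((1_000_000, 1_000_000), stage_seed(seed, "ref"))
    table = plant_sv_events(
        ref,
        {"DEL": 0.5, "DUP": 0.5, "INS": 0.5, "INV": 0.5, "BND": 0.2},
        LogUniformSizeModel(1_500, 20_000),
        n_nuclei=12,
        seed=stage_seed(seed, "plant"),
    )
    aln = simulate_alignments(
        ref, table, coverage=30,
        err=ErrorModel(small_indel_rate=0.0),
        seed=stage_seed(seed, "reads"),
    )
    captured = aln.truth.captured_events()
    calls = call_svs(aln).calls

    def match(call, ev):
        if call.sv_type != ev.sv_type:
            return False
        if ev.sv_type == "BND":
            lo, hi = sorted(
                [(ev.chrom, ev.start), (ev.mate_chrom, ev.mate_pos)]
            )
            return (
                call.chrom == lo[0] and abs(call.start - lo[1]) <= 500
                and call.mate_chrom == hi[0]
                and abs(call.mate_pos - hi[1]) <= 500
            )
        return (
            call.chrom == ev.chrom
            and abs(call.start - ev.start) <= 500
            and abs(call.svlen - ev.length) <= 0.1 * ev.length
        )

    matched_events = sum(1 for ev in captured if any(match(c, ev) for c in calls))
    matched_calls = sum(1 for c in calls if any(match(c, ev) for ev in captured))
    return {
        "n_captured": len(captured),
        "n_calls": len(calls),
        "recall": matched_events / len(captured) if captured else float("nan"),
        "precision": matched_calls / len(calls) if calls else float("nan"),
    }


def error_filter_study(seed: int) -> dict:
    """Platform noise only: nothing should survive the rare-large filter."""
    ref = generate_reference((300_000, 300_000), stage_seed(seed, "ref"))
    table = plant_sv_events(ref, {}, LogUniformSizeModel(), 50,
                            seed=stage_seed(seed, "plant"))
    aln = simulate_alignments(
        ref, table, coverage=20,
        err=ErrorModel(small_indel_rate=1e-3, small_indel_max_len=50),
        seed=stage_seed(seed, "reads"),
    )
    calls = call_svs(aln)
    survivors = filter_rare_large(calls, BurdenConfig())
    return {"n_raw_calls": len(calls), "n_survivors": len(survivors)}


def resampling_study(seed: int) -> dict:
    """Two dissimilar lognormal libraries matched by per-bin resampling."""
    rng = np.random.default_rng(stage_seed(seed, "libs"))
    mk = lambda mu, n, label: ReadLibrary(
        label,
        np.array([f"{label}{i}" for i in range(n)], dtype=object),
        (np.exp(rng.normal(mu, 0.45, n)) + 500).astype(np.int64),
    )
    a = mk(8.3, 4_000, "a")
    b = mk(8.8, 3_200, "b")
    a2, b2, rep = match_libraries(a, b, seed=stage_seed(seed, "match"))
    return {
        "total_a": a2.total_reads,
        "total_b": b2.total_reads,
        "ks_before": rep.ks_before,
        "ks_after": rep.ks_after,
    }


def repeat_null_study(seed: int, n_runs: int = 100, n_calls: int = 40,
                      flank_len: int = 150) -> dict:
    """Breakpoint flanks on random sequence vs the permuted-breakpoint null.

    Returns the fraction of runs where the observed longest-direct-repeat
    distribution is indistinguishable from the null (KS p > 0.05) — the
    computational analogue of finding no specific flanking repeats.
    """
    from .caller import SVCall, SVCallSet

    ok = 0
    for run in range(n_runs):
        sub = stage_seed(seed, f"rep:{run}")
        ref = generate_reference((120_000,), sub)
        rng = np.random.default_rng(stage_seed(sub, "bp"))
        starts = rng.integers(1_000, 115_000, size=n_calls)
        cs = SVCallSet(
            [
                SVCall("DEL", "LGI", int(s), int(s) + 1_000, 1_000, 1,
                       frozenset({f"r{i}"}))
                for i, s in enumerate(starts)
            ]
        )
        obs = scan_callset(ref, cs, flank_len=flank_len)
        null = permuted_breakpoint_null(
            ref, cs, stage_seed(sub, "perm"), flank_len=flank_len
        )
        p = compare_to_null(obs, null)["longest_direct_repeat"]["p_value"]
        ok += p > 0.05
    return {"n_runs": n_runs, "fraction_indistinguishable": ok / n_runs}
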