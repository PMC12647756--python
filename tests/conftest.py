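import pytest

import raresv as rv


@pytest.fixture(scope="session")
def small_genome():
    """Two 100-kb chromosomes, fixed seed."""
    return rv.generate_reference([100_000, 100_000], seed=42)


@pytest.fixture(scope="session")
def sparse_simulation():
    """Noise-free low-density simulation with perfect ground truth.

    Density is kept low enough that distinct planted events essentially
    never fall within one clustering window of each other, so caller output
    can be compared one-to-one against the capture record.
    """
    ref = rv.generate_reference([1_000_000, 1_000_000], seed=7)
    table = rv.plant_sv_events(
        ref,
        {"DEL": 0.5, "DUP": 0.5, "INS": 0.5, "INV": 0.5, "BND": 0.2},
        rv.LogUniformSizeModel(1_500, 20_000),
        n_nuclei=12,
        seed=8,
    )
    aln = rv.simulate_alignments(
        ref, table, coverage=30,
        err=rv.ErrorModel(small_indel_rate=0.0),
        seed=9,
    )
    return ref, table, aln


def calls_match_event(call, event, window=500, svlen_tol=0.1):
    """True if a call matches a planted event in type, locus, and size."""
    if call.sv_type != event.sv_type or event.sv_type == "BND":
        if event.sv_type == "BND" and call.sv_type == "BND":
            ends = sorted(
                [(event.chrom, event.start), (event.mate_chrom, event.mate_pos)]
            )
            return (
                call.chrom == ends[0][0]
                and abs(call.start - ends[0][1]) <= window
                and call.mate_chrom == ends[1][0]
                and abs(call.mate_pos - ends[1][1]) <= window
            )
        return False
    return (
        call.chrom == event.chrom
        and abs(call.start - event.start) <= window
        and abs(call.svlen - event.length) <= svlen_tol * event.length
    )
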