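import itertools

import pytest
from hypothesis import given, settings, strategies as st

from raresv.alignments import (
    AlignmentRecord,
    MalformedAlignmentError,
    SALink,
    parse_cigar,
)
from raresv.caller import (
    SVSignature,
    cluster_signatures,
    extract_signatures,
)


def rec(cigar, pos=10_000, chrom="LGI", strand="+", links=(), supp=False,
        read_id="r1"):
    return AlignmentRecord(
        read_id, chrom, pos, strand, parse_cigar(cigar),
        is_supplementary=supp, sa_links=list(links),
    )


class TestCigarSignatures:
    def test_deletion_read_off(self):
        sigs = extract_signatures(rec("100M5000D100M"), min_signature_len=30)
        assert [(s.sv_type, s.start, s.length) for s in sigs] == [
            ("DEL", 10_100, 5000)
        ]

    def test_below_threshold_ignored(self):
        assert extract_signatures(rec("100M10D100M"), 30) == []

    def test_insertion_read_off(self):
        sigs = extract_signatures(rec("50M200I50M"), 30)
        assert [(s.sv_type, s.start, s.length) for s in sigs] == [
            ("INS", 10_050, 200)
        ]

    def test_adjacent_same_type_ops_merge_across_small_gap(self):
        # two 20-bp deletions 40 M apart merge into one 40-bp signature
        sigs = extract_signatures(rec("100M20D40M20D100M"), 30, merge_gap=100)
        assert [(s.sv_type, s.length) for s in sigs] == [("DEL", 40)]

    def test_no_merge_beyond_gap(self):
        sigs = extract_signatures(rec("100M20D400M20D100M"), 30, merge_gap=100)
        assert sigs == []

    def test_supplementary_record_yields_nothing(self):
        assert extract_signatures(rec("100M5000D100M", supp=True), 30) == []

    def test_supplementary_cigar_evidence_via_links(self):
        link = SALink("LGI", 50_000, "+", tuple(parse_cigar("100S50M40D50M")))
        primary = rec("100M100S", links=[link])
        sigs = extract_signatures(primary, 30)
        assert ("DEL", 50_050, 40) in [
            (s.sv_type, s.start, s.length) for s in sigs
        ]


class TestSplitSignatures:
    def test_split_deletion_geometry(self):
        link = SALink("LGI", 15_000, "+", tuple(parse_cigar("100S100M")))
        primary = rec("100M100S", pos=10_000, links=[link])
        sigs = extract_signatures(primary, 30)
        assert [(s.sv_type, s.start, s.length) for s in sigs] == [
            ("DEL", 10_100, 4900)
        ]

    def test_inversion_strand_flip_geometry(self):
        # forward to 10_100, then reverse segment covering [12_100, 12_200):
        # implied inverted interval [10_100, 12_200), length 2100
        link = SALink("LGI", 12_100, "-", tuple(parse_cigar("100M100S")))
        primary = rec("100M100S", pos=10_000, links=[link])
        sigs = extract_signatures(primary, 30)
        assert [(s.sv_type, s.start, s.length) for s in sigs] == [
            ("INV", 10_100, 2100)
        ]

    def test_duplication_recovered_reference(self):
        # primary reaches 10_100; second segment re-starts at 9_000
        link = SALink("LGI", 9_000, "+", tuple(parse_cigar("100S100M")))
        primary = rec("100M100S", pos=10_000, links=[link])
        sigs = extract_signatures(primary, 30)
        assert [(s.sv_type, s.start, s.length) for s in sigs] == [
            ("DUP", 9_000, 1100)
        ]

    def test_translocation_across_chromosomes(self):
        link = SALink("LGII", 5_000, "+", tuple(parse_cigar("100S100M")))
        primary = rec("100M100S", pos=10_000, links=[link])
        sigs = extract_signatures(primary, 30)
        assert len(sigs) == 1
        s = sigs[0]
        assert s.sv_type == "BND"
        # keyed on the lexicographically smaller breakend
        assert (s.chrom, s.start, s.mate_chrom, s.mate_pos) == (
            "LGI", 10_100, "LGII", 5_000
        )

    def test_inconsistent_query_lengths_raise(self):
        link = SALink("LGI", 15_000, "+", tuple(parse_cigar("100S150M")))
        primary = rec("100M100S", links=[link])
        with pytest.raises(MalformedAlignmentError, match="r1"):
            extract_signatures(primary, 30)


def sig(start, length=5000, sv_type="DEL", read_id="r1", chrom="LGI"):
    return SVSignature(sv_type, chrom, start, length, read_id, "cigar")


def brute_force_single_linkage(sigs, window, ratio):
    """Oracle: exhaustive transitive closure over the pairwise link rule."""
    n = len(sigs)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        a, b = sigs[i], sigs[j]
        lo, hi = sorted([a.length, b.length])
        if abs(a.start - b.start) <= window and (hi == 0 or lo / hi >= ratio):
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(comp)
    return sorted(sorted(c) for c in comps)


class TestClusterSignatures:
    def test_two_reads_same_event_merge(self):
        cs = cluster_signatures(
            [sig(1000, 5000, read_id="a"), sig(1050, 5200, read_id="b")],
            position_window=500, size_ratio_min=0.7,
        )
        assert len(cs) == 1
        assert cs.calls[0].support == 2

    def test_same_read_counted_once(self):
        cs = cluster_signatures(
            [sig(1000, 5000, read_id="a"), sig(1010, 5000, read_id="a")],
            500, 0.7,
        )
        assert len(cs) == 1
        assert cs.calls[0].support == 1

    def test_chain_merge_transitive_closure(self):
        sigs = [sig(0, read_id="a"), sig(400, read_id="b"), sig(800, read_id="c")]
        cs = cluster_signatures(sigs, 500, 0.7)
        assert len(cs) == 1
        assert cs.calls[0].support == 3
        assert cs.calls[0].start == 400  # median

    def test_median_tie_resolves_low(self):
        sigs = [sig(100, read_id="a"), sig(200, read_id="b")]
        cs = cluster_signatures(sigs, 500, 0.7)
        assert cs.calls[0].start == 100

    def test_size_ratio_separates(self):
        sigs = [sig(1000, 1000, read_id="a"), sig(1010, 5000, read_id="b")]
        cs = cluster_signatures(sigs, 500, 0.7)
        assert len(cs) == 2

    def test_types_never_merge(self):
        sigs = [sig(1000, 5000, "DEL"), sig(1000, 5000, "DUP", read_id="b")]
        assert len(cluster_signatures(sigs, 500, 0.7)) == 2

    def test_empty_input(self):
        assert len(cluster_signatures([], 500, 0.7)) == 0

    def test_idempotence(self):
        sigs = [sig(1000, 5000, read_id="a"), sig(9000, 900, read_id="b"),
                sig(30_000, 5000, "INS", read_id="c")]
        once = cluster_signatures(sigs, 500, 0.7)
        again = cluster_signatures(
            [SVSignature(c.sv_type, c.chrom, c.start, c.svlen, min(c.supporting_reads),
                         "cigar") for c in once.calls],
            500, 0.7,
        )
        assert [(c.sv_type, c.start, c.svlen) for c in again.calls] == [
            (c.sv_type, c.start, c.svlen) for c in once.calls
        ]

    def test_support_monotone_in_added_reads(self):
        base = [sig(1000, 5000, read_id=f"r{i}") for i in range(3)]
        before = cluster_signatures(base, 500, 0.7)
        after = cluster_signatures(base + [sig(1001, 5000, read_id="extra")], 500, 0.7)
        assert max(c.support for c in after.calls) >= max(
            c.support for c in before.calls
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            cluster_signatures([], 0, 0.7)
        with pytest.raises(ValueError):
            cluster_signatures([], 500, 0.0)

    @given(
        starts=st.lists(st.integers(0, 5000), min_size=1, max_size=25),
        lengths=st.lists(st.integers(30, 3000), min_size=25, max_size=25),
        window=st.integers(1, 1500),
        ratio=st.floats(0.1, 1.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, starts, lengths, window, ratio):
        sigs = [
            sig(s, l, read_id=f"r{i}")
            for i, (s, l) in enumerate(zip(starts, lengths))
        ]
        cs = cluster_signatures(sigs, window, ratio)
        expected = brute_force_single_linkage(sigs, window, ratio)
        got = sorted(
            sorted(
                i for i, s in enumerate(sigs)
                if s.read_id in c.supporting_reads
            )
            for c in cs.calls
        )
        assert got == expected
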