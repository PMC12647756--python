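import pytest
from hypothesis import given, settings, strategies as st

import raresv as rv
from raresv.caller import SVCall, SVCallSet
from raresv.genome import ReferenceGenome
from raresv.repeats import (
    extract_flanks,
    junction_microhomology,
    longest_shared_repeat,
    permuted_breakpoint_null,
    revcomp,
    scan_callset,
)

DNA = st.text(alphabet="ACGT", max_size=18)


def brute_lcs(a, b):
    best, seq = 0, ""
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            if j - i > best and a[i:j] in b:
                best, seq = j - i, a[i:j]
    return best, seq


def dcall(chrom, start, end, sv_type="DEL"):
    svlen = end - start
    return SVCall(sv_type, chrom, start, end, svlen, 1, frozenset({"r"}))


class TestExtractFlanks:
    def test_interior_flanks_match_reference(self, small_genome):
        c = dcall("LGI", 5_000, 8_000)
        left, right, truncated = extract_flanks(small_genome, c, 10)
        seq = small_genome.sequence("LGI")
        assert left == seq[4_990:5_000]
        assert right == seq[8_000:8_010]
        assert not truncated

    def test_start_of_chromosome_truncates(self, small_genome):
        left, right, truncated = extract_flanks(
            small_genome, dcall("LGI", 0, 1000), 50
        )
        assert left == ""
        assert truncated

    def test_unknown_chromosome(self, small_genome):
        with pytest.raises(ValueError):
            extract_flanks(small_genome, dcall("chr7", 10, 20), 10)

    def test_flanks_equal_ground_truth_context(self):
        """Flanks of a planted deletion equal the simulator's reference."""
        ref = rv.generate_reference([50_000], seed=13)
        ev_start, ev_len = 20_000, 3_000
        c = dcall("LGI", ev_start, ev_start + ev_len)
        left, right, _ = extract_flanks(ref, c, 100)
        s = ref.sequence("LGI")
        assert left == s[ev_start - 100 : ev_start]
        assert right == s[ev_start + ev_len : ev_start + ev_len + 100]


class TestLongestSharedRepeat:
    def test_identity(self):
        assert longest_shared_repeat("ACGT", "ACGT", "direct") == (4, "ACGT")

    def test_tie_breaks_leftmost_in_a(self):
        assert longest_shared_repeat("AAAGTC", "GTCAAA", "direct") == (3, "AAA")

    def test_palindrome_inverted(self):
        # revcomp("ACGT") == "ACGT": the full palindrome matches
        assert longest_shared_repeat("ACGT", "ACGT", "inverted") == (4, "ACGT")

    def test_empty_inputs(self):
        assert longest_shared_repeat("", "ACGT", "direct") == (0, "")

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            longest_shared_repeat("A", "A", "fuzzy")

    @given(a=DNA, b=DNA)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_brute_force(self, a, b):
        length, seq = longest_shared_repeat(a, b, "direct")
        b_len, b_seq = brute_lcs(a, b)
        assert length == b_len
        assert seq == b_seq

    @given(a=DNA, b=DNA)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_inverted_mode_equals_direct_on_revcomp(self, a, b):
        assert longest_shared_repeat(a, b, "inverted") == \
            longest_shared_repeat(a, revcomp(b), "direct")

    @given(a=DNA, b=DNA)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_length_symmetric(self, a, b):
        la, _ = longest_shared_repeat(a, b, "direct")
        lb, _ = longest_shared_repeat(b, a, "direct")
        assert la == lb


class TestJunctionMicrohomology:
    def _genome_with_deletion_homology(self, k):
        # sequence where s[start:start+k] == s[end:end+k] by construction
        base = list("ACGT" * 3000)
        start, end = 4_000, 7_000
        motif = "GATC" * 10
        base[start : start + 40] = motif
        base[end : end + 40] = motif
        # break the homology after k bases
        base[start + k] = "A" if base[end + k] != "A" else "C"
        return ReferenceGenome(("LGI",), ("".join(base),)), start, end

    def test_engineered_four_base_homology(self):
        ref, start, end = self._genome_with_deletion_homology(4)
        mh = junction_microhomology(ref, dcall("LGI", start, end), max_len=25)
        assert mh == 4

    def test_cap_applies(self):
        ref, start, end = self._genome_with_deletion_homology(30)
        mh = junction_microhomology(ref, dcall("LGI", start, end), max_len=10)
        assert mh == 10

    def test_no_homology_zero(self):
        ref = rv.generate_reference([20_000], seed=3)
        seq = ref.sequence("LGI")
        start = next(
            i for i in range(5_000, 6_000) if seq[i] != seq[i + 2_000]
        )
        mh = junction_microhomology(ref, dcall("LGI", start, start + 2_000))
        assert mh == 0

    def test_unsupported_type_is_explicit(self, small_genome):
        out = junction_microhomology(
            small_genome, dcall("LGI", 100, 100, sv_type="INV")
        )
        assert out is None


@pytest.fixture(scope="module")
def scanned(small_genome):
    calls = [dcall("LGI", 10_000 + 2_000 * i, 11_000 + 2_000 * i)
             for i in range(25)]
    cs = SVCallSet(calls)
    return small_genome, cs, scan_callset(small_genome, cs, flank_len=150)


class TestScanCallset:
    def test_one_row_per_call_with_bounded_lengths(self, scanned):
        _, cs, res = scanned
        assert len(res.table) == len(cs)
        assert (res.table.longest_direct_repeat <= 150).all()
        assert (res.table.longest_direct_repeat >= 0).all()
        assert (res.table.microhomology_len >= 0).all()

    def test_monotone_in_flank_len(self, scanned):
        genome, cs, res = scanned
        wider = scan_callset(genome, cs, flank_len=300)
        assert (
            wider.table.longest_direct_repeat
            >= res.table.longest_direct_repeat
        ).all()

    def test_permuted_null_same_shape_and_deterministic(self, scanned):
        genome, cs, _ = scanned
        n1 = permuted_breakpoint_null(genome, cs, seed=5, flank_len=150)
        n2 = permuted_breakpoint_null(genome, cs, seed=5, flank_len=150)
        assert len(n1.table) == len(cs)
        assert n1.table.equals(n2.table)

    def test_random_breakpoints_mean_matches_analytic_null(self):
        """On uniform random sequence the longest shared k-mer between two
        150-mers concentrates near log4(n*m); the scan should agree with a
        directly sampled null within Monte-Carlo error."""
        import numpy as np

        ref = rv.generate_reference([400_000], seed=21)
        rng = np.random.default_rng(22)
        starts = rng.integers(5_000, 390_000, size=120)
        cs = SVCallSet([dcall("LGI", int(s), int(s) + 1_000) for s in starts])
        res = scan_callset(ref, cs, flank_len=150)
        # independent null: fresh random sequence pairs
        other = rv.generate_reference([400_000], seed=23)
        seq = other.sequence("LGI")
        null = [
            longest_shared_repeat(
                seq[i : i + 150], seq[i + 200 : i + 350], "direct"
            )[0]
            for i in range(0, 120 * 400, 400)
        ]
        obs_mean = res.table.longest_direct_repeat.mean()
        null_mean = float(np.mean(null))
        assert abs(obs_mean - null_mean) < 1.0
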