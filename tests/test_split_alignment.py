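"""Split-aligner tests: brute-force oracle equivalence, filter semantics,
classification monotonicity, strand symmetry."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from ampdel import (
    AmpliconReference,
    FilterParams,
    Scoring,
    SplitAligner,
    align_read,
    classify_read,
)
from ampdel.split_alignment import SplitAlignment, Segment

from conftest import random_dna


def brute_force_best_score(read: str, ref: str) -> float:
    """Independent oracle: enumerate every single-deletion placement.

    Plain-Python DP over best gapless segments ending/starting at each
    (read, ref) cell, combined over every read split and every reference gap
    (equivalent to scoring all (deletion start, length) placements with
    gapless flanks), plus the single-segment alternative.
    """
    L, n = len(read), len(ref)
    E = [[-1e18] * (n + 1) for _ in range(L + 1)]
    F = [[-1e18] * (n + 1) for _ in range(L + 1)]
    for i in range(1, L + 1):
        row, prev = E[i], E[i - 1]
        for j in range(1, n + 1):
            s = 1 if read[i - 1] == ref[j - 1] else -1
            row[j] = max(prev[j - 1], 0) + s
    for i in range(L - 1, -1, -1):
        row, nxt = F[i], F[i + 1]
        for j in range(n - 1, -1, -1):
            s = 1 if read[i] == ref[j] else -1
            row[j] = max(nxt[j + 1], 0) + s
    best = max(max(r) for r in E)
    for i in range(1, L):
        sufmax = [-1e18] * (n + 2)
        for j in range(n - 1, -1, -1):
            sufmax[j] = max(sufmax[j + 1], F[i][j])
        for j1 in range(1, n):
            c = E[i][j1] + sufmax[j1 + 1]
            if c > best:
                best = c
    return best


def planted_instance(rng):
    n = int(rng.integers(120, 301))
    ref = "".join(rng.choice(list("ACGT"), size=n))
    gstart = int(rng.integers(25, n - 28))
    glen = int(rng.integers(3, min(150, n - gstart - 25) + 1))
    deleted = ref[:gstart] + ref[gstart + glen :]
    rstart = int(rng.integers(0, max(1, gstart - 20)))
    rlen = int(rng.integers(40, 121))
    read = deleted[rstart : rstart + rlen]
    return ref, read


class TestOracleEquivalence:
    def test_planted_deletions_match_brute_force(self):
        rng = np.random.default_rng(20260102)
        checked = 0
        for _ in range(60):
            ref, read = planted_instance(rng)
            if len(read) < 40:
                continue
            aln = align_read(read, AmpliconReference("r", ref), strand_mode="forward")
            assert aln.score == pytest.approx(brute_force_best_score(read, ref))
            checked += 1
        assert checked >= 50

    def test_exact_window_is_single_full_length_segment(self, amplicon):
        read = amplicon.sequence[300:450]
        aln = align_read(read, amplicon, read_id="wt")
        assert aln.n_segments == 1
        assert aln.junction_size == 0
        assert aln.aligned_ratio == 1.0
        assert aln.identity == 1.0
        assert aln.ref_span == (300, 450)

    def test_excised_interval_recovered_exactly(self, amplicon):
        # read = reference with [800, 1700) excised, 75 bp flanks. Junction
        # microhomology permits equal-scoring placements shifted left; size
        # and score are invariant, the reported start is the leftmost.
        read = amplicon.sequence[725:800] + amplicon.sequence[1700:1775]
        aln = align_read(read, amplicon, read_id="del")
        assert aln.n_segments == 2
        assert aln.junction_size == 900
        assert aln.identity == 1.0
        assert aln.aligned_ratio == 1.0
        start, end = aln.junction
        assert end - start == 900
        h = 800 - start  # microhomology shift
        assert 0 <= h <= 5
        assert amplicon.sequence[start:800] == amplicon.sequence[end : end + h]

    def test_junction_insertion_still_called_spliced(self, amplicon):
        """A 5-base end-joining scar at the junction: under the default
        scoring it is optimal to absorb the scar as near-junction mismatches
        (cost < affine insertion penalty), so the junction shifts by at most
        the scar length and the read stays confidently spliced."""
        read = amplicon.sequence[725:800] + "TTAAC" + amplicon.sequence[1700:1770]
        aln = align_read(read, amplicon, read_id="ins")
        assert aln.n_segments == 2
        assert 895 <= aln.junction_size <= 905
        # never scores below the explicit insertion representation
        explicit = 145 - Scoring().insert_penalty(5)
        assert aln.score >= explicit
        assert classify_read(aln) == "spliced"

    def test_large_junction_insertion_reported_explicitly(self, amplicon):
        """A scar longer than the flank it could mimic is cheaper as an
        explicit insertion once absorbing it would cost more than the affine
        penalty; with a mismatch-heavy 9-mer the insertion wins."""
        # scar bases differ from the reference on both extension diagonals,
        # so absorbing any part of the scar costs 1/base (> 0.5/base affine
        # extension) and the explicit insertion is optimal
        scar = "".join(
            next(c for c in "ACGT" if c != amplicon.sequence[800 + i] and c != amplicon.sequence[1691 + i])
            for i in range(9)
        )
        read = amplicon.sequence[725:800] + scar + amplicon.sequence[1700:1770]
        aln = align_read(read, amplicon, read_id="bigins")
        assert aln.n_segments == 2
        assert aln.inserted_bases == 9
        assert aln.junction == (800, 1700)
        assert aln.aligned_ratio == 1.0
        assert classify_read(aln) == "spliced"

    def test_score_invariant_to_short_nonmatching_flanks(self, amplicon):
        core = amplicon.sequence[725:800] + amplicon.sequence[1700:1775]
        base = align_read(core, amplicon, read_id="c", strand_mode="forward")
        # flanks built to mismatch the reference bases they would extend into
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        lead = "".join(flip[b] for b in amplicon.sequence[715:725])
        tail = "".join(flip[b] for b in amplicon.sequence[1775:1785])
        decorated = lead + core + tail
        aln = align_read(decorated, amplicon, read_id="d", strand_mode="forward")
        assert aln.score == pytest.approx(base.score)
        assert aln.junction_size == base.junction_size

    def test_empty_read_raises(self, amplicon):
        with pytest.raises(ValueError, match="empty"):
            align_read("", amplicon)

    def test_random_reads_never_pass_filters(self, amplicon):
        rng = np.random.default_rng(5)
        params = FilterParams()
        aligner = SplitAligner(amplicon)
        for i in range(300):
            read = "".join(rng.choice(list("ACGT"), size=150))
            aln = aligner.align(read, f"g{i}")
            assert classify_read(aln, params) == "unmapped"


class TestStrand:
    def test_revcomp_read_same_junction_and_class(self, amplicon):
        read = amplicon.sequence[725:800] + amplicon.sequence[1700:1775]
        rc = str(Seq(read).reverse_complement())
        a_fwd = align_read(read, amplicon)
        a_rev = align_read(rc, amplicon)
        assert a_fwd.strand == "+" and a_rev.strand == "-"
        assert a_rev.junction == a_fwd.junction
        assert a_rev.score == pytest.approx(a_fwd.score)
        assert classify_read(a_rev) == classify_read(a_fwd) == "spliced"

    def test_plus_strand_preferred_on_tie(self):
        # palindromic read: identical alignment on both strands
        ref = AmpliconReference("p", "ACGT" * 30)
        read = "ACGT" * 15
        aln = align_read(read, ref)
        assert aln.strand == "+"


def _mk_aln(junction, ratio, identity=1.0, flank=60, read_len=150, inserted=0):
    """Construct a synthetic SplitAlignment with given summary statistics."""
    aligned_each = round((read_len - inserted) * ratio / 2)
    m1 = round(aligned_each * identity)
    segs = (
        Segment(0, aligned_each, 100, 100 + aligned_each, m1, aligned_each - m1),
        Segment(
            aligned_each + inserted,
            2 * aligned_each + inserted,
            100 + aligned_each + junction,
            100 + 2 * aligned_each + junction,
            m1,
            aligned_each - m1,
        ),
    )
    if flank is not None and aligned_each < flank:
        pass
    return SplitAlignment("x", read_len, "+", 0.0, segs, junction, inserted)


class TestClassifySemantics:
    def test_junction_of_two_is_wt_mapped(self, amplicon):
        """A 2-bp junction is not 'larger than 2 bp'."""
        read = amplicon.sequence[650:725] + amplicon.sequence[727:802]
        aln = align_read(read, amplicon)
        assert aln.junction_size == 2
        assert classify_read(aln) == "wt_mapped"

    def test_junction_of_three_is_spliced(self, amplicon):
        read = amplicon.sequence[650:725] + amplicon.sequence[728:803]
        aln = align_read(read, amplicon)
        assert aln.junction_size == 3
        assert classify_read(aln) == "spliced"

    def test_good_junction_low_ratio_unmapped(self):
        aln = _mk_aln(junction=100, ratio=0.90)
        assert aln.aligned_ratio < 0.95
        assert classify_read(aln) == "unmapped"

    def test_good_junction_good_ratio_spliced(self):
        aln = _mk_aln(junction=100, ratio=1.0)
        assert classify_read(aln) == "spliced"

    def test_short_flank_blocks_spliced(self, amplicon):
        read = amplicon.sequence[785:800] + amplicon.sequence[1700:1835]
        aln = align_read(read, amplicon)
        assert aln.n_segments == 2
        assert min(s.length for s in aln.segments) < 20
        assert classify_read(aln) != "spliced"

    @given(
        junction=st.integers(min_value=0, max_value=200),
        ratio=st.floats(min_value=0.5, max_value=1.0),
        identity=st.floats(min_value=0.8, max_value=1.0),
        dj=st.integers(min_value=0, max_value=10),
        dr=st.floats(min_value=0.0, max_value=0.04),
    )
    @settings(max_examples=300, deadline=None)
    def test_tightening_thresholds_never_creates_spliced(
        self, junction, ratio, identity, dj, dr
    ):
        """Monotonicity: raising min_junction / min_aligned_ratio can only
        move reads out of the spliced class, never into it."""
        aln = _mk_aln(junction=max(junction, 1), ratio=ratio, identity=identity)
        loose = FilterParams(min_junction=2, min_aligned_ratio=0.95)
        tight = FilterParams(
            min_junction=2 + dj, min_aligned_ratio=min(0.95 + dr, 1.0)
        )
        if classify_read(aln, loose) != "spliced":
            assert classify_read(aln, tight) != "spliced"

    def test_bad_filter_params_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(min_aligned_ratio=1.5)
        with pytest.raises(ValueError):
            FilterParams(min_junction=-1)
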