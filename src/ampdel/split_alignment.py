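"""Split-read alignment of amplicon reads: at most one internal deletion.

Each read is explained either by a single gapless local segment on the
amplicon (wild-type read) or by a chain of two collinear gapless segments
separated by a free reference gap — the deletion junction — optionally with a
few unaligned read bases inserted at the junction (end-joining scars).
Scoring is match +1 / mismatch -1; the junction itself is free; inserted
junction bases pay an affine penalty. Within-segment indels are not modeled:
an amplicon read is a window of the reference with at most one excision, so
the optimum over all (deletion start, length) placements with gapless flanks
is exactly the quantity of interest, and it is found exactly.

Search strategy: for every candidate diagonal (ref_pos - read_pos) the best
segment ending / starting at every read position is computed by cumulative-sum
prefix/suffix maxima; chains combine any earlier diagonal with any later one
via a running maximum, so the optimum over all two-segment placements is exact
for the diagonals considered. Small problems enumerate *all* diagonals
(provably exact); amplicon-scale references use exact k-mer seeding to
restrict candidates, which finds every diagonal supported by a 13-mer exact
match. Both orientations are attempted; the best score wins, ties prefer the
forward strand.

The classifier applies the spliced-read extraction rule: a read is *spliced*
when its junction is larger than 2 bp (strict) and the rest-of-read alignment
ratio is above 95% (strict), with an identity floor and a minimum flank length
on each side of the junction guarding against spurious chains of random
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .amplicon_model import AmpliconReference

__all__ = [
    "Scoring",
    "FilterParams",
    "Segment",
    "SplitAlignment",
    "SplitAligner",
    "align_read",
    "classify_read",
    "align_and_classify",
    "read_fastx",
    "write_alignment_tsv",
    "write_sam",
]

_NEG = -1.0e18

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANTGCAN"):
    _COMPLEMENT[_a] = _b


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring. Penalties are positive numbers (subtracted).

    ``gap_open``/``gap_extend`` price read bases inserted at the junction:
    cost = open + extend*(k-1) for k >= 1 inserted bases. ``max_insert`` caps
    the inserted-base run considered at a junction.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 4.0
    gap_extend: float = 0.5
    max_insert: int = 10

    def insert_penalty(self, k: int) -> float:
        return 0.0 if k == 0 else self.gap_open + self.gap_extend * (k - 1)


@dataclass(frozen=True)
class FilterParams:
    """Spliced-read extraction thresholds.

    ``min_junction`` and ``min_aligned_ratio`` are strict lower bounds
    (junction must be *larger than* 2 bp; ratio *above* 95%). ``min_identity``
    and ``min_flank`` are additional guards against random chaining.
    """

    min_junction: int = 2
    min_aligned_ratio: float = 0.95
    min_identity: float = 0.95
    min_flank: int = 20

    def __post_init__(self) -> None:
        if self.min_junction < 0 or self.min_flank < 0:
            raise ValueError("min_junction and min_flank must be >= 0")
        for v in (self.min_aligned_ratio, self.min_identity):
            if not (0.0 <= v <= 1.0):
                raise ValueError("ratio thresholds must be in [0, 1]")


@dataclass(frozen=True)
class Segment:
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    matches: int
    mismatches: int

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class SplitAlignment:
    """Best alignment of one read: zero (unmapped), one, or two segments."""

    read_id: str
    read_length: int
    strand: str  # "+" | "-"
    score: float
    segments: tuple[Segment, ...]
    junction_size: int  # reference gap between segments; 0 if <2 segments
    inserted_bases: int  # read bases between segments

    def __post_init__(self) -> None:
        if len(self.segments) == 2 and self.junction_size < 1:
            raise ValueError("two segments require a positive reference junction")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def aligned_bases(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def matches(self) -> int:
        return sum(s.matches for s in self.segments)

    @property
    def aligned_ratio(self) -> float:
        """Aligned fraction of the read outside the junction insertion."""
        denom = self.read_length - self.inserted_bases
        return self.aligned_bases / denom if denom > 0 else 0.0

    @property
    def identity(self) -> float:
        ab = self.aligned_bases
        return self.matches / ab if ab > 0 else 0.0

    @property
    def junction(self) -> tuple[int, int] | None:
        """Reference interval removed from the read, 0-based half-open."""
        if len(self.segments) != 2:
            return None
        return (self.segments[0].ref_end, self.segments[1].ref_start)

    @property
    def ref_span(self) -> tuple[int, int] | None:
        if not self.segments:
            return None
        return (self.segments[0].ref_start, self.segments[-1].ref_end)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


class SplitAligner:
    """Reusable aligner for one amplicon reference.

    Builds a k-mer position index once; per read, candidate diagonals come
    from exact seed hits unless the problem is small enough to enumerate every
    diagonal.
    """

    def __init__(
        self,
        reference: AmpliconReference,
        scoring: Scoring | None = None,
        seed_k: int = 13,
        seed_stride: int = 4,
        exhaustive_limit: int = 150_000,
        max_diagonals: int = 50,
    ) -> None:
        if len(reference.sequence) == 0:
            raise ValueError("empty reference")
        self.reference = reference
        self.scoring = scoring or Scoring()
        self.seed_k = seed_k
        self.seed_stride = seed_stride
        self.exhaustive_limit = exhaustive_limit
        self.max_diagonals = max_diagonals
        self.ref_arr = _encode(reference.sequence)
        self._index: dict[bytes, list[int]] | None = None

    # -- seeding ---------------------------------------------------------

    def _kmer_index(self) -> dict[bytes, list[int]]:
        if self._index is None:
            k = self.seed_k
            seq = self.ref_arr.tobytes()
            index: dict[bytes, list[int]] = {}
            for p in range(len(seq) - k + 1):
                index.setdefault(seq[p : p + k], []).append(p)
            self._index = index
        return self._index

    def _candidate_diagonals(self, read: np.ndarray) -> list[int]:
        k = self.seed_k
        L = read.size
        if L < k:
            return []
        index = self._kmer_index()
        seq = read.tobytes()
        starts = list(range(0, L - k + 1, self.seed_stride))
        if starts[-1] != L - k:
            starts.append(L - k)
        support: dict[int, int] = {}
        for p in starts:
            for rp in index.get(seq[p : p + k], ()):
                d = rp - p
                support[d] = support.get(d, 0) + 1
        if len(support) > self.max_diagonals:
            keep = sorted(support, key=lambda d: -support[d])[: self.max_diagonals]
            return sorted(keep)
        return sorted(support)

    # -- core ------------------------------------------------------------

    def _align_strand(self, read: np.ndarray) -> dict | None:
        """Best single-segment and two-segment placement for one orientation.

        Returns traceback info, or None when nothing aligns with positive
        score.
        """
        L = read.size
        n = self.ref_arr.size
        if L * n <= self.exhaustive_limit:
            diags = list(range(-(L - 1), n))
        else:
            diags = self._candidate_diagonals(read)
        if not diags:
            return None

        sc = self.scoring
        D = len(diags)
        PE = np.full((D, L + 1), _NEG)  # best segment ending at read pos i
        PS = np.full((D, L + 1), _NEG)  # best segment starting at read pos k
        cums: list[tuple[int, np.ndarray] | None] = [None] * D
        S = self.ref_arr
        for idx, d in enumerate(diags):
            i0 = max(0, -d)
            i1 = min(L, n - d)
            m = i1 - i0
            if m <= 0:
                continue
            v = np.where(read[i0:i1] == S[i0 + d : i1 + d], sc.match, sc.mismatch)
            C = np.empty(m + 1)
            C[0] = 0.0
            np.cumsum(v, out=C[1:])
            runmin = np.minimum.accumulate(C)
            PE[idx, i0 + 1 : i1 + 1] = C[1:] - runmin[:-1]
            runmax = np.maximum.accumulate(C[::-1])[::-1]
            PS[idx, i0:i1] = runmax[1:] - C[:-1]
            cums[idx] = (i0, C)

        best_single = float(PE.max())

        best_chain = _NEG
        chain_info = None
        if D >= 2:
            # Q[idx, i]: best seg2 starting at read pos i+delta on this
            # diagonal, net of the insertion penalty for delta skipped bases.
            Q = PS.copy()
            for delta in range(1, sc.max_insert + 1):
                if delta > L:
                    break
                pen = sc.insert_penalty(delta)
                np.maximum(Q[:, : L + 1 - delta], PS[:, delta:] - pen, out=Q[:, : L + 1 - delta])
            cm = np.maximum.accumulate(PE, axis=0)
            chain = cm[:-1, :] + Q[1:, :]
            best_chain = float(chain.max())
            if best_chain > 0:
                cells = np.argwhere(chain >= best_chain - 1e-9)[:20]
                chain_info = (chain, cm, PE, PS, Q, cells)

        if max(best_single, best_chain) <= 0:
            return None
        return {
            "diags": diags,
            "cums": cums,
            "PE": PE,
            "best_single": best_single,
            "best_chain": best_chain,
            "chain_info": chain_info,
            "L": L,
        }

    def _traceback_segment_end(self, idx: int, i: int, cums, diags, read) -> Segment:
        """Segment ending exactly at read pos i on diagonal diags[idx]."""
        i0, C = cums[idx]
        t = i - i0
        a = i0 + int(np.argmin(C[:t]))  # earliest minimum -> longest segment
        d = diags[idx]
        return self._make_segment(a, i, d, read)

    def _traceback_segment_start(self, idx: int, k: int, cums, diags, read) -> Segment:
        """Segment starting exactly at read pos k on diagonal diags[idx]."""
        i0, C = cums[idx]
        t = k - i0
        rest = C[t + 1 :]
        b = k + 1 + (rest.size - 1 - int(np.argmax(rest[::-1])))  # latest max
        d = diags[idx]
        return self._make_segment(k, b, d, read)

    def _make_segment(self, a: int, b: int, d: int, read: np.ndarray) -> Segment:
        matches = int(np.count_nonzero(read[a:b] == self.ref_arr[a + d : b + d]))
        return Segment(a, b, a + d, b + d, matches, (b - a) - matches)

    def _resolve(self, read_id: str, read: np.ndarray, res: dict, strand: str) -> SplitAlignment:
        diags, cums, PE = res["diags"], res["cums"], res["PE"]
        L = res["L"]
        sc = self.scoring

        single_aln = None
        if res["best_single"] > 0:
            j, i = np.unravel_index(int(np.argmax(PE)), PE.shape)
            seg = self._traceback_segment_end(int(j), int(i), cums, diags, read)
            single_aln = SplitAlignment(
                read_id, L, strand, res["best_single"], (seg,), 0, 0
            )

        chain_aln = None
        if res["chain_info"] is not None:
            chain, cm, PE_, PS, Q, cells = res["chain_info"]
            best: tuple | None = None
            for j, i in cells:
                j, i = int(j), int(i)
                j2 = j + 1  # diagonal index of second segment
                # largest earlier diagonal achieving the running max -> the
                # smallest junction among score ties
                col = PE_[: j2, i]
                target = cm[j, i]
                j1 = int(np.max(np.flatnonzero(col >= target - 1e-9)))
                # insertion length attaining Q
                qv = Q[j2, i]
                delta = 0
                for dd in range(0, sc.max_insert + 1):
                    if i + dd <= L and PS[j2, i + dd] - sc.insert_penalty(dd) >= qv - 1e-9:
                        delta = dd
                        break
                junction = delta + diags[j2] - diags[j1]
                jstart = i + diags[j1]
                key = (-junction, -jstart)
                if best is None or key > best[0]:
                    best = (key, j1, j2, i, delta)
            _, j1, j2, i, delta = best
            seg1 = self._traceback_segment_end(j1, i, cums, diags, read)
            seg2 = self._traceback_segment_start(j2, i + delta, cums, diags, read)
            junction = seg2.ref_start - seg1.ref_end
            chain_aln = SplitAlignment(
                read_id, L, strand, res["best_chain"], (seg1, seg2), junction, delta
            )

        if chain_aln is None:
            return single_aln
        if single_aln is None:
            return chain_aln
        # score tie prefers the single segment (smaller junction)
        return chain_aln if chain_aln.score > single_aln.score + 1e-9 else single_aln

    def align(
        self, read: str, read_id: str = "read", strand_mode: str = "auto"
    ) -> SplitAlignment:
        """Align one read; returns an empty (unmapped) alignment when nothing
        scores positively.

        ``strand_mode``: "both" tries both orientations and keeps the higher
        score (ties prefer +); "auto" skips the reverse orientation when the
        forward alignment already passes the default filters; "forward" never
        tries the reverse orientation.
        """
        if strand_mode not in ("auto", "both", "forward"):
            raise ValueError(f"unknown strand_mode {strand_mode!r}")
        if len(read) == 0:
            raise ValueError("empty read")
        arr = _encode(read)
        fwd = self._align_strand(arr)
        fwd_aln = self._resolve(read_id, arr, fwd, "+") if fwd else None

        need_rev = strand_mode == "both"
        if strand_mode == "auto":
            need_rev = not (
                fwd_aln is not None
                and fwd_aln.aligned_ratio > 0.95
                and fwd_aln.identity >= 0.95
            )
        rev_aln = None
        if need_rev:
            rarr = _revcomp_arr(arr)
            rev = self._align_strand(rarr)
            rev_aln = self._resolve(read_id, rarr, rev, "-") if rev else None

        cand = [a for a in (fwd_aln, rev_aln) if a is not None]
        if not cand:
            return SplitAlignment(read_id, len(read), "+", 0.0, (), 0, 0)
        if len(cand) == 2 and rev_aln.score > fwd_aln.score + 1e-9:
            return rev_aln
        return cand[0]


@lru_cache(maxsize=8)
def _cached_aligner(reference: AmpliconReference, scoring: Scoring | None) -> SplitAligner:
    return SplitAligner(reference, scoring)


def align_read(
    read: str,
    reference: AmpliconReference,
    scoring: Scoring | None = None,
    read_id: str = "read",
    strand_mode: str = "both",
) -> SplitAlignment:
    """Convenience wrapper: align one read against an amplicon reference."""
    return _cached_aligner(reference, scoring).align(read, read_id, strand_mode)


def classify_read(aln: SplitAlignment, params: FilterParams | None = None) -> str:
    """Classify an alignment as wt_mapped / spliced / unmapped.

    Spliced requires a junction strictly larger than ``min_junction`` bp, an
    aligned ratio strictly above ``min_aligned_ratio``, identity at least
    ``min_identity`` and both flanks at least ``min_flank`` bp. A read that
    fails the spliced test but aligns well overall is wild-type-mapped;
    anything else is unmapped.
    """
    params = params or FilterParams()
    well_aligned = (
        aln.n_segments > 0
        and aln.aligned_ratio > params.min_aligned_ratio
        and aln.identity >= params.min_identity
    )
    if (
        well_aligned
        and aln.n_segments == 2
        and aln.junction_size > params.min_junction
        and all(s.length >= params.min_flank for s in aln.segments)
    ):
        return "spliced"
    if well_aligned:
        return "wt_mapped"
    return "unmapped"


def align_and_classify(
    reads: Iterable[tuple[str, str]],
    reference: AmpliconReference,
    params: FilterParams | None = None,
    scoring: Scoring | None = None,
    strand_mode: str = "auto",
) -> pd.DataFrame:
    """Align and classify (read_id, sequence) pairs; one row per read."""
    params = params or FilterParams()
    aligner = SplitAligner(reference, scoring)
    rows = []
    for read_id, seq in reads:
        aln = aligner.align(seq, read_id, strand_mode)
        cls = classify_read(aln, params)
        span = aln.ref_span
        junc = aln.junction
        rows.append(
            {
                "read_id": read_id,
                "class": cls,
                "strand": aln.strand,
                "score": aln.score,
                "n_segments": aln.n_segments,
                "ref_start": span[0] if span else pd.NA,
                "ref_end": span[1] if span else pd.NA,
                "junction_start": junc[0] if junc else pd.NA,
                "junction_end": junc[1] if junc else pd.NA,
                "junction_size": aln.junction_size,
                "inserted_bases": aln.inserted_bases,
                "aligned_ratio": aln.aligned_ratio,
                "identity": aln.identity,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("ref_start", "ref_end", "junction_start", "junction_end"):
        df[col] = df[col].astype("Int64")
    return df


def read_fastx(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTQ or FASTA (by extension)."""
    from Bio import SeqIO

    path = str(path)
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, fmt)]


def write_alignment_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_sam(
    alignments: Sequence[SplitAlignment],
    reference: AmpliconReference,
    reads: dict[str, str],
    path: str | Path,
) -> None:
    """Write alignments as SAM, the junction encoded as a CIGAR D operation."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference.name, "LN": len(reference.sequence)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aln.read_id
            seq = reads.get(aln.read_id, "")
            if aln.n_segments == 0:
                a.is_unmapped = True
                a.query_sequence = seq or None
                fh.write(a)
                continue
            if aln.strand == "-":
                a.is_reverse = True
                from Bio.Seq import Seq

                seq = str(Seq(seq).reverse_complement())
            segs = aln.segments
            cigar = []
            lead = segs[0].read_start
            if lead:
                cigar.append((4, lead))  # S
            cigar.append((0, segs[0].length))  # M
            if len(segs) == 2:
                if aln.inserted_bases:
                    cigar.append((1, aln.inserted_bases))  # I
                cigar.append((2, aln.junction_size))  # D
                cigar.append((0, segs[1].length))
            tail = aln.read_length - segs[-1].read_end
            if tail:
                cigar.append((4, tail))
            a.reference_id = 0
            a.reference_start = segs[0].ref_start
            a.cigartuples = cigar
            a.mapping_quality = 60
            a.query_sequence = seq or None
            fh.write(a)
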