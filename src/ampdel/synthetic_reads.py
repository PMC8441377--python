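"""Simulation of pooled dual-guide CRISPR amplicon libraries with ground truth.

Emulates a MiSeq amplicon library from an edited cell pool: each read starts a
fixed offset (default 50 bp) upstream of an upstream-guide cut site, mirroring
the pooled sequencing-primer design, and is either a wild-type window of the
amplicon, a window spanning a deletion junction between one guide pair's cut
sites (with per-breakpoint jitter and optional small junction insertions), or
unmappable garbage. Substitution sequencing error is applied uniformly.

The generator is deterministic given its seed and emits a per-read truth
table so downstream estimates can be scored against known fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .amplicon_model import AmpliconReference, GuidePair

__all__ = [
    "TruthConfig",
    "SimulatedRead",
    "simulate_library",
    "truth_efficiencies",
    "write_fastq",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_Q30_CHAR = chr(30 + 33)


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth composition of a simulated library.

    Fractions are molecule-class probabilities: ``wt_fraction`` plus the sum of
    ``pair_fractions`` must not exceed 1; the remainder is garbage (unmappable)
    reads. ``jitter_sd`` is the per-breakpoint Gaussian SD in bp (rounded to
    integers), emulating end resection around the Cas9 cut sites.
    """

    reference: AmpliconReference
    pairs: tuple[GuidePair, ...]
    pair_fractions: dict[str, float]
    wt_fraction: float
    n_reads: int
    seed: int
    jitter_sd: float = 5.0
    insert_junction_prob: float = 0.1
    subst_error_rate: float = 0.003
    read_length: int = 150
    read_anchor_offset: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        known = {p.pair_id for p in self.pairs}
        unknown = set(self.pair_fractions) - known
        if unknown:
            raise ValueError(f"pair_fractions reference unknown pairs: {sorted(unknown)}")
        fracs = list(self.pair_fractions.values()) + [self.wt_fraction]
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be >= 0")
        total = self.wt_fraction + sum(self.pair_fractions.values())
        if total > 1 + 1e-9:
            raise ValueError(f"wt_fraction + pair fractions = {total:.4f} > 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.read_length < 2:
            raise ValueError("read_length too small")
        if not (0 <= self.subst_error_rate < 1):
            raise ValueError("subst_error_rate must be in [0, 1)")
        if not (0 <= self.insert_junction_prob <= 1):
            raise ValueError("insert_junction_prob must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    @property
    def garbage_fraction(self) -> float:
        return max(0.0, 1.0 - self.wt_fraction - sum(self.pair_fractions.values()))


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    description: str = ""


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _apply_substitutions(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or arr.size == 0:
        return arr
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n == 0:
        return arr
    arr = arr.copy()
    # substitute with one of the three *other* bases
    idx = np.flatnonzero(hit)
    cur = arr[idx]
    # map current base to index 0..3; unknown bases treated as A
    base_idx = np.zeros(n, dtype=np.int64)
    for i, b in enumerate(_BASES):
        base_idx[cur == b] = i
    shift = rng.integers(1, 4, size=n)
    arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr


def simulate_library(config: TruthConfig) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate one library; returns (reads, truth table).

    Deletion reads are built by excising the jittered inter-cut-site interval
    from the reference, optionally inserting 1-5 random bases at the junction,
    applying substitution error, then windowing to ``read_length`` starting
    ``read_anchor_offset`` bp upstream of the (nominal) US cut site, clamped to
    the molecule's bounds. Truth breakpoints record the realized (jittered)
    excised interval on the amplicon.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.reference
    ref_arr = _encode(ref.sequence)
    n = config.n_reads
    L = config.read_length
    offset = config.read_anchor_offset

    pair_ids = [p.pair_id for p in config.pairs]
    by_id = {p.pair_id: p for p in config.pairs}
    active = [pid for pid in pair_ids if config.pair_fractions.get(pid, 0.0) > 0]
    probs = [config.wt_fraction] + [config.pair_fractions[pid] for pid in active]
    probs.append(config.garbage_fraction)
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    classes = rng.choice(len(probs), size=n, p=probs)

    us_anchor_cuts = sorted({p.us_guide.cut_site for p in config.pairs})

    reads: list[SimulatedRead] = []
    truth_rows = []
    desc = f"seed={config.seed}"
    for i in range(n):
        rid = f"r{i:06d}"
        c = classes[i]
        if c == 0:  # wild type
            anchor = us_anchor_cuts[rng.integers(len(us_anchor_cuts))] if us_anchor_cuts else offset
            start = max(0, anchor - offset)
            window = ref_arr[start : start + L]
            seq = _apply_substitutions(window, config.subst_error_rate, rng)
            reads.append(SimulatedRead(rid, _decode(seq), desc))
            truth_rows.append((rid, "wt", None, None, None, None))
        elif c <= len(active):  # deletion for pair active[c-1]
            pid = active[c - 1]
            pair = by_id[pid]
            while True:
                js = pair.us_guide.cut_site
                je = pair.ds_guide.cut_site
                if config.jitter_sd > 0:
                    js += int(round(rng.normal(0, config.jitter_sd)))
                    je += int(round(rng.normal(0, config.jitter_sd)))
                js = max(0, min(js, len(ref_arr)))
                je = max(0, min(je, len(ref_arr)))
                if je > js:
                    break
            parts = [ref_arr[:js]]
            ins = 0
            if config.insert_junction_prob > 0 and rng.random() < config.insert_junction_prob:
                ins = int(rng.integers(1, 6))
                parts.append(_BASES[rng.integers(0, 4, size=ins)])
            parts.append(ref_arr[je:])
            molecule = np.concatenate(parts)
            start = max(0, pair.us_guide.cut_site - offset)
            window = molecule[start : start + L]
            seq = _apply_substitutions(window, config.subst_error_rate, rng)
            reads.append(SimulatedRead(rid, _decode(seq), desc))
            truth_rows.append((rid, "deletion", pid, js, je, je - js))
        else:  # garbage
            seq = _BASES[rng.integers(0, 4, size=L)]
            reads.append(SimulatedRead(rid, _decode(seq), desc))
            truth_rows.append((rid, "garbage", None, None, None, None))

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "class", "pair_id", "true_start", "true_end", "true_deletion_size"],
    )
    return reads, truth


def truth_efficiencies(truth: pd.DataFrame) -> dict[str, float]:
    """Ground-truth per-pair deletion fractions among non-garbage reads."""
    if len(truth) == 0:
        raise ValueError("empty truth table")
    mapped = truth[truth["class"] != "garbage"]
    if len(mapped) == 0:
        raise ValueError("no mapped-class reads")
    out: dict[str, float] = {}
    dels = mapped[mapped["class"] == "deletion"]
    for pid, grp in dels.groupby("pair_id"):
        out[str(pid)] = len(grp) / len(mapped)
    return out


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Write 4-line FASTQ with constant Q30 qualities."""
    with open(path, "w") as fh:
        for r in reads:
            header = f"@{r.read_id}"
            if r.description:
                header += f" {r.description}"
            fh.write(f"{header}\n{r.sequence}\n+\n{_Q30_CHAR * len(r.sequence)}\n")


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
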