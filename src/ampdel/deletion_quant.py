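"""Assignment of spliced reads to sgRNA pairs and per-library efficiencies.

A spliced read's junction (breakpoint pair) is assigned to the guide pair
whose two cut sites both lie within a fixed window (default 60 bp) of the
respective breakpoints; among several candidates the closest by summed
breakpoint distance wins, exact ties are reported as ambiguous rather than
split. Editing efficiency of a pair in a library is the fraction of mapped
reads (wild-type + spliced) whose junction is assigned to that pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .amplicon_model import GuidePair

__all__ = [
    "DeletionCall",
    "LibraryQuant",
    "assign_call",
    "make_calls",
    "quantify_library",
    "aggregate_replicates",
    "deletion_spectrum",
]

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"
DEFAULT_WINDOW = 60


@dataclass(frozen=True)
class DeletionCall:
    """One filtered spliced read: its breakpoints and pair assignment."""

    read_id: str
    start: int
    end: int
    assigned_pair: str  # pair id, "ambiguous" or "unassigned"
    distance_us: int | None = None
    distance_ds: int | None = None

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class LibraryQuant:
    """Per-library read accounting and per-pair efficiencies."""

    library_id: str
    total_reads: int
    mapped_reads: int
    wt_reads: int
    spliced_reads: int
    unassigned_spliced: int
    ambiguous_spliced: int
    pair_counts: dict[str, int]
    efficiencies: dict[str, float]
    efficiency_ci: dict[str, tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "library_id": self.library_id,
                "pair_id": pid,
                "spliced_count": self.pair_counts[pid],
                "mapped_reads": self.mapped_reads,
                "efficiency": self.efficiencies[pid],
                "ci_low": self.efficiency_ci[pid][0],
                "ci_high": self.efficiency_ci[pid][1],
            }
            for pid in self.pair_counts
        ]
        return pd.DataFrame(rows)


def assign_call(
    breakpoints: tuple[int, int],
    pairs: Sequence[GuidePair],
    window: int = DEFAULT_WINDOW,
    mode: str = "two_sided",
) -> tuple[str, int | None, int | None]:
    """Assign one junction to a guide pair.

    two_sided (default): both breakpoints must fall within ``window`` bp of
    the candidate pair's respective cut sites. one_sided: either breakpoint
    suffices (candidates ranked by the same summed distance). Returns
    (pair_id | "ambiguous" | "unassigned", distance_us, distance_ds).
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    if window < 0:
        raise ValueError("window must be >= 0")
    if mode not in ("two_sided", "one_sided"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    start, end = breakpoints
    candidates = []
    for p in pairs:
        du = abs(start - p.us_guide.cut_site)
        dd = abs(end - p.ds_guide.cut_site)
        ok = (du <= window and dd <= window) if mode == "two_sided" else (
            du <= window or dd <= window
        )
        if ok:
            candidates.append((du + dd, du, dd, p.pair_id))
    if not candidates:
        return (UNASSIGNED, None, None)
    candidates.sort(key=lambda c: c[0])
    best = candidates[0]
    if len(candidates) > 1 and candidates[1][0] == best[0]:
        return (AMBIGUOUS, None, None)
    return (best[3], best[1], best[2])


def make_calls(
    aligned: pd.DataFrame,
    pairs: Sequence[GuidePair],
    window: int = DEFAULT_WINDOW,
    mode: str = "two_sided",
) -> list[DeletionCall]:
    """Turn the spliced rows of an alignment table into assigned calls."""
    spliced = aligned[aligned["class"] == "spliced"]
    calls = []
    for _, row in spliced.iterrows():
        bp = (int(row["junction_start"]), int(row["junction_end"]))
        pid, du, dd = assign_call(bp, pairs, window, mode)
        calls.append(DeletionCall(str(row["read_id"]), bp[0], bp[1], pid, du, dd))
    return calls


def quantify_library(
    aligned: pd.DataFrame,
    pairs: Sequence[GuidePair],
    window: int = DEFAULT_WINDOW,
    library_id: str = "library",
    mode: str = "two_sided",
) -> LibraryQuant:
    """Per-pair editing efficiencies for one library.

    Efficiency = spliced reads assigned to the pair / total mapped reads
    (wild-type-mapped + spliced; unmapped reads are excluded from the
    denominator). Ambiguous junctions count as spliced but enter no pair's
    numerator. A Wilson 95% interval accompanies each point estimate.
    """
    counts = aligned["class"].value_counts()
    wt = int(counts.get("wt_mapped", 0))
    spliced = int(counts.get("spliced", 0))
    unmapped = int(counts.get("unmapped", 0))
    mapped = wt + spliced
    if mapped == 0:
        raise ValueError("empty library: no mapped reads")

    calls = make_calls(aligned, pairs, window, mode)
    pair_counts = {p.pair_id: 0 for p in pairs}
    ambiguous = 0
    unassigned = 0
    for c in calls:
        if c.assigned_pair == AMBIGUOUS:
            ambiguous += 1
        elif c.assigned_pair == UNASSIGNED:
            unassigned += 1
        else:
            pair_counts[c.assigned_pair] += 1

    eff = {pid: k / mapped for pid, k in pair_counts.items()}
    ci = {
        pid: tuple(proportion_confint(k, mapped, alpha=0.05, method="wilson"))
        for pid, k in pair_counts.items()
    }
    return LibraryQuant(
        library_id=library_id,
        total_reads=len(aligned),
        mapped_reads=mapped,
        wt_reads=wt,
        spliced_reads=spliced,
        unassigned_spliced=unassigned,
        ambiguous_spliced=ambiguous,
        pair_counts=pair_counts,
        efficiencies=eff,
        efficiency_ci=ci,
    )


def aggregate_replicates(quants: Sequence[LibraryQuant]) -> pd.DataFrame:
    """Mean and sample SD of per-pair efficiencies across replicate libraries.

    A pair absent from some libraries is treated as efficiency 0 there (with a
    warning); a single library yields sd 0 with a warning.
    """
    if not quants:
        raise ValueError("need at least one library")
    all_pairs = sorted({pid for q in quants for pid in q.efficiencies})
    rows = []
    for pid in all_pairs:
        vals = []
        for q in quants:
            if pid not in q.efficiencies:
                logger.warning(
                    "pair %s missing from library %s; treated as 0", pid, q.library_id
                )
                vals.append(0.0)
            else:
                vals.append(q.efficiencies[pid])
        vals = np.asarray(vals)
        if len(vals) == 1:
            logger.warning("single library: sd undefined for %s, reported as 0", pid)
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        rows.append(
            {"pair_id": pid, "mean_efficiency": float(np.mean(vals)), "sd": sd, "n": len(vals)}
        )
    return pd.DataFrame(rows)


def deletion_spectrum(
    calls: Sequence[DeletionCall],
    pairs: Sequence[GuidePair] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unique breakpoint pairs with counts, plus per-pair breakpoint dispersion.

    The spectrum table holds (start, end, size, count) sorted by count
    descending; the dispersion table holds, per assigned pair, the SD of each
    breakpoint around the pair's cut site — the quantity behind horizontal
    cut-site error bars on a deletion map.
    """
    if not calls:
        raise ValueError("no deletion calls")
    df = pd.DataFrame(
        {
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "pair_id": [c.assigned_pair for c in calls],
        }
    )
    spectrum = (
        df.groupby(["start", "end"])
        .size()
        .reset_index(name="count")
        .assign(size=lambda t: t["end"] - t["start"])
        .sort_values(["count", "start"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)[["start", "end", "size", "count"]]
    )
    disp_rows = []
    assigned = df[~df["pair_id"].isin([AMBIGUOUS, UNASSIGNED])]
    cut_by_pair = {p.pair_id: (p.us_guide.cut_site, p.ds_guide.cut_site) for p in pairs} if pairs else {}
    for pid, grp in assigned.groupby("pair_id"):
        if pid in cut_by_pair:
            us_cut, ds_cut = cut_by_pair[pid]
            start_dev = grp["start"] - us_cut
            end_dev = grp["end"] - ds_cut
        else:
            start_dev = grp["start"] - grp["start"].mean()
            end_dev = grp["end"] - grp["end"].mean()
        disp_rows.append(
            {
                "pair_id": pid,
                "n": len(grp),
                "start_sd": float(np.std(start_dev, ddof=1)) if len(grp) > 1 else 0.0,
                "end_sd": float(np.std(end_dev, ddof=1)) if len(grp) > 1 else 0.0,
                "mean_size": float((grp["end"] - grp["start"]).mean()),
            }
        )
    dispersion = pd.DataFrame(disp_rows)
    return spectrum, dispersion
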