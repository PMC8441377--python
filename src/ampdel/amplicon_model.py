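"""Domain model of the amplicon, guides, primers and deletion size arithmetic.

A dual-guide CRISPR deletion experiment amplifies a single genomic region
(the *amplicon*) spanning a set of paired sgRNA cut sites. One upstream (US)
and one downstream (DS) guide form a :class:`GuidePair`; Cas9 cutting at both
sites and end-joining excises the intervening interval, so the expected
deletion size is simply the distance between the two blunt cut sites and the
expected PCR band size is the wild-type product size minus the deletion size.

All coordinates are 0-based half-open and amplicon-local. An optional
``genome_offset`` allows translating to genome coordinates for reporting, but
no computation uses it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AmpliconReference",
    "Guide",
    "GuidePair",
    "GuideNotFoundError",
    "AmbiguousGuideError",
    "NoPamError",
    "cut_site_from_protospacer",
    "predicted_product_size",
    "expected_deletion_size",
    "make_pairs",
    "load_reference_fasta",
    "load_guides_tsv",
    "design_summary",
]

_DNA_ALPHABET = set("ACGTN")

# SpCas9 creates a blunt double-strand break between the 17th and 18th base of
# a 20-nt protospacer, i.e. 3 bp 5' of the NGG PAM on the protospacer strand.
CAS9_CUT_OFFSET = 3


class GuideNotFoundError(ValueError):
    """Protospacer does not occur in the reference on either strand."""


class AmbiguousGuideError(ValueError):
    """Protospacer occurs more than once (counting both strands)."""


class NoPamError(ValueError):
    """Protospacer matches but no adjacent NGG PAM exists."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class AmpliconReference:
    """The wild-type PCR amplicon with primer and optional SNP annotation.

    ``pcr_primer_fwd_start``/``pcr_primer_rev_end`` delimit the outer PCR
    product; their difference is the WT band size observed on a gel.
    """

    name: str
    sequence: str
    pcr_primer_fwd_start: int = 0
    pcr_primer_rev_end: int | None = None
    snp_positions: tuple[int, ...] = ()
    genome_offset: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError("amplicon sequence must be nonempty")
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        if self.pcr_primer_rev_end is None:
            object.__setattr__(self, "pcr_primer_rev_end", len(seq))
        object.__setattr__(self, "snp_positions", tuple(self.snp_positions))
        if not (0 <= self.pcr_primer_fwd_start < len(seq)):
            raise ValueError("pcr_primer_fwd_start outside amplicon")
        if not (0 < self.pcr_primer_rev_end <= len(seq)):
            raise ValueError("pcr_primer_rev_end outside amplicon")
        if self.wt_product_size <= 0:
            raise ValueError("WT product size must be positive")
        for p in self.snp_positions:
            if not (0 <= p < len(seq)):
                raise ValueError(f"snp position {p} outside amplicon")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def wt_product_size(self) -> int:
        return self.pcr_primer_rev_end - self.pcr_primer_fwd_start


@dataclass(frozen=True)
class Guide:
    """One sgRNA: its side relative to the target region and its cut site.

    ``cut_site`` is an inter-base coordinate (0-based): the blunt cut falls
    between ``sequence[cut_site-1]`` and ``sequence[cut_site]``. A guide may
    be specified directly by coordinate or derived from its protospacer via
    :func:`cut_site_from_protospacer`.
    """

    id: str
    side: str  # "upstream" | "downstream"
    cut_site: int
    protospacer: str | None = None
    pam_strand: str | None = None  # "+" | "-"

    def __post_init__(self) -> None:
        if self.side not in ("upstream", "downstream"):
            raise ValueError(f"side must be upstream/downstream, got {self.side!r}")
        if self.pam_strand not in (None, "+", "-"):
            raise ValueError(f"strand must be +/-, got {self.pam_strand!r}")
        if self.cut_site < 0:
            raise ValueError("cut_site must be >= 0")
        if self.protospacer is not None:
            ps = self.protospacer.upper()
            object.__setattr__(self, "protospacer", ps)
            if not (17 <= len(ps) <= 23):
                raise ValueError("protospacer length must be 17-23 nt")


@dataclass(frozen=True)
class GuidePair:
    """An upstream/downstream guide combination — the unit whose deletion
    efficiency is estimated."""

    us_guide: Guide
    ds_guide: Guide

    def __post_init__(self) -> None:
        if self.us_guide.side != "upstream" or self.ds_guide.side != "downstream":
            raise ValueError("GuidePair requires (upstream, downstream) guides")
        if not self.us_guide.cut_site < self.ds_guide.cut_site:
            raise ValueError(
                "upstream cut site must lie strictly before downstream cut site"
            )

    @property
    def pair_id(self) -> str:
        return f"{self.us_guide.id}/{self.ds_guide.id}"

    @property
    def expected_deletion_size(self) -> int:
        return self.ds_guide.cut_site - self.us_guide.cut_site


def cut_site_from_protospacer(
    protospacer: str,
    pam_strand: str | None,
    reference: AmpliconReference,
) -> int:
    """Locate a protospacer (with adjacent NGG PAM) and return the Cas9 cut site.

    Both strands are searched; the protospacer must occur exactly once overall.
    The cut is placed ``CAS9_CUT_OFFSET`` (3) bp 5' of the PAM on the
    protospacer strand, returned as a 0-based inter-base amplicon coordinate.
    ``pam_strand``, if given, restricts the search to that strand.
    """
    ps = protospacer.upper()
    seq = reference.sequence
    hits: list[tuple[int, str]] = []  # (match start on + coords, strand)

    strands = ("+", "-") if pam_strand is None else (pam_strand,)
    if "+" in strands:
        start = seq.find(ps)
        while start != -1:
            hits.append((start, "+"))
            start = seq.find(ps, start + 1)
    if "-" in strands:
        ps_rc = _revcomp(ps)
        start = seq.find(ps_rc)
        while start != -1:
            hits.append((start, "-"))
            start = seq.find(ps_rc, start + 1)

    if not hits:
        raise GuideNotFoundError(f"guide not found: {ps}")
    if len(hits) > 1:
        raise AmbiguousGuideError(f"ambiguous guide placement: {ps} ({len(hits)} hits)")

    start, strand = hits[0]
    end = start + len(ps)
    if strand == "+":
        pam = seq[end : end + 3]
        if len(pam) < 3 or pam[1:] != "GG":
            raise NoPamError(f"no PAM adjacent to {ps} on + strand")
        return end - CAS9_CUT_OFFSET
    # minus strand: PAM in + coordinates is CCN immediately 5' of the match
    pam = seq[start - 3 : start]
    if start < 3 or pam[:2] != "CC":
        raise NoPamError(f"no PAM adjacent to {ps} on - strand")
    return start + CAS9_CUT_OFFSET


def predicted_product_size(wt_product_size: int, deletion_size: int) -> int:
    """Expected PCR band size for a deletion allele.

    A 595 bp deletion of a 2370 bp product yields a 1775 bp band; a
    1739 bp deletion yields 631 bp.
    """
    if deletion_size < 0:
        raise ValueError("deletion size must be >= 0")
    if deletion_size >= wt_product_size:
        raise ValueError("deletion exceeds amplicon")
    return wt_product_size - deletion_size


def expected_deletion_size(pair: GuidePair) -> int:
    """Distance between the pair's cut sites = size of the excised interval."""
    return pair.expected_deletion_size


def make_pairs(guides: Iterable[Guide]) -> list[GuidePair]:
    """All upstream x downstream combinations with positive deletion size."""
    gs = list(guides)
    us = [g for g in gs if g.side == "upstream"]
    ds = [g for g in gs if g.side == "downstream"]
    pairs = []
    for u in us:
        for d in ds:
            if u.cut_site < d.cut_site:
                pairs.append(GuidePair(u, d))
    return pairs


def load_reference_fasta(path: str | Path, **annotations) -> AmpliconReference:
    """Read a single-record FASTA into an :class:`AmpliconReference`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    return AmpliconReference(name=rec.id, sequence=str(rec.seq), **annotations)


def load_guides_tsv(path: str | Path, reference: AmpliconReference) -> list[Guide]:
    """Read guides from TSV with columns id, side, and protospacer and/or
    cut_site (plus optional strand). An explicit cut_site wins over the
    protospacer-derived one when both are present."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "side"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"guide TSV missing columns: {sorted(missing)}")
    guides = []
    for _, row in df.iterrows():
        protospacer = None
        if "protospacer" in df.columns and pd.notna(row.get("protospacer")):
            protospacer = str(row["protospacer"]).upper()
        strand = None
        if "strand" in df.columns and pd.notna(row.get("strand")):
            strand = str(row["strand"])
        if "cut_site" in df.columns and pd.notna(row.get("cut_site")):
            cut = int(row["cut_site"])
        elif protospacer is not None:
            cut = cut_site_from_protospacer(protospacer, strand, reference)
        else:
            raise ValueError(f"guide {row['id']}: need protospacer or cut_site")
        guides.append(
            Guide(
                id=str(row["id"]),
                side=str(row["side"]),
                cut_site=cut,
                protospacer=protospacer,
                pam_strand=strand,
            )
        )
    return guides


def design_summary(
    reference: AmpliconReference, pairs: Sequence[GuidePair]
) -> pd.DataFrame:
    """Per-pair cut sites, expected deletion size and expected band size."""
    wt = reference.wt_product_size
    rows = [
        {
            "pair_id": p.pair_id,
            "us_cut_site": p.us_guide.cut_site,
            "ds_cut_site": p.ds_guide.cut_site,
            "expected_deletion_size": p.expected_deletion_size,
            "expected_band_size": predicted_product_size(wt, p.expected_deletion_size),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)
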