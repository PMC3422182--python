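"""Annotated reference loci and cytosine-context classification.

Plant DNA methylation is read out per cytosine context: CG, CHG and CHH,
where H is A, T or C.  The context of a cytosine is determined solely by
the two bases immediately 3' of it on the analyzed strand.  This module
holds the locus model used throughout the pipeline: a single-strand
sequence partitioned into named regions (e.g. upstream / cds / downstream)
with a complete inventory of its cytosine sites.

Coordinates are 1-based inclusive internally; exported BED/bedGraph tracks
are converted to 0-based half-open at the writer boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

CONTEXTS = ("CG", "CHG", "CHH")
_H = set("ATC")
_ACGT = set("ACGT")


class InputError(ValueError):
    """Invalid user-supplied data (sequence, coordinates, config)."""


class InvariantError(ValueError):
    """A structural invariant of the locus model is violated."""


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval; reversed input coordinates denote '-'."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"

    @classmethod
    def from_coords(cls, chromosome: str, start: int, end: int) -> "GenomicInterval":
        """Normalize a printed coordinate pair: start > end means minus strand."""
        if start <= 0 or end <= 0:
            raise InputError(f"coordinates must be positive, got {start}-{end}")
        if start > end:
            return cls(chromosome, end, start, "-")
        return cls(chromosome, start, end, "+")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def interval_length(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive coordinate pair (either orientation)."""
    if start <= 0 or end <= 0:
        raise InputError(f"coordinates must be positive, got {start}-{end}")
    return abs(start - end) + 1


@dataclass(frozen=True)
class RegionLabel:
    """Named offset range within a locus, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start <= 0 or self.end < self.start:
            raise InputError(f"bad region interval {self.name}=[{self.start},{self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, offset: int) -> bool:
        return self.start <= offset <= self.end


@dataclass(frozen=True)
class CytosineSite:
    """A cytosine on the analyzed strand with its sequence context."""

    offset: int  # 1-based position within the locus
    context: str  # CG | CHG | CHH | UNDEF
    region: str | None = None


@dataclass
class ReferenceLocus:
    """Analyzed-strand sequence with region partition and cytosine inventory."""

    id: str
    sequence: str
    regions: list[RegionLabel] = field(default_factory=list)
    sites: list[CytosineSite] = field(default_factory=list)
    source_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.regions:
            check_tiling(self.regions, len(self.sequence))
        if not self.sites:
            self.sites = classify_contexts(self.sequence)
            if self.regions:
                self.sites = annotate_regions(self.sites, self.regions)

    def __len__(self) -> int:
        return len(self.sequence)

    def region_of(self, offset: int) -> str:
        for reg in self.regions:
            if reg.contains(offset):
                return reg.name
        raise InvariantError(f"offset {offset} outside all regions of {self.id}")

    def sites_in(self, region: str | None = None, context: str | None = None) -> list[CytosineSite]:
        out = self.sites
        if region is not None:
            out = [s for s in out if s.region == region]
        if context is not None:
            out = [s for s in out if s.context == context]
        return out


def check_tiling(regions: Sequence[RegionLabel], locus_length: int) -> None:
    """Regions must be non-overlapping and together tile [1, locus_length]."""
    ordered = sorted(regions, key=lambda r: r.start)
    expected = 1
    for reg in ordered:
        if reg.start != expected:
            raise InvariantError(
                f"regions do not tile the locus: gap/overlap at offset {expected} "
                f"(region {reg.name} starts at {reg.start})"
            )
        expected = reg.end + 1
    if expected != locus_length + 1:
        raise InvariantError(
            f"regions cover [1,{expected - 1}] but locus length is {locus_length}"
        )


def classify_contexts(
    sequence: str,
    flank_3prime: str = "",
    strict: bool = True,
) -> list[CytosineSite]:
    """Classify every C of ``sequence`` into CG/CHG/CHH context.

    The context is decided by the two bases 3' of the C on the same strand.
    ``flank_3prime`` optionally supplies downstream sequence so that
    cytosines near the end of a sub-fragment keep their true context;
    without it, boundary cytosines with insufficient flank are UNDEF.

    In strict mode (default) non-ACGT characters raise; in lenient mode a
    C whose two-base flank contains a non-ACGT character gets UNDEF.
    """
    seq = sequence.upper()
    if not seq:
        raise InputError("empty sequence")
    flank = flank_3prime.upper()
    if strict:
        bad = set(seq + flank) - _ACGT
        if bad:
            raise InputError(f"non-ACGT characters in sequence: {sorted(bad)}")
    extended = seq + flank
    sites: list[CytosineSite] = []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        nxt = extended[i + 1] if i + 1 < len(extended) else None
        nxt2 = extended[i + 2] if i + 2 < len(extended) else None
        context = "UNDEF"
        if nxt == "G":
            context = "CG"
        elif nxt in _H:
            if nxt2 == "G":
                context = "CHG"
            elif nxt2 in _H:
                context = "CHH"
            # nxt2 None or non-ACGT -> UNDEF
        sites.append(CytosineSite(offset=i + 1, context=context))
    return sites


def annotate_regions(
    sites: Iterable[CytosineSite], regions: Sequence[RegionLabel]
) -> list[CytosineSite]:
    """Attach to each site the name of the unique region containing it."""
    ordered = sorted(regions, key=lambda r: r.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise InvariantError(f"regions {a.name} and {b.name} overlap")
    out = []
    for site in sites:
        hit = [r.name for r in ordered if r.contains(site.offset)]
        if not hit:
            raise InvariantError(f"site offset {site.offset} outside all regions")
        out.append(replace(site, region=hit[0]))
    return out


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def kmer_frequency_track(
    sequence: str, k: int, background: Iterable[str]
) -> list[int]:
    """Per-start-position count of each k-mer of ``sequence`` in a background set.

    Counts exact occurrences on both strands of every background sequence
    (overlapping occurrences included).  Used to draw the repeat track
    alongside small-RNA profiles: values > 1 flag repetitive stretches.
    """
    if k <= 0:
        raise InputError(f"k must be positive, got {k}")
    seq = sequence.upper()
    if k > len(seq):
        raise InputError(f"k={k} exceeds sequence length {len(seq)}")
    bgs = [b.upper() for b in background]
    index: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], 0)
    for bg in bgs:
        for strand_seq in (bg, reverse_complement(bg)):
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i : i + k]
                if kmer in index:
                    index[kmer] += 1
    return [index[seq[i : i + k]] for i in range(len(seq) - k + 1)]


# ---------------------------------------------------------------------------
# I/O


def read_locus_fasta(path) -> dict[str, str]:
    """Read a FASTA file of locus sequences into an ordered {id: sequence} dict."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


_REGION_LINE = re.compile(r"^\s*(\w+)\s*=\s*(\d+)\s*\.\.\s*(\d+)\s*$")


def parse_regions(lines: Iterable[str]) -> list[RegionLabel]:
    """Parse ``name=start..end`` region annotation lines (1-based inclusive)."""
    regions = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _REGION_LINE.match(line)
        if not m:
            raise InputError(f"bad region line: {line!r}")
        regions.append(RegionLabel(m.group(1), int(m.group(2)), int(m.group(3))))
    if not regions:
        raise InputError("no region annotations found")
    return regions


def write_sites_bed(locus: ReferenceLocus, path) -> None:
    """Write cytosine sites as BED (0-based half-open, context in the name field)."""
    with open(path, "w") as fh:
        for site in locus.sites:
            fh.write(f"{locus.id}\t{site.offset - 1}\t{site.offset}\t{site.context}\n")
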