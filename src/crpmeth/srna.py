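"""Small-RNA library processing: adapter trimming, signature collapse,
exact reference matching, structural-RNA exclusion, TPM normalization,
hits-normalized abundance (HNA), and per-locus summaries.

A *signature* is a distinct small-RNA sequence with its summed raw
abundance.  Matching is exact, on both strands of every supplied
reference; a signature with exactly one hit is *unique*, with several
*duplicated*.  TPM scales raw abundances per million over the retained
genome-matched total (structural tRNA/rRNA/snRNA/snoRNA matches removed
first; the denominator is configurable to the raw total).  HNA divides a
signature's TPM evenly over its genomic hits, so summing HNA over a locus
counts multi-mapping reads fractionally — the per-locus aggregate is the
HNA sum, with the 24-nt TPM total and the count of unique 24-nt
signatures alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import InputError, reverse_complement


@dataclass(frozen=True)
class SrnaSignature:
    sequence: str
    raw_abundance: int
    hits: int = 0
    positions: tuple[tuple[str, int, str], ...] = ()  # (reference id, 1-based offset, strand)
    tpm: float = float("nan")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def hna_per_hit(self) -> float:
        if self.hits < 1:
            raise InputError(f"hna undefined for unmatched signature {self.sequence}")
        return self.tpm / self.hits

    @property
    def klass(self) -> str:
        return "unique" if self.hits == 1 else "duplicated"


@dataclass
class LibraryAccounting:
    total_reads: int = 0
    genome_matched: int = 0
    structural_excluded: int = 0
    unmatched: int = 0

    @property
    def retained(self) -> int:
        return self.genome_matched


@dataclass(frozen=True)
class LocusSrnaSummary:
    locus_id: str
    hna_sum: float
    abundance_24nt: float
    unique_24nt_count: int


# ---------------------------------------------------------------------------
# Operations


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 5,
    max_mismatch: int = 0,
) -> str | None:
    """Insert before the left-most adapter occurrence, or None.

    An occurrence at read position i aligns the adapter prefix against
    read[i:]; it counts when the overlap is >= min_overlap bases with at
    most max_mismatch mismatches.  Idempotent: a trimmed insert contains
    no further qualifying occurrence by construction of "left-most".
    """
    if not adapter:
        raise InputError("empty adapter")
    read = read.upper()
    adapter = adapter.upper()
    for i in range(len(read) - min_overlap + 1):
        overlap = min(len(adapter), len(read) - i)
        mismatches = sum(
            1 for a, b in zip(read[i : i + overlap], adapter[:overlap]) if a != b
        )
        if mismatches <= max_mismatch:
            return read[:i]
    return None


def trim_library(
    reads: Iterable[str],
    adapter: str,
    min_overlap: int = 5,
    max_mismatch: int = 0,
    min_length: int = 18,
    keep_untrimmed: bool = False,
) -> tuple[list[str], dict[str, int]]:
    """Trim every read; returns (inserts, accounting of drops)."""
    inserts = []
    acct = {"input": 0, "no_adapter": 0, "too_short": 0, "kept": 0}
    for read in reads:
        acct["input"] += 1
        insert = trim_adapter(read, adapter, min_overlap, max_mismatch)
        if insert is None:
            if keep_untrimmed:
                insert = read.upper()
            else:
                acct["no_adapter"] += 1
                continue
        if len(insert) < min_length:
            acct["too_short"] += 1
            continue
        acct["kept"] += 1
        inserts.append(insert)
    return inserts, acct


def collapse_signatures(reads: Iterable[str | tuple[str, int]]) -> list[SrnaSignature]:
    """One signature per distinct sequence, abundances summed, lexicographic order.

    Accepts raw read lists or pre-counted (sequence, count) pairs.
    """
    counts: dict[str, int] = {}
    for item in reads:
        if isinstance(item, tuple):
            seq, n = item
        else:
            seq, n = item, 1
        seq = seq.upper()
        counts[seq] = counts.get(seq, 0) + int(n)
    return [SrnaSignature(seq, counts[seq]) for seq in sorted(counts)]


def _scan(reference: str, query: str) -> list[int]:
    """All (overlapping) 0-based occurrences of query in reference."""
    out = []
    i = reference.find(query)
    while i != -1:
        out.append(i)
        i = reference.find(query, i + 1)
    return out


def match_reference(
    signatures: Sequence[SrnaSignature],
    references: Mapping[str, str],
    max_hits_cap: int | None = None,
) -> list[SrnaSignature]:
    """Exact matching on both strands of every reference.

    ``hits`` counts every occurrence; a position is (reference id,
    1-based start on the plus strand of the reference, strand).  An
    optional cap discards hyper-repetitive signatures (hits > cap).
    Unmatched signatures are retained with hits = 0 for accounting.
    """
    refs = {name: seq.upper() for name, seq in references.items()}
    out = []
    for sig in signatures:
        positions: list[tuple[str, int, str]] = []
        rc = reverse_complement(sig.sequence)
        for name, seq in refs.items():
            for i in _scan(seq, sig.sequence):
                positions.append((name, i + 1, "+"))
            # a reverse-complement palindrome occupies one duplex position;
            # count it once (plus strand) rather than in both orientations
            if rc != sig.sequence:
                for i in _scan(seq, rc):
                    positions.append((name, i + 1, "-"))
        positions.sort()
        if max_hits_cap is not None and len(positions) > max_hits_cap:
            continue
        out.append(replace(sig, hits=len(positions), positions=tuple(positions)))
    return out


def exclude_structural(
    signatures: Sequence[SrnaSignature],
    exclusion_refs: Mapping[str, str],
) -> tuple[list[SrnaSignature], LibraryAccounting]:
    """Remove signatures matching tRNA/rRNA/snRNA/snoRNA references.

    Returns retained signatures and the library accounting (read-level
    totals over raw abundances).
    """
    acct = LibraryAccounting()
    retained = []
    refs = {name: seq.upper() for name, seq in exclusion_refs.items()}
    for sig in signatures:
        acct.total_reads += sig.raw_abundance
        rc = reverse_complement(sig.sequence)
        structural = any(
            seq.find(sig.sequence) != -1 or seq.find(rc) != -1
            for seq in refs.values()
        )
        if structural:
            acct.structural_excluded += sig.raw_abundance
            continue
        if sig.hits > 0:
            acct.genome_matched += sig.raw_abundance
        else:
            acct.unmatched += sig.raw_abundance
        retained.append(sig)
    return retained, acct


def normalize(
    signatures: Sequence[SrnaSignature],
    scale: float = 1e6,
    denominator: str = "matched",
) -> list[SrnaSignature]:
    """TPM: raw_abundance x scale / denominator total.

    ``denominator``: "matched" (default) uses the total raw abundance of
    genome-matched signatures; "all" uses every retained signature.
    """
    if denominator == "matched":
        total = sum(s.raw_abundance for s in signatures if s.hits > 0)
    elif denominator == "all":
        total = sum(s.raw_abundance for s in signatures)
    else:
        raise InputError(f"unknown denominator {denominator!r}")
    if total == 0:
        raise InputError("zero normalization denominator")
    return [replace(s, tpm=s.raw_abundance * scale / total) for s in signatures]


def hits_normalize(signatures: Sequence[SrnaSignature]) -> list[SrnaSignature]:
    """Keep only matched signatures; hna_per_hit = tpm / hits per position."""
    return [s for s in signatures if s.hits > 0]


def summarize_locus(
    locus_id: str,
    interval: tuple[int, int],
    signatures: Sequence[SrnaSignature],
    reference_id: str | None = None,
) -> LocusSrnaSummary:
    """Per-locus aggregate over signature positions starting in the interval.

    A position belongs to the locus iff its start offset lies inside
    ``interval`` (1-based inclusive) on the reference ``reference_id``
    (default: same as locus_id).  hna_sum adds hna_per_hit once per
    in-locus position; abundance_24nt adds the full TPM of each 24-nt
    signature with >= 1 in-locus position; unique_24nt_count counts 24-nt
    signatures with exactly one genomic hit, located in the locus.
    """
    ref = reference_id or locus_id
    lo, hi = interval
    hna_sum = 0.0
    abundance24 = 0.0
    unique24 = 0
    for sig in signatures:
        if sig.hits < 1:
            continue
        in_locus = [
            p for p in sig.positions if p[0] == ref and lo <= p[1] <= hi
        ]
        if not in_locus:
            continue
        hna_sum += sig.hna_per_hit * len(in_locus)
        if sig.length == 24:
            abundance24 += sig.tpm
            if sig.hits == 1:
                unique24 += 1
    return LocusSrnaSummary(locus_id, hna_sum, abundance24, unique24)


def length_profile(
    signatures: Sequence[SrnaSignature],
    reference_id: str,
    interval: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-position track rows (position, length, strand, tpm, class),
    restricted to 21-24-nt signatures; positions by start offset."""
    rows = []
    for sig in signatures:
        if not 21 <= sig.length <= 24 or sig.hits < 1:
            continue
        for ref, pos, strand in sig.positions:
            if ref != reference_id:
                continue
            if interval is not None and not interval[0] <= pos <= interval[1]:
                continue
            rows.append(
                {
                    "position": pos,
                    "length": sig.length,
                    "strand": strand,
                    "tpm": sig.tpm,
                    "hna_per_hit": sig.hna_per_hit,
                    "class": sig.klass,
                    "sequence": sig.sequence,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["position", "length", "strand", "tpm", "hna_per_hit", "class", "sequence"],
    ).sort_values(["position", "length", "strand"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O


def read_srna_tsv(path) -> list[tuple[str, int]]:
    df = pd.read_csv(path, sep="\t")
    if not {"sequence", "abundance"} <= set(df.columns):
        raise InputError(f"{path}: expected columns sequence, abundance")
    return list(zip(df["sequence"].str.upper(), df["abundance"].astype(int)))


def signatures_frame(signatures: Sequence[SrnaSignature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [s.sequence for s in signatures],
            "length": [s.length for s in signatures],
            "raw_abundance": [s.raw_abundance for s in signatures],
            "hits": [s.hits for s in signatures],
            "tpm": [s.tpm for s in signatures],
            "hna_per_hit": [
                s.hna_per_hit if s.hits > 0 else float("nan") for s in signatures
            ],
            "class": [s.klass if s.hits > 0 else "unmatched" for s in signatures],
        }
    )
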