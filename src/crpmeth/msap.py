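"""In-silico methylation-sensitive amplification polymorphism (MSAP) screen.

The wet screen digests genomic DNA with a methylation-sensitive enzyme
(EcoT22I, recognition ATGCAT) and a methylation-insensitive partner
(MseI, TTAA), ligates adapters, and selectively amplifies fragments with
one labeled EcoT22I end and one MseI end; a band present in one sample
and absent in another marks a methylation difference at a restriction
site.  This module models the informative core deterministically:

* site finding (overlap-aware, palindromic recognition sequences cover
  both strands by a top-strand scan);
* a blocking rule — by default any strand-tagged methylated C in the
  6-bp footprint blocks the cut; MseI's TTAA contains no C, so it is
  never blocked without any special-casing;
* double digestion at top-strand cut offsets (band lengths, not sticky
  ends, are the observable);
* the amplification filter: exactly one end of each enzyme, selective
  3' primer bases matched against the genomic bases immediately interior
  to the cut remnant, and a gel-visible size window;
* profile differencing annotated with the site whose cut state changed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .reference import InputError, reverse_complement


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Palindromic restriction enzyme with a top-strand cut offset.

    ``cut_offset`` = number of bases 5' of the cut within the recognition
    site: ATGCA^T is offset 5, T^TAA is offset 1.  ``blocked_positions``
    optionally restricts methylation sensitivity to an explicit set of
    footprint positions (1-based within the site, strand-tagged); the
    default rule is any methylated C anywhere in the footprint.
    """

    name: str
    recognition: str
    cut_offset: int
    blocked_positions: frozenset[tuple[int, str]] | None = None

    def __post_init__(self) -> None:
        if not self.recognition:
            raise InputError("empty recognition sequence")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise InputError(
                f"cut offset {self.cut_offset} outside recognition site "
                f"{self.recognition}"
            )

    @property
    def footprint(self) -> int:
        return len(self.recognition)


ECOT22I = RestrictionEnzyme("EcoT22I", "ATGCAT", 5)
MSEI = RestrictionEnzyme("MseI", "TTAA", 1)


@dataclass(frozen=True)
class MethylationState:
    """Strand-tagged methylated cytosine offsets of one sample's locus."""

    locus_id: str
    methylated: frozenset[tuple[int, str]]  # (1-based offset, '+'|'-')

    @classmethod
    def from_offsets(cls, locus_id: str, offsets: Iterable[tuple[int, str]]) -> "MethylationState":
        return cls(locus_id, frozenset(offsets))

    @classmethod
    def from_landscape_realization(
        cls, locus, landscape, threshold: float = 0.5, both_strands: bool = True
    ) -> "MethylationState":
        """Deterministic realization: sites with p >= threshold are methylated.

        With ``both_strands`` the symmetric CG/CHG contexts methylate the
        complementary-strand cytosine too (the maintenance pathways act on
        both strands), matching what a restriction footprint sees.
        """
        marks: set[tuple[int, str]] = set()
        for site in locus.sites:
            if landscape.p(site.offset) >= threshold:
                marks.add((site.offset, "+"))
                if both_strands and site.context == "CG":
                    marks.add((site.offset + 1, "-"))
                elif both_strands and site.context == "CHG":
                    marks.add((site.offset + 2, "-"))
        return cls(locus.id, frozenset(marks))


@dataclass(frozen=True)
class DigestFragment:
    locus_id: str
    start: int  # 1-based inclusive
    end: int
    left_end: str  # enzyme name | "terminus"
    right_end: str
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SelectivePrimer:
    """AFLP-style primer: adapter+remnant core plus selective 3' bases."""

    name: str
    sequence: str
    enzyme: str
    selective_bases: str

    @classmethod
    def from_sequence(
        cls, name: str, sequence: str, enzyme: str, core_length: int
    ) -> "SelectivePrimer":
        """Parse selective bases as everything 3' of the adapter+remnant core."""
        seq = sequence.upper().replace(" ", "")
        if core_length > len(seq):
            raise InputError(f"core length {core_length} exceeds primer {name}")
        return cls(name, seq, enzyme, seq[core_length:])


# Primer fixtures from the screen's published sequences, split at a 16-nt
# adapter+remnant core (the split itself is configuration).
T21 = SelectivePrimer.from_sequence("T21", "GACTGCGTAGGTGCATCC", "EcoT22I", 16)
M56 = SelectivePrimer.from_sequence("M56", "GATGAGTCCTGAGTAATGT", "MseI", 16)
M1 = SelectivePrimer.from_sequence("M1", "GATGAGTCCTGAGTAATA", "MseI", 16)


@dataclass
class MsapProfile:
    sample: str
    fragments: list[DigestFragment] = field(default_factory=list)

    def keys(self) -> set[tuple]:
        return {
            (f.locus_id, f.start, f.end, f.left_end, f.right_end) for f in self.fragments
        }


# ---------------------------------------------------------------------------
# Operations


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based start offsets of all (overlapping) recognition sites, top strand.

    Both enzymes here are palindromic, so a top-strand scan covers both
    strands.
    """
    seq = sequence.upper()
    rec = enzyme.recognition.upper()
    sites = []
    i = seq.find(rec)
    while i != -1:
        sites.append(i + 1)
        i = seq.find(rec, i + 1)
    return sites


def cut_mask(
    sites: Sequence[int],
    state: MethylationState,
    enzyme: RestrictionEnzyme,
) -> dict[int, bool]:
    """Per-site cut decision: True = cut, False = blocked by methylation.

    Default rule: blocked iff any strand-tagged methylated C lies within
    the site footprint [s, s+len-1].  With ``blocked_positions`` set on
    the enzyme, only those (position-within-site, strand) marks block.
    """
    mask = {}
    for s in sites:
        footprint = range(s, s + enzyme.footprint)
        if enzyme.blocked_positions is None:
            blocked = any(off in footprint for off, _strand in state.methylated)
        else:
            blocked = any(
                (off - s + 1, strand) in enzyme.blocked_positions
                for off, strand in state.methylated
                if off in footprint
            )
        mask[s] = not blocked
    return mask


def double_digest(
    sequence: str,
    cut_masks: Mapping[str, tuple[RestrictionEnzyme, Mapping[int, bool]]],
    locus_id: str = "locus",
) -> list[DigestFragment]:
    """Apply all unblocked cuts of both enzymes; fragments tile the sequence.

    ``cut_masks`` maps enzyme name -> (enzyme, {site_start: cut?}).  A cut
    at site s falls after base s - 1 + cut_offset.  Fragment ends are
    labeled by the cutting enzyme; sequence termini are "terminus".
    """
    cuts: list[tuple[int, str]] = []  # (last base of left fragment, enzyme)
    for name, (enzyme, mask) in cut_masks.items():
        for s, do_cut in mask.items():
            if do_cut:
                pos = s - 1 + enzyme.cut_offset
                if 0 < pos < len(sequence):
                    cuts.append((pos, name))
    cuts.sort()
    fragments = []
    prev_pos, prev_label = 0, "terminus"
    for pos, name in cuts:
        if pos == prev_pos:  # coincident cut; first one already applied
            continue
        fragments.append(
            DigestFragment(
                locus_id, prev_pos + 1, pos, prev_label, name,
                sequence[prev_pos:pos],
            )
        )
        prev_pos, prev_label = pos, name
    fragments.append(
        DigestFragment(
            locus_id, prev_pos + 1, len(sequence), prev_label, "terminus",
            sequence[prev_pos:],
        )
    )
    return fragments


def digest_profile(
    sequence: str,
    state: MethylationState,
    enzymes: Sequence[RestrictionEnzyme] = (ECOT22I, MSEI),
    locus_id: str | None = None,
) -> list[DigestFragment]:
    """Convenience: find sites, apply blocking, double-digest."""
    masks = {
        e.name: (e, cut_mask(find_sites(sequence, e), state, e)) for e in enzymes
    }
    return double_digest(sequence, masks, locus_id or state.locus_id)


def _end_matches(
    fragment: DigestFragment,
    side: str,
    enzyme: RestrictionEnzyme,
    primer: SelectivePrimer,
) -> bool:
    """Check the selective bases immediately interior to one cut end.

    A left end retains recognition[cut_offset:] (remnant length
    footprint - cut_offset); a right end retains recognition[:cut_offset].
    The selective bases extend 3' of the primer into the fragment: read
    directly after the remnant at a left end, and reverse-complemented
    before the remnant at a right end.
    """
    k = len(primer.selective_bases)
    if k == 0:
        return True
    seq = fragment.sequence
    if side == "left":
        remnant = enzyme.footprint - enzyme.cut_offset
        region = seq[remnant : remnant + k]
        return region == primer.selective_bases
    remnant = enzyme.cut_offset
    if len(seq) < remnant + k:
        return False
    region = seq[len(seq) - remnant - k : len(seq) - remnant]
    return reverse_complement(region) == primer.selective_bases


def amplifiable(
    fragments: Sequence[DigestFragment],
    primer_e: SelectivePrimer = T21,
    primer_m: SelectivePrimer = M1,
    enzymes: Mapping[str, RestrictionEnzyme] | None = None,
    size_window: tuple[int, int] | None = (50, 500),
    sample: str = "sample",
) -> MsapProfile:
    """Amplification filter: one EcoT22I end + one MseI end, selective-base
    match at both ends, optional gel-visible size window."""
    enzymes = enzymes or {"EcoT22I": ECOT22I, "MseI": MSEI}
    e_name = primer_e.enzyme
    m_name = primer_m.enzyme
    kept = []
    for frag in fragments:
        ends = {frag.left_end, frag.right_end}
        if ends != {e_name, m_name}:
            continue
        if size_window is not None and not (
            size_window[0] <= frag.length <= size_window[1]
        ):
            continue
        ok = True
        for side, end in (("left", frag.left_end), ("right", frag.right_end)):
            primer = primer_e if end == e_name else primer_m
            if not _end_matches(frag, side, enzymes[end], primer):
                ok = False
                break
        if ok:
            kept.append(frag)
    return MsapProfile(sample, kept)


def diff_profiles(
    profile_a: MsapProfile,
    profile_b: MsapProfile,
    mask_a: Mapping[str, Mapping[int, bool]] | None = None,
    mask_b: Mapping[str, Mapping[int, bool]] | None = None,
) -> list[dict]:
    """Fragments present in exactly one profile, with the explaining sites.

    When the per-enzyme cut masks of both samples are given, each
    polymorphic fragment is annotated with the (enzyme, site) whose cut
    state differs between samples and lies within (or at the boundary of)
    the fragment.
    """
    keys_a, keys_b = profile_a.keys(), profile_b.keys()
    changed_sites = []
    if mask_a is not None and mask_b is not None:
        for enzyme in set(mask_a) | set(mask_b):
            a = mask_a.get(enzyme, {})
            b = mask_b.get(enzyme, {})
            for s in set(a) | set(b):
                if a.get(s) != b.get(s):
                    changed_sites.append((enzyme, s))
    by_key = {}
    for prof, only in ((profile_a, keys_a - keys_b), (profile_b, keys_b - keys_a)):
        for frag in prof.fragments:
            key = (frag.locus_id, frag.start, frag.end, frag.left_end, frag.right_end)
            if key in only and key not in by_key:
                explain = [
                    (enz, s)
                    for enz, s in changed_sites
                    if frag.start - 6 <= s <= frag.end + 6
                ]
                by_key[key] = {
                    "sample": prof.sample,
                    "fragment": frag,
                    "changed_sites": explain,
                }
    return [by_key[k] for k in sorted(by_key)]


def profile_frame(profile: MsapProfile):
    """Profile as a pandas DataFrame (for TSV export)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample": profile.sample,
            "locus": [f.locus_id for f in profile.fragments],
            "start": [f.start for f in profile.fragments],
            "end": [f.end for f in profile.fragments],
            "left_end": [f.left_end for f in profile.fragments],
            "right_end": [f.right_end for f in profile.fragments],
            "length": [f.length for f in profile.fragments],
        }
    )
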