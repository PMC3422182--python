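"""Synthetic data generation with known ground truth.

Every downstream stage of the pipeline (clone methylation calling, the
report tables, the MSAP screen, the small-RNA profile) is exercised on
simulated inputs produced here, so parameter recovery can be checked
against the truth.  The generator emulates the study system: a ~1 kb
repeat-embedded locus split into upstream / coding / downstream regions
with region-dependent cytosine-context density, near-complete CG
methylation, CHH methylation concentrated in the coding region, an
RdDM-mutant genotype that multiplicatively reduces CHH methylation, a
fully unmethylated conversion-control amplicon, and 21-24-nt small-RNA
libraries concentrated in coding regions with controlled multi-mapping.

Clone reads model three error sources: incomplete bisulfite conversion
(an unmethylated C read as C, i.e. a false methylated call), rare
over-conversion of a methylated C to T, and per-base sequencing
substitutions.  Conversion is modeled per cytosine independently; no
indels or chimeric clones are simulated, so clone length always equals
locus length and ungapped alignment downstream is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .reference import (
    CONTEXTS,
    CytosineSite,
    InputError,
    ReferenceLocus,
    RegionLabel,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """Constrained sequence sampling failed to meet the density targets."""


@dataclass
class MethylationLandscape:
    """Per-site methylation probability for one locus."""

    locus_id: str
    probabilities: dict[int, float]  # site offset -> p in [0, 1]

    def __post_init__(self) -> None:
        for off, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise InputError(f"probability {p} at offset {off} outside [0,1]")

    def p(self, offset: int) -> float:
        return self.probabilities[offset]


@dataclass(frozen=True)
class GenotypeEffect:
    """Per-context multiplicative factor on methylation probabilities.

    Wild type is the identity (all factors 1).  An RdDM mutant is modeled
    as f_CHH in [0.2, 0.35], i.e. a 65-80 % CHH reduction, with CG/CHG
    largely retained.
    """

    genotype: str
    factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ctx, f in self.factors.items():
            if not 0.0 <= f <= 1.0:
                raise InputError(f"factor {f} for {ctx} outside [0,1]")

    def factor(self, context: str) -> float:
        return self.factors.get(context, 1.0)

    @classmethod
    def wild_type(cls, genotype: str = "wt") -> "GenotypeEffect":
        return cls(genotype)


@dataclass(frozen=True)
class SimulationConfig:
    """Clone-simulation parameters; identical seed implies identical output."""

    n_clones: int = 15
    conversion_rate: float = 0.995  # P(unmethylated C reads as T)
    overconversion_rate: float = 0.0  # P(methylated C reads as T)
    seq_error_rate: float = 0.001  # per-base substitution probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise InputError("n_clones must be >= 1")
        for name in ("conversion_rate", "overconversion_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0,1]")


@dataclass(frozen=True)
class CloneRead:
    """One sequenced bisulfite clone (a single molecule's pattern)."""

    id: str
    genotype: str
    amplicon: str
    sequence: str


# ---------------------------------------------------------------------------
# Locus construction

#: Site-count targets mirroring the studied 1012-bp repeat monomer:
#: upstream 3 CG / 6 CHG / 51 CHH, coding 11 CG / 20 CHG / 52 CHH,
#: downstream 2 CG / 1 CHG / 28 CHH.
CRP4_LIKE_PROFILE: dict[str, dict[str, int]] = {
    "upstream": {"CG": 3, "CHG": 6, "CHH": 51},
    "cds": {"CG": 11, "CHG": 20, "CHH": 52},
    "downstream": {"CG": 2, "CHG": 1, "CHH": 28},
}

#: Region lengths of the studied monomer (430 + 369 + 213 = 1012 bp).
CRP4_LIKE_LENGTHS = {"upstream": 430, "cds": 369, "downstream": 213}


def _resolve_count(spec, rng) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _region_sequence(length: int, counts: dict[str, int], rng: np.random.Generator) -> str:
    """Build a region with exact CG/CHG/CHH counts.

    Each context is realized as a self-contained token whose single C has
    its full context inside the token (CG -> "CG", CHG -> "CHG" with H in
    {A,T}, CHH -> "CHH" with H in {A,T}); filler bases are drawn from
    {A,G,T} so no cytosine arises outside tokens.  Tokens are shuffled
    among the filler, giving exact site counts without rejection.
    """
    tokens: list[str] = []
    for _ in range(counts.get("CG", 0)):
        tokens.append("CG")
    for _ in range(counts.get("CHG", 0)):
        h = rng.choice(["A", "T"])
        tokens.append(f"C{h}G")
    for _ in range(counts.get("CHH", 0)):
        h1, h2 = rng.choice(["A", "T"], size=2)
        tokens.append(f"C{h1}{h2}")
    token_len = sum(len(t) for t in tokens)
    n_filler = length - token_len
    if n_filler < 0:
        raise GenerationError(
            f"density targets need {token_len} bp but region is {length} bp"
        )
    filler = rng.choice(["A", "G", "T"], size=n_filler).tolist()
    # Interleave: choose token insertion slots among filler positions.
    parts: list[str] = filler
    order = rng.permutation(len(tokens))
    slots = sorted(rng.integers(0, len(filler) + 1, size=len(tokens)), reverse=True)
    for slot, idx in zip(slots, order):
        parts.insert(slot, tokens[idx])
    seq = "".join(parts)
    assert len(seq) == length
    return seq


def make_locus(
    upstream_len: int,
    cds_len: int,
    downstream_len: int,
    context_density_profile: Mapping[str, Mapping] = CRP4_LIKE_PROFILE,
    seed: int = 0,
    locus_id: str = "synthetic_locus",
) -> ReferenceLocus:
    """Generate a region-partitioned locus hitting per-region context targets.

    ``context_density_profile`` maps region name -> {context: count or
    (lo, hi) range}.  The emitted locus tiles upstream/cds/downstream and
    its cytosine inventory matches the requested counts exactly (a range
    is sampled once, then met exactly).
    """
    lengths = {"upstream": upstream_len, "cds": cds_len, "downstream": downstream_len}
    for name, ln in lengths.items():
        if ln < 1:
            raise InputError(f"{name} length must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    regions = []
    start = 1
    for name in ("upstream", "cds", "downstream"):
        counts = {
            ctx: _resolve_count(spec, rng)
            for ctx, spec in context_density_profile.get(name, {}).items()
        }
        parts.append(_region_sequence(lengths[name], counts, rng))
        regions.append(RegionLabel(name, start, start + lengths[name] - 1))
        start += lengths[name]
    locus = ReferenceLocus(id=locus_id, sequence="".join(parts), regions=regions)
    # Verify the construction against the classifier (belt and braces).
    for name in ("upstream", "cds", "downstream"):
        for ctx in CONTEXTS:
            want = context_density_profile.get(name, {}).get(ctx)
            if isinstance(want, int):
                got = len(locus.sites_in(region=name, context=ctx))
                if got != want:
                    raise GenerationError(
                        f"{name}/{ctx}: generated {got} sites, wanted {want}"
                    )
    return locus


# ---------------------------------------------------------------------------
# Methylation landscapes and clone reads

#: Region x context methylation rates of the wild-type study system:
#: CG fully methylated everywhere it occurs, CHG likewise (but a single
#: unmethylated downstream CHG in the observed tallies), CHH ~3 % / 12 % /
#: 6 % overall in upstream / coding / downstream.
CRP4_LIKE_RATES: dict[tuple[str, str], float] = {
    ("upstream", "CG"): 1.0,
    ("upstream", "CHG"): 1.0,
    ("upstream", "CHH"): 0.03,
    ("cds", "CG"): 1.0,
    ("cds", "CHG"): 1.0,
    ("cds", "CHH"): 0.12,
    ("downstream", "CG"): 1.0,
    ("downstream", "CHG"): 1.0,
    ("downstream", "CHH"): 0.06,
}


def simulate_landscape(
    locus: ReferenceLocus,
    region_context_rates: Mapping[tuple[str, str], float],
    genotype_effect: GenotypeEffect | None = None,
) -> MethylationLandscape:
    """Per-site p_i = rate(region_i, context_i) x genotype factor(context_i)."""
    effect = genotype_effect or GenotypeEffect.wild_type()
    probs: dict[int, float] = {}
    for site in locus.sites:
        if site.context == "UNDEF":
            probs[site.offset] = 0.0
            continue
        key = (site.region, site.context)
        if key not in region_context_rates:
            raise InputError(f"no methylation rate configured for {key}")
        probs[site.offset] = region_context_rates[key] * effect.factor(site.context)
    return MethylationLandscape(locus.id, probs)


def simulate_clones(
    locus: ReferenceLocus,
    landscape: MethylationLandscape,
    config: SimulationConfig,
    genotype: str = "wt",
    amplicon: str | None = None,
) -> tuple[list[CloneRead], np.ndarray]:
    """Draw bisulfite clone reads; returns (clones, truth).

    ``truth`` is the (n_clones x n_sites) boolean matrix of simulated
    methylation states (site order = locus.sites order), so zero-noise
    recovery can be asserted exactly.
    """
    rng = np.random.default_rng(config.seed)
    amplicon = amplicon or locus.id
    offsets = [s.offset for s in locus.sites]
    p = np.array([landscape.p(off) for off in offsets])
    n_sites = len(offsets)
    base_arr = np.array(list(locus.sequence))
    clones: list[CloneRead] = []
    truth = np.zeros((config.n_clones, n_sites), dtype=bool)
    for c in range(config.n_clones):
        meth = rng.random(n_sites) < p
        truth[c] = meth
        read = base_arr.copy()
        # bisulfite chemistry at every C
        converted = np.where(
            meth,
            rng.random(n_sites) < config.overconversion_rate,
            rng.random(n_sites) < config.conversion_rate,
        )
        site_idx = np.array([off - 1 for off in offsets], dtype=int)
        read[site_idx[converted]] = "T"
        # sequencing substitutions anywhere
        if config.seq_error_rate > 0:
            err = rng.random(len(read)) < config.seq_error_rate
            for i in np.nonzero(err)[0]:
                choices = [b for b in "ACGT" if b != read[i]]
                read[i] = choices[rng.integers(0, 3)]
        clones.append(
            CloneRead(
                id=f"{amplicon}_{genotype}_clone{c + 1:03d}",
                genotype=genotype,
                amplicon=amplicon,
                sequence="".join(read),
            )
        )
    return clones, truth


def simulate_control_amplicon(
    length: int, config: SimulationConfig, locus_id: str = "conversion_control"
) -> tuple[ReferenceLocus, list[CloneRead]]:
    """Fully unmethylated control locus plus clones (conversion-rate QC).

    Mirrors the role of a known-unmethylated gene sequenced alongside the
    samples to bound the non-conversion artifact.
    """
    rng = np.random.default_rng(config.seed)
    # C-dense in every region: the control exists to measure conversion,
    # so informative (C) positions should dominate
    region_counts = {"CG": max(2, length // 90), "CHG": max(2, length // 90),
                     "CHH": max(4, length // 30)}
    profile = {name: dict(region_counts) for name in ("upstream", "cds", "downstream")}
    third = max(1, length // 3)
    locus = make_locus(
        third, length - 2 * third, third,
        context_density_profile=profile,
        seed=int(rng.integers(0, 2**31 - 1)),
        locus_id=locus_id,
    )
    landscape = MethylationLandscape(locus.id, {s.offset: 0.0 for s in locus.sites})
    clones, _ = simulate_clones(locus, landscape, config, genotype="control")
    return locus, clones


# ---------------------------------------------------------------------------
# Small-RNA libraries


def simulate_srna_library(
    loci: Sequence[ReferenceLocus],
    locus_expression_levels: Mapping[str, float],
    length_distribution: Mapping[int, float],
    total_reads: int,
    genotype_effect_factors: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Draw an sRNA library as (sequence, abundance) pairs.

    Reads are exact substrings of the loci (both strands); locus choice is
    multinomial over expression x genotype factor, read length over
    ``length_distribution`` (support {21,22,23,24}).  A Pol IV-mutant
    genotype is modeled by factors near 0 for the affected loci.
    """
    if total_reads <= 0:
        raise InputError("total_reads must be positive")
    lengths = sorted(length_distribution)
    if any(ln not in (21, 22, 23, 24) for ln in lengths):
        raise InputError("length distribution support must be within {21,22,23,24}")
    factors = genotype_effect_factors or {}
    rng = np.random.default_rng(seed)
    weights = np.array(
        [locus_expression_levels.get(l.id, 0.0) * factors.get(l.id, 1.0) for l in loci]
    )
    if weights.sum() <= 0:
        return []
    weights = weights / weights.sum()
    lprobs = np.array([length_distribution[ln] for ln in lengths], dtype=float)
    lprobs = lprobs / lprobs.sum()
    locus_draw = rng.choice(len(loci), size=total_reads, p=weights)
    len_draw = rng.choice(lengths, size=total_reads, p=lprobs)
    strand_draw = rng.random(total_reads) < 0.5
    counts: dict[str, int] = {}
    for li, ln, minus in zip(locus_draw, len_draw, strand_draw):
        seq = loci[li].sequence
        start = int(rng.integers(0, len(seq) - ln + 1))
        read = seq[start : start + ln]
        if minus:
            read = reverse_complement(read)
        counts[read] = counts.get(read, 0) + 1
    return sorted(counts.items())


def make_reference_set(
    loci: Sequence[ReferenceLocus],
    multimap_copies: Mapping[str, int] | None = None,
    pad: int = 200,
    seed: int = 0,
) -> dict[str, str]:
    """Build a matching background: each locus embedded in random padding,
    repeated ``multimap_copies[id]`` times (default 1) so its reads become
    multi-hit signatures."""
    rng = np.random.default_rng(seed)
    copies = multimap_copies or {}
    refs: dict[str, str] = {}
    for locus in loci:
        n = copies.get(locus.id, 1)
        for c in range(n):
            left = "".join(rng.choice(list("ACGT"), size=pad))
            right = "".join(rng.choice(list("ACGT"), size=pad))
            refs[f"{locus.id}_copy{c + 1}"] = left + locus.sequence + right
    return refs


# ---------------------------------------------------------------------------
# Writers


def write_fasta(records: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_clones_fasta(clones: Sequence[CloneRead], path) -> None:
    """FASTA with the ``>cloneID|genotype|amplicon`` header convention."""
    with open(path, "w") as fh:
        for clone in clones:
            fh.write(f">{clone.id}|{clone.genotype}|{clone.amplicon}\n")
            for i in range(0, len(clone.sequence), 70):
                fh.write(clone.sequence[i : i + 70] + "\n")


def write_srna_tsv(library: Sequence[tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tabundance\n")
        for seq, count in library:
            fh.write(f"{seq}\t{count}\n")


def write_landscape_tsv(locus: ReferenceLocus, landscape: MethylationLandscape, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\toffset\tcontext\tregion\tprobability\n")
        for site in locus.sites:
            fh.write(
                f"{locus.id}\t{site.offset}\t{site.context}\t{site.region}\t"
                f"{landscape.p(site.offset):.6g}\n"
            )
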