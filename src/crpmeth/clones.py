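"""Bisulfite clone alignment, per-site methylation calling and QC.

Each clone is the Sanger sequence of one cloned bisulfite-PCR molecule.
Against the amplicon reference, a reference C read as C is a methylated
call, read as T an unmethylated call (the expected bisulfite event), and
read as A/G (or a gap) an ambiguous call.  A known-unmethylated control
amplicon bounds the conversion-failure artifact: its retained Cs measure
the non-conversion rate, and clones below a conversion threshold are
dropped before reporting.

The default alignment is anchored and ungapped — clones are
primer-delimited amplicons of the reference — with a bisulfite-aware
identity check over non-C reference positions.  A banded gapped mode
(Bio.Align.PairwiseAligner with a C/T-tolerant substitution matrix) is
available for robustness; columns opposite a gap yield no call.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from .reference import CytosineSite, InputError, ReferenceLocus

STATES = ("methylated", "unmethylated", "ambiguous")


class AlignmentRejection(RuntimeError):
    """Clone failed the alignment identity threshold."""


class QCError(RuntimeError):
    """Quality control left no usable clones."""


@dataclass(frozen=True)
class CloneAlignment:
    """1:1 pairing of clone positions onto reference offsets (both 1-based)."""

    clone_id: str
    pairs: tuple[tuple[int, int], ...]  # (ref_offset, clone_pos)
    identity: float  # over non-C reference positions
    bisulfite_events: int  # ref C read as T

    def clone_base_at(self, ref_offset: int, clone_seq: str) -> str | None:
        for ro, cp in self.pairs:
            if ro == ref_offset:
                return clone_seq[cp - 1]
        return None


@dataclass(frozen=True)
class MethylationCall:
    site_offset: int
    clone_id: str
    state: str  # methylated | unmethylated | ambiguous

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise InputError(f"bad call state {self.state!r}")


@dataclass
class ConversionEstimate:
    """Bisulfite conversion efficiency estimated from a control amplicon."""

    rate: float
    n_control_calls: int
    per_clone: dict[str, float] = field(default_factory=dict)


def align_clone(
    clone,
    amplicon: ReferenceLocus,
    mode: str = "anchored-ungapped",
    min_identity: float = 0.9,
    band: int = 5,
) -> CloneAlignment:
    """Align a clone to its amplicon reference, bisulfite-aware.

    Scoring treats reference-C / read-T as a match-equivalent bisulfite
    event; all other mismatches count against identity, which is computed
    over non-C reference positions only (C positions carry the signal and
    must not count as errors either way).  Identity below ``min_identity``
    rejects the clone.
    """
    ref = amplicon.sequence
    read = clone.sequence.upper()
    if mode == "anchored-ungapped":
        if len(read) != len(ref):
            raise AlignmentRejection(
                f"{clone.id}: ungapped mode needs equal lengths "
                f"({len(read)} vs {len(ref)}); use banded-gapped"
            )
        pairs = tuple((i + 1, i + 1) for i in range(len(ref)))
    elif mode == "banded-gapped":
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        # C->T tolerated: score C/T like a match
        matrix = np.full((4, 4), -1.0)
        np.fill_diagonal(matrix, 1.0)
        order = "ACGT"
        matrix[order.index("C"), order.index("T")] = 1.0
        aligner.substitution_matrix = Align.substitution_matrices.Array(
            order, dims=2, data=matrix
        )
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -0.5
        aln = aligner.align(ref, read)[0]
        pairs_list = []
        for (rs, re_), (qs, qe) in zip(*aln.aligned):
            if abs(rs - qs) > band:
                raise AlignmentRejection(f"{clone.id}: alignment outside band {band}")
            for k in range(re_ - rs):
                pairs_list.append((rs + k + 1, qs + k + 1))
        pairs = tuple(pairs_list)
    else:
        raise InputError(f"unknown alignment mode {mode!r}")

    non_c = matches = bis = 0
    for ro, cp in pairs:
        rbase, qbase = ref[ro - 1], read[cp - 1]
        if rbase == "C":
            if qbase == "T":
                bis += 1
            continue
        non_c += 1
        if rbase == qbase:
            matches += 1
    identity = matches / non_c if non_c else 1.0
    if identity < min_identity:
        raise AlignmentRejection(
            f"{clone.id}: non-C identity {identity:.3f} < {min_identity}"
        )
    return CloneAlignment(clone.id, pairs, identity, bis)


def call_sites(
    alignment: CloneAlignment,
    clone,
    sites: list[CytosineSite],
) -> list[MethylationCall]:
    """Per-site calls for one clone; sites outside the pairing are uncovered."""
    read = clone.sequence.upper()
    lookup = {ro: cp for ro, cp in alignment.pairs}
    calls = []
    for site in sites:
        cp = lookup.get(site.offset)
        if cp is None:
            continue  # uncovered, no call
        base = read[cp - 1]
        if base == "C":
            state = "methylated"
        elif base == "T":
            state = "unmethylated"
        else:
            state = "ambiguous"
        calls.append(MethylationCall(site.offset, alignment.clone_id, state))
    return calls


def estimate_conversion(control_calls: list[MethylationCall]) -> ConversionEstimate:
    """Conversion rate from a known-unmethylated control.

    Every informative control call should be unmethylated; retained Cs
    (methylated calls) are conversion failures.  rate = U / (M + U),
    order- and duplication-invariant.
    """
    per_clone_mu: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    m = u = 0
    for call in control_calls:
        if call.state == "methylated":
            m += 1
            per_clone_mu[call.clone_id][0] += 1
        elif call.state == "unmethylated":
            u += 1
            per_clone_mu[call.clone_id][1] += 1
    n = m + u
    if n == 0:
        raise QCError("no informative control calls to estimate conversion from")
    per_clone = {
        cid: (mu[1] / (mu[0] + mu[1])) if (mu[0] + mu[1]) else float("nan")
        for cid, mu in per_clone_mu.items()
    }
    return ConversionEstimate(rate=u / n, n_control_calls=n, per_clone=per_clone)


@dataclass
class QCReport:
    dropped_clones: dict[str, str] = field(default_factory=dict)  # clone -> reason
    warnings: list[str] = field(default_factory=list)
    n_clones_in: int = 0
    n_clones_out: int = 0


def qc_filter(
    calls: list[MethylationCall],
    conversion: ConversionEstimate | None = None,
    min_clones: int = 15,
    min_conversion: float = 0.95,
) -> tuple[list[MethylationCall], QCReport]:
    """Drop clones with measured conversion below threshold; flag low counts.

    A clone without an entry in the conversion estimate's per-clone table
    (the usual case: the control is a separate amplicon) is retained.
    Surviving clone counts below ``min_clones`` produce a warning, not a
    failure; zero surviving clones is fatal.
    """
    clone_ids = sorted({c.clone_id for c in calls})
    report = QCReport(n_clones_in=len(clone_ids))
    dropped = set()
    if conversion is not None:
        for cid in clone_ids:
            rate = conversion.per_clone.get(cid)
            if rate is not None and rate < min_conversion:
                dropped.add(cid)
                report.dropped_clones[cid] = (
                    f"conversion {rate:.3f} < {min_conversion}"
                )
    kept = [c for c in calls if c.clone_id not in dropped]
    surviving = {c.clone_id for c in kept}
    report.n_clones_out = len(surviving)
    if not surviving:
        raise QCError("all clones dropped by conversion QC")
    if len(surviving) < min_clones:
        report.warnings.append(
            f"only {len(surviving)} clones survive QC (minimum design is {min_clones})"
        )
    return kept, report


# ---------------------------------------------------------------------------
# Call matrices


def calls_to_matrix(
    calls: list[MethylationCall],
    locus: ReferenceLocus,
    genotype: str = "wt",
) -> pd.DataFrame:
    """Long-format call matrix: locus, offset, context, region, clone, state."""
    info = {s.offset: s for s in locus.sites}
    rows = []
    for call in calls:
        site = info.get(call.site_offset)
        if site is None:
            raise InputError(f"call at offset {call.site_offset} has no site in {locus.id}")
        rows.append(
            {
                "locus": locus.id,
                "offset": call.site_offset,
                "context": site.context,
                "region": site.region,
                "clone": call.clone_id,
                "genotype": genotype,
                "state": call.state,
            }
        )
    return pd.DataFrame(
        rows, columns=["locus", "offset", "context", "region", "clone", "genotype", "state"]
    )


def merge_amplicons(
    per_amplicon: dict[str, tuple[pd.DataFrame, int]],
    locus: ReferenceLocus,
) -> pd.DataFrame:
    """Re-index per-amplicon call matrices to locus coordinates and pool.

    ``per_amplicon`` maps amplicon id -> (call matrix in amplicon-local
    offsets, 1-based start of the amplicon within the locus).  In overlap
    zones each amplicon's clones contribute independent calls, so the
    clone count per site may vary along the locus.  A site whose context
    in the amplicon disagrees with the locus inventory is a data error.
    """
    info = {s.offset: s for s in locus.sites}
    frames = []
    for amp_id, (matrix, start) in per_amplicon.items():
        df = matrix.copy()
        df["offset"] = df["offset"] + start - 1
        for off, ctx in zip(df["offset"], df["context"]):
            site = info.get(int(off))
            if site is None:
                raise InputError(
                    f"amplicon {amp_id}: offset {off} is not a cytosine of {locus.id}"
                )
            if ctx != "UNDEF" and site.context != ctx:
                raise InputError(
                    f"amplicon {amp_id}: context {ctx} at locus offset {off} "
                    f"conflicts with locus context {site.context}"
                )
        df["locus"] = locus.id
        df["context"] = [info[int(o)].context for o in df["offset"]]
        df["region"] = [info[int(o)].region for o in df["offset"]]
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    return merged.sort_values(["offset", "clone"], kind="stable").reset_index(drop=True)


def read_clones_fasta(path) -> list:
    """Read clones from FASTA with ``>cloneID|genotype|amplicon`` headers."""
    from .simulate import CloneRead

    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) != 3:
            raise InputError(
                f"clone header {rec.id!r} not in cloneID|genotype|amplicon form"
            )
        clones.append(
            CloneRead(id=fields[0], genotype=fields[1], amplicon=fields[2],
                      sequence=str(rec.seq).upper())
        )
    if not clones:
        raise InputError(f"no clone records in {path}")
    return clones


def pipeline_call_matrix(
    clones,
    locus: ReferenceLocus,
    mode: str = "anchored-ungapped",
    min_identity: float = 0.9,
    genotype: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Align + call every clone against one amplicon; returns (matrix, rejected)."""
    all_calls: list[MethylationCall] = []
    rejected: list[str] = []
    gt = genotype
    for clone in clones:
        if gt is None:
            gt = clone.genotype
        try:
            aln = align_clone(clone, locus, mode=mode, min_identity=min_identity)
        except AlignmentRejection:
            rejected.append(clone.id)
            continue
        all_calls.extend(call_sites(aln, clone, locus.sites))
    return calls_to_matrix(all_calls, locus, genotype=gt or "wt"), rejected
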