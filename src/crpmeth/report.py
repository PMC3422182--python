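"""Methylation summary tables: per-site levels, region x context detection
tallies and overall levels, and wild-type vs mutant comparisons.

Three views of one long-format call matrix:

* per-site: level = methylated / (methylated + unmethylated), in percent;
  ambiguous calls are excluded from numerator and denominator alike.
* region x context detection: a site counts as detected when at least
  ``detection_threshold_clones`` clones call it methylated; the fraction
  of detected sites is reported as a rounded integer percent (the "m/n
  (p %)" accounting of the study's tallies).
* region x context overall level: all informative calls of all sites in
  the cell pooled into one percentage.

Cells with no sites, or a wild-type level of zero in a comparison, are
emitted with an explicit NA marker rather than 0 — a 0-site cell and a
0-level cell are different facts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .reference import CONTEXTS, InputError

REGIONS_ORDER = ("upstream", "cds", "downstream")


@dataclass(frozen=True)
class SiteSummary:
    offset: int
    context: str
    region: str
    n_methylated: int
    n_unmethylated: int
    n_ambiguous: int

    @property
    def n_informative(self) -> int:
        return self.n_methylated + self.n_unmethylated

    @property
    def level(self) -> float:
        """Percent methylation; NaN when no informative calls."""
        if self.n_informative == 0:
            return float("nan")
        return 100.0 * self.n_methylated / self.n_informative


def summarize_sites(matrix: pd.DataFrame) -> list[SiteSummary]:
    """One summary per site of the call matrix (brute-force-checkable tallies)."""
    if matrix.empty:
        raise InputError("empty call matrix")
    out = []
    grouped = matrix.groupby(["offset", "context", "region"], sort=True, dropna=False)
    for (offset, context, region), grp in grouped:
        states = grp["state"].value_counts()
        out.append(
            SiteSummary(
                offset=int(offset),
                context=str(context),
                region=str(region),
                n_methylated=int(states.get("methylated", 0)),
                n_unmethylated=int(states.get("unmethylated", 0)),
                n_ambiguous=int(states.get("ambiguous", 0)),
            )
        )
    return out


def _ordered(values, order):
    seen = [v for v in order if v in values]
    return seen + sorted(set(values) - set(order))


def detection_table(
    summaries: list[SiteSummary],
    detection_threshold_clones: int = 1,
) -> pd.DataFrame:
    """Region x context site-detection tallies.

    A site is detected iff n_methylated >= threshold ("at least some
    methylation" at the default of one clone).  Returns columns region,
    context, n_sites_detected, n_sites_total, detected_pct (rounded
    integer percent, NA for empty cells) and the formatted "m/n (p %)"
    cell replica.
    """
    rows = []
    regions = _ordered({s.region for s in summaries}, REGIONS_ORDER)
    for region in regions:
        for context in CONTEXTS:
            cell = [s for s in summaries if s.region == region and s.context == context]
            n_total = len(cell)
            n_det = sum(1 for s in cell if s.n_methylated >= detection_threshold_clones)
            if n_total:
                pct = round(100.0 * n_det / n_total)
                formatted = f"{n_det}/{n_total} ({pct} %)"
            else:
                pct = float("nan")
                formatted = "NA"
            rows.append(
                {
                    "region": region,
                    "context": context,
                    "n_sites_detected": n_det,
                    "n_sites_total": n_total,
                    "detected_pct": pct,
                    "cell": formatted,
                }
            )
    return pd.DataFrame(rows)


def overall_levels(matrix: pd.DataFrame) -> pd.DataFrame:
    """Region x context overall percent methylation, pooling all informative
    calls of all sites in the cell; empty cells carry NaN and a flag."""
    rows = []
    regions = _ordered(set(matrix["region"]), REGIONS_ORDER)
    for region in regions:
        for context in CONTEXTS:
            cell = matrix[(matrix["region"] == region) & (matrix["context"] == context)]
            n_m = int((cell["state"] == "methylated").sum())
            n_u = int((cell["state"] == "unmethylated").sum())
            informative = n_m + n_u
            level = 100.0 * n_m / informative if informative else float("nan")
            rows.append(
                {
                    "region": region,
                    "context": context,
                    "n_methylated_calls": n_m,
                    "n_informative_calls": informative,
                    "overall_level_pct": level,
                    "defined": informative > 0,
                }
            )
    return pd.DataFrame(rows)


def compare_genotypes(levels_wt: pd.DataFrame, levels_mutant: pd.DataFrame) -> pd.DataFrame:
    """Relative reduction 100 x (1 - mutant/wt) per region x context cell.

    Cells where the wild-type level is 0 (or undefined) are reported NA:
    a relative reduction has no meaning there.
    """
    key = ["region", "context"]
    if set(map(tuple, levels_wt[key].values)) != set(map(tuple, levels_mutant[key].values)):
        raise InputError("wild-type and mutant level tables cover different cells")
    merged = levels_wt.merge(
        levels_mutant, on=key, suffixes=("_wt", "_mutant"), validate="one_to_one"
    )
    reductions = []
    for _, row in merged.iterrows():
        wt = row["overall_level_pct_wt"]
        mut = row["overall_level_pct_mutant"]
        if not math.isfinite(wt) or wt == 0 or not math.isfinite(mut):
            reductions.append(float("nan"))
        else:
            reductions.append(100.0 * (1.0 - mut / wt))
    out = merged[key].copy()
    out["level_wt_pct"] = merged["overall_level_pct_wt"]
    out["level_mutant_pct"] = merged["overall_level_pct_mutant"]
    out["relative_reduction_pct"] = reductions
    return out


# ---------------------------------------------------------------------------
# Writers


def site_summaries_frame(summaries: list[SiteSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offset": [s.offset for s in summaries],
            "context": [s.context for s in summaries],
            "region": [s.region for s in summaries],
            "n_methylated": [s.n_methylated for s in summaries],
            "n_unmethylated": [s.n_unmethylated for s in summaries],
            "n_ambiguous": [s.n_ambiguous for s in summaries],
            "level_pct": [s.level for s in summaries],
        }
    )


def write_reports(
    summaries: list[SiteSummary],
    detection: pd.DataFrame,
    levels: pd.DataFrame,
    out_dir,
    locus_id: str = "locus",
    comparison: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write the full report set; returns {name: path}.

    TSVs are machine-readable at full precision; the detection-table
    replica carries the formatted "m/n (p %)" cells; the per-site track
    is bedGraph (0-based half-open) plus a BED of contexts.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    df = site_summaries_frame(summaries)
    paths["site_summaries"] = str(out / "site_summaries.tsv")
    df.to_csv(paths["site_summaries"], sep="\t", index=False, na_rep="NA")

    paths["detection_table"] = str(out / "detection_table.tsv")
    detection.to_csv(paths["detection_table"], sep="\t", index=False, na_rep="NA")

    paths["overall_levels"] = str(out / "overall_levels.tsv")
    levels.to_csv(paths["overall_levels"], sep="\t", index=False, na_rep="NA")

    replica = detection.pivot(index="region", columns="context", values="cell")
    replica = replica.reindex([r for r in REGIONS_ORDER if r in replica.index])
    paths["detection_replica"] = str(out / "detection_replica.tsv")
    replica.to_csv(paths["detection_replica"], sep="\t", na_rep="NA")

    paths["levels_bedgraph"] = str(out / "site_levels.bedgraph")
    with open(paths["levels_bedgraph"], "w") as fh:
        for s in sorted(summaries, key=lambda x: x.offset):
            if s.n_informative:
                fh.write(f"{locus_id}\t{s.offset - 1}\t{s.offset}\t{s.level:.4f}\n")

    paths["contexts_bed"] = str(out / "site_contexts.bed")
    with open(paths["contexts_bed"], "w") as fh:
        for s in sorted(summaries, key=lambda x: x.offset):
            fh.write(f"{locus_id}\t{s.offset - 1}\t{s.offset}\t{s.context}\n")

    if comparison is not None:
        paths["genotype_comparison"] = str(out / "genotype_comparison.tsv")
        comparison.to_csv(paths["genotype_comparison"], sep="\t", index=False, na_rep="NA")
    return paths
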