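#!/usr/bin/env python
"""Align the simulated bisulfite clones, call per-site methylation, and
apply conversion QC.

Reads the outputs of 01_simulate.py, estimates the conversion rate from
the control amplicon, drops clones below the 0.95 per-clone conversion
threshold, and writes one long-format call matrix per genotype under
results/calls/.
"""

from pathlib import Path

from crpmeth.clones import (
    MethylationCall,
    align_clone,
    call_sites,
    estimate_conversion,
    pipeline_call_matrix,
    qc_filter,
    read_clones_fasta,
)
from crpmeth.reference import ReferenceLocus, parse_regions, read_locus_fasta

SIM = Path("results/simulated")
OUT = Path("results/calls")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    locus_id, seq = next(iter(read_locus_fasta(SIM / "locus.fa").items()))
    regions = parse_regions((SIM / "regions.txt").read_text().splitlines())
    locus = ReferenceLocus(id=locus_id, sequence=seq, regions=regions)

    control_id, control_seq = next(iter(read_locus_fasta(SIM / "control.fa").items()))
    control = ReferenceLocus(id=control_id, sequence=control_seq)
    control_calls = []
    for clone in read_clones_fasta(SIM / "control_clones.fa"):
        aln = align_clone(clone, control)
        control_calls.extend(call_sites(aln, clone, control.sites))
    conversion = estimate_conversion(control_calls)
    print(f"conversion control: rate {conversion.rate:.4f} "
          f"from {conversion.n_control_calls} calls")

    for genotype in ("wt", "rddm_mutant"):
        clones = read_clones_fasta(SIM / f"clones_{genotype}.fa")
        matrix, rejected = pipeline_call_matrix(clones, locus, genotype=genotype)
        calls = [MethylationCall(int(r.offset), r.clone, r.state)
                 for r in matrix.itertuples()]
        kept, report = qc_filter(calls, conversion, min_clones=15,
                                 min_conversion=0.95)
        kept_ids = {c.clone_id for c in kept}
        filtered = matrix[matrix["clone"].isin(kept_ids)]
        filtered.to_csv(OUT / f"call_matrix_{genotype}.tsv", sep="\t", index=False)
        print(f"{genotype}: {len(clones)} clones in, {len(rejected)} rejected "
              f"at alignment, {len(report.dropped_clones)} dropped by QC, "
              f"{len(kept_ids)} kept; {len(filtered)} calls")
        for warning in report.warnings:
            print(f"  warning: {warning}")


if __name__ == "__main__":
    main()
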