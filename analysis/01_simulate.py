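#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Builds a 1012-bp locus with the studied monomer's region geometry
(430 bp upstream, 369 bp coding, 213 bp downstream) and per-region
CG/CHG/CHH site counts, then simulates bisulfite clones for a wild type
and an RdDM mutant (f_CHH = 0.25), a fully unmethylated conversion
control, and wild-type / Pol IV-mutant small-RNA libraries.

Writes FASTA/TSV inputs for the later stages under results/simulated/.
"""

from pathlib import Path

from crpmeth import simulate as sim

OUT = Path("results/simulated")
SEED = 2012


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    locus = sim.make_locus(430, 369, 213, seed=SEED, locus_id="crp_locus")
    sim.write_fasta({locus.id: locus.sequence}, OUT / "locus.fa")
    with open(OUT / "regions.txt", "w") as fh:
        for reg in locus.regions:
            fh.write(f"{reg.name}={reg.start}..{reg.end}\n")
    print(f"locus: {len(locus)} bp, {len(locus.sites)} cytosine sites")
    for name in ("upstream", "cds", "downstream"):
        counts = {c: len(locus.sites_in(region=name, context=c))
                  for c in ("CG", "CHG", "CHH")}
        print(f"  {name}: {counts}")

    cfg = sim.SimulationConfig(n_clones=200, conversion_rate=0.995, seed=SEED)
    for genotype, factors in (("wt", {}), ("rddm_mutant", {"CHH": 0.25})):
        effect = sim.GenotypeEffect(genotype, factors)
        landscape = sim.simulate_landscape(locus, sim.CRP4_LIKE_RATES, effect)
        clones, _ = sim.simulate_clones(locus, landscape, cfg, genotype=genotype)
        sim.write_clones_fasta(clones, OUT / f"clones_{genotype}.fa")
        sim.write_landscape_tsv(locus, landscape, OUT / f"landscape_{genotype}.tsv")
        print(f"{genotype}: {len(clones)} clones written")

    control_locus, control_clones = sim.simulate_control_amplicon(600, cfg)
    sim.write_fasta({control_locus.id: control_locus.sequence}, OUT / "control.fa")
    sim.write_clones_fasta(control_clones, OUT / "control_clones.fa")
    print(f"conversion control: {len(control_clones)} clones, "
          f"{len(control_locus.sites)} sites")

    # two target loci plus a background locus (all the other genomic sRNA
    # sources); the Pol IV mutant depletes only the targets, so their share
    # of the fixed-size library collapses
    srna_loci = [sim.make_locus(60, 150, 60, context_density_profile={},
                                seed=SEED + i, locus_id=f"srna_locus{i}")
                 for i in (1, 2)]
    background = sim.make_locus(200, 400, 200, context_density_profile={},
                                seed=SEED + 9, locus_id="background")
    srna_loci.append(background)
    sim.write_fasta({l.id: l.sequence for l in srna_loci}, OUT / "srna_loci.fa")
    expression = {"srna_locus1": 3.0, "srna_locus2": 1.0, "background": 4.0}
    for genotype, factors in (("wt", None),
                              ("polIV_mutant", {"srna_locus1": 0.05,
                                                "srna_locus2": 0.05})):
        lib = sim.simulate_srna_library(
            srna_loci, expression,
            {21: 0.05, 22: 0.05, 23: 0.1, 24: 0.8},
            total_reads=10_000, genotype_effect_factors=factors,
            seed=SEED + (0 if genotype == "wt" else 7))
        sim.write_srna_tsv(lib, OUT / f"srna_{genotype}.tsv")
        print(f"sRNA {genotype}: {sum(n for _, n in lib)} reads, "
              f"{len(lib)} signatures")


if __name__ == "__main__":
    main()
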