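#!/usr/bin/env python
"""Run the in-silico MSAP screen: wild type vs CHH-erased mutant.

Constructs a screen locus in which the methylation-sensitive enzyme's
recognition site (EcoT22I, ATGCAT) carries a CHH cytosine that is
methylated in the wild type and unmethylated in the RdDM mutant, digests
both states with EcoT22I + MseI, applies the amplification filter, and
reports the polymorphic bands — the in-silico analogue of the gel
polymorphism that flagged the repeat fragments in the first place.
Outputs under results/msap/.
"""

from pathlib import Path

import numpy as np

from crpmeth import msap as ms

OUT = Path("results/msap")
SEED = 2012


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    # G/T spacers cannot spawn extra TTAA or ATGCAT sites
    spacer = lambda n: "".join(rng.choice(list("GT"), size=n))
    seq = (spacer(70) + "TTAA" + spacer(90) + "ATGCAT" + spacer(90)
           + "TTAA" + spacer(70))
    esite = ms.find_sites(seq, ms.ECOT22I)[0]
    print(f"screen locus: {len(seq)} bp, EcoT22I site at {esite}, "
          f"MseI sites at {ms.find_sites(seq, ms.MSEI)}")

    # the site's own C (footprint position 4) is a CHH cytosine here
    states = {
        "wt": ms.MethylationState("wt", frozenset([(esite + 3, "+")])),
        "rddm_mutant": ms.MethylationState("rddm_mutant", frozenset()),
    }
    pe = ms.SelectivePrimer("E0", "", "EcoT22I", "")
    pm = ms.SelectivePrimer("M0", "", "MseI", "")
    profiles, masks = {}, {}
    for label, state in states.items():
        mask = {e.name: ms.cut_mask(ms.find_sites(seq, e), state, e)
                for e in (ms.ECOT22I, ms.MSEI)}
        frags = ms.double_digest(
            seq, {e.name: (e, mask[e.name]) for e in (ms.ECOT22I, ms.MSEI)},
            "screen_locus")
        profiles[label] = ms.amplifiable(frags, pe, pm, sample=label)
        masks[label] = mask
        ms.profile_frame(profiles[label]).to_csv(
            OUT / f"profile_{label}.tsv", sep="\t", index=False)
        print(f"{label}: {len(frags)} digest fragments, "
              f"{len(profiles[label].fragments)} amplifiable bands")

    diff = ms.diff_profiles(profiles["wt"], profiles["rddm_mutant"],
                            masks["wt"], masks["rddm_mutant"])
    import pandas as pd

    rows = [{"sample": d["sample"],
             "start": d["fragment"].start, "end": d["fragment"].end,
             "length": d["fragment"].length,
             "left_end": d["fragment"].left_end,
             "right_end": d["fragment"].right_end,
             "changed_sites": ";".join(f"{e}@{s}" for e, s in d["changed_sites"])}
            for d in diff]
    pd.DataFrame(rows, columns=["sample", "start", "end", "length", "left_end",
                                "right_end", "changed_sites"]).to_csv(
        OUT / "polymorphisms.tsv", sep="\t", index=False)
    print(f"\npolymorphic bands: {len(diff)}")
    for row in rows:
        print(f"  only in {row['sample']}: {row['length']} bp "
              f"({row['left_end']}-{row['right_end']}), "
              f"explained by {row['changed_sites']}")


if __name__ == "__main__":
    main()
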