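#!/usr/bin/env python
"""Secondary Vκ→Jκ2 joining by linear RAG scanning from a VκJκ1-based RC.

Applies an inversional primary join of the most distal middle Vκ to Jκ1 —
which inverts the intervening Cer/Sis-containing block and places the
originally inversional middle Vκs in deletional orientation immediately
upstream of the new RC — then simulates Jκ2-bait scanning libraries and
quantifies the two scanning signatures:

* cryptic junctions are used exclusively in convergent orientation in allele
  coordinates (fraction printed below);
* junctions inside the inverted middle block map to the *plus* strand of the
  unrearranged reference, the inversional-appearing pattern that reveals the
  primary inversion.

Writes the rearrangement transform, the per-Vκ usage of the scanning
libraries and the reference-frame region × orientation summary.
"""

import argparse
from pathlib import Path

from kappascan.locus_model import Rearrangement, apply_rearrangement
from kappascan.repertoire_stats import (
    convergent_fraction,
    region_orientation_summary,
    vk_usage_table,
)
from kappascan.synthetic_data import (
    SimulationConfig,
    make_mini_locus,
    simulate_secondary_scanning,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-junctions", type=int, default=20_000)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    locus = make_mini_locus(seed=args.seed)
    rearr = Rearrangement("Vk-m1", "Jk1")
    allele, transform = apply_rearrangement(locus, rearr)
    (args.outdir / "primary_inversion.chain.tsv").write_text(transform.to_tsv())
    flipped = [s.name for s in allele.v_segments
               if s.vk_orientation != locus.segment(s.name).vk_orientation]
    print(f"primary inversional join {rearr.v_name}→{rearr.j_name}: "
          f"{len(flipped)} Vκs flipped to the opposite orientation ({', '.join(flipped)})")

    libraries = []
    for i in range(3):
        cfg = SimulationConfig(
            seed=args.seed + 300 + i,
            n_junctions=args.n_junctions,
            mechanism="scanning_secondary",
        )
        sim = simulate_secondary_scanning(locus, rearr, cfg, replicate_id=f"rep{i + 1}")
        libraries.append(sim.library)

    usage = vk_usage_table(libraries, locus)
    usage = usage[usage.mean_percent > 0]
    usage.to_csv(args.outdir / "vk_usage_secondary.tsv", sep="\t", index=False)
    print("\nVκ usage of Jκ2-bait scanning libraries (mean ± s.e.m.):")
    print(usage[["vk", "mean_percent", "sem_percent"]].round(2).to_string(index=False))

    pooled = libraries[0].with_records(
        [r for lib in libraries for r in lib.records if r.junction_class == "cryptic"]
    )
    res = convergent_fraction(pooled, transform)
    print(f"\ncryptic junctions convergent in allele frame: "
          f"{res.fraction:.3f} (n={res.n_used}, excluded={res.n_excluded})")

    summary = region_orientation_summary(pooled, locus)
    summary.to_csv(args.outdir / "cryptic_region_summary_secondary.tsv", sep="\t", index=False)
    pivot = summary.pivot(index="region", columns="orientation", values="percent").round(1)
    print("\nreference-frame cryptic junctions by region × orientation (%):")
    print(pivot.to_string())
    mid = pivot.loc["middle"]
    within = 100.0 * mid["inversional"] / (mid["inversional"] + mid["deletional"])
    print(f"\nof middle-domain cryptic junctions, {within:.1f}% map to the + strand: "
          "linear scanning across the block inverted by the primary join")


if __name__ == "__main__":
    main()
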