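"""Can noisier perception data masquerade as memory data? Four confound sims.

Simulates reduced SNR, retrieval lapses, associative errors and angular
errors on the perception signal (ROI-correlated draws), refits every
simulated dataset, and scores the fitted location and FWHM against the
memory data's 95% confidence intervals.
"""

import argparse
from pathlib import Path

import pandas as pd

from prftuning import noise, pipeline, synthetic, tuning


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-sims", type=int, default=100)
    ap.add_argument("--bootstrap-n", type=int, default=500)
    ap.add_argument("--table", type=Path, default=Path("results/fixture_table.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    if args.table.exists():
        table = synthetic.read_vertex_table(args.table)
    else:
        table = pipeline.make_fixtures(seed=args.seed)
    rois = sorted(table["roi"].unique())

    memory = {
        roi: tuning.bootstrap_group_fit(
            table, roi, "memory", n=args.bootstrap_n,
            seed=pipeline.stage_seed(args.seed, "memory-ci", i),
        )
        for i, roi in enumerate(rois)
    }

    frames = []
    for family in noise.FAMILIES:
        for level in noise.family_levels(family):
            ds = noise.simulate(family, table, level, n_sims=args.n_sims,
                                seed=pipeline.stage_seed(args.seed, "noise"))
            fits = noise.analyze_simulations(table, ds, rois=rois)
            frames.append(noise.score_against_memory(fits, memory))
    scores = pd.concat(frames, ignore_index=True)
    scores.to_csv(args.outdir / "noise_scores.tsv", sep="\t", index=False, float_format="%.4g")

    print(f"proportion of {args.n_sims} simulations inside the memory 95% CIs:")
    for family, block in scores.groupby("family", sort=False):
        print(f"\n  {family} (levels {list(dict.fromkeys(block['level']))}):")
        for roi, cell in block.groupby("roi", sort=False):
            loc = " ".join(f"{p:4.2f}" for p in cell["prop_location"])
            fw = " ".join(f"{p:4.2f}" for p in cell["prop_fwhm"])
            print(f"    {roi:>4}  location: {loc}   fwhm: {fw}")
    loc0 = scores[(scores.family == "snr") & (scores.level == "p")]["prop_location"]
    locN = scores[(scores.family == "snr") & (scores.level == "m/8")]["prop_location"]
    print(f"\nRaising the noise degrades location reliability (SNR family: mean "
          f"location match {loc0.mean():.2f} at level p vs {locN.mean():.2f} at m/8); "
          f"matching memory FWHM and keeping perception-grade locations are in "
          f"tension across every confound family. Note the memory CIs here come "
          f"from the {table['participant'].nunique()}-participant fixture table "
          f"and are correspondingly wide.")


if __name__ == "__main__":
    main()
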