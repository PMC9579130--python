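"""Polar-angle tuning of perception vs memory: group fits, CIs and contrasts.

Bins each ROI's vertices by polar-angle distance from the stimuli, fits the
difference-of-von-Mises model to the norm-averaged group profile, bootstraps
participants for 68%/95% CIs, and regresses the location / amplitude / FWHM
metrics on task and ROI position across bootstrap replicates.
"""

import argparse
from pathlib import Path

import pandas as pd

from prftuning import pipeline, synthetic, tuning


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bootstrap-n", type=int, default=500)
    ap.add_argument("--table", type=Path, default=Path("results/vertex_table.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    if args.table.exists():
        table = synthetic.read_vertex_table(args.table)
    else:
        table = synthetic.generate_vertex_table(synthetic.GroundTruthConfig(seed=args.seed))
    rois = list(tuning.ROI_ORDER)

    results = pipeline.group_fits(table, rois, n=args.bootstrap_n, master_seed=args.seed)
    fits = pd.DataFrame(
        [pipeline._fit_summary_row(r, t, res) for (r, t), res in results.items()]
    )
    fits.to_csv(args.outdir / "group_fits.tsv", sep="\t", index=False, float_format="%.6g")

    print("group tuning metrics (points with 95% CIs):")
    for _, row in fits.iterrows():
        print(f"  {row['roi']:>4} {row['task']:<10} "
              f"loc {row['location']:+6.1f} [{row['location_ci95_low']:+6.1f},{row['location_ci95_high']:+6.1f}] deg | "
              f"amp {row['amplitude']:5.2f} [{row['amplitude_ci95_low']:4.2f},{row['amplitude_ci95_high']:4.2f}] %sc | "
              f"fwhm {row['fwhm']:6.1f} [{row['fwhm_ci95_low']:5.1f},{row['fwhm_ci95_high']:6.1f}] deg")

    rows = []
    for metric in tuning.METRICS:
        c = tuning.bootstrap_contrasts(results, metric, roi_order=rois)
        for term in c.terms:
            rows.append(dict(metric=metric, term=term, coef=c.point[term],
                             ci95_low=c.ci95[term][0], ci95_high=c.ci95[term][1]))
    contrasts = pd.DataFrame(rows)
    contrasts.to_csv(args.outdir / "contrasts.tsv", sep="\t", index=False, float_format="%.6g")

    print("\ncontrast regressions over bootstrap replicates "
          "(task +0.5 = perception; ROI hierarchy-coded, centered):")
    for _, r in contrasts[contrasts.term != "intercept"].iterrows():
        sig = "*" if r.ci95_low * r.ci95_high > 0 else " "
        print(f"  {r['metric']:<9} {r['term']:<10} beta = {r['coef']:+8.3f} "
              f"95% CI [{r['ci95_low']:+8.3f}, {r['ci95_high']:+8.3f}] {sig}")

    # individual-participant fits, V1 (baseline-removed)
    rf = tuning.participant_response_functions(table, "V1", "perception")
    rfm = tuning.participant_response_functions(table, "V1", "memory")
    ind_p = tuning.individual_fits(rf).set_index("participant")
    ind_m = tuning.individual_fits(rfm).set_index("participant")
    wider = (ind_m["fwhm"] > ind_p["fwhm"]).sum()
    print(f"\nindividual participants with memory FWHM > perception FWHM in V1: "
          f"{wider}/{len(ind_p)} (mean ratio {(ind_m['fwhm']/ind_p['fwhm']).mean():.2f}x)")

    ecc = tuning.eccentricity_response(table, "V1", "perception",
                                       seed=pipeline.stage_seed(args.seed, "ecc"))
    import numpy as np
    peak = ecc.bin_centers[np.nanargmax(ecc.group)]
    print(f"V1 perception eccentricity profile peaks in the bin centered at "
          f"{peak:.2f} dva (stimulus eccentricity 2.0 dva)")


if __name__ == "__main__":
    main()
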