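"""Bidirectional hierarchical pooling model: feedforward vs feedback tuning.

Runs the linear Gaussian-pooling cascade (boxcar stimulus, shared symmetric
kernel), extracts per-layer location / amplitude / FWHM in both directions,
and sweeps depth, stimulus width and kernel size.
"""

import argparse
from pathlib import Path

from prftuning import hierarchy


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = hierarchy.HierarchyConfig()
    ff, fb = hierarchy.run_model(cfg)
    print(f"base model: {cfg.n_layers} layers, {cfg.stimulus_width:.0f} deg boxcar, "
          f"kernel sigma {cfg.kernel_sigma:.0f} deg, grid step {cfg.grid_step} deg")
    print("\nlayer  ff_amp  ff_fwhm   fb_amp  fb_fwhm")
    for l in range(1, cfg.n_layers + 1):
        f = ff.metrics.iloc[l - 1]
        b = fb.metrics.iloc[l - 1]
        print(f"  {l:2d}   {f['amplitude']:.3f}  {f['fwhm']:7.1f}   "
              f"{b['amplitude']:.3f}  {b['fwhm']:7.1f}")
    print("\nFeedforward tuning widens with depth while staying centered; feedback "
          "activity is widest and weakest in layer 1 — the same dissociation the "
          "perception vs memory tuning analysis shows across the visual hierarchy.")

    sweep = hierarchy.parameter_sweep(cfg)
    sweep.to_csv(args.outdir / "hierarchy_sweep.tsv", sep="\t", index=False,
                 float_format="%.6g")
    grid = sweep[sweep.sweep == "stimulus_kernel"]
    print(f"\nsweep: {grid[['stimulus_width','kernel_sigma']].drop_duplicates().shape[0]} "
          f"stimulus x kernel cells x {cfg.n_layers} layers x 2 directions "
          f"({len(grid)} rows) -> {args.outdir/'hierarchy_sweep.tsv'}")


if __name__ == "__main__":
    main()
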