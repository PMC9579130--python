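"""End-to-end orchestration: synthesize -> predict -> fit -> simulate -> report.

`run_all` executes every stage from a single :class:`RunConfig` and writes
tab-separated tables plus a JSON manifest with the resolved configuration,
package version and SHA-256 checksums. Each stage draws its randomness from
a substream of the master seed, so stages are reproducible in isolation and
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import prftuning
from prftuning import hierarchy, noise, synthetic, tuning
from prftuning.forward import ForwardModelSpec, predict_all
from prftuning.apertures import stimulus_apertures


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; serializable to/from YAML."""

    seed: int = 0
    synthetic: synthetic.GroundTruthConfig = field(default_factory=synthetic.GroundTruthConfig)
    forward_variants: tuple = ("dog_css", "css", "linear")
    bootstrap_n: int = 500
    fwhm_reference: str = "zero"
    noise_families: tuple = noise.FAMILIES
    noise_n_sims: int = 20
    hierarchy: hierarchy.HierarchyConfig = field(default_factory=hierarchy.HierarchyConfig)

    def resolved(self) -> "RunConfig":
        """Propagate the master seed into the synthetic config."""
        return dataclasses.replace(
            self, synthetic=dataclasses.replace(self.synthetic, seed=self.seed)
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "synthetic" in d:
            d["synthetic"] = synthetic.GroundTruthConfig.from_dict(d["synthetic"])
        if "hierarchy" in d:
            d["hierarchy"] = hierarchy.HierarchyConfig(**d["hierarchy"])
        for key in ("forward_variants", "noise_families"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic 31-bit per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _fit_summary_row(roi, task, res: tuning.BootstrapResult) -> dict:
    row = {"roi": roi, "task": task}
    for name, val in zip(("mu", "kappa1", "kappa2", "beta1", "beta2"), res.point_fit.params):
        row[name] = val
    row.update(
        location=res.point_metrics.location,
        amplitude=res.point_metrics.amplitude,
        fwhm=res.point_metrics.fwhm,
        fit_r2=res.point_fit.fit_r2,
        n_replicates=res.n_replicates,
        n_failures=res.n_failures,
    )
    for metric in tuning.METRICS:
        for level, ci in (("68", res.ci68[metric]), ("95", res.ci95[metric])):
            row[f"{metric}_ci{level}_low"] = ci[0]
            row[f"{metric}_ci{level}_high"] = ci[1]
    return row


def group_fits(
    table: pd.DataFrame,
    rois,
    tasks=("perception", "memory"),
    n: int = 500,
    master_seed: int = 0,
    fwhm_reference: str = "zero",
) -> dict:
    """Bootstrap group fits for every (ROI, task) cell."""
    results = {}
    for i, roi in enumerate(rois):
        for j, task in enumerate(tasks):
            results[(roi, task)] = tuning.bootstrap_group_fit(
                table,
                roi,
                task,
                n=n,
                seed=stage_seed(master_seed, "fit", i * len(tasks) + j),
                fwhm_reference=fwhm_reference,
            )
    return results


def prediction_evaluation(
    table: pd.DataFrame,
    rois,
    variants=("dog_css", "css", "linear"),
    stim_angles=synthetic.STIM_ANGLES,
) -> pd.DataFrame:
    """Forward-model polar-angle predictions scored against observed profiles.

    Predictions run through the identical binning/averaging pipeline, then
    R2 is computed per (variant, ROI, task) before and after the single
    best-fitting scale factor pooled over all ROIs for that task.
    """
    stimuli = stimulus_apertures(stim_angles)
    rows = []
    for variant in variants:
        spec = ForwardModelSpec(variant=variant)
        pred_rfs = {}
        for roi in rois:
            sub = tuning.select_vertices(table, roi=roi, mode="polar")
            preds = predict_all(sub, stimuli, spec)
            med, _ = tuning.bin_polar_responses(
                sub["polar_angle"].to_numpy(),
                sub["participant"].to_numpy(),
                preds.to_numpy(),
                np.asarray(stim_angles, dtype=float),
            )
            pred_rfs[roi] = tuning.norm_average(med)
        for task in ("perception", "memory"):
            obs = {
                roi: tuning.participant_response_functions(table, roi, task).group
                for roi in rois
            }
            scale = tuning.best_scale_factor(
                [pred_rfs[r] for r in rois], [obs[r] for r in rois]
            )
            for roi in rois:
                ev = tuning.evaluate_predictions(pred_rfs[roi], obs[roi], scale=scale)
                rows.append({"variant": variant, "roi": roi, "task": task, **ev})
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage and write the output tables plus a manifest.

    Outputs: ``vertex_table.tsv``, ``group_fits.tsv``, ``fit_replicates.tsv``,
    ``contrasts.tsv``, ``prediction_eval.tsv``, ``noise_scores.tsv``,
    ``hierarchy_sweep.tsv``, ``run_config.yaml`` and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config.resolved()
    rois = list(config.synthetic.rois)

    table = synthetic.generate_vertex_table(config.synthetic)
    synthetic.validate_vertex_table(table, config.synthetic.stim_angles)
    synthetic.write_vertex_table(table, outdir / "vertex_table.tsv", config.synthetic.stim_angles)

    results = group_fits(
        table,
        rois,
        n=config.bootstrap_n,
        master_seed=config.seed,
        fwhm_reference=config.fwhm_reference,
    )
    fits = pd.DataFrame([_fit_summary_row(r, t, res) for (r, t), res in results.items()])
    fits.to_csv(outdir / "group_fits.tsv", sep="\t", index=False, float_format="%.8g")
    reps = pd.concat(
        [
            res.draws.assign(roi=r, task=t, replicate=np.arange(res.n_replicates))
            for (r, t), res in results.items()
        ],
        ignore_index=True,
    )
    reps.to_csv(outdir / "fit_replicates.tsv", sep="\t", index=False, float_format="%.8g")

    contrast_rows = []
    for metric in tuning.METRICS:
        c = tuning.bootstrap_contrasts(results, metric, roi_order=rois)
        for term in c.terms:
            contrast_rows.append(
                {
                    "metric": metric,
                    "term": term,
                    "coef": c.point[term],
                    "ci95_low": c.ci95[term][0],
                    "ci95_high": c.ci95[term][1],
                    "n_replicates_used": c.n_used,
                }
            )
    pd.DataFrame(contrast_rows).to_csv(
        outdir / "contrasts.tsv", sep="\t", index=False, float_format="%.8g"
    )

    pred_eval = prediction_evaluation(
        table, rois, variants=config.forward_variants,
        stim_angles=config.synthetic.stim_angles,
    )
    pred_eval.to_csv(outdir / "prediction_eval.tsv", sep="\t", index=False, float_format="%.8g")

    memory_results = {roi: results[(roi, "memory")] for roi in rois}
    score_frames = []
    for fam in config.noise_families:
        for level in noise.family_levels(fam):
            ds = noise.simulate(
                fam,
                table,
                level,
                n_sims=config.noise_n_sims,
                seed=stage_seed(config.seed, "noise"),
                stim_angles=config.synthetic.stim_angles,
            )
            fits_df = noise.analyze_simulations(table, ds, rois=rois)
            score_frames.append(noise.score_against_memory(fits_df, memory_results))
    pd.concat(score_frames, ignore_index=True).to_csv(
        outdir / "noise_scores.tsv", sep="\t", index=False, float_format="%.8g"
    )

    sweep = hierarchy.parameter_sweep(config.hierarchy)
    sweep.to_csv(outdir / "hierarchy_sweep.tsv", sep="\t", index=False, float_format="%.8g")

    config.to_yaml(outdir / "run_config.yaml")
    outputs = sorted(p.name for p in outdir.glob("*.tsv")) + ["run_config.yaml"]
    manifest = {
        "package_version": prftuning.__version__,
        "seed": config.seed,
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_fixtures(seed: int = 0) -> pd.DataFrame:
    """Miniature vertex table (2 participants, 2 ROIs, 200 vertices per cell).

    Small enough for fast tests, large enough that the polar-angle bins stay
    populated after gating.
    """
    config = dataclasses.replace(
        synthetic.GroundTruthConfig(),
        n_participants=2,
        rois=("V1", "V3ab"),
        n_vertices_per_roi=200,
        seed=seed,
    )
    table = synthetic.generate_vertex_table(config)
    synthetic.validate_vertex_table(table)
    return table
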