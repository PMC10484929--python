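"""End-to-end orchestration: simulate -> (register) -> build atlas ->
quantify -> group statistics -> report.

A run is fully determined by its config (one seed drives every stochastic
step). Per-animal volumes are generated, optionally mis-posed and registered
back from landmark lines, quantified against an atlas interpolated from
sparse annotations of the first control animal, and the per-region volume
fractions are compared between groups with the exact Mann-Whitney test.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import Atlas, interpolate_atlas
from .registration import LandmarkLine, apply_pose, pose_from_landmarks, PoseZ
from .stats import mann_whitney_exact, summarize
from .synthetic import (
    CohortAnimal,
    PhantomSpec3D,
    generate_annotation_stack,
    generate_brain_volume,
    generate_group_experiment,
    reference_landmarks,
    study_fractions,
)
from .voxel import VoxelClassifierParams, quantify_stack

__all__ = ["RunConfig", "RunReport", "run_end_to_end"]

log = logging.getLogger("brainfrac.pipeline")


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic-cohort run."""

    seed: int
    n_control: int = 6
    n_treated: int = 10
    effect: bool = True  # planted group effect, or a null cohort
    sigma_log: float = 0.15
    phantom: PhantomSpec3D = field(default_factory=PhantomSpec3D)
    mask_threshold: float = 100.0
    k_sigma: float = 2.0
    atlas_n_slices: int = 50
    misalign: bool = False  # random pose per animal + landmark registration
    fdr: bool = False  # Benjamini-Hochberg across regions (off: raw p-values)
    out_dir: str | None = None


@dataclass
class RunReport:
    """All tables of one run; every statistic is recomputable from
    ``per_animal``."""

    per_animal: pd.DataFrame  # animal_id, group, region_id, region_name, ...
    group_summary: pd.DataFrame  # region x group medians [IQR]
    tests: pd.DataFrame  # per-region exact MW results
    truth: pd.DataFrame  # planted per-animal truth fractions
    provenance: dict


def _config_hash(config: RunConfig) -> str:
    d = asdict(config)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _random_pose(rng: np.random.Generator, shape) -> PoseZ:
    """A plausible acquisition mis-pose: small in-plane rotation, near-unit
    scale, a few voxels of translation."""
    theta = rng.uniform(-0.26, 0.26)  # ~15 degrees
    scale = rng.uniform(0.92, 1.08)
    t = rng.uniform(-4, 4, size=3)
    center = np.array([(s - 1) / 2 for s in shape])
    # rotate/scale about the volume center, then shift by t
    pose0 = PoseZ(theta_rad=theta, scale=scale, translation=(0, 0, 0))
    offset = center - pose0.apply(center)[0] + t
    return PoseZ(theta_rad=theta, scale=scale, translation=tuple(offset))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank, idx in list(enumerate(order, start=1))[::-1]:
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def run_end_to_end(config: RunConfig) -> RunReport:
    """Run the whole chain on a simulated cohort and report per-region
    group comparisons. Deterministic given the config."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).generate_state(1)[0])
    ctrl_fr, trt_fr = study_fractions(config.phantom, effect=config.effect)
    animals = generate_group_experiment(
        config.phantom.with_fractions(ctrl_fr),
        config.phantom.with_fractions(trt_fr),
        config.n_control,
        config.n_treated,
        seed=config.seed,
        sigma_log=config.sigma_log,
    )
    params = VoxelClassifierParams(
        mask_threshold=config.mask_threshold, k_sigma=config.k_sigma
    )
    ref_line = reference_landmarks(config.phantom)

    atlas: Atlas | None = None
    rows = []
    truth_rows = []
    for animal in animals:
        log.info("simulating %s (spec hash inputs seed=%d)", animal.animal_id, animal.spec.seed)
        if config.misalign:
            # mis-posed acquisition: render the phantom noise-free, resample
            # into the animal's own frame, then add acquisition noise there,
            # so the acquired stack carries raw (unsmoothed) sensor noise
            clean_spec = replace(animal.spec, noise_sigma=0.0)
            autofluo, antibody, truth = generate_brain_volume(clean_spec)
        else:
            autofluo, antibody, truth = animal.generate()
        if atlas is None:
            # the working atlas: sparse annotations of the first animal's
            # truth, round-tripped through shape-based interpolation
            ann = generate_annotation_stack(truth, config.atlas_n_slices, axis=0)
            atlas = interpolate_atlas(
                ann, truth.atlas.labels.shape, truth.atlas.regions, truth.atlas.spacing_um
            )
        if config.misalign:
            pose = _random_pose(rng, autofluo.shape)
            inv = pose.inverse()
            # acquire into a padded frame so that, after registering back,
            # every reference voxel resamples valid acquired data (no
            # zero-fill steps near the brain)
            pad = np.array([8, 16, 16])
            acq = PoseZ(
                inv.theta_rad,
                inv.scale,
                tuple(np.asarray(inv.translation) + pad),
                inv.scale_z,
            )
            acq_shape = tuple(np.asarray(autofluo.shape) + 2 * pad)
            sample_line = LandmarkLine(
                p0=tuple(acq.apply(np.array(ref_line.p0))[0]),
                p1=tuple(acq.apply(np.array(ref_line.p1))[0]),
            )
            ref_shape = autofluo.shape
            autofluo = apply_pose(autofluo, acq, out_shape=acq_shape, order=1)
            antibody = apply_pose(antibody, acq, out_shape=acq_shape, order=1)
            noise_rng = np.random.default_rng(animal.spec.seed)
            sigma = animal.spec.noise_sigma
            if sigma:
                autofluo.data = autofluo.data + noise_rng.normal(0, sigma, acq_shape)
                antibody.data = antibody.data + noise_rng.normal(0, sigma, acq_shape)
            recovered = pose_from_landmarks(sample_line, ref_line)
            autofluo = apply_pose(autofluo, recovered, out_shape=ref_shape, order=1)
            antibody = apply_pose(antibody, recovered, out_shape=ref_shape, order=1)
        quant = quantify_stack(autofluo, antibody, atlas, params)
        quant.insert(0, "animal_id", animal.animal_id)
        quant.insert(1, "group", animal.group)
        rows.append(quant)
        for rid, f in truth.region_fraction.items():
            truth_rows.append(
                {
                    "animal_id": animal.animal_id,
                    "group": animal.group,
                    "region_id": rid,
                    "truth_fraction_pct": 100.0 * f,
                }
            )
        wb = truth.positive_mask[truth.brain_mask].sum() / truth.brain_mask.sum()
        truth_rows.append(
            {
                "animal_id": animal.animal_id,
                "group": animal.group,
                "region_id": 0,
                "truth_fraction_pct": 100.0 * wb,
            }
        )

    per_animal = pd.concat(rows, ignore_index=True)
    truth_df = pd.DataFrame(truth_rows)

    summaries = []
    tests = []
    for (rid, rname), sub in per_animal.groupby(["region_id", "region_name"], sort=True):
        x = sub.loc[sub.group == "control", "volume_fraction_pct"].to_numpy()
        y = sub.loc[sub.group == "treated", "volume_fraction_pct"].to_numpy()
        for grp, vals in (("control", x), ("treated", y)):
            s = summarize(vals, "median_iqr")
            summaries.append(
                {
                    "region_id": rid,
                    "region_name": rname,
                    "group": grp,
                    "n": s["n"],
                    "median_pct": s["median"],
                    "q25_pct": s["q25"],
                    "q75_pct": s["q75"],
                }
            )
        res = mann_whitney_exact(x, y)
        tests.append(
            {
                "region_id": rid,
                "region_name": rname,
                "U": res.U,
                "n_control": res.n1,
                "n_treated": res.n2,
                "p_two_sided": res.p_two_sided,
                "method": res.method,
            }
        )
    tests_df = pd.DataFrame(tests)
    if config.fdr:
        tests_df["p_adjusted"] = _benjamini_hochberg(tests_df["p_two_sided"].to_numpy())
    summary_df = pd.DataFrame(summaries)
    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
    }
    report = RunReport(
        per_animal=per_animal,
        group_summary=summary_df,
        tests=tests_df,
        truth=truth_df,
        provenance=provenance,
    )
    if config.out_dir:
        _write_report(report, Path(config.out_dir))
    return report


def _write_report(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_animal.to_csv(outdir / "per_animal.csv", index=False)
    report.group_summary.to_csv(outdir / "group_summary.csv", index=False)
    report.tests.to_csv(outdir / "tests.csv", index=False)
    report.truth.to_csv(outdir / "truth.csv", index=False)
    (outdir / "provenance.json").write_text(json.dumps(report.provenance, indent=1))
    lines = ["# Cohort report", "", "## Group comparisons (exact Mann-Whitney)", ""]
    md = report.tests.copy()
    lines.append(md.to_string(index=False))
    lines += ["", "## Group medians [IQR] (% of region volume)", ""]
    lines.append(report.group_summary.to_string(index=False))
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
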