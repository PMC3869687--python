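"""Cohort-level validation experiments.

These are the package's own end-to-end checks, run both by the test suite
and by the results-reproduction script: detection of an injected focal
gray-matter lesion through the full pipeline, type-I-error calibration of
the permutation cluster inference on null cohorts, parameter recovery of
the mixture segmenter, and gray-matter segmentation accuracy against the
phantom ground truth.

Problem sizes (grid, replicate counts) are chosen so a full validation run
completes on a single CPU; the methods note documents them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ct_preprocess import com_init_affine, extract_brain_ct, match_prior_grid
from .head_phantom import (LABELS, AtrophySpec, PhantomSpec,
                           generate_cohort, generate_density_cohort,
                           make_atlas)
from .pipeline import process_subject, run_stats
from .tissue_segmentation import SegmentationConfig, TissuePriorAtlas, fit_mixture
from .volume_io import GridSpec, Volume3D

#: per-arm pipeline settings for the scaled 48^3 / 4 mm cohort experiments
ARM_SETTINGS = {
    "ct": dict(
        seg=dict(sampling_distance_mm=8.0, max_iter=32),
        cutoff_mm=35.0, warp_max_iter=5, warp_sample_points=30000,
        extent_k=15,      # 984 mm^3 at 4 mm voxels, the CT extent volume
    ),
    "mr": dict(
        seg=dict(sampling_distance_mm=8.0, max_iter=24),
        cutoff_mm=25.0, warp_max_iter=4, warp_sample_points=12000,
        extent_k=48,      # 3048 mm^3 at 4 mm voxels, the MR extent volume
    ),
}


def _sphere_mask(grid: GridSpec, atrophy: AtrophySpec) -> np.ndarray:
    ijk = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    world = grid.voxel_to_world(ijk).reshape(*grid.shape, 3)
    c = np.asarray(atrophy.center_mm)
    return ((world - c) ** 2).sum(-1) <= atrophy.radius_mm**2


@dataclass
class DetectionResult:
    modality: str
    n_replicates: int
    n_detected: int
    details: list = field(default_factory=list)

    @property
    def rate(self) -> float:
        return self.n_detected / self.n_replicates


def lesion_detection_rate(
    modality: str = "ct",
    n_replicates: int = 25,
    seed: int = 200,
    spec: PhantomSpec | None = None,
    atrophy: AtrophySpec | None = None,
    atlas: TissuePriorAtlas | None = None,
) -> DetectionResult:
    """Fraction of seeded cohorts (7 controls vs 5 patients) in which the
    full pipeline reports an FDR-significant cluster overlapping the true
    lesion sphere.

    Each replicate draws a fresh cohort, runs every stage (brain extraction
    for CT, segmentation, normalization, smoothing, GLM with random-field
    cluster p-values and Benjamini-Hochberg selection at q = 0.05) and
    checks significant clusters for overlap with the injected sphere.
    """
    spec = spec or PhantomSpec()
    atrophy = atrophy or AtrophySpec()
    atlas = atlas or make_atlas(spec)
    arm = ARM_SETTINGS[modality]
    seg = (SegmentationConfig.ct_default(**arm["seg"]) if modality == "ct"
           else SegmentationConfig.mr_default(**arm["seg"]))
    sphere = _sphere_mask(atlas.grid, atrophy)
    result = DetectionResult(modality, n_replicates, 0)
    for rep in range(n_replicates):
        cohort = generate_cohort(7, 5, spec=spec, atrophy=atrophy,
                                 modality=modality, seed=seed + rep)
        smoothed = [
            process_subject(
                s.image, atlas, seg, atlas.grid,
                cutoff_mm=arm["cutoff_mm"], reg_lambda=0.1,
                affine_max_iter=2, warp_max_iter=arm["warp_max_iter"],
                warp_sample_points=arm["warp_sample_points"], seed=5)
            for s in cohort.subjects
        ]
        maps, table = run_stats(
            smoothed, [s.group for s in cohort.subjects],
            voxel_p=0.005, extent_k=arm["extent_k"], cluster_q=0.05,
            connectivity=18, mode="rft")
        detected = False
        from .vbm_stats import threshold_and_cluster
        clusters = threshold_and_cluster(maps, 0.005, 18, arm["extent_k"])
        sig_sizes = set(
            table.frame.loc[table.frame.fdr_significant, "cluster_size_voxels"])
        for cl in clusters:
            if cl.size in sig_sizes and sphere[tuple(cl.indices.T)].any():
                detected = True
                break
        result.n_detected += detected
        result.details.append(
            {"replicate": rep, "detected": detected,
             "cluster_sizes": [c.size for c in clusters]})
    return result


def null_rejection_rate(
    n_cohorts: int = 200,
    seed: int = 1000,
    spec: PhantomSpec | None = None,
    n_perm: int = 199,
) -> float:
    """Type-I-error of the permutation-mode cluster inference.

    Null cohorts (no lesion, smooth inter-subject variability) are built in
    template space and pushed through smoothing, the GLM, and the
    maximum-cluster-size permutation test at cluster q = 0.05; the returned
    fraction of cohorts with any significant cluster should sit near 0.05.
    """
    spec = spec or PhantomSpec()
    hits = 0
    for i in range(n_cohorts):
        imgs, groups = generate_density_cohort(7, 5, spec=spec, atrophy=None,
                                               seed=seed + i)
        _, table = run_stats(imgs, groups, voxel_p=0.005, extent_k=15,
                             cluster_q=0.05, connectivity=18, mode="perm",
                             n_perm=n_perm, seed=seed + i)
        hits += bool(table.frame["fdr_significant"].any())
    return hits / n_cohorts


def em_parameter_recovery(seed: int = 42) -> dict:
    """Two-class mixture recovery with flat priors at low noise.

    Returns the worst absolute error of the recovered class means (truth 30
    and 70, sd 5) and the hard-assignment accuracy.
    """
    rng = np.random.default_rng(seed)
    grid = GridSpec.isotropic((20, 20, 20), 2.0)
    truth = np.zeros(grid.shape, dtype=int)
    truth[10:] = 1
    data = np.where(truth == 1, 70.0, 30.0) + rng.normal(0, 5.0, grid.shape)
    vol = Volume3D(data, grid.affine, "mr")
    flat = Volume3D(np.full(grid.shape, 0.5), grid.affine, "probability")
    zero = Volume3D(np.zeros(grid.shape), grid.affine, "probability")
    atlas = TissuePriorAtlas(flat, flat, zero, flat)
    cfg = SegmentationConfig(n_gauss=(1, 1, 1, 1), sampling_distance_mm=2.0)
    model, post = fit_mixture(vol, atlas, cfg, seed=seed)
    gm_mean = float(model.means[model.class_of_gauss == 0][0])
    wm_mean = float(model.means[model.class_of_gauss == 1][0])
    lo, hi = sorted([gm_mean, wm_mean])
    mean_err = max(abs(lo - 30.0), abs(hi - 70.0))
    hard = post.gm.data < 0.5 if gm_mean < wm_mean else post.gm.data > 0.5
    acc = float(np.mean(hard.astype(int) == truth))
    return {"max_mean_error": mean_err, "accuracy": max(acc, 1.0 - acc)}


def gm_dice_ct(
    seed: int = 21,
    n_subjects: int = 3,
    spec: PhantomSpec | None = None,
) -> float:
    """Mean Dice of the CT gray-matter posterior (> 0.5) against phantom
    truth at 5 HU noise, on a 2.4 mm grid where partial-volume ambiguity
    does not dominate the score."""
    spec = spec or PhantomSpec(shape=(80, 80, 80), voxel_mm=2.4)
    atlas = make_atlas(spec)
    cfg = SegmentationConfig.ct_default(
        sampling_distance_mm=2 * spec.voxel_mm, max_iter=32)
    cohort = generate_cohort(max(2, n_subjects), 2, spec=spec, atrophy=None,
                             modality="ct", seed=seed)
    dices = []
    for s in cohort.subjects[:n_subjects]:
        _, brain = extract_brain_ct(s.image)
        init = com_init_affine(brain, atlas.grid)
        matched = match_prior_grid(brain, atlas.grid, init)
        _, post = fit_mixture(matched, atlas, cfg, seed=5)
        truth = match_prior_grid(s.truth_labels, atlas.grid, init)
        gm_t = truth.data == LABELS["gm"]
        gm_e = post.gm.data > 0.5
        dices.append(2 * (gm_e & gm_t).sum() / (gm_e.sum() + gm_t.sum()))
    return float(np.mean(dices))
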