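"""End-to-end orchestration: strip -> segment -> normalize -> smooth -> GLM.

One declarative configuration (a YAML file or an equivalent dict) plus a
seed fully determine a run.  Per-subject intermediates (the smoothed,
normalized gray-matter map) are cached inside the results directory, so a
re-run with the same configuration reuses them and reproduces identical
outputs byte for byte.

The CT arm strips the head first; the MR arm runs the identical chain minus
the strip, with the MR segmentation preset and a more flexible warp cutoff
(25 mm vs 35 mm), mirroring the two comparison arms of a CT-vs-MR
morphometry study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ct_preprocess import extract_brain_ct, match_prior_grid
from .errors import CtvbmError
from .head_phantom import AtrophySpec, PhantomSpec, generate_cohort, make_atlas
from .smoothing import smooth_gaussian
from .spatial_normalization import (analysis_grid, apply_normalization,
                                    estimate_affine, estimate_warp)
from .tissue_segmentation import (SegmentationConfig, TissuePriorAtlas,
                                  auto_adjust_gaussians, extract_gray_matter,
                                  fit_mixture)
from .vbm_stats import (ClusterTable, GroupDesign, StatMaps, cluster_p_perm,
                        cluster_p_rft, fdr_select, fit_two_group_glm,
                        make_cluster_table, threshold_and_cluster)
from .volume_io import GridSpec, Volume3D, read_volume, write_volume

DEFAULT_CONFIG = {
    "seed": 7,
    "modality": "ct",
    "out_dir": "ctvbm_results",
    "phantom": None,          # or {n_ctrl, n_pat, severity, shape, voxel_mm, ...}
    "subjects": None,         # or [{id, image, group}, ...]
    "atlas_dir": None,        # None with phantom input -> phantom atlas
    "segmentation": {"auto_adjust": False, "sampling_distance_mm": None,
                     "max_iter": 64},
    "normalization": {"cutoff_mm": None, "reg_lambda": 0.1,
                      "affine_max_iter": 2, "warp_max_iter": 5,
                      "reg_smooth_fwhm_mm": 8.0},
    "analysis_voxel_mm": None,   # None -> template voxel size (no regridding)
    "smoothing_fwhm_mm": 12.0,
    "stats": {"voxel_p": 0.005, "extent_k": 123, "cluster_q": 0.05,
              "connectivity": 18, "mode": "rft", "n_perm": 1000,
              "mask_threshold": 0.05},
}

# default warp cutoffs per arm (shortest represented wavelength, mm)
CUTOFF_MM = {"ct": 35.0, "mr": 25.0}
# default extent thresholds (voxels) per arm, as configuration not semantics
EXTENT_K = {"ct": 123, "mr": 381}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_atlas(atlas_dir) -> TissuePriorAtlas:
    """Load gm/wm/csf priors and the GM template from a directory of NIfTIs."""
    d = Path(atlas_dir)
    return TissuePriorAtlas(
        gm=read_volume(d / "gm_prior.nii.gz", "probability"),
        wm=read_volume(d / "wm_prior.nii.gz", "probability"),
        csf=read_volume(d / "csf_prior.nii.gz", "probability"),
        gm_template=read_volume(d / "gm_template.nii.gz", "probability"),
    )


def save_atlas(atlas: TissuePriorAtlas, atlas_dir) -> Path:
    d = Path(atlas_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(atlas.gm, d / "gm_prior.nii.gz")
    write_volume(atlas.wm, d / "wm_prior.nii.gz")
    write_volume(atlas.csf, d / "csf_prior.nii.gz")
    write_volume(atlas.gm_template, d / "gm_template.nii.gz")
    return d


def process_subject(
    image: Volume3D,
    atlas: TissuePriorAtlas,
    seg_cfg: SegmentationConfig,
    out_grid: GridSpec,
    fwhm_mm: float = 12.0,
    cutoff_mm: float = 35.0,
    reg_lambda: float = 0.1,
    affine_max_iter: int = 2,
    warp_max_iter: int = 5,
    reg_smooth_fwhm_mm: float = 8.0,
    warp_sample_points: int = 30000,
    auto_adjust: bool = False,
    seed: int = 0,
) -> Volume3D:
    """The per-subject chain: (strip,) grid-match, segment, normalize, smooth.

    Normalization parameters are estimated on a smoothed copy of the
    gray-matter map (``reg_smooth_fwhm_mm``) — matching the template's own
    smoothness and denoising the registration objective — and then applied
    to the unsmoothed map.  Returns the smoothed normalized gray-matter
    density on the analysis grid.
    """
    if image.modality == "ct":
        _, image = extract_brain_ct(image)
    matched = match_prior_grid(image, atlas.grid)
    if auto_adjust:
        _, _, post = auto_adjust_gaussians(matched, atlas, seed=seed)
    else:
        _, post = fit_mixture(matched, atlas, seg_cfg, seed=seed)
    gm = extract_gray_matter(post)
    reg_src = (smooth_gaussian(gm, reg_smooth_fwhm_mm)
               if reg_smooth_fwhm_mm > 0 else gm)
    A = estimate_affine(reg_src, atlas.gm_template, max_iter=affine_max_iter)
    params = estimate_warp(reg_src, atlas.gm_template, A, cutoff_mm=cutoff_mm,
                           reg_lambda=reg_lambda, max_iter=warp_max_iter,
                           sample_points=warp_sample_points)
    wgm = apply_normalization(gm, params, out_grid)
    return smooth_gaussian(wgm, fwhm_mm)


def run_stats(
    images: list[Volume3D],
    groups: list[str],
    voxel_p: float = 0.005,
    extent_k: int = 123,
    cluster_q: float = 0.05,
    connectivity: int = 18,
    mode: str = "rft",
    n_perm: int = 1000,
    seed: int = 0,
    mask_threshold: float = 0.05,
) -> tuple[StatMaps, ClusterTable]:
    """GLM + cluster inference on smoothed normalized gray-matter maps.

    ``mode='rft'`` computes uncorrected random-field cluster p-values and
    selects by Benjamini-Hochberg at ``cluster_q`` (topological FDR);
    ``mode='perm'`` computes maximum-cluster-size permutation p-values,
    which are family-wise corrected by construction, and compares them to
    ``cluster_q`` directly.
    """
    design = GroupDesign(images, groups)
    maps = fit_two_group_glm(design, mask_threshold=mask_threshold)
    clusters = threshold_and_cluster(maps, voxel_p=voxel_p,
                                     connectivity=connectivity,
                                     extent_k=extent_k)
    if mode == "rft":
        ps = [cluster_p_rft(c.size, maps, voxel_p=voxel_p) for c in clusters]
        flags = fdr_select(ps, q=cluster_q)
    elif mode == "perm":
        ps = cluster_p_perm(design, [c.size for c in clusters],
                            voxel_p=voxel_p, connectivity=connectivity,
                            n_perm=n_perm, seed=seed,
                            mask_threshold=mask_threshold)
        flags = [p <= cluster_q for p in ps]
    else:
        raise ValueError("stats mode must be 'rft' or 'perm'")
    table = make_cluster_table(clusters, maps, cluster_ps=ps, fdr_flags=flags)
    return maps, table


@dataclass
class VbmResult:
    """Outputs of a pipeline run."""

    out_dir: Path
    maps: StatMaps
    table: ClusterTable
    smoothed: list[Volume3D]
    groups: list[str]


def _phantom_inputs(cfg: dict, modality: str, seed: int):
    ph = dict(cfg["phantom"] or {})
    n_ctrl = int(ph.pop("n_ctrl", 7))
    n_pat = int(ph.pop("n_pat", 5))
    severity = ph.pop("severity", 0.3)
    radius = ph.pop("atrophy_radius_mm", 10.0)
    center = ph.pop("atrophy_center_mm", None)
    spec_kw = {}
    for k in ("shape", "voxel_mm", "ct_noise_sd_hu", "mr_noise_sd",
              "mr_bias_amp", "jitter_warp_mm", "jitter_scale_sd",
              "jitter_rot_deg", "jitter_trans_mm"):
        if k in ph:
            spec_kw[k] = tuple(ph[k]) if k == "shape" else ph[k]
    spec = PhantomSpec(**spec_kw)
    atrophy = None
    if severity and severity > 0:
        kw = {"severity": float(severity), "radius_mm": float(radius)}
        if center is not None:
            kw["center_mm"] = tuple(center)
        atrophy = AtrophySpec(**kw)
    cohort = generate_cohort(n_ctrl, n_pat, spec=spec, atrophy=atrophy,
                             modality=modality, seed=seed)
    images = [(s.subject_id, s.image) for s in cohort.subjects]
    groups = [s.group for s in cohort.subjects]
    return images, groups, spec


def run_vbm(config: dict | str | Path) -> VbmResult:
    """Run the full chain for a cohort from one declarative configuration.

    ``config`` is a YAML path or a dict; unspecified keys take the values in
    ``DEFAULT_CONFIG``.  Subjects come either from ``subjects`` (a list of
    image paths with group labels) or from a ``phantom`` section that
    generates a cohort.  Re-running with an identical configuration reuses
    the per-subject cache and reproduces identical outputs.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    modality = cfg["modality"]
    out_dir = Path(cfg["out_dir"])
    for sub in ("maps", "tables", "logs", "cache"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    if cfg["phantom"] is not None:
        images, groups, spec = _phantom_inputs(cfg, modality, seed)
        atlas = (load_atlas(cfg["atlas_dir"]) if cfg["atlas_dir"]
                 else make_atlas(spec))
    else:
        if not cfg["subjects"]:
            raise CtvbmError("config needs either 'phantom' or 'subjects'")
        if not cfg["atlas_dir"]:
            raise CtvbmError("file-based input requires 'atlas_dir'")
        atlas = load_atlas(cfg["atlas_dir"])
        images, groups = [], []
        for s in cfg["subjects"]:
            images.append((s["id"], read_volume(s["image"], modality)))
            groups.append(s["group"])

    seg_over = cfg["segmentation"]
    seg_cfg = (SegmentationConfig.ct_default() if modality == "ct"
               else SegmentationConfig.mr_default())
    kw = {}
    if seg_over.get("sampling_distance_mm"):
        kw["sampling_distance_mm"] = float(seg_over["sampling_distance_mm"])
    if seg_over.get("max_iter"):
        kw["max_iter"] = int(seg_over["max_iter"])
    if kw:
        from dataclasses import replace
        seg_cfg = replace(seg_cfg, **kw)

    norm = cfg["normalization"]
    cutoff = norm["cutoff_mm"] or CUTOFF_MM[modality]
    if cfg["analysis_voxel_mm"]:
        out_grid = analysis_grid(atlas.grid, float(cfg["analysis_voxel_mm"]))
    else:
        out_grid = atlas.grid

    smoothed = []
    for sid, img in images:
        cache = out_dir / "cache" / f"{sid}_swgm.nii.gz"
        if cache.exists():
            swgm = read_volume(cache, "mr")
        else:
            try:
                swgm = process_subject(
                    img, atlas, seg_cfg, out_grid,
                    fwhm_mm=float(cfg["smoothing_fwhm_mm"]),
                    cutoff_mm=float(cutoff),
                    reg_lambda=float(norm["reg_lambda"]),
                    affine_max_iter=int(norm["affine_max_iter"]),
                    warp_max_iter=int(norm["warp_max_iter"]),
                    reg_smooth_fwhm_mm=float(
                        norm.get("reg_smooth_fwhm_mm", 8.0)),
                    auto_adjust=bool(seg_over.get("auto_adjust", False)),
                    seed=seed,
                )
            except CtvbmError as exc:
                raise CtvbmError(
                    f"subject {sid}: stage failure: {exc}") from exc
            write_volume(Volume3D(swgm.data, swgm.affine, "mr"), cache)
        smoothed.append(swgm)

    st = cfg["stats"]
    maps, table = run_stats(
        smoothed, groups, voxel_p=float(st["voxel_p"]),
        extent_k=int(st["extent_k"]), cluster_q=float(st["cluster_q"]),
        connectivity=int(st["connectivity"]), mode=st["mode"],
        n_perm=int(st["n_perm"]), seed=seed,
        mask_threshold=float(st["mask_threshold"]))

    write_volume(maps.t_map, out_dir / "maps" / "t_map.nii.gz")
    write_volume(maps.z_map, out_dir / "maps" / "z_map.nii.gz")
    table.to_tsv(out_dir / "tables" / "clusters.tsv")
    log = {
        "version": __version__,
        "config": _jsonable(cfg),
        "df": maps.df,
        "resid_fwhm_mm": [float(f) for f in maps.resid_fwhm_mm],
        "n_clusters": int(table.frame["cluster_size_voxels"].nunique()),
    }
    (out_dir / "logs" / "run.json").write_text(json.dumps(log, indent=2))
    return VbmResult(out_dir, maps, table, smoothed, groups)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
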