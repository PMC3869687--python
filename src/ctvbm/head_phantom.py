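"""Synthetic CT/MR head phantoms with known tissue labels.

The phantom is a nested-ellipsoid head: white matter core, a cortical
gray-matter shell with a sinusoidally perturbed inner boundary (a crude
stand-in for gyrification), a thin subarachnoid CSF rim, ellipsoidal
ventricles, a skull shell, scalp, and optionally a detached head-holder
slab under the head.  Tissue intensity models render the same label volume
as CT (Hounsfield units, with a realistically small ~8 HU gray/white
contrast) or as T1-weighted MR (WM > GM > CSF, with an optional smooth
multiplicative bias field).

Cohorts are built by jittering the template geometry per subject (small
random affine plus a smooth random warp) and, for patients, converting a
fraction of gray matter to CSF inside a target sphere — a focal atrophy
model for the medial-temporal gray-matter loss the statistics stage is
meant to detect.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .smoothing import smooth_gaussian
from .tissue_segmentation import TissuePriorAtlas
from .volume_io import GridSpec, Volume3D, write_volume

LABELS = {"air": 0, "skin": 1, "skull": 2, "holder": 3, "csf": 4, "gm": 5, "wm": 6}
_CT_MEANS = {"air": -1000.0, "skin": 40.0, "skull": 1000.0, "holder": 60.0,
             "csf": 8.0, "gm": 35.0, "wm": 27.0}
_MR_MEANS = {"air": 0.0, "skin": 50.0, "skull": 20.0, "holder": 30.0,
             "csf": 10.0, "gm": 60.0, "wm": 90.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity, and inter-subject variability of the phantom.

    Radii and thicknesses are in mm about the grid centre.  ``jitter_*``
    control per-subject variability: independent log-scales (sd
    ``jitter_scale_sd``), rotations (sd ``jitter_rot_deg`` degrees),
    translations (sd ``jitter_trans_mm`` mm), and a smooth random warp of
    peak amplitude ``jitter_warp_mm``.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: float = 4.0
    brain_radii_mm: tuple[float, float, float] = (66.0, 78.0, 62.0)
    gm_thickness_mm: float = 10.0
    gyri_amplitude_mm: float = 2.5
    gyri_wavelength_mm: float = 40.0
    csf_rim_mm: float = 2.5
    skull_thickness_mm: float = 6.0
    skin_thickness_mm: float = 4.0
    ventricle_radii_mm: tuple[float, float, float] = (9.0, 18.0, 10.0)
    ventricle_offset_mm: float = 13.0
    holder: bool = True
    holder_gap_mm: float = 4.0
    holder_thickness_mm: float = 8.0
    ct_noise_sd_hu: float = 5.0
    mr_noise_sd: float = 5.0
    mr_bias_amp: float = 0.1
    jitter_scale_sd: float = 0.02
    jitter_rot_deg: float = 2.0
    jitter_trans_mm: float = 2.0
    jitter_warp_mm: float = 2.0
    supersample: int = 2

    @property
    def grid(self) -> GridSpec:
        return GridSpec.isotropic(self.shape, self.voxel_mm)

    @property
    def fine_grid(self) -> GridSpec:
        """The anatomy grid: ``supersample``-times finer than the render
        grid, so tissue boundaries carry partial-volume fractions instead of
        whole-voxel jumps when block-averaged down."""
        s = max(1, int(self.supersample))
        return GridSpec.isotropic(tuple(d * s for d in self.shape),
                                  self.voxel_mm / s)

    def fine(self) -> "PhantomSpec":
        s = max(1, int(self.supersample))
        return replace(self, shape=tuple(d * s for d in self.shape),
                       voxel_mm=self.voxel_mm / s, supersample=1)


@dataclass(frozen=True)
class AtrophySpec:
    """A spherical focal atrophy target: GM -> CSF conversion.

    ``severity`` is the independent per-voxel probability that a gray-matter
    voxel inside the sphere is reassigned to CSF.  The default centre sits
    in the inferior medial cortical shell, emulating medial-temporal loss.
    """

    center_mm: tuple[float, float, float] = (-20.0, 8.0, -52.0)
    radius_mm: float = 10.0
    severity: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.severity <= 1.0):
            raise ValueError("severity must be in (0, 1]")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


def _world_coords(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ijk = np.indices(grid.shape, dtype=float)
    lin, off = grid.affine[:3, :3], grid.affine[:3, 3]
    x = lin[0, 0] * ijk[0] + lin[0, 1] * ijk[1] + lin[0, 2] * ijk[2] + off[0]
    y = lin[1, 0] * ijk[0] + lin[1, 1] * ijk[1] + lin[1, 2] * ijk[2] + off[1]
    z = lin[2, 0] * ijk[0] + lin[2, 1] * ijk[1] + lin[2, 2] * ijk[2] + off[2]
    return x, y, z


def make_labels(spec: PhantomSpec, seed: int = 0) -> Volume3D:
    """Render the tissue label volume for one (template) head.

    The cortical GM/WM boundary is perturbed by a seeded sum of sinusoids,
    so repeated calls with the same seed are identical.
    """
    r = np.asarray(spec.brain_radii_mm, dtype=float)
    needed = r.max() + spec.csf_rim_mm + spec.skull_thickness_mm \
        + spec.skin_thickness_mm
    half_fov = min(spec.grid.fov_mm) / 2.0
    if needed >= half_fov + spec.voxel_mm:
        raise ValueError("head does not fit the grid: shells exceed the FOV")
    if spec.gm_thickness_mm + spec.gyri_amplitude_mm >= r.min():
        raise ValueError("degenerate geometry: GM shell thicker than brain radius")

    rng = np.random.default_rng(seed)
    grid = spec.grid
    x, y, z = _world_coords(grid)
    rho = np.sqrt((x / r[0]) ** 2 + (y / r[1]) ** 2 + (z / r[2]) ** 2)
    r_nominal = float(r.mean())

    k = 2 * np.pi / spec.gyri_wavelength_mm
    phases = rng.uniform(0, 2 * np.pi, size=6)
    pert = (np.sin(k * x + phases[0]) * np.sin(k * y + phases[1])
            + np.sin(k * y + phases[2]) * np.sin(k * z + phases[3])
            + np.sin(k * z + phases[4]) * np.sin(k * x + phases[5])) / 3.0
    gm_inner = 1.0 - (spec.gm_thickness_mm + spec.gyri_amplitude_mm * pert) \
        / r_nominal

    d_csf = spec.csf_rim_mm / r_nominal
    d_skull = spec.skull_thickness_mm / r_nominal
    d_skin = spec.skin_thickness_mm / r_nominal

    lab = np.full(grid.shape, LABELS["air"], dtype=np.int16)
    lab[rho <= 1.0 + d_csf + d_skull + d_skin] = LABELS["skin"]
    lab[rho <= 1.0 + d_csf + d_skull] = LABELS["skull"]
    lab[rho <= 1.0 + d_csf] = LABELS["csf"]
    lab[rho <= 1.0] = LABELS["gm"]
    lab[rho <= gm_inner] = LABELS["wm"]

    rv = np.asarray(spec.ventricle_radii_mm, dtype=float)
    for sign in (-1.0, 1.0):
        cx = sign * spec.ventricle_offset_mm
        vrho = np.sqrt(((x - cx) / rv[0]) ** 2 + (y / rv[1]) ** 2
                       + (z / rv[2]) ** 2)
        lab[(vrho <= 1.0) & (lab == LABELS["wm"])] = LABELS["csf"]

    if spec.holder:
        z_skin_bottom = -(r[2] + spec.csf_rim_mm + spec.skull_thickness_mm
                          + spec.skin_thickness_mm)
        z_top = z_skin_bottom - spec.holder_gap_mm
        z_bot = z_top - spec.holder_thickness_mm
        in_slab = (z <= z_top) & (z > z_bot) & (np.abs(x) <= r[0]) \
            & (np.abs(y) <= r[1])
        lab[in_slab & (lab == LABELS["air"])] = LABELS["holder"]

    return Volume3D(lab, grid.affine, "label")


def _render(labels: Volume3D, means: dict, noise_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    lab = labels.data
    out = np.zeros(lab.shape, dtype=float)
    for name, code in LABELS.items():
        out[lab == code] = means[name]
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=lab.shape)
    return out


def render_ct(labels: Volume3D, noise_sd_hu: float = 5.0,
              seed: int = 0) -> Volume3D:
    """CT rendering: per-tissue Hounsfield means plus Gaussian noise,
    clipped to the scanner range [-1024, 3071]."""
    rng = np.random.default_rng(seed)
    out = _render(labels, _CT_MEANS, noise_sd_hu, rng)
    return Volume3D(np.clip(out, -1024.0, 3071.0), labels.affine.copy(), "ct")


def _bias_field(shape, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field exp(amp * g) with g scaled to
    [-0.75, 0.75], so max/min sits in [1.2, 1.5] at amp = 0.2."""
    if amp == 0:
        return np.ones(shape)
    ii, jj, kk = np.indices(shape, dtype=float)
    ii, jj, kk = (a / (s - 1) for a, s in zip((ii, jj, kk), shape))
    ph = rng.uniform(0, 2 * np.pi, size=3)
    g = (np.cos(np.pi * ii + ph[0]) + np.cos(np.pi * jj + ph[1])
         + np.cos(np.pi * kk + ph[2]))
    g = g - g.min()
    g = g / g.max() * 1.5 - 0.75
    return np.exp(amp * g)


def render_mr(labels: Volume3D, noise_sd: float = 5.0, bias_amp: float = 0.0,
              seed: int = 0) -> Volume3D:
    """T1-like rendering (WM > GM > CSF) with optional smooth multiplicative
    bias and additive Gaussian noise."""
    rng = np.random.default_rng(seed)
    clean = _render(labels, _MR_MEANS, 0.0, rng)
    clean *= _bias_field(labels.data.shape, bias_amp, rng)
    if noise_sd > 0:
        clean += rng.normal(0.0, noise_sd, size=clean.shape)
    return Volume3D(clean, labels.affine.copy(), "mr")


def apply_atrophy(labels: Volume3D, atrophy: AtrophySpec,
                  seed: int = 0) -> Volume3D:
    """Convert GM to CSF inside the atrophy sphere, independently per voxel
    with probability ``severity``; everything else is untouched."""
    rng = np.random.default_rng(seed)
    x, y, z = _world_coords(labels.grid)
    c = atrophy.center_mm
    in_sphere = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
                 <= atrophy.radius_mm**2)
    gm_in = in_sphere & (labels.data == LABELS["gm"])
    if not gm_in.any():
        raise ValueError("atrophy sphere does not intersect gray matter")
    hit = gm_in & (rng.uniform(size=labels.data.shape) < atrophy.severity)
    out = labels.data.copy()
    out[hit] = LABELS["csf"]
    return Volume3D(out, labels.affine.copy(), "label")


def _tissue_fractions(fine_labels: Volume3D, factor: int) -> np.ndarray:
    """Fractional tissue occupancy (n_labels, coarse shape) by block-averaging
    a fine label volume down by ``factor`` per axis — the partial-volume
    effect of a scanner voxel over sub-voxel anatomy."""
    lab = fine_labels.data
    cs = tuple(s // factor for s in lab.shape)
    fr = np.empty((len(LABELS), *cs))
    for code in LABELS.values():
        ind = (lab == code).astype(float)
        fr[code] = ind.reshape(cs[0], factor, cs[1], factor,
                               cs[2], factor).mean(axis=(1, 3, 5))
    return fr


def _render_fractions(fracs: np.ndarray, means: dict, noise_sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(fracs.shape[1:])
    for name, code in LABELS.items():
        out += fracs[code] * means[name]
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out


def _atrophy_on_fractions(
    fracs: np.ndarray, grid: GridSpec, atrophy: AtrophySpec,
    spec: "PhantomSpec",
) -> np.ndarray:
    """Apply the GM->CSF conversion in fraction space as cortical thinning.

    Focal atrophy presents as coherent tissue destruction, not voxelwise
    salt-and-pepper: all gray matter within a concentric sub-sphere sized to
    hold a ``severity`` share of the target sphere's GM mass is converted to
    CSF wholesale — a full-thickness focal loss like the medial-temporal
    devastation of advanced disease.  The expected in-sphere GM loss equals
    ``severity``, matching the per-voxel Bernoulli model of
    :func:`apply_atrophy`, but the converted core is spatially coherent and
    so survives sub-voxel resampling the way real tissue loss does.
    """
    x, y, z = _world_coords(grid)
    c = atrophy.center_mm
    d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    sph = d2 <= atrophy.radius_mm**2
    gm = fracs[LABELS["gm"]]
    has_gm = sph & (gm > 0)
    if not has_gm.any():
        raise ValueError("atrophy sphere does not intersect gray matter")
    # GM-mass-weighted `severity` quantile of the distance to the centre:
    # everything inside that radius is destroyed
    vals = np.sqrt(d2[has_gm])
    wts = gm[has_gm]
    order = np.argsort(vals)
    cdf = np.cumsum(wts[order]) / wts.sum()
    cut = vals[order][min(np.searchsorted(cdf, atrophy.severity),
                          vals.size - 1)]
    hit = has_gm & (d2 <= cut**2)
    out = fracs.copy()
    out[LABELS["csf"], hit] += out[LABELS["gm"], hit]
    out[LABELS["gm"], hit] = 0.0
    return out


def _warp_fractions(fracs: np.ndarray, grid: GridSpec, A: np.ndarray,
                    disp: np.ndarray) -> np.ndarray:
    """Pull back tissue-fraction channels through affine + warp (trilinear).

    Linear interpolation of fractions is the correct partial-volume model
    for a resampled mixture; channel sums stay 1 with out-of-field mass
    assigned to air.
    """
    ijk = np.indices(grid.shape, dtype=float).reshape(3, -1)
    world = grid.affine[:3, :3] @ ijk + grid.affine[:3, 3:4]
    src_world = A[:3, :3] @ world + A[:3, 3:4] + disp.reshape(3, -1)
    inv = np.linalg.inv(grid.affine)
    vox = inv[:3, :3] @ src_world + inv[:3, 3:4]
    out = np.empty_like(fracs)
    for code in range(fracs.shape[0]):
        cval = 1.0 if code == LABELS["air"] else 0.0
        out[code] = ndimage.map_coordinates(
            fracs[code], vox, order=1, mode="constant", cval=cval,
        ).reshape(grid.shape)
    return out


def _jitter_transform(spec: PhantomSpec, rng: np.random.Generator):
    """A random small affine (template world -> subject world pull-back) and
    a smooth random displacement field generator."""
    s = np.exp(rng.normal(0.0, spec.jitter_scale_sd, size=3))
    ang = np.deg2rad(rng.normal(0.0, spec.jitter_rot_deg, size=3))
    t = rng.normal(0.0, spec.jitter_trans_mm, size=3)
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    A = np.eye(4)
    A[:3, :3] = Rx @ Ry @ Rz @ np.diag(s)
    A[:3, 3] = t
    return A


def _random_warp(grid: GridSpec, amp_mm: float, rng: np.random.Generator):
    """Smooth random displacement field with peak magnitude ``amp_mm``."""
    if amp_mm <= 0:
        return np.zeros((3, *grid.shape))
    x, y, z = _world_coords(grid)
    fov = grid.fov_mm
    d = np.zeros((3, *grid.shape))
    for a in range(3):
        f = np.zeros(grid.shape)
        for _ in range(3):
            kx, ky, kz = (2 * np.pi * rng.integers(1, 3) / fov[i]
                          for i in range(3))
            ph = rng.uniform(0, 2 * np.pi, size=3)
            f += rng.normal() * np.cos(kx * x + ph[0]) \
                * np.cos(ky * y + ph[1]) * np.cos(kz * z + ph[2])
        d[a] = f
    mag = np.sqrt((d**2).sum(axis=0)).max()
    if mag > 0:
        d *= amp_mm / mag
    return d


def _warp_labels(labels: Volume3D, A: np.ndarray, disp: np.ndarray) -> Volume3D:
    """Nearest-neighbour pull-back of a label volume through affine + warp."""
    grid = labels.grid
    ijk = np.indices(grid.shape, dtype=float).reshape(3, -1)
    world = grid.affine[:3, :3] @ ijk + grid.affine[:3, 3:4]
    src_world = A[:3, :3] @ world + A[:3, 3:4] + disp.reshape(3, -1)
    inv = np.linalg.inv(labels.affine)
    vox = inv[:3, :3] @ src_world + inv[:3, 3:4]
    out = ndimage.map_coordinates(labels.data, vox, order=0, mode="constant",
                                  cval=LABELS["air"])
    return Volume3D(out.reshape(grid.shape), labels.affine.copy(), "label")


@dataclass
class Subject:
    subject_id: str
    group: str
    image: Volume3D
    truth_labels: Volume3D


@dataclass
class CohortDataset:
    """A generated two-group cohort with ground-truth labels."""

    subjects: list[Subject]
    spec: PhantomSpec
    atrophy: AtrophySpec | None
    modality: str
    seed: int

    @property
    def groups_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": [s.subject_id for s in self.subjects],
             "group": [s.group for s in self.subjects]})

    def to_dir(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            write_volume(s.image, out / f"{s.subject_id}_{self.modality}.nii.gz")
            write_volume(s.truth_labels, out / f"{s.subject_id}_labels.nii.gz")
        self.groups_table.to_csv(out / "groups.tsv", sep="\t", index=False)
        meta = {"spec": asdict(self.spec), "modality": self.modality,
                "seed": self.seed,
                "atrophy": asdict(self.atrophy) if self.atrophy else None}
        (out / "phantom_spec.json").write_text(json.dumps(meta, indent=2))
        return out


def generate_cohort(
    n_ctrl: int,
    n_pat: int,
    spec: PhantomSpec | None = None,
    atrophy: AtrophySpec | None = None,
    modality: str = "ct",
    seed: int = 0,
) -> CohortDataset:
    """Generate a controls-vs-patients cohort in one modality.

    Each subject is an independently jittered copy of the template head;
    patients additionally carry the atrophy lesion (applied before the
    jitter, so the lesion moves with the anatomy; ``atrophy=None`` builds a
    null cohort).  Anatomy is maintained on a ``spec.supersample``-times
    finer grid and block-averaged to the render grid, so scanner voxels at
    tissue boundaries carry realistic partial-volume fractions.  The
    study-sized design is 7 controls vs 5 patients.
    """
    if n_ctrl < 2 or n_pat < 2:
        raise ValueError("both groups need at least 2 subjects")
    if modality not in ("ct", "mr"):
        raise ValueError("modality must be 'ct' or 'mr'")
    spec = spec or PhantomSpec()
    ss = max(1, int(spec.supersample))
    rng = np.random.default_rng(seed)
    base_seed = int(rng.integers(2**31 - 1))
    if ss > 1:
        base_fine = make_labels(spec.fine(), seed=base_seed)
        base_fracs = _tissue_fractions(base_fine, ss)
    else:
        base_lab = make_labels(spec, seed=base_seed)
        base_fracs = np.stack([
            (base_lab.data == code).astype(float) for code in LABELS.values()
        ])
    means = _CT_MEANS if modality == "ct" else _MR_MEANS
    grid = spec.grid
    patient_fracs = base_fracs
    if atrophy is not None:
        # one thinning band per cohort: the disease affects the same
        # anatomical sub-region in every patient (individualized downstream
        # by each subject's geometric jitter)
        patient_fracs = _atrophy_on_fractions(base_fracs, grid, atrophy, spec)
    subjects = []
    for i in range(n_ctrl + n_pat):
        group = "control" if i < n_ctrl else "patient"
        sub_seed = int(rng.integers(2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        fracs = patient_fracs if group == "patient" else base_fracs
        A = _jitter_transform(spec, sub_rng)
        disp = _random_warp(grid, spec.jitter_warp_mm, sub_rng)
        fracs = _warp_fractions(fracs, grid, A, disp)
        render_rng = np.random.default_rng(int(sub_rng.integers(2**31 - 1)))
        truth = Volume3D(np.argmax(fracs, axis=0).astype(np.int16),
                         grid.affine, "label")
        if modality == "ct":
            data = _render_fractions(fracs, means, spec.ct_noise_sd_hu,
                                     render_rng)
            img = Volume3D(np.clip(data, -1024.0, 3071.0), grid.affine, "ct")
        else:
            clean = _render_fractions(fracs, means, 0.0, render_rng)
            clean *= _bias_field(grid.shape, spec.mr_bias_amp, render_rng)
            if spec.mr_noise_sd > 0:
                clean += render_rng.normal(0.0, spec.mr_noise_sd,
                                           size=clean.shape)
            img = Volume3D(clean, grid.affine, "mr")
        subjects.append(Subject(f"sub-{i+1:02d}", group, img, truth))
    return CohortDataset(subjects, spec, atrophy, modality, seed)


def make_atlas(spec: PhantomSpec | None = None, prior_fwhm_mm: float = 10.0,
               template_fwhm_mm: float = 6.0, seed: int = 0) -> TissuePriorAtlas:
    """Build template-space tissue priors from the unjittered phantom.

    Class indicator volumes of the template labels are blurred (emulating a
    population average) and renormalized where they overlap; the smoothed
    gray-matter map doubles as the normalization template.
    """
    spec = spec or PhantomSpec()
    lab = make_labels(spec, seed=seed)
    vols = {}
    for name in ("gm", "wm", "csf"):
        ind = (lab.data == LABELS[name]).astype(float)
        vols[name] = smooth_gaussian(
            Volume3D(ind, lab.affine, "probability"), prior_fwhm_mm).data
    total = vols["gm"] + vols["wm"] + vols["csf"]
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-12), 1.0)
    grid = spec.grid
    priors = {k: Volume3D(v * scale, grid.affine, "probability")
              for k, v in vols.items()}
    gm_t = smooth_gaussian(
        Volume3D((lab.data == LABELS["gm"]).astype(float), lab.affine,
                 "probability"), template_fwhm_mm)
    return TissuePriorAtlas(priors["gm"], priors["wm"], priors["csf"], gm_t)


def generate_density_cohort(
    n_ctrl: int,
    n_pat: int,
    spec: PhantomSpec | None = None,
    atrophy: AtrophySpec | None = None,
    seed: int = 0,
    fwhm_mm: float = 12.0,
    noise_sd: float = 0.5,
) -> tuple[list[Volume3D], list[str]]:
    """Template-space smoothed gray-matter density cohort (fast path).

    Skips rendering, segmentation, and normalization: each subject is the
    template GM indicator (atrophied for patients), plus voxelwise Gaussian
    noise of sd ``noise_sd``, smoothed at ``fwhm_mm`` — i.e. exactly what
    the statistics stage would receive from an ideal upstream chain, with
    smooth random fields as inter-subject variability.  Used to calibrate
    the inference machinery at scale; see the methods note.
    """
    if n_ctrl < 2 or n_pat < 2:
        raise ValueError("both groups need at least 2 subjects")
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    base = make_labels(spec, seed=int(rng.integers(2**31 - 1)))
    images, groups = [], []
    for i in range(n_ctrl + n_pat):
        group = "control" if i < n_ctrl else "patient"
        lab = base
        if group == "patient" and atrophy is not None and atrophy.severity > 0:
            lab = apply_atrophy(lab, atrophy,
                                seed=int(rng.integers(2**31 - 1)))
        gm = (lab.data == LABELS["gm"]).astype(float)
        gm = gm + rng.normal(0.0, noise_sd, size=gm.shape)
        vol = smooth_gaussian(Volume3D(gm, lab.affine, "mr"), fwhm_mm)
        images.append(vol)
        groups.append(group)
    return images, groups
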