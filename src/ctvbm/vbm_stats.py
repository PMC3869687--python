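"""Mass-univariate two-group statistics with cluster-level inference.

The analysis follows the classical morphometry chain: globals by the
two-pass mean rule, proportional scaling to a common global, a voxelwise
two-group t contrast (controls minus patients, one-tailed for gray-matter
decrease), t -> Z through the exact distribution functions, voxel
thresholding at an uncorrected p, connected-component clustering with an
extent threshold, and cluster-level inference either through the
Gaussian-random-field expected-cluster-extent approximation followed by
Benjamini-Hochberg selection across clusters (topological FDR), or through
a label-permutation maximum-cluster-size null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, gamma

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError
from .volume_io import GridSpec, Volume3D
from .ct_preprocess import BrainMask

GROUP_CONTROL = "control"
GROUP_PATIENT = "patient"

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def compute_global(vol: Volume3D) -> float:
    """Global signal by the two-pass mean rule: the mean over voxels whose
    value exceeds (overall mean) / 8."""
    data = np.asarray(vol.data, dtype=float)
    if float(np.ptp(data)) == 0.0 and float(data.max()) <= 0:
        raise DegenerateInputError("cannot compute a global on a non-positive volume")
    thresh = data.mean() / 8.0
    sel = data > thresh
    if not sel.any():
        raise DegenerateInputError("no voxel exceeds mean/8; global undefined")
    return float(data[sel].mean())


def proportional_scale(
    images: list[Volume3D], globals_: list[float]
) -> list[Volume3D]:
    """Rescale every image so its global equals the cohort mean global."""
    if len(images) != len(globals_):
        raise ValueError("one global per image required")
    g = np.asarray(globals_, dtype=float)
    if np.any(g <= 0):
        raise ValueError("globals must be positive")
    target = float(g.mean())
    return [
        Volume3D(img.data * (target / gi), img.affine.copy(), "mr")
        for img, gi in zip(images, g)
    ]


@dataclass
class GroupDesign:
    """A two-group voxelwise design: images, labels, and globals."""

    images: list[Volume3D]
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.images) != len(self.groups):
            raise ValueError("one group label per image required")
        bad = set(self.groups) - {GROUP_CONTROL, GROUP_PATIENT}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if self.n_control < 2 or self.n_patient < 2:
            raise ValueError("both groups need at least 2 images")
        shapes = {img.data.shape for img in self.images}
        if len(shapes) != 1:
            raise ValueError("all images must share one grid")
        aff0 = self.images[0].affine
        for img in self.images:
            if not np.allclose(img.affine, aff0, atol=1e-6):
                raise ValueError("all images must share one grid affine")

    @property
    def n_control(self) -> int:
        return sum(g == GROUP_CONTROL for g in self.groups)

    @property
    def n_patient(self) -> int:
        return sum(g == GROUP_PATIENT for g in self.groups)

    @property
    def grid(self) -> GridSpec:
        return self.images[0].grid

    def data_matrix(self) -> np.ndarray:
        return np.stack([np.asarray(i.data, dtype=float).ravel()
                         for i in self.images])

    def scaled(self) -> "GroupDesign":
        """Proportionally scaled copy of the design."""
        globals_ = [compute_global(img) for img in self.images]
        return GroupDesign(proportional_scale(self.images, globals_),
                           list(self.groups))


@dataclass
class StatMaps:
    """Voxelwise t and Z maps with their inference metadata."""

    t_map: Volume3D
    z_map: Volume3D
    df: int
    analysis_mask: BrainMask
    resid_fwhm_mm: np.ndarray
    n_zero_variance: int = 0

    @property
    def grid(self) -> GridSpec:
        return self.t_map.grid


def _two_group_t(Y: np.ndarray, is_ctrl: np.ndarray) -> tuple[np.ndarray, int]:
    """Pooled-variance two-sample t (control minus patient) per column."""
    n1 = int(is_ctrl.sum())
    n2 = int((~is_ctrl).sum())
    m1 = Y[is_ctrl].mean(axis=0)
    m2 = Y[~is_ctrl].mean(axis=0)
    ss1 = ((Y[is_ctrl] - m1) ** 2).sum(axis=0)
    ss2 = ((Y[~is_ctrl] - m2) ** 2).sum(axis=0)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return t, df


def _residual_fwhm(Y: np.ndarray, is_ctrl: np.ndarray, mask: np.ndarray,
                   grid: GridSpec) -> np.ndarray:
    """Estimate residual smoothness per axis from standardized residual
    spatial derivatives (Gaussian autocorrelation model).

    For a unit-variance Gaussian-autocorrelated field, E[(de/dx)^2] =
    1/(2 sigma^2), hence FWHM = sqrt(8 ln 2) * sigma = sqrt(4 ln 2 / lambda)
    in voxel units, converted to mm by the voxel size.
    """
    R = Y.copy()
    R[is_ctrl] -= R[is_ctrl].mean(axis=0)
    R[~is_ctrl] -= R[~is_ctrl].mean(axis=0)
    sd = R.std(axis=0)
    good = mask.ravel() & (sd > 0)
    Rn = np.zeros_like(R)
    Rn[:, good] = R[:, good] / sd[good]
    vol_shape = grid.shape
    fwhm = np.zeros(3)
    maskv = good.reshape(vol_shape)
    for a in range(3):
        d = np.diff(Rn.reshape(-1, *vol_shape), axis=a + 1)
        m = np.logical_and(np.take(maskv, range(0, vol_shape[a] - 1), axis=a),
                           np.take(maskv, range(1, vol_shape[a]), axis=a))
        lam = float((d[:, m] ** 2).mean()) if m.any() else np.nan
        if not np.isfinite(lam) or lam <= 0:
            fwhm[a] = np.inf
        else:
            fwhm[a] = np.sqrt(4.0 * np.log(2.0) / lam) * grid.voxel_size_mm[a]
    return fwhm


def fit_two_group_glm(
    design: GroupDesign,
    mask_threshold: float = 0.05,
    scale: bool = True,
) -> StatMaps:
    """Two-group voxelwise GLM (cell means), controls minus patients.

    Inputs are proportionally scaled unless ``scale=False``.  The analysis
    mask keeps voxels whose across-subject mean density exceeds
    ``mask_threshold``, suppressing spurious edge clusters.  Voxels with
    zero residual variance get t = 0 and are counted on the result.
    """
    d = design.scaled() if scale else design
    Y = d.data_matrix()
    is_ctrl = np.array([g == GROUP_CONTROL for g in d.groups])
    mask = Y.mean(axis=0) > mask_threshold
    if not mask.any():
        raise DegenerateInputError("analysis mask is empty")
    t, df = _two_group_t(Y, is_ctrl)
    t = np.where(mask, t, 0.0)
    sd = Y.std(axis=0)
    n_zero = int(np.sum(mask & (sd == 0)))
    z = t_to_z(t, df)
    grid = d.grid
    shape = grid.shape
    fwhm = _residual_fwhm(Y, is_ctrl, mask.reshape(shape), grid)
    return StatMaps(
        t_map=Volume3D(t.reshape(shape), grid.affine, "mr"),
        z_map=Volume3D(z.reshape(shape), grid.affine, "mr"),
        df=df,
        analysis_mask=BrainMask(mask.reshape(shape)),
        resid_fwhm_mm=fwhm,
        n_zero_variance=n_zero,
    )


def t_to_z(t, df: int):
    """Map t deviates to unit-normal deviates through the exact tails.

    Computed via the complementary tail functions on |t| and re-signed, so
    |t| up to ~40 maps without saturating double precision.  Vectorized.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t_arr = np.asarray(t, dtype=float)
    p_upper = stats.t.sf(np.abs(t_arr), df)
    z = stats.norm.isf(p_upper)
    out = np.sign(t_arr) * z
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def t_upper_p(t, df: int):
    """Upper-tail probability of a t deviate (the table's "peak P")."""
    return stats.t.sf(t, df)


@dataclass
class Cluster:
    """A suprathreshold connected component."""

    indices: np.ndarray          # (n, 3) voxel indices
    size: int


def threshold_and_cluster(
    maps: StatMaps,
    voxel_p: float = 0.005,
    connectivity: int = 18,
    extent_k: int = 0,
) -> list[Cluster]:
    """Threshold the t map at an uncorrected upper-tail p and cluster.

    Suprathreshold voxels (inside the analysis mask) are labelled as
    connected components at 6, 18 or 26 connectivity; components smaller
    than ``extent_k`` voxels are discarded.  Clusters are returned sorted
    by size, descending.
    """
    if not (0.0 < voxel_p < 1.0):
        raise ValueError("voxel_p must be in (0, 1)")
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    t_crit = stats.t.isf(voxel_p, maps.df)
    supra = (maps.t_map.data > t_crit) & maps.analysis_mask.mask
    labels, n = ndimage.label(supra, structure=_STRUCTS[connectivity])
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if idx.shape[0] >= extent_k:
            clusters.append(Cluster(indices=idx, size=int(idx.shape[0])))
    clusters.sort(key=lambda c: -c.size)
    return clusters


def _rft_quantities(maps: StatMaps, voxel_p: float):
    """Expected cluster count and suprathreshold volume (in voxels) for a
    thresholded smooth t-field on the analysis mask.

    The expected cluster count is resels times the 3-D Euler-characteristic
    density of a t-field with the map's degrees of freedom at the t
    threshold (Worsley's formula); the expected suprathreshold volume is
    exactly ``S * voxel_p`` by definition of the threshold.
    """
    fwhm_vox = np.asarray(maps.resid_fwhm_mm) / maps.grid.voxel_size_mm
    if not np.all(np.isfinite(fwhm_vox)):
        raise DegenerateInputError("non-finite residual smoothness estimate")
    S = maps.analysis_mask.n_voxels
    nu = float(maps.df)
    u = stats.t.isf(voxel_p, maps.df)
    resels = S / float(np.prod(fwhm_vox))
    ec3 = ((4 * np.log(2.0)) ** 1.5 / (2 * np.pi) ** 2
           * (1 + u**2 / nu) ** (-(nu - 1) / 2.0)
           * ((nu - 1) / nu * u**2 - 1))
    Em = resels * max(ec3, 1e-300)
    EN = S * voxel_p
    return max(Em, 1e-12), EN


def cluster_p_rft(
    cluster_size: int,
    maps: StatMaps,
    voxel_p: float = 0.005,
    corrected: bool = False,
) -> float:
    """Cluster p-value from the Gaussian-random-field expected-extent model.

    With expected cluster count ``E[m]`` and expected suprathreshold volume
    ``E[N]`` at the chosen threshold, a single cluster's extent ``n`` (in
    voxels) satisfies ``P(n >= k) = exp(-beta k^(2/3))`` with ``beta =
    (Gamma(5/2) E[m] / E[N])^(2/3)``.  ``corrected=True`` returns the
    family-wise version ``1 - exp(-E[m] P(n >= k))``, comparable to the
    maximum-cluster-size permutation p.
    """
    if cluster_size <= 0:
        return 1.0
    Em, EN = _rft_quantities(maps, voxel_p)
    beta = (gamma(2.5) * Em / EN) ** (2.0 / 3.0)
    p_unc = float(np.exp(-beta * cluster_size ** (2.0 / 3.0)))
    if not corrected:
        return min(max(p_unc, np.finfo(float).tiny), 1.0)
    return float(min(1.0, -np.expm1(-Em * p_unc)))


def cluster_p_perm(
    design: GroupDesign,
    observed_sizes: list[int],
    voxel_p: float = 0.005,
    connectivity: int = 18,
    n_perm: int = 1000,
    seed: int = 0,
    mask_threshold: float = 0.05,
    scale: bool = True,
) -> list[float]:
    """Permutation cluster p-values from the maximum-cluster-size null.

    Group labels are permuted ``n_perm`` times; for each permutation the
    maximum suprathreshold cluster size is recorded, and each observed
    cluster gets ``p = (1 + #{perm max >= observed}) / (n_perm + 1)``.
    These p-values are corrected for the search over the whole volume by
    construction (maximum statistic).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(design.groups)
    n1 = design.n_control
    if comb(n, n1) < 20:
        raise ValueError(
            f"only {comb(n, n1)} distinct group assignments; need >= 20")
    d = design.scaled() if scale else design
    Y = d.data_matrix()
    mask = Y.mean(axis=0) > mask_threshold
    Ym = Y[:, mask]
    shape = d.grid.shape
    struct = _STRUCTS[connectivity]
    rng = np.random.default_rng(seed)
    df = n - 2
    t_crit = stats.t.isf(voxel_p, df)

    max_sizes = np.zeros(n_perm, dtype=int)
    idx = np.arange(n)
    supra_vol = np.zeros(shape, dtype=bool)
    flat_mask = np.flatnonzero(mask)
    for p in range(n_perm):
        perm = rng.permutation(idx)
        is_ctrl = np.zeros(n, dtype=bool)
        is_ctrl[perm[:n1]] = True
        t, _ = _two_group_t(Ym, is_ctrl)
        supra_vol.ravel()[flat_mask] = t > t_crit
        labels, nlab = ndimage.label(supra_vol, structure=struct)
        if nlab:
            sizes = np.bincount(labels.ravel())[1:]
            max_sizes[p] = int(sizes.max())
        supra_vol.ravel()[flat_mask] = False
    return [
        float((1 + int(np.sum(max_sizes >= s))) / (n_perm + 1)) if s > 0 else 1.0
        for s in observed_sizes
    ]


def fdr_select(cluster_ps: list[float], q: float = 0.05) -> list[bool]:
    """Benjamini-Hochberg step-up selection over cluster p-values."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    if len(cluster_ps) == 0:
        return []
    reject, *_ = multipletests(cluster_ps, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject]


TABLE_COLUMNS = [
    "cluster_size_voxels", "volume_mm3", "peak_p_uncorrected", "peak_t",
    "peak_z", "x_mm", "y_mm", "z_mm", "cluster_p", "fdr_significant",
]

PUBLICATION_COLUMNS = {
    "cluster_size_voxels": "Cluster size, voxels",
    "peak_p_uncorrected": "Peak P (uncorrected)",
    "peak_t": "Peak t value",
    "peak_z": "Peak Z value",
}


@dataclass
class ClusterTable:
    """The reporting schema: one row per local peak, up to three per cluster."""

    frame: pd.DataFrame

    def to_publication_table(self) -> pd.DataFrame:
        """Columns named and ordered as in a standard morphometry results
        table: cluster size, peak P (uncorrected), peak t, peak Z, and the
        peak coordinate."""
        df = self.frame.rename(columns=PUBLICATION_COLUMNS)
        cols = ["Cluster size, voxels", "Peak P (uncorrected)",
                "Peak t value", "Peak Z value", "x_mm", "y_mm", "z_mm"]
        return df[cols]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _cluster_peaks(cluster: Cluster, t_flat: np.ndarray, shape,
                   grid: GridSpec, max_peaks: int, min_dist_mm: float):
    """Greedy selection of up to ``max_peaks`` local peaks >= min_dist apart."""
    flat = np.ravel_multi_index(cluster.indices.T, shape)
    order = np.argsort(-t_flat[flat])
    world = grid.voxel_to_world(cluster.indices[order].astype(float))
    chosen: list[int] = []
    for i in range(order.size):
        if len(chosen) >= max_peaks:
            break
        if all(np.linalg.norm(world[i] - world[j]) >= min_dist_mm
               for j in chosen):
            chosen.append(i)
    return [(cluster.indices[order[i]], world[i]) for i in chosen]


def make_cluster_table(
    clusters: list[Cluster],
    maps: StatMaps,
    grid: GridSpec | None = None,
    cluster_ps: list[float] | None = None,
    fdr_flags: list[bool] | None = None,
    max_peaks: int = 3,
    min_peak_dist_mm: float = 8.0,
) -> ClusterTable:
    """Build the results table: peaks, their statistics, world coordinates.

    Rows are sorted by cluster size descending, and by peak t descending
    within a cluster.  ``volume_mm3`` is the cluster size times the voxel
    volume.
    """
    grid = grid or maps.grid
    t_flat = maps.t_map.data.ravel()
    z_flat = maps.z_map.data.ravel()
    voxel_vol = float(np.prod(grid.voxel_size_mm))
    shape = maps.t_map.data.shape
    rows = []
    for ci, cl in enumerate(clusters):
        peaks = _cluster_peaks(cl, t_flat, shape, grid, max_peaks,
                               min_peak_dist_mm)
        for vox, world in peaks:
            fi = np.ravel_multi_index(tuple(vox), shape)
            t_val = float(t_flat[fi])
            rows.append({
                "cluster_size_voxels": cl.size,
                "volume_mm3": cl.size * voxel_vol,
                "peak_p_uncorrected": float(t_upper_p(t_val, maps.df)),
                "peak_t": t_val,
                "peak_z": float(z_flat[fi]),
                "x_mm": float(world[0]),
                "y_mm": float(world[1]),
                "z_mm": float(world[2]),
                "cluster_p": (float(cluster_ps[ci])
                              if cluster_ps is not None else np.nan),
                "fdr_significant": (bool(fdr_flags[ci])
                                    if fdr_flags is not None else False),
            })
    frame = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return ClusterTable(frame)
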