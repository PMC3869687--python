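"""Spatial normalization of gray-matter maps to a template.

A 12-parameter affine (translation, rotation, log-scale, shear) is estimated
first by minimizing the mean squared intensity difference — after optimal
global intensity scaling — between the warped source and the template,
starting from a centre-of-mass plus second-moment initialisation.  A
nonlinear refinement then optimizes the coefficients of a separable
low-frequency cosine (DCT) displacement basis under a membrane-energy
penalty, by Gauss-Newton with step halving (so the objective trace is
monotone non-increasing by construction).

Conventions: the affine maps *template* world coordinates to *source* world
coordinates (a pull-back), and the displacement field (in mm, one component
per world axis) is added in source world space:

    y(x) = A x + d(x),        source sampled at y, compared to template(x).

The "cutoff" is the shortest spatial wavelength the basis represents, in mm;
the number of basis functions per axis is ``max(2, floor(FOV_mm / cutoff))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from ._basis import dct_basis, separable_field
from .errors import RegistrationError
from .volume_io import GridSpec, Volume3D

DEFAULT_ANALYSIS_VOXEL_MM = 2.0


def n_basis_functions(fov_mm: float, cutoff_mm: float) -> int:
    """Basis functions per axis for a given field of view and cutoff."""
    return max(2, int(np.floor(fov_mm / cutoff_mm)))


@dataclass
class NormalizationParams:
    """Affine + cosine-basis warp mapping template space onto a subject."""

    affine: np.ndarray                       # template world -> source world
    warp_coeffs: np.ndarray                  # (3, n1, n2, n3), mm
    cutoff_mm: float
    reg_lambda: float
    template_grid: GridSpec
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.warp_coeffs = np.asarray(self.warp_coeffs, dtype=float)
        if not np.all(np.isfinite(self.affine)) or not np.all(
            np.isfinite(self.warp_coeffs)
        ):
            raise RegistrationError("non-finite normalization parameters")

    @classmethod
    def identity(cls, template_grid: GridSpec, cutoff_mm: float = 35.0,
                 reg_lambda: float = 0.1) -> "NormalizationParams":
        n = [n_basis_functions(f, cutoff_mm) for f in template_grid.fov_mm]
        return cls(np.eye(4), np.zeros((3, *n)), cutoff_mm, reg_lambda,
                   template_grid)

    def displacement(self, grid: GridSpec) -> np.ndarray:
        """Evaluate the displacement field (3, *grid.shape) in mm on a grid.

        Basis functions are defined over the template grid's voxel axes and
        are evaluated at the (fractional) template-voxel coordinates of the
        requested grid, so any output grid covering the same world space
        sees the same field.
        """
        shape = grid.shape
        ijk = np.indices(shape, dtype=float).reshape(3, -1).T
        world = grid.voxel_to_world(ijk)
        tvox = self.template_grid.world_to_voxel(world)
        n = self.warp_coeffs.shape[1:]
        out = np.empty((3, int(np.prod(shape))))
        # separable evaluation is only valid on a tensor-product grid in
        # template voxel space; fall back to dense evaluation otherwise
        axes_ok = True
        for a in range(3):
            coord = tvox[:, a].reshape(shape)
            ref = np.moveaxis(coord, a, 0)[:, 0, 0]
            if not np.allclose(np.moveaxis(coord, a, 0),
                               ref[:, None, None], atol=1e-6):
                axes_ok = False
                break
        if axes_ok:
            B = []
            for a in range(3):
                coord = np.moveaxis(tvox[:, a].reshape(shape), a, 0)[:, 0, 0]
                B.append(dct_basis(self.template_grid.shape[a], n[a], coord))
            for comp in range(3):
                out[comp] = separable_field(self.warp_coeffs[comp], B).ravel()
        else:  # general (oblique) grids: dense evaluation
            for comp in range(3):
                Ba = [dct_basis(self.template_grid.shape[a], n[a], tvox[:, a])
                      for a in range(3)]
                phi = Ba[0][:, :, None, None] * Ba[1][:, None, :, None] \
                    * Ba[2][:, None, None, :]
                out[comp] = phi.reshape(tvox.shape[0], -1) @ \
                    self.warp_coeffs[comp].ravel()
        return out.reshape(3, *shape)


def _sample_world(vol: Volume3D, world: np.ndarray, order: int = 1) -> np.ndarray:
    """Trilinear sample of ``vol`` at world-mm points of shape (3, n)."""
    inv = np.linalg.inv(vol.affine)
    vox = inv[:3, :3] @ world + inv[:3, 3:4]
    return ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), vox, order=order,
        mode="constant", cval=0.0, prefilter=False)


def _params_to_affine(theta: np.ndarray) -> np.ndarray:
    """12 parameters -> 4x4: translation(3), rotation(3, rad), log-scale(3),
    shear(3)."""
    t, r, s, h = theta[:3], theta[3:6], theta[6:9], theta[9:12]
    cx, sx = np.cos(r[0]), np.sin(r[0])
    cy, sy = np.cos(r[1]), np.sin(r[1])
    cz, sz = np.cos(r[2]), np.sin(r[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(np.exp(s))
    H = np.array([[1, h[0], h[1]], [0, 1, h[2]], [0, 0, 1]])
    A = np.eye(4)
    A[:3, :3] = Rx @ Ry @ Rz @ S @ H
    A[:3, 3] = t
    return A


def _moments(vol: Volume3D) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-weighted world centroid and per-world-axis standard
    deviations."""
    w = np.clip(np.asarray(vol.data, dtype=float), 0.0, None)
    total = w.sum()
    if total <= 0:
        raise RegistrationError("empty (all-zero) image")
    ijk = np.indices(vol.data.shape, dtype=float).reshape(3, -1)
    world = vol.affine[:3, :3] @ ijk + vol.affine[:3, 3:4]
    wf = w.ravel() / total
    com = world @ wf
    var = ((world - com[:, None]) ** 2) @ wf
    return com, np.sqrt(var)


def _strided_grid(grid: GridSpec, max_points: int = 30000) -> GridSpec:
    """Coarsen a grid by an integer stride so it has at most ~max_points."""
    stride = 1
    while np.prod(np.ceil(np.array(grid.shape) / stride)) > max_points:
        stride += 1
    if stride == 1:
        return grid
    shape = tuple(int(np.ceil(s / stride)) for s in grid.shape)
    affine = grid.affine.copy()
    affine[:3, :3] *= stride
    return GridSpec(shape, affine)


def estimate_affine(
    src_gm: Volume3D,
    template_gm: Volume3D,
    max_iter: int = 6,
    sample_points: int = 30000,
) -> np.ndarray:
    """12-parameter affine registration of a gray-matter map to a template.

    Minimizes the mean squared difference (after closed-form optimal global
    intensity scaling) over translation, rotation, log-scale and shear,
    starting from centre-of-mass + second-moment alignment, with a
    deterministic Powell search on a subsampled template grid.
    Returns the template-world -> source-world affine.
    """
    com_s, sd_s = _moments(src_gm)
    com_t, sd_t = _moments(template_gm)

    theta0 = np.zeros(12)
    theta0[:3] = com_s - com_t
    theta0[6:9] = np.log(np.clip(sd_s / np.clip(sd_t, 1e-9, None), 0.25, 4.0))

    eval_grid = _strided_grid(template_gm.grid, sample_points)
    ijk = np.indices(eval_grid.shape, dtype=float).reshape(3, -1)
    x_world = eval_grid.affine[:3, :3] @ ijk + eval_grid.affine[:3, 3:4]
    t_vals = _sample_world(template_gm, x_world)
    t_norm = float(t_vals @ t_vals)
    if t_norm <= 0:
        raise RegistrationError("empty (all-zero) template")

    def objective(theta: np.ndarray) -> float:
        A = _params_to_affine(theta)
        y = A[:3, :3] @ x_world + A[:3, 3:4]
        s_vals = _sample_world(src_gm, y)
        ss = float(s_vals @ s_vals)
        if ss <= 0:
            return float(t_vals @ t_vals)
        alpha = float(s_vals @ t_vals) / ss
        r = alpha * s_vals - t_vals
        return float(r @ r) / t_vals.size

    scales = np.concatenate([np.full(3, 2.0), np.full(3, 0.05),
                             np.full(3, 0.05), np.full(3, 0.05)])
    res = optimize.minimize(
        lambda z: objective(theta0 + scales * z),
        np.zeros(12),
        method="Powell",
        options={"maxiter": max_iter, "xtol": 1e-4, "ftol": 1e-8},
    )
    return _params_to_affine(theta0 + scales * res.x)


def _membrane_kappa(n: tuple[int, int, int], fov_mm: np.ndarray) -> np.ndarray:
    """Membrane-energy weight per basis function: squared spatial frequency
    (mm^-2) of each separable cosine term."""
    i, j, k = np.meshgrid(np.arange(n[0]), np.arange(n[1]), np.arange(n[2]),
                          indexing="ij")
    return ((np.pi * i / fov_mm[0]) ** 2
            + (np.pi * j / fov_mm[1]) ** 2
            + (np.pi * k / fov_mm[2]) ** 2)


def estimate_warp(
    src_gm: Volume3D,
    template_gm: Volume3D,
    affine: np.ndarray,
    cutoff_mm: float = 35.0,
    reg_lambda: float = 0.1,
    max_iter: int = 8,
    sample_points: int = 30000,
) -> NormalizationParams:
    """Estimate the low-frequency nonlinear warp refining an affine.

    Minimizes ``mean squared difference + reg_lambda * membrane energy`` of
    the displacement field over the separable cosine coefficients, by
    Gauss-Newton with step halving; the objective trace (recorded on the
    returned params) is monotone non-increasing.  Displacement magnitude is
    clamped to a quarter of the field of view.
    """
    tgrid = template_gm.grid
    if cutoff_mm <= 2 * float(np.max(tgrid.voxel_size_mm)):
        raise ValueError("cutoff_mm must exceed twice the voxel size")
    fov = tgrid.fov_mm
    n = tuple(n_basis_functions(f, cutoff_mm) for f in fov)
    n_c = int(np.prod(n))

    eval_grid = _strided_grid(tgrid, sample_points)
    ijk = np.indices(eval_grid.shape, dtype=float).reshape(3, -1)
    x_world = eval_grid.affine[:3, :3] @ ijk + eval_grid.affine[:3, 3:4]
    tvox = tgrid.world_to_voxel(x_world.T)
    bases = []
    for a in range(3):
        coord = np.moveaxis(tvox[:, a].reshape(eval_grid.shape), a, 0)[:, 0, 0]
        bases.append(dct_basis(tgrid.shape[a], n[a], coord))
    from ._basis import design_matrix

    Phi = design_matrix(bases)                       # (n_pts, n_c)
    t_vals = _sample_world(template_gm, x_world)

    # penalty = reg_lambda * mean over the template grid of |grad d|^2
    # (mm^2 per mm^2); with columns of Phi orthonormal over the template
    # grid this is a diagonal form in the coefficients.  The constant
    # (zero-frequency) basis has no membrane energy, so it carries a weak
    # zeroth-order penalty instead: rigid translation belongs to the
    # affine, and reg_lambda -> inf must drive every coefficient to zero.
    kappa = _membrane_kappa(n, fov).ravel() / float(np.prod(tgrid.shape))
    kappa = np.maximum(kappa, 0.25 * kappa[kappa > 0].min())

    src_data = np.asarray(src_gm.data, dtype=float)
    grads_vox = np.gradient(src_data)
    inv_lin = np.linalg.inv(src_gm.affine)[:3, :3]
    # d(src)/d(world mm) components as volumes
    grad_world = [
        Volume3D(sum(inv_lin[a_vox, a_mm] * grads_vox[a_vox]
                     for a_vox in range(3)),
                 src_gm.affine, "mr")
        for a_mm in range(3)
    ]

    A = np.asarray(affine, dtype=float)
    C = np.zeros((3, n_c))
    max_disp = float(np.min(fov)) / 4.0

    def warp_points(Cmat):
        d = (Phi @ Cmat.T).T                          # (3, n_pts)
        mag = np.sqrt((d**2).sum(axis=0)).max() if d.size else 0.0
        if mag > max_disp:
            d *= max_disp / mag
        return A[:3, :3] @ x_world + A[:3, 3:4] + d

    def objective(Cmat):
        y = warp_points(Cmat)
        s_vals = _sample_world(src_gm, y)
        ss = float(s_vals @ s_vals)
        alpha = float(s_vals @ t_vals) / ss if ss > 0 else 1.0
        r = alpha * s_vals - t_vals
        reg = float(((Cmat**2) * kappa[None, :]).sum())
        f = float(r @ r) / t_vals.size + reg_lambda * reg
        if not np.isfinite(f):
            raise RegistrationError("non-finite warp objective")
        return f, y, alpha, r

    f0, y, alpha, r = objective(C)
    trace = [f0]
    for _ in range(max_iter):
        g = np.stack([_sample_world(gw, y) for gw in grad_world])  # (3, n_pts)
        # residual r = alpha*s - t; dr/dC[a] = alpha * g[a] * Phi
        J = [(alpha * g[a])[:, None] * Phi for a in range(3)]
        JtJ = np.zeros((3 * n_c, 3 * n_c))
        Jtr = np.zeros(3 * n_c)
        for a in range(3):
            Jtr[a * n_c:(a + 1) * n_c] = J[a].T @ r / t_vals.size
            for b in range(a, 3):
                block = J[a].T @ J[b] / t_vals.size
                JtJ[a * n_c:(a + 1) * n_c, b * n_c:(b + 1) * n_c] = block
                if b != a:
                    JtJ[b * n_c:(b + 1) * n_c, a * n_c:(a + 1) * n_c] = block.T
        P = np.tile(kappa, 3)
        H = JtJ + reg_lambda * np.diag(P) + 1e-9 * np.eye(3 * n_c)
        grad_full = Jtr + reg_lambda * P * C.ravel()
        try:
            delta = np.linalg.solve(H, -grad_full).reshape(3, n_c)
        except np.linalg.LinAlgError as exc:
            raise RegistrationError(f"singular normal equations: {exc}") from exc
        step, improved = 1.0, False
        for _half in range(6):
            C_new = C + step * delta
            f_new, y_new, a_new, r_new = objective(C_new)
            if f_new < trace[-1]:
                C, y, alpha, r = C_new, y_new, a_new, r_new
                trace.append(f_new)
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    return NormalizationParams(
        affine=A, warp_coeffs=C.reshape(3, *n), cutoff_mm=cutoff_mm,
        reg_lambda=reg_lambda, template_grid=tgrid, objective_trace=trace)


def apply_normalization(
    vol: Volume3D,
    params: NormalizationParams,
    out_grid: GridSpec | None = None,
) -> Volume3D:
    """Pull a subject volume into template space on the analysis grid.

    Each output voxel's template-world position ``x`` is mapped to the
    subject as ``A x + d(x)`` and the subject volume is sampled there
    (trilinear).  The default analysis grid is the template grid resampled
    to 2 mm isotropic voxels.
    """
    if out_grid is None:
        out_grid = analysis_grid(params.template_grid)
    shape = out_grid.shape
    ijk = np.indices(shape, dtype=float).reshape(3, -1)
    x_world = out_grid.affine[:3, :3] @ ijk + out_grid.affine[:3, 3:4]
    d = params.displacement(out_grid).reshape(3, -1)
    y = params.affine[:3, :3] @ x_world + params.affine[:3, 3:4] + d
    vals = _sample_world(vol, y).reshape(shape)
    modality = vol.modality
    if modality == "probability":
        vals = np.clip(vals, 0.0, 1.0)
    return Volume3D(vals, out_grid.affine, modality)


def analysis_grid(template_grid: GridSpec,
                  voxel_mm: float = DEFAULT_ANALYSIS_VOXEL_MM) -> GridSpec:
    """The statistics grid: same world bounding box as the template, with
    isotropic voxels of the requested size (default 2 mm)."""
    fov = template_grid.fov_mm
    shape = tuple(int(np.round(f / voxel_mm)) for f in fov)
    corner = template_grid.voxel_to_world(np.array([-0.5, -0.5, -0.5]))
    lin = template_grid.affine[:3, :3] / template_grid.voxel_size_mm
    affine = np.eye(4)
    affine[:3, :3] = lin * voxel_mm
    affine[:3, 3] = corner + lin @ (np.full(3, voxel_mm / 2.0))
    return GridSpec(shape, affine)
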