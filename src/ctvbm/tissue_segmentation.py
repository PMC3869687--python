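"""Gaussian-mixture tissue segmentation with spatial probability priors.

Each tissue class (gray matter, white matter, CSF, other) owns one or more
intensity Gaussians; a tissue-probability atlas weights class membership
spatially.  The model is fitted by EM on a subsampled voxel set and the
posterior is evaluated at full resolution on exit.  For MR, a smooth
multiplicative bias field (low-frequency cosine basis, quadratic penalty)
can be estimated inside the EM loop; CT intensities are calibrated
Hounsfield units, so the CT presets disable the bias model entirely and
compensate the narrow gray/white contrast with more Gaussians for the
heterogeneous CSF-plus-other compartments.

The posterior for Gaussian ``g`` of class ``c`` at voxel ``v`` is

    r(v, g)  ∝  prior_c(v) · w_g · N(y_v ; μ_g, σ_g²)

and the class posterior is the sum over that class's Gaussians.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

from ._basis import dct_basis, separable_field
from .errors import DegenerateInputError, SegmentationError
from .volume_io import GridSpec, Volume3D

CLASSES = ("gm", "wm", "csf", "other")

_BIAS_DEBUG = False


@dataclass
class TissuePriorAtlas:
    """Spatial tissue priors plus the gray-matter normalization template.

    ``gm``, ``wm``, ``csf`` are probability volumes on one common grid;
    the implicit ``other`` prior is ``1 - (gm + wm + csf)``.  ``gm_template``
    is the target for spatial normalization downstream.
    """

    gm: Volume3D
    wm: Volume3D
    csf: Volume3D
    gm_template: Volume3D

    def __post_init__(self) -> None:
        grids = {v.data.shape for v in (self.gm, self.wm, self.csf)}
        if len(grids) != 1:
            raise ValueError("tissue priors must share one grid")
        total = self.gm.data + self.wm.data + self.csf.data
        if float(total.max()) > 1 + 1e-6:
            raise ValueError("gm + wm + csf priors exceed 1")

    @property
    def grid(self) -> GridSpec:
        return self.gm.grid

    def class_priors(self, floor: float = 0.05) -> np.ndarray:
        """Stacked per-class priors, shape (4, n_voxels), floored and renormalized.

        The floor bounds the priors' confidence: tissue-probability maps are
        population averages, and no location is ever certain of its class
        (real cortex is interleaved with sulcal CSF at map resolution), so
        every class keeps at least ``floor`` prior mass everywhere.  Without
        it a confident prior can hard-veto clear intensity evidence — e.g.
        relabelling focally lost tissue back to gray matter.
        """
        gm = self.gm.data.ravel()
        wm = self.wm.data.ravel()
        csf = self.csf.data.ravel()
        other = np.clip(1.0 - gm - wm - csf, 0.0, 1.0)
        P = np.stack([gm, wm, csf, other]) + floor
        return P / P.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class SegmentationConfig:
    """Mixture size and fitting regime.

    ``n_gauss`` is (gm, wm, csf, other).  ``bias_regularization`` is the
    quadratic penalty on the log-bias coefficients; ``inf`` disables the
    bias model (the CT regime).  ``sampling_distance_mm`` sets the EM
    subsampling step.
    """

    n_gauss: tuple[int, int, int, int] = (2, 2, 2, 4)
    bias_regularization: float = np.inf
    sampling_distance_mm: float = 3.0
    max_iter: int = 64
    tol: float = 1e-4
    bias_order: int = 4
    bias_update_every: int = 2

    def __post_init__(self) -> None:
        if len(self.n_gauss) != 4 or any(int(n) < 1 for n in self.n_gauss):
            raise ValueError(f"n_gauss must be 4 counts >= 1, got {self.n_gauss}")
        if self.sampling_distance_mm <= 0:
            raise ValueError("sampling_distance_mm must be positive")

    @classmethod
    def mr_default(cls, **kw) -> "SegmentationConfig":
        """MR regime: 2 Gaussians for GM/WM/CSF, 4 for other; light bias
        regularization; 3 mm sampling."""
        base = dict(n_gauss=(2, 2, 2, 4), bias_regularization=1e-2,
                    sampling_distance_mm=3.0)
        base.update(kw)
        return cls(**base)

    @classmethod
    def ct_default(cls, **kw) -> "SegmentationConfig":
        """CT regime: bias model off (HU are calibrated), 2 mm sampling,
        csf+other jointly 6-8 Gaussians (see :func:`auto_adjust_gaussians`)."""
        base = dict(n_gauss=(2, 2, 3, 4), bias_regularization=np.inf,
                    sampling_distance_mm=2.0)
        base.update(kw)
        return cls(**base)

    @property
    def total_gaussians(self) -> int:
        return int(sum(self.n_gauss))


def ct_config_grid() -> list[SegmentationConfig]:
    """The per-subject CT tuning grid: gm, wm in {1, 2}; csf+other totalling
    6, 7 or 8 Gaussians."""
    grid = []
    for gm, wm, (csf, other) in itertools.product(
        (1, 2), (1, 2), ((2, 4), (3, 4), (4, 4))
    ):
        grid.append(SegmentationConfig.ct_default(n_gauss=(gm, wm, csf, other)))
    return grid


@dataclass
class MixtureModel:
    """Fitted mixture parameters and diagnostics."""

    class_of_gauss: np.ndarray      # (G,) index into CLASSES
    means: np.ndarray               # (G,)
    variances: np.ndarray           # (G,)
    weights: np.ndarray             # (G,) within-class mixing weights
    log_likelihood: list[float] = field(default_factory=list)
    converged: bool = False
    bias_field: Volume3D | None = None
    n_fit: int = 0

    @property
    def n_gaussians(self) -> int:
        return int(self.means.size)


@dataclass
class TissuePosterior:
    """Per-class posterior probability volumes on the source grid."""

    gm: Volume3D
    wm: Volume3D
    csf: Volume3D
    other: Volume3D

    def __post_init__(self) -> None:
        total = (self.gm.data + self.wm.data + self.csf.data + self.other.data)
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValueError("class posteriors must sum to 1 at every voxel")

    @property
    def grid(self) -> GridSpec:
        return self.gm.grid

    def stacked(self) -> np.ndarray:
        return np.stack([c.data for c in (self.gm, self.wm, self.csf, self.other)])

    def map_labels(self) -> np.ndarray:
        """Arg-max class index volume (0=gm, 1=wm, 2=csf, 3=other)."""
        return np.argmax(self.stacked(), axis=0)


def _log_normal(y: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (y - mean) ** 2 / var)


def _subsample_slices(grid: GridSpec, distance_mm: float) -> tuple[slice, ...]:
    steps = np.maximum(1, np.round(distance_mm / grid.voxel_size_mm)).astype(int)
    return tuple(slice(None, None, int(s)) for s in steps)


def _class_centers(vals: np.ndarray, n_c: int) -> list[float]:
    """Initial Gaussian means for one class: dominant histogram peaks.

    Intensity quantiles alone would place every centre inside the class's
    majority mode (e.g. air dominating the MR "other" class and hiding the
    scalp mode), so centres are seeded at up to ``n_c`` local histogram
    maxima — tallest first, separated by at least a quarter of the
    inter-quantile range — and topped up with quantiles of the tallest mode's
    neighbourhood when fewer peaks exist.
    """
    if n_c == 1:
        return [float(np.median(vals))]
    lo, hi = np.quantile(vals, [0.002, 0.998])
    if hi <= lo:
        return [float(lo)] * n_c
    hist, edges = np.histogram(vals, bins=96, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    h = ndimage.uniform_filter1d(hist.astype(float), 5)
    is_peak = np.zeros(h.size, dtype=bool)
    is_peak[1:-1] = (h[1:-1] > h[:-2]) & (h[1:-1] >= h[2:]) & (h[1:-1] > 0)
    order = np.argsort(-h[is_peak])
    peak_pos = mids[is_peak][order]
    min_sep = (hi - lo) / (4.0 * n_c)
    centers: list[float] = []
    for p in peak_pos:
        if len(centers) >= n_c:
            break
        if all(abs(p - c) >= min_sep for c in centers):
            centers.append(float(p))
    if len(centers) < n_c:
        fill = np.quantile(vals, np.linspace(0.15, 0.85, n_c - len(centers)))
        centers.extend(float(f) for f in np.atleast_1d(fill))
    return sorted(centers)


def _stagger_duplicate_classes(all_centers, class_vals, n_gauss, priors):
    """Break exact initialisation ties between classes.

    With spatially flat, equal priors several classes can seed identical
    Gaussians, leaving EM at a symmetric fixed point it cannot escape.
    Classes whose centre lists coincide are re-seeded at staggered
    quantiles of their intensity values, extremes assigned to the classes
    with the largest total prior mass so the dominant classes capture the
    outer modes.
    """
    groups: dict[tuple, list[int]] = {}
    for c, centers in enumerate(all_centers):
        key = tuple(np.round(centers, 6))
        groups.setdefault(key, []).append(c)
    prior_mass = priors.sum(axis=1)
    for members in groups.values():
        m = len(members)
        if m < 2:
            continue
        members = sorted(members, key=lambda c: -prior_mass[c])
        # low-discrepancy order: extremes first
        qs = [(j + 0.5) / m for j in range(m)]
        order = []
        lo_i, hi_i = 0, m - 1
        while lo_i <= hi_i:
            order.append(qs[lo_i])
            if hi_i != lo_i:
                order.append(qs[hi_i])
            lo_i += 1
            hi_i -= 1
        for j, c in enumerate(members):
            q = order[j]
            n_c = n_gauss[c]
            half = 0.5 / m
            sub_qs = np.linspace(q - half * 0.8, q + half * 0.8, n_c)
            all_centers[c] = [float(v) for v in
                              np.quantile(class_vals[c], sub_qs)]


def _init_params(
    y: np.ndarray, priors: np.ndarray, n_gauss, rng: np.random.Generator,
    jitter: float = 0.0,
):
    """Seed Gaussians from the prior-MAP labelling, splitting multi-Gaussian
    classes at intensity quantiles."""
    labels = np.argmax(priors, axis=0)
    class_of_gauss, means, variances, weights = [], [], [], []
    global_var = float(np.var(y)) + 1e-12
    class_vals = []
    for c, n_c in enumerate(n_gauss):
        vals = y[labels == c]
        if vals.size < 8:
            vals = y
        class_vals.append(vals)
    all_centers = [_class_centers(class_vals[c], n_c)
                   for c, n_c in enumerate(n_gauss)]
    _stagger_duplicate_classes(all_centers, class_vals, n_gauss, priors)
    for c, n_c in enumerate(n_gauss):
        vals = class_vals[c]
        centers = all_centers[c]
        for g in range(n_c):
            m = float(centers[g])
            v = float(np.var(vals)) / n_c**2 + 1e-3 * global_var
            if jitter > 0:
                m += rng.normal(0.0, jitter * np.sqrt(global_var))
            class_of_gauss.append(c)
            means.append(m)
            variances.append(v)
            weights.append(1.0 / n_c)
    return (np.array(class_of_gauss), np.array(means),
            np.array(variances), np.array(weights))


def _posterior_responsibilities(y, log_priors, class_of_gauss, means, variances,
                                weights):
    """Log responsibilities (G, n) and per-voxel log evidence (n,)."""
    G = means.size
    log_r = np.empty((G, y.size))
    for g in range(G):
        log_r[g] = (log_priors[class_of_gauss[g]]
                    + np.log(weights[g] + 1e-300)
                    + _log_normal(y, means[g], variances[g]))
    log_evidence = logsumexp(log_r, axis=0)
    log_r -= log_evidence
    return log_r, log_evidence


def _fit_em_once(
    y_raw: np.ndarray,
    log_priors: np.ndarray,
    cfg: SegmentationConfig,
    rng: np.random.Generator,
    bias_design: np.ndarray | None,
    jitter: float,
):
    """One EM run on the subsampled voxels.  Returns params + trace, or
    raises SegmentationError on variance collapse."""
    class_of_gauss, means, variances, weights = _init_params(
        y_raw, np.exp(log_priors), cfg.n_gauss, rng, jitter
    )
    var_floor = 1e-8 * (float(np.var(y_raw)) + 1e-30)
    work_floor = 1e-5 * (float(np.var(y_raw)) + 1e-30)
    use_bias = bias_design is not None
    bias_coeffs = np.zeros(bias_design.shape[1]) if use_bias else None
    log_bias = np.zeros_like(y_raw)
    y = y_raw.copy()
    trace: list[float] = []
    converged = False

    def penalized_ll(y_work, lb, m, v, w):
        _, log_ev = _posterior_responsibilities(
            y_work, log_priors, class_of_gauss, m, v, w)
        ll = float(np.sum(log_ev)) - float(np.sum(lb))
        if use_bias:
            ll -= 0.5 * cfg.bias_regularization * float(bias_coeffs @ bias_coeffs)
        return ll

    for it in range(cfg.max_iter):
        log_r, log_ev = _posterior_responsibilities(
            y, log_priors, class_of_gauss, means, variances, weights)
        ll = float(np.sum(log_ev)) - float(np.sum(log_bias))
        if use_bias:
            ll -= 0.5 * cfg.bias_regularization * float(bias_coeffs @ bias_coeffs)
        if trace and ll < trace[-1] - 1e-6 * abs(trace[-1]):
            raise SegmentationError(
                f"log-likelihood decreased at iteration {it}: {trace[-1]} -> {ll}"
            )
        if trace and abs(ll - trace[-1]) <= cfg.tol * abs(trace[-1]):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

        r = np.exp(log_r)
        Nk = r.sum(axis=1) + 1e-12
        means = (r @ y) / Nk
        variances = (r @ (y**2)) / Nk - means**2
        if np.any(variances < var_floor):
            raise SegmentationError("variance collapse")
        # constrained M-step: a floor on variances keeps sparsely-populated
        # Gaussians proper; maximizing Q under the constraint is still a
        # valid (monotone) generalized EM step
        variances = np.maximum(variances, work_floor)
        for c in range(len(cfg.n_gauss)):
            sel = class_of_gauss == c
            weights[sel] = Nk[sel] / Nk[sel].sum()

        if use_bias and it >= 1 and it % cfg.bias_update_every == 0:
            # weighted LS on log(y) - log(expected mean), ridge-penalized;
            # accepted only if the penalized likelihood improves
            # in work space y_raw*exp(-lb) ~ mu_hat, so the refreshed
            # log-bias estimate is log(y_raw) - log(mu_hat), fitted by
            # weighted ridge LS with delta-method weights mu_hat^2 so that
            # near-zero (air) voxels, whose log-ratios are pure noise,
            # carry no influence
            mu_hat = r.T @ means
            ok = (y_raw > 1e-6) & (mu_hat > 1e-6)
            if ok.sum() > bias_design.shape[1]:
                target = np.log(y_raw[ok] / mu_hat[ok])
                A = bias_design[ok]
                wgt = mu_hat[ok] ** 2
                wgt /= wgt.mean()
                Aw = A * wgt[:, None]
                lam = cfg.bias_regularization * ok.sum() / y_raw.size
                new_coeffs = np.linalg.solve(
                    A.T @ Aw + (lam + 1e-8) * np.eye(A.shape[1]),
                    Aw.T @ target,
                )
                new_lb = bias_design @ new_coeffs
                new_y = y_raw * np.exp(-new_lb)
                old = penalized_ll(y, log_bias, means, variances, weights)
                saved = bias_coeffs
                bias_coeffs = new_coeffs
                new = penalized_ll(new_y, new_lb, means, variances, weights)
                if _BIAS_DEBUG:
                    print(f"    bias it={it}: old={old:.1f} new={new:.1f} "
                          f"lb range=({new_lb.min():.3f},{new_lb.max():.3f})")
                if new >= old:
                    log_bias, y = new_lb, new_y
                else:
                    bias_coeffs = saved
    return (class_of_gauss, means, variances, weights, trace, converged,
            bias_coeffs)


def fit_mixture(
    vol: Volume3D,
    atlas: TissuePriorAtlas,
    cfg: SegmentationConfig,
    seed: int = 0,
    support: np.ndarray | None = None,
) -> tuple[MixtureModel, TissuePosterior]:
    """Fit the prior-weighted Gaussian mixture and return full-resolution
    class posteriors.

    The volume and atlas must already be co-registered on one grid (see
    ``ct_preprocess.match_prior_grid``).  EM runs on voxels subsampled at
    ``cfg.sampling_distance_mm``; on variance collapse the fit restarts
    with jittered initial means (up to 3 restarts).

    ``support`` optionally restricts the *fit* to a boolean voxel subset.
    When omitted and a single exact intensity value covers more than a
    quarter of the volume (the constant background left by brain
    extraction), those voxels are excluded automatically: a zero-variance
    spike cannot be represented by a Gaussian.  Posteriors are still
    evaluated everywhere.
    """
    if vol.data.shape != atlas.grid.shape or not np.allclose(
        vol.affine, atlas.grid.affine, atol=1e-6
    ):
        raise ValueError("volume and atlas must be co-registered on one grid")
    data = np.asarray(vol.data, dtype=float)
    if float(np.ptp(data)) == 0.0:
        raise DegenerateInputError("constant image cannot be segmented")

    sl = _subsample_slices(vol.grid, cfg.sampling_distance_mm)
    y_sub_all = data[sl].ravel()
    priors_full = atlas.class_priors()
    priors_sub = np.stack(
        [p.reshape(data.shape)[sl].ravel() for p in priors_full]
    )
    if support is not None:
        keep = np.asarray(support, dtype=bool)[sl].ravel()
    else:
        vals, counts = np.unique(y_sub_all, return_counts=True)
        top = int(np.argmax(counts))
        if counts[top] > 0.25 * y_sub_all.size:
            keep = y_sub_all != vals[top]
        else:
            keep = np.ones(y_sub_all.size, dtype=bool)
    if keep.sum() < 16:
        raise DegenerateInputError("fewer than 16 voxels available for the fit")
    if float(np.ptp(y_sub_all[keep])) == 0.0:
        raise DegenerateInputError("constant image cannot be segmented")
    y_sub = y_sub_all[keep]
    priors_sub = priors_sub[:, keep]
    log_priors_sub = np.log(priors_sub)

    use_bias = np.isfinite(cfg.bias_regularization) and vol.modality != "ct"
    bias_design = None
    if use_bias:
        full_shape = data.shape
        steps = [slc.step or 1 for slc in sl]
        bases_sub = [
            dct_basis(full_shape[a], cfg.bias_order,
                      np.arange(0, full_shape[a], steps[a], dtype=float))
            for a in range(3)
        ]
        from ._basis import design_matrix

        bias_design = design_matrix(bases_sub)[keep]

    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(4):
        jitter = 0.0 if attempt == 0 else 0.1 * attempt
        try:
            (class_of_gauss, means, variances, weights, trace, converged,
             bias_coeffs) = _fit_em_once(
                y_sub, log_priors_sub, cfg, rng, bias_design, jitter)
            break
        except SegmentationError as exc:
            last_err = exc
    else:
        raise SegmentationError(f"EM failed after 3 restarts: {last_err}")

    # full-resolution pass
    bias_vol = None
    y_full = data.ravel()
    if use_bias and bias_coeffs is not None:
        bases_full = [dct_basis(data.shape[a], cfg.bias_order) for a in range(3)]
        lb_full = separable_field(
            bias_coeffs.reshape((cfg.bias_order,) * 3), bases_full
        ).ravel()
        y_full = y_full * np.exp(-lb_full)
        bias_vol = Volume3D(np.exp(lb_full).reshape(data.shape),
                            vol.affine.copy(), "mr")

    log_priors_full = np.log(priors_full)
    n_classes = len(CLASSES)
    log_class = np.full((n_classes, y_full.size), -np.inf)
    for g in range(means.size):
        contrib = (log_priors_full[class_of_gauss[g]]
                   + np.log(weights[g] + 1e-300)
                   + _log_normal(y_full, means[g], variances[g]))
        log_class[class_of_gauss[g]] = np.logaddexp(
            log_class[class_of_gauss[g]], contrib)
    log_ev = logsumexp(log_class, axis=0)
    # voxels where every Gaussian underflows (e.g. far-out background
    # intensities) fall back to the spatial priors
    bad = ~np.isfinite(log_ev)
    log_class[:, ~bad] -= log_ev[~bad]
    post = np.exp(log_class)
    if bad.any():
        post[:, bad] = priors_full[:, bad]
    post /= post.sum(axis=0, keepdims=True)

    vols = [
        Volume3D(post[c].reshape(data.shape), vol.affine.copy(), "probability")
        for c in range(n_classes)
    ]
    model = MixtureModel(class_of_gauss, means, variances, weights,
                         log_likelihood=trace, converged=converged,
                         bias_field=bias_vol, n_fit=int(y_sub.size))
    posterior = TissuePosterior(*vols)
    return model, posterior


def extract_gray_matter(post: TissuePosterior) -> Volume3D:
    """The gray-matter probability map, passed through unthresholded."""
    gm = post.gm
    return Volume3D(gm.data.copy(), gm.affine.copy(), "probability")


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    denom = a.sum() + b.sum()
    return 2.0 * inter / denom if denom else 0.0


def auto_adjust_gaussians(
    vol: Volume3D,
    atlas: TissuePriorAtlas,
    cfg_grid: list[SegmentationConfig] | None = None,
    seed: int = 0,
) -> tuple[SegmentationConfig, MixtureModel, TissuePosterior]:
    """Per-subject tuning of the mixture sizes, emulating manual adjustment
    "until successful segmentation".

    Each candidate configuration is fitted with the same seed.  A fit is
    *successful* when EM converged and the gray-matter posterior (>0.5)
    reaches Dice >= 0.6 against the prior-MAP gray-matter labelling — the
    guard against GM leaking into bone or CSF.  Among successful fits the
    highest mean per-voxel log-likelihood wins; exact ties go to the model
    with fewer Gaussians.
    """
    if cfg_grid is None:
        cfg_grid = ct_config_grid()
    if not cfg_grid:
        raise ValueError("cfg_grid must be non-empty")

    prior_map_gm = np.argmax(atlas.class_priors(), axis=0).reshape(
        atlas.grid.shape) == 0
    best = None
    diagnostics = []
    for cfg in cfg_grid:
        try:
            model, post = fit_mixture(vol, atlas, cfg, seed=seed)
        except (SegmentationError, DegenerateInputError) as exc:
            diagnostics.append((cfg.n_gauss, f"failed: {exc}"))
            continue
        mean_ll = model.log_likelihood[-1] / max(model.n_fit, 1)
        dice = _dice(post.gm.data > 0.5, prior_map_gm)
        success = model.converged and dice >= 0.6
        diagnostics.append(
            (cfg.n_gauss, f"converged={model.converged} dice={dice:.3f} "
                          f"mean_ll={mean_ll:.4f}"))
        if not success:
            continue
        key = (mean_ll, -cfg.total_gaussians)
        if best is None or key > best[0]:
            best = (key, cfg, model, post)
    if best is None:
        lines = "; ".join(f"{n}: {msg}" for n, msg in diagnostics)
        raise SegmentationError(f"no candidate achieved successful segmentation ({lines})")
    return best[1], best[2], best[3]
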