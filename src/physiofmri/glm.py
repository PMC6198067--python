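"""First- and second-level task GLMs with autonomic parametric modulation.

Model 1 regresses the BOLD series on HRF-convolved congruent/incongruent
stimulus trains plus six motion parameters, a discrete-cosine high-pass
set (cutoff period 128 s) and an intercept.  Models 2 and 3 add, per
condition, a parametrically modulated regressor in which each stimulus is
weighted by its mean-centered trial covariate (skin-conductance or pupil
response amplitude).  Serial correlations are handled by pooled AR(1)
prewhitening; the interference contrast (incongruent - congruent, on the
modulated columns for models 2/3) feeds a voxel-wise paired t-test across
subjects, thresholded at uncorrected voxel p with a cluster-extent rule
whose expected cluster size can be estimated by sign-flip permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import CONGRUENT, INCONGRUENT, BoldImage, EventDesign

logger = logging.getLogger("physiofmri")

#: high-pass cutoff period (s) for the discrete-cosine drift set
DEFAULT_HP_CUTOFF_S = 128.0
#: default cluster-forming voxel threshold (uncorrected p)
DEFAULT_VOXEL_P = 0.005
#: default spatial smoothing kernel (mm, full width at half maximum)
DEFAULT_FWHM_MM = 4.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# hemodynamic response and stimulus regressors
# ---------------------------------------------------------------------------

def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, normalized to peak 1.

    Difference of a peak gamma (shape 6) and an undershoot gamma (shape
    16, weighted 1/6), both with unit scale: the response is 0 at t = 0,
    peaks near 5 s and undershoots around 15 s.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    h[t < 0] = 0.0
    return h / _hrf_peak()


_HRF_PEAK_CACHE: list[float] = []


def _hrf_peak() -> float:
    if not _HRF_PEAK_CACHE:
        fine = np.arange(0.0, 32.0, 0.01)
        _HRF_PEAK_CACHE.append(
            float((stats.gamma.pdf(fine, 6) - stats.gamma.pdf(fine, 16) / 6.0).max()))
    return _HRF_PEAK_CACHE[0]


def condition_regressor(
    events: EventDesign,
    condition: str,
    sample_times: np.ndarray,
    weights: np.ndarray | None = None,
    stick: bool = True,
) -> np.ndarray:
    """HRF response to one condition's stimulus train at the sample times.

    In stick (impulse) mode the regressor is the exact sum of shifted
    HRFs, one per stimulus, optionally weighted per trial; in boxcar mode
    each stimulus contributes the HRF integrated over its duration
    (computed on a 10 ms grid).
    """
    sample_times = np.asarray(sample_times, dtype=float)
    sel = events.conditions == condition
    onsets = events.onsets[sel]
    durations = events.durations[sel]
    if weights is None:
        w = np.ones(len(onsets))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(onsets):
            raise ValueError(
                f"{len(w)} weights for {len(onsets)} {condition} trials")
    out = np.zeros_like(sample_times)
    if stick:
        for onset, wi in zip(onsets, w):
            out += wi * canonical_hrf(sample_times - onset)
    else:
        dt = 0.01
        for onset, dur, wi in zip(onsets, durations, w):
            offs = np.arange(0.0, dur, dt)
            for o in offs:
                out += wi * canonical_hrf(sample_times - onset - o) * dt
    return out


def dct_highpass_basis(n_volumes: int, tr_s: float,
                       cutoff_s: float = DEFAULT_HP_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine drift regressors for periods longer than the cutoff.

    Basis function k (k >= 1) has period 2*N*TR/k; functions are included
    while that period exceeds ``cutoff_s``.
    """
    total = 2.0 * n_volumes * tr_s
    k_max = int(np.floor(total / cutoff_s))
    n = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_volumes))
            for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """First-level design: (volumes, columns) with ordered names."""

    values: np.ndarray
    column_names: list[str]
    frame_times: np.ndarray
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column count does not match names")
        centered = self.values - self.values.mean(axis=0, keepdims=True)
        keep = [i for i, n in enumerate(self.column_names) if n != "intercept"]
        if np.linalg.matrix_rank(centered[:, keep]) < len(keep):
            self.rank_deficient = True
            logger.warning("design matrix is rank deficient after centering")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.column_names))
        for name, w in weights.items():
            if name not in self.column_names:
                raise ValueError(f"design has no column {name!r}")
            c[self.column_names.index(name)] = w
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


def build_design(
    events: EventDesign,
    n_volumes: int,
    tr_s: float,
    model: int = 1,
    modulator: np.ndarray | None = None,
    motion: pd.DataFrame | np.ndarray | None = None,
    hp_cutoff_s: float = DEFAULT_HP_CUTOFF_S,
    stick: bool = True,
    keep_main_effects: bool = True,
) -> DesignMatrix:
    """Assemble the first-level design for model 1, 2 or 3.

    Model 1: one HRF-convolved regressor per condition.  Models 2/3 add a
    parametrically modulated regressor per condition: each stimulus is
    weighted by its trial's modulator value, mean-centered within the
    condition before convolution (so the modulated column is orthogonal
    to the unmodulated stimulus train before convolution).  ``modulator``
    must supply one value per trial, in trial order; it is required
    exactly for models 2 and 3.  Motion (6 columns), the discrete-cosine
    high-pass set and an intercept are appended.
    """
    if model not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    if (model in (2, 3)) != (modulator is not None):
        raise ValueError("a per-trial modulator is required iff model is 2 or 3")
    frame_times = np.arange(n_volumes) * tr_s

    cols: list[np.ndarray] = []
    names: list[str] = []
    for cond in (CONGRUENT, INCONGRUENT):
        if keep_main_effects or model == 1:
            cols.append(condition_regressor(events, cond, frame_times, stick=stick))
            names.append(cond)
    if model in (2, 3):
        modulator = np.asarray(modulator, dtype=float)
        if len(modulator) != len(events):
            raise ValueError(
                f"{len(modulator)} modulator values for {len(events)} trials")
        mod_name = {2: "scr", 3: "pdr"}[model]
        for cond in (CONGRUENT, INCONGRUENT):
            sel = events.conditions == cond
            centered = modulator[sel] - modulator[sel].mean()
            if np.all(centered == 0):
                logger.warning("all %s modulator values equal in %s: "
                               "modulated column is identically zero", mod_name, cond)
            cols.append(condition_regressor(events, cond, frame_times,
                                            weights=centered, stick=stick))
            names.append(f"{cond}x{mod_name}")
    if motion is not None:
        m = motion.to_numpy() if isinstance(motion, pd.DataFrame) else np.asarray(motion)
        if m.shape != (n_volumes, 6):
            raise ValueError(f"motion table must be ({n_volumes}, 6), got {m.shape}")
        for j in range(6):
            cols.append(m[:, j].astype(float))
            names.append(f"motion{j + 1}")
    dct = dct_highpass_basis(n_volumes, tr_s, hp_cutoff_s)
    for k in range(dct.shape[1]):
        cols.append(dct[:, k])
        names.append(f"dct{k + 1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(values=np.column_stack(cols), column_names=names,
                        frame_times=frame_times)


# ---------------------------------------------------------------------------
# first-level fit with AR(1) prewhitening
# ---------------------------------------------------------------------------

@dataclass
class FirstLevelResult:
    """Fitted first-level model over a voxel grid."""

    design: DesignMatrix
    betas: np.ndarray              # (x, y, z, n_columns)
    sigma2: np.ndarray             # (x, y, z) residual variance (whitened)
    xtx_inv: np.ndarray
    df: float
    ar1_rho: float
    mask: np.ndarray               # finite-data analysis mask
    model: int = 1

    def contrast(self, weights: dict[str, float]
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Contrast estimate and t map for a named-weight contrast."""
        c = self.design.contrast_vector(weights)
        con = self.betas @ c
        var = self.sigma2 * float(c @ self.xtx_inv @ c)
        t = np.full(con.shape, np.nan)
        ok = self.mask & (var > 0)
        t[ok] = con[ok] / np.sqrt(var[ok])
        con[~self.mask] = np.nan
        return con, t


def _pooled_ar1(X: np.ndarray, Y: np.ndarray, n_iter: int = 10,
                tol: float = 1e-4) -> float:
    """Pooled AR(1) coefficient of the GLM residuals.

    The lag-1 autocorrelation of residuals from a fitted design
    underestimates the true coefficient, because drift and task columns
    absorb part of the serial correlation.  The estimate is therefore
    refined iteratively: whiten with the current value, measure the
    remaining lag-1 correlation of the whitened residuals, and accumulate
    until it vanishes.
    """
    n = X.shape[0]
    rho = 0.0
    for _ in range(n_iter):
        Xw = _ar1_whiten(X, rho)
        pinv_w = np.linalg.pinv(Xw)
        rw = _ar1_whiten(Y, rho) - Xw @ (pinv_w @ _ar1_whiten(Y, rho))
        den = float((rw ** 2).sum())
        if den == 0:
            return 0.0
        r1 = float((rw[1:] * rw[:-1]).sum()) / den
        # expected lag-1 correlation of white noise passed through the
        # residual projector M = I - H: trace(S M) / trace(M), with S the
        # symmetrized lag-1 shift; subtracting it de-biases the estimate
        H = Xw @ pinv_w
        rank = np.linalg.matrix_rank(Xw)
        bias = -float(np.trace(H, offset=1)) / (n - rank)
        step = r1 - bias
        rho = float(np.clip(rho + step, -0.99, 0.99))
        if abs(step) < tol:
            break
    return rho


def _ar1_whiten(A: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) whitening filter along axis 0."""
    W = A.copy().astype(float)
    W[1:] = A[1:] - rho * A[:-1]
    W[0] = A[0] * np.sqrt(1.0 - rho ** 2)
    return W


def fit_first_level(
    bold: BoldImage,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    model: int = 1,
    ar1: bool = True,
) -> FirstLevelResult:
    """Fit the GLM at every voxel with pooled AR(1) prewhitening.

    The AR(1) coefficient is estimated from the lag-1 autocorrelation of
    ordinary-least-squares residuals pooled over the analysis mask; data
    and design are then prewhitened and refit.  Voxels with non-finite
    data are masked out (and counted in the log).
    """
    X = design.values
    n_t, n_p = X.shape
    if n_t != bold.n_volumes:
        raise ValueError(f"design has {n_t} rows but image has {bold.n_volumes} volumes")

    finite = np.isfinite(bold.data).all(axis=3)
    if mask is not None:
        finite &= np.asarray(mask, dtype=bool)
    n_bad = int((~np.isfinite(bold.data).all(axis=3)).sum())
    if n_bad:
        logger.warning("masked out %d voxels with non-finite data", n_bad)

    Y = bold.data[finite].T  # (t, voxels)
    rho = _pooled_ar1(X, Y) if ar1 else 0.0

    Xw = _ar1_whiten(X, rho)
    Yw = _ar1_whiten(Y, rho)
    pinv_w = np.linalg.pinv(Xw)
    beta = pinv_w @ Yw
    resid_w = Yw - Xw @ beta
    rank = np.linalg.matrix_rank(Xw)
    df = n_t - rank
    sigma2_vec = (resid_w ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)

    betas = np.full(bold.grid + (n_p,), np.nan)
    betas[finite] = beta.T
    sigma2 = np.full(bold.grid, np.nan)
    sigma2[finite] = sigma2_vec
    return FirstLevelResult(design=design, betas=betas, sigma2=sigma2,
                            xtx_inv=xtx_inv, df=float(df), ar1_rho=rho,
                            mask=finite, model=model)


def interference_contrast(result: FirstLevelResult
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Incongruent-minus-congruent contrast and t maps.

    Model 1 contrasts the main-effect columns; models 2/3 contrast the
    parametrically modulated columns.
    """
    names = result.design.column_names
    if result.model == 1:
        pos, neg = INCONGRUENT, CONGRUENT
    else:
        suffix = {2: "scr", 3: "pdr"}[result.model]
        pos, neg = f"{INCONGRUENT}x{suffix}", f"{CONGRUENT}x{suffix}"
    if pos not in names or neg not in names:
        raise ValueError(f"design lacks contrast columns {pos!r}/{neg!r}")
    return result.contrast({pos: 1.0, neg: -1.0})


# ---------------------------------------------------------------------------
# second level and cluster inference
# ---------------------------------------------------------------------------

def second_level_paired(
    subject_maps_cc: list[np.ndarray],
    subject_maps_ic: list[np.ndarray],
) -> tuple[np.ndarray, float]:
    """Voxel-wise paired t across subjects on incongruent - congruent maps.

    The within-subject two-condition factor reduces to a paired t-test
    with df = n_subjects - 1.  Returns (t map, df).
    """
    if len(subject_maps_cc) != len(subject_maps_ic):
        raise ValueError("subject counts differ between conditions")
    n = len(subject_maps_cc)
    if n < 3:
        raise ValueError("second level needs at least 3 subjects")
    cc = np.stack(subject_maps_cc)
    ic = np.stack(subject_maps_ic)
    if cc.shape != ic.shape:
        raise ValueError("subject map grids differ")
    return paired_t_map(ic - cc), float(n - 1)


def paired_t_map(diffs: np.ndarray) -> np.ndarray:
    """One-sample t map over the subject axis (axis 0) of difference maps."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.full(mean.shape, np.nan)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    t[~ok & (mean == 0)] = 0.0
    return t


@dataclass
class ClusterTable:
    """Supra-threshold clusters surviving the extent rule."""

    rows: pd.DataFrame           # label, size_voxels, peak_x/y/z_mm, peak_t
    voxel_p: float
    t_threshold: float
    extent_k: int
    labels: np.ndarray           # labeled grid (0 = background)

    def __len__(self) -> int:
        return len(self.rows)

    def cluster_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _connected_clusters(supra: np.ndarray) -> tuple[np.ndarray, int]:
    """Label a binary volume with 26-connectivity."""
    structure = np.ones((3, 3, 3), dtype=bool)
    return ndimage.label(supra, structure=structure)


def expected_cluster_size(
    subject_diffs: np.ndarray,
    voxel_p: float = DEFAULT_VOXEL_P,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Expected supra-threshold cluster size under sign-flip permutations.

    For each permutation the subject difference maps are randomly
    sign-flipped, the group t map recomputed and thresholded, and all
    cluster sizes collected; the mean size over permutations estimates
    the expected voxels per cluster under the null.
    """
    subject_diffs = np.asarray(subject_diffs, dtype=float)
    n = subject_diffs.shape[0]
    t_crit = stats.t.ppf(1.0 - voxel_p, n - 1)
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    for _ in range(n_permutations):
        flips = rng.choice([-1.0, 1.0], size=n)
        t = paired_t_map(subject_diffs * flips[:, None, None, None])
        supra = np.nan_to_num(t) > t_crit
        if supra.any():
            labels, n_lab = _connected_clusters(supra)
            sizes.extend(np.bincount(labels.ravel())[1:].tolist())
    return float(np.mean(sizes)) if sizes else 1.0


def cluster_threshold(
    t_map: np.ndarray,
    df: float,
    voxel_p: float = DEFAULT_VOXEL_P,
    extent: int | str = 1,
    affine: np.ndarray | None = None,
    subject_diffs: np.ndarray | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ClusterTable:
    """Threshold a t map at an uncorrected voxel p and a cluster extent.

    Voxels with t above the one-sided critical value are labeled by
    26-connectivity; clusters smaller than ``extent`` voxels are dropped.
    ``extent="auto"`` estimates the expected cluster size by sign-flip
    permutation of ``subject_diffs`` (required in that case).  Peak
    coordinates are reported in mm when an affine is supplied, else in
    voxel indices.  An empty table (no supra-threshold voxels) is a valid
    result, not an error.
    """
    t_map = np.asarray(t_map, dtype=float)
    t_crit = float(stats.t.ppf(1.0 - voxel_p, df))
    if extent == "auto":
        if subject_diffs is None:
            raise ValueError("extent='auto' requires the subject difference maps")
        k = int(np.ceil(expected_cluster_size(
            subject_diffs, voxel_p, n_permutations, seed)))
    else:
        k = int(extent)

    supra = np.nan_to_num(t_map, nan=-np.inf) > t_crit
    labels, n_lab = _connected_clusters(supra)
    rows = []
    keep = np.zeros_like(labels)
    for lab in range(1, n_lab + 1):
        vox = labels == lab
        size = int(vox.sum())
        if size < k:
            continue
        idx = np.argwhere(vox)
        peak_local = np.argmax(t_map[vox])
        pk = idx[peak_local]
        if affine is not None:
            mm = (affine @ np.append(pk, 1.0))[:3]
        else:
            mm = pk.astype(float)
        rows.append({"label": lab, "size_voxels": size,
                     "peak_x_mm": mm[0], "peak_y_mm": mm[1], "peak_z_mm": mm[2],
                     "peak_t": float(t_map[vox].max())})
        keep[vox] = lab
    table = pd.DataFrame(rows, columns=["label", "size_voxels", "peak_x_mm",
                                        "peak_y_mm", "peak_z_mm", "peak_t"])
    return ClusterTable(rows=table, voxel_p=voxel_p, t_threshold=t_crit,
                        extent_k=k, labels=keep)


# ---------------------------------------------------------------------------
# atlas overlap and spatial smoothing
# ---------------------------------------------------------------------------

def resample_mask_nearest(mask: np.ndarray, mask_affine: np.ndarray,
                          target_shape: tuple[int, int, int],
                          target_affine: np.ndarray) -> np.ndarray:
    """Nearest-neighbour resampling of a boolean mask onto a target grid."""
    inv = np.linalg.inv(mask_affine)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in target_shape], indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4).T
    src = inv @ target_affine @ vox
    idx = np.round(src[:3]).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(mask.shape)[:, None]), axis=0)
    out = np.zeros(np.prod(target_shape), dtype=bool)
    out[inside] = mask[idx[0, inside], idx[1, inside], idx[2, inside]]
    return out.reshape(target_shape)


def atlas_overlap(
    cluster_mask: np.ndarray,
    atlas_mask: np.ndarray,
    cluster_affine: np.ndarray | None = None,
    atlas_affine: np.ndarray | None = None,
    allow_resample: bool = True,
) -> tuple[int, float]:
    """Voxels of a cluster falling inside an anatomical mask.

    Returns (count, fraction of cluster size).  When the grids differ the
    atlas is resampled to the cluster grid by nearest neighbour (logged),
    unless ``allow_resample`` is False.
    """
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    atlas_mask = np.asarray(atlas_mask, dtype=bool)
    if cluster_mask.shape != atlas_mask.shape or (
            cluster_affine is not None and atlas_affine is not None
            and not np.allclose(cluster_affine, atlas_affine)):
        if not allow_resample:
            raise ValueError("cluster and atlas grids differ; resampling disabled")
        if cluster_affine is None or atlas_affine is None:
            raise ValueError("resampling needs both affines")
        logger.info("resampling atlas mask to the statistical grid (nearest)")
        atlas_mask = resample_mask_nearest(atlas_mask, atlas_affine,
                                           cluster_mask.shape, cluster_affine)
    n_cluster = int(cluster_mask.sum())
    if n_cluster == 0:
        return 0, 0.0
    count = int((cluster_mask & atlas_mask).sum())
    return count, count / n_cluster


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum."""
    return fwhm_mm * FWHM_TO_SIGMA


def gaussian_smooth(image: BoldImage | np.ndarray,
                    fwhm_mm: float = DEFAULT_FWHM_MM,
                    voxel_sizes_mm: np.ndarray | None = None):
    """Separable Gaussian smoothing with an isotropic FWHM in mm.

    Accepts a :class:`BoldImage` (smoothed volume by volume, voxel sizes
    from its affine) or a bare 3-D array with explicit voxel sizes.
    """
    if isinstance(image, BoldImage):
        sigma_vox = fwhm_to_sigma(fwhm_mm) / image.voxel_sizes()
        smoothed = ndimage.gaussian_filter(
            image.data, sigma=tuple(sigma_vox) + (0.0,))
        return BoldImage(data=smoothed, affine=image.affine, tr_s=image.tr_s,
                         slice_times=image.slice_times,
                         slice_axis=image.slice_axis,
                         meta={**image.meta, "fwhm_mm": fwhm_mm})
    if voxel_sizes_mm is None:
        raise ValueError("voxel sizes are required to smooth a bare array")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / np.asarray(voxel_sizes_mm, dtype=float)
    return ndimage.gaussian_filter(np.asarray(image, dtype=float),
                                   sigma=tuple(sigma_vox))
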