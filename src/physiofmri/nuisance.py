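"""Physiological nuisance modelling: 8 RETROICOR + 5 RVT regressors, slice-wise.

The nuisance set has 13 columns per slice: cosine and sine of the cardiac
and respiratory phases at orders 1 and 2 (8 columns), plus respiration
volume per time at lags 0, 5, 10, 15 and 20 s (5 columns).  Phases and
RVT are evaluated at each slice's acquisition times (volume onset + slice
offset), and voxel time series are corrected by least-squares projection
onto their slice's regressors with the temporal mean restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BoldImage
from .physio import (
    PhaseSeries,
    PhysioRecording,
    RvtSeries,
    cardiac_phase,
    detect_cardiac_peaks,
    respiratory_phase,
    rvt_breath_series,
)

logger = logging.getLogger("physiofmri")

#: default lags (s) for the delayed RVT terms
DEFAULT_RVT_LAGS = (0.0, 5.0, 10.0, 15.0, 20.0)
#: default RETROICOR Fourier expansion order per signal
DEFAULT_RETROICOR_ORDER = 2

RETROICOR_NAMES = ("card_cos1", "card_sin1", "card_cos2", "card_sin2",
                   "resp_cos1", "resp_sin1", "resp_cos2", "resp_sin2")


def _rvt_names(lags_s) -> tuple[str, ...]:
    return tuple(f"rvt_lag{int(round(l))}" for l in lags_s)


@dataclass
class NuisanceRegressorSet:
    """Per-slice nuisance matrix: (slices, volumes, 13) with stable names."""

    values: np.ndarray
    names: tuple[str, ...]
    slice_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("nuisance values must be (slices, volumes, columns)")
        if self.values.shape[2] != len(self.names):
            raise ValueError("column count does not match names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite nuisance regressor entries")
        self.slice_times = np.asarray(self.slice_times, dtype=float)

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def n_columns(self) -> int:
        return self.values.shape[2]

    def slice_frame(self, s: int) -> pd.DataFrame:
        return pd.DataFrame(self.values[s], columns=list(self.names))

    def write_tsv(self, out_dir: str | Path, stem: str = "nuisance") -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for s in range(self.n_slices):
            p = out / f"{stem}_slice-{s:03d}.tsv"
            self.slice_frame(s).to_csv(p, sep="\t", index=False)
            paths.append(p)
        return paths


def retroicor_basis(
    cardiac: PhaseSeries,
    resp: PhaseSeries,
    order: int = DEFAULT_RETROICOR_ORDER,
) -> np.ndarray:
    """Low-order Fourier expansion of the cardiac and respiratory phases.

    Returns a (volumes, 4*order) matrix with columns cos(m*phi), sin(m*phi)
    for m = 1..order, cardiac first; with order 2 this is the standard
    8-column RETROICOR basis.
    """
    if cardiac.t.shape != resp.t.shape or not np.allclose(cardiac.t, resp.t):
        raise ValueError("cardiac and respiratory phases have mismatched time bases")
    cols = []
    for phase in (cardiac.phase, resp.phase):
        for m in range(1, order + 1):
            cols.append(np.cos(m * phase))
            cols.append(np.sin(m * phase))
    return np.column_stack(cols)


def rvt_regressors(
    rvt: RvtSeries,
    volume_times: np.ndarray,
    lags_s: list[float] | None = None,
) -> np.ndarray:
    """Delayed copies of the RVT function at the acquisition times.

    Column j at time t is RVT(t - lag_j); times before the start of the
    breath record take the edge value.
    """
    if lags_s is None:
        lags_s = list(DEFAULT_RVT_LAGS)
    if len(lags_s) == 0:
        raise ValueError("lag list must not be empty")
    volume_times = np.asarray(volume_times, dtype=float)
    return np.column_stack([rvt.at(volume_times - lag) for lag in lags_s])


def build_slicewise_nuisance(
    physio: PhysioRecording,
    slice_times: np.ndarray,
    n_volumes: int,
    tr_s: float,
    order: int = DEFAULT_RETROICOR_ORDER,
    rvt_lags: list[float] | None = None,
) -> NuisanceRegressorSet:
    """Assemble the full slice-wise nuisance set from a synchronized recording.

    For each slice s the phases and RVT are evaluated at
    t_k = k * TR + slice_time_s; with the defaults the result has 13
    columns (8 RETROICOR + 5 RVT) per slice.
    """
    if rvt_lags is None:
        rvt_lags = list(DEFAULT_RVT_LAGS)
    slice_times = np.asarray(slice_times, dtype=float)
    if physio.duration + 1.0 / physio.fs < n_volumes * tr_s:
        raise ValueError(
            f"physio recording ({physio.duration:.1f} s) shorter than the scan "
            f"({n_volumes * tr_s:.1f} s)")

    ppg = physio.channels["ppg"]
    resp = physio.channels["respiration"]
    peaks = detect_cardiac_peaks(ppg, physio.fs)
    breath_rvt = rvt_breath_series(resp, physio.fs)

    vol_times = np.arange(n_volumes) * tr_s
    mats = []
    for st in slice_times:
        acq = vol_times + st
        phi_c = cardiac_phase(peaks, acq)
        phi_r = respiratory_phase(resp, physio.fs, acq)
        fourier = retroicor_basis(phi_c, phi_r, order=order)
        rvt_cols = rvt_regressors(breath_rvt, acq, lags_s=rvt_lags)
        mats.append(np.column_stack([fourier, rvt_cols]))

    # documented interleaving: cos1, sin1, cos2, sin2 per signal
    names = []
    for sig in ("card", "resp"):
        for m in range(1, order + 1):
            names += [f"{sig}_cos{m}", f"{sig}_sin{m}"]
    names = tuple(names) + _rvt_names(rvt_lags)

    return NuisanceRegressorSet(values=np.stack(mats), names=names,
                                slice_times=slice_times)


def residualize(bold: BoldImage, nuis: NuisanceRegressorSet) -> BoldImage:
    """Remove the nuisance regressors from every voxel time series.

    Each voxel's series is replaced by the residual of a least-squares
    projection onto [intercept | its slice's regressors], with the voxel
    temporal mean added back, so tSNR remains comparable before and after.
    Collinear columns are dropped (with a warning) rather than failing.
    """
    if nuis.n_volumes != bold.n_volumes:
        raise ValueError(
            f"nuisance rows ({nuis.n_volumes}) != BOLD volumes ({bold.n_volumes})")
    n_slices = bold.data.shape[bold.slice_axis]
    if nuis.n_slices != n_slices:
        raise ValueError(
            f"nuisance slices ({nuis.n_slices}) != image slices ({n_slices})")

    data = np.moveaxis(bold.data, bold.slice_axis, 2)  # (a, b, slice, t)
    out = np.empty_like(data)
    n_t = bold.n_volumes

    for s in range(n_slices):
        X = np.column_stack([np.ones(n_t), nuis.values[s]])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # greedily keep a maximal independent column subset
            keep = [0]
            for j in range(1, X.shape[1]):
                if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                    keep.append(j)
            logger.warning("slice %d: dropped %d collinear nuisance columns",
                           s, X.shape[1] - len(keep))
            X = X[:, keep]
        Y = data[:, :, s, :].reshape(-1, n_t).T  # (t, voxels)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        resid += Y.mean(axis=0, keepdims=True)
        out[:, :, s, :] = resid.T.reshape(data.shape[0], data.shape[1], n_t)

    corrected = np.moveaxis(out, 2, bold.slice_axis)
    return BoldImage(data=corrected, affine=bold.affine, tr_s=bold.tr_s,
                     slice_times=bold.slice_times, slice_axis=bold.slice_axis,
                     meta={**bold.meta, "physio_corrected": True})
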