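"""Temporal signal-to-noise ratio maps and masked summaries.

tSNR is the voxel-wise temporal mean divided by the temporal standard
deviation (sample SD, n-1 denominator).  Voxels with zero temporal SD are
flagged undefined rather than silently mapped to zero, and all summaries
operate on the defined, masked voxels only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoldImage


@dataclass
class TSNRMap:
    """Voxel-wise tSNR with a definedness mask and provenance tag."""

    values: np.ndarray
    defined: np.ndarray
    provenance: str = "uncorrected"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != self.defined.shape:
            raise ValueError("values and defined mask shapes differ")


def tsnr_map(bold: BoldImage, mask: np.ndarray | None = None,
             provenance: str = "uncorrected") -> TSNRMap:
    """Compute the voxel-wise tSNR map: mean_t / sd_t (sample SD).

    Requires at least 3 volumes.  Voxels outside ``mask`` or with zero
    temporal SD are marked undefined (NaN in ``values``).
    """
    if bold.n_volumes < 3:
        raise ValueError("tSNR requires at least 3 volumes")
    mean = bold.data.mean(axis=3)
    sd = bold.data.std(axis=3, ddof=1)
    defined = sd > 0
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != bold.grid:
            raise ValueError("mask grid does not match image grid")
        defined &= mask
    values = np.full(bold.grid, np.nan)
    values[defined] = mean[defined] / sd[defined]
    return TSNRMap(values=values, defined=defined, provenance=provenance)


def tsnr_change(corrected: TSNRMap, uncorrected: TSNRMap) -> np.ndarray:
    """Voxel-wise tSNR difference (corrected - uncorrected).

    NaN wherever either input is undefined.
    """
    if corrected.values.shape != uncorrected.values.shape:
        raise ValueError("tSNR map grids differ")
    both = corrected.defined & uncorrected.defined
    out = np.full(corrected.values.shape, np.nan)
    out[both] = corrected.values[both] - uncorrected.values[both]
    return out


def mask_summary(tsnr: TSNRMap, mask: np.ndarray | None = None
                 ) -> tuple[float, float, int]:
    """Mean, SD and voxel count of a tSNR map within a mask.

    Only defined voxels contribute; an empty intersection is an error.
    """
    sel = tsnr.defined.copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tsnr.values.shape:
            raise ValueError("mask grid does not match map grid")
        sel &= mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError("mask does not intersect any defined voxels")
    vals = tsnr.values[sel]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return float(vals.mean()), sd, n
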