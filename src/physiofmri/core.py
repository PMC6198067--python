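"""Shared containers: the event design and the 4-D BOLD series.

Both are thin wrappers over the field-standard representations — a pandas
DataFrame in BIDS events layout (onset, duration, trial_type,
response_time) and a nibabel NIfTI-1 image — adding the invariants the
pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: condition labels for the colour-word task
CONGRUENT = "CC"
INCONGRUENT = "IC"


@dataclass
class EventDesign:
    """Trial table for the colour-word (Stroop) paradigm.

    ``table`` columns: ``onset`` (s, scan time), ``duration`` (s),
    ``trial_type`` (``CC``/``IC``) and ``response_time`` (s).  Onsets are
    strictly increasing.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"onset", "duration", "trial_type", "response_time"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        onsets = self.table["onset"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset"].to_numpy(dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return self.table["duration"].to_numpy(dtype=float)

    @property
    def conditions(self) -> np.ndarray:
        return self.table["trial_type"].to_numpy()

    @property
    def response_times(self) -> np.ndarray:
        return self.table["response_time"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def n_per_condition(self) -> dict[str, int]:
        return self.table["trial_type"].value_counts().to_dict()

    def shifted(self, offset_s: float) -> "EventDesign":
        """A copy with all onsets shifted by ``offset_s`` (e.g. after
        discarding initial volumes, shift by -n_discard*TR)."""
        t = self.table.copy()
        t["onset"] = t["onset"] + offset_s
        return EventDesign(t)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EventDesign":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class BoldImage:
    """A 4-D BOLD series with voxel-grid metadata.

    ``data`` is (x, y, z, t) float; ``affine`` maps voxel indices to mm;
    ``tr_s`` is the repetition time; ``slice_times`` gives each slice's
    acquisition offset within a TR (s), indexed along ``slice_axis``.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    slice_times: np.ndarray | None = None
    slice_axis: int = 2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if self.slice_times is not None:
            self.slice_times = np.asarray(self.slice_times, dtype=float)
            n_slices = self.data.shape[self.slice_axis]
            if len(self.slice_times) != n_slices:
                raise ValueError(
                    f"slice_times has {len(self.slice_times)} entries but the "
                    f"slice axis has {n_slices} slices")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def frame_times(self) -> np.ndarray:
        """Volume onset times (s), volume k acquired starting at k*TR."""
        return np.arange(self.n_volumes) * self.tr_s

    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def discard_initial(self, n: int) -> "BoldImage":
        if n >= self.n_volumes:
            raise ValueError("cannot discard all volumes")
        return BoldImage(self.data[..., n:], self.affine, self.tr_s,
                         self.slice_times, self.slice_axis,
                         {**self.meta, "n_discarded": n})

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = list(img.header.get_zooms()[:3]) + [self.tr_s]
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, slice_times: np.ndarray | None = None,
             slice_axis: int = 2) -> "BoldImage":
        img = nib.load(str(path))
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, tr,
                   slice_times, slice_axis)


def save_map(values: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3-D statistical or quality map as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask image as a boolean grid (non-zero is inside)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0
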