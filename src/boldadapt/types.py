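"""Core containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = ["EventSchedule", "BOLDRun", "ROIMask", "make_event_schedule"]


@dataclass(frozen=True)
class EventSchedule:
    """Trial onsets of one constant-TOA block.

    toa_s
        Trial onset asynchrony: onset-to-onset interval in seconds.
    onsets_s
        Strictly increasing onset times (seconds from run start).
    duration_s
        Modeled event duration; 0 means a unit impulse at onset.
    """

    toa_s: float
    onsets_s: np.ndarray
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        object.__setattr__(self, "onsets_s", onsets)
        if self.toa_s <= 0:
            raise ValueError(f"toa_s must be positive, got {self.toa_s}")
        if onsets.ndim != 1 or onsets.size < 1:
            raise ValueError("onsets_s must be a non-empty 1-D sequence")
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        diffs = np.diff(onsets)
        if onsets.size > 1 and not np.allclose(diffs, self.toa_s, atol=1e-9):
            raise ValueError("consecutive onsets must be spaced by toa_s")

    @property
    def n_trials(self) -> int:
        return int(self.onsets_s.size)

    @property
    def start_s(self) -> float:
        return float(self.onsets_s[0])

    @property
    def span_s(self) -> float:
        """Block span: first onset to end of last event."""
        return float(self.onsets_s[-1] - self.onsets_s[0] + self.duration_s)

    @property
    def end_s(self) -> float:
        return float(self.onsets_s[-1] + self.duration_s)


def make_event_schedule(
    toa_s: float,
    n_trials: int,
    start_s: float = 0.0,
    duration_s: float = 0.0,
) -> EventSchedule:
    """Build one block's schedule: ``n_trials`` onsets spaced ``toa_s`` apart.

    onsets[i] = start_s + i * toa_s.
    """
    if toa_s <= 0:
        raise ValueError(f"toa_s must be positive, got {toa_s}")
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    onsets = start_s + toa_s * np.arange(n_trials, dtype=float)
    return EventSchedule(toa_s=float(toa_s), onsets_s=onsets, duration_s=float(duration_s))


@dataclass
class BOLDRun:
    """One run's 4-D voxel time series on a fixed grid.

    data
        Array of shape (x, y, z, t), signal units.
    tr_s
        Repetition time (volume-to-volume interval), seconds.
    voxel_size_mm
        Physical voxel edge lengths, millimetres.
    affine
        4x4 voxel-to-world transform (defaults to a scaled identity).
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.array([3.0, 3.0, 3.0]))
    affine: np.ndarray | None = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D (x,y,z,t), got shape {self.data.shape}")
        if self.data.shape[-1] < 2:
            raise ValueError("time dimension must have >= 2 volumes")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_vols(self) -> int:
        return int(self.data.shape[-1])

    @property
    def frame_times_s(self) -> np.ndarray:
        """Acquisition time of each volume (start-of-volume convention)."""
        return np.arange(self.n_vols) * self.tr_s

    def copy_with(self, data: np.ndarray) -> "BOLDRun":
        return BOLDRun(
            data=data,
            tr_s=self.tr_s,
            voxel_size_mm=self.voxel_size_mm.copy(),
            affine=None if self.affine is None else self.affine.copy(),
            qc=dict(self.qc),
        )

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_s))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, tr_s: float | None = None) -> "BOLDRun":
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) else nib.load(str(img_or_path))
        zooms = img.header.get_zooms()
        tr = tr_s if tr_s is not None else (float(zooms[3]) if len(zooms) > 3 else 1.0)
        return cls(
            data=np.asarray(img.dataobj, dtype=float),
            tr_s=tr,
            voxel_size_mm=np.asarray(zooms[:3], dtype=float),
            affine=np.asarray(img.affine, dtype=float),
        )


@dataclass
class ROIMask:
    """A named region of interest as a boolean voxel mask."""

    name: str
    mask: np.ndarray
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be a 3-D volume")
        if not self.mask.any():
            raise ValueError(f"ROI '{self.name}' is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_nifti(self, affine=None) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.mask.astype(np.uint8), np.eye(4) if affine is None else affine)

    @classmethod
    def from_nifti(cls, img_or_path, name: str = "roi", hemisphere: str = "") -> "ROIMask":
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) else nib.load(str(img_or_path))
        return cls(name=name, mask=np.asarray(img.dataobj) > 0, hemisphere=hemisphere)


def box_roi(
    grid_shape: tuple,
    corner: tuple,
    size: tuple,
    name: str = "box",
    hemisphere: str = "",
) -> ROIMask:
    """Axis-aligned box ROI, e.g. an 11x3x3 = 99-voxel stand-in region."""
    mask = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    mask[sl] = True
    if mask.sum() != np.prod(size):
        raise ValueError("box exceeds grid bounds")
    return ROIMask(name=name, mask=mask, hemisphere=hemisphere)
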