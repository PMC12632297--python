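"""Core containers shared across the pipeline.

Conventions used everywhere in this package:

* the unit (voxel or vertex) axis comes first, the frame axis last;
* time is measured in seconds, sampling is uniform with period ``tr_seconds``;
* a run is a single continuous acquisition (e.g. one of AP1/PA1/AP2/PA2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "HeaderError",
    "CollinearityError",
    "BoldRun",
    "Signal1D",
    "MaskSet",
    "SurfaceGeometry",
    "MotionParams",
]


class FormatError(ValueError):
    """An external file or array does not match its declared layout."""


class HeaderError(FormatError):
    """Metadata (e.g. the repetition time in a NIfTI header) is invalid."""


class CollinearityError(ValueError):
    """A regression design matrix is rank deficient."""


VOLUME_GRAYMATTER = "volume_graymatter"
SURFACE = "surface"


@dataclass
class BoldRun:
    """A units x frames matrix of BOLD amplitudes for one fMRI run.

    Parameters
    ----------
    data
        ``(n_units, n_frames)`` float array. Units are voxels for volumetric
        runs and cortical vertices for surface runs.
    tr_seconds
        Repetition time; the study protocol uses 0.8 s.
    space
        ``"volume_graymatter"`` or ``"surface"``.
    run_label
        Free-text run identifier, e.g. ``"AP1"``.
    unit_masks
        Optional named boolean selections over the unit axis. Volumetric
        runs loaded together with a mask set carry ``"gray_matter"`` and
        ``"csf"`` entries so that downstream extraction can address each
        compartment.
    unit_indices
        Optional flat voxel indices (into the original 3-D grid) of each
        unit, recorded at load time so results can be mapped back.
    zero_variance_units
        Indices of units that were constant before z-normalisation and were
        therefore zeroed out rather than divided by a zero SD.
    """

    data: np.ndarray
    tr_seconds: float
    space: str = SURFACE
    run_label: str = ""
    unit_masks: Optional[Mapping[str, np.ndarray]] = None
    unit_indices: Optional[np.ndarray] = None
    zero_variance_units: tuple = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(f"BoldRun.data must be 2-D, got {self.data.ndim}-D")
        if self.data.shape[1] < 2:
            raise FormatError("a run needs at least 2 frames")
        if not self.tr_seconds > 0:
            raise HeaderError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("BoldRun.data contains non-finite values")
        if self.space not in (VOLUME_GRAYMATTER, SURFACE):
            raise FormatError(f"unknown space {self.space!r}")
        if self.unit_masks is not None:
            for name, m in self.unit_masks.items():
                if np.asarray(m).shape != (self.n_units,):
                    raise FormatError(f"unit mask {name!r} does not match unit axis")

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_frames * self.tr_seconds

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_seconds

    def replace_data(self, data: np.ndarray, **extra) -> "BoldRun":
        """Return a copy of this run with new data, keeping metadata."""
        kwargs = dict(
            tr_seconds=self.tr_seconds,
            space=self.space,
            run_label=self.run_label,
            unit_masks=self.unit_masks,
            unit_indices=self.unit_indices,
            zero_variance_units=self.zero_variance_units,
        )
        kwargs.update(extra)
        return BoldRun(data, **kwargs)


@dataclass
class Signal1D:
    """A single uniformly sampled time course (gBOLD, CSF, a parcel mean)."""

    values: np.ndarray
    tr_seconds: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise FormatError("Signal1D needs at least 2 samples")
        if not self.tr_seconds > 0:
            raise HeaderError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"signal {self.label!r} contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.size

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_seconds


@dataclass
class MaskSet:
    """Gray-matter and CSF region-of-interest masks on a common 3-D grid.

    The CSF ROI sits at the bottom slice of the acquisition (below the
    cerebellum), where inflowing unsaturated spins make the fMRI signal
    sensitive to CSF flow; ``bottom_slice_index`` declares which slice along
    ``slice_axis`` that is, and the constructor verifies that the ROI does
    not leave it.
    """

    gray_matter: np.ndarray
    csf_roi: np.ndarray
    slice_axis: int = 2
    bottom_slice_index: int = 0

    def __post_init__(self) -> None:
        self.gray_matter = np.asarray(self.gray_matter, dtype=bool)
        self.csf_roi = np.asarray(self.csf_roi, dtype=bool)
        if self.gray_matter.shape != self.csf_roi.shape:
            raise FormatError("gray-matter and CSF masks must share a grid")
        if self.gray_matter.ndim != 3:
            raise FormatError("masks must be 3-D volumes")
        if not self.gray_matter.any():
            raise FormatError("gray-matter mask is empty")
        if not self.csf_roi.any():
            raise FormatError("CSF ROI is empty")
        slices = np.flatnonzero(self.csf_roi.any(axis=tuple(
            ax for ax in range(3) if ax != self.slice_axis)))
        if not np.array_equal(slices, [self.bottom_slice_index]):
            raise FormatError(
                "CSF ROI must be confined to the declared bottom slice "
                f"(index {self.bottom_slice_index} on axis {self.slice_axis})")

    @property
    def shape(self) -> tuple:
        return self.gray_matter.shape


@dataclass
class SurfaceGeometry:
    """Per-vertex scalars attached to a cortical surface mesh.

    Only scalar fields are needed by this pipeline: the principal-gradient
    (PG) score that orders vertices from unimodal sensory-motor (low) to
    transmodal default-mode (high) cortex, and a parcel id per vertex
    (0 = unassigned / medial wall). Mesh coordinates are never used.
    """

    pg_score: np.ndarray
    parcel_id: Optional[np.ndarray] = None
    parcel_table: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        self.pg_score = np.asarray(self.pg_score, dtype=float).ravel()
        if not np.all(np.isfinite(self.pg_score)):
            raise FormatError("PG scores must be finite")
        if self.parcel_id is None:
            self.parcel_id = np.zeros(self.n_vertices, dtype=int)
        self.parcel_id = np.asarray(self.parcel_id, dtype=int).ravel()
        if self.parcel_id.shape != self.pg_score.shape:
            raise FormatError("parcel_id and pg_score must have equal length")
        if self.parcel_table is None:
            ids = np.unique(self.parcel_id)
            self.parcel_table = tuple(int(i) for i in ids if i != 0)
        else:
            self.parcel_table = tuple(int(i) for i in self.parcel_table)
            declared = set(self.parcel_table) | {0}
            present = set(int(i) for i in np.unique(self.parcel_id))
            if not present <= declared:
                raise FormatError("parcel_id references undeclared parcels")

    @property
    def n_vertices(self) -> int:
        return self.pg_score.size


@dataclass
class MotionParams:
    """Rigid-body realignment parameters, one row per frame.

    Columns are ordered (x, y, z translations in mm; then three rotations,
    by default in radians) following the FSL/HCP ``Movement_Regressors``
    layout.
    """

    params: np.ndarray
    rotation_unit: str = "radians"

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise FormatError(
                f"motion parameters must be T x 6, got {self.params.shape}")
        if not np.all(np.isfinite(self.params)):
            raise FormatError("motion parameters contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]
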