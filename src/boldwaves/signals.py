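"""Temporal filtering, standardisation, and signal extraction.

The per-run processing order is: band-pass filter (0.01–0.1 Hz, the
infra-slow band), per-unit z-normalisation, then spatial averaging into the
global (gBOLD), CSF, or parcel-mean signals. The filter is zero-phase so
that the lag structure the coupling analysis depends on is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import BoldRun, FormatError, MaskSet, Signal1D, SurfaceGeometry

__all__ = [
    "BandpassSpec",
    "bandpass",
    "znorm",
    "zscore_signal",
    "extract_gbold",
    "extract_csf",
    "parcel_means",
    "gbold_amplitude",
    "subject_amplitude",
]

#: minimum run duration, in cycles of the low cutoff, for a stable filter
MIN_CYCLES = 3.0


@dataclass(frozen=True)
class BandpassSpec:
    """Pass band in Hz; the study band is 0.01–0.1 Hz."""

    low_hz: float = 0.01
    high_hz: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")

    def validate_for(self, tr_seconds: float, n_frames: int) -> None:
        nyquist = 0.5 / tr_seconds
        if not self.high_hz < nyquist:
            raise ValueError(
                f"high_hz {self.high_hz} not below Nyquist {nyquist:.4g}")
        min_frames = MIN_CYCLES / self.low_hz / tr_seconds
        if n_frames < min_frames:
            raise ValueError(
                f"run of {n_frames} frames too short for a {self.low_hz} Hz "
                f"cutoff (need >= {int(np.ceil(min_frames))})")


def _bandpass_matrix(data: np.ndarray, tr: float, spec: BandpassSpec) -> np.ndarray:
    # order-2 Butterworth per pass, applied forward and backward (zero phase)
    sos = sps.butter(2, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=1.0 / tr, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def bandpass(run: BoldRun, spec: BandpassSpec = BandpassSpec()) -> BoldRun:
    """Zero-phase band-pass filter every unit's time course."""
    spec.validate_for(run.tr_seconds, run.n_frames)
    return run.replace_data(_bandpass_matrix(run.data, run.tr_seconds, spec))


def znorm(run: BoldRun) -> BoldRun:
    """Z-normalise each unit (subtract its mean, divide by its SD).

    Units with zero variance cannot be scaled; they are set to all-zero and
    their indices recorded in ``zero_variance_units`` rather than aborting
    the run.
    """
    mean = run.data.mean(axis=1, keepdims=True)
    sd = run.data.std(axis=1, keepdims=True)
    flat = sd.ravel() == 0
    sd[flat[:, None]] = 1.0
    out = (run.data - mean) / sd
    out[flat] = 0.0
    return run.replace_data(out, zero_variance_units=tuple(np.flatnonzero(flat)))


def zscore_signal(sig: Signal1D) -> Signal1D:
    sd = sig.values.std()
    if sd == 0:
        return Signal1D(np.zeros_like(sig.values), sig.tr_seconds, sig.label)
    return Signal1D((sig.values - sig.values.mean()) / sd, sig.tr_seconds, sig.label)


def extract_gbold(run: BoldRun) -> Signal1D:
    """Spatial mean across units at each frame — the global BOLD signal.

    For volumetric runs that carry a ``gray_matter`` unit mask, only
    gray-matter voxels enter the average (CSF voxels loaded alongside are
    left out); surface runs average all vertices.
    """
    if run.n_units == 0:
        raise FormatError("empty run")
    data = run.data
    if run.unit_masks is not None and "gray_matter" in run.unit_masks:
        data = data[np.asarray(run.unit_masks["gray_matter"], dtype=bool)]
        if data.shape[0] == 0:
            raise FormatError("no gray-matter units in run")
    return Signal1D(data.mean(axis=0), run.tr_seconds, label="gBOLD")


def extract_csf(run: BoldRun, masks: Optional[MaskSet] = None) -> Signal1D:
    """Mean over CSF-ROI voxels per frame, then z-normalised.

    The ROI is taken from the run's ``csf`` unit mask (attached by
    :func:`boldwaves.io.read_volume_run`); passing ``masks`` merely asserts
    the run was loaded against the same grid.
    """
    if run.unit_masks is None or "csf" not in run.unit_masks:
        raise FormatError("run carries no CSF unit mask")
    sel = np.asarray(run.unit_masks["csf"], dtype=bool)
    if not sel.any():
        raise FormatError("CSF ROI is empty")
    if masks is not None and run.unit_indices is not None:
        expected = np.flatnonzero(masks.csf_roi.ravel())
        if not np.array_equal(np.sort(run.unit_indices[sel]), expected):
            raise FormatError("run CSF units do not match the supplied mask")
    raw = Signal1D(run.data[sel].mean(axis=0), run.tr_seconds, label="CSF")
    return zscore_signal(raw)


def parcel_means(run: BoldRun, geometry: SurfaceGeometry) -> List[Optional[Signal1D]]:
    """Average the run within each declared parcel.

    Returns one :class:`Signal1D` per parcel in declared parcel order;
    parcels with no assigned vertex yield ``None`` (flagged missing).
    Vertices with parcel id 0 (medial wall / unassigned) are excluded.
    """
    if run.n_units != geometry.n_vertices:
        raise FormatError("run and geometry disagree on vertex count")
    out: List[Optional[Signal1D]] = []
    for pid in geometry.parcel_table:
        sel = geometry.parcel_id == pid
        if not sel.any():
            out.append(None)
            continue
        out.append(Signal1D(run.data[sel].mean(axis=0), run.tr_seconds,
                            label=f"parcel_{pid}"))
    return out


def gbold_amplitude(gbold: Signal1D) -> float:
    """Temporal standard deviation of the gBOLD signal of one run.

    gBOLD is a spatial mean of unit-variance time courses, so its SD
    directly measures how synchronously the whole cortex (de)activates —
    large global events raise it, incoherent activity lowers it.
    """
    return float(gbold.values.std())


def subject_amplitude(gbolds: Sequence[Signal1D]) -> float:
    """Subject-level amplitude: mean of the per-run amplitudes."""
    if len(gbolds) == 0:
        raise ValueError("need at least one run")
    return float(np.mean([gbold_amplitude(g) for g in gbolds]))
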