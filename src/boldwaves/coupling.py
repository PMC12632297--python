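"""Cross-correlation and gBOLD–CSF coupling.

Lag-sign convention (fixed throughout the package): ``values[tau]`` is the
Pearson correlation between ``first(t)`` and ``second(t + tau)``. With
``first = gBOLD`` and ``second = CSF``, a *positive* lag therefore pairs
the CSF signal from ``tau`` seconds later with the current gBOLD value —
CSF changes *follow* gBOLD changes. Under this convention a CSF signal
that is a delayed negative copy of gBOLD produces the negative peak at a
positive lag that motivates summarising each subject's coupling at the
fixed +3.2 s lag.

Correlations are computed on the truncated overlap at each lag, with means
and SDs recomputed per lag (no padding, no FFT wraparound).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Signal1D

__all__ = [
    "CrossCorrelation",
    "CouplingResult",
    "xcorr",
    "coupling_at_lag",
    "subject_coupling",
    "gbold_presence",
    "rbold_csf_coupling",
    "group_mean_ccf",
    "DEFAULT_MAX_LAG_S",
    "DEFAULT_COUPLING_LAG_S",
]

DEFAULT_MAX_LAG_S = 16.0
DEFAULT_COUPLING_LAG_S = 3.2


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class CrossCorrelation:
    """A cross-correlation function on a lag grid with step = TR.

    ``sem`` and ``n`` are populated for group means (pointwise standard
    error across subjects).
    """

    lags_seconds: np.ndarray
    values: np.ndarray
    tr_seconds: float
    sem: Optional[np.ndarray] = None
    n: int = 1

    def __post_init__(self) -> None:
        self.lags_seconds = np.asarray(self.lags_seconds, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags_seconds.shape != self.values.shape:
            raise ValueError("lag grid and values must align")

    def value_at(self, lag_seconds: float) -> float:
        return coupling_at_lag(self, lag_seconds)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lag_s": self.lags_seconds, "r": self.values})
        if self.sem is not None:
            df["sem"] = self.sem
        return df


@dataclass
class CouplingResult:
    """Per-run and subject-level coupling at a fixed lag."""

    per_run: List[float]
    subject_value: float
    lag_used_seconds: float
    subject_ccf: CrossCorrelation = field(repr=False, default=None)


def xcorr(first: Signal1D, second: Signal1D,
          max_lag_seconds: float = DEFAULT_MAX_LAG_S) -> CrossCorrelation:
    """Pearson correlation of two equal-TR signals at every lag on the grid.

    The grid spans ``-max_lag .. +max_lag`` in TR steps (at TR 0.8 s a
    16-s range gives lags of -20..+20 frames). ``max_lag_seconds`` must be
    a TR multiple and the signals must be longer than twice the maximal
    lag so every overlap is non-degenerate.
    """
    if first.n_frames != second.n_frames:
        raise ValueError("signals must have equal length")
    if first.tr_seconds != second.tr_seconds:
        raise ValueError("signals must share a TR")
    tr = first.tr_seconds
    k_max_f = max_lag_seconds / tr
    k_max = int(round(k_max_f))
    if abs(k_max_f - k_max) > 1e-9:
        raise ValueError(f"max_lag {max_lag_seconds}s is not a TR multiple")
    n = first.n_frames
    if n <= 2 * k_max:
        raise ValueError(
            f"signals of {n} frames too short for +-{k_max} frame lags")
    x = first.values
    y = second.values
    lags = np.arange(-k_max, k_max + 1)
    vals = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            vals[i] = _pearson(x[: n - k], y[k:])
        else:
            vals[i] = _pearson(x[-k:], y[: n + k])
    return CrossCorrelation(lags * tr, vals, tr)


def coupling_at_lag(cc: CrossCorrelation,
                    lag_seconds: float = DEFAULT_COUPLING_LAG_S) -> float:
    """The correlation at exactly one grid lag — no interpolation."""
    hits = np.flatnonzero(np.isclose(cc.lags_seconds, lag_seconds, atol=1e-6))
    if hits.size != 1:
        raise ValueError(
            f"lag {lag_seconds}s is not on the computed grid "
            f"(step {cc.tr_seconds}s)")
    return float(cc.values[hits[0]])


def subject_coupling(runs: Sequence[Tuple[Signal1D, Signal1D]],
                     max_lag_seconds: float = DEFAULT_MAX_LAG_S,
                     lag_seconds: float = DEFAULT_COUPLING_LAG_S) -> CouplingResult:
    """Average the per-run CCFs pointwise, then read the fixed-lag value.

    Because averaging is pointwise and the readout lag is fixed, the
    subject value equals the arithmetic mean of the per-run values; both
    are returned.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    ccs = [xcorr(g, c, max_lag_seconds) for g, c in runs]
    mean_vals = np.mean([cc.values for cc in ccs], axis=0)
    subject_cc = CrossCorrelation(ccs[0].lags_seconds, mean_vals,
                                  ccs[0].tr_seconds)
    per_run = [coupling_at_lag(cc, lag_seconds) for cc in ccs]
    return CouplingResult(per_run=per_run,
                          subject_value=coupling_at_lag(subject_cc, lag_seconds),
                          lag_used_seconds=lag_seconds,
                          subject_ccf=subject_cc)


def gbold_presence(parcels: Sequence[Optional[Signal1D]],
                   surface_mean: Signal1D,
                   parcel_ids: Optional[Sequence[int]] = None) -> pd.Series:
    """Zero-lag correlation of each parcel mean with the whole-surface mean.

    Measures each region's engagement in global activity. Constant or
    missing parcel signals yield NaN.
    """
    ids = list(parcel_ids) if parcel_ids is not None else list(range(1, len(parcels) + 1))
    out = {}
    for pid, sig in zip(ids, parcels):
        if sig is None:
            out[pid] = np.nan
            continue
        out[pid] = _pearson(sig.values, surface_mean.values)
    return pd.Series(out, name="gbold_presence")


def rbold_csf_coupling(parcels: Sequence[Optional[Signal1D]],
                       csf: Signal1D,
                       lag_seconds: float = DEFAULT_COUPLING_LAG_S,
                       max_lag_seconds: float = DEFAULT_MAX_LAG_S,
                       parcel_ids: Optional[Sequence[int]] = None) -> pd.Series:
    """Per-parcel correlation with the CSF signal at the fixed coupling lag."""
    ids = list(parcel_ids) if parcel_ids is not None else list(range(1, len(parcels) + 1))
    out = {}
    for pid, sig in zip(ids, parcels):
        if sig is None:
            out[pid] = np.nan
            continue
        cc = xcorr(sig, csf, max_lag_seconds)
        out[pid] = coupling_at_lag(cc, lag_seconds)
    return pd.Series(out, name="rbold_csf_coupling")


def group_mean_ccf(subjects: Sequence[CrossCorrelation]) -> CrossCorrelation:
    """Pointwise mean CCF across subjects with a standard-error band."""
    if len(subjects) == 0:
        raise ValueError("need at least one subject")
    lags = subjects[0].lags_seconds
    for cc in subjects[1:]:
        if not np.allclose(cc.lags_seconds, lags):
            raise ValueError("subjects computed on different lag grids")
    stack = np.vstack([cc.values for cc in subjects])
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        sem = np.zeros_like(mean)
    return CrossCorrelation(lags, mean, subjects[0].tr_seconds,
                            sem=sem, n=stack.shape[0])
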