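"""Detection and classification of infra-slow propagating waves.

The cortical surface is ordered by the principal gradient (PG), split into
positional bins of near-equal vertex count, and each bin's band-limited
signal is averaged. The global (whole-surface mean) signal is segmented at
its troughs; within each trough-to-trough segment the largest local peak of
every bin is timed relative to the global peak. A segment counts as a
global event only if at least 80% of bins show a local peak. The Pearson
correlation between peak delay and PG position then classifies each event:

* significant positive correlation (p < 0.01): *bottom-up* — activity
  sweeps from sensory-motor (low PG) toward default-mode (high PG) cortex;
* significant negative correlation (p < 0.01): *top-down*, the reverse;
* no correlation (p > 0.05): a global peak without propagation;
* 0.01 <= p <= 0.05: left unclassified and excluded from wave counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BoldRun, Signal1D, SurfaceGeometry

__all__ = [
    "GradientBinning",
    "BinnedSeries",
    "Segment",
    "PeakTable",
    "WaveEvent",
    "WaveLockedAverage",
    "bin_by_gradient",
    "bin_series",
    "segment_by_troughs",
    "peak_table",
    "classify_segment",
    "classify_run",
    "count_waves",
    "subject_wave_counts",
    "wave_locked_average",
    "wave_score_map",
    "LABELS",
    "DEFAULT_N_BINS",
    "DEFAULT_INVOLVEMENT",
]

DEFAULT_N_BINS = 70
DEFAULT_INVOLVEMENT = 0.8
P_WAVE = 0.01
P_NO_PROPAGATION = 0.05

BOTTOM_UP = "bottom_up"
TOP_DOWN = "top_down"
NO_PROPAGATION = "no_propagation"
UNCLASSIFIED = "unclassified"
EXCLUDED = "excluded_low_involvement"
LABELS = (BOTTOM_UP, TOP_DOWN, NO_PROPAGATION, UNCLASSIFIED, EXCLUDED)


@dataclass
class GradientBinning:
    """Assignment of every vertex to one of ``n_bins`` PG-ordered bins."""

    n_bins: int
    bin_of_vertex: np.ndarray

    def vertices_in(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.bin_of_vertex == b)


@dataclass
class BinnedSeries:
    """Bin-averaged time courses, rows ordered by ascending PG."""

    data: np.ndarray  # (n_bins, n_frames)
    tr_seconds: float

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Segment:
    """One trough-to-trough window, half-open ``[start_frame, end_frame)``."""

    start_frame: int
    end_frame: int
    gbold_peak_frame: int


@dataclass
class PeakTable:
    """Per-bin delay of the largest local peak relative to the global peak.

    ``delay_seconds[b]`` is NaN when bin ``b`` shows no local peak inside
    the segment.
    """

    delay_seconds: np.ndarray

    @property
    def involvement_fraction(self) -> float:
        return float(np.mean(~np.isnan(self.delay_seconds)))


@dataclass
class WaveEvent:
    segment: Segment
    r: float
    p: float
    label: str
    involvement_fraction: float


@dataclass
class WaveLockedAverage:
    """Bin x relative-time average of the signal around event peaks."""

    data: np.ndarray
    rel_time_seconds: np.ndarray
    event_count: int


def _symmetric_bin_sizes(n_vertices: int, n_bins: int) -> np.ndarray:
    """Bin occupancies differing by <= 1 and palindromic in bin order.

    The palindromic layout makes binning commute with a sign flip of the
    PG map, so direction equivariance of the classifier holds exactly.
    """
    base, rem = divmod(n_vertices, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    pairs, odd = divmod(rem, 2)
    half = n_bins // 2
    if pairs:
        # spread the paired extras evenly over the first half, mirrored
        pos = (np.arange(pairs) * half) // pairs
        sizes[pos] += 1
        sizes[n_bins - 1 - pos] += 1
    if odd:
        sizes[n_bins // 2] += 1
    return sizes


def bin_by_gradient(geometry: SurfaceGeometry,
                    n_bins: int = DEFAULT_N_BINS) -> GradientBinning:
    """Sort vertices by PG score and split into near-equal contiguous bins.

    "Evenly divided" is read as equal vertex count per bin (not equal PG
    range); ties in the score are broken by vertex index. Bin 0 is the
    sensory-motor (lowest PG) end.
    """
    n = geometry.n_vertices
    if n_bins > n:
        raise ValueError(f"cannot form {n_bins} bins from {n} vertices")
    order = np.lexsort((np.arange(n), geometry.pg_score))
    sizes = _symmetric_bin_sizes(n, n_bins)
    bin_of_vertex = np.empty(n, dtype=int)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    for b in range(n_bins):
        bin_of_vertex[order[edges[b]:edges[b + 1]]] = b
    return GradientBinning(n_bins=n_bins, bin_of_vertex=bin_of_vertex)


def bin_series(run: BoldRun, binning: GradientBinning) -> BinnedSeries:
    """Average the run within each PG bin."""
    if run.n_units != binning.bin_of_vertex.size:
        raise ValueError("run and binning disagree on vertex count")
    counts = np.bincount(binning.bin_of_vertex, minlength=binning.n_bins)
    sums = np.zeros((binning.n_bins, run.n_frames))
    np.add.at(sums, binning.bin_of_vertex, run.data)
    return BinnedSeries(sums / counts[:, None], run.tr_seconds)


def segment_by_troughs(gbold: Signal1D) -> List[Segment]:
    """Partition the run at strict local minima of the global signal.

    A trough is a frame strictly lower than both neighbours (no prominence
    threshold — the infra-slow band-pass already suppresses spurious
    minima). Consecutive troughs delimit half-open segments; data before
    the first and after the last trough are discarded. Fewer than two
    troughs yield an empty list.
    """
    g = gbold.values
    interior = g[1:-1]
    troughs = 1 + np.flatnonzero((interior < g[:-2]) & (interior < g[2:]))
    segments: List[Segment] = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        peak = int(a + np.argmax(g[a:b]))
        segments.append(Segment(int(a), int(b), peak))
    return segments


def _largest_local_peak(window: np.ndarray) -> Optional[int]:
    """Index (within ``window``) of the highest strict local maximum.

    Plateaus count once, at their earliest frame; the first and last frame
    of the window never qualify. Returns None when no interior local
    maximum exists.
    """
    m = window.size
    if m < 3:
        return None
    best_idx = None
    best_val = -np.inf
    i = 1
    while i < m - 1:
        if window[i] <= window[i - 1]:
            i += 1
            continue
        # climbed up to i; extend over any plateau
        j = i
        while j + 1 < m and window[j + 1] == window[i]:
            j += 1
        if j < m - 1 and window[j + 1] < window[i]:
            if window[i] > best_val:
                best_val = window[i]
                best_idx = i
        i = j + 1
    return best_idx


def peak_table(binned: BinnedSeries, seg: Segment) -> PeakTable:
    """Delay of each bin's largest local peak relative to the global peak."""
    if not (0 <= seg.start_frame < seg.end_frame <= binned.n_frames):
        raise ValueError("segment lies outside the run")
    delays = np.full(binned.n_bins, np.nan)
    for b in range(binned.n_bins):
        idx = _largest_local_peak(binned.data[b, seg.start_frame:seg.end_frame])
        if idx is not None:
            frame = seg.start_frame + idx
            delays[b] = (frame - seg.gbold_peak_frame) * binned.tr_seconds
    return PeakTable(delay_seconds=delays)


def classify_segment(pt: PeakTable, binning: GradientBinning, seg: Segment,
                     involvement_threshold: float = DEFAULT_INVOLVEMENT,
                     p_wave: float = P_WAVE,
                     p_no_propagation: float = P_NO_PROPAGATION) -> WaveEvent:
    """Label one segment from its delay-versus-PG-position correlation.

    The position variable is the bin rank along ascending PG (equal-count
    bins make rank and mean score monotonically equivalent); the test is a
    two-sided t test on Pearson's r over the bins with a detected peak.
    Segments with involvement below the threshold (or fewer than three
    usable bins, where the correlation is degenerate) are excluded.
    """
    involvement = pt.involvement_fraction
    present = ~np.isnan(pt.delay_seconds)
    n_ok = int(present.sum())
    if involvement < involvement_threshold or n_ok < 3:
        return WaveEvent(seg, np.nan, np.nan, EXCLUDED, involvement)
    positions = np.flatnonzero(present).astype(float)
    delays = pt.delay_seconds[present]
    if np.ptp(delays) == 0 or np.ptp(positions) == 0:
        r, p = 0.0, 1.0
    else:
        res = stats.pearsonr(delays, positions)
        r, p = float(res.statistic), float(res.pvalue)
    if p < p_wave:
        label = BOTTOM_UP if r > 0 else TOP_DOWN
    elif p > p_no_propagation:
        label = NO_PROPAGATION
    else:
        label = UNCLASSIFIED
    return WaveEvent(seg, r, p, label, involvement)


def classify_run(binned: BinnedSeries, gbold: Signal1D,
                 binning: GradientBinning,
                 involvement_threshold: float = DEFAULT_INVOLVEMENT,
                 p_wave: float = P_WAVE,
                 p_no_propagation: float = P_NO_PROPAGATION) -> List[WaveEvent]:
    """Segment a run on its global signal and classify every segment."""
    events = []
    for seg in segment_by_troughs(gbold):
        pt = peak_table(binned, seg)
        events.append(classify_segment(pt, binning, seg,
                                       involvement_threshold,
                                       p_wave, p_no_propagation))
    return events


def count_waves(events: Sequence[WaveEvent]) -> Dict[str, int]:
    """Tally events per label (all five labels always present)."""
    counts = {label: 0 for label in LABELS}
    for ev in events:
        counts[ev.label] += 1
    return counts


def subject_wave_counts(per_run_events: Mapping[str, Sequence[WaveEvent]],
                        per_run_duration_s: Optional[Mapping[str, float]] = None
                        ) -> Dict[str, float]:
    """Sum wave counts over a subject's runs.

    Raw counts are only comparable across subjects scanned for the same
    total duration; when per-run durations are supplied and differ, counts
    are normalised to events per minute instead (key ``"per_minute"`` set
    to True in the result).
    """
    total = {label: 0.0 for label in LABELS}
    for events in per_run_events.values():
        for label, c in count_waves(events).items():
            total[label] += c
    result: Dict[str, float] = dict(total)
    result["per_minute"] = False
    if per_run_duration_s is not None:
        durations = [per_run_duration_s[k] for k in per_run_events]
        total_minutes = sum(durations) / 60.0
        if not np.allclose(durations, durations[0]):
            for label in LABELS:
                result[label] = total[label] / total_minutes
            result["per_minute"] = True
    return result


def wave_locked_average(binned: BinnedSeries, events: Sequence[WaveEvent],
                        window_seconds: float) -> WaveLockedAverage:
    """Mean bin x time excerpt aligned on each event's global peak.

    The window is symmetric about the peak; events whose window would run
    past either end of the run are dropped. Raises if no event survives.
    """
    w = int(round(window_seconds / binned.tr_seconds))
    excerpts = []
    for ev in events:
        p = ev.segment.gbold_peak_frame
        if p - w < 0 or p + w + 1 > binned.n_frames:
            continue
        excerpts.append(binned.data[:, p - w:p + w + 1])
    if not excerpts:
        raise ValueError("no event fits the requested window")
    rel = np.arange(-w, w + 1) * binned.tr_seconds
    return WaveLockedAverage(np.mean(excerpts, axis=0), rel, len(excerpts))


def wave_score_map(averages: Sequence[WaveLockedAverage],
                   covariate: Sequence[float],
                   ages: Optional[Sequence[float]] = None):
    """Correlate each (bin, time) cell with a subject covariate.

    When ``ages`` is given, the linear age effect is regressed out of both
    the covariate and every cell before correlating (the cohort-level age
    adjustment). A constant covariate makes the map undefined: both maps
    are returned all-NaN and flagged via the third return value.

    Returns ``(r_map, p_map, valid)``.
    """
    from .cohort import residualize_age  # local import avoids a cycle

    stack = np.stack([a.data for a in averages])  # (n_subj, n_bins, n_t)
    cov = np.asarray(covariate, dtype=float)
    if stack.shape[0] != cov.size:
        raise ValueError("one covariate value per subject required")
    shape = stack.shape[1:]
    if np.ptp(cov) == 0:
        nan = np.full(shape, np.nan)
        return nan, nan.copy(), False
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        cov = residualize_age(cov, ages)
        flat = stack.reshape(stack.shape[0], -1)
        flat = np.column_stack([residualize_age(flat[:, j], ages)
                                for j in range(flat.shape[1])])
        stack = flat.reshape(stack.shape)
    r_map = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    for b in range(shape[0]):
        for t in range(shape[1]):
            cell = stack[:, b, t]
            if np.ptp(cell) == 0:
                continue
            res = stats.pearsonr(cell, cov)
            r_map[b, t] = res.statistic
            p_map[b, t] = res.pvalue
    return r_map, p_map, True


def events_to_frame(events: Sequence[WaveEvent], tr_seconds: float,
                    subject: str = "", run: str = "") -> pd.DataFrame:
    """Flatten events into the exportable TSV layout."""
    rows = []
    for ev in events:
        rows.append({
            "subject": subject,
            "run": run,
            "start_s": ev.segment.start_frame * tr_seconds,
            "end_s": ev.segment.end_frame * tr_seconds,
            "r": ev.r,
            "p": ev.p,
            "label": ev.label,
            "involvement": ev.involvement_fraction,
        })
    return pd.DataFrame(rows, columns=["subject", "run", "start_s", "end_s",
                                       "r", "p", "label", "involvement"])
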