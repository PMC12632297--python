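"""Framewise displacement and head-motion confound checks.

FD is computed literally as the sum of the absolute frame-to-frame
increments of all six rigid-body parameters,

    FD_i = |dpx_i| + |dpy_i| + |dpz_i| + |dpa_i| + |dpb_i| + |dpg_i|,

with dpx_i = px_{i+1} - px_i and likewise for the others. Rotational
increments are summed directly with translations — no conversion of
rotations to arc length on a reference sphere — so the value has mixed
units (mm + radians); the session mean (mFD) is used purely as a relative
motion index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .core import MotionParams

__all__ = ["FDSeries", "framewise_displacement", "motion_adjustment_check"]


@dataclass
class FDSeries:
    """FD per frame transition (length T-1) and its session mean."""

    fd: np.ndarray
    mfd: float


def framewise_displacement(mp: MotionParams) -> FDSeries:
    if mp.n_frames < 2:
        raise ValueError("need at least two frames for FD")
    fd = np.abs(np.diff(mp.params, axis=0)).sum(axis=1)
    return FDSeries(fd=fd, mfd=float(fd.mean()))


def motion_adjustment_check(metric: Sequence[float],
                            mfd: Sequence[float],
                            group_labels: Optional[Sequence[str]] = None,
                            compare: tuple = ("earlier", "later")) -> Dict[str, object]:
    """Assess whether a subject-level metric is confounded by head motion.

    Reports (a) the metric–mFD correlation, (b) the group comparison of
    mFD itself when labels are given, (c) the group comparison of the
    metric before and after residualising mFD out of it, and (d) the
    partial correlation of the adjusted metric with mFD (zero by
    construction; returned as a sanity check).
    """
    from .cohort import correlate, residualize_age, two_sample_t

    metric = np.asarray(metric, dtype=float)
    mfd = np.asarray(mfd, dtype=float)
    report: Dict[str, object] = {"metric_vs_mfd": correlate(metric, mfd)}
    adjusted = residualize_age(metric, mfd)  # OLS residual on (1, mfd)
    report["adjusted_metric_vs_mfd"] = correlate(adjusted, mfd)
    if group_labels is not None:
        labels = np.asarray(group_labels)
        a, b = (metric[labels == g] for g in compare)
        report["metric_group_test"] = two_sample_t(a, b)
        a, b = (adjusted[labels == g] for g in compare)
        report["adjusted_metric_group_test"] = two_sample_t(a, b)
        a, b = (mfd[labels == g] for g in compare)
        report["mfd_group_test"] = two_sample_t(a, b)
    return report
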