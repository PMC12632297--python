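"""Seeded synthetic cohorts with the structure every pipeline stage assumes.

The source cohort is access-controlled, so this module generates data with
the same statistical skeleton: infra-slow band-limited vertex noise,
injected global events that propagate along the principal gradient (in
either direction, or synchronously), a CSF signal that is a delayed
negative copy of the global signal plus noise, random-walk motion traces,
and a phenotype table built so that the split / overlap-exclusion /
tertile cohort logic reproduces its documented counting flow exactly
(124 -> exclude 34 -> 90 -> 30/30/30 at the default sizes).

Three tiers trade realism for cost:

* ``tier="none"``   — phenotypes, planted per-subject effect sizes, and
  wave counts / memory scores only (for cohort-statistics experiments);
* ``tier="signals"``— adds per-run global and CSF time courses plus motion
  (for coupling and amplitude experiments; no vertex matrices);
* ``tier="full"``   — adds vertex x frame surface runs with injected
  propagating events (for the wave-detection stage).

Everything is driven by a single master seed through
``numpy.random.SeedSequence`` spawning, so cohorts are bit-reproducible
and per-subject streams are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .core import BoldRun, MotionParams, Signal1D, SurfaceGeometry
from .signals import BandpassSpec, _bandpass_matrix

__all__ = [
    "SimConfig",
    "SyntheticSubject",
    "Cohort",
    "make_geometry",
    "plan_events",
    "simulate_run",
    "simulate_signal_run",
    "simulate_phenotypes",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Full generative description of a synthetic cohort.

    Acquisition fields mirror the study protocol (four 478-frame runs at
    TR 0.8 s); cohort-size fields mirror its counting flow. Effect-size
    fields are the planted ground truth the pipeline is asked to recover;
    setting them to zero yields a null cohort for calibration checks.
    """

    # cohort sizes (retained + the two exclusion arms)
    n_retained: int = 90
    n_excluded_low: int = 20
    n_excluded_high: int = 14

    # acquisition
    n_vertices: int = 2000
    n_bins: int = 70
    n_parcels: int = 68
    n_runs: int = 4
    n_frames: int = 478
    tr_seconds: float = 0.8

    # vertex noise: AR(1) innovations band-limited to the infra-slow band
    ar_coef: float = 0.4
    vertex_noise_sd: float = 1.0
    band: Tuple[float, float] = (0.01, 0.1)

    # injected global events
    event_rate_per_min: float = 2.0
    event_amplitude: float = 2.0          # in units of post-filter noise SD
    event_duration_s: float = 12.0        # bump FWHM-scale width (sigma = /4)
    propagation_span_s: float = 8.0       # SM-to-DMN traversal time
    direction_mix: Tuple[float, float, float] = (0.4, 0.3, 0.3)  # bu/td/sync

    # CSF generation: lagged negative copy of the global signal + noise
    csf_lag_s: float = 3.2
    csf_gain: float = 1.0
    csf_noise_sd: float = 0.5             # relative to global-signal SD

    # motion random walk
    motion_step_mm: float = 0.02
    motion_step_rad: float = 5e-4

    # covariate model
    split_age: float = 51.0
    mri_overlap: Tuple[float, float] = (52.9, 66.5)
    menopause_mean: float = 50.2
    menopause_sd: float = 3.5
    menopause_range: Tuple[float, float] = (38.0, 56.4)
    score_missing_rate: float = 0.07

    # planted effects
    base_coupling: float = -0.6
    coupling_subject_sd: float = 0.08
    coupling_group_diff: float = 0.15     # earlier-vs-later weakening
    amplitude_group_diff_frac: float = 0.2
    amplitude_subject_cv: float = 0.1
    psmt_group_effect: float = 8.0        # PSMT points lost, earlier group
    wave_memory_rho: float = 0.5          # count/memory corr, earlier group
    count_mean: float = 15.0
    count_sd: float = 4.0

    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_retained, self.n_excluded_low, self.n_excluded_high) < 0:
            raise ValueError("cohort sizes must be non-negative")
        if abs(sum(self.direction_mix) - 1.0) > 1e-9:
            raise ValueError("direction_mix fractions must sum to 1")
        k = self.csf_lag_s / self.tr_seconds
        if abs(k - round(k)) > 1e-9:
            raise ValueError("csf_lag_s must be a TR multiple")
        if self.event_duration_s > self.n_frames * self.tr_seconds:
            raise ValueError("event duration exceeds the run")

    @property
    def n_subjects(self) -> int:
        return self.n_retained + self.n_excluded_low + self.n_excluded_high

    @property
    def run_duration_s(self) -> float:
        return self.n_frames * self.tr_seconds


@dataclass
class SyntheticSubject:
    """One simulated participant; imaging fields depend on the tier."""

    subject_id: str
    gbold: Optional[List[Signal1D]] = None
    csf: Optional[List[Signal1D]] = None
    runs: Optional[List[BoldRun]] = None
    motion: Optional[List[MotionParams]] = None
    events: Optional[pd.DataFrame] = None  # planted ground truth per run


@dataclass
class Cohort:
    config: SimConfig
    phenotypes: pd.DataFrame       # includes group labels from assign_groups
    ground_truth: pd.DataFrame     # per retained subject planted parameters
    geometry: Optional[SurfaceGeometry] = None
    subjects: List[SyntheticSubject] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry

def make_geometry(n_vertices: int = 2000, n_bins: int = 70,
                  n_parcels: int = 68, seed: int = 0) -> SurfaceGeometry:
    """A smooth stand-in principal-gradient map with contiguous parcels.

    PG scores come from heavily smoothed white noise over the vertex index
    (a smooth 1-D latent), demeaned so they are zero-mean by construction.
    Parcels are contiguous blocks of the PG ordering — crude, but it gives
    each parcel a coherent position along the cortical hierarchy, which is
    all the parcel-level analyses rely on.
    """
    if n_bins > n_vertices:
        raise ValueError("n_bins may not exceed n_vertices")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(n_vertices)
    width = max(3, n_vertices // 50)
    kernel = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    pg = np.convolve(raw, kernel / kernel.sum(), mode="same")
    pg = pg - pg.mean()
    order = np.argsort(pg, kind="stable")
    parcel_id = np.zeros(n_vertices, dtype=int)
    for pid, block in enumerate(np.array_split(order, n_parcels), start=1):
        parcel_id[block] = pid
    return SurfaceGeometry(pg_score=pg, parcel_id=parcel_id,
                           parcel_table=range(1, n_parcels + 1))


# ---------------------------------------------------------------------------
# events and runs

def plan_events(cfg: SimConfig, rng: np.random.Generator,
                amp_scale: float = 1.0) -> pd.DataFrame:
    """Event centres, directions and amplitudes for one run.

    Events are laid out on a jittered regular grid (spacing set by the
    event rate) with margins so every bump, including its propagation
    span, fits inside the run.
    """
    sigma = cfg.event_duration_s / 4.0
    lead = cfg.propagation_span_s / 2.0 + 2.0 * sigma
    usable = cfg.run_duration_s - 2.0 * lead
    spacing = 60.0 / cfg.event_rate_per_min
    n_events = max(0, int(usable // spacing))
    rows = []
    labels = ("bottom_up", "top_down", "synchronous")
    for k in range(n_events):
        slot = usable / n_events
        center = lead + (k + 0.5) * slot + rng.uniform(-0.2, 0.2) * slot
        direction = labels[rng.choice(3, p=cfg.direction_mix)]
        rows.append({"center_s": center, "direction": direction,
                     "amplitude": cfg.event_amplitude * amp_scale})
    return pd.DataFrame(rows, columns=["center_s", "direction", "amplitude"])


def _ar1_bandlimited(rng: np.random.Generator, n_units: int, cfg: SimConfig
                     ) -> np.ndarray:
    """AR(1) noise filtered to the infra-slow band, rescaled to target SD."""
    from scipy.signal import lfilter

    if cfg.vertex_noise_sd == 0:
        return np.zeros((n_units, cfg.n_frames))
    w = rng.standard_normal((n_units, cfg.n_frames))
    ar = lfilter([1.0], [1.0, -cfg.ar_coef], w, axis=-1)
    filt = _bandpass_matrix(ar, cfg.tr_seconds, BandpassSpec(*cfg.band))
    scale = cfg.vertex_noise_sd / filt.std(axis=-1).mean()
    return filt * scale


def _inject_events(data: np.ndarray, events: pd.DataFrame,
                   geometry: SurfaceGeometry, cfg: SimConfig) -> None:
    """Add Gaussian bumps whose per-vertex timing encodes the direction."""
    n_v, n_f = data.shape
    t = np.arange(n_f) * cfg.tr_seconds
    frac = np.argsort(np.argsort(geometry.pg_score, kind="stable")) / max(1, n_v - 1)
    sigma = cfg.event_duration_s / 4.0
    half = cfg.propagation_span_s / 2.0
    for ev in events.itertuples():
        if ev.direction == "bottom_up":
            centers = ev.center_s + (frac - 0.5) * 2 * half
        elif ev.direction == "top_down":
            centers = ev.center_s + (0.5 - frac) * 2 * half
        else:
            centers = np.full(n_v, ev.center_s)
        data += ev.amplitude * np.exp(-0.5 * ((t[None, :] - centers[:, None])
                                              / sigma) ** 2)


def _csf_from_global(g: np.ndarray, cfg: SimConfig, rng: np.random.Generator,
                     coupling_target: Optional[float] = None) -> np.ndarray:
    """Delayed negative copy of the global signal plus white noise.

    With a ``coupling_target`` the gain is solved so the expected Pearson
    correlation at the configured lag equals the target given the noise
    level; otherwise the configured gain is used directly.
    """
    k = int(round(cfg.csf_lag_s / cfg.tr_seconds))
    if coupling_target is not None:
        c = abs(coupling_target)
        if not c < 1:
            raise ValueError("coupling target must satisfy |c| < 1")
        gain = (cfg.csf_noise_sd * c / np.sqrt(1 - c * c)
                if cfg.csf_noise_sd > 0 else 1.0)
    else:
        gain = cfg.csf_gain
    shifted = np.concatenate([np.repeat(g[:1], k), g[:-k]]) if k > 0 else g
    noise = cfg.csf_noise_sd * g.std() * rng.standard_normal(g.size)
    return -gain * shifted + noise


def _random_walk_motion(cfg: SimConfig, rng: np.random.Generator) -> MotionParams:
    steps = rng.standard_normal((cfg.n_frames, 6))
    steps[:, :3] *= cfg.motion_step_mm
    steps[:, 3:] *= cfg.motion_step_rad
    return MotionParams(np.cumsum(steps, axis=0))


def simulate_run(cfg: SimConfig, geometry: SurfaceGeometry,
                 rng: np.random.Generator, amp_scale: float = 1.0,
                 coupling_target: Optional[float] = None,
                 events: Optional[pd.DataFrame] = None, run_label: str = ""
                 ) -> Tuple[BoldRun, Signal1D, MotionParams, pd.DataFrame]:
    """Full vertex-level run: noise + events, CSF, motion, ground truth."""
    if events is None:
        events = plan_events(cfg, rng, amp_scale)
    data = _ar1_bandlimited(rng, geometry.n_vertices, cfg)
    _inject_events(data, events, geometry, cfg)
    run = BoldRun(data, cfg.tr_seconds, space="surface", run_label=run_label)
    g = data.mean(axis=0)
    csf = Signal1D(_csf_from_global(g, cfg, rng, coupling_target),
                   cfg.tr_seconds, label="CSF")
    motion = _random_walk_motion(cfg, rng)
    return run, csf, motion, events


def simulate_signal_run(cfg: SimConfig, rng: np.random.Generator,
                        amp_scale: float = 1.0,
                        coupling_target: Optional[float] = None
                        ) -> Tuple[Signal1D, Signal1D]:
    """Signal-tier run: a band-limited global signal and its coupled CSF.

    The global signal is unit-SD infra-slow noise scaled by ``amp_scale``
    (the subject's global-activity strength); no vertex matrix is built.
    """
    g = _bandpass_matrix(rng.standard_normal((1, cfg.n_frames)),
                         cfg.tr_seconds, BandpassSpec(*cfg.band))[0]
    g = g / g.std() * amp_scale
    csf = _csf_from_global(g, cfg, rng, coupling_target)
    return (Signal1D(g, cfg.tr_seconds, label="gBOLD"),
            Signal1D(csf, cfg.tr_seconds, label="CSF"))


# ---------------------------------------------------------------------------
# phenotypes and cohort

def simulate_phenotypes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """A phenotype table whose cohort logic resolves exactly as designed.

    Retained subjects are scanned inside the MRI-age overlap window; the
    two exclusion arms sit below it (early-menopause, scanned young) and
    above it (late-menopause, scanned old). One retained subject on each
    side pins the empirical overlap to the configured window, so the
    split / overlap / tertile pipeline retains exactly ``n_retained``
    subjects whatever the draws.
    """
    lo, hi = cfg.mri_overlap
    mlo, mhi = cfg.menopause_range
    n = cfg.n_retained
    menop = np.clip(rng.normal(cfg.menopause_mean, cfg.menopause_sd, n), mlo, mhi)
    mri = lo + (hi - lo) * rng.beta(2.0, 2.0, n)
    menop = np.round(np.minimum(menop, mri - 1.0), 1)
    mri = np.round(mri, 1)
    if n < 4:
        raise ValueError("need at least 4 retained subjects (2 per split side)")
    # force at least two subjects on each side of the split so both groups
    # have a well-defined MRI-age range
    early = menop < cfg.split_age
    if early.sum() < 2:
        k = 2 - int(early.sum())
        menop[np.argsort(menop)[:k]] = np.round(rng.uniform(46.0, 50.0, k), 1)
    elif (~early).sum() < 2:
        k = 2 - int((~early).sum())
        menop[np.argsort(-menop)[:k]] = np.round(
            rng.uniform(cfg.split_age + 0.5, 54.0, k), 1)
    early = menop < cfg.split_age
    # pin both overlap endpoints on both sides (after rounding, so nothing
    # can shift a pinned subject across the split afterwards): the empirical
    # overlap then equals the configured window exactly
    idx_e = np.flatnonzero(early)
    idx_l = np.flatnonzero(~early)
    mri[idx_e[np.argmax(mri[idx_e])]] = hi
    mri[idx_e[np.argmin(mri[idx_e])]] = lo
    mri[idx_l[np.argmax(mri[idx_l])]] = hi
    j = idx_l[np.argmin(mri[idx_l])]
    mri[j] = lo
    menop[j] = min(menop[j], round(lo - 0.5, 1))

    ex_lo_mri = np.round(rng.uniform(lo - 5.0, lo - 0.2, cfg.n_excluded_low), 1)
    ex_lo_menop = np.round(np.minimum(
        np.clip(rng.normal(46.0, 3.0, cfg.n_excluded_low), mlo, cfg.split_age - 0.6),
        ex_lo_mri - 0.5), 1)
    ex_hi_mri = np.round(rng.uniform(hi + 0.2, hi + 8.0, cfg.n_excluded_high), 1)
    ex_hi_menop = np.round(np.clip(rng.normal(53.0, 1.5, cfg.n_excluded_high),
                                   cfg.split_age, mhi), 1)

    menop_all = np.concatenate([menop, ex_lo_menop, ex_hi_menop])
    mri_all = np.concatenate([mri, ex_lo_mri, ex_hi_mri])
    if (menop_all > mri_all).any():
        raise AssertionError("generator produced menopause age after MRI age")
    n_all = cfg.n_subjects
    df = pd.DataFrame({
        "subject_id": [f"sub{i:04d}" for i in range(n_all)],
        "age_at_mri": mri_all,
        "age_at_menopause": menop_all,
        "education_years": np.round(np.clip(rng.normal(17, 2, n_all), 8, 24), 0),
        "bmi": np.round(np.clip(rng.normal(27, 4, n_all), 16, 45), 1),
    })
    return df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


def _group_shift(group: str, full: float) -> float:
    return {"earlier": full, "intermediate": full / 2.0, "later": 0.0}.get(group, 0.0)


def simulate_cohort(cfg: SimConfig, tier: str = "signals") -> Cohort:
    """Generate a full cohort at the requested realism tier."""
    if tier not in ("none", "signals", "full"):
        raise ValueError(f"unknown tier {tier!r}")
    root = np.random.SeedSequence(cfg.master_seed)
    ss_pheno, ss_geom, ss_subjects = root.spawn(3)
    rng = np.random.default_rng(ss_pheno)
    pheno = simulate_phenotypes(cfg, rng)
    pheno["excluded"] = False
    pheno = cohort_mod.assign_groups(pheno, split_age=cfg.split_age)

    retained = pheno.loc[pheno["included"]].sort_values("subject_id")
    m = rng.standard_normal(len(retained))          # latent memory factor
    groups = retained["group"].to_numpy()
    ages = retained["age_at_mri"].to_numpy(float)

    coupling_target = np.clip(
        cfg.base_coupling
        + np.array([_group_shift(g, cfg.coupling_group_diff) for g in groups])
        + cfg.coupling_subject_sd * rng.standard_normal(len(retained)),
        -0.95, -0.05)
    amp_scale = ((1.0 - np.array([_group_shift(g, cfg.amplitude_group_diff_frac)
                                  for g in groups]))
                 * np.exp(cfg.amplitude_subject_cv
                          * rng.standard_normal(len(retained))))

    rho = cfg.wave_memory_rho
    latent_count = np.where(
        groups == "earlier",
        rho * m + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(len(retained)),
        rng.standard_normal(len(retained)))
    bu_count = np.maximum(0, np.round(cfg.count_mean + cfg.count_sd * latent_count))
    td_count = np.maximum(0, np.round(rng.normal(10, 3, len(retained))))

    psmt = (100.0 - 0.5 * (ages - ages.mean())
            - np.array([_group_shift(g, cfg.psmt_group_effect) for g in groups])
            + 12.0 * m)
    ravlt = (9.0 - 0.1 * (ages - ages.mean())
             - np.array([_group_shift(g, cfg.psmt_group_effect) for g in groups]) / 4.0
             + 3.0 * (0.7 * m + 0.714 * rng.standard_normal(len(retained))))
    miss = rng.random(len(retained)) < cfg.score_missing_rate
    psmt = np.round(psmt, 1)
    ravlt = np.round(ravlt, 1)
    psmt[miss & (np.arange(len(retained)) % 2 == 0)] = 999.0
    psmt[miss & (np.arange(len(retained)) % 2 == 1)] = np.nan

    truth = pd.DataFrame({
        "subject_id": retained["subject_id"].to_numpy(),
        "group": groups,
        "coupling_target": coupling_target,
        "amp_scale": amp_scale,
        "latent_memory": m,
        "bottom_up_count": bu_count,
        "top_down_count": td_count,
    })
    score_map = dict(zip(retained["subject_id"],
                         zip(psmt, ravlt)))
    pheno["psmt_score"] = [score_map.get(s, (np.nan, np.nan))[0]
                           for s in pheno["subject_id"]]
    pheno["ravlt_score"] = [score_map.get(s, (np.nan, np.nan))[1]
                            for s in pheno["subject_id"]]

    geometry = None
    subjects: List[SyntheticSubject] = []
    if tier == "full":
        geometry = make_geometry(cfg.n_vertices, cfg.n_bins, cfg.n_parcels,
                                 seed=np.random.default_rng(ss_geom).integers(2**31))
    if tier in ("signals", "full"):
        child_seeds = ss_subjects.spawn(len(retained))
        for i, row in enumerate(truth.itertuples()):
            srng = np.random.default_rng(child_seeds[i])
            subj = SyntheticSubject(subject_id=row.subject_id)
            subj.motion = [_random_walk_motion(cfg, srng)
                           for _ in range(cfg.n_runs)]
            if tier == "signals":
                pairs = [simulate_signal_run(cfg, srng, row.amp_scale,
                                             row.coupling_target)
                         for _ in range(cfg.n_runs)]
                subj.gbold = [p[0] for p in pairs]
                subj.csf = [p[1] for p in pairs]
            else:
                subj.runs, subj.csf, subj.events = [], [], []
                all_events = []
                for r in range(cfg.n_runs):
                    run, csf, _, ev = simulate_run(
                        cfg, geometry, srng, row.amp_scale,
                        row.coupling_target, run_label=f"run-{r + 1}")
                    subj.runs.append(run)
                    subj.csf.append(csf)
                    ev = ev.assign(run=f"run-{r + 1}")
                    all_events.append(ev)
                subj.events = pd.concat(all_events, ignore_index=True)
            subjects.append(subj)
    return Cohort(config=cfg, phenotypes=pheno, ground_truth=truth,
                  geometry=geometry, subjects=subjects)
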