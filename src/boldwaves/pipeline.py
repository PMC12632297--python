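"""End-to-end orchestration: signals -> coupling -> waves -> motion -> stats.

The pipeline consumes either an in-memory synthetic cohort (built from the
config's generator block) or a dataset directory written by the
``simulate`` CLI command, and writes a reproducible result directory:
every numeric output is a TSV or JSON file, stamped with the config hash
and master seed, so two runs with identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import coupling as coupling_mod
from . import io as io_mod
from . import signals as signals_mod
from . import waves as waves_mod
from .core import Signal1D
from .motion import framewise_displacement
from .synthetic import Cohort, SimConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_dataset", "write_dataset"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline execution.

    Defaults are the study constants: 0.01–0.1 Hz band, +-16 s lag range,
    +3.2 s coupling lag, 70 PG bins, 80% involvement, p < 0.01 / p > 0.05
    wave cutoffs, menopause split at 51 with three groups.
    """

    band: tuple = (0.01, 0.1)
    max_lag_seconds: float = 16.0
    coupling_lag_seconds: float = 3.2
    n_bins: int = 70
    involvement_threshold: float = 0.8
    p_wave: float = 0.01
    p_no_propagation: float = 0.05
    split_age: float = 51.0
    n_groups: int = 3
    wave_window_seconds: float = 8.0
    input_dir: Optional[str] = None
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if not 0 < self.involvement_threshold <= 1:
            raise ValueError("involvement_threshold must lie in (0, 1]")
        if not 0 < self.p_wave < self.p_no_propagation < 1:
            raise ValueError("need 0 < p_wave < p_no_propagation < 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(_plain(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _plain(obj):
    """Recursively convert numpy scalars/tuples for YAML/JSON output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# dataset directories (written by `boldwaves simulate`, read back by `run`)

def write_dataset(out_dir: str, cohort: Cohort) -> None:
    """Write a cohort as a BIDS-like directory of plain-text files."""
    os.makedirs(out_dir, exist_ok=True)
    io_mod.write_phenotypes(os.path.join(out_dir, "phenotypes.tsv"),
                            cohort.phenotypes)
    if cohort.geometry is not None:
        io_mod.write_geometry(os.path.join(out_dir, "geometry.tsv"),
                              cohort.geometry)
    truth = cohort.ground_truth.copy()
    truth.to_csv(os.path.join(out_dir, "ground_truth.tsv"), sep="\t",
                 index=False, float_format="%.10g")
    meta = {"tr_seconds": cohort.config.tr_seconds,
            "n_runs": cohort.config.n_runs,
            "master_seed": cohort.config.master_seed}
    with open(os.path.join(out_dir, "dataset.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    for subj in cohort.subjects:
        sdir = os.path.join(out_dir, subj.subject_id)
        os.makedirs(sdir, exist_ok=True)
        n_runs = len(subj.csf or subj.gbold or [])
        for r in range(n_runs):
            tag = f"run-{r + 1}"
            if subj.runs is not None:
                io_mod.write_surface_run(os.path.join(sdir, f"{tag}_bold.tsv"),
                                         subj.runs[r])
            if subj.gbold is not None:
                np.savetxt(os.path.join(sdir, f"{tag}_gbold.tsv"),
                           subj.gbold[r].values, fmt="%.17g")
            if subj.csf is not None:
                np.savetxt(os.path.join(sdir, f"{tag}_csf.tsv"),
                           subj.csf[r].values, fmt="%.17g")
            if subj.motion is not None:
                io_mod.write_motion_params(
                    os.path.join(sdir, f"{tag}_motion.tsv"), subj.motion[r])


def load_dataset(in_dir: str) -> Cohort:
    """Read a dataset directory back into an in-memory cohort."""
    with open(os.path.join(in_dir, "dataset.json")) as fh:
        meta = json.load(fh)
    tr = float(meta["tr_seconds"])
    pheno = io_mod.read_phenotypes(os.path.join(in_dir, "phenotypes.tsv"))
    geom_path = os.path.join(in_dir, "geometry.tsv")
    geometry = io_mod.read_geometry(geom_path) if os.path.exists(geom_path) else None
    truth = pd.read_csv(os.path.join(in_dir, "ground_truth.tsv"), sep="\t")
    from .synthetic import SyntheticSubject
    subjects: List = []
    for sid in sorted(d for d in os.listdir(in_dir)
                      if os.path.isdir(os.path.join(in_dir, d))):
        sdir = os.path.join(in_dir, sid)
        subj = SyntheticSubject(subject_id=sid)
        runs = sorted({f.split("_")[0] for f in os.listdir(sdir)})
        for tag in runs:
            def path(kind):
                return os.path.join(sdir, f"{tag}_{kind}.tsv")
            if os.path.exists(path("bold")):
                subj.runs = subj.runs or []
                subj.runs.append(io_mod.read_surface_run(
                    path("bold"), geometry, tr_seconds=tr, run_label=tag))
            if os.path.exists(path("gbold")):
                subj.gbold = subj.gbold or []
                subj.gbold.append(Signal1D(np.loadtxt(path("gbold")), tr, "gBOLD"))
            if os.path.exists(path("csf")):
                subj.csf = subj.csf or []
                subj.csf.append(Signal1D(np.loadtxt(path("csf")), tr, "CSF"))
            if os.path.exists(path("motion")):
                subj.motion = subj.motion or []
                subj.motion.append(io_mod.read_motion_params(path("motion")))
        subjects.append(subj)
    cfg = SimConfig(master_seed=int(meta.get("master_seed", 0)),
                    n_runs=int(meta.get("n_runs", 4)))
    return Cohort(config=cfg, phenotypes=pheno, ground_truth=truth,
                  geometry=geometry, subjects=subjects)


# ---------------------------------------------------------------------------
# the pipeline proper

def _subject_metrics(cfg: PipelineConfig, cohort: Cohort) -> tuple:
    """Per-subject derived metrics plus group CCF and wave-event tables."""
    spec = signals_mod.BandpassSpec(*cfg.band)
    binning = None
    if cohort.geometry is not None:
        binning = waves_mod.bin_by_gradient(cohort.geometry, cfg.n_bins)
    rows = []
    subject_ccfs = []
    event_frames = []
    log: Dict[str, float] = {"runs_processed": 0, "segments_found": 0}
    for label in waves_mod.LABELS:
        log[f"events_{label}"] = 0
    for subj in cohort.subjects:
        n_runs = len(subj.csf or subj.gbold or subj.runs or [])
        gbolds: List[Signal1D] = []
        per_run_events = {}
        durations = {}
        for r in range(n_runs):
            if subj.runs is not None:
                run = signals_mod.znorm(
                    signals_mod.bandpass(subj.runs[r], spec))
                gbold = signals_mod.extract_gbold(run)
                binned = waves_mod.bin_series(run, binning)
                events = waves_mod.classify_run(
                    binned, gbold, binning, cfg.involvement_threshold,
                    cfg.p_wave, cfg.p_no_propagation)
                tag = subj.runs[r].run_label or f"run-{r + 1}"
                per_run_events[tag] = events
                durations[tag] = run.duration_seconds
                event_frames.append(waves_mod.events_to_frame(
                    events, run.tr_seconds, subject=subj.subject_id, run=tag))
                log["segments_found"] += len(events)
                for ev in events:
                    log[f"events_{ev.label}"] += 1
            else:
                gbold = subj.gbold[r]
            gbolds.append(gbold)
            log["runs_processed"] += 1
        row: Dict[str, float] = {"subject_id": subj.subject_id}
        if subj.csf is not None and gbolds:
            csfs = [signals_mod.zscore_signal(c) for c in subj.csf]
            result = coupling_mod.subject_coupling(
                list(zip(gbolds, csfs)), cfg.max_lag_seconds,
                cfg.coupling_lag_seconds)
            row["coupling"] = result.subject_value
            subject_ccfs.append(result.subject_ccf)
        if gbolds:
            row["amplitude"] = signals_mod.subject_amplitude(gbolds)
        if per_run_events:
            counts = waves_mod.subject_wave_counts(per_run_events, durations)
            row["bottom_up_count"] = counts[waves_mod.BOTTOM_UP]
            row["top_down_count"] = counts[waves_mod.TOP_DOWN]
            row["no_propagation_count"] = counts[waves_mod.NO_PROPAGATION]
        if subj.motion is not None:
            row["mfd"] = float(np.mean(
                [framewise_displacement(mp).mfd for mp in subj.motion]))
        rows.append(row)
    metrics = pd.DataFrame(rows)
    group_ccf = (coupling_mod.group_mean_ccf(subject_ccfs)
                 if subject_ccfs else None)
    events_table = (pd.concat(event_frames, ignore_index=True)
                    if event_frames else None)
    return metrics, group_ccf, events_table, log


def run_pipeline(cfg: PipelineConfig, out_dir: str,
                 seed: Optional[int] = None) -> Dict[str, object]:
    """Execute every stage and write the result directory.

    Returns a summary dict (also written as ``stats.json``). ``seed``
    overrides the generator's master seed.
    """
    if seed is not None:
        cfg = dataclasses.replace(cfg, sim=dataclasses.replace(
            cfg.sim, master_seed=int(seed)))
    os.makedirs(out_dir, exist_ok=True)
    if cfg.input_dir:
        cohort = load_dataset(cfg.input_dir)
        pheno = cohort.phenotypes
        if "group" not in pheno.columns or pheno["group"].isna().all():
            pheno = cohort_mod.assign_groups(pheno, cfg.split_age, cfg.n_groups)
    else:
        cohort = simulate_cohort(cfg.sim, tier="full")
        pheno = cohort.phenotypes

    metrics, group_ccf, events_table, log = _subject_metrics(cfg, cohort)
    merged = pheno.merge(metrics, on="subject_id", how="left")
    included = merged.loc[merged.get("included", True) == True]  # noqa: E712

    stats = cohort_mod.headline_report(included)
    summary = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.sim.master_seed,
        "n_subjects_total": int(len(pheno)),
        "n_subjects_included": int(len(included)),
        "log": _plain(log),
        "stats": {k: _plain(v.to_dict()) for k, v in stats.items()},
    }

    merged.to_csv(os.path.join(out_dir, "subject_metrics.tsv"), sep="\t",
                  index=False, float_format="%.10g")
    if group_ccf is not None:
        group_ccf.to_frame().to_csv(os.path.join(out_dir, "group_ccf.tsv"),
                                    sep="\t", index=False, float_format="%.10g")
    if events_table is not None:
        events_table.to_csv(os.path.join(out_dir, "wave_events.tsv"),
                            sep="\t", index=False, float_format="%.10g")
    cfg.to_yaml(os.path.join(out_dir, "config.yaml"))
    with open(os.path.join(out_dir, "stats.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
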