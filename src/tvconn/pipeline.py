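"""End-to-end orchestration: synthetic cohort (or raw recording) through
preprocessing, time-varying MVAR fitting, ADTF connectivity, dynamic
network metrics, and group statistics, with a reproducibility manifest.

A run is deterministic given (inputs, config, seed): the root seed derives
per-subject generator streams, and the manifest records the config hash
and a content checksum of every stage output.  Array containers (.npz)
are checksummed over their logical content (member names, dtypes, shapes,
bytes) so the manifest is byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .adtf import connectivity_from_model
from .config import RunConfig, config_hash
from .containers import CohortRecord, EfficiencySeries, TimeVaryingConnectivity, TrialSet
from .io import (file_sha256, read_raw, save_connectivity, save_trialset,
                 write_cohort_tsv, write_ge_series_tsv)
from .network import average_trials, ge_series
from .preprocess import preprocess_recording, preprocess_trials
from .stats import compare_ge, correlate_ge_fma, edgewise_ranksum
from .synth import CohortSpec, ParadigmSpec, generate_cohort
from .tvmvar import fit_trials

__all__ = ["analyze", "run_pipeline", "AnalysisResult", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class AnalysisResult:
    """In-memory result of a full analysis run."""

    records: list[CohortRecord]
    trial_sets: dict[str, TrialSet]
    connectivity: dict[str, dict[str, TimeVaryingConnectivity]]
    ge_series: list[EfficiencySeries]
    summary: dict = field(default_factory=dict)


def content_checksum(path: Path) -> str:
    """Checksum stable across runs: logical content for .npz, bytes otherwise."""
    if path.suffix == ".npz":
        h = hashlib.sha256()
        with np.load(path) as z:
            for name in sorted(z.files):
                arr = z[name]
                h.update(name.encode())
                h.update(str(arr.dtype).encode())
                h.update(str(arr.shape).encode())
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()
    return file_sha256(path)


def _cohort_spec_from_config(cfg: RunConfig) -> CohortSpec:
    sim = cfg.simulate
    paradigm = ParadigmSpec(fs=sim.fs, n_trials_per_class=sim.n_trials_per_class)
    return CohortSpec(n_per_group=sim.n_per_group,
                      coupling_gain_slope=sim.coupling_gain_slope,
                      base_gain=sim.base_gain, hc_gain=sim.hc_gain,
                      seed=cfg.seed, n_channels=sim.n_channels,
                      paradigm=paradigm)


def analyze(cfg: RunConfig) -> AnalysisResult:
    """Run every stage in memory and return the analysis result.

    With ``cfg.inputs`` unset, a synthetic cohort is generated from the
    config; otherwise the raw recording is read and processed as a single
    subject (no group statistics).
    """
    if cfg.inputs is None:
        subjects = generate_cohort(_cohort_spec_from_config(cfg))
        records = [s.record for s in subjects]
        raw_sets = {s.record.subject: s.trials for s in subjects}
        montage = cfg.preprocess.montage
        trial_sets = {}
        for sid, ts in raw_sets.items():
            use_montage = montage if set(montage) <= set(ts.channel_labels) else None
            trial_sets[sid] = preprocess_trials(
                ts, band=cfg.preprocess.band,
                threshold=cfg.preprocess.threshold_uv,
                target_fs=cfg.preprocess.target_fs, montage=use_montage,
                reference=cfg.preprocess.reference)
    else:
        rec = read_raw(cfg.inputs)
        ts = preprocess_recording(
            rec, band=cfg.preprocess.band, window=cfg.preprocess.window,
            threshold=cfg.preprocess.threshold_uv,
            target_fs=cfg.preprocess.target_fs,
            montage=cfg.preprocess.montage, reference=cfg.preprocess.reference)
        records = [CohortRecord(subject="S01", group="HC")]
        trial_sets = {"S01": ts}

    conn_by_subject: dict[str, dict[str, TimeVaryingConnectivity]] = {}
    for sid, ts in trial_sets.items():
        models = fit_trials(ts, p=cfg.model.fixed_order,
                            update_coefficient=cfg.model.update_coefficient,
                            p_range=cfg.model.p_range)
        per_trial = [connectivity_from_model(m, band=cfg.adtf.band,
                                             grid_step=cfg.adtf.grid_step,
                                             times=ts.times,
                                             time_stride=cfg.adtf.time_stride)
                     for m in models]
        conn_by_subject[sid] = {
            cls: average_trials(per_trial, class_label=cls,
                                trial_labels=list(ts.labels))
            for cls in sorted(set(ts.labels))
        }

    all_series: list[EfficiencySeries] = []
    g0, g1 = cfg.network.ge_window
    for rec_ in records:
        for cls, tvc in conn_by_subject[rec_.subject].items():
            s = ge_series(tvc, cost=cfg.network.cost,
                          interval=cfg.network.ge_grid_step, start=g0, stop=g1,
                          subject=rec_.subject, condition=cls)
            rec_.ge_series.append(s)
            all_series.append(s)

    summary = _summarize(cfg, records, conn_by_subject)
    return AnalysisResult(records=records, trial_sets=trial_sets,
                          connectivity=conn_by_subject, ge_series=all_series,
                          summary=summary)


def _summarize(cfg: RunConfig, records: list[CohortRecord],
               conn_by_subject: dict) -> dict:
    summary: dict = {"n_subjects": len(records)}
    by_group = {g: [r for r in records if r.group == g] for g in ("LS", "RS", "HC")}
    if len(by_group["RS"]) >= 2 and len(by_group["HC"]) >= 2:
        stat, p, direction = compare_ge(
            [s for r in by_group["HC"] for s in r.ge_series],
            [s for r in by_group["RS"] for s in r.ge_series],
            window=cfg.network.ge_window)
        summary["ge_hc_vs_rs"] = {"statistic": stat, "p": p, "direction": direction}
    patients = [r for r in records if r.fma is not None]
    if len(patients) >= 3:
        try:
            r_val, p_val = correlate_ge_fma(records, window=cfg.network.ge_window)
            summary["ge_fma_pearson"] = {"r": r_val, "p": p_val, "n": len(patients)}
        except ValueError as err:
            summary["ge_fma_pearson"] = {"error": str(err)}
        summary["severity_counts"] = {
            sev: sum(1 for r in patients if r.severity == sev)
            for sev in ("severe", "moderate", "mild")}
    t0, t1 = cfg.network.task_window
    mid = 0.5 * (t0 + t1)
    contrasts = {}
    for name, ga, gb in (("LS_vs_HC", "LS", "HC"), ("RS_vs_HC", "RS", "HC")):
        if len(by_group[ga]) < 2 or len(by_group[gb]) < 2:
            continue
        mats_a = [_theta_at(conn_by_subject[r.subject], mid) for r in by_group[ga]]
        mats_b = [_theta_at(conn_by_subject[r.subject], mid) for r in by_group[gb]]
        ec = edgewise_ranksum(mats_a, mats_b, alpha=cfg.stats.alpha,
                              groups=(ga, gb), correct=cfg.stats.fdr_correction)
        contrasts[name] = {"n_significant": int(ec.significant.sum()),
                           "alpha": ec.alpha, "corrected": ec.corrected}
    if contrasts:
        summary["edge_contrasts_mid_task"] = contrasts
    return summary


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages and write outputs + ``manifest.json`` under ``out_dir``.

    Returns the manifest dict.  Any stage error halts the run, leaves the
    partial outputs in place, and drops a ``FAILED`` marker naming the
    stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "analyze"
    t_start = time.time()
    try:
        result = analyze(cfg)
        stage = "write"
        if cfg.inputs is None:
            outputs["cohort.tsv"] = write_cohort_tsv(result.records, out / "cohort.tsv")
        first_sid = sorted(result.trial_sets)[0]
        outputs["trials_example.npz"] = save_trialset(
            result.trial_sets[first_sid], out / "trials_example.npz")
        cls0 = sorted(result.connectivity[first_sid])[0]
        outputs["connectivity_example.npz"] = save_connectivity(
            result.connectivity[first_sid][cls0], out / "connectivity_example.npz")
        outputs["ge_series.tsv"] = write_ge_series_tsv(result.ge_series,
                                                       out / "ge_series.tsv")
        summary_path = out / "stats_summary.json"
        summary_path.write_text(
            json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
        outputs["stats_summary.json"] = summary_path

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "config_hash": config_hash(cfg),
            "outputs": {name: content_checksum(Path(p))
                        for name, p in sorted(outputs.items())},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        logger.info("pipeline complete in %.1f s", time.time() - t_start)
        return manifest
    except Exception as err:  # noqa: BLE001 - annotate stage and re-raise
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise PipelineError(stage, err) from err


def _theta_at(by_class: dict, t: float) -> np.ndarray:
    """Mean-over-conditions connectivity matrix nearest to time ``t``."""
    mats = []
    for tvc in by_class.values():
        k = int(np.argmin(np.abs(tvc.times - t)))
        mats.append(tvc.theta[k])
    return np.mean(mats, axis=0)
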