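"""End-to-end orchestration over a study bundle.

A bundle directory (as written by :func:`elbowstiff.synthetic.synth_protocol`,
or assembled by hand with the same manifest layout) holds ``training``, ``e1``
and ``e2`` trial CSVs plus ``manifest.json`` describing each trial's phase,
tempo and load.  The pipeline processes EMG to activations, identifies the 24
model parameters on a training trial, verifies every trial by DTW against the
measured angle, estimates per-trial stiffness traces, and fits the tempo
(power) and load (exponential) functional scales from the per-cycle area
under the stiffness signal.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .dynamics import SegmentProperties, simulate_forward
from .emg import MVCReference, process_trial
from .errors import DataError, ElbowStiffError
from .ga import evolve
from .io import read_params_json, read_trial_csv, write_params_json
from .parameters import split_vector, table_bounds
from .rls import estimate_trace
from .scales import fit_exp_scale, fit_power_scale, segment_repetitions, stiffness_area
from .validation import dtw_avg_deviation

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ElbowStiffError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrapped
    return deco


def _load_bundle(data_dir: Path, cfg: PipelineConfig):
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {data_dir}")
    manifest = json.loads(manifest_path.read_text())
    mvc = MVCReference(cfg.io.mvc_agonist, cfg.io.mvc_antagonist)
    trials = []
    for entry in manifest["trials"]:
        rec = read_trial_csv(data_dir / entry["file"], kind=cfg.emg.input_kind)
        trials.append((entry, rec))
    return manifest, mvc, trials


@_stage("identify")
def _identify(entry, rec, mvc, seg, cfg: PipelineConfig):
    a_ag, a_ant = process_trial(rec.trial, mvc, A=cfg.activation.A,
                                bandpass=tuple(cfg.emg.bandpass),
                                notch=tuple(cfg.emg.notch),
                                envelope_cutoff=cfg.emg.envelope_cutoff)
    bounds = table_bounds()
    return evolve(a_ag, a_ant, rec.angle, rec.time, bounds, cfg.ga_config(),
                  seg=seg.with_load(entry["load"]), sim_cfg=cfg.sim_config())


def run_pipeline(cfg: PipelineConfig, data_dir: str | Path, out_dir: str | Path,
                 seg: SegmentProperties | None = None, *,
                 params_path: str | Path | None = None) -> dict:
    """Run process → identify → simulate → stiffness → validate → scales.

    With ``params_path`` given the identification stage is skipped and the
    stored parameter vector is used instead.  Returns a summary dict; all
    artifacts (params.json, per-trial stiffness CSVs, report.json,
    scale.json) are written under ``out_dir``.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seg = seg or SegmentProperties()
    manifest, mvc, trials = _load_bundle(data_dir, cfg)

    # --- identification on a training trial (30 bpm if present) -----------
    if params_path is not None:
        vector = read_params_json(params_path)
        ga_info = {"source": str(params_path)}
    else:
        training = [(e, r) for e, r in trials if e["phase"] == "training"]
        if not training:
            raise DataError("bundle contains no training trials")
        entry, rec = next(((e, r) for e, r in training if e["tempo"] == 30), training[0])
        log.info("identifying on training trial %s", entry["name"])
        result = _identify(entry, rec, mvc, seg, cfg)
        vector = result.best_vector
        ga_info = {"fitness_deg_s": result.best_fitness,
                   "generations": result.generations,
                   "termination": result.termination,
                   "trial": entry["name"]}
    write_params_json(out_dir / "params.json", vector, {"identification": ga_info})
    hill_p, joint_p = split_vector(vector)

    # --- per-trial simulation, verification and stiffness ------------------
    report: dict = {"identification": ga_info, "trials": {}}
    condition_areas: dict[tuple[str, float, float], list[float]] = {}
    for entry, rec in trials:
        a_ag, a_ant = process_trial(rec.trial, mvc, A=cfg.activation.A,
                                    bandpass=tuple(cfg.emg.bandpass),
                                    notch=tuple(cfg.emg.notch),
                                    envelope_cutoff=cfg.emg.envelope_cutoff)
        sim = simulate_forward(a_ag, a_ant, hill_p, joint_p,
                               seg.with_load(entry["load"]), cfg.sim_config())
        dev = dtw_avg_deviation(rec.angle_deg, np.degrees(sim.q),
                                full_range=cfg.scales.full_range_deg)
        trace = estimate_trace(sim.tau_J, sim.q, sim.time, n_terms=cfg.rls.n_terms,
                               p0=cfg.rls.p0, forgetting=cfg.rls.forgetting,
                               mode=cfg.rls.mode)
        stiff_path = out_dir / f"stiffness_{entry['name']}.csv"
        np.savetxt(stiff_path, np.column_stack([trace.time, trace.stiffness]),
                   delimiter=",", header="time,stiffness", comments="")
        report["trials"][entry["name"]] = {
            "phase": entry["phase"], "tempo": entry["tempo"], "load": entry["load"],
            "dtw_avg_deviation_deg": dev.avg_deviation,
            "percent_of_range": dev.percent_of_range,
        }
        if entry["phase"] in ("e1", "e2"):
            segments = segment_repetitions(trace.time, trace.stiffness, entry["tempo"])
            areas = [stiffness_area(t, v) for t, v in segments]
            key = (entry["phase"], entry["tempo"], entry["load"])
            condition_areas.setdefault(key, []).extend(areas)

    # --- functional scales --------------------------------------------------
    agg = np.median if cfg.scales.aggregate == "median" else np.mean
    scales_out: dict = {}
    e1 = sorted((tempo, float(agg(v))) for (ph, tempo, _), v in condition_areas.items()
                if ph == "e1")
    e2 = sorted((load, float(agg(v))) for (ph, _, load), v in condition_areas.items()
                if ph == "e2")
    if len(e1) >= 2 and all(v > 0 for _, v in e1):
        fit = fit_power_scale([t for t, _ in e1], [v for _, v in e1])
        scales_out["tempo"] = {"form": fit.form, "a": fit.a, "b": fit.b, "rss": fit.rss,
                               "points": e1}
    if len(e2) >= 2 and all(v > 0 for _, v in e2):
        fit = fit_exp_scale([w for w, _ in e2], [v for _, v in e2])
        scales_out["weight"] = {"form": fit.form, "a": fit.a, "b": fit.b, "rss": fit.rss,
                                "points": e2}

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    (out_dir / "scale.json").write_text(json.dumps(scales_out, indent=2))
    return {"params": vector, "report": report, "scales": scales_out}
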