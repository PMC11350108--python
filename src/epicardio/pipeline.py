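"""Run orchestration: simulate -> process -> metrics -> compare -> model.

``RunConfig`` validates a YAML run configuration (unknown keys rejected,
numeric keys range-checked).  ``run_pipeline`` executes the requested
stages into a run directory with a manifest and a human-readable log;
``process_subject`` is the in-memory per-subject processing chain shared
by the disk pipeline, the tests and the acceptance script.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, risk_model, synthetic_cohort as sc
from .delineate import assess_quality, delineate_egm, delineation_table
from .markers import HeartMetrics, global_qrs_start, heart_metrics, node_markers
from .mesh_geometry import EpicardialMesh, export_vtk, prolate_spheroid_mesh
from .pattern_flags import detect_patterns
from .preprocess import match_rois, pick_template, remove_baseline, signal_average

log = logging.getLogger("epicardio")

STAGES = ("simulate", "process", "metrics", "compare", "model")

CANDIDATE_MEASURES = ("peak_at_mean", "recovery_at_mean", "peak_at_grad",
                      "peak_ari_mean", "recovery_ari_mean")


class ValidationError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


_RANGES = {
    ("preprocess", "cutoff_hz"): (0.01, 20.0),
    ("preprocess", "corr_floor"): (0.0, 1.0),
    ("preprocess", "k_beats"): (1, 50),
    ("delineate", "theta_qrs"): (0.01, 0.9),
    ("delineate", "theta_t"): (0.01, 0.9),
    ("delineate", "t_amp_frac"): (0.0, 1.0),
    ("delineate", "deflection_prominence"): (0.0, 1.0),
    ("markers", "radius_mm"): (0.5, 50.0),
    ("markers", "smoothing_ms"): (0.0, 50.0),
    ("model", "alpha"): (0.0, 1.0),
    ("model", "r_threshold"): (0.0, 1.0),
    ("model", "p_stop"): (0.0, 1.0),
    ("model", "k_folds"): (2, 20),
    ("model", "repeats"): (1, 1000),
    ("model", "threshold"): (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Validated run configuration.  Unknown keys are rejected."""

    outdir: str = "run"
    seed: int = 0
    mesh_path: str = None
    preset_path: str = None
    mode: str = "metrics"               # metrics | waveform
    phase: str = "both"
    counts: dict = field(default_factory=lambda: {"HCM_VF": 17, "HCM": 20})
    mesh_nodes: int = 200
    preprocess: dict = field(default_factory=lambda: dict(
        cutoff_hz=0.5, corr_floor=0.8, k_beats=10))
    delineate: dict = field(default_factory=lambda: dict(
        theta_qrs=0.2, theta_t=0.15, t_amp_frac=0.05, deflection_prominence=0.10))
    markers: dict = field(default_factory=lambda: dict(
        radius_mm=5.0, gradient_method="plane", smoothing_ms=10.0))
    model: dict = field(default_factory=lambda: dict(
        alpha=0.05, r_threshold=0.9, p_stop=0.15, k_folds=5, repeats=20,
        threshold=0.5))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        known = set(cfg.__dataclass_fields__)
        for key, val in raw.items():
            if key not in known:
                raise ValidationError(f"unknown config key {key!r}")
            if key == "counts":  # free-form group -> count mapping
                cfg.counts = {str(g): int(c) for g, c in val.items()}
            elif isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                section = dict(getattr(cfg, key))
                for sub, sval in val.items():
                    if sub not in section:
                        raise ValidationError(f"unknown config key {key}.{sub}")
                    section[sub] = sval
                setattr(cfg, key, section)
            else:
                setattr(cfg, key, val)
        cfg.validate()
        return cfg

    def validate(self):
        if self.mode not in ("metrics", "waveform"):
            raise ValidationError(f"mode must be metrics|waveform, got {self.mode!r}")
        if self.phase not in ("peak", "recovery", "both"):
            raise ValidationError(f"invalid phase {self.phase!r}")
        for (section, key), (lo, hi) in _RANGES.items():
            val = getattr(self, section).get(key)
            if val is None:
                continue
            if not (lo <= float(val) <= hi):
                raise ValidationError(
                    f"{section}.{key}={val} outside documented range [{lo}, {hi}]")
        if self.markers.get("gradient_method") not in ("plane", "range"):
            raise ValidationError("markers.gradient_method must be plane|range")
        return self

    def content_hash(self):
        payload = asdict(self)
        payload.pop("outdir", None)  # run location is not part of the science
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# In-memory per-subject processing
# ---------------------------------------------------------------------------

def common_beat_windows(traces, fs_hz, k=10, corr_floor=0.8, pre_ms=140.0,
                        window_ms=600.0):
    """Shared beat windows for a whole map, from the global |dV/dt| envelope.

    All epicardial traces are channels of one recording, so the regions of
    interest used for signal averaging must be the *same* time windows at
    every location — otherwise inter-node activation timing is destroyed.
    Beats are located and template-matched on the map-mean smoothed |dV/dt|
    envelope, a surrogate of the global QRS signature.
    """
    from .delineate import smoothed_derivative

    from .preprocess import detect_beats

    env = np.abs(np.stack([smoothed_derivative(t, fs_hz) for t in traces])).mean(axis=0)
    anchors = detect_beats(env, fs_hz)
    if len(anchors) > 1:
        rr_est = float(np.median(np.diff(anchors))) * 1000.0 / fs_hz
        # each window spans a full cycle plus margin so every node's T wave
        # (which can end just before the next QRS at peak heart rates) is
        # inside it; the delineator bounds the T search before the next QRS
        window_ms = min(window_ms, rr_est + 100.0)
    tpl = pick_template(env, fs_hz, pre_ms=pre_ms, window_ms=window_ms)
    return match_rois(env, tpl, k=k, corr_floor=corr_floor, fs_hz=fs_hz), env


def envelope_qrs_onset(env, window, fs_hz, smooth_ms=10.0, frac=0.04):
    """Global QRS onset (sample index inside ``window``) from the map-mean
    |dV/dt| envelope by tangent extrapolation.

    The rising edge of the envelope at the QRS foot is located at
    ``frac`` of the window maximum and extrapolated linearly back to the
    baseline; half the smoothing width compensates the moving-average
    spread.  Averaging ~200 channels makes this far less noise-sensitive
    than any single node's onset."""
    seg = np.asarray(env[window.start:window.end], float)
    peak = seg.max()
    if peak <= 0:
        return 0
    base = float(np.median(seg[:max(int(np.argmax(seg >= 0.5 * peak)) - 20, 5)]))
    c = int(np.argmax(seg >= base + frac * (peak - base)))
    # slope from the left flank of the edge only: later samples can already
    # carry the earliest intrinsic deflections, which would tilt the fit
    half = max(3, int(0.004 * fs_hz))
    a, b = max(0, c - half), c + 1
    x = np.arange(a, b)
    slope = float(np.polyfit(x, seg[a:b], 1)[0]) if b - a >= 3 else 0.0
    if slope <= 0:
        return c
    t_zero = c - (seg[c] - base) / slope
    return int(round(t_zero + smooth_ms * fs_hz / 1000.0 / 2))


def process_subject(traces, fs_hz, mesh: EpicardialMesh, subject_id=None,
                    phase=None, config: RunConfig = None, window_ms=None,
                    collect=False):
    """Full processing chain for one subject's raw trace matrix.

    filter -> common-window template matching on the global envelope ->
    per-node signal averaging over the shared windows -> delineate ->
    quality-reject -> markers referenced to the global QRS start ->
    whole-heart metrics.  Returns ``(HeartMetrics, extras)`` where extras
    carries per-node markers, delineations and averaged EGMs when
    ``collect`` is true.
    """


    cfg = config or RunConfig()
    pp, dl, mk = cfg.preprocess, cfg.delineate, cfg.markers
    traces = remove_baseline(np.asarray(traces, float), fs_hz,
                             cutoff_hz=pp["cutoff_hz"])
    if window_ms is None:
        window_ms = min(1100.0, traces.shape[1] / fs_hz * 1000.0 / 3)
    windows, env = common_beat_windows(traces, fs_hz, k=pp["k_beats"],
                                       corr_floor=pp["corr_floor"],
                                       window_ms=window_ms)
    onset_floor = envelope_qrs_onset(env, windows[0], fs_hz,
                                     smooth_ms=mk["smoothing_ms"])
    starts = sorted(w.start for w in windows)
    rr_ms = (float(np.median(np.diff(starts))) * 1000.0 / fs_hz
             if len(starts) > 1 else None)
    t_search_end = (onset_floor * 1000.0 / fs_hz + rr_ms - 25.0
                    if rr_ms else None)
    egms, delins = [], []
    for i in range(traces.shape[0]):
        node_id = mesh.node_ids[i]
        try:
            # the shared windows are already at their max-correlation lags
            # (envelope matching); per-node re-alignment would jitter the
            # inter-node timing the markers depend on
            egm = signal_average(windows, traces[i], fs_hz,
                                 max_align_shift_ms=0.0)
            egm.node_id = node_id
            egm.shortfall = max(0, pp["k_beats"] - egm.beats_used)
            d = delineate_egm(egm, theta_qrs=dl["theta_qrs"], theta_t=dl["theta_t"],
                              smooth_ms=mk["smoothing_ms"],
                              search_end_ms=t_search_end)
            d = assess_quality(egm, d, t_amp_frac=dl["t_amp_frac"],
                               prominence_frac=dl["deflection_prominence"])
            # individual nodes cannot resolve the QRS foot better than
            # the map-mean envelope: onsets within one smoothing width of
            # the envelope onset snap to it, and none may precede it
            if abs(d.qrs_on - onset_floor) <= int(0.010 * fs_hz):
                d.qrs_on = onset_floor
            else:
                d.qrs_on = max(d.qrs_on, onset_floor)
        except Exception as exc:  # per-node failure -> rejection, not abort
            log.debug("node %s rejected: %s", node_id, exc)
            egm, d = None, None
        egms.append(egm)
        delins.append(d)
    valid = [d for d in delins if d is not None]
    t0 = global_qrs_start(valid)
    markers = []
    for egm, d in zip(egms, delins):
        if egm is None or d is None:
            continue
        markers.append(node_markers(egm, d, t0))
    hm = heart_metrics(markers, mesh, subject_id=subject_id, phase=phase,
                       radius=mk["radius_mm"])
    extras = {"t0": t0, "n_failed": sum(d is None for d in delins),
              "windows": windows}
    if collect:
        extras.update(markers=markers, delineations=delins, egms=egms)
    return hm, extras


def markers_frame(markers):
    return pd.DataFrame([{"node_id": m.node_id, "LAT_ms": m.lat_ms,
                          "LRT_ms": m.lrt_ms, "ARI_ms": m.ari_ms,
                          "accepted": m.accepted} for m in markers])


# ---------------------------------------------------------------------------
# Staged disk pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, stages=STAGES):
    """Execute the requested stages into ``config.outdir``.

    Stage products: simulate -> feature_table.csv (and raw signals in
    waveform mode); process/metrics -> heart_metrics.csv with pattern
    flags; compare -> comparison_report.csv; model -> model_report.json.
    A manifest (config hash, seed) and a log accompany every run.
    Re-running with unchanged inputs and seed is idempotent.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        presets = sc.load_presets(config.preset_path)
        stages = [s for s in STAGES if s in stages]
        manifest = {"config_hash": config.content_hash(), "seed": config.seed,
                    "stages": stages, "mode": config.mode,
                    "preset_sha256": presets.source_sha256}

        dataset = None
        if "simulate" in stages:
            mesh = None
            if config.mode == "waveform":
                mesh = prolate_spheroid_mesh(config.mesh_nodes, seed=config.seed)
            dataset = sc.generate_cohort(
                presets, config.counts, mesh=mesh, seed=config.seed,
                mode=config.mode, outdir=out, phase=None if config.phase == "both"
                else config.phase)
            log.info("simulated %d subjects (%s mode)",
                     len(dataset["feature_table"]), config.mode)

        if "process" in stages or "metrics" in stages:
            if config.mode == "waveform":
                if dataset is None or not dataset["subjects"]:
                    raise DependencyError("process stage needs simulate outputs "
                                          "(waveform signals)")
                rows = []
                for rec in dataset["subjects"]:
                    hm, extras = process_subject(
                        rec["traces"], rec["params"].fs_hz, rec["truth"].mesh,
                        subject_id=rec["subject_id"], phase=rec["phase"],
                        config=config, collect=True)
                    lat = np.full(rec["truth"].mesh.n_nodes, np.nan)
                    ari = np.full(rec["truth"].mesh.n_nodes, np.nan)
                    for m in extras["markers"]:
                        if m.accepted:
                            i = rec["truth"].mesh.index_of(m.node_id)
                            lat[i], ari[i] = m.lat_ms, m.ari_ms
                    pat = detect_patterns(lat, ari, rec["truth"].polarity,
                                          rec["truth"].mesh)
                    row = hm.as_dict() | {f"pattern_{k}": v
                                          for k, v in pat.as_dict().items()}
                    row["group"] = rec["group"]
                    rows.append(row)
                    mf = markers_frame(extras["markers"])
                    mf.to_csv(out / f"{rec['subject_id']}_{rec['phase']}_markers.csv",
                              index=False)
                    dt = delineation_table(
                        {mesh_id: d for mesh_id, d in
                         zip(rec["truth"].mesh.node_ids, extras["delineations"])
                         if d is not None}, rec["params"].fs_hz)
                    dt.to_csv(out / f"{rec['subject_id']}_{rec['phase']}_delineation.csv",
                              index=False)
                    export_vtk(rec["truth"].mesh,
                               out / f"{rec['subject_id']}_{rec['phase']}_map.vtk",
                               {"LAT": lat, "ARI": ari})
                pd.DataFrame(rows).to_csv(out / "heart_metrics.csv", index=False)
                log.info("processed %d subject-phases", len(rows))
            else:
                ft = out / "feature_table.csv"
                if not ft.exists():
                    raise DependencyError("metrics stage needs feature_table.csv "
                                          "(run simulate first)")

        if "compare" in stages:
            table = _load_measures_table(out, config)
            measures = [c for c in table.columns
                        if any(c.endswith(m) for m in sc.MEASURES)]
            groups = sorted(table["group"].unique())
            reports = []
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    rep = cohort_stats.compare_groups(
                        table[table["group"].isin([groups[a], groups[b]])],
                        measures, groups=[groups[a], groups[b]])
                    reports.append(rep)
            pd.concat(reports, ignore_index=True).to_csv(
                out / "comparison_report.csv", index=False)
            log.info("compared %d group pairs", len(reports))

        if "model" in stages:
            table = _load_measures_table(out, config)
            mcfg = config.model
            sub = table[table["group"].isin(["HCM_VF", "HCM"])].reset_index(drop=True)
            if len(sub) < 2 * mcfg["k_folds"]:
                raise DependencyError("model stage needs an HCM_VF/HCM table")
            candidates = [c for c in CANDIDATE_MEASURES if c in sub.columns]
            report = risk_model.build_risk_model(
                sub, candidates, alpha=mcfg["alpha"],
                r_threshold=mcfg["r_threshold"], p_stop=mcfg["p_stop"],
                k=mcfg["k_folds"], repeats=mcfg["repeats"],
                seed=config.seed, threshold=mcfg["threshold"])
            _write_model_report(report, out)
            for name, p in report["removal_order"]:
                log.info("stepwise removed %s (p=%.3f)", name, p)

        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        return out
    finally:
        log.removeHandler(handler)
        handler.close()


def _load_measures_table(out: Path, config: RunConfig) -> pd.DataFrame:
    if config.mode == "waveform":
        path = out / "heart_metrics.csv"
        if not path.exists():
            raise DependencyError("missing heart_metrics.csv (run process/metrics)")
        wide = pd.read_csv(path)
        # pivot phases into {phase}_{measure} columns
        value_cols = ["at_mean", "at_disp", "at_grad",
                      "ari_mean", "ari_disp", "ari_grad"]
        table = wide.pivot_table(index=["subject_id", "group"], columns="phase",
                                 values=value_cols)
        table.columns = [f"{ph}_{m}" for m, ph in table.columns]
        return table.reset_index()
    path = out / "feature_table.csv"
    if not path.exists():
        raise DependencyError("missing feature_table.csv (run simulate)")
    return pd.read_csv(path)


def _write_model_report(report: dict, out: Path):
    fit = report["fit"]
    cv = report["cv"]
    payload = {
        "qualifying": report["qualifying"],
        "collinearity_log": report["collinearity_log"],
        "retained": report["retained"],
        "removal_order": report["removal_order"],
    }
    if fit is not None:
        payload["fit"] = {
            "measures": fit.measures,
            "intercept": fit.intercept,
            "coef_scaled": fit.coef_scaled.tolist(),
            "wald_p": fit.wald_p.tolist(),
            "odds_ratios": fit.odds_ratios.tolist(),
            "or_ci": fit.or_ci.tolist(),
            "llr_p": fit.llr_p,
            "loglik": fit.loglik,
        }
    if cv is not None:
        payload["cv"] = {
            "auc": cv.auc, "auc_ci": list(cv.auc_ci),
            "balanced_accuracy": cv.balanced_accuracy,
            "balanced_accuracy_ci": list(cv.balanced_accuracy_ci),
            "acc_positive": cv.acc_positive, "acc_negative": cv.acc_negative,
            "youden_sensitivity": cv.youden_sensitivity,
            "youden_specificity": cv.youden_specificity,
            "threshold": cv.threshold, "k": cv.k, "repeats": cv.repeats,
        }
        cv.pooled_predictions.to_csv(out / "predicted_probabilities.csv",
                                     index=False)
    (out / "model_report.json").write_text(json.dumps(payload, indent=1))
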