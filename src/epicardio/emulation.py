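"""Seeded end-to-end study emulations.

These routines re-run the whole analysis under the preset study
conditions: metric-level cohorts for the logistic risk model and its
cross-validated discrimination, and full-waveform cohorts that exercise
the complete signal chain (synthesis -> filtering -> common-window
averaging -> delineation -> Wyatt markers -> whole-heart metrics).  They
are the computational backbone of ``scripts/acceptance.py`` and of the
acceptance test suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import synthetic_cohort as sc
from .mesh_geometry import prolate_spheroid_mesh
from .pipeline import RunConfig, process_subject
from .risk_model import backward_stepwise, crossvalidate, fit_logistic_newton

def _seedseq(seed):
    return seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)


MODEL_MEASURES = ["recovery_at_mean", "recovery_ari_mean"]
STEPWISE_CANDIDATES = ["recovery_at_mean", "recovery_ari_mean",
                       "peak_ari_mean", "peak_at_grad"]


def sample_model_cohort(presets, seed, n_vf=17, n_hcm=20,
                        measures=None):
    """One synthetic HCM_VF/HCM cohort of whole-heart measures."""
    measures = measures or MODEL_MEASURES
    plain = [m.split("_", 1)[1] for m in measures]
    phases = sorted({m.split("_", 1)[0] for m in measures})
    seq = _seedseq(seed).spawn(2)
    phase = phases[0] if len(phases) == 1 else "both"
    vf = sc.sample_subject_metrics(presets, "HCM_VF", n_vf, seq[0], phase=phase,
                                   measures=tuple(dict.fromkeys(plain)))
    hc = sc.sample_subject_metrics(presets, "HCM", n_hcm, seq[1], phase=phase,
                                   measures=tuple(dict.fromkeys(plain)))
    df = pd.concat([vf, hc], ignore_index=True)
    df.insert(0, "subject_id", np.arange(len(df)))
    return df


def run_model_emulation(presets, seed, n_replicates=20, cv_repeats=20, k=5):
    """Fit + cross-validate the 2-variable model on replicate cohorts.

    Per replicate: a fresh 17-vs-20 cohort of recovery mean AT / mean ARI,
    a full-data Newton fit (for the odds ratios per ms), and repeated
    stratified k-fold CV.  Reported values are means across replicates:
    pooled AUC, balanced accuracy at threshold 0.5, and the Youden
    operating point of the aggregated out-of-fold predictions.
    """
    seqs = _seedseq(seed).spawn(n_replicates)
    rows = []
    for i, sq in enumerate(seqs):
        s_cohort, s_cv = sq.spawn(2)
        table = sample_model_cohort(presets, s_cohort)
        fit = fit_logistic_newton(table[MODEL_MEASURES].to_numpy(),
                                  (table["group"] == "HCM_VF").to_numpy(float),
                                  MODEL_MEASURES)
        cv = crossvalidate(table, MODEL_MEASURES, k=k, repeats=cv_repeats,
                           seed=int(s_cv.generate_state(1)[0] % (2 ** 31)))
        rows.append(dict(auc=cv.auc, bal=cv.balanced_accuracy,
                         sens=cv.youden_sensitivity,
                         spec=cv.youden_specificity,
                         or_at=fit.odds_ratios[0],
                         or_ari=fit.odds_ratios[1],
                         llr_p=fit.llr_p))
    rep = pd.DataFrame(rows)
    out = rep.mean().to_dict()
    out["n_replicates"] = n_replicates
    out["per_replicate"] = rep
    return out


def run_stepwise_emulation(presets, seed, n_seeds=200):
    """Backward-stepwise selection frequency over seeded 4-measure cohorts.

    Returns a frequency table of retained measure sets (the modal set is
    the study's reduced 2-variable model in most seeds).
    """
    from collections import Counter

    seqs = _seedseq(seed).spawn(n_seeds)
    counts = Counter()
    for sq in seqs:
        table = sample_model_cohort(presets, sq, measures=STEPWISE_CANDIDATES)
        y = (table["group"] == "HCM_VF").to_numpy(float)
        try:
            _, retained, _ = backward_stepwise(table, STEPWISE_CANDIDATES, y)
        except Exception:
            retained = []
        counts[tuple(sorted(retained))] += 1
    return counts


def generate_and_process_cohort(presets, group, n, phase, seed, mesh=None,
                                params=None, config=None,
                                progress=None):
    """Full-waveform cohort: truth fields + beat trains + complete
    processing chain; returns per-subject extracted HeartMetrics rows."""
    mesh = mesh if mesh is not None else prolate_spheroid_mesh(200, seed=1)
    params = params or sc.WaveformParams()
    config = config or RunConfig()
    s_metrics, s_pat, s_subj = _seedseq(seed).spawn(3)
    table = sc.sample_subject_metrics(presets, group, n, s_metrics, phase=phase)
    pats = sc.sample_patterns(presets, group, n, s_pat,
                              at_grad=table[f"{phase}_at_grad"])
    wf = params if phase == "recovery" else replace(params, t_width_ms=110.0)
    rows = []
    for i, sub_seq in enumerate(s_subj.spawn(n)):
        sd_truth, sd_wave = sub_seq.spawn(2)
        targets = {m: table.iloc[i][f"{phase}_{m}"] for m in sc.MEASURES}
        truth = sc.build_truth_fields(targets, mesh, pats.iloc[i].to_dict(),
                                      seed=sd_truth)
        rng = np.random.default_rng(sd_wave)
        rr_mean = 60000.0 / table.iloc[i][f"{phase}_heart_rate"]
        rr = sc.make_rr_sequence(rr_mean, wf.beats, wf.rr_jitter_frac, rng,
                                 rr_floor_ms=sc.rr_floor_for(truth, wf))
        traces, _, _ = sc.synthesize_subject(truth.at, truth.rt, truth.polarity,
                                             wf, rr, seed=rng.integers(2 ** 31))
        hm, _ = process_subject(traces, wf.fs_hz, mesh,
                                subject_id=f"{group}_{i:03d}", phase=phase,
                                config=config)
        row = hm.as_dict()
        row["group"] = group
        row.update({f"truth_{k}": v for k, v in truth.achieved.items()})
        rows.append(row)
        if progress:
            progress(group, i, n)
    return pd.DataFrame(rows)


def run_waveform_emulation(presets, seed, counts=None, phase="peak",
                           mesh_nodes=200, progress=None):
    """Marker-recovery study: full-waveform cohorts per group at one phase.

    Default groups mirror the study arms: 37 pooled-HCM, 32 normal-heart
    controls and 17 VF survivors.  Returns the per-subject metric table
    and group-level means.
    """
    counts = counts or {"HCM_pooled": 37, "control": 32, "HCM_VF": 17}
    mesh = prolate_spheroid_mesh(mesh_nodes, seed=1)
    seqs = _seedseq(seed).spawn(len(counts))
    tables = []
    for (group, n), sq in zip(sorted(counts.items()), seqs):
        tables.append(generate_and_process_cohort(
            presets, group, n, phase, sq, mesh=mesh, progress=progress))
    table = pd.concat(tables, ignore_index=True)
    summary = table.groupby("group")[
        ["at_mean", "at_disp", "at_grad", "ari_mean", "ari_disp", "ari_grad"]
    ].mean()
    return table, summary
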