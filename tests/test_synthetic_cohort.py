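"""Cohort sampler, truth-field calibration and beat-train synthesis."""

import numpy as np
import pandas as pd
import pytest

import epicardio.synthetic_cohort as sc
from epicardio.markers import dispersion95, mean_spatial_gradient
from tests.conftest import make_canonical_traces

CUSTOM_PRESET = """
version: 1
latent_correlation:
  within_phase: 0.30
  within_phase_at_ari: 0.21
  cross_phase_at_mean: 0.93
  cross_phase_same: 0.72
  cross_phase_other: 0.25
groups:
  demo:
    patterns: {late_patch: 0.0, apical_ari_prolongation: 0.0,
               apical_t_inversion: 0.0, isolated_t_patch: 0.0}
    peak: &blk
      at_mean:  {mean: 60.0, sd: 0.0}
      at_disp:  {mean: 55.0, sd: 0.0}
      at_grad:  {mean: 0.4,  sd: 0.0}
      ari_mean: {mean: 230.0, sd: 0.0}
      ari_disp: {mean: 54.0, sd: 0.0}
      ari_grad: {mean: 1.7,  sd: 0.0}
      heart_rate: {mean: 120.0, sd: 0.0}
    recovery: *blk
"""


def test_sampler_is_deterministic(presets):
    a = sc.sample_subject_metrics(presets, "HCM_VF", 17, 42)
    b = sc.sample_subject_metrics(presets, "HCM_VF", 17, 42)
    pd.testing.assert_frame_equal(a, b)


def test_zero_sd_preset_yields_exact_means(tmp_path):
    path = tmp_path / "p.yaml"
    path.write_text(CUSTOM_PRESET)
    p = sc.load_presets(path)
    df = sc.sample_subject_metrics(p, "demo", 5, 0, phase="peak",
                                   matched=False)
    assert np.allclose(df["peak_at_mean"], 60.0)
    assert np.allclose(df["peak_ari_mean"], 230.0)


def test_large_sample_moments_match_presets(presets):
    """Law-of-large-numbers check of the sampler against its own
    parameters (Gaussian marginals; population mode)."""
    df = sc.sample_subject_metrics(presets, "HCM_pooled", 100_000, 7,
                                   phase="peak", matched=False)
    marg = presets.groups["HCM_pooled"].marginal("peak", "at_mean")
    assert df["peak_at_mean"].mean() == pytest.approx(marg.mean, rel=0.01)
    assert df["peak_at_mean"].std() == pytest.approx(marg.sd, rel=0.01)
    marg2 = presets.groups["HCM_pooled"].marginal("peak", "ari_mean")
    assert df["peak_ari_mean"].mean() == pytest.approx(marg2.mean, rel=0.01)


def test_matched_mode_pins_latent_sample_moments(presets):
    df = sc.sample_subject_metrics(presets, "control", 20, 3, phase="peak")
    m = presets.groups["control"].marginal("peak", "at_mean")
    # Gaussian marginal + matched latents => exact sample moments
    assert df["peak_at_mean"].mean() == pytest.approx(m.mean, abs=1e-8)
    assert df["peak_at_mean"].std(ddof=0) == pytest.approx(m.sd, rel=1e-8)


def test_correlation_matrix_positive_definite(presets):
    keys = [(p, m) for p in sc.PHASES for m in sc.MEASURES]
    C = presets.latent_correlation(keys)
    assert np.linalg.eigvalsh(C).min() > 0


def test_vf_hcm_rank_separation_matches_conditions(presets):
    """The recovery-phase model pair separates VF survivors from other
    HCM patients far more strongly in rank than a normal distribution
    with the same moments would."""
    from scipy import stats

    ps = []
    for seed in range(12):
        vf = sc.sample_subject_metrics(presets, "HCM_VF", 17, seed,
                                       phase="recovery")
        hc = sc.sample_subject_metrics(presets, "HCM", 20, 1000 + seed,
                                       phase="recovery")
        ps.append(stats.mannwhitneyu(vf["recovery_at_mean"],
                                     hc["recovery_at_mean"]).pvalue)
    assert np.median(ps) < 0.02


# ---------------------------------------------------------------------------
# truth fields
# ---------------------------------------------------------------------------

def test_pure_ramp_metric_identities(mesh200):
    """Linear ramp along the area-equalized apico-basal coordinate: node
    values are near-uniform, so the central-95% range is ~95% of the span
    and the gradient is ~span over arc length."""
    R = 60.0
    f = R * mesh200.arc_coordinate
    assert dispersion95(f) == pytest.approx(0.95 * R, rel=0.03)
    grad = mean_spatial_gradient(mesh200, f)
    assert grad == pytest.approx(R / mesh200.arc_length, rel=0.15)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_truth_fields_match_targets_by_own_metrics(mesh200, seed):
    targets = dict(at_mean=60.1, at_disp=55.2, at_grad=0.45,
                   ari_mean=227.0, ari_disp=54.0, ari_grad=1.7)
    tr = sc.build_truth_fields(targets, mesh200, {}, seed=seed)
    assert tr.achieved["at_mean"] == pytest.approx(60.1, abs=1e-6)
    assert tr.achieved["at_disp"] == pytest.approx(55.2, abs=1e-6)
    if "at_gradient_clamped" not in tr.flags:
        assert tr.achieved["at_grad"] == pytest.approx(
            0.45, abs=max(0.02 * 0.45, 0.011))
    assert tr.achieved["ari_mean"] == pytest.approx(227.0, abs=1e-6)
    assert (tr.ari > 0).all()
    assert (tr.rt > tr.at).all()


def test_apical_prolongation_flag_shapes_field(mesh200):
    targets = dict(at_mean=60.0, at_disp=50.0, at_grad=0.4,
                   ari_mean=230.0, ari_disp=54.0, ari_grad=1.6)
    tr = sc.build_truth_fields(targets, mesh200,
                               {"apical_ari_prolongation": True}, seed=5)
    u = mesh200.arc_coordinate
    assert tr.ari[u < 1 / 3].mean() > tr.ari[u > 2 / 3].mean()


def test_invalid_targets_rejected(mesh200):
    bad = dict(at_mean=60.0, at_disp=-1.0, at_grad=0.4,
               ari_mean=230.0, ari_disp=54.0, ari_grad=1.6)
    with pytest.raises(sc.ParameterError):
        sc.build_truth_fields(bad, mesh200, {}, seed=0)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def test_noise_free_beat_slopes_at_configured_times():
    """Steepest negative QRS slope at AT and steepest positive T slope at
    RT, checked by exhaustive scan of the numerical derivative."""
    trace, params = make_canonical_traces(at_ms=40, rt_ms=290, beats=1,
                                          rr_ms=600)
    pad = int(params.pad_ms)
    beat = trace[pad:pad + 550]
    d = np.gradient(beat)
    assert abs(int(np.argmin(d)) - 40) <= 1
    t_region = slice(150, 420)  # after the QRS complex
    assert abs((t_region.start + int(np.argmax(d[t_region]))) - 290) <= 1


def test_inverted_t_steepest_positive_slope_at_rt():
    trace, params = make_canonical_traces(at_ms=40, rt_ms=310, polarity=-1,
                                          beats=1, rr_ms=700)
    pad = int(params.pad_ms)
    d = np.gradient(trace[pad:pad + 600])
    t_region = slice(150, 450)
    assert abs((t_region.start + int(np.argmax(d[t_region]))) - 310) <= 1


def test_ten_beats_trace_duration():
    trace, params = make_canonical_traces(beats=10, rr_ms=600)
    assert len(trace) >= 6000  # >= 6 s at 1 kHz


def test_beat_count_by_threshold(mesh60):
    from epicardio.preprocess import detect_beats

    trace, params = make_canonical_traces(beats=10, rr_ms=600, noise=0.02,
                                          wander=0.3, seed=3)
    from epicardio.preprocess import remove_baseline
    filt = remove_baseline(trace, params.fs_hz)
    assert len(detect_beats(filt, params.fs_hz)) == 10


def test_at_rt_outside_beat_period_rejected():
    params = sc.WaveformParams(rr_jitter_frac=0.0)
    with pytest.raises(sc.ParameterError):
        sc.synthesize_beat_train(40.0, 650.0, 1.0, params,
                                 np.full(3, 600.0), seed=0)
    with pytest.raises(sc.ParameterError):
        sc.synthesize_beat_train(300.0, 200.0, 1.0, params,
                                 np.full(3, 600.0), seed=0)


def test_rr_floor_keeps_t_wave_inside_beat(mesh60):
    targets = dict(at_mean=60.0, at_disp=50.0, at_grad=0.4,
                   ari_mean=300.0, ari_disp=54.0, ari_grad=1.6)
    tr = sc.build_truth_fields(targets, mesh60, {}, seed=1)
    params = sc.WaveformParams(t_width_ms=110.0)
    floor = sc.rr_floor_for(tr, params)
    assert floor >= tr.rt.max() + 0.8 * params.t_width_ms


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def test_metrics_cohort_counts_and_determinism(presets, tmp_path):
    out1, out2 = tmp_path / "a", tmp_path / "b"
    r1 = sc.generate_cohort(presets, {"HCM_VF": 17, "HCM": 20}, seed=9,
                            outdir=out1)
    sc.generate_cohort(presets, {"HCM_VF": 17, "HCM": 20}, seed=9,
                       outdir=out2)
    assert len(r1["feature_table"]) == 37
    assert set(r1["feature_table"]["group"]) == {"HCM_VF", "HCM"}
    assert (out1 / "feature_table.csv").read_bytes() == \
        (out2 / "feature_table.csv").read_bytes()
    assert (out1 / "manifest.json").read_bytes() == \
        (out2 / "manifest.json").read_bytes()


def test_waveform_cohort_signal_shape(presets, mesh60, tmp_path):
    r = sc.generate_cohort(presets, {"control": 1}, mesh=mesh60, seed=4,
                           mode="waveform", outdir=tmp_path, phase="peak")
    rec = r["subjects"][0]
    assert rec["traces"].shape[0] == mesh60.n_nodes
    sidecar = tmp_path / f"{rec['subject_id']}_peak_signals.json"
    assert sidecar.exists()
    truth_csv = tmp_path / f"{rec['subject_id']}_peak_truth.csv"
    truth = pd.read_csv(truth_csv)
    assert len(truth) == mesh60.n_nodes
    assert (truth["ARI_ms"] > 0).all()


def test_pipeline_mean_at_unbiased_over_many_subjects(presets, mesh60):
    """End-to-end unbiasedness: over many seeded subjects, the pipeline's
    whole-heart mean AT tracks the generator truth within +-1 ms."""
    from epicardio.emulation import generate_and_process_cohort

    t = generate_and_process_cohort(presets, "HCM_pooled", 200, "peak",
                                    seed=2024, mesh=mesh60)
    bias = (t["at_mean"] - t["truth_at_mean"]).mean()
    assert abs(bias) < 1.0
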