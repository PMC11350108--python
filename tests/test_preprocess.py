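"""Baseline filtering, template selection, ROI matching, signal averaging."""

import numpy as np
import pytest

from epicardio.preprocess import (BeatWindow, InsufficientBeatsError,
                                  detect_beats, match_rois, pick_template,
                                  remove_baseline, signal_average, sliding_ncc)
from tests.conftest import make_canonical_traces


def _spectral_amp(x, fs, freq):
    t = np.arange(len(x)) / fs
    return 2 * abs(np.mean(x * np.exp(-2j * np.pi * freq * t)))


def test_filter_preserves_drift_free_beats():
    trace, params = make_canonical_traces(beats=10, rr_ms=600)
    filt = remove_baseline(trace, params.fs_hz)
    # inner samples (away from edge transients)
    inner = slice(500, -500)
    assert np.max(np.abs(filt[inner] - trace[inner])) < 0.05 * params.qrs_amp_mv


def test_filter_attenuates_wander_by_20db():
    trace, params = make_canonical_traces(beats=10, rr_ms=600, wander=0.3,
                                          seed=1)
    filt = remove_baseline(trace, params.fs_hz)
    before = _spectral_amp(trace, params.fs_hz, params.wander_freq_hz)
    after = _spectral_amp(filt, params.fs_hz, params.wander_freq_hz)
    assert after < before * 10 ** (-20 / 20)


def test_markers_recover_truth_after_filtering_drift():
    """End-to-end: wander + filtering leave the activation marker within
    1 ms of the generator truth."""
    from epicardio.delineate import delineate_egm
    from epicardio.markers import local_activation_time

    trace, params = make_canonical_traces(at_ms=40, rt_ms=290, beats=10,
                                          rr_ms=600, wander=0.3, seed=2)
    filt = remove_baseline(trace, params.fs_hz)
    tpl = pick_template(filt, params.fs_hz)
    rois = match_rois(filt, tpl, fs_hz=params.fs_hz)
    egm = signal_average(rois, filt, params.fs_hz)
    delin = delineate_egm(egm)
    # the automatic template may anchor any beat; onsets repeat every RR
    onset_in_window = (250 - tpl.start) % 600
    lat = local_activation_time(egm, delin, onset_in_window)
    assert lat == pytest.approx(40.0, abs=1.0)


def test_filter_rejects_bad_rate():
    with pytest.raises(ValueError):
        remove_baseline(np.zeros(2000), 0.0)


# ---------------------------------------------------------------------------
# template selection
# ---------------------------------------------------------------------------

def test_identical_beats_any_template_scores_one():
    trace, params = make_canonical_traces(beats=10, rr_ms=600)
    tpl = pick_template(trace, params.fs_hz)
    assert tpl.score == pytest.approx(1.0, abs=1e-6)


def test_template_avoids_the_odd_beat_out():
    """9 identical beats + 1 amplitude-halved: brute-force enumeration of
    mean cross-correlations says the template is one of the 9."""
    trace, params = make_canonical_traces(beats=10, rr_ms=600)
    # halve beat 4 (onsets at pad + k*600)
    s = 250 + 3 * 600
    trace = trace.copy()
    trace[s:s + 550] *= 0.5
    fs = params.fs_hz
    anchors = detect_beats(trace, fs)
    assert len(anchors) == 10
    pre, length = 120, 600
    starts = [a - pre for a in anchors if a - pre >= 0 and a - pre + length <= len(trace)]
    segs = np.array([trace[s0:s0 + length] for s0 in starts])
    segs = segs - segs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(segs, axis=1)
    c = (segs @ segs.T) / np.outer(norms, norms)
    np.fill_diagonal(c, np.nan)
    oracle_best = starts[int(np.argmax(np.nanmean(c, axis=1)))]
    tpl = pick_template(trace, fs, pre_ms=120, window_ms=600)
    assert tpl.start == oracle_best
    # and the oracle's winner is not the halved beat
    assert not (s - pre - 5 <= tpl.start <= s - pre + 5)


def test_manual_template_index_pass_through():
    trace, params = make_canonical_traces(beats=10, rr_ms=600)
    tpl = pick_template(trace, params.fs_hz, manual_index=3, pre_ms=120)
    anchors = detect_beats(trace, params.fs_hz)
    assert tpl.start == anchors[3] - 120


def test_too_few_beats_raises():
    trace, params = make_canonical_traces(beats=1, rr_ms=600)
    with pytest.raises(InsufficientBeatsError):
        pick_template(trace, params.fs_hz)


# ---------------------------------------------------------------------------
# ROI matching
# ---------------------------------------------------------------------------

def test_ten_identical_beats_ten_perfect_matches():
    trace, params = make_canonical_traces(beats=10, rr_ms=700)
    tpl = pick_template(trace, params.fs_hz, window_ms=550)
    rois = match_rois(trace, tpl, k=10, fs_hz=params.fs_hz)
    assert len(rois) == 10
    assert all(w.score == pytest.approx(1.0, abs=1e-6) for w in rois)
    starts = sorted(w.start for w in rois)
    assert np.allclose(np.diff(starts), 700, atol=1)


def test_matches_agree_with_sliding_scan_oracle(rng):
    trace, params = make_canonical_traces(beats=8, rr_ms=650, noise=0.0)
    # amplitude-jitter the beats
    trace = trace.copy()
    for k in range(8):
        s = 250 + k * 650
        trace[s:s + 600] *= rng.uniform(0.8, 1.2)
    tpl = pick_template(trace, params.fs_hz, window_ms=550)
    rois = match_rois(trace, tpl, k=8, corr_floor=0.8, fs_hz=params.fs_hz)
    # oracle: same greedy rule on an independently computed NCC curve
    tpl_seg = trace[tpl.start:tpl.end]
    L = len(tpl_seg)
    c = np.array([np.corrcoef(trace[s:s + L], tpl_seg)[0, 1]
                  for s in range(len(trace) - L + 1)])
    min_sep = int(0.6 * 650)
    chosen = [tpl.start]
    for lag in np.argsort(c)[::-1]:
        if len(chosen) >= 8 or c[lag] < 0.8:
            break
        if all(abs(lag - s) >= min_sep for s in chosen):
            chosen.append(int(lag))
    assert sorted(w.start for w in rois) == sorted(set(chosen))


def test_shortfall_recorded_for_few_beats():
    trace, params = make_canonical_traces(beats=6, rr_ms=700)
    tpl = pick_template(trace, params.fs_hz, window_ms=550)
    rois = match_rois(trace, tpl, k=10, fs_hz=params.fs_hz)
    assert len(rois) == 6


# ---------------------------------------------------------------------------
# signal averaging
# ---------------------------------------------------------------------------

def test_average_of_identical_beats_is_one_beat():
    trace, params = make_canonical_traces(beats=10, rr_ms=700)
    tpl = pick_template(trace, params.fs_hz, window_ms=550)
    rois = match_rois(trace, tpl, k=10, fs_hz=params.fs_hz)
    egm = signal_average(rois, trace, params.fs_hz)
    ref = trace[tpl.start:tpl.end]
    assert np.allclose(egm.samples, ref, atol=1e-9)
    assert egm.beats_used == 10


def test_single_window_average_is_identity():
    trace, params = make_canonical_traces(beats=3, rr_ms=700)
    w = BeatWindow(250, 800)
    egm = signal_average([w], trace, params.fs_hz)
    assert np.array_equal(egm.samples, trace[250:800])


def test_average_invariant_to_window_order(rng):
    trace, params = make_canonical_traces(beats=10, rr_ms=700, noise=0.02,
                                          seed=5)
    tpl = pick_template(trace, params.fs_hz, window_ms=550)
    rois = match_rois(trace, tpl, k=10, fs_hz=params.fs_hz)
    a = signal_average(rois, trace, params.fs_hz)
    shuffled = [rois[i] for i in rng.permutation(len(rois))]
    b = signal_average(shuffled, trace, params.fs_hz)
    assert np.allclose(a.samples, b.samples)


def test_noise_reduced_by_sqrt_beats():
    """Averaging 10 beats cuts white noise by ~sqrt(10)."""
    resid = []
    for seed in range(6):
        clean, params = make_canonical_traces(beats=10, rr_ms=700)
        noisy, _ = make_canonical_traces(beats=10, rr_ms=700, noise=0.02,
                                         seed=seed)
        tpl = pick_template(clean, params.fs_hz, window_ms=550)
        rois = match_rois(clean, tpl, k=10, fs_hz=params.fs_hz)
        egm = signal_average(rois, noisy, params.fs_hz, max_align_shift_ms=0)
        ref = clean[tpl.start:tpl.end]
        resid.append(np.std(egm.samples - ref))
    expected = 0.02 / np.sqrt(10)
    assert np.mean(resid) == pytest.approx(expected, rel=0.2)


def test_sliding_ncc_bounded():
    trace, params = make_canonical_traces(beats=5, rr_ms=700, noise=0.05,
                                          seed=9)
    c = sliding_ncc(trace, trace[250:800])
    assert np.all(c <= 1.0 + 1e-12) and np.all(c >= -1.0 - 1e-12)
    assert c[250] == pytest.approx(1.0, abs=1e-9)
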