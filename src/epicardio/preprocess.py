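"""Raw multi-beat electrogram conditioning: baseline filtering, template
selection, ROI matching and signal averaging.

The chain turns one noisy multi-beat unipolar trace per node into a single
signal-averaged electrogram: high-pass the trace, pick (or accept) a
template QRS-T complex, find the up-to-10 most template-similar regions of
interest by normalized cross-correlation, and average them pointwise after
lag alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


class InsufficientBeatsError(RuntimeError):
    pass


class NoMatchesError(RuntimeError):
    pass


class AlignmentError(RuntimeError):
    pass


@dataclass(frozen=True)
class BeatWindow:
    """Half-open sample window [start, end) with a correlation score."""

    start: int
    end: int
    score: float = 1.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("window start must precede end")


@dataclass
class AveragedEGM:
    """One signal-averaged electrogram; time zero is the window start."""

    samples: np.ndarray
    fs_hz: float
    beats_used: int
    node_id: object = None
    shortfall: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.beats_used < 1:
            raise ValueError("beats_used must be >= 1")


def remove_baseline(trace, fs_hz, cutoff_hz=0.5, order=2):
    """Zero-phase high-pass (Butterworth) baseline-wander removal.

    Works on a 1D trace or a (nodes, samples) matrix.  Zero-phase filtering
    preserves dV/dt timing, which the activation/repolarization markers
    depend on.
    """
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    trace = np.asarray(trace, float)
    n = trace.shape[-1]
    if n < fs_hz:
        raise ValueError("trace must be at least 1 s long")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=fs_hz, output="sos")
    padlen = min(n - 1, int(3 * fs_hz))
    return sps.sosfiltfilt(sos, trace, axis=-1, padlen=padlen)


def _smoothed_abs_derivative(trace, fs_hz, smooth_ms=10.0):
    d = np.gradient(trace) * fs_hz / 1000.0
    w = max(1, int(round(smooth_ms * fs_hz / 1000.0)))
    kernel = np.ones(w) / w
    return np.convolve(np.abs(d), kernel, mode="same")


def detect_beats(trace, fs_hz, min_separation_ms=250.0, threshold_frac=0.4):
    """Candidate beat anchors: peaks of the smoothed |dV/dt| envelope.

    The anchor of each beat is its sharpest deflection (the QRS intrinsic
    downstroke), detected as local maxima of smoothed |dV/dt| above a
    fraction of the global maximum, separated by a refractory distance.
    """
    env = _smoothed_abs_derivative(trace, fs_hz)
    dist = max(1, int(min_separation_ms * fs_hz / 1000.0))
    peaks, _ = sps.find_peaks(env, height=threshold_frac * env.max(), distance=dist)
    return peaks


def _beat_windows(anchors, pre, length, n_samples):
    """Windows anchored ``pre`` samples before each beat anchor; windows
    extending beyond the trace are dropped."""
    wins = []
    for a in anchors:
        s = a - pre
        if s >= 0 and s + length <= n_samples:
            wins.append(int(s))
    return wins


def _ncc(a, b):
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / den) if den > 0 else 0.0


def pick_template(trace, fs_hz, manual_index=None, pre_ms=120.0,
                  window_ms=600.0, min_separation_ms=250.0):
    """Select the template QRS-T complex.

    The interactive template choice of the mapping software is automated:
    among the detected beats, the one whose window has the highest mean
    normalized cross-correlation against all other beat windows becomes the
    template.  ``manual_index`` (0-based detected-beat index) overrides the
    automatic choice.
    """
    trace = np.asarray(trace, float)
    anchors = detect_beats(trace, fs_hz, min_separation_ms)
    if len(anchors) < 2:
        raise InsufficientBeatsError(f"only {len(anchors)} beats detected")
    pre = int(round(pre_ms * fs_hz / 1000.0))
    length = int(round(window_ms * fs_hz / 1000.0))
    if manual_index is not None:
        if not 0 <= manual_index < len(anchors):
            raise IndexError(f"manual beat index {manual_index} out of range")
        s = int(anchors[manual_index]) - pre
        s = max(0, min(s, len(trace) - length))
        return BeatWindow(s, s + length, 1.0)
    starts = _beat_windows(anchors, pre, length, len(trace))
    if len(starts) < 2:
        raise InsufficientBeatsError("fewer than 2 complete beat windows")
    segs = np.array([trace[s:s + length] for s in starts])
    segs = segs - segs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(segs, axis=1)
    norms[norms == 0] = 1.0
    c = (segs @ segs.T) / np.outer(norms, norms)
    np.fill_diagonal(c, np.nan)
    mean_corr = np.nanmean(c, axis=1)
    best = int(np.argmax(mean_corr))
    return BeatWindow(starts[best], starts[best] + length, float(mean_corr[best]))


def sliding_ncc(trace, template_samples):
    """Normalized cross-correlation of a template at every lag (valid part)."""
    trace = np.asarray(trace, float)
    tpl = np.asarray(template_samples, float)
    tpl = tpl - tpl.mean()
    tn = np.linalg.norm(tpl)
    L = len(tpl)
    num = sps.fftconvolve(trace, tpl[::-1], mode="valid")
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    csum2 = np.concatenate([[0.0], np.cumsum(trace ** 2)])
    winsum = csum[L:] - csum[:-L]
    winsum2 = csum2[L:] - csum2[:-L]
    var = winsum2 - winsum ** 2 / L
    den = tn * np.sqrt(np.clip(var, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 1e-12, num / den, 0.0)
    return np.clip(c, -1.0, 1.0)


def match_rois(trace, template: BeatWindow, k=10, corr_floor=0.8,
               min_separation=None, fs_hz=None):
    """Up to ``k`` non-overlapping windows most similar to the template.

    Template matching by normalized cross-correlation at every lag; matches
    are accepted greedily by descending correlation with a minimum
    separation (default 60% of the median inter-match spacing estimate,
    i.e. 60% of the template-anchor RR), and must score at least
    ``corr_floor``.  The template's own window always qualifies.  If fewer
    than ``k`` qualify the shortfall is recorded, not fatal.
    """
    trace = np.asarray(trace, float)
    tpl = trace[template.start:template.end]
    L = len(tpl)
    c = sliding_ncc(trace, tpl)
    if min_separation is None:
        if fs_hz is not None:
            anchors = detect_beats(trace, fs_hz)
            rr = np.median(np.diff(anchors)) if len(anchors) > 1 else L
            min_separation = int(0.6 * rr)
        else:
            min_separation = int(0.6 * L)
    order = np.argsort(c)[::-1]
    chosen = [template.start]
    # greedy non-overlapping peak picking
    for lag in order:
        if len(chosen) >= k:
            break
        if c[lag] < corr_floor:
            break
        if all(abs(lag - s) >= min_separation for s in chosen):
            chosen.append(int(lag))
    chosen_set = sorted(set(chosen))
    windows = [BeatWindow(s, s + L, float(c[s]) if s < len(c) else 1.0)
               for s in chosen_set]
    windows = windows[:max(k, 1)]
    if not windows:
        raise NoMatchesError("no windows above the correlation floor")
    return windows


def signal_average(windows, trace, fs_hz, max_align_shift_ms=8.0) -> AveragedEGM:
    """Pointwise mean of lag-aligned beat windows.

    Each window is re-aligned to the first (template) window by the lag
    maximizing cross-correlation within a small search range, then the
    aligned segments are averaged.  Invariant to window ordering.
    """
    if len(windows) < 1:
        raise ValueError("need at least one window")
    trace = np.asarray(trace, float)
    windows = sorted(windows, key=lambda w: w.start)
    L = windows[0].end - windows[0].start
    if any(w.end - w.start != L for w in windows):
        raise AlignmentError("window lengths inconsistent")
    ref = trace[windows[0].start:windows[0].end]
    ref0 = ref - ref.mean()
    max_shift = int(round(max_align_shift_ms * fs_hz / 1000.0))
    segs = []
    for w in windows:
        best_s, best_c = 0, -np.inf
        for s in range(-max_shift, max_shift + 1):
            a, b = w.start + s, w.end + s
            if a < 0 or b > len(trace):
                continue
            seg = trace[a:b]
            cc = float((seg - seg.mean()) @ ref0)
            if cc > best_c:
                best_c, best_s = cc, s
        segs.append(trace[w.start + best_s:w.end + best_s])
    avg = np.mean(segs, axis=0)
    return AveragedEGM(avg, fs_hz, beats_used=len(segs))


def average_node(trace, fs_hz, k=10, corr_floor=0.8, pre_ms=120.0,
                 window_ms=600.0, node_id=None, manual_index=None) -> AveragedEGM:
    """Full per-node chain: filter is assumed done; template -> ROIs -> average."""
    tpl = pick_template(trace, fs_hz, manual_index=manual_index,
                        pre_ms=pre_ms, window_ms=window_ms)
    rois = match_rois(trace, tpl, k=k, corr_floor=corr_floor, fs_hz=fs_hz)
    egm = signal_average(rois, trace, fs_hz)
    egm.node_id = node_id
    egm.shortfall = max(0, k - egm.beats_used)
    return egm
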