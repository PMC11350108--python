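"""QRS and T-wave delineation of averaged electrograms, with the
interpretability rejection rules.

The reference delineator is deterministic and threshold-based: the QRS is
the region around the sharpest deflection where the smoothed |dV/dt|
exceeds a fraction of its maximum, expanded outward to the foot of the
wave (a noise-aware hysteresis floor, bridging the brief zero crossings
between the R and S limbs); the T wave is the largest suprathreshold
region after the QRS and before the next beat.  It replaces the pretrained
segmentation network of the original mapping software with an identical
output contract: per-sample labels plus QRS/T boundary indices.

Quality rules: electrograms whose T wave is tiny relative to the QRS, or
whose T segment carries three or more prominent deflections, are rejected
as uninterpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import AveragedEGM

LABEL_BASELINE, LABEL_QRS, LABEL_T = 0, 1, 2

QUALITY_ACCEPTED = "accepted"
QUALITY_LOW_AMP = "rejected_low_amplitude"
QUALITY_T_DEFLECTIONS = "rejected_t_deflections"
QUALITY_NO_T = "rejected_no_t"


class NoQrsError(RuntimeError):
    pass


@dataclass
class Delineation:
    """QRS/T window boundaries (sample indices) and per-sample labels."""

    qrs_on: int
    qrs_off: int
    t_on: int
    t_off: int
    labels: np.ndarray
    quality: str = QUALITY_ACCEPTED
    reason: str = ""

    @property
    def accepted(self) -> bool:
        return self.quality == QUALITY_ACCEPTED


def smoothed_derivative(samples, fs_hz, smooth_ms=10.0):
    """Central-difference derivative (mV/ms) smoothed by a moving average."""
    d = np.gradient(np.asarray(samples, float)) * fs_hz / 1000.0
    w = max(1, int(round(smooth_ms * fs_hz / 1000.0)))
    return np.convolve(d, np.ones(w) / w, mode="same")


def _expand(d, start, stop, floor, direction, bridge=0):
    """Walk from a region edge while |d| stays above ``floor``.

    Sign changes do not stop the walk: the R and S limbs of one unipolar
    complex have opposite slopes but belong to the same wave.  Sub-floor
    stretches shorter than ``bridge`` samples (the zero crossings between
    limbs) are jumped over; only a sustained drop to baseline ends the
    walk."""
    i = start
    while 0 <= i + direction < len(d):
        j = i + direction
        if abs(d[j]) < floor:
            # look ahead for a resumption of suprathreshold activity
            k = j
            hops = 0
            while 0 <= k + direction < len(d) and hops < bridge:
                k += direction
                hops += 1
                if abs(d[k]) >= floor:
                    break
            else:
                break
            if abs(d[k]) < floor:
                break
            j = k
        i = j
    return i


def _suprathreshold_runs(mask):
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    return [(int(r[0]), int(r[-1])) for r in runs]


def delineate_egm(egm: AveragedEGM, theta_qrs=0.2, theta_t=0.15,
                  smooth_ms=10.0, floor_frac=0.015, t_gap_ms=40.0,
                  t_guard_ms=20.0, search_end_ms=None) -> Delineation:
    """Locate QRS and T-wave boundaries on one averaged electrogram.

    QRS: the first strong region where smoothed |dV/dt| exceeds
    ``theta_qrs`` of the window maximum, expanded outward while |dV/dt|
    stays above a hysteresis floor (``floor_frac`` of the maximum or 2.5x
    the baseline noise), bridging sub-floor gaps shorter than 15 ms.
    T: the longest region after the QRS where |dV/dt| exceeds ``theta_t``
    of its own post-QRS maximum (floored at 4x baseline noise);
    suprathreshold runs separated by less than ``t_gap_ms`` (the near-zero
    slope at a T apex) are merged, and the search stops before the next
    beat (``search_end_ms`` or the next strong deflection).
    """
    v = np.asarray(egm.samples, float)
    fs = egm.fs_hz
    if len(v) < 0.3 * fs:
        raise ValueError("averaged EGM must cover at least 300 ms")
    d = smoothed_derivative(v, fs, smooth_ms)
    ad = np.abs(d)
    peak = ad.max()
    if peak <= 0:
        raise NoQrsError("flat electrogram, no QRS found")
    # baseline-noise scale from the quietest 25-ms block of the window
    # (a fixed pre-QRS segment can be contaminated by the previous beat's
    # T wave at high heart rates)
    blk = max(5, int(0.025 * fs))
    n_blk = len(d) // blk
    noise_sd = float(np.min(d[:n_blk * blk].reshape(n_blk, blk).std(axis=1))) \
        if n_blk >= 2 else 0.0
    mask = ad >= theta_qrs * peak
    runs = _suprathreshold_runs(mask)
    # primary complex = first strong suprathreshold run (at high heart
    # rates the window also contains the start of the next beat, whose
    # deflection can be the global maximum)
    strong = [(a, b) for a, b in runs if ad[a:b + 1].max() >= 0.5 * peak]
    if not strong:
        raise NoQrsError("no suprathreshold QRS region")
    core = strong[0]
    # expansion floor: above the noise but below the gentlest limb of the
    # complex, so boundaries reach the true foot of the wave
    floor = max(floor_frac * peak, 2.5 * noise_sd)
    bridge = int(0.015 * fs)
    qrs_on = _expand(d, core[0], 0, floor, -1, bridge=bridge)
    qrs_off = _expand(d, core[1], len(d) - 1, floor, +1, bridge=bridge)
    # absorb immediately adjacent suprathreshold runs (R/S lobes of the
    # same complex) into the QRS before searching for the T wave
    for a, b in runs:
        if a > qrs_off and (a - qrs_off) <= int(t_gap_ms * fs / 1000.0) \
                and (b - core[0]) <= int(0.18 * fs):
            qrs_off = _expand(d, b, len(d) - 1, floor, +1, bridge=bridge)

    labels = np.zeros(len(v), dtype=int)
    labels[qrs_on:qrs_off + 1] = LABEL_QRS

    # bound the T search before the next beat's QRS: an explicit bound
    # (one beat period, from the caller's RR estimate) and/or the onset of
    # the next strong deflection found in the window
    refractory = qrs_off + int(0.06 * fs)
    search_end = len(v)
    if search_end_ms is not None:
        search_end = min(search_end, max(refractory + 5,
                                         int(search_end_ms * fs / 1000.0)))
    for a, b in strong:
        if a > refractory:
            search_end = min(search_end, max(
                refractory, _expand(d, a, 0, floor, -1, bridge=bridge)
                - int(0.005 * fs)))
            break

    guard = int(t_guard_ms * fs / 1000.0)
    post = qrs_off + guard
    t_on = t_off = -1
    if post < search_end - 4:
        ad_post = ad[post:search_end]
        t_peak = ad_post.max()
        if t_peak > 0:
            t_thr = max(theta_t * t_peak, 4.0 * noise_sd)
            t_runs = _suprathreshold_runs(ad_post >= t_thr)
            # merge runs separated by short gaps (biphasic T apex crossing)
            gap = int(t_gap_ms * fs / 1000.0)
            merged = []
            for a, b in t_runs:
                if merged and a - merged[-1][1] <= gap:
                    merged[-1] = (merged[-1][0], b)
                else:
                    merged.append((a, b))
            if merged:
                a, b = max(merged, key=lambda r: r[1] - r[0])
                t_floor = max(floor_frac * t_peak, 3.0 * noise_sd)
                seg = d[post:search_end]
                t_on = post + _expand(seg, a, 0, t_floor, -1)
                t_off = post + _expand(seg, b, len(seg) - 1, t_floor, +1)
                labels[t_on:t_off + 1] = LABEL_T
    quality = QUALITY_ACCEPTED if t_on >= 0 else QUALITY_NO_T
    return Delineation(int(qrs_on), int(qrs_off), int(t_on), int(t_off),
                       labels, quality=quality,
                       reason="" if t_on >= 0 else "no T-wave region found")


def count_deflections(segment, prominence_frac=0.10) -> int:
    """Number of prominent local extrema in a voltage segment.

    An extremum counts when its prominence is at least ``prominence_frac``
    of the segment's peak-to-peak amplitude.  A flat segment has none.
    """
    seg = np.asarray(segment, float)
    if len(seg) == 0:
        raise ValueError("segment is empty")
    p2p = seg.max() - seg.min()
    if p2p <= 0:
        return 0
    prom = prominence_frac * p2p
    up, _ = sps.find_peaks(seg, prominence=prom)
    down, _ = sps.find_peaks(-seg, prominence=prom)
    return int(len(up) + len(down))


def assess_quality(egm: AveragedEGM, delin: Delineation, t_amp_frac=0.05,
                   max_deflections=3, prominence_frac=0.10) -> Delineation:
    """Apply the interpretability rejection rules, recording the reason.

    Rejects when the T-wave peak-to-peak amplitude is below ``t_amp_frac``
    of the QRS peak-to-peak ("low amplitude relative to QRS"), or when the
    T segment has ``max_deflections`` or more prominent deflections.
    """
    v = np.asarray(egm.samples, float)
    if delin.quality == QUALITY_NO_T:
        return delin
    qrs = v[delin.qrs_on:delin.qrs_off + 1]
    t_seg = v[delin.t_on:delin.t_off + 1]
    qrs_amp = qrs.max() - qrs.min() if len(qrs) else 0.0
    t_amp = t_seg.max() - t_seg.min() if len(t_seg) else 0.0
    if qrs_amp <= 0 or t_amp < t_amp_frac * qrs_amp:
        delin.quality = QUALITY_LOW_AMP
        delin.reason = (f"T amplitude {t_amp:.4g} below "
                        f"{t_amp_frac:.0%} of QRS {qrs_amp:.4g}")
        return delin
    n_defl = count_deflections(t_seg, prominence_frac)
    if n_defl >= max_deflections:
        delin.quality = QUALITY_T_DEFLECTIONS
        delin.reason = f"T wave has {n_defl} deflections"
    return delin


def delineation_table(delins: dict, fs_hz: float):
    """Per-node delineation table (times in ms) for CSV export."""
    import pandas as pd

    rows = []
    for node_id, dl in delins.items():
        rows.append({
            "node_id": node_id,
            "qrs_on_ms": dl.qrs_on * 1000.0 / fs_hz,
            "qrs_off_ms": dl.qrs_off * 1000.0 / fs_hz,
            "t_on_ms": dl.t_on * 1000.0 / fs_hz if dl.t_on >= 0 else np.nan,
            "t_off_ms": dl.t_off * 1000.0 / fs_hz if dl.t_off >= 0 else np.nan,
            "quality": dl.quality,
            "reason": dl.reason,
        })
    return pd.DataFrame(rows)
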