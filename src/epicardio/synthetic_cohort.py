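"""Seeded synthetic subjects: cohort-level metric sampling, ground-truth
activation/repolarization fields on a mesh, and raw multi-beat unipolar
electrograms realizing them.

Three layers, each usable on its own:

``sample_subject_metrics``
    Fast metric-level cohort sampler.  Subject-level whole-heart measures
    are drawn from a correlated latent normal and mapped through per-measure
    marginals (Gaussian, or monotone broken-stick transforms for the
    recovery-phase model pair) so that cohorts reproduce the study groups'
    reported means, SDs and rank separation.

``build_truth_fields``
    Turns one subject's target metrics into node-level true activation and
    repolarization times on a mesh, calibrated so that the markers module's
    own mean / central-95% dispersion / 5-mm gradient computed on the true
    fields match the targets.

``synthesize_beat_train`` / ``synthesize_subject``
    Raw multi-beat voltage traces whose QRS steepest-negative-slope and
    T-wave steepest-positive-slope fall exactly at the true AT and RT of
    each node, plus baseline wander and white noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mesh_geometry import EpicardialMesh

MEASURES = ("at_mean", "at_disp", "at_grad", "ari_mean", "ari_disp", "ari_grad")
PHASES = ("peak", "recovery")
PATTERN_NAMES = ("late_patch", "apical_ari_prolongation",
                 "apical_t_inversion", "isolated_t_patch")


class ConfigurationError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BrokenStickTransform:
    """Monotone piecewise-linear map from a latent standard normal.

    ``heavy_side='low'`` puts the steep segment (slope*ratio) below the
    knot, producing a heavy low tail; ``'high'`` mirrors it.
    """

    c: float
    slope: float
    knot: float
    ratio: float
    heavy_side: str

    def __call__(self, z):
        z = np.asarray(z, float)
        c, s, zb, r = self.c, self.slope, self.knot, self.ratio
        if self.heavy_side == "low":
            return np.where(z < zb, c + s * r * (z - zb), c + s * (z - zb))
        return np.where(z < zb, c + s * (z - zb), c + s * r * (z - zb))


@dataclass(frozen=True)
class Marginal:
    """Per-measure sampling marginal: Gaussian or transform of the latent."""

    mean: float = None
    sd: float = None
    transform: BrokenStickTransform = None
    latent_shift: float = 0.0

    def apply(self, z):
        if self.transform is not None:
            return self.transform(np.asarray(z) + self.latent_shift)
        return self.mean + self.sd * np.asarray(z)


@dataclass(frozen=True)
class GroupPreset:
    """Study-group conditions: marginals per phase/measure, heart rates,
    qualitative map-pattern probabilities."""

    label: str
    marginals: dict            # (phase, measure) -> Marginal
    heart_rate: dict           # phase -> (mean bpm, sd bpm)
    patterns: dict             # pattern name -> probability

    def marginal(self, phase, measure) -> Marginal:
        return self.marginals[(phase, measure)]


@dataclass(frozen=True)
class PresetBundle:
    groups: dict               # label -> GroupPreset
    correlation_rules: dict
    source_path: str
    source_sha256: str

    def latent_correlation(self, keys):
        """Correlation matrix for latent variables of (phase, measure) keys."""
        r = self.correlation_rules
        n = len(keys)
        C = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                (pi, mi), (pj, mj) = keys[i], keys[j]
                if pi == pj:
                    pair = {mi, mj}
                    c = r["within_phase_at_ari"] if pair == {"at_mean", "ari_mean"} \
                        else r["within_phase"]
                elif mi == mj:
                    c = r["cross_phase_at_mean"] if mi == "at_mean" else r["cross_phase_same"]
                else:
                    c = r["cross_phase_other"]
                C[i, j] = C[j, i] = c
        w = np.linalg.eigvalsh(C)
        if w.min() <= 0:
            raise ConfigurationError(
                f"latent correlation matrix not positive definite (min eig {w.min():.3g})")
        return C


def default_preset_path() -> Path:
    return Path(resources.files("epicardio") / "presets" / "default.yaml")


def load_presets(path=None) -> PresetBundle:
    path = Path(path) if path is not None else default_preset_path()
    raw = path.read_bytes()
    cfg = yaml.safe_load(raw)
    transforms = {}
    for name, t in cfg.get("transforms", {}).items():
        transforms[name] = (BrokenStickTransform(
            c=float(t["c"]), slope=float(t["slope"]), knot=float(t["knot"]),
            ratio=float(t["ratio"]), heavy_side=t["heavy_side"]),
            {g: float(s) for g, s in t["latent_shift"].items()})
    groups = {}
    for label, g in cfg["groups"].items():
        marginals = {}
        hr = {}
        for phase in PHASES:
            for measure in MEASURES:
                spec = g[phase][measure]
                if "transform" in spec:
                    tr, shifts = transforms[spec["transform"]]
                    marginals[(phase, measure)] = Marginal(
                        transform=tr, latent_shift=shifts.get(label, 0.0))
                else:
                    m, s = float(spec["mean"]), float(spec["sd"])
                    if s < 0:
                        raise ConfigurationError(f"{label}/{phase}/{measure}: sd < 0")
                    marginals[(phase, measure)] = Marginal(mean=m, sd=s)
            hspec = g[phase]["heart_rate"]
            hr[phase] = (float(hspec["mean"]), float(hspec["sd"]))
        pats = {k: float(v) for k, v in g["patterns"].items()}
        if any(not 0 <= v <= 1 for v in pats.values()):
            raise ConfigurationError(f"{label}: pattern probabilities must be in [0,1]")
        groups[label] = GroupPreset(label, marginals, hr, pats)
    rules = {k: float(v) for k, v in cfg["latent_correlation"].items()}
    if any(abs(v) >= 1 for v in rules.values()):
        raise ConfigurationError("latent correlations must satisfy |rho| < 1")
    return PresetBundle(groups, rules, str(path), hashlib.sha256(raw).hexdigest())


# ---------------------------------------------------------------------------
# Metric-level sampler
# ---------------------------------------------------------------------------

def _match_sample_moments(Z, C):
    """Affinely standardize draws so sample mean is 0 and sample covariance
    is exactly ``C``.  Needs more draws than dimensions."""
    Z = Z - Z.mean(axis=0)
    cov = np.cov(Z.T, bias=True).reshape(Z.shape[1], Z.shape[1])
    L = np.linalg.cholesky(cov)
    return Z @ np.linalg.inv(L).T @ np.linalg.cholesky(C).T


def sample_subject_metrics(presets: PresetBundle, group: str, n: int, seed,
                           phase=None, measures=MEASURES,
                           matched: bool = True) -> pd.DataFrame:
    """Draw ``n`` subjects' whole-heart target metrics for one study group.

    Measures are sampled jointly from a latent multivariate normal with the
    preset correlation structure, then mapped through each measure's
    marginal.  With ``matched=True`` (default, requires n > #measures) the
    latent sample moments are standardized exactly, so every cohort carries
    the preset group statistics rather than a sampling-lottery version of
    them.  Heart rates are drawn independently per phase.

    Returns a DataFrame with columns ``{phase}_{measure}`` plus
    ``{phase}_heart_rate``, and one row per subject.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    preset = presets.groups[group]
    phases = PHASES if phase in (None, "both") else (phase,)
    keys = [(ph, m) for ph in phases for m in measures]
    C = presets.latent_correlation(keys)
    rng = np.random.default_rng(seed)
    Z = rng.multivariate_normal(np.zeros(len(keys)), C, size=n,
                                method="cholesky")
    if matched and n > len(keys) + 1:
        Z = _match_sample_moments(Z, C)
    data = {}
    for j, (ph, m) in enumerate(keys):
        data[f"{ph}_{m}"] = preset.marginal(ph, m).apply(Z[:, j])
    for ph in phases:
        hm, hs = preset.heart_rate[ph]
        data[f"{ph}_heart_rate"] = np.clip(hm + hs * rng.standard_normal(n), 40.0, 200.0)
    df = pd.DataFrame(data)
    df.insert(0, "group", group)
    return df


def sample_patterns(presets: PresetBundle, group: str, n: int, seed,
                    at_grad=None) -> pd.DataFrame:
    """Pattern flags per subject from the group prevalences.

    Flags are Bernoulli draws, except the late-activation patch when the
    subjects' sampled activation-gradient targets are supplied: late
    patches ring themselves with steep gradients, so the flag goes to the
    highest-gradient subjects (the group prevalence is preserved exactly).
    """
    rng = np.random.default_rng(seed)
    preset = presets.groups[group]
    out = pd.DataFrame({name: rng.random(n) < preset.patterns[name]
                        for name in PATTERN_NAMES})
    if at_grad is not None and n > 1:
        k = int(round(preset.patterns["late_patch"] * n))
        order = np.argsort(np.asarray(at_grad, float) + 1e-9 * rng.random(n))
        flags = np.zeros(n, bool)
        flags[order[n - k:]] = True
        out["late_patch"] = flags
    return out


# ---------------------------------------------------------------------------
# Ground-truth field synthesis
# ---------------------------------------------------------------------------

@dataclass
class SubjectTruth:
    """Node-level ground truth for one subject and phase.

    Times are ms from the beat's global QRS onset.  ``polarity`` is +1 for
    upright and -1 for inverted T waves.
    """

    mesh: EpicardialMesh
    at: np.ndarray
    rt: np.ndarray
    polarity: np.ndarray
    targets: dict
    achieved: dict
    flags: dict = field(default_factory=dict)

    @property
    def ari(self):
        return self.rt - self.at


def _axial_coordinate(mesh):
    u = getattr(mesh, "arc_coordinate", None)
    if u is None:
        u = mesh.apicobasal_coordinate()
    return np.asarray(u, float)


def _smooth_noise(mesh, length_scale, rng):
    """Unit-variance spatially correlated field (squared-exponential kernel)."""
    d2 = ((mesh.vertices[:, None, :] - mesh.vertices[None, :, :]) ** 2).sum(-1)
    K = np.exp(-0.5 * d2 / length_scale ** 2)
    f = K @ rng.standard_normal(mesh.n_nodes)
    sd = f.std()
    return f / sd if sd > 0 else f


def _raised_cosine_patch(mesh, center_idx, radius, core=0.0):
    """Unit-height bump: optional flat core of radius ``core`` mm, then a
    raised-cosine taper reaching zero at ``radius`` mm."""
    d = np.linalg.norm(mesh.vertices - mesh.vertices[center_idx], axis=1)
    w = np.zeros(mesh.n_nodes)
    w[d <= core] = 1.0
    taper = (d > core) & (d < radius)
    w[taper] = 0.5 * (1 + np.cos(np.pi * (d[taper] - core) / (radius - core)))
    return w


def _dispersion95(values):
    return float(np.percentile(values, 97.5) - np.percentile(values, 2.5))


def _calibrate_field(mesh, shape_parts, mean_t, disp_t, grad_t,
                     radius=5.0, rel_tol=0.02, max_iter=50):
    """Affine + roughness calibration of one scalar field.

    ``shape_parts`` is (base, noise): the field is base + w*noise, then
    affinely rescaled so its central-95% range equals ``disp_t`` and its
    mean equals ``mean_t`` exactly.  The noise weight w >= 0 is tuned so
    the 5-mm plane-fit gradient matches ``grad_t``; if even the smoothest
    field exceeds the target the floor value is recorded and flagged.
    """
    from .markers import mean_spatial_gradient

    base, noise = shape_parts

    def build(w):
        raw = base + w * noise
        d = _dispersion95(raw)
        if d <= 0:
            raise CalibrationError("degenerate field shape (zero dispersion)")
        a = disp_t / d
        f = a * raw
        f += mean_t - f.mean()
        return f

    def grad_of(w):
        return mean_spatial_gradient(mesh, build(w), radius=radius)

    tol = max(rel_tol * grad_t, 0.01)
    lo, g_lo = 0.0, grad_of(0.0)
    flags = {}
    if g_lo >= grad_t:
        # smooth-field floor above target: nearest achievable
        if g_lo - grad_t > tol:
            flags["gradient_clamped"] = True
        w = 0.0
    else:
        hi = 0.5
        g_hi = grad_of(hi)
        it = 0
        while g_hi < grad_t and it < 20:
            hi *= 2.0
            g_hi = grad_of(hi)
            it += 1
        if g_hi < grad_t:
            # roughness saturated below an extreme tail draw: nearest
            # achievable, recorded
            f = build(hi)
            achieved = dict(mean=float(f.mean()), disp=_dispersion95(f),
                            grad=float(g_hi))
            return f, achieved, {"gradient_clamped": True}
        for _ in range(max_iter):
            w = 0.5 * (lo + hi)
            g = grad_of(w)
            if abs(g - grad_t) <= tol:
                break
            if g < grad_t:
                lo = w
            else:
                hi = w
        else:
            w = 0.5 * (lo + hi)
    f = build(w)
    achieved = dict(mean=float(f.mean()), disp=_dispersion95(f),
                    grad=float(mean_spatial_gradient(mesh, f, radius=radius)))
    return f, achieved, flags


def build_truth_fields(targets, mesh: EpicardialMesh, patterns=None,
                       seed=0, radius=5.0, patch_height_ms=12.0) -> SubjectTruth:
    """Construct node-level true AT and RT fields matching subject targets.

    ``targets`` maps measure names (``at_mean``, ``at_disp``, ``at_grad``,
    ``ari_mean``, ``ari_disp``, ``ari_grad``) to the subject's whole-heart
    values.  The AT field is an apico-basal ramp plus smooth correlated
    noise plus 0-3 late raised-cosine patches; the ARI field is built
    analogously (shorter correlation length, optional apical prolongation).
    Both are affinely rescaled and roughness-tuned so the markers module's
    own metrics on the true fields match the targets (mean and dispersion
    exactly, gradient within 2% or 0.01 ms/mm unless floored).
    """
    targets = {k: float(targets[k]) for k in MEASURES}
    if targets["at_disp"] <= 0 or targets["ari_disp"] <= 0:
        raise ParameterError("dispersion targets must be positive")
    if not all(np.isfinite(list(targets.values()))):
        raise ParameterError("targets must be finite")
    patterns = dict(patterns or {})
    rng = np.random.default_rng(seed)
    u = _axial_coordinate(mesh)

    # activation: ramp from apex to base + smooth noise + late patches.
    # Patches sit in late-activating territory (outer ramp third) with a
    # gentle profile: tall enough to clear the late-patch detection rule
    # (~1.5 SD above the map mean) yet wide enough that the whole-heart
    # mean 5-mm gradient stays near the smooth-ramp floor.
    base_at = u.copy()
    patch_nodes = []
    if patterns.get("late_patch"):
        # One isolated late patch of fixed height (ms) in the mid-ramp
        # zone: there its apex stays below the map's top percentiles (the
        # dispersion calibration is unaffected) and the local contrast
        # against the surrounding annulus is the full patch height.
        # Centred where the node sampling can resolve it.
        zone = np.flatnonzero((u > 0.30) & (u < 0.62))
        counts = np.array([len(mesh.tree.query_ball_point(mesh.vertices[i], 8.0))
                           for i in zone])
        top = zone[counts >= min(5, counts.max())]
        center = int(rng.choice(top))
        height = patch_height_ms
        # flat 8-mm core (several full-height nodes) with a 6-mm taper
        w = _raised_cosine_patch(mesh, center, 14.0, core=8.0)
        # one-step fixed point: the affine dispersion scaling barely moves
        # when the patch is added, so height in raw units = h / scale0
        scale0 = targets["at_disp"] / _dispersion95(base_at)
        base_at += (height / scale0) * w
        patch_nodes.append(np.flatnonzero(w > 0.05))
    noise_at = _smooth_noise(mesh, 15.0, rng) * 0.25
    at, ach_at, flags_at = _calibrate_field(
        mesh, (base_at, noise_at), targets["at_mean"], targets["at_disp"],
        targets["at_grad"], radius=radius)

    # ARI: gentler apico-basal trend, rougher texture, optional apical bump
    base_ari = 0.4 * (1 - u) + 0.3 * _smooth_noise(mesh, 20.0, rng)
    if patterns.get("apical_ari_prolongation"):
        apical = np.clip(1 - u / 0.45, 0, 1)
        base_ari += 0.8 * 0.5 * (1 - np.cos(np.pi * apical))
    noise_ari = _smooth_noise(mesh, 7.0, rng)
    ari, ach_ari, flags_ari = _calibrate_field(
        mesh, (base_ari, noise_ari), targets["ari_mean"], targets["ari_disp"],
        targets["ari_grad"], radius=radius)
    if ari.min() <= 0:
        ari = np.clip(ari, 30.0, None)
        flags_ari["ari_clipped"] = True

    polarity = np.ones(mesh.n_nodes)
    if patterns.get("apical_t_inversion"):
        polarity[u < 0.33] = -1
    if patterns.get("isolated_t_patch"):
        center = int(rng.integers(mesh.n_nodes))
        w = _raised_cosine_patch(mesh, center, float(rng.uniform(10.0, 16.0)))
        if (w > 0.05).sum() >= 5:
            polarity[w > 0.05] = -1

    achieved = {f"at_{k}": v for k, v in ach_at.items()}
    achieved.update({f"ari_{k}": v for k, v in ach_ari.items()})
    flags = {f"at_{k}": v for k, v in flags_at.items()}
    flags.update({f"ari_{k}": v for k, v in flags_ari.items()})
    truth = SubjectTruth(mesh, at, at + ari, polarity, targets, achieved, flags)
    truth.patch_nodes = patch_nodes
    truth.patterns = patterns
    return truth


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformParams:
    """Shape and noise parameters of the synthetic unipolar electrograms.

    Amplitude fractions are relative to the QRS peak-to-peak amplitude.
    """

    fs_hz: float = 1000.0
    qrs_width_ms: float = 105.0      # far-field QRS envelope duration
    qrs_lobe_ms: float = 12.0        # intrinsic-deflection downstroke width
    qrs_amp_mv: float = 1.0
    t_width_ms: float = 160.0
    t_amp_frac: float = 0.35
    wander_amp_frac: float = 0.30
    wander_freq_hz: float = 0.25
    noise_sd_frac: float = 0.02
    beats: int = 10
    rr_jitter_frac: float = 0.03
    pad_ms: float = 250.0

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.beats < 1:
            raise ParameterError("beats per strip must be >= 1")
        if min(self.qrs_width_ms, self.qrs_lobe_ms, self.t_width_ms) <= 0:
            raise ParameterError("widths must be positive")


def _beat_templates(at_ms, rt_ms, polarity, params: WaveformParams):
    """Noise-free single-beat waveforms for a set of nodes, vectorized.

    Each beat has a shared far-field QRS envelope starting exactly at the
    beat onset (the map's global QRS start), an intrinsic steepest-negative
    deflection at the node's AT, and a raised-cosine T wave whose steepest
    positive slope falls at the node's RT (upright or inverted).
    Returns (n_nodes, beat_len) voltages and the beat length in samples.
    """
    at = np.atleast_1d(np.asarray(at_ms, float))
    rt = np.atleast_1d(np.asarray(rt_ms, float))
    pol = np.broadcast_to(np.atleast_1d(polarity), at.shape).astype(float)
    if np.any(rt <= at):
        raise ParameterError("RT must exceed AT at every node")
    fs = params.fs_hz
    dt = 1000.0 / fs
    tq = max(params.qrs_width_ms, float(at.max()) + params.qrs_lobe_ms / 2 + 5.0)
    w_t = params.t_width_ms
    t_start = np.where(pol > 0, rt - w_t / 4, rt - 3 * w_t / 4)
    if np.any(t_start <= at + params.qrs_lobe_ms / 2):
        raise ParameterError("T wave overlaps the QRS downstroke; RT too early")
    beat_ms = max(tq, float((t_start + w_t).max())) + 20.0
    n = int(round(beat_ms / dt))
    t = np.arange(n) * dt                                    # (n,)

    # far-field derivative: positive envelope over [0, tq), sharp onset/offset
    d_ff = np.where((t >= 0) & (t < tq), 0.6 + 0.4 * np.sin(np.pi * t / tq), 0.0)
    # intrinsic deflection: negative cosine lobe centred at AT
    rel = t[None, :] - at[:, None]
    half = params.qrs_lobe_ms / 2
    lobe = np.where(np.abs(rel) <= half, np.cos(np.pi * rel / params.qrs_lobe_ms), 0.0)
    # per-node lobe scale so the discrete QRS derivative integrates to zero
    s_ff = d_ff.sum()
    s_lobe = lobe.sum(axis=1)
    scale = np.where(s_lobe > 0, s_ff / s_lobe, 0.0)
    d_qrs = d_ff[None, :] - scale[:, None] * lobe
    v_qrs = np.cumsum(d_qrs, axis=1) * dt
    p2p = v_qrs.max(axis=1) - v_qrs.min(axis=1)
    v_qrs *= (params.qrs_amp_mv / np.where(p2p > 0, p2p, 1.0))[:, None]

    # T wave: raised cosine with steepest positive slope exactly at RT
    tr = t[None, :] - t_start[:, None]
    in_t = (tr >= 0) & (tr <= w_t)
    v_t = np.where(in_t, 0.5 * (1 - np.cos(2 * np.pi * tr / w_t)), 0.0)
    v_t *= (pol * params.t_amp_frac * params.qrs_amp_mv)[:, None]
    return v_qrs + v_t, n


def _verify_beat(beats, at_ms, rt_ms, params: WaveformParams, tol_samples=1.5):
    """Check by numerical differentiation that the steepest slopes of the
    noise-free beats fall at the configured AT and RT (within sub-sample
    quantization of the non-integer marker times)."""
    fs = params.fs_hz
    d = np.gradient(beats, axis=1) * fs / 1000.0
    at_idx = np.argmin(d, axis=1)
    err_at = np.abs(at_idx - np.asarray(at_ms) * fs / 1000.0)
    # RT: steepest positive slope after the whole QRS complex (the S-wave
    # recovery limb of the far-field envelope also slopes upward)
    tq = max(params.qrs_width_ms, float(np.max(at_ms)) + params.qrs_lobe_ms / 2 + 5.0)
    start = int((tq + 5.0) * fs / 1000.0)
    rt_idx = start + np.argmax(d[:, start:], axis=1)
    err_rt = np.abs(rt_idx - np.asarray(rt_ms) * fs / 1000.0)
    if err_at.max() > tol_samples or err_rt.max() > tol_samples:
        raise CalibrationError(
            f"beat construction failed verification (AT err {err_at.max():.2f}, "
            f"RT err {err_rt.max():.2f} samples)")


def make_rr_sequence(rr_mean_ms, n_beats, jitter_frac, rng, rr_floor_ms=None):
    rr = rr_mean_ms * (1 + jitter_frac * rng.standard_normal(n_beats))
    if rr_floor_ms is not None:
        rr = np.maximum(rr, rr_floor_ms)
    return rr


def synthesize_beat_train(at_ms, rt_ms, polarity, params: WaveformParams,
                          rr_sequence_ms, seed=0, verify=True):
    """Raw multi-beat voltage trace for a single node.

    Beat onsets follow ``rr_sequence_ms``; every beat carries the same
    noise-free waveform (steepest slopes at AT / RT, verified numerically),
    with baseline-wander sinusoid and white noise added on top.
    """
    traces, _, _ = synthesize_subject(
        np.atleast_1d(at_ms), np.atleast_1d(rt_ms), np.atleast_1d(polarity),
        params, np.asarray(rr_sequence_ms, float), seed=seed, verify=verify)
    return traces[0]


def synthesize_subject(at_ms, rt_ms, polarity, params: WaveformParams,
                       rr_sequence_ms, seed=0, verify=True):
    """Multi-node beat-train synthesis.

    Returns ``(traces, onsets_ms, beat_len_samples)`` where traces has shape
    (n_nodes, n_samples) and onsets are the beat (global QRS) start times.
    """
    at = np.asarray(at_ms, float)
    rt = np.asarray(rt_ms, float)
    rr = np.asarray(rr_sequence_ms, float)
    beat_period = rr.min()
    if np.any(at < 0) or np.any(rt >= beat_period):
        raise ParameterError("AT/RT must lie inside one beat period")
    rng = np.random.default_rng(seed)
    fs = params.fs_hz
    dt = 1000.0 / fs
    beats, beat_len = _beat_templates(at, rt, polarity, params)
    if verify:
        _verify_beat(beats, at, rt, params)
    pad = int(round(params.pad_ms / dt))
    onsets = pad + np.round(np.concatenate([[0], np.cumsum(rr[:-1])]) / dt).astype(int)
    n_total = onsets[-1] + beat_len + pad
    traces = np.zeros((len(at), n_total))
    for onset in onsets:
        end = min(onset + beat_len, n_total)
        traces[:, onset:end] += beats[:, :end - onset]
    t_s = np.arange(n_total) * dt / 1000.0
    amp = params.qrs_amp_mv
    if params.wander_amp_frac > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        traces += (params.wander_amp_frac * amp
                   * np.sin(2 * np.pi * params.wander_freq_hz * t_s + phase0))[None, :]
    if params.noise_sd_frac > 0:
        traces += params.noise_sd_frac * amp * rng.standard_normal(traces.shape)
    return traces, onsets * dt, beat_len


def truth_labels(at_ms, rt_ms, polarity, params: WaveformParams,
                 n_samples, offset_ms=0.0):
    """Per-sample truth label track for one beat: 0 baseline, 1 QRS, 2 T.

    ``offset_ms`` is the time of the beat onset relative to the first
    sample of the track (positive when the track starts before the beat).
    """
    fs = params.fs_hz
    t = np.arange(n_samples) * 1000.0 / fs - offset_ms
    lab = np.zeros(n_samples, dtype=int)
    tq = max(params.qrs_width_ms, at_ms + params.qrs_lobe_ms / 2 + 5.0)
    lab[(t >= 0) & (t <= tq)] = 1
    w_t = params.t_width_ms
    t0 = rt_ms - w_t / 4 if polarity > 0 else rt_ms - 3 * w_t / 4
    lab[(t >= t0) & (t <= t0 + w_t)] = 2
    return lab


def rr_floor_for(truth: SubjectTruth, params: WaveformParams) -> float:
    """Minimum RR interval keeping every node's T wave inside one beat."""
    return float(truth.rt.max() + 0.8 * params.t_width_ms + 30.0)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def subject_seeds(root_seed, n):
    """Stable per-subject seed sequences spawned from one root seed."""
    return np.random.SeedSequence(root_seed).spawn(n)


def generate_cohort(presets: PresetBundle, counts: dict, mesh=None,
                    params: WaveformParams = None, seed=0,
                    mode="metrics", outdir=None, phase=None,
                    matched=True):
    """Generate a cohort dataset.

    ``counts`` maps group labels to subject counts.  In ``metrics`` mode the
    result is a feature table (one row per subject, whole-heart measures for
    both phases).  In ``waveform`` mode, per-subject raw signal matrices and
    truth tables are also produced for the requested phase(s) on ``mesh``;
    with ``outdir`` set they are written to disk (float32 matrix + JSON
    sidecar + truth CSV) along with a manifest.
    """
    if any(c < 1 for c in counts.values()):
        raise ParameterError("counts must be >= 1")
    if mode not in ("metrics", "waveform"):
        raise ParameterError(f"unknown mode {mode!r}")
    root = np.random.SeedSequence(seed)
    group_seqs = root.spawn(len(counts))
    tables = []
    subjects = []
    for (group, n), seq in zip(sorted(counts.items()), group_seqs):
        s_metrics, s_pat, s_subj = seq.spawn(3)
        df = sample_subject_metrics(presets, group, n, s_metrics,
                                    phase=phase, matched=matched)
        grad_col = "peak_at_grad" if "peak_at_grad" in df else None
        pats = sample_patterns(presets, group, n, s_pat,
                               at_grad=df[grad_col] if grad_col else None)
        df = pd.concat([df, pats], axis=1)
        df.insert(0, "subject_id", [f"{group}_{i:03d}" for i in range(n)])
        tables.append(df)
        if mode == "waveform":
            for i, sub_seq in enumerate(s_subj.spawn(n)):
                subjects.append((group, df.iloc[i], sub_seq))
    table = pd.concat(tables, ignore_index=True)

    manifest = {"seed": int(seed), "mode": mode,
                "counts": {k: int(v) for k, v in sorted(counts.items())},
                "preset_sha256": presets.source_sha256,
                "matched": bool(matched)}
    result = {"feature_table": table, "manifest": manifest, "subjects": []}

    if mode == "waveform":
        if mesh is None:
            raise ParameterError("waveform mode needs a mesh")
        params = params or WaveformParams()
        phases = PHASES if phase in (None, "both") else (phase,)
        for group, row, sub_seq in subjects:
            phase_seqs = sub_seq.spawn(len(phases))
            for ph, ph_seq in zip(phases, phase_seqs):
                sd_truth, sd_wave = ph_seq.spawn(2)
                targets = {m: row[f"{ph}_{m}"] for m in MEASURES}
                patterns = {p: bool(row[p]) for p in PATTERN_NAMES}
                truth = build_truth_fields(targets, mesh, patterns, seed=sd_truth)
                rr_mean = 60000.0 / row[f"{ph}_heart_rate"]
                wf = params if ph == "recovery" else replace(params, t_width_ms=110.0)
                rng = np.random.default_rng(sd_wave)
                rr = make_rr_sequence(rr_mean, wf.beats, wf.rr_jitter_frac,
                                      rng, rr_floor_ms=rr_floor_for(truth, wf))
                traces, onsets, _ = synthesize_subject(
                    truth.at, truth.rt, truth.polarity, wf, rr,
                    seed=rng.integers(2 ** 31))
                rec = {"subject_id": row["subject_id"], "group": group,
                       "phase": ph, "truth": truth, "traces": traces,
                       "onsets_ms": onsets, "params": wf,
                       "rr_ms": rr.tolist()}
                result["subjects"].append(rec)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "feature_table.csv", index=False)
        for rec in result["subjects"]:
            stem = f"{rec['subject_id']}_{rec['phase']}"
            sig = np.asarray(rec["traces"], np.float32)
            sig.T.tofile(out / f"{stem}_signals.f32")  # rows = samples
            sidecar = {"fs_hz": rec["params"].fs_hz, "units": "mV",
                       "node_ids": list(map(str, rec["truth"].mesh.node_ids)),
                       "phase": rec["phase"], "subject_id": rec["subject_id"],
                       "shape": [int(sig.shape[1]), int(sig.shape[0])],
                       "onsets_ms": list(map(float, rec["onsets_ms"]))}
            (out / f"{stem}_signals.json").write_text(json.dumps(sidecar, indent=1))
            t = rec["truth"]
            pd.DataFrame({"node_id": t.mesh.node_ids, "AT_ms": t.at,
                          "RT_ms": t.rt, "ARI_ms": t.ari,
                          "polarity": t.polarity.astype(int)}
                         ).to_csv(out / f"{stem}_truth.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result
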