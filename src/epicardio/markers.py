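"""Per-node activation/repolarization markers and whole-heart map metrics.

Marker definitions (times referenced to the map's global QRS start):

* LAT — local activation time: steepest *negative* slope (min dV/dt) of
  the QRS complex.
* LRT — local repolarization time: steepest *positive* slope (max dV/dt)
  of the T wave; the Wyatt convention, valid for upright and inverted T
  waves alike.
* ARI — activation-recovery interval: LRT − LAT, a surrogate of the local
  action-potential duration.

Whole-heart summaries over accepted nodes, in the study's three analysis
domains: the mean (conduction delay / repolarization prolongation), the
central 95% range (dispersion), and the mean spatial gradient over 5-mm
neighborhoods (steepness), the last via per-node least-squares plane fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineate import Delineation, smoothed_derivative
from .mesh_geometry import EpicardialMesh, neighborhoods
from .preprocess import AveragedEGM


class MarkerError(RuntimeError):
    pass


class EmptyMapError(RuntimeError):
    pass


class SampleSizeError(ValueError):
    pass


class GeometryError(RuntimeError):
    pass


@dataclass
class NodeMarkers:
    node_id: object
    lat_ms: float
    lrt_ms: float
    ari_ms: float
    accepted: bool = True


@dataclass
class HeartMetrics:
    """Per-subject, per-phase whole-heart summary of a marker map."""

    subject_id: object
    phase: str
    at_mean: float
    at_disp: float
    at_grad: float
    ari_mean: float
    ari_disp: float
    ari_grad: float
    nodes_used: int
    nodes_rejected: int

    def as_dict(self):
        return dict(subject_id=self.subject_id, phase=self.phase,
                    at_mean=self.at_mean, at_disp=self.at_disp,
                    at_grad=self.at_grad, ari_mean=self.ari_mean,
                    ari_disp=self.ari_disp, ari_grad=self.ari_grad,
                    nodes_used=self.nodes_used, nodes_rejected=self.nodes_rejected)


def global_qrs_start(delins) -> int:
    """Earliest QRS onset (sample index) across accepted delineations."""
    onsets = [d.qrs_on for d in delins if d.accepted]
    if not onsets:
        raise EmptyMapError("no accepted nodes in map")
    return int(min(onsets))


def _ls_vertex_refine(raw, idx, half, max_shift=2.0):
    """Sub-sample extremum position: least-squares parabola on the raw
    derivative over +-``half`` samples around the localized extremum.

    The smoothed derivative used for localization has a flattened trough
    whose interpolated vertex scallops with the sub-sample phase of the
    deflection; the raw derivative keeps the full curvature, and the
    least-squares fit averages its noise.  Falls back to the grid position
    near edges or with non-convex fits."""
    a = max(0, idx - half)
    b = min(len(raw), idx + half + 1)
    if b - a < 5:
        return float(idx)
    x = np.arange(a, b, dtype=float) - idx
    c2, c1, _ = np.polyfit(x, raw[a:b], 2)
    sign = np.sign(raw[idx]) or 1.0
    if sign * c2 >= 0:  # fit curvature must oppose the extremum
        return float(idx)
    delta = -c1 / (2 * c2)
    return float(idx) + float(np.clip(delta, -max_shift, max_shift))


def local_activation_time(egm: AveragedEGM, delin: Delineation, t0: int,
                          smooth_ms=10.0, refine=True) -> float:
    """LAT in ms: argmin of the smoothed derivative inside the QRS window,
    relative to the global QRS start sample ``t0``.  Ties break earliest;
    with ``refine`` the position is polished to sub-sample precision on
    the raw derivative (see ``_ls_vertex_refine``)."""
    d = smoothed_derivative(egm.samples, egm.fs_hz, smooth_ms)
    seg = d[delin.qrs_on:delin.qrs_off + 1]
    if seg.min() >= 0:
        raise MarkerError("no negative slope inside QRS window")
    idx = delin.qrs_on + int(np.argmin(seg))
    if refine:
        raw = np.gradient(np.asarray(egm.samples, float)) * egm.fs_hz / 1000.0
        pos = _ls_vertex_refine(raw, idx, int(0.006 * egm.fs_hz))
    else:
        pos = float(idx)
    return (pos - t0) * 1000.0 / egm.fs_hz


def local_repolarization_time(egm: AveragedEGM, delin: Delineation, t0: int,
                              smooth_ms=10.0, refine=True) -> float:
    """LRT in ms (Wyatt): argmax of the smoothed derivative inside the
    T window, relative to ``t0``; valid for upright and inverted T waves.
    Ties break earliest; sub-sample refinement as for LAT (wider fit, the
    T upstroke is gentler than the QRS downstroke)."""
    if delin.t_on < 0:
        raise MarkerError("no T window delineated")
    d = smoothed_derivative(egm.samples, egm.fs_hz, smooth_ms)
    seg = d[delin.t_on:delin.t_off + 1]
    if seg.max() <= 0:
        raise MarkerError("no positive slope inside T window")
    idx = delin.t_on + int(np.argmax(seg))
    if refine:
        raw = np.gradient(np.asarray(egm.samples, float)) * egm.fs_hz / 1000.0
        pos = _ls_vertex_refine(raw, idx, int(0.022 * egm.fs_hz), max_shift=5.0)
    else:
        pos = float(idx)
    return (pos - t0) * 1000.0 / egm.fs_hz


def activation_recovery_interval(lat_ms: float, lrt_ms: float):
    """ARI = LRT − LAT; non-positive values flag the node as rejected."""
    ari = lrt_ms - lat_ms
    return ari, ari > 0


def node_markers(egm: AveragedEGM, delin: Delineation, t0: int) -> NodeMarkers:
    if not delin.accepted:
        return NodeMarkers(egm.node_id, np.nan, np.nan, np.nan, accepted=False)
    try:
        lat = local_activation_time(egm, delin, t0)
        lrt = local_repolarization_time(egm, delin, t0)
    except MarkerError:
        return NodeMarkers(egm.node_id, np.nan, np.nan, np.nan, accepted=False)
    ari, ok = activation_recovery_interval(lat, lrt)
    return NodeMarkers(egm.node_id, lat, lrt, ari, accepted=ok)


def dispersion95(values) -> float:
    """Central 95% range: 97.5th − 2.5th percentile (linear interpolation)."""
    values = np.asarray(values, float)
    if len(values) < 10:
        raise SampleSizeError("need at least 10 values for dispersion")
    return float(np.percentile(values, 97.5) - np.percentile(values, 2.5))


def mean_spatial_gradient(mesh: EpicardialMesh, values, radius=5.0,
                          min_points=3, return_pernode=False):
    """Mean magnitude of the local spatial gradient over ``radius``-mm
    neighborhoods.

    Per node, a least-squares plane is fitted to the values of the node and
    its Euclidean neighbors within ``radius``; the gradient magnitude is
    the norm of the fitted slope vector.  Nodes with fewer than
    ``min_points`` neighborhood points (self included) are excluded from
    the whole-heart mean.
    """
    values = np.asarray(values, float)
    nbrs = _cached_neighborhoods(mesh, radius)
    grads = np.full(mesh.n_nodes, np.nan)
    for i, nb in enumerate(nbrs):
        pts_idx = [i] + nb
        if len(pts_idx) < min_points or not np.all(np.isfinite(values[pts_idx])):
            continue
        P = mesh.vertices[pts_idx]
        Q = P - P.mean(axis=0)
        v = values[pts_idx]
        v = v - v.mean()
        # least-squares slope via SVD of the centred point cloud; spatial
        # directions the neighborhood barely spans (singular value below
        # 5% of the largest) are unresolvable and excluded, otherwise
        # near-collinear point sets blow the fit up
        U, s, Vt = np.linalg.svd(Q, full_matrices=False)
        keep = s > 0.05 * s[0]
        g = Vt[keep].T @ ((U[:, keep].T @ v) / s[keep])
        grads[i] = np.linalg.norm(g)
    valid = np.isfinite(grads)
    if not valid.any():
        raise GeometryError("no node has a valid 5-mm neighborhood")
    mean = float(grads[valid].mean())
    if return_pernode:
        return mean, grads
    return mean


def _cached_neighborhoods(mesh, radius):
    cache = getattr(mesh, "_nbr_cache", None)
    if cache is None:
        cache = mesh._nbr_cache = {}
    key = round(float(radius), 6)
    if key not in cache:
        cache[key] = neighborhoods(mesh, radius)
    return cache[key]


def heart_metrics(markers, mesh: EpicardialMesh, subject_id=None, phase=None,
                  radius=5.0) -> HeartMetrics:
    """Whole-heart metric assembly over accepted nodes only."""
    acc = [m for m in markers if m.accepted]
    if len(acc) < 10:
        raise SampleSizeError(f"only {len(acc)} accepted nodes (need >= 10)")
    lat = np.full(mesh.n_nodes, np.nan)
    ari = np.full(mesh.n_nodes, np.nan)
    for m in acc:
        i = mesh.index_of(m.node_id)
        lat[i] = m.lat_ms
        ari[i] = m.ari_ms
    lat_vals = lat[np.isfinite(lat)]
    ari_vals = ari[np.isfinite(ari)]
    return HeartMetrics(
        subject_id=subject_id, phase=phase,
        at_mean=float(lat_vals.mean()), at_disp=dispersion95(lat_vals),
        at_grad=mean_spatial_gradient(mesh, lat, radius=radius),
        ari_mean=float(ari_vals.mean()), ari_disp=dispersion95(ari_vals),
        ari_grad=mean_spatial_gradient(mesh, ari, radius=radius),
        nodes_used=len(acc), nodes_rejected=len(markers) - len(acc))


def rate_correct(interval_ms: float, rr_s: float) -> float:
    """Bazett heart-rate correction: interval / sqrt(RR in seconds).

    The correction formula for rate-corrected ARI is a declared stand-in
    (the convention for QTc on surface ECGs).
    """
    if rr_s <= 0:
        raise ValueError("RR must be positive")
    return interval_ms / np.sqrt(rr_s)
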