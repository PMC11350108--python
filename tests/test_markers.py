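"""Wyatt markers, dispersion and spatial-gradient metrics."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from epicardio.delineate import delineate_egm
from epicardio.markers import (MarkerError, SampleSizeError,
                               activation_recovery_interval, dispersion95,
                               global_qrs_start, heart_metrics,
                               local_activation_time,
                               local_repolarization_time,
                               mean_spatial_gradient, node_markers,
                               rate_correct)
from epicardio.mesh_geometry import EpicardialMesh
from tests.test_delineate import canonical_egm


class FakeDelin:
    def __init__(self, qrs_on, accepted=True):
        self.qrs_on = qrs_on
        self.accepted = accepted


def test_global_qrs_start_is_exhaustive_minimum(rng):
    onsets = rng.integers(40, 200, size=30)
    delins = [FakeDelin(int(o)) for o in onsets]
    delins[3].accepted = False
    accepted = [d.qrs_on for d in delins if d.accepted]
    assert global_qrs_start(delins) == min(accepted)
    # all equal
    assert global_qrs_start([FakeDelin(77)] * 4) == 77
    # one node earlier than the rest
    ds = [FakeDelin(100)] * 5 + [FakeDelin(95)]
    assert global_qrs_start(ds) == 95


def test_lat_matches_construction_and_oracle():
    egm, _, pre = canonical_egm(at=40, rt=290)
    d = delineate_egm(egm)
    t0 = int(pre)
    lat = local_activation_time(egm, d, t0)
    assert lat == pytest.approx(40.0, abs=0.5)
    # exhaustive finite-difference scan oracle (grid resolution)
    from epicardio.delineate import smoothed_derivative
    dd = smoothed_derivative(egm.samples, egm.fs_hz, 10.0)
    oracle = int(np.argmin(dd[d.qrs_on:d.qrs_off + 1])) + d.qrs_on - t0
    assert local_activation_time(egm, d, t0, refine=False) == \
        pytest.approx(oracle, abs=1e-9)


def test_lat_translation_equivariance():
    egm, _, pre = canonical_egm(at=40)
    d = delineate_egm(egm)
    lat0 = local_activation_time(egm, d, int(pre))
    # shifting the reference by -10 samples adds exactly 10 ms
    lat1 = local_activation_time(egm, d, int(pre) - 10)
    assert lat1 - lat0 == pytest.approx(10.0, abs=1e-9)


@pytest.mark.parametrize("rt,polarity", [(290, 1.0), (310, -1.0)])
def test_lrt_wyatt_upright_and_inverted(rt, polarity):
    egm, _, pre = canonical_egm(at=40, rt=rt, polarity=polarity)
    d = delineate_egm(egm)
    lrt = local_repolarization_time(egm, d, int(pre))
    assert lrt == pytest.approx(rt, abs=1.0)
    from epicardio.delineate import smoothed_derivative
    dd = smoothed_derivative(egm.samples, egm.fs_hz, 10.0)
    oracle = int(np.argmax(dd[d.t_on:d.t_off + 1])) + d.t_on - int(pre)
    assert local_repolarization_time(egm, d, int(pre), refine=False) == \
        pytest.approx(oracle, abs=1e-9)


def test_ari_is_difference_and_flags_nonpositive():
    ari, ok = activation_recovery_interval(40.0, 290.0)
    assert ari == 250.0 and ok
    ari, ok = activation_recovery_interval(40.0, 40.0)
    assert ari == 0.0 and not ok


def test_node_markers_ari_column_consistency():
    egm, _, pre = canonical_egm()
    d = delineate_egm(egm)
    m = node_markers(egm, d, int(pre))
    assert m.ari_ms == pytest.approx(m.lrt_ms - m.lat_ms, abs=1e-12)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def test_dispersion95_identities(rng):
    assert dispersion95(np.full(50, 7.0)) == 0.0
    assert dispersion95(np.linspace(0, 100, 1001)) == pytest.approx(95.0)
    # sort-and-interpolate oracle
    v = rng.normal(size=333)
    s = np.sort(v)

    def q(p):
        h = p * (len(s) - 1)
        lo = int(np.floor(h))
        return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

    assert dispersion95(v) == pytest.approx(q(0.975) - q(0.025), abs=1e-12)
    with pytest.raises(SampleSizeError):
        dispersion95([1, 2, 3])


def test_dispersion_shift_equivariance(rng):
    v = rng.normal(size=100)
    assert dispersion95(v + 13.5) == pytest.approx(dispersion95(v), abs=1e-9)
    assert dispersion95(v) <= v.max() - v.min()
    assert dispersion95(rng.permutation(v)) == pytest.approx(dispersion95(v))


# ---------------------------------------------------------------------------
# spatial gradient
# ---------------------------------------------------------------------------

def grid_patch_mesh(n=10, spacing=3.0):
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    pts = np.c_[xs.ravel(), ys.ravel(), np.zeros(n * n)]
    tri = Delaunay(pts[:, :2])
    return EpicardialMesh(pts, tri.simplices)


def test_gradient_constant_field_is_zero(mesh200):
    assert mean_spatial_gradient(mesh200, np.full(200, 5.0)) == \
        pytest.approx(0.0, abs=1e-10)


def test_gradient_exact_on_planar_linear_field():
    mesh = grid_patch_mesh()
    f = 0.5 * mesh.vertices[:, 0] + 2.0
    assert mean_spatial_gradient(mesh, f) == pytest.approx(0.5, abs=1e-9)


def test_gradient_matches_plane_fit_oracle(rng):
    """Independent per-node plane-fit implementation on a 50-node mesh."""
    from epicardio.mesh_geometry import prolate_spheroid_mesh

    mesh = prolate_spheroid_mesh(50, seed=5, equatorial_radius=9.0,
                                 polar_radius=40.0)
    f = rng.normal(size=50) * 5 + mesh.vertices[:, 2]
    got = mean_spatial_gradient(mesh, f, radius=6.0)
    grads = []
    for i in range(50):
        d = np.linalg.norm(mesh.vertices - mesh.vertices[i], axis=1)
        idx = np.flatnonzero(d <= 6.0)
        if len(idx) < 3:
            continue
        Q = mesh.vertices[idx] - mesh.vertices[idx].mean(axis=0)
        v = f[idx] - f[idx].mean()
        U, s, Vt = np.linalg.svd(Q, full_matrices=False)
        keep = s > 0.05 * s[0]
        g = Vt[keep].T @ ((U[:, keep].T @ v) / s[keep])
        grads.append(np.linalg.norm(g))
    assert got == pytest.approx(np.mean(grads), abs=1e-12)


def test_gradient_invariances(mesh200, rng):
    f = mesh200.vertices[:, 2] * 0.5 + rng.normal(size=200)
    g0 = mean_spatial_gradient(mesh200, f)
    # adding a constant changes nothing
    assert mean_spatial_gradient(mesh200, f + 100.0) == pytest.approx(g0)
    # rigid motion of the mesh changes nothing
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = EpicardialMesh(mesh200.vertices @ R.T + np.array([5., -3, 11]),
                           mesh200.faces)
    assert mean_spatial_gradient(moved, f) == pytest.approx(g0, abs=1e-9)


# ---------------------------------------------------------------------------
# heart metrics assembly and rate correction
# ---------------------------------------------------------------------------

def test_heart_metrics_bookkeeping(mesh200, rng):
    from epicardio.markers import NodeMarkers

    lat = mesh200.vertices[:, 2] * 0.3 + 60
    markers = [NodeMarkers(i, lat[i], lat[i] + 230, 230.0) for i in range(200)]
    hm = heart_metrics(markers, mesh200, subject_id="s", phase="peak")
    assert hm.nodes_used == 200 and hm.nodes_rejected == 0
    # whole-heart mean ARI equals mean LRT - mean LAT (linearity)
    assert hm.ari_mean == pytest.approx(
        np.mean([m.lrt_ms for m in markers]) - np.mean([m.lat_ms for m in markers]))
    # excluding k nodes changes the bookkeeping by exactly k
    k = 7
    for i in rng.choice(200, k, replace=False):
        markers[i].accepted = False
    hm2 = heart_metrics(markers, mesh200)
    assert hm2.nodes_used == 200 - k and hm2.nodes_rejected == k


def test_identical_markers_zero_dispersion_and_gradient(mesh200):
    from epicardio.markers import NodeMarkers

    markers = [NodeMarkers(i, 50.0, 280.0, 230.0) for i in range(200)]
    hm = heart_metrics(markers, mesh200)
    assert hm.at_disp == 0.0 and hm.ari_disp == 0.0
    assert hm.at_grad == pytest.approx(0.0, abs=1e-10)


def test_rate_correct_bazett():
    assert rate_correct(400.0, 1.0) == 400.0
    assert rate_correct(400.0, 0.64) == pytest.approx(500.0)
    vals = [rate_correct(400.0, rr) for rr in (1.0, 0.8, 0.6, 0.4)]
    assert np.all(np.diff(vals) > 0)
    with pytest.raises(ValueError):
        rate_correct(400.0, 0.0)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(-1e4, 1e4), min_size=10, max_size=200),
       st.floats(-100, 100), st.floats(0.01, 50))
def test_dispersion95_affine_equivariance(values, shift, scale):
    v = np.asarray(values)
    base = dispersion95(v)
    assert dispersion95(v + shift) == pytest.approx(base, abs=1e-6 * (1 + abs(shift)))
    assert dispersion95(v * scale) == pytest.approx(base * scale, rel=1e-9, abs=1e-9)
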