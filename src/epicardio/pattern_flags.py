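"""Rule-based detectors for the qualitative HCM map patterns.

The visual map-reading calls of the original study (late isolated
activation patches ringed by steep gradients, apically prolonged ARI,
apical or isolated T-wave inversion) are reduced to deterministic numeric
rules so that synthetic pattern injection can be verified.  All rule
parameters are declared stand-ins, exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .markers import GeometryError, mean_spatial_gradient
from .mesh_geometry import EpicardialMesh


@dataclass
class PatternReport:
    late_patch: bool = False
    apical_ari_prolongation: bool = False
    apical_t_inversion: bool = False
    isolated_t_patch: bool = False
    supporting_nodes: dict = field(default_factory=dict)

    def as_dict(self):
        return dict(late_patch=self.late_patch,
                    apical_ari_prolongation=self.apical_ari_prolongation,
                    apical_t_inversion=self.apical_t_inversion,
                    isolated_t_patch=self.isolated_t_patch)


def _components(mesh, node_mask):
    """Connected components of the masked nodes on the triangulation."""
    adj = mesh.vertex_adjacency()
    sub = adj[node_mask][:, node_mask]
    n, labels = connected_components(sub, directed=False)
    idx = np.flatnonzero(node_mask)
    return [idx[labels == k] for k in range(n)]


def local_contrast(mesh: EpicardialMesh, values, r_in=4.0, r_out=16.0):
    """Per-node excess over the median of its surrounding annulus.

    A node embedded in a smooth trend has near-zero excess (the annulus
    median tracks the local level); a node on an isolated bump exceeds its
    surroundings.  Nodes with fewer than 3 annulus neighbors or NaN values
    get NaN.
    """
    values = np.asarray(values, float)
    tree = mesh.tree
    out = np.full(mesh.n_nodes, np.nan)
    for i in range(mesh.n_nodes):
        if not np.isfinite(values[i]):
            continue
        ids = tree.query_ball_point(mesh.vertices[i], r_out)
        d = np.linalg.norm(mesh.vertices[ids] - mesh.vertices[i], axis=1)
        ring = [j for j, dj in zip(ids, d) if r_in <= dj and np.isfinite(values[j])]
        if len(ring) >= 3:
            out[i] = values[i] - np.median(values[ring])
    return out


def detect_patterns(lat, ari, polarity, mesh: EpicardialMesh,
                    min_patch_nodes=4, late_contrast_ms=4.0,
                    annulus=(10.0, 24.0), apical_ari_ms=10.0,
                    apical_frac=0.5, radius=5.0) -> PatternReport:
    """Evaluate the four map-pattern rules on one subject's marker maps.

    * late patch: a connected set of >= ``min_patch_nodes`` nodes each
      activating at least ``late_contrast_ms`` later than the median of
      its surrounding ``annulus`` (mm) ring (an *isolated* late region: a
      node on a smooth activation trend has near-zero local excess, a node
      on a bump is surrounded by steep change by construction);
    * apical ARI prolongation: apical-third mean ARI exceeds the basal
      third by >= ``apical_ari_ms``;
    * apical T inversion: > ``apical_frac`` of apical-third nodes have
      negative T waves;
    * isolated T patch: a connected negative-T set of >= ``min_patch_nodes``
      nodes surrounded by positive-T nodes.

    NaNs (rejected nodes) are ignored.  Deterministic given the inputs and
    invariant to node ordering.
    """
    lat = np.asarray(lat, float)
    ari = np.asarray(ari, float)
    polarity = np.asarray(polarity)
    if mesh.base_centroid is None:
        raise GeometryError("mesh landmarks required for pattern rules")
    u = getattr(mesh, "arc_coordinate", None)
    if u is None:
        u = mesh.apicobasal_coordinate()
    report = PatternReport()
    ok_lat = np.isfinite(lat)

    # --- late activation patch ------------------------------------------
    if ok_lat.sum() >= 10:
        excess = local_contrast(mesh, lat, *annulus)
        late_mask = np.isfinite(excess) & (excess >= late_contrast_ms)
        if late_mask.sum() >= min_patch_nodes:
            for comp in _components(mesh, late_mask):
                if len(comp) >= min_patch_nodes:
                    report.late_patch = True
                    report.supporting_nodes["late_patch"] = comp.tolist()
                    break

    # --- apical ARI prolongation ----------------------------------------
    apical = (u < 1 / 3) & np.isfinite(ari)
    basal = (u > 2 / 3) & np.isfinite(ari)
    if apical.any() and basal.any():
        if ari[apical].mean() - ari[basal].mean() >= apical_ari_ms:
            report.apical_ari_prolongation = True
            report.supporting_nodes["apical_ari"] = np.flatnonzero(apical).tolist()

    # --- apical T inversion ---------------------------------------------
    apical_all = u < 1 / 3
    if apical_all.any():
        neg_frac = (polarity[apical_all] < 0).mean()
        if neg_frac > apical_frac:
            report.apical_t_inversion = True

    # --- isolated negative-T patch --------------------------------------
    neg_mask = polarity < 0
    if min_patch_nodes <= neg_mask.sum() < mesh.n_nodes:
        adj = mesh.vertex_adjacency()
        for comp in _components(mesh, neg_mask):
            if len(comp) < min_patch_nodes:
                continue
            ring = np.setdiff1d(np.unique(adj[comp].indices), comp)
            if len(ring) and np.all(polarity[ring] > 0):
                report.isolated_t_patch = True
                report.supporting_nodes["isolated_t"] = comp.tolist()
                break
    return report
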