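"""Assembly of attributed vascular graphs from B-scans.

Every graph is complete: each pair of vessel nodes is connected, weighted by
the inverse in-plane distance between the vessels.  Nearby vessels couple
strongly (they are more likely to share correlated vascular features),
distant ones weakly.  Depth never enters the distances.

A single-B-scan graph has exactly five nodes; merged graphs over N
consecutive B-scans concatenate the per-B-scan node sets (N*5 nodes) and
recompute the complete edge set with 2-D Euclidean inverse distances in the
(x, y) plane.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import rf_features, segmentation
from .types import (
    BScan,
    CScan,
    N_FEATURES,
    RFGate,
    VascularGraph,
    VesselComponent,
    VesselNode,
)

NODES_PER_BSCAN = 5
#: Gate padding (samples) around a component's depth extent.
GATE_PAD = 16


def edge_weight(node_i: VesselNode, node_j: VesselNode, pitch_x: float = 3e-6) -> float:
    """Inverse in-plane distance between two nodes, in 1/m.

    The distance is Euclidean in (x, y); within one B-scan this reduces to
    the lateral separation |x_i - x_j|.  Co-located nodes are clamped to
    one pixel pitch so the weight stays finite.
    """
    if node_i is node_j:
        raise ValueError("self-loops are not allowed (i must differ from j)")
    dx = node_i.position[0] - node_j.position[0]
    dy = node_i.position[1] - node_j.position[1]
    dist = float(np.hypot(dx, dy))
    return 1.0 / max(dist, pitch_x)


def _weight_matrix(positions: np.ndarray, pitch_x: float) -> np.ndarray:
    """Symmetric inverse-distance weight matrix with zero diagonal."""
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    w = 1.0 / np.maximum(dist, pitch_x)
    np.fill_diagonal(w, 0.0)
    return w


def build_bscan_graph(
    bundle: Sequence[VesselNode],
    y_index: int,
    pitch_x: float = 3e-6,
    label: Optional[int] = None,
    specimen_id: str = "",
) -> VascularGraph:
    """Complete graph on exactly five node slots of one B-scan."""
    if len(bundle) != NODES_PER_BSCAN:
        raise ValueError(
            f"a B-scan graph requires exactly {NODES_PER_BSCAN} node slots, "
            f"got {len(bundle)}"
        )
    feats = np.stack([n.features for n in bundle])
    pos = np.array([n.position for n in bundle], dtype=float)
    valid = np.array([n.valid for n in bundle], dtype=bool)
    return VascularGraph(
        node_features=feats,
        positions=pos,
        valid=valid,
        weights=_weight_matrix(pos, pitch_x),
        window=(y_index, 1),
        label=label,
        specimen_id=specimen_id,
        provenance=[n.provenance for n in bundle],
    )


def merge_graphs(graphs: Sequence[VascularGraph], pitch_x: float = 3e-6) -> VascularGraph:
    """Merge N consecutive single-B-scan graphs into one classifier input.

    Node lists are concatenated and the complete edge set is recomputed
    with 2-D Euclidean inverse-distance weights, so vessels in different
    B-scans are coupled according to their true in-plane separation.
    """
    if len(graphs) == 0:
        raise ValueError("cannot merge an empty graph list")
    y_starts = [g.window[0] for g in graphs]
    if any(b - a != 1 for a, b in zip(y_starts, y_starts[1:])):
        raise ValueError(f"B-scan indices must be consecutive, got {y_starts}")
    specimens = {g.specimen_id for g in graphs}
    if len(specimens) > 1:
        raise ValueError(f"cannot merge graphs from different specimens: {specimens}")

    feats = np.concatenate([g.node_features for g in graphs])
    pos = np.concatenate([g.positions for g in graphs])
    valid = np.concatenate([g.valid for g in graphs])
    prov = sum((g.provenance or [("", -1, -1)] * g.n_nodes for g in graphs), [])
    return VascularGraph(
        node_features=feats,
        positions=pos,
        valid=valid,
        weights=_weight_matrix(pos, pitch_x),
        window=(y_starts[0], len(graphs)),
        label=graphs[0].label,
        specimen_id=graphs[0].specimen_id,
        provenance=prov,
    )


def _component_gate(bscan: BScan, component: VesselComponent) -> RFGate:
    """Depth gate of the component on its centroid A-line."""
    col = int(round(component.centroid[1]))
    col = min(max(col, 0), bscan.n_alines - 1)
    rows = component.pixel_set[:, 0]
    lo = max(int(rows.min()) - GATE_PAD, 0)
    hi = min(int(rows.max()) + GATE_PAD + 1, bscan.rf.shape[0])
    if hi - lo < 16:  # widen degenerate gates to the minimum length
        hi = min(lo + 16, bscan.rf.shape[0])
        lo = max(hi - 16, 0)
    return RFGate(bscan.rf[lo:hi, col], fs=bscan.fs, t0=lo / bscan.fs)


def extract_bscan_nodes(
    bscan: BScan,
    prev_components: Sequence[VesselComponent] = (),
    next_components: Sequence[VesselComponent] = (),
    components: Optional[Sequence[VesselComponent]] = None,
    dynamic_range_db: float = segmentation.DEFAULT_DYNAMIC_RANGE_DB,
    band: Tuple[float, float] = rf_features.DEFAULT_BAND,
    specimen_id: str = "",
    span: int = 1,
    noise_floor: Optional[float] = None,
) -> List[VesselNode]:
    """Five vessel nodes (real or padding) for one B-scan.

    Runs detection (unless ``components`` is supplied), keeps the five
    largest components, and computes the 7-feature vector for each:
    (t1, t2, f_c, slope, intercept, theta, d).  Missing temporal features
    are NaN; padding slots sit at the B-scan center with zero features.
    """
    if noise_floor is None:
        noise_floor = rf_features.estimate_noise_floor(bscan.rf)
    if components is None:
        mask = segmentation.threshold_mask(bscan, dynamic_range_db, noise_floor)
        components = segmentation.extract_components(mask, bscan.pitch_x)
    slots = segmentation.select_top_k(components, NODES_PER_BSCAN)

    y_pos = bscan.y_index * bscan.pitch_y
    nodes: List[VesselNode] = []
    for slot_idx, comp in enumerate(slots):
        prov = (specimen_id, bscan.y_index, slot_idx)
        if comp is None:
            nodes.append(VesselNode.padding((bscan.width / 2, y_pos), prov))
            continue
        geom = segmentation.directionality(
            comp, prev_components, next_components,
            pitch_x=bscan.pitch_x, pitch_y=bscan.pitch_y, span=span,
        )
        gate = _component_gate(bscan, comp)
        temporal = rf_features.rise_times(gate, noise_floor)
        try:
            spectral = rf_features.spectral_features(gate, band=band)
            f_c, sl, ic = spectral.f_c, spectral.slope, spectral.intercept
        except ValueError:
            f_c = sl = ic = np.nan
        nodes.append(
            VesselNode(
                features=np.array(
                    [temporal.t1, temporal.t2, f_c, sl, ic, geom.theta, geom.diameter_d]
                ),
                position=(comp.lateral_position_x, y_pos),
                valid=True,
                provenance=prov,
            )
        )
    return nodes


def build_cscan_graphs(
    cscan: CScan,
    dynamic_range_db: float = segmentation.DEFAULT_DYNAMIC_RANGE_DB,
    band: Tuple[float, float] = rf_features.DEFAULT_BAND,
    span: int = 1,
) -> List[VascularGraph]:
    """One single-B-scan graph per B-scan of a C-scan."""
    comps_per_bscan = []
    noise_floors = []
    for b in cscan.bscans:
        nf = rf_features.estimate_noise_floor(b.rf)
        noise_floors.append(nf)
        mask = segmentation.threshold_mask(b, dynamic_range_db, nf)
        comps_per_bscan.append(segmentation.extract_components(mask, b.pitch_x))

    graphs = []
    n = len(cscan.bscans)
    for i, b in enumerate(cscan.bscans):
        prev_c = comps_per_bscan[i - span] if i - span >= 0 else ()
        next_c = comps_per_bscan[i + span] if i + span < n else ()
        nodes = extract_bscan_nodes(
            b, prev_c, next_c, components=comps_per_bscan[i],
            dynamic_range_db=dynamic_range_db, band=band,
            specimen_id=cscan.specimen_id, span=span,
            noise_floor=noise_floors[i],
        )
        graphs.append(
            build_bscan_graph(nodes, b.y_index, b.pitch_x, cscan.label, cscan.specimen_id)
        )
    return graphs


class GraphFeatureScaler(BaseEstimator, TransformerMixin):
    """Z-scores the seven node features over the valid nodes of a training set.

    Statistics are computed from the *training* graphs only (NaN-aware, so
    missing temporal features do not bias them) and reused verbatim on
    held-out graphs.  After scaling, padding nodes and missing features are
    set to 0, i.e. to the training mean.  Zero-variance features get scale
    1 with a warning.
    """

    def fit(self, X: Sequence[VascularGraph], y=None) -> "GraphFeatureScaler":
        if len(X) < 1:
            raise ValueError("need at least one graph to fit the scaler")
        rows = [g.node_features[g.valid] for g in X if g.valid.any()]
        if not rows:
            raise ValueError("no valid nodes in the training graphs")
        data = np.concatenate(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.mean_ = np.nan_to_num(np.nanmean(data, axis=0))
            scale = np.nan_to_num(np.nanstd(data, axis=0))
        if np.any(scale == 0):
            warnings.warn(
                "zero-variance feature(s) encountered; forcing scale to 1",
                RuntimeWarning,
            )
            scale = np.where(scale == 0, 1.0, scale)
        self.scale_ = scale
        self.n_features_in_ = N_FEATURES
        return self

    def transform(self, X: Sequence[VascularGraph]) -> List[VascularGraph]:
        if not hasattr(self, "mean_"):
            raise RuntimeError("GraphFeatureScaler must be fitted before transform")
        out = []
        for g in X:
            feats = (g.node_features - self.mean_) / self.scale_
            feats = np.nan_to_num(feats, nan=0.0)
            feats[~g.valid] = 0.0
            out.append(
                VascularGraph(
                    node_features=feats,
                    positions=g.positions,
                    valid=g.valid,
                    weights=g.weights,
                    window=g.window,
                    label=g.label,
                    specimen_id=g.specimen_id,
                    provenance=g.provenance,
                )
            )
        return out


def standardize_features(
    graphs: Sequence[VascularGraph],
) -> Tuple[List[VascularGraph], GraphFeatureScaler]:
    """Fit a scaler on ``graphs`` and return (transformed graphs, scaler)."""
    scaler = GraphFeatureScaler().fit(graphs)
    return scaler.transform(graphs), scaler
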