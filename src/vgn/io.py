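"""File formats: HDF5 RF volumes, GraphML/CSV graphs, manifests, checkpoints.

Every artifact written by the pipeline records the seed and a hash of the
configuration that produced it, so runs can be traced and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .graph_builder import GraphFeatureScaler
from .model import VGNClassifier, VGNConfig
from .types import BScan, FEATURE_NAMES, VascularGraph

REQUIRED_VOLUME_ATTRS = ("fs", "pitch_x", "pitch_y")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance(config: dict, seed: int) -> dict:
    return {"seed": int(seed), "config_hash": config_hash(config), "config": config}


# ------------------------------------------------------------------ volumes
def write_rf_volume(
    path, bscans: Sequence[BScan], center_frequency: Optional[float] = None
) -> None:
    """Write a C-scan volume: dataset ``rf`` of shape depth x A-lines x B-scans."""
    rf = np.stack([b.rf for b in bscans], axis=-1)
    first = bscans[0]
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("rf", data=rf)
        dset.attrs["fs"] = first.fs
        dset.attrs["pitch_x"] = first.pitch_x
        dset.attrs["pitch_y"] = first.pitch_y
        if center_frequency is not None:
            dset.attrs["center_frequency"] = center_frequency


def read_rf_volume(path) -> List[BScan]:
    """Load and validate a C-scan volume written by :func:`write_rf_volume`."""
    with h5py.File(path, "r") as f:
        if "rf" not in f:
            raise ValueError(f"{path}: missing dataset 'rf'")
        dset = f["rf"]
        for attr in REQUIRED_VOLUME_ATTRS:
            if attr not in dset.attrs:
                raise ValueError(f"{path}: missing required attribute '{attr}'")
        if dset.ndim != 3:
            raise ValueError(f"{path}: dataset 'rf' must be 3-D, got shape {dset.shape}")
        rf = dset[()]
        fs = float(dset.attrs["fs"])
        px = float(dset.attrs["pitch_x"])
        py = float(dset.attrs["pitch_y"])
    return [
        BScan(rf=rf[:, :, k], y_index=k, fs=fs, pitch_x=px, pitch_y=py)
        for k in range(rf.shape[2])
    ]


# ------------------------------------------------------------------- graphs
def graph_to_networkx(graph: VascularGraph) -> nx.Graph:
    g = nx.Graph(
        window_start=int(graph.window[0]),
        window_n=int(graph.window[1]),
        label=-1 if graph.label is None else int(graph.label),
        specimen_id=graph.specimen_id,
    )
    for i in range(graph.n_nodes):
        attrs = {name: float(graph.node_features[i, j]) for j, name in enumerate(FEATURE_NAMES)}
        g.add_node(
            i,
            x=float(graph.positions[i, 0]),
            y=float(graph.positions[i, 1]),
            valid=bool(graph.valid[i]),
            **attrs,
        )
    iu, ju = np.triu_indices(graph.n_nodes, k=1)
    g.add_weighted_edges_from(
        (int(i), int(j), float(graph.weights[i, j])) for i, j in zip(iu, ju)
    )
    return g


def networkx_to_graph(g: nx.Graph) -> VascularGraph:
    n = g.number_of_nodes()
    feats = np.zeros((n, len(FEATURE_NAMES)))
    pos = np.zeros((n, 2))
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        node = g.nodes[i]
        feats[i] = [node[name] for name in FEATURE_NAMES]
        pos[i] = (node["x"], node["y"])
        valid[i] = bool(node["valid"])
    weights = np.zeros((n, n))
    for i, j, data in g.edges(data=True):
        weights[i, j] = weights[j, i] = data["weight"]
    label = g.graph.get("label", -1)
    return VascularGraph(
        node_features=feats,
        positions=pos,
        valid=valid,
        weights=weights,
        window=(int(g.graph.get("window_start", 0)), int(g.graph.get("window_n", 1))),
        label=None if label == -1 else int(label),
        specimen_id=g.graph.get("specimen_id", ""),
    )


def write_graphml(graph: VascularGraph, path) -> None:
    nx.write_graphml(graph_to_networkx(graph), path)


def read_graphml(path) -> VascularGraph:
    g = nx.read_graphml(path, node_type=int)
    return networkx_to_graph(g)


def graph_node_table(graphs: Sequence[VascularGraph]) -> pd.DataFrame:
    """One row per node: provenance, features, validity."""
    rows = []
    for g in graphs:
        prov = g.provenance or [("", -1, -1)] * g.n_nodes
        for i in range(g.n_nodes):
            sid, b_idx, slot = prov[i]
            row = {"specimen_id": sid or g.specimen_id, "bscan_index": b_idx, "slot": slot,
                   "valid": bool(g.valid[i])}
            row.update({name: g.node_features[i, j] for j, name in enumerate(FEATURE_NAMES)})
            rows.append(row)
    return pd.DataFrame(rows)


def save_mask_png(path, mask: np.ndarray) -> None:
    """Write a binary mask or label map as a PNG image."""
    from matplotlib import image as mpimg

    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    mpimg.imsave(path, arr, cmap="gray")


def write_roc_csv(path, rocs: Dict[int, tuple]) -> None:
    """Per-class ROC curves as tidy CSV columns (class, fpr, tpr)."""
    rows = []
    for cls, (fpr, tpr) in sorted(rocs.items()):
        for f, t in zip(fpr, tpr):
            rows.append({"class": cls, "fpr": float(f), "tpr": float(t)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(path, entries: Dict[str, dict], seed: int, config: dict) -> None:
    payload = {"provenance": provenance(config, seed), "specimens": entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


# -------------------------------------------------------------- checkpoints
def save_checkpoint(path, clf: VGNClassifier, scaler: GraphFeatureScaler,
                    extra: Optional[dict] = None) -> None:
    """Model parameters + config + feature-standardization statistics."""
    config = {k: v for k, v in clf.get_params().items() if k != "class_weights"}
    arrays = {f"param_{i}": arr for i, arr in enumerate(clf.network_.state())}
    meta = {
        "config": config,
        "class_weights": np.asarray(clf.class_weights_).tolist(),
        "extra": extra or {},
    }
    np.savez(
        path,
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
        meta=json.dumps(meta, default=str),
        **arrays,
    )


def load_checkpoint(path):
    """Returns (classifier, scaler) ready for inference."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = meta["config"]
        config["milestones"] = tuple(config.get("milestones", (100, 150)))
        clf = VGNClassifier(**config)
        clf.class_weights_ = np.asarray(meta["class_weights"])
        clf.classes_ = np.arange(clf.n_classes)
        net = clf._build_network()
        n_params = len(net.parameters())
        net.load_state([data[f"param_{i}"] for i in range(n_params)])
        clf.network_ = net
        scaler = GraphFeatureScaler()
        scaler.mean_ = data["scaler_mean"]
        scaler.scale_ = data["scaler_scale"]
        scaler.n_features_in_ = scaler.mean_.size
    return clf, scaler


def default_config_dict(config: Optional[VGNConfig] = None) -> dict:
    cfg = asdict(config or VGNConfig())
    cfg.pop("class_weights", None)
    return cfg
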