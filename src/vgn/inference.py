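"""Sliding-window C-scan classification and color-wheel prediction maps.

A C-scan of L B-scans yields L - N + 1 merged vascular graphs through a
stride-1 sliding window of N consecutive B-scans.  Each window is scored
independently; the per-window score vectors are color-coded onto the
window's center B-scan through a two-dimensional color wheel, and the
specimen-level prediction is the majority vote over all windows.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .graph_builder import build_cscan_graphs, merge_graphs
from .types import CScan, PredictionMap, VascularGraph

DEFAULT_WINDOW = 41


def sliding_window_graphs(
    cscan: CScan,
    window: int = DEFAULT_WINDOW,
    step: int = 1,
    bscan_graphs: Optional[Sequence[VascularGraph]] = None,
) -> List[VascularGraph]:
    """Merged graphs for every window position along the C-scan.

    Window w covers B-scans [w, w + N); its center index is w + (N-1)/2.
    With step 1 this produces exactly L - N + 1 graphs.
    """
    L = len(cscan)
    if L < window:
        raise ValueError(f"C-scan has {L} B-scans but the window needs {window}")
    if bscan_graphs is None:
        bscan_graphs = build_cscan_graphs(cscan)
    pitch_x = cscan.bscans[0].pitch_x
    return [
        merge_graphs(bscan_graphs[w:w + window], pitch_x=pitch_x)
        for w in range(0, L - window + 1, step)
    ]


def majority_vote(scores: Sequence[np.ndarray]) -> int:
    """Class with the most per-window argmax wins.

    Ties are broken toward the class with the larger mean score over the
    tied classes.  Invariant to the ordering of the score list.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.size == 0:
        raise ValueError("majority_vote requires at least one score vector")
    votes = np.bincount(scores.argmax(axis=1), minlength=scores.shape[1])
    top = votes.max()
    tied = np.flatnonzero(votes == top)
    if tied.size == 1:
        return int(tied[0])
    mean_scores = scores.mean(axis=0)
    return int(tied[np.argmax(mean_scores[tied])])


def color_wheel(scores: np.ndarray, anchors: Optional[np.ndarray] = None) -> np.ndarray:
    """Map a 5-class score vector to an RGB triple via a 2-D color wheel.

    Each class k sits at anchor angle 2*pi*k/5 on the wheel; the score
    vector maps to the point p = sum_k scores_k * (cos, sin)(anchor_k).
    Hue is the angle of p, saturation its length (<= 1, achromatic for the
    uniform vector), and value the maximum score, so low-confidence
    windows render dark.
    """
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[-1]
    if anchors is None:
        anchors = 2 * np.pi * np.arange(k) / k
    px = scores @ np.cos(anchors)
    py = scores @ np.sin(anchors)
    hue = (np.arctan2(py, px) / (2 * np.pi)) % 1.0
    sat = np.clip(np.hypot(px, py), 0.0, 1.0)
    val = scores.max(axis=-1)
    hsv = np.stack([hue, sat, val], axis=-1)
    return hsv_to_rgb(hsv)


def render_map(
    cscan: CScan,
    clf,
    scaler,
    window: int = DEFAULT_WINDOW,
    bscan_graphs: Optional[Sequence[VascularGraph]] = None,
) -> PredictionMap:
    """Classify every window of a C-scan and render the prediction map.

    Each center B-scan column is colored by the color wheel; the first and
    last (N-1)/2 columns have no centered window and stay black.  The
    specimen-level vote aggregates all window predictions.
    """
    graphs = sliding_window_graphs(cscan, window=window, bscan_graphs=bscan_graphs)
    scores = clf.predict_proba(scaler.transform(graphs))
    L = len(cscan)
    centers = np.arange(scores.shape[0]) + (window - 1) // 2

    rgb = np.zeros((L, 3))
    rgb[centers] = color_wheel(scores)
    return PredictionMap(
        positions=centers,
        scores=scores,
        rgb=rgb,
        vote=majority_vote(scores),
        specimen_id=cscan.specimen_id,
    )
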