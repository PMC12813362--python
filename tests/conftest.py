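"""Shared fixtures: synthetic gates, B-scans, and small graphs."""

from __future__ import annotations

import numpy as np
import pytest

from vgn.types import RFGate, VascularGraph, VesselNode


def gabor_gate(
    fs: float = 250e6,
    n: int = 256,
    f0: float = 25e6,
    center: float = 0.5e-6,
    sigma: float = 2e-8,
    amplitude: float = 1.0,
) -> RFGate:
    """A Gaussian-modulated sinusoid (Gabor pulse) gate."""
    t = np.arange(n) / fs
    samples = amplitude * np.exp(-((t - center) ** 2) / (2 * sigma**2)) * np.cos(
        2 * np.pi * f0 * (t - center)
    )
    return RFGate(samples=samples, fs=fs)


@pytest.fixture
def pulse_gate() -> RFGate:
    return gabor_gate()


def make_node(
    x: float, y: float = 0.0, features=None, valid: bool = True
) -> VesselNode:
    feats = np.arange(7, dtype=float) if features is None else np.asarray(features)
    return VesselNode(features=feats, position=(x, y), valid=valid)


def make_graph(
    positions: np.ndarray,
    features: np.ndarray = None,
    y_index: int = 0,
    label: int = 0,
    specimen_id: str = "s0",
    pitch_x: float = 3e-6,
) -> VascularGraph:
    """A complete graph with inverse-distance weights from raw positions."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if features is None:
        features = np.tile(np.arange(7, dtype=float), (n, 1))
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    w = 1.0 / np.maximum(dist, pitch_x)
    np.fill_diagonal(w, 0.0)
    return VascularGraph(
        node_features=np.asarray(features, dtype=float),
        positions=positions,
        valid=np.ones(n, dtype=bool),
        weights=w,
        window=(y_index, 1),
        label=label,
        specimen_id=specimen_id,
    )
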