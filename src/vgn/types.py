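"""Core data containers for the vascular-graph pipeline.

Coordinate conventions: x is the lateral (fast-scan) axis within a B-scan,
y is the slow C-scan axis, z is depth.  All positions are stored in meters,
indices are 0-based, and B-scan windows are half-open ``[start, start + N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Canonical class ordering used everywhere (labels, score vectors, votes).
CLASS_NAMES = ("normal", "benign_cystic", "benign_solid", "endometriosis", "malignant")
N_CLASSES = len(CLASS_NAMES)

#: Node feature order: (t1, t2, f_c, slope, intercept, theta, d).
FEATURE_NAMES = ("t1", "t2", "f_c", "slope", "intercept", "theta", "d")
N_FEATURES = len(FEATURE_NAMES)

MIN_GATE_SAMPLES = 16


@dataclass
class RFGate:
    """A gated segment of one RF A-line belonging to a single vessel.

    Parameters
    ----------
    samples : ndarray
        Real-valued RF samples (arbitrary units).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Gate start time in seconds, relative to the A-line trigger.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < MIN_GATE_SAMPLES:
            raise ValueError(
                f"RF gate must be a 1-D array of >= {MIN_GATE_SAMPLES} samples, "
                f"got shape {self.samples.shape}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class TemporalFeatures:
    """Rise times of a vessel echo, measured from the gate start.

    ``t1`` is the delay of the first RF peak above threshold, ``t2`` the
    delay of the envelope peak.  Missing features (no sample above the
    detection threshold) are NaN with ``valid`` False.
    """

    t1: float
    t2: float
    valid: bool = True


@dataclass(frozen=True)
class SpectralFeatures:
    """Band-limited spectral descriptors of a vessel echo.

    ``f_c`` is the power-weighted spectral centroid within the analysis
    band (Hz); ``slope`` and ``intercept`` parameterize the least-squares
    line through the power spectrum in dB versus frequency, the intercept
    evaluated at 0 Hz.
    """

    f_c: float
    slope: float
    intercept: float


@dataclass
class BScan:
    """One 2-D RF frame: depth samples x A-lines."""

    rf: np.ndarray
    y_index: int
    fs: float
    pitch_x: float = 3e-6
    pitch_y: float = 3e-6
    envelope: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=float)
        if self.rf.ndim != 2:
            raise ValueError(f"B-scan RF must be 2-D, got shape {self.rf.shape}")
        if self.envelope is None:
            from scipy.signal import hilbert

            self.envelope = np.abs(hilbert(self.rf, axis=0))
        else:
            self.envelope = np.asarray(self.envelope, dtype=float)
            if self.envelope.shape != self.rf.shape:
                raise ValueError("envelope shape must match rf shape")

    @property
    def n_alines(self) -> int:
        return self.rf.shape[1]

    @property
    def width(self) -> float:
        return self.n_alines * self.pitch_x


@dataclass
class VesselComponent:
    """One connected component on a B-scan envelope mask."""

    pixel_set: np.ndarray  # (n_pixels, 2) array of (depth, lateral) indices
    pixel_count: int
    centroid: tuple  # (z_bar, x_bar) in pixels
    observed_width_w: float  # lateral extent in meters
    lateral_position_x: float  # centroid x in meters

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("a vessel component must contain at least one pixel")


@dataclass(frozen=True)
class Geometry:
    """Local vessel direction and direction-corrected diameter.

    ``theta`` is the angle between the vessel axis and the C-scan (y) axis,
    measured in the x-y plane, in [0, pi/2).  ``diameter_d`` is
    ``observed_width_w * cos(theta)``.
    """

    theta: float
    diameter_d: float


@dataclass
class VesselNode:
    """A graph node: one vessel cross-section with its 7-feature vector."""

    features: np.ndarray  # (t1, t2, f_c, slope, intercept, theta, d)
    position: tuple  # (x, y) in meters
    valid: bool = True
    provenance: tuple = ("", -1, -1)  # (specimen id, B-scan index, node slot)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_FEATURES,):
            raise ValueError(
                f"node feature vector must have length {N_FEATURES}, "
                f"got shape {self.features.shape}"
            )

    @classmethod
    def padding(cls, position: tuple, provenance: tuple = ("", -1, -1)) -> "VesselNode":
        """A padding slot: zero features, flagged invalid."""
        return cls(np.zeros(N_FEATURES), position, valid=False, provenance=provenance)


@dataclass
class VascularGraph:
    """A fully connected, attributed, weighted vascular graph.

    Nodes are stored columnar for efficiency: ``node_features`` is
    (n, 7), ``positions`` (n, 2) in meters, ``valid`` (n,) boolean.
    ``weights`` is the symmetric (n, n) positive edge-weight matrix with
    zero diagonal; the graph is complete by construction.
    """

    node_features: np.ndarray
    positions: np.ndarray
    valid: np.ndarray
    weights: np.ndarray
    window: tuple = (0, 1)  # (first B-scan index, N)
    label: Optional[int] = None
    specimen_id: str = ""
    provenance: Optional[list] = None

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.n_nodes
        if self.node_features.shape != (n, N_FEATURES):
            raise ValueError("node_features must be (n_nodes, 7)")
        if self.positions.shape != (n, 2) or self.valid.shape != (n,):
            raise ValueError("positions must be (n, 2) and valid (n,)")
        if self.weights.shape != (n, n):
            raise ValueError("weights must be a square (n, n) matrix")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def edges(self) -> list:
        """Edge list as (i, j, weight) tuples over the upper triangle."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(iu, ju)]

    @property
    def nodes(self) -> list:
        prov = self.provenance or [("", -1, -1)] * self.n_nodes
        return [
            VesselNode(self.node_features[i], tuple(self.positions[i]),
                       bool(self.valid[i]), prov[i])
            for i in range(self.n_nodes)
        ]


@dataclass
class CScan:
    """An ordered stack of B-scans from one specimen."""

    bscans: Sequence[BScan]
    specimen_id: str = ""
    label: Optional[int] = None

    def __len__(self) -> int:
        return len(self.bscans)


@dataclass
class PredictionMap:
    """Sliding-window scores along a C-scan plus the rendered color map."""

    positions: np.ndarray  # center B-scan indices, (L - N + 1,)
    scores: np.ndarray  # (L - N + 1, 5) rows on the simplex
    rgb: np.ndarray  # (L, 3) per-B-scan colors; uncovered ends are black
    vote: int  # specimen-level majority-vote class
    specimen_id: str = ""


@dataclass
class PhantomSpec:
    """Class-conditioned parameters for one synthetic specimen.

    The phantom emulates superficial ovarian vasculature as seen by a
    raster-scanning photoacoustic microscope: vessels are tubes running
    along the slow (y) axis with lateral random-walk tortuosity, and each
    A-line records Gaussian-modulated echoes at the vessel depths.
    """

    label: int
    density: float = 15.0  # vessels per mm^2 of scanned surface
    diameter_um: float = 50.0  # log-normal median diameter
    diameter_sigma: float = 0.25  # log-sd of the diameter distribution
    tortuosity: float = 0.1  # direction-change sd per B-scan step (rad)
    orientation_sd: float = 0.3  # sd of the base heading angle (rad)
    n_bscans: int = 45
    noise_sd: float = 0.01
    seed: int = 0
    amplitude: float = 1.0
    n_alines: int = 1000
    n_depth: int = 256
    fs: float = 250e6
    pitch_x: float = 3e-6
    pitch_y: float = 3e-6
    f_center: float = 25e6
    depth_offset: float = 0.0  # per-specimen compression offset (m)


@dataclass
class VesselTruth:
    """Ground truth for one rendered phantom vessel."""

    centerline: np.ndarray  # (L, 3) of (x, y, z) per B-scan crossing
    diameter: float  # meters
    theta: np.ndarray  # (L,) true local angle per B-scan crossing (rad)
    depth: float  # nominal depth (m)


@dataclass
class GroundTruth:
    vessels: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.vessels)
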