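"""Class-conditioned synthetic vascular phantoms with known ground truth.

Each phantom emulates the superficial vasculature of one ex vivo specimen
as seen by a raster-scanning photoacoustic microscope: vessels are tubes
running predominantly along the slow (y) axis, with a lateral random walk
controlling tortuosity, log-normal diameters, and a class-dependent
density.  Every A-line records a Gaussian-modulated echo at the transducer
center frequency (25 MHz) for each vessel it intersects, with amplitude
proportional to the acoustic chord length through the vessel, plus white
Gaussian noise.

The echo model is a single-scattering Gabor-pulse convolution, not a full
photoacoustic wave simulation: it is deliberately simple but exercises
every feature extractor (rise times, spectral fits, width, direction).
Specimen-to-specimen compression against the imaging window is emulated
by a random per-specimen depth offset, which downstream processing must be
(and is) insensitive to, since depth never enters the graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .types import BScan, CLASS_NAMES, CScan, GroundTruth, PhantomSpec, VesselTruth

SPEED_OF_SOUND = 1500.0  # m/s, soft tissue
#: -6 dB band of 15-35 MHz around 25 MHz -> Gaussian spectral sd in Hz.
PULSE_SIGMA_F = 10e6 / np.sqrt(2 * np.log(2))
PULSE_SIGMA_T = 1.0 / (2 * np.pi * PULSE_SIGMA_F)
#: Chord length that maps to unit echo amplitude.
REFERENCE_CHORD = 50e-6
MAX_VESSELS_WARN = 50

_VESSEL_DEPTH_RANGE = (0.35e-3, 0.9e-3)  # m, nominal vessel depth band
_MAX_HEADING = 1.2  # rad, keeps tan() bounded


def _sample_vessels(spec: PhantomSpec, rng: np.random.Generator) -> List[dict]:
    width = spec.n_alines * spec.pitch_x
    length = spec.n_bscans * spec.pitch_y
    area_mm2 = (width * 1e3) * (length * 1e3)
    n_vessels = int(rng.poisson(spec.density * area_mm2))
    if n_vessels == 0 and spec.density > 0:
        # a specimen with no vasculature at all cannot represent its class;
        # a scanning protocol would re-site the probe, so guarantee one vessel
        n_vessels = 1
    if n_vessels > MAX_VESSELS_WARN:
        warnings.warn(
            f"phantom density yields {n_vessels} vessels (> {MAX_VESSELS_WARN}); "
            "B-scans will be crowded",
            RuntimeWarning,
        )
    vessels = []
    for _ in range(n_vessels):
        diameter = spec.diameter_um * 1e-6 * np.exp(rng.normal(0.0, spec.diameter_sigma))
        base_heading = rng.normal(0.0, spec.orientation_sd)
        steps = rng.normal(0.0, spec.tortuosity, size=spec.n_bscans)
        headings = np.clip(base_heading + np.cumsum(steps), -_MAX_HEADING, _MAX_HEADING)
        x = np.empty(spec.n_bscans)
        x[0] = rng.uniform(0.0, width)
        for k in range(1, spec.n_bscans):
            x[k] = x[k - 1] + np.tan(headings[k - 1]) * spec.pitch_y
        z = rng.uniform(*_VESSEL_DEPTH_RANGE) + spec.depth_offset
        amp = spec.amplitude * np.exp(rng.normal(0.0, 0.1))
        vessels.append({"x": x, "z": z, "diameter": diameter, "amp": amp})
    return vessels


def _true_angles(x: np.ndarray, pitch_y: float) -> np.ndarray:
    """Local in-plane angle per B-scan crossing, centered differences."""
    theta = np.empty_like(x)
    theta[1:-1] = np.arctan(np.abs(x[2:] - x[:-2]) / (2 * pitch_y))
    theta[0] = np.arctan(np.abs(x[1] - x[0]) / pitch_y) if x.size > 1 else 0.0
    theta[-1] = np.arctan(np.abs(x[-1] - x[-2]) / pitch_y) if x.size > 1 else 0.0
    return theta


def generate_phantom(spec: PhantomSpec) -> Tuple[List[BScan], GroundTruth]:
    """Render one synthetic RF volume and its vessel-level ground truth.

    Deterministic given ``spec.seed``: the same spec always produces a
    bitwise-identical volume.
    """
    rng = np.random.default_rng(spec.seed)
    vessels = _sample_vessels(spec, rng)
    truth = GroundTruth(
        vessels=[
            VesselTruth(
                centerline=np.column_stack(
                    [v["x"], np.arange(spec.n_bscans) * spec.pitch_y,
                     np.full(spec.n_bscans, v["z"])]
                ),
                diameter=float(v["diameter"]),
                theta=_true_angles(v["x"], spec.pitch_y),
                depth=float(v["z"]),
            )
            for v in vessels
        ]
    )
    return _render_volume(spec, vessels, truth, rng), truth


def _render_volume(
    spec: PhantomSpec,
    vessels: List[dict],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> List[BScan]:
    t = np.arange(spec.n_depth) / spec.fs
    x_axis = np.arange(spec.n_alines) * spec.pitch_x
    omega = 2 * np.pi * spec.f_center

    bscans: List[BScan] = []
    for k in range(spec.n_bscans):
        rf = spec.noise_sd * rng.standard_normal(
            (spec.n_depth, spec.n_alines), dtype=np.float32
        ).astype(np.float64)
        for v, vt in zip(vessels, truth.vessels):
            r = v["diameter"] / 2
            theta_k = vt.theta[k]
            cos_t = np.cos(theta_k)
            half_extent = r / cos_t
            xc = v["x"][k]
            cols = np.flatnonzero(np.abs(x_axis - xc) < half_extent)
            if cols.size == 0:
                continue
            offset = (x_axis[cols] - xc) * cos_t
            chord = 2.0 * np.sqrt(np.maximum(r**2 - offset**2, 0.0))
            amp = v["amp"] * chord / REFERENCE_CHORD
            sigma = PULSE_SIGMA_T + chord / (2 * SPEED_OF_SOUND)
            tc = v["z"] / SPEED_OF_SOUND
            dt = t[:, None] - tc
            pulse = np.exp(-(dt**2) / (2 * sigma[None, :] ** 2)) * np.cos(omega * dt)
            rf[:, cols] += amp[None, :] * pulse
        bscans.append(
            BScan(rf=rf, y_index=k, fs=spec.fs, pitch_x=spec.pitch_x, pitch_y=spec.pitch_y)
        )
    return bscans


def render_cylinder(
    diameter: float,
    theta: float,
    n_bscans: int = 5,
    x0: Optional[float] = None,
    depth: float = 0.6e-3,
    amplitude: float = 1.0,
    noise_sd: float = 0.005,
    n_alines: int = 400,
    seed: int = 0,
) -> Tuple[List[BScan], VesselTruth]:
    """A single straight cylinder of known diameter and in-plane tilt.

    The controlled counterpart of :func:`generate_phantom`, used to verify
    that segmentation recovers the width, direction angle, and corrected
    diameter of an ideal vessel.
    """
    spec = PhantomSpec(label=0, n_bscans=n_bscans, noise_sd=noise_sd,
                       n_alines=n_alines, amplitude=amplitude)
    if x0 is None:
        x0 = n_alines * spec.pitch_x / 2
    x = x0 + np.tan(theta) * np.arange(n_bscans) * spec.pitch_y
    vessel = {"x": x, "z": depth, "diameter": diameter, "amp": amplitude}
    vt = VesselTruth(
        centerline=np.column_stack(
            [x, np.arange(n_bscans) * spec.pitch_y, np.full(n_bscans, depth)]
        ),
        diameter=diameter,
        theta=np.full(n_bscans, abs(theta)),
        depth=depth,
    )
    rng = np.random.default_rng(seed)
    bscans = _render_volume(spec, [vessel], GroundTruth(vessels=[vt]), rng)
    return bscans, vt


def default_templates() -> Dict[str, PhantomSpec]:
    """Per-class phantom templates.

    The ordering is qualitative: normal vasculature is the thinnest and
    sparsest with near-straight vessels; malignant the densest, largest,
    most tortuous and strongest-absorbing, with the benign and
    endometriotic categories in between.
    """
    params = {
        "normal": dict(density=8, diameter_um=25, diameter_sigma=0.15,
                       tortuosity=0.05, orientation_sd=0.15, amplitude=0.8),
        "benign_cystic": dict(density=12, diameter_um=90, diameter_sigma=0.20,
                              tortuosity=0.08, orientation_sd=0.25, amplitude=1.0),
        "benign_solid": dict(density=18, diameter_um=35, diameter_sigma=0.20,
                             tortuosity=0.25, orientation_sd=0.35, amplitude=1.3),
        "endometriosis": dict(density=26, diameter_um=60, diameter_sigma=0.25,
                              tortuosity=0.45, orientation_sd=0.45, amplitude=1.6),
        "malignant": dict(density=34, diameter_um=120, diameter_sigma=0.30,
                          tortuosity=0.60, orientation_sd=0.55, amplitude=2.0),
    }
    return {
        name: PhantomSpec(label=CLASS_NAMES.index(name), **kw)
        for name, kw in params.items()
    }


def generate_cohort(
    n_per_class: int = 8,
    seed: int = 0,
    templates: Optional[Dict[str, PhantomSpec]] = None,
    n_bscans: Optional[int] = None,
) -> Tuple[List[PhantomSpec], Dict[str, int]]:
    """Jittered per-specimen phantom specs plus a specimen->label manifest.

    Class templates are treated as distributions, not points: each
    specimen multiplies density, diameter, tortuosity and amplitude by
    independent log-normal jitters and receives a random depth offset
    (emulating variable compression) and its own seed.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 specimens per class")
    templates = templates or default_templates()
    rng = np.random.default_rng(seed)
    specs: List[PhantomSpec] = []
    manifest: Dict[str, int] = {}
    for name in CLASS_NAMES:
        template = templates[name]
        for i in range(n_per_class):
            sid = f"{name}_{i:02d}"
            spec = replace(
                template,
                density=template.density * np.exp(rng.normal(0, 0.08)),
                diameter_um=template.diameter_um * np.exp(rng.normal(0, 0.05)),
                tortuosity=template.tortuosity * np.exp(rng.normal(0, 0.08)),
                amplitude=template.amplitude * np.exp(rng.normal(0, 0.05)),
                depth_offset=float(rng.uniform(0.0, 0.3e-3)),
                seed=int(rng.integers(2**31)),
            )
            if n_bscans is not None:
                spec = replace(spec, n_bscans=n_bscans)
            specs.append(spec)
            manifest[sid] = template.label
    return specs, manifest


def phantom_cscan(spec: PhantomSpec, specimen_id: str, label: Optional[int] = None) -> CScan:
    """Realize a phantom spec as a CScan (ground truth discarded)."""
    bscans, _ = generate_phantom(spec)
    return CScan(bscans=bscans, specimen_id=specimen_id, label=label if label is not None else spec.label)
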