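"""Vessel cross-section detection and geometry on B-scans.

A vessel on a B-scan is a bright connected region of the envelope image.
Detection uses the display convention of a fixed dynamic range below the
frame maximum (default 40 dB) combined with a noise gate; the five largest
8-connected components become the graph nodes of that B-scan.

The local vessel direction theta is estimated from the lateral drift of the
component centroid across neighboring B-scans, and corrects the observed
lateral width w to the true diameter d = w * cos(theta).  Depth tilt is
deliberately ignored: positions enter the pipeline in the x-y plane only.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .rf_features import estimate_noise_floor
from .types import BScan, Geometry, VesselComponent

DEFAULT_DYNAMIC_RANGE_DB = 40.0
#: Lateral matching radius for centroid tracking across B-scans, in pixels.
MATCH_RADIUS_PX = 10.0

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def threshold_mask(
    bscan: BScan,
    dynamic_range_db: float = DEFAULT_DYNAMIC_RANGE_DB,
    noise_floor: Optional[float] = None,
) -> np.ndarray:
    """Binary vessel mask from the envelope image.

    True where the envelope is within ``dynamic_range_db`` of the frame
    maximum (amplitude dB) AND above 3x the noise floor.  A 3x3 binary
    opening removes single-pixel speckle.
    """
    if not dynamic_range_db > 0:
        raise ValueError(f"dynamic range must be positive, got {dynamic_range_db}")
    env = bscan.envelope
    peak = env.max()
    if peak <= 0:
        return np.zeros_like(env, dtype=bool)
    if noise_floor is None:
        noise_floor = estimate_noise_floor(bscan.rf)

    # env (dB re. max) >= -dynamic_range, evaluated in the linear domain
    cut = max(peak * 10.0 ** (-dynamic_range_db / 20.0), 3.0 * noise_floor)
    mask = env > cut if cut > 0 else env >= cut
    if not mask.any():
        return mask
    return ndimage.binary_opening(mask, structure=_STRUCTURE_8)


def extract_components(mask: np.ndarray, pitch_x: float = 3e-6) -> List[VesselComponent]:
    """8-connected components of a binary mask, with lateral geometry.

    The observed width is the component's lateral (column) extent,
    ``(max col - min col + 1) * pitch_x``; the lateral position is the
    centroid column times the pitch.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    components: List[VesselComponent] = []
    if n == 0:
        return components
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        region = labels[sl] == lab
        zz, xx = np.nonzero(region)
        zz = zz + sl[0].start
        xx = xx + sl[1].start
        z_bar = float(zz.mean())
        x_bar = float(xx.mean())
        width = (xx.max() - xx.min() + 1) * pitch_x
        components.append(
            VesselComponent(
                pixel_set=np.column_stack([zz, xx]),
                pixel_count=int(zz.size),
                centroid=(z_bar, x_bar),
                observed_width_w=float(width),
                lateral_position_x=float(x_bar * pitch_x),
            )
        )
    return components


def select_top_k(
    components: Sequence[VesselComponent], k: int = 5
) -> List[Optional[VesselComponent]]:
    """The ``k`` largest components by pixel count, padded to exactly k slots.

    Ties are broken toward the smaller lateral position.  Missing slots are
    ``None`` placeholders; downstream node assembly turns them into padding
    nodes (zero features, invalid) at the B-scan center.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(components, key=lambda c: (-c.pixel_count, c.lateral_position_x))
    slots: List[Optional[VesselComponent]] = list(ranked[:k])
    slots.extend([None] * (k - len(slots)))
    return slots


def _nearest_match(
    component: VesselComponent,
    candidates: Sequence[VesselComponent],
    radius_px: float,
) -> Optional[VesselComponent]:
    """Nearest-centroid candidate within a lateral radius, else None."""
    x0 = component.centroid[1]
    best, best_d = None, radius_px
    for cand in candidates:
        d = abs(cand.centroid[1] - x0)
        if d <= best_d:
            best, best_d = cand, d
    return best


def directionality(
    current: VesselComponent,
    prev_components: Sequence[VesselComponent],
    next_components: Sequence[VesselComponent],
    pitch_x: float = 3e-6,
    pitch_y: float = 3e-6,
    span: int = 1,
) -> Geometry:
    """Local direction angle and corrected diameter of one component.

    The component is matched by nearest centroid (within a 10-pixel lateral
    radius) in the B-scans ``span`` steps before and after.  theta is
    ``arctan(|dx| / dy)`` over the matched span; with no match on either
    side theta = 0.  The corrected diameter is ``w * cos(theta)``.
    """
    prev = _nearest_match(current, prev_components, MATCH_RADIUS_PX)
    nxt = _nearest_match(current, next_components, MATCH_RADIUS_PX)

    if prev is not None and nxt is not None:
        dx_px = nxt.centroid[1] - prev.centroid[1]
        dy = 2 * span * pitch_y
    elif nxt is not None:
        dx_px = nxt.centroid[1] - current.centroid[1]
        dy = span * pitch_y
    elif prev is not None:
        dx_px = current.centroid[1] - prev.centroid[1]
        dy = span * pitch_y
    else:
        return Geometry(theta=0.0, diameter_d=current.observed_width_w)

    theta = math.atan2(abs(dx_px) * pitch_x, dy)
    theta = min(theta, math.pi / 2 - 1e-9)
    return Geometry(theta=theta, diameter_d=current.observed_width_w * math.cos(theta))
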