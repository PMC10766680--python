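"""Ignition, fire placement, and the TWI-mediated intensity field.

At most one fire can occur per simulated year: a uniform draw against the
annual fire probability rating decides ignition; the fire center is uniform
over the simulation area; the affected diameter scales with FPR_ann
relative to the area width (linear by default, an exponent is exposed).
Within the fire disk, each 0.2 m cell receives a fire intensity FI in
[0, 1]: the FPR_ann damped linearly by the local topographic wetness index
(wetter cells burn less; cells at or above the wetness cutoff, and water
cells, receive FI = 0 and are excluded from the burned-cell count).

Flame (scorch) height follows a power law of FI reaching ``h_max`` at
FI = 1; the exponent only needs to be monotone and is configurable — the
shipped default is the impact-calibrated value (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import Landscape

__all__ = ["FireParams", "FireEvent", "draw_ignition", "place_fire",
           "cell_intensity", "flame_height", "make_fire_event",
           "fixed_fire_event"]


@dataclass(frozen=True)
class FireParams:
    """Tunables of fire geometry and intensity.

    ``twi_wet_fraction`` positions the wetness cutoff within the landscape
    TWI range: cells with TWI >= twi_min + fraction*(twi_max - twi_min)
    are too wet to burn.  ``diameter_exponent`` = 1 is the linear mapping
    diameter = FPR_ann * width.  ``flame_exponent`` and ``flame_h_max_m``
    set the scorch-height law h = h_max * FI**exponent.
    """

    twi_wet_fraction: float = 0.8
    diameter_exponent: float = 1.0
    flame_h_max_m: float = 15.0
    flame_exponent: float = 2.0


@dataclass
class FireEvent:
    """One fire: geometry, per-fine-cell intensity, and bookkeeping."""

    year: int
    center_x: float
    center_y: float
    diameter: float
    fpr_ann_at_event: float
    intensity: np.ndarray                  # fine grid, float32, FI in [0, 1]
    burned_cell_count: int = 0

    def __post_init__(self) -> None:
        self.burned_cell_count = int(np.count_nonzero(self.intensity > 0.0))


def draw_ignition(fpr_ann: float, rng: np.random.Generator) -> bool:
    """True with probability exactly ``fpr_ann``."""
    if not 0.0 <= fpr_ann <= 1.0:
        raise ValueError("fpr_ann must be in [0, 1]")
    return bool(rng.random() < fpr_ann)


def place_fire(fpr_ann: float, landscape: Landscape, rng: np.random.Generator,
               params: FireParams | None = None) -> tuple[float, float, float]:
    """Draw a fire center and diameter; returns (center_x, center_y, diameter).

    The center is uniform over the simulation rectangle; the diameter is
    width * fpr_ann**exponent (linear by default), clipped at the area
    boundary when the intensity field is rasterized.
    """
    params = params or FireParams()
    cx = rng.uniform(0.0, landscape.width_m)
    cy = rng.uniform(0.0, landscape.height_m)
    diameter = landscape.width_m * fpr_ann ** params.diameter_exponent
    return cx, cy, diameter


def cell_intensity(fpr_ann: float, twi, twi_min: float, twi_wet: float):
    """TWI-mediated fire intensity of a burnable cell inside the fire disk.

    FI = fpr_ann * max(0, 1 - (twi - twi_min) / (twi_wet - twi_min));
    zero at or beyond the wetness cutoff ``twi_wet``.
    """
    twi = np.asarray(twi, dtype=float)
    if twi_wet <= twi_min:
        damp = np.where(twi >= twi_wet, 0.0, 1.0)
    else:
        damp = np.clip(1.0 - (twi - twi_min) / (twi_wet - twi_min), 0.0, 1.0)
    out = fpr_ann * damp
    return float(out) if out.ndim == 0 else out


def flame_height(fi, h_max: float = 15.0, exponent: float = 2.0):
    """Scorch height in meters: h_max * FI**exponent (0 at FI = 0)."""
    fi = np.asarray(fi, dtype=float)
    out = h_max * fi ** exponent
    return float(out) if out.ndim == 0 else out


def _disk_mask(landscape: Landscape, cx: float, cy: float,
               diameter: float) -> tuple[slice, slice, np.ndarray]:
    """Fine-grid bounding slices and boolean mask of the (clipped) fire disk."""
    res = landscape.fine_res_m
    n = landscape.n_fine
    r = diameter / 2.0
    i0 = max(0, int((cy - r) / res))
    i1 = min(n, int(np.ceil((cy + r) / res)) + 1)
    j0 = max(0, int((cx - r) / res))
    j1 = min(n, int(np.ceil((cx + r) / res)) + 1)
    rows = (np.arange(i0, i1) + 0.5) * res
    cols = (np.arange(j0, j1) + 0.5) * res
    dy = rows[:, None] - cy
    dx = cols[None, :] - cx
    mask = dx ** 2 + dy ** 2 <= r ** 2
    return slice(i0, i1), slice(j0, j1), mask


def make_fire_event(year: int, fpr_ann: float, landscape: Landscape,
                    rng: np.random.Generator,
                    params: FireParams | None = None) -> FireEvent:
    """Place a fire and compute its TWI-mediated intensity field.

    The field is deterministic given (fpr_ann, center, landscape); only the
    center placement consumes randomness here (ignition is drawn upstream).
    Water cells always receive FI = 0; the disk may cover them (there is no
    spread model to route around water).
    """
    params = params or FireParams()
    cx, cy, diameter = place_fire(fpr_ann, landscape, rng, params)
    intensity = np.zeros((landscape.n_fine, landscape.n_fine), dtype=np.float32)
    if diameter > 0.0 and fpr_ann > 0.0:
        twi_min, twi_max = landscape.land_twi_range()
        twi_wet = twi_min + params.twi_wet_fraction * (twi_max - twi_min)
        rows, cols, mask = _disk_mask(landscape, cx, cy, diameter)
        twi_patch = landscape.twi_fine()[rows, cols]
        fi = cell_intensity(fpr_ann, twi_patch, twi_min, twi_wet)
        fi = np.where(mask, fi, 0.0)
        fi = np.where(landscape.water_fine[rows, cols], 0.0, fi)
        intensity[rows, cols] = fi.astype(np.float32)
    return FireEvent(year=year, center_x=cx, center_y=cy, diameter=diameter,
                     fpr_ann_at_event=fpr_ann, intensity=intensity)


def fixed_fire_event(year: int, fi: float, landscape: Landscape) -> FireEvent:
    """Whole-area fire at uniform intensity ``fi`` on land (scenario mode).

    Scenario fires deliberately skip the TWI mediation so that the applied
    intensity is exactly as labeled.
    """
    if not 0.0 <= fi <= 1.0:
        raise ValueError("fi must be in [0, 1]")
    intensity = np.where(landscape.water_fine, 0.0, fi).astype(np.float32)
    width = landscape.width_m
    return FireEvent(year=year, center_x=width / 2.0, center_y=width / 2.0,
                     diameter=width * np.sqrt(2.0),  # circumscribes the square
                     fpr_ann_at_event=fi, intensity=intensity)
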