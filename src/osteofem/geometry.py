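"""Parametric spike layout of the multi-spiked connecting scaffold (MSC-Scaffold).

The scaffold replaces the stem of a resurfacing endoprosthesis with an array of
truncated-cone spikes, press-fit into periarticular trabecular bone.  A central
spike is surrounded by concentric rings of identical spikes with mutually
parallel axes.  This module generates that layout parametrically; it drives the
finite-element load footprints, the periapical regions of interest used for
densitometry, and the densification zones of the synthetic-data generator.

Units are millimetres throughout (project convention: mm, N, MPa).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


@dataclass(frozen=True)
class ScaffoldParams:
    """Geometric parameters of the spike array.

    Defaults follow the prototype: 5 mm truncated-cone spikes with a 0.5 mm
    base diameter, separated by a 0.35 mm gap both circumferentially and
    radially (matching the thickness of cancellous-bone trabeculae).  The apex
    tip diameter is not a prototype datum; a small nonzero default keeps load
    footprints finite.
    """

    spike_height: float = 5.0
    base_diameter: float = 0.5
    apex_diameter: float = 0.1
    inter_spike_gap: float = 0.35
    n_rings: int = 2
    embed_depth_max: float = 3.0

    def __post_init__(self) -> None:
        for name in ("spike_height", "base_diameter", "apex_diameter",
                     "inter_spike_gap", "embed_depth_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.apex_diameter >= self.base_diameter:
            raise ValueError(
                f"apex_diameter ({self.apex_diameter}) must be smaller than "
                f"base_diameter ({self.base_diameter})")
        if self.n_rings < 0:
            raise ValueError("n_rings must be >= 0")
        if self.embed_depth_max > self.spike_height:
            raise ValueError("embed_depth_max cannot exceed spike_height")

    @property
    def radial_pitch(self) -> float:
        """Centre-to-centre ring spacing: base diameter plus inter-spike gap."""
        return self.base_diameter + self.inter_spike_gap


@dataclass(frozen=True)
class Spike:
    center_x: float
    center_y: float
    base_radius: float
    apex_radius: float
    height: float


@dataclass(frozen=True)
class ScaffoldLayout:
    spikes: tuple[Spike, ...]
    radial_pitch: float

    def __len__(self) -> int:
        return len(self.spikes)

    @property
    def outer_radius(self) -> float:
        """Radius of the smallest axis-centred circle containing all spike bases."""
        return max(math.hypot(s.center_x, s.center_y) + s.base_radius
                   for s in self.spikes)


def _spikes_per_ring(ring_index: int, pitch: float, base_diameter: float,
                     gap: float) -> int:
    """Largest spike count whose circumferential arc gap stays >= `gap`.

    The arc between neighbouring base circles on a ring of radius k*pitch is
    2*pi*R/m - base_diameter; requiring it to be >= gap gives
    m <= 2*pi*R/(base_diameter + gap).  The count is additionally reduced, if
    ever needed, so that the straight-line (chord) centre distance also stays
    >= the pitch, which the non-overlap invariant requires.
    """
    radius = ring_index * pitch
    m = int(math.floor(2.0 * math.pi * radius / pitch))
    while m > 1 and 2.0 * radius * math.sin(math.pi / m) < pitch - 1e-12:
        m -= 1
    return max(m, 1)


def build_spike_layout(params: ScaffoldParams) -> ScaffoldLayout:
    """Place the central spike and ``n_rings`` concentric rings of spikes.

    Ring *k* sits at radius ``k * radial_pitch``; within each ring spikes are
    equally spaced in angle at the largest count keeping the circumferential
    base-to-base arc gap at least ``inter_spike_gap``.
    """
    pitch = params.radial_pitch
    base_r = params.base_diameter / 2.0
    apex_r = params.apex_diameter / 2.0

    spikes: list[Spike] = [Spike(0.0, 0.0, base_r, apex_r, params.spike_height)]
    for k in range(1, params.n_rings + 1):
        radius = k * pitch
        m = _spikes_per_ring(k, pitch, params.base_diameter, params.inter_spike_gap)
        for j in range(m):
            theta = 2.0 * math.pi * j / m
            spikes.append(Spike(radius * math.cos(theta), radius * math.sin(theta),
                                base_r, apex_r, params.spike_height))
    return ScaffoldLayout(spikes=tuple(spikes), radial_pitch=pitch)


def spike_section_radius(layout: ScaffoldLayout, depth_from_apex: float) -> list[float]:
    """Cross-section radius of each truncated-cone spike at a given depth.

    ``depth_from_apex`` is measured from the apex towards the base; the radius
    interpolates linearly from the apex radius (depth 0) to the base radius
    (depth = spike height).
    """
    radii = []
    for s in layout.spikes:
        if not (0.0 <= depth_from_apex <= s.height + 1e-12):
            raise ValueError(
                f"depth_from_apex {depth_from_apex} outside [0, {s.height}]")
        t = depth_from_apex / s.height
        radii.append(s.apex_radius + t * (s.base_radius - s.apex_radius))
    return radii


def save_layout(layout: ScaffoldLayout, path: str | Path) -> None:
    """Write the layout as JSON (one record per spike, lengths in mm)."""
    payload = {
        "radial_pitch_mm": layout.radial_pitch,
        "spikes": [
            {"center_x_mm": s.center_x, "center_y_mm": s.center_y,
             "base_radius_mm": s.base_radius, "apex_radius_mm": s.apex_radius,
             "height_mm": s.height}
            for s in layout.spikes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_layout(path: str | Path) -> ScaffoldLayout:
    payload = json.loads(Path(path).read_text())
    spikes = tuple(
        Spike(rec["center_x_mm"], rec["center_y_mm"], rec["base_radius_mm"],
              rec["apex_radius_mm"], rec["height_mm"])
        for rec in payload["spikes"])
    return ScaffoldLayout(spikes=spikes, radial_pitch=payload["radial_pitch_mm"])
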