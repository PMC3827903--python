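"""Agent-based generation of resorption pits and trails on height maps.

Two kinds of resorption traces are simulated, mirroring the two actin-ring
configurations of resorbing osteoclasts:

* **Pits** — a stationary cell seals a round/elliptical area and resorbs
  a discrete cavity with near-vertical walls down to a requested depth,
  never deeper than the donor's depth plateau ``d_max``.

* **Trails** — a migrating cell with a crescent-shaped sealing zone
  resorbs cyclically: each cycle excavates a narrow transverse band of
  the matrix from the surface down to the target depth (layer-by-layer,
  top to bottom), then the cell steps forward by the band width
  ``s`` (mechanistically bounded to 3–21 μm, the observed span between
  the two walls of crescent actin rings) and repeats.  A completed cycle
  leaves the band at full depth plus a descending ramp of horizontal
  extent ``s`` at the new front, so an isolated cycle removes
  ``RAMP_SHAPE_FACTOR * s * w * depth`` of material; the next cycle's
  band replaces the previous ramp, keeping the trail floor continuous.

Events are placed as a homogeneous Poisson process with the preset's
observed intensity; overlapping excavations combine by pointwise
minimum height (deepest wins), so material is only ever removed.
All randomness flows through one ``numpy`` generator, making every run
bit-reproducible from its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryParams, pit_area, trail_area
from .presets import DonorProfile, SubstratePreset
from .surface import HeightMap

__all__ = [
    "STEP_MIN",
    "STEP_MAX",
    "RAMP_SHAPE_FACTOR",
    "TrailCycle",
    "TrailState",
    "ResorptionEvent",
    "place_events",
    "resorb_pit",
    "resorb_trail_cycle",
    "resorb_trail",
    "run_simulation",
]

#: mechanistic bounds on the horizontal advance of one trail cycle, μm
STEP_MIN = 3.0
STEP_MAX = 21.0

#: removed volume of one isolated cycle on a flat surface, relative to
#: step x width x depth: the full-depth band contributes 1.0 and the
#: linear ramp (extent = one step) at the new front contributes 0.5
RAMP_SHAPE_FACTOR = 1.5

#: smallest depth request honoured, μm (keeps events above detection noise)
MIN_DEPTH = 1.0


@dataclass(frozen=True)
class TrailCycle:
    """One resorption cycle of a trail-forming osteoclast."""

    step_length: float  # horizontal advance s, um
    ring_width: float  # trail width at this cycle, um
    target_depth: float  # excavation depth of this cycle, um
    heading: float  # direction of advance, rad

    def __post_init__(self) -> None:
        if not (STEP_MIN <= self.step_length <= STEP_MAX):
            raise ValueError(
                f"step_length must lie in [{STEP_MIN}, {STEP_MAX}] um "
                f"(crescent actin-ring span); got {self.step_length}"
            )
        if not (self.ring_width > 0):
            raise ValueError("ring_width must be > 0")
        if not (self.target_depth > 0):
            raise ValueError("target_depth must be > 0")


@dataclass
class TrailState:
    """Mutable front state of a trail-resorbing agent."""

    x: float  # current front position, um
    y: float
    heading: float  # rad
    d_max: float = math.inf  # donor depth ceiling, um


@dataclass
class ResorptionEvent:
    """Ground-truth record of one simulated pit or trail."""

    event_id: int
    kind: str  # "pit" | "trail"
    x: float  # pit centre / trail start, um
    y: float
    donor_id: str
    d_max: float  # donor depth ceiling applying to this event, um
    depth: float  # requested excavation depth, um
    length: float  # drawn overall length, um
    width: float  # drawn overall width, um
    # pit-only fields
    semi_major: float | None = None
    semi_minor: float | None = None
    orientation: float | None = None  # rad
    # trail-only fields
    cycles: list[TrailCycle] = field(default_factory=list)
    # filled in during application
    realized_volume_um3: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("pit", "trail"):
            raise ValueError("kind must be 'pit' or 'trail'")
        if self.kind == "pit":
            if not (self.semi_major and self.semi_minor) or min(self.semi_major, self.semi_minor) <= 0:
                raise ValueError("pit semi-axes must be > 0")
        else:
            if not self.cycles:
                raise ValueError("trail needs at least one cycle")
            if any(c.target_depth > self.d_max + 1e-9 for c in self.cycles):
                raise ValueError("cycle depths must not exceed the donor d_max")

    @property
    def realized_depth(self) -> float:
        return min(self.depth, self.d_max)


# ----------------------------------------------------------------------
# event placement
# ----------------------------------------------------------------------

def _draw_steps(centreline: float, rng: np.random.Generator) -> list[float]:
    """Step lengths whose sum plus the final ramp spans ``centreline`` μm.

    Every step lies in [STEP_MIN, STEP_MAX].  The terminal ramp has the
    same extent as the last step, so the footprint along the path is
    sum(steps) + steps[-1]; the last step is solved for to make this hit
    the requested centreline length exactly whenever the bounds allow.
    """
    steps: list[float] = []
    remaining = float(centreline)
    while remaining > 2.0 * STEP_MAX:
        s = float(rng.uniform(STEP_MIN, STEP_MAX))
        s = min(s, remaining - 2.0 * STEP_MIN)  # keep a feasible final step
        steps.append(s)
        remaining -= s
    steps.append(float(np.clip(remaining / 2.0, STEP_MIN, STEP_MAX)))
    return steps


def _depth_request(
    nominal_area: float, d_max: float, preset: SubstratePreset, rng: np.random.Generator
) -> float:
    """Depth requested by the agent for an event of given footprint area.

    Depth grows with the worked area and saturates at the donor plateau:
    small events are shallow, large events resorb down to ``d_max`` and
    then grow only in area.  A small multiplicative log-normal noise
    models cell-to-cell variability.
    """
    cv = preset.depth_noise_cv
    sigma = math.sqrt(math.log1p(cv**2)) if cv > 0 else 0.0
    noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma) if sigma > 0 else 1.0
    target = d_max * -math.expm1(-nominal_area / preset.depth_saturation_area)
    return float(np.clip(target * noise, MIN_DEPTH, d_max))


def place_events(
    preset: SubstratePreset,
    donor: DonorProfile,
    area_cm2: float,
    seed: int | np.random.SeedSequence,
    extent_um: tuple[float, float] | None = None,
    geometry: GeometryParams | None = None,
) -> list[ResorptionEvent]:
    """Draw the ground-truth event list for one substrate replicate.

    The event count is Poisson with mean
    ``preset.event_intensity * donor.activity_scale * area_cm2``;
    positions are uniform over the substrate, event types Bernoulli with
    the preset trail fraction, and (length, width) pairs come from the
    preset's calibrated geometry law.  Deterministic for a given seed.
    """
    if not (area_cm2 > 0):
        raise ValueError("area_cm2 must be > 0")
    geometry = geometry if geometry is not None else preset.geometry
    if extent_um is None:
        side = math.sqrt(area_cm2 * 1.0e8)
        extent_um = (side, side)

    rng = np.random.default_rng(seed)
    lam = preset.event_intensity * donor.activity_scale * area_cm2
    n = int(rng.poisson(lam)) if lam > 0 else 0

    events: list[ResorptionEvent] = []
    for k in range(n):
        x = float(rng.uniform(0.0, extent_um[0]))
        y = float(rng.uniform(0.0, extent_um[1]))
        is_trail = bool(rng.random() < preset.trail_fraction)
        length, width = geometry.sample_one(rng)
        if donor.d_max_sd > 0:
            d_max = float(max(MIN_DEPTH, rng.normal(donor.d_max, donor.d_max_sd)))
        else:
            d_max = donor.d_max

        if is_trail:
            nominal = float(trail_area(length, width))
        else:
            nominal = float(pit_area(length, width))
        depth = _depth_request(nominal, d_max, preset, rng)

        if is_trail:
            heading0 = float(rng.uniform(0.0, 2.0 * math.pi))
            # the rounded cap behind the start adds ~width/2 to the
            # footprint, the terminal ramp is part of the centreline
            centreline = max(length - width / 2.0, STEP_MIN)
            steps = _draw_steps(centreline, rng)
            heading = heading0
            cycles = []
            for s in steps:
                cycles.append(
                    TrailCycle(step_length=s, ring_width=width, target_depth=depth, heading=heading)
                )
                heading += float(rng.normal(0.0, preset.heading_sd))
            events.append(
                ResorptionEvent(
                    event_id=k, kind="trail", x=x, y=y, donor_id=donor.donor_id,
                    d_max=d_max, depth=depth, length=length, width=width, cycles=cycles,
                )
            )
        else:
            events.append(
                ResorptionEvent(
                    event_id=k, kind="pit", x=x, y=y, donor_id=donor.donor_id,
                    d_max=d_max, depth=depth, length=length, width=width,
                    semi_major=length / 2.0, semi_minor=width / 2.0,
                    orientation=float(rng.uniform(0.0, math.pi)),
                )
            )
    return events


# ----------------------------------------------------------------------
# excavation primitives
# ----------------------------------------------------------------------

def _window(surface: HeightMap, x_lo, x_hi, y_lo, y_hi):
    """Integer pixel window covering a μm bounding box, clipped to the map."""
    px = surface.pixel_size
    ny, nx = surface.heights.shape
    j0 = max(int(math.floor(x_lo / px)) - 1, 0)
    j1 = min(int(math.ceil(x_hi / px)) + 1, nx)
    i0 = max(int(math.floor(y_lo / px)) - 1, 0)
    i1 = min(int(math.ceil(y_hi / px)) + 1, ny)
    return i0, i1, j0, j1


def _pixel_coords(surface: HeightMap, i0, i1, j0, j1):
    px = surface.pixel_size
    xs = (np.arange(j0, j1) + 0.5) * px
    ys = (np.arange(i0, i1) + 0.5) * px
    return np.meshgrid(xs, ys)


def _carve(surface: HeightMap, pristine_window: np.ndarray, sl, removal: np.ndarray) -> float:
    """Lower heights to pristine - removal (pointwise min); return removed volume."""
    window = surface.heights[sl]
    new = np.minimum(window, pristine_window - removal)
    delta = float((window - new).sum()) * surface.pixel_size**2
    surface.heights[sl] = new
    return delta


def resorb_pit(
    surface: HeightMap, event: ResorptionEvent, pristine: HeightMap | None = None
) -> HeightMap:
    """Excavate an elliptical pit; mutates and returns ``surface``.

    Heights inside the ellipse are lowered to ``min(depth, d_max)`` below
    the local pristine surface with vertical walls (binary footprint, so
    the edge fall-off is at most one pixel).  ``pristine`` supplies the
    local pre-resorption reference; if omitted the current surface is
    used.  The removed volume is accumulated on the event record.  A
    footprint entirely outside the map is a no-op with a warning.
    """
    if event.kind != "pit":
        raise ValueError("resorb_pit requires a pit event")
    depth = event.realized_depth
    if depth <= 0:
        return surface
    a, b, theta = event.semi_major, event.semi_minor, event.orientation or 0.0
    r = max(a, b)
    i0, i1, j0, j1 = _window(surface, event.x - r, event.x + r, event.y - r, event.y + r)
    if i0 >= i1 or j0 >= j1:
        warnings.warn(f"pit event {event.event_id} lies outside the map; skipped")
        return surface
    X, Y = _pixel_coords(surface, i0, i1, j0, j1)
    dx, dy = X - event.x, Y - event.y
    c, s = math.cos(theta), math.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        warnings.warn(f"pit event {event.event_id} has an empty footprint; skipped")
        return surface
    sl = (slice(i0, i1), slice(j0, j1))
    ref = pristine.heights[sl] if pristine is not None else surface.heights[sl].copy()
    event.realized_volume_um3 += _carve(surface, ref, sl, np.where(mask, depth, 0.0))
    return surface


def resorb_trail_cycle(
    surface: HeightMap,
    state: TrailState,
    cycle: TrailCycle,
    pristine: HeightMap | None = None,
) -> tuple[HeightMap, TrailState, float]:
    """Apply one trail cycle; returns (surface, new state, removed volume μm³).

    The band from the current front over one step length is excavated
    from the pristine surface down to the cycle target depth (clamped to
    the state's ``d_max``), with a rounded cap at the trail origin side
    and a linear ramp of one step extent descending ahead of the new
    front.  The front then advances by the step along the cycle heading.
    Heights only decrease; the surface is mutated in place.
    """
    s_len, w = cycle.step_length, cycle.ring_width
    depth = min(cycle.target_depth, state.d_max)
    ux, uy = math.cos(cycle.heading), math.sin(cycle.heading)
    reach = s_len * 2.0 + w  # band + ramp + caps
    x_lo = min(state.x, state.x + reach * ux) - w
    x_hi = max(state.x, state.x + reach * ux) + w
    y_lo = min(state.y, state.y + reach * uy) - w
    y_hi = max(state.y, state.y + reach * uy) + w
    i0, i1, j0, j1 = _window(surface, x_lo, x_hi, y_lo, y_hi)
    new_state = TrailState(
        x=state.x + s_len * ux, y=state.y + s_len * uy, heading=cycle.heading, d_max=state.d_max
    )
    if i0 >= i1 or j0 >= j1:
        return surface, new_state, 0.0
    X, Y = _pixel_coords(surface, i0, i1, j0, j1)
    dx, dy = X - state.x, Y - state.y
    u = dx * ux + dy * uy  # along-path coordinate from the current front
    v = -dx * uy + dy * ux  # transverse coordinate
    inside = np.abs(v) <= w / 2.0
    # full-depth band with a rounded cap behind the front
    band = inside & (u >= 0.0) & (u <= s_len)
    cap = (dx**2 + dy**2) <= (w / 2.0) ** 2
    frac = np.where(band | cap, 1.0, 0.0)
    # descending ramp ahead of the new front, extent = one step
    ramp = inside & (u > s_len) & (u <= 2.0 * s_len)
    frac = np.where(ramp, 1.0 - (u - s_len) / s_len, frac)
    sl = (slice(i0, i1), slice(j0, j1))
    ref = pristine.heights[sl] if pristine is not None else surface.heights[sl].copy()
    delta = _carve(surface, ref, sl, depth * frac)
    return surface, new_state, delta


def resorb_trail(
    surface: HeightMap, event: ResorptionEvent, pristine: HeightMap | None = None
) -> HeightMap:
    """Apply all cycles of a trail event; mutates and returns ``surface``."""
    if event.kind != "trail":
        raise ValueError("resorb_trail requires a trail event")
    if pristine is None:
        # snapshot once so successive cycles share one pre-resorption
        # reference instead of compounding their excavations
        pristine = surface.copy()
    state = TrailState(x=event.x, y=event.y, heading=event.cycles[0].heading, d_max=event.d_max)
    for cycle in event.cycles:
        surface, state, delta = resorb_trail_cycle(surface, state, cycle, pristine=pristine)
        event.realized_volume_um3 += delta
    return surface


# ----------------------------------------------------------------------
# whole-replicate simulation
# ----------------------------------------------------------------------

def run_simulation(
    preset: SubstratePreset,
    donor: DonorProfile,
    surface: HeightMap,
    seed: int | np.random.SeedSequence,
    geometry: GeometryParams | None = None,
) -> tuple[HeightMap, list[ResorptionEvent]]:
    """Simulate one culture replicate on ``surface``.

    Places events for the surface's area and applies each one to a copy
    of the input map, treating the input as the pristine reference.
    Returns the final surface and the ground-truth event list (each event
    carries the incremental volume it actually removed, so the per-event
    volumes sum exactly to the total removed volume even where events
    overlap).  Fully reproducible from the seed.
    """
    events = place_events(
        preset, donor, surface.area_cm2, seed, extent_um=surface.extent_um, geometry=geometry
    )
    final = surface.copy()
    for event in events:
        if event.kind == "pit":
            resorb_pit(final, event, pristine=surface)
        else:
            resorb_trail(final, event, pristine=surface)
    return final, events
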