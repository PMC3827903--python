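"""Synthetic cohorts and ground-truth fixtures.

This module provides (a) exact analytic fixtures for validating the
quantifier (rasterized elliptical pits with known area, axes and
volume), and (b) multi-donor cohort emulation: each synthetic donor
gets a depth plateau drawn from the span observed across real donors
and one simulated substrate replicate, mirroring a study design of
osteoclasts from many blood donors cultured on bone or dentin slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryParams, calibrate_geometry  # re-export  # noqa: F401
from .presets import DonorProfile, SubstratePreset, get_preset
from .quantify import CohortSummary
from .simulate import ResorptionEvent, resorb_pit, run_simulation
from .surface import HeightMap, make_flat, synthesize_roughness

__all__ = [
    "PitTruth",
    "CohortSpec",
    "CohortReplicate",
    "make_fixture_pit",
    "generate_cohort",
    "donor_level_summary",
    "calibrate_geometry",
]


@dataclass(frozen=True)
class PitTruth:
    """Analytic ground truth of a fixture pit."""

    center: tuple[float, float]  # um
    semi_major: float  # um
    semi_minor: float  # um
    depth: float  # um
    orientation: float  # rad
    area: float  # pi * a * b, um^2
    volume: float  # area * depth, um^3
    length: float  # 2 * semi_major, um
    width: float  # 2 * semi_minor, um


def make_fixture_pit(
    surface: HeightMap,
    center: tuple[float, float],
    a: float,
    b: float,
    depth: float,
    orientation: float = 0.0,
) -> tuple[HeightMap, PitTruth]:
    """Excavate one elliptical pit with known analytic truth.

    ``a`` and ``b`` are the semi-axes in μm.  The surface is mutated in
    place (depth 0 leaves it untouched) and returned together with the
    analytic area ``π·a·b``, volume and axis lengths.  A centre outside
    the map raises ``ValueError``.
    """
    if min(a, b) <= 0:
        raise ValueError("semi-axes must be > 0")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    wx, wy = surface.extent_um
    x, y = center
    if not (0.0 <= x <= wx and 0.0 <= y <= wy):
        raise ValueError(f"pit centre {center} lies outside the {wx} x {wy} um map")
    truth = PitTruth(
        center=(float(x), float(y)),
        semi_major=float(max(a, b)),
        semi_minor=float(min(a, b)),
        depth=float(depth),
        orientation=float(orientation),
        area=math.pi * a * b,
        volume=math.pi * a * b * depth,
        length=2.0 * max(a, b),
        width=2.0 * min(a, b),
    )
    if depth > 0:
        event = ResorptionEvent(
            event_id=0, kind="pit", x=float(x), y=float(y), donor_id="fixture",
            d_max=math.inf, depth=float(depth), length=2.0 * a, width=2.0 * b,
            semi_major=float(a), semi_minor=float(b), orientation=float(orientation),
        )
        resorb_pit(surface, event)
    return surface, truth


@dataclass
class CohortSpec:
    """Design of a synthetic multi-donor experiment."""

    preset: str | SubstratePreset = "bone_rough"
    n_donors: int = 16
    replicate_area_cm2: float = 0.02
    d_max_range: tuple[float, float] = (32.0, 68.0)  # um; span of donor plateaus
    activity_sd: float = 0.0  # lognormal sd of per-donor activity scale
    pixel_size: float = 1.0  # um
    with_roughness: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if not (self.replicate_area_cm2 > 0):
            raise ValueError("replicate_area_cm2 must be > 0")
        lo, hi = self.d_max_range
        if not (0 < lo <= hi):
            raise ValueError("d_max_range must satisfy 0 < lo <= hi")


@dataclass
class CohortReplicate:
    """One donor's simulated substrate replicate with ground truth."""

    donor: DonorProfile
    pristine: HeightMap
    final: HeightMap
    events: list[ResorptionEvent]
    seed: int


def generate_cohort(spec: CohortSpec) -> list[CohortReplicate]:
    """Simulate one replicate per synthetic donor; reproducible from the seed.

    Donor depth plateaus are drawn uniformly over ``d_max_range``
    (the observed span across donors and repeat experiments); optional
    log-normal activity scaling emulates donor-to-donor differences in
    resorption potential.
    """
    preset = get_preset(spec.preset) if isinstance(spec.preset, str) else spec.preset
    side_px = int(round(math.sqrt(spec.replicate_area_cm2 * 1.0e8) / spec.pixel_size))
    children = np.random.SeedSequence(spec.master_seed).spawn(spec.n_donors)
    replicates: list[CohortReplicate] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        d_max = float(rng.uniform(*spec.d_max_range))
        activity = float(rng.lognormal(0.0, spec.activity_sd)) if spec.activity_sd > 0 else 1.0
        donor = DonorProfile(
            donor_id=f"synthetic_donor{i + 1:02d}", d_max=d_max, activity_scale=activity
        )
        sim_seed = int(rng.integers(2**31))
        pristine = make_flat(side_px, side_px, spec.pixel_size)
        if spec.with_roughness and preset.ra_target > 0:
            pristine = synthesize_roughness(
                pristine, preset.ra_target, preset.correlation_length, seed=sim_seed + 1
            )
        final, events = run_simulation(preset, donor, pristine, sim_seed)
        replicates.append(
            CohortReplicate(donor=donor, pristine=pristine, final=final, events=events, seed=sim_seed)
        )
    return replicates


def donor_level_summary(summaries: list[CohortSummary]) -> dict[str, float]:
    """Mean of per-donor means with SEM across donors.

    Published cohort statistics average per-donor summaries rather than
    pooling all events, so the experimental unit is the donor.
    """
    if not summaries:
        raise ValueError("no summaries to aggregate")

    def _agg(attr: str) -> tuple[float, float]:
        vals = np.array([getattr(s, attr) for s in summaries], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else float("nan")
        return float(vals.mean()), sem

    out: dict[str, float] = {"n_donors": float(len(summaries))}
    for attr in ("resorbed_area_pct", "events_per_cm2", "mean_area", "mean_length", "mean_width"):
        mean, sem = _agg(attr)
        out[attr] = mean
        out[f"{attr}_sem"] = sem
    return out
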