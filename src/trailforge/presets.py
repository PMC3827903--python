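"""Substrate and donor presets.

A :class:`SubstratePreset` bundles everything the simulator needs to
emulate one experimental condition: the observed resorption-event
intensity (events/cm²), the pit-vs-trail mixing fraction, the calibrated
per-event geometry law, surface-roughness targets and the adhered-cell
density.  A :class:`DonorProfile` carries the donor-level parameters,
chiefly the maximum resorption depth ``d_max`` — the depth plateau
beyond which events grow only in area.

Built-in presets (``bone_rough``, ``bone_smooth``, ``dentin_rough``,
``dentin_smooth``) and donor profiles are loaded from
``data/presets.yaml`` shipped with the package; geometry parameters are
calibrated on first use by moment matching against the preset's
(area, length, width) targets and cached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from .geometry import GeometryParams, calibrate_geometry

__all__ = [
    "SubstratePreset",
    "DonorProfile",
    "get_preset",
    "get_donor",
    "list_presets",
    "list_donors",
    "reference_observations",
]

#: fixed seed for the Monte-Carlo geometry calibration of built-in
#: presets, so that preset construction is reproducible everywhere
CALIBRATION_SEED = 12345


@dataclass(frozen=True)
class DonorProfile:
    """Donor-level simulation parameters.

    ``d_max`` is the donor's maximum resorption depth in μm (the depth
    plateau); ``d_max_sd`` an optional per-event spread around it
    (default 0: every event of a donor shares the donor plateau);
    ``activity_scale`` multiplies the preset event intensity.
    """

    donor_id: str
    d_max: float
    d_max_sd: float = 0.0
    activity_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.d_max > 0):
            raise ValueError("d_max must be > 0")
        if self.d_max_sd < 0:
            raise ValueError("d_max_sd must be >= 0")
        if self.activity_scale < 0:
            raise ValueError("activity_scale must be >= 0")


@dataclass
class SubstratePreset:
    """One substrate/condition: material x surface finish."""

    name: str
    event_intensity: float  # events per cm^2
    trail_fraction: float
    geometry: GeometryParams
    ra_target: float  # um
    rq_target: float  # um (reported companion value; not enforced)
    adhesion_density: float  # cells per cm^2
    geometry_targets: tuple[float, float, float] | None = None  # (area, length, width)
    depth_saturation_area: float = 150.0  # um^2; area scale of depth saturation
    depth_noise_cv: float = 0.08  # multiplicative spread of depth requests
    heading_sd: float = math.radians(2.0)  # per-cycle trail heading wobble, rad
    correlation_length: float = 20.0  # um; roughness texture scale

    def __post_init__(self) -> None:
        if self.event_intensity < 0:
            raise ValueError("event_intensity must be >= 0")
        if not (0.0 <= self.trail_fraction <= 1.0):
            raise ValueError("trail_fraction must be in [0, 1]")
        if self.ra_target < 0:
            raise ValueError("ra_target must be >= 0")


def _load_config() -> dict:
    text = resources.files("trailforge").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=1)
def _config() -> dict:
    return _load_config()


def list_presets() -> list[str]:
    return sorted(_config()["presets"])


def list_donors() -> list[str]:
    return sorted(_config()["donors"])


def reference_observations() -> dict:
    """Published pooled summary observables (inputs for fold-change arithmetic)."""
    return _config()["reference_observations"]


@lru_cache(maxsize=None)
def get_preset(name: str) -> SubstratePreset:
    """Build a named preset, calibrating its geometry law on first use."""
    cfg = _config()
    try:
        raw = cfg["presets"][name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {list_presets()}") from None
    defaults = cfg.get("defaults", {})
    targets = raw["geometry_targets"]
    triple = (
        float(targets["mean_area_um2"]),
        float(targets["mean_length_um"]),
        float(targets["mean_width_um"]),
    )
    trail_fraction = float(raw["trail_fraction"])
    geometry = calibrate_geometry(
        *triple, trail_fraction=trail_fraction, seed=CALIBRATION_SEED
    )
    return SubstratePreset(
        name=name,
        event_intensity=float(raw["event_intensity_per_cm2"]),
        trail_fraction=trail_fraction,
        geometry=geometry,
        ra_target=float(raw["ra_target_um"]),
        rq_target=float(raw["rq_target_um"]),
        adhesion_density=float(raw["adhesion_cells_per_cm2"]),
        geometry_targets=triple,
        depth_saturation_area=float(defaults.get("depth_saturation_area_um2", 150.0)),
        depth_noise_cv=float(defaults.get("depth_noise_cv", 0.08)),
        heading_sd=math.radians(float(defaults.get("heading_sd_deg", 2.0))),
        correlation_length=float(defaults.get("correlation_length_um", 20.0)),
    )


def get_donor(donor_id: str) -> DonorProfile:
    cfg = _config()
    try:
        raw = cfg["donors"][donor_id]
    except KeyError:
        raise KeyError(f"unknown donor {donor_id!r}; available: {list_donors()}") from None
    return DonorProfile(
        donor_id=donor_id,
        d_max=float(raw["d_max_um"]),
        d_max_sd=float(raw.get("d_max_sd_um", 0.0)),
        activity_scale=float(raw.get("activity_scale", 1.0)),
    )
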