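"""Comparative statistics across substrates and donors.

Implements the descriptive and inferential statistics used to compare
osteoclastic resorption between materials: fixed-bin length/width
histograms, fold changes of pooled observables, percentage increase in
adhered-cell density, depth-plateau estimation from per-event
(area, depth) pairs, Welch two-sample t-tests and mean ± SEM summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "HistogramSpec",
    "LENGTH_HISTOGRAM",
    "WIDTH_HISTOGRAM",
    "DepthAreaProfile",
    "EstimationError",
    "histogram",
    "fold_change",
    "adhesion_increase",
    "plateau_depth",
    "two_sample_test",
    "mean_sem",
]


class EstimationError(RuntimeError):
    """Raised when too few events are available for a robust estimate."""


@dataclass(frozen=True)
class HistogramSpec:
    """Fixed binning for an event dimension.

    ``edges`` are the left edges of half-open bins ``[lo, hi)``; the
    final bin is open-ended ``[edges[-1], inf)``.  Values falling on an
    edge go to the upper bin.
    """

    variable: str  # "length" | "width"
    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("need at least two edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges)


#: 14 length bins: 0–20, 20–40, …, 270–300, 300–330 μm and an open tail
#: (the published "300–330 and >300" pair is resolved as [300, 330) and
#: [330, ∞))
LENGTH_HISTOGRAM = HistogramSpec(
    "length", (0, 20, 40, 60, 80, 100, 120, 150, 180, 210, 240, 270, 300, 330)
)

#: 11 width bins: 0–5, …, 25–30, 30–40, …, 60–70 μm and an open tail
#: standing in for the published terminal 70–80 μm bin
WIDTH_HISTOGRAM = HistogramSpec("width", (0, 5, 10, 15, 20, 25, 30, 40, 50, 60, 70))


def _extract(measurements, variable: str) -> np.ndarray:
    vals = [getattr(m, variable, m) for m in measurements]
    return np.asarray([float(v) for v in vals])


def histogram(measurements, spec: HistogramSpec) -> np.ndarray:
    """Bin event dimensions; counts always sum to the number of events.

    ``measurements`` may be raw values or objects exposing the spec's
    variable as an attribute (e.g. ``EventMeasurement``).
    """
    values = _extract(measurements, spec.variable)
    bins = np.append(np.asarray(spec.edges, dtype=float), np.inf)
    counts, _ = np.histogram(values, bins=bins)
    return counts


def fold_change(numerator: float, denominator: float) -> float:
    """Plain ratio of two pooled observables (e.g. resorbed-area %)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return float(numerator) / float(denominator)


def adhesion_increase(bone_density: float, dentin_density: float) -> float:
    """Percent increase of adhered-cell density on dentin over bone."""
    if bone_density <= 0:
        raise ValueError("bone density must be > 0")
    return 100.0 * (float(dentin_density) / float(bone_density) - 1.0)


@dataclass
class DepthAreaProfile:
    """Per-event (area, max depth) pairs of one donor/condition."""

    areas: np.ndarray  # um^2
    depths: np.ndarray  # um

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.areas.shape != self.depths.shape:
            raise ValueError("areas and depths must have the same length")

    @classmethod
    def from_measurements(cls, measurements) -> "DepthAreaProfile":
        return cls(
            areas=np.array([m.area for m in measurements]),
            depths=np.array([m.max_depth for m in measurements]),
        )


def plateau_depth(profile: DepthAreaProfile, area_quantile: float = 0.75) -> float:
    """Estimate the donor depth plateau from the depth/area relationship.

    Event depth increases with worked area up to a donor-specific
    maximum and then stays constant while area keeps growing; the
    plateau is therefore estimated as the mean maximum depth of the
    events above the given area quantile (default: top quartile), which
    is robust to small shallow events.
    """
    if not (0.0 <= area_quantile < 1.0):
        raise ValueError("area_quantile must be in [0, 1)")
    if profile.areas.size < 10:
        raise EstimationError("need at least 10 events for a plateau estimate")
    cut = float(np.quantile(profile.areas, area_quantile))
    sel = profile.areas >= cut
    return float(profile.depths[sel].mean())


def two_sample_test(group_a, group_b) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test; returns (t, two-sided p).

    Donor-to-donor variances differ visibly between conditions, so the
    unequal-variance form is the default.  Degenerate zero-variance
    groups are handled explicitly: identical constant groups give
    (0, 1), separated constant groups (±inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sd/√n; NaN for n = 1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    if arr.size == 1:
        return float(arr[0]), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))
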