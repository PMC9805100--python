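"""Molecular-mass calibration and resampling onto a common mass axis.

In SDS-PAGE the migration distance of a protein is, to good approximation,
linear in the logarithm of its molecular mass.  A prestained ladder of
known masses run alongside the samples therefore calibrates distance to
mass: detected marker bands are paired with the declared ladder masses and
a piecewise-linear interpolant in (distance, log10 mass) — extrapolated
beyond the end segments — assigns a mass to every migration distance.

Once calibrated, each lane profile is conservatively rebinned onto a shared
log-spaced mass grid, producing :class:`MassProfile` objects that can be
correlated across lanes, gels and laboratories regardless of run-to-run
electrophoresis variability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .image import GelError, GelGeometry, GelImage
from .lanes import Band, Lane, LaneProfile


@dataclass
class LadderSpec:
    """Ordered marker masses in kDa, largest (least migrated) first."""

    masses: tuple

    def __post_init__(self):
        self.masses = tuple(float(m) for m in self.masses)
        if len(self.masses) < 2:
            raise GelError("ladder needs at least 2 masses")
        if any(m <= 0 for m in self.masses):
            raise GelError("ladder masses must be positive")
        if any(a >= b for a, b in zip(self.masses[1:], self.masses[:-1])):
            raise GelError("ladder masses must be strictly decreasing")

    def __len__(self):
        return len(self.masses)


@dataclass
class CalibrationCurve:
    """Piecewise-linear mapping distance (px) -> log10 mass (kDa).

    The interpolant passes through every anchor exactly and continues the
    end segments' slopes beyond the anchor span (extrapolation).  Since
    larger proteins migrate less, the mapping is strictly decreasing.
    """

    distances: np.ndarray
    log_masses: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.log_masses = np.asarray(self.log_masses, dtype=float)
        if self.distances.size < 2:
            raise GelError("calibration needs at least 2 anchors")
        if np.any(np.diff(self.distances) <= 0):
            raise GelError("anchor distances must be strictly increasing")
        if np.any(np.diff(self.log_masses) >= 0):
            raise GelError("anchor masses must be strictly decreasing")

    @property
    def anchors(self) -> list[tuple[float, float]]:
        """(distance_px, mass_kDa) pairs."""
        return [(float(d), float(10.0 ** lm))
                for d, lm in zip(self.distances, self.log_masses)]

    def log_mass(self, d) -> np.ndarray:
        """log10 mass at distance(s) d, linearly extrapolated at the ends."""
        d = np.asarray(d, dtype=float)
        lm = np.interp(d, self.distances, self.log_masses)
        x, y = self.distances, self.log_masses
        s_first = (y[1] - y[0]) / (x[1] - x[0])
        s_last = (y[-1] - y[-2]) / (x[-1] - x[-2])
        lm = np.where(d < x[0], y[0] + s_first * (d - x[0]), lm)
        lm = np.where(d > x[-1], y[-1] + s_last * (d - x[-1]), lm)
        return lm

    def mass(self, d):
        """Mass in kDa at distance(s) d."""
        out = 10.0 ** self.log_mass(d)
        return float(out) if np.isscalar(d) else out

    def is_extrapolated(self, d) -> np.ndarray:
        """True where d lies outside the anchor span (less reliable mass)."""
        d = np.asarray(d, dtype=float)
        return (d < self.distances[0]) | (d > self.distances[-1])

    def to_dict(self) -> dict:
        return {"anchors": [{"distance_px": d, "mass_kDa": m}
                            for d, m in self.anchors],
                "model": "piecewise-linear in (distance, log10 mass), "
                         "end segments extrapolated"}


@dataclass
class MassProfile:
    """Intensity rebinned onto a shared, strictly decreasing mass grid.

    The grid (kDa, log-spaced by default) is the exchange axis: any two
    MassProfiles on identical grids are directly comparable, whatever gel
    they came from.
    """

    mass_grid: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mass_grid = np.asarray(self.mass_grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mass_grid.shape != self.intensities.shape:
            raise GelError("mass grid and intensities must have equal length")
        if np.any(np.diff(self.mass_grid) >= 0):
            raise GelError("mass grid must be strictly decreasing")
        if np.any(self.intensities < 0):
            raise GelError("mass-profile intensities must be >= 0")

    @property
    def total(self) -> float:
        return float(self.intensities.sum())

    def same_grid(self, other: "MassProfile") -> bool:
        return (self.mass_grid.shape == other.mass_grid.shape and
                bool(np.allclose(self.mass_grid, other.mass_grid,
                                 rtol=1e-12, atol=0.0)))


def default_mass_grid(n_cells: int = 500, top_kda: float = 260.0,
                      bottom_kda: float = 10.0) -> np.ndarray:
    """Log-spaced mass grid, 260 kDa down to 10 kDa in 500 cells by default
    (spans typical prestained ladders)."""
    if n_cells < 2 or top_kda <= bottom_kda or bottom_kda <= 0:
        raise GelError("invalid mass grid specification")
    return np.geomspace(top_kda, bottom_kda, n_cells)


def assign_marker_masses(bands: list[Band], ladder: LadderSpec
                         ) -> list[tuple[float, float]]:
    """Pair detected marker bands with the declared ladder masses.

    Bands must be sorted by migration distance.  With equal counts the
    pairing is positional (least migrated band <-> largest mass).  With
    surplus bands (spurious peaks), the ``len(ladder)`` bands of highest
    total prominence are kept; because the bands are distance-sorted,
    every subset preserves distance order, so this is exactly the
    maximal-prominence order-preserving assignment.  Prominence ties break
    toward the smaller distance.
    """
    if any(b1.apex_distance > b2.apex_distance
           for b1, b2 in zip(bands, bands[1:])):
        raise GelError("bands must be sorted by apex distance")
    k = len(ladder)
    if len(bands) < k:
        raise GelError(
            f"insufficient marker bands: {len(bands)} detected, "
            f"{k} ladder masses declared")
    if len(bands) > k:
        ranked = sorted(bands, key=lambda b: (-b.prominence, b.apex_distance))
        bands = sorted(ranked[:k], key=lambda b: b.apex_distance)
    return [(b.apex_distance, m) for b, m in zip(bands, ladder.masses)]


def _assign_marker_masses_bruteforce(bands: list[Band], ladder: LadderSpec
                                     ) -> list[tuple[float, float]]:
    """Exhaustive reference: best order-preserving subset over all C(n,k).

    Kept for cross-checking the fast path; O(C(n,k)) so only usable for
    small n.
    """
    k = len(ladder)
    if len(bands) < k:
        raise GelError("insufficient marker bands")
    best, best_score = None, -np.inf
    for subset in itertools.combinations(range(len(bands)), k):
        score = sum(bands[i].prominence for i in subset)
        if score > best_score:
            best_score, best = score, subset
    chosen = [bands[i] for i in best]
    return [(b.apex_distance, m) for b, m in zip(chosen, ladder.masses)]


def fit_calibration(anchors) -> CalibrationCurve:
    """Build the distance -> mass calibration through the given anchors.

    ``anchors`` are (distance_px, mass_kDa) pairs with strictly increasing
    distances and strictly decreasing masses.  This is interpolation, not
    regression: the curve passes through every anchor exactly.
    """
    anchors = list(anchors)
    if len(anchors) < 2:
        raise GelError("calibration needs at least 2 anchors")
    d = np.array([a[0] for a in anchors], dtype=float)
    m = np.array([a[1] for a in anchors], dtype=float)
    if np.any(m <= 0):
        raise GelError("anchor masses must be positive")
    return CalibrationCurve(d, np.log10(m))


def profile_to_mass_axis(profile: LaneProfile, curve: CalibrationCurve,
                         mass_grid: np.ndarray,
                         meta: dict | None = None) -> MassProfile:
    """Conservatively rebin a lane profile onto a mass grid.

    Each unit pixel interval [d, d+1) maps to the mass interval
    [mass(d+1), mass(d)); its intensity is deposited into grid cells in
    proportion to interval overlap in log10-mass coordinates, so total
    intensity is conserved wherever the grid covers the profile's mass
    span.  The operation is linear in the profile.
    """
    if not profile.background_subtracted:
        raise GelError("rebinning requires a background-subtracted profile")
    mass_grid = np.asarray(mass_grid, dtype=float)
    if mass_grid.ndim != 1 or mass_grid.size < 2:
        raise GelError("mass grid must be a 1-D array of >= 2 cells")
    if np.any(np.diff(mass_grid) >= 0):
        raise GelError("mass grid must be strictly decreasing")

    n = profile.intensities.size
    # Work in u = -log10(mass): increasing with migration distance.
    u_src = -curve.log_mass(np.arange(n + 1, dtype=float))
    log_centers = -np.log10(mass_grid)
    # Cell edges at midpoints; end cells extend by half a spacing.
    mids = 0.5 * (log_centers[:-1] + log_centers[1:])
    first = log_centers[0] - (mids[0] - log_centers[0])
    last = log_centers[-1] + (log_centers[-1] - mids[-1])
    u_edges = np.concatenate([[first], mids, [last]])

    out = np.zeros(mass_grid.size)
    y = profile.intensities
    for k in range(n):
        intensity = y[k]
        if intensity == 0.0:
            continue
        a, b = u_src[k], u_src[k + 1]
        if b <= a:
            raise GelError("calibration must be strictly monotone")
        j = int(np.searchsorted(u_edges, a, side="right")) - 1
        width = b - a
        while j < mass_grid.size and u_edges[j] < b:
            if j >= 0:
                lo = max(a, u_edges[j])
                hi = min(b, u_edges[j + 1])
                if hi > lo:
                    out[j] += intensity * (hi - lo) / width
            j += 1
    m = {"lane_index": profile.lane_index, "channel": profile.channel}
    if meta:
        m.update(meta)
    return MassProfile(mass_grid.copy(), out, m)


def estimate_bleed(img: GelImage, geom: GelGeometry, lanes: list[Lane],
                   sample_channel: str, marker_channel: str,
                   marker_lanes: tuple = (0,)) -> float:
    """Estimate the cross-channel bleed coefficient k (sample -> marker).

    A fluorophore emission shoulder can leak sample signal into the marker
    channel.  Over the non-marker lanes of the resolving gel, the marker
    channel should contain only background plus bleed, so k is the least
    squares slope of marker on sample intensity with an intercept
    absorbing background, clipped to [0, 1].  The regression is restricted
    to clearly signal-bearing pixels (sample intensity well above its
    median) — the background's spatial structure is shared by both
    channels and would otherwise bias the slope toward 1.
    """
    s_ch = img.channel(sample_channel)
    m_ch = img.channel(marker_channel)
    rows = slice(geom.resolving_top_row, geom.bottom_row)
    s_parts, m_parts = [], []
    for lane in lanes:
        if lane.index in marker_lanes:
            continue
        cols = slice(lane.left_col, lane.right_col)
        s_parts.append(s_ch[rows, cols].ravel())
        m_parts.append(m_ch[rows, cols].ravel())
    if not s_parts:
        raise GelError("no non-marker lanes available for bleed estimation")
    s = np.concatenate(s_parts)
    m = np.concatenate(m_parts)
    med = np.median(s)
    mad = np.median(np.abs(s - med))
    mask = s > med + 8.0 * mad
    if mask.sum() < 50:
        return 0.0
    s, m = s[mask], m[mask]
    s_c = s - s.mean()
    denom = float(np.dot(s_c, s_c))
    if denom == 0.0:
        return 0.0
    k = float(np.dot(s_c, m - m.mean()) / denom)
    return float(np.clip(k, 0.0, 1.0))


def correct_bleed(img: GelImage, k: float, sample_channel: str,
                  marker_channel: str) -> GelImage:
    """Subtract k x sample channel from the marker channel (clipped at 0)."""
    corrected = np.clip(img.channel(marker_channel)
                        - k * img.channel(sample_channel), 0.0, None)
    return img.with_channel(marker_channel, corrected)
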