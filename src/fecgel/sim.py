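"""Ground-truthed synthetic gel data for testing the full pipeline.

The generator renders two-channel fluorescence gel scans from first
principles: band migration follows the log-linear law d(M) = a − b·log10(M)
(the same idealisation the calibration assumes), bands are vertical
Gaussians spread across their lane with softened edges, the marker ladder
runs in its own channel, and the image receives background plateaus
(scanner margin, stacking gel, resolving gel), optional cross-channel
emission bleed, a global rotation, an exposure scale and additive noise.
Every rendered quantity is recorded in a :class:`GroundTruth` so each
pipeline stage can be scored against the truth.

It also generates the ancillary inputs of a quantification/classification
experiment: fluorophore dilution series and class-specific mass-profile
patterns (near-blank native samples versus the band ladders of stressed or
deglycosylated samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import MassProfile, default_mass_grid
from .image import GelError, GelGeometry, GelImage


@dataclass
class BandSpec:
    """One band: mass (kDa), loaded amount (pmol) and vertical width (px)."""

    mass_kda: float
    amount_pmol: float
    sigma_px: float = 3.0


@dataclass
class LaneSpec:
    """Bands of one lane, the channel they emit in, and a sample label."""

    bands: list = field(default_factory=list)
    channel: str = "700nm"
    label: str = ""


@dataclass
class SimConfig:
    """Synthetic gel configuration.

    Migration law: distance d(M) = a − b·log10(M kDa) with a, b > 0, so
    larger masses migrate less.  The defaults place a 250–10 kDa ladder
    inside a 280 px resolving gel.  ``gain`` converts pmol to integrated
    intensity counts.  Noise is additive Gaussian (optionally Poisson on
    top); ``bleed_k`` leaks that fraction of the 700 nm band signal into
    the 800 nm channel (emission-shoulder crosstalk).
    """

    shape: tuple = (360, 480)
    left: int = 40
    right: int = 440
    gel_top: int = 20
    resolving_top: int = 60
    bottom: int = 340
    a: float = 424.0
    b: float = 164.0
    channels: tuple = ("700nm", "800nm")
    lanes: list = field(default_factory=list)   # list[LaneSpec]
    ladder_masses: tuple = (250.0, 150.0, 100.0, 75.0, 50.0, 37.0, 25.0)
    ladder_channel: str = "800nm"
    marker_lanes: tuple = (0,)
    ladder_amount_pmol: float = 1.0
    ladder_sigma_px: float = 3.0
    rotation_deg: float = 0.0
    background_margin: float = 100.0
    background_stacking: float = 110.0
    background_resolving: float = 200.0
    background_gradient: float = 0.0   # per-row slope inside resolving gel
    noise_sigma: float = 0.0
    poisson: bool = False
    bleed_k: float = 0.0
    exposure: float = 1.0
    gain: float = 1.0e5                # intensity counts per pmol
    curvature: float = 0.0             # optional mild quadratic in log10 M
    seed: int = 0

    def __post_init__(self):
        if self.b <= 0 or self.a <= 0:
            raise GelError("migration law requires a > 0 and b > 0")
        if not (0 <= self.left < self.right <= self.shape[1]):
            raise GelError("gel column bounds outside image")
        if not (0 <= self.gel_top < self.resolving_top < self.bottom
                <= self.shape[0]):
            raise GelError("gel row bounds outside image")

    def migration_distance(self, mass_kda: float) -> float:
        """Distance (px below the resolving border) for a given mass."""
        lm = np.log10(mass_kda)
        return self.a - self.b * lm + self.curvature * lm * lm

    @property
    def n_lanes(self) -> int:
        return len(self.lanes)

    def true_geometry(self) -> GelGeometry:
        return GelGeometry(self.left, self.right, self.resolving_top,
                           self.bottom, rotation_deg=self.rotation_deg)


@dataclass
class TrueBand:
    lane: int
    channel: str
    mass_kda: float
    distance_px: float      # below the resolving border, unrotated frame
    apex_row: float
    total_intensity: float  # integrated counts after exposure, before noise


@dataclass
class GroundTruth:
    """Everything the simulator knows about a rendered gel."""

    geometry: GelGeometry
    rotation_deg: float
    migration_a: float
    migration_b: float
    bands: list = field(default_factory=list)       # list[TrueBand]
    lane_bounds: list = field(default_factory=list)  # (left, right) per lane
    fluor_pmol_per_lane: dict = field(default_factory=dict)
    exposure: float = 1.0
    gain: float = 1.0e5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        return d


def _render_band(raster: np.ndarray, apex_row: float, total: float,
                 sigma: float, left: int, right: int,
                 well_fraction: float = 0.7) -> None:
    """Add one band: vertical Gaussian x soft-edged horizontal box.

    The sample occupies the well width — ``well_fraction`` of the lane
    pitch, centred — with Gaussian shoulders, leaving the inter-lane gaps
    that make vertical lane alignment observable.  Both factors are
    normalised so the band integrates to ``total`` (within Gaussian
    truncation at 6 sigma).
    """
    n_rows = raster.shape[0]
    lo = max(0, int(np.floor(apex_row - 6 * sigma)))
    hi = min(n_rows, int(np.ceil(apex_row + 6 * sigma)) + 1)
    rows = np.arange(lo, hi)
    g = np.exp(-0.5 * ((rows - apex_row) / sigma) ** 2)
    g /= g.sum()
    width = right - left
    cols = np.arange(width)
    centre = (width - 1) / 2.0
    half_well = 0.5 * well_fraction * width
    edge_sigma = max(1.0, 0.05 * width)
    excess = np.clip(np.abs(cols - centre) - half_well, 0.0, None)
    w = np.exp(-0.5 * (excess / edge_sigma) ** 2)
    w /= w.sum()
    raster[lo:hi, left:right] += total * np.outer(g, w)


def _lane_bounds(cfg: SimConfig) -> list[tuple[int, int]]:
    width = cfg.right - cfg.left
    n = cfg.n_lanes
    base, rem = divmod(width, n)
    bounds, left = [], cfg.left
    for i in range(n):
        w = base + (1 if i < rem else 0)
        bounds.append((left, left + w))
        left += w
    return bounds


def simulate_gel(cfg: SimConfig) -> tuple[GelImage, GroundTruth]:
    """Render a synthetic two-channel gel and its ground truth.

    Deterministic for a fixed ``cfg.seed``.
    """
    if cfg.n_lanes < 1:
        raise GelError("simulation needs at least one lane")
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.shape
    signal = {ch: np.zeros((rows, cols)) for ch in cfg.channels}
    bounds = _lane_bounds(cfg)
    truth = GroundTruth(geometry=cfg.true_geometry(),
                        rotation_deg=cfg.rotation_deg,
                        migration_a=cfg.a, migration_b=cfg.b,
                        lane_bounds=[list(b) for b in bounds],
                        exposure=cfg.exposure, gain=cfg.gain, seed=cfg.seed)

    def add_band(lane_i: int, channel: str, band: BandSpec) -> None:
        d = cfg.migration_distance(band.mass_kda)
        apex = cfg.resolving_top + d
        if not (cfg.resolving_top <= apex < cfg.bottom):
            raise GelError(
                f"band of {band.mass_kda} kDa falls outside the resolving gel")
        total = band.amount_pmol * cfg.gain  # exposure applied at assembly
        left, right = bounds[lane_i]
        _render_band(signal[channel], apex, total, band.sigma_px, left, right)
        truth.bands.append(TrueBand(lane_i, channel, band.mass_kda,
                                    float(d), float(apex),
                                    float(total * cfg.exposure)))

    for lane_i in cfg.marker_lanes:
        for mass in cfg.ladder_masses:
            add_band(lane_i, cfg.ladder_channel,
                     BandSpec(mass, cfg.ladder_amount_pmol,
                              cfg.ladder_sigma_px))
    for lane_i, lane in enumerate(cfg.lanes):
        pmol = 0.0
        for band in lane.bands:
            add_band(lane_i, lane.channel, band)
            pmol += band.amount_pmol
        if lane.channel == "700nm":
            truth.fluor_pmol_per_lane[lane_i] = pmol

    # Emission-shoulder bleed: a fraction of the sample band signal leaks
    # into the marker channel (backgrounds do not bleed; they are gel
    # autofluorescence rendered per channel).
    if cfg.bleed_k and "700nm" in signal and "800nm" in signal:
        signal["800nm"] = signal["800nm"] + cfg.bleed_k * signal["700nm"]

    channels_px = []
    for ch in cfg.channels:
        bg = np.full((rows, cols), cfg.background_margin)
        bg[cfg.gel_top:cfg.bottom, cfg.left:cfg.right] = cfg.background_stacking
        resolve = np.full((cfg.bottom - cfg.resolving_top, 1),
                          cfg.background_resolving)
        if cfg.background_gradient:
            resolve = resolve + cfg.background_gradient * \
                np.arange(cfg.bottom - cfg.resolving_top)[:, None]
        bg[cfg.resolving_top:cfg.bottom, cfg.left:cfg.right] = resolve
        channels_px.append((bg + signal[ch]) * cfg.exposure)
    px = np.stack(channels_px)

    if cfg.rotation_deg != 0.0:
        from scipy import ndimage
        margin = cfg.background_margin * cfg.exposure
        px = np.stack([ndimage.rotate(c, cfg.rotation_deg, reshape=False,
                                      order=1, mode="constant", cval=margin)
                       for c in px])

    if cfg.poisson:
        px = rng.poisson(np.clip(px, 0.0, None)).astype(float)
    if cfg.noise_sigma > 0:
        px = px + rng.normal(0.0, cfg.noise_sigma, size=px.shape)
    px = np.clip(px, 0.0, None)

    img = GelImage(px, cfg.channels, 16, {"simulated": True, "seed": cfg.seed})
    return img, truth


# ---------------------------------------------------------------------------
# Class patterns for reference-library experiments


@dataclass
class ClassSpec:
    """A modification class: label plus (mass kDa, relative amplitude)
    bands.  A near-blank native-like class is one with a tiny scale."""

    label: str
    bands: list          # list of (mass_kda, rel_amplitude)
    scale: float = 1.0   # overall intensity multiplier


def render_class_profile(spec: ClassSpec, grid: np.ndarray | None = None,
                         sigma_log: float = 0.018,
                         scale: float | None = None) -> MassProfile:
    """Deterministic noise-free pattern of one class on the mass grid.

    Bands are Gaussians in log10-mass of width ``sigma_log`` decades
    (matching a ~3 px band at the default migration slope).
    """
    if grid is None:
        grid = default_mass_grid()
    lg = np.log10(grid)
    y = np.zeros(grid.size)
    s = spec.scale if scale is None else scale
    for mass, amp in spec.bands:
        y += amp * np.exp(-0.5 * ((lg - np.log10(mass)) / sigma_log) ** 2)
    return MassProfile(grid, s * y, {"label": spec.label, "class": spec.label})


def simulate_class_patterns(classes: list[ClassSpec], n_replicates: int = 3,
                            jitter: float = 0.1, noise_sigma: float = 0.0,
                            seed: int = 0,
                            grid: np.ndarray | None = None
                            ) -> tuple[list[MassProfile], list[MassProfile]]:
    """Reference profiles plus jittered replicate queries per class.

    Replicates receive per-band multiplicative intensity jitter
    (1 + N(0, jitter), floored at 10 %) and additive Gaussian noise —
    the run-to-run variability of real gels.  Classes with identical band
    lists are rejected (they could never be told apart).
    """
    if len(classes) < 2:
        raise GelError("need at least 2 classes")
    seen = {}
    for c in classes:
        key = tuple(sorted((round(m, 6), round(a, 6)) for m, a in c.bands))
        if key in seen:
            raise GelError(
                f"classes {seen[key]!r} and {c.label!r} have identical bands")
        seen[key] = c.label
    if grid is None:
        grid = default_mass_grid()
    rng = np.random.default_rng(seed)
    refs, queries = [], []
    for spec in classes:
        refs.append(render_class_profile(spec, grid))
        for r in range(n_replicates):
            lg = np.log10(grid)
            y = np.zeros(grid.size)
            for mass, amp in spec.bands:
                jit = max(0.1, 1.0 + rng.normal(0.0, jitter)) if jitter else 1.0
                y += amp * jit * np.exp(
                    -0.5 * ((lg - np.log10(mass)) / 0.018) ** 2)
            y = spec.scale * y
            if noise_sigma > 0:
                y = y + rng.normal(0.0, noise_sigma, size=y.size)
            y = np.clip(y, 0.0, None)
            queries.append(MassProfile(grid, y,
                                       {"label": f"{spec.label}_rep{r}",
                                        "class": spec.label}))
    return refs, queries


def canonical_classes() -> list[ClassSpec]:
    """Four canonical antibody modification classes for library experiments.

    Emulates a limited-proteolysis/labelling experiment on an IgG: the
    native sample is near-blank (very low labelling), while UV-stressed,
    heat-stressed and deglycosylated samples show distinct fragment
    ladders of characteristic masses and intensities.
    """
    return [
        ClassSpec("native", [(55.0, 1.0), (28.0, 0.5)], scale=0.15),
        ClassSpec("uv_stress", [(150.0, 0.4), (75.0, 1.0), (50.0, 0.7),
                                (37.0, 0.3)], scale=1.0),
        ClassSpec("heat_stress", [(100.0, 1.0), (60.0, 0.8), (45.0, 0.9),
                                  (30.0, 0.5), (20.0, 0.4)], scale=1.6),
        ClassSpec("deglycosylated", [(140.0, 0.6), (120.0, 0.3), (48.0, 1.0),
                                     (24.0, 0.45)], scale=1.0),
    ]


def class_gel_config(classes: list[ClassSpec], *, base_pmol: float = 1.0,
                     jitter: float = 0.0, seed: int = 0,
                     rotation_deg: float = 0.0, noise_sigma: float = 0.0,
                     exposure: float = 1.0, bleed_k: float = 0.0,
                     extra_lanes: list | None = None,
                     n_lanes: int = 10) -> SimConfig:
    """Gel configuration for a reference-library experiment.

    Lane 0 carries the marker ladder; lanes 1..len(classes) carry one
    sample per class, with band amounts = relative amplitude x class
    scale x ``base_pmol``, optionally jittered multiplicatively per band
    (run-to-run loading/labelling variability).  ``extra_lanes`` appends
    (label, [(mass_kda, amount_pmol), ...]) lanes — e.g. intermediate-dose
    or spike-in mixture samples.  Remaining lanes stay empty.
    """
    rng = np.random.default_rng(seed)
    lanes = [LaneSpec()]
    for spec in classes:
        bands = []
        for mass, amp in spec.bands:
            amount = amp * spec.scale * base_pmol
            if jitter:
                amount *= max(0.1, 1.0 + rng.normal(0.0, jitter))
            bands.append(BandSpec(mass, amount))
        lanes.append(LaneSpec(bands=bands, label=spec.label))
    for label, band_list in (extra_lanes or []):
        lanes.append(LaneSpec(bands=[BandSpec(m, a) for m, a in band_list],
                              label=label))
    while len(lanes) < n_lanes:
        lanes.append(LaneSpec())
    return SimConfig(lanes=lanes, rotation_deg=rotation_deg,
                     noise_sigma=noise_sigma, exposure=exposure,
                     bleed_k=bleed_k, seed=seed)


def spike_in_bands(spike: ClassSpec, diluent: ClassSpec, frac_spike: float,
                   base_pmol: float = 1.0) -> list:
    """Band list of a mixture: ``frac_spike`` of one class diluted into
    another (e.g. 20 % deglycosylated protein in native sample)."""
    bands = [(m, a * spike.scale * base_pmol * frac_spike)
             for m, a in spike.bands]
    bands += [(m, a * diluent.scale * base_pmol * (1.0 - frac_spike))
              for m, a in diluent.bands]
    return bands


def mix_profiles(a: MassProfile, b: MassProfile, frac_a: float,
                 label: str) -> MassProfile:
    """Weighted mixture frac_a * a + (1 - frac_a) * b (spike-in samples)."""
    if not a.same_grid(b):
        raise GelError("mixture components must share the mass grid")
    y = frac_a * a.intensities + (1.0 - frac_a) * b.intensities
    return MassProfile(a.mass_grid.copy(), y, {"label": label})


def simulate_dilution_series(true_slope: float, true_intercept: float = 0.0,
                             n_points: int = 8, noise_sigma: float = 0.0,
                             seed: int = 0, top_pmol: float = 10.0,
                             dilution_factor: float = 2.0):
    """Serial fluorophore dilution with intensities from the linear law.

    Returns (points, truth): points are (pmol, intensity) pairs from a
    ``dilution_factor``-fold serial dilution starting at ``top_pmol``;
    truth records the generating slope/intercept.
    """
    if n_points < 2:
        raise GelError("dilution series needs at least 2 points")
    rng = np.random.default_rng(seed)
    pmol = top_pmol / dilution_factor ** np.arange(n_points)
    intensity = true_slope * pmol + true_intercept
    if noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_sigma, size=n_points)
    points = list(zip(pmol.tolist(), intensity.tolist()))
    truth = {"slope": true_slope, "intercept": true_intercept,
             "noise_sigma": noise_sigma, "seed": seed}
    return points, truth
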