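"""Gel image containers, loading, geometry detection and rotation correction.

An SDS-PAGE fluorescence scan arrives as one grayscale raster per emission
channel (e.g. 700 nm for the Cy5.5-labelled sample, 800 nm for the
prestained molecular-weight ladder).  Before any densitometry the gel
cassette must be located inside the scan, the border between stacking and
resolving gel found (migration distances are measured from it), and a small
global rotation corrected so that lanes run vertically.

Coordinate convention: 0-based pixel indices; the row index increases
downward, i.e. in the direction of electrophoretic migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage


class GelError(Exception):
    """Base class for errors raised by the gel analysis pipeline."""


@dataclass
class GelImage:
    """Multi-channel gel raster.

    Parameters
    ----------
    pixels : ndarray, shape (n_channels, rows, cols)
        Per-channel intensity rasters in arbitrary linear fluorescence
        units.  Stored as float64 internally; integer inputs are preserved
        exactly (float64 represents 16-bit counts without loss).
    channels : sequence of str
        Ordered channel labels, e.g. ``("700nm", "800nm")``.
    bit_depth : int
        Bit depth of the originating scan (8 or 16 typically).
    meta : dict
        Free-form provenance (gel id, date, instrument, ...).
    """

    pixels: np.ndarray
    channels: tuple
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[np.newaxis]
        if self.pixels.ndim != 3:
            raise GelError("pixels must be (n_channels, rows, cols)")
        self.channels = tuple(str(c) for c in self.channels)
        if len(self.channels) == 0:
            raise GelError("at least one channel is required")
        if len(self.channels) != self.pixels.shape[0]:
            raise GelError(
                f"channel count mismatch: {len(self.channels)} labels for "
                f"{self.pixels.shape[0]} pages"
            )
        if len(set(self.channels)) != len(self.channels):
            raise GelError("channel labels must be unique")
        if not np.all(np.isfinite(self.pixels)):
            raise GelError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise GelError("pixel intensities must be >= 0")

    @property
    def shape(self):
        """(rows, cols) of each channel."""
        return self.pixels.shape[1:]

    def channel(self, label: str) -> np.ndarray:
        """Return the 2-D raster for one channel label."""
        try:
            i = self.channels.index(label)
        except ValueError:
            raise GelError(f"unknown channel {label!r}; have {self.channels}")
        return self.pixels[i]

    def sum_channels(self) -> np.ndarray:
        """Sum of all channels — the raster used for geometry detection."""
        return self.pixels.sum(axis=0)

    def with_channel(self, label: str, raster: np.ndarray) -> "GelImage":
        """Return a copy with one channel replaced (e.g. bleed-corrected)."""
        i = self.channels.index(label)
        px = self.pixels.copy()
        px[i] = raster
        return GelImage(px, self.channels, self.bit_depth, dict(self.meta))


@dataclass
class GelGeometry:
    """Detected gel-cassette geometry.

    ``left_col``/``right_col`` bound the gel columns (right exclusive),
    ``resolving_top_row`` is the stacking/resolving border from which
    migration distances are measured, ``bottom_row`` (exclusive) the gel
    cassette bottom.  ``rotation_deg`` records any rotation already applied
    to the image this geometry refers to.
    """

    left_col: int
    right_col: int
    resolving_top_row: int
    bottom_row: int
    rotation_deg: float = 0.0

    def __post_init__(self):
        if not self.left_col < self.right_col:
            raise GelError("left_col must be < right_col")
        if not self.resolving_top_row < self.bottom_row:
            raise GelError("resolving_top_row must be < bottom_row")

    @property
    def width(self) -> int:
        return self.right_col - self.left_col

    @property
    def n_distances(self) -> int:
        """Number of migration-distance samples in the resolving gel."""
        return self.bottom_row - self.resolving_top_row

    def to_dict(self) -> dict:
        return asdict(self)


def load_gel_image(path, channel_labels: Sequence[str]) -> GelImage:
    """Load a single- or multi-page grayscale TIFF (or PNG) as a GelImage.

    The page order must match ``channel_labels``.  Intensities are
    preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise GelError(f"cannot read image: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise GelError(f"expected grayscale pages, got array of shape {arr.shape}")
    # A trailing small axis means RGB(A) colour pages, which are not gel scans.
    if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        raise GelError("non-grayscale (colour) image pages are not supported")
    if arr.shape[0] != len(channel_labels):
        raise GelError(
            f"page/label count mismatch: {arr.shape[0]} pages, "
            f"{len(channel_labels)} labels"
        )
    bit_depth = 16
    if arr.dtype == np.uint8:
        bit_depth = 8
    return GelImage(arr.astype(float), tuple(channel_labels), bit_depth,
                    {"source": str(path)})


def write_gel_tiff(img: GelImage, path) -> np.ndarray:
    """Write a GelImage as a multi-page uint16 TIFF; returns the written array.

    Values are clipped to the uint16 range and rounded; the caller is
    responsible for scaling into range beforehand if needed.
    """
    import tifffile

    arr = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)
    return arr


def _strongest_step(projection: np.ndarray, significance: float):
    """Locate the strongest rising and falling steps of a 1-D projection.

    A step between samples i and i+1 is attributed to index i+1 (the first
    sample on the new level).  Significance is assessed on a smoothed copy
    of the projection, so an edge smeared over a few samples by residual
    rotation still registers; the precise location is then the strongest
    raw sample-to-sample step near the smoothed optimum (exact for an
    ideal step).  Returns (rise_index, fall_index, ok) where ok is False
    when no smoothed step clears ``significance`` times the median
    absolute smoothed step — the featureless-image guard.
    """
    p = projection.astype(float)
    d = np.diff(p)
    if d.size == 0:
        return 0, 0, False
    smooth = ndimage.uniform_filter1d(p, size=5, mode="nearest")
    ds = np.diff(smooth)
    med = np.median(np.abs(ds))
    if not np.max(np.abs(ds)) > significance * med:
        return 0, 0, False

    def localise(coarse: int, sign: float) -> int:
        lo = max(0, coarse - 4)
        hi = min(d.size, coarse + 5)
        return lo + int(np.argmax(sign * d[lo:hi])) + 1

    rise = localise(int(np.argmax(ds)), +1.0)
    fall = localise(int(np.argmin(ds)), -1.0)
    return rise, fall, True


def detect_gel_region(img: GelImage, significance: float = 5.0) -> GelGeometry:
    """Find the gel bounds and the stacking/resolving border.

    The left/right gel boundaries are the strongest rising/falling steps of
    the column-wise intensity projection; the stacking/resolving border is
    the strongest rising step of the row-wise projection (restricted to gel
    columns) within the upper third of the image; the gel bottom is the
    lowest row whose summed intensity still exceeds background.

    Raises ``GelError("no gel detected")`` when no projection step exceeds
    ``significance`` times the median absolute step.
    """
    raster = img.sum_channels()
    n_rows, n_cols = raster.shape

    col_proj = raster.sum(axis=0)
    left, right, ok = _strongest_step(col_proj, significance)
    if not ok or not left < right:
        raise GelError("no gel detected")

    row_proj = raster[:, left:right].sum(axis=1)
    resolving_top, _, ok = _strongest_step(row_proj[: max(2, n_rows // 3)],
                                           significance)
    if not ok:
        raise GelError("no gel detected")

    # Gel bottom: last row whose projection exceeds background by a quarter
    # of the dynamic range (robust percentile estimates of both levels).
    bg = np.percentile(row_proj, 5)
    hi = np.percentile(row_proj, 95)
    thr = bg + 0.25 * (hi - bg)
    above = np.nonzero(row_proj > thr)[0]
    if above.size == 0 or above[-1] <= resolving_top:
        raise GelError("no gel detected")
    bottom = int(above[-1]) + 1

    return GelGeometry(left, right, resolving_top, bottom, rotation_deg=0.0)


def background_median(raster: np.ndarray, frame: int = 5) -> float:
    """Background level estimated as the median of the image border ring.

    The outermost pixels of a gel scan are scanner margin, outside the
    cassette, so their median is a robust background estimate unaffected
    by the gel itself.
    """
    f = max(1, min(frame, raster.shape[0] // 2, raster.shape[1] // 2))
    ring = np.concatenate([raster[:f].ravel(), raster[-f:].ravel(),
                           raster[f:-f, :f].ravel(),
                           raster[f:-f, -f:].ravel()])
    return float(np.median(ring))


def _rotation_grid_search(raster: np.ndarray, geom: GelGeometry,
                          search_range_deg: float, step_deg: float) -> float:
    """Exhaustive search for the angle maximising the alignment score.

    The score of an angle is the variance of the first difference of the
    column-sum projection of the band-bearing window (rows below the
    stacking/resolving border) after rotating the whole raster by that
    angle: vertical lanes concentrate intensity into few columns with
    sharp flanks, maximising the high-frequency content of the
    projection.  Differencing the projection high-passes it, which gives
    a considerably sharper optimum than the variance of the raw
    projection (broad intensity ramps contribute to the latter but carry
    no alignment information).

    Only the gel interior is scored: the window is inset so the slanted
    gel edges and stacking border stay outside it at every candidate
    angle (their wedges would otherwise add variance exactly when
    misaligned).  Ties break toward the smallest ``|angle|``, then
    negative before positive, so a featureless raster scores 0.0.
    """
    full = ndimage.gaussian_filter(raster, sigma=1.0)
    n_rows = geom.n_distances
    n_cols = geom.width
    tan_max = np.tan(np.radians(abs(search_range_deg)))
    row_inset = int(np.ceil(0.5 * n_cols * tan_max)) + 2
    col_inset = int(np.ceil(0.5 * n_rows * tan_max)) + 2
    if n_rows <= 4 * row_inset or n_cols <= 4 * col_inset:
        row_inset = col_inset = 0
    window = (slice(geom.resolving_top_row + row_inset,
                    geom.bottom_row - row_inset),
              slice(geom.left_col + col_inset, geom.right_col - col_inset))
    cval = background_median(full)

    def score(angle: float) -> float:
        if angle != 0.0:
            rotated = ndimage.rotate(full, angle, reshape=False, order=1,
                                     mode="constant", cval=cval)
        else:
            rotated = full
        return float(np.var(np.diff(rotated[window].sum(axis=0))))

    n = int(round(search_range_deg / step_deg))
    angles = np.round(np.arange(-n, n + 1) * step_deg, 10)
    order = sorted(angles, key=lambda a: (abs(a), a >= 0))
    best_angle, best_score = 0.0, -np.inf
    for a in order:
        s = score(float(a))
        # relative tie tolerance: numerically flat landscapes (featureless
        # regions) must resolve by the angle ordering, not float dust
        if s > best_score * (1.0 + 1e-9) + 1e-18:
            best_score, best_angle = s, float(a)
    return best_angle


def _shear_residual(raster: np.ndarray, geom: GelGeometry) -> float:
    """Small residual tilt (degrees) from per-lane centroid shear.

    Loaded samples are horizontally symmetric about their lane centre, so
    within one lane the column centroid of the band signal estimates the
    lane centre at the signal's row centroid, whatever the bands are.
    Splitting the band-bearing region into upper and lower halves, each
    contiguous signal column-cluster (one loaded lane) yields a
    (Δcolumn-centroid / Δrow-centroid) slope — the tangent of the
    residual tilt.  The mass-weighted mean over clusters is converted to
    degrees.  Sub-pixel accurate and invariant to interpolation blur,
    but only valid once the gel is roughly upright.
    """
    window = raster[geom.resolving_top_row:geom.bottom_row,
                    geom.left_col:geom.right_col].astype(float)
    n_rows, n_cols = window.shape
    if n_rows < 16 or n_cols < 4:
        return 0.0
    window = ndimage.gaussian_filter(window, sigma=1.0)
    signal = np.clip(window - np.median(window), 0.0, None)
    colsum = signal.sum(axis=0)
    thr = 0.2 * colsum.max()
    if thr <= 0:
        return 0.0
    on = colsum > thr
    # contiguous column clusters = loaded lanes
    edges = np.flatnonzero(np.diff(on.astype(int)))
    starts = [e + 1 for e in edges if not on[e]]
    if on[0]:
        starts.insert(0, 0)
    ends = [e + 1 for e in edges if on[e]]
    if on[-1]:
        ends.append(n_cols)
    # Extend each cluster into the inter-lane gap (capped at the gap
    # midpoint) so the soft band shoulders are not truncated — truncation
    # at a fixed window biases both centroids toward the window centre
    # and attenuates the measured shear.
    margin = 6
    clusters = []
    for i, (c0, c1) in enumerate(zip(starts, ends)):
        lo_cap = 0 if i == 0 else (ends[i - 1] + c0) // 2
        hi_cap = n_cols if i == len(starts) - 1 else (c1 + starts[i + 1]) // 2
        clusters.append((max(lo_cap, c0 - margin), min(hi_cap, c1 + margin)))
    half = n_rows // 2
    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    slopes, weights = [], []
    for c0, c1 in clusters:
        if c1 - c0 < 3:
            continue
        block_t = signal[:half, c0:c1]
        block_b = signal[half:, c0:c1]
        m_t, m_b = block_t.sum(), block_b.sum()
        if m_t <= 0 or m_b <= 0:
            continue
        ct = float((block_t * cols[c0:c1]).sum() / m_t)
        cb = float((block_b * cols[c0:c1]).sum() / m_b)
        rt = float((block_t.sum(axis=1) * rows[:half]).sum() / m_t)
        rb = float((block_b.sum(axis=1) * rows[half:]).sum() / m_b)
        if rb - rt < 10:
            continue
        slopes.append((cb - ct) / (rb - rt))
        weights.append(min(m_t, m_b) * (rb - rt))
    if not slopes:
        return 0.0
    slope = float(np.average(slopes, weights=weights))
    return float(np.degrees(np.arctan(slope)))


def estimate_rotation(img: GelImage, geom: GelGeometry,
                      search_range_deg: float = 5.0,
                      step_deg: float = 0.1,
                      max_refinements: int = 3) -> float:
    """Estimate the rotation correction (degrees) aligning lanes vertically.

    An exhaustive grid search over ``[-search_range_deg,
    +search_range_deg]`` in steps of ``step_deg`` maximises the variance
    of the differenced column-sum projection of the band-bearing region
    after rotation (see :func:`_rotation_grid_search`).  The coarse
    estimate is then refined: the image is rectified by the current
    estimate, the geometry re-detected, and the residual tilt measured by
    sub-pixel cross-correlation of half-region projections
    (:func:`_shear_residual`) — the projection score alone cannot resolve
    tilts of a few tenths of a degree.  The result is rounded to the
    search resolution and is fully deterministic; a flat image returns
    0.0 by the grid tie-break.
    """
    total = _rotation_grid_search(img.sum_channels(), geom,
                                  search_range_deg, step_deg)
    for _ in range(max_refinements):
        if abs(total) > 10.0:
            break
        try:
            work = rectify(img, total) if total != 0.0 else img
            g = detect_gel_region(work)
        except GelError:
            break
        residual = _shear_residual(work.sum_channels(), g)
        if abs(residual) < 0.5 * step_deg:
            break
        # the residual carries the sign of the remaining applied tilt;
        # the correction is its negative
        total = float(total - residual)
    return float(np.round(np.round(total / step_deg) * step_deg, 10))


def rectify(img: GelImage, angle: float) -> GelImage:
    """Rotate all channels by ``angle`` degrees about the image centre.

    Bilinear interpolation; pixels entering from outside the frame are
    filled with the channel's background median so no spurious edges are
    introduced.  Only small corrections (|angle| <= 10°) are accepted.
    """
    if abs(angle) > 10.0:
        raise GelError(f"rotation angle {angle} out of range (|angle| <= 10)")
    if angle == 0.0:
        return GelImage(img.pixels.copy(), img.channels, img.bit_depth,
                        dict(img.meta))
    out = np.empty_like(img.pixels)
    for i in range(img.pixels.shape[0]):
        ch = img.pixels[i]
        out[i] = ndimage.rotate(ch, angle, reshape=False, order=1,
                                mode="constant", cval=background_median(ch))
    out = np.clip(out, 0.0, None)
    meta = dict(img.meta)
    meta["rotation_applied_deg"] = meta.get("rotation_applied_deg", 0.0) + angle
    return GelImage(out, img.channels, img.bit_depth, meta)
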