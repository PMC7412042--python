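"""Paper-ECG rendering and digitization.

Renders calibrated 3x4 simultaneous-lead printouts (25 mm/s, 10 mm/mV,
standard red millimeter grid, plus a full-length rhythm strip) and
recovers signals from such images: grid pixels are removed by color
thresholding, the remaining trace pixels are reduced column-wise to one
amplitude per image column, and the calibration frame converts pixels
to millivolts and milliseconds.

The renderer doubles as the test-fixture generator: because it returns
the exact layout geometry and calibration it used, render -> digitize
round trips are fully self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from skimage.filters import threshold_otsu

from .records import PaperECGSignals, COLUMN_DURATION, RECORD_DURATION

MM_PER_SECOND = 25.0
MM_PER_MV = 10.0


@dataclass
class CalibrationFrame:
    """Three reference pixels fixing the paper coordinate system.

    ``origin`` maps to (0 ms, 0 mV), ``one_mv`` to (0 ms, 1 mV) and
    ``ms200`` to (200 ms, 0 mV); the derived scale factors convert
    pixel offsets into physical units.
    """

    origin: tuple[float, float]   # (x, y) pixel
    one_mv: tuple[float, float]
    ms200: tuple[float, float]

    def __post_init__(self) -> None:
        p0, p1, p2 = map(np.asarray, (self.origin, self.one_mv, self.ms200))
        u, v = p1 - p0, p2 - p0
        cross = u[0] * v[1] - u[1] * v[0]
        if abs(float(cross)) < 1e-9:
            raise ValueError("calibration points must be non-collinear")
        if self.mv_per_pixel <= 0 or self.ms_per_pixel <= 0:
            raise ValueError("calibration factors must be positive")

    @property
    def mv_per_pixel(self) -> float:
        dy = self.origin[1] - self.one_mv[1]  # image y grows downward
        return 1.0 / dy if dy != 0 else -1.0

    @property
    def ms_per_pixel(self) -> float:
        dx = self.ms200[0] - self.origin[0]
        return 200.0 / dx if dx != 0 else -1.0


@dataclass
class ColorThresholds:
    """Per-channel inclusive bounds classifying waveform (trace) pixels."""

    lower: tuple[int, int, int] = (0, 0, 0)
    upper: tuple[int, int, int] = (120, 120, 120)

    def __post_init__(self) -> None:
        if any(lo > hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class LeadRegion:
    """Pixel extent of one lead's trace on the page."""

    x_start: int
    x_end: int
    y_baseline: float
    y_top: int
    y_bottom: int
    offset: float  # column start time, s


@dataclass
class PageLayout:
    """Geometry of a rendered (or scanned) 3x4 page."""

    regions: dict[str, LeadRegion]
    rhythm_lead: str
    rhythm_region: LeadRegion
    calibration: CalibrationFrame
    dpi: int


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

_ROWS = (("I", "aVR", "V1", "V4"), ("II", "aVL", "V2", "V5"), ("III", "aVF", "V3", "V6"))

_GRID_MINOR = np.array([255, 190, 190], dtype=np.uint8)
_GRID_MAJOR = np.array([255, 130, 130], dtype=np.uint8)
_TRACE = np.array([0, 0, 0], dtype=np.uint8)


def _draw_trace(
    image: np.ndarray,
    samples: np.ndarray,
    fs: float,
    x_start: int,
    n_cols: int,
    sec_per_px: float,
    y_baseline: float,
    px_per_mv: float,
    y_top: int,
    y_bottom: int,
) -> None:
    """Plot a segment like a pen recorder: per pixel column, ink the
    vertical span the signal sweeps during that column's time interval.

    Time zero sits exactly on pixel column ``x_start`` and advances by
    ``sec_per_px`` per column, so the drawing is consistent with the
    calibration frame to sub-pixel accuracy."""
    t_sample = np.arange(len(samples)) / fs
    sub = 8
    for col in range(n_cols):
        t_a = col * sec_per_px
        t_b = (col + 1) * sec_per_px
        tt = np.linspace(t_a, t_b, sub)
        vals = np.interp(tt, t_sample, samples)
        y_lo = y_baseline - vals.max() * px_per_mv
        y_hi = y_baseline - vals.min() * px_per_mv
        if y_hi - y_lo < 1.2:  # minimum pen thickness
            c = (y_lo + y_hi) / 2.0
            y_lo, y_hi = c - 0.6, c + 0.6
        # anti-aliased vertical span: boundary pixels are shaded by their
        # ink coverage, as a real scan of a pen trace would be
        r0 = int(np.floor(y_lo + 0.5))
        r1 = int(np.floor(y_hi + 0.5))
        for r in range(max(r0, y_top), min(r1, y_bottom - 1) + 1):
            cov = min(r + 0.5, y_hi) - max(r - 0.5, y_lo)
            cov = float(np.clip(cov, 0.0, 1.0))
            shade = np.uint8(round(255 * (1.0 - cov)))
            x = x_start + col
            image[r, x] = np.minimum(image[r, x], shade)


def render_paper_image(
    signals: PaperECGSignals, dpi: int = 144, grid: bool = True
) -> tuple[np.ndarray, PageLayout]:
    """Draw a standard 3x4 paper page (plus rhythm strip) from signals.

    Returns the RGB image and the exact layout/calibration geometry used,
    enabling lossless-bookkeeping round trips in tests.
    """
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    px_mm = dpi / 25.4
    margin_mm = 10.0
    row_baselines_mm = (25.0, 60.0, 95.0)
    rhythm_baseline_mm = 130.0
    half_pitch_mm = 17.5
    width_mm = 2 * margin_mm + RECORD_DURATION * MM_PER_SECOND
    height_mm = 150.0
    w = int(round(width_mm * px_mm))
    h = int(round(height_mm * px_mm))
    image = np.full((h, w, 3), 255, dtype=np.uint8)

    if grid:
        for mm in np.arange(0.0, width_mm, 1.0):
            x = int(round(mm * px_mm))
            if x < w:
                image[:, x] = _GRID_MAJOR if mm % 5 == 0 else _GRID_MINOR
        for mm in np.arange(0.0, height_mm, 1.0):
            y = int(round(mm * px_mm))
            if y < h:
                image[y] = _GRID_MAJOR if mm % 5 == 0 else _GRID_MINOR

    col_px = COLUMN_DURATION * MM_PER_SECOND * px_mm
    sec_per_px = 1.0 / (MM_PER_SECOND * px_mm)
    regions: dict[str, LeadRegion] = {}
    for row_idx, row in enumerate(_ROWS):
        y_base = row_baselines_mm[row_idx] * px_mm
        y_top = int(round((row_baselines_mm[row_idx] - half_pitch_mm) * px_mm))
        y_bottom = int(round((row_baselines_mm[row_idx] + half_pitch_mm) * px_mm))
        for col_idx, lead in enumerate(row):
            x0 = int(round(margin_mm * px_mm + col_idx * col_px))
            x1 = int(round(margin_mm * px_mm + (col_idx + 1) * col_px))
            seg = np.asarray(signals.segments[lead], float)
            _draw_trace(
                image, seg, signals.fs, x0, x1 - x0, sec_per_px, y_base,
                MM_PER_MV * px_mm, y_top, y_bottom,
            )
            regions[lead] = LeadRegion(
                x0, x1, y_base, y_top, y_bottom, signals.offsets[lead]
            )

    y_base = rhythm_baseline_mm * px_mm
    y_top = int(round((rhythm_baseline_mm - half_pitch_mm) * px_mm))
    y_bottom = int(round((rhythm_baseline_mm + half_pitch_mm) * px_mm))
    x0 = int(round(margin_mm * px_mm))
    x1 = int(round(margin_mm * px_mm + RECORD_DURATION * MM_PER_SECOND * px_mm))
    _draw_trace(
        image, np.asarray(signals.reference_signal, float), signals.fs,
        x0, x1 - x0, sec_per_px, y_base, MM_PER_MV * px_mm, y_top, y_bottom,
    )
    rhythm_region = LeadRegion(x0, x1, y_base, y_top, y_bottom, 0.0)

    origin = (margin_mm * px_mm, row_baselines_mm[0] * px_mm)
    calibration = CalibrationFrame(
        origin=origin,
        one_mv=(origin[0], origin[1] - MM_PER_MV * px_mm),
        ms200=(origin[0] + 0.2 * MM_PER_SECOND * px_mm, origin[1]),
    )
    layout = PageLayout(
        regions=regions,
        rhythm_lead=signals.reference_lead,
        rhythm_region=rhythm_region,
        calibration=calibration,
        dpi=dpi,
    )
    return image, layout


# --------------------------------------------------------------------------
# grid removal
# --------------------------------------------------------------------------

def remove_grid(image: np.ndarray, thresholds: ColorThresholds | None = None) -> np.ndarray:
    """Binary mask of waveform pixels.

    RGB images are thresholded per channel (default: near-black trace on
    red grid); grayscale images fall back to Otsu thresholding.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 2:  # grayscale: automatic threshold
        thresh = threshold_otsu(img)
        mask = img < thresh
    else:
        th = thresholds or ColorThresholds()
        lo = np.asarray(th.lower)
        hi = np.asarray(th.upper)
        mask = np.all((img >= lo) & (img <= hi), axis=-1)
    if not mask.any():
        raise ValueError("no trace pixels found within the color thresholds")
    return mask


# --------------------------------------------------------------------------
# waveform tracing
# --------------------------------------------------------------------------

def _trace_region(
    mask: np.ndarray,
    region: LeadRegion,
    calib: CalibrationFrame,
    darkness: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a lead region to (time_ms, amplitude_mv) knots.

    Columns holding several disjoint pixel runs (overlap from an
    adjacent row) keep only the run nearest the baseline. When the scan
    intensity is available (``darkness``: ink coverage per pixel in
    [0, 1]), the partially shaded pixels bordering a run refine its
    vertical extent to sub-pixel accuracy. Columns without trace pixels
    are skipped (interpolated later)."""
    sub = mask[region.y_top : region.y_bottom, region.x_start : region.x_end]
    dsub = (
        darkness[region.y_top : region.y_bottom, region.x_start : region.x_end]
        if darkness is not None
        else None
    )
    base_local = region.y_baseline - region.y_top
    cols, mean_amp, hi_amp, lo_amp = [], [], [], []
    for col in range(sub.shape[1]):
        rows = np.flatnonzero(sub[:, col])
        if rows.size == 0:
            continue
        # split into consecutive runs, keep the one nearest the baseline
        breaks = np.flatnonzero(np.diff(rows) > 1)
        runs = np.split(rows, breaks + 1)
        run = min(runs, key=lambda r: abs(float(r.mean()) - base_local))
        rmin, rmax = int(run[0]), int(run[-1])
        c_above = c_below = 0.0
        if dsub is not None:
            if rmin - 1 >= 0:
                c_above = float(dsub[rmin - 1, col])
            if rmax + 1 < sub.shape[0]:
                c_below = float(dsub[rmax + 1, col])
        top = rmin - 0.5 - c_above
        bottom = rmax + 0.5 + c_below
        cols.append(col)
        hi_amp.append((base_local - top) * calib.mv_per_pixel)
        lo_amp.append((base_local - bottom) * calib.mv_per_pixel)
        mean_amp.append((hi_amp[-1] + lo_amp[-1]) / 2.0)
    if not cols:
        raise ValueError("lead region contains no trace pixels")
    cols = np.asarray(cols)
    mean_amp = np.asarray(mean_amp)
    hi_amp = np.asarray(hi_amp)
    lo_amp = np.asarray(lo_amp)

    # Decode the pen path: a plotted trace inks, per column, the full
    # vertical span the signal sweeps during that column's time slice.
    # The signal value at the boundary between two adjacent columns lies
    # in the overlap of their spans (midpoint taken); where a span
    # overshoots both of its boundary values the column contains a local
    # extremum, recorded as an extra knot at the column center.
    quantum = abs(calib.mv_per_pixel)
    knot_t: list[float] = []
    knot_v: list[float] = []
    boundary: dict[int, float] = {}
    for a, b in zip(range(len(cols) - 1), range(1, len(cols))):
        if cols[b] - cols[a] != 1:
            continue  # gap: no shared boundary
        lo = max(lo_amp[a], lo_amp[b])
        hi = min(hi_amp[a], hi_amp[b])
        boundary[a] = (lo + hi) / 2.0
        knot_t.append(float(cols[b]) * calib.ms_per_pixel)
        knot_v.append(boundary[a])
    for i in range(len(cols)):
        left = boundary.get(i - 1)
        right = boundary.get(i)
        neighbors = [v for v in (left, right) if v is not None]
        center_t = (float(cols[i]) + 0.5) * calib.ms_per_pixel
        if not neighbors:
            knot_t.append(center_t)
            knot_v.append(mean_amp[i])
            continue
        if hi_amp[i] > max(neighbors) + quantum:
            knot_t.append(center_t)
            knot_v.append(hi_amp[i])
        elif lo_amp[i] < min(neighbors) - quantum:
            knot_t.append(center_t)
            knot_v.append(lo_amp[i])
    order = np.argsort(knot_t)
    times = region.offset * 1000.0 + np.asarray(knot_t)[order]
    return times, np.asarray(knot_v)[order]


def _ink_coverage(image: np.ndarray | None, mask: np.ndarray) -> np.ndarray | None:
    """Per-pixel ink coverage estimate for near-neutral (gray) pixels;
    colored grid pixels count as zero ink."""
    if image is None:
        return None
    img = np.asarray(image, float)
    if img.ndim == 2:
        gray = img
        neutral = np.ones_like(gray, dtype=bool)
    else:
        gray = img.mean(axis=-1)
        neutral = (img.max(axis=-1) - img.min(axis=-1)) < 60
    cov = np.clip(1.0 - gray / 255.0, 0.0, 1.0)
    cov[~neutral] = 0.0
    cov[mask] = 1.0
    return cov


def trace_waveforms(
    mask: np.ndarray,
    calib: CalibrationFrame,
    layout: PageLayout,
    fs: float = 500.0,
    image: np.ndarray | None = None,
) -> PaperECGSignals:
    """Column-wise tracing of every lead region into calibrated signals,
    resampled to ``fs`` by cubic-spline interpolation (a pixel column is
    wider than a sample interval at typical scan resolutions, and the
    narrow QRS deflections need better-than-linear interpolation)."""

    def _resample(t_ms: np.ndarray, amp: np.ndarray, grid: np.ndarray) -> np.ndarray:
        t_ms, keep = np.unique(t_ms, return_index=True)
        amp = amp[keep]
        if len(t_ms) < 4:
            return np.interp(grid, t_ms, amp)
        inner = CubicSpline(t_ms, amp)(np.clip(grid, t_ms[0], t_ms[-1]))
        return inner

    darkness = _ink_coverage(image, mask)
    segments, offsets = {}, {}
    n_seg = int(round(COLUMN_DURATION * fs))
    for lead, region in layout.regions.items():
        try:
            t_ms, amp = _trace_region(mask, region, calib, darkness)
        except ValueError:
            raise ValueError(f"lead {lead!r}: region contains no trace pixels")
        grid = (region.offset + np.arange(n_seg) / fs) * 1000.0
        segments[lead] = _resample(t_ms, amp, grid)
        offsets[lead] = region.offset
    t_ms, amp = _trace_region(mask, layout.rhythm_region, calib, darkness)
    n_ref = int(round(RECORD_DURATION * fs))
    grid = np.arange(n_ref) / fs * 1000.0
    reference = _resample(t_ms, amp, grid)
    return PaperECGSignals(
        segments=segments,
        offsets=offsets,
        reference_lead=layout.rhythm_lead,
        reference_signal=reference,
        fs=fs,
    )


def digitize_image(
    image: np.ndarray,
    layout: PageLayout,
    thresholds: ColorThresholds | None = None,
    fs: float = 500.0,
) -> PaperECGSignals:
    """Grid removal + tracing in one step."""
    mask = remove_grid(image, thresholds)
    return trace_waveforms(mask, layout.calibration, layout, fs=fs, image=image)
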