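"""Hyperspectral map analysis for trabecular bone FTIR imaging.

A trabecular section is imaged as a grid of 6 μm × 6 μm absorbance spectra.
Analysis follows the conventional workflow: find the longitudinal axis of the
trabeculum from its mask, lay a series of transverse scan lines 6 μm apart
along that axis, sample each line every 6 μm, and reduce every sampled pixel
to four band-ratio parameters:

* mineral-to-matrix ratio (MMR): phosphate ν1ν3 area / amide I area
* carbonate-to-phosphate ratio (CPR): carbonate ν2 area / phosphate area
* crystallinity: 1030 / 1020 cm⁻¹ sub-band height ratio
* cross-linking ratio (XLR): 1660 / 1690 cm⁻¹ height ratio

Band areas are trapezoidal integrals after subtracting a straight baseline
anchored at the band end points; heights are window maxima on the raw
spectrum.  Default band limits are conventional bone-FTIR choices and are
fully configurable through :class:`BandConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralMap",
    "BandConfig",
    "TrabecularAxis",
    "ScanGrid",
    "ScanLine",
    "PixelParams",
    "DegenerateMaskError",
    "integrate_band",
    "peak_height",
    "compute_pixel_params",
    "estimate_axis",
    "build_scan_grid",
    "extract_pixel_table",
]

PIXEL_SIZE_UM = 6.0

PIXEL_COLUMNS = [
    "line_index",
    "point_index",
    "x_um",
    "y_um",
    "mmr",
    "cpr",
    "crystallinity",
    "xlr",
    "valid",
]


class DegenerateMaskError(ValueError):
    """Mask too isotropic to define a longitudinal axis."""


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum on a strictly increasing wavenumber axis."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise ValueError("wavenumber axis must be 1-D with length >= 2")
        if ab.shape != wn.shape:
            raise ValueError("absorbance and wavenumbers must have equal length")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if np.any(wn < 0):
            raise ValueError("wavenumbers must be non-negative")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)


@dataclass
class SpectralMap:
    """H×W grid of spectra sharing one wavenumber axis, plus a trabecular mask.

    ``absorbance`` has shape (H, W, n_wavenumbers); ``mask`` is (H, W) with
    True marking trabecular bone.  Pixel centres sit at
    ``x = col * pixel_size_um``, ``y = row * pixel_size_um``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    mask: np.ndarray
    pixel_size_um: float = PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.absorbance.ndim != 3:
            raise ValueError("absorbance must be H x W x n_wavenumbers")
        if self.absorbance.shape[2] != self.wavenumbers.size:
            raise ValueError("spectral dimension does not match wavenumber axis")
        if self.mask.shape != self.absorbance.shape[:2]:
            raise ValueError("mask dimensions must equal grid dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def spectrum_at(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.absorbance[row, col])


@dataclass(frozen=True)
class BandConfig:
    """Band limits (cm⁻¹) for areas and positions/half-windows for heights."""

    mineral: tuple[float, float] = (900.0, 1200.0)
    matrix: tuple[float, float] = (1585.0, 1720.0)
    carbonate: tuple[float, float] = (840.0, 890.0)
    crystallinity_num: float = 1030.0
    crystallinity_den: float = 1020.0
    crystallinity_halfwindow: float = 4.0
    xlr_num: float = 1660.0
    xlr_den: float = 1690.0
    xlr_halfwindow: float = 6.0

    def __post_init__(self) -> None:
        for name in ("mineral", "matrix", "carbonate"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} band must satisfy lo < hi")
        if self.crystallinity_halfwindow <= 0 or self.xlr_halfwindow <= 0:
            raise ValueError("half-windows must be positive")


@dataclass(frozen=True)
class TrabecularAxis:
    """Longitudinal axis of a trabeculum: anchor point (μm) + unit direction."""

    anchor_um: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("direction must have unit norm")


@dataclass(frozen=True)
class ScanLine:
    center_um: tuple[float, float]
    endpoints_um: tuple[tuple[float, float], tuple[float, float]]
    # sample points as (x_um, y_um, row, col)
    points: tuple[tuple[float, float, int, int], ...]


@dataclass(frozen=True)
class ScanGrid:
    lines: tuple[ScanLine, ...]
    spacing_um: float

    @property
    def n_points(self) -> int:
        return sum(len(ln.points) for ln in self.lines)


@dataclass(frozen=True)
class PixelParams:
    """Band-ratio parameters for one 6 μm × 6 μm bone area."""

    mmr: float
    cpr: float
    crystallinity: float
    xlr: float
    area_um2: float = PIXEL_SIZE_UM**2
    valid: bool = True


def integrate_band(spectrum: Spectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of absorbance over ``band`` = (lo, hi) cm⁻¹.

    The band end points are linearly interpolated onto the axis so the
    integral covers exactly [lo, hi].  Linear in the absorbance scale; no
    baseline is removed here (see :func:`compute_pixel_params`).
    """
    lo, hi = band
    wn = spectrum.wavenumbers
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(f"band ({lo}, {hi}) outside axis range ({wn[0]}, {wn[-1]})")
    inner = (wn > lo) & (wn < hi)
    xs = np.concatenate(([lo], wn[inner], [hi]))
    ys = np.concatenate(
        (
            [np.interp(lo, wn, spectrum.absorbance)],
            spectrum.absorbance[inner],
            [np.interp(hi, wn, spectrum.absorbance)],
        )
    )
    return float(np.trapezoid(ys, xs))


def _baseline_corrected_area(spectrum: Spectrum, band: tuple[float, float]) -> float:
    """Band area after subtracting the straight line joining the end points."""
    lo, hi = band
    a_lo = np.interp(lo, spectrum.wavenumbers, spectrum.absorbance)
    a_hi = np.interp(hi, spectrum.wavenumbers, spectrum.absorbance)
    baseline_area = 0.5 * (a_lo + a_hi) * (hi - lo)
    return integrate_band(spectrum, band) - baseline_area


def peak_height(spectrum: Spectrum, position: float, half_window: float) -> float:
    """Maximum absorbance within ``position ± half_window`` cm⁻¹.

    The window end points are interpolated onto the axis so a window narrower
    than the sampling step is still well defined.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    wn = spectrum.wavenumbers
    lo, hi = position - half_window, position + half_window
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(f"window ({lo}, {hi}) outside axis range")
    inner = spectrum.absorbance[(wn >= lo) & (wn <= hi)]
    edges = [
        np.interp(lo, wn, spectrum.absorbance),
        np.interp(hi, wn, spectrum.absorbance),
    ]
    return float(max(np.max(inner) if inner.size else -np.inf, *edges))


def compute_pixel_params(spectrum: Spectrum, bands: BandConfig) -> PixelParams:
    """Reduce one spectrum to the four bone band-ratio parameters.

    Ratios are invariant under positive rescaling of the spectrum.  A
    non-positive denominator marks the pixel invalid (NaN ratio) rather than
    raising; invalid pixels are excluded downstream.
    """
    mineral = _baseline_corrected_area(spectrum, bands.mineral)
    matrix = _baseline_corrected_area(spectrum, bands.matrix)
    carbonate = _baseline_corrected_area(spectrum, bands.carbonate)
    h_cn = peak_height(spectrum, bands.crystallinity_num, bands.crystallinity_halfwindow)
    h_cd = peak_height(spectrum, bands.crystallinity_den, bands.crystallinity_halfwindow)
    h_xn = peak_height(spectrum, bands.xlr_num, bands.xlr_halfwindow)
    h_xd = peak_height(spectrum, bands.xlr_den, bands.xlr_halfwindow)

    def ratio(num: float, den: float) -> float:
        if den <= 0:
            return np.nan
        return num / den

    mmr = ratio(mineral, matrix)
    cpr = ratio(carbonate, mineral)
    crystallinity = ratio(h_cn, h_cd)
    xlr = ratio(h_xn, h_xd)
    vals = (mmr, cpr, crystallinity, xlr)
    valid = all(np.isfinite(v) and v >= 0 for v in vals)
    return PixelParams(mmr, cpr, crystallinity, xlr, valid=valid)


def estimate_axis(
    mask: np.ndarray,
    pixel_size_um: float = PIXEL_SIZE_UM,
    min_anisotropy: float = 1.2,
) -> TrabecularAxis:
    """Principal (major) axis of the mask pixel coordinates through their centroid.

    Sign convention: the direction has non-negative x; if x is zero, the
    direction has non-negative y.  Raises :class:`DegenerateMaskError` when
    the major/minor second-moment ratio falls below ``min_anisotropy``.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size < 10:
        raise ValueError("mask must contain at least 10 pixels")
    xy = np.column_stack((cols, rows)).astype(float) * pixel_size_um
    centroid = xy.mean(axis=0)
    cov = np.cov((xy - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    minor, major = evals
    if minor <= 0 or major / minor < min_anisotropy:
        raise DegenerateMaskError(
            f"mask too isotropic for axis estimation (ratio "
            f"{major / minor if minor > 0 else np.inf:.3f} < {min_anisotropy})"
        )
    d = evecs[:, 1]
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return TrabecularAxis(anchor_um=tuple(centroid), direction=tuple(d))


def _point_to_index(
    x: float, y: float, shape: tuple[int, int], pixel_size_um: float
) -> tuple[int, int] | None:
    col = int(round(x / pixel_size_um))
    row = int(round(y / pixel_size_um))
    if 0 <= row < shape[0] and 0 <= col < shape[1]:
        return row, col
    return None


def _inside(mask: np.ndarray, x: float, y: float, pixel_size_um: float) -> bool:
    idx = _point_to_index(x, y, mask.shape, pixel_size_um)
    return idx is not None and bool(mask[idx])


def build_scan_grid(
    axis: TrabecularAxis,
    mask: np.ndarray,
    spacing_um: float = PIXEL_SIZE_UM,
    pixel_size_um: float = PIXEL_SIZE_UM,
) -> ScanGrid:
    """Transverse scan lines every ``spacing_um`` along the axis.

    Lines run orthogonal to the longitudinal axis from one mask edge to the
    other; each line is sampled every ``spacing_um`` outward from its centre,
    and only in-mask sample points are kept.  Line centres are placed
    symmetrically about the midpoint of the mask's axial extent, so a mask
    shorter than one spacing yields a single line through the centroid.
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("mask is empty")
    d = np.asarray(axis.direction)
    n = np.array([-d[1], d[0]])  # transverse direction
    anchor = np.asarray(axis.anchor_um)
    xy = np.column_stack((cols, rows)).astype(float) * pixel_size_um
    t = (xy - anchor) @ d
    tmin, tmax = t.min(), t.max()
    n_lines = int(np.floor((tmax - tmin) / spacing_um)) + 1
    t0 = 0.5 * (tmin + tmax) - 0.5 * (n_lines - 1) * spacing_um
    half_diag = 0.5 * np.hypot(*(np.array(mask.shape) * pixel_size_um)) + spacing_um
    n_steps = int(np.ceil(half_diag / spacing_um))

    lines: list[ScanLine] = []
    for i in range(n_lines):
        center = anchor + (t0 + i * spacing_um) * d
        pts: list[tuple[float, float, int, int]] = []
        for s in range(-n_steps, n_steps + 1):
            p = center + s * spacing_um * n
            if _inside(mask, p[0], p[1], pixel_size_um):
                idx = _point_to_index(p[0], p[1], mask.shape, pixel_size_um)
                assert idx is not None
                pts.append((float(p[0]), float(p[1]), idx[0], idx[1]))
        if not pts:
            continue
        endpoints = (
            (pts[0][0], pts[0][1]),
            (pts[-1][0], pts[-1][1]),
        )
        lines.append(
            ScanLine(
                center_um=(float(center[0]), float(center[1])),
                endpoints_um=endpoints,
                points=tuple(pts),
            )
        )
    return ScanGrid(lines=tuple(lines), spacing_um=spacing_um)


def extract_pixel_table(
    smap: SpectralMap,
    bands: BandConfig | None = None,
    spacing_um: float | None = None,
) -> pd.DataFrame:
    """Full image analysis: axis → grid → per-pixel band ratios.

    Returns a DataFrame with one row per grid sample point and columns
    ``line_index, point_index, x_um, y_um, mmr, cpr, crystallinity, xlr,
    valid``.  Invalid pixels are kept in the table (flagged) so total scanned
    area bookkeeping stays explicit; downstream statistics exclude them.
    """
    bands = bands or BandConfig()
    spacing = spacing_um if spacing_um is not None else smap.pixel_size_um
    axis = estimate_axis(smap.mask, smap.pixel_size_um)
    grid = build_scan_grid(axis, smap.mask, spacing, smap.pixel_size_um)
    records = []
    for li, line in enumerate(grid.lines):
        for pi, (x, y, row, col) in enumerate(line.points):
            pp = compute_pixel_params(smap.spectrum_at(row, col), bands)
            records.append(
                (li, pi, x, y, pp.mmr, pp.cpr, pp.crystallinity, pp.xlr, pp.valid)
            )
    if not records:
        raise ValueError("scan grid produced no sample points")
    return pd.DataFrame(records, columns=PIXEL_COLUMNS)
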