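"""Lumen diameter measurement by perpendicular-plane FWHM ellipse calipers.

Each airway segment's voxel path is smoothed into a cubic spline in world
mm. The spline is sampled at a dynamic interval (half the smallest voxel
dimension); at each sample a CT patch perpendicular to the local tangent is
interpolated (at most 40 x 40 mm), and the lumen boundary is located on
radial intensity profiles: the airway wall is modelled as a Gaussian bump
over the dark lumen, and the inner boundary is placed where the fitted
Gaussian crosses half maximum between the lumen baseline and the wall peak
(full-width-at-half-maximum edge cue). A direct least-squares ellipse is
fitted to the accepted boundary points; the reported diameter is the
geometric mean 2*sqrt(r_minor * r_major). A segment's diameter is the mean
over its valid samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage
from skimage.measure import EllipseModel, label as sk_label

from .core_io import ImageVolume
from .skeleton_graph import AirwayGraph, AirwaySegment

__all__ = [
    "CaliperConfig",
    "SegmentSpline",
    "PerpendicularPatch",
    "EllipseFit",
    "SegmentMeasurement",
    "sampling_interval",
    "fit_spline",
    "trim_path",
    "extract_patch",
    "measure_fwhm_ellipse",
    "measure_segment",
    "measure_graph",
    "export_samples_csv",
]

log = logging.getLogger(__name__)

_HALF_MAX = np.sqrt(2.0 * np.log(2.0))  # sigma -> half-max offset


@dataclass
class CaliperConfig:
    """Tunables of the caliper stage (all lengths in mm).

    Defaults: 60 rays; wall-peak dead zone 0.5 mm; minimum peak prominence
    100 HU over the lumen baseline; Gaussian fit window +/- 2 mm around the
    peak; ray outliers beyond 3 scaled-MAD of the median radius discarded;
    a fit is valid with >= 60% accepted rays; a segment with >= 50% valid
    samples. Patch extent capped at 40 mm per side.
    """

    n_rays: int = 60
    max_extent_mm: float = 40.0
    dead_zone_mm: float = 0.5
    min_prominence_hu: float = 100.0
    gauss_window_mm: float = 2.0
    outlier_mad: float = 3.0
    min_ray_fraction: float = 0.6
    min_sample_fraction: float = 0.5
    recentre: bool = True
    recentre_threshold_hu: float = -800.0
    recentre_max_shift_mm: float = 2.0
    # junction blend zones: the medial axis bends into the junction over
    # roughly one lumen radius, so the path is trimmed before spline
    # fitting and diameter samples keep an extra standoff
    end_trim_fraction: float = 0.25
    end_trim_max_mm: float = 3.0
    end_exclusion_fraction: float = 0.1
    end_exclusion_max_mm: float = 1.0
    pitch_mm: float | None = None  # default: sampling_interval(spacing)
    interval_mm: float | None = None  # default: sampling_interval(spacing)
    spline_smooth_voxels: float = 2.0  # path pre-smoothing sigma, in min-spacing units


@dataclass
class SegmentSpline:
    """Smooth centreline curve of one segment in world mm.

    ``arc_length_mm`` (L_a) is the curve length by fine quadrature;
    ``euclidean_length_mm`` (L_e) the straight start-to-end distance.
    """

    tck: tuple
    arc_length_mm: float
    euclidean_length_mm: float
    _u_grid: np.ndarray = field(repr=False, default=None)
    _s_grid: np.ndarray = field(repr=False, default=None)

    def point_at_arc(self, s: float | np.ndarray) -> np.ndarray:
        u = np.interp(s, self._s_grid, self._u_grid)
        return np.stack(interpolate.splev(u, self.tck), axis=-1)

    def tangent_at_arc(self, s: float | np.ndarray) -> np.ndarray:
        u = np.interp(s, self._s_grid, self._u_grid)
        d = np.stack(interpolate.splev(u, self.tck, der=1), axis=-1)
        n = np.linalg.norm(d, axis=-1, keepdims=True)
        return d / np.where(n > 0, n, 1.0)


@dataclass
class PerpendicularPatch:
    """2D HU patch in the plane normal to the centreline tangent.

    The patch grid is centred on the spline sample point; ``extent_mm`` is
    the full physical side length (<= 40 mm). ``oob_fraction`` is the share
    of patch pixels interpolated outside the volume (filled with -1000 HU).
    """

    image: np.ndarray
    pitch_mm: float
    centre_index: tuple[float, float]
    centre_world: np.ndarray
    basis: tuple[np.ndarray, np.ndarray]
    oob_fraction: float

    @property
    def extent_mm(self) -> float:
        return (self.image.shape[0] - 1) * self.pitch_mm


@dataclass
class EllipseFit:
    """Result of one cross-sectional ellipse caliper."""

    valid: bool
    minor_radius_mm: float = np.nan
    major_radius_mm: float = np.nan
    n_rays_used: int = 0
    boundary_points: np.ndarray | None = None
    centre_mm: tuple[float, float] | None = None

    @property
    def diameter_mm(self) -> float:
        return 2.0 * np.sqrt(self.minor_radius_mm * self.major_radius_mm)


@dataclass
class SegmentMeasurement:
    """Per-sample ellipse fits along one segment and their aggregate."""

    fits: list[EllipseFit]
    arc_positions_mm: np.ndarray
    interval_mm: float
    valid: bool
    mean_diameter_mm: float = np.nan

    @property
    def n_valid(self) -> int:
        return sum(f.valid for f in self.fits)


def sampling_interval(spacing: tuple[float, float, float]) -> float:
    """Dynamic measurement interval: half the smallest voxel dimension."""
    if any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")
    return min(spacing) / 2.0


def _smooth_path(pts: np.ndarray, sigma_steps: float) -> np.ndarray:
    """Gaussian-smooth a polyline along its index, preserving end slopes.

    The path is padded by odd reflection about each endpoint (2*p_end - p),
    so smoothing does not drag the ends inward or flatten their tangent;
    this removes voxel staircase zigzag while leaving wavelengths much
    longer than the kernel essentially untouched.
    """
    if sigma_steps <= 0 or len(pts) < 3:
        return pts
    pad = min(len(pts) - 1, max(3, int(np.ceil(4 * sigma_steps))))
    head = 2 * pts[0] - pts[pad:0:-1]
    tail = 2 * pts[-1] - pts[-2 : -pad - 2 : -1]
    ext = np.vstack([head, pts, tail])
    sm = ndimage.gaussian_filter1d(ext, sigma_steps, axis=0, mode="nearest")
    return sm[pad : pad + len(pts)]


def trim_path(
    path_world: np.ndarray,
    trim_fraction: float = 0.25,
    trim_max_mm: float = 3.0,
    trim_proximal: bool = True,
    trim_distal: bool = True,
) -> np.ndarray:
    """Drop the junction blend zone at the ends of a segment path.

    The skeleton bends into a junction over roughly one lumen radius; the
    trim per junction end is ``min(trim_fraction * length, trim_max_mm)``
    of arc. Free ends (the trachea origin, terminal tips) are not blend
    zones and are left untrimmed. At least three central voxels are kept.
    """
    pts = np.asarray(path_world, dtype=float)
    if len(pts) < 5 or trim_fraction <= 0 or not (trim_proximal or trim_distal):
        return pts
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    chord = np.concatenate([[0.0], np.cumsum(steps)])
    total = chord[-1]
    trim = min(trim_fraction * total, trim_max_mm)
    lo = trim if trim_proximal else 0.0
    hi = total - trim if trim_distal else total
    keep = (chord >= lo) & (chord <= hi)
    if keep.sum() < 3:
        mid = len(pts) // 2
        keep[:] = False
        keep[max(0, mid - 1) : mid + 2] = True
    return pts[keep]


def fit_spline(
    segment_path_world: np.ndarray,
    spacing: tuple[float, float, float],
    smooth_voxels: float = 2.0,
) -> SegmentSpline:
    """Fit a cubic spline through a segment's world-mm path.

    The voxel path is first smoothed with a Gaussian of standard deviation
    ``smooth_voxels`` times the smallest spacing (converted to path steps)
    to iron out thinning staircase zigzag, which would otherwise inflate
    arc length; the spline is then fit with a small residual budget and
    parameterized by normalized cumulative chord length. Arc length uses
    quadrature at a step <= interval/10.
    """
    pts = np.asarray(segment_path_world, dtype=float)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    m = len(pts)
    if m < 2:
        raise ValueError("degenerate (zero-length) segment path")
    if m >= 3:
        step = float(
            np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        )
        sigma_steps = smooth_voxels * min(spacing) / step
        pts = _smooth_path(pts, sigma_steps)
    chord = np.zeros(m)
    chord[1:] = np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    total = chord[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) segment path")
    u = chord / total
    k = min(3, m - 1)
    s = m * (0.1 * min(spacing)) ** 2 if m > k + 1 else 0
    tck, _ = interpolate.splprep(pts.T, u=u, k=k, s=s)

    interval = sampling_interval(spacing)
    n_fine = max(16, int(np.ceil(total / (interval / 10.0))) + 1)
    u_fine = np.linspace(0.0, 1.0, n_fine)
    xyz = np.stack(interpolate.splev(u_fine, tck), axis=-1)
    seg_len = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    s_grid = np.concatenate([[0.0], np.cumsum(seg_len)])
    arc = float(s_grid[-1])
    eucl = float(np.linalg.norm(xyz[-1] - xyz[0]))
    return SegmentSpline(
        tck=tck,
        arc_length_mm=max(arc, eucl),
        euclidean_length_mm=eucl,
        _u_grid=u_fine,
        _s_grid=s_grid,
    )


def _plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis perpendicular to tangent."""
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    u = np.cross(t, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(t, np.array([1.0, 0.0, 0.0]))
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def extract_patch(
    volume: ImageVolume,
    point: np.ndarray,
    tangent: np.ndarray,
    pitch: float,
    max_extent: float = 40.0,
) -> PerpendicularPatch:
    """Interpolate a perpendicular HU patch centred on ``point`` (world mm).

    The grid has an odd pixel count so the centre pixel lies exactly on the
    sample point; physical side length never exceeds ``max_extent``.
    Out-of-volume samples are filled with -1000 HU (air) and counted in
    ``oob_fraction``.
    """
    point = np.asarray(point, dtype=float)
    idx = volume.world_to_index(point)
    if np.any(idx < 0) or np.any(idx > np.asarray(volume.shape) - 1):
        raise ValueError(f"patch centre {point} mm is outside the volume")
    u, v = _plane_basis(tangent)
    half_px = int(np.floor((max_extent / 2.0) / pitch))
    offs = np.arange(-half_px, half_px + 1) * pitch
    world = (
        point[None, None, :]
        + offs[:, None, None] * u[None, None, :]
        + offs[None, :, None] * v[None, None, :]
    )
    coords = volume.world_to_index(world)  # (n, n, 3) fractional indices
    img = ndimage.map_coordinates(
        volume.data,
        [coords[..., 0], coords[..., 1], coords[..., 2]],
        order=1,
        mode="constant",
        cval=-1000.0,
    )
    inside = np.all(
        (coords >= 0) & (coords <= np.asarray(volume.shape) - 1), axis=-1
    )
    return PerpendicularPatch(
        image=img.astype(np.float32),
        pitch_mm=pitch,
        centre_index=(float(half_px), float(half_px)),
        centre_world=point,
        basis=(u, v),
        oob_fraction=float(1.0 - inside.mean()),
    )


def _recentre(
    patch: PerpendicularPatch, threshold_hu: float, max_shift_mm: float
) -> tuple[float, float]:
    """Move the ray origin to the centroid of the connected dark (lumen)
    region containing the initial centre.

    The shift is capped at ``max_shift_mm``: the skeleton is only slightly
    off-axis, while near junctions the connected dark region merges with
    the neighbouring lumen and its centroid can run away."""
    ci = int(round(patch.centre_index[0])), int(round(patch.centre_index[1]))
    low = patch.image < threshold_hu
    if not low[ci]:
        return patch.centre_index
    labels = sk_label(low, connectivity=2)
    comp = labels == labels[ci]
    idx = np.argwhere(comp)
    cy, cx = idx.mean(axis=0)
    dy, dx = cy - patch.centre_index[0], cx - patch.centre_index[1]
    shift = np.hypot(dy, dx) * patch.pitch_mm
    if shift > max_shift_mm:
        scale = max_shift_mm / shift
        dy, dx = dy * scale, dx * scale
    return float(patch.centre_index[0] + dy), float(patch.centre_index[1] + dx)


def _gaussian_halfmax_radius(
    radii: np.ndarray, profile: np.ndarray, peak_i: int, baseline: float, window_mm: float
) -> float:
    """Inner half-maximum radius from a log-parabola Gaussian fit.

    Fits log(profile - baseline) as a quadratic in radius over a window
    around the wall peak (Caruana's method); the inner lumen boundary is
    mu - sigma*sqrt(2 ln 2). Returns NaN if the fit is unusable.
    """
    g = profile - baseline
    peak_r = radii[peak_i]
    peak_g = g[peak_i]
    sel = (np.abs(radii - peak_r) <= window_mm) & (g >= 0.2 * peak_g) & (g > 0)
    if sel.sum() < 3:
        return np.nan
    r = radii[sel]
    y = np.log(g[sel])
    a2, a1, _ = np.polyfit(r, y, 2)
    if a2 >= 0:
        return np.nan
    sigma2 = -1.0 / (2.0 * a2)
    mu = a1 * sigma2
    r_inner = mu - np.sqrt(sigma2) * _HALF_MAX
    if not np.isfinite(r_inner) or abs(mu - peak_r) > window_mm:
        return np.nan
    return float(r_inner)


def _halfmax_crossing(radii: np.ndarray, profile: np.ndarray, peak_i: int, baseline: float) -> float:
    """Direct inner half-max crossing by linear interpolation (fallback)."""
    half = (profile[peak_i] + baseline) / 2.0
    for i in range(peak_i, 0, -1):
        if profile[i - 1] <= half <= profile[i]:
            p0, p1 = profile[i - 1], profile[i]
            frac = 0.0 if p1 == p0 else (half - p0) / (p1 - p0)
            return float(radii[i - 1] + frac * (radii[i] - radii[i - 1]))
    return np.nan


def measure_fwhm_ellipse(
    patch: PerpendicularPatch,
    config: CaliperConfig | None = None,
    volume: ImageVolume | None = None,
    prefiltered: np.ndarray | None = None,
) -> EllipseFit:
    """Measure the lumen cross-section on one perpendicular patch.

    Radial profiles at ``n_rays`` equally spaced angles are sampled at half
    the patch pitch. Per ray: the wall peak is the HU maximum beyond a dead
    zone; the lumen baseline the HU minimum between centre and peak; rays
    whose peak prominence is under the threshold are rejected. The boundary
    radius comes from the Gaussian wall model (log-parabola fit), falling
    back to a direct half-max crossing. After 3-scaled-MAD outlier removal a
    direct least-squares ellipse gives the geometric-mean diameter.

    When ``volume`` is given, ray profiles are interpolated directly from
    the volume at the exact in-plane world points with a cubic spline
    (``prefiltered`` caches the spline coefficients across calls): linear
    interpolation low-passes the wall bump, which widens the fitted
    Gaussian and biases the half-maximum radius inward by a noticeable
    fraction of a voxel. The patch still provides recentring and the
    extent contract.
    """
    cfg = config or CaliperConfig()
    img = patch.image
    if cfg.recentre:
        cy, cx = _recentre(patch, cfg.recentre_threshold_hu, cfg.recentre_max_shift_mm)
    else:
        cy, cx = patch.centre_index

    step = patch.pitch_mm / 2.0
    half_extent = patch.extent_mm / 2.0
    r_max = half_extent - patch.pitch_mm
    n_r = int(r_max / step)
    if n_r < 4:
        return EllipseFit(valid=False)
    radii = np.arange(n_r) * step
    angles = 2.0 * np.pi * np.arange(cfg.n_rays) / cfg.n_rays
    if volume is not None:
        u, v = patch.basis
        c0 = patch.centre_index[0]
        off_u = (cy - c0) * patch.pitch_mm + radii[None, :] * np.cos(angles)[:, None]
        off_v = (cx - c0) * patch.pitch_mm + radii[None, :] * np.sin(angles)[:, None]
        world = (
            patch.centre_world[None, None, :]
            + off_u[..., None] * u[None, None, :]
            + off_v[..., None] * v[None, None, :]
        )
        coords = volume.world_to_index(world)
        if prefiltered is None:
            prefiltered = ndimage.spline_filter(volume.data, order=3, output=np.float32)
        profiles = ndimage.map_coordinates(
            prefiltered,
            [coords[..., 0], coords[..., 1], coords[..., 2]],
            order=3,
            prefilter=False,
            mode="constant",
            cval=-1000.0,
        )  # (n_rays, n_r)
    else:
        # pixel coordinates of every ray sample: (n_rays, n_r)
        rows = cy + (radii[None, :] / patch.pitch_mm) * np.cos(angles)[:, None]
        cols = cx + (radii[None, :] / patch.pitch_mm) * np.sin(angles)[:, None]
        profiles = ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")

    i0 = max(1, int(np.ceil(cfg.dead_zone_mm / step)))
    boundary_r = np.full(cfg.n_rays, np.nan)
    for j in range(cfg.n_rays):
        p = profiles[j]
        peak_i = i0 + int(np.argmax(p[i0:]))
        if peak_i >= n_r - 1:
            continue  # wall not framed within the patch
        baseline = float(np.min(p[: peak_i + 1]))
        if p[peak_i] - baseline < cfg.min_prominence_hu:
            continue
        r = _gaussian_halfmax_radius(radii, p, peak_i, baseline, cfg.gauss_window_mm)
        if not np.isfinite(r):
            r = _halfmax_crossing(radii, p, peak_i, baseline)
        if np.isfinite(r) and 0 < r <= radii[peak_i]:
            boundary_r[j] = r

    ok = np.isfinite(boundary_r)
    if ok.sum() >= 3:
        med = np.median(boundary_r[ok])
        mad = 1.4826 * np.median(np.abs(boundary_r[ok] - med))
        if mad > 0:
            ok &= np.abs(np.where(np.isfinite(boundary_r), boundary_r, np.inf) - med) <= cfg.outlier_mad * mad
    n_used = int(ok.sum())
    if n_used < max(5, int(np.ceil(cfg.min_ray_fraction * cfg.n_rays))):
        return EllipseFit(valid=False, n_rays_used=n_used)

    pts = np.stack(
        [boundary_r[ok] * np.cos(angles[ok]), boundary_r[ok] * np.sin(angles[ok])],
        axis=1,
    )
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            return EllipseFit(valid=False, n_rays_used=n_used, boundary_points=pts)
        a, b = model.axis_lengths
    else:  # older scikit-image
        model = EllipseModel()
        if not model.estimate(pts):
            return EllipseFit(valid=False, n_rays_used=n_used, boundary_points=pts)
        _, _, a, b, _ = model.params
    r_minor, r_major = float(min(a, b)), float(max(a, b))
    if not (0 < r_minor <= r_major) or r_major > half_extent:
        return EllipseFit(valid=False, n_rays_used=n_used, boundary_points=pts)
    return EllipseFit(
        valid=True,
        minor_radius_mm=r_minor,
        major_radius_mm=r_major,
        n_rays_used=n_used,
        boundary_points=pts,
        centre_mm=((cy - patch.centre_index[0]) * patch.pitch_mm,
                   (cx - patch.centre_index[1]) * patch.pitch_mm),
    )


def measure_segment(
    volume: ImageVolume,
    spline: SegmentSpline,
    config: CaliperConfig | None = None,
    prefiltered: np.ndarray | None = None,
) -> SegmentMeasurement:
    """Measure a segment's diameter profile along its spline.

    Samples every ``interval`` mm of arc length; each sample yields an
    ellipse fit (invalid when the centre leaves the volume or the wall
    cannot be located). The segment diameter is the mean over valid fits;
    the measurement is flagged invalid if fewer than half the samples are.
    """
    cfg = config or CaliperConfig()
    interval = cfg.interval_mm if cfg.interval_mm is not None else sampling_interval(volume.spacing)
    pitch = cfg.pitch_mm if cfg.pitch_mm is not None else sampling_interval(volume.spacing)
    if prefiltered is None:
        prefiltered = ndimage.spline_filter(volume.data, order=3, output=np.float32)
    # skip the junction blend zone at both ends, where the lumen opens into
    # the parent/children and cross-sections are not single-airway
    excl = min(
        cfg.end_exclusion_fraction * spline.arc_length_mm, cfg.end_exclusion_max_mm
    )
    lo, hi = excl, spline.arc_length_mm - excl
    if hi <= lo:
        lo = hi = spline.arc_length_mm / 2.0
    n = max(1, int(np.floor((hi - lo) / interval)) + 1)
    s_positions = lo + np.arange(n) * interval
    fits: list[EllipseFit] = []
    for s in s_positions:
        point = spline.point_at_arc(float(s))
        tangent = spline.tangent_at_arc(float(s))
        try:
            patch = extract_patch(volume, point, tangent, pitch, cfg.max_extent_mm)
        except ValueError:
            fits.append(EllipseFit(valid=False))
            continue
        fits.append(measure_fwhm_ellipse(patch, cfg, volume=volume, prefiltered=prefiltered))
    diam = np.array([f.diameter_mm for f in fits if f.valid])
    n_valid = len(diam)
    valid = n_valid >= cfg.min_sample_fraction * len(fits) and n_valid > 0
    return SegmentMeasurement(
        fits=fits,
        arc_positions_mm=s_positions,
        interval_mm=interval,
        valid=valid,
        mean_diameter_mm=float(diam.mean()) if n_valid else np.nan,
    )


def measure_graph(
    volume: ImageVolume,
    graph: AirwayGraph,
    config: CaliperConfig | None = None,
) -> AirwayGraph:
    """Fit splines and run the caliper over every segment of the graph."""
    cfg = config or CaliperConfig()
    prefiltered = ndimage.spline_filter(volume.data, order=3, output=np.float32)
    for seg in graph.segments():
        u, v = graph.segment_edge(seg.id)
        path_world = trim_path(
            graph.path_world(seg),
            cfg.end_trim_fraction,
            cfg.end_trim_max_mm,
            trim_proximal=graph.tree.degree(u) >= 2,
            trim_distal=graph.tree.out_degree(v) >= 1,
        )
        try:
            seg.spline = fit_spline(path_world, graph.spacing, cfg.spline_smooth_voxels)
        except ValueError:
            seg.spline = None
            seg.measurement = SegmentMeasurement(
                fits=[], arc_positions_mm=np.array([]), interval_mm=np.nan, valid=False
            )
            continue
        seg.measurement = measure_segment(volume, seg.spline, cfg)
    return graph


def export_samples_csv(graph: AirwayGraph, path) -> None:
    """Per-sample caliper CSV: segment id, arc position, diameter, validity."""
    import pandas as pd

    rows = []
    for seg in graph.segments():
        m = seg.measurement
        if m is None:
            continue
        for s, fit in zip(m.arc_positions_mm, m.fits):
            rows.append(
                {
                    "segment_id": seg.id,
                    "arc_position_mm": float(s),
                    "diameter_mm": float(fit.diameter_mm) if fit.valid else np.nan,
                    "valid": bool(fit.valid),
                    "n_rays_used": fit.n_rays_used,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
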