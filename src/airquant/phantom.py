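"""Synthetic CT airway phantoms with analytic ground truth.

Branches are tubes around parametric centrelines: a straight chord plus an
optional in-plane sinusoidal displacement ``A * sin(2*pi*k*t)`` along a
fixed normal, with a lumen radius linear in the curve parameter. The
intensity model mirrors the assumptions of the FWHM edge cue: a dark lumen
(default -1000 HU), a bright Gaussian-profile wall whose half-maximum
radius coincides exactly with the lumen radius, and intermediate
parenchymal background (default -850 HU). Rasterization uses 2x
supersampling per axis for partial-volume realism.

Ground truth (arc length, Euclidean length, tortuosity, mean diameter,
tapering versus parent) is computed by quadrature on the continuous
centreline, independent of the rasterized image, so every downstream stage
can be validated against known geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import BinaryMask, ImageVolume

__all__ = [
    "PhantomBranch",
    "PhantomSpec",
    "rasterize",
    "single_tube_spec",
    "y_tree_spec",
    "build_standard_tree",
    "standard_cohort",
]

_HALF_MAX = np.sqrt(2.0 * np.log(2.0))


@dataclass
class PhantomBranch:
    """One tube of the phantom tree (all geometry in world mm)."""

    id: int
    parent_id: int | None
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_proximal_mm: float
    radius_distal_mm: float
    amplitude_mm: float = 0.0
    cycles: int = 1
    lobe: str = "TRACHEA_MAIN"
    generation: int = 0

    def __post_init__(self) -> None:
        if self.radius_proximal_mm <= 0 or self.radius_distal_mm <= 0:
            raise ValueError(f"branch {self.id}: radii must be positive")

    @property
    def chord(self) -> np.ndarray:
        return np.asarray(self.end) - np.asarray(self.start)

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.chord))

    def _normal(self) -> np.ndarray:
        """Deterministic unit normal to the chord for the sinusoid plane."""
        c = self.chord / self.chord_length
        n = np.cross(c, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(n) < 1e-8:
            n = np.cross(c, np.array([1.0, 0.0, 0.0]))
        return n / np.linalg.norm(n)

    def centreline(self, t: np.ndarray) -> np.ndarray:
        """Points on the centreline for parameter t in [0, 1], shape (n, 3)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        base = np.asarray(self.start) + t[:, None] * self.chord
        if self.amplitude_mm != 0.0:
            base = base + (
                self.amplitude_mm * np.sin(2.0 * np.pi * self.cycles * t)
            )[:, None] * self._normal()
        return base

    def radius(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self.radius_proximal_mm + t * (self.radius_distal_mm - self.radius_proximal_mm)

    def arc_length(self, n_quad: int = 4001) -> float:
        t = np.linspace(0.0, 1.0, n_quad)
        pts = self.centreline(t)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def mean_diameter(self, n_quad: int = 4001) -> float:
        """Arc-length-weighted mean of 2*radius along the branch."""
        t = np.linspace(0.0, 1.0, n_quad)
        pts = self.centreline(t)
        ds = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        r_mid = self.radius((t[:-1] + t[1:]) / 2.0)
        return float(2.0 * np.sum(r_mid * ds) / np.sum(ds))


@dataclass
class PhantomSpec:
    """Declarative phantom: tree geometry, intensity model, and grid."""

    branches: list[PhantomBranch]
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.7)
    shape: tuple[int, int, int] | None = None  # None: auto-fit to geometry
    origin: tuple[float, float, float] | None = None
    lumen_hu: float = -1000.0
    wall_peak_hu: float = 0.0
    wall_sigma_mm: float = 0.6
    background_hu: float = -850.0
    noise_sigma_hu: float = 0.0
    seed: int = 0
    supersample: int = 2

    def __post_init__(self) -> None:
        ids = [b.id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise ValueError("branch ids must be unique")
        by_id = {b.id: b for b in self.branches}
        roots = [b for b in self.branches if b.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"phantom must have exactly one root, got {len(roots)}")
        for b in self.branches:
            if b.parent_id is not None:
                parent = by_id.get(b.parent_id)
                if parent is None:
                    raise ValueError(f"branch {b.id}: unknown parent {b.parent_id}")
                if not np.allclose(b.start, parent.end, atol=1e-6):
                    raise ValueError(
                        f"branch {b.id} start {b.start} != parent {parent.id} end {parent.end}"
                    )

    def truth_table(self) -> pd.DataFrame:
        """Analytic per-branch ground truth (quadrature where needed)."""
        by_id = {b.id: b for b in self.branches}
        rows = []
        for b in self.branches:
            la = b.arc_length()
            le = b.chord_length
            d = b.mean_diameter()
            if b.parent_id is not None:
                d_p = by_id[b.parent_id].mean_diameter()
                taper = 100.0 * (d_p - d) / d_p
            else:
                taper = np.nan
            rows.append(
                {
                    "branch_id": b.id,
                    "parent_id": -1 if b.parent_id is None else b.parent_id,
                    "lobe": b.lobe,
                    "generation": b.generation,
                    "mean_diameter_mm": d,
                    "arc_length_mm": la,
                    "euclidean_length_mm": le,
                    "tortuosity": la / le,
                    "tapering_vs_parent_pct": taper,
                    "radius_proximal_mm": b.radius_proximal_mm,
                    "radius_distal_mm": b.radius_distal_mm,
                    "amplitude_mm": b.amplitude_mm,
                    "cycles": b.cycles,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            payload = json.load(fh)
        payload["branches"] = [PhantomBranch(**b) for b in payload["branches"]]
        for key in ("spacing", "shape", "origin"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _auto_grid(spec: PhantomSpec) -> tuple[tuple[float, float, float], tuple[int, int, int]]:
    margin = max(
        b.radius_proximal_mm + b.amplitude_mm for b in spec.branches
    ) + 3.0 * spec.wall_sigma_mm + 3.0
    pts = np.vstack([b.centreline(np.linspace(0, 1, 64)) for b in spec.branches])
    sp = np.asarray(spec.spacing)
    # fixed sub-voxel offset so tube axes never align with voxel-centre
    # symmetry planes (real CT grids are never anatomy-aligned; perfectly
    # symmetric masks can defeat parallel thinning)
    lo = pts.min(axis=0) - margin - np.array([0.31, 0.43, 0.27]) * sp
    hi = pts.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / sp[i])) + 1 for i in range(3))
    return tuple(float(v) for v in lo), shape


def _check_geometry(spec: PhantomSpec, origin, shape) -> None:
    sp = np.asarray(spec.spacing)
    world_hi = np.asarray(origin) + (np.asarray(shape) - 1) * sp
    fine = {}
    for b in spec.branches:
        t = np.linspace(0, 1, 256)
        pts = b.centreline(t)
        r = b.radius(t).max()
        pad = r + 3.0 * spec.wall_sigma_mm
        if np.any(pts - pad < np.asarray(origin) - sp / 2) or np.any(
            pts + pad > world_hi + sp / 2
        ):
            raise ValueError(f"branch {b.id} exits the grid")
        fine[b.id] = (pts, r)
    # unrelated-branch overlap: centreline distance must exceed summed radii.
    # Pairs sharing a node (parent-child, siblings) legitimately meet at the
    # junction and are exempt.
    def related(a: PhantomBranch, b: PhantomBranch) -> bool:
        ends_a = (np.asarray(a.start), np.asarray(a.end))
        ends_b = (np.asarray(b.start), np.asarray(b.end))
        return any(
            np.allclose(pa_, pb_, atol=1e-6) for pa_ in ends_a for pb_ in ends_b
        )

    for a in spec.branches:
        for b in spec.branches:
            if b.id <= a.id:
                continue
            if related(a, b):
                continue
            pa, ra = fine[a.id]
            pb, rb = fine[b.id]
            tree = cKDTree(pb)
            d, _ = tree.query(pa, k=1)
            if np.min(d) < ra + rb:
                raise ValueError(
                    f"branches {a.id} and {b.id} overlap "
                    f"(min centreline distance {np.min(d):.2f} mm < {ra + rb:.2f} mm)"
                )


def rasterize(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask, pd.DataFrame]:
    """Render a phantom spec to (CT volume, lumen mask, truth table).

    The wall Gaussian is centred at ``r(t) + sigma*sqrt(2 ln 2)`` so the
    inner half-maximum of the radial profile lies exactly on the lumen
    boundary; voxels are 2x supersampled per axis and averaged. The mask
    marks voxels whose subsample majority lies inside the lumen.
    """
    if spec.origin is None or spec.shape is None:
        origin, shape = _auto_grid(spec)
    else:
        origin, shape = tuple(spec.origin), tuple(spec.shape)
    _check_geometry(spec, origin, shape)

    ss = spec.supersample
    sp = np.asarray(spec.spacing)
    ss_shape = tuple(int(n * ss) for n in shape)
    hu_wall = np.full(ss_shape, spec.background_hu, dtype=np.float32)
    lumen_min = np.full(ss_shape, np.inf, dtype=np.float32)
    lumen_mask = np.zeros(ss_shape, dtype=bool)
    sigma = spec.wall_sigma_mm
    reach_mm = 3.5 * sigma

    # world coordinate of supersampled index j along an axis:
    #   origin + (j/ss - (ss-1)/(2*ss)) * spacing
    off0 = (ss - 1) / (2.0 * ss)

    for b in spec.branches:
        step = min(spec.spacing) / 4.0
        n_fine = max(8, int(np.ceil(b.arc_length(512) / step)) + 1)
        t = np.linspace(0.0, 1.0, n_fine)
        pts = b.centreline(t)
        rads = b.radius(t)
        r_max = float(rads.max())
        reach = r_max + reach_mm
        lo_w = pts.min(axis=0) - reach
        hi_w = pts.max(axis=0) + reach
        lo_i = np.maximum(0, np.floor((lo_w - origin) / sp * ss + off0 * ss).astype(int))
        hi_i = np.minimum(
            np.asarray(ss_shape) - 1,
            np.ceil((hi_w - origin) / sp * ss + off0 * ss).astype(int),
        )
        axes = [np.arange(lo_i[k], hi_i[k] + 1) for k in range(3)]
        coords = [origin[k] + (axes[k] / ss - off0) * sp[k] for k in range(3)]
        gx, gy, gz = np.meshgrid(*coords, indexing="ij")
        query = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        tree = cKDTree(pts)
        dist, idx = tree.query(query, k=1, distance_upper_bound=reach)
        hit = np.isfinite(dist)
        if not hit.any():
            continue
        rho = dist[hit]
        r_here = rads[np.minimum(idx[hit], n_fine - 1)]
        rho_c = r_here + sigma * _HALF_MAX
        bump = np.exp(-((rho - rho_c) ** 2) / (2.0 * sigma**2))
        inner = spec.lumen_hu + (spec.wall_peak_hu - spec.lumen_hu) * bump
        outer = spec.background_hu + (spec.wall_peak_hu - spec.background_hu) * bump
        val = np.where(rho <= rho_c, inner, outer).astype(np.float32)
        inside = rho < r_here

        sl = tuple(slice(lo_i[k], hi_i[k] + 1) for k in range(3))
        box_shape = tuple(hi_i[k] + 1 - lo_i[k] for k in range(3))
        flat_hit = np.flatnonzero(hit)
        box_wall = hu_wall[sl].reshape(-1)
        box_wall[flat_hit] = np.maximum(box_wall[flat_hit], val)
        hu_wall[sl] = box_wall.reshape(box_shape)
        box_lmin = lumen_min[sl].reshape(-1)
        box_lmask = lumen_mask[sl].reshape(-1)
        lum_idx = flat_hit[inside]
        box_lmin[lum_idx] = np.minimum(box_lmin[lum_idx], val[inside])
        box_lmask[lum_idx] = True
        lumen_min[sl] = box_lmin.reshape(box_shape)
        lumen_mask[sl] = box_lmask.reshape(box_shape)

    hu_ss = np.where(lumen_mask, lumen_min, hu_wall)
    # average ss^3 subsamples per voxel
    hu = hu_ss.reshape(shape[0], ss, shape[1], ss, shape[2], ss).mean(axis=(1, 3, 5))
    frac = (
        lumen_mask.astype(np.float32)
        .reshape(shape[0], ss, shape[1], ss, shape[2], ss)
        .mean(axis=(1, 3, 5))
    )
    mask = (frac >= 0.5).astype(np.uint8)
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma_hu, size=hu.shape)
    volume = ImageVolume(data=hu.astype(np.float32), spacing=spec.spacing, origin=origin)
    mask_obj = BinaryMask(data=mask, spacing=spec.spacing, origin=origin)
    return volume, mask_obj, spec.truth_table()


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    th = np.deg2rad(angle_deg)
    return (
        v * np.cos(th)
        + np.cross(axis, v) * np.sin(th)
        + axis * np.dot(axis, v) * (1.0 - np.cos(th))
    )


def single_tube_spec(
    radius_mm: float = 3.0,
    length_mm: float = 50.0,
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.7),
    tilt_deg: float = 0.0,
    amplitude_mm: float = 0.0,
    cycles: int = 1,
    radius_distal_mm: float | None = None,
    **kwargs,
) -> PhantomSpec:
    """A single mostly-vertical tube (superior start, so the trachea seed
    finder applies). ``tilt_deg`` tilts the chord off the z axis in x."""
    d = _rotate(np.array([0.0, 0.0, -1.0]), np.array([0.0, 1.0, 0.0]), tilt_deg)
    start = np.array([0.0, 0.0, length_mm * abs(d[2])])
    end = start + d * length_mm
    branch = PhantomBranch(
        id=0,
        parent_id=None,
        start=tuple(start),
        end=tuple(end),
        radius_proximal_mm=radius_mm,
        radius_distal_mm=radius_distal_mm if radius_distal_mm is not None else radius_mm,
        amplitude_mm=amplitude_mm,
        cycles=cycles,
        lobe="TRACHEA_MAIN",
        generation=0,
    )
    return PhantomSpec(branches=[branch], spacing=spacing, **kwargs)


def y_tree_spec(
    radius_mm: float = 3.5,
    child_ratio: float = 0.75,
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.7),
    **kwargs,
) -> PhantomSpec:
    """A trachea with two diverging children (the minimal branching tree)."""
    top = np.array([0.0, 0.0, 60.0])
    carina = np.array([0.0, 0.0, 30.0])
    r_child = radius_mm * child_ratio
    branches = [
        PhantomBranch(0, None, tuple(top), tuple(carina), radius_mm, radius_mm),
        PhantomBranch(
            1, 0, tuple(carina), tuple(carina + _unit([0.8, 0, -0.6]) * 22),
            r_child, r_child, lobe="RUL", generation=1,
        ),
        PhantomBranch(
            2, 0, tuple(carina), tuple(carina + _unit([-0.8, 0, -0.6]) * 22),
            r_child, r_child, lobe="LUL", generation=1,
        ),
    ]
    return PhantomSpec(branches=branches, spacing=spacing, **kwargs)


def build_standard_tree(
    base_radius_mm: float = 6.5,
    child_ratio: float = 0.75,
    amplitude_mm: float = 0.0,
    cycles: int = 1,
    max_generation: int = 6,
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.7),
    constant_radius: bool = True,
    **kwargs,
) -> PhantomSpec:
    """A six-lobe airway tree with known lobes and generations.

    The trachea descends from the most superior slice; the main bronchi
    split laterally; lobar bronchi are seeded with the directional
    conventions the lobe classifier expects (RUL superior on the right,
    RML anterior off the bronchus intermedius, lingula/LML
    inferior-anterior off the left upper lobe bronchus). Each lobe then
    grows a herringbone of alternating terminal side branches down to
    ``max_generation``. Every child's radius is ``child_ratio`` times its
    parent's; sinusoidal displacement of ``amplitude_mm`` applies to
    branches of generation >= 2.
    """
    branches: list[PhantomBranch] = []
    counter = [0]

    def add(parent_id, start, d, length, radius, gen, lobe, amp=0.0):
        bid = counter[0]
        counter[0] += 1
        end = np.asarray(start) + _unit(d) * length
        branches.append(
            PhantomBranch(
                id=bid,
                parent_id=parent_id,
                start=tuple(np.asarray(start, dtype=float)),
                end=tuple(end),
                radius_proximal_mm=radius,
                radius_distal_mm=radius,
                amplitude_mm=amp,
                cycles=cycles,
                lobe=lobe,
                generation=gen,
            )
        )
        return bid, end

    def grow(parent_id, start, d, length, radius, gen, lobe, sign):
        """Herringbone: one continuing and one terminal child per division."""
        amp = min(amplitude_mm, 0.25 * length) if gen >= 2 else 0.0
        bid, end = add(parent_id, start, d, length, radius, gen, lobe, amp)
        if gen >= max_generation:
            return
        d = _unit(d)
        a1 = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(a1) < 1e-8:
            a1 = np.cross(d, [1.0, 0.0, 0.0])
        a1 = _unit(a1)
        axis = a1 if gen % 2 == 0 else _unit(np.cross(d, a1))
        r_child = radius * child_ratio
        d_term = _rotate(d, axis, sign * 50.0)
        d_cont = _rotate(d, axis, -sign * 18.0)
        add(bid, end, d_term, length * 0.70, r_child, gen + 1, lobe,
            min(amplitude_mm, 0.25 * length * 0.70))
        grow(bid, end, d_cont, length * 0.85, r_child, gen + 1, lobe, -sign)

    r0 = base_radius_mm
    r1 = r0 * child_ratio
    r2 = r1 * child_ratio
    r3 = r2 * child_ratio

    top = np.array([0.0, 0.0, 110.0])
    tid, carina = add(None, top, [0, 0, -1], 40.0, r0, 0, "TRACHEA_MAIN")
    rm_id, rm_end = add(tid, carina, [0.8, 0.0, -0.6], 20.0, r1, 1, "TRACHEA_MAIN")
    lm_id, lm_end = add(tid, carina, [-0.8, 0.0, -0.55], 24.0, r1, 1, "TRACHEA_MAIN")

    # right lung
    grow(rm_id, rm_end, [0.55, 0.15, 0.82], 14.0, r2, 2, "RUL", sign=1)
    bi_id, bi_end = add(rm_id, rm_end, [0.25, 0.05, -0.97], 13.0, r2, 2, "RLL")
    grow(bi_id, bi_end, [0.35, 0.8, -0.48], 12.0, r3, 3, "RML", sign=1)
    grow(bi_id, bi_end, [0.3, -0.35, -0.89], 13.0, r3, 3, "RLL", sign=-1)

    # left lung (mirror of the right: lingula plays the middle-lobe role)
    grow(lm_id, lm_end, [-0.55, 0.15, 0.82], 14.0, r2, 2, "LUL", sign=-1)
    li_id, li_end = add(lm_id, lm_end, [-0.25, 0.05, -0.97], 13.0, r2, 2, "LLL")
    grow(li_id, li_end, [-0.35, 0.8, -0.48], 12.0, r3, 3, "LML", sign=-1)
    grow(li_id, li_end, [-0.3, -0.35, -0.89], 13.0, r3, 3, "LLL", sign=1)

    return PhantomSpec(branches=branches, spacing=spacing, **kwargs)


def standard_cohort(
    n_patients: int,
    seed: int,
    taper_range: tuple[float, float] = (0.20, 0.30),
    amplitude_range_mm: tuple[float, float] = (0.0, 1.5),
    **tree_kwargs,
) -> list[dict]:
    """Deterministic cohort of standard trees with sampled severity.

    Per case, the child narrowing fraction is drawn uniformly from
    ``taper_range`` and the sinusoid amplitude from ``amplitude_range_mm``
    (both recorded in the returned case dicts and recoverable from the
    truth tables). Identical seeds give identical cohorts.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_patients):
        taper = float(rng.uniform(*taper_range))
        amp = float(rng.uniform(*amplitude_range_mm))
        spec = build_standard_tree(
            child_ratio=1.0 - taper, amplitude_mm=amp, seed=seed + i, **tree_kwargs
        )
        cases.append(
            {
                "case_id": f"case{i:03d}",
                "spec": spec,
                "taper_fraction": taper,
                "amplitude_mm": amp,
            }
        )
    return cases
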