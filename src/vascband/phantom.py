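"""Synthetic nodule and vessel-tree phantoms with exact ground truth.

The phantoms stand in for segmented CT structures: a (optionally lobulated)
spherical nodule mask, branching tubular artery/vein trees placed outside the
nodule, and an optional Hounsfield-unit volume with configurable solid /
ground-glass / calcified / cavity intensities.  Every tree carries a
:class:`PhantomTruth` record with the analytically known per-band branch
count, rasterized in-band volume, and mean centerline tortuosity, so the
feature-extraction stage can be validated against known answers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre

from .bands import MIN_TORTUOSITY_PATH_MM
from .grid import VoxelVolume

__all__ = [
    "TubeBranch",
    "PhantomTruth",
    "make_nodule_phantom",
    "make_nodule_hu",
    "grow_vessel_tree",
    "rasterize_tubes",
]

DEFAULT_BANDS = (5.0, 10.0, 15.0)

# canonical CT intensities (HU), configurable in make_nodule_hu
HU_DEFAULTS = {
    "solid": 50.0,
    "ground_glass": -600.0,
    "calcified": 400.0,
    "cavity": -950.0,
    "background": -850.0,
}


@dataclass
class TubeBranch:
    """A tubular vessel branch: an ordered centerline polyline plus a radius."""

    centerline: np.ndarray  # (n, 3) world mm
    radius: float
    compartment: str = "artery"

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be an (n, 3) array of mm points")
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 points")
        steps = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive centerline points must be distinct")
        if self.radius <= 0:
            raise ValueError("radius must be positive (mm)")
        if self.compartment not in ("artery", "vein"):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def curved_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.centerline[-1] - self.centerline[0]))


@dataclass
class PhantomTruth:
    """Ground-truth per-band metrics for a generated vessel tree.

    Keys of the per-band dicts are ``(compartment, band_mm)``.  Volumes are in
    mm^3; ``mean_tortuosity`` is ``None`` for bands no branch reaches.
    """

    nodule_diameter: float
    bands: tuple[float, ...] = DEFAULT_BANDS
    count: dict = field(default_factory=dict)
    volume_mm3: dict = field(default_factory=dict)
    mean_tortuosity: dict = field(default_factory=dict)

    def validate(self) -> None:
        comps = {key[0] for key in self.count}
        for comp in comps:
            counts = [self.count[(comp, d)] for d in self.bands]
            vols = [self.volume_mm3[(comp, d)] for d in self.bands]
            if any(b < a for a, b in zip(counts, counts[1:])):
                raise ValueError("truth counts must be non-decreasing across bands")
            if any(b < a - 1e-9 for a, b in zip(vols, vols[1:])):
                raise ValueError("truth volumes must be non-decreasing across bands")
            for d in self.bands:
                tort = self.mean_tortuosity[(comp, d)]
                if tort is not None and tort < 1.0 - 1e-9:
                    raise ValueError("tortuosity cannot be below 1")

    def merged_with(self, other: "PhantomTruth") -> "PhantomTruth":
        out = PhantomTruth(self.nodule_diameter, self.bands)
        for src in (self, other):
            out.count.update(src.count)
            out.volume_mm3.update(src.volume_mm3)
            out.mean_tortuosity.update(src.mean_tortuosity)
        return out

    def to_json(self) -> str:
        def enc(d):
            return {f"{comp}{band:g}": v for (comp, band), v in d.items()}

        return json.dumps(
            {
                "nodule_diameter": self.nodule_diameter,
                "bands": list(self.bands),
                "count": enc(self.count),
                "volume_mm3": enc(self.volume_mm3),
                "mean_tortuosity": enc(self.mean_tortuosity),
            },
            indent=2,
        )


def _lobulation_field(rng: np.random.Generator, n_modes: int = 4) -> "callable":
    """Random low-order zonal-harmonic bump field on the unit sphere, max |f| ~ 1."""
    axes = rng.normal(size=(n_modes, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    degrees = rng.integers(2, 4, size=n_modes)  # l in {2, 3}
    amps = rng.normal(size=n_modes)

    def f(units: np.ndarray) -> np.ndarray:
        out = np.zeros(len(units))
        for axis, l, a in zip(axes, degrees, amps):
            coeffs = np.zeros(l + 1)
            coeffs[l] = 1.0
            out += a * legendre.legval(units @ axis, coeffs)
        peak = np.abs(out).max()
        return out / peak if peak > 0 else out

    return f


def make_nodule_phantom(
    diameter: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    lobulation: float = 0.0,
    seed: int | None = None,
    margin_mm: float = 2.0,
) -> VoxelVolume:
    """Generate a binary nodule mask: a digitized sphere, optionally lobulated.

    Parameters
    ----------
    diameter : float
        Nominal nodule diameter in mm (the study's nodules span 2.4-39.5 mm).
    spacing : tuple of float
        Voxel spacing in mm (may be anisotropic).
    lobulation : float
        Fractional radius perturbation in [0, 1] from a random low-order
        spherical-harmonic field; 0 gives an exact digitized sphere.
    margin_mm : float
        Empty margin around the nodule.  Use a margin of at least
        ``max(band) + tube length`` when vessel trees will be grown on the
        same grid.
    """
    spacing = tuple(float(s) for s in spacing)
    if diameter < 2.0 * max(spacing):
        raise ValueError("unresolvable nodule: diameter below voxel resolution")
    if not 0.0 <= lobulation <= 1.0:
        raise ValueError("lobulation must lie in [0, 1]")
    radius = diameter / 2.0
    half_extent = radius * (1.0 + lobulation) + margin_mm
    shape = tuple(int(2 * math.ceil(half_extent / s) + 1) for s in spacing)
    center = tuple((n - 1) / 2.0 * s for n, s in zip(shape, spacing))

    grids = np.meshgrid(
        *(np.arange(n) * s - c for n, s, c in zip(shape, spacing, center)),
        indexing="ij",
    )
    dist = np.sqrt(sum(g**2 for g in grids))
    if lobulation == 0:
        mask = dist <= radius
    else:
        rng = np.random.default_rng(seed)
        bump = _lobulation_field(rng)
        with np.errstate(invalid="ignore"):
            units = np.stack([g.ravel() for g in grids], axis=1)
            norms = np.linalg.norm(units, axis=1)
            norms[norms == 0] = 1.0
            units = units / norms[:, None]
        local_radius = radius * (1.0 + lobulation * bump(units)).reshape(shape)
        mask = dist <= local_radius
    return VoxelVolume(mask.astype(np.uint8), spacing, origin=(0.0, 0.0, 0.0))


def make_nodule_hu(
    nodule_mask: VoxelVolume,
    texture: str = "solid",
    cavity_fraction: float = 0.0,
    calcification_fraction: float = 0.0,
    hu_values: dict | None = None,
    seed: int | None = None,
) -> VoxelVolume:
    """Assign Hounsfield intensities to a nodule mask over lung background.

    ``texture`` selects the bulk intensity ("solid" or "ground_glass");
    ``cavity_fraction`` carves a central spherical cavity occupying that
    fraction of the nodule volume; ``calcification_fraction`` adds an
    off-center calcified sphere.
    """
    hu = dict(HU_DEFAULTS)
    if hu_values:
        hu.update(hu_values)
    if texture not in ("solid", "ground_glass"):
        raise ValueError("texture must be 'solid' or 'ground_glass'")
    mask = nodule_mask.as_bool()
    out = np.full(mask.shape, hu["background"], dtype=np.float32)
    out[mask] = hu[texture]

    idx = np.argwhere(mask)
    centroid = idx.mean(axis=0)
    spacing = np.array(nodule_mask.spacing)
    vox_mm = nodule_mask.voxel_volume
    dist = np.linalg.norm((np.indices(mask.shape).reshape(3, -1).T - centroid) * spacing, axis=1)
    dist = dist.reshape(mask.shape)

    if cavity_fraction > 0:
        target = cavity_fraction * mask.sum() * vox_mm
        r_cav = (3 * target / (4 * np.pi)) ** (1 / 3)
        out[mask & (dist <= r_cav)] = hu["cavity"]
    if calcification_fraction > 0:
        rng = np.random.default_rng(seed)
        target = calcification_fraction * mask.sum() * vox_mm
        r_cal = (3 * target / (4 * np.pi)) ** (1 / 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offset_mm = centroid * spacing + direction * max(0.0, dist[mask].max() * 0.4)
        coords = np.indices(mask.shape).reshape(3, -1).T * spacing
        cal = np.linalg.norm(coords - offset_mm, axis=1).reshape(mask.shape) <= r_cal
        out[mask & cal] = hu["calcified"]
    return nodule_mask.like(out)


def _segment_distance_mask(
    mask: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    radius: float,
    spacing: np.ndarray,
    flat_start: bool = False,
    flat_end: bool = False,
) -> None:
    """Mark voxels within ``radius`` of segment pq (world mm) in-place.

    Interior polyline joints use the clamped (capsule) distance so the tube
    surface stays smooth; the first/last segment of a branch cuts its outer
    end flat so a straight tube encloses pi r^2 L, not a capsule volume.
    """
    lo = np.minimum(p, q) - radius
    hi = np.maximum(p, q) + radius
    i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, mask.shape)
    if np.any(i0 >= i1):
        return
    axes = [np.arange(a, b) * s for a, b, s in zip(i0, i1, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    d = q - p
    denom = float(d @ d)
    if denom == 0:
        dist = np.linalg.norm(pts - p, axis=-1)
    else:
        t = ((pts - p) @ d) / denom
        proj = p + np.clip(t, 0.0, 1.0)[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
        outside = np.zeros(t.shape, dtype=bool)
        if flat_start:
            outside |= t < 0.0
        if flat_end:
            outside |= t > 1.0
        dist = np.where(outside, np.inf, dist)
    sub = mask[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]]
    sub |= dist <= radius


def rasterize_tubes(branches: list[TubeBranch], grid: VoxelVolume) -> VoxelVolume:
    """Rasterize tube branches onto a grid: voxel centers within the tube radius."""
    spacing = np.array(grid.spacing)
    mask = np.zeros(grid.shape, dtype=bool)
    for branch in branches:
        pts = branch.centerline - np.array(grid.origin)
        n_seg = len(pts) - 1
        for k, (p, q) in enumerate(zip(pts[:-1], pts[1:])):
            _segment_distance_mask(
                mask, p, q, branch.radius, spacing,
                flat_start=(k == 0), flat_end=(k == n_seg - 1),
            )
    return grid.like(mask.astype(np.uint8))


def _pick_directions(
    rng: np.random.Generator,
    n: int,
    min_angle: float,
    avoid: list[np.ndarray],
    max_tries: int = 20000,
) -> list[np.ndarray]:
    chosen: list[np.ndarray] = []
    existing = [np.asarray(a, dtype=float) for a in avoid]
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} branch directions with angular separation "
                f"{min_angle:.2f} rad; reduce branch count or radius"
            )
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(np.arccos(np.clip(v @ u, -1, 1)) >= min_angle for u in chosen + existing):
            chosen.append(v)
    return chosen


def grow_vessel_tree(
    nodule_mask: VoxelVolume,
    compartment: str = "artery",
    n_branches: int = 3,
    radius: float = 1.0,
    tortuosity_amp: float = 0.0,
    band_targets: dict | None = None,
    seed: int | None = None,
    bands: tuple[float, ...] = DEFAULT_BANDS,
    wavelength: float = 10.0,
    overshoot: float = 3.0,
    avoid: list[TubeBranch] | None = None,
) -> tuple[list[TubeBranch], PhantomTruth]:
    """Grow radial tube branches outside the nodule with known band metrics.

    Branches start at controlled distances from the nodule surface and extend
    outward past the largest band, with an optional sinusoidal in-plane
    perturbation of amplitude ``tortuosity_amp`` (mm).  ``band_targets`` maps
    band distance -> cumulative branch count and must be non-decreasing.

    Returns the branches plus a :class:`PhantomTruth` with the per-band branch
    count, rasterized in-band volume (using the analytic sphere distance), and
    the analytic mean tortuosity of in-band centerline segments.
    """
    if n_branches < 1 and not band_targets:
        raise ValueError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    bands = tuple(sorted(float(b) for b in bands))
    mask = nodule_mask.as_bool()
    if not mask.any():
        raise ValueError("no nodule")
    spacing = np.array(nodule_mask.spacing)
    center = np.argwhere(mask).mean(axis=0) * spacing + np.array(nodule_mask.origin)
    eq_radius = (3 * mask.sum() * nodule_mask.voxel_volume / (4 * np.pi)) ** (1 / 3)

    # starting surface-distances per branch; clear the surface by >= 1.5 mm so
    # the tube wall never enters the nodule, and stay >= 1.5 mm from every band
    # boundary so digitized band membership is unambiguous
    clearance = max(1.5, radius + 0.5)
    if band_targets:
        targets = {float(k): int(v) for k, v in band_targets.items()}
        if set(targets) - set(bands):
            raise ValueError(f"band_targets keys must be a subset of bands {bands}")
        ordered = [targets.get(b) for b in bands]
        filled = []
        prev = 0
        for t in ordered:
            t = prev if t is None else t
            if t < prev:
                raise ValueError("band_targets must be non-decreasing in distance")
            filled.append(t)
            prev = t
        shells = [(0.0, bands[0], filled[0])]
        shells += [
            (bands[i - 1], bands[i], filled[i] - filled[i - 1]) for i in range(1, len(bands))
        ]
        starts = []
        for lo, hi, cnt in shells:
            # keep every in-band centerline arc >= 3 mm so band membership and
            # the minimum-tortuosity-path rule are unambiguous after digitization
            lo_d = max(lo + 1.5, clearance)
            hi_d = hi - 3.0
            if cnt > 0 and lo_d >= hi_d:
                raise ValueError(f"band shell ({lo}, {hi}] too thin for branch placement")
            starts += list(rng.uniform(lo_d, hi_d, size=cnt))
        n_branches = len(starts)
    else:
        hi_d = max(clearance + 0.1, min(bands[0] - 3.0, clearance + 1.0))
        starts = list(rng.uniform(clearance, hi_d, size=n_branches))

    min_sep = 3.0 * radius + 2.0 * float(spacing.max())
    min_angle = min_sep / (eq_radius + min(starts, default=clearance))
    avoid_dirs = []
    for br in avoid or []:
        u = br.centerline[-1] - br.centerline[0]
        avoid_dirs.append(u / np.linalg.norm(u))
    directions = _pick_directions(rng, n_branches, min_angle, avoid_dirs)

    extent_mm = np.array(nodule_mask.shape) * spacing
    branches: list[TubeBranch] = []
    analytic = []  # per branch: (t_samples, dist_samples, points)
    for d0, u in zip(starts, directions):
        length = bands[-1] - d0 + overshoot
        w = np.cross(u, rng.normal(size=3))
        w /= np.linalg.norm(w)
        t = np.arange(0.0, length + 1e-9, 0.05)
        pts = (
            center
            + (eq_radius + d0 + t)[:, None] * u
            + (tortuosity_amp * np.sin(2 * np.pi * t / wavelength))[:, None] * w
        )
        local = pts - np.array(nodule_mask.origin)
        if np.any(local < radius + spacing) or np.any(local > extent_mm - radius - spacing):
            raise ValueError(
                "vessel tree does not fit on the grid; regenerate the nodule with a "
                f"margin of at least {bands[-1] + overshoot + 2 * radius:.0f} mm"
            )
        coarse = pts[:: max(1, int(round(0.25 / 0.05)))]
        if not np.array_equal(coarse[-1], pts[-1]):
            coarse = np.vstack([coarse, pts[-1]])
        branches.append(TubeBranch(coarse, radius, compartment))
        dist = np.linalg.norm(pts - center, axis=1) - eq_radius
        analytic.append((t, dist, pts))

    truth = PhantomTruth(nodule_diameter=2 * eq_radius, bands=bands)
    tube_vol = rasterize_tubes(branches, nodule_mask)
    coords = np.indices(mask.shape).reshape(3, -1).T * spacing + np.array(nodule_mask.origin)
    vox_dist = (np.linalg.norm(coords - center, axis=1) - eq_radius).reshape(mask.shape)
    tube = tube_vol.as_bool() & ~mask
    for d in bands:
        in_band_vox = tube & (vox_dist > 0) & (vox_dist <= d)
        torts = []
        cnt = 0
        for t, dist, pts in analytic:
            sel = dist <= d
            if not sel.any():
                continue
            cnt += 1
            sub = pts[sel]
            if len(sub) < 2:
                continue
            arc = np.linalg.norm(np.diff(sub, axis=0), axis=1).sum()
            chord = np.linalg.norm(sub[-1] - sub[0])
            # same minimum-path rule as the feature extractor's tortuosity mean
            if chord > 1e-9 and arc >= MIN_TORTUOSITY_PATH_MM:
                torts.append(arc / chord)
        truth.count[(compartment, d)] = cnt
        truth.volume_mm3[(compartment, d)] = float(in_band_vox.sum() * nodule_mask.voxel_volume)
        truth.mean_tortuosity[(compartment, d)] = float(np.mean(torts)) if torts else None
    truth.validate()
    return branches, truth
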