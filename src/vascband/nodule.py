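"""CT-derived nodule characteristics from a mask and HU volume.

Computes the classic nodule descriptors used alongside the peri-nodular
vasculature: volume, mean density, mean/maximum diameter, surface area,
irregularity (surface area / volume), composition ratios from HU thresholds
(cavity, ground-glass, fat, solid, calcified), and an Agatston-style
calcification score.  Column names follow the cohort-table convention,
including the historical spelling ``tumor_cavitiy_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

from .grid import VoxelVolume

__all__ = ["HUBins", "NoduleFeatureVector", "nodule_metrics", "NODULE_FEATURE_NAMES"]

NODULE_FEATURE_NAMES = [
    "tumor_volume",
    "tumor_density",
    "tumor_mean_diameter",
    "tumor_max_diameter",
    "tumor_surface_area",
    "tumor_irregularity",
    "tumor_cal_volume",
    "tumor_cavitiy_ratio",
    "tumor_ground_glass_ratio",
    "tumor_fat_ratio",
    "solidness",
    "tumor_AgatstonCal",
]


@dataclass
class HUBins:
    """Disjoint HU composition bins (canonical CT values, all configurable).

    solid is everything above ``ground_glass_hi`` that is neither fat nor
    calcified; the [-900, -750) gap between cavity and ground-glass stays
    unclassified, so the five ratios sum to at most 1.
    """

    cavity_max: float = -900.0
    ground_glass_lo: float = -750.0
    ground_glass_hi: float = -300.0
    fat_lo: float = -120.0
    fat_hi: float = -30.0
    calcified_min: float = 130.0


@dataclass
class NoduleFeatureVector:
    tumor_volume: float  # cm^3
    tumor_density: float  # mean HU
    tumor_mean_diameter: float  # mm, equivalent-sphere
    tumor_max_diameter: float  # mm, max Feret
    tumor_surface_area: float  # mm^2
    tumor_irregularity: float  # mm^-1, surface area / volume (mm units)
    tumor_cal_volume: float  # cm^3
    tumor_cavitiy_ratio: float
    tumor_ground_glass_ratio: float
    tumor_fat_ratio: float
    solidness: float
    tumor_AgatstonCal: float

    def as_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in NODULE_FEATURE_NAMES})


def _max_feret_diameter(mask: np.ndarray, spacing: tuple[float, ...]) -> float:
    pts = np.argwhere(mask) * np.asarray(spacing)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar) clouds: brute force below
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def _surface_area(mask: np.ndarray, spacing: tuple[float, ...]) -> float:
    # pad so the isosurface closes at the border; a one-voxel Gaussian smooth
    # removes the staircase bias of meshing a binary volume directly
    padded = np.pad(mask.astype(np.float32), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def _agatston(
    hu: np.ndarray, mask: np.ndarray, spacing: tuple[float, ...], threshold: float
) -> float:
    """Slice-wise Agatston-style score: per axial connected component of
    >= 1 mm^2 above threshold, area times a 1-4 weight from the peak HU."""
    pixel_area = spacing[0] * spacing[1]
    score = 0.0
    for k in range(hu.shape[2]):
        plane = (hu[:, :, k] >= threshold) & mask[:, :, k]
        if not plane.any():
            continue
        labels = measure.label(plane, connectivity=2)
        for region in measure.regionprops(labels):
            area = region.area * pixel_area
            if area < 1.0:
                continue
            peak = hu[:, :, k][labels == region.label].max()
            weight = 1 + (peak >= 200) + (peak >= 300) + (peak >= 400)
            score += area * weight
    return score


def nodule_metrics(
    nodule_mask: VoxelVolume, hu: VoxelVolume, bins: HUBins | None = None
) -> NoduleFeatureVector:
    """All CT-derived nodule characteristics for one nodule.

    Volume is voxel count x voxel volume (reported in cm^3); mean diameter is
    the equivalent-sphere diameter (6V/pi)^(1/3); max diameter the largest
    pairwise surface distance (Feret); surface area comes from a
    marching-cubes isosurface at the 0.5 level (voxel-face counting would
    systematically overestimate it); irregularity is surface area / volume in
    mm units.
    """
    bins = bins or HUBins()
    if not nodule_mask.same_grid(hu):
        raise ValueError("mask and HU volume must share one grid")
    mask = nodule_mask.as_bool()
    if not mask.any():
        raise ValueError("empty nodule mask")
    spacing = nodule_mask.spacing
    vol_mm3 = float(mask.sum()) * nodule_mask.voxel_volume
    values = np.asarray(hu.data, dtype=float)[mask]

    cavity = values < bins.cavity_max
    ggo = (values >= bins.ground_glass_lo) & (values < bins.ground_glass_hi)
    fat = (values >= bins.fat_lo) & (values <= bins.fat_hi)
    calcified = values > bins.calcified_min
    solid = (values >= bins.ground_glass_hi) & ~fat & ~calcified
    n = len(values)

    surface = _surface_area(mask, spacing)
    return NoduleFeatureVector(
        tumor_volume=vol_mm3 / 1000.0,
        tumor_density=float(values.mean()),
        tumor_mean_diameter=float((6.0 * vol_mm3 / np.pi) ** (1.0 / 3.0)),
        tumor_max_diameter=_max_feret_diameter(mask, spacing),
        tumor_surface_area=surface,
        tumor_irregularity=surface / vol_mm3,
        tumor_cal_volume=float(calcified.sum()) * nodule_mask.voxel_volume / 1000.0,
        tumor_cavitiy_ratio=float(cavity.sum()) / n,
        tumor_ground_glass_ratio=float(ggo.sum()) / n,
        tumor_fat_ratio=float(fat.sum()) / n,
        solidness=float(solid.sum()) / n,
        tumor_AgatstonCal=_agatston(
            np.asarray(hu.data, dtype=float), mask, spacing, bins.calcified_min
        ),
    )
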