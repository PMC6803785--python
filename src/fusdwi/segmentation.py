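"""MDWI lesion delineation, radial layer masks, and volume bookkeeping.

The lesion is the brightest contiguous region on the post-treatment mean DWI.
The cutoff intensity is the smallest intensity present in the brain such that
fewer than a given fraction (default 1.1%) of brain voxels exceed it; among
the 26-connected components of supra-cutoff voxels, the one containing the
global maximum is the lesion ("lesion boundary" region).  One-voxel erosion
isolates the core (guarding against partial-volume rim voxels); one-voxel
dilation gives the outer boundary.  Erosion/dilation use the 6-connected
face-adjacent structuring element: at 1 mm isotropic voxels this is the
closest approximation to peeling/growing a 1 mm radial layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .exceptions import DegenerateImageError, NoLesionFoundError
from .tensor import ScalarMap

__all__ = [
    "LesionLayers",
    "TreatmentCell",
    "select_cutoff",
    "extract_lesion",
    "make_layers",
    "mask_volume",
    "treatment_cell_volume",
    "histology_volume",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class LesionLayers:
    """The thresholded region and its radial layers.

    ``region`` is the full contiguous thresholded mask; ``core`` its one-voxel
    erosion; ``boundary_shell = region - core``; ``outer_shell`` the one-voxel
    dilation ring outside the region; ``nested_outer`` the full dilation.
    """

    region: np.ndarray
    core: np.ndarray
    boundary_shell: np.ndarray
    outer_shell: np.ndarray
    nested_outer: np.ndarray

    def disjoint(self) -> dict:
        """The three pairwise-disjoint analysis layers."""
        return {"core": self.core, "boundary": self.boundary_shell, "outer": self.outer_shell}

    def nested(self) -> dict:
        """The nested interpretation: core within region within dilation."""
        return {"core": self.core, "boundary": self.region, "outer": self.nested_outer}


@dataclass(frozen=True)
class TreatmentCell:
    """Sonication cell geometry: an ellipsoid of revolution (mm)."""

    cross_diameter: float = 4.0
    length: float = 10.0

    def __post_init__(self) -> None:
        if self.cross_diameter <= 0 or self.length <= 0:
            raise ValueError("cell dimensions must be positive")


def select_cutoff(mdwi: ScalarMap, brain: np.ndarray, fraction: float = 0.011) -> float:
    """Voxel-fraction cutoff: smallest present intensity exceeded by < fraction of brain.

    Returns the smallest intensity value c present in the brain-masked MDWI
    such that ``count(intensity > c) / count(brain) < fraction``.  Candidate
    lesion voxels are those strictly above c; if none exist (constant image),
    the image is degenerate.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    brain = np.asarray(brain, dtype=bool)
    values = mdwi.data[brain & mdwi.valid_mask]
    if values.size == 0:
        raise DegenerateImageError("brain mask contains no valid voxels")
    n = values.size
    uniq = np.unique(values)
    # count of voxels strictly above each unique value
    above = n - np.searchsorted(np.sort(values), uniq, side="right")
    ok = above / n < fraction
    cutoff = float(uniq[np.argmax(ok)])  # unique values ascending; first True is smallest
    if above[np.argmax(ok)] == 0:
        raise DegenerateImageError(
            "no voxel exceeds any candidate cutoff (constant image?)"
        )
    return cutoff


def extract_lesion(mdwi: ScalarMap, cutoff: float, brain: np.ndarray) -> np.ndarray:
    """The 26-connected supra-cutoff component containing the global maximum.

    Ties on the maximum intensity are broken by lowest linear voxel index.
    """
    brain = np.asarray(brain, dtype=bool)
    data = np.where(brain & mdwi.valid_mask, mdwi.data, -np.inf)
    candidates = data > cutoff
    if not np.any(candidates):
        raise NoLesionFoundError("no voxel above the cutoff intensity")
    labels = label(candidates, connectivity=3)  # 26-connectivity in 3D
    peak = np.unravel_index(np.argmax(data), data.shape)
    return labels == labels[peak]


def make_layers(region: np.ndarray) -> LesionLayers:
    """Erode and dilate the thresholded region by one 6-connected voxel layer."""
    region = np.asarray(region, dtype=bool)
    if not np.any(region):
        raise ValueError("region must be nonempty")
    core = ndimage.binary_erosion(region, structure=_FACE_STRUCT)
    if not np.any(core):
        warnings.warn("one-voxel erosion emptied the region; core is empty",
                      RuntimeWarning, stacklevel=2)
    dilated = ndimage.binary_dilation(region, structure=_FACE_STRUCT)
    return LesionLayers(
        region=region,
        core=core,
        boundary_shell=region & ~core,
        outer_shell=dilated & ~region,
        nested_outer=dilated,
    )


def mask_volume(mask: np.ndarray, voxel_size: float) -> float:
    """Mask volume in mm^3: voxel count times voxel volume."""
    return float(np.count_nonzero(mask)) * float(voxel_size) ** 3


def treatment_cell_volume(cell: TreatmentCell) -> float:
    """Ellipsoid volume (4/3) pi (d/2)^2 (L/2) of the sonication cell, mm^3."""
    return 4.0 / 3.0 * np.pi * (cell.cross_diameter / 2.0) ** 2 * (cell.length / 2.0)


def histology_volume(slice_areas, slice_thickness: float = 0.2) -> float:
    """Lesion volume from serial sections: sum of area * slice thickness (mm^3)."""
    areas = np.asarray(list(slice_areas), dtype=float)
    if areas.size and np.any(areas < 0):
        raise ValueError("slice areas must be nonnegative")
    if slice_thickness <= 0:
        raise ValueError("slice thickness must be positive")
    return float(areas.sum() * slice_thickness)
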