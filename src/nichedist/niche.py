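"""Reference geometry of the two adult neurogenic niches.

The subventricular zone (SVZ) lines the lateral ventricle walls; it is
modeled as the ventricle *surface* voxels plus a parenchymal rim of
configurable thickness (default 3 mm — the adult SVZ is a few-millimetre
ribbon). The subgranular zone (SGZ) sits in the hippocampal dentate gyrus;
it is modeled as the per-hemisphere center of mass of the dentate-gyrus
label (one point per side of the midline x = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import (
    BinaryMask,
    LabeledVolume,
    VolumeError,
    apply_affine,
    require_same_grid,
)

__all__ = ["NicheGeometry", "extract_svz_band", "sgz_points", "mask_from_labels"]

DEFAULT_SVZ_THICKNESS_MM = 3.0

# 6-connectivity (face neighbors) for surface extraction
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


class EmptyNicheError(VolumeError):
    """The source label mask has no foreground voxels."""


@dataclass
class NicheGeometry:
    """World-space representation of one niche.

    ``elements`` are (N, 3) world-mm coordinates: voxel centers for a
    ``voxel_band`` (SVZ), centroid points for a ``point_set`` (SGZ).
    ``voxel_indices`` accompanies a voxel_band so that exact cell-sharing
    (lesion contact) can be decided without floating-point comparison.
    """

    name: str
    kind: str  # "voxel_band" | "point_set"
    elements: np.ndarray
    affine: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None
    voxel_indices: np.ndarray | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _member: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.elements = np.atleast_2d(np.asarray(self.elements, dtype=float))
        if self.elements.size == 0:
            raise EmptyNicheError(f"niche {self.name!r} has no elements")
        if self.kind not in ("voxel_band", "point_set"):
            raise ValueError(f"unknown niche kind {self.kind!r}")

    @property
    def tree(self) -> cKDTree:
        """KD-tree over elements, built lazily and cached."""
        if self._tree is None:
            self._tree = cKDTree(self.elements)
        return self._tree

    def membership_volume(self) -> np.ndarray | None:
        """Boolean grid marking band voxels (voxel_band on a known grid)."""
        if self.kind != "voxel_band" or self.voxel_indices is None or self.grid_shape is None:
            return None
        if self._member is None:
            m = np.zeros(self.grid_shape, dtype=bool)
            m[tuple(self.voxel_indices.T)] = True
            self._member = m
        return self._member


def extract_svz_band(
    ventricle_mask: BinaryMask,
    brain_mask: BinaryMask,
    thickness_mm: float = DEFAULT_SVZ_THICKNESS_MM,
) -> NicheGeometry:
    """Periventricular band standing in for the SVZ.

    The band contains (a) ventricle *surface* voxels — ventricle voxels with
    at least one 6-connected non-ventricle neighbor — and (b) every voxel
    inside the brain, outside the ventricles, whose center lies within
    ``thickness_mm`` of the nearest ventricle voxel center. Thickness 0
    degenerates to the ventricle surface alone. The Euclidean distance field
    respects anisotropic voxel spacing.
    """
    require_same_grid(ventricle_mask, brain_mask, "ventricle and brain masks")
    if thickness_mm < 0:
        raise ValueError("thickness_mm must be >= 0")
    vent = ventricle_mask.data.astype(bool)
    if not vent.any():
        raise EmptyNicheError("ventricle mask is empty")
    brain = brain_mask.data.astype(bool)

    # distance from each voxel center to the nearest ventricle voxel center
    dist = ndimage.distance_transform_edt(~vent, sampling=ventricle_mask.spacing)
    rim = brain & ~vent & (dist <= thickness_mm + 1e-9)

    eroded = ndimage.binary_erosion(vent, structure=_FACE_STRUCT, border_value=0)
    surface = vent & ~eroded

    band = rim | surface
    idx = np.argwhere(band)
    return NicheGeometry(
        name="SVZ",
        kind="voxel_band",
        elements=apply_affine(ventricle_mask.affine, idx),
        affine=ventricle_mask.affine,
        grid_shape=ventricle_mask.shape,
        voxel_indices=idx,
    )


def sgz_points(dentate_mask: BinaryMask) -> NicheGeometry:
    """Per-hemisphere dentate-gyrus centers of mass.

    Foreground voxel centers are split by the midline plane x = 0 (world
    RAS+): left is x < 0, right is x >= 0. Each non-empty side contributes
    one unweighted centroid, so a bilateral dentate yields two points and
    downstream distances take the minimum over them.
    """
    if not dentate_mask.data.any():
        raise EmptyNicheError("dentate mask is empty")
    world = dentate_mask.foreground_world()
    points = []
    for side in (world[world[:, 0] < 0], world[world[:, 0] >= 0]):
        if len(side):
            points.append(side.mean(axis=0))
    return NicheGeometry(
        name="SGZ",
        kind="point_set",
        elements=np.array(points),
        affine=dentate_mask.affine,
        grid_shape=dentate_mask.shape,
    )


def mask_from_labels(atlas: LabeledVolume, labels) -> BinaryMask:
    """Reduce a multi-label atlas volume to a binary mask of the given ids."""
    data = np.isin(np.asarray(atlas.data), np.asarray(list(labels))).astype(np.uint8)
    return BinaryMask(data=data, affine=atlas.affine)
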