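"""Per-lesion geometry: centroid, volume, niche distances, contact flags.

Conventions. The "tumor center" is the unweighted centroid of foreground
voxel centers (the only parameter-free choice). Border distance is the
minimum Euclidean distance between any lesion voxel center and any niche
element, *set to zero on contact*: a lesion voxel occupying the same grid
cell as an SVZ band voxel, or an SGZ point falling inside a lesion voxel's
cell. Bilateral niches contribute the minimum over both sides. All
distances are world-space millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .niche import NicheGeometry
from .volume_io import BinaryMask, VolumeError

__all__ = [
    "DistanceResult",
    "lesion_centroid",
    "lesion_volume_ml",
    "border_distance",
    "center_distance",
    "contact_flags",
    "measure_lesion",
]

GROUPS = (
    "oligodendroglioma_IDHmut_codel",
    "astrocytoma_IDHmut",
    "astrocytoma_IDHwt",
)
IDH_MUTANT_GROUPS = GROUPS[:2]


class EmptyMaskError(VolumeError):
    """Operation requires at least one foreground voxel."""


@dataclass
class DistanceResult:
    """One lesion's measurements against both niches."""

    subject_id: str
    group: str
    border_svz_mm: float
    center_svz_mm: float
    border_sgz_mm: float
    center_sgz_mm: float
    contact_svz: bool
    contact_sgz: bool
    volume_ml: float
    region: str = "unclassified"

    def __post_init__(self) -> None:
        for niche in ("svz", "sgz"):
            b = getattr(self, f"border_{niche}_mm")
            c = getattr(self, f"center_{niche}_mm")
            if b > c + 1e-9:
                raise ValueError(f"border distance exceeds center distance for {niche}")
            if bool(getattr(self, f"contact_{niche}")) != (b == 0.0):
                raise ValueError(f"contact_{niche} inconsistent with border distance {b}")

    def as_dict(self) -> dict:
        return asdict(self)


def _foreground(mask: BinaryMask) -> np.ndarray:
    world = mask.foreground_world()
    if len(world) == 0:
        raise EmptyMaskError("lesion mask has no foreground voxels")
    return world


def lesion_centroid(mask: BinaryMask) -> np.ndarray:
    """Unweighted mean of foreground voxel-center world coordinates (mm)."""
    return _foreground(mask).mean(axis=0)


def lesion_volume_ml(mask: BinaryMask) -> float:
    """Foreground voxel count x voxel volume, in millilitres."""
    return mask.foreground_count * mask.voxel_volume_mm3 / 1000.0


def _point_inside_lesion(mask: BinaryMask, point: np.ndarray) -> bool:
    """Does a world point fall inside some foreground voxel's cell?"""
    inv = np.linalg.inv(mask.affine)
    cont = inv[:3, :3] @ np.asarray(point, float) + inv[:3, 3]
    idx = np.round(cont).astype(int)  # cell of center i spans [i-1/2, i+1/2)
    if np.any(idx < 0) or np.any(idx >= np.array(mask.shape)):
        return False
    return bool(mask.data[tuple(idx)])


def _in_contact(mask: BinaryMask, niche: NicheGeometry) -> bool:
    """Exact cell-sharing test between lesion and niche."""
    if niche.kind == "voxel_band":
        member = niche.membership_volume()
        if member is not None and niche.affine is not None and np.allclose(
            niche.affine, mask.affine, atol=1e-6
        ) and member.shape == mask.shape:
            return bool(member[mask.data.astype(bool)].any())
        # band on a different grid: fall back to element-in-cell test
        return any(_point_inside_lesion(mask, e) for e in niche.elements)
    return any(_point_inside_lesion(mask, p) for p in niche.elements)


def _border_distance_from(world: np.ndarray, mask: BinaryMask, niche: NicheGeometry) -> float:
    if _in_contact(mask, niche):
        return 0.0
    d, _ = niche.tree.query(world)
    return float(np.min(d))


def border_distance(mask: BinaryMask, niche: NicheGeometry) -> float:
    """Shortest lesion-border to niche distance; 0 on contact."""
    return _border_distance_from(_foreground(mask), mask, niche)


def center_distance(mask: BinaryMask, niche: NicheGeometry) -> float:
    """Distance from the lesion centroid to the nearest niche element."""
    c = lesion_centroid(mask)
    d, _ = niche.tree.query(c)
    return float(d)


def contact_flags(
    mask: BinaryMask, svz: NicheGeometry, sgz: NicheGeometry
) -> tuple[bool, bool]:
    """(contact with SVZ, contact with SGZ), i.e. border distance == 0."""
    return border_distance(mask, svz) == 0.0, border_distance(mask, sgz) == 0.0


def measure_lesion(
    mask: BinaryMask,
    svz: NicheGeometry,
    sgz: NicheGeometry,
    subject_id: str = "",
    group: str = "",
    region: str = "unclassified",
) -> DistanceResult:
    """All DistanceResult fields for one lesion in one pass."""
    world = _foreground(mask)
    centroid = world.mean(axis=0)
    b_svz = _border_distance_from(world, mask, svz)
    b_sgz = _border_distance_from(world, mask, sgz)
    return DistanceResult(
        subject_id=subject_id,
        group=group,
        border_svz_mm=b_svz,
        center_svz_mm=float(svz.tree.query(centroid)[0]),
        border_sgz_mm=b_sgz,
        center_sgz_mm=float(sgz.tree.query(centroid)[0]),
        contact_svz=b_svz == 0.0,
        contact_sgz=b_sgz == 0.0,
        volume_ml=lesion_volume_ml(mask),
        region=region,
    )
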