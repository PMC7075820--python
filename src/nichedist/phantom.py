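"""Template-space brain phantom and stochastic lesion cohorts.

The phantom stands in for a real template plus anatomical atlases: an
ellipsoidal brain on a 91 x 109 x 91 grid at 2 mm isotropic spacing with an
MNI-like origin, two mirrored curved-tube lateral ventricles, two
ellipsoidal dentate gyri near (+/-25, -25, -15) mm, and a coarse lobar
atlas built from half-space rules (frontal, parietal, temporal, deep
central, brainstem/cerebellum).

Lesions are digitized spheres (optionally roughened by a smooth random
surface perturbation of bounded relative amplitude) seeded from a spatial
density proportional to exp(-d_target / lambda), where d_target is the
distance to the chosen niche (SVZ band or SGZ points) and lambda controls
bias strength in mm; lambda small = strong niche attraction, target "none"
= uniform over the brain. Sphere geometry keeps ground-truth distances
analytic: for an unperturbed, unclipped sphere of radius r seeded at
distance d from a niche, the true center distance is d and the true border
distance is max(0, d - r).

Default cohort: three molecular groups of 50/64/45 subjects with log-normal
volumes (medians 48.4/73.4/45.9 ml) and bias settings calibrated so the
group medians of center-to-SGZ distance fall near 42/31/21 mm while the
border-to-SVZ median is 0 mm in every group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.interpolate import make_interp_spline
from scipy.spatial import cKDTree

from .metrics import GROUPS
from .niche import NicheGeometry, extract_svz_band, sgz_points
from .volume_io import BinaryMask, LabeledVolume, apply_affine, write_volume

__all__ = [
    "PhantomSpec",
    "GroupSpec",
    "CohortConfig",
    "Phantom",
    "make_phantom",
    "sample_lesion",
    "generate_cohort",
    "REGION_LABELS",
    "REGION_PRECEDENCE",
]

REGION_LABELS = {
    1: "frontal",
    2: "parietal",
    3: "temporal",
    4: "deep_central",
    5: "brainstem_cerebellum",
}
REGION_PRECEDENCE = (1, 2, 3, 4, 5)


def _mni_affine(shape, spacing) -> np.ndarray:
    """RAS+ affine with the grid centered like common 2 mm templates."""
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    affine[:3, 3] = (-90.0, -126.0, -72.0)
    return affine


@dataclass
class PhantomSpec:
    """Geometry of the synthetic template brain (all coordinates world mm)."""

    shape: tuple[int, int, int] = (91, 109, 91)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_center: tuple[float, float, float] = (0.0, -16.0, 4.0)
    brain_semi_axes: tuple[float, float, float] = (68.0, 86.0, 62.0)
    # one lateral ventricle's centerline control points (left side, x < 0);
    # the right side is its mirror image in x
    ventricle_centerline: tuple[tuple[float, float, float], ...] = (
        (-18.0, 30.0, 4.0),
        (-16.0, 10.0, 14.0),
        (-17.0, -12.0, 16.0),
        (-23.0, -32.0, 10.0),
        (-29.0, -36.0, -6.0),
    )
    ventricle_radius_mm: float = 4.0
    dentate_center: tuple[float, float, float] = (-24.0, -24.0, -16.0)
    dentate_semi_axes: tuple[float, float, float] = (5.0, 13.0, 6.0)
    # lobar half-space parameters
    deep_box: tuple[float, float, float, float, float] = (24.0, -38.0, 8.0, -10.0, 28.0)
    frontal_y_min: float = 8.0
    temporal_z_max: float = -8.0
    cerebellum_y_max: float = -55.0
    cerebellum_z_max: float = -15.0

    @property
    def affine(self) -> np.ndarray:
        return _mni_affine(self.shape, self.spacing)


def _voxel_centers(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    """World coordinates of every voxel center, as three broadcast grids."""
    aff = spec.affine
    xs = aff[0, 0] * np.arange(spec.shape[0]) + aff[0, 3]
    ys = aff[1, 1] * np.arange(spec.shape[1]) + aff[1, 3]
    zs = aff[2, 2] * np.arange(spec.shape[2]) + aff[2, 3]
    return np.meshgrid(xs, ys, zs, indexing="ij")


def _ellipsoid(xg, yg, zg, center, semi) -> np.ndarray:
    return (
        ((xg - center[0]) / semi[0]) ** 2
        + ((yg - center[1]) / semi[1]) ** 2
        + ((zg - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _tube_mask(spec: PhantomSpec, xg, yg, zg, mirror: bool) -> np.ndarray:
    pts = np.array(spec.ventricle_centerline, dtype=float)
    if mirror:
        pts = pts * np.array([-1.0, 1.0, 1.0])
    t = np.linspace(0.0, 1.0, len(pts))
    spline = make_interp_spline(t, pts, k=min(3, len(pts) - 1))
    dense = spline(np.linspace(0.0, 1.0, 400))
    tree = cKDTree(dense)
    r = spec.ventricle_radius_mm
    lo = dense.min(axis=0) - r - 2.0
    hi = dense.max(axis=0) + r + 2.0
    box = (
        (xg >= lo[0]) & (xg <= hi[0])
        & (yg >= lo[1]) & (yg <= hi[1])
        & (zg >= lo[2]) & (zg <= hi[2])
    )
    mask = np.zeros(spec.shape, dtype=bool)
    coords = np.stack([xg[box], yg[box], zg[box]], axis=1)
    d, _ = tree.query(coords)
    mask[box] = d <= r
    return mask


def _region_atlas(spec: PhantomSpec, brain, xg, yg, zg) -> np.ndarray:
    atlas = np.zeros(spec.shape, dtype=np.int16)
    bx, by_lo, by_hi, bz_lo, bz_hi = spec.deep_box
    cerebellum = (yg < spec.cerebellum_y_max) & (zg < spec.cerebellum_z_max)
    deep = (
        (np.abs(xg) <= bx)
        & (yg >= by_lo) & (yg <= by_hi)
        & (zg >= bz_lo) & (zg <= bz_hi)
    )
    frontal = yg >= spec.frontal_y_min
    temporal = zg <= spec.temporal_z_max
    atlas[brain] = 2  # parietal is the remainder
    atlas[brain & temporal] = 3
    atlas[brain & frontal] = 1
    atlas[brain & deep] = 4
    atlas[brain & cerebellum] = 5
    return atlas


@dataclass
class Phantom:
    """Phantom masks plus cached niche geometry and seed-bias distance fields."""

    spec: PhantomSpec
    brain: BinaryMask
    ventricles: BinaryMask
    dentate: BinaryMask
    region_atlas: LabeledVolume
    svz: NicheGeometry
    sgz: NicheGeometry
    d_svz: np.ndarray  # per-voxel distance (mm) to nearest SVZ band voxel center
    d_sgz: np.ndarray  # per-voxel distance (mm) to nearest SGZ point
    brain_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.brain_indices = np.argwhere(self.brain.data > 0)

    def seed_distance_field(self, target: str) -> np.ndarray | None:
        if target == "SVZ":
            return self.d_svz
        if target == "SGZ":
            return self.d_sgz
        if target in ("none", None):
            return None
        raise ValueError(f"unknown bias target {target!r}")


def make_phantom(
    spec: PhantomSpec | None = None, svz_thickness_mm: float = 3.0
) -> Phantom:
    """Build the phantom masks, lobar atlas, and derived niche geometry."""
    spec = spec or PhantomSpec()
    xg, yg, zg = _voxel_centers(spec)
    brain = _ellipsoid(xg, yg, zg, spec.brain_center, spec.brain_semi_axes)
    vent = _tube_mask(spec, xg, yg, zg, mirror=False) | _tube_mask(
        spec, xg, yg, zg, mirror=True
    )
    dc = np.array(spec.dentate_center)
    dentate = _ellipsoid(xg, yg, zg, dc, spec.dentate_semi_axes) | _ellipsoid(
        xg, yg, zg, dc * np.array([-1.0, 1.0, 1.0]), spec.dentate_semi_axes
    )
    if (vent & ~brain).any() or (dentate & ~brain).any():
        raise ValueError("phantom structures exceed the brain ellipsoid")
    atlas = _region_atlas(spec, brain, xg, yg, zg)

    aff = spec.affine
    brain_m = BinaryMask(data=brain.astype(np.uint8), affine=aff)
    vent_m = BinaryMask(data=vent.astype(np.uint8), affine=aff)
    dent_m = BinaryMask(data=dentate.astype(np.uint8), affine=aff)
    atlas_v = LabeledVolume(data=atlas, affine=aff)

    svz = extract_svz_band(vent_m, brain_m, thickness_mm=svz_thickness_mm)
    sgz = sgz_points(dent_m)

    band = svz.membership_volume()
    d_svz = ndimage.distance_transform_edt(~band, sampling=spec.spacing)
    coords = np.stack([xg, yg, zg], axis=-1)
    d_sgz = np.min(
        np.linalg.norm(coords[..., None, :] - sgz.elements[None, None, None, :, :], axis=-1),
        axis=-1,
    )
    return Phantom(
        spec=spec,
        brain=brain_m,
        ventricles=vent_m,
        dentate=dent_m,
        region_atlas=atlas_v,
        svz=svz,
        sgz=sgz,
        d_svz=d_svz,
        d_sgz=d_sgz,
    )


# ---------------------------------------------------------------------------
# lesion sampling


def _smooth_direction_field(rng: np.random.Generator) -> np.ndarray:
    """Random symmetric traceless 3x3 form; u^T A u is smooth on the sphere
    with values in [-1, 1] after normalization."""
    a = rng.normal(size=(3, 3))
    a = (a + a.T) / 2.0
    a -= np.eye(3) * np.trace(a) / 3.0
    w = np.max(np.abs(np.linalg.eigvalsh(a)))
    return a / w if w > 0 else a


def sample_lesion(
    rng: np.random.Generator,
    phantom: Phantom,
    bias_target: str = "none",
    lam: float = 20.0,
    target_volume_ml: float = 50.0,
    roughness: float = 0.0,
    require_svz_contact: bool = False,
) -> tuple[BinaryMask, dict]:
    """Draw one lesion and its ground-truth record.

    The seed voxel is drawn over brain voxels with probability proportional
    to exp(-d_target / lam); the lesion is a sphere of radius
    r = (3 V / 4 pi)^(1/3) at the seed voxel center, intersected with the
    brain mask. ``roughness`` in [0, 0.2] modulates the radius with a smooth
    random surface perturbation of at most that relative amplitude (0 keeps
    the analytic ground truth exact). ``require_svz_contact`` restricts the
    seed density to voxels within r of the SVZ band, so every lesion is
    seeded to touch the ventricle wall.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not 0.0 <= roughness <= 0.2:
        raise ValueError("roughness must be in [0, 0.2]")
    brain_vol_ml = phantom.brain.foreground_count * phantom.brain.voxel_volume_mm3 / 1000.0
    if target_volume_ml <= 0 or target_volume_ml > brain_vol_ml:
        raise ValueError("target volume must be positive and fit in the brain")

    idx = phantom.brain_indices
    r = (3.0 * target_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    if require_svz_contact:
        touching = phantom.d_svz[tuple(idx.T)] <= r
        if not touching.any():
            raise ValueError("no seed voxel can touch the SVZ band at this volume")
        idx = idx[touching]
    dfield = phantom.seed_distance_field(bias_target)
    if dfield is None:
        p = None
    else:
        d = dfield[tuple(idx.T)]
        w = np.exp(-d / lam)
        p = w / w.sum()
    seed_idx = idx[rng.choice(len(idx), p=p)]
    seed_mm = apply_affine(phantom.brain.affine, seed_idx)[0]

    spacing = np.asarray(phantom.brain.spacing)
    half = np.ceil((r * (1.0 + roughness)) / spacing).astype(int) + 1
    lo = np.maximum(seed_idx - half, 0)
    hi = np.minimum(seed_idx + half + 1, np.array(phantom.brain.shape))
    sub = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].reshape(3, -1).T
    world = apply_affine(phantom.brain.affine, sub)
    delta = world - seed_mm
    dist = np.linalg.norm(delta, axis=1)
    if roughness > 0:
        a = _smooth_direction_field(rng)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(dist[:, None] > 0, delta / np.maximum(dist, 1e-12)[:, None], 0.0)
        r_dir = r * (1.0 + roughness * np.einsum("ni,ij,nj->n", u, a, u))
    else:
        r_dir = r
    inside = dist <= r_dir
    data = np.zeros(phantom.brain.shape, dtype=np.uint8)
    data[tuple(sub[inside].T)] = 1
    unclipped = int(data.sum())
    data &= phantom.brain.data
    clipped = bool(int(data.sum()) < unclipped)
    mask = BinaryMask(data=data, affine=phantom.brain.affine)

    seed_vox = tuple(seed_idx)
    truth = {
        "seed_x_mm": seed_mm[0],
        "seed_y_mm": seed_mm[1],
        "seed_z_mm": seed_mm[2],
        "target_volume_ml": target_volume_ml,
        "radius_mm": r,
        "true_center_svz_mm": float(phantom.d_svz[seed_vox]),
        "true_center_sgz_mm": float(phantom.d_sgz[seed_vox]),
        "true_border_svz_mm": max(0.0, float(phantom.d_svz[seed_vox]) - r),
        "true_border_sgz_mm": max(0.0, float(phantom.d_sgz[seed_vox]) - r),
        "clipped": clipped,
        "roughness": roughness,
    }
    return mask, truth


@dataclass
class GroupSpec:
    """Simulation settings for one molecular group."""

    name: str
    n: int
    bias_target: str = "none"  # SVZ | SGZ | none
    lam_mm: float = 20.0
    volume_median_ml: float = 50.0
    volume_sigma: float = 0.8  # log-scale dispersion of the log-normal
    require_svz_contact: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("each group needs n >= 1")
        if self.lam_mm <= 0 or self.volume_median_ml <= 0:
            raise ValueError("lam and volume median must be positive")


@dataclass
class CohortConfig:
    """Cohort-level simulation settings; defaults emulate the study cohort:
    n = 50/64/45, volume medians 48.4/73.4/45.9 ml, and niche-bias settings
    producing center-to-SGZ group medians near 42/31/21 mm with border-to-SVZ
    medians of 0 mm."""

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("oligodendroglioma_IDHmut_codel", 50, "SVZ", 12.0, 48.4, 1.10),
        GroupSpec("astrocytoma_IDHmut", 64, "SGZ", 25.0, 73.4, 0.88),
        GroupSpec("astrocytoma_IDHwt", 45, "SGZ", 9.0, 45.9, 1.25),
    )
    seed: int = 0
    roughness: float = 0.0
    max_volume_ml: float = 250.0  # log-normal tail cap; brain clipping flags the rest

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate_cohort(
    config: CohortConfig,
    phantom: Phantom,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[BinaryMask], pd.DataFrame]:
    """Generate all lesions of a cohort; optionally write the cohort layout.

    Returns (records, masks, truth): ``records`` has one row per subject
    (subject_id, group, mask_path — paths filled when ``outdir`` is given),
    ``truth`` one ground-truth row per lesion. Fully reproducible from
    (config, config.seed).
    """
    rng = np.random.default_rng(config.seed)
    records, masks, truths = [], [], []
    for gspec in config.groups:
        if gspec.name not in GROUPS:
            raise ValueError(f"unknown group {gspec.name!r}")
        for i in range(gspec.n):
            subject = f"{gspec.name}_{i:03d}"
            vol = float(
                np.minimum(
                    np.exp(rng.normal(np.log(gspec.volume_median_ml), gspec.volume_sigma)),
                    config.max_volume_ml,
                )
            )
            mask, truth = sample_lesion(
                rng,
                phantom,
                bias_target=gspec.bias_target,
                lam=gspec.lam_mm,
                target_volume_ml=vol,
                roughness=config.roughness,
                require_svz_contact=gspec.require_svz_contact,
            )
            truth.update({"subject_id": subject, "group": gspec.name})
            records.append({"subject_id": subject, "group": gspec.name, "mask_path": ""})
            masks.append(mask)
            truths.append(truth)
    records_df = pd.DataFrame(records)
    truth_df = pd.DataFrame(truths)

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
        (outdir / "phantom").mkdir(parents=True, exist_ok=True)
        for row, mask in zip(records_df.itertuples(), masks):
            rel = f"masks/{row.subject_id}.nii.gz"
            write_volume(mask, outdir / rel)
            records_df.loc[row.Index, "mask_path"] = rel
        for name, vol in (
            ("brain", phantom.brain),
            ("ventricles", phantom.ventricles),
            ("dentate", phantom.dentate),
            ("region_atlas", phantom.region_atlas),
        ):
            write_volume(vol, outdir / "phantom" / f"{name}.nii.gz")
        records_df.to_csv(outdir / "cohort.csv", index=False)
        truth_df.to_csv(outdir / "truth.csv", index=False, float_format="%.6g")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return records_df, masks, truth_df
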