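"""End-to-end orchestration: cohort table + template masks -> results dir.

Outputs (all deterministic, byte-identical on rerun with one config):
``distances.csv`` (one row per subject), ``tables/table{1,2,3}.csv``,
``tests.json`` (the nonparametric battery), per-group heatmaps as NIfTI
plus PNG axial slices (MNI z in the filename), and ``run.log`` with a
config hash. CSV/JSON floats use 6 significant digits and fixed column
order so idempotence is byte-exact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import cohort_analysis as ca
from .metrics import GROUPS, measure_lesion
from .niche import extract_svz_band, mask_from_labels, sgz_points
from .volume_io import (
    GridMismatchError,
    MaskFileNotFoundError,
    read_mask,
    read_volume,
    same_grid,
    write_volume,
)

log = logging.getLogger("nichedist")

__all__ = ["RunConfig", "run_pipeline"]

DISTANCE_COLUMNS = [
    "subject_id",
    "group",
    "border_svz_mm",
    "center_svz_mm",
    "border_sgz_mm",
    "center_sgz_mm",
    "contact_svz",
    "contact_sgz",
    "volume_ml",
    "region",
]


@dataclass
class RunConfig:
    cohort_csv: str
    ventricle_mask: str
    dentate_mask: str
    brain_mask: str
    region_atlas: str = ""
    svz_thickness_mm: float = 3.0
    binarize_threshold: float = 0.5
    heatmap_slices_z_mm: tuple[float, ...] = (0.0, -20.0)
    outdir: str = "results"
    ventricle_labels: tuple[int, ...] = ()  # if set, reduce a label atlas
    dentate_labels: tuple[int, ...] = ()
    region_labels: dict = field(default_factory=dict)  # id -> name
    region_precedence: tuple[int, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["heatmap_slices_z_mm"] = tuple(raw.get("heatmap_slices_z_mm", (0.0, -20.0)))
        for key in ("ventricle_labels", "dentate_labels", "region_precedence"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "region_labels" in raw:
            raw["region_labels"] = {int(k): v for k, v in raw["region_labels"].items()}
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_binary(path: str, threshold: float, labels=()):
    if labels:
        return mask_from_labels(read_volume(path), labels)
    return read_mask(path, binarize_threshold=threshold)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(type(o))


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, list):
        return [_round6(v) for v in x]
    return x


def _save_slice_png(hm, z_mm: float, path: Path) -> None:
    plane, meta = ca.axial_slice(hm, z_mm)
    fig, ax = plt.subplots(figsize=(4, 4.4))
    # neurological display: left hemisphere on viewer's left, anterior up
    img = ax.imshow(plane.T, origin="lower", cmap="hot", interpolation="nearest")
    ax.set_title(f"z = {meta['z_mm']:g} mm (n overlap)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(img, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full lesion-to-niche analysis; returns the output directory."""
    outdir = Path(config.outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    (outdir / "heatmaps").mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config hash %s", config.hash())
        log.info("numpy %s, pandas %s", np.__version__, pd.__version__)

        cohort = pd.read_csv(config.cohort_csv)
        for col in ("subject_id", "group", "mask_path"):
            if col not in cohort.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        unknown = set(cohort["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")

        brain = _load_binary(config.brain_mask, config.binarize_threshold)
        ventricle = _load_binary(
            config.ventricle_mask, config.binarize_threshold, config.ventricle_labels
        )
        dentate = _load_binary(
            config.dentate_mask, config.binarize_threshold, config.dentate_labels
        )
        for name, vol in (("ventricle", ventricle), ("dentate", dentate)):
            if not same_grid(brain, vol):
                raise GridMismatchError(f"{name} mask is not on the template grid")
        atlas = read_volume(config.region_atlas) if config.region_atlas else None
        if atlas is not None and not same_grid(brain, atlas):
            raise GridMismatchError("region atlas is not on the template grid")

        svz = extract_svz_band(ventricle, brain, thickness_mm=config.svz_thickness_mm)
        sgz = sgz_points(dentate)
        log.info("SVZ band: %d voxels; SGZ points: %d", len(svz.elements), len(sgz.elements))

        base = Path(config.cohort_csv).parent
        results, masks_by_group = [], {g: [] for g in GROUPS}
        for row in cohort.itertuples():
            mask_path = Path(row.mask_path)
            if not mask_path.is_absolute():
                mask_path = base / mask_path
            try:
                mask = read_mask(mask_path, binarize_threshold=config.binarize_threshold)
            except MaskFileNotFoundError as exc:
                raise MaskFileNotFoundError(
                    f"subject {row.subject_id}: mask file missing ({mask_path})"
                ) from exc
            if not same_grid(brain, mask):
                raise GridMismatchError(
                    f"subject {row.subject_id}: mask {mask_path} not on the template grid"
                )
            region = "unclassified"
            if atlas is not None:
                region = ca.region_assignment(
                    mask,
                    atlas,
                    precedence=config.region_precedence or sorted(config.region_labels),
                    label_names=config.region_labels or None,
                )
            res = measure_lesion(
                mask, svz, sgz, subject_id=str(row.subject_id), group=row.group, region=region
            )
            results.append(res)
            masks_by_group[row.group].append(mask)
        log.info("measured %d lesions", len(results))

        df = ca.results_frame(results)[DISTANCE_COLUMNS]
        df.to_csv(outdir / "distances.csv", index=False, float_format="%.6g")

        tables = ca.cohort_tables(results)
        for name, table in tables.items():
            table.to_csv(outdir / "tables" / f"{name}.csv", index=False, float_format="%.6g")

        battery = ca.compare_groups(results)
        with open(outdir / "tests.json", "w") as fh:
            json.dump(_round6(battery), fh, indent=2, default=_json_default)
            fh.write("\n")

        all_masks = [m for g in GROUPS for m in masks_by_group[g]]
        hm_all = ca.accumulate_heatmap(all_masks)
        write_volume(hm_all, outdir / "heatmaps" / "all_groups.nii.gz")
        for g in GROUPS:
            if not masks_by_group[g]:
                continue
            hm = ca.accumulate_heatmap(masks_by_group[g])
            write_volume(hm, outdir / "heatmaps" / f"{g}.nii.gz")
            for z in config.heatmap_slices_z_mm:
                _save_slice_png(hm, z, outdir / "heatmaps" / f"{g}_z{z:+.0f}mm.png")
        log.info("done; outputs in %s", outdir)
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()
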