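"""Cohort-level aggregation and statistics.

Voxel-wise tumor-frequency heatmaps (per-subject binary masks summed on the
shared template grid), axial slice extraction for figure-style panels,
anatomical region assignment, summary tables, and the nonparametric test
battery.

The rank tests are implemented from their tie-corrected formulas. The
Mann-Whitney U statistic is computed from mid-ranks of the pooled sample,
U = R1 - n1(n1+1)/2, with a two-sided p from the normal approximation using
the tie-corrected variance

    Var(U) = n1 n2 / 12 * [ (N + 1) - sum(t^3 - t) / (N (N - 1)) ],

no continuity correction. Kruskal-Wallis uses

    H = [ 12 / (N (N+1)) * sum_j R_j^2 / n_j - 3 (N+1) ] / (1 - sum(t^3 - t) / (N^3 - N)),

df = k - 1, upper chi-square tail. Pearson's chi-square on contingency
tables carries no continuity correction. Degenerate all-tied input returns
U = n1 n2 / 2 (resp. H = 0) with p = 1. Significance threshold is 0.05
throughout, two-sided, with no multiple-testing correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

from .metrics import GROUPS, IDH_MUTANT_GROUPS, DistanceResult
from .niche import NicheGeometry  # noqa: F401  (re-exported surface)
from .volume_io import BinaryMask, LabeledVolume, VolumeError, require_same_grid

__all__ = [
    "Heatmap",
    "TestResult",
    "ContingencyTable",
    "accumulate_heatmap",
    "axial_slice",
    "median_iqr",
    "mann_whitney_u",
    "kruskal_wallis",
    "chi_square",
    "region_assignment",
    "cohort_tables",
    "compare_groups",
    "holm_correction",
]

ALPHA = 0.05
MEASURES = ("border_svz_mm", "center_svz_mm", "border_sgz_mm", "center_sgz_mm")


# ---------------------------------------------------------------------------
# heatmaps


@dataclass
class Heatmap(LabeledVolume):
    """Voxel-wise count of overlapping lesions; max count <= n_subjects."""

    n_subjects: int = 0


def accumulate_heatmap(masks: Sequence[BinaryMask]) -> Heatmap:
    """Sum binary masks voxel-wise into a tumor-frequency map."""
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    total = np.zeros(first.shape, dtype=np.int32)
    for m in masks:
        require_same_grid(first, m, "heatmap input masks")
        total += m.data
    return Heatmap(data=total, affine=first.affine, n_subjects=len(masks))


def axial_slice(hm: LabeledVolume, z_mm: float) -> tuple[np.ndarray, dict]:
    """The axial plane whose voxel-center z is nearest to ``z_mm``.

    Ties (z midway between slices) resolve to the lower slice index. The
    returned metadata records the chosen index and its actual world z;
    display orientation defaults to neurological (left on left).
    """
    nk = hm.shape[2]
    # world z of voxel (0, 0, k); assumes the third axis carries z
    z_centers = hm.affine[2, 2] * np.arange(nk) + hm.affine[2, 3]
    if z_mm < z_centers.min() - abs(hm.affine[2, 2]) / 2 or z_mm > z_centers.max() + abs(
        hm.affine[2, 2]
    ) / 2:
        raise VolumeError(f"z = {z_mm} mm outside field of view")
    k = int(np.argmin(np.abs(z_centers - z_mm)))  # argmin keeps lower index on tie
    return np.asarray(hm.data[:, :, k]), {
        "k": k,
        "z_mm": float(z_centers[k]),
        "requested_z_mm": float(z_mm),
        "orientation": "neurological",
    }


# ---------------------------------------------------------------------------
# descriptive statistics


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation at (n-1)p."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# hypothesis tests


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    df: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_two_sided < ALPHA

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_two_sided,
            "method": self.method,
            "significant": self.significant,
        }


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    """sum over tied groups of (t^3 - t)."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U from mid-ranks, tie-corrected normal p."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    if n > 1:
        var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    else:  # pragma: no cover - n1, n2 >= 1 implies n >= 2
        var = 0.0
    if var <= 0:
        return TestResult(statistic=n1 * n2 / 2.0, p_two_sided=1.0, method="mann-whitney-u")
    z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return TestResult(statistic=float(u), p_two_sided=p, method="mann-whitney-u")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square upper-tail p."""
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        rj = ranks[start : start + a.size].sum()
        h += rj**2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    df = len(arrays) - 1
    if correction <= 0:  # every observation tied
        return TestResult(statistic=0.0, p_two_sided=1.0, method="kruskal-wallis", df=df)
    h /= correction
    p = float(chi2_dist.sf(h, df))
    return TestResult(statistic=float(h), p_two_sided=p, method="kruskal-wallis", df=df)


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 2D table")


def chi_square(table: ContingencyTable) -> TestResult:
    """Pearson X^2 without continuity correction; df = (r-1)(c-1)."""
    obs = table.counts
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("every row and column total must be > 0")
    expected = np.outer(rows, cols) / obs.sum()
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(statistic=x2, p_two_sided=float(chi2_dist.sf(x2, df)), method="chi-square", df=df)


def holm_correction(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(list(pvalues), dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


# ---------------------------------------------------------------------------
# region assignment and summary tables


def region_assignment(
    mask: BinaryMask,
    region_atlas: LabeledVolume,
    precedence: Sequence[int],
    label_names: dict[int, str] | None = None,
) -> str:
    """Region holding the most lesion voxels; ties break by precedence.

    Background label 0 never wins; a lesion overlapping no labeled region is
    "unclassified".
    """
    require_same_grid(mask, region_atlas, "lesion mask and region atlas")
    labels = np.asarray(region_atlas.data)[mask.data.astype(bool)]
    labels = labels[labels != 0]
    if labels.size == 0:
        return "unclassified"
    ids, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    tied = [int(i) for i, c in zip(ids, counts) if c == best]
    rank = {int(lab): k for k, lab in enumerate(precedence)}
    winner = min(tied, key=lambda lab: (rank.get(lab, len(rank)), lab))
    if label_names:
        return label_names.get(winner, str(winner))
    return str(winner)


def _pct(count: int, total: int) -> int:
    """Integer percentage, rounded half-up (table formatting convention)."""
    if total == 0:
        return 0
    return int((Decimal(100) * Decimal(count) / Decimal(total)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def results_frame(results: Sequence[DistanceResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def cohort_tables(results: Sequence[DistanceResult]) -> dict[str, pd.DataFrame]:
    """Summary tables: group sizes/volumes/contacts, distance medians, regions.

    - ``table1``: per-group n (%), volume median (IQR), and niche-contact
      counts (%) for SVZ, SGZ, both, neither.
    - ``table2``: median (Q1-Q3) of each distance measure per molecular
      group and per IDH status (mutant = oligodendroglioma + IDH-mutant
      astrocytoma).
    - ``table3``: region x group counts with integer percentages of the
      group-specific total.
    """
    if not results:
        raise ValueError("empty cohort")
    df = results_frame(results)
    unknown = set(df["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    n_total = len(df)

    rows1 = []
    for g in GROUPS:
        sub = df[df["group"] == g]
        rows1.append(
            {"item": f"n_{g}", "count": len(sub), "percent": _pct(len(sub), n_total), "value": ""}
        )
    for g in GROUPS:
        sub = df[df["group"] == g]
        if len(sub):
            med, q1, q3 = median_iqr(sub["volume_ml"])
            rows1.append(
                {
                    "item": f"volume_ml_{g}",
                    "count": len(sub),
                    "percent": "",
                    "value": f"{med:.6g} ({q3 - q1:.6g})",
                }
            )
    c_svz = int(df["contact_svz"].sum())
    c_sgz = int(df["contact_sgz"].sum())
    c_both = int((df["contact_svz"] & df["contact_sgz"]).sum())
    c_neither = int((~df["contact_svz"] & ~df["contact_sgz"]).sum())
    for item, c in (
        ("contact_svz", c_svz),
        ("contact_sgz", c_sgz),
        ("contact_both", c_both),
        ("contact_neither", c_neither),
    ):
        rows1.append({"item": item, "count": c, "percent": _pct(c, n_total), "value": ""})
    table1 = pd.DataFrame(rows1)

    rows2 = []
    strata = [(g, df["group"] == g) for g in GROUPS] + [
        ("IDH_mutated", df["group"].isin(IDH_MUTANT_GROUPS)),
        ("IDH_wildtype", df["group"] == "astrocytoma_IDHwt"),
    ]
    for name, sel in strata:
        sub = df[sel]
        if not len(sub):
            continue
        row = {"stratum": name, "n": len(sub)}
        for m in MEASURES:
            med, q1, q3 = median_iqr(sub[m])
            row[f"{m}_median"] = med
            row[f"{m}_q1"] = q1
            row[f"{m}_q3"] = q3
        rows2.append(row)
    table2 = pd.DataFrame(rows2)

    regions = sorted(df["region"].unique())
    rows3 = []
    for region in regions:
        row = {"region": region}
        for g in GROUPS:
            sub = df[df["group"] == g]
            c = int((sub["region"] == region).sum())
            row[f"{g}_count"] = c
            row[f"{g}_percent"] = _pct(c, len(sub)) if len(sub) else 0
        rows3.append(row)
    table3 = pd.DataFrame(rows3)
    return {"table1": table1, "table2": table2, "table3": table3}


def compare_groups(results: Sequence[DistanceResult]) -> list[dict]:
    """Kruskal-Wallis across molecular groups and Mann-Whitney for IDH
    status, for each of the four distance measures.

    With exactly two molecular groups present only the Mann-Whitney
    comparison is reported for them; the IDH contrast additionally requires
    both mutant and wild-type lesions.
    """
    df = results_frame(results)
    present = [g for g in GROUPS if (df["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("need at least two groups with members")
    battery: list[dict] = []
    for m in MEASURES:
        samples = [df.loc[df["group"] == g, m].to_numpy() for g in present]
        if len(present) >= 3:
            res = kruskal_wallis(samples)
            battery.append({"measure": m, "test": "kruskal-wallis", **res.as_dict()})
        else:
            res = mann_whitney_u(samples[0], samples[1])
            battery.append({"measure": m, "test": "mann-whitney-u", **res.as_dict()})
        mut = df.loc[df["group"].isin(IDH_MUTANT_GROUPS), m].to_numpy()
        wt = df.loc[df["group"] == "astrocytoma_IDHwt", m].to_numpy()
        if len(mut) and len(wt) and len(present) >= 3:
            res = mann_whitney_u(mut, wt)
            battery.append({"measure": m, "test": "mann-whitney-u_IDH", **res.as_dict()})
    return battery
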