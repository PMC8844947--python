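"""Aggregation of per-voxel records into summary tables and figure data.

Produces the study-style outputs: overall mean/std/median of width, depth,
area and the elliptical quotient (in voxel and physical units); the
width-by-depth count matrix; and per-area-bin boxplot statistics of the
elliptical quotient against the circular baseline eq = 1.

Two rounding conventions coexist deliberately: the width/depth matrix
rounds width to the *nearest* voxel (half-up), while area bins take the
*ceiling* of the area — matching how the two displays are conventionally
binned.  Both are switchable.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .volio import SkeletonVoxelRecord, VoxelSpacing, records_to_frame

__all__ = [
    "summary_stats",
    "to_physical",
    "width_depth_histogram",
    "quotient_by_area_bins",
    "make_report",
]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def _select(records: Sequence[SkeletonVoxelRecord],
            include_boundary: bool) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError(
            "no records to aggregate: run the analyze pipeline first"
        )
    frame = records_to_frame(list(records))
    if not include_boundary:
        kept = frame[~frame.boundary_flag]
        # fall back to all records rather than an empty table
        if len(kept) > 0:
            frame = kept
    return frame


def to_physical(value, kind: str, spacing: VoxelSpacing):
    """Convert a voxel measure to physical units.

    width: * lateral spacing (um); depth: * axial spacing (um);
    area: * lateral * axial (um^2).
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("voxel measures must be non-negative")
    if kind == "width":
        out = v * spacing.lateral
    elif kind == "depth":
        out = v * spacing.sz
    elif kind == "area":
        out = v * spacing.lateral * spacing.sz
    else:
        raise ValueError(f"unknown kind {kind!r}: expected width, depth or area")
    return float(out) if out.ndim == 0 else out


def summary_stats(records: Sequence[SkeletonVoxelRecord],
                  spacing: VoxelSpacing,
                  include_boundary: bool = False) -> pd.DataFrame:
    """Mean, std (n-1 denominator) and median of every per-voxel measure.

    Rows cover width/depth/area in voxel and physical units and the
    elliptical quotient (mean of per-voxel ratios — the headline
    statistic — plus the ratio-of-means as a separate row for
    transparency), and the proportions of sites whose rounded voxel width
    is smaller than / equal to / greater than the voxel depth.  With a
    single record the std is reported as 0 and flagged undefined.
    """
    frame = _select(records, include_boundary)
    n = len(frame)
    std_defined = n > 1

    def _row(name, unit, values):
        values = np.asarray(values, dtype=float)
        return {
            "metric": name, "unit": unit, "n": n,
            "mean": float(values.mean()),
            "std": float(values.std(ddof=1)) if std_defined else 0.0,
            "median": float(np.median(values)),
            "std_is_defined": std_defined,
        }

    rows = [
        _row("width", "vx", frame.width_vx),
        _row("width", "um", frame.width_um),
        _row("depth", "vx", frame.depth_vx),
        _row("depth", "um", frame.depth_um),
        _row("area", "vx2", frame.area_vx),
        _row("area", "um2", frame.area_um2),
        _row("eq", "ratio", frame["eq"]),
    ]
    ratio_of_means = float(frame.depth_um.mean() / frame.width_um.mean())
    rows.append({
        "metric": "eq_ratio_of_means", "unit": "ratio", "n": n,
        "mean": ratio_of_means, "std": float("nan"),
        "median": float("nan"), "std_is_defined": False,
    })

    w = _round_half_up(frame.width_vx.to_numpy())
    d = frame.depth_vx.to_numpy().astype(int)
    for name, prop in (
        ("prop_width_lt_depth", np.mean(w < d)),
        ("prop_width_eq_depth", np.mean(w == d)),
        ("prop_width_gt_depth", np.mean(w > d)),
    ):
        rows.append({
            "metric": name, "unit": "fraction", "n": n,
            "mean": float(prop), "std": float("nan"),
            "median": float("nan"), "std_is_defined": False,
        })
    return pd.DataFrame(rows)


def width_depth_histogram(records: Sequence[SkeletonVoxelRecord],
                          include_boundary: bool = False,
                          rounding: str = "half_up") -> pd.DataFrame:
    """Count matrix of (rounded voxel width) x (voxel depth).

    Rows are width values, columns depth values; the matrix total equals
    the number of records.  ``rounding`` is ``half_up`` (default) or
    ``ceil`` for the voxel width; depth is already integer.
    """
    frame = _select(records, include_boundary)
    if rounding == "half_up":
        w = _round_half_up(frame.width_vx.to_numpy())
    elif rounding == "ceil":
        w = np.ceil(frame.width_vx.to_numpy()).astype(int)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    d = frame.depth_vx.to_numpy().astype(int)
    table = pd.crosstab(pd.Series(w, name="width_vx"),
                        pd.Series(d, name="depth_vx"))
    return table


def quotient_by_area_bins(records: Sequence[SkeletonVoxelRecord],
                          include_boundary: bool = False) -> pd.DataFrame:
    """Boxplot statistics of the elliptical quotient per area bin.

    Bin key is ceil(area in voxels).  Per bin: count, min, Q1, median, Q3,
    max, the 1.5*IQR whisker positions (most extreme data within the
    fences) and the mean.  Quartiles use linear interpolation.  The
    ``baseline`` column carries the circular expectation eq = 1.
    """
    frame = _select(records, include_boundary)
    bins = np.ceil(frame.area_vx.to_numpy()).astype(int)
    eq = frame["eq"].to_numpy()
    rows = []
    for b in np.unique(bins):
        v = np.sort(eq[bins == b])
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        in_fence = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        rows.append({
            "area_bin_vx": int(b), "count": int(v.size),
            "min": float(v[0]), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(v[-1]),
            "whisker_lo": float(in_fence[0]), "whisker_hi": float(in_fence[-1]),
            "mean": float(v.mean()), "baseline": 1.0,
        })
    return pd.DataFrame(rows)


def make_report(records: Sequence[SkeletonVoxelRecord], spacing: VoxelSpacing,
                out_dir: str, include_boundary: bool = False,
                plots: bool = False) -> dict[str, str]:
    """Write summary.csv, width_depth_hist.csv and eq_by_area_bins.csv.

    With ``plots=True`` also renders PNG versions of the width-by-depth
    distribution and the per-bin quotient boxplot.
    """
    os.makedirs(out_dir, exist_ok=True)
    summary = summary_stats(records, spacing, include_boundary)
    hist = width_depth_histogram(records, include_boundary)
    bins = quotient_by_area_bins(records, include_boundary)
    paths = {
        "summary": os.path.join(out_dir, "summary.csv"),
        "hist": os.path.join(out_dir, "width_depth_hist.csv"),
        "bins": os.path.join(out_dir, "eq_by_area_bins.csv"),
    }
    summary.to_csv(paths["summary"], index=False)
    hist.to_csv(paths["hist"])
    bins.to_csv(paths["bins"], index=False)

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(hist.to_numpy(), origin="lower", cmap="viridis",
                       extent=(hist.columns.min() - 0.5, hist.columns.max() + 0.5,
                               hist.index.min() - 0.5, hist.index.max() + 0.5))
        ax.set_xlabel("depth (vx)")
        ax.set_ylabel("width (vx)")
        fig.colorbar(im, ax=ax, label="skeleton voxels")
        fig.savefig(os.path.join(out_dir, "width_depth_hist.png"), dpi=150)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.axhline(1.0, color="black", lw=1, label="circular baseline")
        x = bins.area_bin_vx.to_numpy()
        ax.fill_between(x, bins.q1, bins.q3, alpha=0.3, label="IQR")
        ax.plot(x, bins["median"], "b-", label="median")
        ax.plot(x, bins["mean"], "-", color="tab:orange", label="mean")
        ax.set_xlabel("cross-section area (vx, rounded up)")
        ax.set_ylabel("elliptical quotient")
        ax.legend()
        fig.savefig(os.path.join(out_dir, "eq_by_area_bins.png"), dpi=150)
        plt.close(fig)
        paths["hist_png"] = os.path.join(out_dir, "width_depth_hist.png")
        paths["bins_png"] = os.path.join(out_dir, "eq_by_area_bins.png")
    return paths
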