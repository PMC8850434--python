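"""Morphometry of curvature-classed clathrin segmentation masks.

Works on integer label images (0 background, 1 membrane, 2 flat, 3 dome,
4 sphere) produced by manual segmentation of platinum-replica EM montages
or by the synthetic generator.  Quantities follow the standard replica-EM
analysis: per-structure areas in nm^2 from connected components, percent
membrane occupancy per class (class area / visible membrane area), size
summaries with t-based confidence intervals, and condition fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "SegmentationMask",
    "FoldChange",
    "CLASS_NAMES",
    "structure_areas",
    "occupancy_percent",
    "size_summary",
    "fold_change",
    "round_sig",
]

#: label value -> class name (labels 0/1 are reserved: background/membrane)
CLASS_NAMES = {2: "flat", 3: "dome", 4: "sphere"}

_CONNECT8 = np.ones((3, 3), dtype=int)


@dataclass
class SegmentationMask:
    """Curvature-class label image with its physical scale.

    ``membrane_mask`` optionally carries a separate binary membrane
    footprint; when absent, the footprint is the union of the membrane and
    class labels (structures sit on the membrane by construction).  Default
    scale is 1.2 nm per pixel (15,000x replica EM).
    """

    labels: np.ndarray
    nm_per_px: float = 1.2
    membrane_mask: np.ndarray | None = None
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        if self.membrane_mask is not None:
            self.membrane_mask = np.asarray(self.membrane_mask, dtype=bool)
            if self.membrane_mask.shape != self.labels.shape:
                raise ValueError("membrane_mask must share the label-image grid")
            class_px = self.labels >= 2
            if (class_px & ~self.membrane_mask).any():
                raise ValueError("class pixels fall outside the membrane footprint")

    @property
    def membrane_footprint(self) -> np.ndarray:
        if self.membrane_mask is not None:
            return self.membrane_mask
        return self.labels >= 1


def structure_areas(mask: SegmentationMask) -> pd.DataFrame:
    """Per-structure records from 8-connected components of each class.

    Returns a DataFrame with columns ``structure_id``, ``class_name``,
    ``area_px``, ``area_nm2``, ``cell_id``, ``condition``.  Areas convert by
    ``nm_per_px**2``; structures clipped by the image edge count at their
    visible area.
    """
    rows: list[dict] = []
    sid = 0
    scale2 = mask.nm_per_px**2
    for label_value, name in CLASS_NAMES.items():
        binary = mask.labels == label_value
        if not binary.any():
            continue
        comp, n = ndimage.label(binary, structure=_CONNECT8)
        areas = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        for a in areas:
            rows.append(
                {
                    "structure_id": sid,
                    "class_name": name,
                    "area_px": int(a),
                    "area_nm2": float(a * scale2),
                    "cell_id": mask.cell_id,
                    "condition": mask.condition,
                }
            )
            sid += 1
    return pd.DataFrame(
        rows, columns=["structure_id", "class_name", "area_px", "area_nm2", "cell_id", "condition"]
    )


def occupancy_percent(mask: SegmentationMask) -> pd.DataFrame:
    """Percent membrane occupancy per class plus the all-structures total.

    Occupancy of a class is ``100 * class pixel area / membrane pixel
    area`` where the membrane area includes the structures sitting on it.
    """
    membrane_area = int(mask.membrane_footprint.sum())
    if membrane_area == 0:
        raise ValueError("membrane area is zero; occupancy undefined")
    row: dict = {
        "cell_id": mask.cell_id,
        "condition": mask.condition,
        "membrane_area_px": membrane_area,
    }
    total = 0.0
    for label_value, name in CLASS_NAMES.items():
        pct = 100.0 * float((mask.labels == label_value).sum()) / membrane_area
        row[f"occupancy_{name}"] = pct
        total += pct
    row["occupancy_all"] = total
    return pd.DataFrame([row])


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    if n < 2:
        return (math.nan, math.nan)
    mean = float(values.mean())
    se = float(values.std(ddof=1)) / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, n - 1))
    return (mean - tcrit * se, mean + tcrit * se)


def size_summary(
    records: pd.DataFrame,
    by: tuple[str, ...] = ("class_name", "condition"),
    value_col: str = "area_nm2",
) -> pd.DataFrame:
    """Summarize structure sizes per group.

    Reports n, median, 25th/75th percentiles, mean, SD, and the t-based 95%
    confidence interval of the mean.  With a single record the CI is
    undefined (NaN), not a number pretending to be one.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    rows = []
    for keys, grp in records.groupby(list(by), sort=True):
        v = grp[value_col].to_numpy(dtype=float)
        lo, hi = _t_ci(v)
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            {
                **dict(zip(by, keys)),
                "n": len(v),
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else math.nan,
                "ci95_lo": lo,
                "ci95_hi": hi,
            }
        )
    return pd.DataFrame(rows)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 maps to 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class FoldChange:
    """A treated/control ratio, raw and rounded to 2 significant figures."""

    raw: float
    rounded: float
    direction: str  # "increase" | "decrease" | "unchanged"


def fold_change(treated_mean: float, control_mean: float) -> FoldChange:
    """Ratio of a treated-condition mean over a control mean.

    The raw ratio is reported alongside its 2-significant-figure rounding
    (the conventional "x.y-fold" style).  ``direction`` records whether the
    treated mean is above or below control, so a "decreased by k-fold"
    statement can be formed from the inverse without ambiguity.
    """
    if control_mean <= 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    raw = treated_mean / control_mean
    if raw > 1:
        direction = "increase"
    elif raw < 1:
        direction = "decrease"
    else:
        direction = "unchanged"
    return FoldChange(raw=raw, rounded=round_sig(raw, 2), direction=direction)
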