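"""Per-cell focus counting, positivity calls and the applicability rule.

A focus belongs to the cell territory that owns its pixel; foci on
background pixels are strays and count toward no cell.  A cell is called
positive for a probe iff it contains at least ``threshold`` foci (three by
default).  Quantification is declared not applicable for a region when the
channel averages fewer than 4 dots per DAPI-defined cell or when cell
bodies could not be separated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import FocusSet
from .segmentation import CellLabelMap, SeparabilityReport

__all__ = [
    "ApplicabilityVerdict",
    "assign_foci",
    "call_positive",
    "applicability_check",
    "build_cell_table",
    "CELL_TABLE_BASE_COLUMNS",
]

REASON_LOW_EXPRESSION = "below 4 dots per DAPI-defined cell"
REASON_NOT_SEPARABLE = "cell bodies not separable"

#: fixed leading column order of the cell table CSV; per-channel
#: count_<name> / positive_<name> columns follow in channel order
CELL_TABLE_BASE_COLUMNS = [
    "cell_id",
    "centroid_row",
    "centroid_col",
    "nucleus_area",
    "region",
    "border",
]


@dataclass(frozen=True)
class ApplicabilityVerdict:
    quantifiable: bool
    mean_dots_per_cell: float
    reasons: tuple

    def __bool__(self) -> bool:
        return self.quantifiable


def assign_foci(foci: FocusSet, cells: CellLabelMap) -> tuple[np.ndarray, int]:
    """Attribute each focus to the territory owning its pixel.

    Returns (counts, n_stray): ``counts[i]`` is the focus count of cell
    ``i + 1``; strays are foci on background pixels.  The counts and strays
    always sum to ``len(foci)``.
    """
    labels = cells.labels
    if foci.image_shape is not None and tuple(foci.image_shape) != labels.shape:
        raise ValueError(
            f"focus image shape {foci.image_shape} does not match "
            f"label map shape {labels.shape}"
        )
    h, w = labels.shape
    counts = np.zeros(cells.n_cells, dtype=np.int64)
    strays = 0
    for r, c, _ in foci.foci:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"focus ({r}, {c}) outside label map of shape {labels.shape}")
        owner = int(labels[r, c])
        if owner == 0:
            strays += 1
        else:
            counts[owner - 1] += 1
    return counts, strays


def call_positive(counts, threshold: int = 3) -> np.ndarray:
    """A cell is positive iff it contains >= threshold foci (default three)."""
    if threshold < 1:
        raise ValueError(f"positivity threshold must be >= 1, got {threshold}")
    arr = np.asarray(counts)
    if arr.size and (not np.issubdtype(arr.dtype, np.integer) or arr.min() < 0):
        raise ValueError("counts must be non-negative integers")
    return arr >= threshold


def applicability_check(
    cell_table: pd.DataFrame,
    channel: str,
    region: str | None = None,
    min_mean_dots: float = 4.0,
    separability: SeparabilityReport | bool | None = None,
) -> ApplicabilityVerdict:
    """Decide whether per-cell quantification applies to a region.

    Quantifiable iff the channel's mean foci per DAPI-defined cell (over all
    cells of the region) is at least ``min_mean_dots`` AND cell bodies were
    separable; otherwise the verdict names every failed criterion.
    """
    col = f"count_{channel}"
    if col not in cell_table.columns:
        known = [c[6:] for c in cell_table.columns if c.startswith("count_")]
        raise ValueError(f"unknown channel {channel!r}; known channels: {known}")
    sub = cell_table if region is None else cell_table[cell_table["region"] == region]
    if len(sub) == 0:
        raise ValueError(f"no cells in region {region!r}")
    mean_dots = float(sub[col].mean())
    reasons = []
    if mean_dots < min_mean_dots:
        reasons.append(REASON_LOW_EXPRESSION)
    separable = (
        separability.separable
        if isinstance(separability, SeparabilityReport)
        else (True if separability is None else bool(separability))
    )
    if not separable:
        reasons.append(REASON_NOT_SEPARABLE)
    return ApplicabilityVerdict(not reasons, mean_dots, tuple(reasons))


def _validate_regions(regions: dict) -> None:
    names = list(regions)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.logical_and(regions[a], regions[b]).any():
                raise ValueError(f"region masks overlap: {a!r} and {b!r}")


def build_cell_table(
    cells: CellLabelMap,
    focus_sets: list[FocusSet],
    regions: dict | None = None,
    threshold: int = 3,
) -> pd.DataFrame:
    """One row per cell: centroid, nucleus area, region, counts and calls.

    ``regions`` maps region name -> boolean mask of the image (masks must be
    pairwise disjoint); a cell belongs to the region containing its nucleus
    centroid pixel, or to none.  ``border`` flags nuclei touching the image
    edge.  Rows are ordered by cell_id; coordinates are 0-based (row, col).
    """
    nuc = cells.nucleus_labels
    h, w = nuc.shape
    n = cells.n_cells
    if regions:
        for name, mask in regions.items():
            if np.asarray(mask).shape != (h, w):
                raise ValueError(f"region {name!r} mask shape mismatch")
        _validate_regions(regions)
    for fs in focus_sets:
        if fs.image_shape is not None and tuple(fs.image_shape) != (h, w):
            raise ValueError(f"channel {fs.channel_name!r}: image/label shape mismatch")

    idx = np.arange(1, n + 1)
    area = np.bincount(nuc.ravel(), minlength=n + 1)[1:]
    rows_sum = np.bincount(nuc.ravel(), weights=np.repeat(np.arange(h), w), minlength=n + 1)[1:]
    cols_sum = np.bincount(nuc.ravel(), weights=np.tile(np.arange(w), h), minlength=n + 1)[1:]
    with np.errstate(invalid="ignore"):
        cr = rows_sum / area
        cc = cols_sum / area

    edge = np.zeros(n + 1, dtype=bool)
    for line in (nuc[0, :], nuc[-1, :], nuc[:, 0], nuc[:, -1]):
        edge[np.unique(line)] = True
    border = edge[1:]

    region_col = [None] * n
    if regions:
        for i in range(n):
            if area[i] == 0:
                continue
            pr, pc = int(np.floor(cr[i] + 0.5)), int(np.floor(cc[i] + 0.5))
            for name, mask in regions.items():
                if mask[pr, pc]:
                    region_col[i] = name
                    break

    table = pd.DataFrame(
        {
            "cell_id": idx,
            "centroid_row": cr,
            "centroid_col": cc,
            "nucleus_area": area,
            "region": region_col,
            "border": border,
        }
    )
    for fs in focus_sets:
        counts, _ = assign_foci(fs, cells)
        table[f"count_{fs.channel_name}"] = counts
        table[f"positive_{fs.channel_name}"] = call_positive(counts, threshold)
    return table
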