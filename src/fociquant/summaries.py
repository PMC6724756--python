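"""Region-level expression and co-expression statistics.

The per-region quantities mirror how multiplex FISH studies report results:
percent of all DAPI-defined cells positive for each probe (the heatmap
quantity), conditional co-expression percentages (e.g. the share of
VGlut2-positive cells that also express HCN4), and a partition of cells
into co-expression classes — one class per subset of probes, eight classes
for a three-probe assay.  Percentages are carried at full precision;
conditional percentages with an empty denominator are reported as missing,
never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "RegionSummary",
    "channels_of",
    "summarize_region",
    "heatmap_table",
    "HeatmapResult",
    "classify_cells",
    "pool_summaries",
    "NOT_QUANTIFIED",
]

NOT_QUANTIFIED = "not quantified"
TRIPLE_LABEL = "triple expression"
MAX_CHANNELS = 3  # the assay carries at most three probes beside DAPI


def channels_of(cell_table: pd.DataFrame) -> list[str]:
    """Probe channel names present in a cell table, in column order."""
    return [c[len("positive_") :] for c in cell_table.columns if c.startswith("positive_")]


@dataclass(frozen=True)
class RegionSummary:
    """All expression statistics of one region, computed from flags only.

    percent_positive: channel -> % of all cells of the region.
    conditional: (A, B) -> % of B-positive cells that are A-positive
        (None when there are no B-positive cells).
    class_counts: subset-of-channels tuple -> number of cells positive for
        exactly that subset; the counts sum to n_cells.
    """

    region_name: str | None
    n_cells: int
    percent_positive: dict
    conditional: dict
    class_counts: dict


def _region_rows(cell_table: pd.DataFrame, region_name) -> pd.DataFrame:
    if region_name is None:
        return cell_table
    sub = cell_table[cell_table["region"] == region_name]
    if len(sub) == 0:
        raise ValueError(f"unknown region or empty region: {region_name!r}")
    return sub


def summarize_region(
    cell_table: pd.DataFrame, region_name=None, channels: list[str] | None = None
) -> RegionSummary:
    """Compute a RegionSummary for one region (None = whole table)."""
    channels = channels or channels_of(cell_table)
    sub = _region_rows(cell_table, region_name)
    n = len(sub)
    if n == 0:
        raise ValueError("cannot summarise an empty cell table")
    flags = {ch: sub[f"positive_{ch}"].to_numpy(dtype=bool) for ch in channels}

    percent_positive = {ch: 100.0 * flags[ch].sum() / n for ch in channels}
    conditional: dict = {}
    for a in channels:
        for b in channels:
            if a == b:
                continue
            denom = int(flags[b].sum())
            conditional[(a, b)] = (
                None if denom == 0 else 100.0 * int((flags[a] & flags[b]).sum()) / denom
            )
    class_counts: dict = {}
    for k in range(len(channels) + 1):
        for subset in combinations(channels, k):
            inset = np.ones(n, dtype=bool)
            for ch in channels:
                inset &= flags[ch] if ch in subset else ~flags[ch]
            class_counts[subset] = int(inset.sum())
    return RegionSummary(region_name, n, percent_positive, conditional, class_counts)


@dataclass(frozen=True)
class HeatmapResult:
    """percent-positive matrix (region x channel); entries failing the
    applicability rule are NaN in ``values`` and flagged in ``status``."""

    values: pd.DataFrame
    status: pd.DataFrame

    def to_csv(self, path) -> None:
        out = self.values.copy().astype(object)
        out[self.status != "ok"] = NOT_QUANTIFIED
        out.to_csv(path)


def heatmap_table(
    cell_table: pd.DataFrame,
    regions: list[str],
    channels: list[str] | None = None,
    min_mean_dots: float = 4.0,
    separability: dict | None = None,
) -> HeatmapResult:
    """Percent of all cells positive, per region and channel.

    Entries for (region, channel) pairs that fail the applicability rule —
    mean dots per DAPI-defined cell below ``min_mean_dots``, or a region
    listed as non-separable in ``separability`` — carry an explicit
    not-quantified marker instead of a number.
    """
    from .quantify import applicability_check

    channels = channels or channels_of(cell_table)
    values = pd.DataFrame(index=list(regions), columns=channels, dtype=float)
    status = pd.DataFrame("ok", index=list(regions), columns=channels)
    for region in regions:
        summary = summarize_region(cell_table, region, channels)
        sep = True if separability is None else separability.get(region, True)
        for ch in channels:
            verdict = applicability_check(
                cell_table, ch, region, min_mean_dots=min_mean_dots, separability=sep
            )
            if verdict.quantifiable:
                values.loc[region, ch] = summary.percent_positive[ch]
            else:
                values.loc[region, ch] = np.nan
                status.loc[region, ch] = "; ".join(verdict.reasons)
    return HeatmapResult(values, status)


def classify_cells(cell_table: pd.DataFrame, channels: list[str] | None = None) -> pd.Series:
    """Label each cell by the exact subset of probes it expresses.

    Labels are the probe names joined with '+' ("none" for no probe); a cell
    positive for all three probes of a triple assay is labelled
    "triple expression", as such cells are conventionally called.
    """
    channels = channels or channels_of(cell_table)
    if len(channels) > MAX_CHANNELS:
        raise ValueError(f"at most {MAX_CHANNELS} probe channels supported, got {len(channels)}")
    flags = np.column_stack(
        [cell_table[f"positive_{ch}"].to_numpy(dtype=bool) for ch in channels]
    )

    def label(row: np.ndarray) -> str:
        subset = [ch for ch, f in zip(channels, row) if f]
        if not subset:
            return "none"
        if len(channels) == 3 and len(subset) == 3:
            return TRIPLE_LABEL
        return "+".join(subset)

    return pd.Series(
        [label(row) for row in flags], index=cell_table["cell_id"].to_numpy(), name="class"
    )


def plot_heatmap(result: HeatmapResult, ax=None, cmap: str = "viridis"):
    """Render the percent-positive matrix; not-quantified entries are hatched.

    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + result.values.shape[1], 1.0 + 0.5 * result.values.shape[0]))
    vals = result.values.to_numpy(dtype=float)
    im = ax.imshow(np.ma.masked_invalid(vals), cmap=cmap, vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(len(result.values.columns)), result.values.columns)
    ax.set_yticks(range(len(result.values.index)), result.values.index)
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            if np.isnan(vals[i, j]):
                ax.text(j, i, "n.q.", ha="center", va="center", fontsize=8)
            else:
                ax.text(j, i, f"{vals[i, j]:.0f}", ha="center", va="center", fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="% of cells positive")
    return ax


def pool_summaries(summaries: list[RegionSummary]) -> pd.DataFrame:
    """Mean +/- SEM of percent-positive across slices (one summary per image).

    Matches the reporting convention of averaging per-slice percentages over
    at least three slices; SEM is NaN for a single slice.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    channels = list(summaries[0].percent_positive)
    rows = []
    for ch in channels:
        vals = np.array([s.percent_positive[ch] for s in summaries], dtype=float)
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append((ch, float(vals.mean()), sem, len(vals)))
    return pd.DataFrame(rows, columns=["channel", "mean_percent", "sem_percent", "n_slices"])
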