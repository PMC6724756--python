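"""End-to-end pipeline: segment -> dilate -> detect -> count -> summarise.

A run is fully described by a RunConfig (loadable from YAML/JSON); the same
config and inputs always produce byte-identical outputs.  Every output CSV
uses 0-based (row, col) pixel coordinates, and the QC report records every
parameter needed to reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .detection import DetectionParams, detect_foci
from .io import read_image_stack, read_region_masks, write_label_map
from .quantify import build_cell_table
from .segmentation import dilate_labels, segment_nuclei, separability_check
from .summaries import channels_of, heatmap_table, summarize_region

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one quantification run needs.

    detection maps each probe channel name to DetectionParams fields;
    region_masks maps region names to binary mask TIFF paths.
    """

    image_path: str
    channel_names: tuple
    dapi_channel: str = "DAPI"
    detection: dict = field(default_factory=dict)
    region_masks: dict = field(default_factory=dict)
    smoothing_sigma: float = 1.0
    min_area: int = 50
    min_seed_distance: int = 7
    dilation_radius: float = 3.0
    positivity_threshold: int = 3
    min_mean_dots: float = 4.0
    output_dir: str = "fociquant_out"
    seed: int = 0

    def __post_init__(self) -> None:
        names = list(self.channel_names)
        if len(set(names)) != len(names):
            raise ValueError(f"channel names not unique: {names}")
        if names.count(self.dapi_channel) != 1:
            raise ValueError(
                f"DAPI channel {self.dapi_channel!r} must appear exactly once "
                f"in channel_names {names}"
            )
        probes = [n for n in names if n != self.dapi_channel]
        missing = [p for p in probes if p not in self.detection]
        if missing:
            raise ValueError(f"no detection tolerance configured for channels {missing}")
        object.__setattr__(self, "channel_names", tuple(names))

    @property
    def probe_channels(self) -> list:
        return [n for n in self.channel_names if n != self.dapi_channel]

    def detection_params(self, channel: str) -> DetectionParams:
        return DetectionParams(**self.detection[channel])

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON; referenced paths must exist."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        cfg = cls(**raw)
        if not Path(cfg.image_path).exists():
            raise FileNotFoundError(f"image not found: {cfg.image_path}")
        for name, mpath in cfg.region_masks.items():
            if not Path(mpath).exists():
                raise FileNotFoundError(f"region {name!r} mask not found: {mpath}")
        return cfg

    def to_qc_dict(self) -> dict:
        d = asdict(self)
        d["channel_names"] = list(self.channel_names)
        return d


@dataclass(frozen=True)
class PipelineResult:
    cell_table: pd.DataFrame
    summaries: dict
    heatmap: object
    separability: object
    qc: dict


def _stage(name: str, detail: str = ""):
    def wrap(exc: Exception) -> PipelineError:
        msg = f"stage {name!r} failed" + (f" on {detail}" if detail else "")
        return PipelineError(f"{msg}: {exc}")

    return wrap


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full quantification workflow described by ``config``."""
    outdir = Path(config.output_dir)
    images = read_image_stack(config.image_path, config.channel_names)
    dapi = images[config.dapi_channel]

    try:
        nuclei = segment_nuclei(
            dapi,
            min_area=config.min_area,
            smoothing_sigma=config.smoothing_sigma,
            min_seed_distance=config.min_seed_distance,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise _stage("segment", config.image_path)(exc)
    sep_report = separability_check(nuclei)
    cells = dilate_labels(nuclei, config.dilation_radius)

    focus_sets = []
    for ch in config.probe_channels:
        try:
            focus_sets.append(detect_foci(images[ch], config.detection_params(ch)))
        except Exception as exc:
            raise _stage("detect", f"channel {ch!r}")(exc)

    regions = read_region_masks(config.region_masks) if config.region_masks else None
    try:
        table = build_cell_table(
            cells, focus_sets, regions=regions, threshold=config.positivity_threshold
        )
    except Exception as exc:
        raise _stage("quantify", config.image_path)(exc)

    region_names = sorted(regions) if regions else []
    separability = {r: sep_report.separable for r in region_names}
    summaries = {
        r: summarize_region(table, r) for r in region_names if (table["region"] == r).any()
    }
    summaries[None] = summarize_region(table)
    heatmap = (
        heatmap_table(
            table,
            [r for r in region_names if (table["region"] == r).any()],
            min_mean_dots=config.min_mean_dots,
            separability=separability,
        )
        if region_names
        else None
    )

    qc = {
        "parameters": config.to_qc_dict(),
        "n_nuclei": nuclei.n_nuclei,
        "separability": asdict(sep_report),
        "n_foci": {fs.channel_name: len(fs) for fs in focus_sets},
    }
    result = PipelineResult(table, summaries, heatmap, sep_report, qc)
    if write_outputs:
        _write_outputs(result, nuclei, cells, focus_sets, outdir)
    return result


def _write_outputs(result, nuclei, cells, focus_sets, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.cell_table.to_csv(outdir / "cell_table.csv", index=False)
    for fs in focus_sets:
        fs.to_dataframe().to_csv(outdir / f"foci_{fs.channel_name}.csv", index=False)
    write_label_map(outdir / "nuclei_labels.tif", nuclei.labels)
    write_label_map(outdir / "cell_labels.tif", cells.labels)
    if result.heatmap is not None:
        result.heatmap.to_csv(outdir / "heatmap.csv")
    rows = []
    for region, s in sorted(result.summaries.items(), key=lambda kv: str(kv[0])):
        for ch, pct in s.percent_positive.items():
            rows.append((region if region is not None else "ALL", ch, s.n_cells, pct))
    pd.DataFrame(
        rows, columns=["region", "channel", "n_cells", "percent_positive"]
    ).to_csv(outdir / "region_summary.csv", index=False)
    (outdir / "qc.json").write_text(json.dumps(result.qc, indent=2, sort_keys=True))
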