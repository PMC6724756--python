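"""Synthetic multiplex FISH tissue-image simulator with full ground truth.

Emulates the data regime of single-optical-plane multiplex RNAscope imaging:
a DAPI channel of smoothly shaded nuclear disks (optionally touching, or too
dense to separate), plus up to three probe channels in which each cell
carries k puncta drawn from a zero-inflated Poisson law, rendered as 2D
Gaussian kernels inside the 3-px-dilated nucleus disk.  Diffuse background,
additive Gaussian pixel noise (clipped at zero) and uniform autofluorescent
rectangles (the "optical aberration" failure mode) are added on top.  Every
planted nucleus, spot and per-cell count is recorded in a GroundTruth
object, which is the oracle for segmentation/detection/quantification
recovery tests.

The defaults describe a realistic mid-density field at roughly 3 px/um:
~8-px-radius nuclei, 50 per 320x320 field, spot amplitude 20x the pixel
noise.  They are free parameters of the simulator, documented rather than
claimed to match any particular microscope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelSpec",
    "AberrationPatch",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedScene",
    "SimulationError",
    "simulate_image",
    "write_fixture",
    "zip_tail_ge",
]

# planted spots never stray beyond the nucleus disk dilated by this margin,
# matching the 3-px territory expansion used downstream
MAX_SPOT_MARGIN = 3.0


class SimulationError(RuntimeError):
    """Raised when a requested scene cannot be realised (e.g. over-dense)."""


@dataclass(frozen=True)
class ChannelSpec:
    """One probe channel: count law and spot rendering parameters.

    Per-cell counts follow a zero-inflated Poisson: with probability
    ``zero_inflation`` the cell is a true negative (k = 0), otherwise
    k ~ Poisson(``mean_count``).  ``fixed_count`` short-circuits the law
    with a degenerate distribution (every cell gets exactly that count).
    ``stray_rate`` is the expected number of extracellular spots per image.
    """

    name: str
    zero_inflation: float = 0.0
    mean_count: float = 5.0
    amplitude: float = 40.0
    spot_sigma: float = 1.0
    stray_rate: float = 0.0
    fixed_count: int | None = None

    def effective_amplitude(self, filter_sigma: float = 1.0) -> float:
        """Peak height of a planted spot after Gaussian prefiltering.

        A Gaussian spot of width s convolved with a Gaussian filter of width
        f keeps the fraction s^2 / (s^2 + f^2) of its amplitude (in 2D);
        detection tolerances are naturally phrased against this value, since
        the tolerance criterion operates on the filtered image.
        """
        s2 = self.spot_sigma**2
        return self.amplitude * s2 / (s2 + filter_sigma**2)

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError(f"zero_inflation must be in [0, 1], got {self.zero_inflation}")
        if self.mean_count < 0:
            raise ValueError(f"mean_count must be >= 0, got {self.mean_count}")
        if self.amplitude <= 0 or self.spot_sigma <= 0:
            raise ValueError("amplitude and spot_sigma must be > 0")
        if self.stray_rate < 0:
            raise ValueError("stray_rate must be >= 0")
        if self.fixed_count is not None and self.fixed_count < 0:
            raise ValueError("fixed_count must be >= 0")


@dataclass(frozen=True)
class AberrationPatch:
    """Uniform added intensity over a rectangle (autofluorescent aberration)."""

    row: int
    col: int
    height: int
    width: int
    intensity: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("patch height and width must be > 0")
        if self.intensity < 0:
            raise ValueError("patch intensity must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    image_height: int = 320
    image_width: int = 320
    n_nuclei: int = 50
    nucleus_radius_mean: float = 9.0
    nucleus_radius_sd: float = 1.0
    min_center_spacing: float = 28.0
    channels: tuple = field(default_factory=tuple)
    dapi_amplitude: float = 100.0
    background_level: float = 10.0
    noise_sd: float = 2.0
    aberration_patches: tuple = field(default_factory=tuple)
    spot_margin: float = 1.5
    min_spot_spacing: float = 6.0
    seed: int = 0
    max_placement_attempts: int = 200

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be > 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius_mean <= 0 or self.nucleus_radius_sd < 0:
            raise ValueError("nucleus radius parameters invalid")
        if self.min_center_spacing <= 0:
            raise ValueError("min_center_spacing must be > 0")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be >= 0")
        if not 0 <= self.spot_margin <= MAX_SPOT_MARGIN:
            raise ValueError(f"spot_margin must be in [0, {MAX_SPOT_MARGIN}]")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if "DAPI" in names:
            raise ValueError("'DAPI' is reserved for the nuclear channel")
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "aberration_patches", tuple(self.aberration_patches))


@dataclass(frozen=True)
class GroundTruth:
    """Everything planted: nuclei, per-cell true counts, spot positions.

    nuclei: columns cell_id,row,col,radius (cell_ids contiguous from 1).
    true_counts: columns cell_id,channel,count.
    spots: columns channel,row,col,cell_id (cell_id is NaN for strays).
    """

    nuclei: pd.DataFrame
    true_counts: pd.DataFrame
    spots: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.nuclei)

    def counts_map(self) -> dict:
        """(cell_id, channel) -> planted count."""
        return {
            (int(r.cell_id), r.channel): int(r.count)
            for r in self.true_counts.itertuples()
        }

    def positive_map(self, threshold: int = 3) -> dict:
        return {k: v >= threshold for k, v in self.counts_map().items()}


@dataclass(frozen=True)
class SimulatedScene:
    stack: np.ndarray  # (n_channels, H, W) float32; page 0 is DAPI
    channel_names: tuple
    ground_truth: GroundTruth
    config: SimulationConfig


def zip_tail_ge(k: int, zero_inflation: float, mean_count: float) -> float:
    """P(K >= k) under the zero-inflated Poisson count law (closed form)."""
    from scipy import stats

    if k <= 0:
        return 1.0
    return float((1.0 - zero_inflation) * stats.poisson.sf(k - 1, mean_count))


def _place_nuclei(cfg: SimulationConfig, rng: np.random.Generator):
    lo_r = max(2.0, cfg.nucleus_radius_mean - 3 * cfg.nucleus_radius_sd)
    hi_r = cfg.nucleus_radius_mean + 3 * cfg.nucleus_radius_sd
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    budget = cfg.max_placement_attempts * max(cfg.n_nuclei, 1)
    attempts = 0
    while len(centers) < cfg.n_nuclei:
        if attempts >= budget:
            raise SimulationError(
                f"could not place {cfg.n_nuclei} nuclei with spacing "
                f">= {cfg.min_center_spacing} in a {cfg.image_height}x"
                f"{cfg.image_width} field after {budget} attempts (scene too dense)"
            )
        attempts += 1
        radius = float(np.clip(rng.normal(cfg.nucleus_radius_mean, cfg.nucleus_radius_sd), lo_r, hi_r))
        margin = radius + MAX_SPOT_MARGIN + 2.0
        if 2 * margin >= min(cfg.image_height, cfg.image_width):
            raise SimulationError("nucleus radius too large for the image")
        row = rng.uniform(margin, cfg.image_height - margin)
        col = rng.uniform(margin, cfg.image_width - margin)
        if all(
            (row - r0) ** 2 + (col - c0) ** 2 >= cfg.min_center_spacing**2
            for r0, c0 in centers
        ):
            centers.append((row, col))
            radii.append(radius)
    return centers, radii


def _draw_count(spec: ChannelSpec, rng: np.random.Generator) -> int:
    if spec.fixed_count is not None:
        return spec.fixed_count
    if rng.random() < spec.zero_inflation:
        return 0
    return int(rng.poisson(spec.mean_count))


def _spot_positions_in_cell(
    center, radius, k, cfg: SimulationConfig, rng: np.random.Generator
):
    """k points uniform in the disk of radius+spot_margin, pairwise spaced.

    Rejection sampling with a farthest-fallback keeps the planted count k
    exact even when the spacing constraint cannot be met.
    """
    rmax = radius + cfg.spot_margin
    pts: list[tuple[float, float]] = []
    for _ in range(k):
        best, best_d = None, -1.0
        for _ in range(200):
            rad = rmax * np.sqrt(rng.random())
            ang = rng.uniform(0.0, 2.0 * np.pi)
            cand = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
            d = min(
                (np.hypot(cand[0] - p[0], cand[1] - p[1]) for p in pts),
                default=np.inf,
            )
            if d >= cfg.min_spot_spacing:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        pts.append(best)
    return pts


def _render_spot(img: np.ndarray, row: float, col: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    ext = int(np.ceil(4 * sigma))
    r0, r1 = max(0, int(row) - ext), min(h, int(row) + ext + 1)
    c0, c1 = max(0, int(col) - ext), min(w, int(col) + ext + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amp * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma**2)
    )


def simulate_image(config: SimulationConfig) -> SimulatedScene:
    """Render the scene and return the image stack plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    centers, radii = _place_nuclei(config, rng)

    # DAPI: smoothly shaded disks (logistic edge profile)
    dapi = np.zeros((h, w), dtype=np.float64)
    rr_full, cc_full = np.mgrid[0:h, 0:w]
    for (row, col), radius in zip(centers, radii):
        ext = int(np.ceil(radius + 4))
        r0, r1 = max(0, int(row) - ext), min(h, int(row) + ext + 1)
        c0, c1 = max(0, int(col) - ext), min(w, int(col) + ext + 1)
        rr, cc = rr_full[r0:r1, c0:c1], cc_full[r0:r1, c0:c1]
        d = np.hypot(rr - row, cc - col)
        dapi[r0:r1, c0:c1] += config.dapi_amplitude / (1.0 + np.exp((d - radius) / 0.75))

    spot_rows: list[tuple] = []
    count_rows: list[tuple] = []
    probe_imgs: dict[str, np.ndarray] = {}
    for spec in config.channels:
        img = np.zeros((h, w), dtype=np.float64)
        for cell_id, (center, radius) in enumerate(zip(centers, radii), start=1):
            k = _draw_count(spec, rng)
            count_rows.append((cell_id, spec.name, k))
            for prow, pcol in _spot_positions_in_cell(center, radius, k, config, rng):
                _render_spot(img, prow, pcol, spec.amplitude, spec.spot_sigma)
                spot_rows.append((spec.name, prow, pcol, cell_id))
        # stray (extracellular) spots, outside every possible territory
        n_stray = int(rng.poisson(spec.stray_rate)) if spec.stray_rate > 0 else 0
        for _ in range(n_stray):
            for _ in range(500):
                prow = rng.uniform(5.0, h - 5.0)
                pcol = rng.uniform(5.0, w - 5.0)
                clear = all(
                    np.hypot(prow - r0, pcol - c0) > rad + MAX_SPOT_MARGIN + 3.0
                    for (r0, c0), rad in zip(centers, radii)
                )
                if clear:
                    _render_spot(img, prow, pcol, spec.amplitude, spec.spot_sigma)
                    spot_rows.append((spec.name, prow, pcol, np.nan))
                    break
        probe_imgs[spec.name] = img

    names = ("DAPI",) + tuple(s.name for s in config.channels)
    pages = [dapi] + [probe_imgs[s.name] for s in config.channels]
    stack = np.empty((len(pages), h, w), dtype=np.float32)
    for i, (name, page) in enumerate(zip(names, pages)):
        out = page + config.background_level
        if name != "DAPI":
            for patch in config.aberration_patches:
                out[
                    patch.row : patch.row + patch.height,
                    patch.col : patch.col + patch.width,
                ] += patch.intensity
        if config.noise_sd > 0:
            out = out + rng.normal(0.0, config.noise_sd, size=(h, w))
        stack[i] = np.clip(out, 0.0, None)

    nuclei = pd.DataFrame(
        [
            (cid, row, col, rad)
            for cid, ((row, col), rad) in enumerate(zip(centers, radii), start=1)
        ],
        columns=["cell_id", "row", "col", "radius"],
    )
    counts = pd.DataFrame(count_rows, columns=["cell_id", "channel", "count"])
    spots = pd.DataFrame(spot_rows, columns=["channel", "row", "col", "cell_id"])
    gt = GroundTruth(nuclei=nuclei, true_counts=counts, spots=spots)
    return SimulatedScene(stack=stack, channel_names=names, ground_truth=gt, config=config)


def match_cells(gt: GroundTruth, nucleus_labels: np.ndarray) -> dict:
    """Map segmentation label -> planted cell_id via the label under each
    planted nucleus centre (0 = that nucleus was not recovered)."""
    out = {}
    h, w = nucleus_labels.shape
    for row in gt.nuclei.itertuples():
        r, c = int(round(row.row)), int(round(row.col))
        if 0 <= r < h and 0 <= c < w:
            lab = int(nucleus_labels[r, c])
            if lab > 0:
                out[lab] = int(row.cell_id)
    return out


def detection_scores(gt: GroundTruth, channel: str, focus_set, match_radius: float = 2.0):
    """Spot recall and precision of a FocusSet against the planted positions.

    Greedy nearest matching in planted order within ``match_radius`` pixels;
    each detected focus matches at most one planted spot.
    """
    planted = gt.spots[gt.spots["channel"] == channel][["row", "col"]].to_numpy(float)
    detected = np.array([(r, c) for r, c, _ in focus_set.foci], dtype=float)
    if len(planted) == 0:
        return (1.0, 1.0 if len(detected) == 0 else 0.0)
    if len(detected) == 0:
        return (0.0, 1.0)
    used = np.zeros(len(detected), dtype=bool)
    matched = 0
    for pr, pc in planted:
        d = np.hypot(detected[:, 0] - pr, detected[:, 1] - pc)
        d[used] = np.inf
        j = int(d.argmin())
        if d[j] <= match_radius:
            used[j] = True
            matched += 1
    return matched / len(planted), matched / len(detected)


def write_fixture(scene: SimulatedScene, directory) -> dict:
    """Persist a scene as a multi-page TIFF plus ground-truth CSV tables.

    Returns the paths written: images.tif (one page per channel, channel
    names in metadata), nuclei.csv, counts.csv, spots.csv, config.json.
    """
    from .io import write_image_stack

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "images": directory / "images.tif",
        "nuclei": directory / "nuclei.csv",
        "counts": directory / "counts.csv",
        "spots": directory / "spots.csv",
        "config": directory / "config.json",
    }
    try:
        write_image_stack(paths["images"], scene.stack, scene.channel_names)
        scene.ground_truth.nuclei.to_csv(paths["nuclei"], index=False)
        scene.ground_truth.true_counts.to_csv(paths["counts"], index=False)
        scene.ground_truth.spots.to_csv(paths["spots"], index=False)
        cfg = asdict(scene.config)
        cfg["channels"] = [asdict(c) for c in scene.config.channels]
        cfg["aberration_patches"] = [asdict(p) for p in scene.config.aberration_patches]
        paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths
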