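"""Synthetic fluorescence scenes with ground truth, for testing the
quantification pipeline end to end.

A scene emulates a cross-section of plant leaf tissue as imaged on a
monochrome CCD: one channel carries the autofluorescent cell-wall lattice
that delineates cell boundaries, and one or two signal channels carry
bright, round, diffraction-limited RCA dots rendered as 2-D Gaussians.
Cells are a Lloyd-relaxed Voronoi tessellation of random centers; per cell
the dot count is Poisson with a per-channel rate, and dot positions are
uniform over the cell interior kept a small margin away from the wall
(RCPs sit in the cytoplasm).  Noise is Poisson shot noise followed by
additive Gaussian read noise.  Everything is reproducible from the seed,
and the ground truth (label map, per-dot coordinates and cell ids) is kept
alongside the rendered images.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import disk
from skimage.segmentation import find_boundaries
from skimage.measure import approximate_polygon, find_contours

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "SceneError",
    "simulate_section",
    "write_scene",
    "read_scene",
    "high_snr_params",
    "two_group_pair",
]


class SceneError(RuntimeError):
    pass


@dataclass(frozen=True)
class SceneParams:
    """Study conditions for one synthetic section.

    dot_rate is the per-channel mean RCA dots per cell (Poisson); one entry
    per signal channel.  Intensities are in camera counts of a 16-bit
    sensor.  Defaults describe a high signal-to-noise section of ~50 cells,
    the regime the assay is designed for (bright dots over weak cytoplasmic
    background).
    """

    shape: tuple[int, int] = (512, 512)
    n_cells: int = 50
    wall_thickness: int = 3
    wall_intensity: float = 12000.0
    background: float = 200.0
    dot_rate: tuple[float, ...] = (8.0,)
    dot_peak: float = 8000.0
    dot_sigma: float = 1.2
    poisson_noise: bool = True
    read_noise_sigma: float = 30.0
    dot_margin: int = 4  # px kept clear of the wall when placing dots
    lloyd_iterations: int = 2
    min_cell_interior: int = 50  # px; tessellations violating this retry
    max_retries: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dot_sigma <= 0:
            raise ValueError("dot_sigma must be positive")
        for v in (self.wall_intensity, self.background, self.dot_peak,
                  self.read_noise_sigma):
            if v < 0:
                raise ValueError("intensities and noise sigma must be >= 0")
        if not self.dot_rate or any(r < 0 for r in self.dot_rate):
            raise ValueError("dot_rate must be non-empty and non-negative")


@dataclass
class SyntheticScene:
    """Rendered channels plus the ground truth they were rendered from.

    channels -- {"wall": image, "signal_1": image, ...}, uint16
    labels   -- ground-truth cell label map (0 = wall), same shape
    dots     -- DataFrame (x, y, channel, cell_id); x = column, y = row,
                0-based pixel-center coordinates
    """

    channels: dict[str, np.ndarray]
    labels: np.ndarray
    dots: pd.DataFrame
    params: SceneParams

    @property
    def signal_channels(self) -> list[str]:
        return [c for c in self.channels if c != "wall"]

    def truth_counts(self) -> pd.DataFrame:
        """Per-cell, per-channel ground-truth dot counts (all cells listed,
        zeros included)."""
        n = int(self.labels.max())
        rows = []
        for ch in self.signal_channels:
            sub = self.dots[self.dots["channel"] == ch]
            counts = sub.groupby("cell_id").size()
            for cid in range(1, n + 1):
                rows.append((cid, ch, int(counts.get(cid, 0))))
        return pd.DataFrame(rows, columns=["cell_id", "channel", "count"])


def _voronoi_labels(
    centers: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    yy, xx = np.indices(shape)
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    _, nearest = cKDTree(centers).query(pts)
    return nearest.reshape(shape).astype(np.int32) + 1


def _render_dot(img: np.ndarray, cy: float, cx: float, peak: float,
                sigma: float) -> None:
    r = int(np.ceil(4 * sigma)) + 1
    y0, y1 = max(0, int(cy) - r), min(img.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(img.shape[1], int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += peak * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
    )


def simulate_section(params: SceneParams) -> SyntheticScene:
    """Render one multi-channel section with ground truth.

    Deterministic for a fixed SceneParams (including seed): identical
    parameters give bit-identical images and truth tables.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape)

    wall = labels = None
    cell_pixels: dict[int, np.ndarray] = {}
    for _ in range(params.max_retries):
        centers = rng.uniform((0, 0), shape, size=(params.n_cells, 2))
        labels = _voronoi_labels(centers, shape)
        for _ in range(params.lloyd_iterations):
            coms = ndi.center_of_mass(
                np.ones(shape), labels, index=range(1, params.n_cells + 1)
            )
            centers = np.asarray(coms)
            labels = _voronoi_labels(centers, shape)
        boundaries = find_boundaries(labels, mode="thick")
        wall = ndi.binary_dilation(
            boundaries, structure=disk(max(1, params.wall_thickness // 2))
        )
        interior_ok = ~ndi.binary_dilation(wall, structure=disk(params.dot_margin))
        cell_pixels = {}
        ok = True
        for cid in range(1, params.n_cells + 1):
            pix = np.argwhere((labels == cid) & interior_ok)
            if len(pix) < params.min_cell_interior:
                ok = False
                break
            cell_pixels[cid] = pix
        if ok:
            break
    else:
        raise SceneError(
            f"could not tessellate {params.n_cells} cells with >= "
            f"{params.min_cell_interior} interior px each in shape {shape} "
            f"after {params.max_retries} attempts"
        )

    ideal: dict[str, np.ndarray] = {
        "wall": params.background + params.wall_intensity * wall.astype(float)
    }
    dot_rows: list[tuple[float, float, str, int]] = []
    for ci, lam in enumerate(params.dot_rate, start=1):
        name = f"signal_{ci}"
        img = np.full(shape, params.background, dtype=float)
        for cid in range(1, params.n_cells + 1):
            count = int(rng.poisson(lam))
            if count == 0:
                continue
            pix = cell_pixels[cid]
            idx = rng.integers(len(pix), size=count)
            jitter = rng.uniform(-0.5, 0.5, size=(count, 2))
            for (py, px), (jy, jx) in zip(pix[idx], jitter):
                cy, cx = py + jy, px + jx
                _render_dot(img, cy, cx, params.dot_peak, params.dot_sigma)
                dot_rows.append((cx, cy, name, cid))
        ideal[name] = img

    channels: dict[str, np.ndarray] = {}
    for name, img in ideal.items():
        out = img
        if params.poisson_noise:
            out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if params.read_noise_sigma > 0:
            out = out + rng.normal(0.0, params.read_noise_sigma, size=shape)
        channels[name] = np.clip(np.round(out), 0, 65535).astype(np.uint16)

    truth_labels = np.where(wall, 0, labels).astype(np.int32)
    dots = pd.DataFrame(dot_rows, columns=["x", "y", "channel", "cell_id"])
    return SyntheticScene(
        channels=channels, labels=truth_labels, dots=dots, params=params
    )


def _cell_polygons(labels: np.ndarray) -> pd.DataFrame:
    rows = []
    for cid in range(1, int(labels.max()) + 1):
        mask = (labels == cid).astype(float)
        contours = find_contours(mask, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        poly = approximate_polygon(contour, tolerance=1.0)
        for vi, (ry, rx) in enumerate(poly):
            rows.append((cid, vi, float(rx), float(ry)))
    return pd.DataFrame(rows, columns=["cell_id", "vertex", "x", "y"])


_COORD_NOTE = (
    "# coordinates are 0-based pixel centers; x = column, y = row\n"
)


def write_scene(scene: SyntheticScene, directory: str | Path) -> dict[str, Path]:
    """Write the scene as a multi-page 16-bit TIFF (page order: wall, then
    signal channels) plus truth CSVs and a params echo.

    Returns the paths written.  Pixel values round-trip exactly through
    :func:`read_scene`.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    order = ["wall"] + scene.signal_channels
    stack = np.stack([scene.channels[c] for c in order])
    tif = d / "scene.tif"
    tifffile.imwrite(tif, stack, photometric="minisblack")

    dots_path = d / "dots.csv"
    with open(dots_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_COORD_NOTE)
        scene.dots.to_csv(fh, index=False)

    cells_path = d / "cells.csv"
    with open(cells_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_COORD_NOTE)
        _cell_polygons(scene.labels).to_csv(fh, index=False)

    params_path = d / "scene_params.json"
    payload = asdict(scene.params)
    payload["channel_order"] = order
    with open(params_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {"tif": tif, "dots": dots_path, "cells": cells_path,
            "params": params_path}


def read_scene(directory: str | Path) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Read back (channels, dots) written by :func:`write_scene`."""
    d = Path(directory)
    with open(d / "scene_params.json", encoding="utf-8") as fh:
        payload = json.load(fh)
    order = payload["channel_order"]
    stack = tifffile.imread(d / "scene.tif")
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i] for i, name in enumerate(order)}
    dots = pd.read_csv(d / "dots.csv", comment="#")
    return channels, dots


def high_snr_params(
    n_cells: int = 50,
    dot_rate: tuple[float, ...] = (8.0,),
    seed: int = 0,
    **overrides,
) -> SceneParams:
    """The default high signal-to-noise preset (bright dots, weak noise)."""
    return SceneParams(n_cells=n_cells, dot_rate=dot_rate, seed=seed, **overrides)


def two_group_pair(
    seed: int = 0,
    n_cells: int = 50,
    rate_high: float = 10.0,
    rate_low: float = 2.0,
    **overrides,
) -> dict[str, SyntheticScene]:
    """Two-channel, two-group preset emulating a wild type versus an
    overexpressor: in the "wt" scene channel 1 (the miRNA channel) is low
    and channel 2 (the mRNA channel) high; the "oe" scene reverses them.
    The rates are scenario parameters, chosen to give a clear opposite
    ordering, not measurements of any particular tissue.
    """
    rng = np.random.default_rng(seed)
    seeds = [int(x) for x in rng.integers(0, 2**31 - 1, 2)]
    wt = simulate_section(
        SceneParams(n_cells=n_cells, dot_rate=(rate_low, rate_high),
                    seed=seeds[0], **overrides)
    )
    oe = simulate_section(
        SceneParams(n_cells=n_cells, dot_rate=(rate_high, rate_low),
                    seed=seeds[1], **overrides)
    )
    return {"wt": wt, "oe": oe}
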