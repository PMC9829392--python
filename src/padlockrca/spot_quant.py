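"""Per-cell RCA dot quantification.

The pipeline mirrors the three stages of the published image analysis:
cell boundaries are segmented from the autofluorescence (wall) channel by
smoothing, global thresholding and morphology; fluorescent dots are called
by per-object adaptive thresholding, where every candidate object lineage
is swept across descending intensity thresholds and kept at the threshold
where it best matches an ellipse; dots are then assigned to cells by
centroid containment and counted.  Group differences in per-cell counts
are tested with a Welch t-test or a seeded permutation test.

The ellipse-fit score of a pixel component is the Jaccard overlap between
the component and the equal-area ellipse sharing its centroid, orientation
and second moments (1.0 for a single pixel by convention, 0.0 for exactly
collinear components).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import clear_border

__all__ = [
    "SegmentationParams",
    "SpotParams",
    "CellMask",
    "SpotCall",
    "CellCountTable",
    "GroupComparison",
    "segment_cells",
    "ellipse_fit",
    "detect_spots",
    "assign_spots",
    "compare_groups",
    "quantify",
    "spots_to_frame",
    "match_spots",
    "count_accuracy",
]


# ---------------------------------------------------------------------------
# cell segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentationParams:
    """Wall-channel segmentation knobs (pixels unless noted)."""

    sigma: float = 1.0  # Gaussian smoothing before thresholding
    closing_radius: int = 2  # morphological closing of the wall mask
    min_cell_area: int = 100


@dataclass
class CellMask:
    """Cell label image: 0 = wall/background, labels contiguous 1..n_cells,
    canonically ordered by centroid (row-major), so segmentation of the
    same image is bit-identical across runs."""

    labels: np.ndarray
    n_cells: int
    areas: dict[int, int]


def segment_cells(
    wall_channel: np.ndarray, params: SegmentationParams | None = None
) -> CellMask:
    """Segment cells from the autofluorescent wall channel.

    Smooth -> Otsu threshold on the enhanced wall signal -> morphological
    closing -> wall mask; cells are the 4-connected components of the
    non-wall region, with border-touching and undersized components
    removed.  An image with no detectable walls yields an empty mask with
    a warning, not an exception.
    """
    p = params or SegmentationParams()
    img = np.asarray(wall_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    empty = CellMask(np.zeros(img.shape, dtype=np.int32), 0, {})
    if np.ptp(img) == 0:
        warnings.warn("uniform wall channel; no cells found", stacklevel=2)
        return empty
    smooth = ndi.gaussian_filter(img, p.sigma)
    thr = threshold_otsu(smooth)
    wall = smooth > thr
    if p.closing_radius > 0:
        wall = ndi.binary_closing(wall, structure=disk(p.closing_radius))
    lab = sk_label(~wall, connectivity=1)
    lab = clear_border(lab)
    regions = [
        r for r in regionprops(lab) if r.area >= p.min_cell_area
    ]
    if not regions:
        warnings.warn("no cells found in wall channel", stacklevel=2)
        return empty
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    out = np.zeros_like(lab, dtype=np.int32)
    areas: dict[int, int] = {}
    for new_id, r in enumerate(regions, start=1):
        out[tuple(r.coords.T)] = new_id
        areas[new_id] = int(r.area)
    return CellMask(labels=out, n_cells=len(regions), areas=areas)


# ---------------------------------------------------------------------------
# ellipse fit
# ---------------------------------------------------------------------------


def ellipse_fit(component: np.ndarray) -> float:
    """Jaccard overlap of a pixel component with its moments-equivalent
    equal-area ellipse.

    `component` is a boolean mask or an (N, 2) integer array of (row, col)
    coordinates.  A single pixel scores 1.0 by convention; an exactly
    collinear component scores 0.0 (no 2-D ellipse exists).
    """
    if component.ndim == 2 and component.dtype == bool:
        pts = np.argwhere(component)
    else:
        pts = np.asarray(component)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("component must be a mask or an (N, 2) array")
    n = len(pts)
    if n == 0:
        raise ValueError("empty component")
    if n == 1:
        return 1.0
    pts = pts.astype(np.int64)
    center = pts.mean(axis=0)
    d = pts - center
    cov = d.T @ d / n  # point covariance of pixel centers
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 1e-9:
        return 0.0  # collinear: degenerate
    # account for unit pixel extent, then build the uniform ellipse with the
    # same second moments (variance a^2/4 along each principal semi-axis)
    cov_px = cov + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov_px)
    minor, major = 2.0 * np.sqrt(evals)
    scale = math.sqrt(n / (math.pi * major * minor))
    major *= scale
    minor *= scale
    reach = int(math.ceil(max(major, minor))) + 1
    rmin = min(int(pts[:, 0].min()), int(math.floor(center[0]))) - reach
    rmax = max(int(pts[:, 0].max()), int(math.ceil(center[0]))) + reach
    cmin = min(int(pts[:, 1].min()), int(math.floor(center[1]))) - reach
    cmax = max(int(pts[:, 1].max()), int(math.ceil(center[1]))) + reach
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    rel = np.stack([rr - center[0], cc - center[1]], axis=-1)
    u = rel @ evecs  # [..., 0] along minor axis, [..., 1] along major axis
    inside = (u[..., 1] / major) ** 2 + (u[..., 0] / minor) ** 2 <= 1.0
    comp_mask = np.zeros_like(inside)
    comp_mask[pts[:, 0] - rmin, pts[:, 1] - cmin] = True
    inter = np.count_nonzero(inside & comp_mask)
    union = np.count_nonzero(inside | comp_mask)
    return inter / union


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpotParams:
    """Spot-calling knobs.

    The candidate floor is a robust background estimate (median +
    ``base_k`` scaled MADs); each candidate component lineage is then swept
    over its own descending intensity levels and kept at the level
    maximizing the ellipse fit.  Ties break toward the lower threshold
    (the larger spot).
    """

    min_area: int = 4
    max_area: int = 400
    fit_min: float = 0.7
    base_k: float = 5.0
    max_levels: int = 64  # per-lineage threshold sweep granularity
    max_region_area: int = 20000  # candidate regions larger than this are skipped

    def __post_init__(self) -> None:
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")


@dataclass
class SpotCall:
    x: float  # column, 0-based pixel centers
    y: float  # row
    area: int
    threshold: float
    ellipse_score: float
    channel: str = "signal_1"
    cell_id: int = 0


def _lineage_key(coords: np.ndarray, values: np.ndarray) -> tuple[int, int]:
    """Identify a component lineage by its brightest pixel (lexicographically
    smallest coordinate among ties), which is stable as the threshold
    descends until lineages merge."""
    mx = values.max()
    cand = coords[values == mx]
    i = np.lexsort((cand[:, 1], cand[:, 0]))[0]
    return int(cand[i, 0]), int(cand[i, 1])


def detect_spots(
    signal_channel: np.ndarray,
    params: SpotParams | None = None,
    channel: str = "signal_1",
) -> list[SpotCall]:
    """Per-object ellipse-fit adaptive thresholding.

    For every candidate object above the background floor, sweep the
    thresholds occurring inside it from high to low; each component
    lineage (tracked by its brightest pixel) is scored by ellipse fit at
    every level where its area is within [min_area, max_area], and emitted
    at its best-scoring level if that score reaches ``fit_min``.
    Overlapping accepted components are resolved by keeping the higher
    score.  Deterministic; an empty list is a valid result.
    """
    p = params or SpotParams()
    img = np.asarray(signal_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    base = med + p.base_k * 1.4826 * mad if mad > 0 else med + max(
        1.0, 1e-6 * max(1.0, abs(med))
    )
    mask0 = img > base
    if not mask0.any():
        return []
    lab0 = sk_label(mask0, connectivity=2)
    candidates: list[tuple[float, float, np.ndarray]] = []  # score, thr, coords
    for region in regionprops(lab0):
        if region.area < p.min_area or region.area > p.max_region_area:
            continue
        sl = region.slice
        local = img[sl]
        rmask = lab0[sl] == region.label
        vals = np.unique(local[rmask])[::-1]
        vals = vals[vals > base]
        if len(vals) > p.max_levels:
            qs = np.linspace(0, 1, p.max_levels)
            vals = np.unique(np.quantile(vals, qs))[::-1]
        best: dict[tuple[int, int], tuple[float, float, np.ndarray]] = {}
        off = np.array([sl[0].start, sl[1].start])
        for t in vals:
            sub = sk_label((local >= t) & rmask, connectivity=2)
            for r in regionprops(sub):
                if r.area < p.min_area or r.area > p.max_area:
                    continue
                coords = r.coords
                vv = local[coords[:, 0], coords[:, 1]]
                key = _lineage_key(coords + off, vv)
                score = ellipse_fit(coords)
                prev = best.get(key)
                # descending sweep: an equal score at a lower threshold
                # replaces the earlier one (tie-break toward larger spot)
                if prev is None or score >= prev[0] - 1e-12:
                    best[key] = (score, float(t), coords + off)
        candidates.extend(best.values())

    accepted = [c for c in candidates if c[0] >= p.fit_min]
    accepted.sort(key=lambda c: (-c[0], c[1], c[2][0, 0], c[2][0, 1]))
    claimed = np.zeros(img.shape, dtype=bool)
    spots: list[SpotCall] = []
    for score, thr, coords in accepted:
        if claimed[coords[:, 0], coords[:, 1]].any():
            continue
        claimed[coords[:, 0], coords[:, 1]] = True
        spots.append(
            SpotCall(
                x=float(coords[:, 1].mean()),
                y=float(coords[:, 0].mean()),
                area=int(len(coords)),
                threshold=thr,
                ellipse_score=float(score),
                channel=channel,
            )
        )
    spots.sort(key=lambda s: (s.y, s.x))
    return spots


def spots_to_frame(spots: list[SpotCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.x, s.y, s.channel, s.area, s.threshold, s.ellipse_score, s.cell_id)
            for s in spots
        ],
        columns=["x", "y", "channel", "area", "threshold", "ellipse_fit", "cell_id"],
    )


# ---------------------------------------------------------------------------
# per-cell counting
# ---------------------------------------------------------------------------


@dataclass
class CellCountTable:
    """Per-cell, per-channel dot counts.

    ``counts`` has one row per (cell, channel), zeros included;
    ``unassigned`` counts spots whose centroid fell on wall/background
    (cell_id 0) per channel -- excluded from per-cell counts but reported,
    so counts + unassigned always equals the number of spot calls.
    """

    counts: pd.DataFrame
    unassigned: dict[str, int] = field(default_factory=dict)


def assign_spots(spots: list[SpotCall], mask: CellMask) -> CellCountTable:
    """Assign each spot to the cell containing its centroid (rounded to the
    nearest pixel) and tabulate counts per cell and channel."""
    labels = mask.labels
    h, w = labels.shape
    channels = sorted({s.channel for s in spots}) or ["signal_1"]
    tally: dict[tuple[int, str], int] = {}
    unassigned = {ch: 0 for ch in channels}
    for s in spots:
        r, c = int(round(s.y)), int(round(s.x))
        cid = int(labels[r, c]) if 0 <= r < h and 0 <= c < w else 0
        s.cell_id = cid
        if cid == 0:
            unassigned[s.channel] += 1
        else:
            tally[(cid, s.channel)] = tally.get((cid, s.channel), 0) + 1
    rows = []
    for ch in channels:
        for cid in range(1, mask.n_cells + 1):
            area = mask.areas.get(cid, 0)
            count = tally.get((cid, ch), 0)
            rows.append(
                (cid, ch, count, area, count / area if area else np.nan)
            )
    counts = pd.DataFrame(
        rows, columns=["cell_id", "channel", "dot_count", "cell_area", "density"]
    )
    return CellCountTable(counts=counts, unassigned=unassigned)


@dataclass
class QuantResult:
    mask: CellMask
    spots: list[SpotCall]
    table: CellCountTable


def quantify(
    channels: dict[str, np.ndarray],
    seg_params: SegmentationParams | None = None,
    spot_params: SpotParams | None = None,
    wall_channel: str = "wall",
) -> QuantResult:
    """Full pipeline: segment cells from the wall channel, call spots in
    every signal channel independently, assign and count."""
    if wall_channel not in channels:
        raise KeyError(f"wall channel {wall_channel!r} not in image set")
    mask = segment_cells(channels[wall_channel], seg_params)
    spots: list[SpotCall] = []
    for name in sorted(channels):
        if name == wall_channel:
            continue
        spots.extend(detect_spots(channels[name], spot_params, channel=name))
    table = assign_spots(spots, mask)
    return QuantResult(mask=mask, spots=spots, table=table)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    difference: float
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    test: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def compare_groups(
    counts_a,
    counts_b,
    method: str = "welch",
    n_permutations: int = 10000,
    seed: int = 0,
    exact: bool | None = None,
) -> GroupComparison:
    """Two-sided comparison of per-cell dot counts between two groups.

    ``method='welch'`` is an unequal-variance t-test; ``method='permutation'``
    permutes group labels with the mean difference as statistic.  The
    permutation test enumerates all label assignments exhaustively when
    their number is small (or ``exact=True``), otherwise it draws
    ``n_permutations`` seeded shuffles with the add-one estimator.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = float(a.mean() - b.mean())
    if method == "welch":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        if math.isnan(p):  # zero variance in both groups
            stat, p = 0.0, 1.0
        test = "welch_t"
    elif method == "permutation":
        pooled = np.concatenate([a, b])
        n, na = pooled.size, a.size
        obs = abs(diff)
        total = math.comb(n, na)
        use_exact = exact if exact is not None else total <= 50000
        if use_exact:
            pooled_sum = pooled.sum()
            hits = 0
            for idx in combinations(range(n), na):
                sa = pooled[list(idx)].sum()
                d = sa / na - (pooled_sum - sa) / (n - na)
                if abs(d) >= obs - 1e-12:
                    hits += 1
            p = hits / total
            test = "permutation_exact"
        else:
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pooled)
                d = perm[:na].mean() - perm[na:].mean()
                if abs(d) >= obs - 1e-12:
                    hits += 1
            p = (1 + hits) / (1 + n_permutations)
            test = "permutation_mc"
        stat = diff
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=diff,
        statistic=float(stat),
        p_value=float(p),
        n_a=int(a.size),
        n_b=int(b.size),
        test=test,
    )


# ---------------------------------------------------------------------------
# scoring against ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpotMatch:
    recall: float
    precision: float
    n_matched: int
    n_truth: int
    n_detected: int


def match_spots(
    spots: list[SpotCall] | pd.DataFrame,
    truth: pd.DataFrame,
    channel: str | None = None,
    max_dist: float = 2.0,
) -> SpotMatch:
    """Match detections to ground-truth dots by optimal assignment with a
    distance gate, and report recall and precision."""
    det = spots_to_frame(spots) if isinstance(spots, list) else spots
    if channel is not None:
        det = det[det["channel"] == channel]
        truth = truth[truth["channel"] == channel]
    dxy = det[["x", "y"]].to_numpy(float)
    txy = truth[["x", "y"]].to_numpy(float)
    if len(dxy) == 0 or len(txy) == 0:
        matched = 0
    else:
        dist = np.linalg.norm(dxy[:, None, :] - txy[None, :, :], axis=2)
        big = max_dist * 1000 + 1.0
        cost = np.where(dist <= max_dist, dist, big)
        ri, ci = linear_sum_assignment(cost)
        matched = int(np.sum(dist[ri, ci] <= max_dist))
    recall = matched / len(txy) if len(txy) else 1.0
    precision = matched / len(dxy) if len(dxy) else 1.0
    return SpotMatch(recall, precision, matched, int(len(txy)), int(len(dxy)))


def count_accuracy(
    mask: CellMask,
    truth_labels: np.ndarray,
    table: CellCountTable,
    truth_dots: pd.DataFrame,
    channel: str = "signal_1",
    tolerance: int = 1,
) -> tuple[float, pd.DataFrame]:
    """Fraction of segmented cells whose detected count is within
    ``tolerance`` of the ground-truth count of the matching truth cell.

    Segmented cells map to truth cells by majority overlap; a segmented
    cell with no overlapping truth cell is counted as a failure.
    """
    det_counts = {
        int(r.cell_id): int(r.dot_count)
        for r in table.counts[table.counts["channel"] == channel].itertuples()
    }
    t = truth_dots[truth_dots["channel"] == channel]
    truth_counts = t.groupby("cell_id").size().to_dict()
    rows = []
    for cid in range(1, mask.n_cells + 1):
        overlap = truth_labels[mask.labels == cid]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            rows.append((cid, 0, det_counts.get(cid, 0), np.nan, False))
            continue
        tcid = int(np.bincount(overlap).argmax())
        tc = int(truth_counts.get(tcid, 0))
        dc = det_counts.get(cid, 0)
        rows.append((cid, tcid, dc, tc, abs(dc - tc) <= tolerance))
    df = pd.DataFrame(
        rows, columns=["cell_id", "truth_cell_id", "detected", "truth", "ok"]
    )
    frac = float(df["ok"].mean()) if len(df) else 0.0
    return frac, df
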