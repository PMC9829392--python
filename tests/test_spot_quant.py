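"""Quantification pipeline: cell segmentation, ellipse-fit spot calling,
per-cell counting, and group comparison."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

from padlockrca.imaging_sim import SceneParams, simulate_section
from padlockrca.spot_quant import (
    CellMask,
    SegmentationParams,
    SpotParams,
    assign_spots,
    compare_groups,
    detect_spots,
    ellipse_fit,
    match_spots,
    quantify,
    segment_cells,
)


def grid_wall_image(cell=50, wall=4, n=2, level=10000.0, bg=200.0):
    """An (n x n) grid of cells enclosed by walls, noiseless."""
    size = n * cell + (n + 1) * wall
    img = np.full((size, size), bg)
    for k in range(n + 1):
        a = k * (cell + wall)
        img[a : a + wall, :] = level
        img[:, a : a + wall] = level
    return img


class TestSegmentCells:
    def test_grid_of_four_cells(self):
        mask = segment_cells(grid_wall_image(n=2))
        assert mask.n_cells == 4
        assert sorted(mask.areas) == [1, 2, 3, 4]

    def test_uniform_image_yields_no_cells(self):
        with pytest.warns(UserWarning, match="no cells|uniform"):
            mask = segment_cells(np.full((64, 64), 100.0))
        assert mask.n_cells == 0
        assert not mask.labels.any()

    def test_canonical_labels_bit_identical(self):
        img = grid_wall_image(n=3)
        a = segment_cells(img)
        b = segment_cells(img)
        np.testing.assert_array_equal(a.labels, b.labels)
        # canonical order: centroid row-major, so top-left cell is label 1
        first = np.argwhere(a.labels == 1)
        last = np.argwhere(a.labels == a.n_cells)
        assert first[:, 0].mean() < last[:, 0].mean() or (
            first[:, 0].mean() == last[:, 0].mean()
        )


def _oracle_ellipse_fit(pts: np.ndarray) -> float:
    """Independent loop-based ellipse-fit score (closed-form 2x2 eigen)."""
    n = len(pts)
    if n == 1:
        return 1.0
    cy = sum(p[0] for p in pts) / n
    cx = sum(p[1] for p in pts) / n
    syy = sum((p[0] - cy) ** 2 for p in pts) / n
    sxx = sum((p[1] - cx) ** 2 for p in pts) / n
    sxy = sum((p[0] - cy) * (p[1] - cx) for p in pts) / n
    tr, det = syy + sxx, syy * sxx - sxy**2
    disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
    lam_small = tr / 2 - disc
    if lam_small <= 1e-9:
        return 0.0
    syy, sxx = syy + 1 / 12, sxx + 1 / 12
    tr, det = syy + sxx, syy * sxx - sxy**2
    disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc
    major, minor = 2 * math.sqrt(lam1), 2 * math.sqrt(lam2)
    s = math.sqrt(n / (math.pi * major * minor))
    major, minor = major * s, minor * s
    if abs(sxy) > 1e-12:
        vy, vx = lam1 - sxx, sxy  # eigenvector of [[syy,sxy],[sxy,sxx]]
    elif syy >= sxx:
        vy, vx = 1.0, 0.0
    else:
        vy, vx = 0.0, 1.0
    norm = math.hypot(vy, vx)
    uy, ux = vy / norm, vx / norm
    reach = int(math.ceil(max(major, minor))) + 2
    comp = {(int(p[0]), int(p[1])) for p in pts}
    rs = range(min(p[0] for p in comp) - reach, max(p[0] for p in comp) + reach + 1)
    cs = range(min(p[1] for p in comp) - reach, max(p[1] for p in comp) + reach + 1)
    ell = set()
    for r in rs:
        for c in cs:
            dy, dx = r - cy, c - cx
            along = dy * uy + dx * ux
            perp = -dy * ux + dx * uy
            if (along / major) ** 2 + (perp / minor) ** 2 <= 1.0:
                ell.add((r, c))
    inter = len(comp & ell)
    union = len(comp | ell)
    return inter / union


class TestEllipseFit:
    def test_rasterized_disc_scores_high(self):
        rr, cc = draw_disk((30, 30), 6)
        assert ellipse_fit(np.column_stack([rr, cc])) >= 0.90

    def test_thin_line_scores_low(self):
        line = np.column_stack([np.full(20, 5), np.arange(20)])
        assert ellipse_fit(line) < 0.5

    def test_single_pixel_convention(self):
        assert ellipse_fit(np.array([[7, 9]])) == 1.0

    def test_matches_pixel_set_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            # random blob: union of a few discs, <= 200 px
            img = np.zeros((48, 48), bool)
            for _ in range(int(rng.integers(1, 4))):
                r0, c0 = rng.integers(12, 36, 2)
                rr, cc = draw_disk((int(r0), int(c0)), int(rng.integers(2, 6)),
                                   shape=img.shape)
                img[rr, cc] = True
            pts = np.argwhere(img)
            if not 2 <= len(pts) <= 200:
                continue
            got = ellipse_fit(pts)
            want = _oracle_ellipse_fit([tuple(p) for p in pts])
            assert got == pytest.approx(want, abs=1e-9)


def render_dots(shape, dots, peak=5000.0, sigma=1.2, bg=100.0):
    img = np.full(shape, bg)
    yy, xx = np.indices(shape)
    for (y, x) in dots:
        img += peak * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    return img


class TestDetectSpots:
    def test_blank_images_yield_no_spots(self):
        assert detect_spots(np.zeros((64, 64))) == []
        assert detect_spots(np.full((64, 64), 300.0)) == []

    def test_three_isolated_dots_recovered_within_a_pixel(self):
        truth = [(20.3, 40.7), (70.0, 22.5), (100.6, 90.2)]
        img = render_dots((128, 128), truth)
        spots = detect_spots(img)
        assert len(spots) == 3
        for ty, tx in truth:
            d = min(math.hypot(s.y - ty, s.x - tx) for s in spots)
            assert d <= 1.0

    def test_translation_equivariance(self):
        truth = [(30.0, 30.0), (60.0, 80.0)]
        shift = (7, 11)
        a = detect_spots(render_dots((128, 128), truth))
        b = detect_spots(
            render_dots((128, 128), [(y + shift[0], x + shift[1]) for y, x in truth])
        )
        assert len(a) == len(b) == 2
        for sa, sb in zip(a, b):
            assert sb.y - sa.y == pytest.approx(shift[0], abs=0.2)
            assert sb.x - sa.x == pytest.approx(shift[1], abs=0.2)

    def test_close_pair_resolved_by_overlap_rule(self):
        img = render_dots((64, 64), [(30.0, 28.0), (30.0, 36.0)])
        spots = detect_spots(img)
        assert len(spots) == 2


class TestAssignSpots:
    def _mask(self):
        labels = np.zeros((40, 40), np.int32)
        labels[5:18, 5:18] = 1
        labels[22:38, 22:38] = 2
        return CellMask(labels, 2, {1: 13 * 13, 2: 16 * 16})

    def test_containment_and_conservation(self):
        from padlockrca.spot_quant import SpotCall

        mask = self._mask()
        spots = [
            SpotCall(x=10, y=10, area=9, threshold=1, ellipse_score=1.0),
            SpotCall(x=11, y=9, area=9, threshold=1, ellipse_score=1.0),
            SpotCall(x=30, y=30, area=9, threshold=1, ellipse_score=1.0),
            SpotCall(x=20, y=20, area=9, threshold=1, ellipse_score=1.0),  # wall
        ]
        table = assign_spots(spots, mask)
        counts = table.counts.set_index("cell_id")["dot_count"]
        assert counts[1] == 2 and counts[2] == 1
        assert table.unassigned["signal_1"] == 1
        assert counts.sum() + sum(table.unassigned.values()) == len(spots)

    def test_spot_on_wall_pixel_unassigned(self):
        from padlockrca.spot_quant import SpotCall

        table = assign_spots(
            [SpotCall(x=2, y=2, area=4, threshold=1, ellipse_score=1.0)],
            self._mask(),
        )
        assert (table.counts["dot_count"] == 0).all()
        assert table.unassigned["signal_1"] == 1


class TestCompareGroups:
    def test_group_against_itself_permutation_p_is_one(self):
        a = [3, 5, 2, 7, 4]
        res = compare_groups(a, a, method="permutation", seed=1)
        assert res.difference == 0
        assert res.p_value == 1.0

    def test_large_effect_detected(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(2, 50)
        b = rng.poisson(20, 50)
        assert compare_groups(a, b).p_value < 0.01
        assert compare_groups(a, b, method="permutation", seed=3).p_value < 0.01

    def test_permutation_agrees_with_full_enumeration(self):
        a = [1.0, 4.0, 2.0, 6.0]
        b = [8.0, 9.0, 5.0, 7.0]
        pooled = a + b
        obs = abs(np.mean(a) - np.mean(b))
        hits = total = 0
        for idx in itertools.combinations(range(8), 4):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(8) if i not in idx]
            if abs(np.mean(ga) - np.mean(gb)) >= obs - 1e-12:
                hits += 1
            total += 1
        expected = hits / total
        exact = compare_groups(a, b, method="permutation", exact=True)
        assert exact.p_value == pytest.approx(expected, abs=1e-12)
        mc = compare_groups(a, b, method="permutation", exact=False,
                            n_permutations=20000, seed=5)
        assert mc.p_value == pytest.approx(expected, abs=0.02)

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            compare_groups([1], [2, 3])


class TestEndToEnd:
    def test_small_scene_counts_track_truth(self):
        scene = simulate_section(
            SceneParams(shape=(256, 256), n_cells=12, dot_rate=(5.0,),
                        seed=13, min_cell_interior=30)
        )
        res = quantify(scene.channels)
        assert res.mask.n_cells >= 1
        m = match_spots(res.spots, scene.dots, channel="signal_1")
        assert m.recall >= 0.8 and m.precision >= 0.8
        total = res.table.counts["dot_count"].sum() + sum(
            res.table.unassigned.values()
        )
        assert total == len(res.spots)
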