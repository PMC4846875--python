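"""Nucleus detection, seeded propagation, ring regions, endosome spots."""

import numpy as np
import pytest

from phenoks import segmentation as seg


def draw_disk(shape, center, radius, value=100.0):
    img = np.zeros(shape, float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2] = value
    return img


def brute_force_dilate(mask, radius):
    """Dilation by a Euclidean disk via direct pixel enumeration."""
    out = np.zeros_like(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    for r, c in zip(rows, cols):
        out |= (yy - r) ** 2 + (xx - c) ** 2 <= radius ** 2
    return out


def brute_force_propagate(seeds, guide, lam, fg):
    """Fixpoint (Bellman-Ford style) minimal accumulated-cost labelling."""
    h, w = guide.shape
    best = np.full((h, w), np.inf)
    lab = np.zeros((h, w), dtype=int)
    for r, c in zip(*np.nonzero(seeds)):
        best[r, c] = 0.0
        lab[r, c] = seeds[r, c]
    steps = [(dr, dc, np.hypot(dr, dc))
             for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    changed = True
    while changed:
        changed = False
        for r in range(h):
            for c in range(w):
                if not fg[r, c]:
                    continue
                for dr, dc, dist in steps:
                    pr, pc = r + dr, c + dc
                    if not (0 <= pr < h and 0 <= pc < w):
                        continue
                    if not np.isfinite(best[pr, pc]):
                        continue
                    cost = best[pr, pc] + abs(guide[pr, pc] - guide[r, c]) \
                        + lam * dist
                    if cost < best[r, c] - 1e-12:
                        best[r, c] = cost
                        lab[r, c] = lab[pr, pc]
                        changed = True
    for r, c in zip(*np.nonzero(seeds)):   # seeds keep their own label
        lab[r, c] = seeds[r, c]
    return lab


class TestSegmentNuclei:
    def test_three_disks_counted_with_areas(self):
        img = np.zeros((120, 120))
        for ctr in [(25, 25), (25, 90), (90, 55)]:
            img += draw_disk(img.shape, ctr, 8)
        labels = seg.segment_nuclei(img, min_area=50)
        ids, areas = np.unique(labels[labels > 0], return_counts=True)
        assert len(ids) == 3
        target = np.pi * 64
        assert np.all(np.abs(areas - target) / target < 0.2)

    def test_blank_image_zero_nuclei(self):
        assert seg.segment_nuclei(np.zeros((50, 50))).max() == 0

    def test_small_object_filtered(self):
        img = draw_disk((60, 60), (30, 30), 3)   # area ~28 px^2
        assert seg.segment_nuclei(img, min_area=50).max() == 0

    def test_border_objects_removed(self):
        img = draw_disk((60, 60), (0, 30), 8) + draw_disk((60, 60), (35, 30), 8)
        labels = seg.segment_nuclei(img, min_area=30)
        assert len(np.unique(labels)) == 2   # background + inner disk only

    def test_nan_rejected(self):
        img = np.zeros((10, 10))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            seg.segment_nuclei(img)


class TestPropagateCells:
    def test_symmetric_seeds_split_on_bisector(self):
        # disc and seeds mirror-symmetric about x = 40.5, so the cost
        # bisector falls between pixel columns and the split is exact
        guide = draw_disk((80, 81), (40, 40.5), 32, value=50.0)
        seeds = np.zeros((80, 81), dtype=int)
        seeds[40, 25] = 1
        seeds[40, 56] = 2
        cells = seg.propagate_cells(seeds, guide,
                                    foreground=guide > 0)
        a1 = (cells == 1).sum()
        a2 = (cells == 2).sum()
        assert abs(a1 - a2) / max(a1, a2) < 0.02
        # boundary is the vertical bisector
        assert (cells[:, :41] != 2).all() and (cells[:, 41:] != 1).all()

    def test_single_seed_fills_foreground(self):
        guide = draw_disk((60, 60), (30, 30), 20, value=10.0)
        seeds = np.zeros((60, 60), dtype=int)
        seeds[30, 30] = 1
        cells = seg.propagate_cells(seeds, guide, foreground=guide > 0)
        assert ((cells == 1) == (guide > 0)).all()

    def test_no_seeds_empty(self):
        out = seg.propagate_cells(np.zeros((20, 20), int), np.ones((20, 20)))
        assert out.max() == 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            seg.propagate_cells(np.zeros((5, 5), int), np.zeros((6, 6)))

    def test_dark_ridge_deflects_boundary(self):
        # uniform field with a dark vertical ridge off-center: with small
        # lambda the label boundary snaps to the ridge, not the bisector
        guide = np.full((40, 40), 50.0)
        guide[:, 26] = 5.0
        seeds = np.zeros((40, 40), dtype=int)
        seeds[20, 10] = 1
        seeds[20, 34] = 2
        cells = seg.propagate_cells(seeds, guide, regularization=0.05)
        assert (cells[:, :26] == 1).all()
        assert (cells[:, 27:] == 2).all()

    def test_matches_fixpoint_oracle_on_random_fields(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            guide = rng.uniform(0, 1, size=(18, 18))
            seeds = np.zeros((18, 18), dtype=int)
            seeds[4, 4] = 1
            seeds[13, 12] = 2
            fg = np.ones((18, 18), bool)
            got = seg.propagate_cells(seeds, guide, regularization=0.05,
                                      foreground=fg)
            want = brute_force_propagate(seeds, guide, 0.05, fg)
            assert (got == want).all()

    def test_cell_contains_nucleus(self):
        guide = draw_disk((60, 60), (30, 30), 22, value=30.0)
        seeds = np.zeros((60, 60), dtype=int)
        seeds[27:33, 27:33] = 1
        cells = seg.propagate_cells(seeds, guide)
        assert (cells[seeds > 0] == seeds[seeds > 0]).all()


class TestDeriveRegions:
    def _square_labels(self):
        nuc = np.zeros((60, 60), dtype=int)
        nuc[25:35, 25:35] = 1    # 10x10 nucleus
        cell = np.zeros((60, 60), dtype=int)
        cell[10:50, 10:50] = 1
        return seg.SegmentationLabels(nucleus_labels=nuc, cell_labels=cell)

    def test_perinuclear_matches_brute_force_dilation(self):
        labels = seg.derive_regions(self._square_labels(), expand_px=2,
                                    shrink_px=5)
        nuc = labels.nucleus_labels == 1
        expected_area = brute_force_dilate(nuc, 2).sum() - 100
        assert (labels.perinuclear_labels == 1).sum() == expected_area

    def test_pm_matches_brute_force_erosion(self):
        labels = seg.derive_regions(self._square_labels(), expand_px=2,
                                    shrink_px=3)
        cell = labels.cell_labels == 1
        # erosion = complement of dilation of the complement
        eroded = ~brute_force_dilate(~cell, 3)
        assert ((labels.pm_labels == 1) == (cell & ~eroded)).all()

    def test_set_identities(self):
        labels = seg.derive_regions(self._square_labels())
        nuc = labels.nucleus_labels == 1
        cell = labels.cell_labels == 1
        cyto = labels.cytoplasm_labels == 1
        peri = labels.perinuclear_labels == 1
        pm = labels.pm_labels == 1
        assert (cyto == (cell & ~nuc)).all()
        assert not (peri & nuc).any()
        assert (pm <= cell).all() and (peri <= cell).all()

    def test_zero_expand_empty_ring(self):
        labels = seg.derive_regions(self._square_labels(), expand_px=0,
                                    shrink_px=3)
        assert labels.perinuclear_labels.max() == 0

    def test_overshrink_pm_is_whole_cell(self):
        labels = seg.derive_regions(self._square_labels(), expand_px=2,
                                    shrink_px=45)
        cell = labels.cell_labels == 1
        assert ((labels.pm_labels == 1) == cell).all()

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            seg.derive_regions(self._square_labels(), expand_px=-1)


class TestDetectEndosomes:
    def _one_cell_labels(self, shape=(100, 100)):
        cell = np.ones(shape, dtype=int)
        nuc = np.zeros(shape, dtype=int)
        nuc[45:55, 45:55] = 1
        return seg.derive_regions(
            seg.SegmentationLabels(nucleus_labels=nuc, cell_labels=cell))

    def test_uniform_image_no_objects(self):
        labels = self._one_cell_labels()
        objs = seg.detect_endosomes(np.full((100, 100), 7.0), labels)
        assert len(objs.table) == 0

    def test_five_gaussian_spots_detected(self):
        labels = self._one_cell_labels()
        yy, xx = np.mgrid[0:100, 0:100]
        img = np.zeros((100, 100))
        centers = [(20, 20), (20, 70), (50, 20), (80, 50), (80, 85)]
        for r, c in centers:
            img += 80 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 4))
        objs = seg.detect_endosomes(img, labels, tophat_radius=5)
        assert len(objs.table) == 5
        got = sorted((round(r), round(c)) for r, c in
                     zip(objs.table["centroid_r"], objs.table["centroid_c"]))
        assert got == sorted(centers)

    def test_broad_blob_suppressed(self):
        # a radius-20 blob built as core (+) disk(5) is morphologically open
        # w.r.t. the top-hat element, so the enhanced image is exactly zero
        from skimage import morphology
        labels = self._one_cell_labels()
        yy, xx = np.mgrid[0:100, 0:100]
        core = (yy - 50) ** 2 + (xx - 50) ** 2 <= 15 ** 2
        img = 100.0 * morphology.dilation(core, morphology.disk(5))
        objs = seg.detect_endosomes(img, labels, tophat_radius=5)
        assert len(objs.table) == 0

    def test_objects_assigned_to_regions(self):
        labels = self._one_cell_labels()
        yy, xx = np.mgrid[0:100, 0:100]
        img = 80 * np.exp(-((yy - 50) ** 2 + (xx - 58) ** 2) / (2 * 4))
        objs = seg.detect_endosomes(img, labels, tophat_radius=5)
        assert len(objs.table) == 1
        row = objs.table.iloc[0]
        assert row["cell"] == 1
        assert row["region"] == "perinuclear"
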