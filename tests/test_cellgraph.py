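"""Adjacency graphs, half-link enumeration and interframe classification."""

import numpy as np
import pandas as pd
import pytest

from epimorph.cellgraph import (
    Lineage,
    LineageError,
    build_adjacency,
    classify_half_links,
    division_links,
    division_orientation,
    enumerate_half_links,
    overlap_tracker,
)
from tests.conftest import block_grid, trivial_lineage_df


class TestAdjacency:
    def test_two_abutting_rectangles(self):
        img = np.zeros((8, 12), dtype=np.uint32)
        img[2:6, 1:6] = 1
        img[2:6, 6:11] = 2
        g = build_adjacency(img)
        assert g.neighbors[1] == {2}
        links = enumerate_half_links(g)
        assert len(links) == 2

    def test_corner_touching_cells_are_not_neighbours(self):
        # 2x2 block of four squares meeting at a point: diagonal pairs
        # share only the corner, hence 4 edge adjacencies under
        # 4-connectivity
        img = np.zeros((10, 10), dtype=np.uint32)
        img[1:5, 1:5] = 1
        img[1:5, 5:9] = 2
        img[5:9, 1:5] = 3
        img[5:9, 5:9] = 4
        g = build_adjacency(img)
        pairs = {frozenset(p) for c, ks in g.neighbors.items() for p in
                 [(c, k) for k in ks]}
        assert frozenset((1, 4)) not in pairs
        assert frozenset((2, 3)) not in pairs
        assert len(pairs) == 4
        # the meeting point is recorded as a four-fold configuration
        assert frozenset((1, 2, 3, 4)) in g.fourfold

    def test_honeycomb_interior_cells_have_six_neighbours(self):
        from epimorph.morphosim import hex_seeds, voronoi_labels

        rng = np.random.default_rng(0)
        seeds = hex_seeds(40.0, 10.0, rng, jitter=0.0) + 60.0
        img = voronoi_labels(seeds, (120, 120), 55.0, (60.0, 60.0))
        g = build_adjacency(img)
        medium_adjacent = set()
        lab = img
        for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
            m = (a == 0) & (b != 0)
            medium_adjacent.update(int(v) for v in np.unique(b[m]))
            m = (b == 0) & (a != 0)
            medium_adjacent.update(int(v) for v in np.unique(a[m]))
        interior = g.valid - medium_adjacent
        assert interior
        for c in interior:
            assert len(g.neighbors[c]) == 6

    def test_disconnected_label_rejected(self):
        img = np.zeros((10, 10), dtype=np.uint32)
        img[1:3, 1:3] = 1
        img[7:9, 7:9] = 1
        img[4:6, 4:6] = 2
        with pytest.raises(ValueError, match="not single connected"):
            build_adjacency(img)

    def test_boundary_cells_excluded(self, block_image):
        g = build_adjacency(block_image)
        # 5x5 grid: the 16 outer cells touch the border, 9 interior remain
        assert len(g.border) == 16
        assert len(g.valid) == 9
        links = enumerate_half_links(g)
        # interior cells only: 3x3 rook adjacencies = 12 pairs = 24 half-links
        assert len(links) == 24
        assert g.dropped_border_links > 0

    def test_half_link_antisymmetry(self, block_image):
        g = build_adjacency(block_image, pixel_size=0.5)
        links = enumerate_half_links(g)
        idx = {(c, k): (lx, ly) for c, k, lx, ly in
               zip(links["c"], links["k"], links["lx"], links["ly"])}
        for (c, k), (lx, ly) in idx.items():
            rx, ry = idx[(k, c)]
            assert lx == pytest.approx(-rx)
            assert ly == pytest.approx(-ry)

    def test_frame_of_only_border_cells_is_empty(self):
        img = np.zeros((6, 6), dtype=np.uint32)
        img[:3] = 1
        img[3:] = 2
        g = build_adjacency(img)
        assert len(enumerate_half_links(g)) == 0


# ---------------------------------------------------------------------------
# classification toys (5x5 cell grid, centre cell 13 manipulated)
# ---------------------------------------------------------------------------

def _classify(img0, img1, lineage_df):
    g0 = build_adjacency(img0, frame=0)
    g1 = build_adjacency(img1, frame=1)
    return classify_half_links(g0, g1, Lineage(lineage_df)), (g0, g1)


class TestClassification:
    def test_static_frames_all_conserved(self, block_image):
        (l0, l1), _ = _classify(
            block_image, block_image,
            trivial_lineage_df(range(1, 26), last_frame=1),
        )
        assert set(l0["category"]) == {"conserved"}
        assert set(l1["category"]) == {"conserved"}

    def test_t1_quartet(self):
        # cells 8 (top) and 18 (bottom) initially in contact through the
        # centre; afterwards 12 (left) and 14 (right) are -- a pure T1
        img0 = block_grid()
        img0[12:15, 12:18] = 8
        img0[15:18, 12:18] = 18
        img1 = block_grid()
        img1[12:18, 12:15] = 12
        img1[12:18, 15:18] = 14
        (l0, l1), _ = _classify(
            img0, img1, trivial_lineage_df([c for c in range(1, 26) if c != 13],
                                           last_frame=1),
        )
        r0 = l0[l0["category"] == "rearrangement"]
        r1 = l1[l1["category"] == "rearrangement"]
        assert {(c, k) for c, k in zip(r0["c"], r0["k"])} == {(8, 18), (18, 8)}
        assert {(c, k) for c, k in zip(r1["c"], r1["k"])} == {(12, 14), (14, 12)}
        assert (l0["category"] != "conserved").sum() == 2
        assert (l1["category"] != "conserved").sum() == 2

    def test_division_links_and_sister_flag(self):
        img0 = block_grid()
        img1 = block_grid()
        img1[12:18, 12:15] = 26
        img1[12:18, 15:18] = 27
        lin = trivial_lineage_df([c for c in range(1, 26) if c != 13],
                                 last_frame=1)
        lin = pd.concat([lin, pd.DataFrame([
            dict(cell_id=13, mother_id=-1, first_frame=0, last_frame=0,
                 fate="divides", fate_partner=-1),
            dict(cell_id=26, mother_id=13, first_frame=1, last_frame=1,
                 fate="survives", fate_partner=-1),
            dict(cell_id=27, mother_id=13, first_frame=1, last_frame=1,
                 fate="survives", fate_partner=-1),
        ])], ignore_index=True)
        (l0, l1), (g0, g1) = _classify(img0, img1, lin)
        # every half-link touching the mother at t is division-category
        mother0 = l0[(l0["c"] == 13) | (l0["k"] == 13)]
        assert set(mother0["category"]) == {"division"}
        d1 = l1[(l1["c"].isin([26, 27])) | (l1["k"].isin([26, 27]))]
        assert set(d1["category"]) == {"division"}
        sisters = l1[l1["sister"]]
        assert {(c, k) for c, k in zip(sisters["c"], sisters["k"])} == {
            (26, 27), (27, 26)}
        # Do from the sister links: daughters side by side along x
        sl = division_links(Lineage(lin), g1)
        assert len(sl) == 1
        do = division_orientation(sl)
        assert do.xx > 0 and do.yy < 0
        assert abs(do.xy) < 1e-12

    def test_delamination_creates_delamination_links(self):
        img0 = block_grid()
        img1 = block_grid()
        img1[12:15, 12:18] = 8    # neighbours close over the dead cell
        img1[15:18, 12:18] = 18
        lin = trivial_lineage_df([c for c in range(1, 26) if c != 13],
                                 last_frame=1)
        lin = pd.concat([lin, pd.DataFrame([
            dict(cell_id=13, mother_id=-1, first_frame=0, last_frame=0,
                 fate="delaminates", fate_partner=-1),
        ])], ignore_index=True)
        (l0, l1), _ = _classify(img0, img1, lin)
        dying0 = l0[(l0["c"] == 13) | (l0["k"] == 13)]
        assert set(dying0["category"]) == {"delamination"}
        # every appearing contact among the dead cell's former neighbours
        # carries the delamination category, including the closing pair
        appearing = l1[l1["category"] != "conserved"]
        assert set(appearing["category"]) == {"delamination"}
        pairs = {(c, k) for c, k in zip(appearing["c"], appearing["k"])}
        assert {(8, 18), (18, 8)} <= pairs

    def test_completeness_every_link_has_one_category(self, scenario):
        sc = scenario("delamination")
        stack, lin = sc.result.stack, sc.result.lineage
        g0 = build_adjacency(stack[10], frame=10)
        g1 = build_adjacency(stack[11], frame=11)
        l0, l1 = classify_half_links(g0, g1, lin)
        from epimorph.cellgraph import CATEGORIES
        for table, graph in ((l0, g0), (l1, g1)):
            assert table["category"].isin(CATEGORIES).all()
            assert len(table) == len(enumerate_half_links(graph))

    def test_lineage_contradiction_raises(self, block_image):
        # interior cell 13 present in the images but absent from the lineage
        lin = trivial_lineage_df([c for c in range(1, 26) if c != 13],
                                 last_frame=1)
        with pytest.raises(LineageError):
            _classify(block_image, block_image, lin)

    def test_no_divisions_gives_missing_do(self):
        assert division_orientation(pd.DataFrame(columns=["lx", "ly"])) is None

    def test_opposite_diagonal_divisions_cancel(self):
        sl = pd.DataFrame([
            dict(frame=1, mother=1, d1=2, d2=3, lx=1.0, ly=1.0),
            dict(frame=1, mother=4, d1=5, d2=6, lx=1.0, ly=-1.0),
        ])
        do = division_orientation(sl)
        assert np.allclose(do.as_matrix(), 0.0, atol=1e-12)


class TestOverlapTracker:
    def test_translated_copy_is_identity(self, block_image):
        stack = np.stack([block_image, np.roll(block_image, 2, axis=1)])
        out, lin = overlap_tracker(stack)
        assert (lin.table["fate"] == "survives").all()
        assert len(np.unique(out[0])) == len(np.unique(out[1]))

    def test_interior_removal_is_delamination(self, block_image):
        img1 = block_image.copy()
        img1[12:15, 12:18] = 8
        img1[15:18, 12:18] = 18
        out, lin = overlap_tracker(np.stack([block_image, img1]))
        assert (lin.table["fate"] == "delaminates").sum() == 1

    def test_split_detected_as_division(self, block_image):
        img1 = block_image.copy()
        img1[12:18, 12:15] = 26
        img1[12:18, 15:18] = 27
        out, lin = overlap_tracker(np.stack([block_image, img1]))
        assert (lin.table["fate"] == "divides").sum() == 1
        assert (lin.table["mother_id"] >= 0).sum() == 2

    def test_recovers_simulator_divisions(self, scenario):
        sc = scenario("divisions")
        stack = sc.result.stack
        sub = stack[:21]
        out, lin = overlap_tracker(sub)
        true_divs = sc.result.lineage.table
        n_true = ((true_divs["fate"] == "divides")
                  & (true_divs["last_frame"] < 20)).sum()
        n_found = (lin.table["fate"] == "divides").sum()
        assert n_found == n_true
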