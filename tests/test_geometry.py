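"""Tumor-cluster construction, areas and signed distances."""

import numpy as np
import pytest
from shapely.affinity import rotate, translate
from shapely.geometry import Point

from pdactme.geometry import (
    NoTumorClustersError,
    build_tumor_clusters,
    cluster_area,
    disc_polygon,
    signed_distance,
    signed_distances,
)

from conftest import brute_force_signed_distance, make_cells


class TestClusterConstruction:
    def test_chain_of_cells_within_merge_reach_forms_one_cluster(self):
        # pairwise gaps of 10 µm < 2 * merge_radius: discs overlap
        cells = make_cells([(0, 0, "tumor"), (10, 0, "tumor"), (20, 0, "tumor")])
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=1)
        assert cs.n_clusters == 1

    def test_distant_cells_form_separate_clusters(self):
        cells = make_cells([(0, 0, "tumor"), (100, 0, "tumor")])
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=1)
        assert cs.n_clusters == 2

    def test_single_cell_cluster_area_matches_disc(self):
        cells = make_cells([(0, 0, "tumor")])
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=1)
        expected = np.pi * 15**2 / 1e6
        assert cluster_area(cs) == pytest.approx(expected, rel=0.01)

    def test_coincident_cells_do_not_double_count_area(self):
        cells = make_cells([(5, 5, "tumor"), (5, 5, "tumor")])
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=1)
        assert cluster_area(cs) == pytest.approx(np.pi * 15**2 / 1e6, rel=0.01)

    def test_min_cells_discards_small_components(self):
        cells = make_cells(
            [(0, 0, "tumor"), (5, 0, "tumor"), (5, 5, "tumor"), (300, 300, "tumor")]
        )
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=3)
        assert cs.n_clusters == 1

    def test_no_tumor_cells_gives_empty_set_not_error(self):
        cells = make_cells([(0, 0, "CD8")])
        cs = build_tumor_clusters(cells, merge_radius=15)
        assert cs.is_empty and cs.total_area_mm2 == 0.0

    def test_non_finite_coordinate_rejected(self):
        cells = make_cells([(np.nan, 0, "tumor")])
        with pytest.raises(ValueError, match="non-finite"):
            build_tumor_clusters(cells, merge_radius=15)


class TestExclusions:
    def test_cluster_inside_exclusion_has_zero_area(self):
        cells = make_cells([(0, 0, "tumor")])
        excl = [disc_polygon((0, 0), 50)]
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=1, exclusions=excl)
        assert cluster_area(cs) == 0.0

    def test_exclusion_reduces_area_but_keeps_outline_for_distances(self):
        cells = make_cells([(0, 0, "tumor")])
        excl = [disc_polygon((0, 0), 50)]
        cs = build_tumor_clusters(cells, merge_radius=20, min_cells=1, exclusions=excl)
        # distances still measured to the pre-exclusion outline
        assert signed_distance((0, 0), cs) == pytest.approx(-20, rel=0.01)


class TestSignedDistance:
    def test_center_of_disc_cluster_is_negative_radius(self):
        cells = make_cells([(0, 0, "tumor")])
        cs = build_tumor_clusters(cells, merge_radius=20, min_cells=1)
        assert signed_distance((0, 0), cs) == pytest.approx(-20, rel=0.01)

    def test_outside_point_positive_distance(self):
        cells = make_cells([(0, 0, "tumor")])
        cs = build_tumor_clusters(cells, merge_radius=20, min_cells=1)
        assert signed_distance((50, 0), cs) == pytest.approx(30, rel=0.01)

    def test_empty_cluster_set_signals_no_tumor(self):
        cells = make_cells([(0, 0, "CD8")])
        cs = build_tumor_clusters(cells, merge_radius=15)
        with pytest.raises(NoTumorClustersError):
            signed_distance((0, 0), cs)

    def test_agrees_with_brute_force_segment_oracle(self, rng):
        pts = rng.uniform(-200, 200, size=(40, 2))
        cells = make_cells([(x, y, "tumor") for x, y in pts])
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=1)
        query = rng.uniform(-250, 250, size=(1000, 2))
        d_impl = signed_distances(query, cs)
        d_oracle = brute_force_signed_distance(query, cs)
        assert np.max(np.abs(d_impl - d_oracle)) < 0.5


class TestInvariants:
    def test_translation_invariance_is_exact(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        cells = make_cells([(x, y, "tumor") for x, y in pts])
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=1)
        cells2 = make_cells([(x + 500, y - 200, "tumor") for x, y in pts])
        cs2 = build_tumor_clusters(cells2, merge_radius=15, min_cells=1)
        assert cs2.n_clusters == cs.n_clusters
        assert cs2.total_area_mm2 == pytest.approx(cs.total_area_mm2, rel=1e-9)
        assert signed_distance((550, -150), cs2) == pytest.approx(
            signed_distance((50, 50), cs), abs=1e-6
        )

    def test_rotation_invariance_within_disc_discretisation(self, rng):
        # buffered discs are 64-gons with orientation-fixed vertices, so
        # rotation invariance holds only to the polygonalisation error
        pts = rng.uniform(0, 100, size=(20, 2))
        cells = make_cells([(x, y, "tumor") for x, y in pts])
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=1)
        moved = [rotate(Point(x, y), 30, origin=(0, 0)) for x, y in pts]
        cells2 = make_cells([(p.x, p.y, "tumor") for p in moved])
        cs2 = build_tumor_clusters(cells2, merge_radius=15, min_cells=1)
        assert cs2.n_clusters == cs.n_clusters
        assert cs2.total_area_mm2 == pytest.approx(cs.total_area_mm2, rel=1e-4)
        q = rotate(Point(50, 50), 30, origin=(0, 0))
        assert signed_distance((q.x, q.y), cs2) == pytest.approx(
            signed_distance((50, 50), cs), abs=0.05
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_larger_merge_radius_never_increases_cluster_count(self, seed):
        r = np.random.default_rng(seed)
        pts = r.uniform(0, 300, size=(30, 2))
        cells = make_cells([(x, y, "tumor") for x, y in pts])
        counts = [
            build_tumor_clusters(cells, merge_radius=mr, min_cells=1).n_clusters
            for mr in (5, 10, 20, 40, 80)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_total_area_bounded_by_disc_sum(self, rng):
        pts = rng.uniform(0, 200, size=(25, 2))
        cells = make_cells([(x, y, "tumor") for x, y in pts])
        cs = build_tumor_clusters(cells, merge_radius=15, min_cells=1)
        assert cs.total_area_mm2 <= 25 * np.pi * 15**2 / 1e6 + 1e-12
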