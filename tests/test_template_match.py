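import numpy as np
import pytest
from skimage.draw import circle_perimeter

from conftest import match_oracle
from markalign.errors import DetectionFailureError, DimensionError, ParameterError
from markalign.template_match import (
    find_circle_triad,
    make_circle_template,
    match_template,
)


def stamp_ring(edges, cx, cy, radius):
    rr, cc = circle_perimeter(cy, cx, radius, shape=edges.shape)
    edges[rr, cc] = True
    return edges


class TestMakeCircleTemplate:
    def test_size_formula(self):
        assert make_circle_template(5).size == 15
        assert make_circle_template(10).size == 25

    def test_white_pixel_count_r5(self):
        t = make_circle_template(5, "white_only")
        # midpoint rasterization of r=5 circle: ~2*pi*5 pixels
        assert 28 <= (t.weights == 1.0).sum() <= 32

    def test_gray_boundary_structure(self):
        g = 0.5
        t = make_circle_template(5, "gray_boundary", g)
        vals = set(np.unique(t.weights))
        assert vals == {0.0, g, 1.0}
        # gray rings flank the white circle at radii r-1 and r+1
        c = t.size // 2
        ys, xs = np.nonzero(t.weights == g)
        d = np.hypot(xs - c, ys - c)
        assert d.min() > 3.0 and d.max() < 7.0

    def test_white_only_has_no_gray(self):
        t = make_circle_template(6, "white_only")
        assert set(np.unique(t.weights)) == {0.0, 1.0}

    def test_rot90_symmetry(self):
        for variant in ("white_only", "gray_boundary"):
            w = make_circle_template(7, variant).weights
            assert np.array_equal(w, np.rot90(w))

    def test_rejects_small_radius(self):
        with pytest.raises(ParameterError):
            make_circle_template(1)

    def test_rejects_bad_variant_and_gray(self):
        with pytest.raises(ParameterError):
            make_circle_template(5, "striped")
        with pytest.raises(ParameterError):
            make_circle_template(5, gray_weight=0.0)


class TestMatchTemplate:
    def test_perfect_match_scores_one(self):
        t = make_circle_template(5, "white_only")
        edges = np.zeros((31, 31), dtype=bool)
        c = 15
        half = t.size // 2
        edges[c - half : c + half + 1, c - half : c + half + 1] = t.weights == 1.0
        cmap = match_template(edges, t)
        assert cmap[c, c] == pytest.approx(1.0)
        assert cmap.max() == pytest.approx(1.0)

    def test_empty_edges_score_zero(self):
        t = make_circle_template(4)
        assert not match_template(np.zeros((20, 20), dtype=bool), t).any()

    def test_scores_bounded(self, rng):
        t = make_circle_template(4, "gray_boundary")
        edges = rng.random((30, 30)) < 0.5
        cmap = match_template(edges, t)
        assert (cmap >= 0).all() and (cmap <= 1).all()

    def test_border_positions_score_zero(self, rng):
        t = make_circle_template(4)
        c = t.size // 2
        edges = rng.random((25, 25)) < 0.4
        cmap = match_template(edges, t)
        assert not cmap[:c, :].any() and not cmap[-c:, :].any()
        assert not cmap[:, :c].any() and not cmap[:, -c:].any()

    def test_template_larger_than_image(self):
        with pytest.raises(DimensionError):
            match_template(np.zeros((10, 10), dtype=bool), make_circle_template(10))

    @pytest.mark.parametrize("variant", ["white_only", "gray_boundary"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_nested_loop_oracle(self, variant, seed):
        rng = np.random.default_rng(seed)
        edges = (rng.random((32, 32)) < 0.2).astype(float)
        t = make_circle_template(4, variant)
        expected = match_oracle(edges, t.weights)
        assert np.abs(match_template(edges, t) - expected).max() < 1e-9

    def test_translation_equivariance(self, rng):
        t = make_circle_template(4)
        edges = rng.random((40, 40)) < 0.15
        dx, dy = 3, 2
        shifted = np.zeros_like(edges)
        shifted[dy:, dx:] = edges[:-dy, :-dx]
        c0 = match_template(edges, t)
        c1 = match_template(shifted, t)
        assert np.allclose(c1[12 + dy : 28 + dy, 12 + dx : 28 + dx],
                           c0[12:28, 12:28], atol=1e-9)

    def test_gray_template_tolerates_displaced_ring(self):
        # a ring displaced 1 px from where the template expects it: the
        # gray-boundary template still scores it at the true center better
        # than the white-only template does
        edges = np.zeros((31, 31), dtype=bool)
        stamp_ring(edges, 16, 15, 6)  # ring center displaced +1 px in x
        white = match_template(edges, make_circle_template(6, "white_only"))
        gray = match_template(edges, make_circle_template(6, "gray_boundary"))
        assert gray[15, 15] > white[15, 15]


class TestFindCircleTriad:
    @staticmethod
    def triad_edges(size=120, r=10, centers=((30, 30), (78, 30), (30, 78))):
        edges = np.zeros((size, size), dtype=bool)
        for cx, cy in centers:
            stamp_ring(edges, cx, cy, r)
        return edges

    def test_ideal_rings_recovered_exactly(self):
        edges = self.triad_edges()
        t = make_circle_template(10, "white_only")
        cmap = match_template(edges, t)
        triad = find_circle_triad(cmap, exclusion_radius=20, refine=False)
        assert triad.c1 == (30.0, 30.0)
        assert triad.c2 == (78.0, 30.0)
        assert triad.c3 == (30.0, 78.0)
        assert min(triad.scores) == pytest.approx(1.0)

    def test_refinement_stays_close(self):
        edges = self.triad_edges()
        cmap = match_template(edges, make_circle_template(10, "gray_boundary"))
        triad = find_circle_triad(cmap, exclusion_radius=20, refine=True)
        for found, true in zip(triad.centers, [(30, 30), (78, 30), (30, 78)]):
            assert np.hypot(found[0] - true[0], found[1] - true[1]) < 0.5

    def test_two_rings_fail(self):
        edges = self.triad_edges(centers=((30, 30), (78, 30)))
        cmap = match_template(edges, make_circle_template(10, "white_only"))
        with pytest.raises(DetectionFailureError):
            find_circle_triad(cmap, exclusion_radius=20)

    def test_floor_score_respected(self):
        edges = self.triad_edges()
        cmap = match_template(edges, make_circle_template(10, "white_only"))
        with pytest.raises(DetectionFailureError):
            find_circle_triad(cmap, exclusion_radius=20, floor_score=1.01)

    @pytest.mark.parametrize("seed", range(10))
    def test_robust_to_speckle(self, seed):
        rng = np.random.default_rng(seed)
        edges = self.triad_edges() | (rng.random((120, 120)) < 0.05)
        cmap = match_template(edges, make_circle_template(10, "gray_boundary"))
        triad = find_circle_triad(cmap, exclusion_radius=20)
        for found, true in zip(triad.centers, [(30, 30), (78, 30), (30, 78)]):
            assert np.hypot(found[0] - true[0], found[1] - true[1]) <= 1.0
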