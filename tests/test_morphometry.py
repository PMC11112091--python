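"""Morphometric panel: golden values, brute-force oracles, invariances."""

import math

import numpy as np
import pytest

from gliamorph.image import BinaryCellPair
from gliamorph.morphometry import (
    BoxCountConfig,
    basic_descriptors,
    box_counting_dimension,
    box_counts,
    hull_descriptors,
    lacunarity,
    perimeter_length,
    profile_cell,
)
from gliamorph.synthetic import AMEBOID_PRESET, RAMIFIED_PRESET, generate_cell
from tests.conftest import plus_pentomino, rasterized_disk


# ------------------------------------------------------------------ oracles

def naive_box_count(img: np.ndarray, scale: int, origin: tuple[int, int]) -> int:
    """Nested-loop count of occupied boxes, partial edge boxes included."""
    oy, ox = origin
    h, w = img.shape
    count = 0
    for by in range(-oy, h, scale):
        for bx in range(-ox, w, scale):
            block = img[max(by, 0):by + scale, max(bx, 0):bx + scale]
            if block.size and block.any():
                count += 1
    return count


def naive_lacunarity(img: np.ndarray, config: BoxCountConfig) -> float:
    """Double-loop recomputation of the documented lacunarity definition."""
    rows = np.any(img, axis=1).nonzero()[0]
    cols = np.any(img, axis=0).nonzero()[0]
    r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
    h, w = img.shape
    values = []
    for scale in config.resolve_scales(img.shape):
        for oy, ox in config.origins(scale):
            sy, sx = (-oy) % scale, (-ox) % scale
            masses = []
            for by in range(sy, h - scale + 1, scale):
                for bx in range(sx, w - scale + 1, scale):
                    if by + scale <= r0 or by >= r1 or bx + scale <= c0 or bx >= c1:
                        continue
                    masses.append(float(img[by:by + scale, bx:bx + scale].sum()))
            if masses:
                mu = np.mean(masses)
                if mu > 0:
                    values.append(np.var(masses) / mu ** 2)
    return float(np.mean(values))


def monotone_chain_hull(points: np.ndarray) -> np.ndarray:
    """Brute-force convex hull (Andrew's monotone chain), CCW vertices."""
    pts = sorted(map(tuple, points))
    def half(seq):
        out = []
        for p in seq:
            while len(out) >= 2:
                (ox, oy), (ax, ay) = out[-2], out[-1]
                if (ax - ox) * (p[1] - oy) - (ay - oy) * (p[0] - ox) <= 0:
                    out.pop()
                else:
                    break
            out.append(p)
        return out
    lower, upper = half(pts), half(reversed(pts))
    return np.array(lower[:-1] + upper[:-1])


def shoelace_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def edge_sum(verts: np.ndarray) -> float:
    d = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


# ------------------------------------------------------- fractal dimension

class TestBoxCountingDimension:
    def test_line_is_one_dimensional(self):
        line = np.zeros((256, 256), bool)
        line[128, :] = True
        fit = box_counting_dimension(line)
        assert fit.dimension == pytest.approx(1.0, abs=0.05)

    def test_filled_square_is_plane_filling(self):
        fit = box_counting_dimension(np.ones((256, 256), bool))
        assert fit.dimension == pytest.approx(2.0, abs=0.05)

    def test_sierpinski_triangle_analytic_dimension(self):
        """Depth-7 Sierpinski pattern; similarity dimension log3/log2."""
        yy, xx = np.mgrid[:128, :128]
        sier = (yy & xx) == 0
        fit = box_counting_dimension(sier)
        assert fit.dimension == pytest.approx(math.log(3) / math.log(2), abs=0.05)
        assert fit.r_squared > 0.99

    def test_counts_match_naive_oracle_exactly(self):
        rng = np.random.default_rng(17)
        img = rng.uniform(size=(97, 113)) < 0.2
        cfg = BoxCountConfig(scales=(2, 3, 5, 8, 13), n_grid_positions=4)
        for scale in cfg.resolve_scales(img.shape):
            ours = box_counts(img, scale, cfg)
            oracle = [naive_box_count(img, scale, o) for o in cfg.origins(scale)]
            assert ours == oracle

    def test_too_few_scales_raises(self):
        img = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            box_counting_dimension(img)
        with pytest.raises(ValueError, match="empty"):
            box_counting_dimension(np.zeros((64, 64), bool))


class TestLacunarity:
    def test_translation_invariant_set_scores_zero(self):
        assert lacunarity(np.ones((128, 128), bool)) == pytest.approx(0.0, abs=1e-12)

    def test_heterogeneity_ordering(self):
        frame = np.ones((340, 340), bool)
        blob = np.zeros((340, 340), bool)
        blob[160:165, 160:165] = True
        assert lacunarity(blob) > lacunarity(frame)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(size=(100, 100)) < 0.5
        cfg = BoxCountConfig(scales=(2, 4, 8, 16), n_grid_positions=3)
        assert lacunarity(img, cfg) == pytest.approx(naive_lacunarity(img, cfg),
                                                     abs=1e-9)


# ----------------------------------------------------------------- geometry

class TestHullDescriptors:
    def test_square_analytic_values(self):
        sq = np.zeros((140, 140), bool)
        sq[20:120, 20:120] = True
        h = hull_descriptors(sq)
        assert h["hull_area"] == pytest.approx(1e4, rel=0.02)
        assert h["hull_perimeter"] == pytest.approx(400, rel=0.02)
        assert h["max_span"] == pytest.approx(100 * math.sqrt(2), rel=0.02)
        assert h["bounding_circle_diameter"] == pytest.approx(100 * math.sqrt(2),
                                                              rel=0.02)

    def test_disk_radius_statistics(self):
        h = hull_descriptors(rasterized_disk(100))
        assert h["mean_radius"] == pytest.approx(100, rel=0.02)
        assert h["radius_cv"] <= 0.02
        assert h["span_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_plus_pentomino_shoelace_oracle(self):
        """Hull of the plus sign is a known octagon: area 7·L² exactly."""
        L = 50
        h = hull_descriptors(plus_pentomino(L))
        assert h["hull_area"] == pytest.approx(7 * L * L, rel=0.02)
        assert h["hull_perimeter"] == pytest.approx(4 * L + 4 * L * math.sqrt(2),
                                                    rel=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_monotone_chain_oracle(self, seed):
        """scipy hull vs brute-force chain + shoelace on the same point set."""
        from gliamorph.morphometry import _corner_points
        pair = generate_cell(RAMIFIED_PRESET, seed=seed)
        pts = _corner_points(pair.filled)
        verts = monotone_chain_hull(pts)
        h = hull_descriptors(pair.filled)
        assert h["hull_area"] == pytest.approx(shoelace_area(verts), abs=1e-9)
        assert h["hull_perimeter"] == pytest.approx(edge_sum(verts), abs=1e-9)

    def test_collinear_points_degenerate(self):
        # a 1-px line has corner points spanning a thin rectangle: valid hull;
        # true degeneracy needs < 3 distinct corners, impossible for pixels —
        # assert instead that empty input errors out
        with pytest.raises(ValueError):
            hull_descriptors(np.zeros((10, 10), bool))


class TestBasicDescriptors:
    def test_disk_circularity_approaches_one(self):
        circ = [basic_descriptors(
            BinaryCellPair.from_filled(rasterized_disk(r)))["cell_circularity"]
            for r in (50, 100)]
        assert circ[1] >= 0.97
        assert circ[1] >= circ[0] - 1e-3  # converging toward the circular form

    def test_square_circularity_analytic(self):
        sq = np.zeros((140, 140), bool)
        sq[20:120, 20:120] = True
        bd = basic_descriptors(BinaryCellPair.from_filled(sq))
        assert bd["cell_circularity"] == pytest.approx(math.pi / 4, rel=0.03)

    def test_plus_roughness_and_density_analytic(self):
        L = 50
        bd = basic_descriptors(BinaryCellPair.from_filled(plus_pentomino(L)))
        expected_rough = 12 * L / (4 * L + 4 * L * math.sqrt(2))
        assert bd["roughness"] == pytest.approx(expected_rough, rel=0.03)
        assert bd["density"] == pytest.approx(5 / 7, rel=0.03)
        assert bd["cell_area"] == 5 * L * L

    def test_zero_perimeter_raises(self):
        with pytest.raises(ValueError):
            perimeter_length(np.zeros((10, 10)))


class TestProfileCell:
    def test_convex_shape_density_and_roughness_near_one(self):
        pair = BinaryCellPair.from_filled(rasterized_disk(60))
        prof = profile_cell(pair)
        assert 0.95 <= prof.density <= 1.0
        assert 0.97 <= prof.roughness <= 1.05

    def test_disk_circle_identities(self):
        prof = profile_cell(BinaryCellPair.from_filled(rasterized_disk(80)))
        assert prof.max_span == pytest.approx(prof.bounding_circle_diameter, rel=0.01)
        assert prof.max_span == pytest.approx(2 * prof.mean_radius, rel=0.02)

    def test_profile_invariants(self):
        for preset, seed in ((RAMIFIED_PRESET, 1), (AMEBOID_PRESET, 2)):
            p = profile_cell(generate_cell(preset, seed=seed))
            assert 0 < p.density <= 1.0
            assert p.cell_area <= p.hull_area
            assert p.max_span <= p.bounding_circle_diameter * 1.0 + 1e-6
            assert 0.9 <= p.fractal_dimension <= 2.1
            assert 0 < p.cell_circularity <= 1.05

    def test_ameboid_vs_ramified_fixed_seeds(self):
        ram = profile_cell(generate_cell(RAMIFIED_PRESET, seed=7))
        amo = profile_cell(generate_cell(AMEBOID_PRESET, seed=7))
        assert amo.cell_perimeter < ram.cell_perimeter
        assert amo.density > ram.density


class TestInvariances:
    def test_scale_covariance_on_resolved_shape(self):
        """Features well above the pixel scale: areas ×4, perimeters ×2."""
        pair = BinaryCellPair.from_filled(plus_pentomino(40))
        big = BinaryCellPair.from_filled(np.kron(pair.filled, np.ones((2, 2), bool)))
        p1, p2 = profile_cell(pair), profile_cell(big)
        assert p2.cell_area == pytest.approx(4 * p1.cell_area, rel=0.01)
        assert p2.hull_area == pytest.approx(4 * p1.hull_area, rel=0.03)
        assert p2.cell_perimeter == pytest.approx(2 * p1.cell_perimeter, rel=0.03)
        assert p2.hull_perimeter == pytest.approx(2 * p1.hull_perimeter, rel=0.03)
        for attr in ("density", "roughness", "cell_circularity"):
            assert getattr(p2, attr) == pytest.approx(getattr(p1, attr), abs=0.05)

    def test_scale_covariance_on_cell_areas(self):
        """Cells carry 2-px processes at the resolution limit, so only the
        pixel-count quantities are exactly covariant under upsampling."""
        pair = generate_cell(AMEBOID_PRESET, seed=4)
        big = BinaryCellPair.from_filled(np.kron(pair.filled, np.ones((2, 2), bool)))
        p1, p2 = profile_cell(pair), profile_cell(big)
        assert p2.cell_area == pytest.approx(4 * p1.cell_area, rel=0.01)
        assert p2.hull_area == pytest.approx(4 * p1.hull_area, rel=0.03)
        assert p2.density == pytest.approx(p1.density, abs=0.05)

    def test_quarter_turn_leaves_geometry_unchanged(self):
        pair = generate_cell(RAMIFIED_PRESET, seed=6)
        rot = BinaryCellPair.from_filled(np.rot90(pair.filled))
        p1, p2 = profile_cell(pair), profile_cell(rot)
        for attr in ("cell_area", "hull_area", "cell_perimeter", "hull_perimeter",
                     "max_span", "mean_radius", "density", "roughness",
                     "cell_circularity"):
            assert getattr(p2, attr) == pytest.approx(getattr(p1, attr), rel=1e-6)
        # box-count grid offsets do not rotate with the image: small slack
        assert p2.fractal_dimension == pytest.approx(p1.fractal_dimension, abs=0.03)
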