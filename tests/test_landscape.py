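import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecotrap.landscape import (Aridity, GridMap, MapFormatError, PhenologyCalendar,
                               ScenarioSpec, Species, compute_spatial_metrics,
                               generate_fixture_landscape, generate_scenario_map,
                               host_available, identify_patches,
                               nearest_periphery_distance, patch_shape_index,
                               read_map, write_map)

from conftest import make_map, uniform_map

N = Species.NONE
T = Species.THLASPI
C = Species.CARDAMINE
B = Species.BOECHERA


# ---------------------------------------------------------------------------
# map file I/O
# ---------------------------------------------------------------------------

class TestMapIO:
    def test_decode_small_grid(self, tmp_path):
        gmap = make_map([[N, T], [C, C]])
        path = tmp_path / "m.map"
        write_map(gmap, path)
        back = read_map(path)
        assert (back.host == gmap.host).all()
        assert int(back.thlaspi_mask.sum()) == 1
        assert int(back.mask(C).sum()) == 2

    def test_roundtrip_byte_identical(self, tmp_path):
        gmap = make_map([[N, T, C], [C, C, B]], aridity=Aridity.DRY)
        p1 = tmp_path / "a.map"
        p2 = tmp_path / "b.map"
        write_map(gmap, p1)
        write_map(read_map(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_generated_fixture_roundtrips(self, tmp_path):
        gmap = generate_fixture_landscape(100, 100, seed=1)
        path = tmp_path / "f.map"
        write_map(gmap, path)
        back = read_map(path)
        assert (back.host == gmap.host).all()
        assert (back.aridity == gmap.aridity).all()
        assert back.cell_size == gmap.cell_size

    @pytest.mark.parametrize("mutate, line_frag", [
        (lambda L: ["nrows 2"] + L[1:], "ncols"),               # bad header order
        (lambda L: L[:4] + ["[WRONG]"] + L[5:], "[HOST]"),      # bad marker
        (lambda L: L[:5] + ["0 9"] + L[6:], "unknown code"),    # bad species code
        (lambda L: L[:5] + ["0"] + L[6:], "expected 2"),        # short row
    ])
    def test_parse_errors_name_line(self, tmp_path, mutate, line_frag):
        gmap = make_map([[N, T], [C, C]])
        path = tmp_path / "m.map"
        write_map(gmap, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(mutate(lines)) + "\n")
        with pytest.raises(MapFormatError, match="line"):
            read_map(path)


# ---------------------------------------------------------------------------
# patches and geometry
# ---------------------------------------------------------------------------

class TestPatches:
    def test_singleton_patch(self):
        gmap = make_map([[N, N], [N, T]])
        patches = identify_patches(gmap, T)
        assert len(patches) == 1
        assert patches[0].area == pytest.approx(0.0625)
        assert patches[0].perimeter == pytest.approx(4 * 0.25)

    def test_diagonal_cells_are_two_patches(self):
        gmap = make_map([[T, N], [N, T]])
        assert len(identify_patches(gmap, T)) == 2

    def test_3x3_block_perimeter(self):
        gmap = make_map([[T] * 3] * 3)
        patches = identify_patches(gmap, T)
        assert len(patches) == 1
        assert patches[0].perimeter == pytest.approx(3.0)  # 12 edges * 0.25 m

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_patches_partition_species_cells(self, seed):
        rng = np.random.default_rng(seed)
        host = rng.choice([0, int(T), int(C)], size=(12, 12), p=[0.5, 0.3, 0.2])
        gmap = GridMap(host.astype(np.int8), np.zeros((12, 12), dtype=np.int8))
        patches = identify_patches(gmap, T)
        union = set()
        for p in patches:
            assert not (union & p.cells), "patches overlap"
            union |= p.cells
        expected = set(map(tuple, np.argwhere(gmap.host == int(T)).tolist()))
        assert union == expected


class TestShapeIndex:
    @pytest.mark.parametrize("k", [1, 2, 3, 5, 8])
    def test_square_blocks_have_unit_shape(self, k):
        gmap = make_map([[T] * k for _ in range(k)])
        (patch,) = identify_patches(gmap, T)
        assert patch_shape_index(patch) == pytest.approx(1.0)

    def test_row_of_four_cells(self):
        gmap = make_map([[T, T, T, T]])
        (patch,) = identify_patches(gmap, T)
        # 0.25 m x 1 m rectangle: 0.25 * 2.5 / sqrt(0.25)
        assert patch_shape_index(patch) == pytest.approx(1.25)

    def test_row_of_sixteen_cells(self):
        gmap = make_map([[T] * 16])
        (patch,) = identify_patches(gmap, T)
        assert patch_shape_index(patch) == pytest.approx(2.125)


def _shapely_patch_distance(a, b):
    """Independent continuous-geometry oracle for periphery distance."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    cs = 0.25
    pa = unary_union([box(c * cs, r * cs, (c + 1) * cs, (r + 1) * cs)
                      for r, c in a.cells])
    pb = unary_union([box(c * cs, r * cs, (c + 1) * cs, (r + 1) * cs)
                      for r, c in b.cells])
    return pa.distance(pb)


class TestPeripheryDistance:
    def test_cells_ten_apart_in_a_row(self):
        gmap = make_map([[T] + [N] * 9 + [T]])
        a, b = identify_patches(gmap, T)
        assert nearest_periphery_distance(a, b) == pytest.approx(9 * 0.25)

    def test_touching_patches_distance_zero(self):
        gmap = make_map([[T, C]])
        (a,) = identify_patches(gmap, T)
        (b,) = identify_patches(gmap, C)
        assert nearest_periphery_distance(a, b) == 0.0

    def test_diagonal_offset_matches_oracle(self):
        host = np.zeros((6, 6), dtype=np.int8)
        host[0, 0] = int(T)
        host[3, 4] = int(T)
        gmap = GridMap(host, np.zeros((6, 6), dtype=np.int8))
        a, b = identify_patches(gmap, T)
        d = nearest_periphery_distance(a, b)
        assert d == pytest.approx(_shapely_patch_distance(a, b), abs=1e-9)
        assert d == pytest.approx(math.hypot(0.5, 0.75))

    def test_same_patch_rejected(self):
        gmap = make_map([[T, T]])
        (a,) = identify_patches(gmap, T)
        with pytest.raises(ValueError):
            nearest_periphery_distance(a, a)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_oracle_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        host = (rng.random((15, 15)) < 0.12).astype(np.int8) * int(T)
        gmap = GridMap(host, np.zeros_like(host))
        patches = identify_patches(gmap, T)
        if len(patches) < 2:
            return
        a, b = patches[0], patches[-1]
        d_ab = nearest_periphery_distance(a, b)
        assert d_ab == pytest.approx(nearest_periphery_distance(b, a))
        assert d_ab == pytest.approx(_shapely_patch_distance(a, b), abs=1e-9)


# ---------------------------------------------------------------------------
# spatial metrics
# ---------------------------------------------------------------------------

class TestSpatialMetrics:
    def test_observed_cover_proportion(self):
        host = np.zeros((40, 25), dtype=np.int8)
        host.ravel()[:973] = int(C)
        host.ravel()[973:1000] = int(T)
        gmap = GridMap(host.reshape(40, 25), np.zeros((40, 25), dtype=np.int8))
        m = compute_spatial_metrics(gmap)
        assert m.cover == pytest.approx(0.027)

    def test_single_patch_thdist_missing(self):
        gmap = make_map([[C, N, T], [C, N, N]])
        m = compute_spatial_metrics(gmap)
        assert m.patchnum == 1
        assert math.isnan(m.thdist)

    def test_no_thlaspi(self):
        gmap = make_map([[C, C], [N, N]])
        m = compute_spatial_metrics(gmap)
        assert m.cover == 0.0
        assert m.patchnum == 0
        assert math.isnan(m.area)

    def test_three_patch_toy_map_hand_computed(self):
        # two thlaspi singletons 4 cells apart and one 2x2 block below,
        # one native singleton adjacent to the first thlaspi cell
        host = np.zeros((6, 8), dtype=np.int8)
        host[0, 1] = int(T)
        host[0, 6] = int(T)
        host[3:5, 1:3] = int(T)
        host[0, 0] = int(C)
        gmap = GridMap(host, np.zeros_like(host))
        m = compute_spatial_metrics(gmap)
        assert m.patchnum == 3
        assert m.cover == pytest.approx(6 / 7)
        assert m.area == pytest.approx((0.0625 + 0.0625 + 0.25) / 3)
        # shapes: singletons 1.0, the 2x2 block 1.0
        assert m.shape == pytest.approx(1.0)
        # native distances: touching (0), 5 cells gap -> 1.25 m, block:
        # (rows 3..4, col 1) vs (0,0): dr=2 -> 0.5, dc=0 -> 0 -> 0.5 m
        assert m.dist == pytest.approx((0.0 + 1.25 + 0.5) / 3)
        # thlaspi neighbour distances: a<->b 4 cells -> 1.0 m? (cols 1,6 ->
        # gap 4 cells = 1.0 m); a<->block 0.5 m; b<->block hypot(0.5, 0.75)
        d_ab = 1.0
        d_ablock = 0.5
        d_bblock = math.hypot(0.5, 3 * 0.25)
        expected = (min(d_ab, d_ablock) + min(d_ab, d_bblock) +
                    min(d_ablock, d_bblock)) / 3
        assert m.thdist == pytest.approx(expected)

    def test_hostless_map_rejected(self):
        gmap = make_map([[N, N]])
        with pytest.raises(ValueError):
            compute_spatial_metrics(gmap)


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------

class TestPhenology:
    def test_availability_schedule(self):
        cal = PhenologyCalendar()
        gmap = make_map([[B, T, C, N]])
        assert host_available(gmap, (0, 0), 10, cal)      # all in trimester 1
        assert not host_available(gmap, (0, 0), 19, cal)  # Boechera senesced
        assert not host_available(gmap, (0, 1), 50, cal)  # only Cardamine late
        assert host_available(gmap, (0, 2), 50, cal)
        assert not host_available(gmap, (0, 3), 5, cal)   # empty cell never

    def test_trimester_boundaries(self):
        cal = PhenologyCalendar()
        assert cal.trimester(1) == 1
        assert cal.trimester(18) == 1
        assert cal.trimester(19) == 2
        assert cal.trimester(36) == 2
        assert cal.trimester(37) == 3
        assert cal.trimester(54) == 3
        with pytest.raises(ValueError):
            cal.trimester(55)


# ---------------------------------------------------------------------------
# scenario generation
# ---------------------------------------------------------------------------

def _base_with_natives(seed=4):
    return generate_fixture_landscape(n_rows=80, n_cols=240, thlaspi_cover=0.0,
                                      seed=seed)


class TestScenarioGeneration:
    def test_scatter_singletons(self):
        base = _base_with_natives()
        native = int(base.native_mask.sum())
        k = 40
        cover = k / (native + k)
        out = generate_scenario_map(
            base, ScenarioSpec(mode="scatter", cover=cover, min_spacing=2),
            np.random.default_rng(0))
        m = compute_spatial_metrics(out)
        assert m.patchnum == k
        assert abs(int(out.thlaspi_mask.sum()) - k) <= 1

    def test_square_patch_unit_shape(self):
        base = _base_with_natives()
        native = int(base.native_mask.sum())
        cover = 400 / (native + 400)
        out = generate_scenario_map(
            base, ScenarioSpec(mode="squares", cover=cover, patch_count=1),
            np.random.default_rng(1))
        m = compute_spatial_metrics(out)
        assert m.patchnum == 1
        assert m.shape == pytest.approx(1.0)

    def test_elongated_patches_are_elongated(self):
        base = _base_with_natives()
        native = int(base.native_mask.sum())
        cover = 400 / (native + 400)
        out = generate_scenario_map(
            base, ScenarioSpec(mode="elongated", cover=cover, patch_count=2,
                               aspect=16.0),
            np.random.default_rng(2))
        m = compute_spatial_metrics(out)
        assert m.shape > 1.5

    def test_enlarge_merges_patches(self):
        host = np.zeros((20, 20), dtype=np.int8)
        host[10, 4] = int(T)
        host[10, 8] = int(T)
        host[0, 0] = int(C)
        gmap = GridMap(host, np.zeros_like(host))
        out = gmap
        seen_two = False
        # base cover is 2/3 (two thlaspi cells, one native cell)
        for cover in (0.75, 0.9, 0.99):
            out = generate_scenario_map(
                gmap, ScenarioSpec(mode="enlarge", cover=cover),
                np.random.default_rng(3))
            m = compute_spatial_metrics(out)
            if m.patchnum == 2:
                seen_two = True
        assert seen_two
        assert compute_spatial_metrics(out).patchnum == 1  # fully merged

    def test_enlarge_monotone_cover_and_patchnum(self):
        base = generate_fixture_landscape(n_rows=80, n_cols=240, seed=4)
        rng = np.random.default_rng(5)
        prev = compute_spatial_metrics(base)
        for cover in (0.08, 0.15, 0.25):
            out = generate_scenario_map(
                base, ScenarioSpec(mode="enlarge", cover=cover), rng)
            m = compute_spatial_metrics(out)
            assert m.cover >= prev.cover
            assert m.patchnum <= prev.patchnum
            prev = m

    def test_infeasible_cover_rejected(self):
        base = _base_with_natives()
        with pytest.raises(ValueError):
            generate_scenario_map(
                base, ScenarioSpec(mode="scatter", cover=0.99),
                np.random.default_rng(0))

    def test_placement_close_base_far_ordering(self):
        base = _base_with_natives()
        native = int(base.native_mask.sum())
        cover = 60 / (native + 60)
        dists = {}
        for placement in ("close", "base", "far"):
            out = generate_scenario_map(
                base, ScenarioSpec(mode="scatter", cover=cover,
                                   placement_natives=placement),
                np.random.default_rng(7))
            dists[placement] = compute_spatial_metrics(out).dist
        assert dists["close"] < dists["base"] < dists["far"]


class TestFixtureGenerator:
    def test_deterministic_under_seed(self):
        a = generate_fixture_landscape(60, 200, seed=1)
        b = generate_fixture_landscape(60, 200, seed=1)
        assert (a.host == b.host).all()
        assert (a.aridity == b.aridity).all()

    def test_host_fraction_achieved(self):
        gmap = generate_fixture_landscape(100, 320, host_fraction=0.08, seed=3)
        frac = gmap.host_mask.sum() / (100 * 320)
        assert abs(frac - 0.08) < 0.005

    def test_thlaspi_cover_achieved(self):
        gmap = generate_fixture_landscape(100, 320, thlaspi_cover=0.027, seed=3)
        m = compute_spatial_metrics(gmap)
        assert m.cover == pytest.approx(0.027, abs=0.002)

    def test_hostless_request_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture_landscape(50, 50, host_fraction=0.0, seed=0)
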