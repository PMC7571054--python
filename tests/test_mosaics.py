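"""Mosaic structures, border labeling and assembly, checked against
exhaustive brute-force oracles on small instances."""

import numpy as np
import pytest
from scipy import ndimage

from texsep.augment import AugmentConfig
from texsep.errors import ConfigurationError, InputError
from texsep.mosaics import (
    BorderMask,
    DatasetManifest,
    RegionLabelMap,
    assemble_mosaic,
    border_mask,
    build_dataset,
    circular_structure,
    generate_mosaic,
    random_walk_structure,
    voronoi_structure,
)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_voronoi(size, pts):
    H, W = size
    labels = np.empty((H, W), dtype=int)
    for r in range(H):
        for c in range(W):
            d2 = [(r - pr) ** 2 + (c - pc) ** 2 for pr, pc in pts]
            labels[r, c] = int(np.argmin(d2))  # lowest index wins ties
    return labels


def brute_force_border(labels, radius):
    H, W = labels.shape
    mask = np.zeros((H, W), dtype=np.uint8)
    for r in range(H):
        for c in range(W):
            window = labels[max(0, r - radius): r + radius + 1,
                            max(0, c - radius): c + radius + 1]
            mask[r, c] = len(np.unique(window)) >= 2
    return mask


# ---------------------------------------------------------------------------
# structure generators
# ---------------------------------------------------------------------------

class TestVoronoi:
    def test_two_centroids_split_columns(self, rng):
        # centroids in columns 0 and 7 of an 8x8 grid: nearest-centroid rule
        # splits the image down the middle
        lab = np.empty((8, 8), dtype=int)
        pts = [(0, 0), (0, 7)]
        lab = brute_force_voronoi((8, 8), pts)
        assert np.array_equal(lab[:, :4], np.zeros((8, 4), dtype=int))
        assert np.array_equal(lab[:, 4:], np.ones((8, 4), dtype=int))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        s = voronoi_structure((16, 16), 3, rng)
        # recover the centroids by regenerating with the same stream
        rng2 = np.random.default_rng(7)
        pts = np.stack([rng2.integers(0, 16, size=3), rng2.integers(0, 16, size=3)], axis=1)
        assert np.array_equal(s.labels, brute_force_voronoi((16, 16), [tuple(p) for p in pts]))

    @pytest.mark.parametrize("n_centroids", [2, 5, 10])
    def test_all_labels_occur(self, n_centroids):
        s = voronoi_structure((32, 32), n_centroids, np.random.default_rng(n_centroids))
        assert s.n_regions == n_centroids
        assert len(np.unique(s.labels)) == n_centroids

    @pytest.mark.parametrize("bad", [1, 11])
    def test_centroid_count_range(self, bad, rng):
        with pytest.raises(ConfigurationError):
            voronoi_structure((32, 32), bad, rng)


class TestRandomWalk:
    def test_zero_jitter_single_walk_is_straight_split(self):
        # with jitter pinned to 0 the walk is a straight vertical line
        for seed in range(5):
            s = random_walk_structure((16, 16), np.random.default_rng(seed),
                                      mode="single", jitter=(0,))
            cols = [np.unique(s.labels[:, c]) for c in range(16)]
            assert all(len(u) == 1 for u in cols)  # columns uniform
            assert s.n_regions == 2
            boundary = np.flatnonzero(np.diff(s.labels[0]))
            assert len(boundary) == 1

    def test_two_walk_partition_matches_replayed_paths(self):
        # oracle: replay the RNG stream to recover both walks, rebuild the
        # side-of-path indicators pixel by pixel, and compare partitions
        H = W = 24
        for seed in range(100):
            s = random_walk_structure((H, W), np.random.default_rng(seed))
            assert 2 <= s.n_regions <= 4
            rng = np.random.default_rng(seed)
            col_path = np.clip(
                np.concatenate([[c0 := rng.integers(0, W)],
                                c0 + np.cumsum(rng.integers(0, 3, size=H - 1) - 1)]),
                0, W - 1)
            if rng.integers(2):
                col_path = col_path[::-1]
            row_path = np.clip(
                np.concatenate([[r0 := rng.integers(0, H)],
                                r0 + np.cumsum(rng.integers(0, 3, size=W - 1) - 1)]),
                0, H - 1)
            if rng.integers(2):
                row_path = row_path[::-1]
            combo = np.empty((H, W), dtype=int)
            for r in range(H):
                for c in range(W):
                    combo[r, c] = 2 * (c >= col_path[r]) + (r >= row_path[c])
            # walks are monotone with unit lateral steps and span the image
            assert np.all(np.abs(np.diff(col_path)) <= 1)
            assert np.all(np.abs(np.diff(row_path)) <= 1)
            _, expected = np.unique(combo, return_inverse=True)
            assert np.array_equal(s.labels.ravel(), expected.ravel())

    def test_paths_cross_whole_image(self):
        # every row (and, in two-walk mode, every column) meets a region change
        # or the walk hugged an edge; either way labels partition the image
        s = random_walk_structure((32, 32), np.random.default_rng(3))
        assert s.labels.shape == (32, 32)
        assert set(np.unique(s.labels)) == set(range(s.n_regions))


class TestCircular:
    def test_membership_matches_brute_force(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = circular_structure((24, 24), rng)
            # replay the accepted draw to recover the circle parameters
            rng2 = np.random.default_rng(seed)
            lab = None
            while True:
                k = int(rng2.integers(1, 5))
                cand = np.zeros((24, 24), dtype=int)
                circles = []
                for i in range(k):
                    cy, cx = rng2.uniform(0, 24), rng2.uniform(0, 24)
                    r = rng2.uniform(3.0, 8.0)
                    circles.append((cy, cx, r))
                    for rr in range(24):
                        for cc in range(24):
                            if (rr - cy) ** 2 + (cc - cx) ** 2 <= r * r:
                                cand[rr, cc] = i + 1
                if len(np.unique(cand)) == k + 1:
                    lab = cand
                    break
            assert np.array_equal(s.labels, lab)

    def test_region_count_bounds(self):
        counts = [circular_structure((32, 32), np.random.default_rng(s)).n_regions
                  for s in range(50)]
        assert all(2 <= n <= 5 for n in counts)

    def test_single_forced_circle(self):
        # a lone circle yields exactly two regions: disk and background
        found = [circular_structure((32, 32), np.random.default_rng(s))
                 for s in range(30)]
        assert any(s.n_regions == 2 for s in found)


class TestStructureInvariants:
    @pytest.mark.parametrize("maker", [
        lambda rng: voronoi_structure((32, 32), int(rng.integers(2, 11)), rng),
        lambda rng: random_walk_structure((32, 32), rng),
        lambda rng: circular_structure((32, 32), rng),
    ], ids=["voronoi", "random_walk", "circular"])
    def test_labels_partition_image(self, maker):
        for seed in range(10):
            s = maker(np.random.default_rng(seed))
            present = np.unique(s.labels)
            assert present.min() == 0 and present.max() == s.n_regions - 1
            assert len(present) == s.n_regions


# ---------------------------------------------------------------------------
# border labeling
# ---------------------------------------------------------------------------

class TestBorderMask:
    def test_single_region_gives_empty_mask(self):
        s = RegionLabelMap(labels=np.zeros((16, 16), dtype=int), n_regions=1)
        assert border_mask(s).mask.sum() == 0

    def test_vertical_split_band_columns(self):
        lab = np.zeros((8, 8), dtype=int)
        lab[:, 4:] = 1
        m = border_mask(RegionLabelMap(labels=lab, n_regions=2), border_radius=2)
        expected = np.zeros((8, 8), dtype=np.uint8)
        expected[:, 2:6] = 1
        assert np.array_equal(m.mask, expected)

    def test_matches_window_scan_oracle(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            s = voronoi_structure((20, 20), int(rng.integers(2, 6)), rng)
            for radius in (1, 2, 3):
                m = border_mask(s, border_radius=radius)
                assert np.array_equal(m.mask, brute_force_border(s.labels, radius))

    def test_straight_boundary_band_wider_than_two(self):
        lab = np.zeros((32, 32), dtype=int)
        lab[:, 16:] = 1
        m = border_mask(RegionLabelMap(labels=lab, n_regions=2))
        widths = m.mask.sum(axis=1)
        assert (widths > 2).all()

    def test_invariant_under_label_permutation(self, rng):
        s = voronoi_structure((24, 24), 4, rng)
        perm = np.array([2, 0, 3, 1])
        permuted = RegionLabelMap(labels=perm[s.labels], n_regions=4)
        assert np.array_equal(border_mask(s).mask, border_mask(permuted).mask)

    def test_interior_components_stay_in_one_region(self, rng):
        # zeroing the border band must leave connected components that never
        # straddle two regions
        s = voronoi_structure((48, 48), 6, rng)
        m = border_mask(s)
        interior = ~m.mask.astype(bool)
        cc, n_cc = ndimage.label(interior)
        for i in range(1, n_cc + 1):
            assert len(np.unique(s.labels[cc == i])) == 1


# ---------------------------------------------------------------------------
# assembly and dataset building
# ---------------------------------------------------------------------------

class TestAssembly:
    def test_piecewise_constant_from_constant_textures(self, two_color_library, rng):
        lab = np.zeros((64, 64), dtype=int)
        lab[:, 32:] = 1
        s = RegionLabelMap(labels=lab, n_regions=2)
        sample = assemble_mosaic(s, two_color_library, rng=rng)
        for region in range(2):
            sel = sample.image[s.labels == region]
            assert np.all(sel == sel[0])

    def test_fixed_seed_bit_identical(self, procedural_library):
        a = generate_mosaic(procedural_library, (64, 64), seed=11)
        b = generate_mosaic(procedural_library, (64, 64), seed=11)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.target.mask, b.target.mask)
        assert a.texture_ids == b.texture_ids

    def test_undersized_texture_rejected(self, two_color_library, rng):
        lab = np.zeros((128, 128), dtype=int)
        lab[:, 64:] = 1
        s = RegionLabelMap(labels=lab, n_regions=2)
        with pytest.raises(InputError, match="texture"):
            assemble_mosaic(s, two_color_library, rng=rng)  # textures are 64x64

    def test_region_interiors_independent(self, two_color_library):
        # changing which texture fills region 1 must not change region 0 pixels
        lab = np.zeros((64, 64), dtype=int)
        lab[:, 32:] = 1
        s = RegionLabelMap(labels=lab, n_regions=2)
        a = assemble_mosaic(s, two_color_library, rng=np.random.default_rng(0))
        b = next(
            m for m in (
                assemble_mosaic(s, two_color_library, rng=np.random.default_rng(k))
                for k in range(1, 50)
            )
            if m.texture_ids[0] == a.texture_ids[0]
            and m.texture_ids[1] != a.texture_ids[1]
        )
        sel = s.labels == 0
        assert np.array_equal(a.image[sel], b.image[sel])


class TestBuildDataset:
    def test_files_and_manifest(self, two_color_library, tmp_path):
        manifest = build_dataset(10, two_color_library, tmp_path, rng=0, size=(32, 32))
        assert len(manifest) == 10
        for e in manifest.entries:
            assert (tmp_path / e["image"]).exists()
            assert (tmp_path / e["mask"]).exists()
        reloaded = DatasetManifest.load(tmp_path / "manifest.jsonl")
        assert reloaded.entries == manifest.entries

    def test_structure_type_frequencies_uniform(self, two_color_library, tmp_path):
        manifest = build_dataset(300, two_color_library, tmp_path, rng=5, size=(32, 32))
        types = [e["structure_type"] for e in manifest.entries]
        se = np.sqrt((1 / 3) * (2 / 3) / 300)
        for t in ("voronoi", "random_walk", "circular"):
            assert abs(types.count(t) / 300 - 1 / 3) < 4 * se

    def test_masks_obey_border_invariants(self, two_color_library, tmp_path):
        import imageio.v3 as iio

        manifest = build_dataset(5, two_color_library, tmp_path, rng=2, size=(32, 32))
        for e in manifest.entries:
            mask = np.asarray(iio.imread(tmp_path / e["mask"]))
            assert set(np.unique(mask)) <= {0, 255}
            # regenerating the sample from its recorded seed reproduces the mask
            sample = generate_mosaic(two_color_library, (32, 32), e["seed"])
            assert sample.structure_type == e["structure_type"]
            assert np.array_equal(sample.target.mask, (mask > 127).astype(np.uint8))

    def test_seeds_unique(self, two_color_library, tmp_path):
        manifest = build_dataset(50, two_color_library, tmp_path, rng=1, size=(32, 32))
        seeds = [e["seed"] for e in manifest.entries]
        assert len(set(seeds)) == len(seeds)
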