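import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voxwalk as vw
from voxwalk.engine import (
    EmptyAnnotationError,
    Seed,
    WalkConfig,
    assign_labels,
    classify_interior,
    compute_sigma,
    expected_total_hits,
    extract_seeds,
    run_blocks,
    run_walks,
    step_probabilities,
)
from voxwalk.volumes import IntensityVolume, LabelVolume


def _uniform(shape, value=100):
    return IntensityVolume(np.full(shape, value, dtype=np.uint8),
                           dtype_class="uint8")


class TestExtractSeeds:
    def test_z_planes_enumerated(self):
        img = _uniform((6, 4, 4))
        lab = np.zeros((6, 4, 4), dtype=np.int32)
        lab[0, 1, 1] = 1
        lab[0, 2, 2] = 2
        lab[4, 3, 0] = 1
        ss = extract_seeds(LabelVolume(lab), img)
        assert ss.annotated_planes["z"] == [0, 4]
        assert len(ss) == 3

    def test_singleton_seed(self):
        img = _uniform((5, 5, 6))
        lab = np.zeros((5, 5, 6), dtype=np.int32)
        lab[2, 3, 4] = 7
        ss = extract_seeds(LabelVolume(lab), img)
        assert len(ss) == 1
        s = ss.seeds[0]
        assert s.position == (2, 3, 4) and s.label == 7 and s.axis == "z"

    def test_multi_axis_seeding_tags_axes(self):
        img = _uniform((6, 6, 6))
        lab = np.zeros((6, 6, 6), dtype=np.int32)
        lab[2, :, :] = 1          # a z-plane
        lab[:, 3, :] = 2          # a y-plane
        ss = extract_seeds(LabelVolume(lab), img, axes=("z", "y"))
        # the y-plane annotation touches every z-plane and vice versa
        assert ss.annotated_planes["z"] == list(range(6))
        assert ss.annotated_planes["y"] == list(range(6))
        codes = set(np.unique(ss.axis_codes).tolist())
        assert codes == {0, 1}
        # every annotated voxel yields one seed per requested axis
        n_voxels = np.count_nonzero(lab)
        assert len(ss) == 2 * n_voxels
        both = (ss.positions[:, 0] == 2) & (ss.positions[:, 1] == 3)
        assert both.sum() == 2 * 6  # the intersection line, once per axis

    def test_empty_annotation_rejected(self):
        img = _uniform((4, 4, 4))
        with pytest.raises(EmptyAnnotationError):
            extract_seeds(LabelVolume(np.zeros((4, 4, 4), dtype=np.int32)), img)


class TestComputeSigma:
    def test_constant_neighborhood_clamps_to_sigma_min(self):
        img = _uniform((3, 5, 5))
        assert compute_sigma(img, (1, 2, 2), window=3) == 1.0

    def test_hand_evaluated_rms_deviation(self):
        # 1x3 in-plane neighborhood {10, 10, 13} around center value 10
        arr = np.full((2, 1, 3), 10, dtype=np.uint8)
        arr[0, 0, 2] = 13
        img = IntensityVolume(arr, dtype_class="uint8")
        sig = compute_sigma(img, (0, 0, 1), window=3)
        assert sig == pytest.approx(np.sqrt(3.0))

    def test_window_larger_than_plane_clips(self):
        arr = np.arange(2 * 3 * 3, dtype=np.uint8).reshape(2, 3, 3)
        img = IntensityVolume(arr, dtype_class="uint8")
        sig = compute_sigma(img, (0, 1, 1), window=99)
        win = arr[0].astype(float)
        expected = np.sqrt(np.mean((win - arr[0, 1, 1]) ** 2))
        assert sig == pytest.approx(max(expected, 1.0))


class TestStepProbabilities:
    def test_uniform_interior_is_one_sixth(self, uniform_volume):
        seed = Seed((4, 4, 4), 1, "z", False, sigma=1.0, intensity=100.0)
        p = step_probabilities(uniform_volume, seed, (4, 4, 4))
        assert np.allclose(p, 1 / 6)

    def test_equal_intensity_neighbor_weight_is_one(self):
        arr = np.zeros((3, 3, 3), dtype=np.uint8)
        arr[1, 1, 1] = 50
        arr[0, 1, 1] = 50  # matches the seed intensity exactly
        img = IntensityVolume(arr, dtype_class="uint8")
        seed = Seed((1, 1, 1), 1, "z", False, sigma=1.0, intensity=50.0)
        p = step_probabilities(img, seed, (1, 1, 1))
        # exp(0) = 1 for the matching neighbor; all others exp(-1250)
        assert p[0] == pytest.approx(1.0)

    def test_corner_voxel_renormalizes_over_valid(self, uniform_volume):
        seed = Seed((0, 0, 0), 1, "z", False, sigma=1.0, intensity=100.0)
        p = step_probabilities(uniform_volume, seed, (0, 0, 0))
        # only +z, +y, +x remain
        assert np.allclose(p[[1, 3, 5]], 1 / 3)
        assert np.allclose(p[[0, 2, 4]], 0.0)

    def test_degenerate_volume_rejected(self):
        img = _uniform((1, 1, 1))
        seed = Seed((0, 0, 0), 1, "z", False, sigma=1.0, intensity=100.0)
        with pytest.raises(ValueError):
            step_probabilities(img, seed, (0, 0, 0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_probabilities_sum_to_one(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        arr = rng.integers(0, 256, size=(4, 4, 4)).astype(np.uint8)
        img = IntensityVolume(arr, dtype_class="uint8")
        pos = tuple(int(v) for v in rng.integers(0, 4, size=3))
        seed = Seed(pos, 1, "z", False,
                    sigma=float(rng.uniform(1, 30)),
                    intensity=float(arr[pos]))
        p = step_probabilities(img, seed, pos)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0) and np.all(p <= 1)


class TestClassifyInterior:
    def test_single_label_plane_is_interior(self):
        img = _uniform((3, 40, 40))
        lab = np.zeros((3, 40, 40), dtype=np.int32)
        lab[1, 10:20, 10:20] = 1
        lv = LabelVolume(lab)
        ss = classify_interior(extract_seeds(lv, img), lv, window=101)
        assert ss.interior.all()

    def test_competing_label_within_window_makes_edge(self):
        img = _uniform((3, 10, 200))
        lab = np.zeros((3, 10, 200), dtype=np.int32)
        lab[1, 5, 10] = 1
        lab[1, 5, 40] = 2    # 30 px away: inside the 101-wide window
        lab[1, 5, 180] = 3   # 140 px away from both: interior
        lv = LabelVolume(lab)
        ss = classify_interior(extract_seeds(lv, img), lv, window=101)
        by_label = {int(l): bool(i) for l, i in zip(ss.labels, ss.interior)}
        assert by_label == {1: False, 2: False, 3: True}

    def test_background_does_not_break_interiority(self):
        img = _uniform((3, 60, 60))
        lab = np.zeros((3, 60, 60), dtype=np.int32)
        lab[1, 30, 30] = 4  # alone in a sea of zeros
        lv = LabelVolume(lab)
        ss = classify_interior(extract_seeds(lv, img), lv, window=101)
        assert ss.interior.all()


class TestRunWalks:
    def test_no_steps_single_hit_at_seed(self, uniform_volume, single_seed_set):
        ss = single_seed_set(uniform_volume, (4, 4, 4))
        cfg = WalkConfig(norw=1, sorw=0, adaptive=False)
        hits = run_walks(uniform_volume, ss, cfg)
        assert hits.total_hits() == 1
        assert hits.counts[0, 4, 4, 4] == 1

    def test_hit_conservation_exact(self, small_phantom):
        img, _, sparse = small_phantom
        ss = extract_seeds(sparse, img)
        cfg = WalkConfig(norw=3, sorw=50, adaptive=False, rng_seed=5)
        hits = run_walks(img, ss, cfg)
        assert hits.total_hits() == expected_total_hits(ss, cfg)

    def test_bitwise_determinism(self, small_phantom):
        img, _, sparse = small_phantom
        ss = extract_seeds(sparse, img)
        cfg = WalkConfig(norw=2, sorw=40, rng_seed=9, adaptive=False)
        h1 = run_walks(img, ss, cfg)
        h2 = run_walks(img, ss, cfg)
        assert np.array_equal(h1.counts, h2.counts)

    def test_label_zero_seed_rejected(self, uniform_volume, single_seed_set):
        ss = single_seed_set(uniform_volume, (4, 4, 4), label=0)
        with pytest.raises(ValueError):
            run_walks(uniform_volume, ss, WalkConfig(norw=1, sorw=1))

    def test_line_volume_majority_switches_at_midpoint(self):
        n = 21
        img = IntensityVolume(np.full((1, 1, n), 50, dtype=np.uint8),
                              dtype_class="uint8")
        lab = np.zeros((1, 1, n), dtype=np.int32)
        lab[0, 0, 0] = 1
        lab[0, 0, n - 1] = 2
        ss = extract_seeds(LabelVolume(lab), img, axes=("x",))
        cfg = WalkConfig(norw=400, sorw=60, adaptive=False, rng_seed=3)
        hits = run_walks(img, ss, cfg)
        out = assign_labels(hits).data[0, 0]
        # unbiased walks from both ends: majority flips near the middle
        mid = n // 2
        assert np.all(out[: mid - 2] == 1)
        assert np.all(out[mid + 3:] == 2)
        # symmetry of the hit profile under end swap, within MC tolerance
        prof1 = hits.counts[0, 0, 0].astype(float)
        prof2 = hits.counts[1, 0, 0][::-1].astype(float)
        denom = prof1 + prof2
        mask = denom > 200
        assert np.all(np.abs(prof1 - prof2)[mask] / denom[mask] < 0.2)

    def test_adaptive_reduces_walks_for_interior_seeds(self):
        img = _uniform((3, 30, 30))
        lab = np.zeros((3, 30, 30), dtype=np.int32)
        lab[1, 10:20, 10:20] = 1
        lv = LabelVolume(lab)
        ss = classify_interior(extract_seeds(lv, img), lv)
        cfg = WalkConfig(norw=6, sorw=10, adaptive=True, interior_norw=2)
        hits = run_walks(img, ss, cfg)
        assert hits.total_hits() == len(ss) * 2 * 11  # all interior


@pytest.fixture(scope="module")
def block_setup(small_phantom):
    img, _, sparse = small_phantom
    ss = extract_seeds(sparse, img)
    return img, ss


class TestRunBlocks:
    def test_single_block_equals_run_walks(self, block_setup):
        img, ss = block_setup
        cfg = WalkConfig(norw=2, sorw=30, rng_seed=4, adaptive=False, n_blocks=1)
        assert np.array_equal(run_blocks(img, ss, cfg).counts,
                              run_walks(img, ss, cfg).counts)

    def test_full_ghost_overlap_is_exact(self, block_setup):
        img, ss = block_setup
        cfg = WalkConfig(norw=2, sorw=30, rng_seed=4, adaptive=False,
                         n_blocks=2, ghost=img.shape[0])
        assert np.array_equal(run_blocks(img, ss, cfg).counts,
                              run_walks(img, ss, cfg).counts)

    def test_partial_ghost_agrees_closely(self, small_phantom):
        img, dense, sparse = small_phantom
        ss = extract_seeds(sparse, img)
        single = WalkConfig(norw=3, sorw=150, rng_seed=4, adaptive=False)
        blocked = WalkConfig(norw=3, sorw=150, rng_seed=4, adaptive=False,
                             n_blocks=2, ghost=20)
        lv_single = assign_labels(run_walks(img, ss, single))
        lv_blocks = assign_labels(run_blocks(img, ss, blocked))
        assert vw.dice(lv_single, lv_blocks) >= 0.99

    def test_negative_ghost_rejected(self):
        with pytest.raises(ValueError):
            WalkConfig(ghost=-1)


class TestAssignLabels:
    def _field(self, c1, c2):
        counts = np.zeros((2, 1, 1, 1), dtype=np.int64)
        counts[0, 0, 0, 0] = c1
        counts[1, 0, 0, 0] = c2
        return vw.HitField(counts=counts, label_ids=(1, 2))

    def test_argmax_wins(self):
        assert assign_labels(self._field(5, 3)).data[0, 0, 0] == 1
        assert assign_labels(self._field(3, 5)).data[0, 0, 0] == 2

    def test_never_hit_is_background(self):
        assert assign_labels(self._field(0, 0)).data[0, 0, 0] == 0

    def test_tie_breaks_to_smallest_label(self):
        assert assign_labels(self._field(4, 4)).data[0, 0, 0] == 1


def test_dice_monotone_in_contrast():
    """More contrast between objects and background never hurts recovery."""
    scores = []
    for contrast in (10, 40, 80):
        img, dense = vw.two_object_phantom(contrast=contrast, noise_sd=8,
                                           rng_seed=2, shape=(48, 32, 32))
        sparse = vw.sparsify_labels(dense, every_k=8)
        cfg = WalkConfig(norw=4, sorw=600, rng_seed=12)
        res = vw.interpolate(img, sparse, cfg=cfg)
        scores.append(vw.dice(res["labels"], dense))
    assert scores[1] >= scores[0] - 0.02
    assert scores[2] >= scores[1] - 0.02
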