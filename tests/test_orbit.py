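import itertools

import numpy as np
import pytest

import orbitlakes as ol
from orbitlakes.orbit import OrbitConfig, PixelOrdering, _level_costs

from conftest import correct_extracted_lake, crop_like


def random_instance(rng, max_n=8, max_t=4):
    n = int(rng.integers(1, max_n + 1))
    t = int(rng.integers(1, max_t + 1))
    obs = rng.integers(0, 3, size=(t, n)).astype(np.uint8)
    ordering = PixelOrdering.from_order(rng.permutation(n))
    return obs, ordering


def brute_force_cost(obs, ordering, config):
    t, n = obs.shape
    return min(
        ol.objective(obs, ordering, np.array(ks), config)
        for ks in itertools.product(range(n + 1), repeat=t)
    )


class TestObjective:
    def test_perfect_agreement_costs_zero(self):
        obs = np.array([[1, 1, 0], [1, 0, 0]], dtype=np.uint8)
        ordering = PixelOrdering.from_order(np.array([0, 1, 2]))
        cfg = OrbitConfig(lam=0.0)
        assert ol.objective(obs, ordering, np.array([2, 1]), cfg) == 0.0

    def test_overruled_water_costs_three_by_default(self):
        obs = np.array([[1]], dtype=np.uint8)
        ordering = PixelOrdering.from_order(np.array([0]))
        assert ol.objective(obs, ordering, np.array([0]), OrbitConfig(lam=0.0)) == 3.0

    def test_overruled_land_costs_one(self):
        obs = np.array([[0]], dtype=np.uint8)
        ordering = PixelOrdering.from_order(np.array([0]))
        assert ol.objective(obs, ordering, np.array([1]), OrbitConfig(lam=0.0)) == 1.0

    def test_constant_levels_incur_no_temporal_cost(self):
        obs = np.full((4, 2), 2, dtype=np.uint8)  # all missing: data cost 0
        ordering = PixelOrdering.from_order(np.array([0, 1]))
        assert ol.objective(obs, ordering, np.array([1, 1, 1, 1]),
                            OrbitConfig(lam=5.0)) == 0.0
        assert ol.objective(obs, ordering, np.array([1, 2, 1, 2]),
                            OrbitConfig(lam=5.0)) == 15.0


class TestFitLevels:
    @pytest.mark.parametrize("lam", [0.0, 0.5])
    def test_matches_exhaustive_search_on_small_instances(self, lam):
        rng = np.random.default_rng(2024)
        cfg = OrbitConfig(lam=lam)
        for _ in range(40):
            obs, ordering = random_instance(rng)
            k = ol.fit_levels(obs, ordering, cfg)
            assert ol.objective(obs, ordering, k, cfg) == pytest.approx(
                brute_force_cost(obs, ordering, cfg))

    def test_recovers_truth_on_noise_free_prefix_stack(self, bowl_truth):
        tr = bowl_truth.true_stack
        obs = np.where(tr.reshape(tr.shape[0], -1), ol.WATER, ol.LAND).astype(np.uint8)
        true_rank = np.argsort(bowl_truth.bathymetry.ravel(), kind="stable")
        ordering = PixelOrdering.from_order(true_rank)
        k = ol.fit_levels(obs, ordering, OrbitConfig(lam=0.0))
        np.testing.assert_array_equal(k, tr.sum(axis=(1, 2)))

    def test_all_missing_frame_interpolates_between_neighbours(self):
        obs = np.array([[1, 1, 0, 0],
                        [2, 2, 2, 2],
                        [1, 1, 1, 1]], dtype=np.uint8)
        ordering = PixelOrdering.from_order(np.arange(4))
        k = ol.fit_levels(obs, ordering, OrbitConfig(lam=0.5))
        assert k[0] == 2 and k[2] == 4
        assert 2 <= k[1] <= 4
        # tie rule: smallest cost-equal level
        assert k[1] == 2

    def test_all_missing_frame_with_lam_zero_takes_level_zero(self):
        obs = np.full((1, 3), 2, dtype=np.uint8)
        k = ol.fit_levels(obs, PixelOrdering.from_order(np.arange(3)),
                          OrbitConfig(lam=0.0))
        assert k[0] == 0

    def test_level_costs_shape_and_endpoints(self):
        obs = np.array([[1, 0]], dtype=np.uint8)
        ordering = PixelOrdering.from_order(np.array([0, 1]))
        c = _level_costs(obs, ordering, OrbitConfig())
        # k=0: overrule the water obs (3); k=2: overrule the land obs (1)
        np.testing.assert_allclose(c[0], [3.0, 0.0, 1.0])


class TestUpdateOrdering:
    def test_sorts_by_true_wetness_on_complete_data(self, bowl_truth):
        tr = bowl_truth.true_stack.reshape(bowl_truth.true_stack.shape[0], -1)
        obs = np.where(tr, ol.WATER, ol.LAND).astype(np.uint8)
        cfg = OrbitConfig()
        ordering = ol.initial_ordering(obs, cfg)
        k = ol.fit_levels(obs, ordering, cfg)
        new = ol.update_ordering(obs, k, ordering, cfg)
        wet = obs == ol.WATER
        freq = wet.sum(axis=0)
        assert (np.diff(freq[new.order]) <= 0).all()

    def test_all_missing_leaves_ordering_unchanged(self):
        obs = np.full((3, 5), 2, dtype=np.uint8)
        cur = PixelOrdering.from_order(np.array([3, 1, 4, 0, 2]))
        new = ol.update_ordering(obs, np.zeros(3, dtype=int), cur, OrbitConfig(gamma=0.0))
        np.testing.assert_array_equal(new.order, cur.order)

    def test_more_frequent_water_ranks_wetter(self):
        obs = np.array([[1, 1], [0, 1]], dtype=np.uint8)
        cur = PixelOrdering.from_order(np.array([0, 1]))
        new = ol.update_ordering(obs, np.array([2, 1]), cur, OrbitConfig())
        assert new.order[0] == 1

    def test_idempotent_on_repeated_calls(self):
        rng = np.random.default_rng(0)
        obs = rng.integers(0, 3, size=(6, 10)).astype(np.uint8)
        cfg = OrbitConfig()
        ordering = ol.initial_ordering(obs, cfg)
        k = ol.fit_levels(obs, ordering, cfg)
        once = ol.update_ordering(obs, k, ordering, cfg)
        twice = ol.update_ordering(obs, k, once, cfg)
        np.testing.assert_array_equal(once.order, twice.order)


class TestCorrectStack:
    def test_identity_on_clean_stack(self, clean_stack, bowl_truth):
        corrected = ol.correct_stack(clean_stack, config=OrbitConfig())
        np.testing.assert_array_equal(corrected.binary, bowl_truth.true_stack)
        assert (corrected.metadata["pct_corrected"] == 0).all()
        assert (corrected.metadata["pct_imputed"] == 0).all()

    def test_prefix_property_and_nestedness(self, corrupted_bowl):
        stack, _ = corrupted_bowl
        _, _, corrected = correct_extracted_lake(stack)
        pix = np.nonzero(corrected.mask.ravel())[0]
        flat = corrected.binary.reshape(corrected.binary.shape[0], -1)
        assert not flat[:, np.setdiff1d(np.arange(flat.shape[1]), pix)].any()
        assigned = flat[:, pix]
        for t, k in enumerate(corrected.levels):
            expected = np.zeros(pix.size, dtype=bool)
            expected[corrected.ordering.order[:k]] = True
            np.testing.assert_array_equal(assigned[t], expected)
        areas = assigned.sum(axis=1)
        for a in range(len(areas)):
            for b in range(a + 1, len(areas)):
                inter = (assigned[a] & assigned[b]).sum()
                assert inter == min(areas[a], areas[b])

    def test_objective_not_worse_than_truth_anchored_solution(self):
        # tiny instances: coordinate descent must match or beat the solution
        # built from the true ordering
        rng = np.random.default_rng(7)
        cfg = OrbitConfig(lam=0.5)
        for _ in range(20):
            n, t = 6, 4
            true_order = rng.permutation(n)
            ordering = PixelOrdering.from_order(true_order)
            k_true = rng.integers(0, n + 1, size=t)
            truth_frames = ordering.rank[None, :] < k_true[:, None]
            obs = np.where(truth_frames, ol.WATER, ol.LAND).astype(np.uint8)
            flip = rng.random(obs.shape) < 0.1
            obs[flip] = 1 - obs[flip]
            stack = ol.TernaryStack(
                labels=obs.reshape(t, 1, n),
                timestamps=[(2000, i + 1) for i in range(t)],
            )
            corrected = ol.correct_stack(stack, config=cfg)
            anchor = ol.objective(obs, ordering, ol.fit_levels(obs, ordering, cfg), cfg)
            assert corrected.objective <= anchor + 1e-9

    def test_correction_beats_observation_against_truth(self, corrupted_bowl):
        stack, truth = corrupted_bowl
        rec, local, corrected = correct_extracted_lake(stack)
        tr = crop_like(truth.true_stack, rec, stack.shape)
        acc_obs = np.mean([ol.accuracy(tr[t].astype(int), local.labels[t])
                           for t in range(tr.shape[0])])
        acc_cor = np.mean([ol.accuracy(tr[t].astype(int), corrected.binary[t].astype(int))
                           for t in range(tr.shape[0])])
        assert acc_cor > acc_obs

    def test_metadata_percentages_recomputable(self, corrupted_bowl):
        stack, _ = corrupted_bowl
        _, local, corrected = correct_extracted_lake(stack)
        mask = corrected.mask
        n_mask = int(mask.sum())
        for t in (0, len(corrected.levels) // 2):
            obs = local.labels[t][mask]
            missing = (obs == ol.MISSING).sum()
            assert corrected.metadata.loc[t, "pct_imputed"] == pytest.approx(
                100 * missing / n_mask)
            observed = obs != ol.MISSING
            pred = corrected.binary[t][mask]
            flips = int((observed & (pred != (obs == ol.WATER))).sum())
            n_obs = int(observed.sum())
            expected = 100 * flips / n_obs if n_obs else 0.0
            assert corrected.metadata.loc[t, "pct_corrected"] == pytest.approx(expected)

    def test_raising_water_weight_never_shrinks_water(self):
        # comparative statics of the asymmetric penalty, checked empirically
        rng_seeds = [0, 1, 2]
        for seed in rng_seeds:
            cfg_gen = ol.SyntheticLakeConfig(shape=(25, 25), T=24, seed=seed)
            stack, _ = ol.generate(cfg_gen)
            counts = []
            for w in (1.0, 3.0, 6.0):
                corrected = ol.correct_stack(stack, config=OrbitConfig(w_water=w))
                counts.append(int(corrected.binary.sum()))
            assert counts[0] <= counts[1] <= counts[2]

    def test_degenerate_empty_stack_warns_not_raises(self, caplog):
        stack = ol.TernaryStack(labels=np.zeros((2, 3, 3), dtype=np.uint8),
                                timestamps=[(2000, 1), (2000, 2)])
        with caplog.at_level("WARNING"):
            corrected = ol.correct_stack(stack, mask=np.zeros((3, 3), bool))
        assert corrected.binary.shape == (2, 3, 3)
        assert not corrected.binary.any()


class TestExtractLakeStack:
    def make_scene(self, co_wet_frames):
        # 10-frame scene: a 3x3 reference lake, plus one candidate pixel at
        # (2, 5) that is water and touching the lake in `co_wet_frames` frames
        T = 10
        labels = np.zeros((T, 7, 8), dtype=np.uint8)
        labels[:, 1:4, 1:4] = ol.WATER
        for t in range(co_wet_frames):
            labels[t, 2, 4] = ol.WATER  # bridge
            labels[t, 2, 5] = ol.WATER  # candidate
        stack = ol.TernaryStack(labels=labels,
                                timestamps=[(2000, i + 1) for i in range(T)])
        mask = np.zeros((7, 8), bool)
        mask[1:4, 1:4] = True
        rec = LakeRecordStub(mask)
        return stack, rec

    def test_pixel_co_wet_five_times_is_retained(self):
        stack, rec = self.make_scene(5)
        _, mask = ol.extract_lake_stack(stack, rec, min_connected_count=5, padding=3)
        assert mask[2, 5]

    def test_pixel_co_wet_four_times_is_masked_out(self):
        stack, rec = self.make_scene(4)
        local, mask = ol.extract_lake_stack(stack, rec, min_connected_count=5, padding=3)
        assert not mask[2, 5]
        assert (local.labels[:, 2, 5] == ol.LAND).all()

    def test_disconnected_neighbour_lake_is_masked_out(self):
        T = 10
        labels = np.zeros((T, 7, 9), dtype=np.uint8)
        labels[:, 1:4, 1:4] = ol.WATER
        labels[:, 1:4, 6:9] = ol.WATER  # separate lake, never connected
        mask0 = np.zeros((7, 9), bool)
        mask0[1:4, 1:4] = True
        stack = ol.TernaryStack(labels=labels,
                                timestamps=[(2000, i + 1) for i in range(T)])
        local, mask = ol.extract_lake_stack(stack, LakeRecordStub(mask0),
                                            min_connected_count=5, padding=5)
        assert not mask[1:4, 6:9].any()
        assert (local.labels[:, 1:4, 6:9] == ol.LAND).all()


class LakeRecordStub:
    def __init__(self, mask):
        rows, cols = np.nonzero(mask)
        self.mask = mask
        self.bbox = (rows.min(), rows.max() + 1, cols.min(), cols.max() + 1)
        self.n_pixels = int(mask.sum())


class TestDownsample:
    def test_majority_rules(self):
        frame = np.zeros((10, 10), dtype=np.uint8)
        frame.ravel()[:49] = ol.WATER  # 49 water / 51 land
        stack = ol.TernaryStack(labels=frame[None], timestamps=[(2000, 1)])
        assert ol.downsample_stack(stack, 10).labels[0, 0, 0] == ol.LAND
        frame.ravel()[:51] = ol.WATER
        stack = ol.TernaryStack(labels=frame[None], timestamps=[(2000, 1)])
        assert ol.downsample_stack(stack, 10).labels[0, 0, 0] == ol.WATER

    def test_all_missing_block_stays_missing_and_area_scales(self):
        frame = np.full((10, 10), ol.MISSING, dtype=np.uint8)
        stack = ol.TernaryStack(labels=frame[None], timestamps=[(2000, 1)])
        out = ol.downsample_stack(stack, 10)
        assert out.labels[0, 0, 0] == ol.MISSING
        assert out.pixel_area_km2 == pytest.approx(0.0009 * 100)

    def test_non_divisible_shape_is_padded_with_missing(self):
        frame = np.full((12, 12), ol.WATER, dtype=np.uint8)
        stack = ol.TernaryStack(labels=frame[None], timestamps=[(2000, 1)])
        out = ol.downsample_stack(stack, 10)
        assert out.labels.shape == (1, 2, 2)
        # edge blocks contain real water cells, so they are classified
        assert out.labels[0, 1, 1] == ol.WATER
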