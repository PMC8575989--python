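"""Model-based readout: AUC against a brute-force pair-enumeration oracle,
embedding invariants, threshold regions, and the signed temporal overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perirf import (
    DecodingGrid,
    auc,
    detectability_map,
    discriminability_map,
    make_embeddings,
    temporal_overlap,
    threshold_region,
)
from perirf.decoder import DecodingMap, _frame_onsets


def brute_force_auc(on, off):
    """Independent oracle: enumerate all pairs, ties count one half."""
    wins = sum(1.0 for a in on for b in off if a > b)
    ties = sum(1.0 for a in on for b in off if a == b)
    return (wins + 0.5 * ties) / (len(on) * len(off))


class TestAUC:
    def test_complete_separation(self):
        assert auc([2, 3], [0, 1]) == 1.0

    def test_identical_multisets_are_chance(self):
        assert auc([1, 2, 2, 5], [1, 2, 2, 5]) == 0.5

    def test_matches_pair_enumeration_on_tied_example(self):
        on, off = [0, 1, 2, 3], [1, 2]
        expected = brute_force_auc(on, off)  # 3 wins, 2 ties, 3 losses
        assert expected == 0.5
        assert auc(on, off) == pytest.approx(expected)

    def test_matches_brute_force_on_random_instances(self):
        """200 random small instances with heavy ties."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n_on = int(rng.integers(1, 12))
            n_off = int(rng.integers(1, 12))
            on = rng.integers(0, 5, n_on).astype(float)
            off = rng.integers(0, 5, n_off).astype(float)
            assert auc(on, off) == pytest.approx(brute_force_auc(on, off))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        on=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
        off=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    )
    def test_equivariant_under_increasing_transforms(self, on, off):
        """AUC depends only on ranks: sigmoid vs linear drive agree (values
        kept coarse so the transform cannot create ties by rounding)."""
        f = lambda v: 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))
        assert auc(on, off) == pytest.approx(auc(f(on), f(off)))


class TestEmbeddings:
    def test_on_sequences_contain_target_at_probe_frame(self, planted_model,
                                                        small_grid):
        cfg = DecodingGrid(seed=0)
        onsets, on_c, off_c = make_embeddings(
            small_grid, small_grid.rf1_index, t_star=10.0, tau_star=50.0,
            cfg=cfg, seed=0,
        )
        frame = np.flatnonzero(onsets == 10 - 50)[0]
        assert np.all(on_c[:, frame] == small_grid.rf1_index)
        # strong reading: OFF sequences exclude the target everywhere
        assert np.all(off_c != small_grid.rf1_index)
        # fillers exclude the target (and by default both RF cells)
        mask = np.ones(on_c.shape[1], dtype=bool)
        mask[frame] = False
        assert np.all(on_c[:, mask] != small_grid.rf1_index)
        assert np.all(on_c[:, mask] != small_grid.rf2_index)

    def test_one_probe_per_frame_and_coverage(self):
        onsets = _frame_onsets(t_star=0.0, tau_star=55.0, embedding_ms=200)
        assert np.all(np.diff(onsets) == 7)
        assert onsets[-1] <= -1              # all probes precede the response
        assert onsets[0] >= -206             # and lie within the embedding
        assert np.any(onsets == -55)


@pytest.fixture(scope="module")
def fixation_cfg():
    return DecodingGrid(t_values=np.arange(-300.0, -199.0, 10.0), seed=0)


@pytest.fixture(scope="module")
def fixation_detect_map(planted_model, small_grid, fixation_cfg):
    return detectability_map(planted_model, small_grid.rf1_index, fixation_cfg)


class TestMaps:
    def test_fixation_detectability_peaks_at_planted_latency(
        self, fixation_detect_map, fixation_cfg
    ):
        profile = fixation_detect_map.auc.mean(axis=0)
        peaks = fixation_cfg.tau_values[profile == profile.max()]
        assert abs(peaks.mean() - 55.0) <= 10.0

    def test_stimulus_blind_model_stays_in_chance_band(self, quiet_model,
                                                       small_grid, fixation_cfg):
        dmap = detectability_map(quiet_model, small_grid.rf1_index, fixation_cfg)
        assert np.all(np.abs(dmap.auc - 0.5) <= 0.05)

    def test_map_deterministic_for_equal_seeds(self, planted_model, small_grid):
        cfg = DecodingGrid(t_values=np.array([-250.0]),
                           tau_values=np.array([50.0, 60.0]), seed=3)
        a = detectability_map(planted_model, small_grid.rf1_index, cfg)
        b = detectability_map(planted_model, small_grid.rf1_index, cfg)
        assert np.array_equal(a.auc, b.auc)

    def test_discriminability_requires_interior_center(self, planted_model,
                                                       small_grid):
        cfg = DecodingGrid(t_values=np.array([-250.0]),
                           tau_values=np.array([50.0]), seed=0)
        with pytest.raises(ValueError, match="edge"):
            discriminability_map(planted_model, small_grid.rf1_index, cfg)

    def test_symmetric_model_discriminability_is_chance(self, quiet_model,
                                                        small_grid):
        cfg = DecodingGrid(t_values=np.array([-250.0]),
                           tau_values=np.array([50.0]), seed=0)
        dmap = discriminability_map(quiet_model, small_grid.fp1_index, cfg)
        assert dmap.auc[0, 0] == pytest.approx(0.5)

    def test_discriminability_tracks_detectability_for_center_only_model(
        self, small_grid
    ):
        """A neuron sensitive only to the center probe discriminates it from
        neighbors about as well as it detects it."""
        from perirf import GroundTruthConfig, make_ground_truth_model

        grid = small_grid
        cfg_gt = GroundTruthConfig(late_gain=0.0, rf2_gain=0.0,
                                   history_weights=(0.0,) * 8)
        # RF1 at the interior cell so the 8-neighborhood exists
        center_grid = type(grid)(
            n_cols=3, n_rows=3, rf1_index=4, rf2_index=7, fp1_index=0,
            fp2_index=8,
        )
        model = make_ground_truth_model(cfg_gt, grid=center_grid)
        dcfg = DecodingGrid(t_values=np.array([-250.0]),
                            tau_values=np.array([50.0]), seed=0,
                            exclude_rf_fillers=False)
        det = detectability_map(model, 4, dcfg)
        dis = discriminability_map(model, 4, dcfg)
        assert abs(det.auc[0, 0] - dis.auc[0, 0]) < 0.1


class TestThresholdAndOverlap:
    def test_chance_map_has_empty_region(self):
        dmap = DecodingMap(probe=0, t_values=np.arange(3.0),
                           tau_values=np.arange(2.0),
                           auc=np.full((3, 2), 0.5))
        mask, proj = threshold_region(dmap, 0.61)
        assert not mask.any()
        assert not proj.any()

    def test_regions_nest_as_threshold_drops(self, fixation_detect_map):
        hi_mask, _ = threshold_region(fixation_detect_map, 0.61)
        lo_mask, _ = threshold_region(fixation_detect_map, 0.55)
        assert np.all(lo_mask | ~hi_mask)

    def test_single_cell_projection(self):
        aucs = np.full((4, 3), 0.5)
        aucs[2, 1] = 0.9
        dmap = DecodingMap(probe=0, t_values=np.array([0.0, 10, 20, 30]),
                           tau_values=np.array([30.0, 40, 50]), auc=aucs)
        _, proj = threshold_region(dmap, 0.61)
        assert np.array_equal(np.flatnonzero(proj), [2])

    @pytest.mark.parametrize(
        "r1,r2,expected",
        [((0, 50), (30, 80), 20.0),
         ((0, 50), (60, 80), -10.0),
         ((0, 50), (0, 50), 50.0)],
    )
    def test_signed_overlap_on_intervals(self, r1, r2, expected):
        assert temporal_overlap(r1, r2) == expected
        assert temporal_overlap(r2, r1) == expected  # symmetric

    def test_overlap_from_boolean_projections_uses_largest_run(self):
        t = np.arange(0.0, 100.0, 10.0)
        p1 = np.zeros(10, bool)
        p1[0:4] = True     # [0, 40) -> interval [0, 40]
        p1[8] = True       # speckle, ignored (largest run wins)
        p2 = np.zeros(10, bool)
        p2[2:6] = True     # interval [20, 60]
        assert temporal_overlap(p1, p2, t) == 20.0

    def test_empty_projection_flagged(self):
        t = np.arange(0.0, 50.0, 10.0)
        with pytest.raises(ValueError, match="empty"):
            temporal_overlap(np.zeros(5, bool), np.ones(5, bool), t)
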