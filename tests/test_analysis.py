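"""Perisaccadic analyses: RF estimation, prevalence/modulation arithmetic,
nulling semantics, shared sensitivity, relevance screening, and PMI."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perirf import (
    GroundTruthConfig,
    ProbeGrid,
    estimate_rf,
    find_integration_relevant,
    find_modulated,
    make_ground_truth_model,
    null_stus,
    pmi,
    predict_rate,
    reconstruct_kernels,
    shared_sensitivity,
    simulate_trials,
    spatial_sensitivity,
    stu_prevalence,
)
from perirf.analysis import PrevalenceMap, probe_aligned_response


class TestRFEstimation:
    def test_recovers_planted_rf_cells(self, planted_model, small_grid):
        trials = simulate_trials(planted_model, 300, seed=77)
        rf = estimate_rf(trials)
        assert rf.rf1_cell == small_grid.rf1_index
        assert rf.rf2_cell == small_grid.rf2_index

    def test_constant_rate_neuron_ties_to_lowest_cell(self, quiet_model):
        trials = simulate_trials(quiet_model, 40, seed=5)
        # make the tie exact: identical responses everywhere
        trials = trials.with_spikes(np.ones_like(trials.spikes))
        with pytest.warns(UserWarning, match="tie"):
            rf = estimate_rf(trials)
        assert rf.tied

    def test_smoothing_kernel_has_5ms_fwhm(self):
        from scipy.ndimage import gaussian_filter1d

        sigma = 5.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        impulse = np.zeros(201)
        impulse[100] = 1.0
        sm = gaussian_filter1d(impulse, sigma)
        above = np.flatnonzero(sm >= sm.max() / 2)
        assert abs((above[-1] - above[0]) - 5) <= 1  # grid resolution

    def test_probe_aligned_response_uses_fixation_epochs_only(self, planted_model):
        trials = simulate_trials(planted_model, 100, seed=8)
        pre = probe_aligned_response(trials, "pre")
        assert pre.shape == (trials.grid.n_cells, 201)
        with pytest.raises(ValueError):
            probe_aligned_response(trials, "during")


class TestPrevalence:
    def test_full_lattice_prevalence_is_one(self):
        pm = stu_prevalence(np.ones((30, 156), bool))
        assert np.all(pm.p == 1)
        assert np.all(pm.p1 == 1) and np.all(pm.p2 == 1)

    def test_empty_mask_all_zero(self):
        pm = stu_prevalence(np.zeros((30, 156), bool))
        assert not pm.p.any() and not pm.p1.any() and not pm.p2.any()

    def test_single_interior_stu_contributes_one_ninth(self):
        m = np.zeros((30, 156), bool)
        m[10, 80] = True
        pm = stu_prevalence(m)
        window = pm.p[9:12, 79:82]
        assert np.allclose(window, 1 / 9)
        assert pm.p[10, 83] == 0

    def test_edge_windows_renormalized(self):
        m = np.zeros((30, 156), bool)
        m[0, 0] = True
        pm = stu_prevalence(m)
        assert pm.p[0, 0] == pytest.approx(1 / 4)  # clipped 2x2 corner window


class TestModulationRule:
    @pytest.mark.parametrize(
        "p,p1,p2,h,expected",
        [
            (0.9, 0.1, 0.1, 0.3, True),    # sqrt(0.8 * 0.8) = 0.8 > 0.3
            (0.5, 0.5, 0.1, 0.3, False),   # sqrt(0 * 0.4) = 0
            (0.5, 0.5, 0.5, 0.0, False),   # statistic 0 fails any h > 0... and 0
        ],
    )
    def test_statistic_arithmetic(self, p, p1, p2, h, expected):
        stat = np.sqrt(abs(p - p1) * abs(p - p2))
        pm = PrevalenceMap(
            p=np.full((1, 1), p), p1=np.array([p1]), p2=np.array([p2])
        )
        assert pm.statistic()[0, 0] == pytest.approx(stat)
        assert (pm.statistic()[0, 0] > h) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        p=st.floats(0, 1), p1=st.floats(0, 1), p2=st.floats(0, 1),
    )
    def test_statistic_bounded_in_unit_interval(self, p, p1, p2):
        pm = PrevalenceMap(
            p=np.full((1, 1), p), p1=np.array([p1]), p2=np.array([p2])
        )
        assert 0.0 <= pm.statistic()[0, 0] <= 1.0

    def test_raising_threshold_shrinks_modulated_set(self, planted_model):
        lo = find_modulated(planted_model.selected, h=0.3)
        hi = find_modulated(planted_model.selected, h=0.7)
        assert hi.sum() <= lo.sum()
        assert np.all(lo | ~hi)

    def test_late_enhancement_cluster_is_flagged(self, planted_model, small_grid):
        mod = find_modulated(planted_model.selected, h=0.3)
        basis = planted_model.basis
        dc = np.array([basis.delay_center(i) for i in range(basis.n_delay)])
        tc = np.array([basis.time_center(j) for j in range(basis.n_time)])
        late = np.zeros_like(planted_model.selected)
        for c, i, j in np.argwhere(planted_model.selected):
            if c == small_grid.rf1_index and 75 <= dc[i] <= 130 and 0 <= tc[j] <= 100:
                late[c, i, j] = True
        assert late.sum() > 0
        assert np.all(mod[late])


class TestNulling:
    def test_empty_mask_is_identity(self, planted_model, small_grid):
        nulled = null_stus(planted_model, np.zeros_like(planted_model.selected))
        ev = [np.array([(-50, small_grid.rf1_index)],
                       dtype=[("t_on", "i4"), ("cell", "i4")])]
        assert np.array_equal(
            predict_rate(nulled, ev), predict_rate(planted_model, ev)
        )

    def test_zeroing_all_selected_makes_model_stimulus_blind(self, planted_model,
                                                             small_grid):
        nulled = null_stus(planted_model, planted_model.selected, mode="zero")
        ev_probe = [np.array([(-50, small_grid.rf1_index)],
                             dtype=[("t_on", "i4"), ("cell", "i4")])]
        ev_none = [np.empty(0, dtype=[("t_on", "i4"), ("cell", "i4")])]
        assert np.array_equal(
            predict_rate(nulled, ev_probe), predict_rate(nulled, ev_none)
        )

    def test_fixation_nulling_is_noop_when_weights_equal_fixation(self, small_grid):
        # constant-in-time RF1 kernel: perisaccadic weights equal fixation weights
        cfg = GroundTruthConfig(
            rf1_time_range=(-554.0, 545.0), late_gain=0.0, rf2_gain=0.0,
            history_weights=(0.0,) * 8,
        )
        model = make_ground_truth_model(cfg, grid=small_grid)
        basis = model.basis
        tc = np.array([basis.time_center(j) for j in range(basis.n_time)])
        mask = model.selected & (np.abs(tc) < 50)[None, None, :]
        nulled = null_stus(model, mask, mode="fixation")
        assert np.allclose(nulled.kappa, model.kappa)

    def test_unknown_mode_and_bad_mask_rejected(self, planted_model):
        with pytest.raises(ValueError, match="mode"):
            null_stus(planted_model, planted_model.selected, mode="swap")
        bad = np.zeros_like(planted_model.selected)
        bad[0, 0, 0] = True  # not a selected STU
        with pytest.raises(ValueError, match="outside the selected"):
            null_stus(planted_model, bad)

    def test_original_model_untouched(self, planted_model):
        before = planted_model.kappa.copy()
        null_stus(planted_model, planted_model.selected, mode="zero")
        assert np.array_equal(planted_model.kappa, before)


class TestSharedSensitivity:
    def test_constant_kernel_gives_constant_trace(self):
        from perirf.encoder import KernelMap

        interior = ProbeGrid(n_cols=3, n_rows=3, rf1_index=4, rf2_index=7,
                             fp1_index=0, fp2_index=8)
        t_values = np.arange(-100.0, 101.0)
        km = KernelMap(
            cells=np.arange(9), tau_grid=np.arange(1.0, 201.0),
            t_grid=t_values, values=np.full((9, 200, len(t_values)), 0.37),
        )
        h = spatial_sensitivity(km, 4, grid=interior, t_values=t_values)
        assert np.allclose(h, 0.37, atol=1e-12)

    def test_zero_kernels_zero_trace(self, quiet_model, small_grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = spatial_sensitivity(quiet_model, small_grid.rf1_index)
        assert not h.any()

    def test_matches_brute_force_double_sum(self, planted_model, small_grid):
        t_values = np.arange(-20.0, 20.0, 2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = spatial_sensitivity(planted_model, small_grid.rf1_index,
                                    t_values=t_values)
        cells = small_grid.neighborhood(small_grid.rf1_index)
        km = reconstruct_kernels(planted_model, cells=cells,
                                 tau=np.arange(1.0, 201.0), t=t_values)
        rng = np.random.default_rng(1)
        for a in rng.integers(0, len(t_values), 20):
            brute = sum(
                abs(km.values[c_idx, ti, a])
                for c_idx in range(len(cells))
                for ti in range(200)
            ) / (len(cells) * 200)
            assert h[a] == pytest.approx(brute, abs=1e-12)

    def test_shared_sensitivity_examples_and_symmetry(self):
        h1 = np.full(1001, 2.0)
        h2 = np.full(1001, 3.0)
        assert shared_sensitivity(h1, h2) == 2002.0
        assert shared_sensitivity(h2, h1) == 2002.0
        disjoint = np.zeros(1001)
        disjoint[:500] = 1.0
        other = np.zeros(1001)
        other[500:] = 1.0
        assert shared_sensitivity(disjoint, other) == 0.0
        with pytest.raises(ValueError):
            shared_sensitivity(np.zeros(5), np.zeros(6))


class TestIntegrationRelevance:
    def test_zero_weight_stus_never_relevant(self, planted_model):
        mod = find_modulated(planted_model.selected, h=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = find_integration_relevant(planted_model, mod)
        zero_weight = mod & (planted_model.kappa == 0)
        assert not res.integration_relevant[zero_weight].any()

    def test_single_bridge_stu_found_by_exhaustive_nulling(self, basis):
        """Construct a model whose only overlap between h1 and h2 comes from
        one STU; exactly that STU must be relevant (verified brute force)."""
        from perirf.encoder import SModel

        grid = ProbeGrid(n_cols=5, n_rows=1, rf1_index=1, rf2_index=3,
                         fp1_index=0, fp2_index=4)
        shape = (grid.n_cells, basis.n_delay, basis.n_time)
        kappa = np.zeros(shape)
        # RF1 sensitivity before saccade; RF2 after; one bridge STU at RF1
        # during the early post-saccadic window where RF2 is active
        j_pre = [j for j in range(156) if basis.time_center(j) < -100]
        j_post = [j for j in range(156) if basis.time_center(j) > 0]
        kappa[1, 8, j_pre] = 1.0
        kappa[3, 8, j_post] = 1.0
        bridge = (1, 15, j_post[5])
        kappa[bridge] = 0.5
        m = SModel(grid=grid, basis=basis, kappa=kappa, selected=kappa != 0,
                   h_weights=np.zeros(8), b_weights=np.zeros(basis.n_time),
                   b0=0.0, r0=10.0, rmax=100.0)
        mod = np.zeros(shape, bool)
        mod[bridge] = True
        mod[1, 8, j_pre[2]] = True   # modulated but not integration-relevant
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = find_integration_relevant(m, mod)
            # brute-force verification of both decisions
            for stu in (bridge, (1, 8, j_pre[2])):
                mask = np.zeros(shape, bool)
                mask[stu] = True
                nulled = null_stus(m, mask, mode="zero")
                h1 = spatial_sensitivity(nulled, grid.rf1_index)
                h2 = spatial_sensitivity(nulled, grid.rf2_index)
                brute_drop = shared_sensitivity(h1, h2) < res.delta * (1 - 1e-9)
                assert res.integration_relevant[stu] == brute_drop
        assert res.integration_relevant[bridge]
        assert res.integration_relevant.sum() == 1

    def test_zero_shared_sensitivity_flags_empty_result(self, quiet_model):
        mask = np.zeros_like(quiet_model.selected)
        with pytest.warns(UserWarning, match="zero"):
            res = find_integration_relevant(quiet_model, mask)
        assert res.delta == 0
        assert not res.integration_relevant.any()


class TestPMI:
    @pytest.mark.parametrize(
        "s,f,expected",
        [(10.0, 10.0, 0.0), (5.0, 0.0, 1.0), (30.0, 10.0, 0.5)],
    )
    def test_scalar_arithmetic(self, s, f, expected):
        assert pmi(s, f) == pytest.approx(expected)

    def test_windowed_traces(self):
        t = np.arange(0, 201)
        sacc = np.where((t >= 75) & (t <= 105), 30.0, 0.0)
        fix = np.where((t >= 75) & (t <= 105), 10.0, 99.0)
        assert pmi(sacc, fix, time_grid=t) == pytest.approx(0.5)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            pmi(0.0, 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        s=st.floats(0, 1e3), f=st.floats(0, 1e3),
    )
    def test_always_in_unit_interval(self, s, f):
        if s == 0 and f == 0:
            return
        assert -1.0 <= pmi(s, f) <= 1.0
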