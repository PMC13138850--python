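"""Tests of STA computation, data splitting, fitting bookkeeping and the
frozen-spatial adaptation contract."""

import copy

import numpy as np
import pytest

from rgcadapt.evaluation import held_out_correlation
from rgcadapt.ln_models import (
    N_LAGS,
    build_spatiotemporal_rf,
    spatial_params_to_json,
)
from rgcadapt.synthetic_data import (
    SpikeResponse,
    default_population_spec,
    generate_white_noise,
    make_ground_truth_population,
    simulate_rgc,
)
from rgcadapt.training import (
    FitConfig,
    adapt_ood,
    compute_sta,
    default_lr,
    equalize_training_frames,
    fit_ln,
    split_train_val,
)


class TestComputeSTA:
    def test_single_spike_returns_the_stimulus_snippet(self, small_wn):
        counts = [np.zeros(tr.n_frames, dtype=int) for tr in small_wn.trials]
        t_spike = 200
        counts[0][t_spike] = 1
        sta = compute_sta(small_wn, SpikeResponse(counts=counts, cell_id="c"))
        snippet = small_wn.frames[t_spike - N_LAGS + 1 : t_spike + 1]
        np.testing.assert_allclose(sta.sta, snippet, rtol=1e-6)
        assert sta.n_spikes == 1

    def test_count_doubling_leaves_sta_unchanged(self, small_wn, resp_wn):
        sta1 = compute_sta(small_wn, resp_wn)
        doubled = SpikeResponse(counts=[2 * c for c in resp_wn.counts], cell_id="c")
        sta2 = compute_sta(small_wn, doubled)
        np.testing.assert_allclose(sta1.sta, sta2.sta, rtol=1e-12)

    def test_zero_spikes_rejected(self, small_wn):
        empty = SpikeResponse(
            counts=[np.zeros(tr.n_frames, dtype=int) for tr in small_wn.trials]
        )
        with pytest.raises(ValueError):
            compute_sta(small_wn, empty)

    def test_sta_recovers_ground_truth_filter_on_white_noise(self, geometry):
        """With ample white noise the STA converges to the true
        spatiotemporal filter of a DoG LN-Poisson cell (correlation > 0.8).

        Uses a well-driven cell (strong drive, 30 Hz mean rate) and 15 min
        of noise; at lower firing rates convergence takes proportionally
        longer.
        """
        from rgcadapt.synthetic_data import CellTypeSpec, PopulationSpec

        spec = PopulationSpec(
            types=(CellTypeSpec(name="midget_like", n=1, polarity="OFF"),),
            drive_sd=3.0,
            mean_rate_hz=30.0,
        )
        cell = make_ground_truth_population(spec, seed=50, geometry=geometry)[0]
        stim = generate_white_noise(geometry, n_trials=2, train_seconds=450, test_seconds=2, seed=51)
        resp = simulate_rgc(cell, stim, seed=52)
        sta = compute_sta(stim, resp)
        r, c = cell.params_wn.crop_center
        h = 7
        sta_crop = sta.sta[:, r - h : r - h + 15, c - h : c - h + 15]
        rf = build_spatiotemporal_rf(cell.params_wn).values[::-1]  # chronological
        cc = np.corrcoef(sta_crop.ravel(), rf.ravel())[0, 1]
        assert cc > 0.8
        assert sta.polarity == cell.polarity


class TestSplitTrainVal:
    def test_80_20_split_of_ten_trials(self):
        train, val = split_train_val(range(10), 0.8, seed=0)
        assert len(train) == 8 and len(val) == 2

    def test_partition_properties(self):
        items = list("abcdefg")
        train, val = split_train_val(items, 0.6, seed=3)
        assert sorted(train + val) == sorted(items)
        assert not set(train) & set(val)

    def test_deterministic_given_seed(self):
        assert split_train_val(range(12), 0.75, seed=9) == split_train_val(
            range(12), 0.75, seed=9
        )

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            split_train_val(range(2), 0.9, seed=0)  # round(1.8) = 2 -> empty val


class TestEqualizeFrames:
    def test_noop_when_equal(self, small_wn):
        a, b = equalize_training_frames(small_wn, small_wn)
        assert a.nonrep_frame_count() == b.nonrep_frame_count() == small_wn.nonrep_frame_count()

    def test_min_rule(self, geometry):
        a = generate_white_noise(geometry, n_trials=2, train_seconds=10, test_seconds=1, seed=1)
        b = generate_white_noise(geometry, n_trials=2, train_seconds=6, test_seconds=1, seed=2)
        ta, tb = equalize_training_frames(a, b)
        assert ta.nonrep_frame_count() == tb.nonrep_frame_count() == b.nonrep_frame_count()

    def test_repeating_segments_untouched(self, geometry):
        a = generate_white_noise(geometry, n_trials=3, train_seconds=10, test_seconds=2, seed=3)
        b = generate_white_noise(geometry, n_trials=3, train_seconds=4, test_seconds=2, seed=4)
        ta, _ = equalize_training_frames(a, b)
        for before, after in zip(a.trials, ta.trials):
            assert before.rep == after.rep

    def test_whole_trailing_trials_removed_first(self, geometry):
        a = generate_white_noise(geometry, n_trials=4, train_seconds=10, test_seconds=1, seed=5)
        b = generate_white_noise(geometry, n_trials=4, train_seconds=2, test_seconds=1, seed=6)
        ta, _ = equalize_training_frames(a, b)
        per_trial = [t.nonrep[1] - t.nonrep[0] for t in ta.trials]
        assert per_trial[-1] == 0 and per_trial[-2] == 0  # trailing trials emptied


class TestFitBookkeeping:
    def test_single_epoch_when_max_epochs_one(self, small_wn, resp_wn, sta_wn):
        fit = fit_ln(
            "dog", small_wn, resp_wn,
            FitConfig(max_epochs=1, seed=1),
            sta_wn.crop_center, sta_wn.polarity, sta=sta_wn,
        )
        assert len(fit.history) == 1

    def test_best_epoch_attains_max_validation_correlation(self, short_dog_fit):
        hist = short_dog_fit.history
        vals = hist["val_cc"].to_numpy()
        assert np.nanmax(vals) == pytest.approx(short_dog_fit.best_val_cc)
        assert vals[short_dog_fit.best_epoch] == pytest.approx(short_dog_fit.best_val_cc)

    def test_learning_rate_non_increasing_and_floored(self, short_dog_fit):
        lr = short_dog_fit.history["lr"].to_numpy()
        assert np.all(np.diff(lr) <= 0)
        assert lr.min() >= FitConfig().lr_min

    def test_constraints_preserved_after_fitting(self, short_dog_fit):
        p = short_dog_fit.params
        assert abs(np.linalg.norm(p.t1.weights) - 1) < 1e-6
        assert abs(np.linalg.norm(p.t2.weights) - 1) < 1e-6
        assert p.g1.mean is p.g2.mean  # shared storage
        assert p.g1.amplitude * p.g2.amplitude >= 0

    def test_training_loss_decreases_from_start_to_best(self, short_dog_fit):
        loss = short_dog_fit.history["train_loss"].to_numpy()
        assert loss[short_dog_fit.best_epoch] < loss[0]

    def test_default_learning_rates(self):
        assert default_lr("white_noise") == 0.009
        assert default_lr("natural_surrogate") == 0.005
        assert default_lr("white_noise", adapt=True) == 0.001

    def test_rank_one_fit_approaches_oracle_correlation(self, geometry):
        """Fitting the rank-one model to a rank-one ground-truth cell attains
        a validation correlation within 0.05 of the true parameters'."""
        from rgcadapt.evaluation import correlation
        from rgcadapt.ln_models import predict_rate
        from rgcadapt.training import _counts_by_frame

        cell = make_ground_truth_population(
            default_population_spec(1), seed=60, geometry=geometry
        )[0]
        cell = copy.deepcopy(cell)
        cell.params_wn.g2.amplitude = 0.0  # rank-one ground truth
        cell.params_nm = cell.params_wn
        stim = generate_white_noise(geometry, n_trials=5, train_seconds=45, test_seconds=3, seed=61)
        resp = simulate_rgc(cell, stim, seed=62)
        sta = compute_sta(stim, resp)
        cfg = FitConfig(seed=63)
        fit = fit_ln("rank_one", stim, resp, cfg, sta.crop_center, sta.polarity, sta=sta)
        oracle = copy.deepcopy(cell.params_wn)
        oracle.nonlinearity.alpha /= geometry.frame_rate  # per-bin units
        counts = _counts_by_frame(stim, resp)
        _, val_idx = split_train_val(range(len(stim.trials)), cfg.train_fraction, cfg.seed)
        cropped = stim.crop(sta.crop_center)
        preds, obs = [], []
        for i, seg in stim.segment_slices("nonrep"):
            if i in val_idx:
                preds.append(predict_rate(oracle, cropped[seg]))
                obs.append(counts[seg][N_LAGS - 1 :].astype(float))
        cc_oracle = correlation(np.concatenate(preds), np.concatenate(obs))
        assert fit.best_val_cc > cc_oracle - 0.05

    def test_recovery_improves_with_more_data(self, geometry):
        """Median center-location error at 8 min of white noise does not
        exceed the error at 2 min (5 seeds)."""
        errs = {120: [], 480: []}
        for k in range(5):
            cell = make_ground_truth_population(
                default_population_spec(1), seed=70 + k, geometry=geometry
            )[0]
            for secs in errs:
                stim = generate_white_noise(
                    geometry, n_trials=4, train_seconds=secs / 4, test_seconds=2, seed=80 + k
                )
                resp = simulate_rgc(cell, stim, seed=90 + k)
                sta = compute_sta(stim, resp)
                fit = fit_ln(
                    "dog", stim, resp, FitConfig(seed=95 + k),
                    sta.crop_center, sta.polarity, sta=sta,
                )
                true_g = np.asarray(cell.params_wn.crop_center) + cell.params_wn.g1.mean - 7
                fit_g = np.asarray(fit.params.crop_center) + fit.params.g1.mean - 7
                errs[secs].append(np.linalg.norm(true_g - fit_g))
        assert np.median(errs[480]) <= np.median(errs[120]) + 1e-9


class TestAdaptOOD:
    def test_spatial_parameters_byte_identical(self, short_dog_fit, small_nm, resp_nm):
        ad = adapt_ood(
            short_dog_fit, small_nm, resp_nm,
            FitConfig(max_epochs=15, lr_init=0.001, seed=7),
        )
        assert spatial_params_to_json(ad.params) == spatial_params_to_json(
            short_dog_fit.params
        )
        # temporal / nonlinearity actually updated
        assert not np.allclose(ad.params.t1.weights, short_dog_fit.params.t1.weights)

    def test_self_adaptation_changes_test_correlation_little(
        self, small_wn, resp_wn, short_dog_fit
    ):
        cc_before = held_out_correlation(short_dog_fit.params, small_wn, resp_wn)
        ad = adapt_ood(
            short_dog_fit, small_wn, resp_wn,
            FitConfig(max_epochs=60, lr_init=0.001, seed=8),
        )
        cc_after = held_out_correlation(ad.params, small_wn, resp_wn)
        assert abs(cc_after - cc_before) < 0.05
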