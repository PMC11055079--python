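"""Error aggregation, dynamic thresholding, flagging, forecasting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from timetector.detect import (
    ErrorSeries,
    dynamic_threshold,
    flag_anomalies,
    predict_future,
    reconstruction_errors,
)


def err_series(values):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return ErrorSeries(values, tuple(f"f{i}" for i in range(values.shape[1])))


class TestReconstructionErrors:
    def test_series_from_trained_model(self, tiny_trained):
        model, _, _, val_ds, *_ = tiny_trained
        errors = reconstruction_errors(model, val_ds)
        # coverage equals the span of the windows
        assert errors.n_rows == val_ds.start_indices[-1] + val_ds.window_length
        assert errors.values.shape[1] == 5
        assert np.all(errors.values >= 0)

    def test_single_window_is_elementwise_squared_error(self, tiny_trained):
        model, _, _, val_ds, *_ = tiny_trained
        one = val_ds
        # restrict to the first window only
        from dataclasses import replace

        ds1 = replace(one, X=one.X[:1], Y_future=one.Y_future[:1],
                      start_indices=one.start_indices[:1], X_noisy=None)
        out = model.forward(ds1.X)
        expected = (ds1.X[0] - out.X_rec[0]) ** 2
        errors = reconstruction_errors(model, ds1)
        np.testing.assert_allclose(errors.values, expected, rtol=1e-6, atol=1e-10)

    def test_perfect_reconstruction_gives_zero(self, monkeypatch, tiny_trained):
        from timetector.model import BranchOutputs

        model, _, _, val_ds, *_ = tiny_trained
        monkeypatch.setattr(
            type(model), "forward_batched",
            lambda self, X, batch_size=256: BranchOutputs(np.array(X, dtype=float),
                                                          np.zeros((len(X), 1, X.shape[2]))),
        )
        errors = reconstruction_errors(model, val_ds)
        np.testing.assert_array_equal(errors.values, 0.0)


class TestDynamicThreshold:
    def test_hand_rolling_statistics(self):
        """errors [1,1,1,10,1], w=3, k=1: trailing triples give mean+std of
        1.0, 4+sqrt(18), 4+sqrt(18); warm-up rows reuse the first value."""
        errors = err_series([1.0, 1.0, 1.0, 10.0, 1.0])
        ts = dynamic_threshold(errors, window=3, k=1.0)
        expected_tail = [1.0, 4.0 + np.sqrt(18.0), 4.0 + np.sqrt(18.0)]
        np.testing.assert_allclose(ts.threshold[2:, 0], expected_tail, rtol=1e-12)
        np.testing.assert_allclose(ts.threshold[:2, 0], [1.0, 1.0])
        np.testing.assert_allclose(ts.rolling_mean[2:, 0], [1.0, 4.0, 4.0])
        np.testing.assert_allclose(ts.rolling_std[3, 0], np.sqrt(18.0))

    def test_constant_errors_threshold_equals_error(self):
        errors = err_series(np.full(10, 3.7))
        for k in (0.0, 1.0, 5.0):
            ts = dynamic_threshold(errors, window=4, k=k)
            np.testing.assert_allclose(ts.threshold, 3.7)

    def test_k_zero_gives_rolling_mean(self):
        rng = np.random.default_rng(0)
        errors = err_series(rng.random(50))
        ts = dynamic_threshold(errors, window=5, k=0.0)
        np.testing.assert_allclose(ts.threshold, ts.rolling_mean)

    def test_population_std_convention(self):
        errors = err_series([1.0, 2.0, 3.0, 4.0])
        ts = dynamic_threshold(errors, window=4, k=1.0)
        assert ts.rolling_std[3, 0] == pytest.approx(np.std([1, 2, 3, 4]))  # ddof=0

    @given(st.floats(0.0, 10.0), st.floats(0.0, 10.0))
    def test_threshold_pointwise_nondecreasing_in_k(self, k1, k2):
        lo, hi = sorted((k1, k2))
        rng = np.random.default_rng(17)
        errors = err_series(rng.random((60, 2)))
        t_lo = dynamic_threshold(errors, window=6, k=lo).threshold
        t_hi = dynamic_threshold(errors, window=6, k=hi).threshold
        assert np.all(t_hi >= t_lo - 1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            dynamic_threshold(err_series(np.ones(10)), window=1)
        with pytest.raises(ValueError):
            dynamic_threshold(err_series(np.ones(10)), window=3, k=-1.0)
        with pytest.raises(ValueError):
            dynamic_threshold(err_series(np.ones(3)), window=5)


class TestFlagging:
    def test_all_below_threshold_flags_nothing(self):
        errors = err_series(np.full(20, 0.5))
        ts = dynamic_threshold(errors, window=4, k=1.0)
        mask = flag_anomalies(errors, ts)
        assert not mask.flags.any()
        np.testing.assert_array_equal(mask.percentages, [0.0])

    def test_hand_example_flags_only_the_spike(self):
        errors = err_series([1.0, 1.0, 1.0, 10.0, 1.0])
        mask = flag_anomalies(errors, dynamic_threshold(errors, window=3, k=1.0))
        np.testing.assert_array_equal(mask.flags[:, 0], [False, False, False, True, False])
        np.testing.assert_allclose(mask.percentages, [20.0])

    def test_flag_count_monotone_nonincreasing_in_k(self):
        rng = np.random.default_rng(5)
        errors = err_series(rng.chisquare(1, size=(300, 3)))
        counts = []
        for k in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 1e6):
            mask = flag_anomalies(errors, dynamic_threshold(errors, window=30, k=k))
            counts.append(int(mask.flags.sum()))
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0  # k -> infinity flags nothing

    def test_flags_invariant_to_affine_error_rescaling(self):
        rng = np.random.default_rng(6)
        errors = err_series(rng.random((100, 2)))
        scaled = err_series(errors.values * 37.5)
        a = flag_anomalies(errors, dynamic_threshold(errors, window=10, k=2.0)).flags
        b = flag_anomalies(scaled, dynamic_threshold(scaled, window=10, k=2.0)).flags
        np.testing.assert_array_equal(a, b)

    def test_rolling_mean_smoother_than_raw_errors(self):
        rng = np.random.default_rng(7)
        errors = err_series(rng.chisquare(1, size=500))
        ts = dynamic_threshold(errors, window=50, k=3.0)
        assert ts.rolling_mean[49:, 0].var() <= errors.values[:, 0].var()

    def test_misaligned_shapes_rejected(self):
        errors = err_series(np.ones(10))
        ts = dynamic_threshold(err_series(np.ones((12, 1))), window=3, k=1.0)
        with pytest.raises(ValueError):
            flag_anomalies(errors, ts)


class TestForecasts:
    def test_shapes_and_units(self, tiny_trained):
        model, _, _, val_ds, scaler, val_scaled = tiny_trained
        fc = predict_future(model, val_ds, scaler)
        assert fc.values.shape == (val_ds.n_windows, 1, 5)
        # forecasts come back in physical units: compare to the raw series scale
        from timetector.preprocess import invert_scaler

        raw_val = invert_scaler(val_scaled, scaler)
        lo, hi = raw_val.values.min(axis=0), raw_val.values.max(axis=0)
        span = hi - lo
        assert np.all(fc.values[:, 0].min(axis=0) > lo - 5 * span)
        assert np.all(fc.values[:, 0].max(axis=0) < hi + 5 * span)

    def test_target_alignment(self, tiny_trained):
        model, _, _, val_ds, scaler, _ = tiny_trained
        fc = predict_future(model, val_ds, scaler)
        np.testing.assert_array_equal(
            fc.target_indices[:, 0], val_ds.start_indices + val_ds.window_length
        )

    def test_forecast_beats_mean_predictor_on_easy_data(self):
        """R^2 > 0 per feature against the trivial mean forecast."""
        from test_model import toy_dataset
        from timetector.evaluate import regression_metrics
        from timetector.model import TTTBAD, TTTBADConfig, train
        from timetector.preprocess import ScalerParams

        train_ds = toy_dataset(n=150, seed=0)
        val_ds = toy_dataset(n=40, seed=1, split="val")
        cfg = TTTBADConfig(features=3, max_epochs=8, batch_size=16, seed=2)
        model, _ = train(TTTBAD(cfg), train_ds, val_ds)
        identity = ScalerParams(train_ds.feature_names, np.zeros(3), np.ones(3))
        fc = predict_future(model, val_ds, identity)
        for c in range(3):
            r2 = regression_metrics(val_ds.Y_future[:, 0, c], fc.values[:, 0, c]).r2
            assert r2 > 0

    def test_scaler_mismatch_rejected(self, tiny_trained):
        from timetector.preprocess import ScalerParams

        model, _, _, val_ds, *_ = tiny_trained
        bad = ScalerParams(("a", "b"), np.zeros(2), np.ones(2))
        with pytest.raises(ValueError):
            predict_future(model, val_ds, bad)
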