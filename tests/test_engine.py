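"""Scheduler, training loop, sliding inference and cohort evaluation."""

import numpy as np
import pytest

from slabseg import (MaskVolume, TrainConfig, build_mixed_unet, cosine_lr,
                     evaluate_cohort, predict_volume, quarter_width_config,
                     train)
from slabseg.engine import SegmentationModel


class TestCosineSchedule:
    def test_initial_and_restart_rates(self):
        cfg = TrainConfig()
        assert cosine_lr(0, cfg) == pytest.approx(2e-4)
        assert cosine_lr(300, cfg) == pytest.approx(2e-4)

    def test_midpoint_closed_form(self):
        cfg = TrainConfig()
        assert cosine_lr(150, cfg) == pytest.approx(1.005e-4, rel=1e-6)

    def test_trace_matches_closed_form_everywhere(self):
        cfg = TrainConfig(lr0=1e-3, lr_min=1e-5, t0=50)
        for it in range(160):
            t = it % 50
            expected = 1e-5 + 0.5 * (1e-3 - 1e-5) * (1 + np.cos(np.pi * t / 50))
            assert cosine_lr(it, cfg) == pytest.approx(expected)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr0=1e-6, lr_min=1e-4)
        with pytest.raises(ValueError):
            TrainConfig(t0=0)


class TestTrain:
    def _quick(self, cohort, seed=0, iters=6):
        cfg = TrainConfig(iterations=iters, batch_size=2, seed=seed)
        net = build_mixed_unet(quarter_width_config(), seed=seed)
        return train(net, cohort, cfg)

    def test_history_length_and_lr_trace(self, tiny_cohort):
        _, hist = self._quick(tiny_cohort, iters=6)
        assert len(hist["loss"]) == 6
        cfg = TrainConfig(iterations=6, batch_size=2)
        assert hist["lr"] == [cosine_lr(i, cfg) for i in range(6)]

    def test_seed_reproducibility(self, tiny_cohort):
        _, h1 = self._quick(tiny_cohort, seed=4)
        _, h2 = self._quick(tiny_cohort, seed=4)
        assert h1["loss"] == h2["loss"]

    def test_empty_cohort_rejected(self):
        net = build_mixed_unet(quarter_width_config())
        with pytest.raises(ValueError):
            train(net, [], TrainConfig(iterations=1))


class TestPredictVolume:
    def test_output_matches_volume_shape(self, tiny_case):
        vol, _ = tiny_case
        net = build_mixed_unet(quarter_width_config(), seed=0)
        mask = predict_volume(net, vol)
        assert mask.labels.shape == vol.shape
        assert set(np.unique(mask.labels)) <= {0, 1}

    def test_unreachable_threshold_gives_empty_mask(self, tiny_case):
        vol, _ = tiny_case
        net = build_mixed_unet(quarter_width_config(), seed=0)
        mask = predict_volume(net, vol, threshold=1.01)
        assert mask.labels.sum() == 0

    def test_prediction_uses_only_the_seven_neighbouring_slices(self, tiny_case):
        """Perturbing a slice outside the stack must not change the output."""
        vol, _ = tiny_case
        net = build_mixed_unet(quarter_width_config(), seed=1)
        from slabseg import apply_window, extract_stack, forward_central_slice
        win = apply_window(vol)
        base = forward_central_slice(net, extract_stack(win, 2, 7).slices)
        tampered = win.copy()
        tampered[7] = 1.0 - tampered[7]  # slice 7 is outside 2 +/- 3
        after = forward_central_slice(net, extract_stack(tampered, 2, 7).slices)
        assert np.array_equal(base, after)
        tampered2 = win.copy()
        tampered2[4] = 1.0 - tampered2[4]  # inside the stack
        inside = forward_central_slice(net, extract_stack(tampered2, 2, 7).slices)
        assert not np.array_equal(base, inside)

    def test_slice_reversal_consistency(self, tiny_case):
        """Indexing check: reversing the volume reverses the prediction when
        each stack is reversed accordingly."""
        vol, _ = tiny_case
        net = build_mixed_unet(quarter_width_config(), seed=2)
        from slabseg import apply_window, extract_stack, forward_central_slice
        win = apply_window(vol)
        n = len(win)
        i = 4
        fwd_stack = extract_stack(win, i, 7).slices
        rev_stack = extract_stack(win[::-1], n - 1 - i, 7).slices
        assert np.array_equal(fwd_stack[::-1], rev_stack)


class TestEvaluateCohort:
    class _Oracle:
        """Stands in for a trained network: returns the reference mask."""

        def __init__(self, cases, invert=False):
            self.lookup = {v.case_id: m.labels for v, m in cases}
            self.invert = invert

        def run(self, cases, seed):
            from slabseg.metrics import aggregate_ci, case_metrics
            import pandas as pd
            recs = []
            for vol, mask in cases:
                pred = np.zeros_like(mask.labels) if self.invert else mask.labels
                recs.append(case_metrics(MaskVolume(pred), mask, vol.case_id))
            return pd.DataFrame([r.to_dict() for r in recs]), aggregate_ci(recs, seed)

    def test_oracle_model_scores_perfectly(self, tiny_cohort):
        _, summary = self._Oracle(tiny_cohort).run(tiny_cohort, seed=0)
        assert summary.mean["dice"] == pytest.approx(100.0)
        assert summary.mean["voe"] == pytest.approx(0.0)

    def test_always_empty_model(self, tiny_cohort):
        _, summary = self._Oracle(tiny_cohort, invert=True).run(tiny_cohort, seed=0)
        assert summary.mean["dice"] == pytest.approx(0.0)
        assert summary.mean["spe"] == pytest.approx(100.0)

    def test_end_to_end_determinism(self, tiny_cohort):
        """phantom -> train -> evaluate reproduces metrics bit for bit."""
        results = []
        for _ in range(2):
            cfg = TrainConfig(iterations=4, batch_size=2, seed=9)
            net = build_mixed_unet(quarter_width_config(), seed=9)
            net, hist = train(net, tiny_cohort, cfg)
            frame, _ = evaluate_cohort(net, tiny_cohort, seed=0,
                                       norm=(hist["norm_mean"], hist["norm_sd"]))
            results.append(frame)
        assert results[0].equals(results[1])


class TestFacade:
    def test_fit_returns_results_with_summary(self, tiny_cohort):
        model = SegmentationModel(tiny_cohort, quarter_width_config(),
                                  TrainConfig(iterations=3, batch_size=2, seed=0))
        res = model.fit()
        text = res.summary()
        assert "parameters" in text and "7->6->5->4->2" in text
        pred = res.predict(tiny_cohort[0][0])
        assert pred.labels.shape == tiny_cohort[0][0].shape
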