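import numpy as np
import pytest

from primenet import autodiff as ad
from primenet.autodiff import Tensor
from primenet.interpretability import (AttributionConfig,
                                       ChannelOptimizationConfig,
                                       completeness_gap, extract_attention_maps,
                                       integrated_gradients,
                                       optimize_epigenetic_channel,
                                       select_top_sequences)
from primenet.io_formats import EfficiencyTriple, RegionSpans, TargetRecord
from primenet.network import ModelConfig, PrimeNet

rng = np.random.default_rng(1)


class _LinearModel:
    """F(x) = w . x per head; closed-form oracle for integrated gradients."""

    class _Cfg:
        conv_attention_enabled = False

    def __init__(self, w):
        self.w = w.astype(np.float64)  # (128,8,2,3)
        self.config = self._Cfg()

    def zero_grad(self):
        pass

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=ad.DTYPE))
        flat = x.reshape(x.data.shape[0], -1)
        return flat @ Tensor(self.w.reshape(-1, 3).astype(ad.DTYPE))

    def predict(self, x):
        return self.forward(np.asarray(x, dtype=ad.DTYPE)).data


class TestIntegratedGradients:
    def test_linear_model_gives_w_times_x(self):
        w = rng.normal(size=(128, 8, 2, 3))
        model = _LinearModel(w)
        x = (rng.random((128, 8, 2)) > 0.5).astype(np.float64)
        att = integrated_gradients(model, x, AttributionConfig(steps=16))
        assert np.allclose(att.scores, w[..., 0] * x, atol=1e-4)

    def test_baseline_input_gives_zero(self):
        w = rng.normal(size=(128, 8, 2, 3))
        model = _LinearModel(w)
        x = np.zeros((128, 8, 2))
        att = integrated_gradients(model, x, AttributionConfig(steps=16))
        assert np.abs(att.scores).max() == 0

    def test_completeness_on_trained_model(self, trained_toy_model):
        res = trained_toy_model
        from primenet.workflows import encode_records

        # reuse one held-out image
        x = rng.random((128, 8, 2)).astype("f4")
        att = integrated_gradients(res.model, x,
                                   AttributionConfig(steps=256, target_head="valid"))
        assert completeness_gap(res.model, x, att) < 0.01

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            AttributionConfig(steps=4)


class TestSelectTop:
    def _records(self, effs):
        out = []
        for i, e in enumerate(effs):
            out.append(TargetRecord(
                record_id=f"r{i}", wild_seq="ACGT", edited_seq="ACGT",
                spans=RegionSpans((0, 2), (2, 3), (0, 2), (2, 4)),
                observed=EfficiencyTriple(e, (100 - e) / 2, (100 - e) / 2),
            ))
        return out

    def test_top_n_selection(self):
        effs = list(rng.random(300) * 100)
        recs = self._records(effs)
        top = select_top_sequences(recs, "valid", 200)
        assert len(top) == 200
        selected = {r.record_id for r in top}
        min_sel = min(r.observed.valid for r in top)
        max_exc = max(r.observed.valid for r in recs
                      if r.record_id not in selected)
        assert min_sel >= max_exc

    def test_n_zero_empty(self):
        assert select_top_sequences(self._records([1, 2]), "valid", 0) == []

    def test_tie_broken_by_record_id(self):
        recs = self._records([50.0, 50.0, 50.0])
        top = select_top_sequences(recs, "valid", 2)
        assert [r.record_id for r in top] == ["r0", "r1"]

    def test_overask_returns_all_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            top = select_top_sequences(self._records([1, 2]), "valid", 10)
        assert len(top) == 2


class TestChannelOptimization:
    def test_masked_channels_bit_identical(self, trained_toy_model):
        model = trained_toy_model.model
        seeds = [rng.random((128, 8, 2)).astype("f4") for _ in range(2)]
        before = np.stack(seeds).astype(np.float64)
        cfg = ChannelOptimizationConfig(channel=4, n_steps=5, step_size=0.05)
        optimize_epigenetic_channel(model, list(before.copy()), cfg)
        # the function works on copies; re-run capturing internals via a
        # wrapper: optimize and verify the profile then check the seeds we
        # passed are untouched (pure function) and outputs bounded
        prof = optimize_epigenetic_channel(model, list(before), cfg)
        assert prof.shape == (128, 2)
        assert (prof >= 0).all() and (prof <= 1).all()

    def test_monotone_toy_model_drives_channel_up(self):
        """A linear model increasing in channel 4 at position 10 must push the
        optimized profile there toward the upper clamp."""
        w = np.zeros((128, 8, 2, 3))
        w[10, 4, 0, 0] = 5.0
        model = _LinearModel(w)
        seed_img = np.zeros((128, 8, 2))
        cfg = ChannelOptimizationConfig(channel=4, target_head="valid",
                                        n_steps=50, step_size=0.01)
        prof = optimize_epigenetic_channel(model, [seed_img], cfg)
        assert prof[10, 0] > 0.9
        assert prof[11, 0] == 0.0

    def test_non_target_channels_unchanged_in_output_images(self):
        """Gradient masking: ascending channel 4 must not alter channel 5 even
        when the model's output depends on channel 5."""
        w = np.zeros((128, 8, 2, 3))
        w[:, 4, 0, 0] = 1.0
        w[:, 5, 0, 0] = 1.0
        model = _LinearModel(w)
        x = rng.random((128, 8, 2))
        cfg = ChannelOptimizationConfig(channel=4, n_steps=10, step_size=0.1)
        # capture the optimized image by a 1-seed run and reconstructing:
        # the profile equals the final channel values; channel 5 must be
        # untouched, so re-running with channel=5 from the same seed gives a
        # different profile than x's channel-4 values
        prof4 = optimize_epigenetic_channel(model, [x], cfg)
        assert (prof4 >= x[:, 4, :]).all()  # ascent only increases here

    def test_empty_seed_set_rejected(self, trained_toy_model):
        with pytest.raises(ValueError):
            optimize_epigenetic_channel(trained_toy_model.model, [],
                                        ChannelOptimizationConfig())

    def test_invalid_channel_rejected(self):
        with pytest.raises(ValueError):
            ChannelOptimizationConfig(channel=3)


class TestAttentionMaps:
    def test_maps_in_unit_interval(self, trained_toy_model):
        model = trained_toy_model.model
        imgs = [rng.random((128, 8, 2)).astype("f4") for _ in range(3)]
        maps = extract_attention_maps(model, imgs)
        assert set(maps) == {"att_in", "att0", "att1"}
        for m in maps.values():
            assert m.shape[0] == 128
            assert (m > 0).all() and (m < 1).all()

    def test_single_image_equals_raw_weights(self, trained_toy_model):
        model = trained_toy_model.model
        img = rng.random((128, 8, 2)).astype("f4")
        maps = extract_attention_maps(model, [img])
        model.forward(np.stack([img]), collect_attention=True)
        raw = model._attention_sink
        for stage in maps:
            assert np.allclose(maps[stage], raw[stage][0][0])

    def test_disabled_attention_raises(self):
        cfg = ModelConfig(conv_attention_enabled=False,
                          mixconv_out_channels_per_branch=4,
                          compress_channels=8, conv_channels=(8, 8),
                          trunk_widths=(16,), branch_widths=(8,))
        model = PrimeNet(cfg, seed=0)
        with pytest.raises(ValueError):
            extract_attention_maps(model, [np.zeros((128, 8, 2), dtype="f4")])

    def test_constructed_gate_attends_stripe(self):
        """Force the input conv-attention to weight a stripe by planting a
        strong bias pattern; the averaged map must peak on that stripe."""
        from tests.conftest import SMALL_CONFIG

        model = PrimeNet(SMALL_CONFIG, seed=0)
        # zero the attention conv weight so the logit is bias-driven, then
        # feed an image whose channel-mean is high only on positions 40..49
        model.params["att_in.W"].data = np.ones_like(
            model.params["att_in.W"].data)
        img = np.zeros((128, 8, 2), dtype="f4")
        img[40:50, :, :] = 1.0
        maps = extract_attention_maps(model, [img])
        m = maps["att_in"]
        stripe = m[40:50].mean()
        outside = np.r_[m[:38], m[52:]].mean()
        assert stripe > outside
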