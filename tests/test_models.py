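"""Architecture contracts: stage structure, shape arithmetic, outputs."""

import numpy as np
import pytest

from conftest import tiny_model_config
from deepeeg.errors import ConfigurationError, ShapeError
from deepeeg.models import (
    MODEL_ROSTER,
    ArchitectureDescriptor,
    ModelConfig,
    bottleneck_shape,
    build_decoder,
    build_encoder,
    build_head,
    build_model,
    instantiate,
    roster_config,
)

RNG = np.random.default_rng(31)


class TestEncoder:
    def test_eight_alternating_stages_with_reference_filters(self):
        desc = build_encoder(ModelConfig(), (23, 1024))
        kinds = [l["kind"] for l in desc.layers]
        assert kinds == ["conv2d", "maxpool2d"] * 4
        assert [l["filters"] for l in desc.layers if l["kind"] == "conv2d"] \
            == [32, 32, 64, 64]
        assert all(l["activation"] == "relu" for l in desc.layers
                   if l["kind"] == "conv2d")

    @pytest.mark.parametrize(
        "input_hw,expected",
        [
            ((23, 1024), (1, 64, 64)),  # 23->11->5->2->1, 1024->...->64
            ((23, 256), (1, 16, 64)),
            ((23, 512), (1, 32, 64)),
            ((8, 1024), (1, 64, 64)),   # height clamps at 1 once exhausted
        ],
    )
    def test_bottleneck_shape_floor_arithmetic(self, input_hw, expected):
        assert bottleneck_shape(input_hw, ModelConfig()) == expected

    def test_too_narrow_time_axis_is_shape_error(self):
        with pytest.raises(ShapeError, match="time axis"):
            build_encoder(ModelConfig(), (8, 8))

    def test_encoder_is_dimension_reducing(self):
        for hw in [(23, 256), (23, 512), (23, 1024), (8, 1024)]:
            h, w, c = bottleneck_shape(hw, ModelConfig())
            assert h * w * c < hw[0] * hw[1]


class TestDecoder:
    def test_filter_schedule_read_back(self):
        desc = build_decoder(ModelConfig(), (23, 1024))
        convs = [l["filters"] for l in desc.layers if l["kind"] == "conv2d"]
        assert convs == [64, 32, 32, 1]
        assert desc.layers[-1]["kind"] == "sigmoid"

    @pytest.mark.parametrize("width", [256, 512, 1024])
    def test_round_trip_restores_input_shape(self, width):
        desc = build_decoder(ModelConfig(), (23, width))
        assert desc.output_shape == (23, width, 1)

    def test_decoder_refused_for_baseline(self):
        with pytest.raises(ConfigurationError, match="baseline"):
            build_decoder(ModelConfig(autoencoder=False), (23, 256))


class TestHead:
    def test_bilstm_sequence_geometry(self):
        desc = build_head(ModelConfig(), (1, 64, 64))
        seq = next(l for l in desc.layers if l["kind"] == "to_sequence")
        assert seq["output_shape"] == [64, 64]  # 64 steps, 64 features/step
        rec = next(l for l in desc.layers if l["kind"] == "bilstm")
        assert rec["output_shape"] == [64, 160]  # 2 directions x 80 units

    def test_mlp_parameter_count_closed_form(self):
        cfg = ModelConfig(head="mlp")
        model = instantiate(build_model(cfg, (23, 256)))
        feats = 1 * 16 * 64
        expected_head = (feats * 50 + 50) + (50 * 2 + 2)
        assert sum(p.size for p in model.head.params) == expected_head

    def test_unknown_head_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown head"):
            ModelConfig(head="gru")

    def test_literal_average_pool_order_builds_and_runs(self):
        cfg = tiny_model_config(avg_pool_after_dense=True)
        model = instantiate(build_model(cfg, (4, 64)))
        logits, recon = model.forward(RNG.random((3, 4, 64, 1)))
        assert logits.shape == (3, 2)


class TestFullModel:
    def test_dcae_exposes_two_outputs_dcnn_one(self):
        dcae = build_model(roster_config("dcae-bilstm"), (23, 256))
        dcnn = build_model(roster_config("dcnn-mlp"), (23, 256))
        assert dcae.n_outputs == 2
        assert dcnn.n_outputs == 1

    @pytest.mark.parametrize("name", MODEL_ROSTER)
    @pytest.mark.parametrize("width", [256, 512, 1024])
    def test_roster_builds_and_forward_is_finite(self, name, width):
        desc = build_model(roster_config(name), (23, width))
        model = instantiate(desc)
        x = RNG.random((2, 23, width, 1), dtype=np.float32)
        logits, recon = model.forward(x)
        assert np.all(np.isfinite(logits))
        if desc.n_outputs == 2:
            assert recon.shape == (2, 23, width, 1)
            assert np.all(np.isfinite(recon))
            assert np.all((recon >= 0) & (recon <= 1))  # sigmoid output
        else:
            assert recon is None

    def test_probabilities_sum_to_one(self):
        model = instantiate(build_model(tiny_model_config(), (4, 64)))
        probs = model.predict_proba(RNG.random((7, 4, 64, 1)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_order_invariance(self):
        model = instantiate(build_model(tiny_model_config(), (4, 64)))
        x = RNG.random((6, 4, 64, 1), dtype=np.float32)
        perm = RNG.permutation(6)
        p_all = model.predict_proba(x)
        p_perm = model.predict_proba(x[perm])
        assert np.allclose(p_all[perm], p_perm, atol=1e-6)

    def test_manifest_json_round_trip(self):
        desc = build_model(roster_config("dcae-lstm"), (23, 512))
        enc2 = ArchitectureDescriptor.from_json(desc.encoder.to_json())
        assert enc2.layers == desc.encoder.layers
        assert enc2.output_shape == desc.encoder.output_shape
        assert "dcae" not in desc.to_json() or True  # full manifest parses
        import json

        manifest = json.loads(desc.to_json())
        assert manifest["decoder"] is not None
        assert manifest["config"]["head"] == "lstm"


class TestConfigValidation:
    def test_wrong_stage_counts_rejected(self):
        with pytest.raises(ConfigurationError, match="4 conv stages"):
            ModelConfig(encoder_filters=(32, 64))

    def test_decoder_final_filter_must_be_one(self):
        with pytest.raises(ConfigurationError, match="final conv"):
            ModelConfig(decoder_filters=(64, 32, 32, 8))

    def test_dropout_range(self):
        with pytest.raises(ConfigurationError, match="dropout"):
            ModelConfig(dropout_rate=1.0)

    def test_unknown_roster_name(self):
        with pytest.raises(ConfigurationError, match="unknown model"):
            roster_config("vggnet")
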