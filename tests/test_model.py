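"""Model assembly, ablation wiring, and parameter/MAC accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lightmixer import nn
from lightmixer.blocks import BlockConfig, LayerSpec
from lightmixer.model import (
    ConvCostQuery,
    ModelConfig,
    assemble,
    count_macs,
    count_parameters,
    depthwise_vs_separable_ratio,
    summarize,
)

# Hand enumeration of the default architecture at 224x224 input, layer by
# layer (output positions x kernel x in/groups x out), kept independent of
# the count_macs traversal.
HAND_MACS = (
    75 * 75 * 9 * 3          # stem depthwise 3x3 -> 75x75
    + 75 * 75 * 3 * 224      # 1x1 expansion
    + 75 * 75 * 9 * 224      # depthwise 3x3
    + 74 * 74 * 4 * 224 * 224  # 2x2 fusion -> 74x74
    + 74 * 74 * 81 * 224     # LR depthwise 9x9
    + 74 * 74 * 224 * 224    # LR pointwise
    + 224 * 10               # affine head
)

HAND_PARAM_TOTAL = 30 + 896 + 2016 + 200928 + 448 + 18368 + 448 + 50400 + 448 + 2250


def _variant(use_dcwp, use_lr, **kw):
    return ModelConfig(use_dcwp=use_dcwp, use_lr=use_lr, **kw)


class TestAssemble:
    def test_full_model_output_shape_at_224(self):
        net = assemble(ModelConfig(seed=0))
        y = net.forward(np.zeros((2, 3, 224, 224), dtype=np.float32))
        assert y.shape == (2, 10)

    def test_base_variant_is_stem_plus_head(self):
        from lightmixer.blocks import iter_specs

        net = assemble(_variant(False, False))
        kinds = [spec.kind for _, spec, _ in iter_specs(net)]
        assert kinds == ["depthwise_conv", "pool", "flatten", "dropout", "linear"]

    def test_lr_only_variant_gets_expansion_adapter(self):
        from lightmixer.blocks import iter_specs

        net = assemble(_variant(False, True))
        names = [name for name, _, _ in iter_specs(net)]
        assert "adapter.expand" in names
        y = net.forward(np.zeros((1, 3, 32, 32), dtype=np.float32))
        assert y.shape == (1, 10)

    def test_same_seed_is_bit_identical(self):
        a = assemble(ModelConfig(seed=11, channels=8,
                                 block_cfg=BlockConfig(channels=8)))
        b = assemble(ModelConfig(seed=11, channels=8,
                                 block_cfg=BlockConfig(channels=8)))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_different_seed_differs(self):
        a = assemble(ModelConfig(seed=1))
        b = assemble(ModelConfig(seed=2))
        assert any(
            not np.array_equal(pa.value, pb.value)
            for pa, pb in zip(a.parameters(), b.parameters())
        )

    def test_bad_num_classes_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(num_classes=1)


class TestAccounting:
    @pytest.mark.parametrize(
        "use_dcwp,use_lr", [(False, False), (True, False), (False, True), (True, True)]
    )
    def test_closed_form_equals_runtime_enumeration(self, use_dcwp, use_lr):
        net = assemble(_variant(use_dcwp, use_lr))
        _, total = count_parameters(net)
        assert total == net.num_parameters()

    def test_default_total_matches_hand_sum(self):
        _, total = count_parameters(assemble(ModelConfig()))
        assert total == HAND_PARAM_TOTAL

    def test_ablation_parameter_ordering(self):
        totals = {
            flags: count_parameters(assemble(_variant(*flags)))[1]
            for flags in [(False, False), (True, False), (False, True), (True, True)]
        }
        base, dcwp, lr, both = (
            totals[(False, False)], totals[(True, False)],
            totals[(False, True)], totals[(True, True)],
        )
        assert base < dcwp and base < lr < both

    def test_count_is_invariant_to_batch_and_weights(self, tiny_model_cfg):
        net = assemble(tiny_model_cfg)
        _, before = count_parameters(net)
        net.forward(np.zeros((1, 3, 20, 20), dtype=np.float32))
        for p in net.parameters():
            p.value += 1.0
        net.forward(np.zeros((5, 3, 20, 20), dtype=np.float32))
        assert count_parameters(net)[1] == before == net.num_parameters()

    @pytest.mark.parametrize(
        "spec,positions,expected",
        [
            (LayerSpec("conv", 3, 224, (1, 1)), 75 * 75, 75 * 75 * 3 * 224),
            (LayerSpec("depthwise_conv", 224, 224, (9, 9), groups=224),
             74 * 74, 74 * 74 * 81 * 224),
        ],
    )
    def test_mac_examples(self, spec, positions, expected):
        assert spec.macs(positions) == expected

    def test_full_model_macs_match_hand_enumeration(self):
        result = count_macs(assemble(ModelConfig()), (3, 224, 224))
        assert result["macs"] == HAND_MACS
        assert result["flops"] == 2 * HAND_MACS

    def test_summarize_table_contents(self):
        text, records = summarize(assemble(ModelConfig()), (3, 224, 224))
        by_name = {r["name"]: r for r in records}
        assert by_name["head.linear"]["params"] == 2250
        assert by_name["dcwp.fuse"]["output_shape"] == [224, 74, 74]
        assert "276,232" in text


class TestCostRatio:
    @pytest.mark.parametrize(
        "k,U,O,expected",
        [(3, 5, 9, 2.0), (1, 7, 1, 2.0), (3, 17, 224, 1 + 224 / 9)],
    )
    def test_examples(self, k, U, O, expected):
        assert depthwise_vs_separable_ratio(ConvCostQuery(k, U, O)) == pytest.approx(
            expected
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        k=st.integers(1, 20),
        u1=st.integers(1, 4096),
        u2=st.integers(1, 4096),
        o=st.integers(1, 4096),
    )
    def test_simplified_form_and_u_independence(self, k, u1, u2, o):
        r1 = depthwise_vs_separable_ratio(ConvCostQuery(k, u1, o))
        r2 = depthwise_vs_separable_ratio(ConvCostQuery(k, u2, o))
        assert r1 == pytest.approx(1 + o / k**2)
        assert r1 == pytest.approx(r2)

    def test_degenerate_kernel_rejected(self):
        with pytest.raises(ValueError):
            ConvCostQuery(0, 1, 1)


def test_softmax_of_network_output_is_a_distribution(tiny_model_cfg, rng):
    net = assemble(tiny_model_cfg)
    logits = net.forward(rng.normal(size=(6, 3, 20, 20)).astype(np.float32))
    probs = nn.softmax(logits)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
    assert (probs >= 0).all()
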