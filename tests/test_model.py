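import numpy as np
import pytest

from trisomap.io_formats import CONTROL_LABEL, DS_LABEL
from trisomap.model import (
    BiStreamModelSpec,
    build_bistream,
    build_model,
    build_singlestream,
    conv_param_count,
    spatial_trace,
)
from trisomap.snpmap import MapLayout, dataset_to_map_stacks


@pytest.fixture(scope="module")
def small_spec():
    return BiStreamModelSpec(
        input_size=(16, 16), epochs=8, batch_size=16, seed=2
    )


@pytest.fixture(scope="module")
def small_maps(small_cohort):
    xa, xb = dataset_to_map_stacks(small_cohort, MapLayout(column_width=2, height=16))
    return xa, xb, small_cohort.labels


class TestArchitecture:
    def test_layer_parameter_counts_match_closed_forms(self):
        spec = BiStreamModelSpec()
        net = build_bistream(spec)
        counts = net.layer_param_counts()
        assert counts["C1-A"] == counts["C1-B"] == conv_param_count(16, (3, 3), 1) == 160
        assert counts["C2-A"] == counts["C3-B"] == conv_param_count(16, (3, 3), 16) == 2320
        assert counts["C4"] == conv_param_count(16, (3, 3), 32) == 4624
        single = build_singlestream(spec, "A")
        assert single.layer_param_counts()["C4"] == conv_param_count(16, (3, 3), 16) == 2320
        assert net.n_params == sum(counts.values())

    def test_penultimate_dense_width_is_512(self):
        net = build_bistream(BiStreamModelSpec())
        assert net.layer_registry["dense-512"].w.shape[1] == 512
        assert net.layer_registry["output"].w.shape == (512, 2)

    def test_default_spatial_trace_642_321_160(self):
        trace = spatial_trace(BiStreamModelSpec())
        assert trace == [(642, 642), (321, 321), (321, 321), (160, 160)]

    def test_single_stream_shares_every_hyperparameter(self):
        spec = BiStreamModelSpec(input_size=(16, 16))
        assert build_singlestream(spec, "B").spec == build_bistream(spec).spec

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            BiStreamModelSpec(input_size=(4, 4))


class TestTraining:
    def test_loss_decreases_on_separable_cohort(self, small_maps, small_spec):
        xa, xb, labels = small_maps
        net = build_bistream(small_spec).fit(xa, xb, labels)
        assert net.history[-1] < net.history[0]

    def test_same_seed_gives_identical_histories(self, small_maps, small_spec):
        xa, xb, labels = small_maps
        h1 = build_bistream(small_spec).fit(xa, xb, labels).history
        h2 = build_bistream(small_spec).fit(xa, xb, labels).history
        assert h1 == h2

    def test_single_class_training_rejected(self, small_maps, small_spec):
        xa, xb, _ = small_maps
        labels = np.array([CONTROL_LABEL] * xa.shape[0], dtype=object)
        with pytest.raises(ValueError, match="both classes"):
            build_bistream(small_spec).fit(xa, xb, labels)


@pytest.fixture(scope="module")
def trained(small_maps, small_spec):
    xa, xb, labels = small_maps
    return build_bistream(small_spec).fit(xa, xb, labels), xa, xb


class TestPrediction:
    def test_probabilities_sum_to_one(self, trained):
        net, xa, xb = trained
        probs = net.predict_proba(xa, xb)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert probs.min() >= 0

    def test_inference_is_pure(self, trained):
        net, xa, xb = trained
        dup_a = np.concatenate([xa[:1], xa[:1]])
        dup_b = np.concatenate([xb[:1], xb[:1]])
        probs = net.predict_proba(dup_a, dup_b)
        np.testing.assert_array_equal(probs[0], probs[1])
        np.testing.assert_array_equal(
            net.predict_proba(xa[:3], xb[:3]), net.predict_proba(xa[:3], xb[:3])
        )

    def test_stream_swap_changes_predictions(self, trained):
        """Trained branches are asymmetric: swapping the two input maps moves
        the output probabilities."""
        net, xa, xb = trained
        straight = net.predict_proba(xa[:8], xb[:8])
        swapped = net.predict_proba(xb[:8], xa[:8])
        assert np.abs(straight - swapped).max() > 1e-4

    def test_hard_labels_are_argmax(self, trained):
        net, xa, xb = trained
        probs = net.predict_proba(xa[:8], xb[:8])
        hard = net.predict(xa[:8], xb[:8])
        expected = np.where(probs[:, 1] > probs[:, 0], DS_LABEL, CONTROL_LABEL)
        assert list(hard) == list(expected)

    def test_shape_mismatch_rejected(self, trained, small_maps):
        net, xa, xb = trained
        with pytest.raises(ValueError, match="match spec input"):
            net.predict(xa[:2, :8, :8], xb[:2, :8, :8])


class TestPersistence:
    def test_save_load_round_trip(self, small_maps, small_spec, tmp_path):
        xa, xb, labels = small_maps
        net = build_bistream(small_spec).fit(xa, xb, labels)
        net.save(tmp_path / "model")
        from trisomap.model import _Network

        back = _Network.load(tmp_path / "model")
        assert back.history == net.history
        np.testing.assert_array_equal(
            back.predict_proba(xa[:5], xb[:5]), net.predict_proba(xa[:5], xb[:5])
        )

    @pytest.mark.parametrize("arch", ["single-a", "single-b"])
    def test_single_stream_round_trip(self, small_maps, small_spec, tmp_path, arch):
        xa, xb, labels = small_maps
        net = build_model(arch, small_spec).fit(xa, xb, labels)
        net.save(tmp_path / arch)
        from trisomap.model import _Network

        back = _Network.load(tmp_path / arch)
        np.testing.assert_array_equal(
            back.predict_proba(xa[:4], xb[:4]), net.predict_proba(xa[:4], xb[:4])
        )
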