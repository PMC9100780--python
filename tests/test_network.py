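"""Neuron/layer mathematics: gating, kWTA, masks, parameter accounting, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adnet import (
    NetworkSpec,
    count_nonzero_params,
    dendritic_response,
    forward,
    gate,
    kwta,
    load_params,
    make_sparsity_mask,
    save_params,
)
from adnet.exceptions import ConfigurationError, InvalidInputError
from adnet.network import (
    AdamState,
    adam_step,
    forward_backward,
    init_params,
)

SETTINGS = dict(derandomize=True, max_examples=50, deadline=None)


# ---------------------------------------------------------------------------
# dendritic_response
# ---------------------------------------------------------------------------


class TestDendriticResponse:
    # identity segment matrix: responses equal the context vector itself
    U = np.eye(3)

    def test_absolute_max_keeps_sign(self):
        d, j = dendritic_response(self.U, np.array([0.3, -1.2, 0.5]), "absolute_max")
        assert d == pytest.approx(-1.2)
        assert j == 1

    def test_plain_max(self):
        d, j = dendritic_response(self.U, np.array([0.3, -1.2, 0.5]), "max")
        assert d == pytest.approx(0.5)
        assert j == 2

    def test_zero_segments_tensor_gives_zero(self):
        d, _ = dendritic_response(np.zeros((4, 3)), np.array([1.0, 2.0, 3.0]))
        assert d == 0.0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(InvalidInputError):
            dendritic_response(self.U, np.array([1.0, 2.0]))

    def test_no_segments_raises(self):
        with pytest.raises(ConfigurationError):
            dendritic_response(np.empty((0, 3)), np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# gate
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "t_hat,d,expected",
    [
        (5.0, 0.0, 2.5),                      # sigmoid(0) = 1/2
        (2.0, -1.2, 2.0 / (1.0 + np.exp(1.2))),
        (0.0, 3.7, 0.0),
    ],
)
def test_gate_values(t_hat, d, expected):
    assert gate(t_hat, d) == pytest.approx(expected, rel=1e-12)


@given(st.floats(-50, 50), st.floats(-50, 50))
@settings(**SETTINGS)
def test_gate_attenuates(t_hat, d):
    """|gate(t,d)| <= |t|: the sigmoid can only attenuate, never amplify."""
    assert abs(gate(t_hat, d)) <= abs(t_hat) + 1e-12


@given(st.floats(0.1, 50), st.floats(-20, 20), st.floats(1e-6, 5))
@settings(**SETTINGS)
def test_gate_increasing_in_dendrite_for_positive_drive(t_hat, d, delta):
    assert gate(t_hat, d + delta) > gate(t_hat, d)


# ---------------------------------------------------------------------------
# kwta
# ---------------------------------------------------------------------------


class TestKwta:
    @pytest.mark.parametrize(
        "values,k,expected",
        [
            ([3, 1, 4, 1, 5], 2, [0, 0, 4, 0, 5]),
            ([1, 1, 1], 1, [1, 0, 0]),            # tie broken by lowest index
            ([2.5, -1.0, 0.0], 3, [2.5, -1.0, 0.0]),  # k = n is the identity
        ],
    )
    def test_examples(self, values, k, expected):
        np.testing.assert_array_equal(kwta(np.array(values, float), k), expected)

    @pytest.mark.parametrize("k", [0, 6, -1])
    def test_k_out_of_range(self, k):
        with pytest.raises(InvalidInputError):
            kwta(np.arange(5.0), k)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40, unique=True),
        st.data(),
    )
    @settings(**SETTINGS)
    def test_conservation(self, values, data):
        """Distinct inputs: exactly k survivors, kept bit-exactly."""
        v = np.array(values)
        k = data.draw(st.integers(1, len(values)))
        out = kwta(v, k)
        kept = out != 0
        # zeros in the input may be "kept" invisibly; count via threshold set
        order = np.argsort(-v, kind="stable")[:k]
        expected = np.zeros_like(v)
        expected[order] = v[order]
        np.testing.assert_array_equal(out, expected)
        assert kept.sum() <= k


# ---------------------------------------------------------------------------
# sparsity masks
# ---------------------------------------------------------------------------


class TestSparsityMask:
    def test_zero_sparsity_all_ones(self):
        assert make_sparsity_mask((5, 7), 0.0, seed=0).all()

    def test_exact_zero_count(self):
        m = make_sparsity_mask((10, 10), 0.1, seed=3)
        assert (m == 0).sum() == 10

    def test_deterministic(self):
        a = make_sparsity_mask((20, 20), 0.5, seed=42)
        b = make_sparsity_mask((20, 20), 0.5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_mask_persists_through_training(self, tiny_spec, tiny_params):
        rng = np.random.default_rng(0)
        adam = AdamState.for_params(tiny_params)
        for _ in range(5):
            x = rng.normal(size=(8, 16))
            c = rng.normal(size=(8, 16))
            y = rng.integers(0, 10, 8)
            _, grads, _ = forward_backward(tiny_spec, tiny_params, x, y, c)
            adam_step(tiny_params, grads, adam, 1e-2)
        for p in tiny_params:
            np.testing.assert_array_equal(p.W * (1 - p.M), np.zeros_like(p.W))


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------


class TestForward:
    def test_rl_layer_sparsity_exact(self):
        """25% density on a 2800-unit layer leaves exactly 700 non-zeros."""
        spec = NetworkSpec(
            input_dim=39, hidden_dims=(2800,), output_dim=4, context_dim=10,
            weight_sparsity=0.1, activation_density=0.25, num_segments=10,
            modulated_layers=(0,),
        )
        params = init_params(spec, seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 39))
        c = np.tile(np.eye(10)[0], (4, 1))
        _, traces = forward(spec, params, x, c)
        assert traces[0].k == 700
        assert ((traces[0].y_hat != 0).sum(axis=1) == 700).all()

    def test_zero_context_halves_preactivation(self, tiny_spec, tiny_params):
        x = np.random.default_rng(2).normal(size=(5, 16))
        c = np.zeros((5, 16))
        _, traces = forward(tiny_spec, tiny_params, x, c)
        tr = traces[0]
        gated = tr.t_hat * 0.5
        np.testing.assert_allclose(
            np.where(tr.winners, gated, 0.0), tr.y_hat, rtol=1e-12
        )

    def test_missing_context_raises(self, tiny_spec, tiny_params):
        with pytest.raises(InvalidInputError):
            forward(tiny_spec, tiny_params, np.zeros((2, 16)), None)

    def test_wrong_input_width_raises(self, tiny_spec, tiny_params):
        with pytest.raises(InvalidInputError):
            forward(tiny_spec, tiny_params, np.zeros((2, 15)), np.zeros((2, 16)))


# ---------------------------------------------------------------------------
# gradient locality
# ---------------------------------------------------------------------------


class TestGradientLocality:
    def test_losers_and_nonwinning_segments_untouched(self, tiny_spec):
        """One training step: kWTA losers' rows and non-winning segments are
        bit-identical to their initial values."""
        params = init_params(tiny_spec, seed=3, dtype=np.float64)
        before = [(p.W.copy(), p.b.copy(), None if p.U is None else p.U.copy())
                  for p in params]
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 16))
        c = rng.normal(size=(6, 16))
        y = rng.integers(0, 10, 6)
        _, grads, _ = forward_backward(tiny_spec, params, x, y, c)
        _, traces = forward(tiny_spec, params, x, c)
        adam = AdamState.for_params(params)
        adam_step(params, grads, adam, 1e-2)
        for li in range(2):
            tr = traces[li]
            never_won = ~tr.winners.any(axis=0)
            assert never_won.any()  # the check must actually cover some neurons
            np.testing.assert_array_equal(
                params[li].W[never_won], before[li][0][never_won]
            )
            np.testing.assert_array_equal(
                params[li].b[never_won], before[li][1][never_won]
            )
            # segments: for each neuron, segments never selected on a winning
            # sample are bit-identical
            for o in range(tiny_spec.hidden_dims[li]):
                chosen = set(tr.j_star[tr.winners[:, o], o].tolist())
                for s in range(tiny_spec.num_segments):
                    if s not in chosen:
                        np.testing.assert_array_equal(
                            params[li].U[o, s], before[li][2][o, s]
                        )

    def test_gradients_match_numerical(self, tiny_spec):
        """Analytic gradients agree with central differences on unmasked entries."""
        params = init_params(tiny_spec, seed=5, dtype=np.float64)
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4, 16))
        c = rng.normal(size=(4, 16))
        y = rng.integers(0, 10, 4)
        _, grads, _ = forward_backward(tiny_spec, params, x, y, c)

        def loss():
            l, _, _ = forward_backward(tiny_spec, params, x, y, c)
            return l

        eps = 1e-6
        for li, p in enumerate(params):
            for key in grads[li]:
                arr = getattr(p, key)
                for _ in range(8):
                    idx = tuple(rng.integers(0, s) for s in arr.shape)
                    if key == "W" and p.M[idx] == 0:
                        continue
                    old = arr[idx]
                    arr[idx] = old + eps
                    lp = loss()
                    arr[idx] = old - eps
                    lm = loss()
                    arr[idx] = old
                    assert (lp - lm) / (2 * eps) == pytest.approx(
                        grads[li][key][idx], rel=1e-4, abs=1e-7
                    )


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------


class TestCountNonzeroParams:
    def test_rl_policy_total(self):
        spec = NetworkSpec(
            input_dim=39, hidden_dims=(2800, 2800), output_dim=4, context_dim=10,
            weight_sparsity=0.10, activation_density=0.25, num_segments=10,
            segment_dim=10, modulated_layers=(1,),
        )
        counts = count_nonzero_params(spec)
        assert counts["feedforward_count"] == 7_169_964
        assert counts["dendritic_count"] == 280_000
        assert counts["total"] == 7_449_964

    def test_cl_network_feedforward(self):
        spec = NetworkSpec(
            input_dim=784, hidden_dims=(2048, 2048), output_dim=10, context_dim=784,
            weight_sparsity=0.50, activation_density=0.05, num_segments=10,
        )
        counts = count_nonzero_params(spec)
        assert counts["feedforward_count"] == 2_914_314
        assert counts["dendritic_count"] == 10 * 3_211_264

    def test_dense_spec_equals_full_census(self):
        spec = NetworkSpec(input_dim=5, hidden_dims=(7,), output_dim=3)
        counts = count_nonzero_params(spec)
        assert counts["total"] == 5 * 7 + 7 + 7 * 3 + 3

    def test_matches_brute_force_census_on_random_specs(self):
        """Counts equal a census of non-zero entries in instantiated arrays."""
        rng = np.random.default_rng(123)
        for trial in range(20):
            n_hidden = int(rng.integers(1, 4))
            hidden = tuple(int(rng.integers(3, 30)) for _ in range(n_hidden))
            ctx = int(rng.integers(2, 12))
            modulated = tuple(
                i for i in range(n_hidden) if rng.random() < 0.6
            )
            spec = NetworkSpec(
                input_dim=int(rng.integers(2, 20)),
                hidden_dims=hidden,
                output_dim=int(rng.integers(2, 8)),
                context_dim=ctx if modulated else 0,
                weight_sparsity=float(rng.uniform(0, 0.9)),
                num_segments=int(rng.integers(1, 5)) if modulated else 0,
                modulated_layers=modulated,
            )
            params = init_params(spec, seed=trial, dtype=np.float64)
            census = 0
            for p in params:
                census += int((p.W != 0).sum()) + int((p.b != 0).sum())
                if p.U is not None:
                    census += int((p.U != 0).sum())
            assert census == count_nonzero_params(spec)["total"]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_params_roundtrip(tmp_path, tiny_spec, tiny_params):
    path = tmp_path / "params.npz"
    save_params(path, tiny_spec, tiny_params)
    spec2, params2 = load_params(path)
    assert spec2 == tiny_spec
    for a, b in zip(tiny_params, params2):
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.b, b.b)
        np.testing.assert_array_equal(a.M, b.M)
        if a.U is not None:
            np.testing.assert_array_equal(a.U, b.U)


def test_spec_validation_errors():
    with pytest.raises(ConfigurationError):
        NetworkSpec(input_dim=4, hidden_dims=(8,), output_dim=2, context_dim=3,
                    num_segments=2, segment_dim=4)  # segment_dim != context_dim
    with pytest.raises(ConfigurationError):
        NetworkSpec(input_dim=4, hidden_dims=(8,), output_dim=2,
                    activation_density=0.05)  # k < 1 on an 8-unit layer
    with pytest.raises(ConfigurationError):
        NetworkSpec(input_dim=4, hidden_dims=(8,), output_dim=2, context_dim=4,
                    num_segments=0, modulated_layers=(0,))
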