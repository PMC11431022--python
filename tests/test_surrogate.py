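import numpy as np
import pandas as pd
import pytest

from cpeopt.doe import DesignResponseTable
from cpeopt.factor_space import Factor, FactorSpace, ScalingParams
from cpeopt.surrogate import SurrogateModel, param_count, r_squared, search, train


@pytest.mark.parametrize(
    "topology,expected",
    [((14, 7, 3), 129), ((1, 1, 1), 4), ((14, 5, 3), 93)],
    ids=["reference-topology", "minimal", "five-hidden"],
)
def test_param_count(topology, expected):
    assert param_count(*topology) == expected


def test_param_count_rejects_empty_layers():
    with pytest.raises(ValueError):
        param_count(0, 1, 1)


def _toy_space(n):
    return FactorSpace(
        factors=tuple(
            Factor(f"x{i}", "continuous", low=0, high=1) for i in range(n)
        ),
        response_names=("TPC", "TC", "AA"),
    )


def _toy_table(rng, n_rows=30, n_in=4, noise=0.0):
    space = _toy_space(n_in)
    X = rng.uniform(0, 1, size=(n_rows, n_in))
    B = rng.normal(size=(n_in, 3))
    Y = 5 + X @ B + noise * rng.normal(size=(n_rows, 3))
    Y = Y - Y.min(axis=0) + 1.0     # keep responses positive
    frame = pd.DataFrame(X, columns=[f.name for f in space.factors])
    for j, name in enumerate(space.response_names):
        frame[name] = Y[:, j]
    return DesignResponseTable(space, frame)


class TestForward:
    def test_zero_weights_identity_net_predicts_inverse_scaled_zero(self, rng):
        table = _toy_table(rng)
        m = train(table, 2, seed=0, max_iter=1)
        zero = SurrogateModel(
            n_in=m.n_in, n_hidden=2, n_out=3,
            activations=("identity", "identity"),
            W=np.zeros((m.n_in, 2)), b1=np.zeros(2),
            V=np.zeros((2, 3)), b2=np.zeros(3),
            x_scaling=m.x_scaling, y_scaling=m.y_scaling,
        )
        pred = zero.forward(np.zeros(m.n_in))
        assert np.allclose(pred, m.y_scaling.invert(np.zeros(3)))

    def test_identity_net_is_affine_map(self, rng):
        """forward of an identity/identity net equals x_s @ (W V) + offset."""
        n_in, h, n_out = 5, 3, 2
        W = rng.normal(size=(n_in, h))
        b1 = rng.normal(size=h)
        V = rng.normal(size=(h, n_out))
        b2 = rng.normal(size=n_out)
        xs = ScalingParams(mins=np.zeros(n_in), maxs=np.ones(n_in))
        ys = ScalingParams(mins=np.zeros(n_out), maxs=np.ones(n_out))
        m = SurrogateModel(n_in=n_in, n_hidden=h, n_out=n_out,
                           activations=("identity", "identity"),
                           W=W, b1=b1, V=V, b2=b2, x_scaling=xs, y_scaling=ys)
        X = rng.uniform(size=(20, n_in))
        expected = X @ (W @ V) + (b1 @ V + b2)
        assert np.allclose(m.forward(X), expected, atol=1e-12)
        B, c = m.affine_equivalent()
        assert np.allclose(B, W @ V)

    def test_dimension_mismatch_raises(self, rng):
        table = _toy_table(rng)
        m = train(table, 2, seed=0, max_iter=5)
        with pytest.raises(ValueError, match="inputs"):
            m.forward(np.zeros(m.n_in + 1))


class TestTrain:
    def test_interpolation_matches_least_squares_oracle(self, table2):
        """On the 12-run screening table the identity net reaches the OLS
        optimum: with 14 inputs + bias >= 12 runs that is exact interpolation,
        r^2 = 1.000 for every output."""
        m = train(table2, 7, ("identity", "identity"), seed=1)
        r2 = r_squared(m, table2)
        assert np.all(np.round(r2, 3) == 1.0)
        # normal-equations oracle on the scaled problem
        Xs = m.x_scaling.apply(table2.encoded_inputs())
        Ys = m.y_scaling.apply(table2.response_matrix())
        A = np.column_stack([np.ones(len(Xs)), Xs])
        coef, *_ = np.linalg.lstsq(A, Ys, rcond=None)
        ols_loss = float(np.sum((A @ coef - Ys) ** 2))
        assert m.fit_stats["loss"] <= ols_loss + 1e-6

    def test_predicts_best_run_responses_when_interpolating(self, table2_model,
                                                            table2):
        pred = table2_model.forward(table2.encoded_inputs()[3])
        assert pred[0] == pytest.approx(348.56, abs=0.5)
        assert pred[1] == pytest.approx(16.4, abs=0.05)
        assert pred[2] == pytest.approx(968.99, abs=1.0)

    def test_recovers_generating_affine_coefficients(self, rng):
        """Noiseless linear data: the learned affine product matches OLS on the
        scaled scale (W, V individually are not identified; the product is)."""
        table = _toy_table(rng, n_rows=40, n_in=4, noise=0.0)
        m = train(table, 3, ("identity", "identity"), seed=3, max_iter=2000,
                  tol=1e-12)
        Xs = m.x_scaling.apply(table.encoded_inputs())
        Ys = m.y_scaling.apply(table.response_matrix())
        A = np.column_stack([np.ones(len(Xs)), Xs])
        coef, *_ = np.linalg.lstsq(A, Ys, rcond=None)
        B, c = m.affine_equivalent()
        assert np.allclose(B, coef[1:], atol=1e-4)
        assert np.allclose(c, coef[0], atol=1e-4)

    def test_fixed_seed_refit_is_bit_identical(self, table2):
        a = train(table2, 5, ("tanh", "identity"), seed=7)
        b = train(table2, 5, ("tanh", "identity"), seed=7)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.V, b.V)
        assert a.fit_stats["loss"] == b.fit_stats["loss"]

    def test_predictions_invariant_to_row_order(self, rng):
        table = _toy_table(rng, n_rows=30, n_in=3, noise=0.01)
        perm = rng.permutation(30)
        shuffled = DesignResponseTable(table.space,
                                       table.frame.iloc[perm])
        a = train(table, 1, seed=5, max_iter=2000, tol=1e-12)
        b = train(shuffled, 1, seed=5, max_iter=2000, tol=1e-12)
        X = rng.uniform(size=(10, 3))
        assert np.allclose(a.forward(X), b.forward(X), atol=1e-5)

    def test_loss_non_increasing_vs_initial(self, table2):
        """BFGS is a descent method: the converged loss never exceeds the
        loss at the random initialization (checked via a 0-iteration fit)."""
        start = train(table2, 5, ("logistic", "identity"), seed=11, max_iter=0)
        done = train(table2, 5, ("logistic", "identity"), seed=11)
        assert done.fit_stats["loss"] <= start.fit_stats["loss"]


class TestRSquared:
    def test_perfect_and_mean_only_predictors(self, rng):
        table = _toy_table(rng, n_rows=20, n_in=2)
        Y = table.response_matrix()

        class Stub:
            n_in = 2
            def forward(self, X):
                return Y

        perfect = Stub()
        assert np.allclose(r_squared(perfect, table), 1.0)
        mean = Stub()
        mean.forward = lambda X: np.tile(Y.mean(axis=0), (len(Y), 1))
        assert np.allclose(r_squared(mean, table), 0.0, atol=1e-12)

    def test_matches_textbook_formula_on_random_data(self, rng):
        table = _toy_table(rng, n_rows=25, n_in=3, noise=0.3)
        m = train(table, 2, seed=2, max_iter=50)
        got = r_squared(m, table)
        Y = table.response_matrix()
        P = m.forward(table.encoded_inputs())
        want = 1 - ((Y - P) ** 2).sum(0) / ((Y - Y.mean(0)) ** 2).sum(0)
        assert np.allclose(got, want, atol=1e-12)

    def test_zero_variance_output_reported_as_nan_with_warning(self, rng):
        table = _toy_table(rng, n_rows=10, n_in=2)
        frame = table.frame.copy()
        frame["TC"] = 5.0
        flat = DesignResponseTable(table.space, frame)
        m = train(flat, 2, seed=0, max_iter=5)
        with pytest.warns(UserWarning, match="zero"):
            r2 = r_squared(m, flat)
        assert np.isnan(r2[1])


class TestSearch:
    def test_single_config_single_restart_equals_train(self, table2):
        model, log = search(table2, hidden_sizes=(7,),
                            activation_options=(("identity", "identity"),),
                            n_restarts=1, seed=0)
        assert len(log) == 1
        direct = train(table2, 7, ("identity", "identity"),
                       seed=np.random.SeedSequence([0, 7, 0, 0]))
        assert np.array_equal(model.W, direct.W)

    def test_selected_mean_r2_reaches_one_on_screening_table(self, table2):
        model, _ = search(table2, hidden_sizes=(5, 7),
                          activation_options=(("identity", "identity"),),
                          n_restarts=2, seed=0)
        assert model.fit_stats["mean_r2"] == pytest.approx(1.0, abs=1e-4)

    def test_more_restarts_never_decrease_selected_score(self, rng):
        table = _toy_table(rng, n_rows=15, n_in=3, noise=0.5)
        kw = dict(hidden_sizes=(2, 3),
                  activation_options=(("tanh", "identity"),),
                  seed=4, max_iter=60)
        m1, _ = search(table, n_restarts=1, **kw)
        m2, _ = search(table, n_restarts=3, **kw)
        assert m2.fit_stats["mean_r2"] >= m1.fit_stats["mean_r2"] - 1e-12

    def test_log_flags_interpolation_regime(self, table2):
        _, log = search(table2, hidden_sizes=(7,),
                        activation_options=(("identity", "identity"),),
                        n_restarts=1, seed=0)
        assert log[0]["n_params"] == 129
        assert log[0]["interpolation_warning"] is True


def test_serialization_round_trip_preserves_predictions(table2_model, table2,
                                                        tmp_path):
    path = tmp_path / "model.json"
    table2_model.save(path)
    clone = SurrogateModel.load(path)
    X = table2.encoded_inputs()
    assert np.array_equal(clone.forward(X), table2_model.forward(X))
    assert clone.space.factor_names == table2.space.factor_names
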