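import numpy as np
import pytest

from cpeopt.doe import ovat_grid, pb_design
from cpeopt.factor_space import cpe_screening_space
from cpeopt.sensitivity import yoon
from cpeopt.surrogate import r_squared, train
from cpeopt.synthetic_data import (
    CategoricalEffect,
    ContinuousEffect,
    Gate,
    SimulatorConfig,
    default_config,
    full_ovat_space,
    simulate_table,
    true_effect_sizes,
    true_response,
)


@pytest.fixture(scope="module")
def config():
    return default_config(seed=0)


class TestTrueResponse:
    def test_non_clouding_surfactant_gates_to_zero(self, config):
        s = dict(config.stated_optimum)
        s["X1"] = "Span 85"
        assert np.array_equal(true_response(config, s), [0, 0, 0])
        s["X1"] = "Ceteareth-12"
        assert np.array_equal(true_response(config, s), [0, 0, 0])

    def test_non_separating_salt_and_low_salt_gate_to_zero(self, config):
        s = dict(config.stated_optimum)
        s["X7"] = "KCl"
        assert np.array_equal(true_response(config, s), [0, 0, 0])
        s["X7"] = "NaCl"
        s["X8"] = 10.0
        assert np.array_equal(true_response(config, s), [0, 0, 0])

    def test_stated_optimum_attains_the_maximum(self, config):
        """No single-factor move from the stated optimum improves the
        equally weighted sum of max-normalized responses (the surface is a
        per-factor product, so coordinate optimality is global optimality
        given the stated per-response maxima)."""
        # per-response maximum over the space: product of per-factor maxima
        # (piecewise-linear profiles attain their maxima at knots)
        norm = np.asarray(config.baselines, float).copy()
        for f in config.space.factors:
            eff = config.effects.get(f.name)
            if eff is not None:
                norm *= np.max([eff.at(v) for v in f.ovat_values()], axis=0)
        best = np.sum(true_response(config, config.stated_optimum) / norm)
        for f in config.space.factors:
            for v in f.ovat_values():
                s = dict(config.stated_optimum)
                s[f.name] = v
                score = np.sum(true_response(config, s) / norm)
                assert score <= best + 1e-9, (f.name, v)

    def test_temperature_peak_means_45_beats_75(self, config):
        s45 = dict(config.stated_optimum); s45["X5"] = 45.0
        s75 = dict(config.stated_optimum); s75["X5"] = 75.0
        assert np.all(true_response(config, s45) > true_response(config, s75))

    def test_ratio_peak_at_1_to_50(self, config):
        scores = []
        for ratio in (0.01, 0.02, 0.1):
            s = dict(config.stated_optimum); s["X3"] = ratio
            scores.append(true_response(config, s)[0])
        assert scores[1] > scores[0] and scores[1] > scores[2]


class TestSimulateTable:
    def test_zero_cv_reproduces_noiseless_truth(self, config):
        space = cpe_screening_space()
        design = pb_design(space)
        quiet = SimulatorConfig(
            space=config.space, baselines=config.baselines,
            effects=config.effects, gates=config.gates,
            noise_cv=(0, 0, 0), seed=0,
            stated_optimum=config.stated_optimum,
        )
        table = simulate_table(quiet, design, replicates=2, seed=1)
        expected = np.vstack([
            true_response(quiet, row)
            for _, row in design.settings_frame.iterrows()
        ])
        assert np.allclose(table.response_matrix(), expected)

    def test_fixed_seed_is_bit_identical(self, config):
        design = pb_design(cpe_screening_space())
        a = simulate_table(config, design, replicates=3, seed=5)
        b = simulate_table(config, design, replicates=3, seed=5)
        assert np.array_equal(a.response_matrix(), b.response_matrix())

    def test_gated_runs_stay_exactly_zero_under_noise(self, config):
        space = cpe_screening_space()
        design = ovat_grid(space, "X7", dict(config.stated_optimum))
        table = simulate_table(config, design, replicates=7, seed=2)
        kcl = table.frame["X7"] == "KCl"
        assert np.all(table.response_matrix()[kcl.to_numpy()] == 0.0)

    def test_replicate_mean_concentrates_on_truth(self, config):
        """Law of large numbers: at CV = 3%, the 1000-replicate mean of the
        log-normal noise lies within 0.5% of the noiseless value."""
        noisy = SimulatorConfig(
            space=config.space, baselines=config.baselines,
            effects=config.effects, gates=config.gates,
            noise_cv=(0.03, 0.03, 0.03), seed=0,
            stated_optimum=config.stated_optimum,
        )
        space = cpe_screening_space()
        design = ovat_grid(space, "X10", dict(config.stated_optimum))
        table = simulate_table(noisy, design, replicates=1000, seed=3)
        truth = np.vstack([
            true_response(noisy, row)
            for _, row in design.settings_frame.iterrows()
        ])
        # lognormal mean bias exp(cv^2/2) ~ 1.00045 is inside the band
        assert np.all(np.abs(table.response_matrix() / truth - 1) < 0.005)

    def test_monotone_profile_yields_monotone_simulated_means(self, config):
        space = cpe_screening_space()
        design = ovat_grid(space, "X6", dict(config.stated_optimum))
        table = simulate_table(config, design, replicates=200, seed=4)
        tpc = table.response_matrix()[:, 0]
        assert np.all(np.diff(tpc) < 0)   # equilibration time profile decreases


class TestGroundTruthIdentification:
    def test_single_active_factor_ranks_first_in_influence(self):
        space = cpe_screening_space()
        cfg = SimulatorConfig(
            space=full_ovat_space(), baselines=(300.0, 20.0, 900.0),
            effects={
                "X5": ContinuousEffect(
                    knots=(35, 75),
                    multipliers=((0.2, 1.0), (0.2, 1.0), (0.2, 1.0)),
                ),
            },
            gates=(), noise_cv=(0, 0, 0), seed=0,
        )
        design = pb_design(space)
        table = simulate_table(cfg, design, replicates=1, seed=0)
        model = train(table, 7, ("identity", "identity"), seed=0)
        rep = yoon(model)
        ranking = rep.by_factor_contrast.mean(axis=1)
        assert ranking.idxmax() == "X5"

    def test_noiseless_screening_table_is_interpolated_exactly(self, config):
        quiet = SimulatorConfig(
            space=config.space, baselines=config.baselines,
            effects=config.effects, gates=config.gates,
            noise_cv=(0, 0, 0), seed=0,
            stated_optimum=config.stated_optimum,
        )
        table = simulate_table(quiet, pb_design(cpe_screening_space()),
                               replicates=1, seed=0)
        model = train(table, 7, ("identity", "identity"), seed=0)
        assert np.all(np.round(r_squared(model, table), 3) == 1.0)

    def test_largest_true_effects_are_the_gating_factors(self, config):
        sizes = true_effect_sizes(config, cpe_screening_space())
        top = set(sizes.index[np.isclose(sizes, sizes.max())])
        assert top == {"X7", "X8"}


def test_gate_predicates():
    g = Gate("x", "lt", 5)
    assert g.triggered({"x": 4}) and not g.triggered({"x": 5})
    assert Gate("x", "in", ("a",)).triggered({"x": "a"})
    assert Gate("x", "ne", 1).triggered({"x": 2})
    with pytest.raises(ValueError):
        Gate("x", "within", 1).triggered({"x": 0})


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulatorConfig(space=full_ovat_space(), baselines=(-1, 0, 0),
                        effects={})
    with pytest.raises(ValueError):
        SimulatorConfig(space=full_ovat_space(), baselines=(1, 1, 1),
                        effects={}, noise_cv=(-0.1, 0, 0))
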