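"""Inference: objective contract, recovery, determinism, bootstrap."""

import math

import numpy as np
import pytest

import dcflux as dc
from dcflux.model import LOG_OFFSET, MigrationModel


def _truth_vector(model, params, x0_groups):
    """Full transformed parameter vector at a known truth."""
    rates = {
        "mu0": params.mu0,
        "alpha": params.alpha,
        "m": params.m if params.m > 0 else 1.0,
        "tau": params.tau,
        "delta_alum": params.delta_alum,
        "delta_saline": params.delta_saline,
        "delta": 0.5 * (params.delta_alum + params.delta_saline),
    }
    theta = [math.log(rates[name]) for name in model.spec.rate_param_names()]
    theta += [math.log(x0_groups[key]) for key in model.group_keys]
    return np.array(theta)


def _group_truth(synthetic):
    """Map the simulator's per-design x0 onto (condition, t_pc) group keys."""
    out = {}
    for design in dc.study_designs():
        key = f"{design.condition.value}:tpc{design.t_pc:g}"
        out[key] = synthetic.x0[design.design_id]
    return out


class TestResidualLoss:
    def test_zero_at_generating_truth_on_noiseless_data(self, noiseless_study, canonical):
        model = MigrationModel(noiseless_study.dataset, dc.ModelSpec(name="M3"))
        theta = _truth_vector(model, canonical, _group_truth(noiseless_study))
        assert model.residual_loss(theta) == pytest.approx(0.0, abs=1e-12)

    def test_positive_after_perturbing_any_parameter(self, noiseless_study, canonical):
        model = MigrationModel(noiseless_study.dataset, dc.ModelSpec(name="M3"))
        theta = _truth_vector(model, canonical, _group_truth(noiseless_study))
        for i in range(len(model.spec.rate_param_names())):
            bumped = theta.copy()
            bumped[i] += 0.05
            assert model.residual_loss(bumped) > 1e-8

    def test_loss_at_truth_tracks_lognormal_variance(self, canonical):
        """E[loss at truth] ~ n_obs * ln(1 + cv^2) for counts >> offset."""
        designs = [
            dc.PhotoconversionDesign(c, 12.0, (24.0, 36.0, 48.0), n_replicates=20,
                                     sites=("skin",))
            for c in ("alum", "saline")
        ]
        syn = dc.simulate_dataset(designs, canonical, noise=dc.NoiseModel(cv=0.2),
                                  seed=77)
        model = MigrationModel(syn.dataset, dc.ModelSpec(name="M3"))
        theta = _truth_vector(
            model, canonical,
            {k: syn.x0[d.design_id] for d, k in zip(designs, model.group_keys)},
        )
        expected = syn.dataset.n_obs * math.log(1.0 + 0.2**2)
        assert model.residual_loss(theta) == pytest.approx(expected, rel=0.25)

    def test_penalises_instead_of_raising(self, noisy_study):
        model = MigrationModel(noisy_study.dataset, dc.ModelSpec(name="M3"))
        theta = np.full(len(model.spec.rate_param_names()) + model.n_groups, 100.0)
        assert np.isfinite(model.residual_loss(theta))


class TestFit:
    def test_recovers_truth_from_noiseless_data(self, noiseless_study, canonical):
        model = MigrationModel(noiseless_study.dataset, dc.ModelSpec(name="M3"))
        res = model.fit(dc.OptimizerSettings(n_starts=4, seed=0))
        p = res.params
        for name in ("mu0", "alpha", "m", "tau", "delta_alum", "delta_saline"):
            assert getattr(p, name) == pytest.approx(
                getattr(canonical, name), rel=0.01
            ), name
        truth_x0 = _group_truth(noiseless_study)
        for key, value in res.x0_groups.items():
            assert value == pytest.approx(truth_x0[key], rel=0.01)

    def test_constant_spec_recovers_mu0_from_null_data(self, canonical):
        params = dc.RateParameters(mu0=canonical.mu0, alpha=0.0, m=0.0, tau=2.6,
                                   delta_alum=0.12, delta_saline=0.12)
        syn = dc.simulate_dataset(dc.study_designs(), params,
                                  noise=dc.NoiseModel(cv=0.1), seed=9)
        res = MigrationModel(
            syn.dataset, dc.ModelSpec("constant", "constant", True, name="M0")
        ).fit(dc.OptimizerSettings(n_starts=4, seed=0))
        assert res.rates["mu0"] == pytest.approx(canonical.mu0, rel=0.05)

    def test_identical_settings_give_identical_fit(self, noisy_study):
        settings = dc.OptimizerSettings(n_starts=3, max_iterations=800, seed=11)
        model = MigrationModel(noisy_study.dataset, dc.ModelSpec(name="M3"))
        a = model.fit(settings)
        b = model.fit(settings)
        assert a.rss == b.rss
        np.testing.assert_array_equal(a.theta, b.theta)
        assert a.x0_groups == b.x0_groups

    def test_returned_loss_never_exceeds_any_start(self, noisy_study):
        model = MigrationModel(noisy_study.dataset, dc.ModelSpec(name="M3"))
        res = model.fit(dc.OptimizerSettings(n_starts=5, max_iterations=800, seed=3))
        assert all(res.rss <= start + 1e-9 for start, _ in res.start_losses)

    def test_count_scaling_leaves_rates_unchanged(self, noiseless_study):
        """On noiseless data the optimum is scale-free: x0 absorbs the factor."""
        settings = dc.OptimizerSettings(n_starts=3, seed=0)
        base = MigrationModel(noiseless_study.dataset, dc.ModelSpec(name="M3")).fit(settings)
        scaled = MigrationModel(
            noiseless_study.dataset.scaled(37.0), dc.ModelSpec(name="M3")
        ).fit(settings)
        for name in base.spec.rate_param_names():
            assert scaled.rates[name] == pytest.approx(base.rates[name], rel=1e-6)

    def test_insufficient_data_rejected(self, canonical):
        design = dc.PhotoconversionDesign("alum", 12.0, (24.0,), n_replicates=3)
        syn = dc.simulate_dataset([design], canonical, seed=0)
        with pytest.raises(ValueError):
            MigrationModel(syn.dataset, dc.ModelSpec(name="M3"))

    def test_weak_tau_flag(self, noisy_study, canonical):
        sparse = MigrationModel(noisy_study.dataset, dc.ModelSpec(name="M3"))
        assert sparse.tau_weakly_identified  # earliest dLN lead time is 12 h
        dense = dc.simulate_dataset(dc.dense_designs(), canonical, seed=0)
        assert not MigrationModel(dense.dataset, dc.ModelSpec(name="M3")).tau_weakly_identified

    def test_summary_mentions_model_and_estimates(self, noisy_study):
        res = MigrationModel(noisy_study.dataset, dc.ModelSpec(name="M3")).fit(
            dc.OptimizerSettings(n_starts=2, max_iterations=600, seed=0)
        )
        text = res.summary()
        assert "AIC" in text and "tau" in text and "half-life" in text


class TestBootstrap:
    def test_noiseless_intervals_collapse(self, canonical):
        designs = dc.dense_designs(n_replicates=3)
        syn = dc.simulate_dataset(designs, canonical, noise=dc.NoiseModel(cv=0.0),
                                  seed=0)
        res = MigrationModel(syn.dataset, dc.ModelSpec(name="M3")).fit(
            dc.OptimizerSettings(n_starts=3, seed=0)
        )
        cis = res.bootstrap_cis(
            n_boot=8, seed=1,
            settings=dc.OptimizerSettings(n_starts=1, max_iterations=1000, seed=0),
        )
        for name, (lo, hi) in cis.items():
            est = res.rates[name]
            assert hi - lo <= 0.01 * est, name

    def test_rejects_tiny_n_boot(self, noisy_study):
        res = MigrationModel(noisy_study.dataset, dc.ModelSpec(name="M3")).fit(
            dc.OptimizerSettings(n_starts=1, max_iterations=400, seed=0)
        )
        with pytest.raises(ValueError):
            res.bootstrap_cis(n_boot=1)


def test_log_offset_is_one_cell():
    assert LOG_OFFSET == 1.0
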