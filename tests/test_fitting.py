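"""Global fitting: cost structure, multi-start recovery, stability probe."""

import numpy as np
import pytest

from hergkin import (
    ConfigurationError,
    global_fit,
    residual_cost,
    stability_check,
)
from hergkin.fitting import Dataset, FitProblem
from hergkin.protocols import make_recovery_protocol, make_ssa_protocol
from hergkin.synth import generate_synthetic_dataset


@pytest.fixture(scope="module")
def light_protocols():
    """A reduced two-protocol battery to keep unit tests quick."""
    return [
        (make_ssa_protocol(increment=20.0), "ssa"),
        (make_recovery_protocol(), "recovery_tau"),
    ]


@pytest.fixture(scope="module")
def noiseless_problem(m1, p1a, light_protocols):
    truth = p1a.with_corrections({"aa": (0.5, 1.0), "bb": (2.0, 1.0)})
    ds = generate_synthetic_dataset(truth, m1, light_protocols, noise_sd_fraction=0.0)
    return ds.fit_problem(p1a, free=[("aa", "a"), ("bb", "a")])


class TestResidualCost:
    def test_zero_at_generating_corrections(self, noiseless_problem):
        cost = residual_cost({"aa": (0.5, 1.0), "bb": (2.0, 1.0)}, noiseless_problem)
        assert cost == pytest.approx(0.0, abs=1e-20)

    def test_weight_scales_contribution_linearly(self, m1, p1a, light_protocols):
        truth = p1a.with_corrections({"aa": (0.7, 1.0)})
        base_ds = generate_synthetic_dataset(truth, m1, light_protocols, 0.0)
        identity = {"aa": (1.0, 1.0)}

        def cost_with_weights(w):
            datasets = [
                Dataset(d.protocol, d.kind, d.targets, weight=wi)
                for d, wi in zip(base_ds.datasets, w)
            ]
            prob = FitProblem(
                scheme=m1, base_params=p1a, datasets=datasets, free=[("aa", "a")]
            )
            return residual_cost(identity, prob)

        c11 = cost_with_weights([1.0, 1.0])
        c21 = cost_with_weights([2.0, 1.0])
        c12 = cost_with_weights([1.0, 2.0])
        # doubling one weight adds exactly that dataset's cost again
        assert c21 + c12 == pytest.approx(3.0 * c11, rel=1e-9)

    def test_cost_increases_away_from_optimum(self, noiseless_problem):
        c0 = residual_cost({"aa": (0.5, 1.0), "bb": (2.0, 1.0)}, noiseless_problem)
        for factor in (0.8, 1.25):
            c = residual_cost(
                {"aa": (0.5 * factor, 1.0), "bb": (2.0, 1.0)}, noiseless_problem
            )
            assert c > c0 + 1e-8

    def test_bounds_must_contain_identity(self, m1, p1a, noiseless_problem):
        with pytest.raises(ConfigurationError):
            FitProblem(
                scheme=m1,
                base_params=p1a,
                datasets=noiseless_problem.datasets,
                free=[("aa", "a")],
                bounds_a=(2.0, 100.0),
            )


class TestGlobalFit:
    def test_noiseless_recovery_from_multistart(self, noiseless_problem):
        res = global_fit(noiseless_problem, n_starts=4, seed=5)
        assert res.corrections["aa"][0] == pytest.approx(0.5, rel=0.01)
        assert res.corrections["bb"][0] == pytest.approx(2.0, rel=0.01)

    def test_single_start_from_optimum_stays_there(self, m1, p1a, light_protocols):
        ds = generate_synthetic_dataset(p1a, m1, light_protocols, 0.0)
        prob = ds.fit_problem(p1a, free=[("aa", "a")])
        res = global_fit(prob, n_starts=1, seed=0)
        assert res.cost == pytest.approx(0.0, abs=1e-12)
        assert res.corrections["aa"][0] == pytest.approx(1.0, rel=1e-6)

    def test_same_seed_reproduces_bit_identical_result(self, noiseless_problem):
        r1 = global_fit(noiseless_problem, n_starts=3, seed=42)
        r2 = global_fit(noiseless_problem, n_starts=3, seed=42)
        assert r1.start_costs == r2.start_costs
        assert r1.corrections == r2.corrections
        assert r1.best_start == r2.best_start

    def test_effective_rates_reflect_corrections(self, noiseless_problem):
        res = global_fit(noiseless_problem, n_starts=4, seed=5)
        alpha_eff = res.effective_rates["aa"][0]
        base_alpha = noiseless_problem.base_params.rates["aa"].alpha
        assert alpha_eff == pytest.approx(res.corrections["aa"][0] * base_alpha)


class TestStabilityCheck:
    def test_well_constrained_problem_has_no_flags(self, noiseless_problem):
        res = global_fit(noiseless_problem, n_starts=2, seed=1)
        report = stability_check(res, noiseless_problem, epsilon=0.05, floor=1e-6)
        assert not any(e.unidentifiable for e in report)
        for e in report:
            assert e.curvature > 0

    def test_parameter_without_observable_effect_flagged(self, m1, p1a):
        # an SSA-only problem cannot see corrections to the
        # voltage-independent intermediate closing step at these scales
        ds = generate_synthetic_dataset(
            p1a, m1, [(make_ssa_protocol(increment=35.0), "ssa")], 0.0
        )
        prob = ds.fit_problem(p1a, free=[("bin", "a")])
        res = global_fit(prob, n_starts=1, seed=0)
        report = stability_check(res, prob, epsilon=1e-4, floor=1e-9)
        assert report[0].unidentifiable

    def test_curvature_matches_finite_difference_oracle(self, noiseless_problem):
        res = global_fit(noiseless_problem, n_starts=2, seed=1)
        eps = 1e-3
        report = stability_check(res, noiseless_problem, epsilon=eps)
        # independent central-difference oracle on residual_cost
        c0 = residual_cost(res.corrections, noiseless_problem)
        for j, e in enumerate(report):
            name, which = e.parameter
            x = np.log(res.corrections[name][0]) if which == "a" else res.corrections[name][1]
            step = eps * max(abs(x), 1.0)
            costs = []
            for sgn in (+1, -1):
                corr = dict(res.corrections)
                ca, cb = corr[name]
                if which == "a":
                    corr[name] = (float(np.exp(x + sgn * step)), cb)
                else:
                    corr[name] = (ca, x + sgn * step)
                costs.append(residual_cost(corr, noiseless_problem))
            oracle = (costs[0] + costs[1] - 2 * c0) / step**2
            assert e.curvature == pytest.approx(oracle, rel=1e-6)
            # near the optimum the basin is locally quadratic: the two
            # one-sided costs agree to the cubic correction
            denom = max(e.cost_plus, e.cost_minus, 1e-300)
            assert abs(e.cost_plus - e.cost_minus) / denom < 0.3
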