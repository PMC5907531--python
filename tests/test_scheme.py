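"""Scheme topology, generator assembly, and microscopic reversibility."""

import math

import numpy as np
import pytest

from hergkin import (
    ConfigurationError,
    RateLaw,
    build_generator,
    constrain_reversibility,
    get_scheme,
    loop_closure_ratio,
    mmodel1,
    mmodel2,
)
from hergkin.scheme import ParameterSet


class TestTopology:
    def test_linear_chain_has_five_states_eight_edges(self, m1):
        assert m1.states == ("C3", "C2", "C1", "O", "I")
        assert len(m1.transitions) == 8
        assert not m1.loops

    def test_looped_scheme_adds_direct_closed_inactivated_edge(self, m2):
        assert len(m2.transitions) == 10
        assert m2.loops == (("C1", "O", "I"),)
        assert m2.edge("C1", "I").name == "ci"
        assert m2.edge("I", "C1").constrained

    def test_unknown_scheme_name_rejected(self):
        with pytest.raises(ConfigurationError):
            get_scheme("mmodel3")


class TestBuildGenerator:
    @pytest.mark.parametrize("V", [-120.0, -80.0, 0.0, 40.0])
    def test_chain_generator_has_eight_offdiagonals(self, m1, p1a, V):
        Q = build_generator(m1, p1a, V)
        off = Q[~np.eye(5, dtype=bool)]
        assert (off >= 0).all()
        assert np.count_nonzero(off) == 8
        # non-adjacent pairs exactly zero
        assert Q[0, 2] == 0.0 and Q[4, 0] == 0.0 and Q[3, 0] == 0.0

    @pytest.mark.parametrize("V", [-120.0, -80.0, 0.0, 40.0])
    @pytest.mark.parametrize("which", ["m1a", "m1b", "m2a", "m2b"])
    def test_columns_sum_to_zero(self, V, which, m1, m2, p1a, p1b, p2a, p2b):
        scheme, params = {
            "m1a": (m1, p1a), "m1b": (m1, p1b),
            "m2a": (m2, p2a), "m2b": (m2, p2b),
        }[which]
        params = constrain_reversibility(scheme, params)
        Q = build_generator(scheme, params, V)
        assert np.abs(Q.sum(axis=0)).max() < 1e-12

    def test_looped_scheme_late_activation_entry(self, m2, p2a):
        params = constrain_reversibility(m2, p2a)
        Q = build_generator(m2, params, 0.0)
        i_c1, i_o = m2.state_index("C1"), m2.state_index("O")
        assert Q[i_o, i_c1] == pytest.approx(8.80e-2, rel=1e-12)

    def test_missing_transition_parameter_names_it(self, m1, p1a):
        broken = ParameterSet(
            scheme_name="mmodel1",
            isoform="hERG1a",
            rates={k: v for k, v in p1a.rates.items() if k != "aa"},
        )
        with pytest.raises(ConfigurationError, match="aa"):
            build_generator(m1, broken, 0.0)


class TestReversibility:
    def test_chain_without_loops_returned_unchanged(self, m1, p1a):
        assert constrain_reversibility(m1, p1a) is p1a

    def test_derived_reverse_rate_matches_product_formula(self, m2, p2a):
        # hand oracle: k_IC1 = k_OC1 * k_IO * k_C1I / (k_C1O * k_OI) on alphas
        r = p2a.rates
        alpha = r["bb"].alpha * r["ai"].alpha * r["ci"].alpha / (
            r["aa"].alpha * r["bi"].alpha
        )
        beta = (
            r["bb"].beta + r["ai"].beta + r["ci"].beta
            - r["aa"].beta - r["bi"].beta
        )
        closed = constrain_reversibility(m2, p2a)
        ic = closed.rates["ic"]
        assert ic.alpha == pytest.approx(alpha, rel=1e-12)
        assert ic.alpha == pytest.approx(1.11e-10, rel=5e-3)
        assert ic.beta == pytest.approx(beta, rel=1e-12)

    @pytest.mark.parametrize("V", [-120.0, -80.0, 0.0, 40.0, 60.0])
    @pytest.mark.parametrize("iso", ["a", "b"])
    def test_loop_product_balances_at_all_voltages(self, m2, p2a, p2b, V, iso):
        params = constrain_reversibility(m2, p2a if iso == "a" else p2b)
        assert loop_closure_ratio(m2, params, V) == pytest.approx(1.0, abs=1e-10)

    def test_closure_commutes_with_corrections(self, m2, p2b):
        tweaked = p2b.with_corrections({"aa": (2.0, 1.1), "bi": (0.5, 1.0)})
        params = constrain_reversibility(m2, tweaked)
        for V in (-80.0, 40.0):
            assert loop_closure_ratio(m2, params, V) == pytest.approx(1.0, abs=1e-10)

    def test_underdetermined_loop_rejected(self, m2, p2a):
        from hergkin.scheme import MarkovScheme, Transition

        bad = MarkovScheme(
            name="mmodel2",
            states=m2.states,
            open_state="O",
            inactivated_states=("I",),
            transitions=tuple(
                Transition(t.name, t.source, t.target, t.voltage_dependent, True)
                if t.name in ("ic", "ci")
                else t
                for t in m2.transitions
            ),
            loops=m2.loops,
        )
        with pytest.raises(ConfigurationError, match="constrained"):
            constrain_reversibility(bad, p2a)


class TestShippedTableConsistency:
    """The b/a prefactor ratios implied by the shipped fixtures."""

    def test_chain_model_ratios(self, p1a, p1b):
        assert p1b.rates["aa"].alpha / p1a.rates["aa"].alpha == pytest.approx(3.46, abs=5e-3)
        assert p1b.rates["ain"].alpha / p1a.rates["ain"].alpha == pytest.approx(2.28, abs=5e-3)
        assert p1b.rates["bb"].alpha / p1a.rates["bb"].alpha == pytest.approx(7.83, rel=5e-3)

    def test_looped_model_late_deactivation_ratio(self, p2a, p2b):
        assert p2b.rates["bb"].alpha / p2a.rates["bb"].alpha == pytest.approx(15.28, rel=5e-3)
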