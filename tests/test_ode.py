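"""Mass-action ODE engine and compartmental protocols."""

import math

import numpy as np
import pytest

from plcgamma import ode
from plcgamma.params import ParameterSet
from plcgamma.states import Nsh2


class TestRateFunction:
    def test_zero_rates_give_zero_derivative(self):
        p = ParameterSet(
            **{name: 0.0 for name in (
                "k_on_nSH2", "k_off_nSH2", "k_phos", "k_dephos", "k_bind_c",
                "k_unbind_c", "k_bind_p", "k_unbind_p", "k_act", "k_inact",
            )}
        )
        net = ode.make_network(p)
        rhs = ode.build_rate_function(net)
        c = np.random.default_rng(0).uniform(0, 0.05, net.n_species)
        assert np.all(rhs(0.0, c) == 0.0)

    def test_derivative_conserves_totals_exactly(self, base_network):
        rhs = ode.build_rate_function(base_network)
        rng = np.random.default_rng(1)
        for _ in range(5):
            c = rng.uniform(0, 0.05, base_network.n_species)
            dc = rhs(0.0, c)
            w = base_network.conservation_vectors()
            scale = np.abs(dc).sum()  # fluxes reach χ-scale magnitudes
            assert abs(w["plc"] @ dc) < 1e-14 * scale
            assert abs(w["rtk"] @ dc) < 1e-14 * scale

    def test_bimolecular_flux_arithmetic(self, base_network):
        # k=1 μM⁻¹s⁻¹ × 0.02 μM × 0.05 μM = 0.001 μM/s into the complex
        rhs = ode.build_rate_function(base_network)
        c = np.zeros(base_network.n_species)
        rest = base_network.species_for_state(ode.AUTOINHIBITED)
        c[rest] = 0.02
        c[base_network.rtk_index] = 0.05
        dc = rhs(0.0, c)
        bound = base_network.species_for_state(
            ode.AUTOINHIBITED.replace("nsh2", Nsh2.RTK_BOUND)
        )
        assert dc[bound] == pytest.approx(0.001)

    def test_negative_override_rejected(self, base_network):
        with pytest.raises(ValueError, match="negative rate"):
            ode.build_rate_function(base_network, {"k_act": -1.0})


class TestSimulate:
    def test_conservation_along_trajectory(self, base_network):
        traj = ode.simulate(base_network, t_end=500.0)
        tot = traj.totals()
        assert np.ptp(tot["plc"]) / 0.02 < 1e-6
        assert np.ptp(tot["rtk"]) / 0.05 < 1e-6

    def test_all_rates_zero_trajectory_constant(self):
        p = ParameterSet(
            **{name: 0.0 for name in (
                "k_on_nSH2", "k_off_nSH2", "k_phos", "k_dephos", "k_bind_c",
                "k_unbind_c", "k_bind_p", "k_unbind_p", "k_act", "k_inact",
            )}
        )
        net = ode.make_network(p)
        traj = ode.simulate(net, t_end=100.0)
        assert np.allclose(traj.concentrations, traj.concentrations[:, [0]])

    def test_cytosol_only_equilibrium_matches_three_state_chain(self):
        """Without receptor or phosphorylation the active fraction equals
        K_a/(1 + K_c + K_a): the autoinhibited ⇌ free ⇌ active chain."""
        p = ParameterSet(rtk_total=0.0, k_phos=0.0)
        net = ode.make_network(p)
        res = ode.simulate_to_steady_state(net)
        expected = p.K_a / (1.0 + p.K_c + p.K_a)  # 0.1/101.1
        assert res.converged
        assert res.active_fraction_ss == pytest.approx(expected, rel=1e-4)

    def test_steady_state_independent_of_initial_distribution(self, base_network):
        ref = ode.simulate_to_steady_state(base_network).final_state
        rng = np.random.default_rng(42)
        plc_idx = [
            sp.id for sp in base_network.species if sp.plc_state is not None
        ]
        for _ in range(3):
            c0 = np.zeros(base_network.n_species)
            weights = rng.dirichlet(np.ones(len(plc_idx)))
            c0[plc_idx] = 0.02 * weights
            c0[base_network.rtk_index] = 0.05
            # complexes consume receptor: keep the RTK total consistent
            bound = sum(
                c0[sp.id] for sp in base_network.species
                if sp.plc_state is not None and sp.plc_state.rtk_bound
            )
            c0[base_network.rtk_index] -= bound
            final = ode.simulate_to_steady_state(base_network, c0).final_state
            assert np.allclose(final, ref, atol=1e-8)

    def test_negative_initial_state_rejected(self, base_network):
        c0 = ode.default_initial_state(base_network)
        c0[0] = -1e-3
        with pytest.raises(ValueError):
            ode.simulate(base_network, c0)


def test_equilibrium_satisfies_detailed_balance_without_phosphorylation():
    """With the chemically driven phosphorylation cycle disabled, the
    long-time state has zero net flux through every reversible pair."""
    p = ParameterSet(k_phos=0.0, k_dephos=0.0)
    net = ode.make_network(p)
    traj = ode.simulate(net, t_end=5000.0)
    c = traj.final_state()
    k = np.array([r.rate_value for r in net.reactions])

    def flux(rxn):
        v = k[rxn.id]
        for i in rxn.reactant_ids:
            v *= c[i]
        return v

    scale = max(flux(r) for r in net.reactions) + 1e-30
    for i, j in net.reversible_pairs():
        fwd, rev = flux(net.reactions[i]), flux(net.reactions[j])
        assert abs(fwd - rev) / scale < 1e-6, (i, j)


class TestHalftime:
    def test_single_exponential_closed_form(self):
        lam = 0.03
        t = np.linspace(0, 400, 4001)
        a = 0.7 * (1 - np.exp(-lam * t))
        t_half = ode.activation_halftime(t, a, 0.7)
        assert t_half == pytest.approx(math.log(2) / lam, rel=1e-4)

    def test_two_state_relaxation_rate(self):
        # kf=0.02, kr=0.08 -> t_half = ln2/(kf+kr) = ln2/0.1
        from plcgamma.analysis import two_state_trajectory

        t = np.linspace(0, 200, 2001)
        a = two_state_trajectory(0.02, 0.08, t)
        t_half = ode.activation_halftime(t, a, a[-1])
        assert t_half == pytest.approx(math.log(2) / 0.1, rel=1e-3)

    def test_grid_refinement_invariance(self):
        lam = 0.05
        vals = []
        for n in (201, 2001):
            t = np.linspace(0, 300, n)
            a = 1 - np.exp(-lam * t)
            vals.append(ode.activation_halftime(t, a, 1.0))
        assert vals[0] == pytest.approx(vals[1], rel=1e-3)

    def test_unbracketed_crossing_raises(self):
        t = np.linspace(0, 10, 11)
        a = np.full(11, 0.01)
        with pytest.raises(ValueError, match="not bracketed"):
            ode.activation_halftime(t, a, 1.0)


class TestDoseResponse:
    def test_curve_monotone_in_receptor_dose(self, base_params):
        curve = ode.dose_response(base_params, np.linspace(0.005, 0.05, 5))
        assert (np.diff(curve.active_fraction_ss) > 0).all()

    def test_nonphosphorylatable_below_phosphomimetic_everywhere(self, base_params):
        doses = np.linspace(0.005, 0.05, 4)
        y783f = ode.dose_response(base_params.with_edits(k_phos=0.0), doses)
        mimetic = ode.dose_response(
            base_params.with_edits(k_dephos=0.0), doses, phospho_init=True
        )
        assert (
            y783f.active_fraction_ss.values < mimetic.active_fraction_ss.values
        ).all()

    def test_phosphorylation_rate_effect_saturates(self, base_params):
        """Raising k_phos 1→10 s⁻¹ moves the curve more than 10→100 s⁻¹."""
        doses = [0.02]
        a = {
            k: ode.dose_response(
                base_params.with_edits(k_phos=float(k)), doses
            ).active_fraction_ss[0]
            for k in (1, 10, 100)
        }
        assert a[10] - a[1] > a[100] - a[10] > 0

    def test_zero_dose_limit_equals_cytosolic_equilibrium(self, base_params):
        p = base_params.with_edits(k_phos=0.0)
        curve = ode.dose_response(p, [0.0])
        expected = p.K_a / (1.0 + p.K_c + p.K_a)
        assert curve.active_fraction_ss[0] == pytest.approx(expected, rel=1e-4)


@pytest.mark.parametrize(
    "param, direction",
    [
        ("k_bind_c", -1),   # stronger autoinhibition lowers activity
        ("k_unbind_c", +1),
        ("k_bind_p", +1),
        ("k_act", +1),
        ("k_phos", +1),
    ],
)
def test_steady_state_monotonic_in_parameters(base_params, param, direction):
    a = []
    for fac in (0.5, 2.0):
        p = base_params.scaled(**{param: fac})
        net = ode.make_network(p)
        a.append(ode.simulate_to_steady_state(net, t_end=3000.0).active_fraction_ss)
    assert direction * (a[1] - a[0]) > 0


class TestDecayProtocol:
    def test_active_fraction_decays_monotonically(self, base_params):
        res = ode.decay_protocol(base_params)
        a = res.post.active_fraction
        assert res.half_life > 0
        assert a[-1] < 0.5 * res.active_at_switch
        # allow solver-level wiggle but require monotone decline overall
        assert (np.diff(a) < 1e-6).all()

    def test_half_life_increases_with_k_act(self, base_params):
        base = ode.decay_protocol(base_params).half_life
        fast = ode.decay_protocol(base_params.scaled(k_act=10)).half_life
        assert fast > base

    def test_half_life_insensitive_to_k_phos(self, base_params):
        """10× spans of k_act change the lifetime far more than k_phos."""
        def span(param):
            lo = ode.decay_protocol(base_params.scaled(**{param: 0.1})).half_life
            hi = ode.decay_protocol(base_params.scaled(**{param: 10})).half_life
            return max(lo, hi) / min(lo, hi)

        assert span("k_act") > 5 * span("k_phos")

    def test_unconverged_switch_raises(self, base_params):
        with pytest.raises(RuntimeError, match="not converged"):
            ode.decay_protocol(base_params, switch_time=5.0)
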