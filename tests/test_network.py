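"""Rule expansion into the 17-species / 53-reaction mass-action network."""

import itertools

import numpy as np
import pytest

from plcgamma.network import SpeciesKind, generate_network
from plcgamma.rules import RuleSet

# ---------------------------------------------------------------------------
# Independent oracle: nested loops over plain tuples, no pattern machinery.
# States are (nsh2, y783, csh2, core) strings; a reaction is
# (reactants, products, rate_name) with species as sorted label tuples.
# ---------------------------------------------------------------------------

RTK = "RTK"


def _oracle_states():
    out = []
    for nsh2, y783, csh2, core in itertools.product(
        ["free", "rtk_bound"],
        ["unphos", "phos"],
        ["free", "core_bound", "py_bound"],
        ["inactive", "active"],
    ):
        if csh2 == "core_bound" and core == "active":
            continue
        if csh2 == "py_bound" and y783 == "unphos":
            continue
        out.append((nsh2, y783, csh2, core))
    return out


def _oracle_reactions():
    reactions = []

    def add(r, p, k):
        reactions.append((tuple(sorted(map(str, r))), tuple(sorted(map(str, p))), k))

    for s in _oracle_states():
        nsh2, y783, csh2, core = s
        bound = ("rtk_bound", y783, csh2, core)
        free = ("free", y783, csh2, core)
        if nsh2 == "free" and core == "inactive":
            add([s, RTK], [bound], "k_on_nSH2")
        if nsh2 == "free" and core == "active":
            add([s, RTK], [bound], "k_on_nSH2_2")
        if nsh2 == "rtk_bound":
            add([s], [free, RTK], "k_off_nSH2")
        if nsh2 == "rtk_bound" and y783 == "unphos":
            add([s], [(nsh2, "phos", csh2, core)], "k_phos")
        if y783 == "phos" and csh2 != "py_bound":
            add([s], [(nsh2, "unphos", csh2, core)], "k_dephos")
        if csh2 == "free" and core == "inactive":
            add([s], [(nsh2, y783, "core_bound", core)], "k_bind_c")
        if csh2 == "core_bound":
            add([s], [(nsh2, y783, "free", core)], "k_unbind_c")
        if csh2 == "free" and y783 == "phos":
            add([s], [(nsh2, y783, "py_bound", core)], "k_bind_p")
        if csh2 == "py_bound":
            add([s], [(nsh2, y783, "free", core)], "k_unbind_p")
        if core == "inactive" and csh2 != "core_bound" and nsh2 == "free":
            add([s], [(nsh2, y783, csh2, "active")], "k_act")
        if core == "inactive" and csh2 != "core_bound" and nsh2 == "rtk_bound":
            add([s], [(nsh2, y783, csh2, "active")], "k_act_2")
        if core == "active":
            add([s], [(nsh2, y783, csh2, "inactive")], "k_inact")
    return reactions


def _network_as_multiset(net):
    """Package network rendered in the oracle's tuple vocabulary."""

    def name(idx):
        sp = net.species[idx]
        if sp.kind is SpeciesKind.RTK_FREE:
            return RTK
        st = sp.plc_state
        return str((st.nsh2.value, st.y783.value, st.csh2.value, st.core.value))

    out = []
    for r in net.reactions:
        out.append(
            (
                tuple(sorted(name(i) for i in r.reactant_ids)),
                tuple(sorted(name(i) for i in r.product_ids)),
                r.rate_constant,
            )
        )
    return out


def test_base_network_has_17_species_53_reactions(base_network):
    assert base_network.n_species == 17
    assert base_network.n_reactions == 53
    kinds = [sp.kind for sp in base_network.species]
    assert kinds.count(SpeciesKind.PLC_FREE) == 8
    assert kinds.count(SpeciesKind.PLC_RTK_COMPLEX) == 8
    assert kinds.count(SpeciesKind.RTK_FREE) == 1


def test_expansion_equals_brute_force_oracle(base_network):
    oracle = _oracle_reactions()
    got = _network_as_multiset(base_network)
    assert sorted(got) == sorted(oracle)
    assert len(oracle) == 53


def test_per_rule_instance_counts(ruleset, base_network):
    counts = base_network.per_rule_counts()
    expected = dict(
        zip([r.name for r in ruleset], [5, 3, 8, 3, 6, 4, 4, 4, 4, 3, 3, 6])
    )
    assert counts == expected
    assert sum(counts.values()) == 53


def test_removing_phosphorylation_rule_drops_three_reactions(base_params, ruleset):
    pruned = RuleSet(
        tuple(r for r in ruleset if r.name != "Y783_phosphorylation"),
        ruleset.couplings,
    )
    net = generate_network(pruned, base_params)
    assert net.n_reactions == 50


def test_generation_is_deterministic_and_idempotent(base_params, ruleset):
    a = generate_network(ruleset, base_params)
    b = generate_network(ruleset, base_params)
    assert [sp.label for sp in a.species] == [sp.label for sp in b.species]
    assert np.array_equal(a.stoichiometry_matrix(), b.stoichiometry_matrix())


def test_stoichiometry_conserves_plc_and_rtk(base_network):
    S = base_network.stoichiometry_matrix()
    assert S.shape == (17, 53)
    w = base_network.conservation_vectors()
    assert np.allclose(w["plc"] @ S, 0.0)
    assert np.allclose(w["rtk"] @ S, 0.0)


def test_binding_columns_have_bimolecular_stoichiometry(base_network):
    S = base_network.stoichiometry_matrix()
    for rxn in base_network.reactions:
        col = S[:, rxn.id]
        if rxn.bimolecular:
            assert sorted(col[col != 0]) == [-1, -1, 1]
            assert col[base_network.rtk_index] == -1
        else:
            assert set(col[col != 0]) <= {-1, 1}


def test_chi_enhanced_rates_bound_into_reactions(base_network):
    by_k = {}
    for r in base_network.reactions:
        by_k.setdefault(r.rate_constant, set()).add(r.rate_value)
    assert by_k["k_on_nSH2_2"] == {1000.0}
    assert by_k["k_act_2"] == {10.0}


def test_unknown_rate_constant_rejected(base_params, ruleset):
    from plcgamma.rules import Rule
    from plcgamma.states import Core

    bogus = Rule(
        "bogus", {"core": frozenset([Core.ACTIVE])}, "core", Core.INACTIVE,
        "k_not_a_constant",
    )
    with pytest.raises(ValueError, match="k_not_a_constant"):
        generate_network(RuleSet((bogus,), {}), base_params)


def test_reversible_pair_detection(base_network):
    pairs = base_network.reversible_pairs()
    # every binding/unbinding and activation/inactivation instance pairs up;
    # the 3 phosphorylation events pair with 3 of the dephosphorylations
    assert len(pairs) == 25
    for i, j in pairs:
        ri, rj = base_network.reactions[i], base_network.reactions[j]
        assert sorted(ri.reactant_ids) == sorted(rj.product_ids)
        assert sorted(ri.product_ids) == sorted(rj.reactant_ids)
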