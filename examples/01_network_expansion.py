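"""Expand the 12 PLC-γ1 reaction rules into the full mass-action network.

PLC-γ1 is tracked at four sites (nSH2, Tyr783, cSH2, catalytic core); two
structural constraints leave 16 valid states, and applying the 12 rules to
every matching state yields 17 species and 53 unidirectional reactions.
"""

from plcgamma import (
    ParameterSet,
    build_plcg_ruleset,
    classify_states,
    count_independent_rate_constants,
    enumerate_states,
    make_network,
)

states = enumerate_states()
classes = classify_states(states)
print(f"PLC-γ1 internal states: {len(states)}")
print(f"  receptor-bound: {len(classes['rtk_bound'])}")
print(f"  active (membrane-inserted): {len(classes['active'])}")
print(f"  cytosolic: {len(classes['cytosolic'])}")

ruleset = build_plcg_ruleset()
print(f"\nreaction rules: {len(ruleset)}")
print(f"independent rate constants (shared χ): "
      f"{count_independent_rate_constants(ruleset)}")

network = make_network(ParameterSet())
print(f"\nexpanded network: {network.n_species} species, "
      f"{network.n_reactions} reactions")
print("instances per rule:")
for rule, count in network.per_rule_counts().items():
    print(f"  {rule:32s} {count}")

# The counts say the combinatorics are fully enumerated: every way a rule
# can fire on a valid state appears exactly once as a mass-action reaction.
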