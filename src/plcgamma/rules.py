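"""Reaction rules for PLC-γ1 regulation.

Each rule reads a subset of the four molecular sites (its reactant pattern),
flips exactly one site, and carries a named rate constant.  The two nSH2–RTK
binding rules are bimolecular (they consume one free receptor); everything
else is a unimolecular transition (intramolecular binding, phosphorylation
state change, or membrane insertion treated with an implicit lipid).

The full model is 12 rules.  Two of the twelve rate constants —
``k_on_nSH2_2`` (receptor capture of membrane-inserted PLC-γ1) and
``k_act_2`` (membrane insertion of receptor-tethered PLC-γ1) — are not free:
both equal χ times their cytosolic counterparts, with a single shared
enhancement factor χ.  Sharing χ encodes induced proximity at the membrane
and makes the binding/activation cycle satisfy detailed balance by
construction, leaving 11 independent rate constant values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .states import SITES, Csh2, Core, Nsh2, PLCState, Y783

#: value of a pattern constraint: the set of admissible site values
Pattern = Mapping[str, frozenset]


@dataclass(frozen=True)
class Rule:
    """A single reaction rule.

    ``reactant_pattern`` maps site name -> frozenset of admissible values;
    only sites the rule reads appear.  ``product_site``/``product_value``
    give the one site change the rule performs.
    """

    name: str
    reactant_pattern: Pattern
    product_site: str
    product_value: object
    rate_constant: str
    bimolecular: bool = False  # consumes one free-RTK unit when True

    def __post_init__(self) -> None:
        for site in self.reactant_pattern:
            if site not in SITES:
                raise ValueError(f"unknown site in pattern: {site!r}")
        if self.product_site not in SITES:
            raise ValueError(f"unknown product site: {self.product_site!r}")

    def matches(self, state: PLCState) -> bool:
        return all(
            state.site(site) in allowed
            for site, allowed in self.reactant_pattern.items()
        )

    def apply(self, state: PLCState) -> PLCState:
        return state.replace(self.product_site, self.product_value)


@dataclass(frozen=True)
class RuleSet:
    """An ordered rule collection plus the χ couplings between rate constants.

    ``couplings`` maps a derived rate-constant name to
    ``(base_name, factor_name)``, meaning derived = factor · base.
    """

    rules: tuple[Rule, ...]
    couplings: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def rate_constant_names(self) -> list[str]:
        return [r.rate_constant for r in self.rules]


def _pat(**kwargs) -> Pattern:
    """Build a pattern from site=value or site=(v1, v2) keyword constraints."""
    out = {}
    for site, val in kwargs.items():
        out[site] = frozenset(val) if isinstance(val, tuple) else frozenset([val])
    return out


def build_plcg_ruleset() -> RuleSet:
    """The 12 reaction rules of the PLC-γ1 regulation model.

    Order follows the model's rate-constant table: receptor binding (core
    inactive, then active), receptor unbinding, Tyr783 phosphorylation and
    dephosphorylation, cSH2–core and cSH2–pTyr783 bind/unbind, membrane
    insertion (nSH2 free, then receptor-tethered), and inactivation.
    """
    rules = (
        Rule(
            "nSH2_bind_RTK_core_inactive",
            _pat(nsh2=Nsh2.FREE, core=Core.INACTIVE),
            "nsh2", Nsh2.RTK_BOUND, "k_on_nSH2", bimolecular=True,
        ),
        Rule(
            "nSH2_bind_RTK_core_active",
            _pat(nsh2=Nsh2.FREE, core=Core.ACTIVE),
            "nsh2", Nsh2.RTK_BOUND, "k_on_nSH2_2", bimolecular=True,
        ),
        Rule(
            "nSH2_unbind_RTK",
            _pat(nsh2=Nsh2.RTK_BOUND),
            "nsh2", Nsh2.FREE, "k_off_nSH2",
        ),
        # Tyr783 is only presented to the receptor kinase while tethered.
        Rule(
            "Y783_phosphorylation",
            _pat(nsh2=Nsh2.RTK_BOUND, y783=Y783.UNPHOS),
            "y783", Y783.PHOS, "k_phos",
        ),
        # pTyr783 is protected from phosphatases while held by cSH2.
        Rule(
            "Y783_dephosphorylation",
            _pat(y783=Y783.PHOS, csh2=(Csh2.FREE, Csh2.CORE_BOUND)),
            "y783", Y783.UNPHOS, "k_dephos",
        ),
        Rule(
            "cSH2_bind_core",
            _pat(csh2=Csh2.FREE, core=Core.INACTIVE),
            "csh2", Csh2.CORE_BOUND, "k_bind_c",
        ),
        Rule(
            "cSH2_unbind_core",
            _pat(csh2=Csh2.CORE_BOUND),
            "csh2", Csh2.FREE, "k_unbind_c",
        ),
        Rule(
            "cSH2_bind_pY783",
            _pat(csh2=Csh2.FREE, y783=Y783.PHOS),
            "csh2", Csh2.PY_BOUND, "k_bind_p",
        ),
        Rule(
            "cSH2_unbind_pY783",
            _pat(csh2=Csh2.PY_BOUND),
            "csh2", Csh2.FREE, "k_unbind_p",
        ),
        # Membrane insertion requires an uninhibited core.
        Rule(
            "core_activation_nSH2_free",
            _pat(core=Core.INACTIVE, csh2=(Csh2.FREE, Csh2.PY_BOUND), nsh2=Nsh2.FREE),
            "core", Core.ACTIVE, "k_act",
        ),
        Rule(
            "core_activation_nSH2_bound",
            _pat(core=Core.INACTIVE, csh2=(Csh2.FREE, Csh2.PY_BOUND), nsh2=Nsh2.RTK_BOUND),
            "core", Core.ACTIVE, "k_act_2",
        ),
        Rule(
            "core_inactivation",
            _pat(core=Core.ACTIVE),
            "core", Core.INACTIVE, "k_inact",
        ),
    )
    couplings = {
        "k_on_nSH2_2": ("k_on_nSH2", "chi"),
        "k_act_2": ("k_act", "chi"),
    }
    return RuleSet(rules, couplings)


def count_independent_rate_constants(ruleset: RuleSet) -> int:
    """Number of independent rate-constant values in a rule set.

    Distinct rate-constant names, with each coupled (derived) constant
    replaced by its shared coupling factor: the base model's 12 names
    collapse to 10 free constants plus the single χ, i.e. 11.
    """
    names = set(ruleset.rate_constant_names())
    derived = names & set(ruleset.couplings)
    factors = {ruleset.couplings[d][1] for d in derived}
    return len(names - derived) + len(factors)
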