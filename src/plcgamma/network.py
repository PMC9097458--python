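"""Expansion of the 12 reaction rules into a concrete mass-action network.

Applying each rule to every molecular state whose sites match the rule's
reactant pattern yields 53 unidirectional reactions over 17 species:
8 free PLC-γ1 states, the 8 corresponding PLC-γ1·RTK complexes, and free
RTK.  Generation is deterministic: species follow the canonical state
order (free PLC first, then complexes, then RTK) and reactions follow the
rule order of the parameter table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ParameterSet
from .rules import Rule, RuleSet
from .states import Nsh2, PLCState, enumerate_states


class SpeciesKind(enum.Enum):
    PLC_FREE = "plc_free"
    PLC_RTK_COMPLEX = "plc_rtk_complex"
    RTK_FREE = "rtk_free"


@dataclass(frozen=True)
class Species:
    """One chemical species: a PLC-γ1 state, a PLC-γ1·RTK complex, or free RTK."""

    id: int
    kind: SpeciesKind
    plc_state: PLCState | None
    label: str

    @property
    def plc_content(self) -> int:
        return 0 if self.kind is SpeciesKind.RTK_FREE else 1

    @property
    def rtk_content(self) -> int:
        return 1 if self.kind is not SpeciesKind.PLC_FREE else 0


@dataclass(frozen=True)
class Reaction:
    """A unidirectional mass-action reaction (at most two reactants)."""

    id: int
    reactant_ids: tuple[int, ...]
    product_ids: tuple[int, ...]
    rate_constant: str  # name in the parameter table
    rate_value: float   # s⁻¹ (unimolecular) or μM⁻¹ s⁻¹ (bimolecular)
    source_rule: str

    @property
    def bimolecular(self) -> bool:
        return len(self.reactant_ids) == 2


class ReactionNetwork:
    """Species list, reaction list and stoichiometry of the expanded model."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        params: ParameterSet,
    ):
        self.species = list(species)
        self.reactions = list(reactions)
        self.params = params
        self._by_state: dict[PLCState, int] = {
            sp.plc_state: sp.id for sp in self.species if sp.plc_state is not None
        }

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def rtk_index(self) -> int:
        (idx,) = [sp.id for sp in self.species if sp.kind is SpeciesKind.RTK_FREE]
        return idx

    def species_for_state(self, state: PLCState) -> int:
        return self._by_state[state]

    def species_indices(self, predicate) -> list[int]:
        """Indices of PLC species whose state satisfies ``predicate``."""
        return [
            sp.id
            for sp in self.species
            if sp.plc_state is not None and predicate(sp.plc_state)
        ]

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net coefficient table, species × reactions."""
        S = np.zeros((self.n_species, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for i in rxn.reactant_ids:
                S[i, j] -= 1
            for i in rxn.product_ids:
                S[i, j] += 1
        return S

    def conservation_vectors(self) -> dict[str, np.ndarray]:
        """Per-species PLC and RTK content; both are conserved by every reaction."""
        return {
            "plc": np.array([sp.plc_content for sp in self.species], dtype=float),
            "rtk": np.array([sp.rtk_content for sp in self.species], dtype=float),
        }

    def per_rule_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rxn in self.reactions:
            counts[rxn.source_rule] = counts.get(rxn.source_rule, 0) + 1
        return counts

    def reversible_pairs(self) -> list[tuple[int, int]]:
        """Reaction index pairs (i, j) that are exact reverses of one another."""
        key = {
            (tuple(sorted(r.reactant_ids)), tuple(sorted(r.product_ids))): r.id
            for r in self.reactions
        }
        pairs = []
        for r in self.reactions:
            rev = (tuple(sorted(r.product_ids)), tuple(sorted(r.reactant_ids)))
            j = key.get(rev)
            if j is not None and r.id < j:
                pairs.append((r.id, j))
        return pairs


def _build_species(states: Sequence[PLCState]) -> list[Species]:
    species: list[Species] = []
    for st in states:
        if st.nsh2 is Nsh2.FREE:
            species.append(Species(len(species), SpeciesKind.PLC_FREE, st, st.label()))
    for st in states:
        if st.nsh2 is Nsh2.RTK_BOUND:
            species.append(
                Species(len(species), SpeciesKind.PLC_RTK_COMPLEX, st, st.label() + ".RTK")
            )
    species.append(Species(len(species), SpeciesKind.RTK_FREE, None, "RTK(pY~free)"))
    return species


def generate_network(ruleset: RuleSet, params: ParameterSet) -> ReactionNetwork:
    """Apply every rule to every matching state; returns the 17 × 53 network.

    Duplicate reactions are impossible by construction: each (rule, state)
    pair yields one reaction and states are enumerated without repetition.
    """
    states = enumerate_states()
    species = _build_species(states)
    net = ReactionNetwork(species, [], params)
    rates = params.rate_values()

    reactions: list[Reaction] = []
    for rule in ruleset:
        if rule.rate_constant not in rates:
            raise ValueError(f"no value for rate constant {rule.rate_constant!r}")
        for st in states:
            if not rule.matches(st):
                continue
            product_state = rule.apply(st)
            if not product_state.is_valid():
                raise AssertionError(
                    f"rule {rule.name} produced invalid state from {st.label()}"
                )
            reactant_sp = net.species_for_state(st)
            product_sp = net.species_for_state(product_state)
            if rule.bimolecular:
                # binding consumes a free receptor: PLC + RTK -> PLC·RTK
                reactants: tuple[int, ...] = (reactant_sp, net.rtk_index)
                products: tuple[int, ...] = (product_sp,)
            elif st.nsh2 is Nsh2.RTK_BOUND and product_state.nsh2 is Nsh2.FREE:
                # unbinding releases the receptor: PLC·RTK -> PLC + RTK
                reactants = (reactant_sp,)
                products = (product_sp, net.rtk_index)
            else:
                reactants = (reactant_sp,)
                products = (product_sp,)
            reactions.append(
                Reaction(
                    id=len(reactions),
                    reactant_ids=reactants,
                    product_ids=products,
                    rate_constant=rule.rate_constant,
                    rate_value=rates[rule.rate_constant],
                    source_rule=rule.name,
                )
            )
    return ReactionNetwork(species, reactions, params)
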