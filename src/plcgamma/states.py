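"""Internal state space of the PLC-γ1 molecule.

PLC-γ1 is modeled with four regulatory sites:

* ``nsh2`` — the N-terminal SH2 domain, either free or bound to the
  phosphotyrosine of an activated receptor tyrosine kinase (RTK);
* ``y783`` — the Tyr783 phosphorylation site (unphosphorylated / phosphorylated);
* ``csh2`` — the C-terminal SH2 domain, which can be free, engaged with the
  catalytic core (the autoinhibited configuration) or engaged with
  phosphorylated Tyr783;
* ``core`` — the catalytic core, inactive (off the membrane) or active
  (inserted into the membrane and hydrolyzing PIP2).

Two structural constraints prune the raw 2·2·3·2 = 24 combinations to 16
chemically meaningful states: the cSH2 domain can only sit on an *inactive*
core, and it can only engage Tyr783 once that tyrosine is phosphorylated.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterator


class Nsh2(enum.Enum):
    """Occupancy of the nSH2 domain."""

    FREE = "free"
    RTK_BOUND = "rtk_bound"


class Y783(enum.Enum):
    """Phosphorylation status of Tyr783."""

    UNPHOS = "unphos"
    PHOS = "phos"


class Csh2(enum.Enum):
    """Binding partner of the cSH2 domain."""

    FREE = "free"
    CORE_BOUND = "core_bound"
    PY_BOUND = "py_bound"


class Core(enum.Enum):
    """Activity of the catalytic core (membrane insertion)."""

    INACTIVE = "inactive"
    ACTIVE = "active"


#: Site name -> enum class, in canonical sort-key order.
SITES: dict[str, type[enum.Enum]] = {
    "nsh2": Nsh2,
    "y783": Y783,
    "csh2": Csh2,
    "core": Core,
}


@dataclass(frozen=True)
class PLCState:
    """One internal state of a PLC-γ1 molecule.

    Frozen and hashable so states can key dictionaries and sets; ordering
    of the full state space is provided by :func:`enumerate_states`.
    """

    nsh2: Nsh2
    y783: Y783
    csh2: Csh2
    core: Core

    def is_valid(self) -> bool:
        """Whether the state satisfies both structural constraints."""
        if self.csh2 is Csh2.CORE_BOUND and self.core is Core.ACTIVE:
            return False  # autoinhibition only of the inactive core
        if self.csh2 is Csh2.PY_BOUND and self.y783 is Y783.UNPHOS:
            return False  # cSH2 engages only phosphorylated Tyr783
        return True

    @property
    def rtk_bound(self) -> bool:
        return self.nsh2 is Nsh2.RTK_BOUND

    @property
    def active(self) -> bool:
        return self.core is Core.ACTIVE

    @property
    def cytosolic(self) -> bool:
        """Cytosolic: not tethered by nSH2 and not membrane-inserted."""
        return self.nsh2 is Nsh2.FREE and self.core is Core.INACTIVE

    def site(self, name: str) -> enum.Enum:
        return getattr(self, name)

    def replace(self, name: str, value: enum.Enum) -> "PLCState":
        kwargs = {s: self.site(s) for s in SITES}
        kwargs[name] = value
        return PLCState(**kwargs)  # type: ignore[arg-type]

    def sort_key(self) -> tuple[int, int, int, int]:
        """Lexicographic key on (nsh2, y783, csh2, core) declaration order."""
        key = []
        for name, enum_cls in SITES.items():
            members = list(enum_cls)
            key.append(members.index(self.site(name)))
        return tuple(key)  # type: ignore[return-value]

    def label(self) -> str:
        """Canonical site-grammar label, e.g. ``PLC(nSH2~free,Y783~u,cSH2~core,core~inact)``."""
        abbrev = {
            Nsh2.FREE: "free",
            Nsh2.RTK_BOUND: "rtk",
            Y783.UNPHOS: "u",
            Y783.PHOS: "p",
            Csh2.FREE: "free",
            Csh2.CORE_BOUND: "core",
            Csh2.PY_BOUND: "pY",
            Core.INACTIVE: "inact",
            Core.ACTIVE: "act",
        }
        return (
            f"PLC(nSH2~{abbrev[self.nsh2]},Y783~{abbrev[self.y783]},"
            f"cSH2~{abbrev[self.csh2]},core~{abbrev[self.core]})"
        )


def iter_raw_states() -> Iterator[PLCState]:
    """All 24 raw site combinations, before structural filtering."""
    for nsh2, y783, csh2, core in itertools.product(Nsh2, Y783, Csh2, Core):
        yield PLCState(nsh2, y783, csh2, core)


def enumerate_states() -> list[PLCState]:
    """The 16 valid PLC-γ1 states in canonical (deterministic) order.

    The order is a lexicographic sort on (nsh2, y783, csh2, core) using each
    enum's declaration order, so species indices are reproducible across runs
    and exports.
    """
    valid = [s for s in iter_raw_states() if s.is_valid()]
    return sorted(valid, key=PLCState.sort_key)


def classify_states(
    states: list[PLCState] | None = None,
) -> dict[str, list[PLCState]]:
    """Partition states into (non-disjoint) functional classes.

    Returns membership lists under keys ``rtk_bound`` (8 states tethered to
    the receptor), ``active`` (6 membrane-inserted states whose core
    hydrolyzes PIP2) and ``cytosolic`` (5 states that are neither tethered
    nor membrane-inserted and hence diffuse freely).
    """
    if states is None:
        states = enumerate_states()
    return {
        "rtk_bound": [s for s in states if s.rtk_bound],
        "active": [s for s in states if s.active],
        "cytosolic": [s for s in states if s.cytosolic],
    }
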