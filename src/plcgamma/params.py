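"""Rate constants and concentrations of the PLC-γ1 model.

Base values correspond to the published parameter table of the model:
nSH2–RTK binding with K_D = 1 μM, fast autoinhibitory cSH2–core cycling
(k_bind_c = 100 s⁻¹, k_unbind_c = 1 s⁻¹, so K_c = 100), equally fast
cSH2–pTyr783 cycling (K_p = 100), slow membrane insertion from the cytosol
(k_act = 0.01 s⁻¹) sped up χ = 1000-fold when receptor-tethered, and an
inactivation rate k_inact = 0.1 s⁻¹ (K_a = 0.1).  Total PLC-γ1 is 0.02 μM;
the receptor concentration is the model input, varied over 0.005–0.05 μM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import yaml

#: independent rate constants, s⁻¹ unless noted
_RATE_FIELDS = (
    "k_on_nSH2",   # μM⁻¹ s⁻¹
    "k_off_nSH2",
    "k_phos",
    "k_dephos",
    "k_bind_c",
    "k_unbind_c",
    "k_bind_p",
    "k_unbind_p",
    "k_act",
    "k_inact",
)

#: receptor range (μM) the model treats as its physiological input
RTK_RANGE = (0.005, 0.05)


@dataclass(frozen=True)
class ParameterSet:
    """Independent parameters of the 12-rule model.

    The two χ-enhanced constants are exposed as derived properties rather
    than free fields, which encodes the detailed-balance constraint (one
    shared χ) by construction.
    """

    k_on_nSH2: float = 1.0
    k_off_nSH2: float = 1.0
    k_phos: float = 1.0
    k_dephos: float = 1.0
    k_bind_c: float = 100.0
    k_unbind_c: float = 1.0
    k_bind_p: float = 100.0
    k_unbind_p: float = 1.0
    k_act: float = 0.01
    k_inact: float = 0.1
    chi: float = 1000.0
    plc_total: float = 0.02  # μM
    rtk_total: float = 0.05  # μM

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.chi <= 0:
            raise ValueError("chi must be positive")
        if self.plc_total < 0 or self.rtk_total < 0:
            raise ValueError("totals must be nonnegative")

    # -- derived rate constants and equilibrium constants -------------------

    @property
    def k_on_nSH2_2(self) -> float:
        """Receptor capture of membrane-inserted PLC-γ1, χ·k_on_nSH2 (μM⁻¹ s⁻¹)."""
        return self.chi * self.k_on_nSH2

    @property
    def k_act_2(self) -> float:
        """Membrane insertion of receptor-tethered PLC-γ1, χ·k_act (s⁻¹)."""
        return self.chi * self.k_act

    @property
    def K_p(self) -> float:
        """Intramolecular cSH2–pTyr783 equilibrium constant."""
        return self.k_bind_p / self.k_unbind_p

    @property
    def K_c(self) -> float:
        """Autoinhibition (cSH2–core) equilibrium constant."""
        return self.k_bind_c / self.k_unbind_c

    @property
    def K_a(self) -> float:
        """Membrane-association equilibrium of the uninhibited core."""
        return self.k_act / self.k_inact

    @property
    def K_D(self) -> float:
        """nSH2–RTK dissociation constant (μM)."""
        return self.k_off_nSH2 / self.k_on_nSH2

    def rate_values(self) -> dict[str, float]:
        """All 12 rule rate constants by name, derived ones included."""
        vals = {name: getattr(self, name) for name in _RATE_FIELDS}
        vals["k_on_nSH2_2"] = self.k_on_nSH2_2
        vals["k_act_2"] = self.k_act_2
        return vals

    # -- editing -------------------------------------------------------------

    def with_edits(self, **edits: float) -> "ParameterSet":
        """Return a copy with absolute edits; unknown names rejected."""
        valid = {f.name for f in fields(self)}
        unknown = set(edits) - valid
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **edits)

    def scaled(self, **factors: float) -> "ParameterSet":
        """Return a copy with multiplicative edits (e.g. ``k_act=10`` means ×10).

        Edits to ``k_act`` or ``k_on_nSH2`` propagate to their χ-derived
        partners automatically, preserving the shared-χ constraint.
        """
        edits = {}
        valid = {f.name for f in fields(self)}
        for name, fac in factors.items():
            if name not in valid:
                raise ValueError(f"unknown parameter: {name!r}")
            edits[name] = getattr(self, name) * fac
        return replace(self, **edits)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ParameterSet":
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class CycleReport:
    """Detailed-balance check of the binding/activation square.

    The thermodynamic cycle is cytosolic-inactive → tethered-inactive →
    tethered-active → free-active → cytosolic-inactive.  Around it the
    product of equilibrium constants must be 1 (Wegscheider condition);
    ``residual`` is that product minus 1.  Phosphorylation cycles are
    excluded: they are chemically driven (ATP hydrolysis) and need not
    balance.
    """

    balanced: bool
    residual: float
    cycle: tuple[str, ...]


def check_detailed_balance(
    params: ParameterSet,
    *,
    k_on_nSH2_2: float | None = None,
    k_act_2: float | None = None,
    rtol: float = 1e-12,
) -> CycleReport:
    """Verify detailed balance of the nSH2-binding / membrane-insertion cycle.

    Optional overrides for the two derived constants allow probing broken
    couplings (e.g. two unequal χ factors).  Raises on nonpositive rates.
    """
    k_on = params.k_on_nSH2
    k_off = params.k_off_nSH2
    k_act = params.k_act
    k_inact = params.k_inact
    k_on2 = params.k_on_nSH2_2 if k_on_nSH2_2 is None else k_on_nSH2_2
    k_act2 = params.k_act_2 if k_act_2 is None else k_act_2
    for name, val in [
        ("k_on_nSH2", k_on), ("k_off_nSH2", k_off), ("k_act", k_act),
        ("k_inact", k_inact), ("k_on_nSH2_2", k_on2), ("k_act_2", k_act2),
    ]:
        if val <= 0:
            raise ValueError(f"{name} must be positive for a cycle check")
    # forward equilibrium constants around the square
    log_prod = (
        math.log(k_on / k_off)       # cytosol + RTK ⇌ tethered (inactive)
        + math.log(k_act2 / k_inact)  # tethered inactive ⇌ tethered active
        + math.log(k_off / k_on2)     # tethered active ⇌ free active + RTK
        + math.log(k_inact / k_act)   # free active ⇌ cytosolic inactive
    )
    residual = math.expm1(log_prod)
    cycle = (
        "nSH2_bind_RTK_core_inactive",
        "core_activation_nSH2_bound",
        "nSH2_unbind_RTK",
        "core_inactivation",
    )
    return CycleReport(balanced=abs(residual) <= rtol, residual=residual, cycle=cycle)
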