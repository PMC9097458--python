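"""Deterministic mass-action kinetics of the expanded PLC-γ1 network.

The 17 species obey dc/dt = S·v(c) with elementary mass-action fluxes.
Protocols mirror the model's published simulation design: stiff integration
with a maximum step of 1 s, runs of 5000 s to reach steady state, a
receptor dose–response sweep, and a lifetime (decay) protocol in which the
two cytosolic recruitment channels are switched off at steady state so the
membrane-bound pool relaxes back to the cytosol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import ReactionNetwork
from .params import ParameterSet
from .rules import build_plcg_ruleset
from .states import Core, Csh2, Nsh2, PLCState, Y783

#: solver settings used throughout (stiff, tight tolerances, 1 s max step)
SOLVER_KWARGS = dict(method="LSODA", rtol=1e-8, atol=1e-12, max_step=1.0)

#: steady state declared when max|dc/dt| / plc_total falls below this (s⁻¹)
STEADY_STATE_TOL = 1e-8

#: default horizon (s)
T_END = 5000.0


def build_rate_function(
    network: ReactionNetwork,
    rate_overrides: Mapping[str, float] | None = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the network into a pure derivative evaluator dc/dt = S·v(c).

    ``rate_overrides`` replaces named rate constants (by parameter-table
    name) without touching the network, e.g. ``{"k_on_nSH2": 0.0}`` for the
    decay protocol.  Raises on negative rate constants.
    """
    values = dict(rate_overrides or {})
    k = np.array(
        [values.get(r.rate_constant, r.rate_value) for r in network.reactions]
    )
    if np.any(k < 0):
        bad = [
            network.reactions[j].rate_constant for j in np.flatnonzero(k < 0)
        ]
        raise ValueError(f"negative rate constant(s): {sorted(set(bad))}")
    S = network.stoichiometry_matrix()
    r1 = np.array([r.reactant_ids[0] for r in network.reactions])
    bi = np.array([r.bimolecular for r in network.reactions])
    r2 = np.array(
        [r.reactant_ids[1] if r.bimolecular else 0 for r in network.reactions]
    )

    def rhs(t: float, c: np.ndarray) -> np.ndarray:
        v = k * c[r1]
        v[bi] *= c[r2[bi]]
        return S @ v

    return rhs


@dataclass
class Trajectory:
    """A simulated time course of all species concentrations (μM)."""

    times: np.ndarray
    concentrations: np.ndarray  # species × time
    network: ReactionNetwork
    metadata: dict = field(default_factory=dict)

    @property
    def active_fraction(self) -> np.ndarray:
        """Fraction of total PLC-γ1 in the six membrane-inserted states."""
        idx = self.network.species_indices(lambda s: s.active)
        return self.concentrations[idx].sum(axis=0) / self.network.params.plc_total

    def totals(self) -> dict[str, np.ndarray]:
        vecs = self.network.conservation_vectors()
        return {name: w @ self.concentrations for name, w in vecs.items()}

    def final_state(self) -> np.ndarray:
        return self.concentrations[:, -1].copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.concentrations.T,
            columns=[sp.label for sp in self.network.species],
        )
        df.insert(0, "time", self.times)
        df["active_fraction"] = self.active_fraction
        return df


@dataclass
class SteadyStateResult:
    """Outcome of an activation run from rest to steady state."""

    active_fraction_ss: float
    t_half_activation: float
    converged: bool
    final_state: np.ndarray
    trajectory: Trajectory


AUTOINHIBITED = PLCState(Nsh2.FREE, Y783.UNPHOS, Csh2.CORE_BOUND, Core.INACTIVE)
AUTOINHIBITED_PHOS = PLCState(Nsh2.FREE, Y783.PHOS, Csh2.CORE_BOUND, Core.INACTIVE)


def default_initial_state(
    network: ReactionNetwork, phospho: bool = False
) -> np.ndarray:
    """All PLC-γ1 cytosolic and autoinhibited; all receptor free.

    ``phospho=True`` places the pool in the constitutively phosphorylated
    (phosphomimetic) counterpart of the resting state.
    """
    c0 = np.zeros(network.n_species)
    rest = AUTOINHIBITED_PHOS if phospho else AUTOINHIBITED
    c0[network.species_for_state(rest)] = network.params.plc_total
    c0[network.rtk_index] = network.params.rtk_total
    return c0


def simulate(
    network: ReactionNetwork,
    initial_state: np.ndarray | None = None,
    t_end: float = T_END,
    max_step: float = 1.0,
    rate_overrides: Mapping[str, float] | None = None,
    n_out: int | None = None,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate the network from ``initial_state`` to ``t_end``.

    Output is sampled densely enough (default: at least one point per
    second or 2000 points, whichever is coarser) for half-time
    interpolation.  Raises on solver failure or on negative-concentration
    excursions beyond tolerance.
    """
    if initial_state is None:
        initial_state = default_initial_state(network)
    initial_state = np.asarray(initial_state, dtype=float)
    if np.any(initial_state < 0):
        raise ValueError("initial concentrations must be nonnegative")
    rhs = build_rate_function(network, rate_overrides)
    if n_out is None:
        n_out = min(2001, max(201, int(t_end - t0) + 1))
    t_eval = np.linspace(t0, t_end, n_out)
    kwargs = dict(SOLVER_KWARGS)
    kwargs["max_step"] = max_step
    sol = solve_ivp(rhs, (t0, t_end), initial_state, t_eval=t_eval, **kwargs)
    if not sol.success:
        raise RuntimeError(f"solver failed: {sol.message}")
    if sol.y.min() < -1e-8:
        raise RuntimeError(
            f"negative concentration excursion: {sol.y.min():.3e} μM"
        )
    conc = np.clip(sol.y, 0.0, None)
    meta = {
        "parameters": network.params.to_dict(),
        "rate_overrides": dict(rate_overrides or {}),
        "t_end": t_end,
        "max_step": max_step,
    }
    return Trajectory(sol.t, conc, network, meta)


def is_steady(network: ReactionNetwork, state: np.ndarray,
              rate_overrides: Mapping[str, float] | None = None) -> bool:
    rhs = build_rate_function(network, rate_overrides)
    rate = np.abs(rhs(0.0, state)).max() / network.params.plc_total
    return rate < STEADY_STATE_TOL


def activation_halftime(
    times: np.ndarray, active_fraction: np.ndarray, a_ss: float
) -> float:
    """First crossing time of a_ss/2, by linear interpolation.

    Raises if the trajectory never brackets the half-steady-state level.
    """
    target = 0.5 * a_ss
    above = active_fraction >= target
    if not above.any():
        raise ValueError("half-steady-state crossing not bracketed")
    j = int(np.argmax(above))
    if j == 0:
        return float(times[0])
    t0, t1 = times[j - 1], times[j]
    a0, a1 = active_fraction[j - 1], active_fraction[j]
    return float(t0 + (target - a0) / (a1 - a0) * (t1 - t0))


def simulate_to_steady_state(
    network: ReactionNetwork,
    initial_state: np.ndarray | None = None,
    t_end: float = T_END,
    **kwargs,
) -> SteadyStateResult:
    """Run an activation time course and extract A_ss and t_1/2."""
    traj = simulate(network, initial_state, t_end=t_end, **kwargs)
    a = traj.active_fraction
    a_ss = float(a[-1])
    converged = is_steady(
        network, traj.final_state(), kwargs.get("rate_overrides")
    )
    try:
        t_half = activation_halftime(traj.times, a, a_ss)
    except ValueError:
        t_half = float("nan")
    return SteadyStateResult(a_ss, t_half, converged, traj.final_state(), traj)


def make_network(params: ParameterSet) -> ReactionNetwork:
    """Convenience: expand the standard 12-rule set under ``params``."""
    from .network import generate_network

    return generate_network(build_plcg_ruleset(), params)


def dose_response(
    params: ParameterSet,
    rtk_values: Sequence[float] | None = None,
    phospho_init: bool = False,
    t_end: float = T_END,
) -> pd.DataFrame:
    """Steady-state active fraction versus total receptor concentration.

    One full activation run per dose.  Returns columns
    ``rtk_total, active_fraction_ss, t_half, converged``.
    """
    if rtk_values is None:
        rtk_values = np.linspace(0.005, 0.05, 10)
    rows = []
    for rtk in rtk_values:
        p = params.with_edits(rtk_total=float(rtk))
        net = make_network(p)
        c0 = default_initial_state(net, phospho=phospho_init)
        try:
            res = simulate_to_steady_state(net, c0, t_end=t_end)
        except RuntimeError as err:
            raise RuntimeError(f"dose rtk_total={rtk}: {err}") from err
        rows.append(
            {
                "rtk_total": float(rtk),
                "active_fraction_ss": res.active_fraction_ss,
                "t_half": res.t_half_activation,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DecayResult:
    """Outcome of the lifetime protocol (recruitment switched off)."""

    half_life: float
    active_at_switch: float
    pre: Trajectory
    post: Trajectory


#: the two rules whose reactants are cytosolic: receptor capture of
#: cytosolic PLC-γ1 and direct membrane insertion from the cytosol
RECRUITMENT_CONSTANTS = ("k_on_nSH2", "k_act")


def decay_protocol(
    params: ParameterSet,
    switch_time: float = T_END,
    phospho_init: bool = False,
    max_extra: float = 10.0,
    require_steady: bool = True,
) -> DecayResult:
    """Lifetime of membrane activity after recruitment from the cytosol stops.

    At ``switch_time`` the two cytosolic recruitment constants drop to
    zero while the χ-enhanced rebinding constants (receptor capture of
    membrane-inserted enzyme, insertion of receptor-tethered enzyme) keep
    their pre-switch absolute values, so rebinding still prolongs the
    decay.  The half-life is the time after the switch at which the active
    fraction first reaches half its value at the switch.
    """
    net = make_network(params)
    c0 = default_initial_state(net, phospho=phospho_init)
    pre = simulate(net, c0, t_end=switch_time)
    if require_steady and not is_steady(net, pre.final_state()):
        raise RuntimeError("steady state not converged at switch_time")
    a_switch = float(pre.active_fraction[-1])

    rates = params.rate_values()
    overrides = {name: 0.0 for name in RECRUITMENT_CONSTANTS}
    # pin the rebinding channels at their pre-switch absolute values
    overrides["k_on_nSH2_2"] = rates["k_on_nSH2_2"]
    overrides["k_act_2"] = rates["k_act_2"]

    target = 0.5 * a_switch
    state = pre.final_state()
    t0 = switch_time
    chunks = []
    chunk = switch_time
    while t0 < switch_time + max_extra * switch_time:
        post = simulate(
            net, state, t_end=t0 + chunk, t0=t0, rate_overrides=overrides
        )
        chunks.append(post)
        if post.active_fraction.min() <= target:
            break
        state = post.final_state()
        t0 = post.times[-1]
    times = np.concatenate([c.times for c in chunks])
    conc = np.concatenate([c.concentrations for c in chunks], axis=1)
    post_all = Trajectory(times, conc, net, chunks[0].metadata)
    decayed = a_switch - post_all.active_fraction  # increases from 0
    half_time = activation_halftime(
        post_all.times - switch_time, decayed, a_switch
    )
    return DecayResult(half_time, a_switch, pre, post_all)
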