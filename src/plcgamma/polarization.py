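"""1D reaction–diffusion model of PLC/PKC polarization during gradient sensing.

The 16-state PLC-γ1 activation network replaces the single-step PLC
recruitment term of a PLC/PKC gradient-sensing circuit.  Three couplings
tie the network into the spatial model:

1. receptor availability — the local density of active receptors available
   for nSH2 capture is r(x) minus the sum of the eight RTK-bound PLC-γ1
   species;
2. PIP2 hydrolysis — the hydrolysis flux is proportional to the sum of the
   six active (membrane-inserted) PLC-γ1 species times available PIP2;
3. PFL 1∗ — phosphatidic acid (PA, density d_p) multiplies both membrane
   insertion rate constants by (1 + K_PA·d_p) with K_PA = 10 μm².

The downstream lipid circuit (PIP2 resynthesis, MARCKS sequestration,
DAG → PA conversion by DAG kinase, PA turnover, PKC activation by DAG,
PKC-driven MARCKS release, and the optional PFL 2 Hill term in which
active PKC drives PA production via phospholipase D) is a configurable
stand-in with the structure above; every rate is a named parameter so
alternative forms can be substituted without code changes.

Cytosolic PLC-γ1 species diffuse at 19 μm²/s; receptor- and/or
membrane-bound species and all membrane variables at 0.01 μm²/s.  The
spatial runs use k_on_nSH2 = 0.1 μM⁻¹ s⁻¹ and k_off_nSH2 = 0.1 s⁻¹
(whole-cell receptor binding is slower than the compartmental base case);
all other rule constants keep their base values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import ReactionNetwork
from .ode import make_network
from .params import ParameterSet


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform 1D grid with no-flux boundaries."""

    length: float = 30.0  # μm
    n_points: int = 50

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def h(self) -> float:
        return self.length / max(self.n_points - 1, 1)

    @property
    def coordinates(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_points)


@dataclass(frozen=True)
class PFL2Params:
    """PKC → phospholipase D → PA feedback (Hill form)."""

    enabled: bool = False
    n: float = 2.0
    K_PLD: float = 0.1              # PKC activity at half-saturation
    gamma_V_synth_dp: float = 10.0  # maximal extra PA production (prior-model units)
    #: μm⁻² s⁻¹ of d_p per prior-model production unit — converts the
    #: published production scale into the stand-in circuit's PA density
    unit_conversion: float = 0.01


@dataclass(frozen=True)
class MarcksParams:
    """MARCKS sequestration of PIP2 and its PKC-driven release (stand-in)."""

    enabled: bool = True
    k_on: float = 0.02          # s⁻¹, membrane association
    k_off: float = 0.005        # s⁻¹, basal release
    gamma_release: float = 20.0  # fold-acceleration of release per PKC unit
    kappa_seq: float = 4.0      # PIP2 sequestration strength when bound


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of the spatial model and its stand-in lipid circuit."""

    K_PA: float = 10.0        # μm², PFL 1∗ coupling constant
    k_DAGK: float = 0.2       # s⁻¹, DAG kinase (DAG → PA)
    k_DAG_other: float = 0.2  # s⁻¹, DAG consumption not yielding PA (lipase route)
    k_hyd: float = 30.0       # μM⁻¹ s⁻¹, PIP2 hydrolysis per active PLC
    k_synth: float = 0.05     # s⁻¹, PIP2 resynthesis toward capacity 1
    rho_PA: float = 20.0      # μm⁻² per DAG unit, DAG→PA conversion yield
    k_PA_turn: float = 0.2    # s⁻¹, PA turnover
    k_PKC_on: float = 2.0     # s⁻¹ per DAG unit, PKC activation
    k_PKC_off: float = 0.2    # s⁻¹, PKC deactivation
    pfl2: PFL2Params = field(default_factory=PFL2Params)
    marcks: MarcksParams = field(default_factory=MarcksParams)
    D_cyt: float = 19.0       # μm²/s, cytosolic PLC-γ1 species
    D_mem: float = 0.01       # μm²/s, membrane/receptor-bound species
    k_on_nSH2_sp: float = 0.1   # μM⁻¹ s⁻¹ (spatial override)
    k_off_nSH2_sp: float = 0.1  # s⁻¹ (spatial override)
    receptor_total: float = 0.05  # μM at full occupancy
    rfrac: float = 0.077      # mean fractional receptor occupancy
    steepness: float = 0.10   # relative gradient (front − back)/mean


def receptor_profile(
    rfrac: float, steepness: float, grid: SpatialGrid
) -> np.ndarray:
    """Linear occupancy profile r(x) = rfrac·(1 + steepness·(x/L − ½)).

    Spatial mean equals ``rfrac``; the front (x = L) minus back (x = 0)
    difference relative to the mean equals ``steepness``.  Raises if the
    profile leaves [0, 1].
    """
    if not 0.0 <= rfrac <= 1.0:
        raise ValueError("rfrac must lie in [0, 1]")
    if not 0.0 <= steepness < 2.0:
        raise ValueError("steepness must lie in [0, 2)")
    x = grid.coordinates
    rel = x / grid.length - 0.5 if grid.n_points > 1 else np.zeros(1)
    r = rfrac * (1.0 + steepness * rel)
    if r.min() < 0.0 or r.max() > 1.0:
        raise ValueError("receptor profile leaves [0, 1]")
    return r


def pfl1star_factor(d_p: np.ndarray | float, K_PA: float):
    """PFL 1∗ multiplier (1 + K_PA·d_p) applied to both insertion rates."""
    return 1.0 + K_PA * np.asarray(d_p)


def pfl2_rate(pkc_active: np.ndarray | float, params: PFL2Params):
    """Hill-form PA production driven by active PKC (phospholipase D route)."""
    c = np.asarray(pkc_active, dtype=float)
    cn = np.power(np.clip(c, 0.0, None), params.n)
    return params.gamma_V_synth_dp * cn / (params.K_PLD ** params.n + cn)


#: circuit state variables appended to the 16 PLC states at each grid point
CIRCUIT_VARS = ("PIP2", "DAG", "PA", "MARCKS", "PKC")


class SpatialModel:
    """Method-of-lines discretization of the coupled spatial model.

    State layout is point-major: at each grid point the 16 PLC-γ1 species
    (μM) are followed by PIP2 (relative), DAG (relative), PA (μm⁻²),
    membrane-bound MARCKS (fraction) and active PKC (fraction), giving a
    block-banded Jacobian the stiff solver exploits.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        circuit: CircuitParams,
        grid: SpatialGrid,
        receptor_field: np.ndarray | None = None,
    ):
        self.network = network
        self.circuit = circuit
        self.grid = grid
        self.n_plc = sum(1 for sp in network.species if sp.plc_state is not None)
        self.n_var = self.n_plc + len(CIRCUIT_VARS)
        if receptor_field is None:
            receptor_field = receptor_profile(circuit.rfrac, circuit.steepness, grid)
        self.receptor_field = np.asarray(receptor_field, dtype=float)
        if self.receptor_field.shape != (grid.n_points,):
            raise ValueError("receptor_field shape mismatch")
        self._compile()

    # -- compilation ---------------------------------------------------------

    def _compile(self) -> None:
        net, cir = self.network, self.circuit
        self.bound_idx = np.array(net.species_indices(lambda s: s.rtk_bound))
        self.active_idx = np.array(net.species_indices(lambda s: s.active))
        cyt_idx = net.species_indices(lambda s: s.cytosolic)

        overrides = {
            "k_on_nSH2": cir.k_on_nSH2_sp,
            "k_on_nSH2_2": net.params.chi * cir.k_on_nSH2_sp,
            "k_off_nSH2": cir.k_off_nSH2_sp,
        }
        self._k = np.array(
            [overrides.get(r.rate_constant, r.rate_value) for r in net.reactions]
        )
        self._r1 = np.array([r.reactant_ids[0] for r in net.reactions])
        self._bi = np.array([r.bimolecular for r in net.reactions])
        self._act_rule = np.array(
            [r.rate_constant in ("k_act", "k_act_2") for r in net.reactions]
        )
        # PLC-only stoichiometry (receptor handled algebraically)
        S = net.stoichiometry_matrix()[: self.n_plc]
        self._S_T = S.T.copy()  # reactions × species

        D = np.full(self.n_var, cir.D_mem)
        D[cyt_idx] = cir.D_cyt
        self._D = D
        self._r_total = self.receptor_field * cir.receptor_total

    # -- right-hand side -----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        cir = self.circuit
        Y = y.reshape(self.grid.n_points, self.n_var)
        plc = Y[:, : self.n_plc]
        l, d, a, m, c = (Y[:, self.n_plc + i] for i in range(5))

        avail = np.clip(self._r_total - plc[:, self.bound_idx].sum(axis=1), 0.0, None)
        f1 = pfl1star_factor(a, cir.K_PA)

        # reaction fluxes, points × reactions
        V = self._k * plc[:, self._r1]
        V[:, self._bi] *= avail[:, None]
        V[:, self._act_rule] *= f1[:, None]
        dY = np.zeros_like(Y)
        dY[:, : self.n_plc] = V @ self._S_T

        act_sum = plc[:, self.active_idx].sum(axis=1)
        if cir.marcks.enabled:
            l_free = l / (1.0 + cir.marcks.kappa_seq * m)
        else:
            l_free = l
        v_hyd = cir.k_hyd * act_sum * l_free
        if cir.pfl2.enabled:
            pa_extra = cir.pfl2.unit_conversion * pfl2_rate(c, cir.pfl2)
        else:
            pa_extra = 0.0

        dY[:, self.n_plc + 0] = cir.k_synth * (1.0 - l) - v_hyd
        dY[:, self.n_plc + 1] = v_hyd - (cir.k_DAGK + cir.k_DAG_other) * d
        dY[:, self.n_plc + 2] = cir.rho_PA * cir.k_DAGK * d - cir.k_PA_turn * a + pa_extra
        if cir.marcks.enabled:
            dY[:, self.n_plc + 3] = (
                cir.marcks.k_on * (1.0 - m)
                - cir.marcks.k_off * (1.0 + cir.marcks.gamma_release * c) * m
            )
        dY[:, self.n_plc + 4] = cir.k_PKC_on * d * (1.0 - c) - cir.k_PKC_off * c

        # conservative no-flux diffusion
        if self.grid.n_points > 1:
            F = Y[1:] - Y[:-1]
            lap = np.zeros_like(Y)
            lap[:-1] += F
            lap[1:] -= F
            dY += lap * (self._D / self.grid.h ** 2)
        return dY.ravel()

    def initial_state(self) -> np.ndarray:
        from .ode import AUTOINHIBITED

        Y = np.zeros((self.grid.n_points, self.n_var))
        rest = self.network.species_for_state(AUTOINHIBITED)
        Y[:, rest] = self.network.params.plc_total
        Y[:, self.n_plc + 0] = 1.0  # PIP2 at capacity
        if self.circuit.marcks.enabled:
            m0 = self.circuit.marcks.k_on / (self.circuit.marcks.k_on + self.circuit.marcks.k_off)
            Y[:, self.n_plc + 3] = m0
        return Y.ravel()

    def plc_domain_total(self, y: np.ndarray) -> float:
        """Trapezoidal PLC content over the domain (μM·μm)."""
        Y = y.reshape(self.grid.n_points, self.n_var)
        per_point = Y[:, : self.n_plc].sum(axis=1)
        if self.grid.n_points == 1:
            return float(per_point[0])
        return float(np.trapezoid(per_point, dx=self.grid.h))


@dataclass
class PolarizationResult:
    """Front/back readout of a spatial run.

    Front is the up-gradient end (x = L), back the down-gradient end
    (x = 0); the readout is active PKC.  ``oscillating`` is set when the
    envelope of either end varies by more than 1% over the last tenth of
    the run, in which case ``envelope`` carries (min, max) at each end.
    """

    times: np.ndarray
    front_series: np.ndarray
    back_series: np.ndarray
    final_fields: np.ndarray  # points × variables
    model: SpatialModel
    oscillating: bool
    envelope: dict
    front_value: float
    back_value: float

    @property
    def front_back_ratio(self) -> float:
        return self.front_value / self.back_value

    def field(self, name: str) -> np.ndarray:
        idx = self.model.n_plc + CIRCUIT_VARS.index(name)
        return self.final_fields[:, idx]


def simulate_polarization(
    model: SpatialModel,
    t_end: float = 2000.0,
    n_out: int = 201,
    settle_fraction: float = 0.1,
    envelope_tol: float = 0.01,
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> PolarizationResult:
    """Integrate the spatial model and classify the outcome.

    The run is steady when active PKC at both ends varies by less than
    ``envelope_tol`` (relative) over the last ``settle_fraction`` of the
    run; otherwise it is flagged oscillating and the min/max envelope is
    reported.
    """
    y0 = model.initial_state()
    t_eval = np.linspace(0.0, t_end, n_out)
    band = min(model.n_var, y0.size - 1)
    sol = solve_ivp(
        model.rhs,
        (0.0, t_end),
        y0,
        t_eval=t_eval,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        lband=band,
        uband=band,
    )
    if not sol.success:
        raise RuntimeError(f"spatial solver failed: {sol.message}")
    n_pts, n_var = model.grid.n_points, model.n_var
    pkc_col = model.n_plc + CIRCUIT_VARS.index("PKC")
    fields_t = sol.y.T.reshape(len(sol.t), n_pts, n_var)
    front = fields_t[:, -1, pkc_col]
    back = fields_t[:, 0, pkc_col]

    tail = max(2, int(settle_fraction * len(sol.t)))
    env = {
        "front": (float(front[-tail:].min()), float(front[-tail:].max())),
        "back": (float(back[-tail:].min()), float(back[-tail:].max())),
    }

    def _varies(lo: float, hi: float) -> bool:
        scale = max(abs(hi), abs(lo), 1e-12)
        return (hi - lo) / scale > envelope_tol

    oscillating = _varies(*env["front"]) or _varies(*env["back"])
    front_value = float(front[-tail:].mean())
    back_value = float(back[-tail:].mean())
    return PolarizationResult(
        times=sol.t,
        front_series=front,
        back_series=back,
        final_fields=fields_t[-1],
        model=model,
        oscillating=oscillating,
        envelope=env,
        front_value=front_value,
        back_value=back_value,
    )


def build_spatial_model(
    params: ParameterSet | None = None,
    circuit: CircuitParams | None = None,
    grid: SpatialGrid | None = None,
    receptor_field: np.ndarray | None = None,
) -> SpatialModel:
    """Expand the rule network and wrap it on a grid with the lipid circuit."""
    params = params or ParameterSet()
    circuit = circuit or CircuitParams()
    grid = grid or SpatialGrid()
    return SpatialModel(make_network(params), circuit, grid, receptor_field)


def dose_sweep(
    rfrac_values: Sequence[float],
    params: ParameterSet | None = None,
    circuit: CircuitParams | None = None,
    grid: SpatialGrid | None = None,
    t_end: float = 2000.0,
    model_factory: Callable[[float], SpatialModel] | None = None,
) -> pd.DataFrame:
    """Front/back input–output curve over mean receptor occupancy.

    Per ``rfrac``: steady front/back values (or oscillation envelopes) and
    the front/back ratio; per-point failures are recorded and the sweep
    continues.  The row with the highest steady ratio is flagged ``best``.
    """
    circuit = circuit or CircuitParams()
    rows = []
    for rfrac in rfrac_values:
        row: dict = {"rfrac": float(rfrac), "error": ""}
        try:
            if model_factory is not None:
                model = model_factory(float(rfrac))
            else:
                model = build_spatial_model(
                    params, replace(circuit, rfrac=float(rfrac)), grid
                )
            res = simulate_polarization(model, t_end=t_end)
            row.update(
                front=res.front_value,
                back=res.back_value,
                ratio=res.front_back_ratio,
                oscillating=res.oscillating,
                front_env_min=res.envelope["front"][0],
                front_env_max=res.envelope["front"][1],
            )
        except (RuntimeError, ValueError) as err:
            row["error"] = str(err)
        rows.append(row)
    df = pd.DataFrame(rows)
    steady = df[(df["error"] == "") & (~df["oscillating"].fillna(True).astype(bool))]
    df["best"] = False
    if len(steady):
        df.loc[steady["ratio"].idxmax(), "best"] = True
    return df
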