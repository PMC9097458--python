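# Methods

## Molecular state space and rules

One PLC-γ1 molecule is described by four sites: nSH2 occupancy (free /
RTK-bound), Tyr783 phosphorylation (unphosphorylated / phosphorylated),
cSH2 partner (free / catalytic core / pTyr783) and core activity (inactive
/ membrane-inserted). Two structural constraints encode the known
architecture: the cSH2 domain can occupy only an inactive core
(autoinhibition is a property of the closed enzyme), and it can engage
Tyr783 only once that residue is phosphorylated. Filtering the 2·2·3·2 =
24 raw combinations leaves 16 states. Classification flags follow from the
sites: 8 states are receptor-bound (nSH2 engaged), 6 are active (core
inserted), and 5 are cytosolic (nSH2 free *and* core inactive — the
membrane-free pool, which includes the phosphorylated state whose cSH2
holds pTyr783). Canonical ordering is a lexicographic sort on (nsh2,
y783, csh2, core) in declaration order, so species indices, exports and
stoichiometry matrices are bit-identical across runs.

The 12 rules each read a subset of sites and flip exactly one. The RTK is
a single-site molecule, permanently active and phosphorylated; receptor
binding rules are bimolecular and consume one free-RTK unit. Intramolecular
transitions (cSH2 cycles) and membrane insertion are first-order with
rate constants in s⁻¹; the membrane lipid is implicit, absorbed into
`k_act`. Two rate constants are χ-derived (`k_on_nSH2_2 = χ·k_on_nSH2`,
`k_act_2 = χ·k_act`): exposing χ as one parameter rather than two
independent enhancements encodes the thermodynamic (Wegscheider)
constraint of the binding/activation cycle by construction, which
`check_detailed_balance` verifies as a log-product residual. The
phosphorylation/dephosphorylation cycle is excluded from that check: it is
chemically driven (ATP turnover) and need not balance.

Rule expansion applies every rule to every matching state; a (rule, state)
pair yields exactly one reaction, so duplicates are impossible. The base
rule set expands to 17 species and 53 unidirectional reactions, with
per-rule instance counts {5, 3, 8, 3, 6, 4, 4, 4, 4, 3, 3, 6}. Tests
compare the full reaction multiset against an independent brute-force
generator written with nested loops over plain tuples.

## Base parameters

| constant | value | meaning |
| --- | --- | --- |
| k_on_nSH2 | 1 μM⁻¹s⁻¹ | receptor capture of cytosolic PLC-γ1 (K_D = 1 μM) |
| k_off_nSH2 | 1 s⁻¹ | receptor release |
| k_phos, k_dephos | 1 s⁻¹ | Tyr783 cycle (systematically varied) |
| k_bind_c, k_unbind_c | 100, 1 s⁻¹ | autoinhibition, K_c = 100 |
| k_bind_p, k_unbind_p | 100, 1 s⁻¹ | cSH2–pTyr783, K_p = 100 |
| k_act, k_inact | 0.01, 0.1 s⁻¹ | membrane insertion/release, K_a = 0.1 |
| χ | 1000 | induced-proximity enhancement (shared) |
| plc_total | 0.02 μM | total enzyme |
| rtk_total | 0.005–0.05 μM | model input (default 0.05) |

`ParameterSet` is immutable; `scaled()` performs fold edits and lets χ
carry `k_act_2`/`k_on_nSH2_2` along automatically, so no edit can break
detailed balance silently.

## Compartmental simulation

The 17 mass-action ODEs are integrated with LSODA at rtol 10⁻⁸, atol
10⁻¹² μM, maximum step 1 s, horizon 5000 s. The default initial condition
puts all PLC-γ1 in the cytosolic autoinhibited unphosphorylated state and
all receptor free; steady-state results are initialization-independent
(property-tested from random initial distributions with matched totals).
Steady state is declared when, at the horizon, max|dc/dt|/plc_total <
10⁻⁸ s⁻¹ — the secondary criterion guards slow variants. Activation t½ is
the first crossing of half the steady-state active fraction, located by
linear interpolation between output points; an unbracketed crossing
raises. PLC and RTK totals are conserved to better than 10⁻⁶ relative on
every protocol (tested).

**Phosphorylation extremes.** Y783F is `k_phos = 0`. The phosphomimetic is
a constitutively phosphorylated pool: initialization in the phosphorylated
autoinhibited state with `k_dephos = 0`. Both are treated as limiting
cases, not as literal point mutations.

**Decay (lifetime) protocol.** "Recruitment from the cytosol" is read as
exactly the two rules whose reactants are cytosolic: receptor capture of
cytosolic enzyme (`k_on_nSH2`, core inactive) and direct membrane
insertion from the cytosol (`k_act`, nSH2 free). At the switch these drop
to zero while `k_on_nSH2_2` and `k_act_2` are pinned at their pre-switch
absolute values — the rebinding narrative requires the χ-enhanced
channels to stay live, and pinning prevents the χ coupling from zeroing
them. Integration continues in horizon-sized chunks until the active
fraction falls below half its value at the switch; the half-life is the
interpolated crossing time. The protocol refuses to run if the pre-switch
state has not converged.

**Scan grids.** The phosphorylation-rate grid {0.1, 1, 10, 100} s⁻¹ and
the 10-fold variant edits are recorded in the fixtures; the variant scans
use rtk_total = 0.05 μM (top of the input range) so all variants are well
activated. The reduced-K_p scenario sets `k_bind_p = 10` (on-rate reduced,
off-rate kept).

## Two-state reduction

The reduced model dA/dt = kf(1−A) − kr·A relaxes exponentially with rate
kf + kr toward A_ss = kf/(kf+kr), so a full time course is identified by
kf_app = A_ss·ln2/t½ and kr_app = (1−A_ss)·ln2/t½. On literal two-state
systems the identification is exact up to interpolation error (tested to
≤1% over a log grid of rates). Applied to the full model it is a
projection: it is accurate exactly when the activation time course is
near-exponential, which holds across the variant panel (ln2/kr_app
matches the simulated decay half-life within a factor of ~1.4 at base
parameters).

## Spatial polarization model

A 1D domain (default 30 μm, no-flux ends — cell geometry is a
configuration choice, not a measured quantity) carries the 16 PLC states
plus five circuit variables per grid point, discretized by a conservative
finite-volume Laplacian (method of lines, LSODA with a banded Jacobian;
point-major layout keeps the bandwidth at one block). Cytosolic PLC
species diffuse at 19 μm²/s, everything membrane- or receptor-associated
at 0.01 μm²/s. Receptor binding uses k_on_nSH2 = 0.1 μM⁻¹s⁻¹ and
k_off_nSH2 = 0.1 s⁻¹ (the source text prints "k_on_nSH2 = 0.1 s⁻¹" for
the second value; it is read here as the off-rate, an apparent typo —
noted, not silently corrected). All other rule constants keep base values.

The three couplings of the network into the circuit are: (1) available
receptor density r(x)·R_T minus the sum of the eight receptor-bound PLC
species enters the bimolecular rate laws (equivalent to an explicit free-
RTK species — the single-point model reduces to the compartmental one,
tested); (2) PIP₂ hydrolysis is proportional to the sum of the six active
species times free PIP₂; (3) PFL 1∗ multiplies `k_act` and `k_act_2`
locally by (1 + K_PA·d_p), K_PA = 10 μm², with d_p the local PA density
in μm⁻².

**Stand-in circuit.** The downstream PIP₂/DAG/PA/MARCKS/PKC equations of
the prior polarization model are not published in a reusable form, so the
package implements a documented stand-in with the narrated structure:
PIP₂ resynthesizes toward capacity (k_synth = 0.05 s⁻¹) and is
sequestered by membrane MARCKS (free fraction 1/(1+κ·m), κ = 4); DAG is
produced by hydrolysis (k_hyd = 30 μM⁻¹s⁻¹) and consumed by DAG kinase
(k_DAGK = 0.2 s⁻¹ → PA) and a non-PA route (0.2 s⁻¹, the lipase branch —
without a competing branch the steady PA level would be independent of
k_DAGK and DAG kinase could not steer the feedback); PA turns over at
0.2 s⁻¹ with a DAG→PA yield of 20 μm⁻² per DAG unit chosen so the
operating d_p ≈ 0.1–0.5 μm⁻² makes PFL 1∗ a 2–6× effect; PKC activates
on DAG (2 s⁻¹ per DAG unit, off 0.2 s⁻¹) and accelerates MARCKS release
20-fold at full activity. PFL 2 is the Hill term
γ·c²/(K_PLD² + c²) with n = 2, K_PLD = 0.1, γ = 10 in the prior model's
production units; a conversion constant (0.01 μm⁻²s⁻¹ per unit) expresses
it on the stand-in's d_p scale, since applying the published magnitude
directly to a circuit with a different PA scale saturates the feedback
everywhere and erases polarization. These values are design choices of
the stand-in, fixed in `CircuitParams` and recorded in run manifests.

Consequently the spatial module reproduces *directions*, not curves:
gradient amplification above the input ratio, loss of polarization when
k_DAGK drops 0.3× and gain at 3×, a higher maximal front/back ratio with
PFL 2 over an occupancy sweep, and reduced polarization for K_c
(k_unbind_c × 10) and K_a (k_inact × 0.1) variants. Quantitative
input–output curves depend on the unpublished circuit and are out of
scope.

**Classification.** A run is steady when active PKC at both ends varies
by < 1% over the last 10% of the run; otherwise it is reported as
oscillating with its min/max envelope. The 1%/10% window is an
operational choice needed to mirror envelope-style readouts.

**Problem sizes.** Tests and examples use 25–50 grid points and 1500–3000 s
horizons; grid-refinement tests show the front/back ratio moves < 2% when
the point count doubles, and domain-integrated PLC is conserved to 10⁻⁴
relative.

## What the defaults do and do not show

The generator-style defaults (base parameter table, 0.02 μM enzyme,
0.005–0.05 μM receptor, 10-fold variant edits, 10% gradient steepness)
are the study conditions; passing tests show the mechanism behaves as
described under mass-action, well-mixed (or 1D) deterministic kinetics.
They do not address stochastic fluctuations at low copy number, multiple
phosphorylation sites, PH/SH3-domain interactions, IP₃/calcium dynamics,
or 2D/3D geometry — all outside this model's scope.
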