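"""Hypothetical activating variants and the two-state reduction.

Disease-linked PLC-γ1 substitutions are thought to act through two
mechanisms: weakening the autoinhibitory cSH2–core contact (K_c variants)
or strengthening membrane association of the uninhibited core (K_a
variants).  Both raise steady-state activity, but they leave distinct
kinetic signatures, which the two-state reduction makes explicit: an
activation time course with steady-state active fraction A_ss and
half-time t_1/2 maps onto apparent rate constants

    kf_app = A_ss · ln2 / t_1/2,    kr_app = (1 − A_ss) · ln2 / t_1/2,

the exponential-relaxation identification of dA/dt = kf(1−A) − kr·A.
K_c edits chiefly move kf_app (priming); K_a edits chiefly move kr_app
(maintenance), and ln2/kr_app predicts the decay-protocol half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ode
from .params import ParameterSet


@dataclass(frozen=True)
class VariantSpec:
    """A named parameter perturbation.

    ``scale`` holds multiplicative factors on independent parameters (so
    an edit to ``k_act`` automatically carries ``k_act_2 = χ·k_act`` with
    it, preserving the shared-χ constraint).  ``absolute`` holds absolute
    overrides.  ``phospho_init`` marks the phosphomimetic, simulated with
    a constitutively phosphorylated pool and no dephosphorylation.
    """

    name: str
    kind: str  # {"phospho", "Kc", "Ka", "custom"}
    scale: Mapping[str, float] = field(default_factory=dict)
    absolute: Mapping[str, float] = field(default_factory=dict)
    phospho_init: bool = False

    def apply(self, params: ParameterSet) -> ParameterSet:
        p = params.scaled(**dict(self.scale)) if self.scale else params
        if self.absolute:
            p = p.with_edits(**dict(self.absolute))
        return p


BASE_VARIANT = VariantSpec("base", "custom")


def standard_variants(fold: float = 10.0) -> list[VariantSpec]:
    """The six 10-fold K_c/K_a variants plus the phosphorylation extremes.

    (i) reduced k_bind_c, (ii) increased k_unbind_c, (iii) both — the K_c
    variants; (iv) increased k_act (and with it k_act_2), (v) decreased
    k_inact, (vi) both — the K_a variants.  Y783F is nonphosphorylatable
    (k_phos = 0); the phosphomimetic is constitutively phosphorylated.
    """
    f = fold
    return [
        VariantSpec("Kc_i_bind_down", "Kc", scale={"k_bind_c": 1 / f}),
        VariantSpec("Kc_ii_unbind_up", "Kc", scale={"k_unbind_c": f}),
        VariantSpec("Kc_iii_both", "Kc", scale={"k_bind_c": 1 / f, "k_unbind_c": f}),
        VariantSpec("Ka_iv_act_up", "Ka", scale={"k_act": f}),
        VariantSpec("Ka_v_inact_down", "Ka", scale={"k_inact": 1 / f}),
        VariantSpec("Ka_vi_both", "Ka", scale={"k_act": f, "k_inact": 1 / f}),
        VariantSpec("Y783F", "phospho", absolute={"k_phos": 0.0}),
        VariantSpec(
            "phosphomimetic", "phospho", absolute={"k_dephos": 0.0},
            phospho_init=True,
        ),
    ]


@dataclass(frozen=True)
class TwoStateFit:
    """Apparent two-state rate constants recovered from (A_ss, t_1/2)."""

    kf_app: float
    kr_app: float
    a_ss: float
    t_half: float


def fit_two_state(a_ss: float, t_half: float) -> TwoStateFit:
    """Map (A_ss, t_1/2) onto apparent forward/reverse rate constants.

    Valid for 0 < A_ss < 1 and t_1/2 > 0; the identities
    kf + kr = ln2/t_1/2 and kf/(kf+kr) = A_ss hold exactly.
    """
    if not 0.0 < a_ss < 1.0:
        raise ValueError(f"a_ss must lie in (0, 1), got {a_ss}")
    if t_half <= 0:
        raise ValueError(f"t_half must be positive, got {t_half}")
    lam = math.log(2.0) / t_half
    return TwoStateFit(kf_app=a_ss * lam, kr_app=(1.0 - a_ss) * lam,
                       a_ss=a_ss, t_half=t_half)


def two_state_trajectory(
    kf: float, kr: float, times: np.ndarray
) -> np.ndarray:
    """Closed-form active fraction of the literal two-state system from rest.

    dA/dt = kf(1−A) − kr·A with A(0)=0 gives
    A(t) = A_ss (1 − exp(−(kf+kr) t)), A_ss = kf/(kf+kr).
    """
    lam = kf + kr
    return (kf / lam) * (1.0 - np.exp(-lam * np.asarray(times)))


def variant_scan(
    params: ParameterSet,
    variants: Sequence[VariantSpec] | None = None,
    rtk_total: float = 0.05,
    include_base: bool = True,
    decay: bool = True,
    t_end: float = ode.T_END,
) -> pd.DataFrame:
    """Activation and lifetime metrics for each variant at one receptor dose.

    Per variant: a full activation run (A_ss, t_1/2, two-state fit) and,
    when ``decay`` is set, a lifetime run whose half-life the apparent
    reverse rate constant should predict as ln2/kr_app.  Per-variant
    failures are recorded in the ``error`` column and the scan continues.
    """
    if variants is None:
        variants = standard_variants()
    todo = ([BASE_VARIANT] if include_base else []) + list(variants)
    rows = []
    for var in todo:
        row: dict = {"variant": var.name, "kind": var.kind, "error": ""}
        try:
            p = var.apply(params).with_edits(rtk_total=rtk_total)
            net = ode.make_network(p)
            c0 = ode.default_initial_state(net, phospho=var.phospho_init)
            res = ode.simulate_to_steady_state(net, c0, t_end=t_end)
            row.update(
                a_ss=res.active_fraction_ss,
                t_half=res.t_half_activation,
                converged=res.converged,
            )
            fit = fit_two_state(res.active_fraction_ss, res.t_half_activation)
            row.update(kf_app=fit.kf_app, kr_app=fit.kr_app,
                       predicted_decay_half_life=math.log(2.0) / fit.kr_app)
            if decay:
                dec = ode.decay_protocol(
                    p, switch_time=t_end, phospho_init=var.phospho_init
                )
                row["decay_half_life"] = dec.half_life
        except (RuntimeError, ValueError) as err:
            row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)


def t_half_fold_range(scan: pd.DataFrame) -> float:
    """Max/min ratio of activation half-times across a scan table."""
    vals = scan["t_half"].dropna()
    return float(vals.max() / vals.min())
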