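"""Canned scenario configurations and small synthetic test inputs.

Each fixture is a plain-text file reproducing one of the model's standard
scenarios: the base parameter table, phosphorylation/dephosphorylation
scan grids, lifetime scans, the variant panel, and the polarization
settings.  The two-state oracle fixture holds noisy synthetic activation
curves with known (kf, kr), regenerated deterministically from its seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .analysis import standard_variants, two_state_trajectory
from .params import ParameterSet


def generate_fixtures(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write the fixture bundle into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def dump(name: str, data: dict) -> None:
        path = outdir / name
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        written.append(path)

    base = ParameterSet()
    dump("table1_base.yaml", base.to_dict())

    dump(
        "fig2_phos_scan.yaml",
        {
            "protocol": "dose-response",
            "rtk_values": [float(v) for v in np.linspace(0.005, 0.05, 10)],
            "k_phos_grid": [0.1, 1.0, 10.0, 100.0],
            "k_dephos_grid": [0.1, 1.0, 10.0, 100.0],
            "K_p_cases": {"Kp100": {"k_bind_p": 100.0}, "Kp10": {"k_bind_p": 10.0}},
        },
    )
    dump(
        "fig3_kphos.yaml",
        {"protocol": "decay", "switch_time": 5000.0,
         "k_phos": [0.1, 1.0, 10.0]},
    )
    dump(
        "fig3_kact.yaml",
        {"protocol": "decay", "switch_time": 5000.0,
         "k_act": [0.001, 0.01, 0.1], "note": "k_act_2 = chi * k_act follows"},
    )
    dump(
        "fig4_5_variants.yaml",
        {
            "protocol": "variant-scan",
            "rtk_total": 0.05,
            "fold": 10.0,
            "variants": [v.name for v in standard_variants()],
        },
    )
    dump(
        "fig6_7_polarization.yaml",
        {
            "protocol": "polarize",
            "steepness": 0.10,
            "rfrac_values": [0.01, 0.02, 0.05, 0.077, 0.12],
            "k_on_nSH2": 0.1,
            "k_off_nSH2": 0.1,
            "K_PA": 10.0,
            "pfl2": {"n": 2, "K_PLD": 0.1, "gamma_V_synth_dp": 10.0},
            "k_DAGK_factors": [0.3, 1.0, 3.0],
        },
    )

    # synthetic two-state activation curves with known rate constants
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, 400.0, 201)
    curves = {"time": times.tolist(), "seed": seed, "cases": []}
    for kf, kr in [(0.02, 0.08), (0.005, 0.005), (0.1, 0.02)]:
        a = two_state_trajectory(kf, kr, times)
        noisy = a + rng.normal(0.0, 1e-4, size=a.shape)
        curves["cases"].append(
            {"kf": kf, "kr": kr, "active_fraction": noisy.tolist()}
        )
    path = outdir / "two_state_oracle.json"
    path.write_text(json.dumps(curves))
    written.append(path)
    return written
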