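"""Report generation: closed-form tables, equilibrium reports, the
Monte-Carlo validation CSV and the welfare-crossing figure."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__, model
from .config import ScenarioConfig
from .distributions import UncertaintyDistribution
from .equilibrium import EquilibriumOutcome, solve_equilibrium
from .params import EconomicParameters, Tariff
from .simulate import SimulationConfig, simulate_physician

__all__ = [
    "closed_form_table",
    "write_equilibrium_report",
    "read_equilibrium_report",
    "validation_table",
    "plot_welfare_crossing",
    "run_scenario",
]


def closed_form_table(
    params: EconomicParameters,
    tariff: Tariff,
    n_points: int = 101,
) -> pd.DataFrame:
    """Closed-form physician quantities over a grid of uncertainty levels."""
    b = np.linspace(0.0, params.b_max, n_points)
    return pd.DataFrame(
        {
            "b": b,
            "s_star": model.indifference_threshold(params, b),
            "Q_Ae": model.empiric_prescriptions(params, b),
            "W_e": model.empiric_welfare(params, b),
            "T": model.tests_count(params, b, tariff.t),
            "Q_APOCT": model.poct_prescriptions(params, b, tariff.t),
            "W_POCT": model.poct_welfare(params, b, tariff),
        }
    )


def write_equilibrium_report(outcome: EquilibriumOutcome, out_dir) -> None:
    """Serialize the equilibrium outcome as flat JSON and CSV key/value files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = outcome.as_dict()
    (out_dir / "equilibrium.json").write_text(json.dumps(d, indent=2) + "\n")
    pd.DataFrame(
        {"key": list(d.keys()), "value": list(d.values())}
    ).to_csv(out_dir / "equilibrium.csv", index=False)


def read_equilibrium_report(out_dir) -> dict:
    """Round-trip: parse a written equilibrium JSON report."""
    return json.loads((Path(out_dir) / "equilibrium.json").read_text())


def validation_table(
    params: EconomicParameters,
    tariff: Tariff,
    b_values,
    n_patients: int = 10_000,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Closed forms vs. Monte-Carlo oracle at a few uncertainty levels.

    One row per (quantity, b): the closed-form value, the simulated
    estimate, its standard error and the z-score of the discrepancy.
    """
    rows: List[dict] = []
    for i, b in enumerate(b_values):
        b = float(b)
        emp = simulate_physician(
            params,
            b,
            SimulationConfig(n_patients, n_draws, seed + 2 * i, "empiric"),
        )
        poct = simulate_physician(
            params,
            b,
            SimulationConfig(
                n_patients, n_draws, seed + 2 * i + 1, "poct", tariff
            ),
        )
        checks = [
            ("W_e", float(model.empiric_welfare(params, b)),
             emp.mean_welfare, emp.se_welfare),
            ("Q_Ae", float(model.empiric_prescriptions(params, b)),
             emp.prescription_rate, emp.se_prescription_rate),
            ("W_POCT", float(model.poct_welfare(params, b, tariff)),
             poct.mean_welfare, poct.se_welfare),
            ("Q_APOCT", float(model.poct_prescriptions(params, b, tariff.t)),
             poct.prescription_rate, poct.se_prescription_rate),
            ("T", float(model.tests_count(params, b, tariff.t)),
             poct.test_rate, poct.se_test_rate),
        ]
        for name, closed, est, se in checks:
            z = (est - closed) / se if se > 0 else 0.0
            rows.append(
                {
                    "quantity": name,
                    "b": b,
                    "closed_form": closed,
                    "oracle_estimate": est,
                    "se": se,
                    "z_score": z,
                }
            )
    return pd.DataFrame(rows)


def plot_welfare_crossing(
    params: EconomicParameters,
    dist: UncertaintyDistribution,
    N: int,
    output,
) -> float:
    """Plot empiric vs. POCT welfare at the equilibrium tariff.

    Both curves are linear in ``b`` (POCT welfare is flat at ``t = 0``),
    so they cross exactly once — at the marginal adopter ``b*``, which is
    marked.  Returns the numerically located crossing point.
    """
    outcome = solve_equilibrium(params, dist, N)
    b = np.linspace(0.0, params.b_max, 401)
    w_e = np.asarray(model.empiric_welfare(params, b))
    w_p = np.asarray(model.poct_welfare(params, b, outcome.tariff_star))
    diff = w_e - w_p
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if sign_change.size:
        i = sign_change[0]
        # linear interpolation of the (piecewise linear) difference
        crossing = float(
            b[i] - diff[i] * (b[i + 1] - b[i]) / (diff[i + 1] - diff[i])
        )
    else:
        crossing = float("nan")

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(b, w_e, label=r"$W_e(b)$ (empiric)")
    ax.plot(b, w_p, label=r"$W_{POCT}(b)$ (equilibrium tariff)")
    ax.axvline(outcome.b_star, color="grey", ls=":", lw=1,
               label=rf"$b^*$ = {outcome.b_star:.4g}")
    ax.set_xlabel("physician uncertainty $b$")
    ax.set_ylabel("expected benefit")
    ax.legend(frameon=False)
    fig.tight_layout()
    output = Path(output)
    output.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(output)
    plt.close(fig)
    return crossing


def run_scenario(config: ScenarioConfig, out_dir, seed: Optional[int] = None) -> dict:
    """Run a full scenario: closed-form table, equilibrium report and,
    if the config requests it, the Monte-Carlo validation CSV.

    Writes a run log recording the resolved inputs (including derived
    ``p`` and ``b_max``) and the package version, so reports are
    self-describing.  Returns the equilibrium outcome as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outcome = solve_equilibrium(config.params, config.dist, config.N)

    closed_form_table(config.params, outcome.tariff_star).to_csv(
        out_dir / "closed_forms.csv", index=False
    )
    write_equilibrium_report(outcome, out_dir)

    log = {
        "package": "poctecon",
        "version": __version__,
        "parameters": {
            "B": config.params.B,
            "l": config.params.l,
            "p_a": config.params.p_a,
            "r": config.params.r,
            "a_bar": config.params.a_bar,
            "p": config.params.p,
            "b_max": config.params.b_max,
        },
        "distribution": config.dist.name,
        "N": config.N,
    }
    if config.has_simulation:
        sim_seed = seed if seed is not None else config.seed
        bm = config.params.b_max
        table = validation_table(
            config.params,
            outcome.tariff_star,
            b_values=[0.25 * bm, 0.5 * bm, 0.75 * bm],
            n_patients=config.n_patients,
            n_draws=config.n_draws,
            seed=sim_seed,
        )
        table.to_csv(out_dir / "validation.csv", index=False)
        log["simulation"] = {
            "n_patients": config.n_patients,
            "n_draws": config.n_draws,
            "seed": sim_seed,
        }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return outcome.as_dict()
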