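"""Patient-level Monte-Carlo simulator and brute-force optimizers.

These are independent checks of the closed forms in :mod:`poctecon.model`
and :mod:`poctecon.equilibrium`: they implement only the primitive
decision rules (who is tested, who is prescribed, realized benefits) and
recover the aggregate quantities by sampling or exhaustive search, never
by reusing the algebrara they validate.

Sampling design: the unknown threshold ``A`` is drawn once per replicate,
and a fresh panel of patient symptoms ``s ~ U(0, 1)`` per replicate;
welfare averages over both layers.  A conditional-exact mode
(:func:`empiric_panel_given_a`, :func:`poct_panel_given_a`) integrates the
panel dimension analytically given the realized ``a`` for low-variance
checks of the scenario-conditional benefit components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import model
from .distributions import UncertaintyDistribution
from .params import (
    EconomicParameters,
    ParameterError,
    Tariff,
    as_uncertainty_level,
)

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "simulate_physician",
    "empiric_panel_given_a",
    "poct_panel_given_a",
    "brute_force_threshold",
    "brute_force_testing_set",
    "brute_force_tariff",
]

_CHUNK_ELEMENTS = 4_000_000  # max simultaneous patient outcomes in memory


@dataclass(frozen=True)
class SimulationConfig:
    """Sample sizes, seed and strategy for one physician-level simulation."""

    n_patients: int
    n_draws: int
    seed: int
    strategy: str = "empiric"
    tariff: Optional[Tariff] = None

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_draws < 1:
            raise ParameterError("requires n_patients >= 1 and n_draws >= 1")
        if self.strategy not in ("empiric", "poct"):
            raise ParameterError("requires strategy in {'empiric', 'poct'}")
        if self.strategy == "poct" and self.tariff is None:
            raise ParameterError("requires a tariff for the poct strategy")


@dataclass(frozen=True)
class SimulationSummary:
    """Monte-Carlo estimates with standard errors over replicates."""

    mean_welfare: float
    se_welfare: float
    prescription_rate: float
    se_prescription_rate: float
    test_rate: float
    se_test_rate: float
    untreated_sick_rate: float
    n_effective: int


def _summ(values: np.ndarray) -> Tuple[float, float]:
    n = values.size
    se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(values.mean()), se


def simulate_physician(
    params: EconomicParameters, b, config: SimulationConfig
) -> SimulationSummary:
    """Simulate one physician's panel outcomes under the chosen strategy.

    Empiric: antibiotics iff ``s >= s*(b)``.  POCT: patients in the
    testing band get the error-free test (fee ``t``) and exactly the
    treatment they need; untested patients above the band get antibiotics,
    below it nothing; the device price ``C`` is paid once per physician.
    Realized per-patient benefit is ``B - p`` (treated), ``B`` (untreated,
    cured) or ``-l`` (untreated, sick), minus any testing fee.  Identical
    seeds give bit-identical summaries.
    """
    b = float(as_uncertainty_level(params, b))
    B, l, p, a_bar = params.B, params.l, params.p, params.a_bar
    s_star = float(model.indifference_threshold(params, b))
    poct = config.strategy == "poct"
    if poct:
        t = model.ensure_feasible_fee(params, config.tariff.t)
        C = config.tariff.C
        lo, hi = model.testing_interval(params, b, t)
        lo, hi = float(lo), float(hi)

    rng = np.random.default_rng(config.seed)
    n_d, n_p = config.n_draws, config.n_patients
    chunk = max(1, min(n_d, _CHUNK_ELEMENTS // n_p))
    w_rep = np.empty(n_d)
    presc_rep = np.empty(n_d)
    test_rep = np.empty(n_d)
    sick_rep = np.empty(n_d)

    done = 0
    while done < n_d:
        m = min(chunk, n_d - done)
        a = rng.uniform(a_bar - 0.5 * b, a_bar + 0.5 * b, size=(m, 1))
        s = rng.uniform(0.0, 1.0, size=(m, n_p))
        needs = s > a
        if not poct:
            presc = s >= s_star
            sick = ~presc & needs
            welfare = np.where(presc, B - p, np.where(needs, -l, B))
            test = np.zeros((m, n_p), dtype=bool)
        else:
            tested = (s >= lo) & (s <= hi)
            above = ~tested & (s > hi)
            presc = (tested & needs) | above
            sick = ~tested & ~above & needs
            welfare = np.where(
                tested,
                B - t - p * needs,
                np.where(above, B - p, np.where(needs, -l, B)),
            )
            test = tested
        sl = slice(done, done + m)
        w_rep[sl] = welfare.mean(axis=1) - (C if poct else 0.0)
        presc_rep[sl] = presc.mean(axis=1)
        test_rep[sl] = test.mean(axis=1)
        sick_rep[sl] = sick.mean(axis=1)
        done += m

    mw, sew = _summ(w_rep)
    mp, sep = _summ(presc_rep)
    mt, set_ = _summ(test_rep)
    ms, _ = _summ(sick_rep)
    return SimulationSummary(
        mean_welfare=mw,
        se_welfare=sew,
        prescription_rate=mp,
        se_prescription_rate=sep,
        test_rate=mt,
        se_test_rate=set_,
        untreated_sick_rate=ms,
        n_effective=n_p * n_d,
    )


# ---------------------------------------------------------------------------
# Conditional-exact panel integrals (given the realized threshold a)


def empiric_panel_given_a(params: EconomicParameters, b, a):
    """Exact panel gross benefit and prescriptions given realized ``a``,
    under empiric prescribing with cutoff ``s*(b)``.

    Integrating over ``s ~ U(0, 1)``: benefit
    ``B - p(1 - s*) - (B + l) max(s* - a, 0)``; prescriptions ``1 - s*``.
    """
    b = as_uncertainty_level(params, b)
    s_star = np.asarray(model.indifference_threshold(params, b))
    a = np.asarray(a, dtype=float)
    benefit = (
        params.B
        - params.p * (1.0 - s_star)
        - (params.B + params.l) * np.maximum(s_star - a, 0.0)
    )
    presc = np.broadcast_to(1.0 - s_star, benefit.shape).copy()
    return benefit, presc


def poct_panel_given_a(params: EconomicParameters, b, t: float, a):
    """Exact panel gross benefit and prescriptions given realized ``a``,
    under POCT with per-test fee ``t`` (fee and device price excluded —
    gross means health value minus drug costs only).

    The panel splits at the testing band ``[lo, hi]``: below it the
    untested patient is untreated (sick iff ``s > a``), inside it the test
    assigns the correct treatment, above it antibiotics are given.
    """
    b = as_uncertainty_level(params, b)
    lo, hi = model.testing_interval(params, b, t)
    lo, hi = np.asarray(lo), np.asarray(hi)
    a = np.asarray(a, dtype=float)
    B, l, p = params.B, params.l, params.p
    a_clip = np.clip(a, lo, hi)
    below = np.where(a >= lo, B * lo, B * a - l * (lo - a))  # s in [0, lo)
    tested = B * (hi - lo) - p * (hi - a_clip)               # s in [lo, hi]
    above = (1.0 - hi) * (B - p)                             # s in (hi, 1]
    benefit = below + tested + above
    presc = (hi - a_clip) + (1.0 - hi)
    return benefit, presc


# ---------------------------------------------------------------------------
# Brute-force optimizers


def brute_force_threshold(
    params: EconomicParameters, b, grid_step: float = 1e-4
) -> float:
    """Grid-search the empiric cutoff maximizing expected benefit.

    For a candidate cutoff ``s`` the exact expected benefit, integrating
    the panel and ``A ~ U(a_bar - b/2, a_bar + b/2)`` in closed form, is
    ``B - p(1 - s) - (B + l) E[(s - A)+]``.  Returns the maximizing grid
    point, within one grid step of the analytic cutoff.
    """
    if not grid_step > 0:
        raise ParameterError("requires grid_step > 0")
    b = float(as_uncertainty_level(params, b))
    a_bar, B, l, p = params.a_bar, params.B, params.l, params.p
    lo0, hi0 = a_bar - 0.5 * b, a_bar + 0.5 * b
    if b == 0:
        return a_bar
    s = np.arange(lo0, hi0 + grid_step / 2, grid_step)
    shortfall = (s - lo0) ** 2 / (2.0 * b)  # E[(s - A)+]
    w = B - p * (1.0 - s) - (B + l) * shortfall
    return float(s[np.argmax(w)])


def brute_force_testing_set(
    params: EconomicParameters, b, t: float, grid_step: float = 1e-4
) -> Tuple[float, float]:
    """Per-symptom comparison of test vs. no-test expected benefit.

    For each symptom ``s`` in the uncertainty band, testing yields
    ``B - p F(s) - t``; not testing yields the empiric default
    (``B - p`` above the cutoff, ``B - (B + l) F(s)`` below).  Returns the
    boundary symptoms of the test-preferred set, which is an interval;
    at the fee feasibility bound the set degenerates to a single point.
    """
    if not grid_step > 0:
        raise ParameterError("requires grid_step > 0")
    b = float(as_uncertainty_level(params, b))
    t = model.ensure_feasible_fee(params, t)
    a_bar, B, l, p = params.a_bar, params.B, params.l, params.p
    lo0, hi0 = a_bar - 0.5 * b, a_bar + 0.5 * b
    if b == 0:
        return a_bar, a_bar
    s = np.arange(lo0, hi0 + grid_step / 2, grid_step)
    F = (s - lo0) / b
    test_benefit = B - p * F - t
    s_star = float(model.indifference_threshold(params, b))
    no_test = np.where(s >= s_star, B - p, B - (B + l) * F)
    prefer = test_benefit >= no_test - 1e-12
    if not prefer.any():
        deg = float(s[np.argmax(test_benefit - no_test)])
        return deg, deg
    idx = np.flatnonzero(prefer)
    return float(s[idx[0]]), float(s[idx[-1]])


def _profit_on_grid(
    params: EconomicParameters,
    dist: UncertaintyDistribution,
    N: int,
    C: np.ndarray,
    t: np.ndarray,
) -> np.ndarray:
    """Exact firm profit for each (C, t) pair given physician best responses."""
    p, Bl = params.p, params.B + params.l
    Cg, tg = np.meshgrid(C, t, indexing="ij")
    cap_slope = (p * (Bl - p) - tg * Bl) ** 2 / (2 * p * Bl * (Bl - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        b0 = np.where(cap_slope > 0, Cg / np.where(cap_slope > 0, cap_slope, 1.0), np.where(Cg > 0, np.inf, 0.0))
    profit = np.zeros_like(Cg)
    inside = b0 <= dist.b_max
    if inside.any():
        b0_in = np.clip(b0[inside], 0.0, dist.b_max)
        mass = np.asarray(dist.adopter_mass(b0_in), dtype=float)
        k = ((p - tg[inside]) * Bl - p * p) / (p * (Bl - p))
        pmean = np.asarray(dist.mean_above(b0_in), dtype=float)
        profit[inside] = N * (Cg[inside] * mass + tg[inside] * k * pmean)
    return profit


def brute_force_tariff(
    params: EconomicParameters,
    dist: UncertaintyDistribution,
    N: int,
    n_c: int = 200,
    n_t: int = 200,
    refine: bool = True,
) -> Tuple[Tariff, float]:
    """Exhaustive search of the firm's tariff over a (C, t) grid.

    For each candidate tariff every physician type's adoption decision is
    the best response from the adoption cap, and the firm's expected
    profit is computed exactly from the distribution's integral
    functionals.  A coarse scan is followed by one 10x finer local rescan
    around the incumbent.  Returns the best tariff and its profit.
    """
    if n_c < 2 or n_t < 2:
        raise ParameterError("requires at least 2 grid points per axis")
    c_max = float(model.adoption_price_cap(params, dist.b_max, 0.0))
    t_max = params.max_test_fee
    C = np.linspace(0.0, c_max, n_c)
    t = np.linspace(0.0, t_max, n_t)
    profit = _profit_on_grid(params, dist, N, C, t)
    i, j = np.unravel_index(np.argmax(profit), profit.shape)
    best = (float(C[i]), float(t[j]), float(profit[i, j]))
    if refine:
        dc = C[1] - C[0]
        dt = t[1] - t[0]
        C2 = np.linspace(max(best[0] - dc, 0.0), min(best[0] + dc, c_max), 21)
        t2 = np.linspace(max(best[1] - dt, 0.0), min(best[1] + dt, t_max), 21)
        profit2 = _profit_on_grid(params, dist, N, C2, t2)
        i2, j2 = np.unravel_index(np.argmax(profit2), profit2.shape)
        if profit2[i2, j2] >= best[2]:
            best = (float(C2[i2]), float(t2[j2]), float(profit2[i2, j2]))
    return Tariff(C=best[0], t=best[1]), best[2]
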