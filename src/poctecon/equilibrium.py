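"""Subgame-perfect equilibrium of the firm–physician game.

Solved by backward induction.  In the second stage each physician adopts
the diagnostic device iff the device price is below their adoption cap
(see :func:`poctecon.model.adoption_price_cap`); adoption is monotone in
uncertainty, so the market segments at a marginal adopter ``b*``.  In the
first stage the monopolist firm prices the two-part tariff ``(C, t)``.
Substituting the binding adoption constraint into profits shows the
objective is decreasing in ``t``, so the firm sets ``t = 0`` (it earns
nothing per test and profits only from device sales) and chooses ``b*``
to maximize ``b (1 - G(b))``, whose interior stationarity condition is
``1 - G(b) - b g(b) = 0``.

The device price implied by the binding constraint at ``t = 0`` is
``C* = b* p (B + l - p) / (2 (B + l))``.  The source propositions also
state a variant without the factor 2, inconsistent with their own
adoption cap; this module implements the derivation-consistent form and
reports the variant as ``alternate_device_price`` for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import model
from .distributions import UncertaintyDistribution
from .params import EconomicParameters, ParameterError, Tariff

__all__ = [
    "EquilibriumOutcome",
    "marginal_adopter",
    "optimal_tariff",
    "firm_profit",
    "aggregate_prescription_reduction",
    "internalization_reduction",
    "solve_equilibrium",
]


@dataclass(frozen=True)
class EquilibriumOutcome:
    """Market outcome at the firm's optimal tariff.

    ``prescriptions_reduction`` and ``internalization_reduction`` are
    aggregate patient counts over the ``N`` physicians; all other patient
    quantities are per-physician fractions of a unit-mass panel.
    """

    b_star: float
    tariff_star: Tariff
    firm_profit: float
    adopter_fraction: float
    welfare_adopter: float
    prescriptions_reduction: float
    internalization_reduction: float
    N: int
    alternate_device_price: float

    def as_dict(self) -> dict:
        return {
            "b_star": self.b_star,
            "C_star": self.tariff_star.C,
            "t_star": self.tariff_star.t,
            "firm_profit": self.firm_profit,
            "adopter_fraction": self.adopter_fraction,
            "welfare_adopter": self.welfare_adopter,
            "prescriptions_reduction": self.prescriptions_reduction,
            "internalization_reduction": self.internalization_reduction,
            "N": self.N,
            "alternate_device_price": self.alternate_device_price,
        }


def marginal_adopter(dist: UncertaintyDistribution, n_grid: int = 10_001) -> float:
    """Uncertainty level ``b*`` of the marginal adopter.

    Found as the global maximizer of the firm's reduced objective
    ``b (1 - G(b))`` on ``(0, b_max)`` — a grid scan followed by local
    refinement and, where it brackets, a polish on the stationarity
    condition ``1 - G(b) - b g(b) = 0``.  Maximization rather than naive
    root-finding is used because the stationarity condition may have
    several roots for multimodal densities.
    """
    bm = dist.b_max
    grid = np.linspace(0.0, bm, n_grid)
    obj = grid * (1.0 - np.asarray(dist.G(grid), dtype=float))
    i = int(np.argmax(obj))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda b: -b * (1.0 - float(dist.G(b))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    b_star = float(res.x)

    # polish on the first-order condition if it brackets nearby
    def foc(b):
        return 1.0 - float(dist.G(b)) - b * float(dist.g(b))

    eps = (hi - lo) / 2.0
    a, c = max(b_star - eps, 1e-12), min(b_star + eps, bm - 1e-12)
    try:
        fa, fc = foc(a), foc(c)
        if fa * fc < 0:
            root = float(optimize.brentq(foc, a, c, xtol=1e-14))
            if root * (1.0 - float(dist.G(root))) >= b_star * (
                1.0 - float(dist.G(b_star))
            ):
                b_star = root
    except ValueError:  # pragma: no cover - non-bracketing or singular g
        pass
    return b_star


def optimal_tariff(
    params: EconomicParameters, dist: UncertaintyDistribution
) -> Tariff:
    """The firm's profit-maximizing two-part tariff: ``t = 0`` and the
    device price set at the marginal adopter's cap,
    ``C* = b* p (B + l - p) / (2 (B + l))``."""
    b_star = marginal_adopter(dist)
    C = float(model.adoption_price_cap(params, b_star, 0.0))
    return Tariff(C=C, t=0.0)


def firm_profit(
    params: EconomicParameters,
    dist: UncertaintyDistribution,
    tariff: Tariff,
    b0: float,
    N: int,
) -> float:
    """Aggregate firm profit ``N ∫_{b0}^{b_max} [C + t T(t, x)] g(x) dx``.

    Computed from the definition through the distribution's integral
    functionals: device revenue ``N C (1 - G(b0))`` plus test-fee revenue
    ``N t k(t) ∫_{b0} x g dx`` where ``T(t, x) = x k(t)``.
    """
    t = model.ensure_feasible_fee(params, tariff.t)
    mass = float(dist.adopter_mass(b0))
    profit = N * tariff.C * mass
    if t > 0:
        p, Bl = params.p, params.B + params.l
        k = ((p - t) * Bl - p * p) / (p * (Bl - p))
        profit += N * t * k * float(dist.mean_above(b0))
    return profit


def aggregate_prescription_reduction(
    params: EconomicParameters,
    dist: UncertaintyDistribution,
    b0: float,
    N: int,
) -> float:
    """Prescriptions avoided market-wide by adopters testing at ``t = 0``.

    Each adopter's reduction is ``Q_Ae(b) - Q_APOCT(b) = b(B+l-2p)/(2(B+l))``,
    aggregated: ``N (B+l-2p)/(2(B+l)) ∫_{b0}^{b_max} x g(x) dx``.
    Decreasing in the effective price ``p`` — internalizing the
    resistance cost shrinks the empiric–POCT gap.
    """
    p, Bl = params.p, params.B + params.l
    return N * (Bl - 2 * p) / (2 * Bl) * float(dist.mean_above(b0))


def internalization_reduction(
    params: EconomicParameters,
    dist: UncertaintyDistribution,
    b0: float,
    N: int,
) -> float:
    """Extra prescriptions avoided because physicians price in the
    resistance externality ``r``: ``N r/(B+l) ∫_{b0}^{b_max} x g(x) dx``.

    Equals the shift in aggregate empiric prescribing when the effective
    price rises from ``p_a`` to ``p_a + r`` (holding ``B + l`` fixed);
    zero when ``r = 0`` and linear in ``r``.
    """
    return N * params.r / (params.B + params.l) * float(dist.mean_above(b0))


def solve_equilibrium(
    params: EconomicParameters,
    dist: UncertaintyDistribution,
    N: int,
) -> EquilibriumOutcome:
    """Full backward-induction solution of the two-stage game."""
    if not (isinstance(N, (int, np.integer)) and N >= 1):
        raise ParameterError("requires N >= 1 (integer physician count)")
    if abs(dist.b_max - params.b_max) > 1e-9:
        raise ParameterError(
            "requires the distribution support to equal "
            f"[0, 2 min(a_bar, 1 - a_bar)] = [0, {params.b_max:.6g}]"
        )
    b_star = marginal_adopter(dist)
    tariff = Tariff(C=float(model.adoption_price_cap(params, b_star, 0.0)), t=0.0)
    p, Bl = params.p, params.B + params.l
    return EquilibriumOutcome(
        b_star=b_star,
        tariff_star=tariff,
        firm_profit=firm_profit(params, dist, tariff, b_star, N),
        adopter_fraction=float(dist.adopter_mass(b_star)),
        welfare_adopter=params.B - p * (1.0 - params.a_bar) - tariff.C,
        prescriptions_reduction=aggregate_prescription_reduction(
            params, dist, b_star, N
        ),
        internalization_reduction=internalization_reduction(
            params, dist, b_star, N
        ),
        N=int(N),
        alternate_device_price=b_star * p * (Bl - p) / Bl,
    )
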