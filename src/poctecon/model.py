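"""Closed-form quantities for a single physician of uncertainty level ``b``.

Two prescribing strategies are compared.  Under *empiric* prescribing the
physician picks a symptom cutoff and prescribes above it.  Under
*POCT-guided* prescribing (point-of-care testing) an error-free diagnostic,
bought under a two-part tariff ``(C, t)``, is administered to an interior
band of uncertain patients, who then receive exactly the treatment they
need; patients outside the band are treated as under empiric prescribing.

All patient quantities are fractions of the physician's unit-mass panel;
welfare is expected net benefit per panel (health value minus drug and
testing costs).  Every function accepts scalar or numpy-array ``b``.
"""

from __future__ import annotations

import numpy as np

from .params import (
    EconomicParameters,
    InfeasibleTariffError,
    Tariff,
    as_uncertainty_level,
)

__all__ = [
    "indifference_threshold",
    "empiric_prescriptions",
    "empiric_unneeded_prescriptions",
    "empiric_welfare",
    "ensure_feasible_fee",
    "testing_interval",
    "tests_count",
    "scenario_probabilities",
    "gross_benefit_components",
    "poct_gross_benefit",
    "poct_welfare",
    "poct_prescriptions",
    "adoption_price_cap",
    "adopts_poct",
]

_FEE_TOL = 1e-12


def ensure_feasible_fee(params: EconomicParameters, t: float) -> float:
    """Validate the per-test fee against the testing-feasibility bound.

    The fee must satisfy ``t <= p(B+l-p)/(B+l)`` (equivalently
    ``p^2 <= (B+l)(p-t)``); above it no patient is worth testing.  The
    boundary value itself is accepted — it yields a degenerate testing
    interval and zero tests.
    """
    if t < 0:
        raise InfeasibleTariffError("requires t >= 0")
    bound = params.max_test_fee
    if t > bound * (1 + _FEE_TOL) + _FEE_TOL:
        raise InfeasibleTariffError(
            "requires t <= p(B+l-p)/(B+l): fee "
            f"{t:.6g} exceeds the feasibility bound {bound:.6g}; "
            "no testing region exists"
        )
    return float(t)


# ---------------------------------------------------------------------------
# Empiric prescribing


def indifference_threshold(params: EconomicParameters, b):
    """Symptom cutoff ``s*(b)`` above which the physician prescribes empirically.

    The marginal patient equates the sure benefit of antibiotics, ``B - p``,
    with the expected benefit of no treatment, ``B(1-F(s)) - l F(s)``,
    giving ``s*(b) = a_bar - b/2 + p b / (B + l)``.  Decreasing in ``b``
    because ``B + l > 2p`` is maintained.
    """
    b = as_uncertainty_level(params, b)
    return params.a_bar - 0.5 * np.asarray(b) + params.p * np.asarray(b) / (
        params.B + params.l
    )


def empiric_prescriptions(params: EconomicParameters, b):
    """Fraction of the panel prescribed antibiotics empirically: ``1 - s*(b)``."""
    return 1.0 - indifference_threshold(params, b)


def empiric_unneeded_prescriptions(params: EconomicParameters, b):
    """Expected unneeded prescriptions conditional on ``s*(b) <= a``.

    When the realized threshold ``a`` lies above the cutoff, patients in
    ``[a_bar - b/2, a)`` with symptoms above ``s*(b)`` get antibiotics they
    do not need; the conditional expected mass is
    ``b (B + l - p) / (2 (B + l))``.
    """
    b = as_uncertainty_level(params, b)
    Bl = params.B + params.l
    return 0.5 * np.asarray(b) * (Bl - params.p) / Bl


def empiric_welfare(params: EconomicParameters, b):
    """Expected net benefit per panel under empiric prescribing.

    ``W_e(b) = B - p(1 - a_bar) - p b (B + l - p) / (2 (B + l))``;
    linearly decreasing in uncertainty.
    """
    b = as_uncertainty_level(params, b)
    p, Bl = params.p, params.B + params.l
    return params.B - p * (1.0 - params.a_bar) - 0.5 * p * np.asarray(b) * (
        Bl - p
    ) / Bl


# ---------------------------------------------------------------------------
# POCT-guided prescribing


def testing_interval(params: EconomicParameters, b, t: float):
    """Symptom band ``[lower, upper]`` of patients the physician tests.

    Testing a patient is worthwhile only where its expected gain beats the
    empiric default on both sides of the cutoff, which yields
    ``lower = a_bar - b/2 + t b/(B+l-p)`` and ``upper = a_bar + b/2 - t b/p``.
    At ``t = 0`` the band is the whole uncertainty interval; at the
    feasibility bound it collapses to the point ``s*(b)``.
    """
    b = as_uncertainty_level(params, b)
    t = ensure_feasible_fee(params, t)
    p, Bl = params.p, params.B + params.l
    b = np.asarray(b)
    lower = params.a_bar - 0.5 * b + t * b / (Bl - p)
    upper = params.a_bar + 0.5 * b - t * b / p
    return lower, upper


def tests_count(params: EconomicParameters, b, t: float):
    """Fraction of the panel tested: width of the testing band.

    ``T(t, b) = b [(p - t)(B + l) - p^2] / (p (B + l - p))``.
    """
    b = as_uncertainty_level(params, b)
    t = ensure_feasible_fee(params, t)
    p, Bl = params.p, params.B + params.l
    return np.asarray(b) * ((p - t) * Bl - p * p) / (p * (Bl - p))


def scenario_probabilities(params: EconomicParameters, t: float):
    """Probabilities of the three POCT treatment scenarios.

    Depending on where the realized threshold ``a`` falls relative to the
    testing band: ``q1 = t/(B+l-p)`` (all tested patients need antibiotics),
    ``q2 = t/p`` (none do), ``q3 = 1 - q1 - q2`` (only some do).
    """
    t = ensure_feasible_fee(params, t)
    p, Bl = params.p, params.B + params.l
    q1 = t / (Bl - p)
    q2 = t / p
    return q1, q2, 1.0 - q1 - q2


def gross_benefit_components(params: EconomicParameters, b, t: float):
    """Scenario-conditional gross expected benefits ``(EB1, EB2, EB3)``.

    Gross means before subtracting testing fees and the device price.
    EB1: the realized threshold lies below the band, so every tested
    patient needs antibiotics; some untested low-symptom patients go
    untreated sick.  EB2: the threshold lies above the band, so no tested
    patient needs treatment; some untested high-symptom patients get
    unneeded antibiotics.  EB3: the threshold falls inside the band and
    every tested patient is treated correctly.
    """
    b = as_uncertainty_level(params, b)
    t = ensure_feasible_fee(params, t)
    p, Bl = params.p, params.B + params.l
    b = np.asarray(b)
    base = params.B - p * (1.0 - params.a_bar)
    eb1 = base - 0.5 * t * b * Bl / (Bl - p) - p * b * (0.5 - t / (Bl - p))
    eb2 = base + p * b * (0.5 - t / p)
    eb3 = base - t * b * (Bl - 2 * p) / (2 * (Bl - p))
    return eb1, eb2, eb3


def poct_gross_benefit(params: EconomicParameters, b, t: float):
    """Gross expected benefit under POCT, ``EB(b) = sum_i q_i EB_i``.

    Simplifies to ``B - p(1 - a_bar) - b t^2 (B + l) / (2 p (B + l - p))``.
    """
    b = as_uncertainty_level(params, b)
    t = ensure_feasible_fee(params, t)
    p, Bl = params.p, params.B + params.l
    return (
        params.B
        - p * (1.0 - params.a_bar)
        - np.asarray(b) * t * t * Bl / (2 * p * (Bl - p))
    )


def poct_welfare(params: EconomicParameters, b, tariff: Tariff):
    """Net expected benefit under POCT: gross minus fees minus device price.

    ``W_POCT(b) = B - p(1-a_bar) - t b [1 - t(B+l)/(2p(B+l-p))] - C``.
    Decreasing in ``b`` whenever ``t > 0``; at ``t = 0`` it is flat in
    ``b`` — perfect free information makes uncertainty irrelevant.
    """
    b = as_uncertainty_level(params, b)
    t = ensure_feasible_fee(params, tariff.t)
    p, Bl = params.p, params.B + params.l
    return (
        params.B
        - p * (1.0 - params.a_bar)
        - t * np.asarray(b) * (1.0 - t * Bl / (2 * p * (Bl - p)))
        - tariff.C
    )


def poct_prescriptions(params: EconomicParameters, b, t: float):
    """Expected antibiotic prescriptions per panel under POCT.

    ``Q_APOCT(b) = 1 - a_bar + t^2 b (B+l)(B+l-2p) / (2 p^2 (B+l-p)^2)``.
    Strictly below the empiric quantity for ``b > 0`` whenever
    ``(p - t)(B + l) > p^2``, with equality at the feasibility bound.
    """
    b = as_uncertainty_level(params, b)
    t = ensure_feasible_fee(params, t)
    p, Bl = params.p, params.B + params.l
    return (
        1.0
        - params.a_bar
        + t * t * np.asarray(b) * Bl * (Bl - 2 * p) / (2 * p * p * (Bl - p) ** 2)
    )


# ---------------------------------------------------------------------------
# Adoption


def adoption_price_cap(params: EconomicParameters, b, t: float):
    """Largest device price at which the ``b``-physician adopts POCT.

    Solving ``W_e(b) = W_POCT(b)`` for ``C`` gives
    ``C_cap = b [p(B+l-p) - t(B+l)]^2 / (2 p (B+l) (B+l-p))`` — linear in
    ``b``, zero at ``b = 0`` and at the fee feasibility bound.
    """
    b = as_uncertainty_level(params, b)
    t = ensure_feasible_fee(params, t)
    p, Bl = params.p, params.B + params.l
    return (
        np.asarray(b)
        * (p * (Bl - p) - t * Bl) ** 2
        / (2 * p * Bl * (Bl - p))
    )


def adopts_poct(params: EconomicParameters, b, tariff: Tariff):
    """Whether the ``b``-physician buys the device under ``tariff``.

    Adoption iff ``C <= C_cap(b, t)``; ties adopt.  Monotone: if a
    ``b``-physician adopts, so does every more-uncertain one.
    """
    cap = adoption_price_cap(params, b, tariff.t)
    result = tariff.C <= cap
    return bool(result) if np.ndim(result) == 0 else result
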