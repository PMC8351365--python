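"""Model primitives: economic parameters, physician types and the firm's tariff.

The model describes ``N`` primary-care physicians treating a unit-mass panel
of patients with an infectious disease.  Patients are indexed by a symptom
score ``s`` uniform on [0, 1]; antibiotics are truly needed only above an
unknown threshold ``A`` with mean ``a_bar``.  A physician of uncertainty
level ``b`` believes ``A ~ U(a_bar - b/2, a_bar + b/2)``.  Prescribing an
antibiotic costs the effective price ``p = p_a + r`` (drug price plus the
internalized antimicrobial-resistance externality) and yields the health
value ``B``; an untreated sick patient costs ``l``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ParameterError",
    "InfeasibleTariffError",
    "EconomicParameters",
    "PhysicianType",
    "Tariff",
]


class ParameterError(ValueError):
    """A model primitive violates one of the maintained assumptions."""


class InfeasibleTariffError(ValueError):
    """The per-test fee is so high that no patient would ever be tested."""


@dataclass(frozen=True)
class EconomicParameters:
    """Primitives of the prescribing economy.

    Parameters
    ----------
    B : float
        Economic value of the health gain (willingness to pay for cure),
        in abstract currency units.
    l : float
        Disutility of remaining sick untreated, ``l >= 0``.
    p_a : float
        Antibiotic price, ``p_a > 0``.
    r : float
        Per-prescription resistance externality cost, ``r >= 0``.
    a_bar : float
        Expected symptom threshold above which antibiotics are needed,
        in (0, 1).

    Maintained assumptions (violations raise :class:`ParameterError`):
    ``B > p``, ``B - p >= l`` and ``B + l > 2p`` where ``p = p_a + r``.
    The last (strict) inequality makes the empiric prescription threshold
    strictly decreasing in uncertainty; the boundary case is rejected
    rather than special-cased.
    """

    B: float
    l: float
    p_a: float
    r: float
    a_bar: float

    def __post_init__(self) -> None:
        if not self.p_a > 0:
            raise ParameterError("requires p_a > 0")
        if not self.r >= 0:
            raise ParameterError("requires r >= 0")
        if not self.l >= 0:
            raise ParameterError("requires l >= 0")
        if not 0 < self.a_bar < 1:
            raise ParameterError("requires 0 < a_bar < 1")
        p = self.p_a + self.r
        if not self.B > p:
            raise ParameterError("requires B > p")
        if not self.B - p >= self.l:
            raise ParameterError("requires B - p >= l")
        if not self.B + self.l > 2 * p:
            raise ParameterError("requires B + l > 2p")

    @property
    def p(self) -> float:
        """Effective treatment cost ``p = p_a + r``."""
        return self.p_a + self.r

    @property
    def b_max(self) -> float:
        """Upper bound of physician uncertainty, ``2 min(a_bar, 1 - a_bar)``."""
        return 2.0 * min(self.a_bar, 1.0 - self.a_bar)

    @property
    def max_test_fee(self) -> float:
        """Largest per-test fee at which testing can occur.

        Testing requires ``p^2 <= (B + l)(p - t)``, i.e.
        ``t <= p(B + l - p)/(B + l)``.  At the bound the testing interval
        is degenerate (zero tests) but still well defined.
        """
        p, Bl = self.p, self.B + self.l
        return p * (Bl - p) / Bl


@dataclass(frozen=True)
class PhysicianType:
    """A physician identified by their uncertainty level ``b``.

    ``b`` is the width of the symptom band over which the physician does
    not know the right treatment, ``0 <= b <= b_max`` of the associated
    :class:`EconomicParameters`.
    """

    b: float

    def __post_init__(self) -> None:
        if not self.b >= 0:
            raise ParameterError("requires b >= 0")


@dataclass(frozen=True)
class Tariff:
    """The diagnostic firm's two-part tariff.

    ``C >= 0`` is the one-off device price; ``t >= 0`` the per-test fee.
    The testing-feasibility bound on ``t`` depends on the economy and is
    enforced where the tariff is used (see
    :func:`poctecon.model.ensure_feasible_fee`).
    """

    C: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not self.C >= 0:
            raise ParameterError("requires C >= 0")
        if not self.t >= 0:
            raise ParameterError("requires t >= 0")


def as_uncertainty_level(params: EconomicParameters, b) -> float:
    """Coerce ``b`` (float or :class:`PhysicianType`) and check the support."""
    import numpy as np

    if isinstance(b, PhysicianType):
        b = b.b
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0) or np.any(b_arr > params.b_max * (1 + 1e-12) + 1e-15):
        raise ParameterError(
            f"requires 0 <= b <= b_max = {params.b_max:.6g}"
        )
    return b if np.ndim(b) else float(b_arr)
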