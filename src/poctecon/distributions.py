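"""Distributions of physician uncertainty across the market.

From the diagnostic firm's viewpoint the uncertainty level ``b`` is
distributed across physicians with density ``g`` and CDF ``G`` on
``[0, b_max]`` where ``b_max = 2 min(a_bar, 1 - a_bar)``.  The firm's
problem only needs two integral functionals of ``G``: the adopter mass
``1 - G(b0)`` and the partial mean ``∫_{b0}^{b_max} x g(x) dx``.

Built-in families (uniform, triangular, scaled beta) use closed forms;
arbitrary densities are supported through :func:`from_density`, which
builds the CDF by quadrature cached on a fixed grid with monotone
interpolation.  Distributions with atoms are not supported.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy import integrate, interpolate, special, stats

from .params import ParameterError

__all__ = [
    "UncertaintyDistribution",
    "uniform_uncertainty",
    "triangular_uncertainty",
    "scaled_beta_uncertainty",
    "from_density",
    "adopter_mass",
    "mean_above",
]

_NORM_TOL = 1e-6
_SUPPORT_TOL = 1e-9


class UncertaintyDistribution:
    """Density/CDF pair for physician uncertainty on ``[0, b_max]``.

    Parameters
    ----------
    b_max : float
        Upper support bound, > 0.
    pdf, cdf : callable
        Vectorized density ``g`` and CDF ``G`` on the support.
    partial_mean : callable, optional
        Closed-form ``b0 -> ∫_{b0}^{b_max} x g(x) dx``; computed by
        adaptive quadrature when absent.
    name : str
        Family label used in reports.
    """

    def __init__(
        self,
        b_max: float,
        pdf: Callable,
        cdf: Callable,
        partial_mean: Optional[Callable] = None,
        name: str = "custom",
    ):
        if not b_max > 0:
            raise ParameterError("requires b_max > 0")
        self.b_max = float(b_max)
        self._pdf = pdf
        self._cdf = cdf
        self._partial_mean = partial_mean
        self.name = name
        self._validate()

    def _validate(self) -> None:
        grid = np.linspace(0.0, self.b_max, 1001)
        G = np.asarray(self._cdf(grid), dtype=float)
        if abs(G[0]) > _NORM_TOL or abs(G[-1] - 1.0) > _NORM_TOL:
            raise ParameterError(
                "requires G(0) = 0 and G(b_max) = 1 (density must integrate "
                "to 1 on [0, b_max])"
            )
        if np.any(np.diff(G) < -1e-12):
            raise ParameterError("requires G nondecreasing")
        if np.any(np.asarray(self._pdf(grid), dtype=float) < -1e-12):
            raise ParameterError("requires g >= 0 on the support")

    # -- basic functionals ---------------------------------------------------

    def _check_support(self, b):
        b = np.asarray(b, dtype=float)
        if np.any(b < -_SUPPORT_TOL) or np.any(b > self.b_max + _SUPPORT_TOL):
            raise ParameterError(
                f"requires 0 <= b <= b_max = {self.b_max:.6g}"
            )
        return np.clip(b, 0.0, self.b_max)

    def g(self, b):
        """Density ``g(b)``."""
        return self._pdf(self._check_support(b))

    def G(self, b):
        """CDF ``G(b)``."""
        return self._cdf(self._check_support(b))

    def adopter_mass(self, b0):
        """Fraction of physicians with uncertainty above ``b0``: ``1 - G(b0)``."""
        return 1.0 - self.G(b0)

    def mean_above(self, b0):
        """Partial mean ``∫_{b0}^{b_max} x g(x) dx``."""
        b0 = self._check_support(b0)
        if self._partial_mean is not None:
            return self._partial_mean(b0)
        if np.ndim(b0) == 0:
            val, _ = integrate.quad(
                lambda x: x * float(self._pdf(x)),
                float(b0),
                self.b_max,
                epsabs=1e-9,
                limit=200,
            )
            return val
        return np.array([float(self.mean_above(float(x))) for x in np.ravel(b0)]).reshape(
            np.shape(b0)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"UncertaintyDistribution(name={self.name!r}, b_max={self.b_max!r})"


# ---------------------------------------------------------------------------
# Built-in families


def uniform_uncertainty(b_max: float) -> UncertaintyDistribution:
    """Uniform uncertainty: ``g = 1/b_max``, ``G(b) = b/b_max``."""
    if not b_max > 0:
        raise ParameterError("requires b_max > 0")
    bm = float(b_max)
    return UncertaintyDistribution(
        bm,
        pdf=lambda b: np.full_like(np.asarray(b, dtype=float), 1.0 / bm),
        cdf=lambda b: np.asarray(b, dtype=float) / bm,
        partial_mean=lambda b0: (bm * bm - np.asarray(b0, dtype=float) ** 2)
        / (2.0 * bm),
        name="uniform",
    )


def triangular_uncertainty(b_max: float) -> UncertaintyDistribution:
    """Increasing triangular density ``g(b) = 2b/b_max^2``, ``G(b) = b^2/b_max^2``."""
    if not b_max > 0:
        raise ParameterError("requires b_max > 0")
    bm = float(b_max)
    return UncertaintyDistribution(
        bm,
        pdf=lambda b: 2.0 * np.asarray(b, dtype=float) / bm**2,
        cdf=lambda b: np.asarray(b, dtype=float) ** 2 / bm**2,
        partial_mean=lambda b0: 2.0
        * (bm**3 - np.asarray(b0, dtype=float) ** 3)
        / (3.0 * bm**2),
        name="triangular",
    )


def scaled_beta_uncertainty(
    b_max: float, alpha: float, beta: float
) -> UncertaintyDistribution:
    """Beta(alpha, beta) density rescaled to ``[0, b_max]``."""
    if not b_max > 0:
        raise ParameterError("requires b_max > 0")
    if not (alpha > 0 and beta > 0):
        raise ParameterError("requires beta shape parameters > 0")
    bm = float(b_max)
    rv = stats.beta(alpha, beta, scale=bm)
    mean = rv.mean()

    def partial_mean(b0):
        # E[X; X > b0] via the regularized incomplete beta with shifted shape
        y0 = np.asarray(b0, dtype=float) / bm
        return mean * (1.0 - special.betainc(alpha + 1.0, beta, y0))

    return UncertaintyDistribution(
        bm, pdf=rv.pdf, cdf=rv.cdf, partial_mean=partial_mean,
        name=f"beta({alpha:g},{beta:g})",
    )


def from_density(
    g: Callable, b_max: float, n_nodes: int = 513
) -> UncertaintyDistribution:
    """Build a distribution from an arbitrary density on ``[0, b_max]``.

    The CDF is assembled from per-segment adaptive quadrature on a fixed
    node grid and interpolated monotonically (PCHIP) between nodes.  The
    density must be nonnegative and integrate to 1 within 1e-6; otherwise
    a :class:`~poctecon.params.ParameterError` is raised — densities on a
    different support are rejected, never rescaled.
    """
    if not b_max > 0:
        raise ParameterError("requires b_max > 0")
    bm = float(b_max)

    def g_vec(b):
        b = np.asarray(b, dtype=float)
        out = np.asarray(g(b), dtype=float)
        if out.shape != b.shape:  # non-vectorized callable
            out = np.array([float(g(x)) for x in np.ravel(b)]).reshape(b.shape)
        return out

    nodes = np.linspace(0.0, bm, n_nodes)
    if np.any(g_vec(nodes) < -1e-12):
        raise ParameterError("requires g >= 0 on the support")
    seg = np.empty(n_nodes - 1)
    for i in range(n_nodes - 1):
        seg[i], _ = integrate.quad(
            lambda x: float(g_vec(np.asarray(x))), nodes[i], nodes[i + 1],
            epsabs=1e-12, limit=100,
        )
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if abs(total - 1.0) > _NORM_TOL:
        raise ParameterError(
            f"requires density integrating to 1 on [0, b_max]: got {total:.8g}"
        )
    cum = np.clip(cum / total, 0.0, 1.0)
    cum[-1] = 1.0
    G_interp = interpolate.PchipInterpolator(nodes, cum)

    def cdf(b):
        return np.clip(G_interp(np.asarray(b, dtype=float)), 0.0, 1.0)

    return UncertaintyDistribution(bm, pdf=g_vec, cdf=cdf, name="custom")


# ---------------------------------------------------------------------------
# Module-level wrappers


def adopter_mass(dist: UncertaintyDistribution, b0):
    """Fraction of physicians with uncertainty above ``b0``."""
    return dist.adopter_mass(b0)


def mean_above(dist: UncertaintyDistribution, b0):
    """Partial mean ``∫_{b0}^{b_max} x g(x) dx``."""
    return dist.mean_above(b0)
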