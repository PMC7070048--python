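"""Closed-form destination-selection weights of the universal opportunity
(UO) model and its corner-case models.

The UO model assumes a traveller at origin ``i`` samples a random benefit
for every opportunity and compares the best benefit of the destination
against the best of the origin and of the intervening opportunities.  Two
dimensionless weights govern the comparison:

``alpha``
    exploratory tendency -- the destination must beat the origin *and*
    the intervening opportunities, which favours distant, high-benefit
    destinations;
``beta``
    cautious tendency -- the destination must beat the origin while the
    origin already beats the intervening opportunities, which favours
    near destinations.

Integrating the benefit comparison over the benefit distribution yields a
closed-form selection weight

    Q_ij = (m_i + alpha*s_ij) * m_j
           / ((m_i + (alpha+beta)*s_ij) * (m_i + (alpha+beta)*s_ij + m_j))

which is independent of the benefit distribution.  The corners of the
simplex ``alpha, beta >= 0``, ``alpha + beta <= 1`` recover the radiation
model (0, 1), the opportunity-priority-selection (OPS) model (1, 0) and
the opportunity-only (OO) model (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import fixed_quad

__all__ = [
    "ModelParams",
    "uo_weight",
    "special_case_weight",
    "benefit_integral_oracle",
    "SPECIAL_CASE_PARAMS",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """The (alpha, beta) pair on the unit simplex.

    ``alpha`` is the exploratory tendency, ``beta`` the cautious tendency;
    both are non-negative and ``alpha + beta <= 1``.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        a, b = float(self.alpha), float(self.beta)
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError("alpha and beta must be finite")
        if a < 0 or b < 0 or a + b > 1 + _SIMPLEX_TOL:
            raise ValueError(
                f"(alpha, beta) = ({a}, {b}) outside the simplex "
                "alpha >= 0, beta >= 0, alpha + beta <= 1"
            )

    def as_tuple(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


#: Simplex corners at which the UO model degenerates to a named model.
SPECIAL_CASE_PARAMS = {
    "radiation": ModelParams(0.0, 1.0),
    "ops": ModelParams(1.0, 0.0),
    "oo": ModelParams(0.0, 0.0),
}


def _validate_nonneg(**kwargs) -> dict:
    out = {}
    for name, val in kwargs.items():
        arr = np.asarray(val, dtype=float)
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite and non-negative")
        out[name] = arr
    return out


def uo_weight(m_i, m_j, s_ij, params: ModelParams):
    """Unnormalised UO selection weight Q_ij.

    Accepts scalars or broadcastable arrays.  When the denominator factor
    ``m_i + (alpha+beta)*s_ij`` vanishes the numerator factor
    ``m_i + alpha*s_ij`` vanishes too; the ratio is taken at its
    continuity limit 1, so the weight degenerates to
    ``m_j / (m_i + (alpha+beta)*s_ij + m_j)``.  A destination with
    ``m_j = 0`` always has weight 0.
    """
    v = _validate_nonneg(m_i=m_i, m_j=m_j, s_ij=s_ij)
    m_i, m_j, s = v["m_i"], v["m_j"], v["s_ij"]
    a = params.alpha
    ab = params.alpha + params.beta
    num = m_i + a * s
    base = m_i + ab * s
    outer = base + m_j
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(
            base > 0,
            num * m_j / np.where(base > 0, base * outer, 1.0),
            np.where(outer > 0, m_j / np.where(outer > 0, outer, 1.0), 0.0),
        )
    if q.ndim == 0:
        return float(q)
    return q


def special_case_weight(model: str, m_i, m_j, s_ij):
    """Selection weight of a named corner-case model, in its printed form.

    radiation : m_i*m_j / ((m_i+s)*(m_i+s+m_j))
    ops       : m_j / (m_i+s+m_j)
    oo        : m_j / (m_i+m_j)

    These coincide exactly with :func:`uo_weight` at (0, 1), (1, 0) and
    (0, 0) respectively: the numerator factor of the corner weight cancels
    one denominator factor.  Vanishing denominators take the same
    continuity limits as :func:`uo_weight`.
    """
    v = _validate_nonneg(m_i=m_i, m_j=m_j, s_ij=s_ij)
    m_i, m_j, s = v["m_i"], v["m_j"], v["s_ij"]
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "radiation":
            base = m_i + s
            outer = base + m_j
            q = np.where(
                base > 0,
                m_i * m_j / np.where(base > 0, base * outer, 1.0),
                np.where(outer > 0, m_j / np.where(outer > 0, outer, 1.0), 0.0),
            )
        elif model == "ops":
            den = m_i + s + m_j
            q = np.where(den > 0, m_j / np.where(den > 0, den, 1.0), 0.0)
        elif model == "oo":
            den = m_i + m_j
            q = np.where(den > 0, m_j / np.where(den > 0, den, 1.0), 0.0)
        else:
            raise ValueError(
                f"unknown model {model!r}; use 'radiation', 'ops' or 'oo'"
            )
    if q.ndim == 0:
        return float(q)
    return q


def benefit_integral_oracle(
    m_i: float,
    m_j: float,
    s_ij: float,
    params: ModelParams,
    dist,
    n_points: int = 400,
) -> float:
    """Selection weight by direct quadrature of the benefit integral.

    Integrates, over the benefit axis ``z``,

        (m_i + alpha*s) * F(z)**(m_i + (alpha+beta)*s - 1) * f(z)
            * (1 - F(z)**m_j)

    where ``F`` and ``f`` are the CDF and PDF of the benefit distribution
    ``dist`` (any ``scipy.stats`` frozen continuous distribution, or an
    object with ``cdf``, ``pdf`` and ``ppf`` methods).  The closed form
    :func:`uo_weight` is the exact value of this integral for *every*
    continuous benefit distribution; this routine exists as an independent
    numerical check of that distribution-freeness.

    Uses composite Gauss-Legendre quadrature on panels whose breakpoints
    are quantiles of ``dist``, which concentrates nodes where the benefit
    mass lies.  ``n_points`` is the total node budget (>= 100).
    """
    for attr in ("cdf", "pdf", "ppf"):
        if not hasattr(dist, attr):
            raise ValueError(f"benefit distribution must provide .{attr}()")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    m_i, m_j, s_ij = float(m_i), float(m_j), float(s_ij)
    if min(m_i, m_j, s_ij) < 0:
        raise ValueError("m_i, m_j and s_ij must be non-negative")
    a = params.alpha
    ab = params.alpha + params.beta
    lead = m_i + a * s_ij
    expo = m_i + ab * s_ij
    if expo <= 0:
        raise ValueError(
            "quadrature oracle requires m_i + (alpha+beta)*s_ij > 0; "
            "the closed form handles the degenerate limit"
        )

    def integrand(z):
        F = np.clip(dist.cdf(z), 0.0, 1.0)
        return lead * F ** (expo - 1.0) * dist.pdf(z) * (1.0 - F**m_j)

    # quantile-spaced panels resolve the peak that large exponents push
    # toward the upper tail of the benefit distribution
    levels = np.array(
        [1e-12, 0.05, 0.2, 0.4, 0.6, 0.8, 0.9, 0.97, 0.995, 0.9995, 1 - 1e-12]
    )
    breaks = np.asarray(dist.ppf(levels), dtype=float)
    breaks = np.unique(breaks[np.isfinite(breaks)])
    n_panel = max(20, int(n_points) // (len(breaks) - 1))
    total = 0.0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        total += fixed_quad(integrand, lo, hi, n=n_panel)[0]
    return float(total)
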