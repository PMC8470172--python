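"""Normalized Legendre polynomial basis over standardized age.

Random-regression models for longitudinal traits parameterize every curve
(population mean, additive-genetic, permanent-environment, and the
time-varying SNP effect) on a common orthonormal Legendre basis evaluated at
age standardized onto [-1, 1].  The "order" of a basis is the highest
polynomial degree; a basis of order ``m`` contributes ``m + 1`` regression
coefficients.

The normalization follows the convention standard in animal breeding
(Kirkpatrick et al. covariance-function scaling)::

    phi_l(x) = sqrt((2l + 1) / 2) * P_l(x)

with ``P_l`` the classical Legendre polynomial, so that
``int_{-1}^{1} phi_i phi_j dx = delta_ij``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["LegendreBasis", "phi", "standardize_time", "design_row", "design_matrix"]


@dataclass(frozen=True)
class LegendreBasis:
    """An orthonormal Legendre basis on ages mapped to [-1, 1].

    Parameters
    ----------
    order
        Highest polynomial degree (``order + 1`` coefficients).
    t_min, t_max
        Age interval (months) mapped linearly onto [-1, 1].
    """

    order: int
    t_min: float = 0.0
    t_max: float = 18.0

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError(f"basis order must be >= 0, got {self.order}")
        if not self.t_max > self.t_min:
            raise ValueError(
                f"t_max ({self.t_max}) must exceed t_min ({self.t_min})"
            )

    @property
    def n_coef(self) -> int:
        return self.order + 1

    def with_order(self, order: int) -> "LegendreBasis":
        return LegendreBasis(order=order, t_min=self.t_min, t_max=self.t_max)


def standardize_time(t, basis: LegendreBasis):
    """Map age ``t`` (months) linearly onto [-1, 1].

    Raises
    ------
    ValueError
        If any age falls outside ``[t_min, t_max]`` (no extrapolation).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < basis.t_min) or np.any(t > basis.t_max):
        bad = t[(t < basis.t_min) | (t > basis.t_max)]
        raise ValueError(
            f"age(s) {np.unique(bad)} outside basis range "
            f"[{basis.t_min}, {basis.t_max}]"
        )
    return -1.0 + 2.0 * (t - basis.t_min) / (basis.t_max - basis.t_min)


def phi(l: int, t_star):
    """Normalized Legendre polynomial ``phi_l`` at standardized time."""
    if l < 0:
        raise ValueError("degree must be >= 0")
    coef = np.zeros(l + 1)
    coef[l] = 1.0
    return np.sqrt((2 * l + 1) / 2.0) * npleg.legval(np.asarray(t_star, float), coef)


def design_row(t, basis: LegendreBasis) -> np.ndarray:
    """Basis covariate vector ``[phi_0(t*), ..., phi_order(t*)]`` for one age."""
    return design_matrix(np.atleast_1d(t), basis)[0 if np.ndim(t) == 0 else slice(None)]


def design_matrix(t, basis: LegendreBasis) -> np.ndarray:
    """Rows of basis covariates for a vector of ages (records x coefficients)."""
    t_star = standardize_time(np.asarray(t, dtype=float), basis)
    cols = [phi(l, t_star) for l in range(basis.n_coef)]
    return np.column_stack(cols)
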