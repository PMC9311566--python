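"""Normalized Legendre basis on standardized age.

Longitudinal animal models express each animal's effect as coefficients on
an orthogonal polynomial basis of age.  Ages on ``[age_min, age_max]`` are
mapped to ``[-1, 1]`` and evaluated with normalized Legendre polynomials

    phi_j(x) = sqrt((2j + 1) / 2) * P_j(x),

which are orthonormal on [-1, 1] with respect to Lebesgue measure.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre as _leg


def standardize_age(age, age_min: float, age_max: float) -> np.ndarray:
    """Map ages on [age_min, age_max] linearly onto [-1, 1]."""
    age = np.asarray(age, dtype=float)
    if age_max <= age_min:
        raise ValueError("age_max must exceed age_min")
    x = 2.0 * (age - age_min) / (age_max - age_min) - 1.0
    if np.any(x < -1 - 1e-9) or np.any(x > 1 + 1e-9):
        raise ValueError("age outside standardization bounds")
    return np.clip(x, -1.0, 1.0)


def legendre_basis(x, order: int) -> np.ndarray:
    """Evaluate normalized Legendre polynomials 0..order at x in [-1, 1].

    Returns an array of shape ``(len(x), order + 1)``.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    cols = []
    for j in range(order + 1):
        coef = np.zeros(j + 1)
        coef[j] = 1.0
        cols.append(np.sqrt((2 * j + 1) / 2.0) * _leg.legval(x, coef))
    return np.column_stack(cols)


def basis_at_age(age, age_min: float, age_max: float, order: int) -> np.ndarray:
    """Normalized Legendre basis evaluated at (possibly scalar) ages."""
    x = standardize_age(age, age_min, age_max)
    return legendre_basis(x, order)
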