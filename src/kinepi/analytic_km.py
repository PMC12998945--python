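"""Closed-form epistasis surface for K_M in the two-step mechanism.

With mutation i multiplying k-1 by alpha_i, k2 by beta_i and k1 by gamma_i,
the K_M epistasis factor of an additive double mutant is

    eps = (a1 a2 k-1 + b1 b2 k2) (k-1 + k2)
          -------------------------------------
          (a1 k-1 + b1 k2) (a2 k-1 + b2 k2)

It is independent of gamma, and its sign obeys the exact identity

    (eps - 1) (a1 k-1 + b1 k2)(a2 k-1 + b2 k2) = k-1 k2 (a1 - b1)(a2 - b2)

so epistasis vanishes iff at least one mutation scales k-1 and k2 equally.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .mechanism_core import ValidationError

__all__ = [
    "FoldEffects",
    "km_epsilon",
    "epsilon_sign",
    "grid_scan",
    "kminus1_sweep",
    "DEFAULT_RATIO_GRID",
]

DEFAULT_RATIO_GRID = np.logspace(-2.0, 2.0, 41)


from dataclasses import dataclass


@dataclass(frozen=True)
class FoldEffects:
    """One mutation's fold-changes: alpha on k-1, beta on k2, gamma on k1."""

    alpha: float
    beta: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValidationError(f"{name} must be positive, got {value}")


def _check_positive_arrays(**values) -> None:
    for name, value in values.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr) & (arr > 0)):
            raise ValidationError(f"{name} must be positive and finite")


def km_epsilon(alpha1, beta1, alpha2, beta2, k_minus1, k2):
    """K_M epistasis factor of an additive double mutant (closed form).

    Accepts scalars or broadcastable arrays; gamma (the k1 fold) cancels and
    does not appear.
    """
    _check_positive_arrays(
        alpha1=alpha1, beta1=beta1, alpha2=alpha2, beta2=beta2,
        k_minus1=k_minus1, k2=k2,
    )
    a1, b1, a2, b2, km1, k2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (alpha1, beta1, alpha2, beta2, k_minus1, k2))
    )
    eps = ((a1 * a2 * km1 + b1 * b2 * k2) * (km1 + k2)) / (
        (a1 * km1 + b1 * k2) * (a2 * km1 + b2 * k2)
    )
    return eps if eps.ndim else float(eps)


def epsilon_sign(alpha1, beta1, alpha2, beta2):
    """Sign of (epsilon - 1): sign((alpha1 - beta1)(alpha2 - beta2)).

    Holds for every positive pair of base rates, so the direction of K_M
    epistasis is fixed by the fold-effects alone.
    """
    _check_positive_arrays(alpha1=alpha1, beta1=beta1, alpha2=alpha2, beta2=beta2)
    a1, b1, a2, b2 = (np.asarray(x, dtype=float) for x in (alpha1, beta1, alpha2, beta2))
    sign = np.sign((a1 - b1) * (a2 - b2))
    return sign if sign.ndim else int(sign)


def grid_scan(
    ratio_grid: Sequence[float] | None = None,
    k_minus1: float = 62.1,
    k2: float = 11.5,
    betas: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Evaluate the epistasis surface over a Cartesian ratio grid.

    Each axis is the per-mutation ratio alpha_i/beta_i; by default beta_i is
    fixed at 1 so the axis value is alpha_i itself.  Returns a long-form
    frame with columns ratio1, ratio2, alpha1, beta1, alpha2, beta2,
    k_minus1, k2, epsilon.
    """
    ratios = DEFAULT_RATIO_GRID if ratio_grid is None else np.asarray(ratio_grid, float)
    if ratios.size == 0:
        raise ValidationError("ratio grid is empty")
    _check_positive_arrays(ratio_grid=ratios, k_minus1=k_minus1, k2=k2, betas=betas)
    beta1, beta2 = betas
    r1, r2 = np.meshgrid(ratios, ratios, indexing="ij")
    alpha1 = r1 * beta1
    alpha2 = r2 * beta2
    eps = km_epsilon(alpha1, beta1, alpha2, beta2, k_minus1, k2)
    return pd.DataFrame(
        {
            "ratio1": r1.ravel(),
            "ratio2": r2.ravel(),
            "alpha1": alpha1.ravel(),
            "beta1": beta1,
            "alpha2": alpha2.ravel(),
            "beta2": beta2,
            "k_minus1": k_minus1,
            "k2": k2,
            "epsilon": np.asarray(eps).ravel(),
        }
    )


def kminus1_sweep(
    multipliers: Sequence[float],
    base_k2: float = 11.5,
    ratio_grid: Sequence[float] | None = None,
) -> list[dict]:
    """Scan the surface at k-1 = multiplier * k2 for each multiplier.

    Returns one entry per multiplier with the full grid plus its maximum
    epsilon, for probing how surface extremes move as k-1/k2 departs from 1.
    """
    _check_positive_arrays(multipliers=multipliers, base_k2=base_k2)
    results = []
    for multiplier in multipliers:
        grid = grid_scan(ratio_grid, k_minus1=float(multiplier) * base_k2, k2=base_k2)
        results.append(
            {
                "multiplier": float(multiplier),
                "k_minus1": float(multiplier) * base_k2,
                "k2": float(base_k2),
                "grid": grid,
                "max_epsilon": float(grid["epsilon"].max()),
            }
        )
    return results
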