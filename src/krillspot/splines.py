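"""Fixed-rank thin-plate regression spline basis (one covariate).

A rank-k unpenalised TPRS: cubic radial basis functions |x - t_j|^3 at k
quantile knots, with the polynomial null-space constraints (sum delta_j = 0,
sum delta_j t_j = 0) absorbed so the smooth contributes ``k - 1`` design
columns — one linear column plus ``k - 2`` constrained radial columns.
Columns are centred over the training data (the global intercept carries
the smooth's mean), and the stored knots / constraint basis / centring
reproduce the basis exactly at new x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TprsBasis:
    """Frozen basis metadata; ``evaluate`` rebuilds columns at any x."""

    knots: np.ndarray        # (k,)
    Z: np.ndarray            # (k, k-2) null-space constraint basis
    x_center: float
    x_scale: float
    col_means: np.ndarray    # (k-1,) training-column means

    @property
    def n_cols(self) -> int:
        return self.knots.size - 1

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        B = _raw_columns(x, self.knots, self.Z, self.x_center, self.x_scale)
        return B - self.col_means


def _raw_columns(x, knots, Z, x_center, x_scale):
    lin = ((x - x_center) / x_scale)[:, None]
    E = np.abs(x[:, None] - knots[None, :]) ** 3
    return np.hstack([lin, E @ Z])


def tprs_basis(x, k: int) -> tuple[np.ndarray, TprsBasis]:
    """Build the rank-k TPRS design block at training x.

    Returns the (n, k-1) centred basis matrix and the reusable metadata.
    Raises if fewer than k distinct x values are available.
    """
    x = np.asarray(x, float)
    if k < 3:
        raise ValueError("spline basis dimension k must be >= 3")
    uniq = np.unique(x)
    if uniq.size < k:
        raise ValueError(f"need >= {k} distinct values, got {uniq.size}")
    knots = np.quantile(uniq, np.linspace(0.0, 1.0, k))
    # quantiles of nearly-duplicate values can coincide; fall back to spread knots
    if np.unique(knots).size < k:
        knots = np.linspace(uniq.min(), uniq.max(), k)
    T = np.column_stack([np.ones(k), knots])
    # orthonormal basis of the null space of T^T (absorbs both constraints)
    q, _ = np.linalg.qr(T, mode="complete")
    Z = q[:, 2:]
    x_center = float(x.mean())
    x_scale = float(x.std()) or 1.0
    B = _raw_columns(x, knots, Z, x_center, x_scale)
    col_means = B.mean(axis=0)
    meta = TprsBasis(knots, Z, x_center, x_scale, col_means)
    return B - col_means, meta
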