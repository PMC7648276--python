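"""Quantitative diagnostics for RD signals and contact maps.

* **Centralization score (CS)** — size-weighted fraction of bins whose
  copy number lies within a tolerance (default 0.25 copies) of its nearest
  integer state; high CS means the RD signal concentrates at discrete CN
  levels, which is what makes CNVs callable.
* **Zero score (ZS)** — fraction of bins with copy number exactly zero, a
  sparseness measure; lower is better.
* **1D signal** — column sums of a contact matrix; its per-chromosome
  standard deviation measures residual (e.g. CNV-driven) bias, and its
  rank correlation before vs after correction detects signal inversion.
* **Bias correlation** — Spearman correlation between contact frequencies
  f_kl and the pairwise product feature_k * feature_l, matching the
  product form of the GLM predictors.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .normalization import ContactMatrix, NormalizedMatrix

__all__ = [
    "centralization_score",
    "zero_score",
    "one_d_signal",
    "signal_dispersion",
    "bias_correlation",
]


def centralization_score(cn, weights=None, tol: float = 0.25) -> float:
    """Weighted fraction of bins within ``tol`` of their integer CN state.

    CS = sum_i W_i [|S_i - CN_i| <= tol] / sum_i W_i, with S_i the nearest
    nonnegative integer to CN_i and W_i the bin size (equal by default).
    """
    cn = np.asarray(cn, dtype=float)
    cn = cn[np.isfinite(cn)]
    if len(cn) == 0:
        raise ValueError("empty copy-number input")
    if weights is None:
        weights = np.ones_like(cn)
    else:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(cn) or np.any(weights <= 0):
            raise ValueError("weights must be positive and aligned with cn")
    states = np.maximum(np.round(cn), 0.0)
    near = np.abs(cn - states) <= tol
    return float(weights[near].sum() / weights.sum())


def zero_score(cn) -> float:
    """Fraction of bins with copy number exactly zero (unweighted)."""
    cn = np.asarray(cn, dtype=float)
    cn = cn[np.isfinite(cn)]
    if len(cn) == 0:
        raise ValueError("empty copy-number input")
    return float(np.mean(cn == 0.0))


def _cells(matrix) -> np.ndarray:
    if isinstance(matrix, NormalizedMatrix):
        return matrix.normalized
    if isinstance(matrix, ContactMatrix):
        return matrix.counts
    return np.asarray(matrix, dtype=float)


def one_d_signal(matrix) -> np.ndarray:
    """Column sums of a contact matrix, skipping missing cells."""
    cells = _cells(matrix)
    return np.nansum(cells, axis=0)


def signal_dispersion(one_d) -> float:
    """Sample (n-1) standard deviation of a chromosome's 1D signal."""
    x = np.asarray(one_d, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 bins")
    return float(np.std(x, ddof=1))


def bias_correlation(matrix, feature) -> float:
    """Spearman correlation of cell values with pairwise feature products.

    For a cis matrix only the included upper-triangle cells enter; the
    bias value of cell (k, l) is feature_k * feature_l (the product form
    used by the GLM predictors).  A constant feature makes the correlation
    undefined: returns NaN with a warning.
    """
    cells = _cells(matrix)
    feature = np.asarray(feature, dtype=float)
    n_row, n_col = cells.shape
    if len(feature) != n_row or n_col != n_row:
        raise ValueError("feature not aligned to a square (cis) matrix")
    iu = np.triu_indices(n_row)
    f = cells[iu]
    prod = feature[iu[0]] * feature[iu[1]]
    ok = np.isfinite(f) & np.isfinite(prod)
    f, prod = f[ok], prod[ok]
    if len(f) == 0 or np.ptp(prod) == 0:
        warnings.warn("constant feature: bias correlation undefined", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(f, prod)
    return float(rho)
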