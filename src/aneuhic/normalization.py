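"""Contact-matrix construction and explicit Poisson GLM normalization.

Raw interaction counts f_kl between genomic bins k and l are modelled as
Poisson with a log-linear rate in the pairwise products of four per-bin
covariates — GC content x, mappability y, effective fragment length z and
copy number w:

    log(lambda_kl) = a0 + a1*log(x_k x_l) + a2*log(y_k y_l)
                        + a3*log(z_k z_l) + a4*log(w_k w_l)

The fitted rate lambda-hat divides the raw counts to give the normalized
map f-hat = f / lambda-hat.  Cis and trans matrices are fit separately; by
default a single genome-wide coefficient vector is pooled over all cis
matrices (and one over all trans) for better-conditioned estimation, with
per-chromosome scope available.  Genomic distance is deliberately not a
covariate, so f-hat is a bias-corrected map, not an observed/expected map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "ContactMatrix",
    "BiasModelFit",
    "NormalizedMatrix",
    "PoissonBiasModel",
    "build_contact_matrices",
    "pairwise_design",
    "fit_poisson_glm",
    "predict_rates",
    "normalize_contact_matrix",
]

FEATURE_NAMES = ("gc", "mappability", "effective_length", "cnv")


@dataclass
class ContactMatrix:
    """Raw ligation counts between bins of one chromosome (cis) or two (trans)."""

    row_chrom: str
    col_chrom: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.kind == "cis":
            if self.counts.shape[0] != self.counts.shape[1]:
                raise ValueError("cis matrix must be square")
            if not np.allclose(self.counts, self.counts.T):
                raise ValueError("cis matrix must be symmetric")

    @property
    def kind(self) -> str:
        return "cis" if self.row_chrom == self.col_chrom else "trans"


@dataclass
class BiasModelFit:
    """Fitted GLM coefficients (a0..a4) for one matrix class."""

    coefficients: np.ndarray  # intercept + one slope per feature
    kind: str  # cis | trans
    scope: str = "genome_wide"
    n_pairs: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != 1 + len(FEATURE_NAMES):
            raise ValueError("expected intercept + 4 coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite GLM coefficients")


@dataclass
class NormalizedMatrix:
    """Estimated rates and normalized frequencies f-hat = f / lambda-hat."""

    matrix: ContactMatrix
    rates: np.ndarray  # lambda-hat; NaN where excluded
    normalized: np.ndarray = field(init=False)  # f-hat; NaN where excluded

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != self.matrix.counts.shape:
            raise ValueError("rates not aligned with counts")
        included = np.isfinite(self.rates)
        if np.any(self.rates[included] <= 0):
            raise ValueError("nonpositive rate on an included bin pair")
        out = np.full_like(self.rates, np.nan)
        out[included] = self.matrix.counts[included] / self.rates[included]
        self.normalized = out


def build_contact_matrices(
    valid_pairs: pd.DataFrame,
    chromosome_lengths: dict[str, int],
    bin_size: int = 500_000,
) -> dict[tuple[str, str], ContactMatrix]:
    """Bin valid pairs into cis and trans contact matrices.

    Returns a dict keyed by (row_chrom, col_chrom) with row < col
    lexicographically for trans; cis matrices are symmetrized and include
    the diagonal.
    """
    chroms = sorted(chromosome_lengths)
    nb = {c: -(-chromosome_lengths[c] // bin_size) for c in chroms}
    mats = {}
    for i, ci in enumerate(chroms):
        mats[(ci, ci)] = np.zeros((nb[ci], nb[ci]))
        for cj in chroms[i + 1 :]:
            mats[(ci, cj)] = np.zeros((nb[ci], nb[cj]))
    for c1, p1, c2, p2 in zip(
        valid_pairs["chrom1"], valid_pairs["pos1"], valid_pairs["chrom2"], valid_pairs["pos2"]
    ):
        b1, b2 = int(p1) // bin_size, int(p2) // bin_size
        if c1 == c2:
            mats[(c1, c1)][b1, b2] += 1
            if b1 != b2:
                mats[(c1, c1)][b2, b1] += 1
        else:
            (ca, ba), (cb, bb) = sorted([(c1, b1), (c2, b2)])
            mats[(ca, cb)][ba, bb] += 1
    return {
        key: ContactMatrix(key[0], key[1], bin_size, m) for key, m in mats.items()
    }


def _feature_matrix(features) -> np.ndarray:
    """Stack per-bin (gc, mappability, effective_length, cnv) columns."""
    if isinstance(features, dict):
        cols = [np.asarray(features[name], dtype=float) for name in FEATURE_NAMES]
    else:
        cols = [np.asarray(c, dtype=float) for c in features]
    if len(cols) != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} feature tracks")
    return np.column_stack(cols)


def pairwise_design(features_row, features_col=None, mask_row=None, mask_col=None):
    """Per-bin-pair GLM predictors: log of the product of the bins' features.

    ``features_*`` are dicts (or 4-sequences) of per-bin gc / mappability /
    effective_length / cnv tracks for the row and column bins.  Returns
    ``(design, include)`` where ``design`` has shape (n_row, n_col, 4) and
    ``include`` flags pairs with all factors positive and both bins
    unmasked.
    """
    A = _feature_matrix(features_row)
    B = A if features_col is None else _feature_matrix(features_col)
    ok_a = np.all(A > 0, axis=1) & np.all(np.isfinite(A), axis=1)
    ok_b = np.all(B > 0, axis=1) & np.all(np.isfinite(B), axis=1)
    if mask_row is not None:
        ok_a &= ~np.asarray(mask_row, dtype=bool)
    if mask_col is not None:
        ok_b &= ~np.asarray(mask_col, dtype=bool)
    logA = np.where(A > 0, np.log(np.where(A > 0, A, 1.0)), 0.0)
    logB = np.where(B > 0, np.log(np.where(B > 0, B, 1.0)), 0.0)
    design = logA[:, None, :] + logB[None, :, :]
    include = ok_a[:, None] & ok_b[None, :]
    return design, include


class PoissonBiasModel(BaseEstimator):
    """Log-link Poisson GLM over pairwise bias products of contact bins.

    Scikit-learn-style estimator.  ``fit`` pools the upper triangles of all
    supplied cis matrices (or all trans matrices) into one maximum-
    likelihood Poisson regression; ``transform`` divides a matrix by its
    fitted rates.  Fitting uses iteratively reweighted least squares
    (statsmodels GLM) with a deviance tolerance of 1e-8 and at most 100
    iterations.

    Parameters
    ----------
    kind:
        ``"cis"`` (pool upper triangles, symmetric output) or ``"trans"``.
    scope:
        Label recording whether the fit pooled everything genome-wide or
        was restricted to one chromosome (pair); informational.

    Attributes
    ----------
    coef_ : ndarray, shape (5,) — intercept a0 followed by a1..a4.
    fit_result_ : BiasModelFit
    n_pairs_ : number of included bin pairs in the fit.
    """

    def __init__(self, kind: str = "cis", scope: str = "genome_wide"):
        self.kind = kind
        self.scope = scope

    def fit(self, matrices, designs, y=None):
        """Fit on aligned lists of ContactMatrix and (design, include) pairs."""
        if self.kind not in ("cis", "trans"):
            raise ValueError(f"kind must be cis or trans, got {self.kind!r}")
        rows_X, rows_y = [], []
        for mat, (design, include) in zip(matrices, designs, strict=True):
            if design.shape[:2] != mat.counts.shape:
                raise ValueError("design not aligned with matrix")
            sel = include.copy()
            if self.kind == "cis":
                sel &= np.triu(np.ones_like(sel, dtype=bool))  # k <= l once
            rows_X.append(design[sel])
            rows_y.append(mat.counts[sel])
        X = np.concatenate(rows_X)
        f = np.concatenate(rows_y)
        n_coef = X.shape[1] + 1
        if len(f) < 10 * n_coef:
            raise ValueError(f"only {len(f)} included bin pairs for {n_coef} coefficients")
        Xc = sm.add_constant(X, has_constant="add")
        model = sm.GLM(f, Xc, family=sm.families.Poisson())
        res = model.fit(maxiter=100, tol=1e-8, tol_criterion="deviance")
        if not res.converged:
            raise RuntimeError(
                f"Poisson GLM did not converge within {res.fit_history['iteration']} iterations"
            )
        self.coef_ = np.asarray(res.params, dtype=float)
        self.n_pairs_ = len(f)
        self.fit_result_ = BiasModelFit(self.coef_, self.kind, self.scope, len(f))
        return self

    def predict_rates(self, design, include) -> np.ndarray:
        """Elementwise lambda-hat = exp(a0 + design @ a1..a4); NaN where excluded."""
        eta = self.coef_[0] + design @ self.coef_[1:]
        rates = np.exp(eta)
        rates[~include] = np.nan
        return rates

    def transform(self, matrix: ContactMatrix, design, include) -> NormalizedMatrix:
        return NormalizedMatrix(matrix, self.predict_rates(design, include))


# --------------------------------------------------------------------------
# functional wrappers


def fit_poisson_glm(matrices, designs, kind: str = "cis", scope: str = "genome_wide") -> BiasModelFit:
    """Pooled Poisson GLM fit; see :class:`PoissonBiasModel`."""
    model = PoissonBiasModel(kind=kind, scope=scope).fit(list(matrices), list(designs))
    return model.fit_result_


def predict_rates(fit: BiasModelFit, design, include) -> np.ndarray:
    model = PoissonBiasModel(kind=fit.kind, scope=fit.scope)
    model.coef_ = fit.coefficients
    return model.predict_rates(design, include)


def normalize_contact_matrix(matrix: ContactMatrix, rates: np.ndarray) -> NormalizedMatrix:
    """f-hat = f / lambda-hat, preserving cis symmetry and exclusions."""
    return NormalizedMatrix(matrix, rates)
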