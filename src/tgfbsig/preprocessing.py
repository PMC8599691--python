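"""Gene-wise normalization transformers.

Two transformers, both operating column-wise on an ``(n_samples, n_genes)``
array (sklearn orientation: rows are samples, columns are genes):

* :class:`GenewiseQuantileNormalizer` — forces every gene's value distribution
  across samples onto a common reference distribution (the per-rank mean of
  the genes' sorted value vectors), so afterwards every gene has identical
  sorted values and hence identical mean, median and variance.  This is the
  transpose of conventional sample-wise quantile normalization: the property
  is predicated of genes, not samples.
* :class:`GeneZScorer` — per-gene standardization with sample standard
  deviation (denominator n-1); constant genes map to all-zero.

Module-level functions wrap the transformers for the genes x samples
:class:`~tgfbsig.datatypes.ExpressionMatrix` orientation used elsewhere.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import ExpressionMatrix
from .errors import ValidationError


def _map_column_to_reference(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Assign the sorted reference values by within-column rank; groups of
    tied input values receive the mean of their assigned reference values."""
    n_obs = col.shape[0]
    order = np.argsort(col, kind="mergesort")
    assigned = np.empty(n_obs, dtype=float)
    assigned[order] = reference
    uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
    if len(uniq) < n_obs:
        sums = np.bincount(inverse, weights=assigned)
        assigned = (sums / counts)[inverse]
    return assigned


class GenewiseQuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile-normalize genes so every gene shares one value distribution.

    ``fit`` learns the reference distribution from the training matrix;
    ``transform`` maps each gene's values onto the reference by within-gene
    rank.  When transform is applied to the fitted matrix itself (the usual
    ``fit_transform`` use) the result is exact quantile normalization with
    ties resolved by averaging tied reference values.

    Attributes
    ----------
    reference_ : ndarray of shape (n_samples_fit,)
        Per-rank means of the genes' sorted value vectors.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValidationError("quantile normalization needs >= 2 samples")
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=0).mean(axis=1)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        n_obs = X.shape[0]
        if n_obs == self.reference_.shape[0]:
            reference = self.reference_
        else:  # map through the quantile function of the reference
            grid = np.linspace(0.0, 1.0, self.reference_.shape[0])
            reference = np.interp(np.linspace(0.0, 1.0, n_obs), grid, self.reference_)
        out = np.empty_like(X, dtype=float)
        for j in range(X.shape[1]):
            out[:, j] = _map_column_to_reference(X[:, j], reference)
        return out


class GeneZScorer(TransformerMixin, BaseEstimator):
    """Per-gene z-scoring with sample standard deviation (ddof=1).

    Genes constant across samples transform to all-zero rather than raising,
    so sparse or flat markers do not abort a signature computation.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValidationError("z-scoring needs >= 2 samples")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=float)
        scale = np.where(self.scale_ > 0, self.scale_, 1.0)
        Z = (X - self.mean_) / scale
        Z[:, self.scale_ == 0] = 0.0
        return Z


def quantile_normalize_genewise(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise quantile normalization of a genes x samples matrix.

    After the transform every gene has the same sorted value vector, hence the
    same mean, median and variance.  Idempotent.
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    normalized = GenewiseQuantileNormalizer().fit_transform(matrix.values.T).T
    data = matrix.data.copy()
    data.iloc[:, :] = normalized
    return ExpressionMatrix(data, scale_tag=matrix.scale_tag)


def zscore_by_gene(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores (ddof=1); constant genes map to zero.

    The result is returned with ``scale_tag='log2'`` in the sense of "already
    transformed": downstream scoring treats it as ready-to-average.
    """
    if matrix.n_samples < 2:
        raise ValidationError("z-scoring needs >= 2 samples")
    Z = GeneZScorer().fit_transform(matrix.values.T).T
    data = matrix.data.copy()
    data.iloc[:, :] = Z
    return ExpressionMatrix(data, scale_tag="log2")
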