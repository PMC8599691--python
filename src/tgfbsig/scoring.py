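"""Signature scoring, score stratification and Ki67 binning.

The TGF-beta and ECM scores are computed on gene-wise quantile-normalized
values as mean(up genes) - mean(down genes) per sample; the EMT score uses
per-gene z-scores instead (mesenchymal mean minus epithelial mean).  Cohort
matrices arriving on a linear RPKM/FPKM scale are log2(x+1)-transformed first.

Samples are stratified on the TGF-beta score with cuts at 0 and 10
(low: < 0, intermediate: 0-10 inclusive, high: > 10), and Ki67
percent-positive staining maps to an ordinal 0-8 score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import ExpressionMatrix, GeneSignature, ScoreTable
from .errors import CoverageError, ValidationError
from .preprocessing import GenewiseQuantileNormalizer, GeneZScorer, quantile_normalize_genewise, zscore_by_gene

STRATUM_LOW = "low"
STRATUM_INTERMEDIATE = "intermediate"
STRATUM_HIGH = "high"
STRATA_ORDER = (STRATUM_LOW, STRATUM_INTERMEDIATE, STRATUM_HIGH)


@dataclass(frozen=True)
class StratificationRule:
    """Score cuts for the low / intermediate / high strata.

    low: score < low_cut; intermediate: low_cut <= score <= high_cut;
    high: score > high_cut.  Defaults (0, 10) follow the published strata.
    """

    low_cut: float = 0.0
    high_cut: float = 10.0

    def __post_init__(self) -> None:
        if not self.low_cut < self.high_cut:
            raise ValidationError("low_cut must be < high_cut")


def _present_genes(genes: Iterable[str], index: pd.Index) -> list:
    return [g for g in genes if g in index]


def _check_coverage(signature: GeneSignature, index: pd.Index, min_coverage: float):
    up = _present_genes(signature.up_genes, index)
    down = _present_genes(signature.down_genes, index)
    missing = (set(signature.up_genes) | set(signature.down_genes)) - set(index)
    if len(up) < min_coverage * len(signature.up_genes):
        raise CoverageError(
            f"signature {signature.name!r}: only {len(up)}/{len(signature.up_genes)} "
            f"up genes present (< {min_coverage:.0%})",
            missing_genes=missing,
        )
    if signature.down_genes and len(down) < min_coverage * len(signature.down_genes):
        raise CoverageError(
            f"signature {signature.name!r}: only {len(down)}/{len(signature.down_genes)} "
            f"down genes present (< {min_coverage:.0%})",
            missing_genes=missing,
        )
    return up, down


def signature_score(
    norm_matrix: ExpressionMatrix,
    signature: GeneSignature,
    min_coverage: float = 0.5,
) -> np.ndarray:
    """Per-sample mean(up genes) - mean(down genes) on an already-normalized
    matrix; an empty down component contributes 0.

    Raises :class:`CoverageError` when fewer than ``min_coverage`` of either
    directional component is present in the matrix.
    """
    up, down = _check_coverage(signature, norm_matrix.data.index, min_coverage)
    score = norm_matrix.data.loc[up].mean(axis=0).to_numpy(dtype=float)
    if down:
        score = score - norm_matrix.data.loc[down].mean(axis=0).to_numpy(dtype=float)
    return score


def emt_score(
    matrix: ExpressionMatrix,
    emt_signature: GeneSignature,
    min_coverage: float = 0.5,
) -> np.ndarray:
    """EMT score: per-gene z-scores first, then mesenchymal-mean minus
    epithelial-mean per sample."""
    return signature_score(zscore_by_gene(matrix), emt_signature, min_coverage)


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer computing one signature score per sample.

    Expects a pandas DataFrame ``X`` of shape (n_samples, n_genes) with gene
    symbols as column names.  ``normalization`` selects the preprocessing:
    ``"quantile"`` (gene-wise quantile normalization, used for the TGF-beta
    and ECM scores), ``"zscore"`` (per-gene z-scores, used for the EMT score)
    or ``None`` (X is already normalized).

    Parameters
    ----------
    signature : GeneSignature
    normalization : {"quantile", "zscore", None}, default="quantile"
    log2_transform : {"auto", True, False}, default="auto"
        log2(x+1)-transform the input first; "auto" transforms unless the
        data already contain negative values.
    min_coverage : float, default=0.5
        Minimum fraction of each directional component that must be present.

    Attributes
    ----------
    up_genes_used_ : list of genes of the up component found in X
    down_genes_used_ : list of genes of the down component found in X
    """

    def __init__(self, signature: GeneSignature, normalization: Optional[str] = "quantile",
                 log2_transform: Union[str, bool] = "auto", min_coverage: float = 0.5):
        self.signature = signature
        self.normalization = normalization
        self.log2_transform = log2_transform
        self.min_coverage = min_coverage

    def _prepare(self, X: pd.DataFrame) -> np.ndarray:
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("SignatureScorer requires a DataFrame with gene columns")
        values = X.to_numpy(dtype=float)
        do_log = self.log2_transform is True or (
            self.log2_transform == "auto" and values.size and values.min() >= 0
        )
        if do_log:
            values = np.log2(values + 1.0)
        return values

    def fit(self, X: pd.DataFrame, y=None):
        values = self._prepare(X)
        up, down = _check_coverage(self.signature, pd.Index(X.columns), self.min_coverage)
        self.up_genes_used_ = up
        self.down_genes_used_ = down
        self.feature_names_in_ = np.asarray(X.columns)
        if self.normalization == "quantile":
            self.normalizer_ = GenewiseQuantileNormalizer().fit(values)
        elif self.normalization == "zscore":
            self.normalizer_ = GeneZScorer().fit(values)
        elif self.normalization is None:
            self.normalizer_ = None
        else:
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "up_genes_used_")
        values = self._prepare(X)
        if self.normalizer_ is not None:
            values = self.normalizer_.transform(values)
        frame = pd.DataFrame(values, index=X.index, columns=X.columns)
        score = frame[self.up_genes_used_].mean(axis=1).to_numpy(dtype=float)
        if self.down_genes_used_:
            score = score - frame[self.down_genes_used_].mean(axis=1).to_numpy(dtype=float)
        return score.reshape(-1, 1)


def stratify_scores(scores: Sequence[float], rule: StratificationRule = StratificationRule()) -> np.ndarray:
    """Map scores to 'low' / 'intermediate' / 'high' labels under ``rule``."""
    scores = np.asarray(scores, dtype=float)
    if scores.size and not np.isfinite(scores).all():
        raise ValidationError("scores must be finite")
    labels = np.full(scores.shape, STRATUM_INTERMEDIATE, dtype=object)
    labels[scores < rule.low_cut] = STRATUM_LOW
    labels[scores > rule.high_cut] = STRATUM_HIGH
    return labels


#: upper edges of the Ki67 ordinal bins 1..8; bin 0 is exactly 0%
_KI67_UPPER_EDGES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 75.0, 100.0)


def ki67_bin(percent: float) -> int:
    """Ordinal Ki67 staining score 0-8 from percent positive tumor cells.

    Bins: 0: =0; 1: (0,1]; 2: (1,10]; 3: (10,20]; 4: (20,30]; 5: (30,40];
    6: (40,50]; 7: (50,75]; 8: (75,100] — half-open intervals extending each
    printed label upward.
    """
    percent = float(percent)
    if not 0.0 <= percent <= 100.0:
        raise ValidationError(f"ki67 percent {percent} outside [0, 100]")
    if percent == 0.0:
        return 0
    for score, upper in enumerate(_KI67_UPPER_EDGES, start=1):
        if percent <= upper:
            return score
    raise AssertionError("unreachable")


def ki67_bins(percents: Sequence[float]) -> np.ndarray:
    """Vectorized :func:`ki67_bin`; NaN maps to -1 (missing)."""
    out = np.full(len(percents), -1, dtype=int)
    for i, p in enumerate(np.asarray(percents, dtype=float)):
        if not np.isnan(p):
            out[i] = ki67_bin(p)
    return out


def compute_score_table(
    matrix: ExpressionMatrix,
    tgfb_signature: GeneSignature,
    emt_signature: Optional[GeneSignature] = None,
    ecm_signature: Optional[GeneSignature] = None,
    rule: StratificationRule = StratificationRule(),
    log2_transform: Union[str, bool] = "auto",
    min_coverage: float = 0.5,
) -> ScoreTable:
    """Score a cohort matrix with the TGF-beta (and optionally EMT and ECM)
    signatures and assign TGF-beta strata.

    The matrix is log2(x+1)-transformed when on linear scale (unless
    ``log2_transform=False``); TGF-beta and ECM scores are computed on
    gene-wise quantile-normalized values, the EMT score on per-gene z-scores.
    """
    work = matrix
    if log2_transform is True or (log2_transform == "auto" and matrix.scale_tag == "linear"):
        work = matrix.log2_transform()
    qn = quantile_normalize_genewise(work)

    genes_used: Dict[str, int] = {}

    def _count(sig: GeneSignature) -> int:
        idx = work.data.index
        return len(_present_genes(sig.up_genes, idx)) + len(_present_genes(sig.down_genes, idx))

    tgfb = signature_score(qn, tgfb_signature, min_coverage)
    genes_used[tgfb_signature.name] = _count(tgfb_signature)
    frame = pd.DataFrame({"tgfb_score": tgfb},
                         index=pd.Index(work.sample_ids, name="sample_id"))
    if emt_signature is not None:
        frame["emt_score"] = emt_score(work, emt_signature, min_coverage)
        genes_used[emt_signature.name] = _count(emt_signature)
    if ecm_signature is not None:
        frame["ecm_score"] = signature_score(qn, ecm_signature, min_coverage)
        genes_used[ecm_signature.name] = _count(ecm_signature)
    frame["stratum"] = stratify_scores(tgfb, rule)
    return ScoreTable(frame, genes_used=genes_used)
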