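"""Core in-memory containers.

The pipeline moves four kinds of data around: a genes-by-samples expression
matrix, named gene signatures with up/down direction labels, a per-sample
clinical table (survival, Ki67 immunohistochemistry, categorical covariates),
and a mouse-to-human ortholog symbol map.  All are light wrappers over pandas
structures with the domain invariants enforced at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError

#: allowed values of ``ExpressionMatrix.scale_tag``
SCALE_LINEAR = "linear"
SCALE_LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample id, numeric body.
        Units are RPKM/FPKM when ``scale_tag == "linear"`` and log2-transformed
        abundance when ``scale_tag == "log2"``.
    scale_tag : str
        Either ``"linear"`` or ``"log2"``; operations that assume a scale
        (fold-change filtering needs linear values) check this tag.
    """

    data: pd.DataFrame
    scale_tag: str = SCALE_LINEAR

    def __post_init__(self) -> None:
        if self.scale_tag not in (SCALE_LINEAR, SCALE_LOG2):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")
        if self.scale_tag == SCALE_LINEAR and values.size and (values < 0).any():
            raise ValidationError("linear-scale expression values must be >= 0")

    @property
    def gene_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def log2_transform(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2(x + pseudocount) copy; identity if already log2."""
        if self.scale_tag == SCALE_LOG2:
            return self
        return ExpressionMatrix(np.log2(self.data + pseudocount), SCALE_LOG2)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set split into an up- and a down-regulated component.

    For the EMT signature ``up_genes`` are the mesenchymal markers and
    ``down_genes`` the epithelial markers; for TGF-beta and ECM signatures the
    components are the induced and repressed genes respectively.
    """

    name: str
    up_genes: FrozenSet[str]
    down_genes: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValidationError(
                f"signature {self.name!r}: up/down overlap {sorted(overlap)[:5]}"
            )
        if not self.up_genes:
            raise ValidationError(f"signature {self.name!r}: empty up set")

    @property
    def size(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


REQUIRED_CLINICAL_COLUMNS = ("time", "event")
KNOWN_COVARIATES = ("sex", "age", "smoking", "stage", "ps")


@dataclass
class ClinicalTable:
    """Per-sample survival and clinical annotation.

    ``data`` is indexed by sample id with columns ``time`` (months, >= 0),
    ``event`` (1 = death observed, 0 = censored), optionally ``ki67_percent``
    (percent positive tumor cells, may be missing) and categorical covariates.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        for col in REQUIRED_CLINICAL_COLUMNS:
            if col not in self.data.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        time = self.data["time"].to_numpy(dtype=float)
        if (time < 0).any():
            raise ValidationError("survival_time must be >= 0")
        event = self.data["event"].to_numpy()
        if not np.isin(event, (0, 1)).all():
            raise ValidationError("event must be 0 or 1")
        if "ki67_percent" in self.data.columns:
            ki67 = self.data["ki67_percent"].to_numpy(dtype=float)
            valid = ki67[~np.isnan(ki67)]
            if valid.size and ((valid < 0) | (valid > 100)).any():
                raise ValidationError("ki67_percent must lie in [0, 100]")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def ki67_percent(self) -> Optional[np.ndarray]:
        if "ki67_percent" not in self.data.columns:
            return None
        return self.data["ki67_percent"].to_numpy(dtype=float)

    @property
    def covariates(self) -> pd.DataFrame:
        cols = [c for c in self.data.columns if c in KNOWN_COVARIATES]
        return self.data[cols]


@dataclass(frozen=True)
class OrthologMap:
    """Mouse -> human gene-symbol pairs.

    A source symbol may map to several targets (paralog expansion) and several
    sources may share one target; both directions are preserved.
    """

    pairs: FrozenSet[Tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        for src, tgt in self.pairs:
            if not src or not tgt:
                raise ValidationError(f"empty symbol in ortholog pair ({src!r}, {tgt!r})")

    def targets(self, source: str) -> FrozenSet[str]:
        return frozenset(t for s, t in self.pairs if s == source)

    @property
    def sources(self) -> FrozenSet[str]:
        return frozenset(s for s, _ in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ScoreTable:
    """Per-sample signature scores and the assigned TGF-beta stratum.

    ``scores`` is indexed by sample id with columns ``tgfb_score``,
    ``emt_score``, ``ecm_score`` and ``stratum`` (low/intermediate/high from
    the stratification rule applied to the TGF-beta score); ``genes_used``
    maps signature name to the number of signature genes found in the matrix.
    """

    scores: pd.DataFrame
    genes_used: Mapping[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list:
        return self.scores.index.tolist()


@dataclass
class SimTruth:
    """Ground truth emitted by the synthetic generators.

    Cell-line mode fills the planted gene sets; cohort mode fills
    ``latent_activity`` (the per-sample TGF-beta pathway activity that drives
    signature-gene expression, Ki67 positivity and the hazard).
    """

    planted_up: FrozenSet[str] = frozenset()
    planted_down: FrozenSet[str] = frozenset()
    planted_tnf: FrozenSet[str] = frozenset()
    planted_synergy: FrozenSet[str] = frozenset()
    latent_activity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        sets = [self.planted_up, self.planted_down, self.planted_tnf, self.planted_synergy]
        total = sum(len(s) for s in sets)
        if total != len(frozenset().union(*sets)):
            raise ValidationError("planted gene sets must be disjoint")
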