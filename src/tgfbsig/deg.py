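"""Threshold-based differential-expression selection and ortholog mapping.

Genes are called TGF-beta-induced when the linear RPKM fold change
treated/control exceeds 2 and the treated-condition RPKM exceeds 2; repressed
when the fold change falls below 0.25 with untreated RPKM above 1 (abundance
gate on the *untreated* value, so silencing of expressed genes is detected).
All inequalities are strict.  Fold changes use a small symmetric pseudocount
for zero-abundance robustness.  Mouse gene lists translate to human symbols
through an explicit ortholog map (never case-folding): one-to-many mappings
keep all targets, many-to-one collisions collapse by set union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Set, Tuple

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, OrthologMap
from .errors import PipelineError, ScaleError, ValidationError


@dataclass(frozen=True)
class DEGThresholds:
    """Selection thresholds.

    up: fold change > ``up_fc_min`` and treated RPKM > ``up_rpkm_min``;
    down: fold change < ``down_fc_max`` and untreated RPKM > ``down_rpkm_min``.
    """

    up_fc_min: float = 2.0
    up_rpkm_min: float = 2.0
    down_fc_max: float = 0.25
    down_rpkm_min: float = 1.0
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if not self.up_fc_min > 1:
            raise ValidationError("up_fc_min must be > 1")
        if not 0 < self.down_fc_max < 1:
            raise ValidationError("down_fc_max must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")


@dataclass
class DEGResult:
    """Selected genes for one treated/control condition pair plus the full
    per-gene statistics table (gene, fold_change, rpkm_treated, rpkm_control)."""

    condition_pair: Tuple[str, str]
    up_genes: FrozenSet[str] = frozenset()
    down_genes: FrozenSet[str] = frozenset()
    per_gene_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValidationError("up and down gene sets overlap")


@dataclass(frozen=True)
class VennCounts:
    """Two-set overlap partition: |A only|, |A and B|, |B only|."""

    only_a: int
    shared: int
    only_b: int

    def __post_init__(self) -> None:
        if min(self.only_a, self.shared, self.only_b) < 0:
            raise ValidationError("Venn counts must be >= 0")


def compute_fold_change(rpkm_treated: float, rpkm_control: float, pseudocount: float = 0.1) -> float:
    """(treated + pc) / (control + pc) on linear RPKM values."""
    if rpkm_treated < 0 or rpkm_control < 0:
        raise ValidationError("RPKM values must be >= 0")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and rpkm_control == 0:
        return np.inf if rpkm_treated > 0 else 1.0
    return (rpkm_treated + pseudocount) / (rpkm_control + pseudocount)


def _per_gene_stats(matrix: ExpressionMatrix, treated_id: str, control_id: str,
                    pseudocount: float) -> pd.DataFrame:
    if matrix.scale_tag != "linear":
        raise ScaleError("DEG selection requires a linear-scale (RPKM) matrix")
    for sid in (treated_id, control_id):
        if sid not in matrix.data.columns:
            raise PipelineError(f"unknown sample id {sid!r}")
    treated = matrix.data[treated_id].to_numpy(dtype=float)
    control = matrix.data[control_id].to_numpy(dtype=float)
    fc = (treated + pseudocount) / (control + pseudocount)
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "fold_change": fc,
            "rpkm_treated": treated,
            "rpkm_control": control,
        }
    )


def select_upregulated(matrix: ExpressionMatrix, treated_id: str, control_id: str,
                       thresholds: DEGThresholds = DEGThresholds()) -> DEGResult:
    """Genes with fold change > up_fc_min and treated RPKM > up_rpkm_min
    (both strict)."""
    stats = _per_gene_stats(matrix, treated_id, control_id, thresholds.pseudocount)
    mask = (stats["fold_change"] > thresholds.up_fc_min) & (
        stats["rpkm_treated"] > thresholds.up_rpkm_min
    )
    return DEGResult(
        condition_pair=(treated_id, control_id),
        up_genes=frozenset(stats.loc[mask, "gene"]),
        per_gene_stats=stats,
    )


def select_downregulated(matrix: ExpressionMatrix, treated_id: str, control_id: str,
                         thresholds: DEGThresholds = DEGThresholds()) -> DEGResult:
    """Genes with fold change < down_fc_max and *untreated* RPKM >
    down_rpkm_min (both strict)."""
    stats = _per_gene_stats(matrix, treated_id, control_id, thresholds.pseudocount)
    mask = (stats["fold_change"] < thresholds.down_fc_max) & (
        stats["rpkm_control"] > thresholds.down_rpkm_min
    )
    return DEGResult(
        condition_pair=(treated_id, control_id),
        down_genes=frozenset(stats.loc[mask, "gene"]),
        per_gene_stats=stats,
    )


def venn_overlap(set_a: Set[str], set_b: Set[str]) -> VennCounts:
    """Exact two-set partition counts (A only, shared, B only)."""
    set_a, set_b = set(set_a), set(set_b)
    shared = set_a & set_b
    return VennCounts(len(set_a - shared), len(shared), len(set_b - shared))


def map_orthologs(genes: Set[str], ortholog_map: OrthologMap) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """Translate a gene set through the ortholog map.

    Returns ``(mapped, unmapped)``: the deduplicated union of all targets of
    sources found in the map, and the sources with no pair.  One-to-many
    mappings keep every target; many-to-one collisions collapse to one
    target symbol.
    """
    by_source = {}
    for src, tgt in ortholog_map.pairs:
        by_source.setdefault(src, set()).add(tgt)
    mapped: Set[str] = set()
    unmapped: Set[str] = set()
    for gene in genes:
        targets = by_source.get(gene)
        if targets:
            mapped.update(targets)
        else:
            unmapped.add(gene)
    return frozenset(mapped), frozenset(unmapped)
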