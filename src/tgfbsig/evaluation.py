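"""Recovery and calibration experiments on the synthetic generators.

These drive the whole pipeline end to end against known ground truth:
sensitivity/specificity of the threshold DEG selection, rank agreement of the
TGF-beta score with the latent activity, and type-I error / power of the
score-stratified log-rank test.  Shared by the test suite and the acceptance
script so both report numbers computed the same way.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional, Tuple

import numpy as np

from .datatypes import GeneSignature
from .deg import DEGThresholds, select_upregulated
from .scoring import compute_score_table
from .simulate import (
    CellLineSimConfig,
    CohortSimConfig,
    default_cohort_signature,
    generate_cellline_experiment,
    generate_cohort,
)
from .stats import logrank_test, spearman_rho


def deg_recovery(
    config: CellLineSimConfig,
    n_seeds: int = 20,
    thresholds: DEGThresholds = DEGThresholds(),
) -> Dict[str, float]:
    """Mean sensitivity and specificity of up-regulated gene selection over
    ``n_seeds`` independent simulated experiments."""
    sens, spec = [], []
    for k in range(n_seeds):
        cfg = replace(config, seed=config.seed + k)
        matrix, truth = generate_cellline_experiment(cfg)
        result = select_upregulated(matrix, "tgfb", "ctrl", thresholds)
        planted = truth.planted_up
        others = set(matrix.gene_ids) - planted
        tp = len(result.up_genes & planted)
        fp = len(result.up_genes & others)
        sens.append(tp / len(planted))
        spec.append(1.0 - fp / len(others))
    return {"sensitivity": float(np.mean(sens)), "specificity": float(np.mean(spec))}


def score_recovery(config: CohortSimConfig, signature: Optional[GeneSignature] = None) -> Dict[str, float]:
    """Spearman correlation between the latent TGF-beta activity and the
    computed TGF-beta score on one simulated cohort."""
    if signature is None:
        signature = default_cohort_signature()
    expr, _clin, truth = generate_cohort(config, signature)
    table = compute_score_table(expr, signature)
    res = spearman_rho(truth.latent_activity, table.scores["tgfb_score"].to_numpy())
    return {"rho": res.rho, "p_value": res.p_value, "n": res.n}


def _tertile_extremes(scores: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the bottom- and top-tertile samples by score."""
    lo, hi = np.quantile(scores, [1 / 3, 2 / 3])
    return scores <= lo, scores >= hi


def logrank_rejection_rate(
    config: CohortSimConfig,
    n_replicates: int,
    alpha: float = 0.05,
    signature: Optional[GeneSignature] = None,
) -> float:
    """Fraction of simulated cohorts where the high-vs-low score strata
    log-rank test rejects at level ``alpha``.

    Strata are the empirical score tertiles (bottom vs top third), which
    keeps both groups non-empty on any simulation scale.  With ``gamma=0``
    this measures type-I error; with ``gamma>0`` it measures power.
    """
    if signature is None:
        signature = default_cohort_signature()
    rejections = 0
    for k in range(n_replicates):
        cfg = replace(config, seed=config.seed + k)
        expr, clin, _truth = generate_cohort(cfg, signature)
        table = compute_score_table(expr, signature)
        scores = table.scores["tgfb_score"].to_numpy()
        low_mask, high_mask = _tertile_extremes(scores)
        mask = low_mask | high_mask
        labels = np.where(low_mask[mask], "low", "high")
        res = logrank_test(clin.time[mask], clin.event[mask], labels)
        rejections += res.p_value < alpha
    return rejections / n_replicates
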