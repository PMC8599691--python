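"""Synthetic data generators with known ground truth.

Two study designs are emulated:

* a cell-line cytokine-stimulation experiment — four conditions (control,
  TGF-beta, TNF-alpha, co-stimulation) with planted induced / repressed /
  TNF-responsive / synergy-only genes at known fold changes on a log-normal
  RPKM baseline with multiplicative log2 noise;
* a tumor cohort — a latent per-sample TGF-beta activity factor drives
  signature-gene expression (log2-additive effect), proportional-hazards
  survival with uniform censoring, and Ki67 percent positivity through a
  noisy logistic link.

Defaults mirror the study conditions: a 108-sample cohort, fold-change
ranges clear of the selection thresholds (induced 3-8x, repressed
0.05-0.15x), and an exponential baseline hazard giving roughly half the
cohort an observed event before censoring.

Determinism: a single integer seed drives fixed, independently spawned
sub-streams (baselines, fold changes, noise, survival, Ki67, covariates), so
identical configs produce bit-identical outputs and adding genes does not
reshuffle the survival draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, GeneSignature, OrthologMap, SimTruth
from .errors import ConfigError

CELLLINE_CONDITIONS = ("ctrl", "tgfb", "tnfa", "tgfb_tnfa")


def _stream(seed: int, key: int) -> np.random.Generator:
    """Independent generator stream derived from (seed, key)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class CellLineSimConfig:
    """Configuration of the 2x2 stimulation experiment.

    Fold-change ranges are in linear units; noise_sd is the SD of the
    additive log2 noise applied independently per condition.
    """

    n_genes: int = 2000
    n_up: int = 100
    n_down: int = 60
    n_tnf: int = 50
    n_synergy: int = 50
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    up_fc_range: Tuple[float, float] = (3.0, 8.0)
    down_fc_range: Tuple[float, float] = (0.05, 0.15)
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        planted = self.n_up + self.n_down + self.n_tnf + self.n_synergy
        if planted > self.n_genes:
            raise ConfigError("planted gene counts exceed n_genes")
        if not self.up_fc_range[0] > 2.0:
            raise ConfigError("up_fc_range lower bound must exceed the selection threshold (2)")
        if not self.up_fc_range[0] <= self.up_fc_range[1]:
            raise ConfigError("up_fc_range must be ordered")
        if not 0 < self.down_fc_range[0] <= self.down_fc_range[1] < 0.25:
            raise ConfigError("down_fc_range must lie inside (0, 0.25)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def generate_cellline_experiment(config: CellLineSimConfig) -> Tuple[ExpressionMatrix, SimTruth]:
    """Simulate the 4-condition RPKM matrix with planted response genes.

    Planted induced genes respond in the TGF-beta and co-stimulation columns;
    TNF genes in the TNF-alpha and co-stimulation columns; synergy genes only
    under co-stimulation.  Planted baselines are floored so the true treated
    (induced) or untreated (repressed) abundance clears the selection gates.
    """
    cfg = config
    genes = [f"Gene{i:05d}" for i in range(cfg.n_genes)]
    rng_base = _stream(cfg.seed, 0)
    rng_fc = _stream(cfg.seed, 1)
    rng_noise = _stream(cfg.seed, 2)

    baseline = rng_base.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)

    i0 = 0
    idx_up = np.arange(i0, i0 + cfg.n_up); i0 += cfg.n_up
    idx_down = np.arange(i0, i0 + cfg.n_down); i0 += cfg.n_down
    idx_tnf = np.arange(i0, i0 + cfg.n_tnf); i0 += cfg.n_tnf
    idx_syn = np.arange(i0, i0 + cfg.n_synergy)

    # floor planted baselines so true abundances clear the RPKM gates
    baseline[idx_up] = np.maximum(baseline[idx_up], 1.0)      # RPKM >= 2
    baseline[idx_down] = np.maximum(baseline[idx_down], 1.5)  # RPKM >= 2.8
    baseline[idx_tnf] = np.maximum(baseline[idx_tnf], 1.0)
    baseline[idx_syn] = np.maximum(baseline[idx_syn], 1.0)

    def _draw_log2fc(rng, fc_range, size):
        lo, hi = np.log2(fc_range[0]), np.log2(fc_range[1])
        return rng.uniform(lo, hi, size)

    up_fc = _draw_log2fc(rng_fc, cfg.up_fc_range, cfg.n_up)
    down_fc = _draw_log2fc(rng_fc, cfg.down_fc_range, cfg.n_down)
    tnf_fc = _draw_log2fc(rng_fc, cfg.up_fc_range, cfg.n_tnf)
    syn_fc = _draw_log2fc(rng_fc, cfg.up_fc_range, cfg.n_synergy)

    log2 = np.tile(baseline[:, None], (1, 4))
    col = {c: j for j, c in enumerate(CELLLINE_CONDITIONS)}
    log2[idx_up, col["tgfb"]] += up_fc
    log2[idx_up, col["tgfb_tnfa"]] += up_fc
    log2[idx_down, col["tgfb"]] += down_fc
    log2[idx_down, col["tgfb_tnfa"]] += down_fc
    log2[idx_tnf, col["tnfa"]] += tnf_fc
    log2[idx_tnf, col["tgfb_tnfa"]] += tnf_fc
    log2[idx_syn, col["tgfb_tnfa"]] += syn_fc

    if cfg.noise_sd > 0:
        log2 = log2 + rng_noise.normal(0.0, cfg.noise_sd, log2.shape)

    data = pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene"),
                        columns=list(CELLLINE_CONDITIONS))
    truth = SimTruth(
        planted_up=frozenset(genes[i] for i in idx_up),
        planted_down=frozenset(genes[i] for i in idx_down),
        planted_tnf=frozenset(genes[i] for i in idx_tnf),
        planted_synergy=frozenset(genes[i] for i in idx_syn),
    )
    return ExpressionMatrix(data, scale_tag="linear"), truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of the tumor-cohort generator.

    ``beta`` is the log2 expression shift per unit latent activity on
    signature genes (sign following the gene's direction), ``gamma`` the log
    hazard ratio per unit activity, ``baseline_hazard`` in events/month and
    ``censor_max`` the upper bound of the uniform censoring time (months).
    """

    n_samples: int = 108
    n_genes: int = 200
    latent_sd: float = 1.0
    beta: float = 1.0
    noise_sd: float = 0.5
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    gamma: float = 0.8
    baseline_hazard: float = 0.015
    censor_max: float = 120.0
    ki67_slope: float = 1.0
    ki67_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.censor_max <= 0:
            raise ConfigError("censor_max must be > 0")
        if self.latent_sd <= 0:
            raise ConfigError("latent_sd must be > 0")
        if self.noise_sd < 0 or self.ki67_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")


def default_cohort_signature(n_up: int = 30, n_down: int = 20) -> GeneSignature:
    """The TGF-beta signature whose genes carry the latent-activity effect in
    the default cohort simulation (first genes of the simulated universe)."""
    up = frozenset(f"GENE{i:05d}" for i in range(n_up))
    down = frozenset(f"GENE{i:05d}" for i in range(n_up, n_up + n_down))
    return GeneSignature("TGFB", up, down)


def demo_signature_collection() -> Tuple[GeneSignature, GeneSignature, GeneSignature]:
    """TGFB, EMT and ECM signatures over the simulated cohort gene universe.

    The EMT and ECM sets are nested subsets of the TGFB signature genes, so
    all three scores share the latent driver — mimicking the partial overlap
    between the cell-line-derived signature and the published marker lists.
    """
    tgfb = default_cohort_signature()
    gene = lambda i: f"GENE{i:05d}"
    emt = GeneSignature("EMT",
                        frozenset(gene(i) for i in range(0, 15)),
                        frozenset(gene(i) for i in range(30, 40)))
    ecm = GeneSignature("ECM",
                        frozenset(gene(i) for i in range(15, 30)),
                        frozenset(gene(i) for i in range(40, 50)))
    return tgfb, emt, ecm


def generate_cohort(
    config: CohortSimConfig,
    signature: Optional[GeneSignature] = None,
) -> Tuple[ExpressionMatrix, ClinicalTable, SimTruth]:
    """Simulate a cohort expression matrix, clinical table and ground truth.

    log2 expression of signature genes = baseline + direction*beta*A_i +
    noise; survival times are exponential with hazard
    baseline_hazard*exp(gamma*A_i), censored at Uniform(0, censor_max); Ki67
    percent = 100*logistic(ki67_slope*A_i + noise).
    """
    cfg = config
    if signature is None:
        signature = default_cohort_signature()
    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    gene_set = set(genes)
    missing = (signature.up_genes | signature.down_genes) - gene_set
    if missing:
        raise ConfigError(f"signature genes missing from simulated universe: {sorted(missing)[:5]}")

    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    rng_latent = _stream(cfg.seed, 10)
    rng_base = _stream(cfg.seed, 11)
    rng_noise = _stream(cfg.seed, 12)
    rng_surv = _stream(cfg.seed, 13)
    rng_ki67 = _stream(cfg.seed, 14)
    rng_cov = _stream(cfg.seed, 15)

    activity = rng_latent.normal(0.0, cfg.latent_sd, cfg.n_samples)
    baseline = rng_base.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)

    direction = np.zeros(cfg.n_genes)
    for i, g in enumerate(genes):
        if g in signature.up_genes:
            direction[i] = 1.0
        elif g in signature.down_genes:
            direction[i] = -1.0

    log2 = baseline[:, None] + cfg.beta * direction[:, None] * activity[None, :]
    if cfg.noise_sd > 0:
        log2 = log2 + rng_noise.normal(0.0, cfg.noise_sd, log2.shape)
    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene"), columns=samples),
        scale_tag="linear",
    )

    hazard = cfg.baseline_hazard * np.exp(cfg.gamma * activity)
    event_time = rng_surv.exponential(1.0 / hazard)
    censor_time = rng_surv.uniform(0.0, cfg.censor_max, cfg.n_samples)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    logit = cfg.ki67_slope * activity
    if cfg.ki67_noise_sd > 0:
        logit = logit + rng_ki67.normal(0.0, cfg.ki67_noise_sd, cfg.n_samples)
    ki67 = 100.0 / (1.0 + np.exp(-logit))

    clin = pd.DataFrame(
        {
            "time": observed,
            "event": event,
            "ki67_percent": ki67,
            "sex": rng_cov.choice(["F", "M"], cfg.n_samples),
            "age": rng_cov.choice(["<70", ">=70"], cfg.n_samples),
            "smoking": rng_cov.choice(["never", "ex", "current"], cfg.n_samples),
            "stage": rng_cov.choice(["I", "II", "III", "IV"], cfg.n_samples),
            "ps": rng_cov.choice(["0", "1", "2"], cfg.n_samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = SimTruth(latent_activity=activity)
    return expr, ClinicalTable(clin), truth


def generate_ortholog_map(
    gene_ids: Sequence[str],
    frac_missing: float = 0.0,
    frac_one_to_many: float = 0.0,
    seed: int = 0,
) -> OrthologMap:
    """Mouse -> human map: each symbol maps to its upper-cased counterpart,
    except a ``frac_missing`` subset (no pair) and a disjoint
    ``frac_one_to_many`` subset (two targets, the second suffixed ``B``)."""
    if not (0 <= frac_missing < 1 and 0 <= frac_one_to_many < 1):
        raise ConfigError("fractions must lie in [0, 1)")
    if frac_missing + frac_one_to_many > 1:
        raise ConfigError("frac_missing + frac_one_to_many exceeds 1")
    genes = list(gene_ids)
    n = len(genes)
    n_missing = int(round(frac_missing * n))
    n_multi = int(round(frac_one_to_many * n))
    rng = _stream(seed, 20)
    perm = rng.permutation(n)
    missing = set(perm[:n_missing])
    multi = set(perm[n_missing:n_missing + n_multi])
    pairs = set()
    for i, g in enumerate(genes):
        if i in missing:
            continue
        pairs.add((g, g.upper()))
        if i in multi:
            pairs.add((g, g.upper() + "B"))
    return OrthologMap(frozenset(pairs))
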