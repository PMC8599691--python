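"""End-to-end pipeline stages with configuration and run manifests.

Two stages mirror the study design:

* cell-line stage — threshold DEG selection on the stimulation matrix,
  condition-overlap (Venn) counts, ortholog mapping of the mouse gene lists,
  and a human TGFB_UP/TGFB_DOWN GMT;
* cohort stage — signature scoring of the tumor matrix (TGF-beta / EMT / ECM),
  score-stratum assignment, score correlations, Ki67 subgroup comparison and
  Kaplan-Meier / pairwise log-rank survival analysis.

Every run writes a manifest recording the configuration, gene counts at each
attrition step (conserved: genes_in = selected + rejected), and the package
version, so artifacts are reproducible byte-for-byte from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import ClinicalTable, ExpressionMatrix, GeneSignature, ScoreTable
from .deg import DEGThresholds, map_orthologs, select_downregulated, select_upregulated, venn_overlap
from .errors import ConfigError, PipelineError
from .io import (
    read_clinical_table,
    read_expression_table,
    read_gene_sets,
    read_ortholog_map,
    write_clinical_table,
    write_expression_table,
    write_gene_sets,
    write_ortholog_map,
    write_score_table,
)
from .scoring import StratificationRule, compute_score_table, ki67_bins
from .simulate import (
    CellLineSimConfig,
    CohortSimConfig,
    demo_signature_collection,
    generate_cellline_experiment,
    generate_cohort,
    generate_ortholog_map,
)
from .stats import compare_score_by_group, km_estimate, pairwise_logrank_bonferroni, spearman_rho

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for the pipeline stages.

    Loadable from YAML (:meth:`from_yaml`); CLI flags override config keys.
    """

    out_dir: Path = Path("results")
    seed: int = 0
    # cell-line stage
    cellline_expression: Optional[Path] = None
    ortholog_map: Optional[Path] = None
    control: str = "ctrl"
    treated: str = "tgfb"
    co_treated: Optional[str] = "tgfb_tnfa"
    thresholds: DEGThresholds = field(default_factory=DEGThresholds)
    # cohort stage
    cohort_expression: Optional[Path] = None
    clinical: Optional[Path] = None
    signatures: Optional[Path] = None
    log2_transform: Any = "auto"
    coverage_min: float = 0.5
    low_cut: float = 0.0
    high_cut: float = 10.0
    group_test: str = "mannwhitney"
    ki67_cut: Any = "median"
    # optional simulation front-end for run-all demos
    simulate: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = DEGThresholds(**raw["thresholds"])
        for key in ("out_dir", "cellline_expression", "ortholog_map",
                    "cohort_expression", "clinical", "signatures"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def stratification_rule(self) -> StratificationRule:
        return StratificationRule(low_cut=self.low_cut, high_cut=self.high_cut)


def _write_json(obj: Dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def simulate_inputs(config: PipelineConfig) -> PipelineConfig:
    """Generate synthetic cell-line, ortholog-map, cohort and clinical inputs
    under ``out_dir/sim`` and return a config pointing at them."""
    sim_dir = Path(config.out_dir) / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    cl_cfg = CellLineSimConfig(seed=config.seed)
    matrix, _truth = generate_cellline_experiment(cl_cfg)
    expr_path = sim_dir / "cellline_expression.tsv"
    write_expression_table(matrix, expr_path)
    omap = generate_ortholog_map(matrix.gene_ids, frac_missing=0.08,
                                 frac_one_to_many=0.02, seed=config.seed)
    omap_path = sim_dir / "ortholog_map.tsv"
    write_ortholog_map(omap, omap_path)

    co_cfg = CohortSimConfig(seed=config.seed)
    expr, clin, _ = generate_cohort(co_cfg)
    cohort_path = sim_dir / "cohort_expression.tsv"
    clin_path = sim_dir / "clinical.tsv"
    write_expression_table(expr, cohort_path)
    write_clinical_table(clin, clin_path)
    sigs_path = sim_dir / "signatures.gmt"
    write_gene_sets(demo_signature_collection(), sigs_path)
    return dataclasses.replace(
        config,
        cellline_expression=expr_path,
        ortholog_map=omap_path,
        cohort_expression=cohort_path,
        clinical=clin_path,
        signatures=sigs_path,
    )


def run_cellline_stage(config: PipelineConfig) -> Dict:
    """DEG selection, Venn overlap, ortholog mapping; writes gene lists, the
    Venn JSON, the human signature GMT and a run manifest.  Returns the
    manifest dict."""
    if config.cellline_expression is None:
        raise ConfigError("cell-line stage needs cellline_expression")
    if config.ortholog_map is None:
        raise ConfigError("cell-line stage needs ortholog_map")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        matrix = read_expression_table(config.cellline_expression, scale_tag="linear")
        omap = read_ortholog_map(config.ortholog_map)
    except PipelineError as exc:
        raise PipelineError(f"cellline-stage input: {exc}") from exc

    up = select_upregulated(matrix, config.treated, config.control, config.thresholds)
    down = select_downregulated(matrix, config.treated, config.control, config.thresholds)
    venn = None
    if config.co_treated is not None:
        up_co = select_upregulated(matrix, config.co_treated, config.control, config.thresholds)
        venn = venn_overlap(up.up_genes, up_co.up_genes)
        _write_json(dataclasses.asdict(venn), out / "venn.json")

    up.per_gene_stats.assign(selected=up.per_gene_stats["gene"].isin(up.up_genes)).to_csv(
        out / "degs_up.tsv", sep="\t", index=False, float_format="%.6g")
    down.per_gene_stats.assign(selected=down.per_gene_stats["gene"].isin(down.down_genes)).to_csv(
        out / "degs_down.tsv", sep="\t", index=False, float_format="%.6g")

    up_mapped, up_unmapped = map_orthologs(up.up_genes, omap)
    down_mapped, down_unmapped = map_orthologs(down.down_genes, omap)
    signature = GeneSignature("TGFB", up_mapped, down_mapped - up_mapped)
    write_gene_sets([signature], out / "human_signature.gmt")

    n_genes = matrix.n_genes
    manifest = {
        "stage": "cellline",
        "version": __version__,
        "thresholds": dataclasses.asdict(config.thresholds),
        "conditions": {"control": config.control, "treated": config.treated,
                       "co_treated": config.co_treated},
        "attrition": {
            "genes_in": n_genes,
            "up_selected": len(up.up_genes),
            "up_rejected": n_genes - len(up.up_genes),
            "down_selected": len(down.down_genes),
            "down_rejected": n_genes - len(down.down_genes),
            "up_mapped": len(up_mapped),
            "up_unmapped": len(up_unmapped),
            "down_mapped": len(down_mapped),
            "down_unmapped": len(down_unmapped),
        },
        "venn": dataclasses.asdict(venn) if venn is not None else None,
    }
    _write_json(manifest, out / "cellline_manifest.json")
    return manifest


def _ki67_groups(bins: np.ndarray, cut) -> np.ndarray:
    """Binary Ki67 subgroups from ordinal bins; ``cut='median'`` splits at
    the median bin, an integer cut splits at bin <= cut vs > cut."""
    valid = bins >= 0
    if cut == "median":
        cut_value = float(np.median(bins[valid]))
    else:
        cut_value = float(cut)
    groups = np.where(bins <= cut_value, "low_ki67", "high_ki67")
    groups[~valid] = ""
    return groups


def run_cohort_stage(config: PipelineConfig) -> Dict:
    """Score the cohort, write scores.tsv, correlation / Ki67 JSON, KM curves
    and pairwise log-rank results; returns the manifest dict."""
    for key in ("cohort_expression", "clinical", "signatures"):
        if getattr(config, key) is None:
            raise ConfigError(f"cohort stage needs {key}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_expression_table(config.cohort_expression, scale_tag="linear")
    clinical = read_clinical_table(config.clinical)
    signatures = read_gene_sets(config.signatures)
    if "TGFB" not in signatures:
        raise ConfigError("signature GMT must contain a TGFB set")

    shared = [s for s in matrix.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise PipelineError("no overlapping samples between expression and clinical tables")
    matrix = ExpressionMatrix(matrix.data[shared], scale_tag=matrix.scale_tag)
    clinical = ClinicalTable(clinical.data.loc[shared], n_dropped=clinical.n_dropped)

    table = compute_score_table(
        matrix,
        tgfb_signature=signatures["TGFB"],
        emt_signature=signatures.get("EMT"),
        ecm_signature=signatures.get("ECM"),
        rule=config.stratification_rule(),
        log2_transform=config.log2_transform,
        min_coverage=config.coverage_min,
    )
    write_score_table(table, out / "scores.tsv")

    scores = table.scores
    correlations: Dict[str, Dict] = {}
    for other in ("emt_score", "ecm_score"):
        if other in scores.columns:
            res = spearman_rho(scores["tgfb_score"], scores[other])
            correlations[f"tgfb:{other.replace('_score', '')}"] = dataclasses.asdict(res)

    ki67_result = None
    if clinical.ki67_percent is not None:
        bins = ki67_bins(clinical.ki67_percent)
        groups = _ki67_groups(bins, config.ki67_cut)
        valid = groups != ""
        if valid.sum() >= 4 and len(np.unique(groups[valid])) == 2:
            res = compare_score_by_group(
                scores["tgfb_score"].to_numpy()[valid], groups[valid],
                method="welch" if config.group_test == "welch" else "mannwhitney",
            )
            ki67_result = dataclasses.asdict(res)
    _write_json({"correlations": correlations, "ki67_comparison": ki67_result},
                out / "corr.json")

    strata = scores["stratum"].to_numpy()
    km_rows = []
    for label in pd.unique(strata):
        mask = strata == label
        curve = km_estimate(clinical.time[mask], clinical.event[mask])
        for t, s, n in zip(curve.event_times, curve.survival_probs, curve.at_risk):
            km_rows.append({"stratum": label, "time": t, "survival": s, "at_risk": n})
    pd.DataFrame(km_rows, columns=["stratum", "time", "survival", "at_risk"]).to_csv(
        out / "km.tsv", sep="\t", index=False, float_format="%.6f")

    logrank_results = []
    if len(pd.unique(strata)) >= 2:
        for res in pairwise_logrank_bonferroni(clinical.time, clinical.event, strata):
            logrank_results.append(dataclasses.asdict(res))
    _write_json({"pairwise_logrank": logrank_results}, out / "logrank.json")

    stratum_counts = pd.Series(strata).value_counts().to_dict()
    manifest = {
        "stage": "cohort",
        "version": __version__,
        "n_samples": len(shared),
        "genes_used": dict(table.genes_used),
        "strata": {str(k): int(v) for k, v in stratum_counts.items()},
        "cuts": {"low_cut": config.low_cut, "high_cut": config.high_cut},
        "clinical_rows_dropped": clinical.n_dropped,
    }
    _write_json(manifest, out / "cohort_manifest.json")
    return manifest


def run_all(config: PipelineConfig) -> Dict:
    """Optionally simulate inputs, then run both stages; returns the combined
    manifest."""
    if config.simulate:
        config = simulate_inputs(config)
    manifest = {
        "cellline": run_cellline_stage(config),
        "cohort": run_cohort_stage(config),
    }
    _write_json(manifest, Path(config.out_dir) / "manifest.json")
    return manifest
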