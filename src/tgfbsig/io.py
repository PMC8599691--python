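"""Readers and writers for the external formats the pipeline touches.

Formats: expression matrices as TSV (header row = sample ids, first column =
gene symbol), gene signatures as GMT (MSigDB dialect with an ``_UP``/``_DOWN``
suffix convention pairing directional sets), clinical tables as TSV, ortholog
maps as two-column TSV, and score tables as TSV.

Nothing is dropped silently: duplicate-gene collapses and removed clinical
rows are logged and surfaced as queryable counts on the returned objects.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSignature,
    KNOWN_COVARIATES,
    OrthologMap,
    ScoreTable,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


def read_expression_table(path, scale_tag: str = "linear") -> ExpressionMatrix:
    """Load a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    Duplicate gene symbols are collapsed to the arithmetic mean of their rows
    (order-independent); the number of collapsed rows is logged and stored on
    the returned matrix as ``n_duplicates_collapsed``.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression table") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: expression table has no sample columns")
    df.index = df.index.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced.astype(float)
    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    matrix = ExpressionMatrix(df, scale_tag=scale_tag)
    matrix.n_duplicates_collapsed = n_dup
    return matrix


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV (gene column named ``gene``)."""
    matrix.data.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


_UP_SUFFIX = "_UP"
_DOWN_SUFFIX = "_DOWN"


def read_gene_sets(path) -> Dict[str, GeneSignature]:
    """Parse a GMT file into named signatures.

    Sets named ``<stem>_UP`` / ``<stem>_DOWN`` are merged into one signature
    ``<stem>`` with directional components; an unpaired set becomes a
    signature with an empty down component.
    """
    raw: Dict[str, List[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in raw:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            raw[name] = genes

    signatures: Dict[str, GeneSignature] = {}
    consumed = set()
    for name, genes in raw.items():
        if name in consumed:
            continue
        if name.endswith(_UP_SUFFIX):
            stem = name[: -len(_UP_SUFFIX)]
            partner = stem + _DOWN_SUFFIX
            down = raw.get(partner, [])
            consumed.update({name, partner})
            signatures[stem] = GeneSignature(stem, frozenset(genes), frozenset(down))
        elif name.endswith(_DOWN_SUFFIX):
            stem = name[: -len(_DOWN_SUFFIX)]
            partner = stem + _UP_SUFFIX
            if partner in raw:
                continue  # handled from the _UP side
            consumed.add(name)
            # down-only set: treat listed genes as the up component of a
            # standalone signature named by the full set name
            signatures[name] = GeneSignature(name, frozenset(genes))
        else:
            consumed.add(name)
            signatures[name] = GeneSignature(name, frozenset(genes))
    return signatures


def write_gene_sets(signatures: Iterable[GeneSignature], path) -> None:
    """Write signatures as GMT using the ``_UP``/``_DOWN`` pairing convention."""
    with open(path, "w") as handle:
        for sig in signatures:
            handle.write(
                "\t".join([sig.name + _UP_SUFFIX, "up-regulated", *sorted(sig.up_genes)])
                + "\n"
            )
            if sig.down_genes:
                handle.write(
                    "\t".join(
                        [sig.name + _DOWN_SUFFIX, "down-regulated", *sorted(sig.down_genes)]
                    )
                    + "\n"
                )


def load_packaged_signatures() -> Dict[str, GeneSignature]:
    """Load the EMT/ECM marker signatures shipped with the package.

    The shipped GMT is a synthetic stand-in for the published supplementary
    lists: it reproduces the published set sizes (EMT: 52 mesenchymal + 25
    epithelial; ECM: 30 up + 28 down) using canonical marker symbols.
    """
    ref = resources.files("tgfbsig").joinpath("resources/signatures_synthetic.gmt")
    with resources.as_file(ref) as path:
        return read_gene_sets(path)


def read_clinical_table(path) -> ClinicalTable:
    """Load a clinical TSV (columns ``sample_id``, ``time``, ``event``,
    optional ``ki67_percent`` and covariates).

    Rows missing survival time or event are dropped (count logged and stored
    as ``n_dropped``); covariate columns that are entirely empty are omitted
    with a warning.  Only Ki67 may be missing per-row.
    """
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty clinical table") from exc
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    n_before = len(df)
    df = df.dropna(subset=["time", "event"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d clinical rows missing time/event", n_dropped)
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    event = pd.to_numeric(df["event"], errors="coerce")
    if event.isna().any() or not event.isin([0, 1]).all():
        raise ValidationError(f"{path}: event values must be 0 or 1")
    time = pd.to_numeric(df["time"], errors="coerce")
    if time.isna().any():
        raise FormatError(f"{path}: non-numeric survival time")
    if (time < 0).any():
        raise ValidationError(f"{path}: negative survival time")

    out = pd.DataFrame({"time": time.to_numpy(), "event": event.astype(int).to_numpy()},
                       index=pd.Index(df["sample_id"].astype(str), name="sample_id"))
    if "ki67_percent" in df.columns:
        out["ki67_percent"] = pd.to_numeric(df["ki67_percent"], errors="coerce").to_numpy()
    for cov in KNOWN_COVARIATES:
        if cov in df.columns:
            if df[cov].isna().all():
                logger.warning("covariate column %r is empty; omitted", cov)
                continue
            out[cov] = df[cov].astype(str).to_numpy()
    table = ClinicalTable(out, n_dropped=n_dropped)
    return table


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_ortholog_map(path) -> OrthologMap:
    """Load a two-column (mouse, human) TSV; an optional header is skipped."""
    pairs = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(f"{path}:{lineno}: expected two non-empty fields")
            if lineno == 1 and fields[0].lower() in ("mouse", "source", "mouse_symbol"):
                continue
            pairs.add((fields[0].strip(), fields[1].strip()))
    return OrthologMap(frozenset(pairs))


def write_ortholog_map(omap: OrthologMap, path) -> None:
    with open(path, "w") as handle:
        for src, tgt in sorted(omap.pairs):
            handle.write(f"{src}\t{tgt}\n")


SCORE_COLUMNS = ("tgfb_score", "emt_score", "ecm_score", "stratum")


def write_score_table(table: ScoreTable, path) -> None:
    """Write scores as TSV; numeric columns at 6 decimal places (lossless
    round-trip at 1e-6)."""
    df = table.scores.copy()
    for col in df.columns:
        if col != "stratum":
            df[col] = df[col].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_score_table(path) -> ScoreTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty score table") from exc
    df.index = df.index.astype(str)
    return ScoreTable(df)
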