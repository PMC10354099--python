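"""Readers and writers for every external format the pipeline touches.

Formats: GMT gene-set files, expression TSV / MatrixMarket triplets,
survival TSV, dilution CSV, YAML config and JSON provenance records.
Floats in tabular output are serialized with 6 significant digits.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .types import (
    DilutionAssay,
    ExpressionMatrix,
    GeneSetCollection,
    Modality,
    SurvivalTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """Raised on malformed input files, naming the offending location."""


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path, category: str = "signature") -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated (first occurrence kept)
    with a logged warning; a duplicate set name is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning("GMT set %r: %d duplicate genes removed", name, len(genes) - len(deduped))
            sets[name] = deduped
            descriptions[name] = desc
    if not sets:
        logger.warning("GMT file %s contained no gene sets", path)
        return GeneSetCollection(sets={}, descriptions={}, category=category)  # type: ignore[arg-type]
    return GeneSetCollection(sets=sets, descriptions=descriptions, category=category)  # type: ignore[arg-type]


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    # Duplicate gene rows collapse by per-sample maximum (conservative for
    # enrichment ranks); first-seen row order is preserved.
    if df.index.is_unique:
        return df
    n_dup = len(df) - df.index.nunique()
    logger.warning("%d duplicate gene rows collapsed by per-sample max", n_dup)
    order = df.index[~df.index.duplicated(keep="first")]
    return df.groupby(level=0, sort=False).max().loc[order]


def read_matrix(path: str | Path, modality: Modality = "bulk") -> ExpressionMatrix:
    """Read an expression matrix from TSV (genes x samples) or an MTX triplet.

    For MTX, ``path`` is the ``.mtx`` file and ``<stem>.genes.txt`` /
    ``<stem>.samples.txt`` sidecars hold the row/column identifiers.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        return _read_mtx(path, modality)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value in matrix ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix.from_frame(df, modality=modality)


def _read_mtx(path: Path, modality: Modality) -> ExpressionMatrix:
    gene_file = path.with_suffix("").with_suffix(".genes.txt")
    sample_file = path.with_suffix("").with_suffix(".samples.txt")
    for sidecar in (gene_file, sample_file):
        if not sidecar.exists():
            raise ParseError(f"missing MTX sidecar {sidecar}")
    genes = gene_file.read_text().split()
    samples = sample_file.read_text().split()
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(genes), len(samples)):
        raise ParseError(
            f"{path}: matrix is {mat.shape} but sidecars list "
            f"{len(genes)} genes x {len(samples)} samples"
        )
    df = _collapse_duplicate_genes(pd.DataFrame(mat, index=genes, columns=samples))
    return ExpressionMatrix.from_frame(df, modality=modality)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Survival and dilution tables


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing survival columns {sorted(missing)}")
    return SurvivalTable(
        patient_ids=[str(p) for p in df["patient_id"]],
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(int),
        group=[str(g) for g in df["group"]] if "group" in df.columns else None,
    )


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_dilution_table(path: str | Path) -> DilutionAssay:
    """Read a limiting-dilution CSV with columns group,dose,tested,response."""
    df = pd.read_csv(path)
    required = {"group", "dose", "tested", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing dilution columns {sorted(missing)}")
    try:
        return DilutionAssay(
            group=[str(g) for g in df["group"]],
            dose=df["dose"].to_numpy(float),
            n_tested=df["tested"].to_numpy(int),
            n_response=df["response"].to_numpy(int),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_dilution_table(assay: DilutionAssay, path: str | Path) -> None:
    assay.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Config and provenance


def read_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return cfg


def write_provenance(
    path: str | Path,
    *,
    inputs: dict[str, Any],
    parameters: dict[str, Any],
    seed: int | None,
) -> None:
    """Write a JSON provenance record sufficient to re-run bit-identically.

    Deliberately excludes wall-clock time so reruns are byte-identical.
    """
    record = {
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
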