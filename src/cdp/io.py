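"""Readers and writers for the tabular formats the pipeline consumes.

All tabular files are plain TSV (UTF-8, decimal point, no quoting), matching
the export conventions of public tumor-expression repositories. Gene sets use
the Broad GMT dialect; networks are exported as SIF or a flat edge table.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CASE,
    CONTROL,
    ClinicalTable,
    ExpressionMatrix,
    GeneList,
    GeneSetCollection,
    ScoreMatrix,
    ValidationError,
)


class ParseError(ValueError):
    """Raised on malformed input files; message names the offending location."""


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name <tab> description <tab> gene1 <tab> ...

    Duplicate genes within one line are collapsed preserving first occurrence;
    a duplicated set name or a line with fewer than 3 fields is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            if not genes:
                raise ParseError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = list(dict.fromkeys(genes))
            descriptions[name] = desc
    if not sets:
        raise ParseError(f"{path}: no gene sets")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_expression(
    path: str | Path,
    case_labels: Sequence[str],
    control_labels: Sequence[str],
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    Every sample in the header must appear in exactly one of ``case_labels`` /
    ``control_labels``; unknown samples and non-numeric cells are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ParseError(f"{path}: duplicated gene ids: {dupes[:5]}")
    case_set, control_set = set(case_labels), set(control_labels)
    overlap = case_set & control_set
    if overlap:
        raise ParseError(f"samples listed as both case and control: {sorted(overlap)[:5]}")
    condition = []
    for s in df.columns:
        if s in case_set:
            condition.append(CASE)
        elif s in control_set:
            condition.append(CONTROL)
        else:
            raise ParseError(f"{path}: sample {s!r} not in case or control labels")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at gene "
                    f"{df.index[i]!r}, sample {col!r}"
                ) from None
    return ExpressionMatrix(list(df.index), list(df.columns), values, condition)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns (sample, time, event).

    Rows with missing time or event are dropped and counted in
    ``dropped_count``; negative times and non-binary event codes are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected columns (sample, time, event)")
    df.columns = ["sample", "time", "event", *df.columns[3:]]
    complete = df.dropna(subset=["time", "event"])
    dropped = len(df) - len(complete)
    time = complete["time"].astype(float).to_numpy()
    if np.any(time < 0):
        raise ParseError(f"{path}: negative survival time")
    event_raw = complete["event"].astype(float).to_numpy()
    if not np.all(np.isin(event_raw, (0.0, 1.0))):
        bad = sorted(set(event_raw) - {0.0, 1.0})
        raise ParseError(f"{path}: event status must be 0/1, got {bad}")
    return ClinicalTable(
        list(complete["sample"]), time, event_raw.astype(int), dropped_count=dropped
    )


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": clinical.sample_ids, "time": clinical.time, "event": clinical.event}
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a plain-text gene list, one identifier per line."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g:
                genes.append(g)
    return GeneList(name or Path(path).stem, genes)


_LAYER_SUFFIXES = {"p": ".p", "fdr": ".fdr"}


def write_score_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    """Write a score matrix to TSV; p/fdr layers go to sibling files.

    The NES layer is written to ``path``; when present, the p layer goes to
    ``path`` with a ``.p`` suffix inserted before the extension, and likewise
    ``.fdr``. Round-trips losslessly at full float precision.
    """
    path = Path(path)
    matrix.to_frame("nes").to_csv(path, sep="\t", float_format="%.17g")
    for layer, suffix in _LAYER_SUFFIXES.items():
        arr = getattr(matrix, layer)
        if arr is not None:
            matrix.to_frame(layer).to_csv(
                _layer_path(path, suffix), sep="\t", float_format="%.17g"
            )


def _layer_path(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix + path.suffix)


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    """Read a score matrix written by :func:`write_score_matrix`."""
    path = Path(path)
    nes = pd.read_csv(path, sep="\t", index_col=0)
    layers: dict[str, np.ndarray | None] = {"p": None, "fdr": None}
    for layer, suffix in _LAYER_SUFFIXES.items():
        lp = _layer_path(path, suffix)
        if lp.exists():
            df = pd.read_csv(lp, sep="\t", index_col=0)
            if df.shape != nes.shape:
                raise ParseError(
                    f"{lp}: {layer} layer shape {df.shape} does not match "
                    f"nes shape {nes.shape}"
                )
            layers[layer] = df.to_numpy()
    return ScoreMatrix(
        list(nes.index.astype(str)),
        list(nes.columns.astype(str)),
        nes.to_numpy(),
        p=layers["p"],
        fdr=layers["fdr"],
    )


def export_triplet_network(triplets, path: str | Path, format: str = "sif") -> None:
    """Export drug-pathway-cancer triplets as a SIF or edge-table TSV.

    SIF emits two edge families per triplet: ``drug reverses pathway`` and
    ``pathway dysregulated_in cancer``. The edge table carries one row per
    triplet with PS, CNS, PNS and the prognostic log-rank p as columns.
    """
    fmt = format.lower()
    if fmt not in {"sif", "edge-table", "tsv"}:
        raise ValidationError(f"unknown network format {format!r}")
    path = Path(path)
    if fmt == "sif":
        seen: set[tuple[str, str, str]] = set()
        with open(path, "w", encoding="utf-8") as fh:
            for t in triplets:
                for edge in (
                    (t.drug, "reverses", t.pathway),
                    (t.pathway, "dysregulated_in", t.cancer),
                ):
                    if edge not in seen:
                        seen.add(edge)
                        fh.write("\t".join(edge) + "\n")
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
            writer.writerow(
                ["drug", "pathway", "cancer", "ps", "cns", "pns", "logrank_p"]
            )
            for t in triplets:
                writer.writerow(
                    [
                        t.drug,
                        t.pathway,
                        t.cancer,
                        f"{t.ps:.10g}",
                        f"{t.cns:.10g}",
                        f"{t.pns:.10g}",
                        f"{t.logrank_p:.6g}",
                    ]
                )
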