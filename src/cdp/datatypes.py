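"""Core in-memory containers shared by all pipeline stages.

Everything is a light wrapper around numpy arrays / pandas objects with the
invariants each stage relies on checked at construction time: expression
matrices know their case/control labels, score matrices carry optional
empirical-p and FDR layers, clinical tables are pre-validated survival data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with per-sample condition labels.

    ``condition`` holds one of ``{"case", "control"}`` per sample (tumor vs
    normal for cohorts, treated vs control for perturbation instances).
    Values are unitless normalized expression (FPKM-like).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValidationError(f"duplicated gene ids: {dupes[:5]}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.condition) != len(self.sample_ids):
            raise ValidationError("one condition label required per sample")
        bad = set(self.condition) - {CASE, CONTROL}
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("need at least 1 case and 1 control sample")

    @property
    def n_case(self) -> int:
        return self.condition.count(CASE)

    @property
    def n_control(self) -> int:
        return self.condition.count(CONTROL)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([c == CASE for c in self.condition])

    def case_values(self) -> np.ndarray:
        return self.values[:, self.case_mask]

    def control_values(self) -> np.ndarray:
        return self.values[:, ~self.case_mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (KEGG-pathway-like), as loaded from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                # de-duplicate preserving order
                self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)

    def filter_to_measured(
        self, measured_genes: Iterable[str], min_overlap: int = 2
    ) -> tuple["GeneSetCollection", int]:
        """Restrict every set to genes present in ``measured_genes``.

        Sets retaining fewer than ``min_overlap`` measured genes are dropped
        (an enrichment running sum needs at least 2 members to be meaningful).
        Returns the filtered collection and the number of sets dropped.
        Idempotent: filtering a filtered collection drops nothing further.
        """
        measured = set(measured_genes)
        kept: dict[str, list[str]] = {}
        dropped = 0
        for name, genes in self.sets.items():
            overlap = [g for g in genes if g in measured]
            if len(overlap) >= min_overlap:
                kept[name] = overlap
            else:
                dropped += 1
        return (
            GeneSetCollection(
                kept, {n: d for n, d in self.descriptions.items() if n in kept}
            ),
            dropped,
        )


@dataclass
class ClinicalTable:
    """Survival records: per-sample follow-up time (days) and event status.

    ``event`` is 1 when death was observed, 0 when the patient was censored.
    ``dropped_count`` records how many input rows lacked time or status and
    were excluded before analysis.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    dropped_count: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicated sample ids in clinical table")
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValidationError("clinical columns must have equal length")
        if np.any(self.time < 0):
            raise ValidationError("negative survival time")
        if not np.all(np.isin(self.event, (0, 1))):
            bad = sorted(set(self.event) - {0, 1})
            raise ValidationError(f"event status must be 0/1, got {bad}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids if s in idx]
        return ClinicalTable(
            [self.sample_ids[i] for i in rows],
            self.time[rows],
            self.event[rows],
            dropped_count=self.dropped_count,
        )


@dataclass
class ScoreMatrix:
    """NES score matrix (pathways x cancers, or drugs x pathways).

    ``nes`` is required; ``p`` (empirical p-values) and ``fdr`` (BH-adjusted)
    are optional layers with the same shape.
    """

    row_ids: list[str]
    col_ids: list[str]
    nes: np.ndarray
    p: np.ndarray | None = None
    fdr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nes = np.asarray(self.nes, dtype=float)
        shape = (len(self.row_ids), len(self.col_ids))
        if self.nes.shape != shape:
            raise ValidationError(f"nes shape {self.nes.shape} != {shape}")
        for name in ("p", "fdr"):
            layer = getattr(self, name)
            if layer is None:
                continue
            layer = np.asarray(layer, dtype=float)
            setattr(self, name, layer)
            if layer.shape != shape:
                raise ValidationError(f"{name} shape {layer.shape} != {shape}")
            finite = layer[np.isfinite(layer)]
            if np.any((finite < 0) | (finite > 1)):
                raise ValidationError(f"{name} values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nes.shape

    def to_frame(self, layer: str = "nes") -> pd.DataFrame:
        arr = getattr(self, layer)
        if arr is None:
            raise ValidationError(f"matrix has no {layer!r} layer")
        return pd.DataFrame(arr, index=self.row_ids, columns=self.col_ids)

    def value(self, row: str, col: str, layer: str = "nes") -> float:
        arr = getattr(self, layer)
        return float(arr[self.row_ids.index(row), self.col_ids.index(col)])


@dataclass
class GeneList:
    """A flat named list of gene identifiers (e.g., driver genes, drug targets)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = list(dict.fromkeys(self.genes))
        if not self.genes:
            raise ValidationError(f"gene list {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)
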