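"""Discretize a differential-expression table into signed observations.

Input is a three-column CSV (gene symbol, log2 fold-change, adjusted
p-value), typically the output of an upstream differential-expression
analysis contrasting two patient groups.  A gene becomes an over-expression
observation (+) when its log2 fold-change exceeds the up-threshold, or an
under-expression (-) when it falls below the down-threshold, in both cases
requiring the adjusted p-value to beat alpha; everything else is dropped.
Defaults: up > 2, down < -0.5, alpha = 1e-5 (all strict inequalities, all
CLI-exposed).

Observations attach to the graph's gene nodes only (``SYMBOL_gen``); the
match accounting is reported so a user can see how much of the expression
table the regulatory graph covers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .model import ObservationSet, Sign, SignedInteractionGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DiffExprRecord",
    "AttachResult",
    "read_diffexp",
    "discretize",
    "attach_to_graph",
    "DuplicateObservationError",
    "NoObservationError",
]


class DuplicateObservationError(ValueError):
    """A symbol discretizes to conflicting signs."""


class NoObservationError(ValueError):
    """No discretized symbol matches a gene node of the graph."""


@dataclass(frozen=True)
class DiffExprRecord:
    gene: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not self.gene or self.gene != self.gene.strip():
            raise ValueError(f"invalid gene symbol: {self.gene!r}")
        if math.isnan(self.log2fc) or math.isnan(self.padj):
            raise ValueError(f"{self.gene}: missing numeric field")
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"{self.gene}: adjusted p-value {self.padj} outside [0, 1]")


@dataclass
class AttachResult:
    observations: ObservationSet
    matched: list[str]
    unmatched: list[str]


def read_diffexp(path: str | Path) -> list[DiffExprRecord]:
    """Read a gene,log2fc,padj CSV (header optional) into records."""
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :3]
    # header sniffing: drop the first row when its numeric fields don't parse
    first_numeric = pd.to_numeric(df.iloc[0, 1:], errors="coerce")
    if first_numeric.isna().any():
        df = df.iloc[1:]
    records = []
    for gene, fc, padj in df.itertuples(index=False):
        try:
            records.append(DiffExprRecord(str(gene).strip(), float(fc), float(padj)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad record {gene!r}: {exc}") from exc
    return records


def discretize(
    records: Iterable[DiffExprRecord],
    up_threshold: float = 2.0,
    down_threshold: float = -0.5,
    alpha: float = 1e-5,
) -> dict[str, Sign]:
    """Threshold fold-changes and p-values into a symbol -> sign map."""
    if not down_threshold < up_threshold:
        raise ValueError("down_threshold must be below up_threshold")
    signs: dict[str, Sign] = {}
    conflicts: list[str] = []
    for rec in records:
        if rec.padj >= alpha:
            continue
        if rec.log2fc > up_threshold:
            sign = Sign.PLUS
        elif rec.log2fc < down_threshold:
            sign = Sign.MINUS
        else:
            continue
        prior = signs.get(rec.gene)
        if prior is not None and prior is not sign:
            conflicts.append(rec.gene)
        signs[rec.gene] = sign
    if conflicts:
        raise DuplicateObservationError(
            f"conflicting duplicate records for: {sorted(set(conflicts))}"
        )
    return signs


def attach_to_graph(
    signs: Mapping[str, Sign], graph: SignedInteractionGraph
) -> AttachResult:
    """Map discretized symbols onto the graph's ``_gen`` nodes."""
    matched, unmatched = [], []
    entries: dict[str, Sign] = {}
    for symbol in sorted(signs):
        node = f"{symbol}_gen"
        if node in graph:
            entries[node] = signs[symbol]
            matched.append(symbol)
        else:
            unmatched.append(symbol)
    if not entries:
        raise NoObservationError(
            "no discretized gene matches a gene node of the graph; nothing to infer from"
        )
    logger.info("attached %d observations (%d symbols unmatched)", len(matched), len(unmatched))
    return AttachResult(ObservationSet(entries), matched, unmatched)
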