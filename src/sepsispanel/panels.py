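"""Marker gene panels and per-sample gene-set scoring.

Five canonical peripheral-blood panels capture distinct arms of the host
response in sepsis:

* **NDrG** — neutrophil degranulation (activated in sepsis, direction +1)
* **ISGa** — type I interferon signaling (bidirectional, 0)
* **GBPs** — guanylate-binding proteins, type II interferon signaling (bidirectional, 0)
* **HLAd** — MHC class II (suppressed, −1)
* **LYMd** — lymphocyte / dendritic-cell markers (suppressed, −1)

A panel score is the arithmetic mean of the member genes' log2-normalized
expression in a sample; the composite score is NDrG − HLAd, the quantity
used by the survivor-identification rule (low composite → likely survivor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LOG2_NORMALIZED, ExpressionMatrix

logger = logging.getLogger(__name__)

CANONICAL_PANEL_ORDER = ("NDrG", "ISGa", "GBPs", "HLAd", "LYMd")
COMPOSITE = "composite"


class PanelCoverageError(ValueError):
    """No member gene of a panel was found in the expression matrix."""


class ScaleError(ValueError):
    """Scoring was attempted on a matrix not declared log2-normalized."""


@dataclass(frozen=True)
class GenePanel:
    """A named, ordered marker gene set with a sepsis dysregulation direction.

    direction: +1 activated in sepsis, −1 suppressed, 0 bidirectional.
    """

    name: str
    genes: tuple[str, ...]
    direction: int

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r}: gene list must be non-empty")
        upper = tuple(g.upper() for g in self.genes)
        if len(set(upper)) != len(upper):
            raise ValueError(f"panel {self.name!r}: gene symbols must be unique")
        object.__setattr__(self, "genes", upper)
        if self.direction not in (-1, 0, 1):
            raise ValueError(f"panel {self.name!r}: direction must be -1, 0 or +1")


def builtin_panels() -> list[GenePanel]:
    """The five canonical panels, in order NDrG, ISGa, GBPs, HLAd, LYMd."""
    return [
        GenePanel("NDrG", ("S100A12", "CD177", "HP", "ANXA3", "ARG1"), +1),
        GenePanel("ISGa", ("IFI27", "RSAD2", "IFI44L", "ISG15", "IFITM3"), 0),
        GenePanel("GBPs", ("GBP1", "GBP2", "GBP3", "GBP4", "GBP5"), 0),
        GenePanel("HLAd", ("HLA-DRA", "HLA-DRB1", "HLA-DMA", "HLA-DMB", "HLA-DPA1"), -1),
        GenePanel("LYMd", ("CD4", "CD8A", "CD79A", "CD27", "KLRF1", "FCER1A"), -1),
    ]


def panel_directions(panels: Sequence[GenePanel] | None = None) -> dict[str, int]:
    return {p.name: p.direction for p in (panels or builtin_panels())}


def resolve_panel_genes(
    matrix: ExpressionMatrix, panel: GenePanel
) -> tuple[list[int], list[str]]:
    """Row indices of the panel genes present in ``matrix``.

    Matching is exact on uppercased symbols. Returns one warning string per
    absent symbol; raises :class:`PanelCoverageError` when none are found.
    """
    index = {g: i for i, g in enumerate(matrix.gene_symbols)}
    found: list[int] = []
    warnings: list[str] = []
    for gene in panel.genes:
        i = index.get(gene.upper())
        if i is None:
            warnings.append(f"panel {panel.name}: gene {gene} not found in matrix")
        else:
            found.append(i)
    if not found:
        raise PanelCoverageError(
            f"panel {panel.name}: none of its {len(panel.genes)} genes found in matrix"
        )
    return found, warnings


@dataclass
class PanelScores:
    """Per-sample panel scores, the NDrG−HLAd composite, and panel coverage.

    ``values`` is indexed by sample id with one column per panel plus
    ``composite``; ``coverage`` maps panel name → fraction of member genes
    found in the input matrix.
    """

    values: pd.DataFrame
    coverage: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def panel_names(self) -> list[str]:
        return [c for c in self.values.columns if c != COMPOSITE]

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        for name in self.panel_names:
            out[f"coverage_{name}"] = self.coverage.get(name, np.nan)
        out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanelScores":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        cov_cols = [c for c in df.columns if c.startswith("coverage_")]
        coverage = {c[len("coverage_"):]: float(df[c].iloc[0]) for c in cov_cols}
        return cls(values=df.drop(columns=cov_cols), coverage=coverage)


def score_samples(
    matrix: ExpressionMatrix,
    panels: Sequence[GenePanel] | None = None,
    missing_panel: str = "error",
) -> PanelScores:
    """Mean log2 expression of each panel's member genes, per sample.

    The input matrix must be declared log2-normalized (normalize raw counts
    first). Panels with some genes absent are scored over the available
    members, with coverage recorded and a warning per missing symbol.
    ``missing_panel`` controls zero-coverage panels: ``"error"`` raises,
    ``"nan"`` yields a missing score column.
    """
    if matrix.scale != LOG2_NORMALIZED:
        raise ScaleError(
            f"score_samples requires log2_normalized input, got {matrix.scale!r}; "
            "run normalize_log2 on raw counts first"
        )
    if missing_panel not in ("error", "nan"):
        raise ValueError("missing_panel must be 'error' or 'nan'")
    panels = list(panels) if panels is not None else builtin_panels()
    arr = matrix.values.to_numpy()
    cols: dict[str, np.ndarray] = {}
    coverage: dict[str, float] = {}
    warnings: list[str] = []
    for panel in panels:
        try:
            idx, warns = resolve_panel_genes(matrix, panel)
        except PanelCoverageError:
            if missing_panel == "error":
                raise
            cols[panel.name] = np.full(arr.shape[1], np.nan)
            coverage[panel.name] = 0.0
            warnings.append(f"panel {panel.name}: zero coverage, score set to missing")
            continue
        warnings.extend(warns)
        for w in warns:
            logger.warning("%s", w)
        cols[panel.name] = arr[idx].mean(axis=0)
        coverage[panel.name] = len(idx) / len(panel.genes)
    values = pd.DataFrame(cols, index=pd.Index(matrix.sample_ids, name="sample_id"))
    if "NDrG" in values.columns and "HLAd" in values.columns:
        values[COMPOSITE] = values["NDrG"] - values["HLAd"]
    return PanelScores(values=values, coverage=coverage, warnings=warnings)
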