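"""Tissue-dominance analysis of transcript x tissue expression tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneList, GenomeAnnotation
from .enrichment import BootstrapResult, bootstrap_enrichment, register_statistic

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "TissueDominance",
    "read_expression",
    "write_expression",
    "highest_expressed_variant",
    "tissue_dominance",
    "normalize_across_tissues",
    "lung_enrichment",
]

TRANSCRIPT_COL = "transcript_id"
GENE_COL = "gene_symbol"


@dataclass
class ExpressionMatrix:
    """Transcript-level abundances (FPKM-like) with a gene grouping column.

    ``data`` is indexed by transcript id, has a ``gene_symbol`` column, and
    one non-negative float column per tissue.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if GENE_COL not in self.data.columns:
            raise ValueError(f"expression table lacks a {GENE_COL} column")
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate transcript rows: {dup}")
        tissue_df = self.data[self.tissues]
        if len(self.tissues) < 1:
            raise ValueError("expression table has no tissue columns")
        if not all(pd.api.types.is_numeric_dtype(t) for t in tissue_df.dtypes):
            raise ValueError("non-numeric abundance values")
        if (tissue_df.to_numpy() < 0).any():
            raise ValueError("negative abundance values")
        if len(self.data) == 0:
            raise ValueError("expression table has no rows")

    @property
    def tissues(self) -> list[str]:
        return [c for c in self.data.columns if c != GENE_COL]

    def genes(self) -> list[str]:
        return sorted(self.data[GENE_COL].unique())

    def gene_rows(self, gene_symbol: str) -> pd.DataFrame:
        return self.data[self.data[GENE_COL] == gene_symbol]


@dataclass
class TissueDominance:
    """Per-gene top transcript/tissue and the per-list tissue fractions."""

    per_gene: dict  # gene -> (top transcript id, top tissue)
    fractions: dict  # tissue -> fraction of scored genes
    n_scored: int

    def __post_init__(self) -> None:
        if self.n_scored > 0:
            s = sum(self.fractions.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"dominance fractions sum to {s}")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with transcript_id, gene_symbol, then one column per
    tissue."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[0] == 0:
        raise ValueError(f"{path}: expression table has no data rows")
    if df.columns[0] != TRANSCRIPT_COL or GENE_COL not in df.columns:
        raise ValueError(
            f"{path}: expected columns {TRANSCRIPT_COL}, {GENE_COL}, tissues..."
        )
    df = df.set_index(TRANSCRIPT_COL)
    return ExpressionMatrix(data=df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label=TRANSCRIPT_COL)


def highest_expressed_variant(
    gene_symbol: str, matrix: ExpressionMatrix, mode: str = "total"
) -> str | None:
    """Transcript with the largest abundance for a gene, or None when the
    gene has no positive expression.

    ``total`` (default) ranks by summed abundance across tissues;
    ``max_any`` ranks by the single largest tissue value.  Ties break to
    the lexicographically smallest transcript id.
    """
    rows = matrix.gene_rows(gene_symbol)
    if rows.empty:
        return None
    vals = rows[matrix.tissues]
    score = vals.sum(axis=1) if mode == "total" else vals.max(axis=1)
    if float(score.max()) <= 0.0:
        return None
    best = score[score == score.max()].index.min()
    if (score == score.max()).sum() > 1:
        log.info("tie for top transcript of %s; chose %s", gene_symbol, best)
    return best


def dominant_tissues(
    matrix: ExpressionMatrix, mode: str = "total"
) -> dict[str, tuple[str, str] | None]:
    """Top transcript and its argmax tissue for every gene (None when the
    gene is silent everywhere)."""
    out: dict[str, tuple[str, str] | None] = {}
    tissues = matrix.tissues
    for gene, rows in matrix.data.groupby(GENE_COL, sort=False):
        vals = rows[tissues]
        score = vals.sum(axis=1) if mode == "total" else vals.max(axis=1)
        if float(score.max()) <= 0.0:
            out[gene] = None
            continue
        top = score[score == score.max()].index.min()
        row = vals.loc[top]
        tissue = row[row == row.max()].index[0]
        out[gene] = (top, tissue)
    return out


def tissue_dominance(
    gene_list: GeneList | Sequence[str],
    matrix: ExpressionMatrix,
    mode: str = "total",
) -> TissueDominance:
    """Fraction of list genes whose top transcript is most expressed in
    each tissue.  Genes silent in every tissue are excluded from the
    denominator."""
    dom = dominant_tissues(matrix, mode=mode)
    per_gene: dict = {}
    counts: dict[str, int] = {t: 0 for t in matrix.tissues}
    scored = 0
    for s in gene_list:
        info = dom.get(s)
        if info is None:
            continue
        per_gene[s] = info
        counts[info[1]] += 1
        scored += 1
    fractions = {t: (c / scored if scored else 0.0) for t, c in counts.items()}
    return TissueDominance(per_gene=per_gene, fractions=fractions, n_scored=scored)


def normalize_across_tissues(
    gene_symbol: str, matrix: ExpressionMatrix
) -> pd.DataFrame:
    """Each transcript row of a gene rescaled to sum to one across tissues;
    zero-total rows are dropped with a warning."""
    rows = matrix.gene_rows(gene_symbol)[matrix.tissues]
    totals = rows.sum(axis=1)
    zero = totals[totals <= 0.0].index.tolist()
    if zero:
        log.warning("dropping zero-total transcripts of %s: %s", gene_symbol, zero)
        rows = rows.drop(index=zero)
        totals = totals.drop(index=zero)
    return rows.div(totals, axis=0)


@register_statistic("tissue_fraction")
def _tissue_fraction_factory(
    matrix: ExpressionMatrix,
    tissue: str,
    mode: str = "total",
    dominance_cache: dict | None = None,
    **_,
):
    if tissue not in matrix.tissues:
        raise ValueError(f"tissue {tissue!r} not in expression table")
    dom = dominance_cache if dominance_cache is not None else dominant_tissues(matrix, mode=mode)

    def stat(symbols: Sequence[str]) -> float:
        hits = scored = 0
        for s in symbols:
            info = dom.get(s)
            if info is None:
                continue
            scored += 1
            hits += info[1] == tissue
        return hits / scored if scored else 0.0

    return stat


def lung_enrichment(
    gene_list: GeneList | Sequence[str],
    pool: GeneList | Sequence[str],
    matrix: ExpressionMatrix,
    annotation: GenomeAnnotation,
    *,
    tissue: str = "lung",
    n_lists: int = 1000,
    direction: str = "greater",
    tolerance: float = 0.10,
    mode: str = "total",
    rng: np.random.Generator | int | None = None,
    exclude_list_from_pool: bool = True,
) -> BootstrapResult:
    """Length-matched bootstrap of the fraction of genes whose top variant
    is dominant in the named tissue."""
    return bootstrap_enrichment(
        gene_list,
        pool,
        annotation,
        "tissue_fraction",
        n_lists=n_lists,
        direction=direction,
        tolerance=tolerance,
        rng=rng,
        exclude_list_from_pool=exclude_list_from_pool,
        statistic_context={
            "matrix": matrix,
            "tissue": tissue,
            "mode": mode,
            "dominance_cache": dominant_tissues(matrix, mode=mode),
        },
    )
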