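"""Per-gene presence/length statistics over a species panel.

Three statistics summarise how a gene fares in avian annotation relative to
non-avian vertebrates:

* presence index (PI): fraction of the avian panel in which the gene is
  annotated (0 = missing everywhere, 1 = annotated in all panel genomes).
  The denominator is the *declared* panel size, not the number of species
  that happen to carry annotation.
* length index (LI): mean annotated non-avian transcript length divided by
  mean annotated avian transcript length. Avian lengths sit in the
  denominator, so truncated avian gene models push LI above 1. LI is missing
  (not 0, not inf) when no avian genome annotates the gene.
* presence score: -1/0/+1 coding of occurrence in a (better-annotated,
  less-annotated) genome pair: -1 = only in the better-annotated genome,
  0 = in both, +1 = only in the less-annotated one.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneRecord, OrthoMatrix
from .errors import UndefinedValueError


def presence_index(
    matrix: OrthoMatrix,
    gene: str,
    group: Sequence[str] | None = None,
    denominator: int | None = None,
) -> float:
    """Fraction of the group's genomes (default: the avian panel) annotating ``gene``."""
    group = list(group) if group is not None else list(matrix.panel.avian)
    if not group:
        raise ValueError("presence_index over an empty species group")
    if gene not in matrix.presence.index:
        raise KeyError(gene)
    denom = denominator if denominator is not None else len(group)
    return float(matrix.presence.loc[gene, group].sum()) / denom


def presence_index_track(
    matrix: OrthoMatrix,
    group: Sequence[str] | None = None,
    denominator: int | None = None,
) -> pd.Series:
    """Vectorised :func:`presence_index` for every gene (Series indexed by symbol)."""
    group = list(group) if group is not None else list(matrix.panel.avian)
    if not group:
        raise ValueError("presence_index over an empty species group")
    denom = denominator if denominator is not None else len(group)
    return matrix.presence[group].sum(axis=1) / denom


def length_index(
    matrix: OrthoMatrix,
    gene: str,
    avian: Sequence[str] | None = None,
    non_avian: Sequence[str] | None = None,
) -> float:
    """Non-avian over avian mean transcript length for one gene.

    Means run over the species that annotate the gene in each group (no
    zero-imputation). NaN when the avian mean is undefined;
    :class:`UndefinedValueError` when the non-avian mean is.
    """
    series = length_index_track(matrix, avian, non_avian, _strict_genes=[gene])
    return float(series[gene])


def length_index_track(
    matrix: OrthoMatrix,
    avian: Sequence[str] | None = None,
    non_avian: Sequence[str] | None = None,
    _strict_genes: Sequence[str] | None = None,
) -> pd.Series:
    """LI for every gene; NaN where no avian genome annotates the gene.

    ``non_avian`` defaults to the reference genome plus the panel's non-avian
    species (the six-genome convention: the two reference-grade genomes and
    the four reptile outgroups).
    """
    avian = list(avian) if avian is not None else list(matrix.panel.avian)
    if non_avian is None:
        non_avian = [matrix.panel.reference, *matrix.panel.non_avian]
    non_avian = list(non_avian)
    non_avian_mean = matrix.lengths[non_avian].mean(axis=1)
    avian_mean = matrix.lengths[avian].mean(axis=1)
    if _strict_genes:
        bad = [g for g in _strict_genes if np.isnan(non_avian_mean[g])]
        if bad:
            raise UndefinedValueError(
                f"length index undefined (no non-avian annotation) for {', '.join(bad)}"
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        li = non_avian_mean / avian_mean
    return li.where(non_avian_mean.notna())


def presence_score(
    best_annotated: Iterable[str] | Iterable[GeneRecord],
    less_annotated: Iterable[str] | Iterable[GeneRecord],
    gene: str,
) -> int:
    """-1/0/+1 presence coding of ``gene`` in a two-genome comparison."""
    best = _symbols(best_annotated)
    less = _symbols(less_annotated)
    gene = gene.upper()
    in_best, in_less = gene in best, gene in less
    if in_best and in_less:
        return 0
    if in_best:
        return -1
    if in_less:
        return 1
    raise UndefinedValueError(f"{gene} present in neither catalog; excluded from the track")


def presence_score_track(
    best_annotated: Iterable[str] | Iterable[GeneRecord],
    less_annotated: Iterable[str] | Iterable[GeneRecord],
    genes: Sequence[str],
) -> pd.Series:
    """Presence score per gene; genes in neither catalog are NaN (excluded)."""
    best = _symbols(best_annotated)
    less = _symbols(less_annotated)
    values = []
    for g in genes:
        gu = g.upper()
        in_best, in_less = gu in best, gu in less
        if in_best and in_less:
            values.append(0.0)
        elif in_best:
            values.append(-1.0)
        elif in_less:
            values.append(1.0)
        else:
            values.append(float("nan"))
    return pd.Series(values, index=list(genes))


def index_table(
    matrix: OrthoMatrix,
    denominator: int | None = None,
    avian: Sequence[str] | None = None,
    non_avian: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene PI and LI table (columns: symbol, presence_index, length_index)."""
    pi = presence_index_track(matrix, avian, denominator)
    li = length_index_track(matrix, avian, non_avian)
    return pd.DataFrame(
        {"symbol": matrix.genes, "presence_index": pi.values, "length_index": li.values}
    )


def _symbols(catalog) -> set[str]:
    out = set()
    for item in catalog:
        out.add(item.symbol if isinstance(item, GeneRecord) else str(item).upper())
    return out
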