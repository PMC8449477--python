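"""Pairwise protein divergence and genome-wide normalization (nPD).

For each orthologous protein pair, percent divergence is ``100 - %identity``
of an optimal affine-gap global alignment; identity counts identical columns
over the *full* alignment length, gap columns included (the EMBOSS
convention). Pairs below 30% identity are flagged and excluded from
normalization, since global %identity loses meaning near the twilight zone.
The normalized protein divergence (nPD) of a gene is its divergence divided
by the mean divergence of all included genes for that species pair, so nPD
averages to 1 within every pair and regional excursions above/below 1 mark
faster/slower-than-genome-average protein evolution.

Alignment defaults are BLOSUM62 with gap open 12 and gap extend 2 (the
protein defaults of EMBOSS Stretcher, which this module's scores follow): a
gap of length L costs ``12 + 2*(L-1)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import UndefinedValueError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Identity (%) below which a comparison is excluded from normalization.
MIN_IDENTITY = 30.0


@dataclass(frozen=True)
class AlignParams:
    """Substitution matrix and affine gap penalties (positive costs)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 12.0
    gap_extend: float = 2.0

    def as_metadata(self) -> dict:
        return {"matrix": self.matrix, "gap_open": self.gap_open, "gap_extend": self.gap_extend}


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float

    @property
    def divergence_percent(self) -> float:
        return 100.0 - self.identity_percent


@dataclass
class DivergenceRecord:
    """Divergence of one gene for one (unordered) species pair."""

    symbol: str
    pair: tuple[str, str]
    divergence_percent: float
    included: bool
    npd: float | None = None


@dataclass
class PairSet:
    """Class-tagged species pairs: avian//avian, avian//non-avian, non-avian//non-avian."""

    pairs: list[tuple[str, str, str]]

    def by_class(self, tag: str) -> list[tuple[str, str]]:
        return [(a, b) for a, b, t in self.pairs if t == tag]

    @property
    def counts(self) -> dict[str, int]:
        out = {"avian//avian": 0, "avian//non_avian": 0, "non_avian//non_avian": 0}
        for *_, t in self.pairs:
            out[t] += 1
        return out


def _build_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_global(a: str, b: str, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences.

    Among co-optimal alignments one is returned deterministically; identity
    is identical columns / alignment length (gap columns count in the
    denominator) x 100.
    """
    params = params or AlignParams()
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = sorted(set(seq.upper()) - AA_ALPHABET)
        if bad:
            raise ValueError(f"sequence {name} has non-amino-acid symbol(s): {', '.join(bad)}")
    a, b = a.upper(), b.upper()
    aln = _build_aligner(params).align(a, b)[0]
    row_a, row_b = aln[0], aln[1]
    ident = sum(x == y for x, y in zip(row_a, row_b))
    return AlignmentResult(
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(aln.score),
        identity_percent=100.0 * ident / len(row_a),
    )


def pairwise_divergence(
    catalogs: Mapping[str, Mapping[str, str]],
    pair: tuple[str, str],
    params: AlignParams | None = None,
    min_identity: float = MIN_IDENTITY,
) -> list[DivergenceRecord]:
    """Align every gene shared by the two species' protein sets.

    ``catalogs`` maps species -> {symbol: protein}. One record per shared
    gene (symbol order); comparisons with identity below ``min_identity`` are
    kept but flagged ``included=False``.
    """
    sp_a, sp_b = pair
    shared = sorted(set(catalogs[sp_a]) & set(catalogs[sp_b]))
    shared = [g for g in shared if catalogs[sp_a][g] and catalogs[sp_b][g]]
    if not shared:
        raise ValueError(f"no shared genes with proteins for pair {pair}")
    key = tuple(sorted(pair))
    out = []
    for gene in shared:
        res = align_global(catalogs[sp_a][gene], catalogs[sp_b][gene], params)
        out.append(
            DivergenceRecord(
                symbol=gene,
                pair=key,
                divergence_percent=res.divergence_percent,
                included=res.identity_percent >= min_identity,
            )
        )
    return out


def divergence_from_values(
    symbols: Sequence[str],
    values: Sequence[float],
    pair: tuple[str, str],
    min_identity: float = MIN_IDENTITY,
) -> list[DivergenceRecord]:
    """Build records from precomputed divergence percentages (NaN = no data).

    The identity filter translates to excluding divergences above
    ``100 - min_identity``.
    """
    key = tuple(sorted(pair))
    out = []
    for sym, val in zip(symbols, values):
        if val is None or (isinstance(val, float) and np.isnan(val)):
            continue
        out.append(
            DivergenceRecord(
                symbol=sym,
                pair=key,
                divergence_percent=float(val),
                included=float(val) <= 100.0 - min_identity,
            )
        )
    return out


def normalize_npd(records: Sequence[DivergenceRecord]) -> list[DivergenceRecord]:
    """Divide each included divergence by the pair's mean included divergence.

    The returned records have ``npd`` set for included genes (None for the
    excluded); by construction the mean nPD over included genes is 1.
    """
    included = [r.divergence_percent for r in records if r.included]
    if not included:
        raise UndefinedValueError("all records excluded; nPD normalization undefined")
    mean = float(np.mean(included))
    if mean == 0.0:
        # identical proteomes: every divergence is 0, define nPD = 1 uniformly
        return [replace(r, npd=1.0 if r.included else None) for r in records]
    return [
        replace(r, npd=(r.divergence_percent / mean) if r.included else None) for r in records
    ]


def enumerate_pairs(avian: Sequence[str], non_avian: Sequence[str]) -> PairSet:
    """All species pairs, class-tagged, in deterministic listing order.

    Within-avian pairs first, then avian x non-avian, then within-non-avian
    (the ordering used to number rows of the divergence heatmap: with 8 avian
    and 4 non-avian genomes, rows 1-28 / 29-60 / 61-66).
    """
    pairs: list[tuple[str, str, str]] = []
    pairs += [(a, b, "avian//avian") for a, b in itertools.combinations(avian, 2)]
    pairs += [(a, b, "avian//non_avian") for a in avian for b in non_avian]
    pairs += [(a, b, "non_avian//non_avian") for a, b in itertools.combinations(non_avian, 2)]
    return PairSet(pairs)
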