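"""Per-transcript GC content and per-protein amino-acid usage.

GARP% is the residue fraction of Gly/Ala/Arg/Pro — amino acids whose codons
start with two G/C bases — and FYMINK% the fraction of Phe/Tyr/Met/Ile/Asn/Lys,
whose codons start with two A/U bases. Regionally elevated transcript GC
therefore drags protein composition toward GARP and away from FYMINK, which
is what makes these two percentages useful read-outs of GC-biased gene
conversion acting on coding sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import UndefinedValueError

GARP = frozenset("GARP")
FYMINK = frozenset("FYMINK")
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def gc_content(seq: str) -> float:
    """GC% of a nucleotide sequence: 100*(G+C)/(A+C+G+T), case-insensitive.

    Ambiguity codes (N etc.) and U/T spelling differences are handled by
    excluding everything outside A/C/G/T from both numerator and denominator
    (U counts as T). An empty or all-ambiguous sequence has no defined GC%
    and raises :class:`UndefinedValueError` so callers record it as missing.
    """
    s = seq.upper().replace("U", "T")
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedValueError("GC% undefined for empty/all-ambiguous sequence")
    return 100.0 * gc / (gc + at)


@dataclass
class Composition:
    """Amino-acid usage of one protein (fractions in percent of residues)."""

    aa_fractions: dict[str, float]
    garp_percent: float
    fymink_percent: float
    garp_count: int
    length: int


def aa_usage(protein: str) -> Composition:
    """Residue-usage percentages, GARP%/FYMINK% and the absolute GARP count.

    Stop symbols (``*``) are stripped; ``X`` placeholders are skipped with a
    warning; any other non-canonical letter is an error naming the offenders.
    """
    s = protein.upper().replace("*", "")
    if "X" in s:
        warnings.warn("skipping X residues in amino-acid usage", stacklevel=2)
        s = s.replace("X", "")
    bad = sorted(set(s) - CANONICAL_AA)
    if bad:
        raise ValueError(f"non-canonical amino-acid letter(s): {', '.join(bad)}")
    if not s:
        raise UndefinedValueError("amino-acid usage undefined for empty protein")
    n = len(s)
    fractions = {aa: 100.0 * s.count(aa) / n for aa in sorted(CANONICAL_AA)}
    garp_count = sum(s.count(aa) for aa in GARP)
    return Composition(
        aa_fractions=fractions,
        garp_percent=sum(fractions[aa] for aa in sorted(GARP)),
        fymink_percent=sum(fractions[aa] for aa in sorted(FYMINK)),
        garp_count=garp_count,
        length=n,
    )


def composition_table(records) -> pd.DataFrame:
    """Per-gene composition for a list of :class:`~genescape.catalog.GeneRecord`.

    GC% is computed from the transcript sequence when available, otherwise the
    catalog's precomputed ``gc_percent`` is used; protein statistics need the
    protein sequence. Undefined values are recorded as NaN.
    """
    rows = []
    for r in records:
        gc = garp = fymink = float("nan")
        count: float = float("nan")
        if r.transcript_seq is not None:
            try:
                gc = gc_content(r.transcript_seq)
            except UndefinedValueError:
                pass
        elif r.gc_percent is not None:
            gc = r.gc_percent
        if r.protein_seq is not None:
            try:
                comp = aa_usage(r.protein_seq)
            except UndefinedValueError:
                pass
            else:
                garp, fymink, count = comp.garp_percent, comp.fymink_percent, comp.garp_count
        rows.append(
            {
                "species": r.species,
                "symbol": r.symbol,
                "gc_percent": gc,
                "garp_percent": garp,
                "fymink_percent": fymink,
                "garp_count": count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "symbol", "gc_percent", "garp_percent", "fymink_percent", "garp_count"],
    )
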