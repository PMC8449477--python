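"""Gene-catalog data model and I/O.

A *catalog* is one row per (species, gene): symbol, chromosome, position,
transcript id/length, and optionally the transcript/protein sequence and a
precomputed transcript GC%. Catalogs for a species panel are assembled into
an :class:`OrthoMatrix` (gene x species presence and transcript lengths) and
laid out along a reference genome with :func:`order_by_reference`.

Conventions
-----------
* Catalog files are UTF-8 TSV with a fixed header; sequences travel in FASTA
  files whose identifiers are ``species|SYMBOL``.
* Gene symbols are matched exactly, case-insensitively (stored uppercased).
  LOC-style aliases can be folded in through a two-column alias TSV.
* ``PU`` is the reserved chromosome label for annotated-but-unplaced genes;
  such records carry no position. Positions are 0-based internally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AmbiguityError, CatalogFormatError, ConfigError

log = logging.getLogger(__name__)

#: Reserved chromosome label for "position unknown".
PU = "PU"

CATALOG_COLUMNS = [
    "species",
    "symbol",
    "chromosome",
    "position",
    "transcript_id",
    "transcript_length",
]
OPTIONAL_COLUMNS = ["gc_percent"]


@dataclass
class GeneRecord:
    """One gene in one species.

    ``position`` is present iff ``chromosome`` is not ``"PU"``;
    ``transcript_length`` is absent when the gene is not annotated with a
    transcript; when both the length and the sequence are present they must
    agree.
    """

    species: str
    symbol: str
    chromosome: str
    position: int | None = None
    transcript_id: str = ""
    transcript_length: int | None = None
    transcript_seq: str | None = None
    protein_seq: str | None = None
    gc_percent: float | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise CatalogFormatError("gene symbol must be non-empty")
        self.symbol = self.symbol.upper()
        if self.chromosome == PU:
            if self.position is not None:
                raise CatalogFormatError(
                    f"{self.species}|{self.symbol}: PU record cannot carry a position"
                )
        else:
            if self.position is None:
                raise CatalogFormatError(
                    f"{self.species}|{self.symbol}: placed record needs a position"
                )
            if self.position < 0:
                raise CatalogFormatError(
                    f"{self.species}|{self.symbol}: negative position"
                )
        if self.transcript_length is not None and self.transcript_length <= 0:
            raise CatalogFormatError(
                f"{self.species}|{self.symbol}: transcript_length must be positive"
            )
        if (
            self.transcript_length is not None
            and self.transcript_seq is not None
            and len(self.transcript_seq) != self.transcript_length
        ):
            raise CatalogFormatError(
                f"{self.species}|{self.symbol}: transcript_length "
                f"{self.transcript_length} != sequence length {len(self.transcript_seq)}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.symbol)


@dataclass(frozen=True)
class SpeciesPanel:
    """Species grouping: one reference genome, non-avian outgroups, avians.

    The groups are disjoint; ``reference`` is the genome whose gene order
    anchors the landscapes (the non-avian *length* group conventionally
    includes it, see :func:`genescape.indices.length_index_track`).
    """

    reference: str
    avian: tuple[str, ...]
    non_avian: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = [{self.reference}, set(self.avian), set(self.non_avian)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ConfigError("species panel groups must be disjoint")
        if total == 0:
            raise ConfigError("species panel is empty")

    @property
    def all_species(self) -> tuple[str, ...]:
        return (self.reference, *self.non_avian, *self.avian)

    def group_of(self, species: str) -> str:
        if species == self.reference:
            return "reference"
        if species in self.avian:
            return "avian"
        if species in self.non_avian:
            return "non_avian"
        raise KeyError(species)


@dataclass
class OrthoMatrix:
    """Gene x species presence/length tables over a species panel.

    ``presence`` is True exactly where ``lengths`` is non-missing: a catalog
    record without an annotated transcript length does not count as presence.
    """

    genes: list[str]
    panel: SpeciesPanel
    presence: pd.DataFrame
    lengths: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.presence.index) != self.genes or list(self.lengths.index) != self.genes:
            raise ConfigError("presence/lengths index must equal the gene list")
        if (self.presence & self.lengths.isna()).any().any():
            raise ConfigError("presence true where transcript length is missing")

    def subset(self, genes: Sequence[str]) -> "OrthoMatrix":
        genes = list(genes)
        return OrthoMatrix(
            genes, self.panel, self.presence.loc[genes], self.lengths.loc[genes]
        )


@dataclass
class ReferenceOrder:
    """Dense 0-based gene ranks along a reference genome.

    Placed genes come first, sorted by (karyotype chromosome order, position);
    unplaced (``PU``) genes follow in symbol order, mirroring how landscapes
    draw the PU block after the chromosomes.
    """

    reference_species: str
    symbols: list[str]
    chromosomes: list[str]
    positions: list[int | None]
    unplaced: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ranks: dict[str, int] = {s: i for i, s in enumerate(self.symbols)}
        if len(self.ranks) != len(self.symbols):
            raise ConfigError("duplicate symbols in reference order")

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def chromosome_bounds(self) -> list[tuple[str, int, int]]:
        """Half-open rank intervals per chromosome block (PU last)."""
        bounds: list[tuple[str, int, int]] = []
        start = 0
        for i in range(1, len(self.chromosomes) + 1):
            if i == len(self.chromosomes) or self.chromosomes[i] != self.chromosomes[start]:
                bounds.append((self.chromosomes[start], start, i))
                start = i
        return bounds


def natural_chrom_key(label: str) -> tuple:
    """Sort chromosome labels numerically where possible; PU always last."""
    if label == PU:
        return (2, 0, "")
    m = re.search(r"(\d+)$", label)
    if m:
        return (0, int(m.group(1)), label[: m.start()])
    return (1, 0, label)


def _parse_int(value: str, column: str, lineno: int) -> int | None:
    if value == "" or value is None:
        return None
    try:
        return int(float(value))
    except ValueError as exc:
        raise CatalogFormatError(f"line {lineno}: bad {column} value {value!r}") from exc


def read_catalog(
    path: str | Path,
    transcript_fasta: str | Path | None = None,
    protein_fasta: str | Path | None = None,
    alias_table: str | Path | None = None,
    dedup: str | None = None,
) -> list[GeneRecord]:
    """Read a gene-catalog TSV, optionally joining FASTA sequences.

    FASTA entries are matched on a ``species|SYMBOL`` identifier. ``alias_table``
    is a two-column TSV mapping alternative symbols (e.g. LOC numbers) onto
    canonical ones, applied before matching. Duplicate (species, symbol) rows
    with conflicting transcript lengths raise :class:`AmbiguityError` unless a
    ``dedup`` policy (``"longest"`` or ``"first"``) is given.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    aliases: dict[str, str] = {}
    if alias_table is not None:
        adf = pd.read_csv(alias_table, sep="\t", dtype=str, header=None)
        aliases = {a.upper(): b.upper() for a, b in zip(adf[0], adf[1])}

    tseqs = _index_fasta(transcript_fasta)
    pseqs = _index_fasta(protein_fasta)

    records: list[GeneRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        symbol = row.symbol.upper()
        symbol = aliases.get(symbol, symbol)
        key = f"{row.species}|{symbol}"
        gc = None
        if "gc_percent" in df.columns and getattr(row, "gc_percent", "") != "":
            gc = float(row.gc_percent)
        records.append(
            GeneRecord(
                species=row.species,
                symbol=symbol,
                chromosome=row.chromosome,
                position=_parse_int(row.position, "position", i),
                transcript_id=row.transcript_id,
                transcript_length=_parse_int(row.transcript_length, "transcript_length", i),
                transcript_seq=tseqs.get(key),
                protein_seq=pseqs.get(key),
                gc_percent=gc,
            )
        )
    if dedup is not None:
        records = dedup_records(records, dedup)
    else:
        _check_ambiguous(records)
    return records


def _index_fasta(path: str | Path | None) -> dict[str, str]:
    if path is None:
        return {}
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        species, _, symbol = rec.id.partition("|")
        out[f"{species}|{symbol.upper()}"] = str(rec.seq)
    return out


def _check_ambiguous(records: Iterable[GeneRecord]) -> None:
    seen: dict[tuple[str, str], int | None] = {}
    for rec in records:
        if rec.key in seen and seen[rec.key] != rec.transcript_length:
            raise AmbiguityError(
                f"duplicate entry {rec.key} with conflicting transcript lengths "
                f"({seen[rec.key]} vs {rec.transcript_length}); set a dedup policy"
            )
        seen[rec.key] = rec.transcript_length


def dedup_records(records: Iterable[GeneRecord], policy: str = "longest") -> list[GeneRecord]:
    """Collapse duplicate (species, symbol) entries.

    ``"longest"`` keeps the longest annotated transcript (the usual surrogate
    when one representative isoform per gene is wanted); ``"first"`` keeps the
    first occurrence.
    """
    if policy not in {"longest", "first"}:
        raise ConfigError(f"unknown dedup policy {policy!r}")
    kept: dict[tuple[str, str], GeneRecord] = {}
    for rec in records:
        prev = kept.get(rec.key)
        if prev is None:
            kept[rec.key] = rec
        elif policy == "longest" and (prev.transcript_length or 0) < (rec.transcript_length or 0):
            kept[rec.key] = rec
    return list(kept.values())


def write_catalog(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write records as a catalog TSV (sequences are written separately)."""
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species,
                "symbol": r.symbol,
                "chromosome": r.chromosome,
                "position": "" if r.position is None else r.position,
                "transcript_id": r.transcript_id,
                "transcript_length": "" if r.transcript_length is None else r.transcript_length,
                "gc_percent": "" if r.gc_percent is None else repr(r.gc_percent),
            }
        )
    pd.DataFrame(rows, columns=CATALOG_COLUMNS + OPTIONAL_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_fasta(records: Sequence[GeneRecord], path: str | Path, kind: str = "transcript") -> int:
    """Write ``species|SYMBOL`` FASTA for records carrying the requested sequence."""
    attr = {"transcript": "transcript_seq", "protein": "protein_seq"}[kind]
    out = [
        SeqRecord(Seq(getattr(r, attr)), id=f"{r.species}|{r.symbol}", description="")
        for r in records
        if getattr(r, attr) is not None
    ]
    return SeqIO.write(out, str(path), "fasta")


def build_ortho_matrix(
    records: Sequence[GeneRecord],
    panel: SpeciesPanel,
    dedup: str = "longest",
    restrict_common: bool = True,
) -> OrthoMatrix:
    """Assemble the gene x species presence/length matrix.

    With ``restrict_common`` (the default) the gene list is restricted to the
    *common vertebrate set*: genes annotated in the reference genome and in at
    least one non-avian species. This is the inclusion rule under which genes
    absent from every avian genome are meaningfully "missing" rather than
    simply unobservable.
    """
    if not panel.all_species:
        raise ConfigError("empty species panel")
    records = dedup_records(records, dedup)
    records = [r for r in records if r.species in panel.all_species]

    genes = sorted({r.symbol for r in records})
    annotated = [r for r in records if r.transcript_length is not None]
    if annotated:
        df = pd.DataFrame(
            {
                "symbol": [r.symbol for r in annotated],
                "species": [r.species for r in annotated],
                "length": [float(r.transcript_length) for r in annotated],
            }
        )
        lengths = df.pivot_table(
            index="symbol", columns="species", values="length", aggfunc="first"
        ).reindex(index=genes, columns=list(panel.all_species))
    else:
        lengths = pd.DataFrame(
            float("nan"), index=genes, columns=list(panel.all_species), dtype=float
        )
    lengths.index.name = None
    lengths.columns.name = None
    presence = lengths.notna()

    if restrict_common:
        non_avian_cols = list(panel.non_avian)
        keep = presence[panel.reference]
        if non_avian_cols:
            keep = keep & presence[non_avian_cols].any(axis=1)
        genes = [g for g in genes if keep[g]]
        presence = presence.loc[genes]
        lengths = lengths.loc[genes]
    return OrthoMatrix(genes, panel, presence, lengths)


def order_by_reference(
    matrix: OrthoMatrix,
    reference_catalog: Sequence[GeneRecord],
    karyotype: Sequence[str] | None = None,
) -> ReferenceOrder:
    """Rank the matrix genes along the reference genome.

    Genes absent from the reference catalog are dropped (a chicken-ordered
    landscape, e.g., excludes genes not annotated in chicken). Placed genes
    sort by (karyotype order, position, symbol); PU genes are appended in
    symbol order. Identical (chromosome, position) pairs tie-break by symbol
    with a logged warning.
    """
    wanted = set(matrix.genes)
    by_symbol: dict[str, GeneRecord] = {}
    ref_species = None
    for rec in reference_catalog:
        if rec.symbol in wanted and rec.symbol not in by_symbol:
            by_symbol[rec.symbol] = rec
            ref_species = rec.species
    if not by_symbol:
        raise ConfigError("reference catalog covers no gene of the matrix")

    if karyotype is not None:
        karyo_rank = {c: (0, i, "") for i, c in enumerate(karyotype)}
        chrom_key = lambda c: karyo_rank.get(c, (1,) + natural_chrom_key(c)[1:])
    else:
        chrom_key = natural_chrom_key

    placed = [r for r in by_symbol.values() if r.chromosome != PU]
    unplaced = sorted(r.symbol for r in by_symbol.values() if r.chromosome == PU)

    seen_pos: set[tuple[str, int]] = set()
    for r in placed:
        loc = (r.chromosome, r.position)
        if loc in seen_pos:
            log.warning("tie at %s:%s broken by symbol order", r.chromosome, r.position)
        seen_pos.add(loc)

    placed.sort(key=lambda r: (chrom_key(r.chromosome), r.position, r.symbol))
    symbols = [r.symbol for r in placed] + unplaced
    chroms = [r.chromosome for r in placed] + [PU] * len(unplaced)
    positions: list[int | None] = [r.position for r in placed] + [None] * len(unplaced)
    return ReferenceOrder(
        reference_species=ref_species or matrix.panel.reference,
        symbols=symbols,
        chromosomes=chroms,
        positions=positions,
        unplaced=unplaced,
    )
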