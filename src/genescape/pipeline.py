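"""End-to-end analysis wiring: catalogs -> indices -> landscapes -> nulls ->
regions -> divergence heatmaps.

Two surfaces are provided. :func:`analyze` runs the whole analysis in memory
on an :class:`~genescape.simulate.SimResult` or on loaded catalogs and
returns an :class:`AnalysisResult`. The ``stage_*`` functions are the
file-based counterparts used by the CLI: each reads its inputs from and
writes its outputs into one bundle directory, so running ``run`` or the
individual subcommands in sequence produces identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import (
    GeneRecord,
    OrthoMatrix,
    ReferenceOrder,
    SpeciesPanel,
    build_ortho_matrix,
    order_by_reference,
    read_catalog,
    write_catalog,
    write_fasta,
)
from .divergence import AlignParams, divergence_from_values, enumerate_pairs, normalize_npd, pairwise_divergence
from .errors import ConfigError, UndefinedValueError
from .indices import index_table, presence_index_track, length_index_track
from .landscape import (
    LandscapeTrack,
    Region,
    WindowSpec,
    detect_regions,
    heatmap_matrix,
    make_track,
    regions_to_bed,
    track_correlation,
)
from .permutation import NullModel, exceedance_stats, null_distribution
from .seqstats import aa_usage
from .simulate import GroundTruth, RecoveryReport, SimConfig, SimResult, evaluate_recovery, simulate_panel

log = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Knobs of the landscape analysis (defaults follow the standard protocol)."""

    window: WindowSpec = field(default_factory=WindowSpec)
    alpha: float = 0.001
    n_sets: int = 1000
    set_size: int = 101
    gap_max: int = 25
    min_width: int = 5
    refine_fraction: float = 0.6
    pi_denominator: int | None = None
    align: AlignParams = field(default_factory=AlignParams)
    heatmap_non_avian: tuple[str, ...] | None = None
    seed: int = 0

    def as_metadata(self) -> dict:
        return {
            "window": asdict(self.window),
            "alpha": self.alpha,
            "n_sets": self.n_sets,
            "set_size": self.set_size,
            "gap_max": self.gap_max,
            "min_width": self.min_width,
            "refine_fraction": self.refine_fraction,
            "pi_denominator": self.pi_denominator,
            "align": self.align.as_metadata(),
            "heatmap_non_avian": list(self.heatmap_non_avian or []),
            "seed": self.seed,
        }


@dataclass
class AnalysisResult:
    matrix: OrthoMatrix
    order: ReferenceOrder
    tracks: dict[str, LandscapeTrack]
    nulls: dict[str, NullModel]
    regions: dict[str, list[Region]]
    exceedance: dict[str, dict]
    correlations: dict[str, float]
    npd_tracks: list[LandscapeTrack]
    heatmap: pd.DataFrame | None
    recovery: RecoveryReport | None
    params: AnalysisParams


def analyze(
    sim: SimResult | None = None,
    records: Sequence[GeneRecord] | None = None,
    panel: SpeciesPanel | None = None,
    params: AnalysisParams | None = None,
    divergence_values: Mapping[tuple[str, str], np.ndarray] | None = None,
    truth: GroundTruth | None = None,
    karyotype: Sequence[str] | None = None,
) -> AnalysisResult:
    """Run the full landscape analysis in memory.

    Either pass a simulation result, or explicit ``records`` + ``panel``
    (with optional precomputed per-pair ``divergence_values`` aligned to the
    simulator's gene list, and recovery ``truth``).
    """
    params = params or AnalysisParams()
    if sim is not None:
        records = sim.records
        panel = sim.panel
        divergence_values = divergence_values or sim.divergence
        truth = truth or sim.truth
    if records is None or panel is None:
        raise ConfigError("analyze needs a SimResult or records + panel")

    matrix = build_ortho_matrix(records, panel)
    ref_records = [r for r in records if r.species == panel.reference]
    order = order_by_reference(matrix, ref_records, karyotype)
    spec = params.window

    # per-gene indices -> smoothed tracks
    pi = presence_index_track(matrix, denominator=params.pi_denominator)
    li = length_index_track(matrix)
    tracks = {
        "presence_index": make_track(order, pi, "presence_index", spec),
        "length_index": make_track(order, li, "length_index", spec),
    }

    # composition tracks per species with data (GC always; GARP/FYMINK where proteins exist)
    by_species: dict[str, dict[str, GeneRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, {})[r.symbol] = r
    for sp in panel.all_species:
        recs = by_species.get(sp, {})
        gc_vals = {s: r.gc_percent for s, r in recs.items() if r.gc_percent is not None}
        if gc_vals:
            tracks[f"gc:{sp}"] = make_track(order, gc_vals, f"gc:{sp}", spec)
        prot = {s: r.protein_seq for s, r in recs.items() if r.protein_seq}
        if prot:
            garp, fymink = {}, {}
            for s, p in prot.items():
                comp = aa_usage(p)
                garp[s] = comp.garp_percent
                fymink[s] = comp.fymink_percent
            tracks[f"garp:{sp}"] = make_track(order, garp, f"garp:{sp}", spec)
            tracks[f"fymink:{sp}"] = make_track(order, fymink, f"fymink:{sp}", spec)

    # permutation nulls and thresholded regions
    nulls = {
        "presence_index": null_distribution(
            tracks["presence_index"].raw, params.set_size, params.n_sets,
            seed=params.seed, alpha=params.alpha, statistic="presence_index",
        ),
        "length_index": null_distribution(
            tracks["length_index"].raw, params.set_size, params.n_sets,
            seed=params.seed + 1, alpha=params.alpha, statistic="length_index",
        ),
    }
    regions = {
        "presence_index": detect_regions(
            tracks["presence_index"], nulls["presence_index"].threshold_low, "below",
            params.gap_max, params.min_width, params.refine_fraction,
        ),
        "length_index": detect_regions(
            tracks["length_index"], nulls["length_index"].threshold_high, "above",
            params.gap_max, params.min_width, params.refine_fraction,
        ),
    }
    exceedance = {
        "presence_index": exceedance_stats(
            tracks["presence_index"], nulls["presence_index"], direction="below"
        ).as_metadata(),
        "length_index": exceedance_stats(
            tracks["length_index"], nulls["length_index"], direction="above"
        ).as_metadata(),
    }

    correlations = _correlations(tracks, panel)

    # normalized protein divergence heatmap
    npd_tracks: list[LandscapeTrack] = []
    heatmap = None
    if divergence_values:
        heat_na = params.heatmap_non_avian or tuple(
            sp for sp in panel.non_avian if not sp.startswith("REF")
        )
        pairset = enumerate_pairs(list(panel.avian), list(heat_na))
        symbols = sim.symbols if sim is not None else list(matrix.genes)
        for a, b, _tag in pairset.pairs:
            key = (a, b) if (a, b) in divergence_values else (b, a)
            if key not in divergence_values:
                continue
            vals = np.asarray(divergence_values[key], dtype=float)
            recs = divergence_from_values(symbols, vals, (a, b))
            recs = normalize_npd(recs)
            npd_by_symbol = {r.symbol: r.npd for r in recs if r.npd is not None}
            npd_tracks.append(make_track(order, npd_by_symbol, f"{a}//{b}", spec))
        if npd_tracks:
            heatmap = heatmap_matrix(npd_tracks)

    recovery = None
    if truth is not None:
        aligned = _align_truth(truth, order)
        recovery = evaluate_recovery(regions["presence_index"], aligned)

    return AnalysisResult(
        matrix=matrix,
        order=order,
        tracks=tracks,
        nulls=nulls,
        regions=regions,
        exceedance=exceedance,
        correlations=correlations,
        npd_tracks=npd_tracks,
        heatmap=heatmap,
        recovery=recovery,
        params=params,
    )


def _correlations(tracks: dict[str, LandscapeTrack], panel: SpeciesPanel) -> dict[str, float]:
    out: dict[str, float] = {}

    def corr(name: str, a: str, b: str) -> None:
        if a in tracks and b in tracks:
            try:
                out[name] = track_correlation(tracks[a], tracks[b])
            except UndefinedValueError:
                pass

    corr("swpi_swli", "presence_index", "length_index")
    exemplars = [sp for sp in panel.all_species if f"gc:{sp}" in tracks]
    avian_ex = next((sp for sp in exemplars if sp in panel.avian), None)
    if avian_ex:
        corr("gc_swpi", f"gc:{avian_ex}", "presence_index")
        corr("gc_swli", f"gc:{avian_ex}", "length_index")
    for sp in exemplars:
        corr(f"gc_garp:{sp}", f"gc:{sp}", f"garp:{sp}")
        corr(f"gc_fymink:{sp}", f"gc:{sp}", f"fymink:{sp}")
    return out


def _align_truth(truth: GroundTruth, order: ReferenceOrder) -> GroundTruth:
    """Re-express planted flags in the realized reference-order rank space."""
    flags_by_symbol = truth.flags_by_symbol
    aligned = np.array(
        [bool(flags_by_symbol.get(s, False)) for s in order.symbols], dtype=bool
    )
    padded = np.concatenate([[False], aligned, [False]]).astype(int)
    diff = np.diff(padded)
    intervals = list(zip(np.flatnonzero(diff == 1).tolist(), np.flatnonzero(diff == -1).tolist()))
    return GroundTruth(cluster_intervals=intervals, in_cluster=aligned, symbols=list(order.symbols))


# --------------------------------------------------------------------------
# file-based stages (one bundle directory; each stage reads the previous
# stage's outputs, so `run` and composed subcommands write identical bundles)
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Merged configuration of a pipeline run (echoed into the manifest)."""

    outdir: Path
    sim: SimConfig | None = None
    catalog: Path | None = None
    transcript_fasta: Path | None = None
    protein_fasta: Path | None = None
    panel: SpeciesPanel | None = None
    karyotype: tuple[str, ...] | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    align_proteins: bool = False  # align proteins instead of using divergence values

    def validate(self) -> None:
        if self.sim is None:
            if self.catalog is None:
                raise ConfigError("either a simulation config or a catalog path is required")
            if self.panel is None or self.panel.reference is None:
                raise ConfigError("a species panel with a reference genome is required")
            if not Path(self.catalog).exists():
                raise ConfigError(f"catalog not found: {self.catalog}")


def _load(config: RunConfig):
    outdir = Path(config.outdir)
    if config.sim is not None:
        cat = outdir / "catalog.tsv"
        records = read_catalog(
            cat,
            transcript_fasta=_existing(outdir / "transcripts.fasta"),
            protein_fasta=_existing(outdir / "proteins.fasta"),
        )
        panel = config.sim.panel()
    else:
        records = read_catalog(
            config.catalog,
            transcript_fasta=config.transcript_fasta,
            protein_fasta=config.protein_fasta,
        )
        panel = config.panel
    return records, panel


def _existing(p: Path) -> Path | None:
    return p if p.exists() else None


def stage_simulate(config: RunConfig) -> None:
    """Generate a synthetic panel and write its catalog/FASTA/truth/divergences."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_panel(config.sim or SimConfig())
    write_catalog(sim.records, outdir / "catalog.tsv")
    write_fasta(sim.records, outdir / "transcripts.fasta", "transcript")
    write_fasta(sim.records, outdir / "proteins.fasta", "protein")
    sim.truth.flags_by_symbol.astype(int).rename("in_cluster").rename_axis("symbol").to_csv(
        outdir / "truth.tsv", sep="\t"
    )
    rows = []
    for (a, b), vals in sorted(sim.divergence.items()):
        for sym, v in zip(sim.symbols, vals):
            if np.isfinite(v):
                rows.append((sym, a, b, v))
    pd.DataFrame(rows, columns=["symbol", "species_a", "species_b", "divergence_percent"]).to_csv(
        outdir / "divergence_values.tsv", sep="\t", index=False
    )


def _run_analysis(config: RunConfig) -> AnalysisResult:
    records, panel = _load(config)
    outdir = Path(config.outdir)
    divergence_values = None
    truth = None
    dv_path = outdir / "divergence_values.tsv"
    if config.align_proteins:
        divergence_values = _aligned_divergences(records, panel, config.params)
    elif dv_path.exists():
        df = pd.read_csv(dv_path, sep="\t")
        symbols = sorted({r.symbol for r in records})
        sym_idx = {s: i for i, s in enumerate(symbols)}
        divergence_values = {}
        for (a, b), grp in df.groupby(["species_a", "species_b"]):
            arr = np.full(len(symbols), np.nan)
            arr[[sym_idx[s] for s in grp["symbol"]]] = grp["divergence_percent"].to_numpy()
            divergence_values[(a, b)] = arr
    truth_path = outdir / "truth.tsv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t")
        flags = tdf["in_cluster"].astype(bool).to_numpy()
        truth = GroundTruth(cluster_intervals=[], in_cluster=flags, symbols=list(tdf["symbol"]))

    result = analyze(
        records=records,
        panel=panel,
        params=config.params,
        truth=truth,
        karyotype=config.karyotype,
    )
    # attach divergence-derived outputs (symbol-keyed, independent of sim indexing)
    if divergence_values:
        spec = config.params.window
        heat_na = config.params.heatmap_non_avian or tuple(
            sp for sp in panel.non_avian if not sp.startswith("REF")
        )
        pairset = enumerate_pairs(list(panel.avian), list(heat_na))
        symbols = sorted({r.symbol for r in records})
        for a, b, _tag in pairset.pairs:
            key = (a, b) if (a, b) in divergence_values else (b, a)
            if key not in divergence_values:
                continue
            recs = divergence_from_values(symbols, divergence_values[key], (a, b))
            recs = normalize_npd(recs)
            npd = {r.symbol: r.npd for r in recs if r.npd is not None}
            result.npd_tracks.append(make_track(result.order, npd, f"{a}//{b}", spec))
        if result.npd_tracks:
            result.heatmap = heatmap_matrix(result.npd_tracks)
    return result


def _aligned_divergences(records, panel, params: AnalysisParams):
    catalogs: dict[str, dict[str, str]] = {}
    for r in records:
        if r.protein_seq:
            catalogs.setdefault(r.species, {})[r.symbol] = r.protein_seq
    symbols = sorted({r.symbol for r in records})
    sym_idx = {s: i for i, s in enumerate(symbols)}
    heat_na = params.heatmap_non_avian or tuple(
        sp for sp in panel.non_avian if not sp.startswith("REF")
    )
    out = {}
    for a, b, _tag in enumerate_pairs(list(panel.avian), list(heat_na)).pairs:
        if a not in catalogs or b not in catalogs:
            continue
        arr = np.full(len(symbols), np.nan)
        for rec in pairwise_divergence(catalogs, (a, b), params.align):
            arr[sym_idx[rec.symbol]] = rec.divergence_percent
        out[(a, b)] = arr
    return out


def stage_indices(config: RunConfig) -> AnalysisResult:
    result = _run_analysis(config)
    outdir = Path(config.outdir)
    table = index_table(result.matrix, denominator=config.params.pi_denominator)
    ranks = pd.Series(result.order.ranks, name="rank")
    table["rank"] = table["symbol"].map(ranks)
    table.sort_values("rank", na_position="last").to_csv(
        outdir / "indices.tsv", sep="\t", index=False
    )
    return result


def stage_landscape(config: RunConfig, result: AnalysisResult | None = None) -> AnalysisResult:
    result = result or _run_analysis(config)
    outdir = Path(config.outdir)
    for name, track in result.tracks.items():
        safe = name.replace(":", "_").replace("/", "_")
        track.to_frame().to_csv(outdir / f"track_{safe}.tsv", sep="\t", index=False)
    return result


def stage_permute(config: RunConfig, result: AnalysisResult | None = None) -> AnalysisResult:
    result = result or _run_analysis(config)
    outdir = Path(config.outdir)
    meta = {}
    for name, model in result.nulls.items():
        pd.Series(model.null_values, name="null_mean").to_csv(
            outdir / f"null_{name}.tsv", sep="\t", index=False
        )
        meta[name] = model.as_metadata()
    (outdir / "nulls.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return result


def stage_regions(config: RunConfig, result: AnalysisResult | None = None) -> AnalysisResult:
    result = result or _run_analysis(config)
    outdir = Path(config.outdir)
    for name, regions in result.regions.items():
        bed = regions_to_bed(regions, result.order)
        bed.to_csv(outdir / f"regions_{name}.bed", sep="\t", index=False, header=False)
    stats: dict = {
        "exceedance": result.exceedance,
        "correlations": result.correlations,
        "n_regions": {k: len(v) for k, v in result.regions.items()},
    }
    if result.recovery is not None:
        stats["recovery"] = {
            "precision": result.recovery.precision,
            "recall": result.recovery.recall,
            "jaccard_mean": result.recovery.jaccard_mean,
        }
    (outdir / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
    return result


def stage_divergence(config: RunConfig, result: AnalysisResult | None = None) -> AnalysisResult:
    """Write the per-gene nPD values of every heatmap pair."""
    result = result or _run_analysis(config)
    outdir = Path(config.outdir)
    rows = []
    for t in result.npd_tracks:
        for sym, v in zip(result.order.symbols, t.raw):
            if np.isfinite(v):
                rows.append((t.name, sym, v))
    pd.DataFrame(rows, columns=["pair", "symbol", "npd"]).to_csv(
        outdir / "npd.tsv", sep="\t", index=False
    )
    return result


def stage_heatmap(config: RunConfig, result: AnalysisResult | None = None) -> AnalysisResult:
    result = result or _run_analysis(config)
    outdir = Path(config.outdir)
    if result.heatmap is not None:
        result.heatmap.rename_axis("pair").to_csv(outdir / "heatmap_npd.tsv", sep="\t")
    return result


def write_manifest(config: RunConfig) -> None:
    outdir = Path(config.outdir)
    manifest = {
        "genescape_version": __version__,
        "params": config.params.as_metadata(),
        "simulated": config.sim is not None,
        "sim_config": asdict(config.sim) if config.sim is not None else None,
        "karyotype": list(config.karyotype) if config.karyotype else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_full_analysis(config: RunConfig) -> AnalysisResult:
    """All stages in order into one bundle directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        if config.sim is not None:
            stage_simulate(config)
        result = stage_indices(config)
        stage_landscape(config, result)
        stage_permute(config, result)
        stage_regions(config, result)
        stage_divergence(config, result)
        stage_heatmap(config, result)
        write_manifest(config)
    except Exception:
        (outdir / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise
    return result
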