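# Methods

This note documents the models, defaults and numerical choices behind
`genescape`, the reasoning where the design was genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## Data model and inclusion rules

A *catalog* holds one row per (species, gene): symbol, chromosome,
position, transcript id/length, optionally the transcript/protein
sequences and a precomputed transcript GC%. Symbols are matched exactly
and case-insensitively; LOC-style aliases can be folded in with a
two-column alias table, but no synteny- or homology-based ortholog
inference is attempted (that is curation, not computation). Duplicate
(species, gene) rows are collapsed by keeping the longest transcript —
the usual surrogate when one representative isoform per gene is wanted —
unless another policy is chosen.

The *common vertebrate gene set* used by the analysis keeps genes
annotated in the reference genome and in at least one non-avian genome.
Under this rule a gene missing from every avian genome is meaningfully
"missing" rather than unobservable. A catalog row without an annotated
transcript length does not count as presence: the ortholog matrix keeps
the invariant `presence == length available`, which makes the presence and
length indices consistent with each other.

Gene order is taken from a declared reference genome: placed genes sort by
(karyotype chromosome order, position, symbol — the symbol as a logged
deterministic tie-break), genes absent from the reference are dropped, and
annotated-but-unplaced (`PU`) genes are appended after all chromosomes in
symbol order, mirroring how landscape figures draw the PU block last.
Positions are 0-based internally and only converted at BED boundaries.

## Indices

- Presence index: annotated fraction of the declared avian panel. The
  denominator is the configured panel size (8 by default, e.g. 75 for an
  extended panel) even if some catalogs are empty, so PI values remain
  comparable across runs.
- Length index: mean annotated non-avian length / mean annotated avian
  length. No zero-imputation: both means run over species that annotate
  the gene, because the ratio compares *existing* gene models. The
  non-avian group by default includes the reference-grade genomes plus the
  reptile outgroups (six species). LI is recorded as missing when no avian
  annotation exists, and is undefined (an error) without any non-avian
  annotation.
- Presence score for two-genome comparisons: −1 / 0 / +1 for
  best-annotated-only / both / less-annotated-only; genes in neither
  catalog are excluded from the track rather than scored.

## Alignment and nPD

Protein divergence is `100 − %identity` of an optimal affine-gap global
alignment, with identity counted over the full alignment length including
gap columns (the EMBOSS convention). Defaults are BLOSUM62 with gap open
12 and gap extend 2; a gap of length L costs `12 + 2·(L−1)` (the penalty
applies to the first gap residue, extension to the rest). These parameters
are echoed into the run manifest because published pipelines rarely state
them. The aligner is Biopython's `PairwiseAligner`; the test suite checks
it against an independent hand-written three-state affine dynamic program
with full co-optimal traceback enumeration — scores must agree exactly and
the reported identity must be attained by some co-optimal alignment (ties
between co-optimal alignments are resolved deterministically but can
differ in identity, which is why the oracle enumerates the whole set).

Pairs below 30% identity are excluded from normalization (global identity
loses meaning near the twilight zone); nPD divides each included gene's
divergence by the pair's mean included divergence, so nPD has unit mean
within every species pair and is invariant under rescaling all
divergences. Divergence is rounded only at report time; nPD is kept at
full precision and reported both as a ratio and ×100, since "%"-style
usage is ambiguous in the literature. When divergences arrive as
precomputed numbers instead of sequences (the simulator's fast mode), the
identity filter translates to excluding divergences above 70.

## Sliding windows, thresholds, regions

Smoothing is a centered boxcar of odd size (default 101 = focal gene ±50)
with skip-missing means: each window averages its non-missing members and
is itself missing when fewer than half the window's ranks are valid
(`min_valid_fraction` 0.5) — LI is undefined for fully-missing avian genes
yet the landscapes should remain continuous. Windows span chromosome
boundaries by default (genome-wide landscapes are drawn continuously);
per-chromosome clipping is available. Edges truncate by default so every
rank gets a value; a `drop` policy leaves half-window edges missing.

Null thresholds come from 1000 random sets of `window` genes drawn without
replacement from the non-missing raw values, independently across sets —
scrambling the gene order and re-windowing has the same marginal
distribution, and independent sets are simpler. At α = 0.001 with 1000
sets the thresholds are the extreme null set means (minimum for
"below", maximum for "above"). Exceedance reports use the add-one ECDF
correction `p̂ = (k+1)/(n_sets+1)` (1000 draws cannot resolve p below
1/1001) and a binomial upper-tail p-value, which deliberately retains the
random-sampling-with-replacement assumption. Because neighboring windows
share all but one gene, threshold crossings arrive in runs: the *marginal*
crossing rate is calibrated, but per-panel counts are overdispersed
relative to that binomial (on cluster-free synthetic panels the count
stays within 3 binomial SDs of expectation in roughly 85% of panels, not
95%+; excursions, when they occur, span ~10–40 windows). The
overdispersion is documented here and in the report rather than corrected;
block-permutation nulls would fix it but are a different method.

Regions are maximal runs of threshold-crossing windows, with runs
separated by at most `gap_max` = 25 ranks merged and merged regions
narrower than `min_width` = 5 dropped. No published rule delimits such
clusters, so these defaults were chosen to make planted synthetic clusters
well-separated and recoverable, and they are echoed into the run manifest.
The pipeline additionally applies a boxcar-edge *refinement*: each
detected region is trimmed to the span where the smoothed track passes
60% of the way from the detection threshold to the region's extreme.
Rationale: a compact anomaly of width w < window convolved with a boxcar
of half-width h produces sub-threshold runs dilated by up to h on each
side, with linear ramps; the exact edge sits where the window half-covers
the anomaly, i.e. at (h+1)/w of the depth below background. For the
default geometry (w = 80, window 101, null-extreme thresholds) that point
lies close to 60% of the threshold→extreme span, so trimming at that level
recovers the true edges to within a few ranks. The fraction is a
configurable parameter (`refine_fraction`, 0 disables).

Track correlations are Pearson r over jointly non-missing smoothed ranks
(≥3 required; zero variance is an undefined-value signal). Normality
checks use Shapiro–Wilk with normality retained unless p < 0.01.

## Synthetic panels

The generator emulates the statistical structure the analysis assumes,
with ground truth for recovery scoring. Defaults (the standard study
conditions): 3000 genes on 5 chromosomes; 8 avian genomes, 6 non-avian
(the ordering reference `REF1`, which carries every gene, a second
reference-grade genome `REF2`, and four reptile-like outgroups
`NA1..NA4`); 6 planted clusters of 80 genes, auto-placed round-robin and
centered in equal per-chromosome slots so clusters are separated by more
than one window width of background; transcript GC ~ N(48, 4)% outside
and N(65, 3)% inside clusters with per-species jitter of SD 1; avian
presence 0.95 outside / 0.30 inside clusters, non-avian presence 0.98
everywhere; avian transcript lengths halved inside clusters; base lengths
lognormal with median 1500 nt and log-SD 0.35 (a typical vertebrate mRNA
length distribution), ±10% per-species multiplicative noise, lengths kept
multiples of 3; per-pair divergence N(15, 4)% inflated ×1.5 inside
clusters. All draws flow from one seed through deterministically spawned
sub-streams.

Sequences are realized through GC-calibrated codon sampling: codon weights
∝ exp(β·GC(codon)) with β interpolated per gene so the expected codon GC
matches the gene's target; an ancestral codon sequence is drawn per gene
and each species' copy resamples codons at a rate matched to the target
divergence. This couples composition to GC (GARP% rises with GC because
Gly/Ala/Arg/Pro codons are GC-rich) and gives aligned proteins the
intended approximate divergence. Sampling noise makes realized GC deviate
from the target by ~1–2 percentage points for typical lengths. By default
sequences are emitted only for two exemplar species (`AV1`, `NA1`) —
enough to drive composition landscapes, mirroring how such analyses
compare one avian and one reptile genome — while divergences for all pairs
are drawn directly as numbers (fast mode); `sequence_species="all"`
realizes sequences for every species so the full alignment path can be
exercised on small panels.

What the generator does **not** emulate: real karyotypes and synteny
breaks (all species share the reference layout), GC-biased gene conversion
as a mechanism (clusters are planted, not evolved), read-level sequencing
artifacts, paralogy/annotation-name confusion, and phylogenetic
correlation between species (draws are independent given the gene).
Passing recovery tests therefore shows the *pipeline* is correct and
well-calibrated on data with the assumed structure — not that real "missing"
genes are artifacts; that inference needs real catalogs.

## Degenerate inputs and tie-breaks

Empty or all-ambiguous sequences, proteins without canonical residues,
zero-variance correlation inputs and fully-excluded divergence sets raise
an undefined-value signal and are recorded as missing, never as 0. `X`
residues are skipped with a warning; stop symbols are stripped; any other
non-canonical letter is an error naming the offenders. Identical
(chromosome, position) pairs order by symbol with a logged warning. With
equal-valued thresholds, "below"/"above" relations are strict, so a rank
can never fall in both a below-t and an above-t region at gap 0.

## Problem sizes

Default test and acceptance runs use the generator's standard conditions
(3000-gene panels; 8–20 seeds for recovery statistics, 60–100 cluster-free
panels for calibration, 1000 null sets of 101 genes), sizes at which every
reported statistic is stable to well within the asserted margins.

## Known limitations

- The binomial exceedance p-value ignores window overlap (see above).
- Region counts are parameter-dependent (`gap_max`, `min_width`,
  `refine_fraction`); there is no canonical delimitation of clusters.
- Alignment parameters are assumed, not fitted; identity of co-optimal
  alignments is tie-broken deterministically.
- GC% is computed on whatever transcript sequence the catalog supplies
  (full mRNA vs CDS is the caller's choice); no CDS extraction or
  codon-position statistics (GC3) are attempted.
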