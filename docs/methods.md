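# Methods

## Coordinate and data model

All coordinates are 0-based, half-open, matching BED/bedGraph conventions.
Windows around a site midpoint are `[pos − floor(w/2), pos + ceil(w/2))`,
clipped at chromosome bounds; clipped windows are used as-is rather than
discarded, so edge sites stay in the analysis. Fragments count toward a
window when they overlap it by at least one base (not midpoint containment).
Coverage lives in `CoverageTrack`: per-chromosome vectors of per-bin counts
(default bin 200 bp; the last bin of a chromosome may be short) plus the
sample's total fragment count (`library_size`). Window sums weight partial
bins by overlap fraction, and counts-per-million (CPM) scaling divides by
`library_size / 1e6`. Strand is ignored throughout: all windows are
symmetric around the cut midpoint.

## Break calling

The chain is fixed: reconstitute → length-filter → deduplicate → count →
call → select.

- Fragments span `[min(mate starts), max(mate ends))`; pairs with mates on
  different chromosomes cannot form a genomic fragment and are dropped
  (counted in the log).
- The length cap is strict: > 500 bp is dropped, 500 bp kept.
- Duplicates are exact-coordinate triples (chrom, start, end); one survives.
  Because both the length filter and deduplication are per-fragment
  predicates on coordinates, their order is irrelevant (property-tested).
- Outliers use Tukey's rule on the per-site 1 kb window counts:
  `count > Q3 + 1.5 × IQR`. The quartile estimator is linear interpolation
  of order statistics (Hyndman–Fan type 7, the numpy default); Tukey hinges
  would differ slightly and the convention is configurable in principle by
  replacing one `np.quantile` call. Fewer than 4 sites is an error.
- Validation keeps the `top_k = 80` outliers by count, ties broken by
  ascending site id for reproducibility; when fewer outliers exist, all are
  validated and a warning logged.

## Pathway classification

Per validated site, the score is
`(numerator CPM sum in 4 kb + 1) / (denominator CPM sum in 1 kb + 1)` with
RAD51 as the default numerator and XRCC4 (or DNA ligase IV) as denominator.
Counts are CPM-normalized before the ratio and the pseudocount is 1.0 on
that scale; raw counts are available via a flag. Top-30 ratios → HR-prone,
bottom-30 → NHEJ-prone, remainder unassigned; ties at either cutoff break by
site id, and on site sets smaller than 2k the class size shrinks to
`floor(n/2)` with a warning rather than failing, which keeps fixture-scale
runs meaningful. An all-equal ratio vector is flagged degenerate in the log.

## Control regions

1,000 positions drawn uniformly over the non-Y genome (chromosomes weighted
by length), filtered by two independent predicates — distance ≥ 1 Mb from
every excluded site (the caller passes the top 150 by break-window count)
and a non-zero raw count in a 1 kb window in every provided track — then 80
survivors sampled uniformly. Both filters are pure predicates, so their
order cannot affect the surviving set (property-tested). Exhausting the pool
raises an error naming each filter's attrition.

## Statistics

All group comparisons are unpaired Mann-Whitney-Wilcoxon tests (scipy
implementation behind the module surface). The exact permutation null is
used when the combined sample size is ≤ 20 and the data are tie-free;
otherwise the normal approximation with tie and continuity corrections. The
bridging error between the two paths is ≤ 0.02 in two-sided p on tie-free
samples of size 8–10 (tested). Damage-change tests compare the per-site
damaged vs undamaged window-count vectors across sites as independent
samples; the change direction is the sign of the median difference, and
categories follow the 0.01 / 0.05 thresholds (`strong_increase`,
`increase`, `ns`, `decrease`, `strong_decrease`). No false-discovery-rate
procedure is applied anywhere; the only multiplicity correction is
Bonferroni on the compartment tests, with factor
`n_compartments × 2 directions × 2 break categories`. Compartment
enrichment/depletion are the upper/lower hypergeometric tails of the
observed loop count drawing `n_category` loops from the labelled pool.
Spearman correlations use average ranks; a constant column yields an
undefined (NaN) correlation rather than a silent zero.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

- **Genome**: five 30 Mb autosome-like chromosomes plus a 6 Mb chrY
  (156 Mb total) — large enough to hold 1,211 candidate sites at ≥ 20 kb
  spacing with room for megabase spreading domains, small enough that the
  whole study simulates in seconds.
- **Sites**: 1,211 candidates, rejection-sampled uniformly with 20 kb
  minimum spacing; two sit on chrY to exercise the control sampler's Y
  exclusion. 174 non-Y sites are cleaved with efficiencies uniform on
  [0.1, 1]. Pathway labels (30 HR + 30 NHEJ) go to the highest-efficiency
  cleaved sites — shuffled between the two labels — so that labelled sites
  are expected to survive top-80 validation.
- **Fragments**: background is Poisson(rate × chromosome length) with
  uniform starts and lengths uniform on [100, 500] bp; each cleaved site
  adds Poisson(200 × efficiency) fragments with one end within ±50 bp of
  the cut (mimicking ligation at blunted break ends). 2% of fragments are
  redrawn with aberrant lengths in (500, 2000] and 5% are emitted twice as
  exact duplicates. The background rate default is 5×10⁻³ fragments/bp,
  a synthetic calibration chosen so the candidate-count distribution has
  non-degenerate quartiles: with a near-zero background the third quartile
  and IQR collapse to 0 and every stray background fragment becomes a false
  outlier, which no caller operating on the stated rule could avoid.
- **Coverage**: undamaged bins are Poisson(baseline, default 5 per 200 bp
  bin); damaged bins multiply the mean by `fold` (or `1/fold` for
  decreases) within `spread_bp` of cleaved sites matching the feature's
  pathway specificity, leaving non-matching sites' expected ratio exactly 1.
  Optional Gamma overdispersion multiplies per-bin means. Library size is
  the realized total, floored at 1 so CPM stays defined on all-zero tracks.
- **Feature panel**: repair factors (RAD51: fold 8 over ±2 kb at HR sites;
  XRCC4 and ligase IV: fold 6 over ±0.5 kb at NHEJ sites) and chromatin
  features spanning the kb-to-Mb scales seen at real breaks (Mb-scale
  phospho-H2AX and ubiquitin gains, Mb-scale H1 loss at HR sites, a kb-scale
  H2B K120 ubiquitination→acetylation switch at all breaks, kb-scale
  HR-restricted nucleosome losses, an NHEJ-restricted gain, and one null
  feature for calibration).
- **Determinism**: one master seed; every sub-simulation derives a child
  seed by SHA-256 hashing of (seed, stage, feature, condition), so adding a
  feature never perturbs existing draws. Identical configs are
  byte-identical on disk.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: mappability and GC bias, chromatin-state
covariates, replication timing, resection-induced signal asymmetry,
fragment-size structure of real libraries, and realistic inter-feature
correlations. Two deliberate simplifications matter for interpretation.
First, end-joining-factor enrichment is simulated as NHEJ-specific so the
ratio classifier can be scored against ground truth; at real breaks XRCC4
binds all DSBs and only the *relative* RAD51/XRCC4 level separates the
pathways. Second, total-count normalization on a 156 Mb genome with
megabase spreading at 174 sites inflates the damaged library by a factor
several-fold (most of the synthetic genome lies inside a spreading domain),
so Mb-scale log2 ratios are compressed and distal regions can show apparent
opposite-sign changes — a composition effect that is far milder on a 3 Gb
genome where domains cover ~10% of the sequence.

## Profiles and numerical choices

Averaged profiles are position-wise means across sites of the per-bin
signal at each offset; sites whose window exceeds the chromosome contribute
only defined positions. Smoothing is a centred moving average with span
`smooth_span / step` points (odd-ified), truncated at profile edges, which
preserves constants. Log2-ratio tracks equalise libraries on the count scale
by scaling the larger library down to the smaller before
`log2((t + 1)/(u + 1))`; a pseudocount applied on the per-million scale
instead would dwarf typical per-bin CPM values (~1) and flatten every
profile. bedGraph round-trips are exact at matching bin size because the
writer records the library size in a leading comment and the reader rebins
by overlap-weighted averaging against each bin's effective width.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on fixture-scale genomes (2–14 Mb, 12–120
sites) where brute-force oracles are feasible. Structural counts, caller
recovery (5 seeds), classifier recovery (3 seeds) and signature
calibration/power (20 replicates) run at the full default conditions
(1,211 sites, 156 Mb); the type-I error check uses 400 direct Poisson null
simulations of 80 sites. These sizes keep the whole suite under a few
minutes while leaving every quantity computed at the conditions it is
quoted for.

## Known limitations

- The outlier rule is scale-free but assumes the uncleaved majority
  dominates the quartiles; site sets where more than ~40% of candidates are
  cleaved push Q3 into the signal and the rule under-calls (this is a
  property of the published rule, reproduced faithfully).
- The classifier is rank-based and always returns exactly k sites per class
  when 2k sites are available, regardless of how weak the ratio contrast
  is; the degenerate-input warning is the only guard.
- No BAM/bigWig input; the pipeline consumes aligned fragments (BED/BEDPE)
  and binned coverage (bedGraph) only.
- Compartment labels are consumed as input (or synthesised for
  demonstration); the pipeline does not derive compartments.
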