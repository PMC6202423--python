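# breakscape

Calling enzyme-induced DNA double-strand breaks (DSBs), classifying them by
repair pathway, and quantifying the multi-scale chromatin changes around
them — as a tested, reusable pipeline exercised end-to-end on a synthetic
data generator with known ground truth.

## The problem

Sequence-specific nucleases such as AsiSI (in DIvA cells) cut the genome at
predicted recognition motifs, but only a minority of candidate sites is
actually cleaved in vivo. Direct break labelling (BLESS/END-seq-style
sequencing of ligated break ends) produces fragment pile-ups precisely at cut
positions; repair-factor ChIP-seq distinguishes breaks channelled into
homologous recombination (HR, RAD51-dependent) from those joined by
non-homologous end joining (NHEJ, XRCC4/DNA-ligase-IV-dependent); and
chromatin-feature ChIP-seq before and after damage reveals modification
changes spreading from ~1 kb up to megabase-scale γH2AX domains.

The pipeline implements the quantitative core of that analysis:

1. **Break calling.** Fragments are reconstituted from read pairs, lengths
   > 500 bp dropped as aberrant, exact-coordinate duplicates collapsed, and
   fragments counted in a 1 kb window around each candidate site. A site is
   called cleaved when its count exceeds `Q3 + 1.5 × IQR` of all candidate
   counts (type-7 quartiles, strict inequality); the top 80 outliers by count
   form the validated break set.
2. **Pathway classification.** Each validated break is scored by
   `(RAD51 CPM, 4 kb window + 1) / (XRCC4 CPM, 1 kb window + 1)`; the 30
   highest ratios are HR-prone, the 30 lowest NHEJ-prone, the rest
   unassigned.
3. **Background controls.** 1,000 random non-chrY positions, filtered to be
   ≥ 1 Mb from the top-150 cleaved sites and to have non-zero coverage in
   every provided track; 80 survivors are sampled.
4. **Signatures.** Unpaired Mann-Whitney-Wilcoxon tests compare damaged vs
   undamaged window counts per feature, group (all breaks / controls /
   HR / NHEJ) and window size, with significance categories at p < 0.01 and
   p < 0.05; HR-vs-NHEJ comparisons over increasing window sizes; basal
   (pre-damage) enrichment; Spearman correlation matrices; hypergeometric
   compartment enrichment with Bonferroni correction.
5. **Profiles.** Per-bp averaged log2(damaged/undamaged) profiles around
   breaks, smoothed with a 50 kb span at megabase scale.

The synthetic generator (`breakscape.simulate`) emulates the study's signal
structure — 1,211 candidate sites, 174 cleaved with variable efficiency,
sharp fragment pile-ups over uniform background, and per-feature coverage
changes with configurable direction, fold, spreading width (1 kb–2 Mb) and
pathway specificity — so every stage is testable against known truth without
any downloads.

## Worked example

```python
from breakscape import (SimulationConfig, make_genome, simulate_bless,
                        simulate_chip, run_bless, classify_from_tracks)
from breakscape.simulate import fragments_to_pairs

cfg = SimulationConfig(seed=1)                 # the default study conditions
cs, sites, truth = make_genome(cfg)            # 1,211 sites, 174 cleaved
pairs = fragments_to_pairs(simulate_bless(cfg, cs, sites, truth))
result = run_bless(pairs, sites, cs)           # reconstitute→filter→dedup→count→call
print(result.n_outliers, len(result.validated_ids))
rad51, _ = simulate_chip(cfg, cs, sites, truth, "RAD51")
xrcc4, _ = simulate_chip(cfg, cs, sites, truth, "XRCC4")
call = classify_from_tracks(rad51, xrcc4, sites.subset(result.validated_ids), cs)
print(call.table["label"].value_counts().to_dict())
```

prints

```
176 80
{'HR': 30, 'NHEJ': 30, 'unassigned': 20}
```

i.e. 176 of the 1,211 candidates exceed the IQR threshold (174 truly cleaved
plus a couple of background flukes), exactly 80 are validated, and the ratio
classifier splits them 30/30/20. Against ground truth this run recovers all
cleaved sites with efficiency ≥ 0.3 (sensitivity 1.00, precision 0.99) and
labels every true-HR site correctly.

The numbered scripts under `analysis/` run each stage at study scale and
write their tables under `results/` (`cd analysis && python 01_simulate.py`,
etc.). A full run is also available behind a single TOML config:
`breakscape run config.toml`, with per-stage subcommands `simulate`,
`bless-call`, `classify`, `controls` and `report`.

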