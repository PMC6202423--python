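"""Synthetic genomes, break-labelling fragment data, and ChIP coverage tracks.

The generator emulates the signal structure of an enzyme-induced
double-strand-break mapping experiment: ~1,211 candidate recognition sites of
which a minority (174 by default) are truly cleaved with variable efficiency,
sharp fragment pile-ups at cut positions over a uniform genomic background,
and per-feature damage-induced coverage changes with configurable direction,
fold, spreading width and repair-pathway specificity. Every draw derives from
a single master seed, so identical configurations yield identical data.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CandidateSite, CandidateSiteSet, CoverageTrack, fragments_frame, n_bins
from . import io as bsio

MATE_LENGTH = 50  # bp per sequencing mate when emitting read pairs
CUT_END_JITTER = 50  # one fragment end falls within +/- this of the cut
MIN_SITE_SPACING = 20_000
ABERRANT_MAX_LEN = 2000


@dataclass(frozen=True)
class FeatureSpec:
    """One chromatin feature's damage response in the simulation.

    ``spread_bp`` is the half-width of the affected region around a cut;
    ``fold`` multiplies (direction=increase) or divides (decrease) the
    Poisson mean of damaged-condition bins inside that region at sites
    matching ``pathway_specificity``. ``baseline_mean`` is the expected count
    per bin away from damage; optional Gamma overdispersion multiplies the
    per-bin mean.
    """

    name: str
    direction: str = "none"  # increase | decrease | none
    fold: float = 1.0
    spread_bp: int = 1000
    pathway_specificity: str = "all"  # all | HR_only | NHEJ_only
    baseline_mean: float = 5.0
    overdispersion: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease", "none"):
            raise ValueError(f"{self.name}: bad direction {self.direction!r}")
        if self.pathway_specificity not in ("all", "HR_only", "NHEJ_only"):
            raise ValueError(
                f"{self.name}: bad pathway_specificity {self.pathway_specificity!r}"
            )
        if self.fold <= 0:
            raise ValueError(f"{self.name}: fold must be > 0")
        if self.spread_bp <= 0:
            raise ValueError(f"{self.name}: spread_bp must be > 0")
        if self.baseline_mean < 0:
            raise ValueError(f"{self.name}: baseline_mean must be >= 0")


def default_features() -> list[FeatureSpec]:
    """Feature panel emulating the study's observed damage responses.

    Repair factors: a resection/strand-invasion factor accumulating over a
    4 kb window at HR sites, and two end-joining factors (primary and
    alternative denominator) at NHEJ sites. Chromatin features span the
    kb-to-Mb scales seen around real breaks: Mb-scale phospho-H2AX and
    ubiquitin accumulation, Mb-scale linker-histone H1 loss at HR sites, a
    kb-scale H2B K120 ubiquitination-to-acetylation switch, and kb-scale
    nucleosome changes restricted to one pathway. One feature is a null
    (no damage response) for calibration.
    """
    return [
        FeatureSpec("RAD51", "increase", 8.0, 2000, "HR_only"),
        FeatureSpec("XRCC4", "increase", 6.0, 500, "NHEJ_only"),
        FeatureSpec("LIG4", "increase", 6.0, 500, "NHEJ_only"),
        FeatureSpec("gH2AX", "increase", 6.0, 1_000_000, "all"),
        FeatureSpec("ubiquitin", "increase", 2.0, 1_000_000, "all"),
        FeatureSpec("H1", "decrease", 1.5, 1_000_000, "HR_only"),
        FeatureSpec("H2BK120ub", "decrease", 4.0, 1000, "all"),
        FeatureSpec("H2BK120ac", "increase", 4.0, 1000, "all"),
        FeatureSpec("macroH2A", "increase", 2.0, 3000, "all"),
        FeatureSpec("H4S1P", "increase", 2.0, 5000, "all"),
        FeatureSpec("H2AZ", "decrease", 4.0, 1000, "HR_only"),
        FeatureSpec("H3K36me3", "increase", 3.0, 1000, "NHEJ_only"),
        FeatureSpec("H3K9me3", "none", 1.0, 1000, "all"),
    ]


def default_chrom_spec() -> dict[str, int]:
    return {
        "chr1": 30_000_000,
        "chr2": 30_000_000,
        "chr3": 30_000_000,
        "chr4": 30_000_000,
        "chr5": 30_000_000,
        "chrY": 6_000_000,
    }


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment; the seed is mandatory."""

    seed: int
    chrom_spec: dict[str, int] = field(default_factory=default_chrom_spec)
    n_candidate_sites: int = 1211
    n_cleaved: int = 174
    cleavage_efficiency_range: tuple[float, float] = (0.1, 1.0)
    n_hr: int = 30
    n_nhej: int = 30
    bless_depth: float = 200.0
    background_rate: float = 5e-3
    frag_len_range: tuple[int, int] = (100, 500)
    aberrant_frac: float = 0.02
    duplicate_rate: float = 0.05
    feature_specs: list[FeatureSpec] = field(default_factory=default_features)
    binsize: int = 200

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if "chrY" not in self.chrom_spec:
            raise ValueError("chrom_spec must contain a chrY entry")
        if any(l <= 0 for l in self.chrom_spec.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_cleaved > self.n_candidate_sites:
            raise ValueError("n_cleaved must be <= n_candidate_sites")
        if self.n_hr + self.n_nhej > self.n_cleaved:
            raise ValueError("n_hr + n_nhej must be <= n_cleaved")
        lo, hi = self.cleavage_efficiency_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("cleavage_efficiency_range must lie in (0, 1]")
        if self.bless_depth < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.aberrant_frac <= 1 and 0 <= self.duplicate_rate <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frag_len_range[0] <= 0 or self.frag_len_range[0] > self.frag_len_range[1]:
            raise ValueError("bad frag_len_range")
        if self.binsize < 1:
            raise ValueError("binsize must be >= 1")
        names = [f.name for f in self.feature_specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def feature(self, name: str) -> FeatureSpec:
        for f in self.feature_specs:
            if f.name == name:
                return f
        raise KeyError(f"unknown feature {name!r}")


def child_seed(master: int, *names: str) -> int:
    """Stable sub-seed from the master seed and a path of names.

    Uses SHA-256 so adding features or stages never perturbs the draws of
    existing ones.
    """
    h = hashlib.sha256((str(int(master)) + "/" + "/".join(names)).encode())
    return int.from_bytes(h.digest()[:4], "big") & 0x7FFFFFFF


@dataclass
class GroundTruth:
    """Per-site cleavage flag, efficiency and pathway label (HR/NHEJ/none)."""

    table: pd.DataFrame  # columns: site_id, cleaved, efficiency, pathway

    def __post_init__(self) -> None:
        required = {"site_id", "cleaved", "efficiency", "pathway"}
        if not required <= set(self.table.columns):
            raise ValueError(f"truth table needs columns {sorted(required)}")
        bad = self.table.loc[~self.table["cleaved"], "pathway"] != "none"
        if bad.any():
            raise ValueError("uncleaved sites cannot carry a pathway label")

    def cleaved_ids(self) -> list[str]:
        return list(self.table.loc[self.table["cleaved"], "site_id"])

    def pathway_ids(self, pathway: str) -> list[str]:
        return list(self.table.loc[self.table["pathway"] == pathway, "site_id"])

    def efficiency(self) -> pd.Series:
        return self.table.set_index("site_id")["efficiency"]


def make_genome(
    config: SimulationConfig,
) -> tuple[dict[str, int], CandidateSiteSet, GroundTruth]:
    """Place candidate sites and assign cleavage/pathway ground truth.

    Sites go uniformly at random on non-Y chromosomes with a minimum spacing
    of 20 kb (rejection sampling); two of the requested sites always land on
    chrY so the Y-exclusion of the control sampler is exercised. Cleaved
    sites draw efficiencies uniformly from the configured range; pathway
    labels are assigned among the highest-efficiency cleaved sites so that
    labelled sites are expected to survive top-k validation downstream.
    """
    rng = np.random.default_rng(child_seed(config.seed, "genome"))
    chromsizes = dict(config.chrom_spec)
    non_y = [c for c in chromsizes if c != "chrY"]
    if not non_y:
        raise ValueError("need at least one non-Y chromosome")
    n_y = min(2, config.n_candidate_sites)
    n_auto = config.n_candidate_sites - n_y

    lengths = np.array([chromsizes[c] for c in non_y], dtype=float)
    probs = lengths / lengths.sum()
    alloc = rng.multinomial(n_auto, probs)

    positions: list[tuple[str, int]] = []
    margin = 1000  # keep sites off the extreme chromosome ends
    for chrom, k in zip(non_y, alloc):
        positions.extend(
            (chrom, p) for p in _spaced_positions(
                rng, chromsizes[chrom], int(k), MIN_SITE_SPACING, margin
            )
        )
    positions.extend(
        ("chrY", p) for p in _spaced_positions(
            rng, chromsizes["chrY"], n_y, MIN_SITE_SPACING, margin
        )
    )
    positions.sort(key=lambda t: (t[0], t[1]))
    width = len(str(len(positions)))
    sites = CandidateSiteSet(
        CandidateSite(f"site_{i + 1:0{width}d}", chrom, pos)
        for i, (chrom, pos) in enumerate(positions)
    )

    # cleavage restricted to non-Y sites (the control stage excludes chrY)
    ids = np.array(sites.site_ids)
    non_y_mask = np.array([s.chrom != "chrY" for s in sites])
    eligible = np.flatnonzero(non_y_mask)
    if config.n_cleaved > len(eligible):
        raise ValueError("not enough non-Y sites to cleave")
    cleaved_idx = rng.choice(eligible, size=config.n_cleaved, replace=False)
    cleaved = np.zeros(len(ids), dtype=bool)
    cleaved[cleaved_idx] = True
    lo, hi = config.cleavage_efficiency_range
    efficiency = np.zeros(len(ids))
    efficiency[cleaved_idx] = rng.uniform(lo, hi, size=config.n_cleaved)

    pathway = np.array(["none"] * len(ids), dtype=object)
    n_label = config.n_hr + config.n_nhej
    if n_label:
        order = cleaved_idx[np.argsort(-efficiency[cleaved_idx], kind="stable")]
        top = order[:n_label].copy()
        rng.shuffle(top)
        pathway[top[: config.n_hr]] = "HR"
        pathway[top[config.n_hr:]] = "NHEJ"

    truth = GroundTruth(
        pd.DataFrame(
            {
                "site_id": ids,
                "cleaved": cleaved,
                "efficiency": efficiency,
                "pathway": pathway,
            }
        )
    )
    return chromsizes, sites, truth


def _spaced_positions(
    rng: np.random.Generator, length: int, k: int, spacing: int, margin: int
) -> list[int]:
    if k == 0:
        return []
    lo, hi = margin, length - margin
    if hi <= lo or (hi - lo) < (k - 1) * spacing:
        raise ValueError(
            f"chromosome of length {length} too small for {k} sites "
            f"at {spacing} bp spacing"
        )
    chosen: list[int] = []
    attempts = 0
    max_attempts = 2000 * k + 10_000
    while len(chosen) < k:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"rejection sampling failed: {k} sites at {spacing} bp "
                f"spacing on a {length} bp chromosome"
            )
        p = int(rng.integers(lo, hi))
        if all(abs(p - q) >= spacing for q in chosen):
            chosen.append(p)
    return sorted(chosen)


def simulate_bless(
    config: SimulationConfig,
    chromsizes: Mapping[str, int],
    sites: CandidateSiteSet,
    truth: GroundTruth,
) -> pd.DataFrame:
    """Draw break-labelling fragments: cut-site pile-ups over uniform background.

    Background fragments per chromosome are Poisson(background_rate x length)
    with uniform starts; each cleaved site contributes
    Poisson(bless_depth x efficiency) fragments with one end within +/-50 bp
    of the cut. A configured fraction of fragments is redrawn with aberrant
    lengths in (500, 2000], and a fraction is emitted twice with identical
    coordinates (PCR-style duplicates).
    """
    rng = np.random.default_rng(child_seed(config.seed, "bless"))
    lmin, lmax = config.frag_len_range
    chroms: list[str] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []

    def emit(chrom: str, s: np.ndarray, e: np.ndarray) -> None:
        if len(s):
            chroms.extend([chrom] * len(s))
            starts.append(s)
            ends.append(e)

    for chrom, length in chromsizes.items():
        n_bg = rng.poisson(config.background_rate * length)
        if n_bg:
            lens = rng.integers(lmin, lmax + 1, size=n_bg)
            s = rng.integers(0, np.maximum(1, length - lens))
            emit(chrom, s, s + lens)

    eff = truth.efficiency()
    for site in sites:
        e_val = float(eff.get(site.site_id, 0.0))
        if e_val <= 0:
            continue
        n = rng.poisson(config.bless_depth * e_val)
        if not n:
            continue
        lens = rng.integers(lmin, lmax + 1, size=n)
        offset = rng.integers(-CUT_END_JITTER, CUT_END_JITTER + 1, size=n)
        left_anchor = rng.random(n) < 0.5
        s = np.where(left_anchor, site.position + offset,
                     site.position + offset - lens)
        length = chromsizes[site.chrom]
        s = np.clip(s, 0, length - lens)
        emit(site.chrom, s, s + lens)

    if not starts:
        return fragments_frame([])
    frag = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts).astype(np.int64),
            "end": np.concatenate(ends).astype(np.int64),
        }
    )

    if config.aberrant_frac > 0:
        mask = rng.random(len(frag)) < config.aberrant_frac
        n_ab = int(mask.sum())
        if n_ab:
            ab_lens = rng.integers(501, ABERRANT_MAX_LEN + 1, size=n_ab)
            limits = frag.loc[mask, "chrom"].map(chromsizes).to_numpy(np.int64)
            s = frag.loc[mask, "start"].to_numpy(np.int64)
            s = np.minimum(s, np.maximum(0, limits - ab_lens))
            frag.loc[mask, "start"] = s
            frag.loc[mask, "end"] = s + ab_lens

    if config.duplicate_rate > 0:
        dup_mask = rng.random(len(frag)) < config.duplicate_rate
        frag = pd.concat([frag, frag[dup_mask]], ignore_index=True)

    frag = frag[["chrom", "start", "end"]].reset_index(drop=True)
    frag["start"] = frag["start"].astype(np.int64)
    frag["end"] = frag["end"].astype(np.int64)
    return frag


def fragments_to_pairs(fragments: pd.DataFrame) -> pd.DataFrame:
    """Paired-read view: two MATE_LENGTH bp mates at the fragment ends."""
    mate = np.minimum(MATE_LENGTH, fragments["end"] - fragments["start"])
    return pd.DataFrame(
        {
            "chrom1": fragments["chrom"],
            "start1": fragments["start"],
            "end1": fragments["start"] + mate,
            "chrom2": fragments["chrom"],
            "start2": fragments["end"] - mate,
            "end2": fragments["end"],
        }
    )


def simulate_chip(
    config: SimulationConfig,
    chromsizes: Mapping[str, int],
    sites: CandidateSiteSet,
    truth: GroundTruth,
    feature: FeatureSpec | str,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Draw damaged/undamaged coverage for one feature.

    Undamaged bins are Poisson(baseline_mean); damaged bins multiply the mean
    by ``fold`` (increase) or ``1/fold`` (decrease) within ``spread_bp`` of
    cleaved sites matching the feature's pathway specificity, leaving
    non-matching sites' expected damaged/undamaged ratio at exactly 1.
    Returns ``(damaged, undamaged)``; each track's library size is its
    realized total (floored at 1 so normalization stays defined).
    """
    if isinstance(feature, str):
        feature = config.feature(feature)
    bs = config.binsize
    truth_by_id = truth.table.set_index("site_id")

    multiplier: dict[str, np.ndarray] = {
        chrom: np.ones(n_bins(length, bs)) for chrom, length in chromsizes.items()
    }
    if feature.direction != "none":
        m_val = feature.fold if feature.direction == "increase" else 1.0 / feature.fold
        for site in sites:
            row = truth_by_id.loc[site.site_id]
            if not bool(row["cleaved"]):
                continue
            pw = str(row["pathway"])
            if feature.pathway_specificity == "HR_only" and pw != "HR":
                continue
            if feature.pathway_specificity == "NHEJ_only" and pw != "NHEJ":
                continue
            arr = multiplier[site.chrom]
            b0 = max(0, (site.position - feature.spread_bp) // bs)
            b1 = min(len(arr), (site.position + feature.spread_bp) // bs + 1)
            arr[b0:b1] = m_val

    tracks: list[CoverageTrack] = []
    for condition, use_mult in (("damaged", True), ("undamaged", False)):
        rng = np.random.default_rng(
            child_seed(config.seed, "chip", feature.name, condition)
        )
        values: dict[str, np.ndarray] = {}
        total = 0.0
        for chrom, length in chromsizes.items():
            mean = np.full(n_bins(length, bs), feature.baseline_mean)
            if use_mult:
                mean = mean * multiplier[chrom]
            if feature.overdispersion:
                shape = 1.0 / feature.overdispersion
                mean = mean * rng.gamma(shape, feature.overdispersion, size=len(mean))
            v = rng.poisson(mean).astype(float)
            values[chrom] = v
            total += v.sum()
        tracks.append(
            CoverageTrack(binsize=bs, values=values, library_size=max(1.0, total))
        )
    return tracks[0], tracks[1]


def simulate_all_chip(
    config: SimulationConfig,
    chromsizes: Mapping[str, int],
    sites: CandidateSiteSet,
    truth: GroundTruth,
) -> dict[str, dict[str, CoverageTrack]]:
    """All configured features; result[name] = {"damaged": ..., "undamaged": ...}."""
    out: dict[str, dict[str, CoverageTrack]] = {}
    for feat in config.feature_specs:
        damaged, undamaged = simulate_chip(config, chromsizes, sites, truth, feat)
        out[feat.name] = {"damaged": damaged, "undamaged": undamaged}
    return out


def write_fixture_bundle(config: SimulationConfig, outdir: str | Path) -> pd.DataFrame:
    """Run the full simulation and write every artefact as plain text.

    Emits sites BED, fragments BED + BEDPE, per-feature damaged/undamaged
    bedGraphs, chrom.sizes, the truth TSV and the config echoed as TOML, plus
    a manifest TSV listing each file with its row count. Intended for
    fixture-scale configurations; returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chromsizes, sites, truth = make_genome(config)
    fragments = simulate_bless(config, chromsizes, sites, truth)
    pairs = fragments_to_pairs(fragments)

    manifest_rows: list[tuple[str, int]] = []

    def record(name: str, rows: int) -> None:
        manifest_rows.append((name, rows))

    bsio.write_chromsizes(chromsizes, outdir / "chrom.sizes")
    record("chrom.sizes", len(chromsizes))
    bsio.write_sites(sites, outdir / "sites.bed")
    record("sites.bed", len(sites))
    bsio.write_fragments_bed(fragments, outdir / "fragments.bed")
    record("fragments.bed", len(fragments))
    bsio.write_bedpe(pairs, outdir / "fragments.bedpe")
    record("fragments.bedpe", len(pairs))
    bsio.write_table(truth.table, outdir / "truth.tsv")
    record("truth.tsv", len(truth.table))

    for feat in config.feature_specs:
        damaged, undamaged = simulate_chip(config, chromsizes, sites, truth, feat)
        for cond, track in (("damaged", damaged), ("undamaged", undamaged)):
            fname = f"{feat.name}.{cond}.bedgraph"
            bsio.write_coverage(track, outdir / fname, chromsizes)
            record(fname, sum(len(v) for v in track.values.values()))

    (outdir / "config.toml").write_text(config_to_toml(config))
    record("config.toml", len(config_to_toml(config).splitlines()))

    manifest = pd.DataFrame(manifest_rows, columns=["file", "rows"])
    bsio.write_table(manifest, outdir / "manifest.tsv")
    return manifest


def config_to_toml(config: SimulationConfig) -> str:
    """Echo the configuration as TOML (stable key order)."""
    lines = ["[simulation]"]
    lines.append(f"seed = {config.seed}")
    lines.append(f"n_candidate_sites = {config.n_candidate_sites}")
    lines.append(f"n_cleaved = {config.n_cleaved}")
    lo, hi = config.cleavage_efficiency_range
    lines.append(f"cleavage_efficiency_range = [{lo}, {hi}]")
    lines.append(f"n_hr = {config.n_hr}")
    lines.append(f"n_nhej = {config.n_nhej}")
    lines.append(f"bless_depth = {config.bless_depth}")
    lines.append(f"background_rate = {config.background_rate}")
    lines.append(f"frag_len_range = [{config.frag_len_range[0]}, {config.frag_len_range[1]}]")
    lines.append(f"aberrant_frac = {config.aberrant_frac}")
    lines.append(f"duplicate_rate = {config.duplicate_rate}")
    lines.append(f"binsize = {config.binsize}")
    lines.append("")
    lines.append("[simulation.chrom_spec]")
    for chrom, length in config.chrom_spec.items():
        lines.append(f'"{chrom}" = {length}')
    for feat in config.feature_specs:
        lines.append("")
        lines.append("[[simulation.features]]")
        lines.append(f'name = "{feat.name}"')
        lines.append(f'direction = "{feat.direction}"')
        lines.append(f"fold = {feat.fold}")
        lines.append(f"spread_bp = {feat.spread_bp}")
        lines.append(f'pathway_specificity = "{feat.pathway_specificity}"')
        lines.append(f"baseline_mean = {feat.baseline_mean}")
        if feat.overdispersion is not None:
            lines.append(f"overdispersion = {feat.overdispersion}")
    return "\n".join(lines) + "\n"
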