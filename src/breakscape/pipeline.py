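"""One-config orchestration: simulate -> call -> classify -> controls ->
signatures -> profiles, with a manifest making runs reproducible.

The configuration is TOML. Defaults mirror the study's printed parameters:
1 kb break-calling window, 500 bp fragment-length cap, top 80 validated
breaks, 4 kb / 1 kb pathway-ratio windows with 30 sites per class, a
1000-position control pool filtered at 1 Mb from the top 150 cleaved sites
down to 80 controls, 0.01/0.05 significance thresholds and a 50 kb profile
smoothing span.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import io as bsio
from .bless import BlessCallResult, run_bless
from .controls import generate_controls
from .core import (
    CandidateSiteSet,
    CoverageTrack,
    average_profile,
    log2_ratio_track,
    window_count_matrix,
)
from .pathway import classify_from_tracks
from .simulate import (
    FeatureSpec,
    GroundTruth,
    SimulationConfig,
    fragments_to_pairs,
    make_genome,
    simulate_all_chip,
    simulate_bless,
)
from .stats import (
    basal_group_enrichment,
    damage_change_test,
    multiscale_compare,
    spearman_matrix,
)

logger = logging.getLogger(__name__)

_KNOWN_TOP = {"mode", "seed", "outdir", "simulate", "bless", "classify",
              "controls", "signature", "profile", "paths"}


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; every stochastic stage gets a seed."""

    seed: int
    mode: str = "synthetic"
    outdir: str = "runs/breakscape"
    simulate: dict[str, Any] = field(default_factory=dict)
    bless: dict[str, Any] = field(default_factory=dict)
    classify: dict[str, Any] = field(default_factory=dict)
    controls: dict[str, Any] = field(default_factory=dict)
    signature: dict[str, Any] = field(default_factory=dict)
    profile: dict[str, Any] = field(default_factory=dict)
    paths: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_TOP
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        cfg = cls(
            seed=int(raw["seed"]),
            mode=raw.get("mode", "synthetic"),
            outdir=raw.get("outdir", "runs/breakscape"),
            simulate=dict(raw.get("simulate", {})),
            bless=dict(raw.get("bless", {})),
            classify=dict(raw.get("classify", {})),
            controls=dict(raw.get("controls", {})),
            signature=dict(raw.get("signature", {})),
            profile=dict(raw.get("profile", {})),
            paths=dict(raw.get("paths", {})),
        )
        if cfg.mode not in ("synthetic", "user_data"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        return cfg

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulate)
        feats = kwargs.pop("features", None)
        if feats is not None:
            kwargs["feature_specs"] = [FeatureSpec(**f) for f in feats]
        if "cleavage_efficiency_range" in kwargs:
            kwargs["cleavage_efficiency_range"] = tuple(
                kwargs["cleavage_efficiency_range"]
            )
        if "frag_len_range" in kwargs:
            kwargs["frag_len_range"] = tuple(kwargs["frag_len_range"])
        return SimulationConfig(seed=self.seed, **kwargs)


DEFAULT_DAMAGE_WINDOWS = [1000, 1_000_000]
DEFAULT_MULTISCALE_WINDOWS = [1000, 2000, 4000, 10_000, 1_000_000]
DEFAULT_BASAL_WINDOW = 4000
DEFAULT_PROFILE_FEATURES = ["gH2AX", "ubiquitin", "H1", "H2AZ", "H2BK120ac"]


@dataclass
class PipelineRun:
    """In-memory handles to every stage product of one run."""

    config: PipelineConfig
    chromsizes: dict[str, int]
    sites: CandidateSiteSet
    truth: GroundTruth | None
    tracks: dict[str, dict[str, CoverageTrack]]
    bless_result: BlessCallResult
    pathway_call: Any
    control_sites: CandidateSiteSet
    signature_table: pd.DataFrame
    multiscale: pd.DataFrame
    basal: pd.Series
    spearman: pd.DataFrame
    profiles: pd.DataFrame
    outdir: Path


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineRun:
    """Execute every stage in fixed order and write stage tables + manifest."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "stages": [],
        "files": {},
    }

    def finish_stage(name: str, **info: Any) -> None:
        manifest["stages"].append({"name": name, **info})
        logger.info("[%s] done %s", name, info)

    def write(df: pd.DataFrame, name: str, comments: list[str] | None = None) -> None:
        path = outdir / name
        bsio.write_table(df, path, comments)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][name] = {"rows": len(df), "sha256": digest}

    try:
        # -- stage 1: inputs -------------------------------------------------
        if config.mode == "synthetic":
            sim = config.simulation_config()
            chromsizes, sites, truth = make_genome(sim)
            fragments = simulate_bless(sim, chromsizes, sites, truth)
            pairs = fragments_to_pairs(fragments)
            tracks = simulate_all_chip(sim, chromsizes, sites, truth)
            truth_out = truth.table.copy()
            truth_out["efficiency"] = truth_out["efficiency"].round(4)
            write(truth_out, "truth.tsv")
            write(sites.to_frame(), "sites.tsv")
            finish_stage("simulate", n_sites=len(sites), n_fragments=len(fragments),
                         n_features=len(tracks))
        else:
            chromsizes, sites, truth, pairs, tracks = _load_user_data(config)
            finish_stage("load", n_sites=len(sites), n_pairs=len(pairs),
                         n_features=len(tracks))

        # -- stage 2: break calling -----------------------------------------
        b = config.bless
        bless_result = run_bless(
            pairs, sites, chromsizes,
            window_bp=b.get("window_bp", 1000),
            max_len=b.get("max_len", 500),
            top_k=b.get("top_k", 80),
        )
        tbl = bless_result.table.copy()
        tbl["count"] = tbl["count"].round(1)
        write(tbl, "bless.tsv",
              [f"threshold={bless_result.threshold:g} q1={bless_result.q1:g} "
               f"q3={bless_result.q3:g} window_bp={bless_result.window_bp}"])
        finish_stage("bless-call", n_outliers=bless_result.n_outliers,
                     n_validated=len(bless_result.validated_ids),
                     threshold=bless_result.threshold)

        # -- stage 3: pathway classification --------------------------------
        c = config.classify
        validated = sites.subset(bless_result.validated_ids)
        num_name = c.get("numerator", "RAD51")
        den_name = c.get("denominator", "XRCC4")
        pathway_call = classify_from_tracks(
            tracks[num_name]["damaged"], tracks[den_name]["damaged"],
            validated, chromsizes,
            w_num=c.get("w_num", 4000), w_den=c.get("w_den", 1000),
            k=c.get("k", 30), pseudocount=c.get("pseudocount", 1.0),
        )
        out = pathway_call.table.copy()
        out["ratio"] = out["ratio"].round(4)
        write(out, "labels.tsv")
        finish_stage("classify",
                     n_hr=len(pathway_call.ids("HR")),
                     n_nhej=len(pathway_call.ids("NHEJ")),
                     n_unassigned=len(pathway_call.ids("unassigned")))

        # -- stage 4: control regions ---------------------------------------
        ct = config.controls
        n_exclude = ct.get("exclude_top", 150)
        top = bless_result.table.nsmallest(n_exclude, "rank")["site_id"]
        excluded = sites.subset(list(top))
        all_tracks = [t for pair in tracks.values() for t in pair.values()]
        control_sites = generate_controls(
            chromsizes, excluded, all_tracks,
            n_pool=ct.get("n_pool", 1000), n_out=ct.get("n_out", 80),
            min_dist=ct.get("min_dist", 1_000_000),
            check_window=ct.get("check_window", 1000),
            seed=ct.get("seed", config.seed + 1),
        )
        write(control_sites.to_frame(), "controls.tsv")
        finish_stage("controls", n_controls=len(control_sites))

        # -- stage 5: signatures --------------------------------------------
        sg = config.signature
        damage_windows = sg.get("damage_windows", DEFAULT_DAMAGE_WINDOWS)
        ms_windows = sg.get("multiscale_windows", DEFAULT_MULTISCALE_WINDOWS)
        basal_window = sg.get("basal_window", DEFAULT_BASAL_WINDOW)
        groups = {
            "all_DSB": validated,
            "random": control_sites,
            "HR": sites.subset(pathway_call.ids("HR")),
            "NHEJ": sites.subset(pathway_call.ids("NHEJ")),
        }
        feature_names = list(tracks)
        sig_rows = []
        ms_hr: dict[int, pd.DataFrame] = {}
        ms_nhej: dict[int, pd.DataFrame] = {}
        for w in sorted(set(damage_windows) | set(ms_windows) | {basal_window}):
            per_group: dict[str, dict[str, pd.DataFrame]] = {}
            for gname, gsites in groups.items():
                flat = {}
                for feat in feature_names:
                    for cond in ("damaged", "undamaged"):
                        flat[f"{feat}.{cond}"] = tracks[feat][cond]
                wcm = window_count_matrix(flat, gsites, w, chromsizes)
                frame = wcm.to_frame()
                per_group[gname] = {
                    "damaged": frame[[f"{f}.damaged" for f in feature_names]]
                    .rename(columns=lambda s: s[: -len(".damaged")]),
                    "undamaged": frame[[f"{f}.undamaged" for f in feature_names]]
                    .rename(columns=lambda s: s[: -len(".undamaged")]),
                }
            if w in damage_windows:
                for gname in groups:
                    for feat in feature_names:
                        res = damage_change_test(
                            per_group[gname]["damaged"][feat],
                            per_group[gname]["undamaged"][feat],
                            feature=feat, window_bp=w, group=gname,
                        )
                        sig_rows.append(vars(res))
            if w in ms_windows:
                ms_hr[w] = per_group["HR"]["damaged"]
                ms_nhej[w] = per_group["NHEJ"]["damaged"]
            if w == basal_window:
                basal = basal_group_enrichment(
                    per_group["HR"]["undamaged"], per_group["NHEJ"]["undamaged"]
                )
                spear = spearman_matrix(per_group["all_DSB"]["damaged"])
        signature_table = pd.DataFrame(sig_rows)
        signature_table["p_value"] = signature_table["p_value"].map(
            lambda p: float(f"{p:.3g}")
        )
        write(signature_table, "signature.tsv")
        ms = multiscale_compare(ms_hr, ms_nhej)
        ms_long = ms.stack().rename("p_value").reset_index()
        ms_long["p_value"] = ms_long["p_value"].map(lambda p: float(f"{p:.3g}"))
        write(ms_long, "multiscale.tsv")
        write(basal.rename_axis("feature").reset_index(), "basal.tsv")
        write(spear.round(3).rename_axis("feature").reset_index(), "spearman.tsv")
        finish_stage("signature", n_tests=len(signature_table),
                     n_multiscale=ms.size)

        # -- stage 6: profiles ----------------------------------------------
        pf = config.profile
        feats = pf.get("features", [f for f in DEFAULT_PROFILE_FEATURES
                                    if f in tracks])
        half_window = pf.get("half_window", 5_000_000)
        smooth_span = pf.get("smooth_span", 50_000)
        step = pf.get("step", max(2000, half_window // 250))
        prof_rows = []
        for feat in feats:
            ratio = log2_ratio_track(
                tracks[feat]["damaged"], tracks[feat]["undamaged"],
                pseudocount=pf.get("pseudocount", 1.0),
            )
            offsets, prof = average_profile(
                ratio, validated, half_window,
                smooth_span=smooth_span, chromsizes=chromsizes, step=step,
            )
            prof_rows.append(pd.DataFrame(
                {"feature": feat, "offset": offsets, "log2_ratio": np.round(prof, 4)}
            ))
        profiles = pd.concat(prof_rows, ignore_index=True)
        write(profiles, "profiles.tsv")
        finish_stage("profile", n_features=len(feats), n_points=len(profiles))

    except Exception as e:
        stage = manifest["stages"][-1]["name"] if manifest["stages"] else "init"
        manifest["error"] = {"after_stage": stage, "message": str(e)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline aborted after stage {stage!r}: {e}") from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    run = PipelineRun(
        config=config, chromsizes=chromsizes, sites=sites,
        truth=truth, tracks=tracks, bless_result=bless_result,
        pathway_call=pathway_call, control_sites=control_sites,
        signature_table=signature_table, multiscale=ms_long, basal=basal,
        spearman=spear, profiles=profiles, outdir=outdir,
    )
    report_summary(outdir)
    return run


def _load_user_data(config: PipelineConfig):
    """Load aligned inputs for user_data mode from the [paths] section."""
    p = config.paths
    for key in ("chromsizes", "sites", "pairs"):
        if key not in p:
            raise ValueError(f"user_data mode requires paths.{key}")
    chromsizes = bsio.read_chromsizes(p["chromsizes"])
    sites = bsio.read_sites(p["sites"])
    pairs = bsio.read_bedpe(p["pairs"])
    binsize = int(p.get("binsize", 200))
    tracks: dict[str, dict[str, CoverageTrack]] = {}
    for entry in p.get("tracks", []):
        tracks[entry["name"]] = {
            "damaged": bsio.read_coverage(entry["damaged"], chromsizes, binsize),
            "undamaged": bsio.read_coverage(entry["undamaged"], chromsizes, binsize),
        }
    if not tracks:
        raise ValueError("user_data mode requires at least one [[paths.tracks]] entry")
    return chromsizes, sites, None, pairs, tracks


def report_summary(run_dir: str | Path) -> pd.DataFrame:
    """Tabulate the run: class sizes plus one category per feature x window x group.

    Reads the stage tables back from disk, so it also validates that a run
    directory is complete; writes summary.tsv and summary.md alongside them.
    """
    run_dir = Path(run_dir)
    needed = ["bless.tsv", "labels.tsv", "signature.tsv", "manifest.json"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run directory, missing {missing}")
    bless = bsio.read_table(run_dir / "bless.tsv")
    labels = bsio.read_table(run_dir / "labels.tsv")
    signature = bsio.read_table(run_dir / "signature.tsv")

    class_sizes = labels["label"].value_counts().to_dict()
    summary = signature[["feature", "window_bp", "group", "category"]].copy()
    bsio.write_table(summary, run_dir / "summary.tsv")

    lines = ["# Run summary", ""]
    lines.append(f"- candidate sites: {len(bless)}")
    lines.append(f"- outlier (cleaved) sites: {int(bless['outlier'].sum())}")
    lines.append(f"- validated breaks: {int(bless['validated'].sum())}")
    for label in ("HR", "NHEJ", "unassigned"):
        lines.append(f"- {label}: {class_sizes.get(label, 0)}")
    lines.append("")
    lines.append("| feature | window_bp | group | category |")
    lines.append("|---|---|---|---|")
    for r in summary.itertuples():
        lines.append(f"| {r.feature} | {r.window_bp} | {r.group} | {r.category} |")
    (run_dir / "summary.md").write_text("\n".join(lines) + "\n")
    return summary
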