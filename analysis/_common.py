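"""Shared configuration for the numbered analysis drivers.

Every driver recomputes its inputs deterministically from STUDY_SEED through
the library, so the scripts can run independently and in any order.
"""

from pathlib import Path

from breakscape.bless import run_bless
from breakscape.pathway import classify_from_tracks
from breakscape.simulate import (
    SimulationConfig,
    fragments_to_pairs,
    make_genome,
    simulate_bless,
    simulate_chip,
)

STUDY_SEED = 11
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config() -> SimulationConfig:
    return SimulationConfig(seed=STUDY_SEED)


def simulate_study(cfg=None):
    cfg = cfg or study_config()
    chromsizes, sites, truth = make_genome(cfg)
    fragments = simulate_bless(cfg, chromsizes, sites, truth)
    return cfg, chromsizes, sites, truth, fragments


def call_breaks(cfg, chromsizes, sites, fragments):
    return run_bless(fragments_to_pairs(fragments), sites, chromsizes)


def classify_breaks(cfg, chromsizes, sites, truth, validated_ids):
    rad51, _ = simulate_chip(cfg, chromsizes, sites, truth, "RAD51")
    xrcc4, _ = simulate_chip(cfg, chromsizes, sites, truth, "XRCC4")
    validated = sites.subset(validated_ids)
    return classify_from_tracks(rad51, xrcc4, validated, chromsizes, k=30)
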