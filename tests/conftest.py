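import numpy as np
import pandas as pd
import pytest

from breakscape.core import CandidateSite, CandidateSiteSet, CoverageTrack
from breakscape.simulate import FeatureSpec, SimulationConfig, make_genome


@pytest.fixture
def small_config() -> SimulationConfig:
    """Fixture-scale simulation: 60 candidate sites on a 4.2 Mb genome."""
    return SimulationConfig(
        seed=7,
        chrom_spec={"chr1": 2_000_000, "chr2": 2_000_000, "chrY": 200_000},
        n_candidate_sites=60,
        n_cleaved=24,
        n_hr=8,
        n_nhej=8,
        feature_specs=[
            FeatureSpec("RAD51", "increase", 8.0, 2000, "HR_only"),
            FeatureSpec("XRCC4", "increase", 6.0, 500, "NHEJ_only"),
            FeatureSpec("LIG4", "increase", 6.0, 500, "NHEJ_only"),
            FeatureSpec("mark_dec", "decrease", 4.0, 1000, "HR_only"),
            FeatureSpec("mark_null", "none", 1.0, 1000, "all"),
        ],
    )


@pytest.fixture
def small_genome(small_config):
    return make_genome(small_config)


@pytest.fixture
def flat_track() -> CoverageTrack:
    """Constant value 2.0 per 100 bp bin over a single 100 kb chromosome."""
    return CoverageTrack(
        binsize=100,
        values={"chr1": np.full(1000, 2.0)},
        library_size=1_000_000,
    )


@pytest.fixture
def three_sites() -> CandidateSiteSet:
    return CandidateSiteSet(
        [
            CandidateSite("a", "chr1", 10_000),
            CandidateSite("b", "chr1", 50_000),
            CandidateSite("c", "chr1", 90_000),
        ]
    )


def random_fragments(rng: np.random.Generator, n: int, length: int = 100_000) -> pd.DataFrame:
    starts = rng.integers(0, length - 500, size=n)
    lens = rng.integers(1, 500, size=n)
    return pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + lens}
    ).astype({"start": np.int64, "end": np.int64})
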