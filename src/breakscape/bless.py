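"""Break calling from fragment data at candidate cut sites.

The processing chain is fixed: reconstitute fragments from read pairs,
drop aberrantly long fragments (> 500 bp), collapse exact-coordinate
duplicates, count fragments in a 1 kb window around every candidate site,
flag IQR outliers (count > Q3 + 1.5 x IQR, type-7 quartiles) as cleaved, and
keep the top 80 outliers by count as the validated break set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    CandidateSiteSet,
    WindowCountMatrix,
    count_fragments_in_windows,
    window_around,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1000
DEFAULT_MAX_FRAGMENT_LEN = 500
DEFAULT_TOP_K = 80


def reconstitute_fragments(pairs: pd.DataFrame) -> pd.DataFrame:
    """One fragment per proper pair, spanning [min(starts), max(ends)).

    Pairs with mates on different chromosomes cannot form a genomic fragment;
    they are dropped and counted in the log.
    """
    if len(pairs) == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    same = pairs["chrom1"] == pairs["chrom2"]
    n_dropped = int((~same).sum())
    if n_dropped:
        logger.info("dropped %d inter-chromosomal pairs", n_dropped)
    kept = pairs[same]
    frag = pd.DataFrame(
        {
            "chrom": kept["chrom1"].astype(str),
            "start": np.minimum(kept["start1"], kept["start2"]).astype(np.int64),
            "end": np.maximum(kept["end1"], kept["end2"]).astype(np.int64),
        }
    ).reset_index(drop=True)
    if (frag["start"] >= frag["end"]).any():
        raise ValueError("degenerate pair produced an empty fragment")
    return frag


def filter_fragment_length(
    fragments: pd.DataFrame, max_len: int = DEFAULT_MAX_FRAGMENT_LEN
) -> pd.DataFrame:
    """Drop fragments with length strictly greater than ``max_len``."""
    if len(fragments) == 0:
        return fragments.copy()
    keep = (fragments["end"] - fragments["start"]) <= max_len
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("length filter dropped %d/%d fragments (> %d bp)",
                    n_dropped, len(fragments), max_len)
    return fragments[keep].reset_index(drop=True)


def deduplicate_fragments(fragments: pd.DataFrame) -> pd.DataFrame:
    """Keep one fragment per exact (chrom, start, end); output sorted."""
    out = (
        fragments.drop_duplicates(subset=["chrom", "start", "end"])
        .sort_values(["chrom", "start", "end"], kind="stable")
        .reset_index(drop=True)
    )
    n_dup = len(fragments) - len(out)
    if n_dup:
        logger.info("removed %d exact-coordinate duplicates", n_dup)
    return out


def count_candidate_windows(
    fragments: pd.DataFrame,
    sites: CandidateSiteSet,
    chromsizes: Mapping[str, int],
    window_bp: int = DEFAULT_WINDOW_BP,
    dataset_id: str = "BLESS",
) -> WindowCountMatrix:
    """Per-site fragment overlap counts in a window around each site."""
    if len(sites) == 0:
        raise ValueError("site set is empty")
    intervals = [window_around(s, window_bp, chromsizes[s.chrom]) for s in sites]
    counts = count_fragments_in_windows(fragments, intervals)
    return WindowCountMatrix(
        site_ids=sites.site_ids,
        dataset_ids=[dataset_id],
        window_bp=window_bp,
        counts=counts[:, None].astype(float),
    )


@dataclass
class BlessCallResult:
    """Outlier calls plus validation flags over the candidate sites.

    ``table`` columns: site_id, chrom, position, count, outlier, validated,
    rank (1 = highest count, ties broken by site_id).
    """

    table: pd.DataFrame
    q1: float
    q3: float
    threshold: float
    window_bp: int
    top_k: int | None = None

    @property
    def n_outliers(self) -> int:
        return int(self.table["outlier"].sum())

    @property
    def validated_ids(self) -> list[str]:
        return list(self.table.loc[self.table["validated"], "site_id"])

    @property
    def outlier_ids(self) -> list[str]:
        return list(self.table.loc[self.table["outlier"], "site_id"])


def call_outliers(
    counts: WindowCountMatrix,
    sites: CandidateSiteSet | None = None,
) -> BlessCallResult:
    """Flag sites whose window count exceeds Q3 + 1.5 x IQR.

    Quartiles use linear interpolation of order statistics (Hyndman-Fan
    type 7, the numpy default); the comparison is strictly greater-than.
    """
    values = counts.counts[:, 0]
    if len(values) < 4:
        raise ValueError("need at least 4 sites for stable quartiles")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation = type 7
    threshold = q3 + 1.5 * (q3 - q1)
    outlier = values > threshold

    site_ids = counts.site_ids
    order = sorted(
        range(len(site_ids)), key=lambda i: (-values[i], site_ids[i])
    )
    rank = np.empty(len(site_ids), dtype=np.int64)
    rank[order] = np.arange(1, len(site_ids) + 1)

    table = pd.DataFrame(
        {
            "site_id": site_ids,
            "count": values,
            "outlier": outlier,
            "validated": False,
            "rank": rank,
        }
    )
    if sites is not None:
        meta = sites.to_frame()
        table = table.merge(meta, on="site_id", how="left")
        table = table[
            ["site_id", "chrom", "position", "count", "outlier", "validated", "rank"]
        ]
    return BlessCallResult(
        table=table,
        q1=float(q1),
        q3=float(q3),
        threshold=float(threshold),
        window_bp=counts.window_bp,
    )


def select_validated(result: BlessCallResult, top_k: int = DEFAULT_TOP_K) -> BlessCallResult:
    """Mark the ``top_k`` outliers with the highest counts as validated.

    When fewer outliers exist than ``top_k`` every outlier is validated and a
    warning is logged. Ties at the cutoff resolve by ascending site_id.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    table = result.table.copy()
    outliers = table[table["outlier"]]
    if len(outliers) < top_k:
        logger.warning(
            "only %d outliers available for top_k=%d", len(outliers), top_k
        )
    chosen = (
        outliers.sort_values(["count", "site_id"],
                             ascending=[False, True], kind="stable")
        .head(top_k)["site_id"]
    )
    table["validated"] = table["site_id"].isin(set(chosen))
    return BlessCallResult(
        table=table,
        q1=result.q1,
        q3=result.q3,
        threshold=result.threshold,
        window_bp=result.window_bp,
        top_k=top_k,
    )


def run_bless(
    pairs: pd.DataFrame,
    sites: CandidateSiteSet,
    chromsizes: Mapping[str, int],
    window_bp: int = DEFAULT_WINDOW_BP,
    max_len: int = DEFAULT_MAX_FRAGMENT_LEN,
    top_k: int = DEFAULT_TOP_K,
) -> BlessCallResult:
    """Full chain: reconstitute -> length-filter -> dedup -> count -> call -> select."""
    fragments = reconstitute_fragments(pairs)
    fragments = filter_fragment_length(fragments, max_len)
    fragments = deduplicate_fragments(fragments)
    counts = count_candidate_windows(fragments, sites, chromsizes, window_bp)
    result = call_outliers(counts, sites)
    return select_validated(result, top_k)


def run_bless_fragments(
    fragments: pd.DataFrame,
    sites: CandidateSiteSet,
    chromsizes: Mapping[str, int],
    window_bp: int = DEFAULT_WINDOW_BP,
    max_len: int = DEFAULT_MAX_FRAGMENT_LEN,
    top_k: int = DEFAULT_TOP_K,
) -> BlessCallResult:
    """Same chain entered at the fragment stage (already-reconstituted input)."""
    fragments = filter_fragment_length(fragments, max_len)
    fragments = deduplicate_fragments(fragments)
    counts = count_candidate_windows(fragments, sites, chromsizes, window_bp)
    result = call_outliers(counts, sites)
    return select_validated(result, top_k)
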