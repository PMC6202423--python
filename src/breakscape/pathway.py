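"""HR-prone / NHEJ-prone classification of validated breaks.

A break's repair-pathway bias is scored as the ratio of a resection-factor
ChIP signal in a 4 kb window (numerator, e.g. RAD51) to an end-joining-factor
signal in a 1 kb window (denominator, e.g. XRCC4 or DNA ligase IV), both on
the counts-per-million scale with a pseudocount. The top k ratios are called
HR-prone and the bottom k NHEJ-prone (k = 30 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CandidateSiteSet, CoverageTrack, track_window_sums, window_around

logger = logging.getLogger(__name__)

DEFAULT_W_NUM = 4000
DEFAULT_W_DEN = 1000
DEFAULT_K = 30


def pathway_ratio(
    num_track: CoverageTrack,
    den_track: CoverageTrack,
    sites: CandidateSiteSet,
    chromsizes: Mapping[str, int],
    w_num: int = DEFAULT_W_NUM,
    w_den: int = DEFAULT_W_DEN,
    pseudocount: float = 1.0,
    normalized: bool = True,
) -> pd.Series:
    """Per-site (numerator window sum + pc) / (denominator window sum + pc)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    num_iv = [window_around(s, w_num, chromsizes[s.chrom]) for s in sites]
    den_iv = [window_around(s, w_den, chromsizes[s.chrom]) for s in sites]
    num = track_window_sums(num_track, num_iv, normalized=normalized)
    den = track_window_sums(den_track, den_iv, normalized=normalized)
    ratios = (num + pseudocount) / (den + pseudocount)
    return pd.Series(ratios, index=sites.site_ids, name="ratio")


@dataclass
class PathwayCall:
    """Classification outcome; table columns: site_id, ratio, label."""

    table: pd.DataFrame
    k: int
    degenerate: bool = False

    def ids(self, label: str) -> list[str]:
        return list(self.table.loc[self.table["label"] == label, "site_id"])

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("site_id")["label"]


def classify(ratios: pd.Series, k: int = DEFAULT_K) -> PathwayCall:
    """Top-k ratios -> HR, bottom-k -> NHEJ, remainder unassigned.

    Ties at either cutoff break by ascending site_id. If fewer than 2k sites
    are available k shrinks to floor(n/2) with a warning.
    """
    n = len(ratios)
    if n < 2:
        raise ValueError("need at least 2 sites to classify")
    eff_k = k
    if n < 2 * k:
        eff_k = n // 2
        logger.warning("only %d sites: shrinking k from %d to %d", n, k, eff_k)
    df = pd.DataFrame({"site_id": ratios.index, "ratio": ratios.to_numpy(float)})
    if df["ratio"].nunique() == 1:
        logger.warning("degenerate classification: all ratios equal; "
                       "membership determined solely by site_id order")
        degenerate = True
    else:
        degenerate = False
    # sort once, descending ratio with site_id ascending as the tie-break
    order = df.sort_values(["ratio", "site_id"],
                           ascending=[False, True], kind="stable")
    labels = pd.Series("unassigned", index=order.index, dtype=object)
    labels.iloc[:eff_k] = "HR"
    if eff_k:
        # bottom-k among the remaining rows: lowest ratios, ties by site_id
        remaining = df.loc[~df.index.isin(order.index[:eff_k])]
        bottom = remaining.sort_values(
            ["ratio", "site_id"], ascending=[True, True], kind="stable"
        ).index[:eff_k]
        labels.loc[bottom] = "NHEJ"
    df["label"] = labels.sort_index()
    df = df.sort_values("site_id", kind="stable").reset_index(drop=True)
    return PathwayCall(table=df, k=eff_k, degenerate=degenerate)


def classify_from_tracks(
    num_track: CoverageTrack,
    den_track: CoverageTrack,
    sites: CandidateSiteSet,
    chromsizes: Mapping[str, int],
    w_num: int = DEFAULT_W_NUM,
    w_den: int = DEFAULT_W_DEN,
    k: int = DEFAULT_K,
    pseudocount: float = 1.0,
) -> PathwayCall:
    ratios = pathway_ratio(
        num_track, den_track, sites, chromsizes,
        w_num=w_num, w_den=w_den, pseudocount=pseudocount,
    )
    return classify(ratios, k=k)
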