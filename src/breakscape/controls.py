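"""Constrained random control regions used as the comparison background.

A pool of positions is drawn uniformly over the non-Y genome (chromosomes
weighted by length), then filtered: positions within 1 Mb of any excluded
top-cleaved site are removed, as are positions whose 1 kb window has zero
signal in ANY provided coverage track (systematically underrepresented
regions). A fixed number of survivors is sampled uniformly.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .core import (
    CandidateSite,
    CandidateSiteSet,
    CoverageTrack,
    GenomicInterval,
    track_window_sums,
)

DEFAULT_N_POOL = 1000
DEFAULT_N_OUT = 80
DEFAULT_MIN_DIST = 1_000_000
DEFAULT_CHECK_WINDOW = 1000


class ControlSamplingError(RuntimeError):
    """Raised when the filters exhaust the pool; message lists attrition."""


def generate_controls(
    chromsizes: Mapping[str, int],
    excluded_sites: Sequence[CandidateSite] | CandidateSiteSet,
    tracks: Sequence[CoverageTrack],
    n_pool: int = DEFAULT_N_POOL,
    n_out: int = DEFAULT_N_OUT,
    min_dist: int = DEFAULT_MIN_DIST,
    check_window: int = DEFAULT_CHECK_WINDOW,
    seed: int | None = None,
) -> CandidateSiteSet:
    """Draw the control-region set; deterministic under ``seed``.

    ``excluded_sites`` should carry the top-ranked cleaved positions (the
    caller passes the top 150 by break-signal count). Raises
    :class:`ControlSamplingError` when fewer than ``n_out`` positions survive,
    naming each filter's attrition count.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if not tracks:
        raise ValueError("at least one coverage track is required")
    rng = np.random.default_rng(seed)

    non_y = [c for c in chromsizes if c != "chrY"]
    lengths = np.array([chromsizes[c] for c in non_y], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(non_y), size=n_pool, p=probs)
    positions = np.array(
        [int(rng.integers(0, chromsizes[non_y[i]])) for i in chrom_idx]
    )
    pool = [(non_y[i], p) for i, p in zip(chrom_idx, positions)]

    excl_lists: dict[str, list[int]] = {}
    for s in excluded_sites:
        excl_lists.setdefault(s.chrom, []).append(s.position)
    excl_by_chrom = {c: np.sort(np.array(v)) for c, v in excl_lists.items()}

    def far_enough(chrom: str, pos: int) -> bool:
        arr = excl_by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            return True
        i = np.searchsorted(arr, pos)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(int(arr[j]) - pos) < min_dist:
                return False
        return True

    after_dist = [(c, p) for c, p in pool if far_enough(c, p)]
    n_dist_removed = len(pool) - len(after_dist)

    def check_intervals(entries: list[tuple[str, int]]) -> list[GenomicInterval]:
        ivs = []
        for chrom, pos in entries:
            start = max(0, pos - check_window // 2)
            end = min(chromsizes[chrom], pos + (check_window + 1) // 2)
            if start >= end:
                start, end = max(0, chromsizes[chrom] - 1), chromsizes[chrom]
            ivs.append(GenomicInterval(chrom, start, end))
        return ivs

    survivors = after_dist
    n_null_removed = 0
    if survivors:
        ivs = check_intervals(survivors)
        nonzero = np.ones(len(survivors), dtype=bool)
        for track in tracks:
            sums = track_window_sums(track, ivs, normalized=False)
            nonzero &= sums > 0
        n_null_removed = int((~nonzero).sum())
        survivors = [e for e, ok in zip(survivors, nonzero) if ok]

    if len(survivors) < n_out:
        raise ControlSamplingError(
            f"only {len(survivors)}/{n_pool} positions survive the filters "
            f"(need {n_out}): distance filter removed {n_dist_removed}/{n_pool}, "
            f"null-count filter removed {n_null_removed}/{len(after_dist)}"
        )
    keep = rng.choice(len(survivors), size=n_out, replace=False)
    chosen = sorted((survivors[i] for i in keep), key=lambda t: (t[0], t[1]))
    width = len(str(n_out))
    return CandidateSiteSet(
        CandidateSite(f"ctrl_{i + 1:0{width}d}", chrom, pos)
        for i, (chrom, pos) in enumerate(chosen)
    )
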