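"""Genomic primitives shared by every pipeline stage.

Coordinates are 0-based, half-open everywhere, matching BED/bedGraph
conventions. Coverage is held as per-bin counts (``CoverageTrack``); window
sums weight partial bins by overlap fraction and can be scaled to
counts-per-million using the track's library size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CandidateSite:
    """A candidate cut site, reduced to the midpoint of its recognition motif."""

    site_id: str
    chrom: str
    position: int

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        if self.position < 0:
            raise ValueError(f"site {self.site_id}: position must be >= 0")


class CandidateSiteSet:
    """Ordered collection of :class:`CandidateSite` with unique identifiers."""

    def __init__(self, sites: Iterable[CandidateSite]):
        self._sites = list(sites)
        seen: set[str] = set()
        for s in self._sites:
            if s.site_id in seen:
                raise ValueError(f"duplicate site_id {s.site_id!r}")
            seen.add(s.site_id)

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self) -> Iterator[CandidateSite]:
        return iter(self._sites)

    def __getitem__(self, i: int) -> CandidateSite:
        return self._sites[i]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self._sites]

    def subset(self, ids: Sequence[str]) -> "CandidateSiteSet":
        by_id = {s.site_id: s for s in self._sites}
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise KeyError(f"unknown site ids: {missing[:5]}")
        return CandidateSiteSet(by_id[i] for i in ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [s.site_id for s in self._sites],
                "chrom": [s.chrom for s in self._sites],
                "position": [s.position for s in self._sites],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CandidateSiteSet":
        return cls(
            CandidateSite(str(r.site_id), str(r.chrom), int(r.position))
            for r in df.itertuples()
        )


class FragmentRecord(NamedTuple):
    """One reconstituted sequencing fragment as a half-open interval."""

    chrom: str
    start: int
    end: int


def fragments_frame(records: Iterable[FragmentRecord | tuple]) -> pd.DataFrame:
    """Build the canonical fragment table (columns chrom/start/end)."""
    df = pd.DataFrame(records, columns=FRAGMENT_COLUMNS)
    if len(df):
        if (df["start"] >= df["end"]).any():
            raise ValueError("fragments must satisfy start < end")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    else:
        df = df.astype({"start": np.int64, "end": np.int64, "chrom": str})
    return df


@dataclass
class CoverageTrack:
    """Binned non-negative coverage per chromosome plus the library size.

    ``values[chrom]`` has ``ceil(length / binsize)`` entries holding the raw
    per-bin signal; the final bin may cover fewer than ``binsize`` bases.
    ``library_size`` is the total raw fragment/read count of the sample and
    drives counts-per-million normalization.
    """

    binsize: int
    values: dict[str, np.ndarray]
    library_size: float

    def __post_init__(self) -> None:
        if self.binsize < 1:
            raise ValueError("binsize must be >= 1")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if (v < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.values[chrom] = v

    def chrom_length(self, chrom: str) -> int:
        # upper bound implied by the bin vector; callers holding true
        # chromosome sizes should prefer those
        return len(self.values[chrom]) * self.binsize

    @property
    def cpm_factor(self) -> float:
        return 1e6 / self.library_size


@dataclass
class WindowCountMatrix:
    """Sites x datasets matrix of window-summed signal at one window width."""

    site_ids: list[str]
    dataset_ids: list[str]
    window_bp: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.site_ids), len(self.dataset_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.dataset_ids)} datasets"
            )
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.site_ids, columns=self.dataset_ids)

    def column(self, dataset_id: str) -> np.ndarray:
        return self.counts[:, self.dataset_ids.index(dataset_id)]


def window_around(site: CandidateSite, width: int, chrom_length: int) -> GenomicInterval:
    """Symmetric window of ``width`` bp centred on a site, clipped to the chromosome.

    The window is ``[position - floor(width/2), position + ceil(width/2))``;
    clipping at ``[0, chrom_length)`` may shorten it, and clipped windows are
    used as-is rather than discarded.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    start = max(0, site.position - width // 2)
    end = min(chrom_length, site.position + (width + 1) // 2)
    if start >= end:  # site beyond chromosome end; degenerate but defined
        raise ValueError(
            f"window for {site.site_id} at {site.chrom}:{site.position} "
            f"falls outside chromosome of length {chrom_length}"
        )
    return GenomicInterval(site.chrom, start, end)


class _FragmentIndex:
    """Sorted start/end arrays per chromosome for O(log n) overlap counting."""

    def __init__(self, fragments: pd.DataFrame):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, grp in fragments.groupby("chrom", sort=False):
            self._starts[str(chrom)] = np.sort(grp["start"].to_numpy(np.int64))
            self._ends[str(chrom)] = np.sort(grp["end"].to_numpy(np.int64))

    def count(self, interval: GenomicInterval) -> int:
        starts = self._starts.get(interval.chrom)
        if starts is None:
            return 0
        ends = self._ends[interval.chrom]
        # overlap by >= 1 bp: start < interval.end and end > interval.start
        n_start_before_end = int(np.searchsorted(starts, interval.end, side="left"))
        n_end_at_or_before_start = int(
            np.searchsorted(ends, interval.start, side="right")
        )
        return n_start_before_end - n_end_at_or_before_start


def count_fragments_in_window(fragments: pd.DataFrame, interval: GenomicInterval) -> int:
    """Number of fragments overlapping ``interval`` by at least one base."""
    if len(fragments) == 0:
        return 0
    return _FragmentIndex(fragments).count(interval)


def count_fragments_in_windows(
    fragments: pd.DataFrame, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Vectorised overlap counts for many windows over one fragment set."""
    idx = _FragmentIndex(fragments) if len(fragments) else None
    out = np.zeros(len(intervals), dtype=np.int64)
    if idx is None:
        return out
    for i, iv in enumerate(intervals):
        out[i] = idx.count(iv)
    return out


def _bin_cumulative(track: CoverageTrack, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    vals = track.values[chrom]
    edges = np.minimum(
        np.arange(len(vals) + 1, dtype=np.int64) * track.binsize,
        len(vals) * track.binsize,
    )
    return vals, edges


def track_window_sum(
    track: CoverageTrack, interval: GenomicInterval, normalized: bool = True
) -> float:
    """Sum of track signal over an interval, partial bins weighted by overlap.

    With ``normalized=True`` the raw sum is scaled by ``1e6 / library_size``
    (counts per million).
    """
    return float(
        track_window_sums(track, [interval], normalized=normalized)[0]
    )


def track_window_sums(
    track: CoverageTrack,
    intervals: Sequence[GenomicInterval],
    normalized: bool = True,
) -> np.ndarray:
    """Vectorised :func:`track_window_sum` over many intervals."""
    out = np.zeros(len(intervals), dtype=float)
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        if chrom not in track.values:
            raise KeyError(f"chromosome {chrom!r} not present in track")
        vals = track.values[chrom]
        bs = track.binsize
        nbins = len(vals)
        csum = np.concatenate([[0.0], np.cumsum(vals)])

        def cum_at(pos: np.ndarray) -> np.ndarray:
            # integral of per-bp density from 0 to pos; last bin may be short
            k = np.clip(pos // bs, 0, nbins - 1)
            frac = (pos - k * bs) / bs
            return csum[k] + vals[k] * np.clip(frac, 0.0, 1.0)

        starts = np.array([intervals[i].start for i in idxs], dtype=np.int64)
        ends = np.array([intervals[i].end for i in idxs], dtype=np.int64)
        limit = nbins * bs
        if (ends > limit).any():
            bad = [i for i in idxs if intervals[i].end > limit]
            raise ValueError(
                f"interval beyond track extent on {chrom}: "
                f"{intervals[bad[0]].start}-{intervals[bad[0]].end} > {limit}"
            )
        sums = cum_at(ends) - cum_at(starts)
        out[np.array(idxs)] = sums
    if normalized:
        out *= track.cpm_factor
    return out


def log2_ratio(treated_sum: float, untreated_sum: float, pseudocount: float = 1.0) -> float:
    """``log2((treated + pc) / (untreated + pc))`` on the per-million scale."""
    if treated_sum < 0 or untreated_sum < 0:
        raise ValueError("sums must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return float(np.log2((treated_sum + pseudocount) / (untreated_sum + pseudocount)))


def window_count_matrix(
    tracks: Mapping[str, CoverageTrack],
    sites: CandidateSiteSet,
    window_bp: int,
    chromsizes: Mapping[str, int],
    normalized: bool = True,
) -> WindowCountMatrix:
    """Window sums for every site x track, as one matrix at ``window_bp``."""
    dataset_ids = list(tracks)
    intervals = [
        window_around(s, window_bp, chromsizes[s.chrom]) for s in sites
    ]
    cols = [
        track_window_sums(tracks[d], intervals, normalized=normalized)
        for d in dataset_ids
    ]
    return WindowCountMatrix(
        site_ids=sites.site_ids,
        dataset_ids=dataset_ids,
        window_bp=window_bp,
        counts=np.column_stack(cols) if cols else np.zeros((len(sites), 0)),
    )


def moving_average(values: np.ndarray, span_points: int) -> np.ndarray:
    """Centred moving average truncated at the edges (constants preserved)."""
    v = np.asarray(values, dtype=float)
    if span_points <= 1 or len(v) == 0:
        return v.copy()
    if span_points % 2 == 0:
        span_points += 1
    kernel = np.ones(span_points)
    mask = np.isfinite(v)
    filled = np.where(mask, v, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(mask.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def average_profile(
    track: CoverageTrack,
    sites: CandidateSiteSet,
    half_window: int,
    smooth_span: int = 0,
    chromsizes: Mapping[str, int] | None = None,
    step: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean signal around sites as a function of offset from the site.

    Returns ``(offsets, profile)`` where offsets run over
    ``[-half_window, +half_window)`` with stride ``step`` (default: the track
    binsize). Sites whose window sticks out of the chromosome contribute only
    their defined positions. ``smooth_span`` > 0 applies a centred moving
    average of that many bp, truncated at the profile edges.
    """
    if len(sites) == 0:
        raise ValueError("site set is empty")
    if half_window <= 0:
        raise ValueError("half_window must be > 0")
    if smooth_span < 0:
        raise ValueError("smooth_span must be >= 0")
    step = step or track.binsize
    offsets = np.arange(-half_window, half_window, step, dtype=np.int64)
    total = np.zeros(len(offsets), dtype=float)
    count = np.zeros(len(offsets), dtype=float)
    for site in sites:
        vals = track.values.get(site.chrom)
        if vals is None:
            raise KeyError(f"chromosome {site.chrom!r} not in track")
        length = (
            chromsizes[site.chrom] if chromsizes is not None
            else len(vals) * track.binsize
        )
        pos = site.position + offsets
        ok = (pos >= 0) & (pos < length)
        bins = pos[ok] // track.binsize
        total[ok] += vals[bins]
        count[ok] += 1.0
    with np.errstate(invalid="ignore"):
        profile = total / count
    profile[count == 0] = np.nan
    if smooth_span > 0:
        profile = moving_average(profile, int(round(smooth_span / step)))
    return offsets, profile


def log2_ratio_track(
    treated: CoverageTrack,
    untreated: CoverageTrack,
    pseudocount: float = 1.0,
) -> CoverageTrack:
    """Per-bin log2 ratio of treated over untreated coverage.

    Libraries are equalised on the count scale by scaling the larger one down
    to the smaller (the usual coverage-comparison convention), so the
    pseudocount stays small relative to typical bin counts. The result reuses
    :class:`CoverageTrack` as a container for an already-normalized signal
    (library_size 1e6, CPM factor 1); bin values may be negative, so
    validation is bypassed.
    """
    if treated.binsize != untreated.binsize:
        raise ValueError("tracks must share a binsize")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    ref = min(treated.library_size, untreated.library_size)
    f_t = ref / treated.library_size
    f_u = ref / untreated.library_size
    out = CoverageTrack.__new__(CoverageTrack)
    out.binsize = treated.binsize
    out.library_size = 1e6
    vals: dict[str, np.ndarray] = {}
    for chrom in treated.values:
        if chrom not in untreated.values:
            raise KeyError(f"chromosome {chrom!r} missing from untreated track")
        t = treated.values[chrom] * f_t
        u = untreated.values[chrom] * f_u
        vals[chrom] = np.log2((t + pseudocount) / (u + pseudocount))
    out.values = vals
    return out


def math_ceil_div(a: int, b: int) -> int:
    return -(-a // b)


def n_bins(length: int, binsize: int) -> int:
    if length <= 0 or binsize <= 0:
        raise ValueError("length and binsize must be positive")
    return math_ceil_div(length, binsize)
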