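"""Readers and writers for the plain-text genomic formats the pipeline touches.

BED/BEDPE/bedGraph are emitted tab-separated, newline-terminated, without
headers; result tables are TSV with a single header row. bedGraph files carry
the library size in a leading ``# library_size=`` comment so coverage tracks
round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    CandidateSite,
    CandidateSiteSet,
    CoverageTrack,
    fragments_frame,
    n_bins,
)


class ParseError(ValueError):
    """Malformed row in a genomic text format; message carries the line number."""


def read_chromsizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                length = int(parts[1])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from e
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: length must be positive")
            if parts[0] in sizes:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {parts[0]!r}")
            sizes[parts[0]] = length
    return sizes


def write_chromsizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_sites(path: str | Path) -> CandidateSiteSet:
    """Read candidate cut sites from BED3+; position = interval midpoint.

    Auto-generates ids ``site_<n>`` when the name column is absent; duplicate
    names are an error.
    """
    sites: list[CandidateSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected BED3+, got {len(parts)} columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from e
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: need 0 <= start < end")
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else f"site_{lineno}"
            sites.append(CandidateSite(name, parts[0], (start + end) // 2))
    try:
        return CandidateSiteSet(sites)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def write_sites(sites: CandidateSiteSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.site_id}\n")


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected BED3+")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from e
            if rows[-1][1] >= rows[-1][2]:
                raise ParseError(f"{path}:{lineno}: need start < end")
    return fragments_frame(rows)


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments.to_csv(path, sep="\t", header=False, index=False,
                     columns=["chrom", "start", "end"])


BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def read_bedpe(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected BEDPE (>= 6 columns)")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]),
                     parts[3], int(parts[4]), int(parts[5]))
                )
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from e
    df = pd.DataFrame(rows, columns=BEDPE_COLUMNS)
    if len(df) == 0:
        df = df.astype(
            {c: (np.int64 if c.startswith(("start", "end")) else str)
             for c in BEDPE_COLUMNS}
        )
    return df


def write_bedpe(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", header=False, index=False, columns=BEDPE_COLUMNS)


def read_coverage(
    path: str | Path,
    chromsizes: Mapping[str, int],
    binsize: int,
    library_size: float | None = None,
) -> CoverageTrack:
    """Read a bedGraph into a binned track.

    Intervals must be non-overlapping per chromosome and inside ``chromsizes``.
    Intervals not aligned to bins are rebinned by overlap-weighted averaging
    (a bin's value is the mean of the piecewise-constant signal over the bin,
    uncovered bases counting as 0). The library size is taken from a leading
    ``# library_size=`` comment unless given explicitly; it defaults to the
    rounded total signal if neither is available.
    """
    values = {
        chrom: np.zeros(n_bins(length, binsize), dtype=float)
        for chrom, length in chromsizes.items()
    }
    parsed_lib: float | None = None
    last_end: dict[str, int] = {}
    intervals_seen: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("library_size="):
                    parsed_lib = float(stripped.split("=", 1)[1])
                continue
            if not line or line.startswith(("track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected bedGraph (4 columns)")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: bad bedGraph row") from e
            if chrom not in values:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: need 0 <= start < end")
            if end > chromsizes[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: interval end {end} beyond chromosome "
                    f"{chrom} length {chromsizes[chrom]}"
                )
            intervals_seen.setdefault(chrom, []).append((start, end))
            _add_interval(values[chrom], binsize, chromsizes[chrom], start, end, value)
    for chrom, ivs in intervals_seen.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ParseError(
                    f"{path}: overlapping intervals on {chrom}: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
    if library_size is None:
        library_size = parsed_lib
    if library_size is None:
        library_size = max(1.0, float(round(sum(v.sum() for v in values.values()))))
    return CoverageTrack(binsize=binsize, values=values, library_size=library_size)


def _add_interval(
    bins: np.ndarray, binsize: int, chrom_length: int, start: int, end: int, value: float
) -> None:
    b0 = start // binsize
    b1 = (end - 1) // binsize
    for b in range(b0, b1 + 1):
        lo = max(start, b * binsize)
        hi = min(end, (b + 1) * binsize)
        width = min(binsize, chrom_length - b * binsize)
        bins[b] += value * (hi - lo) / width


def write_coverage(
    track: CoverageTrack, path: str | Path, chromsizes: Mapping[str, int] | None = None
) -> None:
    """Write a track as bedGraph, one row per bin, library size in a comment."""
    bs = track.binsize
    with open(path, "w") as fh:
        fh.write(f"# library_size={track.library_size:g}\n")
        for chrom, vals in track.values.items():
            length = chromsizes[chrom] if chromsizes else len(vals) * bs
            starts = np.arange(len(vals), dtype=np.int64) * bs
            ends = np.minimum(starts + bs, length)
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_table(df: pd.DataFrame, path: str | Path, header_comments: list[str] | None = None) -> None:
    """Result-table TSV: optional ``#`` comment lines then one header row."""
    with open(path, "w") as fh:
        for c in header_comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
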