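"""Read-to-fragment counting and normalized coverage tracks.

4C observations are the per-fragment counts of unique, deduplicated reads.
A read belongs to the restriction fragment that contains its 5' coordinate
(4C reads start at ligation junctions, so the 5' end is the informative
position).  Coverage-track generation follows the standard ChIP-seq recipe:
extend each unique read 3'-ward to the library fragment length and scale to
a fixed sequencing depth (default 20 million reads).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .restriction import FragmentLibrary

__all__ = [
    "AlignedRead",
    "FragmentCounts",
    "CoverageTrack",
    "read_alignments",
    "write_alignments",
    "assign_reads",
    "exclude_bait_zone",
    "make_track",
    "write_counts",
    "read_counts",
]


class AlignedRead(NamedTuple):
    """A placed read: half-open interval, strand and unique-mapping flag."""

    chrom: str
    start: int
    end: int
    strand: str
    unique: bool

    @property
    def five_prime(self) -> int:
        """0-based coordinate of the 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class FragmentCounts:
    """Unique-read counts per restriction fragment for one replicate.

    ``counts`` maps every fragment_id in the library to a non-negative
    integer; ``total`` is their sum; ``unplaced`` tallies retained reads
    whose chromosome is absent from the library (reported, never silently
    dropped).  ``masked`` holds fragment_ids excluded from downstream
    statistics (bait / self-ligation zone).
    """

    library: FragmentLibrary
    counts: Dict[str, int]
    replicate_id: str = "rep1"
    unplaced: int = 0
    masked: FrozenSet[str] = frozenset()

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def as_series(self) -> pd.Series:
        """Counts as a pandas Series in library fragment order."""
        ids = self.library.fragment_ids
        return pd.Series([self.counts.get(i, 0) for i in ids], index=ids, name="count")

    def unmasked_ids(self) -> List[str]:
        return [i for i in self.library.fragment_ids if i not in self.masked]


def read_alignments(path: str | Path, min_mapq: int = 1) -> List[AlignedRead]:
    """Load aligned-read placements from TSV or SAM/BAM.

    TSV columns: chrom, start, end, strand, unique (header required).
    For SAM/BAM (via pysam) a read is unique if it is a mapped primary,
    non-supplementary alignment with MAPQ >= ``min_mapq``.
    """
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam"}:
        import pysam

        reads: List[AlignedRead] = []
        mode = "r" if path.suffix.lower() == ".sam" else "rb"
        with pysam.AlignmentFile(str(path), mode) as fh:
            for aln in fh:
                if aln.is_unmapped:
                    continue
                unique = (
                    not aln.is_secondary
                    and not aln.is_supplementary
                    and aln.mapping_quality >= min_mapq
                )
                strand = "-" if aln.is_reverse else "+"
                reads.append(
                    AlignedRead(
                        aln.reference_name,
                        aln.reference_start,
                        aln.reference_end,
                        strand,
                        unique,
                    )
                )
        return reads
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "strand", "unique"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        AlignedRead(str(r.chrom), int(r.start), int(r.end), str(r.strand), bool(r.unique))
        for r in df.itertuples(index=False)
    ]


def write_alignments(reads: Sequence[AlignedRead], path: str | Path) -> None:
    pd.DataFrame(reads, columns=["chrom", "start", "end", "strand", "unique"]).to_csv(
        path, sep="\t", index=False
    )


def assign_reads(
    reads: Iterable[AlignedRead],
    library: FragmentLibrary,
    replicate_id: str = "rep1",
) -> FragmentCounts:
    """Count unique, deduplicated reads per fragment by 5' position.

    Non-unique reads are discarded; duplicates — identical (chrom, 5' pos,
    strand) — collapse to one; each retained read is assigned to the single
    fragment containing its 5' coordinate.  Reads on chromosomes absent from
    the library are tallied as ``unplaced``.  Count conservation holds
    exactly: sum(counts) + unplaced == number of retained reads.
    """
    seen: set = set()
    counts: Dict[str, int] = {fid: 0 for fid in library.fragment_ids}
    unplaced = 0
    for read in reads:
        if not read.unique:
            continue
        key = (read.chrom, read.five_prime, read.strand)
        if key in seen:
            continue
        seen.add(key)
        frag = library.locate(read.chrom, read.five_prime)
        if frag is None:
            unplaced += 1
        else:
            counts[frag.fragment_id] += 1
    return FragmentCounts(
        library=library, counts=counts, replicate_id=replicate_id, unplaced=unplaced
    )


def exclude_bait_zone(
    counts: FragmentCounts, bait: str, radius: int = 0
) -> FragmentCounts:
    """Mask the bait fragment and any fragment within ``radius`` bp of it.

    Distance is the genomic gap between intervals (0 for adjacent
    fragments).  ``radius=0`` (the default) masks the bait fragment only;
    any positive radius additionally masks every cis fragment whose gap to
    the bait is <= radius.  Masked fragments stay in the counts table but
    are excluded from the estimate universe (the bait and self-ligation
    products dominate a 4C library without carrying contact information).
    Returns a new FragmentCounts; the input is unmodified.
    """
    if bait not in counts.library:
        raise KeyError(f"bait fragment {bait!r} not in library")
    bfrag = counts.library[bait]
    masked = set(counts.masked)
    masked.add(bait)
    if radius > 0:
        for frag in counts.library.chrom_fragments(bfrag.chrom):
            if frag.end <= bfrag.start:
                gap = bfrag.start - frag.end
            elif frag.start >= bfrag.end:
                gap = frag.start - bfrag.end
            else:
                gap = 0
            if gap <= radius:
                masked.add(frag.fragment_id)
    return replace(counts, masked=frozenset(masked))


@dataclass
class CoverageTrack:
    """Per-interval normalized coverage (bedGraph-style runs).

    ``intervals`` is a DataFrame (chrom, start, end, value); total signal
    mass equals ``normalization_target * extension_length`` when no read
    extension is clipped at position 0.
    """

    intervals: pd.DataFrame
    normalization_target: float
    extension_length: int

    @property
    def total_mass(self) -> float:
        iv = self.intervals
        return float(((iv["end"] - iv["start"]) * iv["value"]).sum())

    def to_bedgraph(self, path: str | Path, decimals: int = 4) -> None:
        out = self.intervals.copy()
        out["value"] = out["value"].round(decimals)
        out.to_csv(path, sep="\t", header=False, index=False)


def make_track(
    reads: Sequence[AlignedRead],
    extension_length: int,
    normalization_target: float = 20_000_000,
) -> CoverageTrack:
    """Build a depth-normalized coverage track from unique reads.

    Each unique read is extended 3'-ward to ``extension_length`` bases from
    its 5' end; per-base coverage is scaled by
    ``normalization_target / n_retained`` so the track is comparable across
    libraries of different depth.
    """
    if extension_length <= 0:
        raise ValueError("extension length must be positive")
    retained = [r for r in reads if r.unique]
    if not retained:
        raise ValueError("no retained (unique) reads; cannot normalize")
    weight = normalization_target / len(retained)
    # difference arrays per chromosome
    events: Dict[str, Dict[int, float]] = {}
    for r in retained:
        if r.strand == "+":
            start, end = r.start, r.start + extension_length
        else:
            start, end = r.end - extension_length, r.end
        start = max(start, 0)
        if end <= start:
            continue
        ev = events.setdefault(r.chrom, {})
        ev[start] = ev.get(start, 0.0) + weight
        ev[end] = ev.get(end, 0.0) - weight
    rows: List[tuple] = []
    for chrom in sorted(events):
        ev = events[chrom]
        pos = np.array(sorted(ev), dtype=np.int64)
        depth = np.cumsum([ev[p] for p in pos])
        for i in range(len(pos) - 1):
            if abs(depth[i]) > 1e-12:
                rows.append((chrom, int(pos[i]), int(pos[i + 1]), float(depth[i])))
    iv = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return CoverageTrack(
        intervals=iv,
        normalization_target=normalization_target,
        extension_length=extension_length,
    )


def write_counts(counts: FragmentCounts, path: str | Path) -> None:
    """Write a per-fragment counts table (fragment_id, chrom, start, end, count, masked)."""
    lib = counts.library
    df = lib.to_dataframe()
    df["count"] = [counts.counts.get(i, 0) for i in df["fragment_id"]]
    df["masked"] = [i in counts.masked for i in df["fragment_id"]]
    df = df[["fragment_id", "chrom", "start", "end", "count", "masked"]]
    df.to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path, library: FragmentLibrary, replicate_id: str = "rep1"
) -> FragmentCounts:
    """Read a counts table written by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t")
    counts = {str(r.fragment_id): int(r.count) for r in df.itertuples(index=False)}
    unknown = set(counts) - set(library.fragment_ids)
    if unknown:
        raise ValueError(f"{path}: fragments not in library: {sorted(unknown)[:5]}")
    masked = frozenset(
        str(r.fragment_id) for r in df.itertuples(index=False) if getattr(r, "masked", False)
    )
    full = {fid: counts.get(fid, 0) for fid in library.fragment_ids}
    return FragmentCounts(
        library=library, counts=full, replicate_id=replicate_id, masked=masked
    )
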