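"""In-silico restriction digestion and fragment libraries.

4C-seq statistics are computed over the set of restriction fragments that
tile the genome: each chromosome is partitioned into the intervals between
consecutive enzyme cut sites.  This module builds, validates and serializes
those fragment libraries.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Enzyme",
    "RestrictionFragment",
    "FragmentLibrary",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "find_cut_positions",
    "digest",
    "read_fasta",
    "write_library",
    "read_library",
    "UnknownEnzymeError",
    "LibraryError",
]

_DNA = set("ACGT")


class UnknownEnzymeError(ValueError):
    """Raised when an enzyme name is not in the registry."""


class LibraryError(ValueError):
    """Raised when a fragment library violates the tiling invariant."""


@dataclass(frozen=True)
class Enzyme:
    """A type II restriction enzyme defined by its recognition site.

    Parameters
    ----------
    name : str
        Enzyme name, e.g. ``"EcoRI"``.
    recognition_site : str
        Top-strand recognition sequence over {A, C, G, T}, length >= 4.
    cut_offset : int
        Bases from the site start to the top-strand cut position
        (EcoRI G^AATTC -> offset 1).
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        object.__setattr__(self, "recognition_site", site)
        if len(site) < 4:
            raise ValueError(f"recognition site {site!r} shorter than 4 bp")
        if not set(site) <= _DNA:
            raise ValueError(f"recognition site {site!r} has non-ACGT bases")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"cut offset {self.cut_offset} outside site of length {len(site)}"
            )


#: Enzymes used for primary and secondary 4C digestions.
BUILTIN_ENZYMES: Dict[str, Enzyme] = {
    "EcoRI": Enzyme("EcoRI", "GAATTC", 1),
    "MseI": Enzyme("MseI", "TTAA", 1),
    "DpnII": Enzyme("DpnII", "GATC", 0),
}


def get_enzyme(name: str) -> Enzyme:
    """Look up a built-in enzyme by name (case-sensitive)."""
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        known = ", ".join(sorted(BUILTIN_ENZYMES))
        raise UnknownEnzymeError(f"unknown enzyme {name!r}; built-ins: {known}") from None


@dataclass(frozen=True)
class RestrictionFragment:
    """One restriction fragment: a half-open genomic interval."""

    chrom: str
    start: int
    end: int
    fragment_id: str
    enzyme: str = "EcoRI"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.fragment_id}: start {self.start} >= end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class FragmentLibrary:
    """Ordered restriction fragments exactly tiling each chromosome.

    The library is the "interval universe" over which 4C read counts and
    proportion estimates are defined.  Per chromosome the fragments are
    sorted, non-overlapping and cover ``[0, chrom_size)`` without gaps.

    Parameters
    ----------
    fragments : sequence of RestrictionFragment
    chrom_sizes : mapping chrom -> length
    enzyme : str
        Primary digestion enzyme name.
    secondary_enzyme : str, optional
        Secondary digestion enzyme, recorded as metadata only; counting
        always uses the primary-enzyme intervals.
    """

    def __init__(
        self,
        fragments: Sequence[RestrictionFragment],
        chrom_sizes: Mapping[str, int],
        enzyme: str = "EcoRI",
        secondary_enzyme: Optional[str] = None,
    ) -> None:
        self.fragments: List[RestrictionFragment] = sorted(
            fragments, key=lambda f: (f.chrom, f.start)
        )
        self.chrom_sizes: Dict[str, int] = dict(chrom_sizes)
        self.enzyme = enzyme
        self.secondary_enzyme = secondary_enzyme
        self._by_id = {f.fragment_id: f for f in self.fragments}
        if len(self._by_id) != len(self.fragments):
            raise LibraryError("fragment_id values are not unique")
        # per-chrom start arrays for O(log n) read assignment
        self._chrom_frags: Dict[str, List[RestrictionFragment]] = {}
        for frag in self.fragments:
            self._chrom_frags.setdefault(frag.chrom, []).append(frag)
        self._chrom_starts = {
            c: np.array([f.start for f in fl], dtype=np.int64)
            for c, fl in self._chrom_frags.items()
        }
        self.validate()

    def validate(self) -> None:
        """Assert the exact-tiling invariant; raise :class:`LibraryError` otherwise."""
        for chrom, frags in self._chrom_frags.items():
            if chrom not in self.chrom_sizes:
                raise LibraryError(f"chromosome {chrom} missing from chrom_sizes")
            size = self.chrom_sizes[chrom]
            if frags[0].start != 0:
                raise LibraryError(f"{chrom}: first fragment starts at {frags[0].start}")
            if frags[-1].end != size:
                raise LibraryError(
                    f"{chrom}: last fragment ends at {frags[-1].end}, size {size}"
                )
            for a, b in itertools.pairwise(frags):
                if a.end != b.start:
                    raise LibraryError(
                        f"{chrom}: gap/overlap between {a.fragment_id} and {b.fragment_id}"
                    )

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentLibrary):
            return NotImplemented
        return (
            self.fragments == other.fragments and self.chrom_sizes == other.chrom_sizes
        )

    def __getitem__(self, fragment_id: str) -> RestrictionFragment:
        return self._by_id[fragment_id]

    def __contains__(self, fragment_id: str) -> bool:
        return fragment_id in self._by_id

    @property
    def fragment_ids(self) -> List[str]:
        return [f.fragment_id for f in self.fragments]

    def chrom_fragments(self, chrom: str) -> List[RestrictionFragment]:
        return list(self._chrom_frags.get(chrom, []))

    def locate(self, chrom: str, pos: int) -> Optional[RestrictionFragment]:
        """Return the fragment containing position ``pos``, or None."""
        starts = self._chrom_starts.get(chrom)
        if starts is None or pos < 0 or pos >= self.chrom_sizes.get(chrom, 0):
            return None
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        return self._chrom_frags[chrom][idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [f.chrom for f in self.fragments],
                "start": [f.start for f in self.fragments],
                "end": [f.end for f in self.fragments],
                "fragment_id": [f.fragment_id for f in self.fragments],
            }
        )


def find_cut_positions(sequence: str, enzyme: Enzyme) -> List[int]:
    """Find all top-strand cut coordinates of ``enzyme`` in ``sequence``.

    Overlapping recognition-site occurrences each yield a cut.  Ambiguous
    bases (N) never match.  Returns sorted 0-based cut coordinates, i.e.
    (occurrence start + cut_offset).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    site = enzyme.recognition_site
    cuts: List[int] = []
    i = seq.find(site)
    while i != -1:
        cuts.append(i + enzyme.cut_offset)
        i = seq.find(site, i + 1)
    return cuts


def digest(
    genome: Mapping[str, str],
    enzyme: Enzyme | str,
    secondary_enzyme: Optional[str] = None,
    id_prefix: str = "frag",
) -> FragmentLibrary:
    """Digest named sequences into a :class:`FragmentLibrary`.

    Fragments are the intervals between consecutive cut positions plus the
    chromosome ends.  Cuts at coordinate 0 or at the chromosome end, and
    duplicate cut coordinates, are merged so no zero-length fragment arises.
    """
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    names = list(genome.keys())
    if not names:
        raise ValueError("empty genome: no sequences to digest")
    fragments: List[RestrictionFragment] = []
    chrom_sizes: Dict[str, int] = {}
    for chrom in names:
        seq = str(genome[chrom])
        if not seq:
            raise ValueError(f"chromosome {chrom} has empty sequence")
        size = len(seq)
        chrom_sizes[chrom] = size
        cuts = sorted({c for c in find_cut_positions(seq, enzyme) if 0 < c < size})
        bounds = [0, *cuts, size]
        for i, (start, end) in enumerate(itertools.pairwise(bounds)):
            fragments.append(
                RestrictionFragment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    fragment_id=f"{chrom}_{id_prefix}{i:05d}",
                    enzyme=enzyme.name,
                )
            )
    return FragmentLibrary(
        fragments, chrom_sizes, enzyme=enzyme.name, secondary_enzyme=secondary_enzyme
    )


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a (possibly line-wrapped) multi-record FASTA into a dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_library(library: FragmentLibrary, path: str | Path) -> None:
    """Serialize a library as BED4 (chrom, start, end, fragment_id)."""
    library.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


def read_library(
    path: str | Path,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    enzyme: str = "EcoRI",
) -> FragmentLibrary:
    """Read a BED4 fragment library, re-sort and re-validate the tiling.

    If ``chrom_sizes`` is not given, each chromosome's size is taken as the
    maximum fragment end observed.  Malformed lines raise a parse error that
    names the offending line number.
    """
    fragments: List[RestrictionFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 BED columns")
            chrom, start_s, end_s, frag_id = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start {start} >= end {end}")
            fragments.append(RestrictionFragment(chrom, start, end, frag_id, enzyme))
    if not fragments:
        raise ValueError(f"{path}: no fragments")
    if chrom_sizes is None:
        sizes: Dict[str, int] = {}
        for f in fragments:
            sizes[f.chrom] = max(sizes.get(f.chrom, 0), f.end)
        chrom_sizes = sizes
    return FragmentLibrary(fragments, chrom_sizes, enzyme=enzyme)
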