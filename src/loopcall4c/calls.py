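"""Strong-interaction calling, replicate intersection and binning.

A "strongly positive interaction" is defined by rank: the top 10% (by
expected log2-proportion) of interacting sites — fragments with at least one
read, outside the masked bait zone.  Reproducible interactions are the
fragments common to every replicate's call set.  Calls are labelled cis
(bait chromosome) or trans, summarized by distance to the bait, and count
profiles can be re-aggregated into fixed-width genomic bins (default 1 Mb)
for a coarser interaction landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .counts import FragmentCounts
from .model import InteractionResults, PriorSpec, InteractionModel
from .restriction import FragmentLibrary, RestrictionFragment

__all__ = [
    "BaitSpec",
    "CallSet",
    "CommonSet",
    "BinProfile",
    "call_strong",
    "classify_cis_trans",
    "intersect_replicates",
    "distance_summary",
    "bin_profile",
]


@dataclass(frozen=True)
class BaitSpec:
    """The bait restriction fragment from which interactions are measured."""

    name: str
    chrom: str
    start: int
    end: int

    @classmethod
    def from_fragment(cls, frag: RestrictionFragment, name: Optional[str] = None) -> "BaitSpec":
        return cls(name or frag.fragment_id, frag.chrom, frag.start, frag.end)

    def gap_to(self, start: int, end: int) -> int:
        """Genomic gap to an interval on the bait chromosome (0 if overlapping)."""
        if end <= self.start:
            return self.start - end
        if start >= self.end:
            return start - self.end
        return 0


@dataclass
class CallSet:
    """Top-quantile interaction calls for one replicate.

    ``calls`` has columns fragment_id, chrom, start, end, count, elog2p,
    linear_scaled and (after classification) label in {cis, trans}.
    """

    replicate_id: str
    calls: pd.DataFrame
    q: float
    universe_size: int

    @property
    def fragment_ids(self) -> List[str]:
        return list(self.calls["fragment_id"])

    def __len__(self) -> int:
        return len(self.calls)

    def label_counts(self) -> Dict[str, int]:
        if "label" not in self.calls.columns:
            return {}
        return self.calls["label"].value_counts().to_dict()

    def to_bed(self, path) -> None:
        out = self.calls[["chrom", "start", "end", "fragment_id", "linear_scaled"]]
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CommonSet:
    """Fragments (or merged regions) called in every replicate."""

    calls: pd.DataFrame
    n_replicates: int
    mode: str = "identity"

    @property
    def fragment_ids(self) -> List[str]:
        return list(self.calls["fragment_id"])

    def __len__(self) -> int:
        return len(self.calls)

    def label_counts(self) -> Dict[str, int]:
        if "label" not in self.calls.columns:
            return {}
        return self.calls["label"].value_counts().to_dict()

    def to_bed(self, path) -> None:
        cols = [c for c in ["chrom", "start", "end", "fragment_id"] if c in self.calls]
        self.calls[cols].to_csv(path, sep="\t", header=False, index=False)


def call_strong(results: InteractionResults, q: float = 0.10) -> CallSet:
    """Call the top-``q`` fraction of interacting sites.

    The universe is the set of fragments with count >= 1 in the estimate
    table (the bait zone was already excluded upstream).  Exactly
    ``floor(q * |universe|)`` fragments are returned, ranked by elog2p;
    boundary ties break deterministically by (higher count, then lower
    genomic coordinate).
    """
    if not 0 < q < 1:
        raise ValueError("quantile q must be in (0, 1)")
    est = results.estimates
    universe = est[est["interacting"]].copy()
    n_call = int(np.floor(q * len(universe)))
    if len(universe) == 0 or n_call == 0:
        if len(universe) == 0:
            warnings.warn("empty interacting-site universe; no calls made")
        empty = universe.iloc[0:0]
        return CallSet(
            replicate_id=results.model.counts.replicate_id,
            calls=empty,
            q=q,
            universe_size=len(universe),
        )
    ranked = universe.sort_values(
        ["elog2p", "count", "chrom", "start"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    calls = ranked.head(n_call).reset_index(drop=True)
    return CallSet(
        replicate_id=results.model.counts.replicate_id,
        calls=calls,
        q=q,
        universe_size=len(universe),
    )


def classify_cis_trans(callset: CallSet, bait: BaitSpec) -> CallSet:
    """Label each call cis (same chromosome as the bait) or trans."""
    calls = callset.calls.copy()
    calls["label"] = np.where(calls["chrom"] == bait.chrom, "cis", "trans")
    return CallSet(callset.replicate_id, calls, callset.q, callset.universe_size)


def _merge_regions(df: pd.DataFrame, tolerance: int) -> List[Tuple[str, int, int, List[str]]]:
    regions: List[Tuple[str, int, int, List[str]]] = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur = None
        for r in sub.itertuples(index=False):
            if cur is not None and r.start - cur[2] <= tolerance:
                cur = (chrom, cur[1], max(cur[2], r.end), cur[3] + [r.fragment_id])
            else:
                if cur is not None:
                    regions.append(cur)
                cur = (chrom, r.start, r.end, [r.fragment_id])
        if cur is not None:
            regions.append(cur)
    return regions


def intersect_replicates(
    callsets: Sequence[CallSet],
    mode: str = "identity",
    tolerance: int = 0,
) -> CommonSet:
    """Fragments called in every replicate.

    ``identity`` mode (default) intersects fragment_id sets — all replicates
    share one fragment library, so identity is exact.  ``proximity`` mode
    first merges each replicate's calls into regions (gap <= tolerance),
    then keeps regions overlapping a region in every other replicate.
    Symmetric and associative; the result is a subset of each input.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two replicate call sets to intersect")
    if mode == "identity":
        common_ids = set(callsets[0].fragment_ids)
        for cs in callsets[1:]:
            common_ids &= set(cs.fragment_ids)
        base = callsets[0].calls
        calls = base[base["fragment_id"].isin(common_ids)].reset_index(drop=True)
        return CommonSet(calls=calls, n_replicates=len(callsets), mode=mode)
    if mode == "proximity":
        region_sets = [_merge_regions(cs.calls, tolerance) for cs in callsets]
        kept_rows = []
        for chrom, start, end, frag_ids in region_sets[0]:
            hit_all = all(
                any(
                    rc == chrom and rs < end + tolerance and start - tolerance < re
                    for rc, rs, re, _ in regions
                )
                for regions in region_sets[1:]
            )
            if hit_all:
                kept_rows.append(
                    {"chrom": chrom, "start": start, "end": end,
                     "fragment_id": ";".join(frag_ids)}
                )
        calls = pd.DataFrame(kept_rows, columns=["chrom", "start", "end", "fragment_id"])
        return CommonSet(calls=calls, n_replicates=len(callsets), mode=mode)
    raise ValueError(f"unknown intersection mode {mode!r}")


def distance_summary(
    common: CommonSet,
    bait: BaitSpec,
    strata: Sequence[int] = (50_000, 1_000_000),
) -> pd.DataFrame:
    """Stratify cis calls by genomic distance to the bait.

    Distance is the gap between the fragment interval and the bait interval
    (0 if they overlap or touch).  Default strata: <=50 kb, <=1 Mb, >1 Mb.
    Stratum counts sum to the number of cis calls.
    """
    calls = common.calls
    cis = calls[calls["chrom"] == bait.chrom]
    dists = np.array(
        [bait.gap_to(int(r.start), int(r.end)) for r in cis.itertuples(index=False)],
        dtype=np.int64,
    )
    bounds = sorted(strata)
    labels = [f"<={b:,} bp" for b in bounds] + [f">{bounds[-1]:,} bp"]
    counts = []
    lower = -1
    for b in bounds:
        counts.append(int(((dists > lower) & (dists <= b)).sum()))
        lower = b
    counts.append(int((dists > lower).sum()))
    return pd.DataFrame({"stratum": labels, "n_calls": counts})


@dataclass
class BinProfile:
    """Counts and proportion estimates aggregated in fixed-width bins."""

    bins: pd.DataFrame  # chrom, bin_start, bin_end, count, elog2p, linear_scaled
    bin_width: int

    def to_bedgraph(self, path) -> None:
        self.bins[["chrom", "bin_start", "bin_end", "linear_scaled"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def bin_profile(
    counts: FragmentCounts,
    bin_width: int = 1_000_000,
    prior: Optional[PriorSpec] = None,
) -> BinProfile:
    """Aggregate fragment counts into ``bin_width`` genomic bins.

    Each fragment's count goes to the bin containing its midpoint (half-open
    bins; a midpoint exactly on a boundary belongs to the upper bin), so no
    fragment is double-counted and the bin totals conserve the fragment
    total.  Expected log2-proportions are then re-estimated on the binned
    counts with the same Dirichlet machinery, giving the coarse interaction
    landscape.
    """
    from .restriction import FragmentLibrary, RestrictionFragment

    lib = counts.library
    rows: Dict[Tuple[str, int], int] = {}
    for chrom, size in lib.chrom_sizes.items():
        for b in range(0, size, bin_width):
            rows[(chrom, b)] = 0
    for frag in lib:
        b = (frag.midpoint // bin_width) * bin_width
        rows[(frag.chrom, b)] += counts.counts.get(frag.fragment_id, 0)
    keys = sorted(rows)
    bin_frags = []
    bin_counts = {}
    for chrom, b in keys:
        end = min(b + bin_width, lib.chrom_sizes[chrom])
        fid = f"{chrom}_bin{b // bin_width:05d}"
        bin_frags.append(RestrictionFragment(chrom, b, end, fid, enzyme="bin"))
        bin_counts[fid] = rows[(chrom, b)]
    bin_lib = FragmentLibrary(bin_frags, lib.chrom_sizes, enzyme="bin")
    bc = FragmentCounts(
        library=bin_lib, counts=bin_counts, replicate_id=counts.replicate_id
    )
    res = InteractionModel(bc, prior=prior).fit()
    est = res.estimates.rename(columns={"start": "bin_start", "end": "bin_end"})
    bins = est[["chrom", "bin_start", "bin_end", "count", "elog2p", "linear_scaled"]]
    return BinProfile(bins=bins.reset_index(drop=True), bin_width=bin_width)
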