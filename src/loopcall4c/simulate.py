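"""Seeded synthetic data with the statistical structure 4C analysis assumes.

The generators emulate, at desk scale, the three kinds of measurement the
package quantifies:

* **4C read counts over restriction fragments** — a bait on one chromosome
  with a power-law cis distance decay ``(1 + d/d0)**-alpha``, a uniform
  trans-level background floor, an inflated self-ligation weight on the
  bait fragment, planted strong contacts as multiplicative enrichments, and
  between-replicate Dirichlet-multinomial overdispersion.
* **qPCR Ct tables** — exponential amplification ``Ct = -log_E(quantity)``
  with configurable primer efficiency and Gaussian Ct noise (inverts
  exactly at zero noise).
* **3D FISH center pairs** — co-localized pairs at distances Uniform(0, t),
  the rest Uniform(t, 5t), so the realized frequency matches the request by
  construction.

Everything is bit-reproducible given a seed.  The cis weight model is the
decay curve with a uniform background floor, ``w = m_i * max(decay(d),
w_bg)``, so planted multipliers are exact fold enrichments over the local
background both in cis (outside the decay zone) and in trans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .counts import FragmentCounts
from .restriction import Enzyme, FragmentLibrary, RestrictionFragment, get_enzyme

__all__ = [
    "ContactTruth",
    "QpcrTruth",
    "simulate_genome",
    "synthetic_library",
    "contact_weights",
    "simulate_4c_counts",
    "simulate_4c_replicates",
    "simulate_ct_table",
    "simulate_fish",
    "FourCScenario",
    "recovery_scenario",
    "null_scenario",
]

_BASES = np.array(list("ACGT"))


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def _all_occurrences(s: str, sub: str) -> List[int]:
    out: List[int] = []
    i = s.find(sub)
    while i != -1:
        out.append(i)
        i = s.find(sub, i + 1)
    return out


# ---------------------------------------------------------------------------
# genome simulation


def simulate_genome(
    n_chroms: int,
    lengths: Sequence[int],
    site_density: float,
    seed: int,
    enzyme: Enzyme | str = "EcoRI",
) -> Tuple[Dict[str, str], Dict[str, List[int]]]:
    """Random sequences with Poisson-placed recognition sites.

    Site occurrences are planted at the requested per-base density; the
    random background between sites is scrubbed of accidental occurrences so
    the recorded positions are the complete truth.  Returns
    ``(genome, {chrom: sorted site start positions})``.
    """
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    if site_density < 0:
        raise ValueError("site density must be >= 0")
    if len(lengths) != n_chroms:
        raise ValueError("need one length per chromosome")
    site = enzyme.recognition_site
    slen = len(site)
    rng = _rng(seed, 0xFA57A)
    genome: Dict[str, str] = {}
    truth: Dict[str, List[int]] = {}
    for ci in range(n_chroms):
        length = int(lengths[ci])
        chrom = f"chr{ci + 1}"
        n_sites = rng.poisson(site_density * length) if site_density > 0 else 0
        # sample non-overlapping site start positions
        positions: List[int] = []
        if n_sites > 0 and length > slen:
            cand = np.sort(rng.choice(length - slen, size=min(n_sites, (length - slen) // slen), replace=False))
            prev = -slen
            for p in cand:
                if p - prev >= slen:
                    positions.append(int(p))
                    prev = p
        s_list = list(rng.choice(_BASES, size=length))
        planted = set(positions)
        for p in positions:
            s_list[p : p + slen] = list(site)
        in_planted = [False] * length
        for p in positions:
            for k in range(p, p + slen):
                in_planted[k] = True
        # scrub accidental occurrences until only planted sites remain;
        # each mutation targets a base outside every planted window
        while True:
            s = "".join(s_list)
            bad = [
                i
                for i in _all_occurrences(s, site)
                if i not in planted
            ]
            if not bad:
                break
            for i in bad:
                j = next(
                    (k for k in range(i, i + slen) if not in_planted[k]), None
                )
                if j is None:  # spans adjoining planted windows: keep as truth
                    planted.add(i)
                    continue
                s_list[j] = "A" if s_list[j] != "A" else "C"
        genome[chrom] = s
        truth[chrom] = sorted(planted)
    return genome, truth


def synthetic_library(
    chrom_lengths: Mapping[str, int],
    mean_fragment: int = 25_000,
    min_fragment: int = 500,
    seed: int = 0,
    enzyme: str = "EcoRI",
) -> FragmentLibrary:
    """A fragment library with exponential inter-cut spacings.

    Builds the interval universe directly (no sequence round trip), for
    scenarios where only the fragment geometry matters.
    """
    rng = _rng(seed, 0x11B)
    fragments: List[RestrictionFragment] = []
    for chrom, length in chrom_lengths.items():
        cuts: List[int] = []
        pos = 0
        while True:
            step = max(min_fragment, int(rng.exponential(mean_fragment)))
            pos += step
            if pos >= length - min_fragment:
                break
            cuts.append(pos)
        bounds = [0, *cuts, length]
        for i in range(len(bounds) - 1):
            fragments.append(
                RestrictionFragment(
                    chrom, bounds[i], bounds[i + 1], f"{chrom}_frag{i:05d}", enzyme
                )
            )
    return FragmentLibrary(fragments, dict(chrom_lengths), enzyme=enzyme)


# ---------------------------------------------------------------------------
# 4C counts


@dataclass
class ContactTruth:
    """Ground-truth interaction structure around one bait.

    alpha : cis distance-decay exponent (0 disables decay)
    d0 : decay scale in bp
    trans_background : uniform weight for trans fragments and the cis floor
    planted : fragment_id -> multiplicative enrichment (> 1)
    self_ligation : extra weight multiplier on the bait fragment itself
    phi : Dirichlet-multinomial overdispersion — per-fragment intensity is
        Gamma(shape w_i/phi, scale phi), i.e. variance-to-mean ratio phi
    """

    bait_fragment_id: str
    alpha: float = 1.0
    d0: float = 10_000.0
    trans_background: float = 0.01
    planted: Dict[str, float] = field(default_factory=dict)
    self_ligation: float = 20.0
    phi: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.d0 <= 0:
            raise ValueError("decay parameters must satisfy alpha >= 0, d0 > 0")
        if self.trans_background < 0:
            raise ValueError("background weight must be >= 0")
        if any(m <= 1 for m in self.planted.values()):
            raise ValueError("planted multipliers must exceed 1")
        if self.phi < 0:
            raise ValueError("overdispersion phi must be >= 0")


def contact_weights(truth: ContactTruth, library: FragmentLibrary) -> pd.Series:
    """Expected relative contact weight per fragment under the truth model."""
    bait = library[truth.bait_fragment_id]
    weights = np.empty(len(library))
    for i, frag in enumerate(library):
        if frag.chrom == bait.chrom:
            if frag.end <= bait.start:
                d = bait.start - frag.end
            elif frag.start >= bait.end:
                d = frag.start - bait.end
            else:
                d = 0
            decay = (1.0 + d / truth.d0) ** (-truth.alpha)
            w = max(decay, truth.trans_background)
            if frag.fragment_id == truth.bait_fragment_id:
                w *= truth.self_ligation
        else:
            w = truth.trans_background
        w *= truth.planted.get(frag.fragment_id, 1.0)
        weights[i] = w
    return pd.Series(weights, index=library.fragment_ids, name="weight")


def simulate_4c_counts(
    truth: ContactTruth,
    library: FragmentLibrary,
    n_reads: int,
    n_reps: int,
    seed: int,
) -> List[FragmentCounts]:
    """Draw per-replicate fragment counts Dirichlet-multinomial around the
    truth weights.

    Each replicate draws an independent per-fragment intensity
    ``Gamma(w_i/phi, phi)`` (mean ``w_i``, variance ``phi * w_i``), then a
    multinomial with the normalized intensities — together a
    Dirichlet-multinomial with concentrations ``w_i/phi``.  ``phi = 0``
    degenerates to a plain multinomial.
    """
    w = contact_weights(truth, library).to_numpy()
    out: List[FragmentCounts] = []
    for rep in range(n_reps):
        rng = _rng(seed, 0x4C, rep)
        if truth.phi > 0:
            lam = rng.gamma(shape=w / truth.phi, scale=truth.phi)
            lam = np.maximum(lam, np.finfo(float).tiny)
        else:
            lam = w
        p = lam / lam.sum()
        n = rng.multinomial(n_reads, p)
        counts = dict(zip(library.fragment_ids, map(int, n)))
        out.append(
            FragmentCounts(
                library=library, counts=counts, replicate_id=f"rep{rep + 1}"
            )
        )
    return out


def simulate_4c_replicates(
    truth: ContactTruth,
    library: FragmentLibrary,
    n_reads: int,
    n_reps: int,
    seed: int,
    read_length: int = 50,
) -> List[pd.DataFrame]:
    """Per-replicate aligned-read tables realizing the truth model.

    Counts are drawn as in :func:`simulate_4c_counts`; each fragment's reads
    are placed at distinct uniformly chosen 5' positions within the fragment
    (so downstream deduplication does not collapse simulated signal) with
    random strands.  Columns: chrom, start, end, strand, unique.
    """
    rep_counts = simulate_4c_counts(truth, library, n_reads, n_reps, seed)
    tables: List[pd.DataFrame] = []
    for rep, fc in enumerate(rep_counts):
        rng = _rng(seed, 0x5EAD, rep)
        rows_chrom: List[str] = []
        rows_start: List[int] = []
        rows_end: List[int] = []
        rows_strand: List[str] = []
        for frag in library:
            c = fc.counts[frag.fragment_id]
            if c == 0:
                continue
            flen = len(frag)
            if c <= flen:
                pos5 = rng.choice(flen, size=c, replace=False)
            else:  # fragment shorter than count: allow duplicates (collapse later)
                pos5 = rng.integers(0, flen, size=c)
            strands = rng.choice(["+", "-"], size=c)
            for p, s in zip(pos5, strands):
                five = frag.start + int(p)
                if s == "+":
                    start, end = five, five + read_length
                else:
                    start, end = max(0, five + 1 - read_length), five + 1
                rows_chrom.append(frag.chrom)
                rows_start.append(start)
                rows_end.append(end)
                rows_strand.append(s)
        tables.append(
            pd.DataFrame(
                {
                    "chrom": rows_chrom,
                    "start": rows_start,
                    "end": rows_end,
                    "strand": rows_strand,
                    "unique": True,
                }
            )
        )
    return tables


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class QpcrTruth:
    """True template quantities behind a simulated Ct table.

    quantities : (target, condition) -> true relative quantity (> 0)
    efficiencies : target -> per-cycle amplification factor (default 2.0)
    noise_sd : Gaussian Ct noise standard deviation (cycles)
    n_replicates : technical replicates per (target, condition)
    """

    quantities: Dict[Tuple[str, str], float]
    efficiencies: Dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if any(q <= 0 for q in self.quantities.values()):
            raise ValueError("true quantities must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def efficiency(self, target: str) -> float:
        return self.efficiencies.get(target, 2.0)


def simulate_ct_table(truth: QpcrTruth, seed: int) -> pd.DataFrame:
    """Ct table under exponential amplification: ``Ct = -log_E(q) + noise``.

    At zero noise the quantification functions invert the table exactly.
    Columns: target, condition, replicate_id, ct.
    """
    rng = _rng(seed, 0xC7)
    rows = []
    for (target, condition), quantity in truth.quantities.items():
        eff = truth.efficiency(target)
        base_ct = -np.log(quantity) / np.log(eff)
        for rep in range(truth.n_replicates):
            noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
            rows.append(
                {
                    "target": target,
                    "condition": condition,
                    "replicate_id": f"rep{rep + 1}",
                    "ct": base_ct + noise,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FISH


def simulate_fish(
    freq_by_genotype: Mapping[str, float],
    n_cells: int,
    threshold: float = 1.0,
    seed: int = 0,
    box_um: float = 8.0,
) -> pd.DataFrame:
    """Paired FISH centers with genotype-dependent co-localization.

    Exactly ``round(freq * n_cells)`` pairs per genotype are co-localized
    (distance Uniform(0, threshold)); the rest get Uniform(threshold,
    5 * threshold).  Columns: cell_id, genotype, x1..z2.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rng = _rng(seed, 0xF15)
    rows = []
    for genotype, freq in freq_by_genotype.items():
        if not 0 <= freq <= 1:
            raise ValueError(f"frequency for {genotype!r} outside [0, 1]")
        k = int(round(freq * n_cells))
        for cell in range(n_cells):
            if cell < k:
                dist = rng.uniform(0.0, threshold) * (1 - 1e-9)
            else:
                dist = rng.uniform(threshold, 5.0 * threshold)
            a = rng.uniform(0.0, box_um, size=3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            b = a + direction * dist
            rows.append(
                {
                    "cell_id": f"{genotype}_cell{cell:04d}",
                    "genotype": genotype,
                    "x1": a[0], "y1": a[1], "z1": a[2],
                    "x2": b[0], "y2": b[1], "z2": b[2],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end scenarios


@dataclass
class FourCScenario:
    """A complete simulated 4C experiment plus its ground truth."""

    library: FragmentLibrary
    truth: ContactTruth
    bait_fragment_id: str
    mask_radius: int
    n_reads: int
    n_reps: int
    seed: int

    def read_tables(self) -> List[pd.DataFrame]:
        return simulate_4c_replicates(
            self.truth, self.library, self.n_reads, self.n_reps, self.seed
        )

    def replicate_counts(self) -> List[FragmentCounts]:
        return simulate_4c_counts(
            self.truth, self.library, self.n_reads, self.n_reps, self.seed
        )

    @property
    def planted_ids(self) -> List[str]:
        return sorted(self.truth.planted)


_DEFAULT_CHROMS = {
    "chr1": 6_000_000,   # cis chromosome carrying the bait
    "chr2": 2_500_000,
    "chr3": 2_500_000,
    "chr4": 2_500_000,
    "chr5": 2_500_000,
}


def recovery_scenario(
    seed: int,
    n_planted_cis: int = 30,
    n_planted_trans: int = 20,
    multiplier: float = 20.0,
    n_reads: int = 100_000,
    n_reps: int = 2,
    mask_radius: int = 1_000_000,
    phi: float = 0.01,
) -> FourCScenario:
    """Planted-contact scenario for end-to-end parameter recovery.

    ~640 fragments over one 6 Mb cis chromosome plus four 2.5 Mb trans
    chromosomes (mean fragment 25 kb); the bait sits mid-chr1 with a 1 Mb
    masked zone.  Cis contacts are planted only outside the mask (where the
    decay curve has reached the background floor) so every planted fragment
    is an exact ``multiplier``-fold enrichment over background.
    """
    library = synthetic_library(_DEFAULT_CHROMS, mean_fragment=25_000, seed=seed)
    bait = library.locate("chr1", _DEFAULT_CHROMS["chr1"] // 2)
    assert bait is not None
    rng = _rng(seed, 0x9C0)
    cis_candidates = [
        f.fragment_id
        for f in library.chrom_fragments("chr1")
        if (f.end <= bait.start - mask_radius - 200_000)
        or (f.start >= bait.end + mask_radius + 200_000)
    ]
    trans_candidates = [f.fragment_id for f in library if f.chrom != "chr1"]
    planted_cis = rng.choice(cis_candidates, size=n_planted_cis, replace=False)
    planted_trans = rng.choice(trans_candidates, size=n_planted_trans, replace=False)
    planted = {fid: multiplier for fid in [*planted_cis, *planted_trans]}
    truth = ContactTruth(
        bait_fragment_id=bait.fragment_id,
        alpha=1.0,
        d0=10_000.0,
        # background depth keeps essentially every fragment observed
        # (>= 1 read), so the interacting-site universe stays close to the
        # full library and the top-q call budget exceeds the planted count
        trans_background=0.02,
        planted=planted,
        self_ligation=20.0,
        phi=phi,
    )
    return FourCScenario(
        library=library,
        truth=truth,
        bait_fragment_id=bait.fragment_id,
        mask_radius=mask_radius,
        n_reads=n_reads,
        n_reps=n_reps,
        seed=seed,
    )


def null_scenario(
    seed: int,
    n_reads: int = 30_000,
    n_reps: int = 2,
    phi: float = 0.01,
) -> FourCScenario:
    """No planted contacts, uniform weights: calls should be random.

    Decay is disabled (alpha = 0) and the background equals the cis weight,
    so every non-bait fragment has identical expected proportion; the
    replicate intersection size then concentrates at q^2 x |universe|.
    """
    library = synthetic_library(_DEFAULT_CHROMS, mean_fragment=25_000, seed=seed)
    bait = library.locate("chr1", _DEFAULT_CHROMS["chr1"] // 2)
    assert bait is not None
    truth = ContactTruth(
        bait_fragment_id=bait.fragment_id,
        alpha=0.0,
        d0=10_000.0,
        trans_background=1.0,
        planted={},
        self_ligation=1.0,
        phi=phi,
    )
    return FourCScenario(
        library=library,
        truth=truth,
        bait_fragment_id=bait.fragment_id,
        mask_radius=0,
        n_reads=n_reads,
        n_reps=n_reps,
        seed=seed,
    )
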