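"""Ct-based quantification: 3C interaction frequencies, digestion QC,
primer efficiency, allele-specific nucleosome occupancy.

All arithmetic follows the exponential-amplification model: the quantity of
template behind a threshold cycle Ct is proportional to ``E**-Ct`` where E
is the per-cycle amplification factor of the primer pair (E = 2 for perfect
doubling).  From this one identity follow

* primer efficiency from a standard curve: slope m of Ct vs log10(input)
  gives ``E = 10**(-1/m)`` (m = -3.3219 for E = 2);
* restriction-digestion QC: the intact fraction across a cut site is
  ``E**-(Ct_digested - Ct_undigested)``, and the protocol requires >= 96%
  digestion at every assayed site;
* relative 3C interaction frequency: efficiency-corrected target quantity
  normalized to a ligation-independent reference locus (XPB/ERCC3);
* nucleosome protection: target quantity normalized to the geometric mean
  of two reference genes (Gapdh, beta-actin) — the delta-delta-Ct scheme —
  compared mutant vs control, fold > 1 meaning increased protection.

Group comparisons use the two-sample two-tailed Student t-test (the
experimental design compares few littermate pairs; Welch's correction is
available via a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtMeasurement",
    "PrimerEfficiency",
    "FoldChangeResult",
    "efficiency_from_standard",
    "digestion_efficiency",
    "digestion_qc",
    "threec_frequency",
    "fold_change_test",
    "occupancy_fold",
    "occupancy_profile",
    "mcrbc_allele_check",
    "DIGESTION_QC_THRESHOLD",
]

#: Minimum percent digestion required at every assayed site.
DIGESTION_QC_THRESHOLD = 96.0


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR threshold-cycle measurement."""

    target: str
    condition: str
    replicate_id: str
    ct: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"Ct must be finite and positive, got {self.ct}")


@dataclass(frozen=True)
class PrimerEfficiency:
    """Per-cycle amplification factor of a primer pair.

    ``efficiency`` is the fold amplification per cycle, in (1, 2.2];
    ``max_ct_spread`` is the largest Ct disagreement between replicate
    measurements at equal input, and ``within_two_ct`` records the
    within-2-Cts acceptance check for the standard curve.
    """

    target: str
    efficiency: float
    slope: Optional[float] = None
    r_squared: Optional[float] = None
    max_ct_spread: float = 0.0

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.2:
            raise ValueError(
                f"{self.target}: amplification factor {self.efficiency:.3f} "
                "outside (1, 2.2]"
            )

    @property
    def within_two_ct(self) -> bool:
        return self.max_ct_spread <= 2.0


def efficiency_from_standard(
    dilution_cts: Sequence[Tuple[float, float]],
    target: str = "target",
) -> PrimerEfficiency:
    """Fit primer efficiency from a dilution-series standard curve.

    Parameters
    ----------
    dilution_cts : sequence of (log10 input, Ct)
        At least three points; replicate Cts at the same input are allowed
        and used for the within-2-Cts spread check.

    Returns
    -------
    PrimerEfficiency with ``efficiency = 10**(-1/slope)``.

    Raises
    ------
    ValueError if fewer than 3 points or |slope| < 1 (amplification not
    exponential in the dilution range).
    """
    pts = np.asarray(dilution_cts, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("standard curve needs at least 3 (log10 input, Ct) points")
    x, y = pts[:, 0], pts[:, 1]
    slope, intercept = np.polyfit(x, y, 1)
    if abs(slope) < 1.0:
        raise ValueError(
            f"standard-curve slope {slope:.3f} too shallow: non-exponential curve"
        )
    efficiency = 10.0 ** (-1.0 / slope)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    spread = 0.0
    for xv in np.unique(x):
        ys = y[x == xv]
        if len(ys) > 1:
            spread = max(spread, float(ys.max() - ys.min()))
    return PrimerEfficiency(
        target=target, efficiency=efficiency, slope=float(slope),
        r_squared=r2, max_ct_spread=spread,
    )


def digestion_efficiency(
    ct_digested: float, ct_undigested: float, efficiency: float = 2.0
) -> Tuple[float, bool]:
    """Percent of template cut at a restriction site, from paired Cts.

    The amplicon spans the site, so only intact (uncut) template amplifies:
    ``intact = E**-(Ct_digested - Ct_undigested)`` and
    ``percent_digested = 100 * (1 - intact)``.  QC passes at >= 96%.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification factor must exceed 1")
    delta = ct_digested - ct_undigested
    intact = efficiency ** (-delta)
    percent = 100.0 * (1.0 - intact)
    return percent, percent >= DIGESTION_QC_THRESHOLD


def digestion_qc(
    site_cts: Mapping[str, Tuple[float, float]], efficiency: float = 2.0
) -> pd.DataFrame:
    """Digestion QC across several sites; overall pass needs every site >= 96%.

    ``site_cts`` maps site name -> (Ct_digested, Ct_undigested).
    """
    rows = []
    for site, (ct_d, ct_u) in site_cts.items():
        pct, ok = digestion_efficiency(ct_d, ct_u, efficiency)
        rows.append({"site": site, "percent_digested": pct, "pass": ok})
    df = pd.DataFrame(rows)
    df.attrs["qc_pass"] = bool(df["pass"].all()) if len(df) else False
    return df


def threec_frequency(
    ct_target: float,
    ct_reference: float,
    eff_target: float = 2.0,
    eff_reference: float = 2.0,
    bac_correction: float = 1.0,
) -> float:
    """Relative 3C interaction frequency, efficiency-corrected and
    normalized to a ligation-independent reference amplicon (XPB/ERCC3).

    ``frequency = (E_t**-Ct_t / E_r**-Ct_r) / bac_correction``; the optional
    ``bac_correction`` divides out a per-primer random-ligation (BAC
    template) factor when one was measured.
    """
    if eff_target <= 1.0 or eff_reference <= 1.0:
        raise ValueError("amplification factors must exceed 1")
    if bac_correction <= 0:
        raise ValueError("BAC correction factor must be positive")
    return (eff_target**-ct_target) / (eff_reference**-ct_reference) / bac_correction


@dataclass(frozen=True)
class FoldChangeResult:
    """Mutant-vs-control fold change with uncertainty and two-sided p."""

    fold: float
    sem_control: float
    sem_mutant: float
    t_statistic: float
    p_value: float
    n_control: int
    n_mutant: int


def fold_change_test(
    control: Sequence[float],
    mutant: Sequence[float],
    equal_var: bool = True,
) -> FoldChangeResult:
    """Mean fold change mutant/control with a two-tailed t-test.

    Student's pooled-variance t-test by default (``equal_var=False`` gives
    Welch).  Degenerate zero-variance groups are handled explicitly: equal
    means give p = 1, different means give p = 0 (reported as < 1e-6)
    rather than NaN.
    """
    c = np.asarray(control, dtype=float)
    m = np.asarray(mutant, dtype=float)
    if c.size < 2 or m.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(c).all() and np.isfinite(m).all()):
        raise ValueError("non-finite values in input")
    if c.mean() == 0:
        raise ValueError("control mean is zero; fold change undefined")
    fold = m.mean() / c.mean()
    sem_c = float(c.std(ddof=1) / np.sqrt(c.size))
    sem_m = float(m.std(ddof=1) / np.sqrt(m.size))
    if c.std(ddof=1) == 0 and m.std(ddof=1) == 0:
        if m.mean() == c.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = np.inf if m.mean() > c.mean() else -np.inf, 0.0
    else:
        t_stat, p = stats.ttest_ind(m, c, equal_var=equal_var)
    return FoldChangeResult(
        fold=float(fold), sem_control=sem_c, sem_mutant=sem_m,
        t_statistic=float(t_stat), p_value=float(p),
        n_control=int(c.size), n_mutant=int(m.size),
    )


def occupancy_fold(
    target_cts: Mapping[str, float],
    reference_cts: Mapping[str, Sequence[float]],
    efficiency: float = 2.0,
    control: str = "control",
    mutant: str = "mutant",
) -> float:
    """Delta-delta-Ct nucleosome-protection fold change, dual references.

    ``target_cts`` maps condition -> target Ct; ``reference_cts`` maps
    condition -> (Ct_Gapdh, Ct_actin).  Per condition the normalized
    quantity is ``E**-Ct_target / E**-mean(reference Cts)`` (arithmetic mean
    of reference Cts = geometric mean of reference quantities); the returned
    fold is mutant/control, > 1 meaning increased protection.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification factor must exceed 1")

    def _norm(cond: str) -> float:
        refs = np.asarray(reference_cts[cond], dtype=float)
        ref_ct = float(refs.mean())
        return efficiency ** -(target_cts[cond]) / efficiency ** -(ref_ct)

    return _norm(mutant) / _norm(control)


def occupancy_profile(
    table: pd.DataFrame,
    reference_targets: Sequence[str] = ("Gapdh", "Actb"),
    efficiency: float = 2.0,
    control: str = "control",
    mutant: str = "mutant",
) -> pd.DataFrame:
    """Per-amplicon protection fold changes with replicate-level t-tests.

    ``table`` columns: target, condition, replicate_id, ct.  Reference-gene
    Cts are averaged within (condition, replicate); every non-reference
    amplicon gets a normalized quantity per replicate, a mutant/control fold
    of replicate means, and a two-tailed t-test across replicates.
    """
    required = {"target", "condition", "replicate_id", "ct"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    refs = table[table["target"].isin(reference_targets)]
    if refs.empty:
        raise ValueError(f"no reference-gene rows ({reference_targets}) in table")
    ref_ct = refs.groupby(["condition", "replicate_id"])["ct"].mean()
    rows = []
    for target, sub in table[~table["target"].isin(reference_targets)].groupby("target"):
        quants: Dict[str, List[float]] = {control: [], mutant: []}
        for r in sub.itertuples(index=False):
            if r.condition not in quants:
                continue
            ref = ref_ct.get((r.condition, r.replicate_id))
            if ref is None or not np.isfinite(ref):
                raise ValueError(
                    f"no reference Cts for condition={r.condition}, "
                    f"replicate={r.replicate_id}"
                )
            quants[r.condition].append(efficiency**-(r.ct) / efficiency**-(ref))
        res = fold_change_test(quants[control], quants[mutant])
        rows.append(
            {"target": target, "fold": res.fold, "sem_control": res.sem_control,
             "sem_mutant": res.sem_mutant, "p_value": res.p_value}
        )
    return pd.DataFrame(rows)


def mcrbc_allele_check(
    maternal_signal: float,
    paternal_signal: float,
    mcrbc_retention: float,
    purity_threshold: float = 0.9,
) -> Dict[str, float | bool]:
    """Allele-specificity of the McrBC selection step.

    McrBC degrades the methylated paternal allele; ``mcrbc_retention`` is
    the fraction of paternal template surviving digestion.  The post-McrBC
    signal is ``maternal + retention * paternal`` and the maternal purity is
    ``maternal / (maternal + retention * paternal)``; purity below the
    threshold flags the assay as insufficiently allele-specific.
    """
    if maternal_signal < 0 or paternal_signal < 0 or not 0 <= mcrbc_retention <= 1:
        raise ValueError("signals must be >= 0 and retention in [0, 1]")
    residual = mcrbc_retention * paternal_signal
    total = maternal_signal + residual
    if total == 0:
        raise ValueError("no signal after McrBC digestion")
    purity = maternal_signal / total
    return {
        "post_mcrbc_signal": total,
        "maternal_purity": purity,
        "flagged": purity < purity_threshold,
    }
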