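"""3D DNA-FISH co-localization analysis.

Two loci are scored as interacting in a nucleus when the 3D center-to-center
distance of their FISH signals is strictly below a threshold (default
1.0 um).  Inputs are physical coordinates in micrometres; a helper converts
(pixel, pixel, z-slice) triplets using the configured xy pixel size and
z-step (confocal stacks here are taken at 0.3 um intervals).  Per-genotype
co-localization frequencies are compared with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignalCenter",
    "FishPair",
    "pair_distance",
    "classify_pair",
    "coloc_frequency",
    "centers_from_pixels",
    "DEFAULT_THRESHOLD_UM",
    "DEFAULT_Z_STEP_UM",
]

DEFAULT_THRESHOLD_UM = 1.0
DEFAULT_Z_STEP_UM = 0.3


@dataclass(frozen=True)
class SignalCenter:
    """3D center of a FISH signal, in micrometres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise ValueError("signal center coordinates must be finite")


def centers_from_pixels(
    px: float, py: float, z_index: float,
    xy_pixel_um: float, z_step_um: float = DEFAULT_Z_STEP_UM,
) -> SignalCenter:
    """Convert detector coordinates (pixel, pixel, stack index) to um."""
    if xy_pixel_um <= 0 or z_step_um <= 0:
        raise ValueError("pixel size and z step must be positive")
    return SignalCenter(px * xy_pixel_um, py * xy_pixel_um, z_index * z_step_um)


@dataclass(frozen=True)
class FishPair:
    """A pair of FISH signals in one cell with its co-localization state."""

    cell_id: str
    genotype: str
    center_a: SignalCenter
    center_b: SignalCenter
    threshold: float = DEFAULT_THRESHOLD_UM

    @property
    def distance(self) -> float:
        return pair_distance(self.center_a, self.center_b)

    @property
    def colocalized(self) -> bool:
        return classify_pair(self.distance, self.threshold)


def pair_distance(a: SignalCenter, b: SignalCenter) -> float:
    """Euclidean 3D center-to-center distance in micrometres."""
    return math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))


def classify_pair(distance: float, threshold: float = DEFAULT_THRESHOLD_UM) -> bool:
    """Interacting iff distance is strictly below the threshold."""
    if distance < 0:
        raise ValueError("distance cannot be negative")
    return distance < threshold


def coloc_frequency(
    pairs: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD_UM,
    test: str = "fisher",
) -> Tuple[pd.DataFrame, Optional[float]]:
    """Per-genotype co-localization frequencies with a two-sided comparison.

    ``pairs`` needs columns genotype and either distance or the six
    coordinate columns x1..z2.  Returns (summary table, p value); the p
    value compares the first two genotypes' 2x2 table (co-localized vs not)
    by Fisher's exact test (``test="chi2"`` for the chi-square alternative)
    and is None when only one genotype is present.
    """
    df = pairs.copy()
    if "distance" not in df.columns:
        coords = ["x1", "y1", "z1", "x2", "y2", "z2"]
        if not set(coords) <= set(df.columns):
            raise ValueError("need a distance column or x1..z2 coordinates")
        d = df[coords].to_numpy(dtype=float)
        df["distance"] = np.sqrt(((d[:, :3] - d[:, 3:]) ** 2).sum(axis=1))
    df["colocalized"] = df["distance"] < threshold
    rows = []
    for genotype, sub in df.groupby("genotype", sort=True):
        n = len(sub)
        if n == 0:
            raise ValueError(f"empty genotype group {genotype!r}")
        k = int(sub["colocalized"].sum())
        rows.append(
            {"genotype": genotype, "n_pairs": n, "n_colocalized": k,
             "frequency": k / n}
        )
    summary = pd.DataFrame(rows)
    if summary.empty or (summary["n_pairs"] == 0).any():
        raise ValueError("empty genotype group")
    p_value: Optional[float] = None
    if len(summary) >= 2:
        a, b = summary.iloc[0], summary.iloc[1]
        table = [
            [a["n_colocalized"], a["n_pairs"] - a["n_colocalized"]],
            [b["n_colocalized"], b["n_pairs"] - b["n_colocalized"]],
        ]
        if test == "fisher":
            _, p_value = stats.fisher_exact(table, alternative="two-sided")
        elif test == "chi2":
            _, p_value, _, _ = stats.chi2_contingency(table, correction=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        p_value = float(p_value)
    return summary, p_value
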