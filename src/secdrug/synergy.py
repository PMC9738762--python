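"""Chou-Talalay median-effect modelling and combination-index synergy.

Each single agent is summarized by the median-effect equation
``fa/fu = (D/Dm)^m`` (fa = fraction affected, fu = 1 - fa, Dm = median-effect
dose, m = slope), fitted by ordinary least squares on the linearized form
``log(fa/fu) = m log D - m log Dm``. For a combination measured at doses
(d1, d2) producing effect fa, the mutually-exclusive combination index is

    CI = d1/Dx1 + d2/Dx2,   Dx_j = Dm_j (fa/(1-fa))^(1/m_j),

where Dx_j is the single-agent dose of drug j needed for the same effect.
CI < 1 indicates synergy, CI = 1 additivity, CI > 1 antagonism; the reported
labels use the conventional bands (<= 0.3 strong synergism, 0.3-0.9
synergism, 0.9-1.1 additive window, > 1.1 antagonism window; band edges go
to the lower band). The dose-reduction index DRI_j = Dx_j/d_j is the fold by
which drug j's dose is spared in the combination at that effect level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import CytotoxicityCurve

#: default clipping bound on the fraction affected
DEFAULT_EPS = 0.005


@dataclass
class MedianEffectFit:
    drug_id: str
    Dm: float  # median-effect dose, nM
    m: float   # slope of the median-effect plot
    r: float   # linear correlation of the median-effect plot
    n_points_used: int

    def dx(self, fa) -> np.ndarray:
        """Single-agent dose producing fraction affected ``fa``."""
        fa = np.asarray(fa, dtype=float)
        return self.Dm * (fa / (1.0 - fa)) ** (1.0 / self.m)

    def fa(self, dose) -> np.ndarray:
        """Fraction affected at ``dose`` under the median-effect model."""
        d = np.asarray(dose, dtype=float)
        ratio = (d / self.Dm) ** self.m
        return ratio / (1.0 + ratio)


@dataclass
class CombinationMeasurement:
    """Observed combination effects: dose pairs (nM) with fraction affected."""

    pairs: pd.DataFrame  # columns: d1, d2, fa
    fixed_ratio: bool = False

    def __post_init__(self) -> None:
        need = {"d1", "d2", "fa"}
        if not need.issubset(self.pairs.columns):
            raise ValueError(f"pairs needs columns {sorted(need)}")
        if ((self.pairs["d1"] <= 0) & (self.pairs["d2"] <= 0)).any():
            raise ValueError("each pair needs at least one positive dose")


@dataclass
class CombinationIndexResult:
    table: pd.DataFrame  # per pair: d1, d2, fa, Dx1, Dx2, CI, DRI1, DRI2, label
    drug1_id: str
    drug2_id: str


def classify_ci(ci: float) -> str:
    """Synergy band for a combination-index value (edges to the lower band)."""
    if ci <= 0.3:
        return "strong_synergism"
    if ci <= 0.9:
        return "synergism"
    if ci <= 1.1:
        return "additive_window"
    return "antagonism_window"


def fit_median_effect(
    curve: CytotoxicityCurve, eps: float = DEFAULT_EPS
) -> MedianEffectFit:
    """Fit the median-effect line to a single-agent cytotoxicity curve.

    fa = 1 - survival/100 per point; points with zero dose or with fa
    outside [eps, 1-eps] are excluded (the logit is undefined or unstable
    there). Needs >= 3 usable points.
    """
    pts = curve.nonzero()
    d = pts["concentration_nM"].to_numpy(dtype=float)
    fa = 1.0 - pts["percent_survival"].to_numpy(dtype=float) / 100.0
    usable = (fa >= eps) & (fa <= 1.0 - eps)
    if usable.sum() < 3:
        excluded = [
            f"(D={di:g}, fa={fi:.3f})" for di, fi in zip(d[~usable], fa[~usable])
        ]
        raise ValueError(
            f"only {int(usable.sum())} points with fa in [{eps}, {1 - eps}]; "
            f"excluded: {', '.join(excluded)}"
        )
    d, fa = d[usable], fa[usable]
    y = np.log(fa / (1.0 - fa))
    x = np.log(d)
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError(f"non-positive median-effect slope m={m:.3g}")
    dm = float(np.exp(-res.intercept / m))
    return MedianEffectFit(curve.drug_id, dm, m, float(res.rvalue), int(len(d)))


def compute_ci(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    combo: CombinationMeasurement,
    eps: float = DEFAULT_EPS,
) -> CombinationIndexResult:
    """Combination index and dose-reduction indices per measured dose pair.

    Uses the two-term, mutually-exclusive CI form. The fraction affected is
    taken from the observed combination survival; pairs with fa outside
    (eps, 1-eps) are skipped with a warning. A zero dose contributes no CI
    term and has undefined DRI (reported as inf).
    """
    rows = []
    for _, rec in combo.pairs.iterrows():
        d1, d2, fa = float(rec["d1"]), float(rec["d2"]), float(rec["fa"])
        if not eps < fa < 1.0 - eps:
            warnings.warn(
                f"pair (d1={d1:g}, d2={d2:g}) skipped: fa={fa:.4f} outside "
                f"({eps}, {1 - eps})",
                stacklevel=2,
            )
            continue
        dx1 = float(fit1.dx(fa))
        dx2 = float(fit2.dx(fa))
        ci = (d1 / dx1 if d1 > 0 else 0.0) + (d2 / dx2 if d2 > 0 else 0.0)
        rows.append(
            {
                "d1": d1, "d2": d2, "fa": fa, "Dx1": dx1, "Dx2": dx2,
                "CI": ci,
                "DRI1": dx1 / d1 if d1 > 0 else np.inf,
                "DRI2": dx2 / d2 if d2 > 0 else np.inf,
                "label": classify_ci(ci),
            }
        )
    table = pd.DataFrame(
        rows, columns=["d1", "d2", "fa", "Dx1", "Dx2", "CI", "DRI1", "DRI2", "label"]
    )
    return CombinationIndexResult(table, fit1.drug_id, fit2.drug_id)


def isobologram_points(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fa_levels,
    ci_result: CombinationIndexResult | None = None,
) -> pd.DataFrame:
    """Isobologram coordinates at the requested effect levels.

    For each fa level, the additivity line runs between the axis intercepts
    (Dx1, 0) and (0, Dx2). Combination points are plotted in normalized
    coordinates (d1/Dx1, d2/Dx2) at their own fa, so a point's coordinate
    sum equals its CI and points below the unit line x + y = 1 are
    synergistic.
    """
    fa_levels = np.asarray(list(fa_levels), dtype=float)
    if np.any((fa_levels <= 0) | (fa_levels >= 1)):
        raise ValueError("fa levels must lie in (0, 1)")
    rows = [
        {"fa": fa, "kind": "intercept", "x": float(fit1.dx(fa)), "y": float(fit2.dx(fa))}
        for fa in fa_levels
    ]
    if ci_result is not None:
        for _, rec in ci_result.table.iterrows():
            rows.append(
                {
                    "fa": rec["fa"], "kind": "combination",
                    "x": rec["d1"] / rec["Dx1"], "y": rec["d2"] / rec["Dx2"],
                }
            )
    return pd.DataFrame(rows, columns=["fa", "kind", "x", "y"])
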