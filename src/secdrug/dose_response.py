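"""Cytotoxicity normalization and variable-slope sigmoidal (4PL) IC50 fits.

Raw plate readings are normalized to percent survival relative to the mean
of untreated control wells (control mean == 100%). IC50 is then estimated by
least squares on the four-parameter logistic

    S(D) = bottom + (top - bottom) / (1 + (D / ic50)^hill),

fitted on log10 concentration; zero-dose points anchor the normalization
only and are excluded from the sigmoid fit. A fit whose IC50 lands outside
[min_dose/10, max_dose*10] is reported with ``converged=False`` rather than
trusted as an extrapolation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class CytotoxicityCurve:
    """Percent-survival points for one drug, relative to untreated control."""

    drug_id: str
    points: pd.DataFrame  # columns: concentration_nM, percent_survival, replicate_id
    control_cv: float = np.nan
    control_definition: str = "untreated wells"

    def nonzero(self) -> pd.DataFrame:
        return self.points[self.points["concentration_nM"] > 0]


@dataclass
class FourPLFit:
    drug_id: str
    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    n_points: int

    def predict(self, conc_nM) -> np.ndarray:
        d = np.asarray(conc_nM, dtype=float)
        return _four_pl(d, self.bottom, self.top, self.ic50, self.hill)


class NoResponseError(ValueError):
    """Survival does not decrease with concentration: nothing to fit."""


def normalize_survival(
    raw: pd.DataFrame, control_wells, drug_id: str = "drug"
) -> CytotoxicityCurve:
    """Convert raw readings to percent survival against the control mean.

    ``raw`` needs columns ``concentration_nM`` and ``reading`` (and
    optionally ``replicate_id``). Requires >= 2 control wells with a
    positive mean; the control coefficient of variation is recorded on the
    returned curve.
    """
    controls = np.asarray(control_wells, dtype=float)
    if controls.size < 2:
        raise ValueError("need >= 2 control wells")
    cmean = controls.mean()
    if cmean <= 0:
        raise ValueError(f"control mean {cmean:.4g} <= 0")
    cv = float(controls.std(ddof=1) / cmean)
    pts = raw.copy()
    pts["percent_survival"] = pts["reading"] / cmean * 100.0
    if "replicate_id" not in pts.columns:
        pts["replicate_id"] = 1
    pts = pts[["concentration_nM", "percent_survival", "replicate_id"]]
    return CytotoxicityCurve(drug_id, pts.reset_index(drop=True), control_cv=cv)


def _four_pl(d, bottom, top, ic50, hill):
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


def _four_pl_log(logd, bottom, top, log_ic50, hill):
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - log_ic50)))


def fit_4pl(curve: CytotoxicityCurve) -> FourPLFit:
    """Fit the variable-slope sigmoid to a cytotoxicity curve.

    Replicates enter as pooled points, so the residual sum of squares
    reflects replicate scatter. Initialization: top = max observed,
    bottom = min observed, ic50 = dose whose mean survival is nearest the
    half-range, hill = 1. Raises :class:`NoResponseError` when mean
    survival is monotone non-decreasing in dose.
    """
    pts = curve.nonzero()
    concs = pts["concentration_nM"].to_numpy(dtype=float)
    surv = pts["percent_survival"].to_numpy(dtype=float)
    if len(np.unique(concs)) < 5:
        raise ValueError("need >= 5 distinct non-zero concentrations")

    by_dose = pts.groupby("concentration_nM")["percent_survival"].mean().sort_index()
    if np.all(np.diff(by_dose.to_numpy()) >= 0):
        raise NoResponseError(
            f"no response for {curve.drug_id!r}: survival does not decrease with dose"
        )

    top0, bot0 = float(surv.max()), float(surv.min())
    half = (top0 + bot0) / 2.0
    ic50_0 = float(by_dose.index[np.argmin(np.abs(by_dose.to_numpy() - half))])
    logd = np.log10(concs)
    p0 = [bot0, top0, math.log10(ic50_0), 1.0]
    lo = [-np.inf, -np.inf, logd.min() - 2.0, 1e-3]
    hi = [np.inf, np.inf, logd.max() + 2.0, 50.0]
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            _four_pl_log, logd, surv, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError:
        popt, converged = np.asarray(p0), False
    bottom, top, log_ic50, hill = popt
    if bottom > top:  # keep the reported orientation canonical
        bottom, top, hill = top, bottom, -hill
    ic50 = 10.0 ** log_ic50
    rss = float(np.sum((surv - _four_pl_log(logd, *popt)) ** 2))
    window = (concs.min() / 10.0, concs.max() * 10.0)
    if not (window[0] <= ic50 <= window[1]):
        converged = False
    return FourPLFit(
        curve.drug_id, float(bottom), float(top), float(ic50), float(hill),
        rss, bool(converged), int(len(surv)),
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact two-sided permutation p.

    For n <= 8 tie-free pairs the p-value is exact: the fraction of the n!
    rank permutations whose |rho| is at least the observed |rho| (so a
    perfect anticorrelation of 5 pairs gives p = 2/120 ~ 0.0167). Larger or
    tied samples fall back on the usual t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    rho, p_asym = stats.spearmanr(x, y)
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 8 and tie_free:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        return float(rho), count / total
    return float(rho), float(p_asym)
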