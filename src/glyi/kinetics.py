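"""GLYI rate models and estimation.

The enzyme converts the MG-GSH hemithioacetal (HA) to
S-D-lactoylglutathione (S-LG), monitored spectrophotometrically at 240 nm
(epsilon = 2.86 mM^-1 cm^-1).  This module covers:

* Beer-Lambert conversion of an absorbance slope to a specific activity
  (enzyme units per mg protein);
* the Michaelis-Menten rate law and its nonlinear least-squares fit, with
  the four classical linearizations (Lineweaver-Burk, Eadie-Hofstee,
  Eadie-Scatchard, Hanes) as diagnostics;
* competitive inhibition (free GSH competes with HA for the active site)
  with the inhibition constant estimated both from Dixon-plot line
  intersections and from a global fit of the competitive model;
* the linear Zn2+ activation dose-response.

Substrate and inhibitor concentrations are in mM (Km is displayed in uM
where the field convention calls for it); rates in umol min^-1 mg^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "EPSILON_SLG_240NM",
    "EPSILON_TNB_412NM",
    "KineticsDataset",
    "KineticParams",
    "ActivityRecord",
    "KineticsError",
    "rate_from_absorbance",
    "mm_rate",
    "competitive_rate",
    "fit_mm",
    "fit_competitive",
    "linearize",
    "dixon_ki",
    "metal_activation",
]

#: Molar absorption coefficient of S-LG at 240 nm, mM^-1 cm^-1.
EPSILON_SLG_240NM = 2.86
#: Molar absorption coefficient of TNB at 412 nm (glutathione recycling
#: assay), mM^-1 cm^-1.
EPSILON_TNB_412NM = 13.6


class KineticsError(ValueError):
    pass


@dataclass
class KineticsDataset:
    """(S, I, v) observations: substrate HA (mM), inhibitor free GSH (mM),
    rate (umol min^-1 mg^-1)."""

    s: np.ndarray
    v: np.ndarray
    i: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.i = (np.zeros_like(self.s) if self.i is None
                  else np.asarray(self.i, dtype=float))
        if not (self.s.shape == self.v.shape == self.i.shape):
            raise KineticsError("S, I and v must have identical shapes")
        if (self.s < 0).any() or (self.i < 0).any() or (self.v < 0).any():
            raise KineticsError("concentrations and rates must be nonnegative")
        if np.unique(self.s).size < 2:
            raise KineticsError("need at least 2 distinct substrate levels")

    @classmethod
    def from_tsv(cls, path) -> "KineticsDataset":
        df = pd.read_csv(path, sep="\t")
        return cls(s=df["S_mM"].to_numpy(),
                   v=df["rate"].to_numpy(),
                   i=df["I_mM"].to_numpy() if "I_mM" in df else None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"S_mM": self.s, "I_mM": self.i, "rate": self.v})


@dataclass
class KineticParams:
    vmax: float                       # umol min^-1 mg^-1
    km: float                         # mM
    ki: float | None = None           # mM
    vmax_se: float | None = None
    km_se: float | None = None
    ki_se: float | None = None
    residual_ss: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise KineticsError("vmax and km must be positive")
        if self.ki is not None and self.ki <= 0:
            raise KineticsError("ki must be positive when present")

    @property
    def km_um(self) -> float:
        """Km in uM (display convention)."""
        return self.km * 1000.0


@dataclass(frozen=True)
class ActivityRecord:
    slope: float                      # A min^-1
    epsilon: float                    # mM^-1 cm^-1
    path: float                       # cm
    volume: float                     # mL
    protein: float                    # mg
    specific_activity: float          # umol min^-1 mg^-1


def rate_from_absorbance(slope: float,
                         epsilon: float = EPSILON_SLG_240NM,
                         path: float = 1.0,
                         volume: float = 0.4,
                         protein: float | None = None) -> ActivityRecord:
    """Specific activity from an absorbance slope (Beer-Lambert).

    rate = |slope| / (epsilon * path) gives mM min^-1 in the cuvette;
    times the assay volume in mL this is umol min^-1 (enzyme units),
    divided by mg protein the specific activity.  The magnitude of the
    slope is used: HA -> S-LG is monitored as an absorbance increase at
    240 nm but the sign carries no kinetic information.
    """
    if protein is None or protein <= 0:
        raise KineticsError("protein mass (mg) must be positive")
    if epsilon <= 0 or path <= 0 or volume <= 0:
        raise KineticsError("epsilon, path and volume must be positive")
    specific = abs(slope) / (epsilon * path) * volume / protein
    return ActivityRecord(slope, epsilon, path, volume, protein, specific)


def mm_rate(params: KineticParams, s) -> np.ndarray | float:
    """Michaelis-Menten rate v = Vmax * S / (Km + S)."""
    s = np.asarray(s, dtype=float)
    out = params.vmax * s / (params.km + s)
    return out.item() if out.ndim == 0 else out


def competitive_rate(params: KineticParams, s, i) -> np.ndarray | float:
    """Competitive inhibition v = Vmax * S / (Km * (1 + I/Ki) + S)."""
    if params.ki is None:
        raise KineticsError("competitive_rate requires ki")
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    out = params.vmax * s / (params.km * (1.0 + i / params.ki) + s)
    return out.item() if out.ndim == 0 else out


def _hanes_start(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    # Hanes: S/v = S/Vmax + Km/Vmax -> slope 1/Vmax, intercept Km/Vmax
    mask = v > 0
    fit = linregress(s[mask], s[mask] / v[mask])
    if fit.slope <= 0:
        return float(v.max()) or 1.0, float(np.median(s)) or 1.0
    vmax0 = 1.0 / fit.slope
    km0 = max(fit.intercept * vmax0, 1e-6)
    return vmax0, km0


def fit_mm(data: KineticsDataset) -> KineticParams:
    """Nonlinear least squares of the untransformed Michaelis-Menten model.

    Starting values come from a Hanes linearization.  A design with fewer
    than 3 distinct substrate levels, or one that does not straddle the
    fitted Km, is flagged with a warning (poorly conditioned).
    """
    s, v = data.s, data.v
    if np.unique(s).size < 3:
        warnings.warn("fewer than 3 distinct substrate levels: fit is "
                      "poorly determined", stacklevel=2)
    p0 = _hanes_start(s, v)
    try:
        popt, pcov = curve_fit(
            lambda x, vmax, km: vmax * x / (km + x), s, v, p0=p0, maxfev=10000,
        )
    except RuntimeError as exc:
        raise KineticsError(f"Michaelis-Menten fit did not converge "
                            f"(start {p0}): {exc}") from exc
    vmax, km = popt
    if not (s.min() < km < s.max()):
        warnings.warn("fitted Km outside the substrate range: estimate is "
                      "an extrapolation", stacklevel=2)
    se = np.sqrt(np.diag(pcov)) if np.isfinite(pcov).all() else (np.nan, np.nan)
    resid = v - vmax * s / (km + s)
    return KineticParams(vmax=vmax, km=km,
                         vmax_se=float(se[0]), km_se=float(se[1]),
                         residual_ss=float(resid @ resid), converged=True)


def fit_competitive(data: KineticsDataset) -> KineticParams:
    """Global nonlinear fit of the competitive-inhibition model."""
    s, i, v = data.s, data.i, data.v
    if np.unique(i).size < 2:
        raise KineticsError("need at least 2 inhibitor levels")
    vmax0, km0 = _hanes_start(s[i == i.min()], v[i == i.min()])
    p0 = (vmax0, km0, max(np.median(i), 1e-3))
    try:
        popt, pcov = curve_fit(
            lambda x, vmax, km, ki: vmax * x[0] / (km * (1 + x[1] / ki) + x[0]),
            np.vstack([s, i]), v, p0=p0, maxfev=20000,
        )
    except RuntimeError as exc:
        raise KineticsError(f"competitive fit did not converge: {exc}") from exc
    vmax, km, ki = popt
    se = np.sqrt(np.diag(pcov)) if np.isfinite(pcov).all() else [np.nan] * 3
    resid = v - vmax * s / (km * (1 + i / ki) + s)
    return KineticParams(vmax=vmax, km=km, ki=ki,
                         vmax_se=float(se[0]), km_se=float(se[1]),
                         ki_se=float(se[2]),
                         residual_ss=float(resid @ resid), converged=True)


# ---------------------------------------------------------------------------
# linearization diagnostics
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    kind: str
    x: np.ndarray
    y: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    vmax: float
    km: float
    n_excluded: int = 0


_TRANSFORMS = ("lineweaver_burk", "eadie_hofstee", "eadie_scatchard", "hanes")


def linearize(data: KineticsDataset, kind: str) -> LinearFit:
    """Classical linear transforms of Michaelis-Menten data.

    Parameter interpretation by transform:

    * lineweaver_burk: 1/v vs 1/S, slope Km/Vmax, intercept 1/Vmax
    * eadie_hofstee:   v vs v/S,   slope -Km,    intercept Vmax
    * eadie_scatchard: v/S vs v,   slope -1/Km,  intercept Vmax/Km
    * hanes:           S/v vs S,   slope 1/Vmax, intercept Km/Vmax

    Points with zero rate (or zero substrate for reciprocal transforms)
    are excluded with a warning.
    """
    if kind not in _TRANSFORMS:
        raise KineticsError(f"unknown transform {kind!r}; choose from {_TRANSFORMS}")
    mask = (data.v > 0) & (data.s > 0)
    n_excluded = int((~mask).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} zero-rate/zero-substrate point(s) "
                      f"excluded from {kind} transform", stacklevel=2)
    s, v = data.s[mask], data.v[mask]
    if kind == "lineweaver_burk":
        x, y = 1.0 / s, 1.0 / v
    elif kind == "eadie_hofstee":
        x, y = v / s, v
    elif kind == "eadie_scatchard":
        x, y = v, v / s
    else:
        x, y = s, s / v
    fit = linregress(x, y)
    slope, intercept = fit.slope, fit.intercept
    if kind == "lineweaver_burk":
        vmax, km = 1.0 / intercept, slope / intercept
    elif kind == "eadie_hofstee":
        vmax, km = intercept, -slope
    elif kind == "eadie_scatchard":
        km = -1.0 / slope
        vmax = intercept * km
    else:
        vmax, km = 1.0 / slope, intercept / slope
    return LinearFit(kind=kind, x=x, y=y, slope=slope, intercept=intercept,
                     r_squared=float(fit.rvalue ** 2), vmax=float(vmax),
                     km=float(km), n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Dixon analysis
# ---------------------------------------------------------------------------

@dataclass
class DixonResult:
    ki: float                          # mM, from the common intersection
    intersection_y: float              # 1/v at the common intersection
    lines: dict[float, tuple[float, float]]   # S -> (intercept, slope) of 1/v vs I
    global_fit: KineticParams | None = None


def dixon_ki(data: KineticsDataset,
             with_global_fit: bool = True) -> DixonResult:
    """Inhibition constant from Dixon-plot line intersections.

    For each substrate level a line 1/v = a_S + b_S * I is fitted; for a
    competitive inhibitor the lines share a point at I = -Ki.  The common
    intersection is the least-squares point (x*, y*) minimizing
    sum_S (a_S + b_S x - y)^2, and Ki = -x*.  Near-parallel lines (the
    non-competitive degenerate pattern) are reported as having no finite
    intersection.  A global competitive-model fit is returned alongside
    for comparison.
    """
    s, i, v = data.s, data.i, data.v
    if (v <= 0).any():
        raise KineticsError("Dixon analysis requires strictly positive rates")
    s_levels = np.unique(s)
    if s_levels.size < 2:
        raise KineticsError("need at least 2 substrate series")
    lines: dict[float, tuple[float, float]] = {}
    for sl in s_levels:
        mask = s == sl
        if np.unique(i[mask]).size < 2:
            raise KineticsError(
                f"substrate series S={sl} has fewer than 2 inhibitor levels"
            )
        fit = linregress(i[mask], 1.0 / v[mask])
        lines[float(sl)] = (float(fit.intercept), float(fit.slope))

    a = np.array([ab[0] for ab in lines.values()])
    b = np.array([ab[1] for ab in lines.values()])
    slope_spread = np.ptp(b)
    scale = max(abs(b).max(), 1e-300)
    if slope_spread <= 1e-9 * scale:
        raise KineticsError("no finite intersection: Dixon lines are "
                            "parallel (non-competitive pattern)")
    # least-squares common point: minimize sum (a + b x - y)^2 over (x, y)
    n = len(a)
    sb, sbb = b.sum(), (b * b).sum()
    sa, sab = a.sum(), (a * b).sum()
    det = n * sbb - sb * sb
    x_star = (sa * sb - n * sab) / det
    y_star = (sa * sbb - sab * sb) / det
    global_fit = fit_competitive(data) if with_global_fit else None
    return DixonResult(ki=-x_star, intersection_y=y_star, lines=lines,
                       global_fit=global_fit)


# ---------------------------------------------------------------------------
# metal activation
# ---------------------------------------------------------------------------

@dataclass
class ActivationFit:
    slope: float                      # percent activation per mM
    intercept: float                  # percent activation at zero dose
    r_squared: float
    dose_range: tuple[float, float]

    def predict(self, dose: float) -> float:
        lo, hi = self.dose_range
        if not lo <= dose <= hi:
            warnings.warn(f"dose {dose} mM outside the fitted range "
                          f"[{lo}, {hi}] mM", stacklevel=2)
        return self.intercept + self.slope * dose


def metal_activation(doses, activation_percent) -> ActivationFit:
    """Least-squares line of percent activation versus metal dose (mM).

    The intercept is reported as fitted, not forced through the origin.
    """
    doses = np.asarray(doses, dtype=float)
    act = np.asarray(activation_percent, dtype=float)
    if doses.shape != act.shape:
        raise KineticsError("doses and activations must match in shape")
    if np.unique(doses).size < 2:
        raise KineticsError("need at least 2 distinct doses")
    fit = linregress(doses, act)
    r2 = float(fit.rvalue ** 2) if np.ptp(act) > 0 else 1.0
    return ActivationFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=r2,
                         dose_range=(float(doses.min()), float(doses.max())))
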