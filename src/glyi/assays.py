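"""Quantification layer for the methylglyoxal and glutathione assays.

MG is derivatized with 2,4-dinitrophenylhydrazine (DNPH) and read at
432 nm against a linear standard curve (0.5-30 uM standards); tissue
content follows from inverse prediction, dilution factor, extract volume
and fresh weight.  The glutathione pool is measured by the DTNB/
glutathione-reductase recycling assay: total glutathione and GSSG (after
masking GSH with 2-vinylpyridine) are read separately and
GSH = total - GSSG.  A Pearson correlation helper supports the
MG-vs-GLYI-activity association analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AssayError",
    "CalibrationCurve",
    "GlutathionePool",
    "MgQuantification",
    "fit_calibration",
    "quantify_mg",
    "glutathione_pool",
    "pearson_r",
]


class AssayError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    """Ordinary least-squares line response = slope * conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]     # uM, span of the standards

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def invert(self, response: float) -> float:
        """Inverse prediction: concentration (uM) from a response."""
        return (response - self.intercept) / self.slope

    def in_range(self, conc: float) -> bool:
        lo, hi = self.conc_range
        return lo <= conc <= hi


def fit_calibration(concentrations, responses) -> CalibrationCurve:
    """Fit an unweighted OLS standard curve (intercept not forced to zero)."""
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.size < 3:
        raise AssayError("need >= 3 matched standards")
    if np.unique(conc).size < 2:
        raise AssayError("need >= 2 distinct standard concentrations")
    if (resp < 0).any():
        raise AssayError("responses must be nonnegative")
    fit = stats.linregress(conc, resp)
    if fit.slope == 0:
        raise AssayError("zero calibration slope: curve is non-identifiable")
    return CalibrationCurve(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            conc_range=(float(conc.min()), float(conc.max())))


@dataclass(frozen=True)
class MgQuantification:
    content: float                     # umol g^-1 FW
    extract_conc: float                # uM in the undiluted extract
    assay_conc: float                  # uM read off the curve
    extrapolated: bool
    clipped: bool


def quantify_mg(response: float, curve: CalibrationCurve,
                dilution: float, tissue_mass_g: float,
                extract_volume_ml: float) -> MgQuantification:
    """MG tissue content from an extract absorbance reading.

    Unit chain: the curve inverts the 432 nm response to uM in the assay;
    times the dilution factor this is uM in the extract; times the extract
    volume (mL / 1000 -> umol) and divided by the fresh weight it becomes
    umol g^-1 FW.  Readings outside the standard range are flagged as
    extrapolated; a negative inverse prediction is clipped to zero with a
    warning.
    """
    if dilution <= 0 or tissue_mass_g <= 0 or extract_volume_ml <= 0:
        raise AssayError("dilution, mass and volume must be positive")
    assay_conc = curve.invert(response)
    extrapolated = not curve.in_range(assay_conc)
    if extrapolated:
        warnings.warn(
            f"predicted {assay_conc:.3g} uM outside the standard range "
            f"{curve.conc_range} uM (extrapolation)", stacklevel=2,
        )
    clipped = assay_conc < 0
    if clipped:
        warnings.warn("negative predicted concentration clipped to 0",
                      stacklevel=2)
        assay_conc = 0.0
    extract_conc = assay_conc * dilution
    content = extract_conc * (extract_volume_ml / 1000.0) / tissue_mass_g
    return MgQuantification(content=content, extract_conc=extract_conc,
                            assay_conc=assay_conc, extrapolated=extrapolated,
                            clipped=clipped)


@dataclass(frozen=True)
class GlutathionePool:
    total: float                       # umol g^-1 FW
    gssg: float
    gsh: float
    ratio: float | None                # GSH/GSSG, None when GSSG = 0


def glutathione_pool(total_measured: float,
                     gssg_measured: float) -> GlutathionePool:
    """Split the measured glutathione pool: GSH = total - GSSG.

    GSSG is kept in the assay's own bookkeeping units (as calibrated
    against VPD-treated GSSG standards); the GSH/GSSG ratio is undefined
    (None) when no GSSG was measured.
    """
    if gssg_measured < 0 or total_measured < 0:
        raise AssayError("measured amounts must be nonnegative")
    if gssg_measured > total_measured:
        raise AssayError(
            f"inconsistent pool: GSSG {gssg_measured} > total {total_measured}"
        )
    gsh = total_measured - gssg_measured
    ratio = gsh / gssg_measured if gssg_measured > 0 else None
    return GlutathionePool(total=total_measured, gssg=gssg_measured,
                           gsh=gsh, ratio=ratio)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise AssayError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AssayError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
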