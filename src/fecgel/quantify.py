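"""Absolute quantification of fluorescent labelling.

A dilution series of the free fluorophore, scanned alongside the gel,
gives a standard curve of fluorescence intensity versus molar amount.
Inverting it converts a lane's background-subtracted signal into moles of
coupled fluorophore, and hence into the degree of labelling (DoL): the
percentage of protein molecules carrying a label — legitimately above
100 % when molecules carry several labels — and the percentage of lysine
residues labelled (labels attach to lysines via transglutamination).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .image import GelError

log = logging.getLogger(__name__)


@dataclass
class StandardCurve:
    """OLS line intensity = slope * moles + intercept.

    The intercept absorbs the scanner's blank/background offset; a valid
    curve has positive slope (more fluorophore, more signal).
    """

    slope: float
    intercept: float
    r_squared: float
    points: list = field(default_factory=list)

    def moles_from_intensity(self, intensity: float) -> float:
        """Invert the curve; negative inferred amounts clip to zero."""
        if self.slope <= 0:
            raise GelError("standard curve slope must be positive")
        moles = (intensity - self.intercept) / self.slope
        if moles < 0:
            log.warning("inferred fluorophore amount %.3g below zero; "
                        "clipping to 0", moles)
            moles = 0.0
        return float(moles)


@dataclass
class LabellingResult:
    """Degree-of-labelling result for one lane/sample."""

    fluor_moles: float
    protein_moles: float
    dol_protein_pct: float
    dol_lysine_pct: float | None = None
    n_lysine: int | None = None

    def to_dict(self) -> dict:
        return {"fluor_moles": self.fluor_moles,
                "protein_moles": self.protein_moles,
                "dol_protein_pct": self.dol_protein_pct,
                "dol_lysine_pct": self.dol_lysine_pct,
                "n_lysine": self.n_lysine}


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least-squares fit of (moles, intensity) pairs."""
    pts = [(float(m), float(i)) for m, i in points]
    if len(pts) < 2:
        raise GelError("standard curve needs at least 2 points")
    moles = np.array([p[0] for p in pts])
    intens = np.array([p[1] for p in pts])
    if np.unique(moles).size < 2:
        raise GelError("standard curve needs at least 2 distinct mole values")
    fit = stats.linregress(moles, intens)
    return StandardCurve(slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2),
                         points=pts)


def degree_of_labelling(band_intensity: float, curve: StandardCurve,
                        protein_moles: float) -> LabellingResult:
    """Percent of protein molecules labelled, from a lane's total signal.

    ``band_intensity`` is the background-subtracted lane total (same
    intensity units as the standard curve); ``protein_moles`` the loaded
    protein amount.  100 % means one fluorophore per protein molecule on
    average; multiply-labelled molecules push the value above 100 %.
    """
    if protein_moles <= 0:
        raise GelError("protein amount must be positive")
    fluor = curve.moles_from_intensity(float(band_intensity))
    return LabellingResult(fluor_moles=fluor,
                           protein_moles=float(protein_moles),
                           dol_protein_pct=100.0 * fluor / protein_moles)


def lysine_labelling_fraction(dol_protein_pct: float, n_lysine: int) -> float:
    """Percent of lysine residues labelled: per-protein DoL / lysine count."""
    if n_lysine < 1:
        raise GelError("n_lysine must be >= 1")
    return float(dol_protein_pct) / float(n_lysine)


def with_lysine_fraction(result: LabellingResult,
                         n_lysine: int) -> LabellingResult:
    """Attach the lysine-residue labelling fraction to a result."""
    return LabellingResult(result.fluor_moles, result.protein_moles,
                           result.dol_protein_pct,
                           lysine_labelling_fraction(result.dol_protein_pct,
                                                     n_lysine),
                           int(n_lysine))
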