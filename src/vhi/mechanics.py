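"""Passive vascular wall mechanics: circumferential stress-strain analysis.

Under Ca2+-free conditions a vessel's inner and outer diameter are recorded
over an intralumenal pressure ramp (5 mmHg standing in for the 0 mmHg point,
then 20-mmHg increments up to 160 mmHg).  Thin-wall definitions convert each
pressure step into circumferential stress and strain,

    sigma = P * ID / (2 * WT),    WT = (OD - ID) / 2,
    eps   = (ID - ID0) / ID0,     ID0 = inner diameter at the lowest pressure,

with P converted from mmHg to dyn/cm^2.  The stress-strain relation is then
fit with an exponential growth curve sigma = sigma0 * exp(beta * eps) by
ordinary least squares of ln(sigma) on eps; the slope beta is the wall
stiffness component of the health index (higher beta = stiffer wall), and
fits with r^2 <= 0.85 are flagged unacceptable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "MMHG_TO_DYN",
    "MechanicsSeries",
    "StressStrainSeries",
    "MechanicsFit",
    "compute_stress_strain",
    "fit_exponential",
]

#: dyn/cm^2 per mmHg
MMHG_TO_DYN = 1333.22

#: r^2 threshold below which an exponential stress-strain fit is rejected
R2_ACCEPTANCE = 0.85


@dataclass(frozen=True)
class MechanicsSeries:
    """Per-animal passive (pressure, inner/outer diameter) observations.

    Pressures are in mmHg, strictly ascending, at least four steps; diameters
    in um with ``outer > inner > 0`` at every step.
    """

    animal_id: str
    bed: str
    pressures: np.ndarray
    inner_diameters: np.ndarray
    outer_diameters: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pressures, dtype=float)
        idi = np.asarray(self.inner_diameters, dtype=float)
        odi = np.asarray(self.outer_diameters, dtype=float)
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "inner_diameters", idi)
        object.__setattr__(self, "outer_diameters", odi)
        if not (p.shape == idi.shape == odi.shape) or p.ndim != 1:
            raise InvalidInputError("pressures and diameters must be 1-D and equal length")
        if p.size < 4:
            raise InvalidInputError(f"need >= 4 pressure steps, got {p.size}")
        if np.any(np.diff(p) <= 0):
            raise InvalidInputError("pressures must be strictly ascending")
        if not np.all(np.isfinite(idi)) or not np.all(np.isfinite(odi)):
            raise InvalidInputError("diameters must be finite")
        if np.any(idi <= 0):
            raise InvalidInputError("inner diameters must be positive")
        if np.any(odi <= idi):
            raise InvalidInputError("outer diameter must exceed inner diameter at every step")


@dataclass(frozen=True)
class StressStrainSeries:
    """Derived circumferential stress (dyn/cm^2) vs strain (dimensionless)."""

    animal_id: str
    bed: str
    strains: np.ndarray
    stresses: np.ndarray
    reference_inner_diameter: float  # um, inner diameter at the lowest pressure


@dataclass(frozen=True)
class MechanicsFit:
    """Log-linear OLS fit of the exponential stress-strain relation."""

    animal_id: str
    bed: str
    beta: float           # dimensionless stiffness slope
    log_intercept: float  # ln(dyn/cm^2)
    r_squared: float
    acceptable: bool      # r_squared > 0.85
    n_obs: int = 0


def compute_stress_strain(series: MechanicsSeries, mmhg_to_dyn: float = MMHG_TO_DYN) -> StressStrainSeries:
    """Convert a pressure-diameter series to circumferential stress and strain.

    Strain is referenced to the inner diameter at the lowest pressure, so the
    first strain is exactly zero.  Wall thickness at each step comes from the
    measured diameters; a non-positive thickness is a data error and is
    reported with its pressure step.
    """
    if mmhg_to_dyn <= 0:
        raise InvalidInputError("mmhg_to_dyn must be positive")
    p = series.pressures
    idi = series.inner_diameters
    odi = series.outer_diameters
    wt = (odi - idi) / 2.0
    bad = np.nonzero(wt <= 0)[0]
    if bad.size:
        raise InvalidInputError(
            f"non-positive wall thickness at pressure {p[bad[0]]:g} mmHg"
        )
    id0 = idi[0]
    strains = (idi - id0) / id0
    strains = strains.copy()
    strains[0] = 0.0
    stresses = (p * mmhg_to_dyn) * idi / (2.0 * wt)
    return StressStrainSeries(
        animal_id=series.animal_id,
        bed=series.bed,
        strains=strains,
        stresses=stresses,
        reference_inner_diameter=float(id0),
    )


def fit_exponential(ss: StressStrainSeries) -> MechanicsFit:
    """OLS of ln(stress) on strain; the slope is the stiffness coefficient beta.

    Raises
    ------
    InvalidInputError
        Fewer than three points, non-positive stresses, or zero strain
        variance.
    """
    eps = np.asarray(ss.strains, dtype=float)
    sig = np.asarray(ss.stresses, dtype=float)
    if eps.size < 3:
        raise InvalidInputError(f"need >= 3 stress-strain points, got {eps.size}")
    if np.any(sig <= 0) or not np.all(np.isfinite(sig)):
        raise InvalidInputError("stresses must be positive and finite")
    if np.ptp(eps) == 0:
        raise InvalidInputError("zero strain variance: cannot fit a slope")

    y = np.log(sig)
    xbar, ybar = eps.mean(), y.mean()
    sxx = float(np.sum((eps - xbar) ** 2))
    sxy = float(np.sum((eps - xbar) * (y - ybar)))
    beta = sxy / sxx
    intercept = ybar - beta * xbar
    resid = y - (intercept + beta * eps)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return MechanicsFit(
        animal_id=ss.animal_id,
        bed=ss.bed,
        beta=float(beta),
        log_intercept=float(intercept),
        r_squared=float(r2),
        acceptable=bool(r2 > R2_ACCEPTANCE),
        n_obs=int(eps.size),
    )
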