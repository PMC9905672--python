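"""Endothelium-dependent dilation: logistic concentration-response fitting.

Arteriolar responses to increasing acetylcholine concentration are summarised
by the three-parameter logistic

    y = min + (max - min) / (1 + 10**(logEC50 - x)),

where ``x`` is log10 of the agonist concentration (mol/L), ``y`` the vessel
diameter (um), ``min``/``max`` the lower and upper response bounds and
``logEC50`` the half-maximal concentration on the log10 scale.  The fitted
upper bound is the dilator-capacity component fed into the health index.

The slope is fixed at one (base-10 logistic exactly as written above); no
Hill-coefficient extension is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidInputError

__all__ = ["DoseResponseSeries", "DoseResponseFit", "logistic_response", "fit_logistic"]


@dataclass(frozen=True)
class DoseResponseSeries:
    """One animal's (concentration, diameter) observations for one vessel bed.

    Parameters
    ----------
    animal_id : str
        Opaque identifier.
    bed : str
        ``"skeletal"`` (gracilis arteriole) or ``"cerebral"`` (MCA).
    concentrations : array-like
        Molar acetylcholine concentrations, strictly positive and strictly
        ascending, at least four values.
    responses : array-like
        Vessel diameters (um), finite and positive, same length.
    """

    animal_id: str
    bed: str
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if conc.ndim != 1 or resp.ndim != 1 or conc.size != resp.size:
            raise InvalidInputError("concentrations and responses must be 1-D and equal length")
        if conc.size < 4:
            raise InvalidInputError(f"need >= 4 observation pairs, got {conc.size}")
        if not np.all(np.isfinite(conc)) or np.any(conc <= 0):
            raise InvalidInputError("concentrations must be finite and strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise InvalidInputError("concentrations must be strictly ascending")
        if not np.all(np.isfinite(resp)) or np.any(resp <= 0):
            raise InvalidInputError("responses must be finite and positive")

    @property
    def log_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted logistic parameters and diagnostics for one series."""

    animal_id: str
    bed: str
    lower_bound: float      # um
    upper_bound: float      # um; the VHI dilation component
    log_ec50: float         # log10(mol/L)
    residual_ss: float      # um^2
    r_squared: float
    converged: bool
    n_obs: int = field(default=0)


def logistic_response(x, lower, upper, log_ec50):
    """Evaluate the base-10 logistic at log10 concentration ``x``."""
    x = np.asarray(x, dtype=float)
    return lower + (upper - lower) / (1.0 + 10.0 ** (log_ec50 - x))


def fit_logistic(series: DoseResponseSeries, tolerance: float = 1e-8) -> DoseResponseFit:
    """Least-squares fit of the logistic concentration-response curve.

    Parameters are initialised at ``min(y)``, ``max(y)`` and ``median(x)``;
    the upper bound is constrained to lie at or above the lower bound and
    ``logEC50`` is boxed to ``[min(x) - 2, max(x) + 2]``.  Optimiser failure
    is reported through ``converged=False``, never as an exception.

    Parameters
    ----------
    series : DoseResponseSeries
        Validated observations.
    tolerance : float
        Convergence tolerance on the sum of squared residuals.

    Returns
    -------
    DoseResponseFit
    """
    if tolerance <= 0:
        raise InvalidInputError("tolerance must be positive")
    x = series.log_concentrations
    y = series.responses

    lo0 = float(np.min(y))
    delta0 = max(float(np.max(y) - np.min(y)), 1e-9)
    ec0 = float(np.median(x))
    ec_lo, ec_hi = float(x.min() - 2.0), float(x.max() + 2.0)

    # parameterise as (lower, upper - lower, logEC50) so upper >= lower is a
    # simple non-negativity bound
    def residuals(p):
        lower, delta, log_ec50 = p
        return logistic_response(x, lower, lower + delta, log_ec50) - y

    try:
        result = least_squares(
            residuals,
            x0=[lo0, delta0, ec0],
            bounds=([-np.inf, 0.0, ec_lo], [np.inf, np.inf, ec_hi]),
            ftol=tolerance, xtol=tolerance * 1e-2, gtol=tolerance,
            max_nfev=10_000,
        )
        converged = bool(result.success)
        lower, delta, log_ec50 = result.x
    except Exception:
        converged = False
        lower, delta, log_ec50 = lo0, delta0, ec0

    fitted = logistic_response(x, lower, lower + delta, log_ec50)
    ss_res = float(np.sum((fitted - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)

    return DoseResponseFit(
        animal_id=series.animal_id,
        bed=series.bed,
        lower_bound=float(lower),
        upper_bound=float(lower + delta),
        log_ec50=float(log_ec50),
        residual_ss=ss_res,
        r_squared=r2,
        converged=converged,
        n_obs=int(x.size),
    )
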