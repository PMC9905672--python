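"""Synthetic cohort generation calibrated to the published group summaries.

The raw animal data behind the index are not deposited, so this module
generates per-animal raw measurements — acetylcholine dose-response series,
passive pressure-diameter series, microvessel density and plasma biomarkers —
whose group x age x bed distributions match the printed means +/- SE, and
whose biomarkers are negatively coupled to vascular health through a latent
per-animal health factor ``z``.  That coupling is what reproduces the strong
negative index-vs-insulin / index-vs-TNF-alpha correlations used for
criterion validity.

Model per animal: draw z ~ N(0, 1) once; each component is

    value = mean + SD * (s * rho * z + sqrt(1 - rho^2) * eps),  eps ~ N(0,1)

with SD reconstructed as SE * sqrt(n_source) and the sign s chosen so larger
z is healthier (raises dilation and density, lowers stiffness beta and the
insulin/glucose/TNF biomarkers).  Dose-response series come from the logistic
forward model with that animal's dilation bound as its upper asymptote;
passive mechanics series come from an exponential stress-strain stress
balance solved for inner diameter at each pressure (wall cross-sectional
area conserved).  Everything is a pure function of (spec, seed).

TNF-alpha summaries are not published for these cohorts: the fixture carries
synthetic placeholder levels (arbitrary units) whose coupling — not scale —
is what downstream validity checks consume; they are flagged in the fixture
file's ``synthetic_fields`` column, as are the pentoxifylline component
cells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidInputError, ModelInconsistencyError
from .mechanics import MMHG_TO_DYN, MechanicsSeries
from .reactivity import DoseResponseSeries, logistic_response
from .scoring import AGES, BEDS, GROUPS, AnimalRecord

__all__ = [
    "DoseResponseShape",
    "MechanicsShape",
    "CohortSpec",
    "StudyBundle",
    "fixture_tables",
    "simulate_passive_mechanics",
    "generate_cohort",
    "generate_study",
]

#: log10 molar acetylcholine grid: 7 half-log steps, 1e-9 to 1e-6 M
DOSE_LOG10_GRID = np.arange(-9.0, -5.75, 0.5)

#: intralumenal pressure grid (mmHg); 5 mmHg stands in for the 0 mmHg point
PRESSURE_GRID = np.array([5.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 140.0, 160.0])

DEFAULT_COUPLING_RHO = 0.7


@dataclass(frozen=True)
class DoseResponseShape:
    """Forward-model shape of a generated dose-response series."""

    lower_bound: float        # um, baseline (pre-agonist) diameter
    log_ec50_mean: float = -7.5
    log_ec50_sd: float = 0.15
    noise_sd: float = 1.0     # um, observation noise on diameters


@dataclass(frozen=True)
class MechanicsShape:
    """Forward-model geometry of a generated passive mechanics series."""

    id0: float                # um, inner diameter at the 5 mmHg reference
    wt0: float                # um, wall thickness at the reference
    sigma0: Optional[float] = None   # dyn/cm^2; None = consistent with 5 mmHg
    noise_sd: float = 0.5     # um, observation noise on diameters


# per-bed geometry for generated series (gracilis arteriole vs MCA)
_BED_DR_LOWER_FRACTION = 0.60
_BED_MECH = {
    "skeletal": MechanicsShape(id0=90.0, wt0=12.0),
    "cerebral": MechanicsShape(id0=120.0, wt0=15.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generating distribution for one (group, age, bed) cohort.

    ``component_means``/``component_ses`` are (ach_upper um, mvd /mm^2, beta);
    ``biomarker_means``/``biomarker_ses`` are (mass g, insulin ng/mL,
    glucose mg/dL, tnf_alpha a.u.).  ``n_source`` is the published sample
    size used to reconstruct SDs from SEs; ``coupling_rho`` in [0, 1] sets
    how strongly a shared latent health factor drives all coupled draws.
    """

    group: str
    age_wk: int
    bed: str
    n: int
    component_means: tuple
    component_ses: tuple
    n_source: int
    biomarker_means: tuple = (0.0, 0.0, 0.0, 0.0)
    biomarker_ses: tuple = (0.0, 0.0, 0.0, 0.0)
    coupling_rho: float = DEFAULT_COUPLING_RHO
    dr_shape: Optional[DoseResponseShape] = None
    mech_shape: Optional[MechanicsShape] = None
    synthetic_fields: tuple = ()

    def __post_init__(self):
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        if self.age_wk not in AGES:
            raise InvalidInputError(f"age_wk must be one of {AGES}")
        if self.bed not in BEDS:
            raise InvalidInputError(f"bed must be one of {BEDS}")
        if self.n < 0:
            raise InvalidInputError("n must be >= 0")
        if self.n_source < 1:
            raise InvalidInputError("n_source must be >= 1")
        if not (0.0 <= self.coupling_rho <= 1.0):
            raise InvalidInputError("coupling_rho must be in [0, 1]")
        if len(self.component_means) != 3 or len(self.component_ses) != 3:
            raise InvalidInputError("component_means/ses must have 3 entries")
        if any(se < 0 for se in self.component_ses) or any(se < 0 for se in self.biomarker_ses):
            raise InvalidInputError("SEs must be >= 0")
        if self.dr_shape is None:
            object.__setattr__(self, "dr_shape", DoseResponseShape(
                lower_bound=_BED_DR_LOWER_FRACTION * self.component_means[0]))
        if self.mech_shape is None:
            object.__setattr__(self, "mech_shape", _BED_MECH[self.bed])

    @property
    def component_sds(self) -> np.ndarray:
        return np.asarray(self.component_ses) * np.sqrt(self.n_source)

    @property
    def biomarker_sds(self) -> np.ndarray:
        return np.asarray(self.biomarker_ses) * np.sqrt(self.n_source)


def fixture_tables(
    groups: Optional[Sequence[str]] = None,
    ages: Optional[Sequence[int]] = None,
    beds: Optional[Sequence[str]] = None,
    coupling_rho: float = DEFAULT_COUPLING_RHO,
) -> list[CohortSpec]:
    """Load the packaged group x age x bed summary fixture as CohortSpecs.

    One spec per printed cohort cell; cells absent from the published tables
    are simply missing.  Optional filters restrict by group, age or bed.
    """
    with resources.files("vhi.data").joinpath("cohort_tables.csv").open("r") as fh:
        df = pd.read_csv(fh)
    specs = []
    for row in df.itertuples(index=False):
        if groups is not None and row.group not in groups:
            continue
        if ages is not None and row.age_wk not in ages:
            continue
        if beds is not None and row.bed not in beds:
            continue
        syn = tuple(str(row.synthetic_fields).split()) if isinstance(row.synthetic_fields, str) else ()
        specs.append(CohortSpec(
            group=row.group, age_wk=int(row.age_wk), bed=row.bed, n=int(row.n),
            component_means=(row.ach_mean, row.mvd_mean, row.beta_mean),
            component_ses=(row.ach_se, row.mvd_se, row.beta_se),
            n_source=int(row.n),
            biomarker_means=(row.mass_mean, row.insulin_mean, row.glucose_mean, row.tnf_mean),
            biomarker_ses=(row.mass_se, row.insulin_se, row.glucose_se, row.tnf_se),
            coupling_rho=coupling_rho,
            synthetic_fields=syn,
        ))
    return specs


def _stress_balance_root(p_dyn, sigma0, beta, id0, area_const, lo, hi_start):
    """Inner diameter where wall stress equals sigma0 * exp(beta * strain)."""

    def f(idi):
        od = np.sqrt(idi * idi + area_const)
        wt = (od - idi) / 2.0
        return np.log(p_dyn * idi / (2.0 * wt)) - np.log(sigma0) - beta * (idi - id0) / id0

    hi = hi_start
    flo = f(lo)
    if flo < 0:
        # search upward for a positive point (can occur with a user-supplied
        # inconsistent sigma0); give up quickly if none exists
        grid = lo * np.array([1.05, 1.1, 1.2, 1.5, 2.0])
        for g in grid:
            if f(g) > 0:
                lo = g
                flo = f(g)
                break
        else:
            raise ModelInconsistencyError(
                f"no stress-balance solution at {p_dyn / MMHG_TO_DYN:.3g} mmHg")
    for _ in range(60):
        if f(hi) < 0:
            break
        hi *= 1.3
    else:
        raise ModelInconsistencyError(
            f"no stress-balance solution at {p_dyn / MMHG_TO_DYN:.3g} mmHg")
    return brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)


def simulate_passive_mechanics(
    beta: float,
    id0: float,
    wt0: float,
    sigma0: Optional[float] = None,
    pressures: Optional[Sequence[float]] = None,
    mmhg_to_dyn: float = MMHG_TO_DYN,
    animal_id: str = "synthetic",
    bed: str = "skeletal",
) -> MechanicsSeries:
    """Forward model: pressure-diameter series of a vessel with stiffness beta.

    At each pressure P the inner diameter solves the stress balance

        P * ID / (2 * WT) = sigma0 * exp(beta * (ID - id0) / id0),

    with the wall cross-sectional area pi/4 * (OD^2 - ID^2) conserved from its
    reference value, so OD follows from ID.  When ``sigma0`` is omitted it is
    derived from the balance at the lowest pressure, making ID there equal
    ``id0`` exactly (zero strain at the reference point).  Solved by root
    bracketing to |sigma_lhs - sigma_rhs| far below 1e-6 * sigma0.
    """
    if beta <= 0 or id0 <= 0 or wt0 <= 0:
        raise InvalidInputError("beta, id0 and wt0 must be positive")
    p = np.asarray(PRESSURE_GRID if pressures is None else pressures, dtype=float)
    if p.size < 4 or np.any(np.diff(p) <= 0):
        raise InvalidInputError("need >= 4 strictly ascending pressures")
    od0 = id0 + 2.0 * wt0
    area_const = od0 * od0 - id0 * id0  # pi/4 cancels
    p_dyn = p * mmhg_to_dyn
    if sigma0 is None:
        sigma0 = p_dyn[0] * id0 / (2.0 * wt0)
    if sigma0 <= 0:
        raise InvalidInputError("sigma0 must be positive")

    inner = np.empty_like(p)
    prev = id0 * 0.8
    for i, pd_i in enumerate(p_dyn):
        # reference point solves exactly when sigma0 is consistent
        if i == 0 and abs(pd_i * id0 / (2.0 * wt0) - sigma0) < 1e-9 * sigma0:
            inner[0] = id0
            prev = id0
            continue
        inner[i] = _stress_balance_root(pd_i, sigma0, beta, id0, area_const,
                                        lo=prev, hi_start=max(prev, id0) * 1.5)
        prev = inner[i]
    outer = np.sqrt(inner * inner + area_const)
    return MechanicsSeries(
        animal_id=animal_id, bed=bed,
        pressures=p, inner_diameters=inner, outer_diameters=outer,
    )


def _cohort_rng(spec: CohortSpec, seed: int) -> np.random.Generator:
    # order-stable sub-seed: depends only on (seed, group, age, bed)
    key = f"{spec.group}|{spec.age_wk}|{spec.bed}".encode()
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(key)]))


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    with_series: bool = True,
) -> list[tuple]:
    """Generate one cohort: (AnimalRecord, DoseResponseSeries, MechanicsSeries) per animal.

    A single latent health factor z per animal drives all coupled draws (see
    module docstring).  Component draws that land non-positive are redrawn
    (rare at table-calibrated parameters).  With ``with_series=False`` only
    the records are produced (series slots are None) — useful for large-n
    calibration runs.  Identical (spec, seed) gives bit-identical output.
    """
    rng = _cohort_rng(spec, seed)
    rho = spec.coupling_rho
    comp_means = np.asarray(spec.component_means, dtype=float)
    comp_sds = spec.component_sds
    bio_means = np.asarray(spec.biomarker_means, dtype=float)
    bio_sds = spec.biomarker_sds
    # signs: larger z is healthier
    comp_signs = np.array([+1.0, +1.0, -1.0])          # ach, mvd, beta
    bio_signs = np.array([0.0, -1.0, -1.0, -1.0])      # mass uncoupled; insulin/glucose/tnf negative
    root = np.sqrt(1.0 - rho * rho)

    out = []
    tag = f"{spec.group}-{spec.age_wk}wk-{spec.bed}"
    for i in range(spec.n):
        z = rng.standard_normal()

        def draw(mean, sd, sign):
            if sd == 0:
                return float(mean)
            for _ in range(200):
                v = mean + sd * (sign * rho * z + root * rng.standard_normal())
                if v > 0:
                    return float(v)
            raise InvalidInputError(
                f"could not draw a positive value for cohort {tag} (mean {mean}, sd {sd})")

        ach, mvd, beta = (draw(comp_means[j], comp_sds[j], comp_signs[j]) for j in range(3))
        mass = draw(bio_means[0], bio_sds[0], bio_signs[0])
        insulin = draw(bio_means[1], bio_sds[1], bio_signs[1])
        glucose = draw(bio_means[2], bio_sds[2], bio_signs[2])
        tnf = draw(bio_means[3], bio_sds[3], bio_signs[3])

        rec = AnimalRecord(
            animal_id=f"{tag}-{i:03d}", group=spec.group, age_wk=spec.age_wk,
            bed=spec.bed, ach_upper=ach, mvd=mvd, beta=beta,
            mass=mass, insulin=insulin, glucose=glucose, tnf_alpha=tnf,
        )
        drs = mech = None
        if with_series:
            dr = spec.dr_shape
            log_ec50 = rng.normal(dr.log_ec50_mean, dr.log_ec50_sd)
            clean = logistic_response(DOSE_LOG10_GRID, dr.lower_bound, ach, log_ec50)
            noisy = clean + rng.normal(0.0, dr.noise_sd, size=clean.size)
            noisy = np.maximum(noisy, 1.0)
            drs = DoseResponseSeries(
                animal_id=rec.animal_id, bed=spec.bed,
                concentrations=10.0 ** DOSE_LOG10_GRID, responses=noisy,
            )
            ms = spec.mech_shape
            base = simulate_passive_mechanics(
                beta=beta, id0=ms.id0, wt0=ms.wt0, sigma0=ms.sigma0,
                animal_id=rec.animal_id, bed=spec.bed,
            )
            if ms.noise_sd > 0:
                idi = base.inner_diameters + rng.normal(0.0, ms.noise_sd, base.pressures.size)
                odi = base.outer_diameters + rng.normal(0.0, ms.noise_sd, base.pressures.size)
                odi = np.maximum(odi, idi + 1.0)  # keep a physical wall
                mech = MechanicsSeries(
                    animal_id=rec.animal_id, bed=spec.bed,
                    pressures=base.pressures, inner_diameters=idi, outer_diameters=odi,
                )
            else:
                mech = base
        out.append((rec, drs, mech))
    return out


@dataclass(frozen=True)
class StudyBundle:
    """All cohorts of one generated study plus the seed that produced them."""

    records: tuple
    dose_series: tuple
    mechanics_series: tuple
    seed: int

    def animals_frame(self) -> pd.DataFrame:
        rows = [{
            "animal_id": r.animal_id, "group": r.group, "age_wk": r.age_wk,
            "bed": r.bed, "ach_upper_um": r.ach_upper, "mvd_per_mm2": r.mvd,
            "beta": r.beta, "mass_g": r.mass, "insulin_ng_ml": r.insulin,
            "glucose_mg_dl": r.glucose, "tnf_alpha": r.tnf_alpha,
        } for r in self.records]
        return pd.DataFrame(rows)

    def dose_response_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.dose_series:
            for c, d in zip(s.concentrations, s.responses):
                rows.append({"animal_id": s.animal_id, "bed": s.bed,
                             "concentration_M": c, "diameter_um": d})
        return pd.DataFrame(rows)

    def mechanics_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.mechanics_series:
            for p, idi, odi in zip(s.pressures, s.inner_diameters, s.outer_diameters):
                rows.append({"animal_id": s.animal_id, "bed": s.bed,
                             "pressure_mmHg": p, "inner_diameter_um": idi,
                             "outer_diameter_um": odi})
        return pd.DataFrame(rows)


def generate_study(specs: Sequence[CohortSpec], seed: int, with_series: bool = True) -> StudyBundle:
    """Generate all cohorts of a study; stable under reordering of ``specs``.

    Each cohort derives its own sub-seed from (seed, group, age, bed), so
    permuting the spec list changes nothing per animal.  Duplicate strata
    are rejected.
    """
    seen = set()
    for s in specs:
        key = (s.group, s.age_wk, s.bed)
        if key in seen:
            raise InvalidInputError(f"duplicate stratum {key} in spec list")
        seen.add(key)
    records, dose, mech = [], [], []
    for s in sorted(specs, key=lambda s: (s.bed, s.group, s.age_wk)):
        for rec, drs, ms in generate_cohort(s, seed, with_series=with_series):
            records.append(rec)
            if drs is not None:
                dose.append(drs)
            if ms is not None:
                mech.append(ms)
    return StudyBundle(records=tuple(records), dose_series=tuple(dose),
                       mechanics_series=tuple(mech), seed=int(seed))
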