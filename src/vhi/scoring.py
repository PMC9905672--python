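"""Vascular Health Index construction.

Each animal contributes three components — acetylcholine dilation upper bound
(um), microvessel density (vessels/mm^2) and wall stiffness slope beta — which
are expressed as percent-of-ideal against the age- and bed-matched mean of
untreated lean (LZR) control animals:

* components that fall with disease (dilation, density):
  ``score = 100 * measurement / standard``
* components that rise with disease (stiffness beta):
  ``score = 100 + (100 - 100 * measurement / standard)``

so every component reads "percent of ideal vascular health" and a stiffness
excess above the standard is a matching deficit.  The index is the unweighted
mean of the three component scores ("percentage" mode).  In "percentile" mode
each component's percentage scores are first converted to Hazen percentile
ranks within the pooled (age, bed) population, the three ranks are averaged,
and the result is rescaled so the LZR cohort mean is exactly 100; ranking
stops the wide dynamic range of beta from dominating the composite.

Scores are not clamped by default: a stiffness score below zero is meaningful
signal (beta more than double the standard).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import InvalidInputError, MissingStandardError, NormalizationError

__all__ = [
    "Direction",
    "GROUPS",
    "AGES",
    "BEDS",
    "AnimalRecord",
    "HealthStandard",
    "VHIResult",
    "CohortSummary",
    "component_percent",
    "percentile_ranks",
    "compute_standards",
    "compute_vhi",
    "summarize_cohorts",
    "time_average",
    "relative_improvement",
]

GROUPS = (
    "LZR", "OZR", "OZR+HYD", "OZR+CAP", "OZR+GEM", "OZR+ATOR",
    "OZR+PEN", "OZR+MET", "OZR+ROSI", "OZR+TEM", "OZR+LNM",
)
AGES = (7, 10, 13, 17, 20)
BEDS = ("skeletal", "cerebral")


class Direction(Enum):
    """Expected deviation of a component from the healthy standard with disease."""

    DECREASES_WITH_DISEASE = "decreases_with_disease"
    INCREASES_WITH_DISEASE = "increases_with_disease"


#: fixed component -> direction mapping
COMPONENT_DIRECTIONS = {
    "ach_upper": Direction.DECREASES_WITH_DISEASE,
    "mvd": Direction.DECREASES_WITH_DISEASE,
    "beta": Direction.INCREASES_WITH_DISEASE,
}


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's group membership, VHI components and plasma biomarkers."""

    animal_id: str
    group: str
    age_wk: int
    bed: str
    ach_upper: Optional[float] = None   # um
    mvd: Optional[float] = None         # vessels/mm^2
    beta: Optional[float] = None        # dimensionless
    mass: Optional[float] = None        # g
    insulin: Optional[float] = None     # ng/mL
    glucose: Optional[float] = None     # mg/dL
    tnf_alpha: Optional[float] = None   # arbitrary units, as supplied

    def __post_init__(self):
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        if self.age_wk not in AGES:
            raise InvalidInputError(f"age_wk must be one of {AGES}, got {self.age_wk}")
        if self.bed not in BEDS:
            raise InvalidInputError(f"bed must be one of {BEDS}, got {self.bed!r}")
        for name in ("ach_upper", "mvd"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be positive and finite, got {v}")
        if self.beta is not None and not math.isfinite(self.beta):
            raise InvalidInputError("beta must be finite")

    @property
    def has_all_components(self) -> bool:
        return None not in (self.ach_upper, self.mvd, self.beta)


@dataclass(frozen=True)
class HealthStandard:
    """Ideal (LZR mean) component values for one (age, bed) stratum."""

    age_wk: int
    bed: str
    ach_upper_std: float
    mvd_std: float
    beta_std: float
    n_lzr: int

    def __post_init__(self):
        for name in ("ach_upper_std", "mvd_std", "beta_std"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class VHIResult:
    """Per-animal component scores and the averaged index."""

    animal_id: str
    group: str
    age_wk: int
    bed: str
    ach_score: float
    mvd_score: float
    stiffness_score: float
    vhi: float
    mode: str                                   # "percentage" | "percentile"
    component_ranks: Optional[tuple] = None     # (ach, mvd, stiffness), percentile mode only


@dataclass(frozen=True)
class CohortSummary:
    """Mean +/- SE of the index for one (group, age, bed) cohort.

    ``age_wk is None`` marks a time-averaged (all-ages compiled) summary.
    """

    group: str
    age_wk: Optional[int]
    bed: str
    n: int
    vhi_mean: float
    vhi_se: float


def component_percent(measurement: float, standard: float, direction: Direction) -> float:
    """Percent-of-ideal score of one component against its healthy standard.

    A component that decreases with disease scores ``100 * m / s``; one that
    increases scores ``100 + (100 - 100 * m / s)``, so exceeding the standard
    shows up as a deficit.  The result is not clamped and may leave [0, 100].
    """
    if not (math.isfinite(standard) and standard > 0):
        raise InvalidInputError(f"standard must be positive, got {standard}")
    if not math.isfinite(measurement):
        raise InvalidInputError(f"measurement must be finite, got {measurement}")
    pct = 100.0 * measurement / standard
    if direction is Direction.DECREASES_WITH_DISEASE:
        return pct
    return 100.0 + (100.0 - pct)


def percentile_ranks(scores: Sequence[float]) -> np.ndarray:
    """Hazen percentile ranks, 100 * (i - 0.5) / n, ties sharing the mean rank.

    The output preserves input order; its mean is exactly 50 for any input.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot rank an empty score list")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("scores must be finite")
    ranks = rankdata(arr, method="average")
    return 100.0 * (ranks - 0.5) / arr.size


def compute_standards(lzr_records: Iterable[AnimalRecord]) -> list[HealthStandard]:
    """Arithmetic-mean LZR component values per (age, bed) stratum."""
    strata: dict[tuple, list[AnimalRecord]] = {}
    for rec in lzr_records:
        if rec.group != "LZR":
            continue
        if not rec.has_all_components:
            warnings.warn(f"LZR animal {rec.animal_id} missing a component; excluded from standards")
            continue
        strata.setdefault((rec.age_wk, rec.bed), []).append(rec)
    if not strata:
        raise InvalidInputError("no complete LZR records to compute standards from")
    out = []
    for (age, bed), recs in sorted(strata.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        out.append(HealthStandard(
            age_wk=age, bed=bed,
            ach_upper_std=float(np.mean([r.ach_upper for r in recs])),
            mvd_std=float(np.mean([r.mvd for r in recs])),
            beta_std=float(np.mean([r.beta for r in recs])),
            n_lzr=len(recs),
        ))
    return out


def _standards_index(standards: Iterable[HealthStandard]) -> dict:
    idx = {}
    for s in standards:
        key = (s.age_wk, s.bed)
        if key in idx:
            raise InvalidInputError(f"duplicate standard for stratum {key}")
        idx[key] = s
    return idx


def _component_scores(rec: AnimalRecord, std: HealthStandard, clamp_zero: bool):
    a = component_percent(rec.ach_upper, std.ach_upper_std, Direction.DECREASES_WITH_DISEASE)
    m = component_percent(rec.mvd, std.mvd_std, Direction.DECREASES_WITH_DISEASE)
    b = component_percent(rec.beta, std.beta_std, Direction.INCREASES_WITH_DISEASE)
    if clamp_zero:
        a, m, b = max(a, 0.0), max(m, 0.0), max(b, 0.0)
    return a, m, b


def compute_vhi(
    records: Sequence[AnimalRecord],
    standards: Iterable[HealthStandard],
    mode: str = "percentage",
    clamp_zero: bool = False,
) -> list[VHIResult]:
    """Score animals against health standards and average into the index.

    Percentage mode averages the three percent-of-ideal scores per animal.
    Percentile mode pools all animals of one (age, bed) stratum, converts each
    component's percentage scores to Hazen percentile ranks within that pool,
    averages the three ranks, and rescales so the pooled LZR mean is 100
    (by definition the LZR index is 100%); it therefore needs at least two
    animals and at least one LZR animal per stratum.

    Animals missing any component are excluded with a warning.  Output order
    matches input order (minus exclusions).
    """
    if mode not in ("percentage", "percentile"):
        raise InvalidInputError(f"mode must be 'percentage' or 'percentile', got {mode!r}")
    idx = _standards_index(standards)

    usable: list[AnimalRecord] = []
    for rec in records:
        if not rec.has_all_components:
            warnings.warn(f"animal {rec.animal_id} missing a VHI component; excluded")
            continue
        if (rec.age_wk, rec.bed) not in idx:
            raise MissingStandardError(rec.age_wk, rec.bed)
        usable.append(rec)

    if mode == "percentage":
        out = []
        for rec in usable:
            a, m, b = _component_scores(rec, idx[(rec.age_wk, rec.bed)], clamp_zero)
            out.append(VHIResult(
                animal_id=rec.animal_id, group=rec.group, age_wk=rec.age_wk,
                bed=rec.bed, ach_score=a, mvd_score=m, stiffness_score=b,
                vhi=(a + m + b) / 3.0, mode=mode,
            ))
        return out

    # percentile mode: rank within each pooled (age, bed) population
    strata: dict[tuple, list[int]] = {}
    for i, rec in enumerate(usable):
        strata.setdefault((rec.age_wk, rec.bed), []).append(i)
    results: dict[int, VHIResult] = {}
    for key, members in strata.items():
        if len(members) < 2:
            raise InvalidInputError(
                f"percentile mode needs >= 2 animals in stratum {key}, got {len(members)}"
            )
        std = idx[key]
        scores = np.array([_component_scores(usable[i], std, clamp_zero) for i in members])
        ranks = np.column_stack([percentile_ranks(scores[:, j]) for j in range(3)])
        raw = ranks.mean(axis=1)
        lzr_mask = np.array([usable[i].group == "LZR" for i in members])
        if not lzr_mask.any():
            raise NormalizationError(f"percentile mode: no LZR animals in stratum {key}")
        lzr_mean = raw[lzr_mask].mean()
        if lzr_mean <= 0:
            raise NormalizationError(f"percentile mode: non-positive LZR mean rank in stratum {key}")
        vhi = 100.0 * raw / lzr_mean
        for pos, i in enumerate(members):
            rec = usable[i]
            a, m, b = scores[pos]
            results[i] = VHIResult(
                animal_id=rec.animal_id, group=rec.group, age_wk=rec.age_wk,
                bed=rec.bed, ach_score=float(a), mvd_score=float(m),
                stiffness_score=float(b), vhi=float(vhi[pos]), mode=mode,
                component_ranks=tuple(float(r) for r in ranks[pos]),
            )
    return [results[i] for i in range(len(usable))]


def summarize_cohorts(results: Sequence[VHIResult]) -> list[CohortSummary]:
    """Mean +/- SE (sample SD / sqrt(n)) of the index per (group, age, bed)."""
    if not results:
        raise InvalidInputError("no results to summarize")
    strata: dict[tuple, list[float]] = {}
    for r in results:
        strata.setdefault((r.group, r.age_wk, r.bed), []).append(r.vhi)
    out = []
    for (group, age, bed), vals in sorted(
        strata.items(), key=lambda kv: (kv[0][2], kv[0][0], kv[0][1])
    ):
        arr = np.asarray(vals)
        se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        out.append(CohortSummary(
            group=group, age_wk=age, bed=bed, n=arr.size,
            vhi_mean=float(arr.mean()), vhi_se=se,
        ))
    return out


def time_average(summaries: Sequence[CohortSummary]) -> CohortSummary:
    """Compile one group's per-age cohort means into a single all-ages value.

    The mean is unweighted across ages; the SE propagates as
    sqrt(sum(se_i^2)) / k since each age is a disjoint set of animals.
    """
    if not summaries:
        raise InvalidInputError("time_average needs at least one age point")
    groups = {s.group for s in summaries}
    beds = {s.bed for s in summaries}
    if len(groups) != 1 or len(beds) != 1:
        raise InvalidInputError("time_average expects summaries from one group and one bed")
    ages = [s.age_wk for s in summaries]
    if len(set(ages)) != len(ages):
        raise InvalidInputError("duplicate age points in time_average input")
    k = len(summaries)
    mean = float(np.mean([s.vhi_mean for s in summaries]))
    se = float(math.sqrt(sum(s.vhi_se**2 for s in summaries)) / k)
    return CohortSummary(
        group=groups.pop(), age_wk=None, bed=beds.pop(),
        n=sum(s.n for s in summaries), vhi_mean=mean, vhi_se=se,
    )


def relative_improvement(treated: CohortSummary, untreated: CohortSummary) -> float:
    """Percent change of the treated cohort mean relative to the untreated one.

    Negative when treatment made the index worse; no clamping.
    """
    if treated.age_wk != untreated.age_wk or treated.bed != untreated.bed:
        raise InvalidInputError("treated and untreated summaries must share age and bed")
    if untreated.vhi_mean <= 0:
        raise InvalidInputError("untreated mean must be positive")
    return 100.0 * (treated.vhi_mean - untreated.vhi_mean) / untreated.vhi_mean
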