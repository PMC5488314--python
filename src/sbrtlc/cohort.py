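"""Cohorts and plan realizations: the bundled 17-patient reference cohort
plus seeded generators for synthetic cohorts and per-plan Dmax scatter.

The bundled fixture carries the published per-patient id / sex / age /
T-stage of the 17-patient NSCLC SBRT cohort (14 T1, 3 T2, ages 51–76).
Tumor diameters and volumes were reported only as cohort summaries
(2.5 ± 0.9 cm, 12.4 ± 17.4 cc), so per-patient diameters are *imputed* by a
seeded truncated-normal draw and flagged as synthetic wherever they appear.

Plan realizations model the planning constraint that the plan maximum
(isocenter) dose sits "about" 110% or 120% of prescription: each plan's
achieved Dmax factor is the scenario's nominal factor plus bounded uniform
jitter.  Jitter 0 reproduces the nominal factor exactly.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lq import FractionScheme, NormalizationScenario

__all__ = [
    "Patient",
    "Plan",
    "FixtureIntegrityError",
    "load_table1_fixture",
    "impute_diameters",
    "simulate_cohort",
    "simulate_plans",
    "cohort_to_csv",
    "cohort_from_csv",
    "plans_to_csv",
    "plans_from_csv",
]

_FIXTURE_NAME = "cohort17.csv"
_FIXTURE_SHA256 = "d929d41397c0ed887d2333e488c1ad68b47a623800bb29d4aa589d1465394478"


class FixtureIntegrityError(RuntimeError):
    """The bundled cohort fixture does not match its recorded checksum."""


@dataclass(frozen=True)
class Patient:
    id: str
    age: int
    sex: str  # "M" or "F"
    stage: str  # "T1" or "T2"
    diameter: float | None = None  # greatest tumor diameter, cm
    volume: float | None = None  # tumor volume, cc

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.stage not in ("T1", "T2"):
            raise ValueError(f"stage must be 'T1' or 'T2', got {self.stage!r}")
        if self.diameter is not None and not self.diameter > 0:
            raise ValueError(f"diameter must be > 0 cm, got {self.diameter!r}")
        if self.volume is not None and not self.volume > 0:
            raise ValueError(f"volume must be > 0 cc, got {self.volume!r}")


@dataclass(frozen=True)
class Plan:
    """One delivered-dose realization: a prescription for one patient under
    one normalization scenario, with the achieved Dmax/prescription
    factor."""

    patient_id: str
    scheme: FractionScheme
    scenario: str
    achieved_dmax_factor: float

    def __post_init__(self) -> None:
        if not self.achieved_dmax_factor > 1.0:
            raise ValueError(
                f"achieved Dmax factor must exceed 1.0, got {self.achieved_dmax_factor!r}"
            )


def _read_fixture_bytes() -> bytes:
    return resources.files("sbrtlc.data").joinpath(_FIXTURE_NAME).read_bytes()


def load_table1_fixture() -> list[Patient]:
    """The bundled 17-patient cohort (id, sex, age, stage; no diameters).

    Verifies the file checksum and raises :class:`FixtureIntegrityError`
    on mismatch.  Diameters are absent and must be imputed with
    :func:`impute_diameters` before running size-aware models.
    """
    raw = _read_fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"cohort fixture checksum mismatch: expected {_FIXTURE_SHA256}, got {digest}"
        )
    frame = pd.read_csv(io.BytesIO(raw), dtype={"id": str})
    return [
        Patient(id=row.id, age=int(row.age), sex=row.sex, stage=row.stage)
        for row in frame.itertuples()
    ]


def _draw_diameters(
    rng: np.random.Generator, n: int, mean: float, sd: float, floor: float
) -> np.ndarray:
    """Truncated-normal diameters (cm), truncated below at ``floor``."""
    if sd == 0:
        if mean < floor:
            raise ValueError("degenerate diameter distribution below the floor")
        return np.full(n, float(mean))
    a = (floor - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def impute_diameters(
    cohort: Sequence[Patient],
    seed: int,
    mean: float = 2.5,
    sd: float = 0.9,
    floor: float = 0.5,
) -> list[Patient]:
    """Return a copy of ``cohort`` with synthetic diameters drawn from a
    seeded truncated normal (cm).  Used for the bundled fixture, whose
    per-patient diameters were never published."""
    rng = np.random.default_rng(seed)
    draws = _draw_diameters(rng, len(cohort), mean, sd, floor)
    return [replace(p, diameter=float(d)) for p, d in zip(cohort, draws)]


def simulate_cohort(
    n: int,
    seed: int,
    diameter_mean: float = 2.5,
    diameter_sd: float = 0.9,
    t2_fraction: float = 3.0 / 17.0,
    age_range: tuple[int, int] = (51, 76),
    diameter_floor: float = 0.5,
) -> list[Patient]:
    """Generate a synthetic cohort with the reference cohort's marginals.

    Diameters ~ normal(mean, sd) truncated below at ``diameter_floor``;
    stage ~ Bernoulli(t2_fraction); ages uniform over ``age_range``
    inclusive; sex ~ Bernoulli(0.5).  Reproducible given ``seed``.
    """
    if n < 0:
        raise ValueError(f"cohort size must be ≥ 0, got {n!r}")
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    stages = np.where(rng.random(n) < t2_fraction, "T2", "T1")
    diameters = _draw_diameters(rng, n, diameter_mean, diameter_sd, diameter_floor)
    return [
        Patient(
            id=str(i + 1),
            age=int(ages[i]),
            sex=str(sexes[i]),
            stage=str(stages[i]),
            diameter=float(diameters[i]),
        )
        for i in range(n)
    ]


def simulate_plans(
    cohort: Sequence[Patient],
    schemes: Sequence[FractionScheme],
    scenario: NormalizationScenario,
    jitter_halfwidth: float = 0.02,
    seed: int = 0,
) -> list[Plan]:
    """One plan per (patient, scheme) with achieved Dmax factor drawn
    uniformly from [nominal − jitter, nominal + jitter].

    Jitter 0 gives exactly the nominal factor for every plan.
    """
    if jitter_halfwidth < 0:
        raise ValueError(f"jitter halfwidth must be ≥ 0, got {jitter_halfwidth!r}")
    rng = np.random.default_rng(seed)
    plans: list[Plan] = []
    for patient in cohort:
        for scheme in schemes:
            factor = scenario.dmax_factor
            if jitter_halfwidth > 0:
                factor += rng.uniform(-jitter_halfwidth, jitter_halfwidth)
            plans.append(
                Plan(
                    patient_id=patient.id,
                    scheme=scheme,
                    scenario=scenario.name,
                    achieved_dmax_factor=float(factor),
                )
            )
    return plans


# ---------------------------------------------------------------------------
# CSV round-trip.  Floats are written with repr-faithful precision so that a
# seeded run re-serializes byte-identically.

def cohort_to_frame(cohort: Sequence[Patient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "sex": [p.sex for p in cohort],
            "age": [p.age for p in cohort],
            "stage": [p.stage for p in cohort],
            "diameter_cm": [p.diameter for p in cohort],
            "volume_cc": [p.volume for p in cohort],
        }
    )


def cohort_to_csv(cohort: Sequence[Patient], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False, float_format="%.17g")


def cohort_from_csv(path) -> list[Patient]:
    frame = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    out = []
    for row in frame.itertuples():
        diameter = getattr(row, "diameter_cm", None)
        volume = getattr(row, "volume_cc", None)
        out.append(
            Patient(
                id=row.id,
                age=int(row.age),
                sex=row.sex,
                stage=row.stage,
                diameter=None if pd.isna(diameter) else float(diameter),
                volume=None if volume is None or pd.isna(volume) else float(volume),
            )
        )
    return out


def plans_to_csv(plans: Sequence[Plan], path) -> None:
    frame = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in plans],
            "scheme": [p.scheme.to_string() for p in plans],
            "scenario": [p.scenario for p in plans],
            "achieved_dmax_factor": [p.achieved_dmax_factor for p in plans],
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def plans_from_csv(path) -> list[Plan]:
    frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    return [
        Plan(
            patient_id=row.patient_id,
            scheme=FractionScheme.from_string(row.scheme),
            scenario=row.scenario,
            achieved_dmax_factor=float(row.achieved_dmax_factor),
        )
        for row in frame.itertuples()
    ]
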