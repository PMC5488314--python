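"""Biophysical local-control (tumor control probability) models for lung SBRT.

Five published dose-response models are provided behind one uniform
interface.  Each maps a scalar dose quantity derived from the plan — either
the prescription dose or the isocenter (plan-maximum) dose, expressed as a
BED or a 2-Gy-equivalent dose — to a probability of local control (LC) at a
fixed follow-up horizon:

===========  =======  =============  =====================================
model        horizon  dose input     functional form
===========  =======  =============  =====================================
Martel       2 y      isocenter      logit dose-response on EQD2,
                                     D50 = 72.0 Gy, γ50 = 2.0
Ohri         2 y      prescription   logistic in size-adjusted BED₁₀,
                                     TCD50 = 0 Gy, k = 31 Gy, c = 10 Gy/cm
Tai          2 & 3 y  isocenter      regrowth dose-response in BED₁₀
                                     (config-injected parameters)
Guckenberger 3 y      isocenter      logistic in BED₁₀,
("Gucken")                           TCD50 = −1 Gy, k = 80 Gy
Santiago     3 y      isocenter      logistic in BED₁₀,
                                     TCD50 = −60.2 Gy, k = 113.3 Gy
===========  =======  =============  =====================================

All use α/β = 10 Gy for the LQ conversion.  The Ohri model is the only one
that (a) consumes the prescription ("treatment") dose, so it is invariant
to the plan's dose normalization, and (b) penalizes tumor size: its
effective dose is BED − c·L for a tumor of greatest diameter L cm.

The shipped Tai parameters are a synthetic placeholder logistic family
(midpoint shifting upward with the horizon, so 3-year LC ≤ 2-year LC at any
dose); they are NOT the multi-institutional "Model Fit II" coefficients of
Tai et al., which must be supplied through configuration to reproduce that
model's published predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from scipy.special import expit

from .lq import (
    FractionScheme,
    NormalizationScenario,
    RadiobiologyParams,
    bed,
    eqd2,
    isocenter_scheme,
)

__all__ = [
    "LogisticTcpParams",
    "MartelParams",
    "OhriParams",
    "TaiParams",
    "ModelLibrary",
    "TcpModelSpec",
    "PlanContext",
    "ModelContractError",
    "logistic_tcp",
    "martel_tcp",
    "ohri_tcp",
    "gucken_tcp",
    "santiago_tcp",
    "tai_lc",
    "predict",
    "GUCKEN_PARAMS",
    "SANTIAGO_PARAMS",
    "MODEL_ROSTER",
]


class ModelContractError(ValueError):
    """A model was asked for a horizon or input it does not define."""


@dataclass(frozen=True)
class LogisticTcpParams:
    """Two-parameter logistic dose-response on a BED scale.

    ``tcd50`` is the dose (Gy) at 50% control — as a fitted regression
    constant it may legitimately be negative — and ``k`` (> 0, Gy) is the
    slope scale: smaller k, steeper curve.
    """

    tcd50: float
    k: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"logistic slope scale k must be > 0 Gy, got {self.k!r}")


@dataclass(frozen=True)
class MartelParams:
    """Logit dose-response: D50 (Gy) at 50% control, normalized slope γ50.

    ``form`` selects the parametrization: ``'logit-power'`` is
    1/(1 + (D50/D)^(4·γ50)); ``'exponential-logistic'`` is
    1/(1 + exp(4·γ50·(1 − D/D50))).  Both cross 0.5 at D = D50 with the
    same normalized slope; published reproductions may require either.
    """

    d50: float = 72.0
    gamma50: float = 2.0
    form: Literal["logit-power", "exponential-logistic"] = "logit-power"

    def __post_init__(self) -> None:
        if not self.d50 > 0:
            raise ValueError(f"d50 must be > 0 Gy, got {self.d50!r}")
        if not self.gamma50 > 0:
            raise ValueError(f"gamma50 must be > 0, got {self.gamma50!r}")
        if self.form not in ("logit-power", "exponential-logistic"):
            raise ValueError(f"unknown Martel form {self.form!r}")


@dataclass(frozen=True)
class OhriParams:
    """Size-adjusted logistic: TCD50 = 0 Gy, k = 31 Gy on the prescription
    BED₁₀, with a linear size penalty of c = 10 Gy per cm of diameter."""

    logistic: LogisticTcpParams = field(
        default_factory=lambda: LogisticTcpParams(tcd50=0.0, k=31.0)
    )
    c: float = 10.0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"size penalty c must be ≥ 0 Gy/cm, got {self.c!r}")


@dataclass(frozen=True)
class TaiParams:
    """Regrowth dose-response parameters, keyed by follow-up horizon.

    The model predicts LC at 2 and 3 years from the isocenter BED₁₀; local
    regrowth between the horizons means the 3-year curve sits at or below
    the 2-year curve, which here is encoded as a horizon-dependent midpoint
    ``tcd50_by_horizon`` (non-decreasing in the horizon) with a shared
    slope scale ``k``.

    ``placeholder=True`` marks the shipped defaults as a synthetic
    stand-in, not the Tai et al. multi-institutional "Model Fit II"
    coefficients; supply the published values via configuration to
    reproduce that fit.
    """

    k: float = 45.0
    tcd50_by_horizon: dict[int, float] = field(
        default_factory=lambda: {2: -15.0, 3: 5.0}
    )
    placeholder: bool = True

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"Tai slope scale k must be > 0 Gy, got {self.k!r}")
        horizons = sorted(self.tcd50_by_horizon)
        if any(h not in (2, 3) for h in horizons):
            raise ValueError(
                f"Tai horizons must be within {{2, 3}} years, got {horizons}"
            )
        for lo, hi in zip(horizons, horizons[1:]):
            if self.tcd50_by_horizon[hi] < self.tcd50_by_horizon[lo]:
                raise ValueError(
                    "Tai midpoint must be non-decreasing in the horizon "
                    "(later follow-up cannot predict more control at the same dose)"
                )

    def midpoint(self, horizon: int) -> float:
        try:
            return self.tcd50_by_horizon[horizon]
        except KeyError:
            raise ModelContractError(
                f"Tai model has no parameter set for a {horizon}-year horizon; "
                "the published coefficients are the multi-institutional 'Model "
                "Fit II' of Tai et al. and must be supplied via configuration"
            ) from None


GUCKEN_PARAMS = LogisticTcpParams(tcd50=-1.0, k=80.0)
SANTIAGO_PARAMS = LogisticTcpParams(tcd50=-60.2, k=113.3)


def logistic_tcp(dose_metric: float, params: LogisticTcpParams) -> float:
    """exp((x − TCD50)/k) / (1 + exp((x − TCD50)/k)), overflow-safe.

    Evaluated through :func:`scipy.special.expit`, which saturates cleanly
    to 0/1 for large |x| instead of overflowing.
    """
    return float(expit((dose_metric - params.tcd50) / params.k))


def martel_tcp(dose_2gy_equivalent: float, params: MartelParams = MartelParams()) -> float:
    """Logit dose-response on the 2-Gy-equivalent dose; 0.5 at D = D50."""
    d = float(dose_2gy_equivalent)
    if d < 0:
        raise ValueError(f"dose must be ≥ 0 Gy, got {d!r}")
    if params.form == "logit-power":
        if d == 0.0:
            return 0.0
        # 1/(1+(d50/D)^(4γ)) via expit(4γ·ln(D/d50)) for numerical symmetry
        import math

        return float(expit(4.0 * params.gamma50 * math.log(d / params.d50)))
    return float(expit(4.0 * params.gamma50 * (d / params.d50 - 1.0)))


def ohri_tcp(
    prescription_bed: float, diameter: float, params: OhriParams = OhriParams()
) -> float:
    """Size-adjusted logistic TCP: the effective dose is BED − c·L for a
    tumor of greatest diameter L (cm), so control falls with size at fixed
    dose."""
    if diameter < 0:
        raise ValueError(f"tumor diameter must be ≥ 0 cm, got {diameter!r}")
    return logistic_tcp(prescription_bed - params.c * diameter, params.logistic)


def gucken_tcp(isocenter_bed: float, params: LogisticTcpParams = GUCKEN_PARAMS) -> float:
    """Guckenberger 3-year LC: logistic in isocenter BED₁₀ (TCD50 = −1 Gy,
    k = 80 Gy)."""
    return logistic_tcp(isocenter_bed, params)


def santiago_tcp(isocenter_bed: float, params: LogisticTcpParams = SANTIAGO_PARAMS) -> float:
    """Santiago 3-year LC: logistic in isocenter BED₁₀ (TCD50 = −60.2 Gy,
    k = 113.3 Gy)."""
    return logistic_tcp(isocenter_bed, params)


def tai_lc(isocenter_bed: float, horizon: int, params: TaiParams = TaiParams()) -> float:
    """Tai regrowth LC at a 2- or 3-year horizon from the isocenter BED₁₀.

    Strictly increasing in dose at fixed horizon and non-increasing in the
    horizon at fixed dose.
    """
    if horizon not in (2, 3):
        raise ModelContractError(f"Tai horizon must be 2 or 3 years, got {horizon!r}")
    return logistic_tcp(isocenter_bed, LogisticTcpParams(params.midpoint(horizon), params.k))


@dataclass(frozen=True)
class ModelLibrary:
    """One parameter block per model; defaults are the published values
    (except Tai — see :class:`TaiParams`)."""

    radiobiology: RadiobiologyParams = field(default_factory=RadiobiologyParams)
    martel: MartelParams = field(default_factory=MartelParams)
    ohri: OhriParams = field(default_factory=OhriParams)
    gucken: LogisticTcpParams = GUCKEN_PARAMS
    santiago: LogisticTcpParams = SANTIAGO_PARAMS
    tai: TaiParams = field(default_factory=TaiParams)


@dataclass(frozen=True)
class TcpModelSpec:
    """Roster entry: model name, which dose quantity it consumes, and its
    prediction horizon in years."""

    name: Literal["Martel", "Ohri", "Gucken", "Santiago", "Tai2y", "Tai3y"]
    dose_input: Literal["isocenter", "prescription"]
    horizon: int


# The roster: which model predicts which horizon, from which dose quantity.
# The Ohri model consumes the prescription ("treatment") dose; all others
# consume the isocenter dose.  Martel is routed through EQD2, the rest
# through BED.
MODEL_ROSTER: dict[str, TcpModelSpec] = {
    "Martel": TcpModelSpec("Martel", "isocenter", 2),
    "Ohri": TcpModelSpec("Ohri", "prescription", 2),
    "Tai2y": TcpModelSpec("Tai2y", "isocenter", 2),
    "Gucken": TcpModelSpec("Gucken", "isocenter", 3),
    "Santiago": TcpModelSpec("Santiago", "isocenter", 3),
    "Tai3y": TcpModelSpec("Tai3y", "isocenter", 3),
}


@dataclass(frozen=True)
class PlanContext:
    """Everything a model needs about one delivered plan: the prescribed
    scheme, the realized Dmax/prescription factor, and the tumor diameter
    (cm; may be None for size-blind models)."""

    prescription: FractionScheme
    dmax_factor: float
    diameter: float | None = None


def predict(
    model: TcpModelSpec | str,
    context: PlanContext,
    library: ModelLibrary = ModelLibrary(),
    horizon: int | None = None,
) -> float:
    """Route the correct dose quantity to the correct model function.

    ``model`` may be a roster name or a :class:`TcpModelSpec`.  If
    ``horizon`` is given it is checked against the model's contract —
    asking a 2-year-only model for a 3-year value raises
    :class:`ModelContractError`.
    """
    spec = MODEL_ROSTER[model] if isinstance(model, str) else model
    if horizon is not None and horizon != spec.horizon:
        raise ModelContractError(
            f"model {spec.name} predicts {spec.horizon}-year LC, not {horizon}-year"
        )

    rb = library.radiobiology
    if spec.dose_input == "isocenter":
        dose_scheme = isocenter_scheme(context.prescription, context.dmax_factor)
    else:
        dose_scheme = context.prescription

    if spec.name == "Martel":
        return martel_tcp(eqd2(dose_scheme, rb), library.martel)
    if spec.name == "Ohri":
        if context.diameter is None:
            raise ValueError("Ohri model requires a tumor diameter")
        return ohri_tcp(bed(dose_scheme, rb), context.diameter, library.ohri)
    if spec.name == "Gucken":
        return gucken_tcp(bed(dose_scheme, rb), library.gucken)
    if spec.name == "Santiago":
        return santiago_tcp(bed(dose_scheme, rb), library.santiago)
    if spec.name in ("Tai2y", "Tai3y"):
        return tai_lc(bed(dose_scheme, rb), spec.horizon, library.tai)
    raise ModelContractError(f"unknown model {spec.name!r}")
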