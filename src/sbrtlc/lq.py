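"""Linear-quadratic (LQ) dose conversions and dose-normalization arithmetic.

The LQ formalism converts a fractionated prescription ``n × d`` into
iso-effect quantities shared by all dose-response models in this package:

* biologically effective dose ``BED = n·d·(1 + d/(α/β))``
* equivalent total dose in 2-Gy fractions
  ``EQD2 = n·d·(d + α/β)/(2 + α/β)``

Hypofractionated stereotactic schedules (large ``d``, small ``n``) therefore
carry a much larger BED than the same physical dose in conventional 2-Gy
fractionation.  A plan's maximum (isocenter) dose is modelled as the
prescription scaled per fraction by a normalization factor (e.g. 1.10 when
the plan maximum is pinned at 110% of prescription), so the isocenter BED
reflects both the higher total dose and the larger fraction size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FractionScheme",
    "RadiobiologyParams",
    "NormalizationScenario",
    "P110",
    "P120",
    "bed",
    "eqd2",
    "scale_scheme",
    "isocenter_scheme",
]


@dataclass(frozen=True)
class FractionScheme:
    """A fractionated prescription: ``n_fractions`` fractions of
    ``dose_per_fraction`` Gy each."""

    n_fractions: int
    dose_per_fraction: float

    def __post_init__(self) -> None:
        if not isinstance(self.n_fractions, int) or self.n_fractions < 1:
            raise ValueError(
                f"n_fractions must be a positive integer, got {self.n_fractions!r}"
            )
        if not self.dose_per_fraction > 0:
            raise ValueError(
                f"dose_per_fraction must be > 0 Gy, got {self.dose_per_fraction!r}"
            )

    @property
    def total_dose(self) -> float:
        """Total physical dose in Gy (always derived, never stored)."""
        return self.n_fractions * self.dose_per_fraction

    @property
    def label(self) -> str:
        """Display form, e.g. ``'5 × 10 Gy'``."""
        d = self.dose_per_fraction
        d_str = f"{d:g}"
        return f"{self.n_fractions} × {d_str} Gy"

    @classmethod
    def from_string(cls, text: str) -> "FractionScheme":
        """Parse the compact ``'<n>x<d>'`` form used in CLI/config,
        e.g. ``'5x10'`` or ``'3x18'`` (case-insensitive separator)."""
        raw = text.strip().lower().replace("×", "x")
        parts = raw.split("x")
        if len(parts) != 2:
            raise ValueError(f"cannot parse fraction scheme {text!r}; expected '<n>x<d>'")
        try:
            n = int(parts[0])
            d = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"cannot parse fraction scheme {text!r}: {exc}") from None
        return cls(n_fractions=n, dose_per_fraction=d)

    def to_string(self) -> str:
        """Compact round-trippable form, e.g. ``'5x10'``."""
        return f"{self.n_fractions}x{self.dose_per_fraction:g}"


@dataclass(frozen=True)
class RadiobiologyParams:
    """LQ tissue parameter: the α/β ratio in Gy (10 Gy for lung tumor)."""

    alpha_beta: float = 10.0

    def __post_init__(self) -> None:
        if not self.alpha_beta > 0:
            raise ValueError(f"alpha_beta must be > 0 Gy, got {self.alpha_beta!r}")


@dataclass(frozen=True)
class NormalizationScenario:
    """Plan dose normalization: the plan maximum (isocenter) dose as a
    multiple of prescription, e.g. P110 pins Dmax at 110% of prescription."""

    name: str
    dmax_factor: float

    def __post_init__(self) -> None:
        if not self.dmax_factor > 1.0:
            raise ValueError(
                f"dmax_factor must exceed 1.0 (plan maximum above prescription), "
                f"got {self.dmax_factor!r}"
            )


P110 = NormalizationScenario(name="P110", dmax_factor=1.10)
P120 = NormalizationScenario(name="P120", dmax_factor=1.20)

_SCENARIOS = {"P110": P110, "P120": P120}


def scenario_from_name(name: str) -> NormalizationScenario:
    """Look up a built-in normalization scenario by name (P110 / P120)."""
    try:
        return _SCENARIOS[name.strip().upper()]
    except KeyError:
        raise ValueError(
            f"unknown normalization scenario {name!r}; expected one of {sorted(_SCENARIOS)}"
        ) from None


def bed(scheme: FractionScheme, params: RadiobiologyParams = RadiobiologyParams()) -> float:
    """Biologically effective dose ``n·d·(1 + d/(α/β))`` in Gy.

    Strictly exceeds the physical dose for any d > 0; BED with α/β = 10 Gy
    is conventionally written BED₁₀.
    """
    n, d = scheme.n_fractions, scheme.dose_per_fraction
    return n * d * (1.0 + d / params.alpha_beta)


def eqd2(scheme: FractionScheme, params: RadiobiologyParams = RadiobiologyParams()) -> float:
    """Equivalent total dose in 2-Gy fractions, ``n·d·(d + α/β)/(2 + α/β)``.

    Equals the physical total dose exactly when d = 2 Gy.
    """
    n, d = scheme.n_fractions, scheme.dose_per_fraction
    ab = params.alpha_beta
    return n * d * (d + ab) / (2.0 + ab)


def scale_scheme(scheme: FractionScheme, factor: float) -> FractionScheme:
    """Scale the dose per fraction by ``factor`` (> 0), keeping the fraction
    count.  factor = 1 returns an identical scheme."""
    if not factor > 0:
        raise ValueError(f"scale factor must be > 0, got {factor!r}")
    return FractionScheme(
        n_fractions=scheme.n_fractions,
        dose_per_fraction=scheme.dose_per_fraction * factor,
    )


def isocenter_scheme(
    prescription: FractionScheme, scenario: NormalizationScenario | float
) -> FractionScheme:
    """The scheme actually delivered at the isocenter: same fraction count,
    dose per fraction scaled by the normalization factor.

    Per-fraction scaling matters because BED is nonlinear in the fraction
    size: the isocenter dose is delivered in the same number of fractions,
    so its BED reflects the larger d, not just the larger total.

    ``scenario`` may be a :class:`NormalizationScenario` or a bare realized
    factor (e.g. a plan's achieved Dmax/prescription ratio).
    """
    factor = scenario.dmax_factor if isinstance(scenario, NormalizationScenario) else float(scenario)
    return scale_scheme(prescription, factor)
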