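"""Model-comparison pipeline: per-patient LC predictions over a grid of
fraction schemes and normalization scenarios, pairwise differences against a
benchmark model, median/range summaries, and Wilcoxon signed-rank tests.

For each horizon the report has one row per (fraction scheme, scenario,
comparator model): the per-patient difference comparator − benchmark in
percentage points, its median and range, and the two-sided signed-rank
p-value on the paired per-patient predictions.  The benchmark itself is
rendered as "NA" in the human-readable table, mirroring the usual layout of
such comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Patient, Plan
from .models import ModelLibrary, PlanContext, TcpModelSpec, MODEL_ROSTER, predict

__all__ = [
    "LcMatrix",
    "DifferenceSummary",
    "compute_lc_matrix",
    "pairwise_difference",
    "summarize",
    "wilcoxon_signed_rank",
    "build_report",
    "render_text_table",
    "DEFAULT_BENCHMARKS",
]

DEFAULT_BENCHMARKS: dict[int, str] = {2: "Martel", 3: "Gucken"}

# exact signed-rank null distribution up to this many nonzero pairs,
# normal approximation (with tie correction and continuity) above
EXACT_N_MAX = 25


@dataclass(frozen=True)
class LcMatrix:
    """Tidy per-cell LC predictions.

    ``frame`` columns: patient_id, model, scheme (compact string),
    scenario, horizon (years), lc (probability).  Model–horizon
    combinations outside each model's contract are simply absent.
    """

    frame: pd.DataFrame

    def models(self, horizon: int | None = None) -> list[str]:
        f = self.frame
        if horizon is not None:
            f = f[f["horizon"] == horizon]
        return sorted(f["model"].unique())

    def select(
        self,
        model: str,
        horizon: int,
        scheme: str | None = None,
        scenario: str | None = None,
    ) -> pd.Series:
        """LC values for one model at one horizon, indexed by
        (patient_id, scheme, scenario) for paired alignment."""
        f = self.frame
        mask = (f["model"] == model) & (f["horizon"] == horizon)
        if scheme is not None:
            mask &= f["scheme"] == scheme
        if scenario is not None:
            mask &= f["scenario"] == scenario
        sub = f[mask]
        return sub.set_index(["patient_id", "scheme", "scenario"])["lc"]


def compute_lc_matrix(
    cohort: Sequence[Patient],
    plans: Sequence[Plan],
    roster: Sequence[TcpModelSpec | str] | None = None,
    library: ModelLibrary = ModelLibrary(),
) -> LcMatrix:
    """Evaluate every roster model on every plan, using each plan's
    achieved Dmax factor.

    Raises KeyError if a plan references an unknown patient, and ValueError
    naming the patient if a size-aware (Ohri) cell lacks a diameter.
    """
    specs = [MODEL_ROSTER[m] if isinstance(m, str) else m for m in (roster or MODEL_ROSTER.values())]
    patients = {p.id: p for p in cohort}
    records = []
    for plan in plans:
        if plan.patient_id not in patients:
            raise KeyError(f"plan references unknown patient {plan.patient_id!r}")
        patient = patients[plan.patient_id]
        context = PlanContext(
            prescription=plan.scheme,
            dmax_factor=plan.achieved_dmax_factor,
            diameter=patient.diameter,
        )
        for spec in specs:
            if spec.name == "Ohri" and patient.diameter is None:
                raise ValueError(
                    f"patient {patient.id!r} has no tumor diameter; the Ohri "
                    "model requires one (impute or supply diameter_cm)"
                )
            records.append(
                {
                    "patient_id": plan.patient_id,
                    "model": spec.name,
                    "scheme": plan.scheme.to_string(),
                    "scenario": plan.scenario,
                    "horizon": spec.horizon,
                    "lc": predict(spec, context, library),
                }
            )
    columns = ["patient_id", "model", "scheme", "scenario", "horizon", "lc"]
    return LcMatrix(pd.DataFrame.from_records(records, columns=columns))


def pairwise_difference(
    matrix: LcMatrix,
    comparator: str,
    reference: str,
    horizon: int,
    scheme: str | None = None,
    scenario: str | None = None,
) -> pd.Series:
    """Per-patient paired difference (comparator − reference) × 100, in
    percentage points, aligned on (patient, scheme, scenario)."""
    for name in (comparator, reference):
        spec = MODEL_ROSTER.get(name)
        if spec is not None and spec.horizon != horizon:
            raise ValueError(
                f"model {name} predicts {spec.horizon}-year LC; cannot compare at {horizon} years"
            )
    a = matrix.select(comparator, horizon, scheme, scenario)
    b = matrix.select(reference, horizon, scheme, scenario)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"no cells for {comparator!r} vs {reference!r} at {horizon} years"
        )
    a, b = a.align(b, join="inner")
    return (a - b) * 100.0


@dataclass(frozen=True)
class DifferenceSummary:
    """Median and range of per-patient differences (percentage points) plus
    the paired signed-rank p-value for one comparator/benchmark cell."""

    comparator: str
    reference: str
    scheme: str
    scenario: str
    differences: tuple[float, ...]
    median: float
    range_min: float
    range_max: float
    p_value: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value is not None and self.p_value < alpha


def summarize(
    differences: Sequence[float] | pd.Series,
    comparator: str = "",
    reference: str = "",
    scheme: str = "",
    scenario: str = "",
    p_value: float | None = None,
) -> DifferenceSummary:
    """Median (midpoint of the central pair for even n) and (min, max)
    range of a non-empty difference vector."""
    values = np.asarray(differences, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty difference vector")
    return DifferenceSummary(
        comparator=comparator,
        reference=reference,
        scheme=scheme,
        scenario=scenario,
        differences=tuple(values.tolist()),
        median=float(np.median(values)),
        range_min=float(values.min()),
        range_max=float(values.max()),
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
#
# The exact branch computes the null distribution of the positive rank sum
# W+ by dynamic programming over the (mid)ranks of |d|: each rank enters
# W+ independently with probability 1/2 under the null.  Midranks from ties
# are handled by doubling all ranks to integers, so the exact p-value is
# valid with ties — unlike the classical no-tie tables.  The two-sided
# p-value is min(1, 2·min(P(W+ ≤ w), P(W+ ≥ w))).


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    doubled = np.rint(2.0 * ranks).astype(np.int64)  # midranks -> integers
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=object)  # exact integer counts
    counts[0] = 1
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(round(2.0 * w_plus))
    n_total = 1 << len(ranks)
    count_le = int(sum(counts[: w2 + 1]))
    count_ge = int(sum(counts[w2:]))
    return min(1.0, 2.0 * min(count_le, count_ge) / n_total)


def _approx_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    m = len(ranks)
    mean = m * (m + 1) / 4.0
    # variance with tie correction expressed through the realized ranks
    var = float(np.sum(ranks**2)) / 4.0
    if var == 0:
        return 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float],
    zero_policy: str = "drop",
    method: str = "auto",
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    ``zero_policy``: "drop" discards zero differences before ranking (the
    classical convention); "pratt" ranks them with the rest but excludes
    their ranks from both rank sums.  All-zero differences give p = 1.

    ``method``: "exact" forces the exact null distribution (valid with
    ties via midranks), "approx" the normal approximation with tie
    correction and continuity correction, "auto" picks exact for up to
    25 nonzero pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must be 1-d and equal length, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("paired samples must be non-empty")
    if zero_policy not in ("drop", "pratt"):
        raise ValueError(f"unknown zero policy {zero_policy!r}")

    d = a - b
    if zero_policy == "drop":
        d = d[d != 0.0]
        if d.size == 0:
            return 1.0
        ranks = stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
    else:  # pratt: rank zeros, then discard their ranks
        if np.all(d == 0.0):
            return 1.0
        all_ranks = stats.rankdata(np.abs(d))
        nonzero = d != 0.0
        ranks = all_ranks[nonzero]
        d = d[nonzero]
        w_plus = float(ranks[d > 0].sum())

    if method == "exact" or (method == "auto" and len(ranks) <= EXACT_N_MAX):
        return _exact_signed_rank_p(ranks, w_plus)
    return _approx_signed_rank_p(ranks, w_plus)


# ---------------------------------------------------------------------------
# Report assembly


def build_report(
    matrix: LcMatrix,
    benchmarks: Mapping[int, str] = DEFAULT_BENCHMARKS,
    alpha: float = 0.05,
    zero_policy: str = "drop",
) -> dict[int, pd.DataFrame]:
    """One tidy table per horizon: rows = (scheme, scenario, comparator),
    columns median_pct / min_pct / max_pct / p_value / significant.

    The benchmark model is the reference in every row; comparisons use the
    per-patient paired LC vectors, with the signed-rank test applied to the
    raw probabilities.
    """
    reports: dict[int, pd.DataFrame] = {}
    frame = matrix.frame
    for horizon in sorted(frame["horizon"].unique()):
        benchmark = benchmarks.get(int(horizon))
        if benchmark is None:
            raise ValueError(f"no benchmark configured for the {horizon}-year horizon")
        horizon_models = matrix.models(horizon=int(horizon))
        if benchmark not in horizon_models:
            raise ValueError(
                f"benchmark {benchmark!r} absent from the {horizon}-year matrix"
            )
        comparators = [m for m in horizon_models if m != benchmark]
        sub = frame[frame["horizon"] == horizon]
        rows = []
        for scheme in sub["scheme"].unique():  # preserves plan order
            for scenario in sorted(sub["scenario"].unique()):
                ref = matrix.select(benchmark, int(horizon), scheme, scenario)
                for comparator in comparators:
                    comp = matrix.select(comparator, int(horizon), scheme, scenario)
                    comp, ref_aligned = comp.align(ref, join="inner")
                    diffs = (comp - ref_aligned) * 100.0
                    p = wilcoxon_signed_rank(
                        comp.to_numpy(), ref_aligned.to_numpy(), zero_policy=zero_policy
                    )
                    summary = summarize(
                        diffs, comparator, benchmark, scheme, scenario, p_value=p
                    )
                    rows.append(
                        {
                            "scheme": scheme,
                            "scenario": scenario,
                            "comparator": comparator,
                            "reference": benchmark,
                            "median_pct": summary.median,
                            "min_pct": summary.range_min,
                            "max_pct": summary.range_max,
                            "p_value": p,
                            "significant": summary.significant(alpha),
                        }
                    )
        reports[int(horizon)] = pd.DataFrame(rows)
    return reports


def _fmt_cell(median: float, lo: float, hi: float, significant: bool) -> str:
    dagger = "†" if significant else ""
    return f"{median:.1f}{dagger} ({lo:.1f}~{hi:.1f})"


def render_text_table(report: pd.DataFrame, benchmark: str) -> str:
    """Human-readable table: rows = fraction schemes, column groups =
    scenario, benchmark column rendered "NA", cells "median (min~max)"
    in percentage points with a dagger marking p < 0.05."""
    scenarios = sorted(report["scenario"].unique())
    comparators = list(dict.fromkeys(report["comparator"]))
    header = ["FS"]
    for scenario in scenarios:
        header.append(f"{benchmark}[{scenario}]")
        header.extend(f"{c} (%)[{scenario}]" for c in comparators)
    lines = ["\t".join(header)]
    for scheme in dict.fromkeys(report["scheme"]):
        row = [scheme]
        for scenario in scenarios:
            row.append("NA")
            for comparator in comparators:
                cell = report[
                    (report["scheme"] == scheme)
                    & (report["scenario"] == scenario)
                    & (report["comparator"] == comparator)
                ]
                if len(cell) != 1:
                    raise ValueError(
                        f"expected exactly one report row for {scheme}/{scenario}/{comparator}"
                    )
                c = cell.iloc[0]
                row.append(
                    _fmt_cell(c["median_pct"], c["min_pct"], c["max_pct"], bool(c["significant"]))
                )
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
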