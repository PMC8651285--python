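"""Yield and purity statistics for comparing EV isolation methods.

Each isolation condition is summarised by the measured concentrations (pM)
of the three tetraspanin EV markers (CD9, CD63, CD81) and of albumin, the
dominant free-protein contaminant.  Two headline statistics are computed:

* relative EV recovery — each tetraspanin's concentration is divided by the
  same tetraspanin's concentration in an explicitly chosen reference
  condition, and the three ratios are averaged;
* purity — the sum of the three tetraspanin concentrations divided by the
  albumin concentration.

The reference condition is a required parameter: different experiments
normalise against different conditions, so no default is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "TETRASPANINS",
    "ALBUMIN",
    "MARKERS",
    "MethodMeasurement",
    "RecoveryResult",
    "PurityResult",
    "RankingReport",
    "correct_input_volume",
    "average_day_replicates",
    "relative_recovery",
    "purity_score",
    "rank_methods",
    "fold_change",
]

TETRASPANINS: tuple[str, ...] = ("CD9", "CD63", "CD81")
ALBUMIN = "ALB"
MARKERS: tuple[str, ...] = TETRASPANINS + (ALBUMIN,)


@dataclass(frozen=True)
class MethodMeasurement:
    """Averaged marker concentrations for one isolation condition."""

    biofluid: str
    method: str
    marker_values_pM: Mapping[str, float]
    input_volume_ml: float = 0.5
    n_day_replicates: int = 1

    def __post_init__(self) -> None:
        missing = [m for m in MARKERS if m not in self.marker_values_pM]
        if missing:
            raise ConfigurationError(f"{self.method}: missing markers {missing}")
        if any(v < 0 for v in self.marker_values_pM.values()):
            raise ConfigurationError(f"{self.method}: negative concentration")
        if self.input_volume_ml <= 0:
            raise ConfigurationError("input_volume_ml must be positive")

    def value(self, marker: str) -> float:
        return float(self.marker_values_pM[marker])

    @property
    def tetraspanin_sum_pM(self) -> float:
        return sum(self.value(m) for m in TETRASPANINS)


@dataclass(frozen=True)
class RecoveryResult:
    """Relative EV recovery of one condition against a reference."""

    method: str
    per_marker_ratio: Mapping[str, float]
    combined_recovery: float
    reference: str


@dataclass(frozen=True)
class PurityResult:
    """Tetraspanin-to-albumin purity of one condition."""

    method: str
    tetraspanin_sum_pM: float
    albumin_pM: float
    purity: float


@dataclass(frozen=True)
class RankingReport:
    """Best method by yield and by purity, with tie information."""

    high_yield: str
    high_purity: str
    yield_ties: tuple[str, ...] = ()
    purity_ties: tuple[str, ...] = ()


def correct_input_volume(
    measurement: MethodMeasurement, standard_volume_ml: float = 0.5
) -> MethodMeasurement:
    """Rescale marker values to a standard input volume.

    A condition run from half the standard sample volume has all its values
    doubled, making conditions with unequal inputs directly comparable.
    Idempotent once the input volume matches the standard.
    """
    if standard_volume_ml <= 0:
        raise ConfigurationError("standard_volume_ml must be positive")
    factor = standard_volume_ml / measurement.input_volume_ml
    scaled = {m: v * factor for m, v in measurement.marker_values_pM.items()}
    return replace(
        measurement, marker_values_pM=scaled, input_volume_ml=standard_volume_ml
    )


def average_day_replicates(
    measurements: Sequence[MethodMeasurement],
) -> MethodMeasurement:
    """Marker-wise arithmetic mean over repeated isolations of one condition."""
    if not measurements:
        raise ConfigurationError("no measurements to average")
    keys = {(m.biofluid, m.method) for m in measurements}
    if len(keys) != 1:
        raise ConfigurationError(f"mixed biofluid/method in replicates: {sorted(keys)}")
    markers = measurements[0].marker_values_pM.keys()
    averaged = {
        mk: float(np.mean([m.value(mk) for m in measurements])) for mk in markers
    }
    return replace(
        measurements[0],
        marker_values_pM=averaged,
        n_day_replicates=len(measurements),
    )


def relative_recovery(
    measurements: Sequence[MethodMeasurement], reference: str
) -> list[RecoveryResult]:
    """Per-tetraspanin ratios to the reference condition, averaged.

    Albumin is excluded; the combined recovery is the arithmetic mean of
    the three tetraspanin ratios, so the reference itself scores exactly 1.
    """
    by_method = {m.method: m for m in measurements}
    if reference not in by_method:
        raise ConfigurationError(f"reference method {reference!r} not in measurements")
    ref = by_method[reference]
    for marker in TETRASPANINS:
        if ref.value(marker) <= 0:
            raise DomainError(
                f"reference {reference!r} has non-positive {marker}; "
                "relative recovery is undefined"
            )
    results = []
    for m in measurements:
        ratios = {mk: m.value(mk) / ref.value(mk) for mk in TETRASPANINS}
        results.append(
            RecoveryResult(
                method=m.method,
                per_marker_ratio=ratios,
                combined_recovery=float(np.mean(list(ratios.values()))),
                reference=reference,
            )
        )
    return results


def purity_score(measurement: MethodMeasurement) -> PurityResult:
    """Sum of tetraspanins over albumin; undefined at zero albumin."""
    albumin = measurement.value(ALBUMIN)
    if albumin <= 0:
        raise DomainError(
            f"{measurement.method}: albumin is {albumin}; purity is undefined"
        )
    tet = measurement.tetraspanin_sum_pM
    return PurityResult(
        method=measurement.method,
        tetraspanin_sum_pM=tet,
        albumin_pM=albumin,
        purity=tet / albumin,
    )


def _argmax_with_ties(pairs: list[tuple[str, float]]) -> tuple[str, tuple[str, ...]]:
    best = max(v for _, v in pairs)
    winners = sorted(name for name, v in pairs if v == best)
    return winners[0], tuple(winners[1:])


def rank_methods(
    recoveries: Sequence[RecoveryResult], purities: Sequence[PurityResult]
) -> RankingReport:
    """Pick the highest-yield and highest-purity conditions.

    Ties are broken by lexicographic method name and reported explicitly.
    """
    rec_methods = {r.method for r in recoveries}
    pur_methods = {p.method for p in purities}
    if rec_methods != pur_methods:
        raise ConfigurationError(
            f"method sets differ: {sorted(rec_methods ^ pur_methods)}"
        )
    if not recoveries:
        raise ConfigurationError("no methods to rank")
    high_yield, yield_ties = _argmax_with_ties(
        [(r.method, r.combined_recovery) for r in recoveries]
    )
    high_purity, purity_ties = _argmax_with_ties(
        [(p.method, p.purity) for p in purities]
    )
    return RankingReport(
        high_yield=high_yield,
        high_purity=high_purity,
        yield_ties=yield_ties,
        purity_ties=purity_ties,
    )


def fold_change(a: float, b: float) -> float:
    """Ratio a/b of two comparable scalars (recoveries, purities, pM values)."""
    if b <= 0:
        raise DomainError("fold change needs a positive denominator")
    if a < 0:
        raise DomainError("fold change needs a non-negative numerator")
    return a / b
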