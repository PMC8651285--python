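"""Digital single-molecule immunoassay model.

Simulates and inverts a bead-based digital ELISA of the Simoa type: beads
carrying at most one immunocomplex are isolated in femtoliter wells, "on"
wells are counted, and the fraction of on wells is converted to the mean
number of enzyme labels per bead (AEB) through the Poisson occupancy
correction ``AEB = -ln(1 - f_on)``.  Concentrations are recovered from AEB
via a four-parameter logistic (4PL) calibration curve fitted to recombinant
protein standards.

The forward model for a replicate measurement of a sample at true
concentration ``c`` (pM) is::

    lambda_eff = capture_efficiency * (c / dilution_factor) + background_aeb
    P(well on) = 1 - exp(-lambda_eff)
    n_on ~ Binomial(n_wells_loaded, P(well on))

Reported concentration estimates are dilution-corrected back to the neat
(undiluted) sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, DomainError, FitError, SaturatedArrayError

__all__ = [
    "BeadAssayParams",
    "WellArrayReading",
    "CalibrationStandard",
    "CalibrationCurve",
    "ConcentrationEstimate",
    "aeb_from_fraction_on",
    "simulate_digital_readout",
    "fit_calibration",
    "concentration_from_reading",
    "average_technical_replicates",
]

#: fraction-on level above which the single-label counting regime no longer
#: holds; readings at or above this are flagged rather than modelled.
SATURATION_FRACTION_ON = 0.7


@dataclass(frozen=True)
class BeadAssayParams:
    """Physical parameters of one digital-immunoassay configuration.

    Parameters
    ----------
    n_beads
        Beads incubated with the sample per replicate.
    n_wells_loaded
        Beads actually counted in the microwell array (<= ``n_beads``).
    capture_efficiency
        Expected captured immunocomplexes per bead per pM of analyte at the
        assay (post-dilution) concentration, in pM^-1.
    background_aeb
        Mean enzymes per bead at zero analyte (nonspecific binding).
    dilution_factor
        Fold dilution applied to the sample before measurement (>= 1).
    """

    n_beads: int
    n_wells_loaded: int
    capture_efficiency: float
    background_aeb: float = 0.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_beads <= 0 or self.n_wells_loaded <= 0:
            raise ConfigurationError("bead counts must be positive")
        if self.n_wells_loaded > self.n_beads:
            raise ConfigurationError("cannot count more wells than beads incubated")
        if not 0.0 < self.capture_efficiency:
            raise ConfigurationError("capture_efficiency must be positive")
        if self.background_aeb < 0:
            raise ConfigurationError("background_aeb must be non-negative")
        if self.dilution_factor < 1:
            raise ConfigurationError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class WellArrayReading:
    """Counted wells from one array load.

    ``fraction_on`` and ``aeb`` are derived from the counts, so the
    invariants ``fraction_on == n_on / n_total`` and ``aeb == 0 iff
    n_on == 0`` hold by construction.
    """

    n_on: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ConfigurationError("n_total must be positive")
        if not 0 <= self.n_on <= self.n_total:
            raise ConfigurationError("n_on must lie in [0, n_total]")

    @property
    def fraction_on(self) -> float:
        return self.n_on / self.n_total

    @property
    def saturated(self) -> bool:
        """True when the array is outside the digital counting regime."""
        return self.fraction_on >= SATURATION_FRACTION_ON

    @property
    def aeb(self) -> float:
        """Poisson-corrected average enzymes per bead."""
        return aeb_from_fraction_on(self.fraction_on)


@dataclass(frozen=True)
class CalibrationStandard:
    """One concentration level of a recombinant-protein calibrator."""

    marker: str
    concentration_pM: float
    signal_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.concentration_pM < 0:
            raise ConfigurationError("standard concentration must be non-negative")
        if len(self.signal_replicates) == 0:
            raise ConfigurationError("standard needs at least one signal replicate")
        if any(s < 0 for s in self.signal_replicates):
            raise ConfigurationError("AEB signals must be non-negative")

    @property
    def mean_signal(self) -> float:
        return float(np.mean(self.signal_replicates))


@dataclass(frozen=True)
class CalibrationCurve:
    """Four-parameter logistic response AEB(c), strictly increasing.

    Response model (Hill form, increasing for ``slope > 0``)::

        aeb(c) = lower + (upper - lower) * c**slope / (midpoint**slope + c**slope)

    Inversion is defined only for AEB strictly between the asymptotes.
    """

    marker: str
    lower: float
    upper: float
    midpoint: float
    slope: float
    valid_range: tuple[float, float]
    fit_residual: float

    def __post_init__(self) -> None:
        if not (self.upper > self.lower >= 0):
            raise FitError("calibration curve must be strictly increasing (upper > lower)")
        if self.midpoint <= 0 or self.slope <= 0:
            raise FitError("midpoint and slope must be positive for a monotone curve")

    def response(self, concentration_pM: float | np.ndarray) -> float | np.ndarray:
        c = np.asarray(concentration_pM, dtype=float)
        with np.errstate(divide="ignore"):
            frac = np.where(
                c > 0, c**self.slope / (self.midpoint**self.slope + c**self.slope), 0.0
            )
        out = self.lower + (self.upper - self.lower) * frac
        return float(out) if np.isscalar(concentration_pM) or out.ndim == 0 else out

    def inverse(self, aeb: float) -> float:
        """Concentration (assay-level pM) at which the curve equals ``aeb``.

        Only valid for ``lower < aeb < upper``; callers are expected to
        clamp-and-flag outside that interval (see
        :func:`concentration_from_reading`).
        """
        if not self.lower < aeb < self.upper:
            raise DomainError("AEB outside the open asymptote interval")
        ratio = (aeb - self.lower) / (self.upper - aeb)
        return self.midpoint * ratio ** (1.0 / self.slope)


@dataclass(frozen=True)
class ConcentrationEstimate:
    """A back-calculated, dilution-corrected (neat-sample) concentration."""

    marker: str
    value_pM: float
    cv: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)
    n_replicates: int = 1


def aeb_from_fraction_on(f_on: float) -> float:
    """Poisson occupancy correction: mean enzymes per bead from f_on.

    Solves ``f_on = 1 - exp(-lam)`` for ``lam``; strictly increasing, 0 at 0.

    Raises
    ------
    SaturatedArrayError
        If every well is on (``f_on >= 1``): the load is unbounded.
    DomainError
        If ``f_on`` is negative.
    """
    if f_on < 0:
        raise DomainError(f"fraction of on wells cannot be negative (got {f_on})")
    if f_on >= 1:
        raise SaturatedArrayError("all wells on: AEB is unbounded")
    return -math.log1p(-f_on)


def simulate_digital_readout(
    true_conc_pM: float,
    params: BeadAssayParams,
    seed: int | np.random.Generator,
) -> WellArrayReading:
    """Draw one well-array reading for a sample at ``true_conc_pM``.

    Each counted well is on independently with probability
    ``1 - exp(-lambda_eff)`` where ``lambda_eff = capture_efficiency *
    (true_conc / dilution_factor) + background_aeb``.  Deterministic given
    the seed.
    """
    if true_conc_pM < 0:
        raise DomainError("true concentration must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = params.capture_efficiency * (true_conc_pM / params.dilution_factor)
    lam += params.background_aeb
    p_on = -math.expm1(-lam)
    n_on = int(rng.binomial(params.n_wells_loaded, p_on))
    return WellArrayReading(n_on=n_on, n_total=params.n_wells_loaded)


def _fit_4pl(conc: np.ndarray, aeb: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit of the increasing 4PL to (conc, mean AEB) pairs."""

    lo0 = float(aeb[conc == conc.min()].mean())
    hi0 = float(aeb.max())
    nonzero = conc[conc > 0]
    mid0 = float(np.median(nonzero))

    def _frac(theta: np.ndarray) -> np.ndarray:
        _, _, mid, h = theta
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(conc > 0, conc**h / (mid**h + conc**h), 0.0)

    def resid(theta: np.ndarray) -> np.ndarray:
        lo, hi, _, _ = theta
        return lo + (hi - lo) * _frac(theta) - aeb

    def jac(theta: np.ndarray) -> np.ndarray:
        lo, hi, mid, h = theta
        f = _frac(theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(conc > 0, (conc / mid) ** h, 0.0)
            logr = np.where(conc > 0, np.log(conc / mid), 0.0)
        g = (hi - lo) / (1.0 + u) ** 2
        return np.column_stack([1.0 - f, f, -g * h * u / mid, g * u * logr])

    best = None
    # two midpoint starts make the ridge-shaped landscape of nearly linear
    # data (no saturation in range) reliably convergent
    for mid_start in (mid0, float(nonzero.max()) * 10.0):
        theta0 = np.array([lo0, max(hi0 * 2.0, lo0 + 1e-9), mid_start, 1.0])
        try:
            sol = least_squares(
                resid,
                theta0,
                jac=jac,
                bounds=([0.0, 0.0, 1e-12, 0.05], [np.inf, np.inf, np.inf, 20.0]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                # standards without in-range saturation leave (upper, midpoint)
                # on an unidentifiable ridge; their ratio (the low-end slope)
                # converges within a few dozen steps, so a tight cap costs
                # nothing in back-calculation accuracy
                max_nfev=300,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            raise FitError(f"calibration fit diverged: {exc}") from exc
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= (1e-9 * max(1.0, float(aeb.max()))) ** 2:
            break  # exact to numerical precision; no second start needed
    assert best is not None
    rms = math.sqrt(2.0 * best.cost / len(conc))
    return best.x, rms


def fit_calibration(standards: list[CalibrationStandard]) -> CalibrationCurve:
    """Fit the 4PL calibration curve to a set of standards.

    Requires at least four distinct concentrations including a blank
    (zero-concentration) standard; refuses degenerate (flat) responses.
    """
    if not standards:
        raise ConfigurationError("no calibration standards supplied")
    markers = {s.marker for s in standards}
    if len(markers) != 1:
        raise ConfigurationError(f"standards mix markers: {sorted(markers)}")
    (marker,) = markers

    conc = np.array([s.concentration_pM for s in standards], dtype=float)
    aeb = np.array([s.mean_signal for s in standards], dtype=float)
    levels = np.unique(conc)
    if len(levels) < 4:
        raise ConfigurationError(
            f"need >=4 distinct concentrations, got {len(levels)}"
        )
    if 0.0 not in levels:
        raise ConfigurationError("a blank (zero-concentration) standard is required")
    if np.ptp(aeb) <= 0:
        raise FitError("degenerate standards: response does not vary")

    (lo, hi, mid, h), rms = _fit_4pl(conc, aeb)
    if not hi > lo:
        raise FitError("fitted curve is not monotone increasing")
    return CalibrationCurve(
        marker=marker,
        lower=lo,
        upper=hi,
        midpoint=mid,
        slope=h,
        valid_range=(float(levels[levels > 0].min()), float(levels.max())),
        fit_residual=rms,
    )


def concentration_from_reading(
    reading: WellArrayReading,
    curve: CalibrationCurve,
    dilution_factor: float,
) -> ConcentrationEstimate:
    """Invert the calibration curve at the reading's AEB.

    The returned value is multiplied by ``dilution_factor`` (neat-sample
    equivalent).  AEB outside the invertible region is clamped to the
    nearest boundary of the curve's valid range and flagged — never
    extrapolated.  Out-of-range conditions produce flags, not exceptions.
    """
    if dilution_factor <= 0:
        raise ConfigurationError("dilution_factor must be positive")
    flags: set[str] = set()
    try:
        y = reading.aeb
    except SaturatedArrayError:
        y = math.inf
    if reading.saturated:
        flags.add("saturated")

    vmin, vmax = curve.valid_range
    y_low = curve.response(vmin)
    y_high = curve.response(vmax)
    if y <= curve.lower:
        flags.add("blank_level")
        value = 0.0
    elif y < y_low:
        flags.add("below_curve")
        value = vmin * dilution_factor
    elif y >= curve.upper or y > y_high:
        flags.add("above_curve")
        value = vmax * dilution_factor
    else:
        value = curve.inverse(y) * dilution_factor
    return ConcentrationEstimate(
        marker=curve.marker, value_pM=value, cv=None, flags=frozenset(flags)
    )


def average_technical_replicates(
    estimates: list[ConcentrationEstimate],
) -> ConcentrationEstimate:
    """Arithmetic mean of technical replicates of one marker.

    The coefficient of variation is the sample standard deviation (ddof=1)
    over the mean; it is 0 for a single replicate or a zero mean.  Flags are
    the union over replicates.
    """
    if not estimates:
        raise ConfigurationError("no estimates to average")
    markers = {e.marker for e in estimates}
    if len(markers) != 1:
        raise ConfigurationError(f"cannot average across markers: {sorted(markers)}")
    values = np.array([e.value_pM for e in estimates], dtype=float)
    mean = float(values.mean())
    if len(values) >= 2 and mean > 0:
        cv = float(values.std(ddof=1) / mean)
    else:
        cv = 0.0
    flags = frozenset().union(*(e.flags for e in estimates))
    return ConcentrationEstimate(
        marker=estimates[0].marker,
        value_pM=mean,
        cv=cv,
        flags=flags,
        n_replicates=len(values),
    )
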