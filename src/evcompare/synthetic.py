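"""Synthetic comparison experiments with known ground truth.

Generates complete, regenerable datasets emulating a method-comparison
study: aliquots of one biofluid with known true marker concentrations are
"isolated" either by a one-pot method (ultracentrifugation, polymer
precipitation — characterised phenomenologically by a per-marker recovery
and an albumin carryover) or by an SEC column (run through the mechanistic
elution model and pooled over a fraction window), then measured by the
digital-immunoassay model with technical replicates and a calibration
curve, with multiplicative log-normal day-to-day noise.

All default concentrations, recoveries and noise levels are synthetic
stand-ins chosen to be plausible for human plasma and CSF; none is a
measured value.  Every observable is a deterministic function of the
configuration and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import assay as am
from . import sec as sm
from .compare import (
    ALBUMIN,
    MARKERS,
    TETRASPANINS,
    MethodMeasurement,
    average_day_replicates,
)
from .errors import ConfigurationError

__all__ = [
    "OnePotMethod",
    "SECMethod",
    "ExperimentConfig",
    "SyntheticDataset",
    "DEFAULT_EV_SIZE",
    "ALBUMIN_RADIUS_NM",
    "default_plasma_config",
    "default_csf_config",
    "focused_comparison_config",
    "graded_recovery_config",
    "generate_experiment",
    "generate_full_panel",
]

#: heterogeneous small-EV population: log-normal hydrodynamic radius
DEFAULT_EV_SIZE = sm.LogNormalRadius(median_nm=35.0, geometric_sd=1.6)
#: hydrodynamic radius of serum albumin
ALBUMIN_RADIUS_NM = 3.5


@dataclass(frozen=True)
class OnePotMethod:
    """A non-chromatographic isolation producing a single eluate.

    ``tetraspanin_recovery`` maps each tetraspanin to the fraction of input
    EVs recovered; ``albumin_carryover`` is the fraction of input albumin
    retained in the eluate.
    """

    name: str
    tetraspanin_recovery: Mapping[str, float]
    albumin_carryover: float
    input_volume_ml: float = 0.5
    eluate_volume_ml: float = 0.5

    def __post_init__(self) -> None:
        missing = [m for m in TETRASPANINS if m not in self.tetraspanin_recovery]
        if missing:
            raise ConfigurationError(f"{self.name}: missing recoveries for {missing}")
        bad = {m: v for m, v in self.tetraspanin_recovery.items() if not 0 <= v <= 1}
        if bad or not 0 <= self.albumin_carryover <= 1:
            raise ConfigurationError(f"{self.name}: recoveries/carryover must be in [0,1]")
        if self.input_volume_ml <= 0 or self.eluate_volume_ml <= 0:
            raise ConfigurationError(f"{self.name}: volumes must be positive")


@dataclass(frozen=True)
class SECMethod:
    """An SEC column condition with its pooled fraction window."""

    name: str
    column: sm.Column
    pool_window: tuple[int, int]
    load_volume_ml: float = 0.5
    input_volume_ml: float = 0.5

    def __post_init__(self) -> None:
        first, last = self.pool_window
        if not (
            self.column.first_collected_fraction
            <= first
            <= last
            <= self.column.last_collected_fraction
        ):
            raise ConfigurationError(
                f"{self.name}: pool window outside collected fractions"
            )
        if self.load_volume_ml <= 0:
            raise ConfigurationError(f"{self.name}: load volume must be positive")

    @property
    def pool_volume_ml(self) -> float:
        first, last = self.pool_window
        return (last - first + 1) * self.column.fraction_volume_ml


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one synthetic comparison experiment.

    ``assay=None`` selects the ideal-assay mode in which eluate
    concentrations are observed exactly (no digital readout, no
    calibration); useful for separating isolation physics from measurement
    noise.
    """

    biofluid: str
    true_marker_concentrations_pM: Mapping[str, float]
    methods: tuple[OnePotMethod | SECMethod, ...]
    assay: Mapping[str, am.BeadAssayParams] | None = None
    calibration_concentrations: Mapping[str, tuple[float, ...]] | None = None
    n_day_replicates: int = 2
    n_technical_replicates: int = 2
    n_column_replicates: int = 1
    day_cv: float = 0.15
    seed: int = 0
    ev_size: sm.LogNormalRadius = DEFAULT_EV_SIZE

    def __post_init__(self) -> None:
        missing = [m for m in MARKERS if m not in self.true_marker_concentrations_pM]
        if missing:
            raise ConfigurationError(f"missing true concentrations for {missing}")
        if any(v <= 0 for v in self.true_marker_concentrations_pM.values()):
            raise ConfigurationError("true concentrations must be positive")
        if not self.methods:
            raise ConfigurationError("at least one method is required")
        names = [m.name for m in self.methods]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate method names")
        if min(self.n_day_replicates, self.n_technical_replicates, self.n_column_replicates) < 1:
            raise ConfigurationError("replicate counts must be positive")
        if self.day_cv < 0:
            raise ConfigurationError("day_cv must be non-negative")
        if self.assay is not None:
            missing = [m for m in MARKERS if m not in self.assay]
            if missing:
                raise ConfigurationError(f"missing assay parameters for {missing}")
            if self.calibration_concentrations is None:
                raise ConfigurationError(
                    "calibration_concentrations required when assay is configured"
                )


@dataclass
class SyntheticDataset:
    """All observables of one generated experiment, plus its ground truth."""

    config: ExperimentConfig
    ground_truth: dict
    measurements: list[MethodMeasurement]
    measurement_table: pd.DataFrame
    fraction_table: pd.DataFrame
    plate_table: pd.DataFrame | None = None
    calibration_table: pd.DataFrame | None = None
    calibration_curves: dict[str, am.CalibrationCurve] = field(default_factory=dict)


def _standard_assay() -> dict[str, am.BeadAssayParams]:
    """Default assay configurations: 4x on-board dilution for tetraspanins,
    20x manual dilution for albumin; capture efficiencies reflect the much
    higher abundance of albumin."""
    tet = dict(
        n_beads=500_000,
        n_wells_loaded=50_000,
        capture_efficiency=0.5,
        background_aeb=0.003,
        dilution_factor=4.0,
    )
    alb = dict(
        n_beads=500_000,
        n_wells_loaded=50_000,
        capture_efficiency=2e-6,
        background_aeb=0.002,
        dilution_factor=20.0,
    )
    return {m: am.BeadAssayParams(**tet) for m in TETRASPANINS} | {
        ALBUMIN: am.BeadAssayParams(**alb)
    }


#: assay-level (post-dilution) calibrator concentrations, pM
_CAL_CONCS: dict[str, tuple[float, ...]] = {
    **{m: (0.0, 0.005, 0.02, 0.08, 0.3, 1.0, 2.0) for m in TETRASPANINS},
    ALBUMIN: (0.0, 30.0, 100.0, 1e3, 1e4, 1e5, 3e5),
}


def _standard_method_panel(csf: bool) -> tuple[OnePotMethod | SECMethod, ...]:
    """The 12-condition comparison panel: six conventional isolation methods
    (ultracentrifugation with/without wash, two precipitation kits, two
    commercial SEC columns) plus the six custom Sepharose columns
    (CL-2B/4B/6B at 10 and 20 ml beds)."""
    exoquick_rec = (
        {"CD9": 0.40, "CD63": 0.34, "CD81": 0.37}
        if csf
        else {"CD9": 0.22, "CD63": 0.18, "CD81": 0.20}
    )
    one_pot = (
        OnePotMethod(
            "UC",
            tetraspanin_recovery={"CD9": 0.06, "CD63": 0.05, "CD81": 0.055},
            albumin_carryover=1e-3,
        ),
        OnePotMethod(
            "UC wash",
            tetraspanin_recovery={"CD9": 0.035, "CD63": 0.03, "CD81": 0.032},
            albumin_carryover=3e-4,
        ),
        OnePotMethod(
            "ExoQuick",
            tetraspanin_recovery=exoquick_rec,
            albumin_carryover=8e-3,
        ),
        OnePotMethod(
            "ExoQuick ULTRA",
            tetraspanin_recovery={m: v * 0.75 for m, v in exoquick_rec.items()},
            albumin_carryover=2e-3,
            input_volume_ml=0.25,
        ),
    )
    sec_methods = [
        SECMethod("Izon 35nm", sm.make_column(sm.IZON_35, 10.0), pool_window=(7, 10)),
        SECMethod("Izon 70nm", sm.make_column(sm.IZON_70, 10.0), pool_window=(7, 10)),
    ]
    for resin in (sm.SEPHAROSE_CL2B, sm.SEPHAROSE_CL4B, sm.SEPHAROSE_CL6B):
        short = resin.name.split()[-1]  # CL-2B etc.
        sec_methods.append(
            SECMethod(f"{short} 10ml", sm.make_column(resin, 10.0), pool_window=(7, 10))
        )
        sec_methods.append(
            SECMethod(f"{short} 20ml", sm.make_column(resin, 20.0), pool_window=(14, 17))
        )
    return one_pot + tuple(sec_methods)


def default_plasma_config(seed: int = 0, ideal_assay: bool = False) -> ExperimentConfig:
    """Synthetic plasma preset: pM-level tetraspanins against sub-mM albumin."""
    return ExperimentConfig(
        biofluid="plasma",
        true_marker_concentrations_pM={
            "CD9": 20.0,
            "CD63": 8.0,
            "CD81": 12.0,
            ALBUMIN: 6e8,
        },
        methods=_standard_method_panel(csf=False),
        assay=None if ideal_assay else _standard_assay(),
        calibration_concentrations=None if ideal_assay else _CAL_CONCS,
        seed=seed,
    )


def default_csf_config(seed: int = 0, ideal_assay: bool = False) -> ExperimentConfig:
    """Synthetic CSF preset: ~200-fold less albumin and ~10-fold fewer EVs
    than the plasma preset."""
    return ExperimentConfig(
        biofluid="CSF",
        true_marker_concentrations_pM={
            "CD9": 2.0,
            "CD63": 1.0,
            "CD81": 1.5,
            ALBUMIN: 3e6,
        },
        methods=_standard_method_panel(csf=True),
        assay=None if ideal_assay else _standard_assay(),
        calibration_concentrations=None if ideal_assay else _CAL_CONCS,
        seed=seed,
    )


def focused_comparison_config(
    biofluid: str = "plasma", seed: int = 0, ideal_assay: bool = False
) -> ExperimentConfig:
    """Head-to-head run of the best yield/purity columns against the
    conventional CL-2B 10 ml column, with four column replicates each."""
    base = default_plasma_config(seed, ideal_assay) if biofluid == "plasma" else default_csf_config(seed, ideal_assay)
    purity_col = (
        SECMethod("CL-4B 20ml", sm.make_column(sm.SEPHAROSE_CL4B, 20.0), (14, 17))
        if biofluid == "plasma"
        else SECMethod("CL-4B 10ml", sm.make_column(sm.SEPHAROSE_CL4B, 10.0), (7, 10))
    )
    methods = (
        SECMethod("CL-2B 10ml", sm.make_column(sm.SEPHAROSE_CL2B, 10.0), (7, 10)),
        SECMethod("CL-6B 10ml", sm.make_column(sm.SEPHAROSE_CL6B, 10.0), (7, 10)),
        purity_col,
    )
    return ExperimentConfig(
        biofluid=base.biofluid,
        true_marker_concentrations_pM=base.true_marker_concentrations_pM,
        methods=methods,
        assay=base.assay,
        calibration_concentrations=base.calibration_concentrations,
        n_day_replicates=1,
        n_column_replicates=4,
        seed=seed,
    )


def graded_recovery_config(
    seed: int = 0, ideal_assay: bool = False
) -> ExperimentConfig:
    """Validation scenario: three one-pot methods with well-separated true
    recoveries (reference 1.0, then 0.65 and 0.40 — pairwise gaps > 30%),
    used to check that estimated recoveries track and rank the configured
    truth.  Marker levels are kept low enough that the digital readout
    stays in the counting regime at full recovery."""
    methods = (
        OnePotMethod(
            "reference",
            tetraspanin_recovery={m: 1.0 for m in TETRASPANINS},
            albumin_carryover=1e-3,
        ),
        OnePotMethod(
            "mid",
            tetraspanin_recovery={m: 0.65 for m in TETRASPANINS},
            albumin_carryover=1e-3,
        ),
        OnePotMethod(
            "low",
            tetraspanin_recovery={m: 0.40 for m in TETRASPANINS},
            albumin_carryover=1e-3,
        ),
    )
    return ExperimentConfig(
        biofluid="plasma",
        true_marker_concentrations_pM={"CD9": 4.0, "CD63": 3.0, "CD81": 5.0, ALBUMIN: 6e8},
        methods=methods,
        assay=None if ideal_assay else _standard_assay(),
        calibration_concentrations=None if ideal_assay else _CAL_CONCS,
        seed=seed,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _expected_eluate_concentrations(
    method: OnePotMethod | SECMethod, config: ExperimentConfig
) -> tuple[dict[str, float], list[dict]]:
    """Noise-free eluate concentration per marker, plus fraction-table rows."""
    truth = config.true_marker_concentrations_pM
    rows: list[dict] = []
    if isinstance(method, OnePotMethod):
        conc = {}
        for m in TETRASPANINS:
            amount = truth[m] * method.input_volume_ml * method.tetraspanin_recovery[m]
            conc[m] = amount / method.eluate_volume_ml
        alb_amount = truth[ALBUMIN] * method.input_volume_ml * method.albumin_carryover
        conc[ALBUMIN] = alb_amount / method.eluate_volume_ml
        return conc, rows

    # SEC: one elution profile per species shape, scaled per marker
    ev_unit = sm.collect_fractions(
        sm.elution_profile(
            sm.Species("EV", config.ev_size, input_amount=1.0),
            method.column,
            method.load_volume_ml,
        ),
        method.column,
    )
    alb_unit = sm.collect_fractions(
        sm.elution_profile(
            sm.Species(ALBUMIN, ALBUMIN_RADIUS_NM, input_amount=1.0),
            method.column,
            method.load_volume_ml,
        ),
        method.column,
    )
    conc = {}
    for m in MARKERS:
        unit = alb_unit if m == ALBUMIN else ev_unit
        input_amount = truth[m] * method.load_volume_ml
        pooled_amount, _ = sm.pool_window(unit, method.pool_window)
        conc[m] = pooled_amount * input_amount / method.pool_volume_ml
        for k, a in zip(unit.fraction_ids, unit.amounts):
            rows.append(
                dict(
                    biofluid=config.biofluid,
                    method=method.name,
                    species=m,
                    fraction=k,
                    amount_fmol=a * input_amount,
                    concentration_pM=a * input_amount / method.column.fraction_volume_ml,
                )
            )
    return conc, rows


def _simulate_calibration(
    config: ExperimentConfig, rng: np.random.Generator
) -> tuple[dict[str, am.CalibrationCurve], pd.DataFrame]:
    curves: dict[str, am.CalibrationCurve] = {}
    rows: list[dict] = []
    assert config.assay is not None and config.calibration_concentrations is not None
    for marker in MARKERS:
        params = config.assay[marker]
        # calibrators are read without sample dilution
        cal_params = am.BeadAssayParams(
            n_beads=params.n_beads,
            n_wells_loaded=params.n_wells_loaded,
            capture_efficiency=params.capture_efficiency,
            background_aeb=params.background_aeb,
            dilution_factor=1.0,
        )
        standards = []
        for conc in config.calibration_concentrations[marker]:
            sigs = []
            for rep in range(config.n_technical_replicates):
                reading = am.simulate_digital_readout(conc, cal_params, rng)
                sigs.append(reading.aeb)
                rows.append(
                    dict(marker=marker, concentration_pM=conc, replicate=rep + 1, aeb=reading.aeb)
                )
            standards.append(
                am.CalibrationStandard(marker, conc, tuple(sigs))
            )
        curves[marker] = am.fit_calibration(standards)
    return curves, pd.DataFrame(rows)


def generate_experiment(config: ExperimentConfig) -> SyntheticDataset:
    """Run the full generative model for one experiment configuration.

    Deterministic given ``config`` (including its seed): regeneration
    yields identical tables.
    """
    rng = np.random.default_rng(config.seed)

    curves: dict[str, am.CalibrationCurve] = {}
    calibration_table = None
    plate_rows: list[dict] = []
    if config.assay is not None:
        curves, calibration_table = _simulate_calibration(config, rng)

    fraction_rows: list[dict] = []
    measurement_rows: list[dict] = []
    measurements: list[MethodMeasurement] = []
    truth_per_method: dict[str, dict[str, float]] = {}

    for method in config.methods:
        expected, frac_rows = _expected_eluate_concentrations(method, config)
        truth_per_method[method.name] = expected
        fraction_rows.extend(frac_rows)

        replicate_measurements = []
        rep_index = 0
        for day in range(config.n_day_replicates):
            for col in range(config.n_column_replicates):
                rep_index += 1
                observed: dict[str, float] = {}
                for marker in MARKERS:
                    noisy = expected[marker] * _lognormal_factor(rng, config.day_cv)
                    if config.assay is None:
                        value = noisy
                    else:
                        params = config.assay[marker]
                        estimates = []
                        for tech in range(config.n_technical_replicates):
                            reading = am.simulate_digital_readout(noisy, params, rng)
                            plate_rows.append(
                                dict(
                                    sample_id=f"{method.name}|rep{rep_index}",
                                    marker=marker,
                                    replicate=tech + 1,
                                    n_on=reading.n_on,
                                    n_total=reading.n_total,
                                )
                            )
                            estimates.append(
                                am.concentration_from_reading(
                                    reading, curves[marker], params.dilution_factor
                                )
                            )
                        value = am.average_technical_replicates(estimates).value_pM
                    observed[marker] = value
                    measurement_rows.append(
                        dict(
                            biofluid=config.biofluid,
                            method=method.name,
                            marker=marker,
                            replicate_day=rep_index,
                            value_pM=value,
                            input_volume_ml=method.input_volume_ml,
                        )
                    )
                replicate_measurements.append(
                    MethodMeasurement(
                        biofluid=config.biofluid,
                        method=method.name,
                        marker_values_pM=observed,
                        input_volume_ml=method.input_volume_ml,
                    )
                )
        measurements.append(average_day_replicates(replicate_measurements))

    ground_truth = dict(
        seed=config.seed,
        biofluid=config.biofluid,
        true_marker_concentrations_pM=dict(config.true_marker_concentrations_pM),
        day_cv=config.day_cv,
        ideal_assay=config.assay is None,
        expected_eluate_concentrations_pM=truth_per_method,
        methods={
            m.name: (
                dict(
                    kind="one_pot",
                    tetraspanin_recovery=dict(m.tetraspanin_recovery),
                    albumin_carryover=m.albumin_carryover,
                    input_volume_ml=m.input_volume_ml,
                )
                if isinstance(m, OnePotMethod)
                else dict(
                    kind="sec",
                    resin=m.column.resin.name,
                    bed_volume_ml=m.column.bed_volume_ml,
                    pool_window=list(m.pool_window),
                    load_volume_ml=m.load_volume_ml,
                )
            )
            for m in config.methods
        },
    )

    return SyntheticDataset(
        config=config,
        ground_truth=ground_truth,
        measurements=measurements,
        measurement_table=pd.DataFrame(measurement_rows),
        fraction_table=pd.DataFrame(
            fraction_rows,
            columns=[
                "biofluid",
                "method",
                "species",
                "fraction",
                "amount_fmol",
                "concentration_pM",
            ],
        ),
        plate_table=pd.DataFrame(plate_rows) if plate_rows else None,
        calibration_table=calibration_table,
        calibration_curves=curves,
    )


def generate_full_panel(
    seed: int = 0, ideal_assay: bool = False
) -> dict[str, SyntheticDataset]:
    """Both biofluids run through the 12-condition panel."""
    return {
        "plasma": generate_experiment(default_plasma_config(seed, ideal_assay)),
        "CSF": generate_experiment(default_csf_config(seed + 1, ideal_assay)),
    }
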