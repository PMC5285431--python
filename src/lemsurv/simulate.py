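"""Seeded synthetic clonogenic-assay datasets with known LQ ground truth.

The generator emulates the benchmark study layout — three kilovoltage
X-ray spectra, four nanoparticle concentrations (0, 0.25, 0.5, 1.0
mMol/L), each curve a control plus five dose irradiations measured in
triplicate — with the interpolated LQ response as the noiseless mean.

Two noise mechanisms are provided:

* ``gaussian`` — multiplicative Gaussian scatter on the survival fraction,
  ``sf = SF_true * (1 + eps)``, ``eps ~ N(0, sigma^2)``, summarising the
  replicate draws into mean and standard deviation (the usual shape of
  published assay tables);
* ``poisson_colony`` — a mechanistic idealised clonogenic assay: each
  plated cell draws a Poisson number of lethal lesions with mean
  ``alpha*D + beta*D^2`` and founds a colony iff it has none and an
  independent plating-success draw (probability ``plating_efficiency``)
  succeeds.  Colony counts are normalised, by standard clonogenic
  practice, to the same condition's mean control count.

Randomness follows one root seed with stable per-condition substreams, so
adding a spectrum or concentration to a design does not perturb the draws
of the other conditions.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .benchmark import benchmark_models
from .errors import ConfigurationError, DomainError
from .fitting import SurvivalCurve, SurvivalMeasurement
from .model import InterpolationModel, interpolated_sf

__all__ = [
    "AssayDesign",
    "GroundTruth",
    "ColonySimulation",
    "true_sf",
    "simulate_gaussian",
    "simulate_poisson_colony",
    "generate_benchmark_fixture",
]

#: Floor applied to Gaussian survival draws; negative survival is unphysical
#: and log-space fitting needs strictly positive values.
SF_FLOOR = 1e-6

DEFAULT_DOSES_GY = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_CONCENTRATIONS = (0.0, 0.25, 0.5, 1.0)
DEFAULT_SPECTRA = ("80 kVp", "100 kVp", "150 kVp")


@dataclass(frozen=True)
class AssayDesign:
    """Layout and noise model of a synthetic clonogenic study.

    Defaults reproduce the benchmark design: a 0 Gy control plus five
    1 Gy-spaced doses inside the 1-6 Gy LQ validity range, four
    concentrations, three spectra, triplicate trials, multiplicative
    Gaussian noise of 5%.
    """

    doses: Tuple[float, ...] = DEFAULT_DOSES_GY
    concentrations: Tuple[float, ...] = DEFAULT_CONCENTRATIONS
    spectra: Tuple[str, ...] = DEFAULT_SPECTRA
    n_replicates: int = 3
    noise: str = "gaussian"
    sigma: float = 0.05
    cells_plated: int = 1000
    plating_efficiency: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )
        object.__setattr__(self, "spectra", tuple(self.spectra))
        doses = self.doses
        if any(d < 0 for d in doses) or any(
            b <= a for a, b in zip(doses, doses[1:])
        ):
            raise ConfigurationError(
                f"dose grid must be non-negative and strictly increasing, got {doses}"
            )
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.noise not in ("gaussian", "poisson_colony"):
            raise ConfigurationError(
                f"unknown noise model {self.noise!r}; "
                "use 'gaussian' or 'poisson_colony'"
            )
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.cells_plated < 1:
            raise ConfigurationError("cells_plated must be >= 1")
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise ConfigurationError("plating_efficiency must lie in (0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """One interpolation model per spectrum: the generative law of a study."""

    models: Mapping[str, InterpolationModel]

    def __post_init__(self) -> None:
        for label, model in self.models.items():
            if model.spectrum_label != label:
                raise ConfigurationError(
                    f"truth key {label!r} does not match model spectrum "
                    f"{model.spectrum_label!r}"
                )

    @classmethod
    def from_models(cls, models: Iterable[InterpolationModel]) -> "GroundTruth":
        return cls({m.spectrum_label: m for m in models})

    def model_for(self, spectrum: str) -> InterpolationModel:
        try:
            return self.models[spectrum]
        except KeyError:
            raise ConfigurationError(
                f"unknown spectrum {spectrum!r}; truth defines {sorted(self.models)}"
            ) from None


def benchmark_ground_truth() -> GroundTruth:
    """Ground truth built from the published benchmark endpoint parameters."""
    return GroundTruth(benchmark_models())


def true_sf(truth: GroundTruth, spectrum: str, c: float, dose: float) -> float:
    """Noiseless mean survival fraction of the generator at one point."""
    model = truth.model_for(spectrum)
    return float(interpolated_sf(model, c, [float(dose)])[0])


def _condition_rng(seed: int, spectrum: str, concentration: float) -> np.random.Generator:
    """Independent, stable substream for one (spectrum, concentration)."""
    key = (zlib.crc32(spectrum.encode("utf-8")), int(round(concentration * 1e9)))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _summarise(draws: np.ndarray) -> Tuple[float, float]:
    if np.all(draws == draws[0]):  # keeps the noiseless limit bitwise exact
        return float(draws[0]), 0.0
    mean = float(np.mean(draws))
    sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
    return mean, sd


def simulate_gaussian(design: AssayDesign, truth: GroundTruth) -> List[SurvivalCurve]:
    """Simulate summary survival tables with multiplicative Gaussian noise.

    Per condition and dose, ``n_replicates`` draws of
    ``SF_true * (1 + eps)``, ``eps ~ N(0, sigma^2)``, floored at a small
    positive value; the curve stores the replicate mean and standard
    deviation.  The 0 Gy control keeps its raw mean (it may exceed 1).
    Deterministic for a given (design, truth, seed).
    """
    if design.noise != "gaussian":
        raise ConfigurationError(
            f"design.noise is {design.noise!r}; simulate_gaussian needs 'gaussian'"
        )
    curves: List[SurvivalCurve] = []
    doses = np.asarray(design.doses)
    for spectrum in design.spectra:
        model = truth.model_for(spectrum)
        for c in design.concentrations:
            rng = _condition_rng(design.seed, spectrum, c)
            means = interpolated_sf(model, c, doses)
            measurements = []
            for dose, mu in zip(design.doses, means):
                eps = rng.normal(0.0, design.sigma, size=design.n_replicates)
                draws = np.maximum(mu * (1.0 + eps), SF_FLOOR)
                sf_mean, sf_sd = _summarise(draws)
                measurements.append(
                    SurvivalMeasurement(
                        dose=dose,
                        sf_mean=sf_mean,
                        sf_sd=sf_sd,
                        n_replicates=design.n_replicates,
                    )
                )
            curves.append(
                SurvivalCurve(
                    spectrum_label=spectrum,
                    concentration=c,
                    measurements=tuple(measurements),
                )
            )
    return curves


@dataclass(frozen=True)
class ColonySimulation:
    """Mechanistic simulation output: summary curves plus raw colony counts."""

    curves: Tuple[SurvivalCurve, ...]
    counts: pd.DataFrame = field(repr=False, default=None)


def simulate_poisson_colony(
    design: AssayDesign, truth: GroundTruth, *, normalise: str = "control"
) -> ColonySimulation:
    """Simulate an idealised clonogenic assay via Poisson lethal lesions.

    Each plated cell survives irradiation with probability
    ``exp(-(alpha*D + beta*D^2))`` (the Poisson zero-lesion class) and then
    forms a colony with probability ``plating_efficiency``; the colony
    count per replicate is therefore binomial with success probability
    ``plating_efficiency * exp(-lambda)``.

    normalise "control" (default, standard clonogenic practice): replicate
    SF = colonies / mean control-colony count of the same condition.
    normalise "expected": divide by ``cells_plated * plating_efficiency``.
    Replicate SF values are floored at half a colony so log fits stay
    defined when a replicate yields zero colonies.
    """
    if design.noise != "poisson_colony":
        raise ConfigurationError(
            f"design.noise is {design.noise!r}; "
            "simulate_poisson_colony needs 'poisson_colony'"
        )
    if normalise not in ("control", "expected"):
        raise ConfigurationError(
            f"unknown normalise {normalise!r}; use 'control' or 'expected'"
        )
    if 0.0 not in design.doses and normalise == "control":
        raise ConfigurationError(
            "control normalisation requires a 0 Gy dose in the design"
        )

    curves: List[SurvivalCurve] = []
    records = []
    doses = np.asarray(design.doses)
    for spectrum in design.spectra:
        model = truth.model_for(spectrum)
        for c in design.concentrations:
            rng = _condition_rng(design.seed, spectrum, c)
            p_surv = interpolated_sf(model, c, doses)
            counts = np.empty((doses.size, design.n_replicates), dtype=np.int64)
            for i, p in enumerate(p_surv):
                counts[i] = rng.binomial(
                    design.cells_plated,
                    design.plating_efficiency * p,
                    size=design.n_replicates,
                )
                for rep in range(design.n_replicates):
                    records.append(
                        {
                            "spectrum_label": spectrum,
                            "concentration": c,
                            "dose_gy": design.doses[i],
                            "replicate": rep,
                            "colonies": int(counts[i, rep]),
                        }
                    )
            if normalise == "control":
                denom = float(np.mean(counts[list(design.doses).index(0.0)]))
                if denom <= 0.0:
                    raise DomainError(
                        f"zero control colonies for {spectrum!r} c={c:g}; "
                        "increase cells_plated or plating_efficiency"
                    )
            else:
                denom = design.cells_plated * design.plating_efficiency
            sf = np.maximum(counts / denom, 0.5 / denom)
            measurements = []
            for i, dose in enumerate(design.doses):
                sf_mean, sf_sd = _summarise(sf[i])
                measurements.append(
                    SurvivalMeasurement(
                        dose=dose,
                        sf_mean=sf_mean,
                        sf_sd=sf_sd,
                        n_replicates=design.n_replicates,
                    )
                )
            curves.append(
                SurvivalCurve(
                    spectrum_label=spectrum,
                    concentration=c,
                    measurements=tuple(measurements),
                )
            )
    return ColonySimulation(
        curves=tuple(curves),
        counts=pd.DataFrame.from_records(records),
    )


def simulate(design: AssayDesign, truth: GroundTruth):
    """Dispatch on the design's noise model; returns the curves list."""
    if design.noise == "gaussian":
        return simulate_gaussian(design, truth)
    return list(simulate_poisson_colony(design, truth).curves)


def generate_benchmark_fixture(seed: int) -> Tuple[List[SurvivalCurve], GroundTruth]:
    """Full benchmark-layout dataset with published-parameter ground truth.

    3 spectra x 4 concentrations x (control + 5 doses) x 3 replicates,
    Gaussian noise sigma = 0.05.  Returns (curves, truth).
    """
    truth = benchmark_ground_truth()
    design = AssayDesign(seed=seed)
    return simulate_gaussian(design, truth), truth
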