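"""Benchmarking diagnostics for interpolated survival predictions.

Two analyses mirror how concentration-interpolated curves are judged
against clonogenic measurements:

* percentage difference of observed survival with respect to the fitted
  LQ response, per point — convention ``100 * (observed - fitted) / fitted``
  (positive means the measurement sits above the fitted curve);
* within-uncertainty coverage counting: a prediction covers a measurement
  when ``|sf_pred - sf_mean| <= k * sf_sd``, with k = 1 by default
  (error bars are +/- one cell-survival standard deviation).

``prediction_workflow`` is the end-to-end pipeline: endpoint fits in,
interpolated predictions at intermediate concentrations out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import AlignmentError, ConfigurationError
from .fitting import FitResult, SurvivalCurve
from .model import (
    InterpolationModel,
    LQParameters,
    SurvivalPrediction,
    predict_survival,
)

__all__ = [
    "PercentDifferencePoint",
    "PercentDifferenceReport",
    "CoveragePoint",
    "CoverageReport",
    "percent_difference",
    "coverage_within_uncertainty",
    "prediction_workflow",
    "models_from_parameters",
]


@dataclass(frozen=True)
class PercentDifferencePoint:
    dose: float
    observed: float
    fitted: float
    percent: Optional[float]  # None when the fitted value underflowed to 0
    flagged: bool = False


@dataclass(frozen=True)
class PercentDifferenceReport:
    """Per-point percentage differences plus |%| summary for one curve."""

    spectrum_label: str
    concentration: float
    points: Tuple[PercentDifferencePoint, ...]
    max_abs_percent: float
    mean_abs_percent: float


def percent_difference(
    curve: SurvivalCurve, params: LQParameters, *, include_control: bool = False
) -> PercentDifferenceReport:
    """Percentage difference of measured vs fitted survival, point by point.

    Positive-dose points only by default (``include_control=True`` adds the
    0 Gy control, whose fitted value is exactly 1).  Points whose fitted
    survival underflows to zero are flagged and excluded from the summary.
    """
    points: List[PercentDifferencePoint] = []
    for m in curve.measurements:
        if m.dose == 0.0 and not include_control:
            continue
        fitted = float(np.exp(-params.mean_lesions(m.dose)))
        if fitted == 0.0:
            points.append(PercentDifferencePoint(m.dose, m.sf_mean, fitted, None, True))
            continue
        pct = 100.0 * (m.sf_mean - fitted) / fitted
        points.append(PercentDifferencePoint(m.dose, m.sf_mean, fitted, pct))
    valid = np.array([p.percent for p in points if not p.flagged], dtype=float)
    max_abs = float(np.max(np.abs(valid))) if valid.size else float("nan")
    mean_abs = float(np.mean(np.abs(valid))) if valid.size else float("nan")
    return PercentDifferenceReport(
        spectrum_label=curve.spectrum_label,
        concentration=curve.concentration,
        points=tuple(points),
        max_abs_percent=max_abs,
        mean_abs_percent=mean_abs,
    )


@dataclass(frozen=True)
class CoveragePoint:
    dose: float
    predicted: float
    observed: float
    sf_sd: float
    covered: bool


@dataclass(frozen=True)
class CoverageReport:
    """Counts of measurements covered by predictions within k standard deviations."""

    spectrum_label: str
    concentration: float
    points: Tuple[CoveragePoint, ...]
    n_covered: int
    n_total: int
    k: float


def coverage_within_uncertainty(
    curve: SurvivalCurve,
    predictions: Sequence[SurvivalPrediction],
    *,
    k: float = 1.0,
) -> CoverageReport:
    """Count measurements whose predicted SF falls within k*sd of the mean.

    Predictions must be aligned to the curve's dose grid: every measured
    dose needs exactly one prediction at the same dose (exact match; no
    interpolation across dose is performed here).
    """
    if k < 0.0:
        raise ConfigurationError(f"tolerance multiplier k must be >= 0, got {k!r}")
    by_dose: Dict[float, SurvivalPrediction] = {}
    for p in predictions:
        if p.dose in by_dose:
            raise AlignmentError(f"duplicate prediction at dose {p.dose:g} Gy")
        by_dose[p.dose] = p
    missing = [m.dose for m in curve.measurements if m.dose not in by_dose]
    if missing:
        raise AlignmentError(
            f"no prediction at measured dose(s) {missing} Gy; predictions must "
            "be generated on the measured dose grid"
        )
    points = []
    for m in curve.measurements:
        pred = by_dose[m.dose]
        covered = bool(abs(pred.sf - m.sf_mean) <= k * m.sf_sd)
        points.append(
            CoveragePoint(
                float(m.dose), float(pred.sf), float(m.sf_mean), float(m.sf_sd), covered
            )
        )
    n_covered = int(sum(p.covered for p in points))
    return CoverageReport(
        spectrum_label=curve.spectrum_label,
        concentration=curve.concentration,
        points=tuple(points),
        n_covered=n_covered,
        n_total=len(points),
        k=k,
    )


def models_from_parameters(
    parameter_sets: Iterable[LQParameters],
) -> Dict[str, InterpolationModel]:
    """Pair endpoint parameter sets into one interpolation model per spectrum.

    The undoped endpoint is the (unique) concentration-0 set; the reference
    endpoint is the set at the highest concentration.  Doped sets at
    intermediate concentrations are ignored — the interpolation is defined
    by its endpoints.  Duplicate concentrations or a missing endpoint raise
    a :class:`ConfigurationError`.
    """
    by_spectrum: Dict[str, Dict[float, LQParameters]] = {}
    for p in parameter_sets:
        slot = by_spectrum.setdefault(p.spectrum_label, {})
        if p.concentration in slot:
            raise ConfigurationError(
                f"multiple parameter sets at concentration {p.concentration:g} "
                f"for spectrum {p.spectrum_label!r}"
            )
        slot[p.concentration] = p
    models = {}
    for label, slot in sorted(by_spectrum.items()):
        if 0.0 not in slot:
            raise ConfigurationError(
                f"spectrum {label!r} is missing an undoped (concentration 0) fit"
            )
        doped = [c for c in slot if c > 0.0]
        if not doped:
            raise ConfigurationError(
                f"spectrum {label!r} is missing a doped endpoint fit"
            )
        models[label] = InterpolationModel(
            params_undoped=slot[0.0], params_reference=slot[max(doped)]
        )
    return models


def _models_from_fits(fits: Iterable[FitResult]) -> Dict[str, InterpolationModel]:
    return models_from_parameters(fit.params for fit in fits)


def prediction_workflow(
    fits: Iterable[FitResult],
    targets: Sequence[Tuple[float, Sequence[float]]],
    *,
    allow_extrapolation: bool = False,
) -> List[SurvivalPrediction]:
    """Predict survival curves at intermediate concentrations from endpoint fits.

    Parameters
    ----------
    fits
        Fit results containing, for each spectrum, exactly one undoped
        (concentration 0) and one doped endpoint.
    targets
        ``(concentration, dose_grid)`` pairs evaluated for every spectrum.

    Returns a flat list of predictions ordered by spectrum label, then
    target order, then dose — independent of the input order of ``fits``.
    """
    models = _models_from_fits(fits)
    predictions: List[SurvivalPrediction] = []
    for label in sorted(models):
        model = models[label]
        for c, dose_grid in targets:
            for d in np.asarray(dose_grid, dtype=float):
                predictions.append(
                    predict_survival(
                        model, c, float(d), allow_extrapolation=allow_extrapolation
                    )
                )
    return predictions
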