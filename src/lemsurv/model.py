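"""Closed-form local-effect-model / linear-quadratic mathematics.

The survival fraction of a cell population irradiated with a mean dose
``D`` (Gy) is modelled by the linear-quadratic (LQ) response

    SF(D) = exp(-alpha*D - beta*D^2),

equivalently ``SF = exp(-<N>)`` where ``<N> = alpha*D + beta*D^2`` is the
mean number of lethal lesions (Poisson-distributed local DNA damage events,
any one of which inactivates the cell).

For a cell line doped with high-Z nanoparticles at concentration ``C``, the
extra lethal lesions contributed by the nanoparticles scale linearly with
average nanoparticle density up to the reference concentration ``C0`` at
which doped survival data exist.  Writing ``N_U`` for the undoped lesion
count and ``N_total(C0)`` for the doped one,

    N_NP(C, D) = (C/C0) * (N_total(C0, D) - N_U(D)),

so the interpolated response is again linear-quadratic with coefficients

    alpha(C) = alpha_U + (C/C0) * (alpha_total(C0) - alpha_U)
    beta(C)  = beta_U  + (C/C0) * (beta_total(C0)  - beta_U),

i.e. log-survival is affine in concentration at fixed dose, and the
interpolated curve is the geometric interpolation of the endpoint curves:
``SF(C, D) = SF_U(D)**(1-t) * SF_total(C0, D)**t`` with ``t = C/C0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import (
    CoefficientClampWarning,
    ConfigurationError,
    DomainError,
    DoseRangeWarning,
    ExtrapolationError,
    ExtrapolationWarning,
)

__all__ = [
    "LQ_DOSE_VALIDITY_GY",
    "LQParameters",
    "InterpolationModel",
    "SurvivalPrediction",
    "survival_fraction",
    "mean_lethal_lesions",
    "survival_from_lesions",
    "np_lesion_contribution",
    "interpolate_parameters",
    "predict_survival",
    "interpolated_sf",
]

#: Dose range (Gy) over which the linear-quadratic response is considered
#: valid; evaluation outside it is allowed but triggers a warning.
LQ_DOSE_VALIDITY_GY = (1.0, 6.0)


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic radiosensitivity parameters for one condition.

    Parameters
    ----------
    alpha : float
        Linear coefficient (Gy^-1); must be non-negative.
    beta : float
        Quadratic coefficient (Gy^-2); must be non-negative.
    alpha_se, beta_se : float, optional
        Standard errors of the coefficients (same units).
    spectrum_label : str
        Free-text beam-quality label, e.g. ``"100 kVp"``.
    concentration : float
        Nanoparticle concentration of the condition (study units, e.g.
        mMol/L); non-negative.
    """

    alpha: float
    beta: float
    alpha_se: Optional[float] = None
    beta_se: Optional[float] = None
    spectrum_label: str = ""
    concentration: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0.0:
                raise DomainError(
                    f"{name} must be finite and >= 0, got {value!r} "
                    f"(positivity restriction of the LQ fit)"
                )
        for name in ("alpha_se", "beta_se"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0.0):
                raise DomainError(f"{name} must be finite and >= 0, got {value!r}")
        if not math.isfinite(self.concentration) or self.concentration < 0.0:
            raise DomainError(
                f"concentration must be finite and >= 0, got {self.concentration!r}"
            )

    def mean_lesions(self, dose):
        """Mean lethal-lesion count ``alpha*D + beta*D^2`` (no warnings)."""
        dose = _check_dose(dose)
        return self.alpha * dose + self.beta * dose * dose


@dataclass(frozen=True)
class InterpolationModel:
    """Paired undoped / doped-at-C0 LQ parameters for one photon spectrum.

    The two endpoints fully determine the concentration interpolation;
    ``delta_alpha`` and ``delta_beta`` are always recomputed from them.
    """

    params_undoped: LQParameters
    params_reference: LQParameters

    def __post_init__(self) -> None:
        if self.params_undoped.concentration != 0.0:
            raise ConfigurationError(
                "params_undoped must have concentration 0, got "
                f"{self.params_undoped.concentration!r}"
            )
        if self.params_reference.concentration <= 0.0:
            raise ConfigurationError(
                "reference concentration C0 must be > 0, got "
                f"{self.params_reference.concentration!r}"
            )
        if self.params_undoped.spectrum_label != self.params_reference.spectrum_label:
            raise ConfigurationError(
                "spectrum labels differ between endpoints: "
                f"{self.params_undoped.spectrum_label!r} vs "
                f"{self.params_reference.spectrum_label!r}"
            )

    @property
    def spectrum_label(self) -> str:
        return self.params_undoped.spectrum_label

    @property
    def c0(self) -> float:
        """Reference concentration C0 (> 0)."""
        return self.params_reference.concentration

    @property
    def delta_alpha(self) -> float:
        """alpha_total(C0) - alpha_U (Gy^-1)."""
        return self.params_reference.alpha - self.params_undoped.alpha

    @property
    def delta_beta(self) -> float:
        """beta_total(C0) - beta_U (Gy^-2)."""
        return self.params_reference.beta - self.params_undoped.beta


@dataclass(frozen=True)
class SurvivalPrediction:
    """One predicted survival-fraction point.

    ``sf_lower``/``sf_upper`` are optional first-order (delta-method)
    uncertainty bounds propagated from the endpoint standard errors.
    """

    dose: float
    concentration: float
    sf: float
    sf_lower: Optional[float] = None
    sf_upper: Optional[float] = None
    spectrum_label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.sf <= 1.0):
            raise DomainError(f"survival fraction must lie in (0, 1], got {self.sf!r}")
        for name in ("sf_lower", "sf_upper"):
            value = getattr(self, name)
            if value is not None and not (0.0 < value <= 1.0):
                raise DomainError(f"{name} must lie in (0, 1], got {value!r}")


def _check_dose(dose):
    """Validate and return dose as float or ndarray; negative dose is an error."""
    arr = np.asarray(dose, dtype=float)
    if np.any(arr < 0.0) or not np.all(np.isfinite(arr)):
        raise DomainError(f"dose must be finite and >= 0 Gy, got {dose!r}")
    if arr.ndim == 0:
        return float(arr)
    return arr


def _warn_dose_range(dose) -> None:
    lo, hi = LQ_DOSE_VALIDITY_GY
    arr = np.atleast_1d(np.asarray(dose, dtype=float))
    outside = arr[(arr < lo) | (arr > hi)]
    if outside.size:
        warnings.warn(
            f"dose value(s) outside the {lo}-{hi} Gy validity range of the "
            f"linear-quadratic model (e.g. {outside[0]:g} Gy); the result is "
            "returned unchanged",
            DoseRangeWarning,
            stacklevel=3,
        )


def survival_fraction(params: LQParameters, dose):
    """Evaluate the LQ survival fraction ``exp(-alpha*D - beta*D^2)``.

    Accepts a scalar dose or an array of doses (Gy).  Doses outside the
    1-6 Gy LQ validity range emit a :class:`DoseRangeWarning` but are
    evaluated normally (controls at 0 Gy are routine).
    """
    dose = _check_dose(dose)
    _warn_dose_range(dose)
    return np.exp(-params.mean_lesions(dose)) if np.ndim(dose) else math.exp(
        -params.mean_lesions(dose)
    )


def mean_lethal_lesions(sf):
    """Mean lethal-lesion count ``-ln(SF)`` for a survival fraction in (0, 1]."""
    arr = np.asarray(sf, dtype=float)
    if np.any(arr <= 0.0):
        raise DomainError("survival fraction must be > 0 (zero survival implies an infinite lesion count)")
    if np.any(arr > 1.0) or not np.all(np.isfinite(arr)):
        raise DomainError(f"survival fraction must lie in (0, 1], got {sf!r}")
    out = -np.log(arr)
    return float(out) if out.ndim == 0 else out


def survival_from_lesions(n):
    """Survival fraction ``exp(-n)`` for a mean lethal-lesion count ``n >= 0``."""
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 0.0) or not np.all(np.isfinite(arr)):
        raise DomainError(f"lesion count must be finite and >= 0, got {n!r}")
    out = np.exp(-arr)
    return float(out) if out.ndim == 0 else out


def _check_concentration(model: InterpolationModel, c: float, allow_extrapolation: bool) -> float:
    c = float(c)
    if not math.isfinite(c):
        raise DomainError(f"concentration must be finite, got {c!r}")
    if c < 0.0 or c > model.c0:
        if not allow_extrapolation:
            raise ExtrapolationError(
                f"concentration {c:g} outside the interpolation domain "
                f"[0, {model.c0:g}]; the lesion-scaling assumption is only "
                "supported up to the doped reference concentration "
                "(pass allow_extrapolation=True to override)"
            )
        warnings.warn(
            f"extrapolating to concentration {c:g} outside [0, {model.c0:g}]; "
            "the linear lesion-scaling assumption may fail (saturation)",
            ExtrapolationWarning,
            stacklevel=3,
        )
    return c


def np_lesion_contribution(
    model: InterpolationModel, c: float, dose, *, allow_extrapolation: bool = False
):
    """Mean lethal lesions attributable to the nanoparticles at concentration c.

    Computed as ``(c/c0) * (N_total(C0, D) - N_U(D))`` from the endpoint
    parameter sets.
    """
    c = _check_concentration(model, c, allow_extrapolation)
    dose = _check_dose(dose)
    t = c / model.c0
    return t * (
        model.params_reference.mean_lesions(dose)
        - model.params_undoped.mean_lesions(dose)
    )


def interpolate_parameters(
    model: InterpolationModel, c: float, *, allow_extrapolation: bool = False
) -> LQParameters:
    """LQ parameters at concentration ``c`` via linear lesion scaling.

    Returns ``(alpha_U + t*delta_alpha, beta_U + t*delta_beta)`` with
    ``t = c/c0``.  The endpoints are returned exactly (bitwise) at ``c = 0``
    and ``c = c0``.  A coefficient that would come out negative (possible
    only when an endpoint difference is negative, i.e. an apparently
    protective particle) is clamped to zero with a warning, mirroring the
    positivity restriction of the fits.

    Endpoint standard errors, when both present, are propagated assuming
    independent endpoint fits: ``se(c)^2 = (1-t)^2 se_U^2 + t^2 se_C0^2``.
    """
    c = _check_concentration(model, c, allow_extrapolation)
    if c == 0.0:
        return model.params_undoped
    if c == model.c0:
        return model.params_reference

    t = c / model.c0
    alpha = model.params_undoped.alpha + t * model.delta_alpha
    beta = model.params_undoped.beta + t * model.delta_beta
    for name, value in (("alpha", alpha), ("beta", beta)):
        if value < 0.0:
            warnings.warn(
                f"interpolated {name} = {value:.3g} at c = {c:g} is negative; "
                "clamped to 0 (positivity restriction)",
                CoefficientClampWarning,
                stacklevel=2,
            )
    alpha = max(alpha, 0.0)
    beta = max(beta, 0.0)

    alpha_se = beta_se = None
    u, r = model.params_undoped, model.params_reference
    if u.alpha_se is not None and r.alpha_se is not None:
        alpha_se = math.hypot((1.0 - t) * u.alpha_se, t * r.alpha_se)
    if u.beta_se is not None and r.beta_se is not None:
        beta_se = math.hypot((1.0 - t) * u.beta_se, t * r.beta_se)

    return LQParameters(
        alpha=alpha,
        beta=beta,
        alpha_se=alpha_se,
        beta_se=beta_se,
        spectrum_label=model.spectrum_label,
        concentration=c,
    )


def predict_survival(
    model: InterpolationModel,
    c: float,
    dose: float,
    *,
    allow_extrapolation: bool = False,
) -> SurvivalPrediction:
    """Predicted survival fraction at concentration ``c`` and dose ``D`` (Gy).

    Numerically identical to evaluating the LQ response with the
    interpolated parameters; algebraically the geometric interpolation
    ``SF_U^(1-t) * SF_total^t`` of the endpoint curves.  When both endpoint
    parameter sets carry standard errors, first-order bounds on SF are
    attached (one-sigma, via ``var(ln SF) = D^2 var(alpha) + D^4 var(beta)``).
    """
    params = interpolate_parameters(model, c, allow_extrapolation=allow_extrapolation)
    dose = _check_dose(float(dose))
    _warn_dose_range(dose)
    n = params.mean_lesions(dose)
    sf = math.exp(-n)

    lower = upper = None
    if params.alpha_se is not None and params.beta_se is not None:
        sd_n = math.hypot(dose * params.alpha_se, dose * dose * params.beta_se)
        lower = math.exp(-(n + sd_n))
        upper = min(1.0, math.exp(-(n - sd_n)))
    return SurvivalPrediction(
        dose=dose,
        concentration=c,
        sf=sf,
        sf_lower=lower,
        sf_upper=upper,
        spectrum_label=model.spectrum_label,
    )


def interpolated_sf(
    model: InterpolationModel, c: float, doses, *, allow_extrapolation: bool = False
) -> np.ndarray:
    """Vectorised interpolated survival fractions over a dose grid (Gy).

    Same mathematics as :func:`predict_survival`, without per-point
    prediction objects or dose-range warnings; intended for grid
    evaluation (plots, diagnostics, simulation means).
    """
    params = interpolate_parameters(model, c, allow_extrapolation=allow_extrapolation)
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    if np.any(doses < 0.0):
        raise DomainError("dose must be >= 0 Gy")
    return np.exp(-params.mean_lesions(doses))


def prediction_to_dict(pred: SurvivalPrediction) -> dict:
    """Plain-dict form of a prediction (JSON/CSV friendly)."""
    return {
        "spectrum_label": pred.spectrum_label,
        "concentration": pred.concentration,
        "dose_gy": pred.dose,
        "sf": pred.sf,
        "sf_lower": pred.sf_lower,
        "sf_upper": pred.sf_upper,
    }


def _replace_params(params: LQParameters, **kwargs) -> LQParameters:
    return replace(params, **kwargs)
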