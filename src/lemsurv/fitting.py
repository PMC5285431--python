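"""Constrained least-squares estimation of linear-quadratic parameters.

The fitting protocol mirrors how published clonogenic survival curves are
reduced to (alpha, beta) pairs: least-squares regression with both
coefficients restricted to non-negative values.

Default fit space is log-survival, where the LQ model is linear in the
parameters,

    -ln SF_i ~ alpha * D_i + beta * D_i**2,

and the positivity restriction makes the problem a textbook non-negative
least squares (NNLS).  There is no intercept: SF(0) = 1 by construction, so
the D = 0 control contributes a zero design row and is excluded from the
regression.  An alternative fit space ("sf") minimises residuals on the
survival-fraction scale directly with box constraints.

Parameter uncertainty comes either from the analytic linear-model
covariance in the fitting space, or (default) from a residual-resampling
bootstrap refit with the same constraints.  Bootstrap resampling uses
leverage-adjusted, centred residuals — with only a handful of design
points, raw residuals systematically understate the noise level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.optimize

from .errors import (
    ConfigurationError,
    DataError,
    DomainError,
    InsufficientDataError,
)
from .model import LQParameters, _replace_params

__all__ = [
    "SurvivalMeasurement",
    "SurvivalCurve",
    "FitResult",
    "FitOutcome",
    "fit_lq",
    "parameter_uncertainty",
    "fit_study",
]

_KKT_TOL = 1e-8


@dataclass(frozen=True)
class SurvivalMeasurement:
    """Mean survival fraction at one dose, summarised over replicates."""

    dose: float
    sf_mean: float
    sf_sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.dose) or self.dose < 0.0:
            raise DomainError(f"dose must be finite and >= 0 Gy, got {self.dose!r}")
        if not math.isfinite(self.sf_mean):
            raise DomainError(f"sf_mean must be finite, got {self.sf_mean!r}")
        if not math.isfinite(self.sf_sd) or self.sf_sd < 0.0:
            raise DomainError(f"sf_sd must be finite and >= 0, got {self.sf_sd!r}")
        if self.n_replicates < 1:
            raise DomainError(f"n_replicates must be >= 1, got {self.n_replicates!r}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Ordered dose-response measurements for one (spectrum, concentration)."""

    spectrum_label: str
    concentration: float
    measurements: Tuple[SurvivalMeasurement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if not math.isfinite(self.concentration) or self.concentration < 0.0:
            raise DomainError(
                f"concentration must be finite and >= 0, got {self.concentration!r}"
            )
        doses = [m.dose for m in self.measurements]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise DataError(
                f"doses must be strictly increasing with no duplicates, got {doses}"
            )

    @property
    def doses(self) -> np.ndarray:
        return np.array([m.dose for m in self.measurements], dtype=float)

    @property
    def sf_means(self) -> np.ndarray:
        return np.array([m.sf_mean for m in self.measurements], dtype=float)

    @property
    def sf_sds(self) -> np.ndarray:
        return np.array([m.sf_sd for m in self.measurements], dtype=float)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a constrained LQ fit.

    ``residuals`` are observed-minus-model differences in the fitting space
    for the fitted (positive-dose) points; ``sum_sq`` is the (weighted)
    objective at the optimum.  ``covariance`` is the 2x2 parameter
    covariance in the fitting space, or ``None`` when a positivity
    constraint is active (the linear approximation breaks down at the
    boundary).  ``active_constraints`` flags (alpha, beta) clamped at zero.
    """

    params: LQParameters
    residuals: np.ndarray
    covariance: Optional[np.ndarray]
    active_constraints: Tuple[bool, bool]
    sum_sq: float
    fit_space: str
    doses: np.ndarray = field(repr=False, default=None)
    alpha_ci: Optional[Tuple[float, float]] = None
    beta_ci: Optional[Tuple[float, float]] = None
    se_method: Optional[str] = None


def _fitting_arrays(
    curve: SurvivalCurve, *, drop_nonpositive: bool
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive-dose doses, survival means and sds usable for fitting."""
    mask = curve.doses > 0.0
    doses, sf, sd = curve.doses[mask], curve.sf_means[mask], curve.sf_sds[mask]
    bad = sf <= 0.0
    if np.any(bad):
        if not drop_nonpositive:
            raise DataError(
                f"non-positive sf_mean at dose(s) {doses[bad].tolist()} Gy; "
                "drop them explicitly with drop_nonpositive=True"
            )
        warnings.warn(
            f"dropping {int(bad.sum())} point(s) with non-positive sf_mean",
            UserWarning,
            stacklevel=3,
        )
        doses, sf, sd = doses[~bad], sf[~bad], sd[~bad]
    if np.unique(doses).size < 2:
        raise InsufficientDataError(
            "at least 2 distinct strictly positive doses with sf_mean > 0 are "
            f"required to fit alpha and beta; got {np.unique(doses).size}"
        )
    return doses, sf, sd


def _weights(
    sf: np.ndarray, sd: np.ndarray, *, weighted: bool, fit_space: str
) -> np.ndarray:
    """Per-point weights; inverse variance mapped into the fitting space."""
    if not weighted:
        return np.ones_like(sf)
    if fit_space == "log":
        var = (sd / sf) ** 2  # delta method: var(ln sf) ~ sd^2 / sf^2
    else:
        var = sd**2
    var = np.maximum(var, 1e-12)  # guard zero-sd points
    return 1.0 / var


def _nnls_design(doses: np.ndarray) -> np.ndarray:
    return np.column_stack([doses, doses**2])


def _active_flags(
    coef: np.ndarray, design: np.ndarray, y: np.ndarray
) -> Tuple[bool, bool]:
    """KKT-based activity: coefficient at 0 with the gradient pushing negative."""
    grad = design.T @ (design @ coef - y)
    return tuple(bool(c <= 0.0 and g > _KKT_TOL) for c, g in zip(coef, grad))


def _log_space_fit(doses, sf, w):
    y = -np.log(sf)
    design = _nnls_design(doses)
    sw = np.sqrt(w)
    coef, _ = scipy.optimize.nnls(design * sw[:, None], y * sw)
    residuals = y - design @ coef
    sum_sq = float(np.sum(w * residuals**2))
    active = _active_flags(coef, design * sw[:, None], y * sw)
    return coef, residuals, sum_sq, active, design * sw[:, None]


def _sf_space_fit(doses, sf, w, x0):
    sw = np.sqrt(w)

    def resid(p):
        return sw * (sf - np.exp(-p[0] * doses - p[1] * doses**2))

    sol = scipy.optimize.least_squares(
        resid, x0=np.maximum(x0, 0.0), bounds=([0.0, 0.0], [np.inf, np.inf]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    coef = sol.x
    residuals = sf - np.exp(-coef[0] * doses - coef[1] * doses**2)
    sum_sq = float(np.sum(w * residuals**2))
    grad = sol.jac.T @ resid(coef)
    active = tuple(bool(c <= 1e-12 and g > _KKT_TOL) for c, g in zip(coef, grad))
    return coef, residuals, sum_sq, active, sol.jac


def _covariance(jac, residuals_w_sumsq, n, active):
    """sigma^2 * (J^T J)^-1 when both constraints are inactive and dof > 0."""
    if any(active):
        return None
    dof = n - 2
    if dof <= 0:
        return None
    sigma2 = residuals_w_sumsq / dof
    try:
        jtj_inv = scipy.linalg.inv(jac.T @ jac)
    except scipy.linalg.LinAlgError:
        return None
    return sigma2 * jtj_inv


def fit_lq(
    curve: SurvivalCurve,
    *,
    fit_space: str = "log",
    weighted: bool = False,
    drop_nonpositive: bool = False,
) -> FitResult:
    """Fit alpha and beta to one survival curve with the positivity restriction.

    Parameters
    ----------
    curve : SurvivalCurve
        Measurements for one condition; at least two distinct positive
        doses with positive mean survival are required.  Measured means
        slightly above 1 are retained (their log is negative; the
        constraint handles them) — clipping would silently bias alpha down.
    fit_space : {"log", "sf"}
        "log" (default) fits ``-ln SF`` by non-negative least squares;
        "sf" fits survival fractions directly with box constraints.
    weighted : bool
        Inverse-variance weighting from the per-point standard deviations,
        mapped into the fitting space by the delta method; default
        unweighted.
    drop_nonpositive : bool
        Drop (with a warning) points whose mean survival is <= 0 instead
        of raising.
    """
    if fit_space not in ("log", "sf"):
        raise ConfigurationError(f"unknown fit_space {fit_space!r}; use 'log' or 'sf'")
    doses, sf, sd = _fitting_arrays(curve, drop_nonpositive=drop_nonpositive)
    w = _weights(sf, sd, weighted=weighted, fit_space=fit_space)

    coef, residuals, sum_sq, active, jac = _log_space_fit(doses, sf, w)
    if fit_space == "sf":
        w_sf = _weights(sf, sd, weighted=weighted, fit_space="sf")
        coef, residuals, sum_sq, active, jac = _sf_space_fit(doses, sf, w_sf, coef)
        w = w_sf

    params = LQParameters(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        spectrum_label=curve.spectrum_label,
        concentration=curve.concentration,
    )
    cov = _covariance(jac, sum_sq, doses.size, active)
    return FitResult(
        params=params,
        residuals=residuals,
        covariance=cov,
        active_constraints=active,
        sum_sq=sum_sq,
        fit_space=fit_space,
        doses=doses,
    )


def _nnls2_batch(design: np.ndarray, y_batch: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares for a two-column design, vectorised.

    With p = 2 the optimal active set is one of three candidates: the
    unconstrained solution (if feasible), or the best single-coefficient
    non-negative solution.  Used for bootstrap refits; agreement with
    ``scipy.optimize.nnls`` is covered by tests.

    Parameters
    ----------
    design : (n, 2) array
    y_batch : (B, n) array of response vectors

    Returns
    -------
    (B, 2) array of non-negative solutions.
    """
    gram = design.T @ design  # 2x2
    xty = y_batch @ design  # (B, 2)
    det = gram[0, 0] * gram[1, 1] - gram[0, 1] ** 2
    out = np.empty_like(xty)
    # unconstrained solution
    out[:, 0] = (gram[1, 1] * xty[:, 0] - gram[0, 1] * xty[:, 1]) / det
    out[:, 1] = (gram[0, 0] * xty[:, 1] - gram[0, 1] * xty[:, 0]) / det
    infeasible = (out[:, 0] < 0.0) | (out[:, 1] < 0.0)
    if np.any(infeasible):
        b1 = np.maximum(xty[infeasible, 0] / gram[0, 0], 0.0)
        b2 = np.maximum(xty[infeasible, 1] / gram[1, 1], 0.0)
        # objective difference (constant term dropped): b^2 * G_jj - 2 b * xty_j
        f1 = b1**2 * gram[0, 0] - 2.0 * b1 * xty[infeasible, 0]
        f2 = b2**2 * gram[1, 1] - 2.0 * b2 * xty[infeasible, 1]
        pick1 = f1 <= f2
        sub = np.zeros((int(infeasible.sum()), 2))
        sub[pick1, 0] = b1[pick1]
        sub[~pick1, 1] = b2[~pick1]
        out[infeasible] = sub
    return out


def _leverage_adjusted_residuals(residuals: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Centre residuals after inflating by 1/sqrt(1 - h_i) (hat leverages)."""
    gram_inv = scipy.linalg.pinv(design.T @ design)
    h = np.einsum("ij,jk,ik->i", design, gram_inv, design)
    h = np.clip(h, 0.0, 0.99)
    adj = residuals / np.sqrt(1.0 - h)
    centred = adj - adj.mean()
    if adj.size > 1:  # restore the variance removed by centring
        centred *= math.sqrt(adj.size / (adj.size - 1.0))
    return centred


def parameter_uncertainty(
    fit: FitResult,
    curve: SurvivalCurve,
    *,
    method: str = "bootstrap",
    b: int = 2000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> FitResult:
    """Attach standard errors (and bootstrap CIs) to a fit.

    method "analytic": linear-model covariance in the fitting space;
    standard errors are reported as absent when a positivity constraint is
    active (the quadratic approximation does not hold on the boundary) —
    never silently as zero.

    method "bootstrap" (default): residual-resampling bootstrap with
    ``b`` refits under the same constraints; standard errors from the
    bootstrap distribution and percentile confidence intervals at
    ``level``.  Deterministic given ``seed`` (required).
    """
    if method == "analytic":
        if fit.covariance is None:
            se_a = se_b = None
        else:
            se_a = float(math.sqrt(max(fit.covariance[0, 0], 0.0)))
            se_b = float(math.sqrt(max(fit.covariance[1, 1], 0.0)))
        params = _replace_params(fit.params, alpha_se=se_a, beta_se=se_b)
        return replace(fit, params=params, se_method="analytic")

    if method != "bootstrap":
        raise ConfigurationError(
            f"unknown uncertainty method {method!r}; use 'analytic' or 'bootstrap'"
        )
    if seed is None:
        raise ConfigurationError("bootstrap uncertainty requires an explicit seed")
    if fit.fit_space != "log":
        # refit in log space for the resampling engine; sf-space bootstrap
        # would need a nonlinear refit per replicate.
        base = fit_lq(curve, fit_space="log")
        base = parameter_uncertainty(
            base, curve, method="bootstrap", b=b, seed=seed, level=level
        )
        params = _replace_params(
            fit.params, alpha_se=base.params.alpha_se, beta_se=base.params.beta_se
        )
        return replace(
            fit,
            params=params,
            alpha_ci=base.alpha_ci,
            beta_ci=base.beta_ci,
            se_method="bootstrap(log)",
        )

    rng = np.random.default_rng(seed)
    design = _nnls_design(fit.doses)
    coef = np.array([fit.params.alpha, fit.params.beta])
    fitted = design @ coef
    pool = _leverage_adjusted_residuals(fit.residuals, design)
    n = pool.size
    idx = rng.integers(0, n, size=(b, n))
    y_star = fitted[None, :] + pool[idx]
    boot = _nnls2_batch(design, y_star)  # constrained refits -> reported SEs

    se_a = float(np.std(boot[:, 0], ddof=1))
    se_b = float(np.std(boot[:, 1], ddof=1))

    # Studentised (bootstrap-t) intervals.  With a handful of design points
    # percentile intervals undercover (the residual-scale estimate is itself
    # noisy); studentising restores calibration (Davison & Hinkley).  The
    # pivot is built from the *unconstrained* linear refits: clamping the
    # resampled estimates at zero would truncate the pivot's tails whenever
    # the estimate sits within a few SEs of the boundary, cutting the upper
    # bound exactly in the studies that need it.  The interval is intersected
    # with the non-negative parameter space at the end.
    gram = design.T @ design
    gram_inv = scipy.linalg.pinv(gram)
    diag = np.sqrt(np.maximum(np.diag(gram_inv), 0.0))
    h = np.clip(np.einsum("ij,jk,ik->i", design, gram_inv, design), 0.0, 0.99)

    y_orig = fitted + fit.residuals
    coef_u = gram_inv @ (design.T @ y_orig)  # unconstrained original estimate
    pool_u = _leverage_adjusted_residuals(y_orig - design @ coef_u, design)
    sigma_hat = math.sqrt(float(np.mean(pool_u**2)))
    se_hat = sigma_hat * diag  # (2,)

    y_star_u = (design @ coef_u)[None, :] + pool_u[idx]
    boot_u = y_star_u @ (gram_inv @ design.T).T  # (b, 2) unconstrained refits
    resid_star = y_star_u - boot_u @ design.T  # (b, n)
    sigma_star = np.sqrt(np.mean(resid_star**2 / (1.0 - h)[None, :], axis=1))
    se_star = sigma_star[:, None] * diag[None, :]  # (b, 2)
    lo_q, hi_q = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    cis = []
    for j in range(2):
        if se_hat[j] == 0.0:
            cis.append((float(coef[j]), float(coef[j])))
            continue
        ok = se_star[:, j] > 0.0
        t_star = (boot_u[ok, j] - coef_u[j]) / se_star[ok, j]
        t_lo, t_hi = np.quantile(t_star, [lo_q, hi_q])
        cis.append(
            (
                max(0.0, float(coef_u[j] - t_hi * se_hat[j])),
                max(0.0, float(coef_u[j] - t_lo * se_hat[j])),
            )
        )

    params = _replace_params(fit.params, alpha_se=se_a, beta_se=se_b)
    return replace(
        fit,
        params=params,
        alpha_ci=cis[0],
        beta_ci=cis[1],
        se_method="bootstrap",
    )


@dataclass(frozen=True)
class FitOutcome:
    """Per-curve entry of a batch fit: either a result or an error message."""

    spectrum_label: str
    concentration: float
    result: Optional[FitResult]
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.result is not None


def fit_study(curves: Iterable[SurvivalCurve], **options) -> List[FitOutcome]:
    """Fit every curve of a study; failures are reported per curve.

    Returns one :class:`FitOutcome` per input curve, in input order.  An
    empty input yields an empty list with a warning.
    """
    curves = list(curves)
    if not curves:
        warnings.warn("fit_study called with no curves", UserWarning, stacklevel=2)
        return []
    outcomes: List[FitOutcome] = []
    for curve in curves:
        try:
            result = fit_lq(curve, **options)
            outcomes.append(
                FitOutcome(curve.spectrum_label, curve.concentration, result)
            )
        except (DataError, InsufficientDataError, DomainError) as exc:
            outcomes.append(
                FitOutcome(curve.spectrum_label, curve.concentration, None, str(exc))
            )
    return outcomes
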