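"""CSV/JSON readers and writers for survival tables, fits and predictions.

Survival tables travel as CSV with columns ``spectrum_label,
concentration, dose_gy, sf_mean, sf_sd, n_replicates`` (case-insensitive,
any order); fitted parameters and ground truth travel as schema-versioned
JSON.  All numeric round trips are full precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DataError, NoDataError, SchemaError
from .fitting import FitResult, SurvivalCurve, SurvivalMeasurement
from .model import InterpolationModel, LQParameters, SurvivalPrediction
from .simulate import AssayDesign, GroundTruth

__all__ = [
    "FitRecord",
    "read_survival_csv",
    "write_survival_csv",
    "write_fits_json",
    "read_fits_json",
    "write_predictions_csv",
    "read_predictions_csv",
    "write_truth_json",
    "read_truth_json",
    "read_design_json",
    "write_design_json",
]

FITS_SCHEMA_VERSION = 1
SURVIVAL_COLUMNS = (
    "spectrum_label",
    "concentration",
    "dose_gy",
    "sf_mean",
    "sf_sd",
    "n_replicates",
)


@dataclasses.dataclass(frozen=True)
class FitRecord:
    """Flat, serialisable view of one fitted (or interpolated) parameter set."""

    spectrum_label: str
    concentration: float
    alpha: float
    beta: float
    alpha_se: Optional[float] = None
    beta_se: Optional[float] = None
    fit_space: Optional[str] = None
    active_alpha: bool = False
    active_beta: bool = False
    sum_sq: Optional[float] = None

    @classmethod
    def from_fit(cls, fit: FitResult) -> "FitRecord":
        p = fit.params
        return cls(
            spectrum_label=p.spectrum_label,
            concentration=p.concentration,
            alpha=p.alpha,
            beta=p.beta,
            alpha_se=p.alpha_se,
            beta_se=p.beta_se,
            fit_space=fit.fit_space,
            active_alpha=fit.active_constraints[0],
            active_beta=fit.active_constraints[1],
            sum_sq=fit.sum_sq,
        )

    @classmethod
    def from_params(cls, params: LQParameters, **extra) -> "FitRecord":
        return cls(
            spectrum_label=params.spectrum_label,
            concentration=params.concentration,
            alpha=params.alpha,
            beta=params.beta,
            alpha_se=params.alpha_se,
            beta_se=params.beta_se,
            **extra,
        )

    def to_params(self) -> LQParameters:
        return LQParameters(
            alpha=self.alpha,
            beta=self.beta,
            alpha_se=self.alpha_se,
            beta_se=self.beta_se,
            spectrum_label=self.spectrum_label,
            concentration=self.concentration,
        )


def read_survival_csv(path: Union[str, Path]) -> List[SurvivalCurve]:
    """Read a survival table, grouped into curves sorted by dose.

    Validation errors carry 1-based data row numbers (header excluded).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise NoDataError(f"{path}: file is empty") from None
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in SURVIVAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if frame.empty:
        raise NoDataError(f"{path}: no data rows")

    # float() (not pd.to_numeric) so values round-trip to the exact double
    numeric = {}
    for col in ("concentration", "dose_gy", "sf_mean", "sf_sd"):
        values = []
        for row, raw in enumerate(frame[col]):
            try:
                values.append(float(raw))
            except (TypeError, ValueError):
                raise DataError(
                    f"{path}: unparseable {col} value {raw!r} in data row {row + 1}"
                ) from None
        numeric[col] = np.asarray(values)
    reps = []
    for row, raw in enumerate(frame["n_replicates"]):
        try:
            reps.append(int(float(raw)))
        except (TypeError, ValueError):
            raise DataError(
                f"{path}: unparseable n_replicates value {raw!r} in data row {row + 1}"
            ) from None

    keys = list(
        zip(frame["spectrum_label"].astype(str), numeric["concentration"],
            numeric["dose_gy"])
    )
    seen: Dict[tuple, int] = {}
    for row, key in enumerate(keys):
        if key in seen:
            raise DataError(
                f"{path}: duplicate (spectrum, concentration, dose) "
                f"{key} in data rows {seen[key] + 1} and {row + 1}"
            )
        seen[key] = row

    curves: Dict[tuple, List[SurvivalMeasurement]] = {}
    order: List[tuple] = []
    for row in range(len(frame)):
        key = (str(frame["spectrum_label"].iloc[row]), numeric["concentration"][row])
        if key not in curves:
            curves[key] = []
            order.append(key)
        try:
            curves[key].append(
                SurvivalMeasurement(
                    dose=float(numeric["dose_gy"][row]),
                    sf_mean=float(numeric["sf_mean"][row]),
                    sf_sd=float(numeric["sf_sd"][row]),
                    n_replicates=reps[row],
                )
            )
        except Exception as exc:
            raise DataError(f"{path}: data row {row + 1}: {exc}") from exc

    out = []
    for key in order:
        measurements = sorted(curves[key], key=lambda m: m.dose)
        out.append(
            SurvivalCurve(
                spectrum_label=key[0],
                concentration=key[1],
                measurements=tuple(measurements),
            )
        )
    return out


def write_survival_csv(curves: Iterable[SurvivalCurve], path: Union[str, Path]) -> None:
    """Write curves in the standard survival-table schema, full precision."""
    rows = [
        {
            "spectrum_label": c.spectrum_label,
            "concentration": c.concentration,
            "dose_gy": m.dose,
            "sf_mean": m.sf_mean,
            "sf_sd": m.sf_sd,
            "n_replicates": m.n_replicates,
        }
        for c in curves
        for m in c.measurements
    ]
    pd.DataFrame(rows, columns=list(SURVIVAL_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def _record_to_json(record: FitRecord) -> dict:
    out = dataclasses.asdict(record)
    return {k: v for k, v in out.items() if v is not None}


def write_fits_json(
    fits: Sequence[Union[FitRecord, FitResult]], path: Union[str, Path]
) -> None:
    """Write fit records as schema-versioned JSON (lossless round trip)."""
    records = [
        f if isinstance(f, FitRecord) else FitRecord.from_fit(f) for f in fits
    ]
    payload = {
        "schema": "lemsurv-fits",
        "version": FITS_SCHEMA_VERSION,
        "fits": [_record_to_json(r) for r in records],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fits_json(path: Union[str, Path]) -> List[FitRecord]:
    path = Path(path)
    payload = json.loads(path.read_text())
    version = payload.get("version")
    if version != FITS_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: fits schema version {version!r} is not supported "
            f"(expected {FITS_SCHEMA_VERSION}); re-export the file"
        )
    return [FitRecord(**entry) for entry in payload.get("fits", [])]


def write_predictions_csv(
    predictions: Sequence[SurvivalPrediction], path: Union[str, Path]
) -> None:
    rows = [
        {
            "spectrum_label": p.spectrum_label,
            "concentration": p.concentration,
            "dose_gy": p.dose,
            "sf": p.sf,
            "sf_lower": p.sf_lower if p.sf_lower is not None else np.nan,
            "sf_upper": p.sf_upper if p.sf_upper is not None else np.nan,
        }
        for p in predictions
    ]
    pd.DataFrame(
        rows,
        columns=["spectrum_label", "concentration", "dose_gy", "sf", "sf_lower", "sf_upper"],
    ).to_csv(path, index=False, float_format="%.17g")


def read_predictions_csv(path: Union[str, Path]) -> List[SurvivalPrediction]:
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"spectrum_label", "concentration", "dose_gy", "sf"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        lower = row.get("sf_lower")
        upper = row.get("sf_upper")
        out.append(
            SurvivalPrediction(
                dose=float(row["dose_gy"]),
                concentration=float(row["concentration"]),
                sf=float(row["sf"]),
                sf_lower=None if pd.isna(lower) else float(lower),
                sf_upper=None if pd.isna(upper) else float(upper),
                spectrum_label=str(row["spectrum_label"]),
            )
        )
    return out


def _params_to_json(p: LQParameters) -> dict:
    out = {
        "alpha": p.alpha,
        "beta": p.beta,
        "spectrum_label": p.spectrum_label,
        "concentration": p.concentration,
    }
    if p.alpha_se is not None:
        out["alpha_se"] = p.alpha_se
    if p.beta_se is not None:
        out["beta_se"] = p.beta_se
    return out


def write_truth_json(truth: GroundTruth, path: Union[str, Path]) -> None:
    payload = {
        "schema": "lemsurv-truth",
        "version": 1,
        "models": [
            {
                "spectrum_label": label,
                "c0": model.c0,
                "undoped": _params_to_json(model.params_undoped),
                "reference": _params_to_json(model.params_reference),
            }
            for label, model in sorted(truth.models.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth_json(path: Union[str, Path]) -> GroundTruth:
    path = Path(path)
    payload = json.loads(path.read_text())
    if payload.get("version") != 1:
        raise SchemaError(f"{path}: unsupported truth schema version")
    models = {}
    for entry in payload["models"]:
        models[entry["spectrum_label"]] = InterpolationModel(
            params_undoped=LQParameters(**entry["undoped"]),
            params_reference=LQParameters(**entry["reference"]),
        )
    return GroundTruth(models)


def write_design_json(design: AssayDesign, path: Union[str, Path]) -> None:
    payload = {"schema": "lemsurv-design", "version": 1}
    payload.update(dataclasses.asdict(design))
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_design_json(path: Union[str, Path]) -> AssayDesign:
    path = Path(path)
    payload = json.loads(path.read_text())
    if payload.get("version") not in (None, 1):
        raise SchemaError(f"{path}: unsupported design schema version")
    payload.pop("schema", None)
    payload.pop("version", None)
    valid = {f.name for f in dataclasses.fields(AssayDesign)}
    unknown = set(payload) - valid
    if unknown:
        raise SchemaError(f"{path}: unknown design field(s) {sorted(unknown)}")
    return AssayDesign(**payload)
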