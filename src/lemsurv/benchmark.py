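"""Reference LQ parameters of the kilovoltage AuNP/BAEC benchmark study.

Published linear-quadratic fits for bovine aortic endothelial cells doped
with 1.9 nm gold nanoparticles (0 and 1.0 mMol/L) and irradiated with
80, 100 and 150 kVp superficial X-ray spectra.  Each curve was fitted by
least-squares regression with alpha and beta restricted to positive
values; the quoted +/- values are carried as standard errors.

These six parameter sets are the standard endpoint inputs for the
interpolation examples, the synthetic-data generator's default ground
truth, and the test suite.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .model import InterpolationModel, LQParameters

__all__ = [
    "REFERENCE_CONCENTRATION_MMOL_L",
    "benchmark_parameters",
    "benchmark_models",
]

#: Highest doped concentration with measured survival data (mMol/L); the
#: interpolation domain is [0, this value].
REFERENCE_CONCENTRATION_MMOL_L = 1.0

_TABLE = (
    # (spectrum, concentration, alpha, alpha_se, beta, beta_se)
    ("80 kVp", 0.0, 0.00, 1.66e-2, 1.96e-2, 4.36e-3),
    ("80 kVp", 1.0, 1.58e-2, 4.64e-2, 8.10e-2, 1.67e-2),
    ("100 kVp", 0.0, 2.52e-2, 3.69e-3, 1.30e-3, 9.39e-4),
    ("100 kVp", 1.0, 3.47e-2, 3.36e-3, 9.04e-3, 9.64e-4),
    ("150 kVp", 0.0, 0.00, 3.95e-3, 7.14e-3, 1.08e-3),
    ("150 kVp", 1.0, 2.03e-2, 4.44e-3, 1.34e-2, 1.26e-3),
)


def benchmark_parameters() -> Tuple[LQParameters, ...]:
    """The six published endpoint LQ parameter sets (three spectra x two concentrations)."""
    return tuple(
        LQParameters(
            alpha=alpha,
            beta=beta,
            alpha_se=alpha_se,
            beta_se=beta_se,
            spectrum_label=spectrum,
            concentration=concentration,
        )
        for spectrum, concentration, alpha, alpha_se, beta, beta_se in _TABLE
    )


def benchmark_models() -> Dict[str, InterpolationModel]:
    """One :class:`InterpolationModel` per spectrum, keyed by spectrum label."""
    params = benchmark_parameters()
    by_spectrum: Dict[str, dict] = {}
    for p in params:
        slot = by_spectrum.setdefault(p.spectrum_label, {})
        slot["reference" if p.concentration > 0 else "undoped"] = p
    return {
        label: InterpolationModel(
            params_undoped=slot["undoped"], params_reference=slot["reference"]
        )
        for label, slot in by_spectrum.items()
    }
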