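"""Method-validation statistics: precision, CV and signal-to-noise LOD/LOQ.

Precision follows the usual pharmacopoeial layout: repeatability is the
pooled within-run (intra-assay) coefficient of variation, reproducibility
the between-run CV of run means; both are also reported as the percentage
scores 100 − CV that quality-control reports print.  Detection limits come
from the signal-to-noise route, LOD = 3·sigma/slope and LOQ = 10·sigma/slope
with sigma the noise estimate in the response units of the calibration
slope, so LOD = 0.3·LOQ by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .calibration import LinearFit
from .chromatogram import Chromatogram, baseline_correct
from .errors import DomainError, InsufficientDesignError

__all__ = [
    "PrecisionReport",
    "SensitivityReport",
    "cv",
    "precision",
    "lod_loq",
    "blank_noise_sd",
]

LOD_FACTOR = 3.0
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class PrecisionReport:
    """Intra-/inter-run precision of repeated injections."""

    cv_intra: float  # pooled within-run CV, %
    cv_inter: float | None  # CV of run means, %; None for a single run
    repeatability_pct: float  # 100 - cv_intra
    reproducibility_pct: float | None  # 100 - cv_inter
    n_replicates: int
    n_runs: int

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class SensitivityReport:
    """Signal-to-noise detection and quantification limits."""

    noise_sd: float  # response units (same units as the curve's y)
    slope: float  # response per mg/L
    lod: float  # mg/L
    loq: float  # mg/L

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2)


def cv(values) -> float:
    """Coefficient of variation, % : 100·s/mean with the sample (n−1) SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("CV needs at least two values")
    mean = x.mean()
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def precision(replicates_by_run) -> PrecisionReport:
    """Precision report from replicate measurements grouped by run.

    ``replicates_by_run`` is a mapping run-label -> values, or a sequence of
    per-run value sequences.  The pooled intra-run CV uses the
    degrees-of-freedom-weighted pooled within-run variance over the grand
    mean; the inter-run CV is the CV of the run means and needs >= 2 runs
    (``cv_inter`` is None otherwise).
    """
    if hasattr(replicates_by_run, "values"):
        runs = [np.asarray(v, dtype=float) for v in replicates_by_run.values()]
    else:
        runs = [np.asarray(v, dtype=float) for v in replicates_by_run]
    if not runs:
        raise InsufficientDesignError("no runs provided")
    if any(r.size < 2 for r in runs):
        raise InsufficientDesignError("repeatability needs >= 2 replicates per run")

    grand_mean = float(np.concatenate(runs).mean())
    if grand_mean == 0:
        raise DomainError("CV undefined for zero grand mean")
    dof = sum(r.size - 1 for r in runs)
    pooled_var = sum((r.size - 1) * r.var(ddof=1) for r in runs) / dof
    cv_intra = 100.0 * math.sqrt(pooled_var) / grand_mean

    if len(runs) >= 2:
        cv_inter = cv([r.mean() for r in runs])
        reproducibility = 100.0 - cv_inter
    else:
        cv_inter = None
        reproducibility = None
    return PrecisionReport(
        cv_intra=cv_intra,
        cv_inter=cv_inter,
        repeatability_pct=100.0 - cv_intra,
        reproducibility_pct=reproducibility,
        n_replicates=sum(r.size for r in runs),
        n_runs=len(runs),
    )


def lod_loq(noise_sd: float, fit: LinearFit) -> SensitivityReport:
    """Detection/quantification limits from a noise estimate and a calibration.

    ``noise_sd`` must be expressed in the same response units as the
    concentration curve's y (peak area); see :func:`blank_noise_sd` for a
    blank-window estimate and its area-equivalent conversion.
    """
    if fit.curve_kind != "concentration":
        raise DomainError("LOD/LOQ need a concentration calibration curve")
    if fit.slope <= 0:
        raise DomainError("calibration slope must be positive")
    if noise_sd < 0:
        raise DomainError("noise SD must be non-negative")
    return SensitivityReport(
        noise_sd=float(noise_sd),
        slope=fit.slope,
        lod=LOD_FACTOR * noise_sd / fit.slope,
        loq=LOQ_FACTOR * noise_sd / fit.slope,
    )


def blank_noise_sd(
    chrom: Chromatogram,
    window: tuple[float, float],
    peak_width_min: float | None = None,
) -> float:
    """Noise estimate from a signal-free (blank) region of the trace.

    The window is baseline-corrected with its own endpoints and the sample
    standard deviation of the residual signal inside it is returned.  With
    ``peak_width_min`` the signal-unit SD is converted to an area-equivalent
    (SD × width), matching the units of a peak-area calibration; without it
    the raw signal-unit SD is returned and the caller owns the unit match.
    """
    corrected = baseline_correct(chrom, window)
    mask = (corrected.time >= window[0]) & (corrected.time <= window[1])
    if mask.sum() < 3:
        raise DomainError("blank window contains too few samples")
    sd = float(corrected.signal[mask].std(ddof=1))
    return sd * peak_width_min if peak_width_min is not None else sd
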