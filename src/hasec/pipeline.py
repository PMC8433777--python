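"""Run configuration and the assembled analysis workflows.

Ties the stages into the method's workflow: calibrate (concentration and MW
curves) → analyze a sample chromatogram (baseline → peak → concentration →
DP slicing → distribution moments) → validate the method (linearity,
precision, LOD/LOQ) → spike recovery.  Each workflow is a plain function
over the library types; the CLI in :mod:`hasec.cli` is a thin wrapper.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mwd
from .calibration import (
    LinearFit,
    fit_concentration_curve,
    fit_mw_curve,
    predict_concentration,
    t_test_coefficients,
)
from .chromatogram import Chromatogram, Peak, baseline_correct, detect_main_peak
from .column import ColumnGeometry, kav
from .errors import ConfigurationError, HasecWarning
from .recovery import RecoveryResult
from .validation import PrecisionReport, SensitivityReport, lod_loq, precision

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "ValidationReport",
    "load_config",
    "fit_mw_curve_from_table",
    "select_concentration_fit",
    "analyze_sample",
    "validate_method",
    "fit_to_dict",
    "fit_from_dict",
]

CV_ACCEPTANCE_PCT = 5.0  # international acceptance: CV < 5 %


@dataclass
class RunConfig:
    """Structured run configuration (YAML/JSON), one block per stage."""

    geom: ColumnGeometry
    conc_standards_csv: str | None = None
    mw_standards_csv: str | None = None
    dp_min: int = 1
    dp_max: int = 10_000
    dp_step: int = 1
    baseline_window: tuple[float, float] | None = None
    peak_threshold_frac: float = 0.005
    blank_window: tuple[float, float] | None = None
    dilution_factor: float = 1.0
    basis: str = "mg_per_l"
    dissolved_volume_ml: float | None = None
    sample_mass_mg: float | None = None
    output_dir: str = "."
    seed: int = 0

    @property
    def dp_grid(self) -> np.ndarray:
        return np.arange(self.dp_min, self.dp_max + 1, self.dp_step)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (keys mirror the dataclass, nested blocks)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "column" not in raw:
        raise ConfigurationError("config must be a mapping with a 'column' block")
    col = raw["column"]
    try:
        geom = ColumnGeometry(
            v0_ml=col["v0_ml"],
            vt_ml=col["vt_ml"],
            flow_ml_min=col["flow_ml_min"],
            vc_ml=col.get("vc_ml"),
            t0_min=col.get("t0_min"),
            tt_min=col.get("tt_min"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"column block missing key {exc}") from exc
    cal = raw.get("calibration", {})
    dp = raw.get("dp_grid", {})
    peak = raw.get("peak", {})
    sample = raw.get("sample", {})
    cfg = RunConfig(
        geom=geom,
        conc_standards_csv=cal.get("concentration_standards"),
        mw_standards_csv=cal.get("mw_standards"),
        dp_min=int(dp.get("dp_min", 1)),
        dp_max=int(dp.get("dp_max", 10_000)),
        dp_step=int(dp.get("dp_step", 1)),
        baseline_window=tuple(raw["baseline_window"]) if raw.get("baseline_window") else None,
        peak_threshold_frac=float(peak.get("threshold_frac", 0.005)),
        blank_window=tuple(raw["blank_window"]) if raw.get("blank_window") else None,
        dilution_factor=float(sample.get("dilution_factor", 1.0)),
        basis=sample.get("basis", "mg_per_l"),
        dissolved_volume_ml=sample.get("dissolved_volume_ml"),
        sample_mass_mg=sample.get("sample_mass_mg"),
        output_dir=raw.get("output_dir", "."),
        seed=int(raw.get("seed", 0)),
    )
    if cfg.dp_min < 1 or cfg.dp_max <= cfg.dp_min or cfg.dp_step < 1:
        raise ConfigurationError("dp grid must satisfy 1 <= dp_min < dp_max, step >= 1")
    return cfg


def fit_mw_curve_from_table(table: pd.DataFrame, geom: ColumnGeometry) -> LinearFit:
    """MW calibration from a standards table with ``standard_mw_da`` and
    ``kav``, ``ve_ml`` or ``tr_min`` columns (first available, in that order)."""
    mw_col = table["standard_mw_da"].to_numpy(dtype=float)
    if "kav" in table.columns:
        k = table["kav"].to_numpy(dtype=float)
    elif "ve_ml" in table.columns:
        k = np.array([kav(v, geom) for v in table["ve_ml"]])
    elif "tr_min" in table.columns:
        ve = table["tr_min"].to_numpy(dtype=float) * geom.flow_ml_min
        k = np.array([kav(v, geom) for v in ve])
    else:
        raise ConfigurationError("MW standards need a kav, ve_ml or tr_min column")
    return fit_mw_curve(list(zip(mw_col, k)))


def select_concentration_fit(
    fits_by_mw: dict[float, LinearFit], sample_avg_mw: float
) -> LinearFit:
    """Pick the concentration curve of the standard nearest the sample's MW.

    The response factor varies with standard MW, so curves are fit per
    standard and the nearest one (in ln MW) quantifies the sample.
    """
    if not fits_by_mw:
        raise ConfigurationError("no concentration curves available")
    key = min(fits_by_mw, key=lambda m: abs(np.log(m) - np.log(sample_avg_mw)))
    return fits_by_mw[key]


@dataclass
class AnalysisResult:
    """Full per-sample output of the analyze workflow."""

    summary: mwd.MWDSummary
    distribution: mwd.DPDistribution
    peak: Peak
    warnings: dict[str, int] = field(default_factory=dict)

    def write(self, outdir, stem: str = "sample") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        p = outdir / f"{stem}_summary.json"
        p.write_text(self.summary.to_json(warnings=self.warnings) + "\n")
        paths.append(p)
        p = outdir / f"{stem}_distribution.csv"
        self.distribution.to_frame().to_csv(p, index=False)
        paths.append(p)
        edges = np.unique(
            np.geomspace(
                max(1, self.distribution.dp[0]), self.distribution.dp[-1] + 1, 25
            ).astype(int)
        )
        p = outdir / f"{stem}_histogram.csv"
        self.distribution.histogram(edges).to_csv(p, index=False)
        paths.append(p)
        return paths


def analyze_sample(
    chrom: Chromatogram,
    conc_fit: LinearFit | dict[float, LinearFit],
    mw_fit: LinearFit,
    geom: ColumnGeometry,
    *,
    dp_grid=None,
    baseline_window: tuple[float, float] | None = None,
    baseline_endpoint_avg_min: float = 0.5,
    threshold_frac: float = 0.005,
    bound_smooth_min: float = 0.2,
    dilution_factor: float | None = None,
) -> AnalysisResult:
    """Run the full per-sample workflow on one chromatogram.

    Baseline-corrects (default window: the whole trace), finds the main
    peak, slices it into DP fractions, computes the distribution moments and
    the concentration from the peak area.  ``conc_fit`` may be a single
    curve or a dict keyed by standard MW, in which case the curve nearest
    the sample's peak-average MW is selected.  Warnings raised along the way
    (extrapolation, clipped areas, Kav range) are counted into the result.
    """
    window = baseline_window or (chrom.t_min, chrom.t_max)
    dilution = (
        dilution_factor
        if dilution_factor is not None
        else chrom.meta.get("dilution_factor", 1.0)
    )
    counters: dict[str, int] = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", HasecWarning)
        corrected = baseline_correct(
            chrom, window, endpoint_avg_min=baseline_endpoint_avg_min
        )
        peak = detect_main_peak(corrected, threshold_frac, smooth_min=bound_smooth_min)
        dist = mwd.differential_distribution(
            corrected, mw_fit, geom, dp_grid=dp_grid, window=(peak.t_start, peak.t_end)
        )
        mn = mwd.number_average(dist)
        mw_avg = mwd.weight_average(dist)
        peak_mw = mwd.peak_average_mw(peak, mw_fit, geom)
        if isinstance(conc_fit, dict):
            conc_fit = select_concentration_fit(conc_fit, peak_mw)
        conc = predict_concentration(peak.area, conc_fit) * dilution
    for w in caught:
        if issubclass(w.category, HasecWarning):
            name = w.category.__name__
            counters[name] = counters.get(name, 0) + 1

    summary = mwd.MWDSummary(
        mn=mn,
        mw=mw_avg,
        dispersity=mwd.dispersity(mn, mw_avg),
        dp_n=mwd.dp_n(mn),
        dp_w=mwd.dp_w(mw_avg),
        peak_avg_mw=peak_mw,
        concentration=conc,
    )
    return AnalysisResult(
        summary=summary, distribution=dist, peak=peak, warnings=counters
    )


@dataclass
class ValidationReport:
    """Linearity + precision + sensitivity with pass/fail acceptance flags."""

    linearity: dict[float, LinearFit]
    precision: PrecisionReport
    sensitivity: dict[float, SensitivityReport]
    flags: dict[str, bool]

    def to_json(self) -> str:
        payload = {
            "linearity": {
                str(mw): {**fit_to_dict(f), "t_tests": dict(
                    zip(("t_slope", "p_slope", "t_intercept", "p_intercept"),
                        t_test_coefficients(f))
                )}
                for mw, f in self.linearity.items()
            },
            "precision": json.loads(self.precision.to_json()),
            "sensitivity": {
                str(mw): json.loads(s.to_json()) for mw, s in self.sensitivity.items()
            },
            "flags": self.flags,
        }
        return json.dumps(payload, indent=2)


def validate_method(
    conc_table: pd.DataFrame,
    replicates_by_run,
    noise_sd: float,
) -> ValidationReport:
    """Method validation from calibration standards and replicate injections.

    ``conc_table`` has columns ``standard_mw_da, concentration_mg_L,
    peak_area`` (one curve fit per standard MW, as the method prescribes);
    ``replicates_by_run`` feeds :func:`hasec.validation.precision`;
    ``noise_sd`` is the blank-noise estimate in peak-area units.  Acceptance
    flags implement the CV < 5 % international criterion and slope
    significance at alpha = 0.05.
    """
    required = {"standard_mw_da", "concentration_mg_L", "peak_area"}
    if not required <= set(conc_table.columns):
        raise ConfigurationError(f"concentration table needs columns {sorted(required)}")
    fits: dict[float, LinearFit] = {}
    for mw_std, grp in conc_table.groupby("standard_mw_da"):
        fits[float(mw_std)] = fit_concentration_curve(
            list(zip(grp["concentration_mg_L"], grp["peak_area"]))
        )
    prec = precision(replicates_by_run)
    sens = {mw_std: lod_loq(noise_sd, f) for mw_std, f in fits.items()}
    slope_ps = [t_test_coefficients(f)[1] for f in fits.values()]
    flags = {
        "cv_intra_lt_5pct": prec.cv_intra < CV_ACCEPTANCE_PCT,
        "cv_inter_lt_5pct": (
            prec.cv_inter is not None and prec.cv_inter < CV_ACCEPTANCE_PCT
        ),
        "slopes_significant": all(p < 0.05 for p in slope_ps),
        "linearity_r2_ge_0_999": all(f.r2 >= 0.999 for f in fits.values()),
    }
    return ValidationReport(
        linearity=fits, precision=prec, sensitivity=sens, flags=flags
    )


def recovery_report(table: pd.DataFrame) -> list[RecoveryResult]:
    """Recovery results from a ``method,measured_mg_L,spiked_mg_L`` table."""
    required = {"measured_mg_L", "spiked_mg_L"}
    if not required <= set(table.columns):
        raise ConfigurationError(f"recovery table needs columns {sorted(required)}")
    return [
        RecoveryResult.from_measurement(row["measured_mg_L"], row["spiked_mg_L"])
        for _, row in table.iterrows()
    ]


# --- LinearFit JSON round trip -------------------------------------------

def fit_to_dict(fit: LinearFit) -> dict:
    from dataclasses import asdict

    return asdict(fit)


def fit_from_dict(d: dict) -> LinearFit:
    return LinearFit(**d)
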