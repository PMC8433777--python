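"""Synthetic SEC chromatogram generator with known ground truth.

Emulates an aqueous SEC system (Ultrahydrogel-2000-like geometry, refractive-
index detection) running polydisperse hyaluronic-acid samples:

* the sample's molecular-weight distribution is either an explicit discrete
  mixture of (MW, mass fraction) species or a log-normal (normal in ln MW)
  discretized into log-spaced species;
* each species elutes as a Gaussian centred at the retention time given by
  the true Kav–ln(MW) law through the column geometry, with a common
  instrumental broadening sigma;
* the species' peak area is mass fraction × concentration × response factor
  (RI response is mass-proportional);
* a linear baseline drift and i.i.d. Gaussian noise are added on a uniform
  sampling grid.

Every random draw flows from the single integer ``seed`` through
``numpy.random.default_rng``, so a fixed seed and spec give bit-identical
output.  Ground-truth moments are computed from the noiseless species table
with areas playing the role of the abundances n_i — the same convention the
analysis applies to measured differential areas — so simulator and analyzer
are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatogram import Chromatogram
from .column import ColumnGeometry, retention_time_from_kav
from .errors import DomainError, GenerationError, PeakPlacementWarning

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "DEFAULT_KAV_LAW",
    "DEFAULT_MW_STANDARDS",
    "DEFAULT_CONC_LEVELS",
    "simulate_chromatogram",
    "simulate_standard_sets",
    "simulate_replicates",
]

# True partition law used unless overridden: places the 0.011–2.2 MDa
# standards at Kav ~0.85–0.15 on the column.
DEFAULT_KAV_LAW = (-0.132, 2.079)

# The four HA calibration standards (Da) and the seven-level 100–1000 mg/L
# concentration design of the validated method.
DEFAULT_MW_STANDARDS = (11_000.0, 95_000.0, 1_125_000.0, 2_200_000.0)
DEFAULT_CONC_LEVELS = (100.0, 250.0, 400.0, 550.0, 700.0, 850.0, 1000.0)


@dataclass
class SimulationSpec:
    """Everything needed to generate one synthetic chromatogram.

    The molecular-weight distribution is a log-normal with mass-median
    ``median_mw`` (Da) and ``sigma_ln_mw`` (SD of ln MW), or an explicit
    ``mixture`` of (MW Da, mass fraction) pairs which takes precedence.
    ``response_factor`` is the RI peak area per mg/L of injected analyte;
    ``peak_sigma_min`` the per-species Gaussian broadening; ``noise_sd`` and
    ``drift`` the additive baseline noise SD (signal units) and linear drift
    (signal units per min).
    """

    geom: ColumnGeometry = field(
        default_factory=lambda: ColumnGeometry.ultrahydrogel_2000()
    )
    kav_slope: float = DEFAULT_KAV_LAW[0]
    kav_intercept: float = DEFAULT_KAV_LAW[1]
    median_mw: float = 900_000.0
    sigma_ln_mw: float = 0.6
    mixture: list[tuple[float, float]] | None = None
    concentration: float = 600.0  # mg/L
    response_factor: float = 190.0  # area units per mg/L
    peak_sigma_min: float = 0.05
    noise_sd: float = 400.0
    drift: float = 5.0  # signal units per min
    sampling_interval: float = 0.01  # min
    t_start_min: float = 0.0
    t_end_min: float | None = None  # default: geom.tt + 3 min
    n_species: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kav_slope >= 0:
            raise DomainError("kav law slope must be negative")
        if self.peak_sigma_min < 0 or self.noise_sd < 0:
            raise DomainError("sigma and noise_sd must be non-negative")
        if self.sampling_interval <= 0:
            raise DomainError("sampling interval must be positive")
        if self.concentration <= 0 or self.response_factor <= 0:
            raise DomainError("concentration and response factor must be positive")
        if self.mixture is not None:
            fracs = np.array([f for _, f in self.mixture], dtype=float)
            if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
                raise DomainError("mixture mass fractions must be >= 0 and sum to 1")
        elif self.median_mw <= 0 or self.sigma_ln_mw < 0:
            raise DomainError("median_mw must be > 0 and sigma_ln_mw >= 0")

    @property
    def t_end(self) -> float:
        return self.t_end_min if self.t_end_min is not None else self.geom.tt + 3.0

    def true_retention_time(self, mw):
        """Retention time of a species of mass ``mw`` under the true Kav law."""
        kav = self.kav_slope * np.log(mw) + self.kav_intercept
        return retention_time_from_kav(kav, self.geom)

    def species_table(self) -> pd.DataFrame:
        """Discrete (mw, mass_fraction, tR, area) species the trace is built from."""
        if self.mixture is not None:
            mw = np.array([m for m, _ in self.mixture], dtype=float)
            frac = np.array([f for _, f in self.mixture], dtype=float)
        elif self.sigma_ln_mw == 0:
            mw = np.array([self.median_mw])
            frac = np.array([1.0])
        else:
            mu = np.log(self.median_mw)
            ln_mw = np.linspace(
                mu - 4 * self.sigma_ln_mw, mu + 4 * self.sigma_ln_mw, self.n_species
            )
            w = np.exp(-0.5 * ((ln_mw - mu) / self.sigma_ln_mw) ** 2)
            mw = np.exp(ln_mw)
            frac = w / w.sum()
        area = frac * self.concentration * self.response_factor
        return pd.DataFrame(
            {
                "mw_da": mw,
                "mass_fraction": frac,
                "tr_min": self.true_retention_time(mw),
                "area": area,
            }
        )


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth behind one simulated chromatogram.

    Moments use the species areas as abundances (the RI/area convention of
    the analysis); ``peak_mw`` is the mass at the apex of the noiseless
    composite trace.
    """

    mn: float
    mw: float
    dispersity: float
    peak_mw: float
    concentration: float
    total_area: float
    species: pd.DataFrame


def _gaussian_profile(t, centers, areas, sigma):
    """Sum of area-normalized Gaussians; degenerates to nearest-sample spikes."""
    if sigma > 0:
        z = (t[None, :] - centers[:, None]) / sigma
        return (areas[:, None] / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * z**2)).sum(
            axis=0
        )
    # zero broadening: deposit each species' area on its nearest sample
    dt = t[1] - t[0]
    sig = np.zeros_like(t)
    idx = np.clip(np.round((centers - t[0]) / dt).astype(int), 0, t.size - 1)
    np.add.at(sig, idx, areas / dt)
    return sig


def simulate_chromatogram(spec: SimulationSpec) -> tuple[Chromatogram, GroundTruth]:
    """Generate one chromatogram and its ground truth.

    Species eluting outside the column's [t0, tT] window trigger a
    :class:`PeakPlacementWarning`; a spec whose species all miss the sampled
    trace entirely raises :class:`GenerationError`.
    """
    species = spec.species_table()
    tr = species["tr_min"].to_numpy()
    areas = species["area"].to_numpy()

    if np.all((tr < spec.t_start_min) | (tr > spec.t_end)):
        raise GenerationError("all species elute outside the sampled trace")
    outside = (tr < spec.geom.t0) | (tr > spec.geom.tt)
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} species elute outside the column window "
            f"[{spec.geom.t0:.2f}, {spec.geom.tt:.2f}] min",
            PeakPlacementWarning,
            stacklevel=2,
        )

    n = int(np.floor((spec.t_end - spec.t_start_min) / spec.sampling_interval)) + 1
    t = spec.t_start_min + spec.sampling_interval * np.arange(n)
    clean = _gaussian_profile(t, tr, areas, spec.peak_sigma_min)

    # apex of the noiseless composite, inverted through the true Kav law
    t_apex = float(t[np.argmax(clean)])
    geom = spec.geom
    kav_apex = (t_apex - geom.t0) / (geom.tt - geom.t0)
    peak_mw = float(np.exp((kav_apex - spec.kav_intercept) / spec.kav_slope))

    rng = np.random.default_rng(spec.seed)
    signal = clean + spec.drift * t + rng.normal(0.0, spec.noise_sd, size=t.size)

    m = species["mw_da"].to_numpy()
    mn_true = float(np.dot(areas, m) / areas.sum())
    mw_true = float(np.dot(areas, m * m) / np.dot(areas, m))
    truth = GroundTruth(
        mn=mn_true,
        mw=mw_true,
        dispersity=mw_true / mn_true,
        peak_mw=peak_mw,
        concentration=spec.concentration,
        total_area=float(areas.sum()),
        species=species,
    )
    meta = {
        "flow_ml_min": spec.geom.flow_ml_min,
        "dilution_factor": 1.0,
        "label": "synthetic",
    }
    return Chromatogram(t, signal, meta), truth


def simulate_standard_sets(
    spec: SimulationSpec,
    mw_standards=DEFAULT_MW_STANDARDS,
    conc_levels=DEFAULT_CONC_LEVELS,
    area_noise_sd: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Calibration inputs consistent with the spec's true laws.

    Returns ``{"concentration": ..., "mw": ...}``:

    * concentration table — one block per MW standard with columns
      ``standard_mw_da, level, concentration_mg_L, peak_area``; areas are
      ``response_factor * concentration`` plus optional Gaussian noise
      (``area_noise_sd``, area units);
    * MW table — ``standard_mw_da, kav, ve_ml, tr_min`` from the true Kav
      law, noiseless.
    """
    if len(conc_levels) < 3:
        raise DomainError("need at least 3 concentration levels")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for mw_std in mw_standards:
        for level, conc in enumerate(conc_levels, start=1):
            area = spec.response_factor * conc
            if area_noise_sd > 0:
                area += rng.normal(0.0, area_noise_sd)
            rows.append((mw_std, level, conc, area))
    conc_df = pd.DataFrame(
        rows, columns=["standard_mw_da", "level", "concentration_mg_L", "peak_area"]
    )

    mw_arr = np.asarray(mw_standards, dtype=float)
    kav = spec.kav_slope * np.log(mw_arr) + spec.kav_intercept
    ve = spec.geom.v0_ml + kav * (spec.geom.vt_ml - spec.geom.v0_ml)
    tr = retention_time_from_kav(kav, spec.geom)
    mw_df = pd.DataFrame(
        {"standard_mw_da": mw_arr, "kav": kav, "ve_ml": ve, "tr_min": tr}
    )
    return {"concentration": conc_df, "mw": mw_df}


def simulate_replicates(
    spec: SimulationSpec,
    n_runs: int,
    n_reps: int,
    cv_intra: float,
    cv_inter: float,
) -> dict[str, np.ndarray]:
    """Replicate peak-area measurements grouped by run.

    Run means are drawn around the spec's nominal area with relative SD
    ``cv_inter`` (%); replicates around their run mean with relative SD
    ``cv_intra`` (%).  Returns ``{run label: replicate array}``.
    """
    if cv_intra < 0 or cv_inter < 0:
        raise DomainError("CVs must be non-negative")
    if n_runs < 1 or n_reps < 1:
        raise DomainError("need at least one run and one replicate")
    rng = np.random.default_rng(spec.seed)
    nominal = spec.concentration * spec.response_factor
    out = {}
    for j in range(n_runs):
        run_mean = nominal * (1.0 + rng.normal(0.0, cv_inter / 100.0))
        reps = run_mean * (1.0 + rng.normal(0.0, cv_intra / 100.0, size=n_reps))
        out[f"run{j + 1}"] = reps
    return out
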