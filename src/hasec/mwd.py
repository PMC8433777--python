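"""Molecular-weight distribution by theoretical degree-of-polymerization slicing.

The chromatographic peak of a hyaluronic-acid (HA) sample is divided into
fractions, one per degree of polymerization (DP): the theoretical mass of a
DP-mer is

    M(DP) = 846.8 * DP + 18        (846.8 Da = HA disaccharide repeat,
                                    18 Da = terminal water)

and its theoretical retention time follows from the MW calibration,

    tR(DP) = Kav_theo(M(DP)) * (tT - t0) + t0 .

The differential area n_i of the trace inside fraction i's retention window
is taken as that fraction's abundance, and the distribution moments are

    Mn = sum(n_i M_i) / sum(n_i)          (number average)
    Mw = sum(n_i M_i^2) / sum(n_i M_i)    (weight average)
    D  = Mw / Mn                          (dispersity, >= 1)
    DPn = (Mn - 18) / 846.8,  DPw = (Mw - 18) / 846.8

Note the differential areas of a refractive-index detector are proportional
to mass, not molar, concentration; the moments above nevertheless use the
areas directly as the n_i, which is the convention of the method being
implemented.  The simulator's ground truth uses the same convention, so
round trips are consistent; see docs/methods.md for the caveat.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .calibration import LinearFit, kav_theoretical, mw_from_kav
from .chromatogram import Chromatogram, Peak, cumulative_area
from .column import ColumnGeometry, kav_from_time, retention_time_from_kav
from .errors import (
    CalibrationDirectionError,
    ClippedAreaWarning,
    DomainError,
    EmptyDistributionError,
)

__all__ = [
    "HA_DIMER_MW",
    "WATER_MW",
    "DPDistribution",
    "MWDSummary",
    "theoretical_mw",
    "dp_boundaries",
    "differential_distribution",
    "number_average",
    "weight_average",
    "dispersity",
    "dp_n",
    "dp_w",
    "peak_average_mw",
]

HA_DIMER_MW = 846.8  # Da, D-glucuronic acid + N-acetyl-glucosamine repeat
WATER_MW = 18.0  # Da, chain-terminating water


def theoretical_mw(dp):
    """Theoretical mass (Da) of an HA chain of ``dp`` disaccharide repeats."""
    dp_arr = np.asarray(dp)
    if np.any(dp_arr < 1):
        raise DomainError("degree of polymerization must be >= 1")
    out = HA_DIMER_MW * dp_arr + WATER_MW
    return float(out) if np.isscalar(dp) else out.astype(float)


def dp_n(mn: float) -> float:
    """Number-average DP from the number-average molecular weight (Da)."""
    if mn <= WATER_MW:
        raise DomainError(f"molecular weight must exceed {WATER_MW} Da")
    return (mn - WATER_MW) / HA_DIMER_MW


def dp_w(mw: float) -> float:
    """Weight-average DP from the weight-average molecular weight (Da)."""
    if mw <= WATER_MW:
        raise DomainError(f"molecular weight must exceed {WATER_MW} Da")
    return (mw - WATER_MW) / HA_DIMER_MW


def dispersity(mn: float, mw: float) -> float:
    """Dispersity (polydispersity index) D = Mw / Mn; 1 for a monodisperse sample."""
    if mn <= 0:
        raise DomainError("Mn must be strictly positive")
    return mw / mn


@dataclass
class DPDistribution:
    """Differential areas per DP fraction.

    ``dp`` is the (strictly increasing) DP grid; ``m_i`` the theoretical mass
    of each fraction's lower-DP edge; ``t_bounds`` the ``len(dp)+1`` fraction
    edges in retention time, strictly decreasing with DP (larger species
    elute earlier); ``n_i`` the clipped differential areas and ``n_clipped``
    how many fractions had (noise-driven) negative raw area.
    """

    dp: np.ndarray
    m_i: np.ndarray
    t_bounds: np.ndarray
    n_i: np.ndarray
    n_clipped: int = 0

    @property
    def total_area(self) -> float:
        return float(self.n_i.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per fraction with its time window and area."""
        return pd.DataFrame(
            {
                "dp": self.dp,
                "m_da": self.m_i,
                "t_start_min": self.t_bounds[1:],
                "t_end_min": self.t_bounds[:-1],
                "area": self.n_i,
            }
        )

    def histogram(self, bin_edges) -> pd.DataFrame:
        """Fractions pooled into DP bins, normalized so the areas sum to 100%."""
        total = self.total_area
        if total <= 0:
            raise EmptyDistributionError("distribution carries no area")
        idx = np.digitize(self.dp, bin_edges) - 1
        rows = []
        for b in range(len(bin_edges) - 1):
            pct = 100.0 * self.n_i[idx == b].sum() / total
            rows.append((f"{bin_edges[b]}-{bin_edges[b + 1]}", pct))
        return pd.DataFrame(rows, columns=["dp_bin", "percent"])


@dataclass
class MWDSummary:
    """Molecular-weight distribution summary for one sample."""

    mn: float
    mw: float
    dispersity: float
    dp_n: float
    dp_w: float
    peak_avg_mw: float
    concentration: float | None = None

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2)


def dp_boundaries(dp_grid, mw_fit: LinearFit, geom: ColumnGeometry) -> np.ndarray:
    """Retention-time edges of the DP fraction windows.

    Returns ``len(dp_grid) + 1`` edges: fraction i spans
    ``[tR(dp_{i+1}), tR(dp_i)]`` (one extra edge one grid step past the last
    DP), strictly decreasing with DP so the windows partition the covered
    time range with no gaps or overlaps.  Requires a negative calibration
    slope; otherwise retention would not decrease with size.
    """
    dp_grid = np.asarray(dp_grid, dtype=float)
    if dp_grid.size < 1 or np.any(np.diff(dp_grid) <= 0):
        raise DomainError("dp grid must be non-empty and strictly increasing")
    if mw_fit.slope >= 0:
        raise CalibrationDirectionError(
            "MW calibration slope must be negative (larger species elute earlier)"
        )
    step = dp_grid[-1] - dp_grid[-2] if dp_grid.size > 1 else 1.0
    edges_dp = np.append(dp_grid, dp_grid[-1] + step)
    with warnings.catch_warnings():
        # slicing deliberately spans DP 1..dp_max, beyond the standards
        warnings.simplefilter("ignore")
        kavs = kav_theoretical(theoretical_mw(edges_dp), mw_fit)
    t_edges = retention_time_from_kav(kavs, geom)
    if np.any(np.diff(t_edges) >= 0):
        raise CalibrationDirectionError("retention times are not decreasing with DP")
    return t_edges


def differential_distribution(
    chrom: Chromatogram,
    mw_fit: LinearFit,
    geom: ColumnGeometry,
    dp_grid=None,
    window: tuple[float, float] | None = None,
) -> DPDistribution:
    """Slice a baseline-corrected chromatogram into per-DP differential areas.

    Each fraction's raw area is the trapezoid integral of the trace over its
    retention window (clipped to the trace and, if given, to ``window`` —
    typically the detected peak bounds, so baseline noise outside the peak is
    excluded).  The raw areas telescope, so their sum equals the integral
    over the union window exactly; negative raw areas (baseline noise) are
    then clipped to zero with a :class:`ClippedAreaWarning` carrying the
    count.
    """
    if dp_grid is None:
        dp_grid = np.arange(1, 10_001)
    dp_grid = np.asarray(dp_grid)
    t_edges = dp_boundaries(dp_grid, mw_fit, geom)

    lo = chrom.t_min if window is None else max(window[0], chrom.t_min)
    hi = chrom.t_max if window is None else min(window[1], chrom.t_max)
    if lo >= hi:
        raise DomainError("integration window is empty")
    t_clip = np.clip(t_edges, lo, hi)
    f = cumulative_area(chrom, t_clip)
    # fraction i window is [t_edges[i+1], t_edges[i]] (time falls with DP)
    raw = f[:-1] - f[1:]
    n_clipped = int(np.sum(raw < 0))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} fractions had negative differential area (clipped to 0)",
            ClippedAreaWarning,
            stacklevel=2,
        )
    n_i = np.clip(raw, 0.0, None)
    if n_i.sum() <= 0:
        raise EmptyDistributionError("no area inside the DP windows")
    return DPDistribution(
        dp=dp_grid,
        m_i=theoretical_mw(dp_grid),
        t_bounds=t_edges,
        n_i=n_i,
        n_clipped=n_clipped,
    )


def _moments_input(dist):
    if isinstance(dist, DPDistribution):
        n, m = dist.n_i, dist.m_i
    else:
        n, m = (np.asarray(a, dtype=float) for a in dist)
    if np.any(n < 0):
        raise DomainError("differential areas must be non-negative")
    if n.sum() <= 0:
        raise EmptyDistributionError("distribution carries no area")
    return n, m


def number_average(dist) -> float:
    """Number-average molecular weight Mn = sum(n_i M_i)/sum(n_i), Da.

    ``dist`` is a :class:`DPDistribution` or an ``(n_i, m_i)`` pair of arrays.
    """
    n, m = _moments_input(dist)
    return float(np.dot(n, m) / n.sum())


def weight_average(dist) -> float:
    """Weight-average molecular weight Mw = sum(n_i M_i^2)/sum(n_i M_i), Da."""
    n, m = _moments_input(dist)
    return float(np.dot(n, m * m) / np.dot(n, m))


def peak_average_mw(peak: Peak, mw_fit: LinearFit, geom: ColumnGeometry) -> float:
    """Peak-average molecular weight Mp: the MW read at the apex retention time.

    The apex must lie inside the column's [t0, tT] window; apexes at Kav
    outside the standards' range are extrapolations and are flagged by the
    calibration layer.
    """
    if not geom.t0 <= peak.t_apex <= geom.tt:
        raise DomainError(
            f"apex at {peak.t_apex:.3f} min outside the column window "
            f"[{geom.t0:.3f}, {geom.tt:.3f}] min"
        )
    return float(mw_from_kav(kav_from_time(peak.t_apex, geom), mw_fit))
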