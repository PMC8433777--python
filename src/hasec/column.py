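"""SEC column geometry and the elution-volume / partition-coefficient / time maps.

In size-exclusion chromatography a solute's partition coefficient

    Kav = (Ve - V0) / (VT - V0)

expresses the fraction of the stationary-phase pore volume it can access:
0 for species fully excluded (eluting at the void volume ``V0``) and 1 for
species permeating the entire pore volume (eluting at the total retention
volume ``VT``).  Retention times map linearly onto Kav through the void and
total retention times ``t0`` and ``tT``:

    tR = Kav * (tT - t0) + t0

``t0``/``tT`` may be supplied directly (instruments often report a measured
void time that differs from ``V0 / flow``) or derived from the volumes and
the flow rate when absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import DegenerateGeometryError, DomainError, KavRangeWarning

__all__ = [
    "ColumnGeometry",
    "kav",
    "kav_from_time",
    "retention_time_from_kav",
    "time_to_volume",
    "volume_to_time",
]


@dataclass(frozen=True)
class ColumnGeometry:
    """Geometry of one SEC column plus the run's mobile-phase flow.

    Parameters
    ----------
    v0_ml :
        Void (exclusion) volume, mL.
    vt_ml :
        Total retention volume, mL.
    flow_ml_min :
        Mobile-phase flow rate, mL/min.
    vc_ml :
        Total (geometric) column volume, mL.  Metadata only; not used in any
        transform.
    t0_min, tt_min :
        Void and total retention times, min.  Optional: when omitted they are
        derived as ``v0/flow`` and ``vt/flow``.  Supplying them allows a
        measured void time that is not volume-consistent to be used as-is.
    """

    v0_ml: float
    vt_ml: float
    flow_ml_min: float
    vc_ml: float | None = None
    t0_min: float | None = field(default=None)
    tt_min: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.v0_ml <= 0 or self.vt_ml <= 0:
            raise DomainError("column volumes must be strictly positive")
        if self.flow_ml_min <= 0:
            raise DomainError("flow rate must be strictly positive")
        if self.v0_ml >= self.vt_ml:
            raise DegenerateGeometryError(
                f"void volume ({self.v0_ml} mL) must be smaller than total "
                f"retention volume ({self.vt_ml} mL)"
            )
        if self.t0 <= 0 or self.tt <= 0:
            raise DomainError("retention times must be strictly positive")
        if self.t0 >= self.tt:
            raise DegenerateGeometryError(
                f"void time ({self.t0} min) must be smaller than total "
                f"retention time ({self.tt} min)"
            )

    @property
    def t0(self) -> float:
        """Void retention time, min (supplied, else ``v0 / flow``)."""
        return self.t0_min if self.t0_min is not None else self.v0_ml / self.flow_ml_min

    @property
    def tt(self) -> float:
        """Total retention time, min (supplied, else ``vt / flow``)."""
        return self.tt_min if self.tt_min is not None else self.vt_ml / self.flow_ml_min

    @classmethod
    def ultrahydrogel_2000(cls, *, derived_times: bool = True) -> "ColumnGeometry":
        """The Waters Ultrahydrogel 2000 (7.8 x 300 mm) at 0.8 mL/min.

        With ``derived_times=True`` (default) the void/total times are the
        volume-consistent ``V0/flow`` and ``VT/flow``, which is what the
        simulator needs for a self-consistent round trip.  With ``False`` the
        instrument-reported void time of 6.00 min is used instead.
        """
        t0 = None if derived_times else 6.00
        return cls(v0_ml=6.87, vt_ml=13.75, vc_ml=14.34, flow_ml_min=0.8, t0_min=t0)


def kav(ve: float, geom: ColumnGeometry) -> float:
    """Partition coefficient for a species eluting at volume ``ve`` (mL).

    Values outside [0, 1] are physically suspect (full exclusion below 0,
    adsorption above 1); they are returned unclamped with a
    :class:`KavRangeWarning` so the artefact stays visible.
    """
    span = geom.vt_ml - geom.v0_ml
    if span == 0:  # unreachable through the validated dataclass, kept for raw use
        raise DegenerateGeometryError("VT == V0: partition coefficient undefined")
    k = (ve - geom.v0_ml) / span
    if k < 0 or k > 1:
        warnings.warn(
            f"Kav = {k:.4f} outside [0, 1] for Ve = {ve} mL "
            "(solute excluded or adsorbed)",
            KavRangeWarning,
            stacklevel=2,
        )
    return k


def kav_from_time(t: float, geom: ColumnGeometry) -> float:
    """Partition coefficient for a species eluting at time ``t`` (min)."""
    return (t - geom.t0) / (geom.tt - geom.t0)


def retention_time_from_kav(kav_theo, geom: ColumnGeometry):
    """Retention time (min) of a species with theoretical partition coefficient.

    Accepts scalars or arrays; strictly increasing in ``kav_theo``.
    """
    return kav_theo * (geom.tt - geom.t0) + geom.t0


def time_to_volume(t, geom: ColumnGeometry):
    """Elution time (min) to elution volume (mL) at the run's flow rate."""
    return t * geom.flow_ml_min


def volume_to_time(v, geom: ColumnGeometry):
    """Elution volume (mL) to elution time (min) at the run's flow rate."""
    return v / geom.flow_ml_min
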