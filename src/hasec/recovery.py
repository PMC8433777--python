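"""Spike-recovery accounting and sample-content unit conversion.

Recovery experiments spike a known analyte concentration into a matrix and
compare what the method measures back:

    recovery % = 100 * measured / spiked

Sample content converts the measured solution concentration into the basis
a product label uses (mg/L of the original sample, mg per capsule, or
mg per 100 mg of product), undoing the dilution applied before injection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .errors import ConfigurationError, DomainError

__all__ = ["RecoveryResult", "recovery_rate", "sample_content", "round_display"]


def recovery_rate(measured: float, spiked: float) -> float:
    """Percent recovery of a spiked analyte: 100·measured/spiked."""
    if spiked <= 0:
        raise DomainError("spiked concentration must be strictly positive")
    if measured < 0:
        raise DomainError("measured concentration must be non-negative")
    return 100.0 * measured / spiked


def round_display(value: float, ndigits: int = 2) -> float:
    """Round half away from zero for display (reports print 2 decimals)."""
    scale = 10**ndigits
    sign = 1.0 if value >= 0 else -1.0
    return sign * int(abs(value) * scale + 0.5) / scale


@dataclass(frozen=True)
class RecoveryResult:
    """One spike-recovery determination."""

    measured: float  # mg/L
    spiked: float  # mg/L
    recovery_pct: float
    avg_mw: float | None = None  # Da, absent for methods that cannot report it

    @classmethod
    def from_measurement(
        cls, measured: float, spiked: float, avg_mw: float | None = None
    ) -> "RecoveryResult":
        return cls(
            measured=measured,
            spiked=spiked,
            recovery_pct=recovery_rate(measured, spiked),
            avg_mw=avg_mw,
        )

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d["recovery_pct"] = round_display(self.recovery_pct)
        d.update(extra)
        return json.dumps(d, indent=2)


def sample_content(
    concentration_mg_l: float,
    dilution_factor: float,
    *,
    basis: str = "mg_per_l",
    dissolved_volume_ml: float | None = None,
    sample_mass_mg: float | None = None,
    n_units: float = 1.0,
) -> float:
    """Analyte content of the original sample in the requested reporting basis.

    ``concentration_mg_l`` is the concentration measured in the injected
    solution; ``dilution_factor`` (>= 1) undoes any dilution between the
    dissolved sample and the injection.

    basis:
        ``"mg_per_l"``     — concentration of the dissolved sample, mg/L.
        ``"mg_per_unit"``  — mg per unit (e.g. capsule): needs
                             ``dissolved_volume_ml`` (total dissolution
                             volume) and ``n_units`` dissolved in it.
        ``"mg_per_100mg"`` — mg per 100 mg of product: needs
                             ``dissolved_volume_ml`` and ``sample_mass_mg``.
    """
    if dilution_factor < 1:
        raise DomainError("dilution factor must be >= 1")
    original = concentration_mg_l * dilution_factor
    if basis == "mg_per_l":
        return original
    if dissolved_volume_ml is None or dissolved_volume_ml <= 0:
        raise ConfigurationError(f"basis {basis!r} needs dissolved_volume_ml > 0")
    total_mg = original * dissolved_volume_ml / 1000.0
    if basis == "mg_per_unit":
        if n_units <= 0:
            raise ConfigurationError("n_units must be > 0")
        return total_mg / n_units
    if basis == "mg_per_100mg":
        if sample_mass_mg is None or sample_mass_mg <= 0:
            raise ConfigurationError("basis 'mg_per_100mg' needs sample_mass_mg > 0")
        return 100.0 * total_mg / sample_mass_mg
    raise ConfigurationError(f"unknown basis {basis!r}")
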