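"""Seawater ammonia speciation and carbon isotope bookkeeping.

Shared chemistry for the tracer stages: the NH3/NH4+ equilibrium in seawater
(the ammonia-oxidizer substrate is the unionized NH3 species), the
delta-13C <-> atom% conversion against the VPDB standard, and mass-balance
mixing of dissolved-inorganic-carbon (DIC) pools when a 13C-bicarbonate
label is added to seawater.

The ammonium dissociation constant uses a stoichiometric seawater
formulation linear in temperature and salinity::

    pKa*(T, S) = 10.0423 - 0.0315536*T + 0.003071*S     (T in degC, S in PSU)

so the NH3 fraction follows Henderson-Hasselbalch,
``f = 1 / (1 + 10**(pKa* - pH))``.  At 25 degC, S = 35 and pH around 8.05
this puts roughly 4-5% of total ammoniacal nitrogen in the NH3 form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import UndefinedMixtureError, ValidationError

#: 13C/12C isotope ratio of the VPDB standard (Craig value).
R_VPDB = 0.0112372

#: Natural abundance of 15N, atom percent.
N15_NATURAL_ATOM_PERCENT = 0.3663


@dataclass(frozen=True)
class IsotopeConstants:
    """Reference isotope constants used throughout the tracer bookkeeping.

    Parameters
    ----------
    r_vpdb : float
        13C/12C ratio of the VPDB standard defining delta-13C = 0 permil.
    n15_natural : float
        Natural-abundance 15N in atom percent.
    """

    r_vpdb: float = R_VPDB
    n15_natural: float = N15_NATURAL_ATOM_PERCENT

    def __post_init__(self):
        if not self.r_vpdb > 0:
            raise ValidationError(f"r_vpdb must be > 0, got {self.r_vpdb}")
        if not 0 < self.n15_natural < 100:
            raise ValidationError(
                f"n15_natural must lie in (0, 100) atom%, got {self.n15_natural}"
            )


DEFAULT_CONSTANTS = IsotopeConstants()


@dataclass(frozen=True)
class SeawaterState:
    """Physico-chemical state of incubation seawater.

    temperature in degC, salinity in PSU, pH on the total scale,
    total_ammonia (NH3 + NH4+) in uM.
    """

    temperature: float = 25.0
    salinity: float = 35.0
    ph: float = 8.05
    total_ammonia: float = 0.0

    def __post_init__(self):
        if not -2.0 <= self.temperature <= 40.0:
            raise ValidationError(
                f"temperature must lie in [-2, 40] degC, got {self.temperature}"
            )
        if not 0.0 <= self.salinity <= 45.0:
            raise ValidationError(
                f"salinity must lie in [0, 45] PSU, got {self.salinity}"
            )
        if not 6.0 <= self.ph <= 10.0:
            raise ValidationError(f"ph must lie in [6, 10], got {self.ph}")
        if self.total_ammonia < 0:
            raise ValidationError(
                f"total_ammonia must be >= 0 uM, got {self.total_ammonia}"
            )


@dataclass(frozen=True)
class DICPool:
    """A dissolved-inorganic-carbon pool: concentration (uM) and 13C atom%."""

    concentration: float
    atom_percent_13c: float

    def __post_init__(self):
        if self.concentration < 0:
            raise ValidationError(
                f"concentration must be >= 0 uM, got {self.concentration}"
            )
        if not 0.0 <= self.atom_percent_13c <= 100.0:
            raise ValidationError(
                f"atom_percent_13c must lie in [0, 100], got {self.atom_percent_13c}"
            )


@dataclass(frozen=True)
class MixedDIC(DICPool):
    """A mixed DIC pool, carrying its atom% excess over the background pool."""

    atom_percent_excess: float = 0.0


def ammonium_pka(temperature: float, salinity: float) -> float:
    """Stoichiometric seawater pKa* of NH4+ at the given T (degC) and S (PSU)."""
    return 10.0423 - 0.0315536 * temperature + 0.003071 * salinity


def ammonia_fraction(state: SeawaterState) -> float:
    """Fraction (0-1) of total ammoniacal N present as unionized NH3.

    Henderson-Hasselbalch with the seawater pKa*; strictly increasing in pH
    and in temperature.
    """
    pka = ammonium_pka(state.temperature, state.salinity)
    return 1.0 / (1.0 + 10.0 ** (pka - state.ph))


def delta13c_to_atom_percent(
    delta: float, constants: IsotopeConstants = DEFAULT_CONSTANTS
) -> float:
    """Convert delta-13C (permil vs VPDB) to atom% 13C.

    ``at% = 100 * R / (1 + R)`` with ``R = r_vpdb * (1 + delta/1000)``.
    """
    if delta <= -1000.0:
        raise ValidationError(
            f"delta must be > -1000 permil (isotope ratio would be <= 0), got {delta}"
        )
    r = constants.r_vpdb * (1.0 + delta / 1000.0)
    return 100.0 * r / (1.0 + r)


def atom_percent_to_delta(
    atom_percent: float, constants: IsotopeConstants = DEFAULT_CONSTANTS
) -> float:
    """Inverse of :func:`delta13c_to_atom_percent` (exact round trip)."""
    if not 0.0 <= atom_percent < 100.0:
        raise ValidationError(
            f"atom_percent must lie in [0, 100), got {atom_percent}"
        )
    r = atom_percent / (100.0 - atom_percent)
    return (r / constants.r_vpdb - 1.0) * 1000.0


def mix_dic_label(background: DICPool, additions: list[DICPool]) -> MixedDIC:
    """Pool a background DIC pool with label additions by isotope mass balance.

    Returns the mixed pool, whose ``atom_percent_excess`` is the mixed atom%
    minus the background atom% (the quantity entering fixation-rate
    calculations).  The mixed atom% is a concentration-weighted mean, so it
    always lies between the minimum and maximum input atom%.
    """
    pools = [background, *additions]
    total = sum(p.concentration for p in pools)
    if total <= 0:
        raise UndefinedMixtureError(
            "total DIC concentration is zero; mixture atom% undefined"
        )
    atpct = sum(p.concentration * p.atom_percent_13c for p in pools) / total
    return MixedDIC(
        concentration=total,
        atom_percent_13c=atpct,
        atom_percent_excess=atpct - background.atom_percent_13c,
    )
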