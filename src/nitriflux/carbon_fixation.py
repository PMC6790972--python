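"""Inorganic carbon fixation from tissue 13C enrichment, and N:C coupling.

A 13C-bicarbonate label raises the atom% 13C of the DIC pool above natural
abundance by ``dic_excess`` atom%.  Carbon fixed from that pool over the
incubation raises the tissue atom% proportionally, so the fixation rate is
the tissue atom% gain divided by the source excess, scaled by tissue carbon
content and incubation length:

    rate = (at%_final - at%_initial) / dic_excess * tissue_carbon / duration

in umol C per g per day.  The coupling between gross nitrification (N) and
carbon fixation (C) is an ordinary least-squares fit of N on C; its slope is
the N:C ratio of the nitrifying symbiont population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import chem
from .errors import DegenerateFitError, ValidationError


@dataclass(frozen=True)
class TracerCarbonSample:
    """End-point tissue 13C observation from a labelled incubation.

    delta13c values in permil vs VPDB; tissue_carbon in umol C g-1 (basis
    recorded by the caller); duration in days; dic_excess in atom% 13C
    (from :func:`nitriflux.chem.mix_dic_label`).
    """

    delta13c_initial: float
    delta13c_final: float
    tissue_carbon: float
    duration: float
    dic_excess: float

    def __post_init__(self):
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0 d, got {self.duration}")
        if not self.dic_excess > 0:
            raise ValidationError(
                f"dic_excess must be > 0 atom%, got {self.dic_excess}"
            )
        if not self.tissue_carbon > 0:
            raise ValidationError(
                f"tissue_carbon must be > 0 umol g-1, got {self.tissue_carbon}"
            )
        for name in ("delta13c_initial", "delta13c_final"):
            if getattr(self, name) <= -1000:
                raise ValidationError(f"{name} must be > -1000 permil")


@dataclass(frozen=True)
class FixationRate:
    """Carbon fixation rate (umol C g-1 d-1) with quality flags."""

    value: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CouplingFit:
    """OLS fit of gross nitrification on carbon fixation.

    slope is the N:C ratio (umol N per umol C); reciprocal_slope is 1/slope
    for the C:N reading; r is the Pearson correlation.
    """

    slope: float
    intercept: float
    r: float
    n: int
    p_value: float = math.nan

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation must lie in [-1, 1], got {self.r}")
        if self.n < 2:
            raise ValidationError(f"need n >= 2 points, got {self.n}")

    @property
    def reciprocal_slope(self) -> float:
        return 1.0 / self.slope


def fixation_rate(
    sample: TracerCarbonSample,
    constants: chem.IsotopeConstants = chem.DEFAULT_CONSTANTS,
    label_retention: float = 1.0,
) -> FixationRate:
    """Carbon fixation rate from a tissue 13C enrichment observation.

    ``label_retention`` in (0, 1] down-weights the DIC excess to account for
    loss of added label in intermittently open incubations (retention 1
    assumes the post-mixing excess held for the whole incubation; lower
    values raise the inferred rate).
    """
    if not 0 < label_retention <= 1:
        raise ValidationError(
            f"label_retention must lie in (0, 1], got {label_retention}"
        )
    at_initial = chem.delta13c_to_atom_percent(sample.delta13c_initial, constants)
    at_final = chem.delta13c_to_atom_percent(sample.delta13c_final, constants)
    enrichment = at_final - at_initial
    if enrichment < 0:
        return FixationRate(0.0, ("depleted_tissue",))
    rate = (
        enrichment
        / (sample.dic_excess * label_retention)
        * sample.tissue_carbon
        / sample.duration
    )
    return FixationRate(rate)


def nc_coupling(pairs: list[tuple[float, float]]) -> CouplingFit:
    """Fit gross nitrification (response) on carbon fixation (predictor).

    ``pairs`` holds (carbon_fixation, gross_nitrification) tuples in
    umol g-1 d-1.  The slope is the N:C ratio.
    """
    if len(pairs) < 2:
        raise ValidationError(f"need >= 2 pairs, got {len(pairs)}")
    cfix = np.asarray([p[0] for p in pairs], dtype=float)
    nitr = np.asarray([p[1] for p in pairs], dtype=float)
    if not (np.isfinite(cfix).all() and np.isfinite(nitr).all()):
        raise ValidationError("all coupling pairs must be finite")
    if np.ptp(cfix) == 0:
        raise DegenerateFitError("carbon fixation values have zero variance")
    fit = stats.linregress(cfix, nitr)
    return CouplingFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n=len(pairs),
        p_value=float(fit.pvalue),
    )
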