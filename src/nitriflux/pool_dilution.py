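"""Gross nitrification by 15N isotope pool dilution, and net DIN fluxes.

The pool-dilution principle: the NO2- + NO3- product pool is spiked with
15N-nitrate.  Gross nitrification adds unlabelled nitrogen to the pool and
so dilutes the 15N enrichment, while consumption removes labelled and
unlabelled N indiscriminately and leaves the enrichment untouched.  With
constant gross production ``p`` and consumption ``c`` the pool size and
atom%-excess obey

    dC/dt   = p - c
    dAPE/dt = -p * APE / C

whose Kirkham-Bartholomew inversion from two sampling points (t0, t) is

    p = (Ct - C0)/dt * ln(APE0/APEt) / ln(Ct/C0)        (Ct != C0)
    p = C0/dt * ln(APE0/APEt)                           (Ct == C0)
    c = p - (Ct - C0)/dt

Net fluxes of individual DIN species are linear concentration changes over a
fixed window (6-18 h by default) and net nitrification is the summed
NO2- + NO3- flux.  All rates are normalized to sponge wet weight and
expressed in umol N per g wet weight per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import N15_NATURAL_ATOM_PERCENT
from .errors import ValidationError, WindowUncoveredError

HOURS_PER_DAY = 24.0

#: |ct - c0| below this relative tolerance uses the constant-pool limiting form.
EQUAL_POOL_RTOL = 1e-9

#: Negative rates within this fraction of the estimate scale are treated as
#: numerical noise and clamped to zero; larger negatives flag a model violation.
NEGATIVE_CLAMP_FRACTION = 0.05

#: Window endpoints may be linearly interpolated from samples within this
#: many hours of the nominal endpoint.
INTERPOLATION_TOLERANCE_H = 1.0

RATE_KINDS = frozenset(
    {"gross_production", "gross_consumption", "net_flux", "net_nitrification"}
)


@dataclass(frozen=True)
class IncubationSeries:
    """Time course of one incubation container.

    samples hold (time_h, nh4, no2, no3) in uM; isotope_samples hold
    (time_h, APE of the combined NO2-+NO3- pool in atom% 15N excess).
    """

    container_id: str
    volume: float  # L
    wet_weight: float  # g
    samples: tuple[tuple[float, float, float, float], ...]
    isotope_samples: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if not self.volume > 0:
            raise ValidationError(f"volume must be > 0 L, got {self.volume}")
        if not self.wet_weight > 0:
            raise ValidationError(
                f"wet_weight must be > 0 g, got {self.wet_weight}"
            )
        for name, rows in (("samples", self.samples), ("isotope_samples", self.isotope_samples)):
            times = [r[0] for r in rows]
            if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
                raise ValidationError(f"{name} times must be strictly increasing")
        if any(v < 0 for row in self.samples for v in row[1:]):
            raise ValidationError("concentrations must be >= 0 uM")
        if any(not 0 <= ape < 100 for _, ape in self.isotope_samples):
            raise ValidationError("APE values must lie in [0, 100) atom%")

    def concentration(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """(times_h, values) arrays for one species in {nh4, no2, no3, nox}."""
        idx = {"nh4": 1, "no2": 2, "no3": 3}
        t = np.array([r[0] for r in self.samples], dtype=float)
        if species == "nox":
            v = np.array([r[2] + r[3] for r in self.samples], dtype=float)
        elif species in idx:
            v = np.array([r[idx[species]] for r in self.samples], dtype=float)
        else:
            raise ValidationError(f"unknown species {species!r}")
        return t, v


@dataclass(frozen=True)
class RateEstimate:
    """A rate with units umol N g-1 d-1 (or uM d-1 before normalization)."""

    value: float
    kind: str
    window: tuple[float, float]  # hours
    flags: tuple[str, ...] = ()
    container_id: str = ""

    def __post_init__(self):
        if self.kind not in RATE_KINDS:
            raise ValidationError(f"kind must be one of {sorted(RATE_KINDS)}")
        if not self.window[0] < self.window[1]:
            raise ValidationError(f"window must be well ordered, got {self.window}")


@dataclass(frozen=True)
class LabelPlan:
    """Planned 15N-nitrate label addition, as a fraction of the target pool."""

    pool_concentration: float  # uM
    target_fraction: float  # of the post-addition pool by default
    label_at_percent: float = 98.0

    def __post_init__(self):
        if not self.pool_concentration > 0:
            raise ValidationError(
                f"pool_concentration must be > 0 uM, got {self.pool_concentration}"
            )
        if not 0 < self.target_fraction <= 0.10:
            raise ValidationError(
                f"target_fraction must lie in (0, 0.10], got {self.target_fraction}"
            )
        if not 0 < self.label_at_percent <= 100:
            raise ValidationError(
                f"label_at_percent must lie in (0, 100], got {self.label_at_percent}"
            )


@dataclass(frozen=True)
class GrossRates:
    """Paired gross production/consumption estimates with quality flags.

    Values are NaN when the pool-dilution model assumptions were violated
    (enrichment increased over the incubation).
    """

    production: float  # uM d-1
    consumption: float  # uM d-1
    flags: tuple[str, ...] = ()


def gross_rates_ipd(
    c0: float, ct: float, ape0: float, apet: float, dt: float
) -> GrossRates:
    """Invert a two-point pool-dilution observation to gross rates.

    Parameters are the combined NO2-+NO3- pool (uM) and its 15N atom%
    excess at the start and end of the interval ``dt`` (days).
    """
    if not (c0 > 0 and ct > 0):
        raise ValidationError(f"pool sizes must be > 0 uM, got c0={c0}, ct={ct}")
    if not ape0 > 0:
        raise ValidationError(f"ape0 must be > 0 atom% excess, got {ape0}")
    if not apet > 0:
        raise ValidationError(f"apet must be > 0 atom% excess, got {apet}")
    if not dt > 0:
        raise ValidationError(f"dt must be > 0 d, got {dt}")
    if apet > ape0:
        # unlabelled-influx model cannot raise enrichment: no estimate
        return GrossRates(math.nan, math.nan, ("enrichment_increased",))

    net = (ct - c0) / dt
    if abs(ct - c0) < EQUAL_POOL_RTOL * max(c0, ct):
        p = (c0 / dt) * math.log(ape0 / apet)
    else:
        p = net * math.log(ape0 / apet) / math.log(ct / c0)
    c = p - net

    flags: list[str] = []
    scale = max(abs(p), abs(c), 1e-300)
    clamped = []
    for v in (p, c):
        if v < 0:
            if -v <= NEGATIVE_CLAMP_FRACTION * scale:
                clamped.append(0.0)
                flags.append("clamped_negative")
            else:
                clamped.append(v)
                flags.append("model_violation")
        else:
            clamped.append(v)
    return GrossRates(clamped[0], clamped[1], tuple(flags))


def to_specific_rate(volumetric: float, volume: float, wet_weight: float) -> float:
    """Convert a volumetric rate (uM d-1) to umol N per g wet weight per day."""
    if not volume > 0:
        raise ValidationError(f"volume must be > 0 L, got {volume}")
    if not wet_weight > 0:
        raise ValidationError(f"wet_weight must be > 0 g, got {wet_weight}")
    return volumetric * volume / wet_weight


def _value_at(times: np.ndarray, values: np.ndarray, t: float) -> float:
    """Concentration at time t, interpolating within the documented tolerance."""
    exact = np.isclose(times, t)
    if exact.any():
        return float(values[exact][0])
    lo = times[times <= t]
    hi = times[times >= t]
    if len(lo) == 0 or len(hi) == 0:
        raise WindowUncoveredError(
            f"no samples bracket window endpoint {t} h"
        )
    t_lo, t_hi = lo.max(), hi.min()
    if t - t_lo > INTERPOLATION_TOLERANCE_H or t_hi - t > INTERPOLATION_TOLERANCE_H:
        raise WindowUncoveredError(
            f"nearest samples at {t_lo} h and {t_hi} h exceed the "
            f"+/-{INTERPOLATION_TOLERANCE_H} h interpolation tolerance for endpoint {t} h"
        )
    v_lo = float(values[times == t_lo][0])
    v_hi = float(values[times == t_hi][0])
    if t_hi == t_lo:
        return v_lo
    return v_lo + (v_hi - v_lo) * (t - t_lo) / (t_hi - t_lo)


def net_flux(
    series: IncubationSeries,
    species: str,
    window: tuple[float, float] = (6.0, 18.0),
) -> RateEstimate:
    """Net flux of one DIN species over a time window, in umol g-1 d-1.

    The flux is the linear concentration change over the window scaled by
    container volume and wet weight; the sign is preserved (negative means
    net consumption).
    """
    t_start, t_end = window
    if not t_start < t_end:
        raise ValidationError(f"window must be well ordered, got {window}")
    times, values = series.concentration(species)
    c_start = _value_at(times, values, t_start)
    c_end = _value_at(times, values, t_end)
    dt_days = (t_end - t_start) / HOURS_PER_DAY
    volumetric = (c_end - c_start) / dt_days
    value = volumetric * series.volume / series.wet_weight
    return RateEstimate(
        value=value,
        kind="net_flux",
        window=window,
        container_id=series.container_id,
    )


def net_nitrification(
    no2_flux: RateEstimate, no3_flux: RateEstimate
) -> RateEstimate:
    """Summed NO2- + NO3- net flux; also exposes the NO2:NO3 ratio as a flag."""
    if no2_flux.window != no3_flux.window:
        raise ValidationError(
            f"flux windows differ: {no2_flux.window} vs {no3_flux.window}"
        )
    flags = list(no2_flux.flags) + list(no3_flux.flags)
    if no3_flux.value != 0:
        flags.append(f"no2_no3_ratio={no2_flux.value / no3_flux.value:.3g}")
    return RateEstimate(
        value=no2_flux.value + no3_flux.value,
        kind="net_nitrification",
        window=no2_flux.window,
        flags=tuple(flags),
        container_id=no2_flux.container_id,
    )


@dataclass(frozen=True)
class LabelAddition:
    """Resolved label addition: concentration to add and the resulting APE0."""

    added_concentration: float  # uM
    ape0: float  # atom% excess of the post-addition pool


def plan_label_addition(
    plan: LabelPlan,
    n15_natural: float = N15_NATURAL_ATOM_PERCENT,
    fraction_basis: str = "post",
) -> LabelAddition:
    """Concentration of 15N-nitrate to add for a target label fraction.

    With ``fraction_basis='post'`` (default) the target fraction refers to
    the post-addition pool, so ``added = pool * f / (1 - f)``; with ``'pre'``
    it refers to the unamended pool, ``added = pool * f``.
    """
    if fraction_basis not in ("pre", "post"):
        raise ValidationError(f"fraction_basis must be 'pre' or 'post', got {fraction_basis!r}")
    f = plan.target_fraction
    if fraction_basis == "post":
        added = plan.pool_concentration * f / (1.0 - f)
    else:
        added = plan.pool_concentration * f
    total = plan.pool_concentration + added
    mixed_atpct = (
        plan.pool_concentration * n15_natural + added * plan.label_at_percent
    ) / total
    return LabelAddition(added_concentration=added, ape0=mixed_atpct - n15_natural)


# ---------------------------------------------------------------------------
# tabular I/O

ANALYTES = ("NH4", "NO2", "NO3", "APE_NOx")


def read_incubations(samples_csv, containers_csv) -> list[IncubationSeries]:
    """Assemble IncubationSeries from the long-format sample and container CSVs.

    samples: container_id, time_h, analyte in {NH4, NO2, NO3, APE_NOx}, value.
    containers: container_id, volume_L, wet_weight_g (extra columns ignored).
    """
    samples = pd.read_csv(samples_csv)
    containers = pd.read_csv(containers_csv).set_index("container_id")
    out = []
    for cid, grp in samples.groupby("container_id", sort=True):
        if cid not in containers.index:
            raise ValidationError(f"container_id {cid!r} missing from containers table")
        wide = (
            grp[grp["analyte"] != "APE_NOx"]
            .pivot_table(index="time_h", columns="analyte", values="value")
            .sort_index()
        )
        rows = tuple(
            (float(t), float(r.get("NH4", 0.0)), float(r.get("NO2", 0.0)), float(r.get("NO3", 0.0)))
            for t, r in wide.iterrows()
        )
        ape = grp[grp["analyte"] == "APE_NOx"].sort_values("time_h")
        iso = tuple((float(t), float(v)) for t, v in zip(ape["time_h"], ape["value"]))
        meta = containers.loc[cid]
        out.append(
            IncubationSeries(
                container_id=str(cid),
                volume=float(meta["volume_L"]),
                wet_weight=float(meta["wet_weight_g"]),
                samples=rows,
                isotope_samples=iso,
            )
        )
    return out


def rates_to_frame(estimates: list[RateEstimate]) -> pd.DataFrame:
    """Tidy rates table: container_id, kind, window, value, flags."""
    return pd.DataFrame(
        {
            "container_id": [e.container_id for e in estimates],
            "kind": [e.kind for e in estimates],
            "window_start_h": [e.window[0] for e in estimates],
            "window_end_h": [e.window[1] for e in estimates],
            "value": [e.value for e in estimates],
            "flags": [";".join(e.flags) for e in estimates],
        }
    )
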