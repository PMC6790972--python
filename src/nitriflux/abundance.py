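"""Symbiont quantification: qPCR standard curves, FISH counts, cell rates.

Absolute abundance comes from 16S rRNA gene qPCR against a log-linear
standard curve (Cq vs log10 copies); relative abundance from FISH image
counts; and cell-specific ammonia-oxidation rates from dividing a bulk
wet-weight-normalized rate by the per-gram cell density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: efficiency outside this band gets a quality flag on the fitted curve
EFFICIENCY_BAND = (0.9, 1.1)


@dataclass(frozen=True)
class StandardCurve:
    """qPCR calibration: Cq = intercept + slope * log10(copies per ul).

    efficiency = 10**(-1/slope) - 1; a perfect doubling per cycle gives
    slope -3.3219 and efficiency 1.0.
    """

    slope: float
    intercept: float
    r2: float
    efficiency: float
    cq_range: tuple[float, float] = (-math.inf, math.inf)
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.slope < 0:
            raise ValidationError(f"slope must be < 0, got {self.slope}")
        if not 0 < self.efficiency <= 1.2:
            raise ValidationError(
                f"efficiency must lie in (0, 1.2], got {self.efficiency}"
            )


@dataclass(frozen=True)
class AbundanceRecord:
    """Absolute symbiont abundance for one sample."""

    sample_id: str
    copies_per_g: float
    copies_per_cell: float = 1.0
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.copies_per_g < 0 or self.copies_per_cell <= 0:
            raise ValidationError("abundances must be >= 0; copies_per_cell > 0")

    @property
    def cells_per_g(self) -> float:
        return self.copies_per_g / self.copies_per_cell


@dataclass(frozen=True)
class FishCounts:
    """Archaeal and bacterial cell counts on one FISH image."""

    image_id: str
    archaeal: int
    bacterial: int

    def __post_init__(self):
        if self.archaeal < 0 or self.bacterial < 0:
            raise ValidationError("counts must be >= 0")


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Least-squares standard curve from (copies per ul, Cq) calibration points.

    Requires at least three distinct copy levels; the fitted efficiency is
    flagged ``efficiency_out_of_band`` outside [0.9, 1.1].
    """
    if any(c <= 0 for c, _ in points):
        raise ValidationError("standard copies must be > 0")
    levels = {c for c, _ in points}
    if len(levels) < 3:
        raise ValidationError(
            f"need >= 3 distinct copy levels, got {len(levels)}"
        )
    log_copies = np.log10([c for c, _ in points])
    cq = np.asarray([q for _, q in points], dtype=float)
    fit = stats.linregress(log_copies, cq)
    if fit.slope >= 0:
        raise ValidationError(
            f"inverted_curve: fitted slope {fit.slope:.3g} is not negative"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    flags = ()
    if not EFFICIENCY_BAND[0] <= efficiency <= EFFICIENCY_BAND[1]:
        flags = ("efficiency_out_of_band",)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        efficiency=float(efficiency),
        cq_range=(float(cq.min()), float(cq.max())),
        flags=flags,
    )


def quantify(
    cq: float,
    curve: StandardCurve,
    template_volume: float,
    elution_volume: float,
    tissue_mass: float,
    sample_id: str = "",
    copies_per_cell: float = 1.0,
) -> AbundanceRecord:
    """Invert a sample Cq to copies per gram wet weight.

    Copies per ul of template extract = 10**((intercept - cq) / -slope);
    scaled to the whole elution volume and divided by the extracted tissue
    mass.  Cq outside the calibrated range flags ``extrapolated``.
    """
    for name, v in (
        ("template_volume", template_volume),
        ("elution_volume", elution_volume),
        ("tissue_mass", tissue_mass),
    ):
        if not v > 0:
            raise ValidationError(f"{name} must be > 0, got {v}")
    copies_per_ul = 10.0 ** ((curve.intercept - cq) / (-curve.slope))
    copies_per_g = copies_per_ul * elution_volume / tissue_mass
    flags = ()
    if not curve.cq_range[0] <= cq <= curve.cq_range[1]:
        flags = ("extrapolated",)
    return AbundanceRecord(
        sample_id=sample_id,
        copies_per_g=copies_per_g,
        copies_per_cell=copies_per_cell,
        flags=flags,
    )


def cell_specific_rate(
    rate: float, copies_per_g: float, copies_per_cell: float = 1.0
) -> float:
    """Per-cell ammonia-oxidation rate in fmol N cell-1 d-1.

    ``rate`` is a bulk rate in umol N g-1 d-1; cells per gram are
    copies_per_g / copies_per_cell (thaumarchaeotes carry a single rRNA
    operon, so the default treats gene copies as cells).
    """
    if not copies_per_g > 0:
        raise ValidationError(
            f"copies_per_g must be > 0 to normalize a rate, got {copies_per_g}"
        )
    if not copies_per_cell > 0:
        raise ValidationError(f"copies_per_cell must be > 0, got {copies_per_cell}")
    cells_per_g = copies_per_g / copies_per_cell
    return rate * 1e9 / cells_per_g  # umol -> fmol


def fish_relative_abundance(counts: list[FishCounts]) -> tuple[float, float]:
    """(mean %, SE %) archaeal share of archaeal+bacterial cells over images.

    Images with zero total cells are excluded with a warning.  SE is the
    standard error of the per-image percentages (0 for a single image).
    """
    shares = []
    for rec in counts:
        total = rec.archaeal + rec.bacterial
        if total == 0:
            warnings.warn(
                f"image {rec.image_id!r} has no cells; excluded", stacklevel=2
            )
            continue
        shares.append(100.0 * rec.archaeal / total)
    if not shares:
        raise ValidationError("no images with non-zero cell counts")
    arr = np.asarray(shares)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return float(arr.mean()), se


# ---------------------------------------------------------------------------
# tabular plumbing

def quantify_samples(qpcr_table: pd.DataFrame, copies_per_cell: float = 1.0):
    """Fit a curve from the standard wells and quantify the unknowns.

    Expects columns sample_id, well, cq, is_standard, standard_copies_per_ul,
    template_ul, elution_ul, tissue_g.  Duplicate wells are averaged on the
    Cq scale per sample before inversion.  Returns (curve, records).
    """
    std = qpcr_table[qpcr_table["is_standard"].astype(bool)]
    curve = fit_standard_curve(
        list(zip(std["standard_copies_per_ul"].astype(float), std["cq"].astype(float)))
    )
    records = []
    unknowns = qpcr_table[~qpcr_table["is_standard"].astype(bool)]
    for sid, grp in unknowns.groupby("sample_id", sort=True):
        records.append(
            quantify(
                cq=float(grp["cq"].mean()),
                curve=curve,
                template_volume=float(grp["template_ul"].iloc[0]),
                elution_volume=float(grp["elution_ul"].iloc[0]),
                tissue_mass=float(grp["tissue_g"].iloc[0]),
                sample_id=str(sid),
                copies_per_cell=copies_per_cell,
            )
        )
    return curve, records
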