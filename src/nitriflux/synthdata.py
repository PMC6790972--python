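"""Seeded forward models producing inputs for every analysis stage.

Each generator simulates the data-generating process its paired estimator
assumes — tracer kinetics under constant gross production and consumption,
tissue 13C enrichment under a constant fixation rate, log-linear qPCR
dilution series with Gaussian Cq noise, multinomial spectral-count sampling,
and toy genome pairs mutated at a controlled per-site rate — and returns the
hidden truth alongside the observable data, so estimator recovery can be
checked exactly (noise-free) or within Monte-Carlo tolerance (with noise).

The incubation forward model integrates

    dC/dt    = p - c                   (NO2-+NO3- pool, uM)
    dAPE/dt  = -p * APE / C            (unlabelled influx dilutes the label)
    dNH4/dt  = excretion - p

with a fixed-step RK4 scheme (step <= 0.01 d); the analytic solution
``APE(t) = APE0 * (C(t)/C0) ** (-p/(p-c))`` is available as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import DICPool, atom_percent_to_delta, delta13c_to_atom_percent
from .errors import SimulationError, ValidationError
from .pool_dilution import (
    HOURS_PER_DAY,
    IncubationSeries,
    LabelPlan,
    plan_label_addition,
)

RK4_MAX_STEP_D = 0.01


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the incubation forward model.

    Rates are volumetric (uM d-1): gross_production is gross nitrification
    into the NO2-+NO3- pool, nox_consumption removes from that pool,
    nh4_excretion is host ammonium release.  Defaults mirror a 1.5 L
    container with a ~5 g sponge clone sampled over one incubation day.
    """

    seed: int = 0
    gross_production: float = 7.0  # uM d-1
    nox_consumption: float = 2.0  # uM d-1
    nh4_excretion: float = 10.0  # uM d-1
    volume: float = 1.5  # L
    wet_weight: float = 5.1  # g
    label: LabelPlan = field(
        default_factory=lambda: LabelPlan(pool_concentration=10.0, target_fraction=0.10)
    )
    nh4_initial: float = 0.29  # uM, ambient seawater
    no2_fraction_of_production: float = 2.8 / 3.8  # NO2:NO3 accumulation 2.8
    conc_noise_sd: float = 0.0  # uM
    ape_noise_sd: float = 0.0  # atom%
    sample_times: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 20.0)  # h

    def __post_init__(self):
        for name in ("gross_production", "nox_consumption", "nh4_excretion"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.conc_noise_sd < 0 or self.ape_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        if not 0 <= self.no2_fraction_of_production <= 1:
            raise ValidationError("no2_fraction_of_production must lie in [0, 1]")


def analytic_pool(p: float, c: float, c0: float, t_days: float) -> float:
    """Pool size under constant production p and consumption c."""
    return c0 + (p - c) * t_days


def analytic_ape(p: float, c: float, c0: float, ape0: float, t_days: float) -> float:
    """APE under the pool-dilution model (closed form of dAPE/dt = -p*APE/C)."""
    if p == 0:
        return ape0
    if abs(p - c) < 1e-12:
        return ape0 * math.exp(-p * t_days / c0)
    ct = analytic_pool(p, c, c0, t_days)
    return ape0 * (ct / c0) ** (-p / (p - c))


def simulate_incubation(
    config: SimulationConfig, container_id: str = "sim"
) -> tuple[IncubationSeries, dict]:
    """Forward-simulate one container; returns (series, truth record).

    The 15N label is added at t=0 per ``config.label`` (the label mass is
    part of the pool at t=0).  The truth record carries the volumetric and
    wet-weight-specific gross rates and the noise-free trajectories.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    addition = plan_label_addition(config.label)
    c0 = config.label.pool_concentration + addition.added_concentration
    ape0 = addition.ape0
    p, c = config.gross_production, config.nox_consumption
    f_no2 = config.no2_fraction_of_production

    t_end_d = max(config.sample_times) / HOURS_PER_DAY
    n_steps = max(1, math.ceil(t_end_d / RK4_MAX_STEP_D))
    h = t_end_d / n_steps if t_end_d > 0 else 0.0

    # state: [C_nox, APE, NH4, NO2]; NO3 = C_nox - NO2
    no2_0 = 0.3 * config.label.pool_concentration
    state = np.array([c0, ape0, config.nh4_initial, no2_0], dtype=float)

    def deriv(s):
        C, a, nh4, no2 = s
        if C <= 0:
            raise SimulationError(
                "NO2-+NO3- pool driven non-positive; shorten the horizon or "
                "reduce consumption"
            )
        return np.array(
            [
                p - c,
                -p * a / C,
                config.nh4_excretion - p,
                f_no2 * p - c * no2 / C,
            ]
        )

    times_d = [t / HOURS_PER_DAY for t in config.sample_times]
    t = 0.0
    grid = [state.copy()]
    grid_t = [0.0]
    for _ in range(n_steps):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * h * k1)
        k3 = deriv(state + 0.5 * h * k2)
        k4 = deriv(state + h * k3)
        state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        if state[0] <= 0 or state[2] < -1e-9:
            raise SimulationError(
                "a pool was driven negative; shorten the horizon"
            )
        grid.append(state.copy())
        grid_t.append(t)
    grid = np.array(grid)
    grid_t = np.array(grid_t)

    def at_time(td: float) -> np.ndarray:
        return np.array(
            [np.interp(td, grid_t, grid[:, i]) for i in range(grid.shape[1])]
        )

    samples = []
    iso = []
    clean = []
    for th, td in zip(config.sample_times, times_d):
        C, a, nh4, no2 = at_time(td)
        no3 = C - no2
        clean.append((th, nh4, no2, no3, a))
        noise = rng.normal(0.0, config.conc_noise_sd, size=3) if config.conc_noise_sd else np.zeros(3)
        ape_noise = rng.normal(0.0, config.ape_noise_sd) if config.ape_noise_sd else 0.0
        samples.append(
            (
                float(th),
                max(0.0, nh4 + noise[0]),
                max(0.0, no2 + noise[1]),
                max(0.0, no3 + noise[2]),
            )
        )
        iso.append((float(th), float(min(99.999, max(1e-9, a + ape_noise)))))

    series = IncubationSeries(
        container_id=container_id,
        volume=config.volume,
        wet_weight=config.wet_weight,
        samples=tuple(samples),
        isotope_samples=tuple(iso),
    )
    to_specific = config.volume / config.wet_weight
    truth = {
        "gross_production_uM_d": p,
        "nox_consumption_uM_d": c,
        "nh4_excretion_uM_d": config.nh4_excretion,
        "gross_production_specific": p * to_specific,
        "nox_consumption_specific": c * to_specific,
        "c0": c0,
        "ape0": ape0,
        "clean_trajectory": clean,
        "seed": config.seed,
    }
    return series, truth


def simulate_tissue_labeling(
    true_rate: float,
    tissue_carbon: float,
    dic: DICPool,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    delta13c_initial: float = -20.0,
    dic_excess: float | None = None,
):
    """Invert the fixation-rate formula to a final tissue delta-13C.

    ``dic_excess`` defaults to the pool's atom% above the natural-abundance
    VPDB value; Gaussian noise (permil) is added to the final delta.
    Returns a :class:`nitriflux.carbon_fixation.TracerCarbonSample`.
    """
    from .carbon_fixation import TracerCarbonSample

    if tissue_carbon <= 0 or duration <= 0:
        raise ValidationError("tissue_carbon and duration must be > 0")
    if dic_excess is None:
        dic_excess = dic.atom_percent_13c - delta13c_to_atom_percent(0.0)
    if dic_excess <= 0:
        raise ValidationError("DIC pool must be enriched above background")
    at_initial = delta13c_to_atom_percent(delta13c_initial)
    at_final = at_initial + true_rate * duration * dic_excess / tissue_carbon
    if at_final >= 100:
        raise SimulationError("simulated tissue enrichment exceeds 100 atom%")
    delta_final = atom_percent_to_delta(at_final)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        delta_final += rng.normal(0.0, noise_sd)
    return TracerCarbonSample(
        delta13c_initial=delta13c_initial,
        delta13c_final=delta_final,
        tissue_carbon=tissue_carbon,
        duration=duration,
        dic_excess=dic_excess,
    )


def simulate_qpcr(
    true_copies_per_g: float,
    efficiency: float = 1.0,
    intercept: float = 38.0,
    cq_noise_sd: float = 0.0,
    seed: int = 0,
    template_ul: float = 1.0,
    elution_ul: float = 100.0,
    tissue_g: float = 0.1,
    replicates: int = 2,
    sample_id: str = "sample1",
) -> pd.DataFrame:
    """Standard dilution series (10^6..10^0 copies/ul) plus an unknown sample.

    Cq = intercept - log10(copies) / log10(1 + efficiency) + Gaussian noise;
    an efficiency of 1 (perfect doubling) gives slope -3.3219.  Output rows
    follow the qPCR input schema consumed by
    :func:`nitriflux.abundance.quantify_samples`.
    """
    if not 0.7 < efficiency <= 1.1:
        raise ValidationError(f"efficiency must lie in (0.7, 1.1], got {efficiency}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    slope = -1.0 / math.log10(1.0 + efficiency)

    def cq_for(copies_per_ul: float) -> float:
        cq = intercept + slope * math.log10(copies_per_ul)
        if cq_noise_sd > 0:
            cq += rng.normal(0.0, cq_noise_sd)
        return cq

    rows = []
    well = 0
    for exp in range(6, -1, -1):
        copies = 10.0**exp
        for _ in range(replicates):
            well += 1
            rows.append(
                dict(
                    sample_id=f"std_1e{exp}",
                    target="16S",
                    well=f"W{well}",
                    cq=cq_for(copies),
                    is_standard=True,
                    standard_copies_per_ul=copies,
                    template_ul=template_ul,
                    elution_ul=elution_ul,
                    tissue_g=tissue_g,
                )
            )
    unknown_copies_per_ul = true_copies_per_g * tissue_g / elution_ul
    for _ in range(replicates):
        well += 1
        rows.append(
            dict(
                sample_id=sample_id,
                target="16S",
                well=f"W{well}",
                cq=cq_for(unknown_copies_per_ul),
                is_standard=False,
                standard_copies_per_ul=math.nan,
                template_ul=template_ul,
                elution_ul=elution_ul,
                tissue_g=tissue_g,
            )
        )
    return pd.DataFrame(rows)


def simulate_proteome(
    true_shares: dict[str, float],
    n_proteins: int = 200,
    depth: int = 100_000,
    seed: int = 0,
    sample_ids: tuple[str, ...] = ("S1",),
) -> pd.DataFrame:
    """Multinomial spectral counts whose expected bin NSAF shares equal
    ``true_shares``.

    Protein sampling weights are proportional to share * length (within a
    bin each protein gets weight share_b * L_k / n_b), so SpC/L — and hence
    NSAF — is flat within a bin and bin NSAF shares recover the inputs.
    Lengths are log-normal.  Returns a spectral-count table in the schema of
    :mod:`nitriflux.proteomics`.
    """
    if abs(sum(true_shares.values()) - 1.0) > 1e-9:
        raise ValidationError("true_shares must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    bins = sorted(true_shares)
    # allocate proteins to bins roughly proportionally, at least one each
    alloc = {b: max(1, round(true_shares[b] * n_proteins)) for b in bins}
    rows = []
    pid = 0
    weights = []
    meta = []
    for b in bins:
        n_b = alloc[b]
        lengths = np.exp(rng.normal(math.log(300.0), 0.35, size=n_b))
        for L in lengths:
            pid += 1
            meta.append((f"P{pid:05d}", b, float(L)))
            weights.append(true_shares[b] * L / n_b)
    weights = np.asarray(weights)
    probs = weights / weights.sum()
    for sample in sample_ids:
        counts = rng.multinomial(depth, probs)
        for (protein_id, b, L), spc in zip(meta, counts):
            rows.append(
                dict(
                    protein_id=protein_id,
                    sample_id=sample,
                    spectral_count=int(spc),
                    length_aa=max(1.0, L),
                    bin=b,
                    category="",
                    exclusive_unique_peptides=2 + rng.poisson(3),
                    is_decoy=False,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy genomes

_BASES = np.array(list("ACGT"))


def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def mutate_sequence(seq: str, rate: float, rng) -> str:
    """Substitute each site with probability ``rate`` to a different base."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_genome_pair(
    n_genes: int = 20,
    mean_identity: float = 98.0,
    seed: int = 0,
    length_range: tuple[int, int] = (300, 1500),
    with_decoys: bool = True,
):
    """Toy gene-set pair with controlled pairwise identity, plus hit tables.

    Genome B genes are genome A genes mutated at per-site rate
    1 - mean_identity/100.  The returned hit tables (A->B and B->A, in the
    14-column dialect) contain the true pairings at their observed per-site
    identity plus, optionally, decoy hits that are always outscored.
    Returns (records_a, records_b, hits_ab, hits_ba, truth) where truth maps
    each A gene to its partner and observed identity.
    """
    if not 50.0 < mean_identity <= 100.0:
        raise ValidationError(
            f"mean_identity must lie in (50, 100], got {mean_identity}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rate = 1.0 - mean_identity / 100.0
    records_a, records_b = [], []
    rows_ab, rows_ba = [], []
    truth = {}
    ids_a = [f"a{i:03d}" for i in range(n_genes)]
    ids_b = [f"b{i:03d}" for i in range(n_genes)]
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_genes)

    def hit_row(q, s, ident, length):
        return dict(
            query=q, subject=s, identity=ident, align_length=length,
            mismatches=round(length * (1 - ident / 100)), gap_opens=0,
            qstart=1, qend=length, sstart=1, send=length, evalue=1e-50,
            bitscore=2.0 * length * ident / 100.0,
            query_length=length, subject_length=length,
        )

    for qa, qb, L in zip(ids_a, ids_b, lengths):
        seq_a = _random_sequence(rng, int(L))
        seq_b = mutate_sequence(seq_a, rate, rng)
        ident = 100.0 * sum(x == y for x, y in zip(seq_a, seq_b)) / L
        records_a.append(SeqRecord(Seq(seq_a), id=qa, description=""))
        records_b.append(SeqRecord(Seq(seq_b), id=qb, description=""))
        truth[qa] = {"partner": qb, "identity": ident, "length": int(L)}
        rows_ab.append(hit_row(qa, qb, ident, int(L)))
        rows_ba.append(hit_row(qb, qa, ident, int(L)))
        if with_decoys and n_genes > 1:
            other = ids_b[(ids_b.index(qb) + 1) % n_genes]
            decoy = hit_row(qa, other, ident * 0.5, int(L))
            decoy["bitscore"] *= 0.4
            rows_ab.append(decoy)
            other_a = ids_a[(ids_a.index(qa) + 1) % n_genes]
            decoy = hit_row(qb, other_a, ident * 0.5, int(L))
            decoy["bitscore"] *= 0.4
            rows_ba.append(decoy)
    return (
        records_a,
        records_b,
        pd.DataFrame(rows_ab),
        pd.DataFrame(rows_ba),
        truth,
    )


def fragment_hit_tables(
    records_a, records_b, width: int = 1020
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positional fragment hit tables for a co-linear genome pair.

    Both genomes are fragmented; homologous fragments (same contig index and
    offset — the toy pair has no indels) are compared site-by-site to yield
    identity.  Produces reciprocal hit tables for
    :func:`nitriflux.compgen.ani_fragment`.
    """
    from .compgen import fragment_genome

    frags_a = fragment_genome(records_a, width)
    frags_b = fragment_genome(records_b, width)
    contig_map = {a.id: b.id for a, b in zip(records_a, records_b)}
    by_id_b = {f.id: f for f in frags_b}
    rows_ab, rows_ba = [], []
    for fa in frags_a:
        contig, offset = fa.id.split(":", 1)
        fb = by_id_b.get(f"{contig_map[contig]}:{offset}")
        if fb is None:
            continue
        ident = 100.0 * sum(
            x == y for x, y in zip(str(fa.seq), str(fb.seq))
        ) / width
        base = dict(
            identity=ident, align_length=width,
            mismatches=round(width * (1 - ident / 100)), gap_opens=0,
            qstart=1, qend=width, sstart=1, send=width, evalue=1e-50,
            bitscore=2.0 * width * ident / 100.0,
            query_length=width, subject_length=width,
        )
        rows_ab.append(dict(query=fa.id, subject=fb.id, **base))
        rows_ba.append(dict(query=fb.id, subject=fa.id, **base))
    return pd.DataFrame(rows_ab), pd.DataFrame(rows_ba)
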