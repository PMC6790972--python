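"""End-to-end orchestration: incubation design -> rate tables -> couplings.

Runs the full analysis over a multi-treatment, multi-day incubation design
(synthetic by default): gross nitrification by pool dilution on the
gross-measurement days, net DIN fluxes over the 6-18 h window, the paired
gross-vs-net regression, carbon fixation from end-point tissue 13C with the
N:C coupling fit, and cell-specific ammonia-oxidation rates from qPCR
abundances.  The unit of analysis is the container-day (clones move to
fresh containers daily).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import abundance, carbon_fixation, chem, pool_dilution, synthdata
from .errors import ValidationError


@dataclass(frozen=True)
class TreatmentSpec:
    """One ammonium-amendment treatment arm of the incubation design."""

    name: str
    nh4_initial: float  # uM
    gross_production: float  # uM d-1, true volumetric gross rate
    nox_consumption: float = 0.5  # uM d-1
    replicates: int = 3


@dataclass(frozen=True)
class RunManifest:
    """Resolved configuration of a pipeline run.

    The default design mirrors a 7-day incubation: triplicate clones under
    ambient, +25 uM and +100 uM ammonium; pool-dilution measurements on days
    1, 3 and 5 (0 h / 20 h sampling); net fluxes on days 1, 3, 5 and 7
    (6-18 h window); end-point tissue 13C and qPCR on day 7.
    """

    seed: int = 0
    output_dir: str | None = None
    treatments: tuple[TreatmentSpec, ...] = (
        TreatmentSpec("ambient", 0.29, 5.0),
        TreatmentSpec("nh4_25uM", 25.0, 8.0),
        TreatmentSpec("nh4_100uM", 100.0, 12.0),
    )
    gross_days: tuple[int, ...] = (1, 3, 5)
    net_days: tuple[int, ...] = (1, 3, 5, 7)
    volume: float = 1.5  # L
    wet_weight: float = 5.1  # g
    nitrate_pool: float = 10.0  # uM pre-label NO2-+NO3-
    label_fraction: float = 0.10
    conc_noise_sd: float = 0.05  # uM
    ape_noise_sd: float = 0.02  # atom%
    nc_ratio: float = 43.0  # true gross-N : fixed-C ratio of the synthetic world
    tissue_carbon: float = 100.0  # umol C g-1
    delta13c_noise_sd: float = 0.2  # permil
    copies_per_g: float = 1.64e10  # true symbiont 16S copies per g on day 7
    cq_noise_sd: float = 0.15

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "treatments" in raw:
            raw["treatments"] = tuple(
                TreatmentSpec(**t) for t in raw["treatments"]
            )
        for key in ("gross_days", "net_days"):
            if key in raw:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown manifest keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Tables and fits produced by one pipeline run."""

    rates: pd.DataFrame  # per container-day gross/net estimates
    gross_net: pd.DataFrame  # paired gross vs net nitrification
    gross_net_fit: dict  # OLS of gross on net
    coupling: carbon_fixation.CouplingFit | None
    coupling_pairs: pd.DataFrame
    cell_rates: pd.DataFrame
    truth: dict


def _label_dic() -> chem.MixedDIC:
    """DIC pool after one 100 uM 99 atom% bicarbonate addition to seawater."""
    background = chem.DICPool(1975.0, chem.delta13c_to_atom_percent(0.0))
    return chem.mix_dic_label(background, [chem.DICPool(100.0, 99.0)])


def run_pipeline(manifest: RunManifest) -> PipelineResult:
    """Execute the synthetic-design pipeline described by the manifest."""
    out_dir = Path(manifest.output_dir) if manifest.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        resolved = dataclasses.asdict(manifest)
        (out_dir / "manifest-resolved.json").write_text(
            json.dumps(resolved, indent=2, default=str)
        )

    root = np.random.SeedSequence(manifest.seed)
    rate_rows = []
    gross_net_rows = []
    coupling_pairs = []
    cell_rows = []
    truth: dict = {"treatments": {}}
    all_days = sorted(set(manifest.gross_days) | set(manifest.net_days))
    dic = _label_dic()

    for t_idx, treatment in enumerate(manifest.treatments):
        truth["treatments"][treatment.name] = {
            "gross_production_uM_d": treatment.gross_production,
            "gross_production_specific": treatment.gross_production
            * manifest.volume
            / manifest.wet_weight,
        }
        for rep in range(treatment.replicates):
            rep_seed = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
            day_seq = np.random.SeedSequence(rep_seed)
            last_gross_specific = None
            for day in all_days:
                cid = f"{treatment.name}-r{rep + 1}-d{day}"
                sub = int(day_seq.spawn(1)[0].generate_state(1)[0] % 2**31)
                config = synthdata.SimulationConfig(
                    seed=sub,
                    gross_production=treatment.gross_production,
                    nox_consumption=treatment.nox_consumption,
                    nh4_excretion=treatment.gross_production + 2.0,
                    volume=manifest.volume,
                    wet_weight=manifest.wet_weight,
                    label=pool_dilution.LabelPlan(
                        manifest.nitrate_pool, manifest.label_fraction
                    ),
                    nh4_initial=treatment.nh4_initial,
                    conc_noise_sd=manifest.conc_noise_sd,
                    ape_noise_sd=manifest.ape_noise_sd,
                )
                series, _ = synthdata.simulate_incubation(config, cid)

                gross_specific = None
                if day in manifest.gross_days:
                    t, nox = series.concentration("nox")
                    iso = dict(series.isotope_samples)
                    res = pool_dilution.gross_rates_ipd(
                        c0=float(nox[t == 0.0][0]),
                        ct=float(nox[t == 20.0][0]),
                        ape0=iso[0.0],
                        apet=iso[20.0],
                        dt=20.0 / pool_dilution.HOURS_PER_DAY,
                    )
                    gross_specific = pool_dilution.to_specific_rate(
                        res.production, series.volume, series.wet_weight
                    )
                    last_gross_specific = gross_specific
                    rate_rows.append(
                        dict(
                            container_id=cid, treatment=treatment.name, day=day,
                            kind="gross_production", value=gross_specific,
                            flags=";".join(res.flags),
                        )
                    )

                if day in manifest.net_days:
                    fluxes = {
                        sp: pool_dilution.net_flux(series, sp)
                        for sp in ("nh4", "no2", "no3")
                    }
                    net_nit = pool_dilution.net_nitrification(
                        fluxes["no2"], fluxes["no3"]
                    )
                    for sp, fl in fluxes.items():
                        rate_rows.append(
                            dict(
                                container_id=cid, treatment=treatment.name,
                                day=day, kind=f"net_flux_{sp}",
                                value=fl.value, flags=";".join(fl.flags),
                            )
                        )
                    rate_rows.append(
                        dict(
                            container_id=cid, treatment=treatment.name, day=day,
                            kind="net_nitrification", value=net_nit.value,
                            flags=";".join(net_nit.flags),
                        )
                    )
                    if gross_specific is not None:
                        gross_net_rows.append(
                            dict(
                                container_id=cid, treatment=treatment.name,
                                day=day, gross=gross_specific, net=net_nit.value,
                            )
                        )
                    if day == max(all_days):
                        # day-7 cell-specific rate from simulated qPCR
                        qseed = int(
                            day_seq.spawn(1)[0].generate_state(1)[0] % 2**31
                        )
                        qpcr = synthdata.simulate_qpcr(
                            manifest.copies_per_g,
                            cq_noise_sd=manifest.cq_noise_sd,
                            seed=qseed,
                            sample_id=cid,
                        )
                        _, records = abundance.quantify_samples(qpcr)
                        cell_rows.append(
                            dict(
                                container_id=cid, treatment=treatment.name,
                                day=day,
                                copies_per_g=records[0].copies_per_g,
                                cell_rate_fmol=abundance.cell_specific_rate(
                                    net_nit.value, records[0].copies_per_g
                                ),
                            )
                        )

            # end-point tissue 13C on the final day, one sample per replicate
            true_gross_specific = (
                treatment.gross_production * manifest.volume / manifest.wet_weight
            )
            cseed = int(day_seq.spawn(1)[0].generate_state(1)[0] % 2**31)
            true_cfix = true_gross_specific / manifest.nc_ratio
            sample = synthdata.simulate_tissue_labeling(
                true_rate=true_cfix,
                tissue_carbon=manifest.tissue_carbon,
                dic=dic,
                duration=float(max(all_days)),
                noise_sd=manifest.delta13c_noise_sd,
                seed=cseed,
                dic_excess=dic.atom_percent_excess,
            )
            cfix = carbon_fixation.fixation_rate(sample)
            if last_gross_specific is not None:
                coupling_pairs.append(
                    dict(
                        treatment=treatment.name, replicate=rep + 1,
                        carbon_fixation=cfix.value,
                        gross_nitrification=last_gross_specific,
                    )
                )

    rates = pd.DataFrame(rate_rows)
    gross_net = pd.DataFrame(gross_net_rows)
    if len(gross_net) >= 2 and gross_net["net"].nunique() > 1:
        fit = stats.linregress(gross_net["net"], gross_net["gross"])
        gross_net_fit = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r2": float(fit.rvalue**2),
        }
    else:
        gross_net_fit = {}
    pairs_df = pd.DataFrame(coupling_pairs)
    coupling = None
    if len(pairs_df) >= 2:
        coupling = carbon_fixation.nc_coupling(
            list(zip(pairs_df["carbon_fixation"], pairs_df["gross_nitrification"]))
        )
    cell_rates = pd.DataFrame(cell_rows)
    truth["nc_ratio"] = manifest.nc_ratio
    truth["copies_per_g"] = manifest.copies_per_g

    result = PipelineResult(
        rates=rates,
        gross_net=gross_net,
        gross_net_fit=gross_net_fit,
        coupling=coupling,
        coupling_pairs=pairs_df,
        cell_rates=cell_rates,
        truth=truth,
    )
    if out_dir:
        rates.to_csv(out_dir / "rates.csv", index=False)
        gross_net.to_csv(out_dir / "gross_net.csv", index=False)
        pairs_df.to_csv(out_dir / "coupling.csv", index=False)
        cell_rates.to_csv(out_dir / "cellrates.csv", index=False)
        summary = {
            "gross_net_fit": gross_net_fit,
            "coupling": dataclasses.asdict(coupling) if coupling else None,
            "truth": truth,
        }
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=float)
        )
    return result
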