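"""NSAF quantification of spectral-count data with identification filters.

The normalized spectral abundance factor of protein k in a sample is

    NSAF_k = (SpC_k / L_k) / sum_i (SpC_i / L_i)

(spectral count over protein length, normalized to sum to one per sample).
Identification filtering requires a minimum number of exclusively unique
peptides per protein, and the protein-level false-discovery rate is
estimated from a concatenated target-decoy search as FDR = 2D/(T+D).
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

REQUIRED_COLUMNS = [
    "protein_id", "sample_id", "spectral_count", "length_aa",
    "bin", "category", "exclusive_unique_peptides", "is_decoy",
]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"spectral-count table missing columns {missing}")
    if (table["spectral_count"] < 0).any():
        raise ValidationError("spectral counts must be >= 0")
    if (table["length_aa"] <= 0).any():
        raise ValidationError("protein lengths must be > 0")
    return table


def estimate_fdr(n_target: int, n_decoy: int, convention: str = "concatenated") -> float:
    """Protein-level FDR from target/decoy identification counts.

    'concatenated' uses 2D/(T+D); 'simple' uses D/T.
    """
    if n_target <= 0:
        raise ValidationError("FDR undefined with no target identifications")
    if n_decoy < 0:
        raise ValidationError("decoy count must be >= 0")
    if convention == "concatenated":
        return 2.0 * n_decoy / (n_target + n_decoy)
    if convention == "simple":
        return n_decoy / n_target
    raise ValidationError(f"unknown FDR convention {convention!r}")


def filter_identifications(
    table: pd.DataFrame, min_unique_peptides: int = 2
) -> pd.DataFrame:
    """Drop proteins below the unique-peptide threshold, and all decoys.

    Returns the filtered table; the removal tally is attached as
    ``.attrs['filter_tally']``.
    """
    validate_table(table)
    below = table["exclusive_unique_peptides"] < min_unique_peptides
    decoy = table["is_decoy"].astype(bool)
    kept = table[~below & ~decoy].copy()
    kept.attrs["filter_tally"] = {
        "input_rows": len(table),
        "removed_below_threshold": int(below.sum()),
        "removed_decoys": int((decoy & ~below).sum()),
        "retained": len(kept),
    }
    return kept


def nsaf(table: pd.DataFrame, sample: str) -> pd.Series:
    """Per-protein NSAF values for one sample (indexed by protein_id, sums to 1)."""
    validate_table(table)
    sub = table[table["sample_id"] == sample]
    if len(sub) == 0 or (sub["spectral_count"] <= 0).all():
        raise ValidationError(
            f"sample {sample!r} has no positive spectral counts"
        )
    saf = sub["spectral_count"] / sub["length_aa"]
    values = saf / saf.sum()
    values.index = sub["protein_id"]
    return values.rename("nsaf")


def nsaf_all_samples(table: pd.DataFrame) -> pd.DataFrame:
    """NSAF per protein per sample, long format (protein_id, sample_id, nsaf).

    Proteins absent (zero counts) in a sample contribute NSAF 0 there.
    """
    frames = []
    for sample in sorted(table["sample_id"].unique()):
        vals = nsaf(table, sample).reset_index()
        vals["sample_id"] = sample
        frames.append(vals)
    return pd.concat(frames, ignore_index=True)


def aggregate_nsaf(table: pd.DataFrame, group_by: str = "bin") -> pd.DataFrame:
    """Group NSAF shares (%) averaged across samples, with count shares.

    ``group_by`` is 'bin' or 'category'.  Per sample, the group share is the
    summed NSAF of the group's proteins (NSAF already sums to one per
    sample); shares are then arithmetically averaged over samples and
    expressed as percent.  Proteins with a null/empty group label are
    collected under 'unassigned'.  Protein-count shares (percent of distinct
    proteins) are reported alongside.
    """
    if group_by not in ("bin", "category"):
        raise ValidationError(f"group_by must be 'bin' or 'category', got {group_by!r}")
    validate_table(table)
    work = table.copy()
    work[group_by] = work[group_by].fillna("unassigned").replace("", "unassigned")
    per_sample = nsaf_all_samples(work)
    groups = work[["protein_id", group_by]].drop_duplicates("protein_id")
    merged = per_sample.merge(groups, on="protein_id", how="left")
    shares = (
        merged.groupby(["sample_id", group_by])["nsaf"].sum().unstack(fill_value=0.0)
    )
    mean_share = shares.mean(axis=0) * 100.0
    n_proteins = groups.groupby(group_by)["protein_id"].nunique()
    count_share = 100.0 * n_proteins / n_proteins.sum()
    out = pd.DataFrame(
        {"nsaf_percent": mean_share, "protein_count_percent": count_share}
    ).fillna(0.0)
    out.index.name = group_by
    return out.sort_index()
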