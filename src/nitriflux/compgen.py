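"""Comparative-genomics metrics: assembly stats, AAI, fragment ANI, families.

These are the selection/aggregation mathematics over pre-computed alignment
hit tables (BLAST tabular dialect with qlen/slen); the aligner itself is
external.  Average amino acid identity (AAI) follows the
bidirectional-best-hit convention: per direction the best hit per query by
bitscore, filtered to alignments covering at least 70% of the query length,
reciprocal pairs retained, and identities averaged weighted by gene length.
Fragment-based ANI chops both genomes into fixed windows, keeps reciprocal
best fragment mappings above an identity floor, and reports their mean
identity plus the aligned fraction of the smaller genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import NoAlignmentError, NoReciprocalHitsError, ValidationError

HIT_COLUMNS = [
    "query", "subject", "identity", "align_length", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "query_length", "subject_length",
]

DNA_UNAMBIGUOUS = set("ACGT")
DNA_AMBIGUOUS = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class AssemblyStats:
    """Summary statistics of a genome assembly."""

    n_contigs: int
    total_length: int
    gc_percent: float
    n50: int


@dataclass(frozen=True)
class AaiResult:
    """Average amino acid identity over bidirectional best hits.

    aai is the headline value (weighted by the A->B query length); the
    reciprocal weighting, the unweighted mean, and the symmetrized mean of
    the two weighted values are reported alongside.
    """

    aai: float
    n_bbh: int
    aai_reverse_weighted: float
    aai_unweighted: float

    @property
    def aai_symmetric(self) -> float:
        return 0.5 * (self.aai + self.aai_reverse_weighted)


@dataclass(frozen=True)
class AniResult:
    """Fragment-based average nucleotide identity."""

    ani: float
    aligned_fraction: float
    n_fragments: int


def read_hit_table(path) -> pd.DataFrame:
    """Read a 14-column BLAST tabular file (outfmt 6 plus qlen, slen)."""
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None)


def assembly_stats(contigs) -> AssemblyStats:
    """Contig count, total length, GC% and N50 of a set of SeqRecords.

    GC is (G+C)/(A+C+G+T); IUPAC ambiguity codes are excluded from both
    numerator and denominator.  N50 is the shortest contig length at which
    the cumulative length of contigs at least that long reaches half the
    assembly.
    """
    lengths = []
    gc = at = 0
    for rec in contigs:
        seq = str(rec.seq).upper()
        if not seq:
            continue
        if not set(seq) <= DNA_AMBIGUOUS:
            bad = sorted(set(seq) - DNA_AMBIGUOUS)
            raise ValidationError(
                f"record {rec.id!r} has non-nucleotide characters {bad}"
            )
        lengths.append(len(seq))
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if not lengths:
        raise ValidationError("no non-empty sequences in assembly")
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = 0
    for L in sorted(lengths, reverse=True):
        cum += L
        if cum >= half:
            n50 = L
            break
    gc_percent = 100.0 * gc / (gc + at) if gc + at else 0.0
    return AssemblyStats(
        n_contigs=len(lengths), total_length=total, gc_percent=gc_percent, n50=n50
    )


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One best hit per query: highest bitscore, then identity, then
    lexicographically smallest subject id (deterministic tie-break)."""
    ordered = hits.sort_values(
        ["query", "bitscore", "identity", "subject"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("query", keep="first")


def aai(
    a_to_b: pd.DataFrame,
    b_to_a: pd.DataFrame,
    coverage_threshold: float = 0.70,
) -> AaiResult:
    """Length-weighted AAI from reciprocal best hits of two hit tables.

    Pipeline per direction: best hit per query by bitscore; drop hits whose
    alignment covers less than ``coverage_threshold`` of the query length;
    keep pairs that are reciprocal best hits.  AAI is the identity mean
    weighted by the A->B query gene length.
    """
    if len(a_to_b) == 0 or len(b_to_a) == 0:
        raise ValidationError("hit tables must be non-empty")
    tally: dict[str, int] = {}

    def filtered_best(hits: pd.DataFrame, label: str) -> pd.DataFrame:
        best = _best_hits(hits)
        covered = best[
            best["align_length"] >= coverage_threshold * best["query_length"]
        ]
        tally[f"{label}_best"] = len(best)
        tally[f"{label}_failed_coverage"] = len(best) - len(covered)
        return covered

    fwd = filtered_best(a_to_b, "a_to_b")
    rev = filtered_best(b_to_a, "b_to_a")
    rev_best = dict(zip(rev["query"], rev["subject"]))
    pairs = fwd[
        fwd.apply(lambda r: rev_best.get(r["subject"]) == r["query"], axis=1)
    ] if len(fwd) else fwd
    tally["reciprocal_pairs"] = len(pairs)
    if len(pairs) == 0:
        raise NoReciprocalHitsError(
            f"no_bbh: no reciprocal best hits survived the filters ({tally})",
            tally,
        )
    w = pairs["query_length"].to_numpy(dtype=float)
    ident = pairs["identity"].to_numpy(dtype=float)
    rev_idx = rev.set_index("query")
    rev_pairs = rev_idx.loc[pairs["subject"]]
    w_rev = rev_pairs["query_length"].to_numpy(dtype=float)
    ident_rev = rev_pairs["identity"].to_numpy(dtype=float)
    return AaiResult(
        aai=float(np.average(ident, weights=w)),
        n_bbh=len(pairs),
        aai_reverse_weighted=float(np.average(ident_rev, weights=w_rev)),
        aai_unweighted=float(ident.mean()),
    )


def fragment_genome(contigs, width: int = 1020) -> list[SeqRecord]:
    """Chop contigs into non-overlapping windows of ``width`` bp.

    Terminal remainders shorter than the width are discarded.  Fragment ids
    are ``<contig>:<start>-<end>`` with 0-based half-open coordinates.
    """
    if not width > 0:
        raise ValidationError(f"width must be > 0 bp, got {width}")
    fragments = []
    for rec in contigs:
        seq = str(rec.seq)
        for start in range(0, len(seq) - width + 1, width):
            fragments.append(
                SeqRecord(
                    Seq(seq[start : start + width]),
                    id=f"{rec.id}:{start}-{start + width}",
                    description="",
                )
            )
    return fragments


def ani_fragment(
    a_to_b_fragments: pd.DataFrame,
    b_to_a_fragments: pd.DataFrame,
    smaller_genome_length: int,
    fragment_width: int = 1020,
    identity_floor: float = 70.0,
) -> AniResult:
    """ANI from reciprocal best mappings of fixed-width genome fragments.

    Fragments are retained when they map reciprocally and with identity at
    or above ``identity_floor``%.  ANI is the mean identity of retained
    fragments; aligned_fraction is their summed width over the smaller
    genome length.
    """
    fwd = _best_hits(a_to_b_fragments)
    rev = _best_hits(b_to_a_fragments)
    rev_best = dict(zip(rev["query"], rev["subject"]))
    keep = fwd[
        (fwd["identity"] >= identity_floor)
        & fwd.apply(lambda r: rev_best.get(r["subject"]) == r["query"], axis=1)
    ] if len(fwd) else fwd
    if len(keep) == 0:
        raise NoAlignmentError("no_alignment: no fragments retained above the floor")
    return AniResult(
        ani=float(keep["identity"].mean()),
        aligned_fraction=len(keep) * fragment_width / smaller_genome_length,
        n_fragments=len(keep),
    )


# ---------------------------------------------------------------------------
# gene-family algebra


@dataclass(frozen=True)
class PresenceMatrix:
    """Gene counts per (family, genome), as a families x genomes DataFrame."""

    counts: pd.DataFrame  # index: family ids; columns: genome ids

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("membership counts must be non-negative integers")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0).astype(int))


def exclusive_shared_families(
    matrix: PresenceMatrix, focal_set: set[str]
) -> tuple[int, list[str]]:
    """Families present in every focal genome and absent from all others."""
    genomes = set(matrix.counts.columns)
    unknown = set(focal_set) - genomes
    if unknown:
        raise ValidationError(f"unknown genome ids: {sorted(unknown)}")
    if len(focal_set) < 2:
        raise ValidationError("focal_set must contain >= 2 genomes")
    focal = sorted(focal_set)
    others = sorted(genomes - set(focal_set))
    df = matrix.counts
    mask = (df[focal] >= 1).all(axis=1)
    if others:
        mask &= (df[others] == 0).all(axis=1)
    fams = list(df.index[mask])
    return len(fams), fams


def family_category_fractions(
    matrix: PresenceMatrix, focal: str
) -> dict[str, float]:
    """Fractions of the focal genome's genes in core/unique/other families.

    core: families present in every genome; unique: families present only in
    the focal genome; other: the remainder.  Fractions are over focal gene
    counts and sum to 1.
    """
    df = matrix.counts
    if focal not in df.columns:
        raise ValidationError(f"unknown genome id: {focal!r}")
    present = df >= 1
    in_focal = present[focal]
    core = present.all(axis=1)
    others = [g for g in df.columns if g != focal]
    unique = in_focal & ~(present[others].any(axis=1) if others else False)
    total_genes = df.loc[in_focal, focal].sum()
    if total_genes == 0:
        return {"core": 0.0, "unique": 0.0, "other": 0.0}
    core_genes = df.loc[core & in_focal, focal].sum()
    unique_genes = df.loc[unique, focal].sum()
    return {
        "core": core_genes / total_genes,
        "unique": unique_genes / total_genes,
        "other": (total_genes - core_genes - unique_genes) / total_genes,
    }
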