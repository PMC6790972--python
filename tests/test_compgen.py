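import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from nitriflux import compgen as cg
from nitriflux import synthdata as sd
from nitriflux.errors import NoAlignmentError, NoReciprocalHitsError, ValidationError

from conftest import hit_frame, make_hit, random_hit_tables


def rec(seq, rid="x"):
    return SeqRecord(Seq(seq), id=rid)


class TestAssemblyStats:
    def test_single_contig(self):
        st = cg.assembly_stats([rec("GGCC")])
        assert (st.n_contigs, st.total_length, st.gc_percent) == (1, 4, 100.0)

    def test_two_contigs(self):
        st = cg.assembly_stats([rec("AT", "a"), rec("GC", "b")])
        assert st.gc_percent == pytest.approx(50.0)
        assert st.n50 == 2

    def test_ambiguity_codes_excluded(self):
        st = cg.assembly_stats([rec("ATGCN")])
        assert st.gc_percent == pytest.approx(50.0)
        assert st.total_length == 5

    def test_total_length_matches_independent_sum(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=int(n))) for n in rng.integers(50, 500, 12)]
        st = cg.assembly_stats([rec(s, f"c{i}") for i, s in enumerate(seqs)])
        assert st.total_length == sum(len(s) for s in seqs)

    def test_n50_definition(self):
        lengths = [10, 20, 30, 40]  # total 100, cumulative from largest: 40, 70
        st = cg.assembly_stats(
            [rec("A" * n, f"c{n}") for n in lengths]
        )
        assert st.n50 == 30

    def test_bad_alphabet_names_record(self):
        with pytest.raises(ValidationError, match="weird"):
            cg.assembly_stats([rec("ATGXQ", "weird")])

    def test_empty_input(self):
        with pytest.raises(ValidationError):
            cg.assembly_stats([])


def brute_force_aai(a_to_b, b_to_a, coverage=0.70):
    """Plain-loop BBH + weighted mean, independent of the pandas pipeline."""

    def best(hits):
        out = {}
        for row in hits.to_dict("records"):
            cur = out.get(row["query"])
            if cur is None:
                out[row["query"]] = row
            elif (row["bitscore"], row["identity"]) > (cur["bitscore"], cur["identity"]):
                out[row["query"]] = row
            elif (
                (row["bitscore"], row["identity"]) == (cur["bitscore"], cur["identity"])
                and row["subject"] < cur["subject"]
            ):
                out[row["query"]] = row
        return out

    fwd, rev = best(a_to_b), best(b_to_a)
    pairs = []
    for q, row in fwd.items():
        if row["align_length"] < coverage * row["query_length"]:
            continue
        partner = rev.get(row["subject"])
        if partner is None or partner["subject"] != q:
            continue
        if partner["align_length"] < coverage * partner["query_length"]:
            continue
        pairs.append(row)
    if not pairs:
        return None
    w = sum(r["query_length"] for r in pairs)
    return sum(r["identity"] * r["query_length"] for r in pairs) / w, len(pairs)


class TestAai:
    def test_weighted_mean(self, reciprocal_hits):
        res = cg.aai(*reciprocal_hits)
        assert res.aai == pytest.approx(63.3333, abs=1e-3)
        assert res.n_bbh == 3
        assert res.aai_unweighted == pytest.approx(60.0)

    def test_coverage_filter_excludes_short_alignment(self, reciprocal_hits):
        fwd, rev = reciprocal_hits
        # shrink one alignment to 65% of the query: pair must drop
        fwd = fwd.copy()
        fwd.loc[fwd["query"] == "a2", "align_length"] = 195  # 65% of 300
        res = cg.aai(fwd, rev)
        assert res.n_bbh == 2
        assert res.aai == pytest.approx((50 * 100 + 60 * 200) / 300.0)

    def test_decoy_hits_never_win(self):
        _, _, hits_ab, hits_ba, truth = sd.simulate_genome_pair(15, 95.0, seed=2)
        res = cg.aai(hits_ab, hits_ba)
        assert res.n_bbh == 15
        expected = np.average(
            [t["identity"] for t in truth.values()],
            weights=[t["length"] for t in truth.values()],
        )
        assert res.aai == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a_to_b, b_to_a = random_hit_tables(rng)
        expected = brute_force_aai(a_to_b, b_to_a)
        if expected is None:
            with pytest.raises(NoReciprocalHitsError):
                cg.aai(a_to_b, b_to_a)
        else:
            res = cg.aai(a_to_b, b_to_a)
            assert res.aai == pytest.approx(expected[0], rel=1e-12)
            assert res.n_bbh == expected[1]

    def test_no_bbh_error_carries_tally(self):
        fwd = hit_frame([make_hit("a0", "b0", 90.0, 50, 100.0, query_length=100)])
        rev = hit_frame([make_hit("b0", "a0", 90.0, 50, 100.0, query_length=100)])
        with pytest.raises(NoReciprocalHitsError) as exc:
            cg.aai(fwd, rev)
        assert exc.value.tally["a_to_b_failed_coverage"] == 1


class TestFragmentGenome:
    def test_window_coordinates(self):
        frags = cg.fragment_genome([rec("A" * 2500, "c1")], width=1020)
        assert [f.id for f in frags] == ["c1:0-1020", "c1:1020-2040"]

    def test_short_contig_skipped(self):
        assert cg.fragment_genome([rec("A" * 100, "c1")], width=1020) == []

    def test_length_conservation(self):
        rng = np.random.default_rng(0)
        contigs = [rec("A" * int(n), f"c{i}") for i, n in enumerate(rng.integers(100, 5000, 8))]
        width = 1020
        frags = cg.fragment_genome(contigs, width)
        expected = sum(width * (len(c.seq) // width) for c in contigs)
        assert sum(len(f.seq) for f in frags) == expected


class TestAniFragment:
    def make_pair(self, identity, seed=0, length=40000):
        rng = np.random.default_rng(seed)
        a = [rec("".join(rng.choice(list("ACGT"), size=length)), "g1")]
        b = [rec(sd.mutate_sequence(str(a[0].seq), 1 - identity / 100, rng), "g1m")]
        return a, b

    def test_identical_genomes(self):
        a, b = self.make_pair(100.0)
        fab, fba = sd.fragment_hit_tables(a, b)
        res = cg.ani_fragment(fab, fba, smaller_genome_length=40000)
        assert res.ani == pytest.approx(100.0)
        assert res.aligned_fraction == pytest.approx(39 * 1020 / 40000)

    def test_two_percent_divergence(self):
        a, b = self.make_pair(98.0, seed=3)
        fab, fba = sd.fragment_hit_tables(a, b)
        res = cg.ani_fragment(fab, fba, smaller_genome_length=40000)
        # binomial error on ~40 kb at 2% per site is well under 0.3 points
        assert res.ani == pytest.approx(98.0, abs=0.3)

    def test_unmapped_fragments_reduce_fraction(self):
        a, b = self.make_pair(100.0)
        fab, fba = sd.fragment_hit_tables(a, b)
        keep = fab["query"].iloc[: len(fab) // 2]
        fab_half = fab[fab["query"].isin(keep)]
        fba_half = fba[fba["subject"].isin(keep)]
        res = cg.ani_fragment(fab_half, fba_half, smaller_genome_length=40000)
        assert res.n_fragments == len(fab) // 2

    def test_identity_floor(self):
        a, b = self.make_pair(60.0, seed=4)
        fab, fba = sd.fragment_hit_tables(a, b)
        with pytest.raises(NoAlignmentError):
            cg.ani_fragment(fab, fba, smaller_genome_length=40000, identity_floor=70.0)


def brute_force_exclusive(counts: pd.DataFrame, focal: set):
    out = []
    for fam in counts.index:
        row = counts.loc[fam]
        if all(row[g] >= 1 for g in focal) and all(
            row[g] == 0 for g in counts.columns if g not in focal
        ):
            out.append(fam)
    return out


class TestFamilyAlgebra:
    MATRIX = pd.DataFrame(
        {
            "A": [1, 2, 1, 0, 3, 1],
            "B": [1, 1, 0, 1, 2, 0],
            "C": [1, 0, 0, 0, 1, 0],
            "D": [2, 0, 0, 0, 1, 0],
        },
        index=[f"f{i}" for i in range(6)],
    )

    def test_pair_exclusive(self):
        pm = cg.PresenceMatrix(self.MATRIX)
        n, fams = cg.exclusive_shared_families(pm, {"A", "B"})
        assert fams == ["f1"]  # f1 present only in A and B

    def test_superset_presence_not_counted(self):
        pm = cg.PresenceMatrix(self.MATRIX)
        # f4 is present in all four genomes: exclusive to no pair
        for pair in [{"A", "B"}, {"A", "C"}, {"C", "D"}]:
            _, fams = cg.exclusive_shared_families(pm, pair)
            assert "f4" not in fams

    def test_unknown_genome(self):
        pm = cg.PresenceMatrix(self.MATRIX)
        with pytest.raises(ValidationError):
            cg.exclusive_shared_families(pm, {"A", "Z"})

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(0, 3, size=(50, 4)),
            columns=list("ABCD"),
            index=[f"f{i}" for i in range(50)],
        )
        pm = cg.PresenceMatrix(counts)
        for focal in [{"A", "B"}, {"B", "C"}, {"A", "C", "D"}]:
            n, fams = cg.exclusive_shared_families(pm, focal)
            assert sorted(fams) == sorted(brute_force_exclusive(counts, focal))

    def test_pairwise_partition(self):
        """A family exclusive to pair (A,B) belongs to no other focal pair."""
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(
            rng.integers(0, 2, size=(60, 4)),
            columns=list("ABCD"),
            index=[f"f{i}" for i in range(60)],
        )
        pm = cg.PresenceMatrix(counts)
        import itertools

        seen = {}
        for pair in itertools.combinations("ABCD", 2):
            _, fams = cg.exclusive_shared_families(pm, set(pair))
            for fam in fams:
                assert fam not in seen, f"{fam} counted for {seen.get(fam)} and {pair}"
                seen[fam] = pair


class TestCategoryFractions:
    def test_all_core(self):
        counts = pd.DataFrame(
            {"A": [1, 2], "B": [1, 1], "C": [3, 1]}, index=["f0", "f1"]
        )
        fr = cg.family_category_fractions(cg.PresenceMatrix(counts), "A")
        assert fr["core"] == pytest.approx(1.0)

    def test_all_unique(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]}, index=["f0", "f1"])
        fr = cg.family_category_fractions(cg.PresenceMatrix(counts), "A")
        assert fr["unique"] == pytest.approx(1.0)

    def test_hand_tally_mixed_matrix(self):
        counts = pd.DataFrame(
            {
                "A": [2, 1, 3, 0, 1, 1],  # 8 genes in focal families
                "B": [1, 0, 1, 1, 0, 2],
                "C": [1, 0, 0, 0, 0, 1],
            },
            index=[f"f{i}" for i in range(6)],
        )
        # core (all genomes): f0, f5 -> 2+1 = 3 focal genes
        # unique (A only): f1, f4 -> 1+1 = 2 focal genes
        # other: f2 -> 3 genes; total focal genes = 8
        fr = cg.family_category_fractions(cg.PresenceMatrix(counts), "A")
        assert fr["core"] == pytest.approx(3 / 8)
        assert fr["unique"] == pytest.approx(2 / 8)
        assert fr["other"] == pytest.approx(3 / 8)
        assert sum(fr.values()) == pytest.approx(1.0)
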