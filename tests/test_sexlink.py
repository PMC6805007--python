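"""CQ / YGS contig scoring, candidate calling, SNP density and group
comparison."""

import numpy as np
import pandas as pd
import pytest

from wolbsex.sexlink import (
    KmerSet,
    call_candidates,
    canonical_kmers,
    count_kmers,
    cq_scores,
    depth_table,
    group_compare,
    snp_density,
    ygs_scores,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


class TestKmers:
    def test_strand_invariance(self):
        seq = "ACGTTGCAATGCGT"
        k1 = np.sort(canonical_kmers(seq, 5))
        k2 = np.sort(canonical_kmers(revcomp(seq), 5))
        assert np.array_equal(k1, k2)

    def test_ambiguous_bases_drop_windows(self):
        assert canonical_kmers("ACGTNACGT", 4).size == 2 * 1 + 0  # two clean windows
        assert canonical_kmers("NNNN", 2).size == 0

    def test_counts(self):
        ks = count_kmers(["AAAA", "AAAA"], 3)
        # AAA canonical occurs twice per sequence
        assert ks.kmers.size == 1
        assert ks.counts[0] == 4

    def test_short_sequence_empty(self):
        assert canonical_kmers("ACG", 5).size == 0


class TestDepthAndCq:
    def test_identical_read_sets_give_equal_depths(self, rng):
        contig = "".join(rng.choice(list("ACGT"), 300))
        reads = [contig[i : i + 50] for i in range(0, 250, 10)]
        table = depth_table({"c": contig}, reads, list(reads), k=21)
        assert table.loc[0, "male_depth"] == pytest.approx(table.loc[0, "female_depth"])

    def test_doubled_female_dose_doubles_the_ratio(self, rng):
        # X-diverged contig: twice in the female genome, once in the male
        # (whose second dose is a fully diverged Y); library sizes equal
        auto = "".join(rng.choice(list("ACGT"), 2000))
        xcon = "".join(rng.choice(list("ACGT"), 2000))
        ycon = "".join(rng.choice(list("ACGT"), 2000))

        def tile(seqs, step=25, rl=100):
            return [s[i : i + rl] for s in seqs for i in range(0, len(s) - rl + 1, step)]

        male = tile([auto, auto, xcon, ycon])
        female = tile([auto, auto, xcon, xcon])
        table = depth_table({"auto": auto, "x": xcon}, male, female, k=21)
        scored = cq_scores(table)
        cq = dict(zip(scored.contig_id, scored.cq))
        assert cq["auto"] == pytest.approx(1.0, rel=0.1)
        assert cq["x"] == pytest.approx(2.0, rel=0.1)

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            depth_table({"c": "ACGT" * 20}, [], ["ACGT"])

    @pytest.mark.parametrize(
        "female, male, expected", [(30, 30, 1.0), (0, 20, 0.0), (40, 20, 2.0)]
    )
    def test_cq_ratio(self, female, male, expected):
        df = pd.DataFrame(
            dict(contig_id=["c"], length=[100], male_depth=[male], female_depth=[female])
        )
        assert cq_scores(df).loc[0, "cq"] == pytest.approx(expected)

    def test_zero_male_depth_undefined_not_candidate(self):
        df = pd.DataFrame(
            dict(
                contig_id=["a", "b"],
                length=[100, 100],
                male_depth=[20.0, 0.0],
                female_depth=[20.0, 5.0],
            )
        )
        scored = cq_scores(df)
        assert np.isnan(scored.loc[1, "cq"])
        scored["ygs"] = [50.0, 50.0]
        called = call_candidates(scored, cq_max=10, ygs_min=0)
        assert not called.loc[1, "candidate"]


class TestYgs:
    def _sets(self, contig, female_seqs, k=5):
        return (
            count_kmers([contig], k, "assembly"),
            count_kmers(female_seqs * 2, k, "female_reads"),  # count >= 2
        )

    def test_fully_matched_scores_zero(self, rng):
        contig = "".join(rng.choice(list("ACGT"), 100))
        ak, fk = self._sets(contig, [contig])
        assert ygs_scores({"c": contig}, ak, fk).loc[0, "ygs"] == 0.0

    def test_fully_unmatched_scores_hundred(self, rng):
        # k long enough that two random sequences share no k-mer
        contig = "".join(rng.choice(list("ACGT"), 100))
        other = "".join(rng.choice(list("ACGT"), 100))
        ak, fk = self._sets(contig, [other], k=13)
        assert ygs_scores({"c": contig}, ak, fk).loc[0, "ygs"] == pytest.approx(100.0)

    def test_half_matched_scores_fifty(self):
        # two disjoint halves; female reads cover only the first
        left, right = "ACGTACGTAC", "GGATCCGGAT"
        contig = left + right
        ak = count_kmers([contig], 10, "assembly")
        fk = count_kmers([left] * 2, 10, "female_reads")
        table = ygs_scores({"c": contig}, ak, fk)
        # contig has 11 k-mers of size 10; exactly one (the pure left half) matches
        assert table.loc[0, "ygs"] == pytest.approx(100.0 * 10 / 11)

    def test_invariant_to_duplicating_female_reads(self, rng):
        contig = "".join(rng.choice(list("ACGT"), 200))
        female = [contig[:120]] * 2
        ak = count_kmers([contig], 7, "assembly")
        y1 = ygs_scores({"c": contig}, ak, count_kmers(female, 7))
        y2 = ygs_scores({"c": contig}, ak, count_kmers(female * 5, 7))
        assert y1.loc[0, "ygs"] == pytest.approx(y2.loc[0, "ygs"])

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            ygs_scores({}, count_kmers(["ACGTACG"], 5), count_kmers(["ACGTACG"], 7))


class TestCandidates:
    @pytest.mark.parametrize(
        "cq, ygs, expected",
        [(0.2, 40.0, True), (0.2, 30.0, False), (1.0, 90.0, False), (0.35, 35.0, True)],
    )
    def test_default_thresholds(self, cq, ygs, expected):
        df = pd.DataFrame(dict(contig_id=["c"], cq=[cq], ygs=[ygs]))
        assert call_candidates(df).loc[0, "candidate"] == expected


class TestSnpDensity:
    def test_arithmetic(self):
        variants = pd.DataFrame(
            dict(
                chrom=["c"] * 10,
                pos=np.arange(1001, 1011),
                ref=["A"] * 10,
                alt=["G"] * 10,
                het=[True] * 10,
            )
        )
        mask = pd.DataFrame(dict(chrom=["c"], start=[4000], end=[5000]))
        out = snp_density(variants, {"c": 5000}, mask)
        assert out.loc[0, "snp_density"] == pytest.approx(10 / 4000 * 1000)

    def test_zero_snps(self):
        out = snp_density(
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "het"]), {"c": 1000}
        )
        assert out.loc[0, "snp_density"] == 0.0

    def test_masked_variants_and_length_excluded(self):
        variants = pd.DataFrame(
            dict(chrom=["c", "c"], pos=[50, 500], ref=["A", "C"], alt=["T", "G"], het=[True, True])
        )
        mask = pd.DataFrame(dict(chrom=["c"], start=[0], end=[100]))
        out = snp_density(variants, {"c": 1000}, mask)
        assert out.loc[0, "n_het_snps"] == 1
        assert out.loc[0, "unmasked_length"] == 900

    def test_fully_masked_contig_undefined(self):
        mask = pd.DataFrame(dict(chrom=["c"], start=[0], end=[1000]))
        out = snp_density(
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "het"]), {"c": 1000}, mask
        )
        assert np.isnan(out.loc[0, "snp_density"])

    def test_unknown_contig_rejected(self):
        variants = pd.DataFrame(
            dict(chrom=["zzz"], pos=[5], ref=["A"], alt=["T"], het=[True])
        )
        with pytest.raises(ValueError, match="zzz"):
            snp_density(variants, {"c": 1000})

    def test_non_snp_records_ignored(self):
        variants = pd.DataFrame(
            dict(
                chrom=["c", "c", "c"],
                pos=[10, 20, 30],
                ref=["A", "AT", "A"],
                alt=["G", "A", "G,T"],
                het=[True, True, True],
            )
        )
        out = snp_density(variants, {"c": 1000})
        assert out.loc[0, "n_het_snps"] == 1


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare([1, 2, 3, 1, 2, 3], [True, True, True, False, False, False])
        assert res["median_group"] == res["median_rest"]
        assert res["p_two_sided"] == pytest.approx(1.0)

    def test_complete_separation(self):
        res = group_compare([1, 2, 3, 4], [True, True, False, False])
        assert 0.0 in (res["u1"], res["u2"])

    def test_u_from_pairwise_wins(self, rng):
        v = rng.integers(0, 10, 10).astype(float)
        g = np.array([True] * 5 + [False] * 5)
        res = group_compare(v, g)
        wins = sum(1.0 for x in v[g] for y in v[~g] if x > y) + 0.5 * sum(
            1 for x in v[g] for y in v[~g] if x == y
        )
        assert res["u1"] == pytest.approx(wins)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], [True, True])
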