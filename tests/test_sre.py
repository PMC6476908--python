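"""SRE calling, quantification, decile partition and classification."""

import numpy as np
import pandas as pd
import pytest
from conftest import coverage_oracle, make_annotation, make_reads, segment_oracle

from spermkit import sre
from spermkit.simulate import SimulationConfig, generate_annotation, simulate_reads


class TestCallSres:
    def test_single_stack(self):
        reads = make_reads("s1", [("chr1", 100, 175)] * 5)
        out = sre.call_sres([reads], min_support=3, max_gap=0)
        assert list(out[["chrom", "start", "end"]].itertuples(index=False, name=None)) \
            == [("chr1", 100, 175)]

    def test_two_stacks_split_by_gap(self):
        reads = make_reads("s1", [("chr1", 100, 175)] * 5 + [("chr1", 675, 750)] * 5)
        out = sre.call_sres([reads], min_support=3, max_gap=0)
        assert len(out) == 2
        cov = coverage_oracle([(100, 175)] * 5 + [(675, 750)] * 5, 1000)
        assert list(out[["start", "end"]].itertuples(index=False, name=None)) \
            == segment_oracle(cov, 3, 0)

    def test_support_threshold(self):
        reads = make_reads("s1", [("chr1", 100, 175)] * 2)
        assert len(sre.call_sres([reads], min_support=3)) == 0

    def test_empty_input(self):
        assert len(sre.call_sres([], min_support=3)) == 0

    def test_gap_merging(self):
        # two stacks 100 bp apart merge iff max_gap >= 100
        reads = make_reads("s1", [("chr1", 0, 50)] * 4 + [("chr1", 150, 200)] * 4)
        assert len(sre.call_sres([reads], min_support=3, max_gap=99)) == 2
        assert len(sre.call_sres([reads], min_support=3, max_gap=100)) == 1

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_bruteforce_oracle(self, trial):
        """Randomized instances <= 100 kb agree with per-base segmentation."""
        rng = np.random.default_rng(1000 + trial)
        L = 10_000
        n = int(rng.integers(1, 120))
        starts = rng.integers(0, L - 80, size=n)
        lengths = rng.integers(1, 80, size=n)
        intervals = [("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)]
        min_support = int(rng.integers(1, 5))
        max_gap = int(rng.integers(0, 300))
        got = sre.call_sres([make_reads("s1", intervals)],
                            min_support=min_support, max_gap=max_gap)
        cov = coverage_oracle([(s, e) for _, s, e in intervals], L)
        expected = segment_oracle(cov, min_support, max_gap)
        assert list(got[["start", "end"]].itertuples(index=False, name=None)) == expected

    def test_output_disjoint_and_sorted(self):
        rng = np.random.default_rng(7)
        intervals = [("chr1", int(s), int(s) + 60) for s in rng.integers(0, 5000, 200)]
        out = sre.call_sres([make_reads("s1", intervals)], min_support=1, max_gap=10)
        assert (out["start"].diff().dropna() > 0).all()
        assert (out["start"].to_numpy()[1:] >= out["end"].to_numpy()[:-1]).all()


class TestQuantify:
    def test_rpkm_formula(self):
        sres = pd.DataFrame({"sre_id": ["SRE1"], "chrom": ["chr1"],
                             "start": [0], "end": [1000]})
        reads = make_reads("s1", [("chr1", i * 10, i * 10 + 50) for i in range(10)],
                           total=1_000_000)
        mat = sre.quantify_sres(sres, [reads])
        # 10 reads / 1 kb / 1 M mapped reads
        assert mat.values.loc["SRE1", "s1"] == pytest.approx(10.0)

    def test_no_overlap_zero(self):
        sres = pd.DataFrame({"sre_id": ["SRE1"], "chrom": ["chr1"],
                             "start": [0], "end": [100]})
        reads = make_reads("s1", [("chr2", 0, 50)], total=100)
        assert sre.quantify_sres(sres, [reads]).values.loc["SRE1", "s1"] == 0

    def test_identical_samples_sd_zero(self):
        sres = pd.DataFrame({"sre_id": ["SRE1"], "chrom": ["chr1"],
                             "start": [0], "end": [100]})
        reads = [make_reads(s, [("chr1", 10, 60)], total=1000) for s in ("a", "b", "c")]
        ms = sre.quantify_sres(sres, reads).mean_sd()
        assert ms.loc["SRE1", "abundance_sd"] == 0

    def test_zero_total_raises(self):
        sres = pd.DataFrame({"sre_id": ["SRE1"], "chrom": ["chr1"],
                             "start": [0], "end": [100]})
        reads = make_reads("s1", [], total=0)
        with pytest.raises(ZeroDivisionError):
            sre.quantify_sres(sres, [reads])

    def test_counts_match_bruteforce(self):
        """Overlap counting equals a per-read loop on a random instance."""
        rng = np.random.default_rng(5)
        starts = np.sort(rng.choice(np.arange(0, 5000, 10), 40, replace=False))
        sres = pd.DataFrame({"sre_id": [f"S{i}" for i in range(40)],
                             "chrom": "chr1", "start": starts, "end": starts + 8})
        intervals = [("chr1", int(s), int(s + l))
                     for s, l in zip(rng.integers(0, 5000, 300), rng.integers(1, 90, 300))]
        reads = make_reads("s1", intervals, total=10_000)
        got = sre.quantify_sres(sres, [reads]).values["s1"]
        for i, row in sres.iterrows():
            expected = sum(1 for _, a, b in intervals
                           if a < row["end"] and b > row["start"])
            rpkm = expected * 1e9 / ((row["end"] - row["start"]) * 10_000)
            assert got.iloc[i] == pytest.approx(rpkm)


class TestDeciles:
    def _matrix(self, means):
        vals = pd.DataFrame({"s1": means, "s2": means},
                            index=[f"S{i}" for i in range(len(means))])
        return sre.AbundanceMatrix(values=vals, unit="RPKM")

    def test_ten_distinct_one_per_decile(self):
        mat = self._matrix(list(range(10, 0, -1)))
        dec, _ = sre.partition_deciles(mat)
        assert list(dec) == list(range(1, 11))

    def test_uniform_mass_share(self):
        mat = self._matrix([5.0] * 10)
        _, share = sre.partition_deciles(mat)
        assert share[1] == pytest.approx(10.0)
        assert share.sum() == pytest.approx(100.0)

    def test_fewer_than_ten_raises(self):
        with pytest.raises(ValueError):
            sre.partition_deciles(self._matrix([1.0] * 9))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        means = rng.lognormal(0, 2, 50)
        mat = self._matrix(list(means))
        dec, _ = sre.partition_deciles(mat)
        perm = rng.permutation(50)
        mat2 = sre.AbundanceMatrix(values=mat.values.iloc[perm], unit="RPKM")
        dec2, _ = sre.partition_deciles(mat2)
        assert dec2.reindex(dec.index).equals(dec)

    def test_heavy_tail_calibration(self):
        """At default generator settings the top decile carries 55-75% of
        the abundance mass, matching the skew of the sperm transcriptome.

        A single cohort's share is dominated by its largest abundance draw,
        so the check averages over ten seeded cohorts.
        """
        shares = []
        for seed in range(1, 11):
            cfg = SimulationConfig(seed=seed)
            ann, _ = generate_annotation(cfg)
            reads, _ = simulate_reads(ann, cfg)
            called = sre.call_sres(list(reads.values()))
            mat = sre.quantify_sres(called, list(reads.values()))
            _, share = sre.partition_deciles(mat, called)
            shares.append(float(share[1]))
        assert 55.0 <= np.mean(shares) <= 75.0


class TestClassify:
    @pytest.fixture
    def ann(self):
        return make_annotation([
            {"gene_id": "G00001", "chrom": "chr1", "start": 1000, "end": 3000,
             "exons": [(1000, 1400), (2600, 3000)]},
            {"gene_id": "G00002", "chrom": "chr1", "start": 1200, "end": 1600,
             "exons": [(1200, 1600)]},
        ])

    def _classify(self, ann, start, end):
        sres = pd.DataFrame({"sre_id": ["X"], "chrom": ["chr1"],
                             "start": [start], "end": [end]})
        return sre.classify_sres(sres, ann).iloc[0]

    def test_exon_overlap_wins(self, ann):
        row = self._classify(ann, 1100, 1150)
        assert row["sre_class"] == "EXON" and row["linked_gene_ids"] == ["G00001"]

    def test_exon_links_all_overlapping_genes(self, ann):
        row = self._classify(ann, 1250, 1300)
        assert row["linked_gene_ids"] == ["G00001", "G00002"]

    def test_intronic(self, ann):
        row = self._classify(ann, 1700, 1800)
        assert row["sre_class"] == "NOVEL_INTRONIC"

    def test_downstream_within_10kb(self, ann):
        row = self._classify(ann, 8000, 8100)  # 5,000 bp past G00001 end
        assert row["sre_class"] == "UPDOWN10K"

    def test_boundary_exactly_10kb_is_updown(self, ann):
        row = self._classify(ann, 13000, 13100)  # gap exactly 10,000
        assert row["sre_class"] == "UPDOWN10K"

    def test_orphan_with_distance(self, ann):
        row = self._classify(ann, 53000, 53100)
        assert row["sre_class"] == "ORPHAN"
        assert row["distance_to_nearest_gene"] == 50_000

    def test_every_sre_gets_exactly_one_class(self, ann):
        rng = np.random.default_rng(9)
        starts = np.sort(rng.integers(0, 60_000, 100))
        sres = pd.DataFrame({"sre_id": [f"S{i}" for i in range(100)],
                             "chrom": "chr1", "start": starts, "end": starts + 50})
        out = sre.classify_sres(sres, ann)
        assert out["sre_class"].isin(sre.SRE_CLASSES).all()


class TestOrphanProximity:
    def _orphans(self, coords):
        df = pd.DataFrame({"sre_id": [f"O{i}" for i in range(len(coords))],
                           "chrom": [c[0] for c in coords],
                           "start": [c[1] for c in coords],
                           "end": [c[2] for c in coords]})
        df["sre_class"] = "ORPHAN"
        df["linked_gene_ids"] = [[] for _ in coords]
        return df

    def test_within_and_beyond_threshold(self):
        ann = make_annotation([
            {"gene_id": "G1", "chrom": "chr1", "start": 0, "end": 1000,
             "exons": [(0, 1000)]}])
        orphans = self._orphans([("chr1", 26_000, 26_100),   # 25,000 away
                                 ("chr1", 31_001, 31_101)])  # 30,001 away
        dists, frac = sre.orphan_proximity(orphans, ann, threshold=30_000)
        assert dists.tolist() == [25_000, 30_001]
        assert frac == pytest.approx(0.5)

    def test_no_orphans_gives_none(self, toy_annotation):
        empty = self._orphans([]).iloc[0:0]
        empty["sre_class"] = empty.get("sre_class", "")
        dists, frac = sre.orphan_proximity(empty, toy_annotation)
        assert frac is None and len(dists) == 0

    def test_empty_annotation_fraction_zero(self):
        ann = make_annotation([])
        orphans = self._orphans([("chr1", 0, 100)])
        dists, frac = sre.orphan_proximity(orphans, ann)
        assert np.isinf(dists.iloc[0]) and frac == 0.0


class TestAbundantGeneSet:
    def _classified(self):
        return pd.DataFrame({
            "sre_id": ["A", "B", "C", "D"],
            "chrom": "chr1", "start": [0, 10, 20, 30], "end": [5, 15, 25, 35],
            "sre_class": ["EXON", "EXON", "ORPHAN", "UPDOWN10K"],
            "linked_gene_ids": [["G1"], ["G1"], [], ["G2"]],
        })

    def test_union_deduplicates(self):
        deciles = pd.Series([1, 1, 1, 2], index=["A", "B", "C", "D"])
        assert sre.abundant_gene_set(self._classified(), deciles) == {"G1"}

    def test_orphans_contribute_nothing(self):
        deciles = pd.Series([2, 2, 1, 2], index=["A", "B", "C", "D"])
        assert sre.abundant_gene_set(self._classified(), deciles) == set()

    def test_updown_contributes(self):
        deciles = pd.Series([2, 2, 2, 1], index=["A", "B", "C", "D"])
        assert sre.abundant_gene_set(self._classified(), deciles) == {"G2"}
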