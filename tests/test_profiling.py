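"""Read processing, OTU handling, abundance and summary regressions."""

import numpy as np
import pytest

from probioplex import profiling as pf
from probioplex import synth
from probioplex.panel import TaxonLabel
from probioplex.profiling import Read, ReadSet

import oracles


def _rs(seqs, q=38, sample="s1"):
    return ReadSet(sample, [Read(s, (q,) * len(s)) for s in seqs])


class TestMergePairs:
    def test_exact_overlap_length_arithmetic(self):
        rng = np.random.default_rng(0)
        template = "".join(rng.choice(list("ACGT"), size=80))
        f = template[:50]
        r = oracles.revcomp(template[30:])       # 20-nt overlap
        res = pf.merge_pairs(_rs([f]), _rs([r]), min_overlap=10)
        assert res.n_merged == 1
        assert len(res.reads.reads[0].sequence) == 80
        assert res.reads.reads[0].sequence == template

    def test_no_overlap_drops_pair(self):
        res = pf.merge_pairs(_rs(["A" * 40]), _rs(["C" * 40]), min_overlap=20)
        assert res.n_merged == 0 and res.n_dropped == 1

    def test_higher_quality_base_wins_disagreement(self):
        rng = np.random.default_rng(21)
        template = "".join(rng.choice(list("ACGT"), size=24))
        f = template[:16]
        r_seq = oracles.revcomp(template[8:])
        fwd = ReadSet("s", [Read(f, (20,) * len(f))])
        # plant a disagreement at overlap start with higher reverse quality:
        # the reverse read's last base maps to template position 8
        mutated = r_seq[:-1] + ("A" if r_seq[-1] != "A" else "C")
        rev = ReadSet("s", [Read(mutated, (40,) * len(mutated))])
        res = pf.merge_pairs(fwd, rev, min_overlap=8, max_overlap_mismatch_frac=0.3)
        assert res.n_merged == 1
        rc_mut = oracles.revcomp(mutated)
        assert res.reads.reads[0].sequence[8] == rc_mut[0]
        assert res.reads.reads[0].sequence[8] != template[8]

    def test_mate_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            pf.merge_pairs(_rs(["ACGT"]), _rs([]))

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_overlap_recovered(self, seed):
        rng = np.random.default_rng(300 + seed)
        total = int(rng.integers(60, 120))
        read_len = int(rng.integers(40, min(80, total)))
        if 2 * read_len - total < 12:
            read_len = (total + 12 + 1) // 2
        template = "".join(rng.choice(list("ACGT"), size=total))
        f = template[:read_len]
        r = oracles.revcomp(template[total - read_len:])
        res = pf.merge_pairs(_rs([f]), _rs([r]), min_overlap=12)
        assert res.n_merged == 1
        assert res.reads.reads[0].sequence == template


class TestQualityFilter:
    def test_read_with_n_removed(self):
        res = pf.quality_filter(_rs(["ACGN", "ACGT"]))
        assert res.n_retained == 1 and res.n_removed == 1

    def test_q30_boundary_retained(self):
        res = pf.quality_filter(_rs(["ACGT"], q=30))
        assert res.n_retained == 1

    def test_q29_removed(self):
        res = pf.quality_filter(_rs(["ACGT"], q=29))
        assert res.n_retained == 0

    def test_planted_low_quality_counted_exactly(self, v4_refs, s16_panel):
        comm = synth.generate_mock_community("even", [], s16_panel.taxa)
        fwd, rev, _ = synth.simulate_reads(comm, v4_refs, n_reads=1000, seed=5,
                                           n_low_quality=100, low_q=29)
        merged = pf.merge_pairs(fwd, rev)
        res = pf.quality_filter(merged.reads)
        assert merged.n_merged == 1000
        assert res.n_retained == 900
        assert res.n_removed == 100


class TestDereplicate:
    def test_copies_collapse(self):
        t = pf.dereplicate(_rs(["ACGT"] * 10))
        assert len(t.otus) == 1 and t.otus[0].total == 10

    def test_distinct_sequences_stay_apart(self):
        t = pf.dereplicate(_rs(["ACGT", "ACGA", "TTTT"]))
        assert len(t.otus) == 3

    def test_single_base_difference_separates(self):
        t = pf.dereplicate(_rs(["ACGTACGT", "ACGTACGA"]))
        assert len(t.otus) == 2

    def test_counts_conserved(self):
        rs = _rs(["ACGT", "ACGT", "AAAA", "CCCC", "AAAA"])
        t = pf.dereplicate(rs)
        assert t.grand_total == len(rs.reads)


class TestAssignTaxonomy:
    def _refs(self):
        return pf.build_reference_set([
            (TaxonLabel("Lactobacillus", "casei"), "ACGTACGTACGTACGTACGT"),
            (TaxonLabel("Lactobacillus", "gasseri"), "TTGGTTGGTTGGTTGGTTGG"),
        ])

    def test_identical_read_full_identity(self):
        t = pf.dereplicate(_rs(["ACGTACGTACGTACGTACGT"]))
        pf.assign_taxonomy(t, self._refs())
        assert t.otus[0].taxon_group == "Lactobacillus casei"
        assert t.otus[0].identity == 100.0

    def test_tie_becomes_union_group(self):
        refs = pf.build_reference_set([
            (TaxonLabel("Lactobacillus", "casei"), "AAAAAAAATT"),
            (TaxonLabel("Lactobacillus", "gasseri"), "TTAAAAAAAA"),
        ])
        t = pf.dereplicate(_rs(["AAAAAAAAAA"]))
        pf.assign_taxonomy(t, refs)
        assert t.otus[0].ambiguous
        assert t.otus[0].taxon_group == "Lactobacillus casei|Lactobacillus gasseri"

    def test_identical_references_collapse_into_one_group(self):
        refs = pf.build_reference_set([
            (TaxonLabel("Lactobacillus", "casei"), "ACGTACGTAC"),
            (TaxonLabel("Lactobacillus", "paracasei"), "ACGTACGTAC"),
        ])
        assert len(refs.entries) == 1
        assert refs.group_of(TaxonLabel("Lactobacillus", "casei")) == \
            refs.group_of(TaxonLabel("Lactobacillus", "paracasei"))


class TestMinorFilter:
    def _table(self, counts):
        otus = [pf.OTU("A" * (i + 1), {"s1": c}) for i, c in enumerate(counts)]
        return pf.OTUTable(otus, ["s1"])

    def test_exactly_at_threshold_removed(self):
        t = self._table([999, 1])     # 1/1000 == 0.1% exactly
        res = pf.filter_minor(t, 0.001)
        assert res.removed_otus == 1

    def test_above_threshold_retained(self):
        t = self._table([998, 2])     # 0.2%
        res = pf.filter_minor(t, 0.001)
        assert res.removed_otus == 0

    def test_mass_conservation(self):
        t = self._table([700, 200, 60, 30, 9, 1])
        res = pf.filter_minor(t, 0.05)
        assert res.table.grand_total + res.removed_reads == 1000


class TestRelativeAbundance:
    def test_single_group_is_100(self):
        t = pf.dereplicate(_rs(["ACGTACGTAC"] * 5))
        pf.assign_taxonomy(t, pf.build_reference_set(
            [(TaxonLabel("Lactobacillus", "casei"), "ACGTACGTAC")]))
        ab = pf.relative_abundance(t)
        assert ab.loc["Lactobacillus casei", "s1"] == pytest.approx(100.0)

    def test_75_25_split(self):
        t = pf.dereplicate(_rs(["ACGTACGTAC"] * 75 + ["TTGGTTGGTT"] * 25))
        pf.assign_taxonomy(t, pf.build_reference_set([
            (TaxonLabel("Lactobacillus", "casei"), "ACGTACGTAC"),
            (TaxonLabel("Lactobacillus", "gasseri"), "TTGGTTGGTT")]))
        ab = pf.relative_abundance(t)
        assert ab["s1"].loc["Lactobacillus casei"] == pytest.approx(75.0)
        assert ab["s1"].loc["Lactobacillus gasseri"] == pytest.approx(25.0)

    def test_zero_read_sample_excluded_with_warning(self):
        t = pf.OTUTable([pf.OTU("ACGT", {"s1": 10})], ["s1", "s2"])
        with pytest.warns(UserWarning, match="s2"):
            ab = pf.relative_abundance(t)
        assert "s2" not in ab.columns

    def test_columns_sum_to_100(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(6)]
        reads = [s for s in seqs for _ in range(int(rng.integers(1, 30)))]
        t = pf.dereplicate(_rs(reads))
        pf.assign_taxonomy(t, pf.build_reference_set(
            [(TaxonLabel("Lactobacillus", f"sp{i}"), s) for i, s in enumerate(seqs)]))
        ab = pf.relative_abundance(t)
        assert ab["s1"].sum() == pytest.approx(100.0, abs=1e-9)


class TestRegressions:
    def test_collinear_points_r2_one(self):
        pts = [(5.0, 10.0), (6.0, 20.0), (7.0, 30.0), (8.0, 40.0)]
        res = pf.cfu_read_regression(pts)
        assert res.slope == pytest.approx(10.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError):
            pf.cfu_read_regression([(5.0, 1.0), (5.0, 2.0), (5.0, 3.0)])

    def test_rank_fit_recovers_log_decrease(self):
        ab = synth.log_decreasing_abundances(10, top=40.7, bottom=0.6)
        res = pf.rank_abundance_fit(ab)
        b = (40.7 - 0.6) / np.log(10)
        assert res.slope == pytest.approx(-b)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_abundances_zero_slope(self):
        res = pf.rank_abundance_fit([5.0, 5.0, 5.0, 5.0])
        assert res.slope == 0.0


class TestConservation:
    def test_read_counts_conserved_through_stages(self, v4_refs, s16_panel):
        comm = synth.generate_mock_community("even", [], s16_panel.taxa)
        fwd, rev, _ = synth.simulate_reads(comm, v4_refs, n_reads=2000, seed=11,
                                           n_low_quality=40, n_ambiguous=25)
        merged = pf.merge_pairs(fwd, rev)
        assert merged.n_merged + merged.n_dropped == merged.n_pairs
        qf = pf.quality_filter(merged.reads)
        assert qf.n_retained + qf.n_removed == merged.n_merged
        table = pf.dereplicate(qf.reads)
        assert table.grand_total == qf.n_retained
        pf.assign_taxonomy(table, v4_refs)
        minor = pf.filter_minor(table, 0.001)
        assert minor.table.grand_total + minor.removed_reads == qf.n_retained


class TestFastqIO:
    def test_roundtrip(self, tmp_path):
        rs = ReadSet("s1", [Read("ACGTN", (38, 38, 2, 40, 30))])
        path = tmp_path / "r.fastq"
        pf.write_fastq(rs, path)
        back = pf.read_fastq(path, "s1")
        assert back.reads == rs.reads
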