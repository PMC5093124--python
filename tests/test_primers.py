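"""Primer screening, specificity scoring and assay selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from probioplex import primers as pr
from probioplex import pcr
from probioplex.panel import MarkerPanel, MarkerSequence, TaxonLabel, build_consensus
from probioplex.primers import DesignParams

import oracles


class TestTmWallace:
    @pytest.mark.parametrize("seq,expected", [
        ("AATT", 8), ("GGCC", 16), ("ACGT", 12),
    ])
    def test_examples(self, seq, expected):
        assert pr.tm_wallace(seq) == expected

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            pr.tm_wallace("ACGW")

    @given(seq=st.text(alphabet="ACGT", min_size=1, max_size=30),
           pos=st.integers(min_value=0, max_value=29),
           strong=st.sampled_from("GC"))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_gc_substitution_raises_tm(self, seq, pos, strong):
        pos %= len(seq)
        if seq[pos] in "GC":
            return
        swapped = seq[:pos] + strong + seq[pos + 1:]
        assert pr.tm_wallace(swapped) > pr.tm_wallace(seq)


class TestComplementarityRun:
    @pytest.mark.parametrize("a,b,max_run", [
        ("AAAA", "TTTT", 4),
        ("ACGT", "ACGT", 4),     # self-reverse-complement palindrome
        ("AAAA", "AAAA", 0),     # A:A does not pair
    ])
    def test_examples(self, a, b, max_run):
        assert pr.complementarity_run(a, b)["max_run"] == max_run

    def test_three_prime_anchored_run(self):
        # a's last three bases CGT pair with ACG at b's start after reversal
        r = pr.complementarity_run("AACGT", "ACGAA")
        assert r["three_prime_run_a"] >= 3


class TestEnumerateCandidates:
    def _profile(self, consensus):
        return build_consensus([consensus], TaxonLabel("Lactobacillus", "casei"))

    def test_no_window_spans_degenerate_symbol(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), size=120))
        cons = base[:60] + "W" + base[61:]
        prof = pr.ConsensusProfile(TaxonLabel("Lactobacillus", "casei"), cons,
                                   np.ones(len(cons), dtype=int))
        for cand in pr.enumerate_candidates(prof):
            assert not (cand.start <= 60 < cand.end)

    def test_all_a_fails_gc_filter(self):
        assert pr.enumerate_candidates(self._profile("A" * 100)) == []

    def test_filters_idempotent_on_output(self):
        rng = np.random.default_rng(7)
        cons = "".join(rng.choice(list("ACGT"), size=400))
        params = DesignParams()
        out = pr.enumerate_candidates(self._profile(cons), params)
        assert out
        for cand in out:
            lo, hi = params.primer_len_range
            assert lo <= len(cand) <= hi
            assert params.gc_range[0] <= cand.gc <= params.gc_range[1]
            assert params.tm_range[0] <= cand.tm <= params.tm_range[1]
            assert cand.tm == pr.tm_wallace(cand.sequence)
            assert pr.passes_hairpin_screen(cand.sequence, params)

    def test_deterministic_ordering(self):
        rng = np.random.default_rng(7)
        cons = "".join(rng.choice(list("ACGT"), size=300))
        a = pr.enumerate_candidates(self._profile(cons))
        b = pr.enumerate_candidates(self._profile(cons))
        assert a == b
        keys = [(c.start, len(c)) for c in a]
        assert keys == sorted(keys)


def _panel_from(seqs_by_taxon):
    entries = []
    for name, seqs in seqs_by_taxon.items():
        taxon = TaxonLabel.parse(name)
        for i, s in enumerate(seqs):
            entries.append(MarkerSequence(taxon, "pgi", s, f"{name}-{i}"))
    return MarkerPanel(entries, "pgi")


class TestSpecificityProfile:
    def test_identical_window_scores_zero(self):
        panel = _panel_from({"Lactobacillus casei": ["TTTTACGTACGTACGTACGTTTTT"]})
        prof = pr.specificity_profile("ACGTACGTACGTACGT", panel)
        hit = prof[TaxonLabel("Lactobacillus", "casei")]
        assert hit == {"min_mismatches": 0, "three_prime_mismatches": 0}

    def test_reverse_complement_strand_found(self):
        # template contains only the reverse complement of the primer
        panel = _panel_from({"Lactobacillus casei": ["GGGG" + oracles.revcomp("ACGTTACGTAAC") + "GGGG"]})
        prof = pr.specificity_profile("ACGTTACGTAAC", panel)
        assert prof[TaxonLabel("Lactobacillus", "casei")]["min_mismatches"] == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        primer = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 22))))
        seqs = ["".join(rng.choice(list("ACGTN"), size=int(rng.integers(60, 200)),
                                   p=[0.24, 0.24, 0.24, 0.24, 0.04]))
                for _ in range(2)]
        panel = _panel_from({"Lactobacillus casei": seqs})
        got = pr.specificity_profile(primer, panel)[TaxonLabel("Lactobacillus", "casei")]
        mm, anc = oracles.naive_specificity(primer, seqs)
        assert (got["min_mismatches"], got["three_prime_mismatches"]) == (mm, anc)


class TestDesignAssay:
    def test_identical_target_and_offtarget_infeasible(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        panel = _panel_from({"Lactobacillus casei": [seq],
                             "Lactobacillus paracasei": [seq]})
        with pytest.raises(pr.DesignInfeasibleError):
            pr.design_assay(TaxonLabel("Lactobacillus", "casei"), panel)

    def test_single_taxon_panel_rejected(self):
        rng = np.random.default_rng(5)
        panel = _panel_from({"Lactobacillus casei":
                             ["".join(rng.choice(list("ACGT"), size=400))]})
        with pytest.raises(ValueError):
            pr.design_assay(TaxonLabel("Lactobacillus", "casei"), panel)

    def test_divergent_insert_is_targeted(self):
        rng = np.random.default_rng(9)
        shared = "".join(rng.choice(list("ACGT"), size=500))
        insert = "".join(rng.choice(list("ACGT"), size=30))
        target = shared[:250] + insert + shared[250:]
        panel = _panel_from({"Lactobacillus casei": [target],
                             "Lactobacillus paracasei": [shared]})
        assay = pr.design_assay(TaxonLabel("Lactobacillus", "casei"), panel,
                                DesignParams(amplicon_len_range=(100, 500)))
        off = panel.subset([TaxonLabel("Lactobacillus", "paracasei")])
        key = TaxonLabel("Lactobacillus", "paracasei")
        better = max(pr.specificity_profile(assay.forward, off)[key]["min_mismatches"],
                     pr.specificity_profile(assay.reverse, off)[key]["min_mismatches"])
        assert better >= 1
        # at least one primer overlaps the divergent insert region [250, 280)
        intervals = [(assay.forward.start, assay.forward.end),
                     (assay.reverse.start, assay.reverse.end)]
        assert any(s < 280 and e > 250 for s, e in intervals)
        # and the pair predicts no product on the off-target
        assert pcr.predict_amplicons(assay, shared) == []

    def test_determinism(self, small_panel):
        taxon = small_panel.taxa[0]
        a = pr.design_assay(taxon, small_panel)
        b = pr.design_assay(taxon, small_panel)
        assert a == b

    def test_closure_on_own_taxon(self, small_panel):
        """Every designed assay amplifies its own taxon at exactly the
        expected length under the strict policy."""
        for taxon in small_panel.taxa:
            assay = pr.design_assay(taxon, small_panel)
            for entry in small_panel.sequences_of(taxon):
                amps = pcr.predict_amplicons(assay, entry)
                assert [a.length for a in amps] == [assay.expected_length]


class TestAssayIO:
    def test_tsv_roundtrip(self, tmp_path, small_panel):
        assays = [pr.design_assay(t, small_panel) for t in small_panel.taxa[:2]]
        path = tmp_path / "assays.tsv"
        pr.write_assay_tsv(assays, path)
        back = pr.read_assay_tsv(path)
        for orig, re_read in zip(assays, back):
            assert orig.forward.sequence == re_read.forward.sequence
            assert orig.reverse.sequence == re_read.reverse.sequence
            assert orig.expected_length == re_read.expected_length
            assert str(orig.taxon) == str(re_read.taxon)
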