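"""Virtual-gel calls and label-claim auditing."""

import pytest

from probioplex import genotype as gt
from probioplex import scheme as sc
from probioplex import synth
from probioplex.genotype import (BandPattern, LabelClaim, PresenceCall,
                                 audit_against_label, call_presence, percentage,
                                 summarize_audit, virtual_gel)
from probioplex.panel import TaxonLabel


def _taxon(name):
    return TaxonLabel.parse(name)


@pytest.fixture(scope="module")
def small_scheme(small_panel):
    from probioplex import primers
    assays = primers.design_panel_assays(small_panel)
    return sc.partition_assays(assays, plex_size=3)


class TestVirtualGel:
    def test_single_taxon_single_band(self, small_panel, small_scheme):
        taxon = small_panel.taxa[0]
        seqs = [e.sequence for e in small_panel.sequences_of(taxon)]
        pattern = virtual_gel(seqs, small_scheme)
        rxn = small_scheme.reaction_of(taxon)
        expected = next(a.expected_length for r in small_scheme.reactions for a in r
                        if str(a.taxon) == str(taxon))
        for i, bands in enumerate(pattern.bands):
            assert bands == ([expected] if i == rxn else [])

    def test_empty_sample_all_reactions_empty(self, small_scheme):
        pattern = virtual_gel([], small_scheme)
        assert all(b == [] for b in pattern.bands)

    def test_two_taxa_same_reaction_two_bands(self, small_panel, small_scheme):
        rxn0 = small_scheme.reactions[0]
        taxa = [a.taxon for a in rxn0[:2]]
        seqs = [e.sequence for t in taxa for e in small_panel.sequences_of(t)]
        pattern = virtual_gel(seqs, small_scheme)
        assert pattern.bands[0] == sorted(a.expected_length for a in rxn0[:2])


class TestCallPresence:
    def _scheme(self, lengths, tolerance=0):
        from tests_helpers import make_assays
        assays = make_assays(lengths)
        return sc.partition_assays(assays, plex_size=len(lengths),
                                   gel=sc.GelModel(50, tolerance))

    def test_exact_band_detected(self):
        s = self._scheme([300, 400])
        calls = call_presence(BandPattern([[300]]), s)
        by = {str(c.taxon): c for c in calls}
        assert by[str(s.reactions[0][0].taxon)].detected
        assert by[str(s.reactions[0][0].taxon)].matched_length == 300

    def test_off_by_ten_not_detected_at_zero_tolerance(self):
        s = self._scheme([300, 400])
        calls = call_presence(BandPattern([[310]]), s)
        assert not any(c.detected for c in calls)

    def test_tolerance_allows_near_band(self):
        s = self._scheme([300, 400], tolerance=15)
        calls = call_presence(BandPattern([[310]]), s)
        detected = [c for c in calls if c.detected]
        assert len(detected) == 1
        assert detected[0].matched_length == 310

    def test_band_assigned_to_single_nearest_assay(self):
        s = self._scheme([300, 400], tolerance=60)
        calls = call_presence(BandPattern([[340]]), s)
        assert [c.detected for c in calls].count(True) == 1
        winner = next(c for c in calls if c.detected)
        assert str(winner.taxon) == str(s.reactions[0][0].taxon)  # nearer to 300

    def test_equidistant_tie_prefers_lower_and_flags(self):
        s = self._scheme([300, 400], tolerance=60)
        calls = call_presence(BandPattern([[350]]), s)
        winner = next(c for c in calls if c.detected)
        assert str(winner.taxon) == str(s.reactions[0][0].taxon)
        assert winner.ambiguous

    def test_misaligned_pattern_rejected(self):
        s = self._scheme([300, 400])
        with pytest.raises(ValueError):
            call_presence(BandPattern([[300], [400]]), s)


class TestAudit:
    def _calls(self, detected, panel=("A a", "B b", "C c")):
        return [PresenceCall(_taxon(t), t in detected, 100 if t in detected else None)
                for t in panel]

    def _claim(self, taxa, **kw):
        return LabelClaim("P1", frozenset(_taxon(t) for t in taxa), 1e10, **kw)

    def test_claimed_absent(self):
        row = audit_against_label(self._calls({"A a"}), self._claim(["A a", "B b"]))
        assert row.categories["A a"] == gt.CLAIMED_PRESENT
        assert row.categories["B b"] == gt.CLAIMED_ABSENT
        assert row.categories["C c"] == gt.UNCLAIMED_ABSENT
        assert row.retest

    def test_unclaimed_present(self):
        row = audit_against_label(self._calls({"A a", "C c"}), self._claim(["A a"]))
        assert row.categories["C c"] == gt.UNCLAIMED_PRESENT

    def test_categories_partition_panel(self):
        row = audit_against_label(self._calls({"A a"}), self._claim(["B b"]))
        assert set(row.categories) == {"A a", "B b", "C c"}

    def test_out_of_panel_claim_not_testable(self):
        row = audit_against_label(self._calls(set()), self._claim(["Z z"]))
        assert row.not_testable == ["Z z"]
        assert not row.discrepant

    def test_strain_confirmed_mismatched_unresolvable(self):
        claim = self._claim(["A a"])
        claim = LabelClaim("P1", claim.claimed_taxa, 1e10,
                           claimed_strains=frozenset({_taxon("A a . S1"),
                                                      _taxon("A a . S2"),
                                                      _taxon("B b . S9")}))
        strain_calls = [PresenceCall(_taxon("A a . S1"), True, 120),
                        PresenceCall(_taxon("A a . S2"), False)]
        row = audit_against_label(self._calls({"A a"}), claim, strain_calls)
        assert row.strain_categories == {"A a . S1": gt.STRAIN_CONFIRMED,
                                         "A a . S2": gt.STRAIN_MISMATCHED,
                                         "B b . S9": gt.STRAIN_UNRESOLVABLE}

    def test_swap_fixture_yields_paired_discrepancy(self, pgi_panel):
        fx, _ = synth.generate_product_fixture(pgi_panel, ("swap_related",), seed=4)
        (kind, a, b) = fx.injected_errors[0]
        assert kind == "swap"
        calls = [PresenceCall(t, t in fx.true_taxa, 100 if t in fx.true_taxa else None)
                 for t in pgi_panel.taxa]
        row = audit_against_label(calls, fx.label)
        assert row.categories[a] == gt.CLAIMED_ABSENT
        assert row.categories[b] == gt.UNCLAIMED_PRESENT


class TestSummaries:
    def test_survey_percentages_from_printed_counts(self):
        """The published cohort arithmetic: 22/52 discrepant -> 42.3%,
        18/52 with an extra organism -> 34.6%, 35/52 above claim -> 67.3%."""
        assert percentage(22, 52) == 42.3
        assert percentage(18, 52) == 34.6
        assert percentage(35, 52) == 67.3

    def test_all_correct_cohort(self):
        rows = [gt.AuditRow(f"P{i}", {"A a": gt.CLAIMED_PRESENT}) for i in range(5)]
        s = summarize_audit(gt.AuditMatrix(rows))
        assert s["n_discrepant"] == 0
        assert s["pct_discrepant"] == 0.0

    def test_counts_match_categories(self):
        rows = [
            gt.AuditRow("P1", {"A a": gt.CLAIMED_ABSENT, "B b": gt.UNCLAIMED_PRESENT}),
            gt.AuditRow("P2", {"A a": gt.CLAIMED_PRESENT, "B b": gt.UNCLAIMED_ABSENT}),
            gt.AuditRow("P3", {"A a": gt.UNCLAIMED_PRESENT, "B b": gt.CLAIMED_PRESENT}),
        ]
        s = summarize_audit(gt.AuditMatrix(rows))
        assert s["n_products"] == 3
        assert s["n_with_missing_claimed"] == 1
        assert s["n_with_unclaimed"] == 2
        assert s["n_discrepant"] == 2
        assert s["pct_discrepant"] == 66.7


class TestClaimIO:
    def test_tsv_roundtrip(self, tmp_path):
        claims = [LabelClaim("P1", frozenset({_taxon("Lactobacillus casei")}), 5e9,
                             "time_of_manufacture", 6.5,
                             frozenset({_taxon("Lactobacillus casei . X1")}))]
        path = tmp_path / "claims.tsv"
        gt.write_claims_tsv(claims, path)
        back = gt.read_claims_tsv(path)
        assert back == claims
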