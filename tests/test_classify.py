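"""GC groups, substitution spectra, pseudogene calls, discriminating windows."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rdnarip import classify as cls
from rdnarip import synthetic as syn
from rdnarip.align import pairwise_align

from conftest import gotoh_score

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 0.5), ("AATT", 0.0), ("GCGC", 1.0), ("A-G-", 0.5), ("ANGN", 0.5)],
    )
    def test_values(self, seq, expected):
        assert cls.gc_content(seq) == expected

    def test_no_countable_bases(self):
        with pytest.raises(ValueError):
            cls.gc_content("NN--")


class TestSplitGcGroups:
    def test_splits_at_observed_functional_pseudogene_boundary(self):
        """The split lands in the gap between the empirically unoverlapping
        GC bands of functional (46.45-52.55%) and pseudogenic (12.26-44.43%)
        rDNA copies."""
        high_band = [(f"f{i}", v) for i, v in enumerate(np.linspace(46.45, 52.55, 5))]
        low_band = [(f"p{i}", v) for i, v in enumerate(np.linspace(12.26, 44.43, 20))]
        high, low, gap = cls.split_gc_groups(high_band + low_band)
        assert {i for i, _ in high} == {i for i, _ in high_band}
        assert {i for i, _ in low} == {i for i, _ in low_band}
        assert gap == pytest.approx(46.45 - 44.43)

    def test_no_bimodality_single_group(self):
        high, low, _ = cls.split_gc_groups([("a", 48.0), ("b", 47.5), ("c", 47.9)])
        assert len(high) == 3 and low == []

    def test_two_values(self):
        high, low, gap = cls.split_gc_groups([("a", 50.0), ("b", 30.0)])
        assert high == [("a", 50.0)] and low == [("b", 30.0)] and gap == 20.0


class TestPairwiseAlign:
    def test_identical_no_gaps(self):
        gq, gr, _ = pairwise_align("ACGT", "ACGT")
        assert gq == gr == "ACGT"

    def test_single_gap_column(self):
        gq, gr, _ = pairwise_align("AGT", "ACGT")
        assert len(gq) == 4 and gq.count("-") == 1 and gr == "ACGT"

    @given(dna, dna)
    def test_score_matches_exhaustive_dp(self, a, b):
        _, _, score = pairwise_align(a, b)
        assert score == pytest.approx(gotoh_score(a, b))

    def test_deterministic(self):
        r1 = pairwise_align("ACGTACGTAA", "ACGTCGTAA")
        r2 = pairwise_align("ACGTACGTAA", "ACGTCGTAA")
        assert r1 == r2


class TestMutationSpectrum:
    def test_single_c_to_t(self):
        spec = cls.mutation_spectrum("ATGT", "ACGT")
        assert spec.counts["C>T"] == 1
        assert spec.total_substitutions == 1
        assert spec.aligned_sites == 4

    def test_identical_zero(self):
        spec = cls.mutation_spectrum("ACGT", "ACGT")
        assert spec.total_substitutions == 0

    def test_gap_columns_counted_separately(self):
        spec = cls.mutation_spectrum("AC-T", "ACGT")
        assert spec.indel_columns == 1 and spec.aligned_sites == 3

    def test_matches_simulator_log(self, template):
        """Spectrum vs the unmutated template equals the mutation log
        aggregated by substitution class."""
        out, log = syn.apply_rip(template.sequence, syn.RipParams(seed=5), rng_seed=5)
        spec = cls.mutation_spectrum(out, template.sequence)
        from collections import Counter
        expected = Counter(f"{ev.ref_base}>{ev.alt_base}" for ev in log)
        for klass in cls.SUBSTITUTION_CLASSES:
            assert spec.counts[klass] == expected.get(klass, 0), klass
        assert spec.aligned_sites == template.length

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            cls.mutation_spectrum("ACG", "ACGT")


class TestTransitionRates:
    def test_rates_over_aligned_sites(self):
        counts = dict.fromkeys(cls.SUBSTITUTION_CLASSES, 0)
        counts["G>A"], counts["C>T"] = 3, 2
        spec = cls.MutationSpectrum(counts, 0, 100)
        rates = cls.transition_rates(spec)
        assert rates == {"gA_rate": 0.03, "cT_rate": 0.02, "other_rate": 0.0}

    def test_empty_spectrum(self):
        spec = cls.MutationSpectrum(dict.fromkeys(cls.SUBSTITUTION_CLASSES, 0), 0, 0)
        assert cls.transition_rates(spec) == {
            "gA_rate": 0.0,
            "cT_rate": 0.0,
            "other_rate": 0.0,
        }

    def test_denominator_consistency(self, template):
        out, _ = syn.apply_rip(template.sequence, syn.RipParams(seed=8), rng_seed=8)
        spec = cls.mutation_spectrum(out, template.sequence)
        r = cls.transition_rates(spec)
        total = r["gA_rate"] + r["cT_rate"] + r["other_rate"]
        assert total <= 1.0
        assert total == pytest.approx(spec.total_substitutions / spec.aligned_sites)


def _record(group, gc=0.30):
    return cls.ParalogRecord("p1", "18S", "ACGT", gc, group=group)


def _spectrum(ga, ct, other, n=1000):
    counts = dict.fromkeys(cls.SUBSTITUTION_CLASSES, 0)
    counts["G>A"], counts["C>T"], counts["A>C"] = ga, ct, other
    return cls.MutationSpectrum(counts, 0, n)


class TestCallPseudogene:
    def test_low_gc_uniform_transitions_is_pseudogene(self):
        call = cls.call_pseudogene(_record("low_gc"), _spectrum(100, 80, 0))
        assert call == "pseudogene"

    def test_high_gc_is_functional(self):
        call = cls.call_pseudogene(_record("high_gc", gc=0.48), _spectrum(0, 0, 0))
        assert call == "functional"

    def test_low_gc_with_excess_other_mutations_undetermined(self):
        call = cls.call_pseudogene(_record("low_gc"), _spectrum(100, 80, 50))
        assert call == "undetermined"

    def test_missing_group_is_error(self):
        with pytest.raises(ValueError):
            cls.call_pseudogene(_record("unassigned"), _spectrum(1, 1, 0))

    def test_recovery_on_synthetic_paralogs(self, pipeline_result):
        """Pseudogene calling reaches >=99% sensitivity and specificity
        against the simulator truth table."""
        conf = pipeline_result.confusion
        assert conf["sensitivity"] >= 0.99
        assert conf["specificity"] >= 0.99

    def test_gc_call_concordance(self, pipeline_result):
        """Every pseudogene call sits strictly below the lowest functional
        GC of the same subunit (the unoverlapping-bands property)."""
        for subunit, recs in pipeline_result.records.items():
            func_gc = [r.gc for r in recs if r.call == "functional"]
            for r in recs:
                if r.call == "pseudogene":
                    assert r.gc < min(func_gc), (subunit, r.paralog_id)


class TestFindDiscriminatingSites:
    def test_constructed_fixture_has_window(self):
        aln = {
            "f1": "ACGACGACGACGACGACGAC",
            "f2": "ACGACGACGACGACGACGAC",
            "p1": "ATGATGATAATGATGATAAC",
            "p2": "ATGATGATAATGATGATAAC",
        }
        labels = {"f1": "functional", "f2": "functional",
                  "p1": "pseudogene", "p2": "pseudogene"}
        wins = cls.find_discriminating_sites(aln, labels)
        assert wins and all(w.min_mismatches >= 2 for w in wins)

    def test_identical_sets_empty(self):
        aln = {"f1": "ACGTACGTACGTACGTACGT", "p1": "ACGTACGTACGTACGTACGT"}
        labels = {"f1": "functional", "p1": "pseudogene"}
        assert cls.find_discriminating_sites(aln, labels) == []

    def test_low_gc_window_flagged(self):
        aln = {
            "f1": "GCGCGCGCGCGCGCGCGCGC",
            "p1": "ATATATATATATATATATAT",
        }
        labels = {"f1": "functional", "p1": "pseudogene"}
        wins = cls.find_discriminating_sites(aln, labels)
        assert wins and "low_complexity" in wins[0].warnings

    def test_windows_separate_truth_classes(self, pipeline_result):
        """Every reported window separates simulated functional from
        pseudogene sequences with zero mismatch errors."""
        from rdnarip import msa

        checked = 0
        for subunit, recs in pipeline_result.records.items():
            by_call = {r.paralog_id: r.call for r in recs
                       if r.call in ("functional", "pseudogene")}
            if len(set(by_call.values())) < 2:
                continue
            ref = pipeline_result.reference_ids[subunit]
            aln = msa.reference_anchored_msa(
                {r.paralog_id: r.sequence for r in recs}, ref
            )
            aln = {i: s for i, s in aln.items() if i in by_call}
            wins = cls.find_discriminating_sites(aln, by_call)
            for w in wins:
                checked += 1
                col = slice(w.start_column, w.start_column + len(w.sequence))
                pseudo = {aln[i][col] for i, c in by_call.items() if c == "pseudogene"}
                func = {aln[i][col] for i, c in by_call.items() if c == "functional"}
                assert len(pseudo) == 1
                assert all(sum(1 for x, y in zip(p, f) if x != y) >= 2
                           for p in pseudo for f in func)
        assert checked > 0

    def test_needs_both_labels(self):
        with pytest.raises(ValueError):
            cls.find_discriminating_sites({"a": "ACGT"}, {"a": "functional"})
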