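"""SSR detection, compound merging, motif canonicalization, primer screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrchar import (
    DEFAULT_MIN_REPEATS,
    PrimerCriteria,
    PrimerPair,
    SequenceRecord,
    brute_force_ssrs,
    canonicalize_motif,
    find_perfect_ssrs,
    melting_temperature,
    merge_compound,
    screen_primer_pair,
    simulate_ssr_sequence,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=6)


class TestCanonicalize:
    @pytest.mark.parametrize(
        "unit,canonical",
        [("TG", "GT"), ("A", "A"), ("CGCAC", "ACCGC"), ("acat", "ACAT")],
    )
    def test_minimal_rotation(self, unit, canonical):
        assert canonicalize_motif(unit).canonical_unit == canonical

    def test_cgcac_matches_rotation_enumeration(self):
        # oracle: enumerate all rotations explicitly
        rotations = {"CGCAC"[i:] + "CGCAC"[:i] for i in range(5)}
        assert canonicalize_motif("CGCAC").canonical_unit == min(rotations)

    @given(dna)
    @settings(deadline=None)
    def test_idempotent_and_rotation_invariant(self, unit):
        canon = canonicalize_motif(unit).canonical_unit
        assert canonicalize_motif(canon).canonical_unit == canon
        for i in range(len(unit)):
            rotated = unit[i:] + unit[:i]
            assert canonicalize_motif(rotated).canonical_unit == canon

    def test_revcomp_folding_merges_complement_classes(self):
        plain = canonicalize_motif("AC").canonical_unit
        folded_ac = canonicalize_motif("AC", fold_revcomp=True).canonical_unit
        folded_gt = canonicalize_motif("GT", fold_revcomp=True).canonical_unit
        assert folded_ac == folded_gt
        assert plain != canonicalize_motif("GT").canonical_unit

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            canonicalize_motif("ACGTACG")  # 7 bp
        with pytest.raises(ValueError):
            canonicalize_motif("AX")


class TestFindPerfect:
    def test_exact_tandem(self):
        loci = find_perfect_ssrs(SequenceRecord("s", "ACACACACACAC"), {2: 6})
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.motif.unit, l.repeat_count) == (0, 12, "AC", 6)

    def test_offset_run_with_partial_edges(self):
        loci = find_perfect_ssrs(SequenceRecord("s", "TTGTGTGTGTGTGTGTT"), {2: 6})
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.motif.unit, l.repeat_count) == (1, 15, "TG", 7)

    def test_coordinate_conservation(self):
        seq = SequenceRecord("s", "GGGACACACACACACTTTATTATTATTAGG")
        for l in find_perfect_ssrs(seq, {2: 6, 3: 4}):
            assert seq.residues[l.start : l.end] == l.motif.unit * l.repeat_count

    def test_n_terminates_runs(self):
        loci = find_perfect_ssrs(SequenceRecord("s", "ACACACNACACAC"), {2: 3})
        assert [(l.start, l.end) for l in loci] == [(0, 6), (7, 13)]

    def test_nonprimitive_units_not_reported(self):
        # a (AC)8 run must not also be reported as (ACAC)4
        loci = find_perfect_ssrs(SequenceRecord("s", "ACACACACACACACAC"), {2: 6, 4: 3})
        assert [l.motif.unit for l in loci] == ["AC"]

    def test_mononucleotide_excluded_by_default(self):
        assert find_perfect_ssrs(SequenceRecord("s", "AAAAAAAAAAAA")) == []
        loci = find_perfect_ssrs(SequenceRecord("s", "AAAAAAAAAAAA"), {1: 10})
        assert [(l.motif.unit, l.repeat_count) for l in loci] == [("A", 12)]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_sequence_without_runs_is_empty_like_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = SequenceRecord("r", "".join(rng.choice(list("ACGT"), size=200)))
        assert find_perfect_ssrs(seq) == brute_force_ssrs(seq)

    @pytest.mark.parametrize("seed", range(200))
    def test_oracle_equivalence_on_random_sequences(self, seed):
        """Scanner output equals exhaustive per-(start, unit-length) search."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(20, 501))
        # biased alphabet (sometimes with N) to make runs likely
        alphabet = list("ACGTN") if seed % 5 == 0 else list("ACGT")
        probs = np.array([0.4, 0.35, 0.1, 0.1, 0.05])[: len(alphabet)]
        probs = probs / probs.sum()
        seq = SequenceRecord("r", "".join(rng.choice(alphabet, size=n, p=probs)))
        thresholds = {1: 8, 2: 4, 3: 3, 4: 3, 5: 2, 6: 2}
        got = find_perfect_ssrs(seq, thresholds)
        expected = brute_force_ssrs(seq, thresholds)
        assert [(l.start, l.end, l.motif.unit) for l in got] == [
            (l.start, l.end, l.motif.unit) for l in expected
        ]

    @pytest.mark.parametrize("seed", range(20))
    def test_reverse_complement_preserves_locus_count(self, seed):
        rng = np.random.default_rng(seed)
        seq = SequenceRecord(
            "r", "".join(rng.choice(list("ACGT"), size=300, p=[0.4, 0.3, 0.2, 0.1]))
        )
        thresholds = {2: 4, 3: 3, 4: 3}
        fwd = find_perfect_ssrs(seq, thresholds)
        rev = find_perfect_ssrs(seq.reverse_complement(), thresholds)
        assert len(fwd) == len(rev)


class TestMergeCompound:
    def _runs(self, residues, thresholds):
        seq = SequenceRecord("s", residues)
        return seq, find_perfect_ssrs(seq, thresholds)

    def test_gt8_ca_gt7_compound(self):
        seq, runs = self._runs("GT" * 8 + "CA" + "GT" * 7, {2: 6})
        merged = merge_compound(runs, seq, max_gap=4)
        assert len(merged) == 1
        assert merged[0].motif_string() == "(GT)8CA(GT)7"
        assert merged[0].kind == "compound"
        assert (merged[0].start, merged[0].end) == (0, 32)

    def test_ta5_a_gt23_compound(self):
        seq, runs = self._runs("TA" * 5 + "A" + "GT" * 23, {2: 5})
        merged = merge_compound(runs, seq, max_gap=4)
        assert [m.motif_string() for m in merged] == ["(TA)5A(GT)23"]

    def test_zero_gap_compound(self):
        seq, runs = self._runs("ATT" * 2 + "CA" * 8, {2: 6, 3: 2})
        merged = merge_compound(runs, seq, max_gap=4)
        assert [m.motif_string() for m in merged] == ["(ATT)2(CA)8"]

    def test_wide_gap_left_unmerged(self):
        seq, runs = self._runs("GT" * 8 + "CATGA" + "GT" * 7, {2: 6})
        merged = merge_compound(runs, seq, max_gap=4)
        assert [m.kind for m in merged] == ["perfect", "perfect"]

    def test_overlapping_input_rejected(self):
        seq = SequenceRecord("s", "ACACACACACAC")
        runs = find_perfect_ssrs(seq, {2: 3})
        doubled = sorted(runs + runs, key=lambda l: l.start)
        with pytest.raises(ValueError, match="[Oo]verlap"):
            merge_compound(doubled, seq)

    def test_span_invariant(self):
        seq, runs = self._runs("GT" * 8 + "CA" + "GT" * 7, {2: 6})
        (m,) = merge_compound(runs, seq, max_gap=4)
        span = sum(len(p.motif.unit) * p.count + len(p.gap_after) for p in m.parts)
        assert m.end - m.start == span


class TestSimulatedSequences:
    def test_single_run_recovered_exactly(self):
        seq, truth = simulate_ssr_sequence([("GT", 8)], seed=1)
        got = find_perfect_ssrs(seq)
        assert [(l.start, l.end, l.motif.unit) for l in got] == [
            (l.start, l.end, l.motif.unit) for l in truth
        ]

    def test_compound_reconstruction(self):
        seq, truth = simulate_ssr_sequence([("GT", 8), ("GT", 7)], gaps=["CA"], seed=2)
        merged = merge_compound(find_perfect_ssrs(seq), seq, max_gap=4)
        assert [m.motif_string() for m in merged] == ["(GT)8CA(GT)7"]

    @pytest.mark.parametrize("seed", range(100))
    def test_detector_equals_truth_on_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        n_runs = int(rng.integers(1, 3))
        motifs = []
        for _ in range(n_runs):
            length = int(rng.integers(2, 5))
            unit = "".join(rng.choice(list("ACGT"), size=length))
            while not all(
                unit != unit[:d] * (length // d)
                for d in range(1, length)
                if length % d == 0
            ):
                unit = "".join(rng.choice(list("ACGT"), size=length))
            motifs.append((unit, int(rng.integers(6, 12))))
        gaps = ["TTTCC"[: int(rng.integers(5, 6))]] * (n_runs - 1)  # gap > max merge
        seq, truth = simulate_ssr_sequence(
            motifs, gaps=gaps, seed=int(rng.integers(0, 2**31)),
            min_repeats={2: 5, 3: 4, 4: 3},
        )
        got = find_perfect_ssrs(seq, {2: 5, 3: 4, 4: 3})
        assert [(l.start, l.end, l.motif.unit) for l in got] == [
            (l.start, l.end, l.motif.unit) for l in truth
        ]


class TestPrimerScreening:
    def test_published_primer_passes_length_and_gc(self):
        pair = PrimerPair(
            forward="GTGCAACACTATGACACCAG",
            reverse="ACAGTGCCCAATTGTTGT",
            product_size=177,
        )
        report = screen_primer_pair(pair, tm_method="wallace")
        by_name = {c.criterion: c for c in report.checks}
        assert by_name["forward_length"].value == 20
        assert by_name["forward_length"].passed
        assert by_name["forward_gc"].value == pytest.approx(0.50)
        assert by_name["forward_gc"].passed

    def test_too_short_primer_fails_length(self):
        pair = PrimerPair(forward="ACGTACGT", reverse="ACGTACGTACGTACGTACGT",
                          product_size=150)
        report = screen_primer_pair(pair)
        assert "forward_length" in report.failed_criteria()
        assert not report.passed

    def test_product_size_boundary(self):
        pair = PrimerPair(
            forward="GTGCAACACTATGACACCAG",
            reverse="ACAGTGCCCAATTGTTGTAC",
            product_size=97,
        )
        report = screen_primer_pair(pair)
        assert "product_size" in report.failed_criteria()

    def test_wallace_rule_value(self):
        # 2(A+T) + 4(G+C): 10 AT and 10 GC in this 20-mer -> 60
        assert melting_temperature("GTGCAACACTATGACACCAG", "wallace") == 60.0

    def test_unknown_tm_method_rejected(self):
        with pytest.raises(ValueError, match="tm_method"):
            melting_temperature("ACGTACGTACGT", "salt_adjusted")

    @pytest.mark.parametrize("method", ["wallace", "nearest_neighbor"])
    def test_widening_criteria_is_monotone(self, method):
        rng = np.random.default_rng(7)
        narrow = PrimerCriteria()
        wide = PrimerCriteria(
            size_range=(10, 40), tm_range=(20.0, 90.0),
            product_range=(50, 1000), gc_range=(0.0, 1.0),
        )
        for _ in range(25):
            f = "".join(rng.choice(list("ACGT"), size=int(rng.integers(12, 30))))
            r = "".join(rng.choice(list("ACGT"), size=int(rng.integers(12, 30))))
            pair = PrimerPair(f, r, product_size=int(rng.integers(60, 500)))
            if screen_primer_pair(pair, narrow, method).passed:
                assert screen_primer_pair(pair, wide, method).passed
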