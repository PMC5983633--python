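"""Target-site penalty scoring and degradome cleavage classification."""

import pytest

from mirstalk.seqio import SequenceRecord, reverse_complement
from mirstalk.targeting import (DegradomeProfile, NoCleavageEvidence,
                                PenaltyParams, categorize, cleavage_position,
                                map_degradome, scan_transcript, score_duplex)

from conftest import random_seq


def brute_force_score(mirna: str, site: str, params: PenaltyParams) -> float:
    """Independent per-position re-scoring used as the oracle."""
    total = 0.0
    n = len(mirna)
    for pos in range(1, n + 1):  # miRNA position, 1-based from 5'
        a = mirna[pos - 1]
        b = site[n - pos]
        if (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
            pen = 0.0
        elif (a, b) in {("G", "T"), ("T", "G")}:
            pen = params.gu_penalty
        else:
            pen = params.mismatch_penalty
        if pen and params.core_start <= pos <= params.core_end:
            pen *= params.core_multiplier
        total += pen
    return total


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self, rng):
        mirna = random_seq(rng, 21)
        site = score_duplex(mirna, reverse_complement(mirna))
        assert site.score == 0.0
        assert site.pairing == "|" * 21

    def test_gu_outside_core(self, rng):
        mirna = "A" * 14 + "G" + "A" * 6  # G at position 15
        target = reverse_complement(mirna)
        # opposite position 15 becomes U(T): G:U wobble outside the core
        mutated = target[:6] + "T" + target[7:]
        site = score_duplex(mirna, mutated)
        assert site.score == 0.5
        assert site.pairing[14] == "o"

    def test_mismatch_inside_core_doubled(self, rng):
        mirna = "A" * 21
        target = reverse_complement(mirna)  # all T
        # non-G:U mismatch opposite miRNA position 5: penalty 0.5 x 2
        mutated = target[:16] + "C" + target[17:]
        site = score_duplex(mirna, mutated)
        assert site.score == 1.0
        assert site.pairing[4] == "x"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_duplex("ACGT" * 5, "ACGT" * 6)

    def test_monotone_in_mismatches(self, rng):
        mirna = random_seq(rng, 21)
        site = reverse_complement(mirna)
        last = score_duplex(mirna, site).score
        for pos in range(21):
            current = site[pos]
            replacement = next(b for b in "ACGT" if b != current)
            site = site[:pos] + replacement + site[pos + 1:]
            score = score_duplex(mirna, site).score
            assert score >= last
            last = score

    def test_oracle_equivalence(self, rng):
        params = PenaltyParams()
        for _ in range(200):
            mirna = random_seq(rng, int(rng.integers(18, 25)))
            site = random_seq(rng, len(mirna))
            assert score_duplex(mirna, site, params).score == \
                pytest.approx(brute_force_score(mirna, site, params))


class TestScanTranscript:
    def test_planted_perfect_site(self, rng):
        mirna = random_seq(rng, 21)
        planted = reverse_complement(mirna)
        transcript = random_seq(rng, 300) + planted + random_seq(rng, 300)
        sites = scan_transcript(mirna, transcript)
        assert sites and sites[0].score == 0.0 and sites[0].start == 300

    def test_short_transcript_empty(self, rng):
        assert scan_transcript(random_seq(rng, 21), "ACGT") == []

    def test_brute_force_all_windows(self, rng):
        params = PenaltyParams()
        for _ in range(100):
            mirna = random_seq(rng, 21)
            transcript = random_seq(rng, int(rng.integers(100, 2000)))
            got = {(s.start, s.score) for s in
                   scan_transcript(mirna, transcript, params)}
            expected = set()
            for start in range(len(transcript) - 21 + 1):
                score = brute_force_score(
                    mirna, transcript[start:start + 21], params)
                if score <= params.score_cutoff:
                    expected.add((start, score))
            assert got == expected

    def test_sorted_by_score_then_position(self, rng):
        mirna = random_seq(rng, 21)
        planted = reverse_complement(mirna)
        transcript = planted + random_seq(rng, 100) + planted
        sites = scan_transcript(mirna, transcript)
        keys = [(s.score, s.start) for s in sites]
        assert keys == sorted(keys)


class TestCleavagePosition:
    def test_window_arithmetic(self):
        from mirstalk.targeting import TargetSite
        site = TargetSite("m", "t", 100, 121, "|" * 21)
        assert cleavage_position(site) == 111

    def test_window_at_transcript_start(self):
        from mirstalk.targeting import TargetSite
        site = TargetSite("m", "t", 0, 21, "|" * 21)
        assert cleavage_position(site) == 11


class TestCategorize:
    def _profile(self, counts: dict) -> DegradomeProfile:
        return DegradomeProfile("t", dict(counts))

    def test_unique_maximum_is_category_1(self):
        assert categorize(self._profile({111: 8, 50: 2, 60: 2}), 111) == 1

    def test_tied_maximum_is_category_2(self):
        assert categorize(self._profile({111: 5, 300: 5, 50: 2}), 111) == 2

    def test_above_median_is_category_3(self):
        # site 5 below max 9, median of {5,9,3,2} = 4 <= 5
        assert categorize(self._profile({111: 5, 300: 9, 50: 3, 60: 2}),
                          111) == 3

    def test_below_median_is_category_4(self):
        # median of {2,9,4,4} = 4 > 2
        assert categorize(self._profile({111: 2, 300: 9, 50: 4, 60: 4}),
                          111) == 4

    def test_singleton_is_category_5(self):
        assert categorize(self._profile({111: 1, 300: 9}), 111) == 5

    def test_no_evidence_raises(self):
        with pytest.raises(NoCleavageEvidence):
            categorize(self._profile({300: 9}), 111)

    def test_categories_total_and_exclusive(self, rng):
        for _ in range(100):
            positions = rng.choice(500, size=6, replace=False)
            counts = {int(p): int(rng.integers(1, 12)) for p in positions}
            profile = self._profile(counts)
            for pos in counts:
                assert categorize(profile, pos) in {1, 2, 3, 4, 5}


class TestMapDegradome:
    def test_single_read_single_position(self, rng):
        transcript = SequenceRecord("t", random_seq(rng, 400))
        read = transcript.sequence[100:130]
        profiles = map_degradome([read], [transcript])
        assert profiles["t"].counts == {100: 1}

    def test_no_matches(self, rng):
        transcript = SequenceRecord("t", random_seq(rng, 200))
        profiles = map_degradome(["N" * 30], [transcript])
        assert profiles["t"].total == 0

    def test_planted_peaks_recovered(self, rng):
        transcript = SequenceRecord("t", random_seq(rng, 600))
        peaks = {50: 10, 222: 4, 480: 7}
        reads = []
        for pos, height in peaks.items():
            reads += [transcript.sequence[pos:pos + 20]] * height
        profiles = map_degradome(reads, [transcript])
        assert profiles["t"].counts == peaks
        assert profiles["t"].total == sum(peaks.values())

    def test_multi_transcript_hits_increment_each(self, rng):
        shared = random_seq(rng, 40)
        t1 = SequenceRecord("t1", shared + random_seq(rng, 100))
        t2 = SequenceRecord("t2", random_seq(rng, 50) + shared)
        profiles = map_degradome([shared[:20]], [t1, t2])
        assert profiles["t1"].counts == {0: 1}
        assert profiles["t2"].counts == {50: 1}
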