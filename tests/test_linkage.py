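"""Adherence accounting, SGIC construction and fuzzy code matching."""

import numpy as np
import pytest

from nof1series import (
    GenParams,
    SGICAnswers,
    build_sgic,
    compute_adherence,
    generate_cohort,
    linkage_rate,
    match_codes,
    osa_distance,
)
from nof1series.cohort import CohortDataset, ParticipantSeries, PRORecord, TrialSchedule
from nof1series.linkage import hamming_distance


def toy_dataset(flags):
    """Single ABAB participant, one record per (day, performed) pair."""
    sched = TrialSchedule("ABAB")
    recs = [
        PRORecord("p", day, sched.phase_of_day(day), performed=perf, stress_today=5)
        for day, perf in flags
    ]
    return CohortDataset([ParticipantSeries("p", sched, recs, arm="box")])


class TestComputeAdherence:
    def test_all_adherent(self):
        flags = [(d, True) for d in range(1, 6)] + [(d, False) for d in range(8, 13)]
        report = compute_adherence(toy_dataset(flags))
        assert report.overall_fraction == 1.0

    def test_hand_counted_fraction(self):
        # 7 adherent of 10: A-days 1-5 (4 performed), B-days 8-12 (3 skipped)
        flags = [(1, True), (2, True), (3, True), (4, True), (5, False)]
        flags += [(8, False), (9, False), (10, False), (11, True), (12, True)]
        report = compute_adherence(toy_dataset(flags))
        assert report.overall_fraction == pytest.approx(0.7)

    def test_control_cell_fraction(self):
        # 244 of 246 control-phase records without the exercise performed
        flags = [(8, False)] * 0  # placeholder, built below
        sched = TrialSchedule("ABAB", 246, 4)
        recs = [
            PRORecord("p", day, "B", performed=(i < 2), stress_today=5)
            for i, day in enumerate(range(247, 493))
        ]
        ds = CohortDataset([ParticipantSeries("p", sched, recs, arm="mindfulness")])
        report = compute_adherence(ds)
        assert report.cell_fraction("mindfulness", "B") * 100 == pytest.approx(99.2, abs=0.05)

    def test_overall_is_documented_weighted_cell_mean(self):
        cohort = generate_cohort(GenParams(n_participants=10, seed=3))
        report = compute_adherence(cohort)
        weighted = sum(adh for adh, _ in report.cells.values()) / sum(
            doc for _, doc in report.cells.values()
        )
        assert report.overall_fraction == pytest.approx(weighted)

    def test_no_flags_rejected(self):
        sched = TrialSchedule("ABAB")
        ds = CohortDataset([ParticipantSeries("p", sched, [PRORecord("p", 1, "A")])])
        with pytest.raises(ValueError, match="no documented"):
            compute_adherence(ds)


class TestBuildSgic:
    def test_stated_fields_concatenate(self):
        answers = SGICAnswers("Anna", "Berlin", "F", 1, "23", "10115")
        assert build_sgic(answers) == "ANBEF135"

    def test_case_and_diacritics_folded(self):
        a = SGICAnswers("anna", "berlin", "f", 1, "23", "10115")
        b = SGICAnswers("ÁNNA", "Bérlin", "female", 1, "23", "10115")
        assert build_sgic(a) == build_sgic(b) == "ANBEF135"

    def test_sibling_count_capped_at_nine(self):
        answers = SGICAnswers("Anna", "Berlin", "F", 12, "23", "10115")
        assert build_sgic(answers)[5] == "9"

    def test_short_fields_padded_with_warning(self):
        answers = SGICAnswers("A", "Berlin", "M", 0, "x", "10115")
        with pytest.warns(UserWarning, match="padded"):
            code = build_sgic(answers)
        assert code == "A_BEM0_5"

    def test_seven_symbol_variant_drops_sex(self):
        answers = SGICAnswers("Anna", "Berlin", "F", 1, "23", "10115")
        assert build_sgic(answers, include_sex=False) == "ANBE135"


class TestOsaDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [
            ("ANBEF135", "ANBEF135", 0),
            ("ANBEF135", "ANBEF136", 1),
            ("ANBEF135", "ANBFE135", 1),  # adjacent transposition
            ("ANBEF135", "ANBEF35", 1),  # deletion
            ("ANBEF135", "XNBEF136", 2),
        ],
    )
    def test_known_distances(self, a, b, d):
        assert osa_distance(a, b) == d

    def test_hamming_requires_equal_length(self):
        with pytest.raises(ValueError):
            hamming_distance("AB", "ABC")


class TestMatchCodes:
    def test_exact_match(self):
        result = match_codes(["ANBEF135"], ["ANBEF135"])
        assert result.exact == [("ANBEF135", "ANBEF135")]

    def test_fuzzy_single_substitution(self):
        result = match_codes(["ANBEF135"], ["ANBEF136"])
        assert result.fuzzy == [("ANBEF135", "ANBEF136", 1)]

    def test_equidistant_candidates_ambiguous(self):
        result = match_codes(["AAAA1111", "AAAA1112"], ["AAAA1113"])
        assert result.ambiguous == ["AAAA1113"]
        assert not result.fuzzy

    def test_duplicate_baselines_excluded_and_reported(self):
        result = match_codes(["AAAA1111", "AAAA1111"], ["AAAA1111"])
        assert result.duplicate_baselines == ["AAAA1111"]
        assert result.unmatched == ["AAAA1111"]

    def test_partition_is_disjoint_and_complete(self):
        base = ["ANBEF135", "MUHAM041", "KLKOX922"]
        follow = ["ANBEF135", "MUHAM042", "ZZZZ9999"]
        r = match_codes(base, follow)
        buckets = (
            [f for _, f in r.exact]
            + [f for _, f, _ in r.fuzzy]
            + r.ambiguous
            + r.unmatched
        )
        assert sorted(buckets) == sorted(follow)

    def test_symmetric_when_codes_unique(self):
        base = ["ANBEF135", "MUHAM041"]
        follow = ["ANBEF136", "MUHAM041"]
        fwd = match_codes(base, follow)
        rev = match_codes(follow, base)
        fwd_pairs = {(b, f) for b, f in fwd.exact} | {(b, f) for b, f, _ in fwd.fuzzy}
        rev_pairs = {(f, b) for b, f in rev.exact} | {(f, b) for b, f, _ in rev.fuzzy}
        assert fwd_pairs == rev_pairs


class TestLinkageRate:
    def test_study_scale_rates(self):
        # 27 exact + 4 fuzzy of 39 follow-ups; baseline codes built pairwise
        # far apart so each fuzzy follow-up has a unique closest candidate
        rng = np.random.default_rng(0)
        alphabet = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
        codes = []
        while len(codes) < 58:
            cand = "".join(rng.choice(alphabet, 8))
            if all(osa_distance(cand, c) >= 3 for c in codes):
                codes.append(cand)
        baseline, alien = codes[:50], codes[50:]
        followups = (
            baseline[:27]
            + [("Q" if c[0] != "Q" else "Z") + c[1:] for c in baseline[27:31]]
            + alien
        )
        result = match_codes(baseline, followups)
        assert len(result.exact) == 27 and len(result.fuzzy) == 4
        rates = linkage_rate(result, 39)
        assert rates.exact_percent == 69.2
        assert rates.total_percent == 79.5

    def test_none_matched(self):
        rates = linkage_rate(match_codes(["AAAA0000"], ["BBBB9999"]), 10)
        assert rates.total_percent == 0.0

    def test_all_matched(self):
        rates = linkage_rate(match_codes(["A1"], ["A1"]), 1)
        assert rates.exact_percent == 100.0

    def test_zero_followups_rejected(self):
        with pytest.raises(ValueError):
            linkage_rate(match_codes([], []), 0)
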