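import itertools

import pytest

from crctnm.config import TnmConfig
from crctnm.corpus import ClinicalReport, TextSpan
from crctnm.synth import distractor_bank
from crctnm.tnm import (ALLOWED_VALUES, CATEGORIES, RANKING, TNMPhrase,
                        aggregate_max, extract_tnm, find_tnm_phrases,
                        guard_false_positive, normalize_value, parse_phrase)


def tokens_of(phrases):
    return [(cv.category, cv.prefix, cv.value)
            for p in phrases for cv in p.tokens]


# ---------------------------------------------------------------------------
# find_tnm_phrases


class TestFindPhrases:
    def test_cue_anchored_singleton(self, make_report):
        phrases = find_tnm_phrases(make_report("Staged as T2"))
        assert len(phrases) == 1
        assert phrases[0].anchored_by_cue
        assert tokens_of(phrases) == [("T", "", "2")]

    def test_empty_input(self, make_report):
        assert find_tnm_phrases(make_report("")) == []

    def test_mri_sequence_rejected(self, make_report):
        text = "Axial T1 and T2 weighted sequences were acquired"
        assert find_tnm_phrases(make_report(text)) == []

    def test_variable_order_six_tokens(self, make_report):
        phrases = find_tnm_phrases(make_report("R0 pT3 L0 V0 N0 Mx"))
        assert len(phrases) == 1
        assert [cv.category for cv in phrases[0].tokens] == \
            ["R", "T", "L", "V", "N", "M"]

    def test_unanchored_singleton_dropped(self, make_report):
        assert find_tnm_phrases(make_report("Measured T2 on review")) == []

    def test_sentence_breaks_phrase(self, make_report):
        phrases = find_tnm_phrases(make_report("pT3 N1. V0 R0"))
        assert len(phrases) == 2

    def test_phrase_span_matches_text(self, make_report):
        report = make_report("Conclusion: pT2 N0 M0 found.")
        (phrase,) = find_tnm_phrases(report)
        assert report.text[phrase.span.start:phrase.span.end] == phrase.span.text
        assert phrase.span.text == "pT2 N0 M0"

    def test_single_category_invariant(self, make_report):
        # any emitted phrase with < 2 distinct categories must be cue-anchored
        for text in ("Staged as T2", "T0 N0", "TNM stage T3", "stage SM2"):
            for phrase in find_tnm_phrases(make_report(text)):
                cats = {cv.category for cv in phrase.tokens}
                if len(cats) < 2:
                    assert phrase.anchored_by_cue


# ---------------------------------------------------------------------------
# parse_phrase (Table-style dialect conformance)


@pytest.mark.parametrize("text,expected", [
    ("T1/2/3 N0 V0", [("T", "", "1"), ("T", "", "2"), ("T", "", "3"),
                      ("N", "", "0"), ("V", "", "0")]),
    ("T1N0M0", [("T", "", "1"), ("N", "", "0"), ("M", "", "0")]),
    ("T 1 N0M0", [("T", "", "1"), ("N", "", "0"), ("M", "", "0")]),
    ("pT1 N0", [("T", "p", "1"), ("N", "", "0")]),
    ("ypT1 N0", [("T", "yp", "1"), ("N", "", "0")]),
    ("ymrT1 N0", [("T", "ymr", "1"), ("N", "", "0")]),
    ("T1a (solitary tumour) N0", [("T", "", "1a"), ("N", "", "0")]),
    ("T1 n1", [("T", "", "1"), ("N", "", "1")]),
    ("Tis N0", [("T", "", "is"), ("N", "", "0")]),
    ("SM2 V1", [("SM", "", "2"), ("V", "", "1")]),
    ("Pn1 L1", [("Pn", "", "1"), ("L", "", "1")]),
    ("H III N0", [("H", "", "3"), ("N", "", "0")]),
])
def test_parse_phrase_dialects(text, expected):
    got = [(cv.category, cv.prefix, cv.value) for cv in parse_phrase(text)]
    assert got == expected


def test_parse_phrase_offset():
    values = parse_phrase("pT3 N1", offset=100)
    assert values[0].span.start == 100
    assert values[0].span.text == "pT3"


def test_parse_phrase_skips_residue():
    got = [(cv.category, cv.value) for cv in parse_phrase("junk T2 blah N1 xyz")]
    assert got == [("T", "2"), ("N", "1")]


def test_unknown_prefix_dropped():
    # "ca" is not a whitelisted combination: the token must not survive
    assert parse_phrase("caT2 N0")[0].category == "N"


# ---------------------------------------------------------------------------
# normalize_value


class TestNormalize:
    def test_o_substitution_equals_corrected_parse(self):
        left = [(cv.category, cv.prefix, cv.value)
                for cv in parse_phrase("pT3 NO MX")]
        right = [(cv.category, cv.prefix, cv.value)
                 for cv in parse_phrase("pT3 N0 MX")]
        assert left == right

    def test_x_case_fold(self):
        assert normalize_value("x", "M") == "X"

    def test_out_of_range_rejected(self):
        assert normalize_value("5", "T") is None
        assert normalize_value("3", "M") is None
        assert normalize_value("X", "SM") is None

    def test_substage_case_fold(self):
        assert normalize_value("1A", "T") == "1a"

    def test_roman_haggitt(self):
        assert normalize_value("IV", "H") == "4"
        assert normalize_value("ii", "H") == "2"

    def test_allowed_sets_match_documented_sizes(self):
        sizes = {"T": 23, "N": 14, "M": 6, "V": 4, "R": 4, "L": 3,
                 "Pn": 3, "G": 5, "SM": 3, "H": 5}
        assert {c: len(v) for c, v in ALLOWED_VALUES.items()} == sizes


# ---------------------------------------------------------------------------
# guards


class TestGuards:
    @pytest.mark.parametrize("text,start,end", [
        ("T1-weighted images", 0, 2),
        ("first thoracic vertebra (T1)", 25, 27),
        ("T2 signal is high", 0, 2),
        ("level of T12/L1 disc", 13, 15),
    ])
    def test_rejects_distractor_context(self, text, start, end):
        span = TextSpan(start, end, text[start:end])
        assert guard_false_positive(span, text) is True

    def test_accepts_real_staging(self):
        text = "T0 N0"
        assert guard_false_positive(TextSpan(0, 2, "T0"), text) is False

    def test_guard_is_sentence_bounded(self):
        # guard vocabulary in the NEXT sentence must not affect the candidate
        text = "pT3 N0 M0. T2 weighted sequences acquired."
        assert guard_false_positive(TextSpan(7, 9, "M0"), text) is False


# ---------------------------------------------------------------------------
# aggregate_max


def phrase_from(text):
    report = ClinicalReport(report_id="x", report_type="pathology",
                            text="stage " + text)
    phrases = find_tnm_phrases(report)
    assert phrases, text
    return phrases


def test_aggregate_two_phrases_takes_per_category_maxima(make_report):
    report = make_report("R0 pT3 L0 V0 N0 Mx. Also pT2 N1 Mx L0 V0 R1")
    result = aggregate_max(find_tnm_phrases(report), "x")
    assert result.values["T"] == "3"
    assert result.values["Tpre"] == "p"
    assert result.values["N"] == "1"
    assert result.values["M"] == "X"
    assert result.values["L"] == "0"
    assert result.values["V"] == "0"
    assert result.values["R"] == "1"


def test_aggregate_single_phrase_identity(make_report):
    result = aggregate_max(find_tnm_phrases(make_report("T2 N0")), "x")
    assert result.values["T"] == "2"
    assert result.values["N"] == "0"
    absent = [c for c in CATEGORIES if c not in ("T", "N")]
    assert all(result.values[c] is None for c in absent)


def _pairwise_max(category, values):
    """Oracle: exhaustive pairwise comparison under the documented ranking."""
    informative = [v for v in values if v != "X"]
    if not informative:
        return "X"
    best = informative[0]
    for v in informative[1:]:
        if RANKING[category].index(v) >= RANKING[category].index(best):
            best = v
    return best


@pytest.mark.parametrize("values,expected", [
    (["1a", "1d", "2"], "2"),
    (["X", "0"], "0"),
    (["is", "1"], "1"),
])
def test_aggregate_ranking_examples(values, expected, make_report):
    text = ". ".join(f"stage T{v} N0" if v != "X" else "stage TX N0"
                     for v in values)
    result = aggregate_max(find_tnm_phrases(make_report(text)), "x")
    assert result.values["T"] == expected
    assert expected == _pairwise_max("T", values)


def test_aggregate_matches_pairwise_oracle_exhaustively(make_report):
    for values in itertools.product(["0", "is", "1", "1b", "2", "4d", "X"],
                                    repeat=2):
        text = ". ".join(f"stage T{v} N0" for v in values)
        result = aggregate_max(find_tnm_phrases(make_report(text)), "x")
        assert result.values["T"] == _pairwise_max("T", list(values)), values


def test_aggregate_permutation_invariance(make_report):
    report = make_report("pT2 N1 M0. ypT3a N0 MX. T1 N2a V1")
    phrases = find_tnm_phrases(report)
    base = aggregate_max(phrases, "x").values
    for perm in itertools.permutations(phrases):
        assert aggregate_max(list(perm), "x").values == base


def test_tpre_tie_breaks_to_last_occurrence(make_report):
    report = make_report("pT2 N0. ypT2 N0")
    result = aggregate_max(find_tnm_phrases(report), "x")
    assert result.values["T"] == "2"
    assert result.values["Tpre"] == "yp"


def test_x_only_when_sole_observation(make_report):
    result = aggregate_max(find_tnm_phrases(make_report("TX N0")), "x")
    assert result.values["T"] == "X"


# ---------------------------------------------------------------------------
# extract_tnm


def test_extract_exact_intro_example(make_report):
    results = extract_tnm([make_report("T1 N0 M0")])
    assert results[0].values["T"] == "1"
    assert results[0].values["N"] == "0"
    assert results[0].values["M"] == "0"


def test_extract_no_staging(make_report):
    (res,) = extract_tnm([make_report("Unremarkable appearances throughout.")])
    assert all(v is None for v in res.values.values())
    assert res.phrases == []


def test_distractor_locality(make_report):
    base = "CONCLUSION:\nStaging: pT3 N1 M0.\n"
    baseline = extract_tnm([make_report(base)])[0].values
    for distractor in distractor_bank():
        res = extract_tnm([make_report(base + "\n" + distractor)])[0]
        assert res.values == baseline, distractor


def test_extract_deterministic(make_report):
    reports = [make_report(f"Staging: pT{i % 4 + 1} N0 M0.", report_id=f"r{i}")
               for i in range(10)]
    a = [r.to_row() for r in extract_tnm(reports)]
    b = [r.to_row() for r in extract_tnm(reports)]
    assert a == b


def test_workers_match_serial(make_report):
    reports = [make_report(f"Staging: pT{i % 4 + 1} N{i % 3} M0.",
                           report_id=f"r{i}") for i in range(12)]
    serial = [r.to_row() for r in extract_tnm(reports, workers=1)]
    parallel = [r.to_row() for r in extract_tnm(reports, workers=4)]
    assert serial == parallel


def test_drop_historical_scope(make_report):
    report = make_report(
        "Previous staging recorded: pT2 N0 (2019).\nStaging: pT3 N1 M0.")
    full = extract_tnm([report])[0]
    current = extract_tnm([report], drop_historical=True)[0]
    assert full.values["T"] == "3"
    assert current.values["T"] == "3"
    assert len(full.phrases) == 2
    assert len(current.phrases) == 1


def test_config_cue_list_is_respected(make_report):
    no_cues = TnmConfig(cues=())
    assert find_tnm_phrases(make_report("Staged as T2"), config=no_cues) == []
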