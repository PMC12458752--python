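"""Synthetic clinical-report generator with exhaustive ground truth.

Reports mimic sectioned pathology (CLINICAL DETAILS / MACROSCOPY /
MICROSCOPY / CONCLUSION) and imaging (TECHNIQUE / FINDINGS / IMPRESSION)
documents. Staging phrases are drawn from a deterministic enumeration of
every category/value token rendered under each supported documentation
dialect, so the generating truth is known exactly; distractor strings
(MRI sequences, vertebral levels, measurements) can be injected at a
configurable rate and must never parse.
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from . import tnm
from .context import MODIFIERS
from .corpus import ClinicalReport, TextSpan
from .errors import ValidationError

#: documentation dialects, mirroring the observed reporting variants
DIALECTS = (
    "multi_value",        # T1/2/3 N0
    "o_substitution",     # NO for N0
    "lowercase",          # t1 n0
    "no_gap",             # T1N0
    "letter_gap",         # T 1 N0
    "prefixed",           # ypT1 N0
    "bracketed_comment",  # T1a (solitary tumour) N0
    "variable_order",     # R0 pT3 ... N0
    "cue_singleton",      # Staged as T2
)

#: written (surface) value tokens per category, including Roman Haggitt forms
WRITTEN_VALUES: dict[str, tuple[str, ...]] = {
    **{cat: vals for cat, vals in tnm.ALLOWED_VALUES.items() if cat != "H"},
    "H": ("0", "1", "2", "3", "4", "I", "II", "III", "IV"),
}

_ROMAN_TO_ARABIC = {"I": "1", "II": "2", "III": "3", "IV": "4"}


@dataclass(frozen=True)
class PhraseExample:
    """One enumerated phrase with its expected parse."""

    text: str
    expected: tuple[tuple[str, str, str], ...]  # (category, prefix, value)
    dialect: str


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus generator."""

    n_reports: int = 100
    report_type_mix: float = 0.5          # probability of a pathology report
    p_tnm_phrase: float = 0.8
    dialect_weights: dict = field(
        default_factory=lambda: {d: 1.0 for d in DIALECTS})
    distractor_rate: float = 0.0          # expected distractors per report
    crc_positive_rate: float = 0.6
    modifier_mix: dict = field(
        default_factory=lambda: {m: 1.0 for m in MODIFIERS})
    seed: int = 0
    p_historical_stage: float = 0.0       # extra historical staging phrase
    p_implicit_stage: float = 0.0         # implicit stage instead of explicit

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValidationError("n_reports must be >= 0")
        for name in ("report_type_mix", "p_tnm_phrase", "crc_positive_rate",
                     "p_historical_stage", "p_implicit_stage"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {val}")
        if self.distractor_rate < 0:
            raise ValidationError("distractor_rate must be >= 0")
        for label, weights, keys in (
                ("dialect_weights", self.dialect_weights, DIALECTS),
                ("modifier_mix", self.modifier_mix, MODIFIERS)):
            unknown = set(weights) - set(keys)
            if unknown:
                raise ValidationError(f"{label}: unknown keys {sorted(unknown)}")
            if any(w < 0 for w in weights.values()):
                raise ValidationError(f"{label}: weights must be >= 0")
            if not any(w > 0 for w in weights.values()):
                raise ValidationError(f"{label}: at least one weight must be > 0")


@dataclass
class GoldRecord:
    """Exhaustive truth for one generated report."""

    report_id: str
    crc_status: bool
    tnm_gold: dict = field(default_factory=dict)
    tnm_historical: dict = field(default_factory=dict)
    tnm_implicit: dict = field(default_factory=dict)
    phrase_spans: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phrase_spans"] = [s.to_dict() if isinstance(s, TextSpan) else s
                             for s in self.phrase_spans]
        return d


# ---------------------------------------------------------------------------
# phrase grammar enumeration


def _canonical(category: str, written: str) -> str:
    if category == "H":
        return _ROMAN_TO_ARABIC.get(written, written)
    return written


def _render(category: str, written: str, prefix: str = "") -> str:
    gap = " " if category == "H" and written in _ROMAN_TO_ARABIC else ""
    return f"{prefix}{category}{gap}{written}"


def _partner(category: str) -> tuple[str, tuple[str, str, str]]:
    if category != "N":
        return "N0", ("N", "", "0")
    return "M0", ("M", "", "0")


def _mv_values(category: str) -> list[str]:
    return [v for v in WRITTEN_VALUES[category] if v.isdigit()][:3]


def enumerate_phrase_grammar() -> list[PhraseExample]:
    """Deterministic cross-product of category tokens and dialect renderings.

    Every entry pairs a phrase text with the exact (category, prefix,
    value) tokens extraction must recover from it.
    """
    out: list[PhraseExample] = []
    seps = {"/": "/", ",": ", ", "or": " or ", "-": "-"}

    for cat in tnm.RANKING:  # stable category order
        partner_txt, partner_tok = _partner(cat)
        for written in WRITTEN_VALUES[cat]:
            value = _canonical(cat, written)
            tok = _render(cat, written)
            expect_one = ((cat, "", value),)
            expect_pair = expect_one + (partner_tok,)

            out.append(PhraseExample(f"Staged as {tok}", expect_one,
                                     "cue_singleton"))
            out.append(PhraseExample(f"{tok.lower()} {partner_txt.lower()}",
                                     expect_pair, "lowercase"))
            out.append(PhraseExample(f"{cat} {written} {partner_txt}",
                                     expect_pair, "letter_gap"))
            out.append(PhraseExample(
                f"{tok} (solitary lesion) {partner_txt}", expect_pair,
                "bracketed_comment"))
            p1, p2 = [p for p in ("R0", "V0", "L0")
                      if not p.startswith(cat)][:2]
            expect_vo = ((p1[0], "", "0"), (cat, "", value), (p2[0], "", "0"))
            out.append(PhraseExample(f"{p1} {tok} {p2}", expect_vo,
                                     "variable_order"))
            if not (cat == "H" and written in _ROMAN_TO_ARABIC):
                out.append(PhraseExample(f"{tok}{partner_txt}", expect_pair,
                                         "no_gap"))
            if cat == "T":
                for prefix in ("c", "p", "y", "r", "a", "m", "yp", "mr",
                               "ymr", "cp"):
                    expect_pref = ((cat, prefix, value), partner_tok)
                    ptok = _render(cat, written, prefix)
                    out.append(PhraseExample(f"{ptok} {partner_txt}",
                                             expect_pref, "prefixed"))
                    out.append(PhraseExample(
                        f"{ptok.lower()} {partner_txt.lower()}", expect_pref,
                        "prefixed"))
                    out.append(PhraseExample(f"{ptok}{partner_txt}",
                                             expect_pref, "prefixed"))

        if "0" in WRITTEN_VALUES[cat]:
            expect = ((cat, "", "0"), partner_tok)
            out.append(PhraseExample(f"{cat}O {partner_txt}", expect,
                                     "o_substitution"))

        values = _mv_values(cat)
        for sep, joiner in seps.items():
            mv = values if sep != "-" else values[:2]
            text = f"{cat}{joiner.join(mv)} {partner_txt}"
            expect = tuple((cat, "", v) for v in mv) + (partner_tok,)
            out.append(PhraseExample(text, expect, "multi_value"))
    return out


def distractor_bank() -> tuple[str, ...]:
    """TNM look-alike strings that must never yield staging tokens."""
    return (
        "Axial T1 and T2 weighted sequences were acquired.",
        "T1-weighted imaging of the pelvis was performed.",
        "T2-weighted sagittal sequences were reviewed.",
        "T2 FLAIR sequences were obtained.",
        "High T2 signal in the presacral space.",
        "Sagittal T2 TSE and axial T1 sequences.",
        "Seen on the T2W TSE sequence.",
        "Enhancement noted at T1 and T2 post-contrast.",
        "T1-T12 vertebral bodies appear normal.",
        "No suspicious marrow signal at the first thoracic vertebra (T1).",
        "Degenerative change at T12/L1.",
        "Metal fixation from T10 to L2.",
        "Vertebral level L1 appears intact.",
        "L1 and L2 vertebral bodies are normal.",
        "Polyp measuring 10 x 2 mm.",
        "Nodule measuring 2.3 x 1.2 cm in the axial plane.",
        "Discussed at MDT on 01/02/2021.",
        "Please see prior imaging dated 12/03/2019.",
        "Contact the department on 01865 123456.",
        "Mobile number 07700 900123.",
        "Prescribed oxaliplatin 85 mg/m2.",
        "CT chest abdomen pelvis with contrast.",
        "MRI rectum protocol, 3 Tesla magnet.",
        "Specimen container labelled RMH 123.",
    )


# ---------------------------------------------------------------------------
# corpus generation

_POSITIVE_TERMS = ("tumour", "adenocarcinoma", "carcinoma", "cancer", "mass")
_POSITIVE_SITES = ("sigmoid colon", "rectum", "caecum", "transverse colon",
                   "descending colon", "splenic flexure")

_NEGATIVE_TEMPLATES = {
    "negated": "No evidence of {term} in the {site}.",
    "historical": "History of {site} {term}, resected in 2015.",
    "general": "Screening for {site} {term}.",
    "nondefinite": "Possible {term} in the {site}.",
    "metastasis": "Liver deposits in keeping with metastases from {site} {term}.",
    "recurrence": "Recurrent {term} at the {site}.",
    "treatment_response": "Good response to chemotherapy with smaller {site} {term}.",
}

_NO_KEYWORD_SENTENCES = (
    "Normal appearances throughout.",
    "Unremarkable study.",
    "Within normal limits.",
)


class _TextBuilder:
    def __init__(self) -> None:
        self._parts: list[str] = []
        self._len = 0

    def add(self, piece: str) -> tuple[int, int]:
        start = self._len
        self._parts.append(piece)
        self._len += len(piece)
        return start, self._len

    def text(self) -> str:
        return "".join(self._parts)


def _weighted_choice(rng: random.Random, weights: dict) -> str:
    keys = [k for k, w in weights.items() if w > 0]
    cum = []
    total = 0.0
    for k in keys:
        total += weights[k]
        cum.append(total)
    x = rng.random() * total
    for k, c in zip(keys, cum):
        if x <= c:
            return k
    return keys[-1]


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    # Knuth's method; fine for the small rates used here
    limit = math.exp(-lam)
    k, prod = 0, rng.random()
    while prod > limit:
        k += 1
        prod *= rng.random()
    return k


def _gold_from_expected(expected: Sequence[tuple[str, str, str]]) -> dict:
    """Per-category ranking maxima for a set of generated tokens."""
    by_cat: dict[str, list[tuple[str, str]]] = {}
    for cat, prefix, value in expected:
        by_cat.setdefault(cat, []).append((prefix, value))
    gold: dict[str, str] = {}
    for cat, pairs in by_cat.items():
        informative = [(p, v) for p, v in pairs if v != "X"]
        if not informative:
            gold[cat] = "X"
            continue
        best = max(enumerate(informative),
                   key=lambda kv: (tnm.RANKING[cat].index(kv[1][1]), kv[0]))[1]
        gold[cat] = best[1]
        if cat == "T" and best[0]:
            gold["Tpre"] = best[0]
    return gold


def _grammar_by_dialect() -> dict[str, list[PhraseExample]]:
    table: dict[str, list[PhraseExample]] = {d: [] for d in DIALECTS}
    for ex in enumerate_phrase_grammar():
        table[ex.dialect].append(ex)
    return table


_GRAMMAR_CACHE: Optional[dict[str, list[PhraseExample]]] = None


def _grammar() -> dict[str, list[PhraseExample]]:
    global _GRAMMAR_CACHE
    if _GRAMMAR_CACHE is None:
        _GRAMMAR_CACHE = _grammar_by_dialect()
    return _GRAMMAR_CACHE


def generate_corpus(config: GeneratorConfig
                    ) -> tuple[list[ClinicalReport], list[GoldRecord]]:
    """Generate a seeded corpus with its exhaustive gold records."""
    config.validate()
    rng = random.Random(config.seed)
    grammar = _grammar()
    bank = distractor_bank()

    reports: list[ClinicalReport] = []
    golds: list[GoldRecord] = []
    for idx in range(config.n_reports):
        rid = f"r{idx:05d}"
        is_path = rng.random() < config.report_type_mix
        rtype = "pathology" if is_path else "imaging"
        builder = _TextBuilder()
        gold = GoldRecord(report_id=rid, crc_status=False,
                          provenance={"dialects": [], "modifiers": [],
                                      "historical": False, "implicit": False})

        headers = (("CLINICAL DETAILS", "MACROSCOPY", "MICROSCOPY", "CONCLUSION")
                   if is_path else ("TECHNIQUE", "FINDINGS", "IMPRESSION"))
        intro = {"CLINICAL DETAILS": "Assessment as requested.",
                 "MACROSCOPY": "Specimen received intact.",
                 "MICROSCOPY": "Sections examined.",
                 "CONCLUSION": "See below.",
                 "TECHNIQUE": "Examination performed per departmental protocol.",
                 "FINDINGS": "Review of the study.",
                 "IMPRESSION": "Summary follows."}

        n_distract = _poisson(rng, config.distractor_rate)
        distractors = [bank[rng.randrange(len(bank))] for _ in range(n_distract)]

        crc_positive = rng.random() < config.crc_positive_rate
        term = _POSITIVE_TERMS[rng.randrange(len(_POSITIVE_TERMS))]
        site = _POSITIVE_SITES[rng.randrange(len(_POSITIVE_SITES))]
        if crc_positive:
            crc_sentence = f"There is a {term} in the {site}."
            gold.crc_status = True
        elif rng.random() < 0.3:
            crc_sentence = _NO_KEYWORD_SENTENCES[
                rng.randrange(len(_NO_KEYWORD_SENTENCES))]
        else:
            modifier = _weighted_choice(rng, config.modifier_mix)
            crc_sentence = _NEGATIVE_TEMPLATES[modifier].format(
                term=term, site=site)
            gold.provenance["modifiers"].append(modifier)

        has_tnm = rng.random() < config.p_tnm_phrase
        implicit = has_tnm and rng.random() < config.p_implicit_stage
        historical = (has_tnm and not implicit
                      and rng.random() < config.p_historical_stage)

        staging_sentence = None
        staging_phrase_text = None
        if has_tnm and not implicit:
            dialect = _weighted_choice(rng, config.dialect_weights)
            example = grammar[dialect][rng.randrange(len(grammar[dialect]))]
            staging_phrase_text = example.text
            gold.provenance["dialects"].append(dialect)
            if historical:
                gold.tnm_historical = _gold_from_expected(example.expected)
                gold.provenance["historical"] = True
            else:
                gold.tnm_gold = _gold_from_expected(example.expected)
        elif implicit:
            gold.tnm_implicit = {"T": "0"}
            gold.provenance["implicit"] = True

        for header in headers:
            builder.add(f"{header}:\n")
            builder.add(intro[header] + "\n")
            if header in ("TECHNIQUE", "MACROSCOPY"):
                for d in distractors:
                    builder.add(d + "\n")
            if header in ("MICROSCOPY", "FINDINGS"):
                builder.add(crc_sentence + "\n")
                if implicit:
                    builder.add("No residual tumour is identified.\n")
            if header in ("CONCLUSION", "IMPRESSION") and staging_phrase_text:
                if historical:
                    builder.add("Previous staging recorded: ")
                    start, end = builder.add(staging_phrase_text)
                    builder.add(" (2019).\n")
                else:
                    builder.add("Staging: ")
                    start, end = builder.add(staging_phrase_text)
                    builder.add(".\n")
                gold.phrase_spans.append(
                    TextSpan(start, end, staging_phrase_text))
            builder.add("\n")

        text = builder.text()
        reports.append(ClinicalReport(report_id=rid, report_type=rtype,
                                      text=text))
        golds.append(gold)
    return reports, golds


def gold_rows(golds: Sequence[GoldRecord]) -> list[dict]:
    return [g.to_dict() for g in golds]
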