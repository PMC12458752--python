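"""Primary colorectal-cancer report detection.

Tumour keywords are matched first; a keyword counts only when linked to a
colorectal site term in the same sentence (or when it is a self-sufficient
compound term such as "colorectal cancer"). Linked mentions are then run
through the modifier-scoping engine, and any mention carrying a
disqualifying modifier (negated, historical, general, non-definite,
metastasis, recurrence, treatment response) is excluded. A report is
positive when at least one linked, unmodified mention survives.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .config import CrcConfig
from .corpus import ClinicalReport, TextSpan
from .context import ModifierAssignment, TriggerRule, default_trigger_rules, \
    scope_modifiers
from .errors import ConfigurationError

_SENTENCE_END = re.compile(r"[.;!?\n]")

LEXICON_FILES = ("tumour_terms.txt", "sites.txt", "compound_terms.txt")


@dataclass(frozen=True)
class CrcLexicons:
    """Active tumour, anatomical-site, and compound term lists."""

    tumour_terms: tuple[str, ...]
    site_terms: tuple[str, ...]
    compound_terms: tuple[str, ...]


@dataclass(frozen=True)
class KeywordMatch:
    """One tumour-keyword mention with its linkage and modifier labels."""

    tumour_span: TextSpan
    site_span: Optional[TextSpan]
    linked: bool
    modifiers: frozenset[str]
    included: bool
    left_context: str
    right_context: str

    def to_dict(self) -> dict:
        return {
            "tumour": self.tumour_span.to_dict(),
            "site": self.site_span.to_dict() if self.site_span else None,
            "linked": self.linked,
            "modifiers": sorted(self.modifiers),
            "included": self.included,
            "left_context": self.left_context,
            "right_context": self.right_context,
        }


@dataclass
class CRCResult:
    """Per-report decision with reviewable included/excluded phrases."""

    report_id: str
    crc_status: bool
    included_phrases: list[KeywordMatch]
    excluded_phrases: list[KeywordMatch]

    def to_row(self) -> dict:
        return {
            "report_id": self.report_id,
            "crc_status": self.crc_status,
            "n_included": len(self.included_phrases),
            "n_excluded": len(self.excluded_phrases),
            "included_json": [m.to_dict() for m in self.included_phrases],
            "excluded_json": [m.to_dict() for m in self.excluded_phrases],
        }


RESULT_COLUMNS = ("report_id", "crc_status", "n_included", "n_excluded",
                  "included_json", "excluded_json")


def _read_terms(path: Path) -> tuple[str, ...]:
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped and not stripped.startswith("#"):
                terms.append(stripped.lower())
    return tuple(dict.fromkeys(terms))


def load_crc_lexicons(directory: str | Path) -> CrcLexicons:
    """Load the three term files from ``directory``.

    Expects ``tumour_terms.txt``, ``sites.txt`` and ``compound_terms.txt``,
    one term per line with ``#`` comments.
    """
    directory = Path(directory)
    paths = {}
    for name in LEXICON_FILES:
        p = directory / name
        if not p.exists():
            raise ConfigurationError(f"missing lexicon file: {p}")
        paths[name] = p
    return CrcLexicons(
        tumour_terms=_read_terms(paths["tumour_terms.txt"]),
        site_terms=_read_terms(paths["sites.txt"]),
        compound_terms=_read_terms(paths["compound_terms.txt"]),
    )


def default_crc_lexicons() -> CrcLexicons:
    """Lexicons packaged with the artifact."""
    base = resources.files("crctnm") / "lexicons"
    lists = {}
    for name in LEXICON_FILES:
        text = (base / name).read_text(encoding="utf-8")
        terms = [ln.strip().lower() for ln in text.splitlines()
                 if ln.strip() and not ln.strip().startswith("#")]
        lists[name] = tuple(dict.fromkeys(terms))
    return CrcLexicons(
        tumour_terms=lists["tumour_terms.txt"],
        site_terms=lists["sites.txt"],
        compound_terms=lists["compound_terms.txt"],
    )


def _term_regex(terms: Sequence[str]) -> Optional[re.Pattern]:
    if not terms:
        return None
    alts = sorted(terms, key=len, reverse=True)
    src = r"(?<!\w)(?:" + "|".join(re.escape(t) for t in alts) + r")(?!\w)"
    return re.compile(src, re.IGNORECASE)


def _find_spans(text: str, pattern: Optional[re.Pattern]) -> list[TextSpan]:
    if pattern is None:
        return []
    return [TextSpan(m.start(), m.end(), m.group(0))
            for m in pattern.finditer(text)]


def _same_sentence(text: str, a: int, b: int) -> bool:
    lo, hi = sorted((a, b))
    return _SENTENCE_END.search(text, lo, hi) is None


def _context(text: str, span: TextSpan, width: int) -> tuple[str, str]:
    return (text[max(0, span.start - width):span.start],
            text[span.end:span.end + width])


def find_keyword_matches(report: ClinicalReport, lexicons: CrcLexicons,
                         config: Optional[CrcConfig] = None
                         ) -> list[KeywordMatch]:
    """Locate tumour-keyword mentions, with site linkage but no modifiers yet.

    Compound terms are matched first and suppress overlapping plain tumour
    terms; a plain tumour term is linked when a site term starts within the
    linkage window in the same sentence.
    """
    cfg = config or CrcConfig()
    text = report.text
    compound_spans = _find_spans(text, _term_regex(lexicons.compound_terms))
    tumour_spans = [
        s for s in _find_spans(text, _term_regex(lexicons.tumour_terms))
        if not any(c.start <= s.start and s.end <= c.end for c in compound_spans)
    ]
    site_spans = _find_spans(text, _term_regex(lexicons.site_terms))

    matches: list[KeywordMatch] = []
    for span in sorted(compound_spans + tumour_spans, key=lambda s: s.start):
        left, right = _context(text, span, cfg.context_chars)
        if span in compound_spans:
            matches.append(KeywordMatch(
                tumour_span=span, site_span=None, linked=True,
                modifiers=frozenset(), included=True,
                left_context=left, right_context=right))
            continue
        best_site = None
        best_dist = None
        for site in site_spans:
            dist = abs(site.start - span.start)
            if dist > cfg.linkage_window:
                continue
            if not _same_sentence(text, span.start, site.start):
                continue
            if best_dist is None or dist < best_dist:
                best_site, best_dist = site, dist
        matches.append(KeywordMatch(
            tumour_span=span, site_span=best_site, linked=best_site is not None,
            modifiers=frozenset(), included=best_site is not None,
            left_context=left, right_context=right))
    return matches


def classify_crc(report: ClinicalReport,
                 lexicons: Optional[CrcLexicons] = None,
                 trigger_rules: Optional[Sequence[TriggerRule]] = None,
                 config: Optional[CrcConfig] = None) -> CRCResult:
    """Decide whether a report describes current primary colorectal cancer."""
    cfg = config or CrcConfig()
    lex = lexicons if lexicons is not None else default_crc_lexicons()
    rules = trigger_rules if trigger_rules is not None else default_trigger_rules()

    raw = find_keyword_matches(report, lex, cfg)
    assignments = scope_modifiers(report.text, [m.tumour_span for m in raw], rules)

    included: list[KeywordMatch] = []
    excluded: list[KeywordMatch] = []
    for match, assignment in zip(raw, assignments):
        mods = assignment.modifiers
        final = KeywordMatch(
            tumour_span=match.tumour_span,
            site_span=match.site_span,
            linked=match.linked,
            modifiers=mods,
            included=match.linked and not mods,
            left_context=match.left_context,
            right_context=match.right_context,
        )
        (included if final.included else excluded).append(final)
    return CRCResult(
        report_id=report.report_id,
        crc_status=bool(included),
        included_phrases=included,
        excluded_phrases=excluded,
    )


def detect_crc(corpus: Iterable[ClinicalReport],
               lexicons: Optional[CrcLexicons] = None,
               trigger_rules: Optional[Sequence[TriggerRule]] = None,
               config: Optional[CrcConfig] = None) -> list[CRCResult]:
    """Classify every report in a corpus, preserving order."""
    lex = lexicons if lexicons is not None else default_crc_lexicons()
    rules = trigger_rules if trigger_rules is not None else default_trigger_rules()
    return [classify_crc(r, lex, rules, config) for r in corpus]


def result_rows(results: Sequence[CRCResult]) -> list[dict]:
    return [r.to_row() for r in results]
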