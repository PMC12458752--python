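"""Explicit TNM staging extraction.

The extractor works in two stages: scan the text for candidate staging
tokens (category letter + value, with optional prefix letters), then
assemble nearby tokens into phrases. Look-alike strings (MRI sequence
names, vertebral levels) are rejected by context guards, and a phrase
that carries only a single category is kept only when a staging cue such
as "staged as" anchors it.

Categories and their value sets::

    Tpre  prefix letters from {a,c,m,p,r,y} attached to T (e.g. "yp")
    T     0, is, 1, 1a-1d, 2, 2a-2d, 3, 3a-3d, 4, 4a-4d, X
    N     0, 1, 1a-1c, 2, 2a-2c, 3, 3a-3c, X
    M     0, 1, 1a-1c, X
    V     0, 1, 2, X          R   0, 1, 2, X
    L     0, 1, X             Pn  0, 1, X
    G     1, 2, 3, 4, X
    SM    1, 2, 3             H   0-4 (Roman numerals normalized)

Per report, the maximum observed value of each category is reported
under a clinical severity ordering in which "X" (not assessable) ranks
below every informative value and is reported only when it is the sole
observation.
"""
from __future__ import annotations

import functools
import logging
import re
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import RunConfig, TnmConfig
from .corpus import ClinicalReport, TextSpan

logger = logging.getLogger(__name__)

CATEGORIES = ("Tpre", "T", "N", "M", "V", "R", "L", "Pn", "G", "SM", "H")

#: category match order: longest letter groups first so "Pn1" is not "N1"
_CAT_ORDER = ("Pn", "SM", "T", "N", "M", "V", "R", "L", "G", "H")

_SUBSTAGED = lambda top, subs: [f"{i}{s}" for i in top for s in [""] + list(subs)]

#: allowed canonical values per category (after normalization)
ALLOWED_VALUES: dict[str, tuple[str, ...]] = {
    "T": tuple(["0", "is"] + _SUBSTAGED("1234", "abcd") + ["X"]),
    "N": tuple(["0"] + _SUBSTAGED("123", "abc") + ["X"]),
    "M": tuple(["0"] + _SUBSTAGED("1", "abc") + ["X"]),
    "V": ("0", "1", "2", "X"),
    "R": ("0", "1", "2", "X"),
    "L": ("0", "1", "X"),
    "Pn": ("0", "1", "X"),
    "G": ("1", "2", "3", "4", "X"),
    "SM": ("1", "2", "3"),
    "H": ("0", "1", "2", "3", "4"),
}

#: severity ranking of informative (non-X) values, ascending
RANKING: dict[str, tuple[str, ...]] = {
    "T": tuple(["0", "is"] + _SUBSTAGED("1234", "abcd")),
    "N": tuple(["0"] + _SUBSTAGED("123", "abc")),
    "M": tuple(["0"] + _SUBSTAGED("1", "abc")),
    "V": ("0", "1", "2"),
    "R": ("0", "1", "2"),
    "L": ("0", "1"),
    "Pn": ("0", "1"),
    "G": ("1", "2", "3", "4"),
    "SM": ("1", "2", "3"),
    "H": ("0", "1", "2", "3", "4"),
}

_ROMAN = {"i": "1", "ii": "2", "iii": "3", "iv": "4"}

#: value-atom regex per category (case-insensitive); "o" stands in for a
#: mis-typed zero wherever 0 is an allowed value
_ATOM_SRC = {
    "T": r"(?:[1-4][a-d]?|0|is|[xo])",
    "N": r"(?:[1-3][a-c]?|0|[xo])",
    "M": r"(?:1[a-c]?|0|[xo])",
    "V": r"(?:[012]|[xo])",
    "R": r"(?:[012]|[xo])",
    "L": r"(?:[01]|[xo])",
    "Pn": r"(?:[01]|[xo])",
    "G": r"(?:[1-4]|x)",
    "SM": r"(?:[1-3])",
    "H": r"(?:iv|iii|ii|i|[0-4o])",
}

_SENTENCE_END = re.compile(r"[.;!?\n]")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CategoryValue:
    """One parsed staging token: category, optional prefix, normalized value."""

    category: str
    prefix: str
    value: str
    span: TextSpan


@dataclass(frozen=True)
class TNMPhrase:
    """A run of staging tokens treated as one staging statement."""

    span: TextSpan
    tokens: tuple[CategoryValue, ...]
    anchored_by_cue: bool


@dataclass
class TNMResult:
    """Per-report category maxima plus the supporting phrases."""

    report_id: str
    values: dict[str, Optional[str]]
    phrases: list[TNMPhrase] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {"report_id": self.report_id}
        for cat in CATEGORIES:
            key = "t_prefix" if cat == "Tpre" else cat.lower()
            val = self.values.get(cat)
            row[key] = "" if val is None else val
        row["n_phrases"] = len(self.phrases)
        return row


RESULT_COLUMNS = ("report_id", "t_prefix", "t", "n", "m", "v", "r", "l",
                  "pn", "g", "sm", "h", "n_phrases")
PHRASE_COLUMNS = ("report_id", "phrase_start", "phrase_end", "phrase_text",
                  "anchored_by_cue", "tokens_json")


# ---------------------------------------------------------------------------
# normalization


def normalize_value(raw: str, category: str) -> Optional[str]:
    """Normalize a raw value token; return None if outside the allowed set.

    Letter O in value position maps to 0, x folds to X, substage letters
    fold to lower case, and Haggitt Roman numerals map to Arabic digits.
    """
    val = raw.strip().lower()
    if val == "o":
        val = "0"
    elif val == "x":
        val = "X"
    elif category == "H" and val in _ROMAN:
        val = _ROMAN[val]
    if val not in ALLOWED_VALUES[category]:
        logger.debug("dropping value %r for category %s", raw, category)
        return None
    return val


# ---------------------------------------------------------------------------
# token scanning


@dataclass
class _RawToken:
    category: str
    prefix: str           # recorded prefix (already filtered by config)
    raw_prefix: str       # prefix letters as matched, "" if none
    values: list[tuple[str, int, int]]   # (raw, abs_start, abs_end)
    start: int
    end: int
    o_word: bool          # lone "No"-style token that needs a neighbour


class _Patterns:
    def __init__(self, cfg: TnmConfig) -> None:
        sep_parts = []
        for sep in cfg.multi_value_separators:
            if sep == "or":
                sep_parts.append(r"\s+or\s+")
            else:
                sep_parts.append(r"\s*" + re.escape(sep) + r"\s*")
        sep_src = "(?:" + "|".join(sep_parts) + ")" if sep_parts else r"(?!)"
        self.atom = {c: re.compile(_ATOM_SRC[c], re.IGNORECASE) for c in _CAT_ORDER}
        self.sep = re.compile(sep_src, re.IGNORECASE)
        self.plain = {}
        self.prefixed = {}
        for cat in _CAT_ORDER:
            core = (re.escape(cat) + r"[ ]?" +
                    f"(?P<vals>{_ATOM_SRC[cat]}(?:{sep_src}{_ATOM_SRC[cat]})*)")
            self.plain[cat] = re.compile(core, re.IGNORECASE)
            self.prefixed[cat] = re.compile(
                r"(?P<pre>[acmpry]{1,3})" + core, re.IGNORECASE)
        self.cue = re.compile(
            r"(?<!\w)(?:" + "|".join(
                re.escape(c) for c in sorted(cfg.cues, key=len, reverse=True)
            ) + r")(?!\w)", re.IGNORECASE) if cfg.cues else None
        self.guard_window = [re.compile(p, re.IGNORECASE)
                             for p in cfg.guard_window_patterns]
        self.guard_right = [re.compile(p, re.IGNORECASE)
                            for p in cfg.guard_right_patterns]
        self.guard_left = [re.compile(p, re.IGNORECASE)
                           for p in cfg.guard_left_patterns]
        self.guard_token = [re.compile(p, re.IGNORECASE)
                            for p in cfg.guard_token_patterns]


@functools.lru_cache(maxsize=8)
def _patterns(cfg: TnmConfig) -> _Patterns:
    return _Patterns(cfg)


def _split_values(vals: str, offset: int, pats: _Patterns, category: str
                  ) -> list[tuple[str, int, int]]:
    out = []
    pos = 0
    atom = pats.atom[category]
    while pos < len(vals):
        m = atom.match(vals, pos)
        if m is None:  # separator
            s = pats.sep.match(vals, pos)
            if s is None:
                break
            pos = s.end()
            continue
        out.append((m.group(0), offset + m.start(), offset + m.end()))
        pos = m.end()
    return out


def _match_token_at(text: str, pos: int, cfg: TnmConfig, pats: _Patterns
                    ) -> Optional[_RawToken]:
    """Try to match one staging token starting exactly at ``pos``."""
    for use_prefix in (False, True):
        table = pats.prefixed if use_prefix else pats.plain
        for cat in _CAT_ORDER:
            m = table[cat].match(text, pos)
            if m is None:
                continue
            raw_prefix = m.group("pre") if use_prefix else ""
            if use_prefix and raw_prefix.lower() not in cfg.prefix_whitelist:
                logger.debug("unknown prefix %r before %s at %d",
                             raw_prefix, cat, pos)
                continue
            vals_raw = _split_values(m.group("vals"), m.start("vals"), pats, cat)
            values = [(raw, s, e) for raw, s, e in vals_raw
                      if normalize_value(raw, cat) is not None]
            if not values:
                continue
            prefix = raw_prefix.lower() if cat in cfg.prefix_categories else ""
            o_word = (cat == "N" and not raw_prefix
                      and len(values) == 1 and values[0][0].lower() == "o")
            return _RawToken(category=cat, prefix=prefix, raw_prefix=raw_prefix,
                             values=values, start=pos, end=m.end(), o_word=o_word)
    return None


def _scan_tokens(text: str, cfg: TnmConfig) -> list[_RawToken]:
    """Scan text left-to-right for runs of adjacent staging tokens.

    A token may be chained to the next one with no separator ("T1N0M0");
    a run is accepted only if every chained continuation parses, which
    rejects strings such as "T2Weighted" or "T12" outright.
    """
    pats = _patterns(cfg)
    tokens: list[_RawToken] = []
    i, n = 0, len(text)
    while i < n:
        if not text[i].isalpha() or (i > 0 and text[i - 1].isalnum()):
            i += 1
            continue
        run: list[_RawToken] = []
        j = i
        ok = True
        while True:
            tok = _match_token_at(text, j, cfg, pats)
            if tok is None:
                ok = False
                break
            run.append(tok)
            j = tok.end
            if j < n and text[j].isalnum():
                if text[j].isdigit():
                    ok = False  # e.g. vertebral "T12"
                    break
                continue  # letters may only continue another token
            break
        if ok and run:
            tokens.extend(run)
            i = j
        else:
            i += 1
    return tokens


# ---------------------------------------------------------------------------
# false-positive guards


def _sentence_bounds(text: str, start: int, end: int) -> tuple[int, int]:
    lo = 0
    for m in _SENTENCE_END.finditer(text, 0, start):
        lo = m.end()
    m = _SENTENCE_END.search(text, end)
    hi = m.start() if m else len(text)
    return lo, hi


def guard_false_positive(candidate: TextSpan, report_text: str,
                         config: Optional[TnmConfig] = None) -> bool:
    """Return True when a staging look-alike should be rejected.

    The guard inspects the sentence-bounded context around the candidate
    for MRI-sequence and vertebral-level vocabulary, adjacent vertebral
    ranges ("T1-T12"), and look-alike token shapes ("HIV").
    """
    cfg = config or TnmConfig()
    pats = _patterns(cfg)
    lo, hi = _sentence_bounds(report_text, candidate.start, candidate.end)
    left = report_text[max(lo, candidate.start - cfg.guard_window):candidate.start]
    right = report_text[candidate.end:min(hi, candidate.end + cfg.guard_window)]
    token_text = candidate.text.strip()
    for pat in pats.guard_token:
        if pat.search(token_text):
            return True
    for pat in pats.guard_window:
        if pat.search(left) or pat.search(right):
            return True
    for pat in pats.guard_right:
        if pat.search(right):
            return True
    for pat in pats.guard_left:
        if pat.search(left):
            return True
    return False


def _filter_o_word(tokens: list[_RawToken], text: str) -> list[_RawToken]:
    """Keep "No"-as-N0 tokens only when adjacent to another staging token."""
    if not any(t.o_word for t in tokens):
        return tokens
    kept = {id(t): not t.o_word for t in tokens}
    changed = True
    while changed:
        changed = False
        for idx, tok in enumerate(tokens):
            if kept[id(tok)]:
                continue
            for nb in (tokens[idx - 1] if idx > 0 else None,
                       tokens[idx + 1] if idx + 1 < len(tokens) else None):
                if nb is None or not kept[id(nb)]:
                    continue
                gap = (text[nb.end:tok.start] if nb.end <= tok.start
                       else text[tok.end:nb.start])
                if len(gap) <= 2 and gap.strip() == "":
                    kept[id(tok)] = True
                    changed = True
                    break
    return [t for t in tokens if kept[id(t)]]


# ---------------------------------------------------------------------------
# phrase assembly


def _gap_ok(gap: str, cfg: TnmConfig) -> bool:
    if len(gap) > cfg.phrase_gap_chars:
        return False
    reduced = re.sub(r"\([^()\n]*\)", "", gap, count=1)
    if _SENTENCE_END.search(reduced):
        return False
    return re.fullmatch(r"[^\w]*", reduced) is not None


def _cue_before(text: str, start: int, cfg: TnmConfig, pats: _Patterns) -> bool:
    if pats.cue is None:
        return False
    lo = max(0, start - cfg.cue_window)
    left = text[lo:start]
    cut = None
    for m in _SENTENCE_END.finditer(left):
        cut = m.end()
    if cut is not None:
        left = left[cut:]
    return pats.cue.search(left) is not None


def _token_to_values(tok: _RawToken, text: str, offset: int = 0
                     ) -> list[CategoryValue]:
    out = []
    for k, (raw, s, e) in enumerate(tok.values):
        norm = normalize_value(raw, tok.category)
        if norm is None:  # pragma: no cover - filtered earlier
            continue
        span_start = tok.start if k == 0 else s
        span = TextSpan(offset + span_start, offset + e, text[span_start:e])
        out.append(CategoryValue(category=tok.category, prefix=tok.prefix,
                                 value=norm, span=span))
    return out


def parse_phrase(candidate_text: str, offset: int = 0,
                 config: Optional[TnmConfig] = None) -> list[CategoryValue]:
    """Parse a candidate staging phrase into category/prefix/value tokens.

    Unparseable residue is skipped silently; multi-valued tokens such as
    "T1/2/3" expand to one :class:`CategoryValue` per value. Span offsets
    are shifted by ``offset`` so they can refer back into a full report.
    """
    cfg = config or TnmConfig()
    tokens = _filter_o_word(_scan_tokens(candidate_text, cfg), candidate_text)
    values: list[CategoryValue] = []
    for tok in tokens:
        values.extend(_token_to_values(tok, candidate_text, offset))
    return values


def find_tnm_phrases(report: ClinicalReport,
                     config: Optional[TnmConfig] = None) -> list[TNMPhrase]:
    """Locate accepted TNM staging phrases in a report, in document order."""
    cfg = config or TnmConfig()
    pats = _patterns(cfg)
    text = report.text
    tokens = _scan_tokens(text, cfg)
    tokens = [
        t for t in tokens
        if not guard_false_positive(TextSpan(t.start, t.end, text[t.start:t.end]),
                                    text, cfg)
    ]
    tokens = _filter_o_word(tokens, text)

    groups: list[list[_RawToken]] = []
    for tok in tokens:
        if groups and _gap_ok(text[groups[-1][-1].end:tok.start], cfg):
            groups[-1].append(tok)
        else:
            groups.append([tok])

    phrases: list[TNMPhrase] = []
    for grp in groups:
        distinct = {t.category for t in grp}
        anchored = _cue_before(text, grp[0].start, cfg, pats)
        if len(distinct) < 2 and not anchored:
            continue
        cvs: list[CategoryValue] = []
        for tok in grp:
            cvs.extend(_token_to_values(tok, text))
        start, end = grp[0].start, grp[-1].end
        phrases.append(TNMPhrase(
            span=TextSpan(start, end, text[start:end]),
            tokens=tuple(cvs),
            anchored_by_cue=anchored,
        ))
    return phrases


# ---------------------------------------------------------------------------
# aggregation


def _rank(category: str, value: str) -> int:
    return RANKING[category].index(value)


def aggregate_max(phrases: Sequence[TNMPhrase], report_id: str) -> TNMResult:
    """Reduce phrases to the per-category maximum staging values.

    "X" is reported only when it is the only value observed for a
    category. The T-prefix reported is the one attached to the token that
    supplied the T maximum; ties resolve to the last occurrence in
    document order.
    """
    observed: dict[str, list[CategoryValue]] = {}
    for phrase in sorted(phrases, key=lambda p: p.span.start):
        for cv in phrase.tokens:
            observed.setdefault(cv.category, []).append(cv)

    values: dict[str, Optional[str]] = {cat: None for cat in CATEGORIES}
    for cat, cvs in observed.items():
        informative = [cv for cv in cvs if cv.value != "X"]
        if not informative:
            values[cat] = "X"
            continue
        best = max(enumerate(informative),
                   key=lambda pair: (_rank(cat, pair[1].value), pair[0]))[1]
        values[cat] = best.value
        if cat == "T":
            best_rank = _rank("T", best.value)
            winner = [cv for cv in informative
                      if _rank("T", cv.value) == best_rank][-1]
            values["Tpre"] = winner.prefix or None
    return TNMResult(report_id=report_id, values=values, phrases=list(phrases))


# ---------------------------------------------------------------------------
# corpus-level extraction


def _drop_historical_phrases(report: ClinicalReport, phrases: list[TNMPhrase],
                             trigger_rules) -> list[TNMPhrase]:
    from .context import scope_modifiers

    spans = [p.span for p in phrases]
    assignments = scope_modifiers(report.text, spans, trigger_rules)
    return [p for p, a in zip(phrases, assignments)
            if "historical" not in a.modifiers]


def _extract_one(report: ClinicalReport, cfg: TnmConfig,
                 drop_historical: bool, trigger_rules) -> TNMResult:
    phrases = find_tnm_phrases(report, cfg)
    if drop_historical and trigger_rules:
        phrases = _drop_historical_phrases(report, phrases, trigger_rules)
    return aggregate_max(phrases, report.report_id)


def _extract_batch(args) -> list[TNMResult]:
    reports, cfg, drop_historical, trigger_rules = args
    return [_extract_one(r, cfg, drop_historical, trigger_rules)
            for r in reports]


def extract_tnm(corpus: Iterable[ClinicalReport],
                config: Optional[TnmConfig] = None,
                workers: int = 1,
                drop_historical: bool = False) -> list[TNMResult]:
    """Run TNM extraction over a corpus, one result per report, in order.

    With ``drop_historical`` the packaged historical-modifier triggers are
    used to discard phrases inside a historical scope before aggregation.
    ``workers > 1`` partitions reports across processes; outputs are
    reassembled in input order and are identical to a serial run.
    """
    cfg = config or TnmConfig()
    reports = list(corpus)
    trigger_rules = None
    if drop_historical:
        from .context import default_trigger_rules

        trigger_rules = [r for r in default_trigger_rules()
                         if r.modifier == "historical"]
    if workers <= 1 or len(reports) < 2:
        return [_extract_one(r, cfg, drop_historical, trigger_rules)
                for r in reports]
    chunk = max(1, (len(reports) + workers - 1) // workers)
    batches = [(reports[k:k + chunk], cfg, drop_historical, trigger_rules)
               for k in range(0, len(reports), chunk)]
    results: list[TNMResult] = []
    with ProcessPoolExecutor(max_workers=workers) as pool:
        for part in pool.map(_extract_batch, batches):
            results.extend(part)
    return results


def result_rows(results: Sequence[TNMResult]) -> list[dict]:
    return [r.to_row() for r in results]


def phrase_rows(results: Sequence[TNMResult]) -> list[dict]:
    rows = []
    for res in results:
        for ph in res.phrases:
            rows.append({
                "report_id": res.report_id,
                "phrase_start": ph.span.start,
                "phrase_end": ph.span.end,
                "phrase_text": ph.span.text,
                "anchored_by_cue": ph.anchored_by_cue,
                "tokens_json": [
                    {"category": cv.category, "prefix": cv.prefix,
                     "value": cv.value, "start": cv.span.start,
                     "end": cv.span.end}
                    for cv in ph.tokens
                ],
            })
    return rows
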