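"""Trigger-based modifier scoping for concept mentions.

A trigger term opens a scope that runs in its direction (forward,
backward, or both) until the first sentence terminator or the
scope-length limit. Every concept span fully inside a scope receives
that trigger's modifier label, so adding trigger rules can only ever add
labels, never remove them.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus import TextSpan
from .errors import ConfigurationError

MODIFIERS = (
    "negated",
    "historical",
    "general",
    "nondefinite",
    "metastasis",
    "recurrence",
    "treatment_response",
)

DIRECTIONS = ("forward", "backward", "bidirectional")

#: scope terminators: sentence punctuation, newlines, and adversative "but"
_TERMINATOR = re.compile(r"[.;!?\n]|(?<!\w)but(?!\w)", re.IGNORECASE)


@dataclass(frozen=True)
class TriggerRule:
    """One trigger pattern with its modifier label and scope geometry."""

    pattern: str
    modifier: str
    direction: str
    max_scope_chars: int

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ConfigurationError("trigger pattern must be non-empty")
        if self.modifier not in MODIFIERS:
            raise ConfigurationError(f"unknown modifier {self.modifier!r}")
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.max_scope_chars <= 0:
            raise ConfigurationError("max_scope_chars must be positive")


@dataclass(frozen=True)
class ModifierAssignment:
    """Modifier labels attached to one concept span, with their evidence."""

    concept_span: TextSpan
    modifiers: frozenset[str]
    trigger_spans: tuple[TextSpan, ...]


def load_trigger_lexicon(path: str | Path) -> list[TriggerRule]:
    """Load trigger rules from a tab-separated lexicon file.

    Each non-comment line reads ``pattern<TAB>modifier<TAB>direction<TAB>scope``.
    Duplicate rules collapse to one; order of first occurrence is kept.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"trigger lexicon does not exist: {path}")
    with open(path, encoding="utf-8") as fh:
        return parse_trigger_lines(fh, source=str(path))


def parse_trigger_lines(lines: Iterable[str], source: str = "<memory>"
                        ) -> list[TriggerRule]:
    rules: list[TriggerRule] = []
    seen = set()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 4:
            raise ConfigurationError(
                f"{source}:{lineno}: expected 4 tab-separated fields, "
                f"got {len(parts)}"
            )
        pattern, modifier, direction, scope = (p.strip() for p in parts)
        try:
            scope_chars = int(scope)
        except ValueError as exc:
            raise ConfigurationError(
                f"{source}:{lineno}: scope must be an integer, got {scope!r}"
            ) from exc
        try:
            rule = TriggerRule(pattern=pattern, modifier=modifier,
                               direction=direction, max_scope_chars=scope_chars)
        except ConfigurationError as exc:
            raise ConfigurationError(f"{source}:{lineno}: {exc}") from exc
        key = (rule.pattern.lower(), rule.modifier, rule.direction,
               rule.max_scope_chars)
        if key in seen:
            continue
        seen.add(key)
        rules.append(rule)
    return rules


def default_trigger_rules() -> list[TriggerRule]:
    """Rules from the packaged trigger lexicon."""
    text = (resources.files("crctnm") / "lexicons" / "triggers.tsv").read_text(
        encoding="utf-8")
    return parse_trigger_lines(text.splitlines(), source="packaged triggers.tsv")


def _trigger_occurrences(text: str, rules: Sequence[TriggerRule]
                         ) -> list[tuple[TriggerRule, int, int]]:
    occurrences = []
    for rule in rules:
        pat = re.compile(r"(?<!\w)" + re.escape(rule.pattern) + r"(?!\w)",
                         re.IGNORECASE)
        for m in pat.finditer(text):
            occurrences.append((rule, m.start(), m.end()))
    occurrences.sort(key=lambda t: (t[1], t[2]))
    return occurrences


def scope_intervals(text: str, rule: TriggerRule, start: int, end: int
                    ) -> list[tuple[int, int]]:
    """Character interval(s) covered by one trigger occurrence's scope."""
    intervals = []
    if rule.direction in ("forward", "bidirectional"):
        hi = min(len(text), end + rule.max_scope_chars)
        m = _TERMINATOR.search(text, end)
        if m and m.start() < hi:
            hi = m.start()
        intervals.append((end, hi))
    if rule.direction in ("backward", "bidirectional"):
        lo = max(0, start - rule.max_scope_chars)
        last_term = None
        for m in _TERMINATOR.finditer(text, 0, start):
            last_term = m.end()
        if last_term is not None and last_term > lo:
            lo = last_term
        intervals.append((lo, start))
    return intervals


def scope_modifiers(text: str, concepts: Sequence[TextSpan],
                    rules: Sequence[TriggerRule]) -> list[ModifierAssignment]:
    """Assign modifier labels to each concept span, preserving input order."""
    occurrences = _trigger_occurrences(text, rules)

    assignments = []
    for concept in concepts:
        mods: set[str] = set()
        evidence: list[TextSpan] = []
        for rule, s, e in occurrences:
            for lo, hi in scope_intervals(text, rule, s, e):
                if lo <= concept.start and concept.end <= hi:
                    mods.add(rule.modifier)
                    evidence.append(TextSpan(s, e, text[s:e]))
                    break
        assignments.append(ModifierAssignment(
            concept_span=concept,
            modifiers=frozenset(mods),
            trigger_spans=tuple(evidence),
        ))
    return assignments
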