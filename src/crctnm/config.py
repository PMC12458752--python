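"""Tunable parameters for the extraction rules, loadable from YAML.

Every threshold, cue list, separator set and guard pattern that the
algorithms consult lives here, so behaviour can be adapted to another
centre's reporting style without touching code.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError

# Known prefix-letter combinations (subset of {a,c,m,p,r,y} strings).
DEFAULT_PREFIX_WHITELIST = ("c", "p", "y", "r", "a", "m", "yp", "mr", "ymr", "cp")

# Context patterns that mark a staging look-alike as a false positive.
# "window" patterns are searched in the sentence-bounded text around the
# candidate; "right"/"left" patterns are anchored at the candidate edge;
# "token" patterns are matched against the candidate text itself.
DEFAULT_GUARDS = {
    "window": (
        r"(?<!\w)weighted(?!\w)",
        r"(?<!\w)sequences?(?!\w)",
        r"(?<!\w)signal(?!\w)",
        r"(?<!\w)flair(?!\w)",
        r"(?<!\w)stir(?!\w)",
        r"(?<!\w)tse(?!\w)",
        r"(?<!\w)haste(?!\w)",
        r"(?<!\w)vertebra[el]?(?!\w)",
        r"(?<!\w)spine(?!\w)",
        r"(?<!\w)spinal(?!\w)",
        r"(?<!\w)thoracic(?!\w)",
        r"(?<!\w)lumbar(?!\w)",
        r"(?<!\w)sacral(?!\w)",
        r"(?<!\w)pedicle(?!\w)",
    ),
    "right": (
        # "T2-W", "T2 W TSE"
        r"^[\s\-–/]*w(?!\w)",
        # vertebral range continuation: "T1-T12", "T12/L1"
        r"^\s*[\-–/]\s*[tlcs]\d{1,2}(?!\w)",
    ),
    "left": (
        # vertebral range lead-in: the "L1" in "T12/L1"
        r"[tlcs]\d{1,2}\s*[\-–/]\s*$",
    ),
    "token": (
        r"^hiv$",
    ),
}


@dataclass(frozen=True)
class TnmConfig:
    """Parameters of the TNM phrase finder and parser."""

    #: cues that license a single-category phrase ("Staged as T2")
    cues: tuple[str, ...] = ("staged as", "staging", "stage", "tnm")
    #: how far (chars) before a phrase a cue may sit, within the sentence
    cue_window: int = 30
    #: max chars of non-word filler (plus one bracketed comment) between tokens
    phrase_gap_chars: int = 40
    #: separators allowed between multiple values of one category letter
    multi_value_separators: tuple[str, ...] = ("/", ",", "or", "-")
    #: accepted prefix-letter combinations
    prefix_whitelist: tuple[str, ...] = DEFAULT_PREFIX_WHITELIST
    #: categories for which a prefix is recorded in the output
    prefix_categories: tuple[str, ...] = ("T",)
    #: chars of sentence-bounded context inspected by false-positive guards
    guard_window: int = 30
    guard_window_patterns: tuple[str, ...] = DEFAULT_GUARDS["window"]
    guard_right_patterns: tuple[str, ...] = DEFAULT_GUARDS["right"]
    guard_left_patterns: tuple[str, ...] = DEFAULT_GUARDS["left"]
    guard_token_patterns: tuple[str, ...] = DEFAULT_GUARDS["token"]


@dataclass(frozen=True)
class CrcConfig:
    """Parameters of the colorectal-cancer report detector."""

    #: max chars between tumour-term start and site-term start (same sentence)
    linkage_window: int = 120
    #: context snippet width (chars each side) attached to keyword matches
    context_chars: int = 60


@dataclass(frozen=True)
class ContextConfig:
    """Parameters of the modifier-scoping engine."""

    default_forward_scope: int = 120
    default_backward_scope: int = 60


@dataclass(frozen=True)
class RunConfig:
    """Bundle of all rule parameters plus optional lexicon overrides."""

    tnm: TnmConfig = field(default_factory=TnmConfig)
    crc: CrcConfig = field(default_factory=CrcConfig)
    context: ContextConfig = field(default_factory=ContextConfig)
    #: optional path to a trigger lexicon replacing the packaged default
    trigger_lexicon: Optional[str] = None
    #: optional directory with tumour/site/compound term files
    crc_lexicon_dir: Optional[str] = None


def _merge_dataclass(cls, defaults, overrides: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - names
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} option(s): {sorted(unknown)}"
        )
    values = dataclasses.asdict(defaults)
    for key, val in overrides.items():
        if isinstance(values[key], tuple) and isinstance(val, list):
            val = tuple(val)
        values[key] = val
    return cls(**values)


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Build a :class:`RunConfig` from defaults plus a YAML override file."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file does not exist: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    known = {"tnm", "crc", "context", "lexicons"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
    tnm = _merge_dataclass(TnmConfig, TnmConfig(), raw.get("tnm", {}) or {})
    crc = _merge_dataclass(CrcConfig, CrcConfig(), raw.get("crc", {}) or {})
    ctx = _merge_dataclass(ContextConfig, ContextConfig(), raw.get("context", {}) or {})
    lex = raw.get("lexicons", {}) or {}
    return RunConfig(
        tnm=tnm,
        crc=crc,
        context=ctx,
        trigger_lexicon=lex.get("triggers"),
        crc_lexicon_dir=lex.get("crc_dir"),
    )
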