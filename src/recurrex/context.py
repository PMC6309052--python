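"""Negation and contextual-cue filtering of concept mentions.

Two mechanisms, applied in a fixed order:

1. **Sentence-level cues** — a sentence containing a negation cue
   ("no", "rule out", "deny", "unremarkable", ...) or an uncertainty cue
   ("risk", "concern", "worry", "evaluation", ...) is dropped wholesale,
   mentions and all.  This deliberately trades recall for precision:
   differential-diagnosis and patient-anxiety sentences mention recurrence
   without asserting it.
2. **NegEx** — within surviving sentences, a concept mention is flagged
   negated when it falls inside the scope of a negation trigger phrase:
   six tokens after a pre-trigger ("no evidence of ...") or six tokens
   before a post-trigger ("... was ruled out"), with the scope cut at
   terminators such as "but".  Negated mentions are removed.

The final retained set is order-independent between the two stages; the
fixed order exists only so per-stage drop counts are reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from recurrex.corpus import Sentence
from recurrex.tagger import ConceptMention, set_negated

NEGEX_WINDOW = 6  # tokens of scope on either side of a trigger

# Stems every default lexicon must carry.
SEED_NEGATION_CUES = ("no", "rule out", "deny", "unremarkable")
SEED_UNCERTAINTY_CUES = ("risk", "concern", "worry", "evaluation")

# Short stems (< this many chars in the final word) must match a whole token;
# longer stems match as token prefixes so "concern" hits "concerned".
MIN_PREFIX_STEM = 4


@dataclass(frozen=True)
class TriggerLexicon:
    negex_pre: tuple[str, ...] = ()
    negex_post: tuple[str, ...] = ()
    scope_terminators: tuple[str, ...] = ()
    sentence_negation_cues: tuple[str, ...] = ()
    sentence_uncertainty_cues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for group in (self.negex_pre, self.negex_post, self.scope_terminators,
                      self.sentence_negation_cues, self.sentence_uncertainty_cues):
            for phrase in group:
                if phrase != phrase.lower():
                    raise ValueError(f"trigger phrase must be lowercase: {phrase!r}")

    @property
    def all_cues(self) -> tuple[str, ...]:
        return self.sentence_negation_cues + self.sentence_uncertainty_cues


def default_triggers() -> TriggerLexicon:
    """The built-in trigger lexicon (always contains the eight seed stems)."""
    from recurrex.resources import triggers_path

    return load_triggers(triggers_path())


def load_triggers(path: str | Path) -> TriggerLexicon:
    """Load a YAML trigger lexicon with the five standard keys."""
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    def grab(key: str) -> tuple[str, ...]:
        vals = data.get(key) or []
        return tuple(str(v).lower() for v in vals)
    return TriggerLexicon(
        negex_pre=grab("negex_pre"),
        negex_post=grab("negex_post"),
        scope_terminators=grab("scope_terminators"),
        sentence_negation_cues=grab("sentence_negation_cues"),
        sentence_uncertainty_cues=grab("sentence_uncertainty_cues"),
    )


def _token_offsets(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"\S+", text)]


def _phrase_positions(tokens: list[str], phrase: str) -> list[tuple[int, int]]:
    """Token (start, end) half-open positions of exact phrase occurrences."""
    words = phrase.split()
    k = len(words)
    if k == 0 or k > len(tokens):
        return []
    return [(i, i + k) for i in range(len(tokens) - k + 1) if tokens[i:i + k] == words]


def _cue_matches_at(tokens: list[str], i: int, cue: str) -> bool:
    """Does the cue phrase match at token i (last word may be a prefix)?"""
    words = cue.split()
    if i + len(words) > len(tokens):
        return False
    for j, w in enumerate(words[:-1]):
        if tokens[i + j] != w:
            return False
    last = words[-1]
    tok = tokens[i + len(words) - 1]
    if len(last) >= MIN_PREFIX_STEM:
        return tok.startswith(last)
    return tok == last


def has_contextual_cue(sentence: Sentence, triggers: TriggerLexicon) -> tuple[bool, str | None]:
    """Return (True, cue) if any configured cue stem occurs at a word boundary.

    Stems of four or more characters match as token prefixes ("concern"
    matches "concerned"); shorter stems ("no") must match a whole token so
    that "now" and "normal" do not fire.
    """
    tokens = sentence.text.split()
    for i in range(len(tokens)):
        for cue in triggers.all_cues:
            if _cue_matches_at(tokens, i, cue):
                return True, cue
    return False, None


def detect_negated(
    sentence: Sentence,
    mentions: Iterable[ConceptMention],
    triggers: TriggerLexicon,
) -> list[ConceptMention]:
    """Set NegEx negation flags on the mentions of one sentence.

    A pre-trigger negates mentions whose first token starts within
    ``NEGEX_WINDOW`` tokens after it; a post-trigger negates mentions ending
    within ``NEGEX_WINDOW`` tokens before it.  A scope terminator between
    trigger and mention cuts the scope.
    """
    tokens = sentence.text.split()
    offsets = _token_offsets(sentence.text)

    def token_index(char_pos: int) -> int:
        for idx, (s, e) in enumerate(offsets):
            if s <= char_pos < e:
                return idx
        return max(0, len(offsets) - 1)

    terminator_starts: set[int] = set()
    for term in triggers.scope_terminators:
        for s, _e in _phrase_positions(tokens, term):
            terminator_starts.add(s)

    pre_scopes: list[tuple[int, int]] = []  # half-open token ranges
    for trig in triggers.negex_pre:
        for _s, e in _phrase_positions(tokens, trig):
            stop = min(len(tokens), e + NEGEX_WINDOW)
            for t in sorted(terminator_starts):
                if e <= t < stop:
                    stop = t
                    break
            pre_scopes.append((e, stop))
    post_scopes: list[tuple[int, int]] = []
    for trig in triggers.negex_post:
        for s, _e in _phrase_positions(tokens, trig):
            start = max(0, s - NEGEX_WINDOW)
            for t in sorted(terminator_starts, reverse=True):
                if start <= t < s:
                    start = t + 1
                    break
            post_scopes.append((start, s))

    out = []
    for m in mentions:
        first_tok = token_index(m.start)
        last_tok = token_index(max(m.start, m.end - 1))
        negated = any(s <= first_tok < e for s, e in pre_scopes) or \
            any(s <= last_tok < e for s, e in post_scopes)
        out.append(set_negated(m, negated))
    return out


@dataclass
class FilterStats:
    """Per-stage mention drop counts for the pipeline log."""

    mentions_in: int = 0
    dropped_by_cue: int = 0
    dropped_by_negex: int = 0
    sentences_dropped: int = 0
    cue_hits: dict[str, int] = field(default_factory=dict)

    @property
    def mentions_retained(self) -> int:
        return self.mentions_in - self.dropped_by_cue - self.dropped_by_negex


def apply_context_filters(
    tagged: Mapping[tuple[str, str, int], tuple[Sentence, list[ConceptMention]]],
    triggers: TriggerLexicon,
) -> tuple[dict[tuple[str, str, int], tuple[Sentence, list[ConceptMention]]], FilterStats]:
    """Drop cue-bearing sentences, then NegEx-negated mentions.

    Returns the retained (sentence, mentions) mapping — a subset of the
    input mentions, never new ones — plus drop statistics.
    """
    stats = FilterStats()
    retained: dict[tuple[str, str, int], tuple[Sentence, list[ConceptMention]]] = {}
    for key, (sentence, mentions) in tagged.items():
        stats.mentions_in += len(mentions)
        hit, cue = has_contextual_cue(sentence, triggers)
        if hit:
            stats.sentences_dropped += 1
            stats.dropped_by_cue += len(mentions)
            stats.cue_hits[cue] = stats.cue_hits.get(cue, 0) + 1  # type: ignore[index]
            retained[key] = (sentence, [])
            continue
        flagged = detect_negated(sentence, mentions, triggers)
        kept = [m for m in flagged if not m.negated]
        stats.dropped_by_negex += len(flagged) - len(kept)
        retained[key] = (sentence, kept)
    return retained, stats
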