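"""Dictionary concept tagger: map normalized sentences to UMLS CUIs.

A lexicon row maps one lowercase surface form to one CUI with a relevance
score.  Tagging matches every surface form as a whole-word contiguous token
run; overlapping matches from *different* entries are all kept (one phrase
may legitimately denote several concepts), but when two CUIs claim the exact
same character span only the highest-scoring CUI survives, ties broken by
the lexicographically smallest CUI.  Within a sentence, repeated CUIs
collapse to their first occurrence.

The tagger satisfies the ``Tagger`` protocol so a MetaMap or cTAKES adapter
can be plugged in behind the same contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Protocol

from recurrex.corpus import PatientRecord, Sentence, preprocess_record

_CUI_RE = re.compile(r"^C\d+$")


class LexiconError(ValueError):
    """Raised for malformed or empty lexicon files."""


@dataclass(frozen=True)
class LexiconEntry:
    """One concept with its surface forms and a MetaMap-like relevance score."""

    cui: str
    preferred_name: str
    surface_forms: tuple[str, ...]
    score: float = 1.0


@dataclass(frozen=True)
class ConceptMention:
    """A CUI grounded to a character span of one normalized sentence."""

    cui: str
    patient_id: str
    note_id: str
    sentence_index: int
    start: int
    end: int
    matched_text: str
    score: float = 1.0
    negated: bool = False


class Tagger(Protocol):
    def __call__(self, sentence: Sentence) -> list[ConceptMention]: ...


def load_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Load a TSV lexicon (cui, preferred_name, surface_form, score).

    Rows are grouped by CUI; duplicate (cui, surface_form) rows collapse to
    the maximum score.  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise LexiconError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            cui, name, form = parts[0].strip(), parts[1].strip(), parts[2].strip().lower()
            score = float(parts[3]) if len(parts) > 3 and parts[3].strip() else 1.0
            if not _CUI_RE.match(cui):
                raise LexiconError(f"{path}:{lineno}: malformed CUI {cui!r}")
            if not form:
                raise LexiconError(f"{path}:{lineno}: empty surface form")
            rows.append((cui, name, form, score))
    if not rows:
        raise LexiconError(f"{path}: lexicon is empty")
    return build_lexicon(rows)


def build_lexicon(rows: Iterable[tuple[str, str, str, float]]) -> list[LexiconEntry]:
    """Group (cui, name, form, score) rows into entries, max score per form."""
    by_cui: dict[str, dict[str, float]] = {}
    names: dict[str, str] = {}
    for cui, name, form, score in rows:
        forms = by_cui.setdefault(cui, {})
        forms[form] = max(forms.get(form, float("-inf")), score)
        names.setdefault(cui, name)
    return [
        LexiconEntry(cui=cui, preferred_name=names[cui],
                     surface_forms=tuple(sorted(forms)), score=max(forms.values()))
        for cui, forms in sorted(by_cui.items())
    ]


def _index_forms(lexicon: Iterable[LexiconEntry]) -> dict[tuple[str, ...], list[tuple[str, float]]]:
    """Map tokenized surface form -> [(cui, score), ...], deterministic order."""
    index: dict[tuple[str, ...], list[tuple[str, float]]] = {}
    seen: dict[tuple[str, ...], set[str]] = {}
    for entry in sorted(lexicon, key=lambda e: e.cui):
        for form in entry.surface_forms:
            toks = tuple(form.split())
            if not toks:
                continue
            if entry.cui in seen.setdefault(toks, set()):
                continue
            seen[toks].add(entry.cui)
            index.setdefault(toks, []).append((entry.cui, entry.score))
    return index


def tag_sentence(sentence: Sentence, lexicon: Iterable[LexiconEntry]) -> list[ConceptMention]:
    """Tag every whole-word occurrence of every lexicon surface form.

    Same-span collisions keep the max-score CUI (ties: smallest CUI);
    duplicate CUIs within the sentence collapse to the first occurrence.
    Output is ordered by (start, end, cui).
    """
    tokens = sentence.text.split()
    if not tokens:
        return []
    # character offset of each token in the normalized sentence
    offsets = []
    pos = 0
    for tok in tokens:
        start = sentence.text.index(tok, pos)
        offsets.append((start, start + len(tok)))
        pos = start + len(tok)
    index = _index_forms(lexicon)
    max_len = max(len(toks) for toks in index) if index else 0
    # span -> (score, cui): per-span disambiguation by max score then min CUI
    by_span: dict[tuple[int, int], tuple[float, str]] = {}
    for i in range(len(tokens)):
        for length in range(1, min(max_len, len(tokens) - i) + 1):
            window = tuple(tokens[i:i + length])
            for cui, score in index.get(window, ()):
                span = (offsets[i][0], offsets[i + length - 1][1])
                incumbent = by_span.get(span)
                if (incumbent is None or score > incumbent[0]
                        or (score == incumbent[0] and cui < incumbent[1])):
                    by_span[span] = (score, cui)
    mentions = []
    seen_cuis: set[str] = set()
    for (start, end), (score, cui) in sorted(by_span.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[1][1])):
        if cui in seen_cuis:
            continue
        seen_cuis.add(cui)
        mentions.append(ConceptMention(
            cui=cui, patient_id=sentence.patient_id, note_id=sentence.note_id,
            sentence_index=sentence.index, start=start, end=end,
            matched_text=sentence.text[start:end], score=score,
        ))
    return mentions


def tag_corpus(
    records: Iterable[PatientRecord],
    lexicon: Iterable[LexiconEntry],
) -> dict[tuple[str, str, int], tuple[Sentence, list[ConceptMention]]]:
    """Preprocess and tag every sentence of every record.

    Returns a mapping keyed by (patient_id, note_id, sentence_index) so
    downstream filters can address sentences deterministically.
    """
    lexicon = list(lexicon)
    out: dict[tuple[str, str, int], tuple[Sentence, list[ConceptMention]]] = {}
    for record in records:
        for sent in preprocess_record(record):
            out[(sent.patient_id, sent.note_id, sent.index)] = (sent, tag_sentence(sent, lexicon))
    return out


def set_negated(mention: ConceptMention, flag: bool) -> ConceptMention:
    return replace(mention, negated=flag)
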