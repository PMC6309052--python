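"""The positive concept set: the CUI whitelist gating all narrative features.

The whitelist is built once from a development corpus of recurrence-positive
partial sentences: the fragments are tagged with the concept dictionary, the
tagged CUIs are pooled, and function-word concepts ("the", "then", "to")
are removed via a declarative exclusion file — the reproducible analogue of
the original manual filtering step.  The shipped default is a 48-CUI
synthetic reconstruction (see :mod:`recurrex.resources`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from recurrex.corpus import Sentence, normalize_text
from recurrex.tagger import _CUI_RE, ConceptMention, LexiconEntry, tag_sentence


class PositiveSetError(ValueError):
    """Raised for empty or malformed positive-set inputs."""


@dataclass(frozen=True)
class PositiveConceptSet:
    """A non-empty whitelist of well-formed CUIs with preferred names."""

    cuis: frozenset[str]
    preferred_names: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.cuis:
            raise PositiveSetError("positive concept set must be non-empty")
        bad = [c for c in self.cuis if not _CUI_RE.match(c)]
        if bad:
            raise PositiveSetError(f"malformed CUIs in positive set: {bad!r}")

    def __contains__(self, cui: str) -> bool:
        return cui in self.cuis

    def __len__(self) -> int:
        return len(self.cuis)


def load_positive_set(path: str | Path) -> PositiveConceptSet:
    """Load a positive concept set from TSV (cui, preferred_name).

    Duplicate CUIs collapse; an empty file or malformed CUI is an error.
    """
    path = Path(path)
    names: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            cui = parts[0].strip()
            if not _CUI_RE.match(cui):
                raise PositiveSetError(f"{path}:{lineno}: malformed CUI {cui!r}")
            names.setdefault(cui, parts[1].strip() if len(parts) > 1 else "")
    if not names:
        raise PositiveSetError(f"{path}: no CUIs found")
    return PositiveConceptSet(cuis=frozenset(names), preferred_names=names,
                              provenance=str(path))


def load_partial_sentences(path: str | Path) -> list[str]:
    """Load development partial sentences, one normalized fragment per line."""
    path = Path(path)
    out = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(normalize_text(line))
    if not out:
        raise PositiveSetError(f"{path}: no partial sentences found")
    return out


def load_exclusion(path: str | Path) -> frozenset[str]:
    """Load the exclusion CUI list (first TSV column)."""
    path = Path(path)
    cuis = set()
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                cuis.add(line.split("\t")[0].strip())
    return frozenset(cuis)


def derive_positive_set(
    partials: Sequence[str],
    lexicon: Iterable[LexiconEntry],
    exclusion: frozenset[str] | set[str] = frozenset(),
    provenance: str = "derived from partial sentences",
) -> PositiveConceptSet:
    """Re-derive the positive set: tag all partials, pool CUIs, subtract exclusions.

    Deterministic and invariant to the order of the partial sentences.
    Raises :class:`PositiveSetError` if nothing survives.
    """
    lexicon = list(lexicon)
    names = {e.cui: e.preferred_name for e in lexicon}
    cuis: set[str] = set()
    for i, fragment in enumerate(partials):
        sent = Sentence(patient_id="", note_id="partials", index=i,
                        text=normalize_text(fragment))
        cuis.update(m.cui for m in tag_sentence(sent, lexicon))
    cuis -= set(exclusion)
    if not cuis:
        raise PositiveSetError("derivation produced an empty positive set")
    return PositiveConceptSet(
        cuis=frozenset(cuis),
        preferred_names={c: names.get(c, "") for c in sorted(cuis)},
        provenance=provenance,
    )


def filter_to_positive(
    mentions: Iterable[ConceptMention],
    positive: PositiveConceptSet,
) -> list[ConceptMention]:
    """Keep exactly the mentions whose CUI is whitelisted, order preserved."""
    return [m for m in mentions if m.cui in positive]


def default_positive_set() -> PositiveConceptSet:
    from recurrex.resources import positive_set_path

    return load_positive_set(positive_set_path())
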