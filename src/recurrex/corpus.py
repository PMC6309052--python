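"""Patient/note data model, corpus I/O, deduplication, and text normalization.

A corpus is a JSON-lines file, one patient per line::

    {"patient_id": str, "primary_diagnosis_date": "YYYY-MM-DD",
     "label": 0 | 1 | null,
     "notes": [{"note_id": str, "date": "YYYY-MM-DD", "text": str}, ...],
     "pathology_report_dates": ["YYYY-MM-DD", ...]}

Notes are free clinical text.  Downstream stages operate on normalized
sentences: lowercase, alphanumeric tokens separated by single spaces.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence


class CorpusSchemaError(ValueError):
    """Raised when a corpus line violates the JSONL schema."""


@dataclass(frozen=True)
class ProgressNote:
    """One free-text clinical note for one encounter."""

    note_id: str
    patient_id: str
    date: _dt.date
    text: str


@dataclass
class PatientRecord:
    """All data the pipeline uses for one patient."""

    patient_id: str
    primary_diagnosis_date: _dt.date
    notes: list[ProgressNote] = field(default_factory=list)
    pathology_report_dates: list[_dt.date] = field(default_factory=list)
    label: int | None = None


@dataclass(frozen=True)
class Sentence:
    """A normalized sentence addressed by (patient_id, note_id, index)."""

    patient_id: str
    note_id: str
    index: int
    text: str


_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")

# Abbreviations whose trailing period never ends a sentence.  Matched
# case-insensitively before splitting; extend via preprocess_note(abbreviations=...).
DEFAULT_ABBREVIATIONS = (
    "dr", "pt", "mr", "mrs", "ms", "st", "vs", "approx", "appt",
    "h/o", "s/p", "y.o", "yo", "wk", "mo", "yr",
)

_SENTINEL = "\x00"


def _parse_date(value: object, *, line: int, field_name: str) -> _dt.date:
    if not isinstance(value, str) or not _DATE_RE.match(value):
        raise CorpusSchemaError(
            f"line {line}: field {field_name!r} is not an ISO-8601 date: {value!r}"
        )
    try:
        return _dt.date.fromisoformat(value)
    except ValueError as exc:
        raise CorpusSchemaError(f"line {line}: unparseable date in {field_name!r}: {value!r}") from exc


def _require(obj: dict, key: str, line: int) -> object:
    if key not in obj:
        raise CorpusSchemaError(f"line {line}: missing required field {key!r}")
    return obj[key]


def read_corpus(path: str | Path) -> list[PatientRecord]:
    """Read a JSONL corpus into one :class:`PatientRecord` per patient.

    Raises :class:`CorpusSchemaError` naming the offending line for any
    missing field, duplicate patient_id, or unparseable date.
    """
    records: list[PatientRecord] = []
    seen: set[str] = set()
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise CorpusSchemaError(f"line {lineno}: invalid JSON: {exc}") from exc
            pid = _require(obj, "patient_id", lineno)
            if not isinstance(pid, str) or not pid:
                raise CorpusSchemaError(f"line {lineno}: patient_id must be a non-empty string")
            if pid in seen:
                raise CorpusSchemaError(f"line {lineno}: duplicate patient_id {pid!r}")
            seen.add(pid)
            dx = _parse_date(_require(obj, "primary_diagnosis_date", lineno),
                             line=lineno, field_name="primary_diagnosis_date")
            label = obj.get("label")
            if label not in (0, 1, None):
                raise CorpusSchemaError(f"line {lineno}: label must be 0, 1, or null, got {label!r}")
            notes = []
            for note in _require(obj, "notes", lineno):
                nid = _require(note, "note_id", lineno)
                text = _require(note, "text", lineno)
                if not isinstance(text, str) or not text:
                    raise CorpusSchemaError(f"line {lineno}: note {nid!r} has empty text")
                notes.append(ProgressNote(
                    note_id=str(nid), patient_id=pid,
                    date=_parse_date(_require(note, "date", lineno), line=lineno, field_name="notes.date"),
                    text=text,
                ))
            path_dates = [
                _parse_date(d, line=lineno, field_name="pathology_report_dates")
                for d in _require(obj, "pathology_report_dates", lineno)
            ]
            records.append(PatientRecord(
                patient_id=pid, primary_diagnosis_date=dx, notes=notes,
                pathology_report_dates=path_dates, label=label,
            ))
    return records


def write_corpus(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records as canonical JSONL (sorted keys, ISO dates)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "patient_id": rec.patient_id,
                "primary_diagnosis_date": rec.primary_diagnosis_date.isoformat(),
                "label": rec.label,
                "notes": [
                    {"note_id": n.note_id, "date": n.date.isoformat(), "text": n.text}
                    for n in rec.notes
                ],
                "pathology_report_dates": [d.isoformat() for d in rec.pathology_report_dates],
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def normalize_text(text: str) -> str:
    """Lowercase, replace non-alphanumerics with spaces, collapse whitespace."""
    lowered = text.lower()
    cleaned = re.sub(r"[^a-z0-9]+", " ", lowered)
    return cleaned.strip()


def deduplicate_notes(record: PatientRecord) -> PatientRecord:
    """Drop later-dated exact copies of a note, keeping the earliest.

    Two notes are duplicates when their normalized texts are identical.
    Non-duplicate notes keep their original relative order.
    """
    best: dict[str, int] = {}  # normalized text -> index of retained note
    for i, note in enumerate(record.notes):
        key = normalize_text(note.text)
        if key not in best:
            best[key] = i
        elif note.date < record.notes[best[key]].date:
            best[key] = i
    keep = sorted(best.values())
    return replace_notes(record, [record.notes[i] for i in keep])


def replace_notes(record: PatientRecord, notes: list[ProgressNote]) -> PatientRecord:
    return PatientRecord(
        patient_id=record.patient_id,
        primary_diagnosis_date=record.primary_diagnosis_date,
        notes=notes,
        pathology_report_dates=list(record.pathology_report_dates),
        label=record.label,
    )


def _protect_abbreviations(text: str, abbreviations: Sequence[str]) -> str:
    for abbr in abbreviations:
        # "dr." -> "dr<SENTINEL>" so the period is not a boundary candidate
        pattern = re.compile(r"(?i)\b" + re.escape(abbr) + r"\.")
        text = pattern.sub(lambda m: m.group(0)[:-1] + _SENTINEL, text)
    return text


_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[A-Z0-9]|\s*$)")


def split_sentences(text: str, abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS) -> list[str]:
    """Rule-based sentence splitting on terminal punctuation.

    A run of ``.!?`` ends a sentence when followed by whitespace plus an
    uppercase letter or digit, or by end of text.  Abbreviation periods are
    masked first so "Dr. Smith" stays in one sentence.
    """
    protected = _protect_abbreviations(text, abbreviations)
    pieces, last = [], 0
    for m in _BOUNDARY_RE.finditer(protected):
        pieces.append(protected[last:m.end()])
        last = m.end()
    if last < len(protected):
        pieces.append(protected[last:])
    return [p.replace(_SENTINEL, ".").strip() for p in pieces if p.strip()]


def preprocess_note(
    text: str,
    *,
    patient_id: str = "",
    note_id: str = "",
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> list[Sentence]:
    """Split a note into normalized :class:`Sentence` objects.

    Output sentences are lowercase with non-alphanumerics replaced by single
    spaces; empty sentences are dropped and indices are consecutive from 0.
    """
    sentences = []
    idx = 0
    for chunk in split_sentences(text, abbreviations):
        norm = normalize_text(chunk)
        if not norm:
            continue
        sentences.append(Sentence(patient_id=patient_id, note_id=note_id, index=idx, text=norm))
        idx += 1
    return sentences


def preprocess_record(record: PatientRecord) -> list[Sentence]:
    """Deduplicate a patient's notes and return all normalized sentences."""
    deduped = deduplicate_notes(record)
    out: list[Sentence] = []
    for note in deduped.notes:
        out.extend(preprocess_note(note.text, patient_id=record.patient_id, note_id=note.note_id))
    return out
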