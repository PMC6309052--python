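"""Synthetic labeled patient corpora with the statistical structure the
pipeline assumes.

Each patient gets a handful of notes built from filler clinical sentences.
Recurrence-positive patients additionally receive sentences drawn from a
pool of positive recurrence templates (unless a noise draw suppresses all of
them); any patient may receive negated/uncertain recurrence sentences that
the contextual filter is expected to drop; and, at a configurable confound
rate, recurrence-negative patients receive contralateral/distant-recurrence
phrasing that *survives* filtering — the known failure mode of a local-
recurrence classifier built on narrative concepts.

Per-patient pathology-report counts (reports >= 120 days after diagnosis)
are drawn from class-conditional negative binomials with means 4.55
(recurrent) and 0.92 (non-recurrent) — the published class-conditional
averages — and dispersion 1.0 so the variance can exceed the mean.

Every inserted template is recorded in a trace so tests can check which
sentences ought to survive the contextual filter.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from recurrex.corpus import PatientRecord, ProgressNote, write_corpus
from recurrex.resources import (
    confound_templates_path,
    filler_templates_path,
    negative_templates_path,
    positive_templates_path,
)

LATERALITIES = ("left", "right", "ipsilateral")
YEARS = tuple(str(y) for y in range(1995, 2016))


def _load_pool(path: Path) -> tuple[str, ...]:
    lines = [
        ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty template pool: {path}")
    return tuple(lines)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    Defaults mirror the double-annotated cohort: 701 patients at 27.53%
    recurrence prevalence, with class-conditional mean qualifying pathology
    counts of 4.55 (recurrent) and 0.92 (non-recurrent).
    """

    n_patients: int = 701
    prevalence: float = 0.2753
    mean_notes_per_patient: float = 3.0
    mean_fillers_per_note: float = 4.0
    mean_positive_templates: float = 1.5  # per positive patient (min 1 unless noise)
    droppable_template_rate: float = 0.7  # prob a patient gets >=1 filter-droppable sentence
    confound_rate: float = 0.0            # prob a negative patient gets confound phrasing
    positive_noise_rate: float = 0.0      # prob a positive patient gets NO positive template
    pathology_mean_recurrent: float = 4.55
    pathology_mean_nonrecurrent: float = 0.92
    pathology_dispersion: float = 1.0
    seed: int = 0
    positive_pool: tuple[str, ...] = ()
    negative_pool: tuple[str, ...] = ()
    confound_pool: tuple[str, ...] = ()
    filler_pool: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for p in (self.prevalence, self.droppable_template_rate,
                  self.confound_rate, self.positive_noise_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if min(self.pathology_mean_recurrent, self.pathology_mean_nonrecurrent) < 0:
            raise ValueError("pathology means must be >= 0")
        if not self.positive_pool:
            self.positive_pool = _load_pool(positive_templates_path())
        if not self.negative_pool:
            self.negative_pool = _load_pool(negative_templates_path())
        if not self.confound_pool:
            self.confound_pool = _load_pool(confound_templates_path())
        if not self.filler_pool:
            self.filler_pool = _load_pool(filler_templates_path())


@dataclass
class GeneratedCorpus:
    records: list[PatientRecord]
    traces: dict[str, list[dict]]
    config: GeneratorConfig

    def write(self, corpus_path: str | Path, trace_path: str | Path | None = None) -> None:
        write_corpus(self.records, corpus_path)
        if trace_path is not None:
            with Path(trace_path).open("w", encoding="utf-8") as fh:
                for pid in sorted(self.traces):
                    for entry in self.traces[pid]:
                        fh.write(json.dumps({"patient_id": pid, **entry}, sort_keys=True) + "\n")


def _neg_binom(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial draw parameterized by mean and dispersion (size)."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _fill_slots(template: str, rng: np.random.Generator) -> str:
    out = template
    while "{lat}" in out:
        out = out.replace("{lat}", str(rng.choice(LATERALITIES)), 1)
    while "{year}" in out:
        out = out.replace("{year}", str(rng.choice(YEARS)), 1)
    return out


def _pick(rng: np.random.Generator, pool: Sequence[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def generate_patient(
    label: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    patient_id: str = "P0",
) -> tuple[PatientRecord, list[dict]]:
    """Assemble one synthetic patient and the trace of inserted templates.

    The trace records, per inserted template sentence: its note, sentence
    index, kind, and whether its concept mentions should survive the
    contextual filter (positive and confound templates yes, droppable
    negative templates no).
    """
    dx = _dt.date(2008, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 1461)))
    n_notes = 1 + int(rng.poisson(config.mean_notes_per_patient))

    # decide special sentences to insert across the patient's notes
    inserts: list[tuple[str, str, bool]] = []  # (kind, text, should_survive)
    if label == 1 and rng.random() >= config.positive_noise_rate:
        k = max(1, int(rng.poisson(config.mean_positive_templates)))
        for _ in range(k):
            inserts.append(("positive", _fill_slots(_pick(rng, config.positive_pool), rng), True))
    if rng.random() < config.droppable_template_rate:
        for _ in range(1 + int(rng.poisson(0.5))):
            inserts.append(("droppable", _fill_slots(_pick(rng, config.negative_pool), rng), False))
    confounded = label == 0 and rng.random() < config.confound_rate
    if confounded:
        for _ in range(1 + int(rng.poisson(0.5))):
            inserts.append(("confound", _fill_slots(_pick(rng, config.confound_pool), rng), True))

    notes: list[list[tuple[str, str | None, bool]]] = []  # (text, kind, survive)
    for i in range(n_notes):
        n_fill = 1 + int(rng.poisson(config.mean_fillers_per_note))
        # a unique header sentence keeps sibling notes from ever being
        # byte-identical, so deduplication never silently removes one
        header = (f"clinic visit number {i + 1} for routine follow up", None, False)
        notes.append([header] + [(_pick(rng, config.filler_pool), None, False)
                                 for _ in range(n_fill)])
    for kind, text, survive in inserts:
        note_i = int(rng.integers(n_notes))
        pos = int(rng.integers(len(notes[note_i]) + 1))
        notes[note_i].insert(pos, (text, kind, survive))

    trace: list[dict] = []
    note_objs = []
    note_dates = sorted(
        dx + _dt.timedelta(days=int(d)) for d in rng.integers(30, 1800, size=n_notes)
    )
    for i, sents in enumerate(notes):
        note_id = f"{patient_id}-N{i}"
        text = ". ".join(s[0][0].upper() + s[0][1:] for s in sents) + "."
        note_objs.append(ProgressNote(note_id=note_id, patient_id=patient_id,
                                      date=note_dates[i], text=text))
        for j, (sent, kind, survive) in enumerate(sents):
            if kind is not None:
                trace.append({"note_id": note_id, "sentence_index": j, "kind": kind,
                              "text": sent, "should_survive": survive})

    # A contralateral/distant event generates its own biopsies and surgeries,
    # so confounded negatives draw counts from the recurrent-class distribution.
    mean = (config.pathology_mean_recurrent if label == 1 or confounded
            else config.pathology_mean_nonrecurrent)
    n_qual = _neg_binom(rng, mean, config.pathology_dispersion)
    path_dates = [
        dx + _dt.timedelta(days=120 + int(d)) for d in rng.integers(0, 901, size=n_qual)
    ]
    if rng.random() < 0.7:  # an early diagnostic biopsy that never qualifies
        path_dates.append(dx + _dt.timedelta(days=int(rng.integers(0, 60))))
    record = PatientRecord(
        patient_id=patient_id, primary_diagnosis_date=dx, notes=note_objs,
        pathology_report_dates=sorted(path_dates), label=label,
    )
    return record, trace


def generate_corpus(config: GeneratorConfig) -> GeneratedCorpus:
    """Generate ``n_patients`` records with labels drawn at the prevalence.

    Deterministic: the same config (including seed) yields byte-identical
    corpora when written with :func:`recurrex.corpus.write_corpus`.
    """
    rng = np.random.default_rng(config.seed)
    labels = (rng.random(config.n_patients) < config.prevalence).astype(int)
    records, traces = [], {}
    width = len(str(max(config.n_patients - 1, 1)))
    for i, label in enumerate(labels):
        pid = f"P{i:0{width}d}"
        rec, trace = generate_patient(int(label), config, rng, patient_id=pid)
        records.append(rec)
        traces[pid] = trace
    return GeneratedCorpus(records=records, traces=traces, config=config)
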