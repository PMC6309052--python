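"""Patient feature construction.

The proposed feature space has two parts:

* **Power-set concept features** — for each sentence, every non-empty subset
  of size <= 3 of the whitelisted CUIs co-occurring in that sentence becomes
  one binary presence feature.  Single CUIs are often ambiguous ("recurrent"
  alone does not imply a local recurrence); pairs and triples restore the
  within-sentence context that makes them informative.
* **Pathology-report count** — the number of pathology reports dated at
  least 120 days after the primary diagnosis.  Recurrence workups generate
  biopsies and surgeries, hence late pathology reports.

Three baseline spaces mirror the comparison models: singleton concepts
without the positive-set gate (``full_concepts``), the gated power-set
features without the count (``filtered_concepts``), and per-patient TF-IDF
bag of words over raw note text (``bag_of_words``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from recurrex.context import TriggerLexicon, apply_context_filters
from recurrex.corpus import PatientRecord
from recurrex.positive import PositiveConceptSet, filter_to_positive
from recurrex.tagger import ConceptMention, LexiconEntry, tag_corpus

MODES = ("proposed", "filtered_concepts", "full_concepts", "bag_of_words")
POWERSET_MAX_SIZE = 3
DEFAULT_CUI_CAP = 10
DEFAULT_MIN_DAYS = 120


@dataclass(frozen=True, order=True)
class FeatureKey:
    """One column of the feature matrix.

    kind ``cui_set``: members is a sorted tuple of 1-3 CUIs.
    kind ``token``: members is a single vocabulary token.
    kind ``pathology_count``: members is empty; at most one per space.
    """

    kind: str
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "cui_set":
            if not (1 <= len(self.members) <= POWERSET_MAX_SIZE):
                raise ValueError(f"cui_set size must be 1..{POWERSET_MAX_SIZE}")
            if tuple(sorted(set(self.members))) != self.members:
                raise ValueError("cui_set members must be sorted and unique")
        elif self.kind == "pathology_count":
            if self.members:
                raise ValueError("pathology_count key carries no members")
        elif self.kind != "token":
            raise ValueError(f"unknown feature kind {self.kind!r}")


PATHOLOGY_KEY = FeatureKey(kind="pathology_count")


@dataclass
class FeatureMatrix:
    """Sparse patient x feature matrix with aligned ids, keys, and labels."""

    patient_ids: list[str]
    keys: list[FeatureKey]
    X: sp.csr_matrix
    labels: np.ndarray | None = None
    mode: str = "proposed"

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.patient_ids), len(self.keys)):
            raise ValueError("matrix shape does not match ids/keys")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate feature keys")

    def column(self, key: FeatureKey) -> np.ndarray:
        return np.asarray(self.X[:, self.keys.index(key)].todense()).ravel()

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            patient_ids=[self.patient_ids[i] for i in idx],
            keys=list(self.keys),
            X=self.X[idx],
            labels=None if self.labels is None else self.labels[idx],
            mode=self.mode,
        )


def sentence_powerset(cuis: Iterable[str], max_size: int = POWERSET_MAX_SIZE) -> set[FeatureKey]:
    """All non-empty subsets of size <= max_size of the sentence's CUIs."""
    unique = sorted(set(cuis))
    out: set[FeatureKey] = set()
    for size in range(1, min(max_size, len(unique)) + 1):
        for combo in combinations(unique, size):
            out.add(FeatureKey(kind="cui_set", members=combo))
    return out


def count_pathology_reports(record: PatientRecord, min_days: int = DEFAULT_MIN_DAYS) -> int:
    """Pathology reports dated >= min_days after the primary diagnosis.

    The boundary is inclusive: a report exactly min_days later qualifies.
    Pre-diagnosis reports simply do not qualify.
    """
    dx = record.primary_diagnosis_date
    return sum(1 for d in record.pathology_report_dates if (d - dx).days >= min_days)


def build_patient_vector(
    record: PatientRecord,
    mentions_by_sentence: Mapping[tuple[str, str, int], Sequence[ConceptMention]],
    include_pathology: bool = True,
    *,
    min_days: int = DEFAULT_MIN_DAYS,
    cui_cap: int = DEFAULT_CUI_CAP,
) -> dict[FeatureKey, float]:
    """Union of per-sentence power sets (binary), plus the pathology count.

    ``mentions_by_sentence`` holds the patient's retained (context- and
    positive-filtered) mentions keyed by (patient_id, note_id, index).
    Sentences with more than ``cui_cap`` distinct CUIs are truncated to the
    lexicographically first ``cui_cap`` before expansion, with a warning.
    """
    vec: dict[FeatureKey, float] = {}
    for key in sorted(mentions_by_sentence):
        if key[0] != record.patient_id:
            continue
        cuis = sorted({m.cui for m in mentions_by_sentence[key]})
        if len(cuis) > cui_cap:
            warnings.warn(
                f"sentence {key} has {len(cuis)} positive CUIs; capping at {cui_cap}",
                stacklevel=2,
            )
            cuis = cuis[:cui_cap]
        for fkey in sentence_powerset(cuis):
            vec[fkey] = 1.0
    if include_pathology:
        vec[PATHOLOGY_KEY] = float(count_pathology_reports(record, min_days))
    return vec


def _matrix_from_vectors(
    records: Sequence[PatientRecord],
    vectors: Sequence[Mapping[FeatureKey, float]],
    mode: str,
) -> FeatureMatrix:
    keys = sorted({k for vec in vectors for k in vec})
    col = {k: j for j, k in enumerate(keys)}
    rows, cols, vals = [], [], []
    for i, vec in enumerate(vectors):
        for k, v in vec.items():
            rows.append(i)
            cols.append(col[k])
            vals.append(v)
    X = sp.csr_matrix((vals, (rows, cols)), shape=(len(records), len(keys)), dtype=np.float64)
    labels = _labels_or_none(records)
    return FeatureMatrix(
        patient_ids=[r.patient_id for r in records], keys=keys, X=X,
        labels=labels, mode=mode,
    )


def _labels_or_none(records: Sequence[PatientRecord]) -> np.ndarray | None:
    if any(r.label is None for r in records):
        return None
    return np.array([r.label for r in records], dtype=np.int64)


def save_matrix(matrix: FeatureMatrix, outdir) -> None:
    """Serialize a matrix: keys TSV + MatrixMarket triplets + id/label files."""
    from pathlib import Path

    import scipy.io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "keys.tsv").open("w", encoding="utf-8") as fh:
        for i, k in enumerate(matrix.keys):
            fh.write(f"{i}\t{k.kind}\t{'|'.join(k.members)}\n")
    sio.mmwrite(str(outdir / "values.mtx"), matrix.X)
    (outdir / "patients.txt").write_text(
        "".join(p + "\n" for p in matrix.patient_ids), encoding="utf-8")
    (outdir / "mode.txt").write_text(matrix.mode + "\n", encoding="utf-8")
    if matrix.labels is not None:
        (outdir / "labels.txt").write_text(
            "".join(f"{v}\n" for v in matrix.labels), encoding="utf-8")


def load_matrix(outdir) -> FeatureMatrix:
    from pathlib import Path

    import scipy.io as sio

    outdir = Path(outdir)
    keys = []
    for line in (outdir / "keys.tsv").read_text(encoding="utf-8").splitlines():
        _i, kind, members = line.split("\t")
        keys.append(FeatureKey(kind=kind, members=tuple(members.split("|")) if members else ()))
    X = sp.csr_matrix(sio.mmread(str(outdir / "values.mtx")))
    patient_ids = (outdir / "patients.txt").read_text(encoding="utf-8").split()
    mode = (outdir / "mode.txt").read_text(encoding="utf-8").strip()
    labels = None
    labels_file = outdir / "labels.txt"
    if labels_file.exists():
        labels = np.array([int(v) for v in labels_file.read_text().split()], dtype=np.int64)
    return FeatureMatrix(patient_ids=patient_ids, keys=keys, X=X, labels=labels, mode=mode)


def assemble_matrix(
    records: Sequence[PatientRecord],
    mode: str,
    *,
    lexicon: Iterable[LexiconEntry] | None = None,
    triggers: TriggerLexicon | None = None,
    positive: PositiveConceptSet | None = None,
    min_days: int = DEFAULT_MIN_DAYS,
    cui_cap: int = DEFAULT_CUI_CAP,
    tagged: Mapping[tuple[str, str, int], tuple] | None = None,
) -> FeatureMatrix:
    """Build the feature matrix for one mode.

    ``proposed``          gated power sets + pathology count.
    ``filtered_concepts`` gated power sets only.
    ``full_concepts``     singleton keys for every context-filtered CUI
                          (no positive gate, no power sets).
    ``bag_of_words``      per-patient TF-IDF over raw note text.

    Pass ``tagged`` (the output of :func:`recurrex.tagger.tag_corpus`) to
    reuse one tagging pass across modes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")

    if mode == "bag_of_words":
        docs = [" ".join(n.text for n in r.notes) for r in records]
        vectorizer = TfidfVectorizer(lowercase=True)
        X = vectorizer.fit_transform(docs).tocsr().astype(np.float64)
        vocab = vectorizer.get_feature_names_out()
        order = np.argsort(vocab)
        keys = [FeatureKey(kind="token", members=(str(vocab[j]),)) for j in order]
        return FeatureMatrix(
            patient_ids=[r.patient_id for r in records], keys=keys,
            X=X[:, order], labels=_labels_or_none(records), mode=mode,
        )

    if tagged is None:
        if lexicon is None:
            raise ValueError(f"mode {mode!r} requires a lexicon (or pre-tagged corpus)")
        tagged = tag_corpus(records, lexicon)
    if triggers is None:
        from recurrex.context import default_triggers

        triggers = default_triggers()
    retained, _stats = apply_context_filters(tagged, triggers)

    by_patient: dict[str, dict[tuple[str, str, int], list[ConceptMention]]] = {}
    for key, (_s, ms) in retained.items():
        by_patient.setdefault(key[0], {})[key] = ms

    if mode == "full_concepts":
        vectors = []
        for r in records:
            cuis = {m.cui for ms in by_patient.get(r.patient_id, {}).values() for m in ms}
            vectors.append({FeatureKey(kind="cui_set", members=(c,)): 1.0 for c in cuis})
        return _matrix_from_vectors(records, vectors, mode)

    if positive is None:
        from recurrex.positive import default_positive_set

        positive = default_positive_set()
    include_pathology = mode == "proposed"
    vectors = []
    for r in records:
        gated = {
            key: filter_to_positive(ms, positive)
            for key, ms in by_patient.get(r.patient_id, {}).items()
        }
        vectors.append(build_patient_vector(r, gated, include_pathology,
                                            min_days=min_days, cui_cap=cui_cap))
    return _matrix_from_vectors(records, vectors, mode)
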