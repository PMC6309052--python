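import datetime as dt

import pytest

from recurrex.context import default_triggers
from recurrex.corpus import PatientRecord, ProgressNote
from recurrex.positive import default_positive_set
from recurrex.resources import lexicon_path
from recurrex.tagger import build_lexicon, load_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon(lexicon_path())


@pytest.fixture(scope="session")
def triggers():
    return default_triggers()


@pytest.fixture(scope="session")
def positive_set():
    return default_positive_set()


@pytest.fixture
def three_cui_lexicon():
    """Minimal lexicon reproducing the worked three-concept example."""
    return build_lexicon([
        ("C1997028", "History of malignant neoplasm of breast",
         "history of recurrent breast cancer", 1.0),
        ("C1387407", "Personal history of primary malignant neoplasm of breast",
         "history of recurrent breast", 1.0),
        ("C2945760", "Recurrent", "recurrent", 1.0),
    ])


def make_record(patient_id="P1", dx="2010-01-01", notes=(), path_dates=(), label=None):
    dxd = dt.date.fromisoformat(dx)
    note_objs = [
        ProgressNote(note_id=f"{patient_id}-N{i}", patient_id=patient_id,
                     date=dt.date.fromisoformat(d), text=t)
        for i, (d, t) in enumerate(notes)
    ]
    return PatientRecord(
        patient_id=patient_id, primary_diagnosis_date=dxd, notes=note_objs,
        pathology_report_dates=[dt.date.fromisoformat(d) for d in path_dates],
        label=label,
    )


@pytest.fixture
def record_factory():
    return make_record
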