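import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recurrex.features import (
    PATHOLOGY_KEY,
    FeatureKey,
    assemble_matrix,
    build_patient_vector,
    count_pathology_reports,
    load_matrix,
    save_matrix,
    sentence_powerset,
)
from recurrex.tagger import tag_corpus

from .conftest import make_record

THREE = ("C1387407", "C1997028", "C2945760")


def brute_force_powerset(cuis, max_size=3):
    unique = sorted(set(cuis))
    out = set()
    for size in range(1, len(unique) + 1):
        if size > max_size:
            continue
        for combo in itertools.combinations(unique, size):
            out.add(FeatureKey(kind="cui_set", members=combo))
    return out


def test_feature_key_invariants():
    with pytest.raises(ValueError):
        FeatureKey(kind="cui_set", members=())
    with pytest.raises(ValueError):
        FeatureKey(kind="cui_set", members=("C2", "C1"))  # unsorted
    with pytest.raises(ValueError):
        FeatureKey(kind="cui_set", members=("C1", "C1"))  # duplicate
    with pytest.raises(ValueError):
        FeatureKey(kind="cui_set", members=("C1", "C2", "C3", "C4"))  # size > 3
    with pytest.raises(ValueError):
        FeatureKey(kind="pathology_count", members=("C1",))
    with pytest.raises(ValueError):
        FeatureKey(kind="nope")


def test_powerset_singleton():
    assert sentence_powerset(["C2945760"]) == {
        FeatureKey(kind="cui_set", members=("C2945760",))}


def test_powerset_three_cuis_seven_keys():
    out = sentence_powerset(THREE)
    expected = {
        FeatureKey("cui_set", ("C1997028",)),
        FeatureKey("cui_set", ("C1387407",)),
        FeatureKey("cui_set", ("C2945760",)),
        FeatureKey("cui_set", ("C1387407", "C1997028")),
        FeatureKey("cui_set", ("C1997028", "C2945760")),
        FeatureKey("cui_set", ("C1387407", "C2945760")),
        FeatureKey("cui_set", ("C1387407", "C1997028", "C2945760")),
    }
    assert out == expected


def test_powerset_four_cuis_fourteen_keys():
    out = sentence_powerset([f"C{i}" for i in range(1, 5)])
    assert len(out) == 4 + 6 + 4


@settings(derandomize=True, max_examples=60)
@given(st.sets(st.integers(min_value=0, max_value=20), min_size=1, max_size=8))
def test_powerset_matches_brute_force(ids):
    cuis = [f"C{i:03d}" for i in ids]
    assert sentence_powerset(cuis) == brute_force_powerset(cuis)


def test_powerset_duplicates_collapse():
    assert sentence_powerset(["C1", "C1", "C2"]) == sentence_powerset(["C2", "C1"])


def test_count_pathology_reports():
    rec = make_record(path_dates=["2010-01-31", "2010-05-01", "2011-06-01"])
    # 2010-05-01 is day 120 exactly: inclusive boundary
    assert count_pathology_reports(rec) == 2
    assert count_pathology_reports(make_record()) == 0
    pre = make_record(dx="2010-06-01", path_dates=["2010-01-01"])
    assert count_pathology_reports(pre) == 0


def _mentions_for(record, lexicon):
    return {k: ms for k, (_s, ms) in tag_corpus([record], lexicon).items()}


def test_build_patient_vector_composition(three_cui_lexicon):
    rec = make_record(notes=[("2010-06-01", "History of recurrent breast cancer.")],
                      path_dates=["2011-01-01", "2011-02-01"])
    vec = build_patient_vector(rec, _mentions_for(rec, three_cui_lexicon))
    keys = set(vec)
    assert PATHOLOGY_KEY in keys
    assert keys - {PATHOLOGY_KEY} == sentence_powerset(THREE)
    assert vec[PATHOLOGY_KEY] == 2.0
    assert all(v == 1.0 for k, v in vec.items() if k != PATHOLOGY_KEY)


def test_build_patient_vector_no_mentions(three_cui_lexicon):
    rec = make_record(notes=[("2010-06-01", "Doing well today.")])
    vec = build_patient_vector(rec, _mentions_for(rec, three_cui_lexicon))
    assert vec == {PATHOLOGY_KEY: 0.0}


def test_build_patient_vector_binary_across_sentences(three_cui_lexicon):
    rec = make_record(notes=[("2010-06-01", "Recurrent disease. Still recurrent disease.")])
    vec = build_patient_vector(rec, _mentions_for(rec, three_cui_lexicon))
    key = FeatureKey("cui_set", ("C2945760",))
    assert vec[key] == 1.0


def test_build_patient_vector_cap_warns(three_cui_lexicon):
    mentions = _mentions_for(
        make_record(notes=[("2010-06-01", "Recurrent disease.")]), three_cui_lexicon)
    rec = make_record()
    with pytest.warns(UserWarning, match="capping"):
        vec = build_patient_vector(rec, {("P1", "N", 0): [
            m for key in mentions for m in mentions[key]]}, cui_cap=0)
    assert vec == {PATHOLOGY_KEY: 0.0}


def corpus_for_modes(lexicon):
    recs = [
        make_record("P1", notes=[("2010-06-01", "History of recurrent breast cancer.")],
                    path_dates=["2011-01-01"], label=1),
        make_record("P2", notes=[("2010-06-01", "Routine follow up with no concerns.")],
                    label=0),
    ]
    return recs


def test_proposed_vs_filtered_differ_by_pathology(lexicon, triggers, positive_set):
    recs = corpus_for_modes(lexicon)
    kw = dict(lexicon=lexicon, triggers=triggers, positive=positive_set)
    proposed = assemble_matrix(recs, "proposed", **kw)
    filtered = assemble_matrix(recs, "filtered_concepts", **kw)
    assert set(proposed.keys) == set(filtered.keys) | {PATHOLOGY_KEY}
    assert len(proposed.keys) == len(filtered.keys) + 1


def test_full_concepts_singletons_only(lexicon, triggers, positive_set):
    recs = corpus_for_modes(lexicon)
    m = assemble_matrix(recs, "full_concepts", lexicon=lexicon, triggers=triggers,
                        positive=positive_set)
    assert all(k.kind == "cui_set" and len(k.members) == 1 for k in m.keys)


def test_binary_cells_in_concept_modes(lexicon, triggers, positive_set):
    recs = corpus_for_modes(lexicon)
    kw = dict(lexicon=lexicon, triggers=triggers, positive=positive_set)
    for mode in ("proposed", "filtered_concepts", "full_concepts"):
        m = assemble_matrix(recs, mode, **kw)
        dense = np.asarray(m.X.todense())
        for j, key in enumerate(m.keys):
            if key.kind == "cui_set":
                assert set(np.unique(dense[:, j])) <= {0.0, 1.0}


def test_bag_of_words_tfidf():
    recs = [
        make_record("P1", notes=[("2010-06-01", "hello hello")], label=0),
        make_record("P2", notes=[("2010-06-01", "hello")], label=1),
    ]
    m = assemble_matrix(recs, "bag_of_words")
    assert [k.kind for k in m.keys] == ["token"]
    # a term present in every document still gets weight 1 after L2 row norm
    dense = np.asarray(m.X.todense())
    assert np.allclose(dense, [[1.0], [1.0]])


def test_bag_of_words_columns_sorted():
    recs = [make_record("P1", notes=[("2010-06-01", "zebra alpha mid")], label=0),
            make_record("P2", notes=[("2010-06-01", "alpha")], label=1)]
    m = assemble_matrix(recs, "bag_of_words")
    tokens = [k.members[0] for k in m.keys]
    assert tokens == sorted(tokens)


def test_unknown_mode_errors(lexicon):
    with pytest.raises(ValueError, match="unknown mode"):
        assemble_matrix([], "nope", lexicon=lexicon)


def test_matrix_save_load_roundtrip(tmp_path, lexicon, triggers, positive_set):
    recs = corpus_for_modes(lexicon)
    m = assemble_matrix(recs, "proposed", lexicon=lexicon, triggers=triggers,
                        positive=positive_set)
    save_matrix(m, tmp_path / "feat")
    back = load_matrix(tmp_path / "feat")
    assert back.patient_ids == m.patient_ids
    assert back.keys == m.keys
    assert back.mode == m.mode
    assert (back.X != m.X).nnz == 0
    assert np.array_equal(back.labels, m.labels)


def test_labels_none_when_any_missing(lexicon, triggers, positive_set):
    recs = corpus_for_modes(lexicon)
    recs[0].label = None
    m = assemble_matrix(recs, "proposed", lexicon=lexicon, triggers=triggers,
                        positive=positive_set)
    assert m.labels is None
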