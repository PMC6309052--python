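import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import chi2_contingency

from recurrex.features import PATHOLOGY_KEY, FeatureKey, FeatureMatrix
from recurrex.model import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    KERNEL_ORDER,
    ModelSpec,
    RecurrenceModel,
    align_matrix,
    chi2_binary,
    chi_square_select,
    grid_search_svm,
    predict,
    train,
)


def make_matrix(X, labels=None, with_pathology=False, patient_prefix="P"):
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    keys = [FeatureKey("cui_set", (f"C{j:04d}",)) for j in range(d)]
    if with_pathology:
        keys[-1] = PATHOLOGY_KEY
    return FeatureMatrix(
        patient_ids=[f"{patient_prefix}{i}" for i in range(n)],
        keys=keys, X=sp.csr_matrix(X),
        labels=None if labels is None else np.asarray(labels, dtype=int),
    )


def test_model_spec_validation():
    with pytest.raises(ValueError, match="kernel"):
        ModelSpec(kernel="cubic")
    with pytest.raises(ValueError, match="positive"):
        ModelSpec(C=0)
    with pytest.raises(ValueError, match="positive"):
        ModelSpec(gamma=-1)


def test_default_grids_match_published_ranges():
    assert DEFAULT_C_GRID == tuple(range(1, 100, 10))
    assert DEFAULT_GAMMA_GRID[0] == 0.0001
    assert DEFAULT_GAMMA_GRID[-1] == 0.0091
    assert len(DEFAULT_GAMMA_GRID) == 10
    assert KERNEL_ORDER == ("rbf", "linear", "poly", "sigmoid")


def test_chi2_binary_against_scipy():
    rng = np.random.default_rng(42)
    for _ in range(100):
        x = rng.integers(0, 2, size=20)
        y = rng.integers(0, 2, size=20)
        table = np.array([
            [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
            [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
        ])
        ours = chi2_binary(x, y)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            assert ours == 0.0
            continue
        ref = chi2_contingency(table, correction=False)[0]
        assert ours == pytest.approx(ref, abs=1e-10)


def test_chi2_degenerate_tables():
    assert chi2_binary(np.ones(10), np.array([0] * 5 + [1] * 5)) == 0.0
    assert chi2_binary(np.zeros(10), np.array([0] * 5 + [1] * 5)) == 0.0


def test_select_keeps_top_half_and_pathology():
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 10)
    X = rng.integers(0, 2, size=(20, 11)).astype(float)
    X[:, 0] = y  # perfectly label-aligned feature must rank first
    m = make_matrix(X, y, with_pathology=True)
    sel = chi_square_select(m, fraction=0.5)
    assert len(sel.retained) == 5 + 1  # ceil(0.5*10) candidates + pathology
    assert sel.retained[0] == FeatureKey("cui_set", ("C0000",))
    assert sel.retained[-1] == PATHOLOGY_KEY
    assert PATHOLOGY_KEY not in sel.scores


def test_select_fraction_one_keeps_all():
    y = np.array([0, 1] * 5)
    m = make_matrix(np.eye(10), y)
    sel = chi_square_select(m, fraction=1.0)
    assert len(sel.retained) == 10


def test_select_tie_break_is_key_order():
    y = np.array([0, 1] * 5)
    X = np.zeros((10, 4))  # all-zero features: all scores tie at 0
    m = make_matrix(X, y)
    sel = chi_square_select(m, fraction=0.5)
    assert sel.retained == m.keys[:2]


def test_select_errors():
    m = make_matrix(np.eye(4), [1, 1, 1, 1])
    with pytest.raises(ValueError, match="both classes"):
        chi_square_select(m)
    m2 = make_matrix(np.eye(4), [0, 1, 0, 1])
    with pytest.raises(ValueError, match="fraction"):
        chi_square_select(m2, fraction=0.0)
    with pytest.raises(ValueError, match="fraction"):
        chi_square_select(m2, fraction=1.5)


def test_align_matrix_missing_keys_zero():
    m = make_matrix(np.ones((2, 2)), [0, 1])
    extra = FeatureKey("cui_set", ("C9999",))
    aligned = align_matrix(m, [m.keys[1], extra])
    dense = np.asarray(aligned.X.todense())
    assert dense.shape == (2, 2)
    assert np.all(dense[:, 0] == 1)
    assert np.all(dense[:, 1] == 0)


def separable_matrix(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 0.1, size=(n, 3))
    X[:, 0] += 3 * y
    return make_matrix(X, y), y


def test_grid_search_separable_and_deterministic():
    m, y = separable_matrix()
    kw = dict(kernels=("rbf", "linear"), C_grid=(1, 11), gamma_grid=(0.001, 0.01), seed=3)
    best1, table1 = grid_search_svm(m, **kw)
    best2, _ = grid_search_svm(m, **kw)
    assert best1 == best2
    assert max(r["mean_micro_f1"] for r in table1) == 1.0
    # linear kernel collapses the gamma axis to a single placeholder value
    n_linear = sum(1 for r in table1 if r["spec"].kernel == "linear")
    assert n_linear == 2  # |C_grid| x 1


def test_grid_search_tie_break_canonical():
    m, _ = separable_matrix()
    best, table = grid_search_svm(m, kernels=("sigmoid", "linear", "rbf"),
                                  C_grid=(51, 11, 91), gamma_grid=(0.009, 0.001), seed=0)
    top = max(r["mean_micro_f1"] for r in table)
    tied = [r["spec"] for r in table if r["mean_micro_f1"] == top]
    kernel_rank = {k: i for i, k in enumerate(KERNEL_ORDER)}
    expected = min(tied, key=lambda s: (s.C, s.gamma, kernel_rank[s.kernel]))
    assert best == expected


def test_grid_search_needs_both_classes():
    m = make_matrix(np.eye(6), [1] * 6)
    with pytest.raises(ValueError, match="per class"):
        grid_search_svm(m)


def test_train_predict_separable_roundtrip(tmp_path):
    m, y = separable_matrix()
    model = train(m, spec=ModelSpec(kernel="linear", C=11, gamma=0.001),
                  fraction=1.0)
    scores, labels = predict(model, m)
    assert np.array_equal(labels, y)
    assert np.all((scores >= 0) & (scores <= 1))
    path = tmp_path / "model.joblib"
    model.save(path)
    back = RecurrenceModel.load(path)
    assert np.allclose(back.predict_scores(m), scores)
    assert back.spec == model.spec


def test_linear_coefficients_exposed():
    m, _ = separable_matrix()
    model = train(m, spec=ModelSpec(kernel="linear"), fraction=1.0)
    coefs = model.linear_coefficients()
    assert set(coefs) == set(model.selection.retained)
    # the separating feature carries the dominant weight
    top = max(coefs, key=lambda k: abs(coefs[k]))
    assert top == FeatureKey("cui_set", ("C0000",))
    rbf = train(m, spec=ModelSpec(kernel="rbf"), fraction=1.0)
    with pytest.raises(ValueError, match="linear"):
        rbf.linear_coefficients()


def test_pathology_column_standardized():
    rng = np.random.default_rng(1)
    y = np.array([0, 1] * 20)
    X = np.zeros((40, 2))
    X[:, 0] = rng.integers(0, 2, size=40)
    X[:, 1] = y * 5 + rng.poisson(1, size=40)  # count-like column
    m = make_matrix(X, y, with_pathology=True)
    model = train(m, spec=ModelSpec(kernel="linear"), fraction=1.0)
    j, mean, std = model.scale
    col = np.asarray(model.selection.transform(m).X.todense())[:, j]
    assert mean == pytest.approx(col.mean())
    assert std == pytest.approx(col.std())


def test_predict_unseen_keys_align_to_training_space():
    m, y = separable_matrix()
    model = train(m, fraction=1.0)
    other = make_matrix(np.ones((3, 1)), None)
    other.keys[0] = FeatureKey("cui_set", ("C7777",))  # unseen key only
    scores, labels = predict(model, other)
    assert scores.shape == (3,)
    assert set(labels) <= {0, 1}


def test_train_errors():
    with pytest.raises(ValueError, match="labels"):
        train(make_matrix(np.eye(4)))
    empty = FeatureMatrix(patient_ids=[], keys=[], X=sp.csr_matrix((0, 0)),
                          labels=np.array([], dtype=int))
    with pytest.raises(ValueError, match="empty"):
        train(empty)
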