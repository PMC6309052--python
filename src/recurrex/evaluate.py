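"""Splitting, metrics, experiment harness, and error analysis.

The experiment harness mirrors the study design: a seeded 7:3 random split
of the labeled cohort, chi-square selection on the training portion,
grid-searched SVM tuning by five-fold cross-validated micro-F1, per-fold
precision/recall/F1/AUC (mean and SD), one held-out evaluation per feature
mode, and paired t-tests across folds between the proposed model and each
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from recurrex.corpus import PatientRecord
from recurrex.features import (
    DEFAULT_CUI_CAP,
    DEFAULT_MIN_DAYS,
    FeatureMatrix,
    assemble_matrix,
    count_pathology_reports,
)
from recurrex.model import (
    DEFAULT_C_GRID,
    DEFAULT_FRACTION,
    DEFAULT_GAMMA_GRID,
    KERNEL_ORDER,
    ModelSpec,
    RecurrenceModel,
    _apply_scale,
    _dense,
    _make_svc,
    _scale_params,
    chi_square_select,
    grid_search_svm,
    train,
)


@dataclass
class MetricsReport:
    """Confusion counts and derived metrics at one probability cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None
    n: int
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "auc": self.auc, "n": self.n, "cutoff": self.cutoff,
        }


def split_train_test(
    records: Sequence[PatientRecord],
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Seeded simple random split into train/test patient-id lists.

    The training size is ``round(ratio * n)`` (Python banker's rounding).
    The split is not stratified: class balance may drift between halves,
    as it does in any simple random split.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratio * n))
    ids = [r.patient_id for r in records]
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def compute_metrics(
    labels: Sequence[int],
    scores: Sequence[float],
    cutoff: float = 0.5,
) -> MetricsReport:
    """Confusion counts at the cutoff (score >= cutoff is positive),
    precision/recall/F1 from the counts, and midrank AUC.

    With a single-class label vector the AUC is undefined and reported as
    None with a warning.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: AUC undefined", stacklevel=2)
        auc = None
    else:
        auc = float(roc_auc_score(y, s))
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                         recall=recall, f1=f1, auc=auc, n=int(y.size), cutoff=cutoff)


def cohen_kappa(ann1: Sequence[int], ann2: Sequence[int]) -> float:
    """Cohen's kappa with marginal-product chance agreement."""
    a = np.asarray(ann1, dtype=int)
    b = np.asarray(ann2, dtype=int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("annotation vectors must be equal-length and non-empty")
    n = a.size
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    p_e = float(sum((np.mean(a == c)) * (np.mean(b == c)) for c in cats))
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 but observed is not")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class ExperimentConfig:
    """Everything a full comparison run needs, in one reproducible bundle."""

    modes: tuple[str, ...] = ("proposed", "filtered_concepts", "full_concepts", "bag_of_words")
    split_ratio: float = 0.7
    fraction: float = DEFAULT_FRACTION
    folds: int = 5
    cutoff: float = 0.5
    seed: int = 0
    kernels: tuple[str, ...] = KERNEL_ORDER
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    min_days: int = DEFAULT_MIN_DAYS
    cui_cap: int = DEFAULT_CUI_CAP


_FOLD_METRICS = ("precision", "recall", "f1", "auc")


def _fold_metrics(
    matrix: FeatureMatrix,
    y: np.ndarray,
    spec: ModelSpec,
    folds: int,
    seed: int,
    cutoff: float,
) -> list[MetricsReport]:
    """Refit the winning spec per CV fold and score the validation folds."""
    X = _dense(matrix)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out = []
    for tr, va in skf.split(X, y):
        params = _scale_params(X[tr], matrix.keys)
        clf = _make_svc(spec, probability=True)
        clf.fit(_apply_scale(X[tr], params), y[tr])
        pos = list(clf.classes_).index(1)
        scores = clf.predict_proba(_apply_scale(X[va], params))[:, pos]
        out.append(compute_metrics(y[va], scores, cutoff))
    return out


def run_experiment(
    records: Sequence[PatientRecord],
    config: ExperimentConfig,
    *,
    lexicon=None,
    triggers=None,
    positive=None,
) -> dict:
    """Compare the proposed feature space against the baselines.

    Returns a JSON-serializable report: per mode the feature count, the
    winning SVM configuration, fold-wise CV metrics (mean, SD), and the
    held-out metrics; plus paired t-test p-values (proposed vs baseline)
    over fold-wise metrics.  Deterministic given the seed.
    """
    if any(r.label is None for r in records):
        raise ValueError("all records need labels for an experiment")
    if lexicon is None:
        from recurrex.resources import lexicon_path
        from recurrex.tagger import load_lexicon

        lexicon = load_lexicon(lexicon_path())
    if triggers is None:
        from recurrex.context import default_triggers

        triggers = default_triggers()
    if positive is None:
        from recurrex.positive import default_positive_set

        positive = default_positive_set()

    from recurrex.tagger import tag_corpus

    needs_tagging = any(m != "bag_of_words" for m in config.modes)
    tagged = tag_corpus(records, lexicon) if needs_tagging else None

    train_ids, test_ids = split_train_test(records, config.split_ratio, config.seed)
    row = {r.patient_id: i for i, r in enumerate(records)}
    tr_idx = [row[p] for p in train_ids]
    te_idx = [row[p] for p in test_ids]

    report: dict = {
        "seed": config.seed,
        "n": len(records),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "modes": {},
        "significance": {},
    }
    fold_tables: dict[str, list[MetricsReport]] = {}
    for mode in config.modes:
        matrix = assemble_matrix(
            records, mode, lexicon=lexicon, triggers=triggers, positive=positive,
            min_days=config.min_days, cui_cap=config.cui_cap,
            tagged=tagged if mode != "bag_of_words" else None,
        )
        m_train = matrix.subset_rows(tr_idx)
        m_test = matrix.subset_rows(te_idx)
        y_train = m_train.labels
        sel = chi_square_select(m_train, fraction=config.fraction)
        m_sel = sel.transform(m_train)
        best, _table = grid_search_svm(
            m_sel, kernels=config.kernels, C_grid=config.C_grid,
            gamma_grid=config.gamma_grid, folds=config.folds, seed=config.seed,
        )
        folds = _fold_metrics(m_sel, y_train, best, config.folds, config.seed, config.cutoff)
        fold_tables[mode] = folds
        model = train(m_train, spec=best, selection=sel, cutoff=config.cutoff)
        heldout_scores = model.predict_scores(m_test)
        heldout = compute_metrics(m_test.labels, heldout_scores, config.cutoff)
        cv_summary = {}
        for metric in _FOLD_METRICS:
            vals = [getattr(f, metric) for f in folds]
            clean = [v for v in vals if v is not None]
            cv_summary[metric] = {
                "mean": float(np.mean(clean)) if clean else None,
                "sd": float(np.std(clean, ddof=1)) if len(clean) > 1 else None,
                "folds": vals,
            }
        report["modes"][mode] = {
            "n_features": len(matrix.keys),
            "n_selected": len(sel.retained),
            "best_spec": {"kernel": best.kernel, "C": best.C, "gamma": best.gamma},
            "cv": cv_summary,
            "heldout": heldout.to_dict(),
        }
    if "proposed" in fold_tables:
        for mode, folds in fold_tables.items():
            if mode == "proposed":
                continue
            pvals = {}
            for metric in _FOLD_METRICS:
                a = [getattr(f, metric) for f in fold_tables["proposed"]]
                b = [getattr(f, metric) for f in folds]
                if None in a or None in b:
                    pvals[metric] = None
                    continue
                t = sstats.ttest_rel(a, b)
                pvals[metric] = None if np.isnan(t.pvalue) else float(t.pvalue)
            report["significance"][mode] = pvals
    return report


def error_analysis(
    records: Sequence[PatientRecord],
    scores: Sequence[float],
    *,
    cutoff: float = 0.5,
    min_days: int = DEFAULT_MIN_DAYS,
    evidence: Mapping[str, list[str]] | None = None,
) -> dict:
    """Misclassification listing and pathology-count group structure.

    For every false positive and false negative: the score, the pathology
    count, and (when ``evidence`` maps patient ids to their surviving
    positive-concept sentences) the sentence evidence.  Also reports mean
    pathology counts per confusion group and the Pearson correlation
    between pathology count and score within the false negatives.
    """
    s = np.asarray(scores, dtype=float)
    y = np.array([r.label for r in records], dtype=int)
    pred = (s >= cutoff).astype(int)
    counts = np.array([count_pathology_reports(r, min_days) for r in records], dtype=float)
    groups = {
        "TP": (pred == 1) & (y == 1),
        "FP": (pred == 1) & (y == 0),
        "FN": (pred == 0) & (y == 1),
        "TN": (pred == 0) & (y == 0),
    }
    group_means = {
        g: (float(np.mean(counts[mask])) if mask.any() else None)
        for g, mask in groups.items()
    }
    listing = []
    for i, r in enumerate(records):
        g = next(g for g, mask in groups.items() if mask[i])
        if g not in ("FP", "FN"):
            continue
        listing.append({
            "patient_id": r.patient_id, "group": g, "score": float(s[i]),
            "pathology_count": int(counts[i]),
            "evidence": (evidence or {}).get(r.patient_id, []),
        })
    fn_mask = groups["FN"]
    fn_corr = None
    if fn_mask.sum() >= 2 and np.std(counts[fn_mask]) > 0 and np.std(s[fn_mask]) > 0:
        fn_corr = float(np.corrcoef(counts[fn_mask], s[fn_mask])[0, 1])
    return {
        "misclassified": listing,
        "group_mean_pathology_counts": group_means,
        "fn_count_score_correlation": fn_corr,
    }
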