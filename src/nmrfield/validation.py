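"""Model validation: cross-validation schemes, AUROC/CVER, permutation
testing, and double (nested) cross-validation for multilevel PLS-DA.

Scheme rule: leave-one-out for models with 20 or fewer spectra, interleaved
"Venetian blinds" folds otherwise.  Centering, OSC and PLS are fitted on
training folds only and applied to held-out folds through stored means and
weights.  Every source of randomness (permutations, inner-fold reshuffles)
flows from one explicit seed via spawned ``SeedSequence`` children, so all
reported numbers are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, ttest_ind

from .multivariate import encode_classes, fit_plsda, multilevel_split, predict

__all__ = [
    "ModelSpec", "ValidationResult", "PermutationRecord",
    "choose_scheme", "venetian_blind_folds", "cross_validate",
    "auroc", "cver", "permutation_test",
    "double_cross_validate", "paired_permutation_test",
]

VENETIAN_BLINDS = "venetian_blinds"
LEAVE_ONE_OUT = "leave_one_out"


@dataclass(frozen=True)
class ModelSpec:
    """Supervised-model hyperparameters used inside every CV fold."""
    n_osc: int = 1
    max_lv: int = 3


@dataclass
class PermutationRecord:
    n_cycles: int
    null_errors: np.ndarray
    observed_error: float
    empirical_p: float
    per_class_p: dict


@dataclass
class ValidationResult:
    scheme: str
    n_folds: int
    per_lv_cver: list
    chosen_n_lv: int
    cv_scores: np.ndarray        # per-sample continuous predictions (n x m)
    cv_classes: np.ndarray       # per-sample class assignments
    cver: float
    auroc_per_class: dict
    classes: list
    permutation: PermutationRecord | None = None


def choose_scheme(n_samples: int) -> str:
    """Leave-one-out iff the model holds 20 or fewer spectra."""
    if n_samples < 3:
        raise ValueError("need at least 3 samples to cross-validate")
    return LEAVE_ONE_OUT if n_samples <= 20 else VENETIAN_BLINDS


def venetian_blind_folds(y, n_folds: int) -> np.ndarray:
    """Interleaved fold ids: sample i of the class-sorted order -> i mod k."""
    y = np.asarray(y)
    order = np.argsort(y, kind="stable")
    fold = np.empty(y.size, dtype=int)
    fold[order] = np.arange(y.size) % n_folds
    return fold


def _fold_ids(y, scheme: str) -> np.ndarray:
    n = len(y)
    if scheme == LEAVE_ONE_OUT:
        return np.arange(n)
    return venetian_blind_folds(y, min(10, n // 3))


def _class_scores(yhat: np.ndarray, classes, cls) -> np.ndarray:
    """Continuous score toward class ``cls`` (±1 column or one-hot column)."""
    j = classes.index(cls)
    if len(classes) == 2:
        return yhat[:, 0] * (1.0 if j == 1 else -1.0)
    return yhat[:, j]


def cver(class_predictions, labels) -> float:
    """Cross-validated error rate: misclassified / total."""
    pred = np.asarray(class_predictions)
    lab = np.asarray(labels)
    if pred.size == 0:
        raise ValueError("empty predictions")
    if pred.size != lab.size:
        raise ValueError("predictions and labels differ in length")
    return float(np.mean(pred != lab))


def auroc(continuous_predictions, binary_labels) -> float:
    """Mann-Whitney AUROC: P(score+ > score-) + 0.5 P(tie)."""
    s = np.asarray(continuous_predictions, dtype=float)
    lab = np.asarray(binary_labels).astype(bool)
    n_pos, n_neg = int(lab.sum()), int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both labels must be present for AUROC")
    r = rankdata(s)
    return float((r[lab].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def cross_validate(X, y, spec: ModelSpec | None = None,
                   scheme: str | None = None, seed: int = 0
                   ) -> ValidationResult:
    """Cross-validated o-PLS-DA with per-LV error and LV selection.

    For each fold, centering/OSC/PLS are fitted on the training rows only;
    the latent-variable count is the arg-min of the cross-validated error
    over 1..max_lv (smallest count on ties).  ``seed`` is accepted for
    interface symmetry: both fold schemes are deterministic.
    """
    del seed  # fold assignment is deterministic for both schemes
    spec = spec or ModelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    scheme = scheme or choose_scheme(len(y))
    folds = _fold_ids(y, scheme)
    n_folds = int(folds.max()) + 1
    classes = sorted(np.unique(y).tolist())
    m = 1 if len(classes) == 2 else len(classes)

    scores_lv = np.zeros((spec.max_lv, len(y), m))
    classes_lv = np.empty((spec.max_lv, len(y)), dtype=object)
    for f in range(n_folds):
        test = folds == f
        train = ~test
        y_tr = y[train]
        if len(np.unique(y_tr)) < len(classes):
            raise ValueError(
                f"training fold {f} lost a class; use fewer folds")
        model = fit_plsda(X[train], y_tr, n_lv=spec.max_lv,
                          n_osc=spec.n_osc, classes=classes)
        for a in range(1, spec.max_lv + 1):
            yhat, assign = predict(model, X[test], n_lv=a)
            scores_lv[a - 1, test] = yhat
            classes_lv[a - 1, test] = assign

    per_lv = [cver(classes_lv[a], y) for a in range(spec.max_lv)]
    chosen = int(np.argmin(per_lv)) + 1          # ties -> fewest LVs
    cv_scores = scores_lv[chosen - 1]
    cv_classes = classes_lv[chosen - 1]
    aur = {c: auroc(_class_scores(cv_scores, classes, c), y == c)
           for c in classes}
    return ValidationResult(
        scheme=scheme, n_folds=n_folds, per_lv_cver=per_lv,
        chosen_n_lv=chosen, cv_scores=cv_scores,
        cv_classes=np.asarray(cv_classes), cver=per_lv[chosen - 1],
        auroc_per_class=aur, classes=classes)


def _empirical_p(null_errors: np.ndarray, observed: float) -> float:
    """Add-one estimator: p is never exactly 0."""
    k = int(np.sum(null_errors <= observed))
    return (k + 1.0) / (null_errors.size + 1.0)


def _per_class_p(observed: ValidationResult, null_scores, null_labels,
                 classes) -> dict:
    """One-sided Welch t per class: observed own-class scores vs the pooled
    scores of permuted samples carrying that (permuted) label."""
    out = {}
    for c in classes:
        obs_c = _class_scores(observed.cv_scores, classes, c)[
            observed._true_labels == c]
        pooled = np.concatenate([
            _class_scores(s, classes, c)[np.asarray(lab) == c]
            for s, lab in zip(null_scores, null_labels)]) if null_scores \
            else np.empty(0)
        if obs_c.size < 2 or pooled.size < 2:
            out[c] = 1.0
            continue
        out[c] = float(ttest_ind(obs_c, pooled, equal_var=False,
                                 alternative="greater").pvalue)
    return out


def permutation_test(X, y, spec: ModelSpec | None = None,
                     n_cycles: int = 100, seed: int = 0,
                     scheme: str | None = None) -> ValidationResult:
    """Label-permutation null for the cross-validated model.

    Each cycle permutes the labels, re-runs the full cross-validation, and
    records the error; empirical p uses the add-one estimator
    ``(#(null <= observed) + 1) / (n_cycles + 1)``.  Per-class p-values come
    from a one-sided Welch t-test of each class's observed cross-validated
    scores against the pooled permuted scores ("random t tests").
    """
    if n_cycles < 19:
        raise ValueError("n_cycles must be >= 19 (p resolution too coarse)")
    spec = spec or ModelSpec()
    y = np.asarray(y)
    scheme = scheme or choose_scheme(len(y))
    observed = cross_validate(X, y, spec, scheme)
    observed._true_labels = y
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null_errors = np.empty(n_cycles)
    null_scores, null_labels = [], []
    for c in range(n_cycles):
        y_perm = rng.permutation(y)
        res = cross_validate(X, y_perm, spec, scheme)
        null_errors[c] = res.cver
        null_scores.append(res.cv_scores)
        null_labels.append(y_perm)
    observed.permutation = PermutationRecord(
        n_cycles=n_cycles, null_errors=null_errors,
        observed_error=observed.cver,
        empirical_p=_empirical_p(null_errors, observed.cver),
        per_class_p=_per_class_p(observed, null_scores, null_labels,
                                 observed.classes))
    return observed


# --------------------------------------------------------------------------
# double cross-validation (multilevel PLS-DA)

def _check_paired(y, subject_ids):
    subject_ids = np.asarray(subject_ids)
    y = np.asarray(y)
    subjects = np.unique(subject_ids)
    classes = np.unique(y)
    for s in subjects:
        labels = y[subject_ids == s]
        counts = [int(np.sum(labels == c)) for c in classes]
        if len(set(counts)) != 1 or counts[0] == 0:
            raise ValueError(
                f"subject {s!r} is not class-balanced: paired design required")
    return subjects


def double_cross_validate(X_within, y, subject_ids, n_repeats: int = 20,
                          max_lv: int = 3, n_osc: int = 0, seed: int = 0
                          ) -> ValidationResult:
    """Nested CV on the within-subject matrix (ML-PLS-DA).

    Outer loop: leave one subject out (all of a subject's samples held out
    together, so neither centering nor OSC nor PLS ever sees them).  Inner
    loop: subject-level folds on the remaining subjects select the LV count
    by inner error.  The whole procedure is repeated ``n_repeats`` times with
    reshuffled inner folds; the reported error is the mean outer
    misclassification over repeats, and AUROCs are computed from the
    repeat-averaged continuous predictions.
    """
    X = np.asarray(X_within, dtype=float)
    y = np.asarray(y)
    subject_ids = np.asarray(subject_ids)
    multilevel_split(X, subject_ids)          # validates >= 2 samples/subject
    subjects = _check_paired(y, subject_ids)
    if subjects.size < 4:
        raise ValueError("double cross-validation needs at least 4 subjects")
    classes = sorted(np.unique(y).tolist())
    m = 1 if len(classes) == 2 else len(classes)

    rng_children = np.random.SeedSequence(seed).spawn(n_repeats)
    sum_scores = np.zeros((len(y), m))
    repeat_errors = np.empty(n_repeats)
    chosen_lvs = []
    for r in range(n_repeats):
        rng = np.random.default_rng(rng_children[r])
        assign = np.empty(len(y), dtype=object)
        for s in subjects:
            test = subject_ids == s
            train = ~test
            train_subjects = [t for t in subjects if t != s]
            k = min(7, len(train_subjects))
            order = rng.permutation(len(train_subjects))
            fold_of_subj = {train_subjects[order[i]]: i % k
                            for i in range(len(train_subjects))}
            inner_err = np.zeros(max_lv)
            inner_n = 0
            for f in range(k):
                inner_test_subj = [t for t in train_subjects
                                   if fold_of_subj[t] == f]
                it_mask = np.isin(subject_ids, inner_test_subj)
                tr_mask = train & ~it_mask
                if len(np.unique(y[tr_mask])) < len(classes):
                    continue
                model = fit_plsda(X[tr_mask], y[tr_mask], n_lv=max_lv,
                                  n_osc=n_osc, classes=classes)
                for a in range(1, max_lv + 1):
                    _, pred = predict(model, X[it_mask], n_lv=a)
                    inner_err[a - 1] += int(np.sum(pred != y[it_mask]))
                inner_n += int(it_mask.sum())
            lv = int(np.argmin(inner_err)) + 1 if inner_n else 1
            chosen_lvs.append(lv)
            model = fit_plsda(X[train], y[train], n_lv=max_lv, n_osc=n_osc,
                              classes=classes)
            yhat, pred = predict(model, X[test], n_lv=lv)
            sum_scores[test] += yhat
            assign[test] = pred
        repeat_errors[r] = cver(assign, y)

    mean_scores = sum_scores / n_repeats
    # class assignment from the repeat-averaged continuous prediction
    _, _, targets = encode_classes(y, classes)
    d2 = ((mean_scores[:, None, :] - targets[None, :, :]) ** 2).sum(-1)
    cv_classes = np.asarray([classes[j] for j in np.argmin(d2, axis=1)])
    aur = {c: auroc(_class_scores(mean_scores, classes, c), y == c)
           for c in classes}
    res = ValidationResult(
        scheme="leave_one_subject_out", n_folds=int(subjects.size),
        per_lv_cver=[], chosen_n_lv=int(np.median(chosen_lvs)),
        cv_scores=mean_scores, cv_classes=cv_classes,
        cver=float(repeat_errors.mean()), auroc_per_class=aur,
        classes=classes)
    res._true_labels = y
    return res


def paired_permutation_test(X_within, y, subject_ids, n_cycles: int = 200,
                            n_repeats: int = 20, perm_repeats: int = 5,
                            max_lv: int = 3, n_osc: int = 0, seed: int = 0
                            ) -> ValidationResult:
    """Permutation null for ML-PLS-DA: labels permuted within each subject.

    Observed error uses ``n_repeats`` double-CV repeats; null cycles use
    ``perm_repeats`` to keep the null affordable (the null distribution's
    location is insensitive to the repeat count).
    """
    if n_cycles < 19:
        raise ValueError("n_cycles must be >= 19 (p resolution too coarse)")
    y = np.asarray(y)
    subject_ids = np.asarray(subject_ids)
    observed = double_cross_validate(X_within, y, subject_ids,
                                     n_repeats=n_repeats, max_lv=max_lv,
                                     n_osc=n_osc, seed=seed)
    subjects = np.unique(subject_ids)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    null_errors = np.empty(n_cycles)
    null_scores, null_labels = [], []
    for c in range(n_cycles):
        y_perm = y.copy()
        for s in subjects:
            rows = np.flatnonzero(subject_ids == s)
            y_perm[rows] = rng.permutation(y[rows])
        if np.unique(y_perm).size < 2:
            null_errors[c] = 0.5
            continue
        res = double_cross_validate(X_within, y_perm, subject_ids,
                                    n_repeats=perm_repeats, max_lv=max_lv,
                                    n_osc=n_osc, seed=seed + 1 + c)
        null_errors[c] = res.cver
        null_scores.append(res.cv_scores)
        null_labels.append(y_perm)
    observed.permutation = PermutationRecord(
        n_cycles=n_cycles, null_errors=null_errors,
        observed_error=observed.cver,
        empirical_p=_empirical_p(null_errors, observed.cver),
        per_class_p=_per_class_p(observed, null_scores, null_labels,
                                 observed.classes))
    return observed
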