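"""Feature assembly and cross-validated classification of group membership.

Feature vectors combine per-subject contrast summaries from the group-level
activation analysis with Granger causality indices that distinguish the
groups.  Classification uses a soft-margin linear SVM or a
maximum-uncertainty linear discriminant (MLDA): ordinary LDA with the
pooled within-class scatter regularised by replacing eigenvalues below
their mean with the mean, which stabilises the inverse when subjects are
few and features correlated.

Accuracy is estimated by repeated random cross-validation (five-fold,
Monte-Carlo leave-one-out, or leave-M-blocks), and significance by a
permutation test that re-runs the entire CV under shuffled labels.

Feature selection on the whole sample before CV (as is common in small
fMRI studies) is circular; both that mode and a nested, per-fold selection
are provided so the optimism can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group import two_sample_t_from_samples

__all__ = [
    "FeatureMatrix",
    "CvScheme",
    "ClassificationReport",
    "LinearModel",
    "select_features",
    "train_mlda",
    "train_svm_linear",
    "cross_validate",
    "permutation_test",
    "feature_contributions",
    "evaluate_sensitivity_specificity",
]


@dataclass
class FeatureMatrix:
    """Subject x feature matrix with labels and feature provenance tags."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray  # group label per subject
    origins: list[str] = field(default_factory=list)  # e.g. contrast_cI_cC | gci

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("values shape inconsistent with labels/names")
        if np.isnan(self.values).any():
            raise ValueError("missing entries in feature matrix")
        if not self.origins:
            self.origins = ["unknown"] * len(self.feature_names)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation scheme: kfold, loo_random or leave_blocks.

    kfold: per repeat, a random 5-fold split, train on 4, test on 1.
    loo_random: per repeat, one randomly chosen held-out subject.
    leave_blocks: per repeat, a random 5-block partition; train on
    ``m_training_blocks`` blocks, test on the remainder.
    """

    kind: str = "kfold"
    n_folds: int = 5
    n_repeats: int = 1000
    m_training_blocks: int = 4
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("kfold", "loo_random", "leave_blocks", "loo_exhaustive"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.kind == "leave_blocks" and not (
            1 <= self.m_training_blocks <= self.n_folds - 1
        ):
            raise ValueError("m_training_blocks must be in [1, n_folds - 1]")


@dataclass
class ClassificationReport:
    mean_accuracy: float  # percent
    accuracy_sd: float  # percent
    accuracies: np.ndarray  # per repeat, percent
    permutation_p: float | None = None
    null_accuracies: np.ndarray | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    contributions: dict[str, float] | None = None


@dataclass
class LinearModel:
    """Linear decision function f(x) = w.x + b; f > 0 predicts class_pos."""

    weights: np.ndarray
    intercept: float
    class_pos: object
    class_neg: object
    tie_break: object = None  # class assigned at exactly f == 0

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision(X)
        tie = self.tie_break if self.tie_break is not None else self.class_pos
        out = np.where(f > 0, self.class_pos, np.where(f < 0, self.class_neg, tie))
        return out


def _two_classes(labels: np.ndarray):
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    return classes


def select_features(
    candidates: pd.DataFrame,
    labels: np.ndarray,
    p_threshold: float = 0.05,
    mode: str = "as_published",
    origins: dict[str, str] | None = None,
) -> tuple[FeatureMatrix, dict]:
    """Select features whose two-sample test separates the groups.

    Parameters
    ----------
    candidates : subject x candidate-feature table.
    mode : "as_published" selects on the whole sample (circular — the same
        subjects are later cross-validated; flagged in the manifest);
        "nested" defers selection to the CV loop (the returned matrix keeps
        all candidates and records the threshold for per-fold use).

    Returns the feature matrix and a selection manifest.
    """
    labels = np.asarray(labels)
    _two_classes(labels)
    manifest: dict = {"mode": mode, "p_threshold": p_threshold, "pvalues": {}}
    if mode == "as_published":
        manifest["circular"] = True
        selected = []
        for col in candidates.columns:
            res = _column_test(candidates[col].to_numpy(dtype=float), labels)
            manifest["pvalues"][col] = res.p_two_sided
            if res.p_two_sided < p_threshold:
                selected.append(col)
        if not selected:
            raise ValueError(
                f"no feature reached p < {p_threshold}; "
                f"smallest p = {min(manifest['pvalues'].values()):.4f}"
            )
        manifest["selected"] = selected
    elif mode == "nested":
        manifest["circular"] = False
        manifest["selected"] = list(candidates.columns)  # per-fold selection
        manifest["nested_threshold"] = p_threshold
    else:
        raise ValueError(f"mode must be 'as_published' or 'nested', got {mode!r}")
    cols = manifest["selected"]
    fm = FeatureMatrix(
        values=candidates[cols].to_numpy(dtype=float),
        feature_names=list(cols),
        labels=labels,
        origins=[(origins or {}).get(c, "unknown") for c in cols],
    )
    return fm, manifest


def _column_test(x: np.ndarray, labels: np.ndarray):
    classes = _two_classes(labels)
    return two_sample_t_from_samples(x[labels == classes[0]], x[labels == classes[1]])


def train_mlda(features: np.ndarray, labels: np.ndarray) -> LinearModel:
    """Maximum-uncertainty LDA.

    The pooled within-class scatter is eigendecomposed and eigenvalues
    below their mean are raised to the mean; the discriminant direction is
    w = S_reg^-1 (mu1 - mu2), with the boundary at the midpoint of the
    projected class means.  Ties at the boundary go to the larger training
    class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = _two_classes(y)
    c1, c2 = classes
    X1, X2 = X[y == c1], X[y == c2]
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    n1, n2 = len(X1), len(X2)
    dof = max(n1 + n2 - 2, 1)
    Sp = ((X1 - mu1).T @ (X1 - mu1) + (X2 - mu2).T @ (X2 - mu2)) / dof
    evals, evecs = np.linalg.eigh(Sp)
    lam = evals.mean()
    if lam <= 1e-12:  # zero within-class scatter (e.g. one sample per class)
        w = mu1 - mu2
    else:
        evals_reg = np.where(evals < lam, lam, evals)
        S_reg = evecs @ np.diag(evals_reg) @ evecs.T
        w = np.linalg.solve(S_reg, mu1 - mu2)
    b = -float(w @ (mu1 + mu2) / 2.0)
    majority = c1 if n1 >= n2 else c2
    return LinearModel(
        weights=w, intercept=b, class_pos=c1, class_neg=c2, tie_break=majority
    )


def train_svm_linear(
    features: np.ndarray, labels: np.ndarray, C: float = 1.0
) -> LinearModel:
    """Soft-margin linear SVM (scikit-learn behind this interface)."""
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = _two_classes(y)
    c1, c2 = classes
    n1, n2 = int(np.sum(y == c1)), int(np.sum(y == c2))
    clf = SVC(kernel="linear", C=C)
    # encode so positive decision corresponds to c1
    ybin = np.where(y == c1, 1, -1)
    clf.fit(X, ybin)
    w = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    majority = c1 if n1 >= n2 else c2
    return LinearModel(
        weights=w, intercept=b, class_pos=c1, class_neg=c2, tie_break=majority
    )


def _make_trainer(model_spec, C: float = 1.0):
    if callable(model_spec):
        return model_spec
    if model_spec == "mlda":
        return train_mlda
    if model_spec == "svm":
        return lambda X, y: train_svm_linear(X, y, C=C)
    raise ValueError(f"unknown model spec {model_spec!r}")


def _zscore_train_test(Xtr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _random_partition(
    n: int, n_folds: int, labels: np.ndarray, stratified: bool, rng
) -> list[np.ndarray]:
    """Indices per fold; stratified keeps class proportions balanced."""
    if stratified:
        folds: list[list[int]] = [[] for _ in range(n_folds)]
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            offset = rng.integers(n_folds)
            for j, i in enumerate(idx):
                folds[(j + offset) % n_folds].append(int(i))
        return [np.array(sorted(f)) for f in folds]
    idx = rng.permutation(n)
    return [np.array(sorted(f)) for f in np.array_split(idx, n_folds)]


def _fold_selection(Xtr, ytr, Xte, p_threshold):
    keep = []
    for j in range(Xtr.shape[1]):
        col = Xtr[:, j]
        classes = np.unique(ytr)
        a, b = col[ytr == classes[0]], col[ytr == classes[1]]
        if len(a) < 2 or len(b) < 2 or (a.std() == 0 and b.std() == 0):
            continue
        if two_sample_t_from_samples(a, b).p_two_sided < p_threshold:
            keep.append(j)
    if not keep:  # fall back to all candidates rather than an empty model
        keep = list(range(Xtr.shape[1]))
    return Xtr[:, keep], Xte[:, keep]


def cross_validate(
    model_spec,
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    scheme: CvScheme = CvScheme(),
    C: float = 1.0,
    standardize: bool = True,
    nested_selection_p: float | None = None,
    rng: np.random.Generator | None = None,
) -> ClassificationReport:
    """Repeated random cross-validation accuracy.

    Per repeat the mean fold accuracy (or the single held-out hit for
    loo_random) is recorded; the report carries the mean and sd over
    repeats, in percent.  Deterministic given the scheme's seed.
    """
    if isinstance(features, FeatureMatrix):
        X, y = features.values, features.labels
    else:
        X, y = np.asarray(features, dtype=float), np.asarray(labels)
    n = len(y)
    _two_classes(y)
    trainer = _make_trainer(model_spec, C)
    rng = rng or np.random.default_rng(scheme.seed)
    accs = np.empty(scheme.n_repeats if scheme.kind != "loo_exhaustive" else n)

    def run_fold(train_idx, test_idx) -> float:
        Xtr, Xte = X[train_idx], X[test_idx]
        ytr, yte = y[train_idx], y[test_idx]
        if len(np.unique(ytr)) < 2:
            return np.nan
        if standardize:
            Xtr, Xte = _zscore_train_test(Xtr, Xte)
        if nested_selection_p is not None:
            Xtr, Xte = _fold_selection(Xtr, ytr, Xte, nested_selection_p)
        model = trainer(Xtr, ytr)
        return float(np.mean(model.predict(Xte) == yte))

    if scheme.kind == "loo_exhaustive":
        for i in range(n):
            train = np.delete(np.arange(n), i)
            accs[i] = run_fold(train, np.array([i]))
    else:
        for r in range(scheme.n_repeats):
            if scheme.kind == "loo_random":
                i = int(rng.integers(n))
                train = np.delete(np.arange(n), i)
                accs[r] = run_fold(train, np.array([i]))
            elif scheme.kind == "kfold":
                fold_accs = []
                for _ in range(20):  # resample if a fold lacks both classes
                    folds = _random_partition(
                        n, scheme.n_folds, y, scheme.stratified, rng
                    )
                    fold_accs = [
                        run_fold(
                            np.setdiff1d(np.arange(n), f), f
                        )
                        for f in folds
                        if len(f)
                    ]
                    if not np.isnan(fold_accs).any():
                        break
                accs[r] = float(np.nanmean(fold_accs))
            else:  # leave_blocks
                for _ in range(20):
                    folds = _random_partition(
                        n, scheme.n_folds, y, scheme.stratified, rng
                    )
                    block_ids = rng.choice(
                        scheme.n_folds, size=scheme.m_training_blocks, replace=False
                    )
                    train = np.concatenate([folds[b] for b in block_ids])
                    test = np.setdiff1d(np.arange(n), train)
                    if len(np.unique(y[train])) == 2 and len(test):
                        break
                accs[r] = run_fold(train, test)

    accs_pct = accs * 100.0
    return ClassificationReport(
        mean_accuracy=float(np.nanmean(accs_pct)),
        accuracy_sd=float(np.nanstd(accs_pct, ddof=1)) if len(accs_pct) > 1 else 0.0,
        accuracies=accs_pct,
    )


def permutation_test(
    model_spec,
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    scheme: CvScheme = CvScheme(n_repeats=100),
    n_permutations: int = 1000,
    seed: int = 0,
    p_definition: str = "smoothed",
    **cv_kwargs,
) -> ClassificationReport:
    """Permutation p-value for the CV accuracy.

    Labels are permuted ``n_permutations`` times and the full CV repeated;
    p = (1 + #{null >= observed}) / (n_permutations + 1) by default, or the
    unsmoothed #{null >= observed} / n_permutations with
    ``p_definition="paper"``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if isinstance(features, FeatureMatrix):
        X, y = features.values, features.labels
    else:
        X, y = np.asarray(features, dtype=float), np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = cross_validate(
        model_spec, X, y, scheme=scheme,
        rng=np.random.default_rng(rng.integers(2**31)), **cv_kwargs,
    )
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        rep = cross_validate(
            model_spec, X, yp, scheme=scheme,
            rng=np.random.default_rng(rng.integers(2**31)), **cv_kwargs,
        )
        null[b] = rep.mean_accuracy
    exceed = int(np.sum(null >= observed.mean_accuracy))
    if p_definition == "smoothed":
        p = (1.0 + exceed) / (n_permutations + 1.0)
    elif p_definition == "paper":
        p = exceed / n_permutations
    else:
        raise ValueError("p_definition must be 'smoothed' or 'paper'")
    observed.permutation_p = float(p)
    observed.null_accuracies = null
    return observed


def feature_contributions(
    model: LinearModel, feature_names: list[str] | None = None
) -> dict[str, float]:
    """Per-feature contribution: |w_i| of the unit-norm hyperplane normal."""
    if not isinstance(model, LinearModel):
        raise TypeError("contributions are defined only for linear models")
    w = np.asarray(model.weights, dtype=float)
    norm = np.linalg.norm(w)
    contrib = np.abs(w) / norm if norm > 0 else np.zeros_like(w)
    names = feature_names or [f"f{i}" for i in range(len(w))]
    return dict(zip(names, contrib.tolist()))


def evaluate_sensitivity_specificity(
    predictions: np.ndarray, labels: np.ndarray, positive_class
) -> tuple[float, float]:
    """Sensitivity and specificity in percent for the given positive class."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    classes = set(np.unique(labels).tolist())
    unseen = set(np.unique(predictions).tolist()) - classes
    if unseen:
        raise ValueError(f"predictions contain unseen classes {unseen}")
    pos = labels == positive_class
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present in labels")
    tp = int(np.sum((predictions == positive_class) & pos))
    tn = int(np.sum((predictions != positive_class) & neg))
    sens = 100.0 * tp / int(pos.sum())
    spec = 100.0 * tn / int(neg.sum())
    return sens, spec
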