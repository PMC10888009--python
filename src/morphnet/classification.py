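"""Connectome classification cascade.

Feature vectors are the strict upper triangle of each subject's similarity
matrix (4005 values for the full 90x90 matrix, 105 for the 15-region
submatrix). A per-feature Gaussian-process regression on the 3-level
medication code removes the confound, features are standardized, optionally
reduced by an autoencoder or a supervised feedforward network, and fed to
an SVM, random forest, or gradient-boosted-tree classifier under stratified
5-fold cross-validation. Every train-only step (residualization, scaling,
reduction) is fitted inside the training fold.

Reported metrics: sensitivity, specificity, and balanced accuracy (their
mean), from confusion counts pooled across folds (the per-fold values and
their mean are also kept). A label-permutation test assesses whether the
observed balanced accuracy beats chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .kls_network import SimilarityMatrix

REDUCERS = ("none", "ae", "dnn")
CLASSIFIERS = ("svm", "rf", "xgb")

#: The 15 regions whose pairwise similarities form the reduced feature set
#: for the BD-vs-MDD task (regions with nodal differences between the
#: patient groups).
BD_MDD_SUBMATRIX_REGIONS = [
    "Frontal_Sup_L",
    "Frontal_Sup_R",
    "Frontal_Sup_Orb_L",
    "Frontal_Mid_L",
    "Frontal_Mid_R",
    "Frontal_Inf_Oper_R",
    "Supp_Motor_Area_L",
    "Supp_Motor_Area_R",
    "Frontal_Sup_Medial_L",
    "Frontal_Sup_Medial_R",
    "Hippocampus_L",
    "Parietal_Sup_L",
    "Caudate_R",
    "Thalamus_L",
    "Temporal_Pole_Sup_R",
]


@dataclass
class FeatureTable:
    subject_ids: list[str]
    labels: np.ndarray  # 1 = positive class
    features: np.ndarray  # (subjects, features)
    provenance: str = "full"
    feature_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature table contains missing/non-finite values")
        if self.features.shape[0] != self.labels.size or len(self.subject_ids) != self.labels.size:
            raise ValueError("subjects, labels, and feature rows must align")


@dataclass
class ClassificationReport:
    task: str
    reducer: str
    classifier: str
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    fold_balanced_accuracies: list[float]
    fold_mean_balanced_accuracy: float
    confusion: dict[str, int]
    p_perm: float | None = None
    positive_class: str = "patients"


def vectorize(
    matrices: list[SimilarityMatrix],
    subject_ids: list[str],
    labels: np.ndarray,
    region_subset: list[str] | None = None,
) -> FeatureTable:
    """Strict upper triangle of each matrix, row-major, as one feature row."""
    ref = matrices[0].labels
    for m in matrices:
        if m.labels != ref:
            raise ValueError("all matrices must share the same region labels")
    if region_subset is not None:
        unknown = [r for r in region_subset if r not in ref]
        if unknown:
            raise ValueError(f"unknown region names: {unknown}")
        idx = np.array([ref.index(r) for r in region_subset])
        provenance = "submatrix"
        names = list(region_subset)
    else:
        idx = np.arange(len(ref))
        provenance = "full"
        names = list(ref)
    iu, ju = np.triu_indices(idx.size, k=1)
    rows = [m.values[np.ix_(idx, idx)][iu, ju] for m in matrices]
    pairs = [(names[i], names[j]) for i, j in zip(iu, ju)]
    return FeatureTable(
        subject_ids=list(subject_ids),
        labels=labels,
        features=np.stack(rows),
        provenance=provenance,
        feature_pairs=pairs,
    )


def unvectorize(row: np.ndarray, n: int) -> np.ndarray:
    """Rebuild the symmetric matrix (unit diagonal) from an upper-triangle row."""
    out = np.eye(n)
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = row
    out[ju, iu] = row
    return out


# ---------------------------------------------------------------------------
# confound residualization


class GPConfoundResidualizer:
    """Per-feature Gaussian-process regression of features on a confound.

    An RBF-plus-noise kernel is optimized by marginal likelihood per
    feature. With few features this is a full scikit-learn GP fit each; with
    many features (connectome vectors have thousands) the RBF length scale
    is fixed at 1.0 — the confound levels are one unit apart — and the
    signal-to-noise split of each feature's variance is optimized by exact
    marginal likelihood on a grid, vectorized across features through one
    eigendecomposition of the shared Gram matrix. Fitted on training
    subjects only; ``transform`` applies the frozen predictors to new
    subjects.
    """

    def __init__(self, seed: int = 0, per_feature_limit: int = 16, ratio_grid: int = 41):
        self.seed = seed
        self.per_feature_limit = per_feature_limit
        self.ratio_grid = ratio_grid
        self._degenerate = False

    def _make_gpr(self) -> GaussianProcessRegressor:
        kernel = ConstantKernel(1.0, (1e-4, 1e4)) * RBF(1.0, (1e-2, 1e2)) + WhiteKernel(
            0.1, (1e-8, 1e4)
        )
        return GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=self.seed, n_restarts_optimizer=1
        )

    def fit(self, X: np.ndarray, confound: np.ndarray) -> "GPConfoundResidualizer":
        X = np.asarray(X, dtype=float)
        c = np.asarray(confound, dtype=float).reshape(-1, 1)
        self.train_mean_ = X.mean(axis=0)
        if np.ptp(c) == 0:
            warnings.warn(
                "constant confound in training data; residualizing against the mean",
                stacklevel=2,
            )
            self._degenerate = True
            return self
        self._degenerate = False
        n_feat = X.shape[1]
        if n_feat <= self.per_feature_limit:
            self._gprs = []
            for j in range(n_feat):
                gpr = self._make_gpr()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gpr.fit(c, X[:, j])
                self._gprs.append(gpr)
            self._shared = False
            return self
        # vectorized fast path: K_j = s_j * B + w_j * I with shared
        # B = RBF(length_scale=1); s_j + w_j fixed to the feature variance
        # and the split chosen by exact marginal likelihood per feature
        n = c.shape[0]
        B = RBF(length_scale=1.0)(c)
        lam, U = np.linalg.eigh(B)
        Y = X - self.train_mean_
        Z = U.T @ Y  # rotated residual responses, (n, p)
        var = Y.var(axis=0) + 1e-12
        ratios = np.linspace(0.01, 0.99, self.ratio_grid)
        best_ll = np.full(X.shape[1], -np.inf)
        best_ratio = np.empty(X.shape[1])
        for rho in ratios:
            # per-eigenvalue variances, scaled per feature by var
            d = rho * lam[:, None] + (1 - rho)  # (n, 1) broadcastable
            quad = (Z**2 / (d * var[None, :])).sum(axis=0)
            logdet = np.log(d).sum() + n * np.log(var)
            ll = -0.5 * (quad + logdet)
            better = ll > best_ll
            best_ll[better] = ll[better]
            best_ratio[better] = rho
        s = best_ratio * var
        w = (1 - best_ratio) * var
        # alpha_j = (s_j B + w_j I)^{-1} y_j computed in the eigenbasis
        denom = best_ratio[None, :] * lam[:, None] + (1 - best_ratio)[None, :]
        self._alpha = U @ (Z / denom)  # (n, p); absorbs the 1/var scaling
        self._signal_ratio = best_ratio
        self._train_confound = c
        self._shared = True
        return self

    def _predict(self, confound: np.ndarray, n_features: int) -> np.ndarray:
        c = np.asarray(confound, dtype=float).reshape(-1, 1)
        if self._degenerate:
            return np.tile(self.train_mean_, (c.shape[0], 1))
        if self._shared:
            k_star = RBF(length_scale=1.0)(c, self._train_confound)
            return self.train_mean_ + (k_star @ self._alpha) * self._signal_ratio[None, :]
        preds = np.column_stack([gpr.predict(c) for gpr in self._gprs])
        return preds

    def transform(self, X: np.ndarray, confound: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X - self._predict(confound, X.shape[1])


def residualize_confound(
    train_features: np.ndarray,
    train_confound: np.ndarray,
    apply_to: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Fit GP residualization on the training data; optionally also apply the
    frozen per-feature predictors to held-out ``apply_to = (X, confound)``."""
    res = GPConfoundResidualizer(seed=seed).fit(train_features, train_confound)
    train_resid = res.transform(train_features, train_confound)
    if apply_to is None:
        return train_resid
    return train_resid, res.transform(*apply_to)


# ---------------------------------------------------------------------------
# reducers


def _forward(coefs, intercepts, X: np.ndarray, n_layers: int, activation: str) -> np.ndarray:
    a = X
    for i in range(n_layers):
        a = a @ coefs[i] + intercepts[i]
        a = np.maximum(a, 0.0) if activation == "relu" else np.tanh(a)
    return a


def _hidden_width(n_in: int, dim: int) -> int:
    # geometric mean between input and bottleneck, capped to keep lbfgs
    # tractable at connectome widths
    return min(256, max(dim, int(round(np.sqrt(n_in * dim)))))


class AEReducer:
    """Autoencoder: symmetric MLP trained on reconstruction; the encoder
    output (bottleneck activations) is the reduced representation."""

    kind = "ae"

    def __init__(self, dim: int, seed: int = 0, max_iter: int = 400, activation: str = "tanh"):
        self.dim = dim
        self.seed = seed
        self.max_iter = max_iter
        self.activation = activation

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "AEReducer":
        if self.dim >= X.shape[1]:
            raise ValueError(f"bottleneck dim {self.dim} must be < input width {X.shape[1]}")
        h = _hidden_width(X.shape[1], self.dim)
        self._net = MLPRegressor(
            hidden_layer_sizes=(h, self.dim, h),
            activation=self.activation,
            solver="lbfgs",
            random_state=self.seed,
            max_iter=self.max_iter,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._net.fit(X, X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return _forward(self._net.coefs_, self._net.intercepts_, X, 2, self.activation)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._net.predict(X)


class DNNReducer:
    """Supervised feedforward network; penultimate-layer activations are the
    reduced representation."""

    kind = "dnn"

    def __init__(self, dim: int, seed: int = 0, max_iter: int = 400, activation: str = "relu"):
        self.dim = dim
        self.seed = seed
        self.max_iter = max_iter
        self.activation = activation

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DNNReducer":
        if self.dim >= X.shape[1]:
            raise ValueError(f"dim {self.dim} must be < input width {X.shape[1]}")
        h = _hidden_width(X.shape[1], self.dim)
        self._net = MLPClassifier(
            hidden_layer_sizes=(h, self.dim),
            activation=self.activation,
            solver="lbfgs",
            random_state=self.seed,
            max_iter=self.max_iter,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._net.fit(X, y)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return _forward(self._net.coefs_, self._net.intercepts_, X, 2, self.activation)


def fit_reducer(kind: str, train_features, train_labels, dim: int, seed: int = 0, max_iter: int = 400):
    if kind == "ae":
        return AEReducer(dim, seed=seed, max_iter=max_iter).fit(train_features)
    if kind == "dnn":
        return DNNReducer(dim, seed=seed, max_iter=max_iter).fit(train_features, train_labels)
    raise ValueError(f"unknown reducer kind {kind!r}")


def apply_reducer(reducer, features: np.ndarray) -> np.ndarray:
    return reducer.transform(features)


# ---------------------------------------------------------------------------
# classifiers


def make_classifier(kind: str, seed: int = 0, n_trees: int = 500):
    if kind == "svm":
        return SVC(C=1.0, kernel="rbf", random_state=seed)
    if kind == "rf":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    if kind == "xgb":
        try:  # pragma: no cover - xgboost optional
            from xgboost import XGBClassifier

            return XGBClassifier(random_state=seed, n_estimators=200, verbosity=0)
        except ImportError:
            return HistGradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


# ---------------------------------------------------------------------------
# evaluation


def _rates(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return (sens + spec) / 2.0, sens, spec


def _run_cells(
    table: FeatureTable,
    cells: list[tuple[str, str]],
    confound: np.ndarray | None,
    k_folds: int,
    seed: int,
    dim: int | None,
    task: str,
    reducer_max_iter: int,
    n_trees: int,
) -> dict[tuple[str, str], ClassificationReport]:
    """Shared CV engine: residualization/scaling computed once per fold and
    each reducer fitted once per fold, reused across classifier cells."""
    for red, clf in cells:
        if red not in REDUCERS or clf not in CLASSIFIERS:
            raise ValueError(f"unknown reducer/classifier: {red}/{clf}")
    X, y = table.features, table.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    if counts.min() < k_folds:
        raise ValueError(f"need >= {k_folds} subjects per class for {k_folds}-fold CV")
    if dim is None:
        dim = 16 if X.shape[1] <= 200 else 64

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    counts_by_cell = {cell: [0, 0, 0, 0] for cell in cells}  # tp, fn, tn, fp
    fold_bacs: dict[tuple[str, str], list[float]] = {cell: [] for cell in cells}
    reducer_kinds = {red for red, _ in cells}
    for fold, (train, test) in enumerate(skf.split(X, y)):
        Xtr0, Xte0 = X[train], X[test]
        if confound is not None:
            Xtr0, Xte0 = residualize_confound(
                Xtr0, confound[train], apply_to=(Xte0, confound[test]), seed=seed + fold
            )
        scaler = StandardScaler().fit(Xtr0)
        Xtr0, Xte0 = scaler.transform(Xtr0), scaler.transform(Xte0)
        reduced: dict[str, tuple[np.ndarray, np.ndarray]] = {"none": (Xtr0, Xte0)}
        for kind in sorted(reducer_kinds - {"none"}):
            red = fit_reducer(
                kind, Xtr0, y[train], dim=dim, seed=seed + fold, max_iter=reducer_max_iter
            )
            reduced[kind] = (red.transform(Xtr0), red.transform(Xte0))
        truth = y[test]
        for cell in cells:
            red_kind, clf_kind = cell
            Xtr, Xte = reduced[red_kind]
            clf = make_classifier(clf_kind, seed=seed + fold, n_trees=n_trees)
            clf.fit(Xtr, y[train])
            pred = np.asarray(clf.predict(Xte))
            f_tp = int(((pred == 1) & (truth == 1)).sum())
            f_fn = int(((pred == 0) & (truth == 1)).sum())
            f_tn = int(((pred == 0) & (truth == 0)).sum())
            f_fp = int(((pred == 1) & (truth == 0)).sum())
            c = counts_by_cell[cell]
            c[0] += f_tp; c[1] += f_fn; c[2] += f_tn; c[3] += f_fp
            fold_bacs[cell].append(_rates(f_tp, f_fn, f_tn, f_fp)[0])

    reports = {}
    for cell in cells:
        tp, fn, tn, fp = counts_by_cell[cell]
        bac, sens, spec = _rates(tp, fn, tn, fp)
        reports[cell] = ClassificationReport(
            task=task,
            reducer=cell[0],
            classifier=cell[1],
            balanced_accuracy=bac,
            sensitivity=sens,
            specificity=spec,
            fold_balanced_accuracies=fold_bacs[cell],
            fold_mean_balanced_accuracy=float(np.mean(fold_bacs[cell])),
            confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        )
    return reports


def evaluate(
    table: FeatureTable,
    reducer: str = "none",
    classifier: str = "svm",
    confound: np.ndarray | None = None,
    k_folds: int = 5,
    seed: int = 0,
    dim: int | None = None,
    task: str = "",
    reducer_max_iter: int = 400,
    n_trees: int = 500,
) -> ClassificationReport:
    """Stratified k-fold CV of one reducer x classifier cell.

    All fitted transforms (GP residualization, standardization, reduction)
    see only the training fold; the pooled cross-fold confusion counts give
    the headline balanced accuracy.
    """
    cell = (reducer, classifier)
    return _run_cells(
        table, [cell], confound, k_folds, seed, dim, task, reducer_max_iter, n_trees
    )[cell]


def label_permutation_test(
    table: FeatureTable,
    reducer: str = "none",
    classifier: str = "svm",
    confound: np.ndarray | None = None,
    n_perm: int = 1000,
    k_folds: int = 5,
    seed: int = 0,
    observed: float | None = None,
    **eval_kwargs,
) -> float:
    """p = (1 + #{permuted BAC >= observed BAC}) / (n_perm + 1)."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if observed is None:
        observed = evaluate(
            table, reducer, classifier, confound=confound, k_folds=k_folds, seed=seed, **eval_kwargs
        ).balanced_accuracy
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        shuffled = FeatureTable(
            subject_ids=table.subject_ids,
            labels=rng.permutation(table.labels),
            features=table.features,
            provenance=table.provenance,
        )
        # same CV seed as the observed run: only the labels differ, so the
        # permutation null is not widened by split-to-split variance
        rep = evaluate(
            shuffled, reducer, classifier, confound=confound, k_folds=k_folds,
            seed=seed, **eval_kwargs,
        )
        if rep.balanced_accuracy >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def run_grid(
    table: FeatureTable,
    confound: np.ndarray | None = None,
    reducers: tuple[str, ...] = REDUCERS,
    classifiers: tuple[str, ...] = CLASSIFIERS,
    k_folds: int = 5,
    seed: int = 0,
    n_perm: int = 0,
    task: str = "",
    **eval_kwargs,
) -> list[ClassificationReport]:
    """Full reducer x classifier grid for one task (Table-shaped report)."""
    cells = [(red, clf) for red in reducers for clf in classifiers]
    dim = eval_kwargs.pop("dim", None)
    reducer_max_iter = eval_kwargs.pop("reducer_max_iter", 400)
    n_trees = eval_kwargs.pop("n_trees", 500)
    if eval_kwargs:
        raise TypeError(f"unexpected keyword arguments: {sorted(eval_kwargs)}")
    by_cell = _run_cells(
        table, cells, confound, k_folds, seed, dim, task, reducer_max_iter, n_trees
    )
    reports = []
    for cell in cells:
        rep = by_cell[cell]
        if n_perm:
            rep.p_perm = label_permutation_test(
                table, cell[0], cell[1], confound=confound, n_perm=n_perm, k_folds=k_folds,
                seed=seed, observed=rep.balanced_accuracy, dim=dim,
                reducer_max_iter=reducer_max_iter, n_trees=n_trees,
            )
        reports.append(rep)
    return reports
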