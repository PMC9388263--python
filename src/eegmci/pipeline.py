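"""Feature assembly, selection, classification and validation.

Ties the three feature sets into a samples x features matrix, z-scores with
training statistics only, runs sequential backward (floating) selection
with an LDA 10-fold-accuracy criterion, trains one of eight classifier
families, and evaluates with stratified 10-fold or leave-one-participant-out
cross-validation.  Selection and scaling are always fitted inside the
training fold, never on held-out data.

Metrics (MCI = positive class), reported as percentages:
AC = (TP+TN)/all, SE = TP/(TP+FN), SP = TN/(FP+TN),
F1 = 2TP/(2TP+FP+FN), and FDR either as FP/(FP+TP) (``reported`` mode,
the conventional false-discovery rate) or FP/(FP+TN) (``eq27`` mode).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import DEFAULT_BANDS, EEGRecording, Label
from .connectivity import SLParams, sl_matrix
from .nonlinear import ApEnParams, HiguchiParams, nonlinear_feature_vector
from .spectral import spectral_feature_vector

__all__ = [
    "FeatureMatrix",
    "ConfusionCounts",
    "MetricReport",
    "SelectionResult",
    "PipelineSpec",
    "FittedFold",
    "CLASSIFIER_NAMES",
    "FEATURE_SET_ORDER",
    "assemble_features",
    "zscore_fit",
    "zscore_apply",
    "sbfs",
    "train_classifier",
    "predict",
    "confusion_from_labels",
    "confusion_metrics",
    "fit_fold",
    "kfold_cv",
    "lopo_cv",
    "lopo_cv_features",
    "ttest_features",
    "rank_connectivity",
]

#: Concatenation order of the feature sets in the assembled matrix.
FEATURE_SET_ORDER: tuple[str, ...] = ("connectivity", "spectral", "nonlinear")

CLASSIFIER_NAMES: tuple[str, ...] = (
    "LSVM", "RBFSVM", "LR", "KNN", "DT", "NB", "GB", "RB",
)


# ---------------------------------------------------------------------------
# Feature matrix container
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """samples x named features with per-sample subject ids and labels."""

    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise ValueError("feature_names must match the number of columns")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids and labels must align with rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels)

    def select(self, names: list[str]) -> "FeatureMatrix":
        """Column subset, preserving the requested order."""
        idx = [self.feature_names.index(n) for n in names]
        return replace(self, values=self.values[:, idx], feature_names=list(names))

    def rows(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )

    def to_csv(self, path: str | Path) -> Path:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "subject_id", self.subject_ids)
        frame.insert(1, "label", self.labels)
        frame.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        names = [c for c in frame.columns if c not in ("subject_id", "label")]
        return cls(
            values=frame[names].to_numpy(dtype=float),
            feature_names=names,
            subject_ids=[str(s) for s in frame["subject_id"]],
            labels=[str(s) for s in frame["label"]],
        )


def assemble_features(
    segments: list[EEGRecording],
    sets: tuple[str, ...] = FEATURE_SET_ORDER,
    bands=DEFAULT_BANDS,
    sl_params: SLParams = SLParams(),
    sl_stride: int = 1,
    apen_params: ApEnParams = ApEnParams(),
    higuchi_params: HiguchiParams = HiguchiParams(),
    nonlinear_max_samples: int | None = 4096,
) -> FeatureMatrix:
    """Extract the requested feature sets from every segment.

    Columns follow the fixed order connectivity, spectral, nonlinear
    (full width 171 + 108 + 152 = 431); rows carry each segment's subject
    id and class label.
    """
    if not segments:
        raise ValueError("no segments to extract features from")
    unknown = set(sets) - set(FEATURE_SET_ORDER)
    if unknown:
        raise ValueError(f"unknown feature sets: {sorted(unknown)}")
    ordered = [s for s in FEATURE_SET_ORDER if s in sets]

    rows, names = [], None
    for seg in segments:
        feats: dict[str, float] = {}
        try:
            if "connectivity" in ordered:
                _, sl_feats = sl_matrix(seg, sl_params, stride=sl_stride)
                feats.update(sl_feats)
            if "spectral" in ordered:
                feats.update(spectral_feature_vector(seg, bands=bands))
            if "nonlinear" in ordered:
                feats.update(
                    nonlinear_feature_vector(
                        seg,
                        apen_params=apen_params,
                        higuchi_params=higuchi_params,
                        max_samples=nonlinear_max_samples,
                    )
                )
        except ValueError as exc:
            raise ValueError(
                f"feature extraction failed for subject "
                f"{seg.subject_id!r}: {exc}"
            ) from exc
        if names is None:
            names = list(feats)
        rows.append([feats[n] for n in names])
    return FeatureMatrix(
        values=np.asarray(rows),
        feature_names=names,
        subject_ids=[s.subject_id for s in segments],
        labels=[s.label for s in segments],
    )


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZScoreStats:
    mean: np.ndarray
    sd: np.ndarray


def zscore_fit(train: np.ndarray | FeatureMatrix) -> ZScoreStats:
    """Per-feature mean and sample (n-1) standard deviation of training rows."""
    x = train.values if isinstance(train, FeatureMatrix) else np.asarray(train)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    return ZScoreStats(mean=x.mean(axis=0), sd=sd)


def zscore_apply(stats: ZScoreStats, data: np.ndarray | FeatureMatrix):
    """Standardize with training statistics; constant columns map to zero."""
    x = data.values if isinstance(data, FeatureMatrix) else np.asarray(data)
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    z = (x - stats.mean) / sd
    z[:, stats.sd == 0] = 0.0
    if isinstance(data, FeatureMatrix):
        return replace(data, values=z)
    return z


# ---------------------------------------------------------------------------
# Sequential backward (floating) selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Selected feature names and the (subset size, J) acceptance trace."""

    selected: list[str]
    trace: list[tuple[int, float]]


def _lda_cv_criterion(y: np.ndarray, k: int, seed: int):
    """J(X) = mean LDA accuracy under internal stratified k-fold CV."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("selection criterion needs two classes")
    k_eff = int(min(k, counts.min()))
    if k_eff < 2:
        raise ValueError("too few samples in the smallest class for CV")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(y.size), y))

    def criterion(x_sub: np.ndarray) -> float:
        accs = []
        for tr, te in folds:
            clf = LinearDiscriminantAnalysis()
            clf.fit(x_sub[tr], y[tr])
            accs.append(float(np.mean(clf.predict(x_sub[te]) == y[te])))
        return float(np.mean(accs))

    return criterion


def sbfs(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    criterion=None,
    floating: bool = True,
    seed: int = 0,
    k_inner: int = 10,
    min_features: int = 1,
) -> SelectionResult:
    """Sequential backward (floating) feature selection.

    Starts from the full set and repeatedly removes the feature whose
    removal maximizes the criterion J (default: mean LDA accuracy under
    internal stratified 10-fold CV), accepting a removal only while J
    strictly increases.  With ``floating=True``, after each removal the
    previously discarded feature that most increases J is conditionally
    re-admitted.  Deterministic given the seed; ties break toward the
    lowest column index.
    """
    if isinstance(X, FeatureMatrix):
        names = X.feature_names
        values = X.values
        if y is None:
            y = X.y
    else:
        values = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(values.shape[1])]
    y = np.asarray(y)
    d = values.shape[1]
    if d < 2:
        raise ValueError("selection needs at least two features")
    if criterion is None:
        criterion = _lda_cv_criterion(y, k_inner, seed)

    current = list(range(d))
    removed: list[int] = []
    j_cur = criterion(values[:, current])
    trace = [(len(current), j_cur)]

    while len(current) > min_features:
        # exclusion: best single removal
        best_j, best_f = -np.inf, None
        for f in current:
            sub = [g for g in current if g != f]
            j_try = criterion(values[:, sub])
            if j_try > best_j:
                best_j, best_f = j_try, f
        if best_j <= j_cur:
            break
        current.remove(best_f)
        removed.append(best_f)
        j_cur = best_j
        trace.append((len(current), j_cur))

        if floating:
            # conditional inclusion of earlier-removed features
            improved = True
            while improved and len(removed) > 1:
                improved = False
                best_j_add, best_g = j_cur, None
                for g in removed:
                    if g == best_f:  # never re-admit the one just removed
                        continue
                    j_try = criterion(values[:, sorted(current + [g])])
                    if j_try > best_j_add:
                        best_j_add, best_g = j_try, g
                if best_g is not None:
                    removed.remove(best_g)
                    current = sorted(current + [best_g])
                    j_cur = best_j_add
                    trace.append((len(current), j_cur))
                    improved = True

    return SelectionResult(selected=[names[i] for i in current], trace=trace)


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosting on a randomly undersampled (class-balanced) training set.

    AdaBoost fitted after the majority class is randomly undersampled to
    the minority class size, the core idea of random-undersampling
    boosting for imbalanced data.
    """

    def __init__(self, n_estimators: int = 50, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        keep = np.concatenate(
            [
                rng.choice(np.nonzero(y == c)[0], size=n_min, replace=False)
                for c in classes
            ]
        )
        keep.sort()
        self.estimator_ = AdaBoostClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        )
        self.estimator_.fit(X[keep], y[keep])
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X):
        return self.estimator_.predict(X)


def _make_classifier(name, n_train: int, seed: int, **params):
    if not isinstance(name, str):  # a ready sklearn-style estimator
        return clone(name)
    if name == "LSVM":
        return SVC(kernel="linear", **{"C": 1.0, **params})
    if name == "RBFSVM":
        return SVC(kernel="rbf", **{"C": 1.0, "gamma": "scale", **params})
    if name == "LR":
        return LogisticRegression(**{"max_iter": 2000, "random_state": seed,
                                     **params})
    if name == "KNN":
        return KNeighborsClassifier(
            **{"n_neighbors": min(5, n_train), **params})
    if name == "DT":
        return DecisionTreeClassifier(**{"random_state": seed, **params})
    if name == "NB":
        return GaussianNB(**params)
    if name == "GB":
        return GradientBoostingClassifier(**{"random_state": seed, **params})
    if name == "RB":
        return RUSBoostClassifier(**{"random_state": seed, **params})
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def train_classifier(name, X: np.ndarray, y: np.ndarray, seed: int = 0,
                     **params):
    """Train one of the eight classifier families on z-scored features.

    ``name`` may also be a ready scikit-learn estimator, which is cloned
    and fitted as-is; ``params`` override the family's fixed defaults.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data contain a single class")
    model = _make_classifier(name, X.shape[0], seed, **params)
    return model.fit(X, y)


def predict(model, X: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(X))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with MCI as the positive class."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FN + other.FN,
            self.FP + other.FP,
            self.TN + other.TN,
        )


@dataclass(frozen=True)
class MetricReport:
    """AC/SE/SP/F1/FDR as percentages in [0, 100] (FDR may be NaN)."""

    AC: float
    SE: float
    SP: float
    F1: float
    FDR: float

    def as_dict(self) -> dict[str, float]:
        return {"AC": self.AC, "SE": self.SE, "SP": self.SP,
                "F1": self.F1, "FDR": self.FDR}

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Values rounded for display, matching one-decimal reporting."""
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str = Label.MCI
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
    )


def confusion_metrics(
    c: ConfusionCounts, fdr_mode: str = "reported"
) -> MetricReport:
    """The five evaluation metrics from confusion counts, in percent.

    ``fdr_mode='reported'`` computes FDR = FP/(FP+TP), the conventional
    false-discovery rate; ``'eq27'`` computes FP/(FP+TN) instead.  With no
    positive predictions the reported-mode FDR is undefined (NaN).
    """
    if c.TP + c.FN == 0 or c.FP + c.TN == 0:
        raise ValueError(
            f"metrics undefined: need both true classes present, got {c}"
        )
    total = c.TP + c.FN + c.FP + c.TN
    ac = 100.0 * (c.TP + c.TN) / total
    se = 100.0 * c.TP / (c.TP + c.FN)
    sp = 100.0 * c.TN / (c.FP + c.TN)
    f1 = 100.0 * 2 * c.TP / (2 * c.TP + c.FP + c.FN) if c.TP + c.FP + c.FN else 100.0
    if fdr_mode == "reported":
        if c.FP + c.TP == 0:
            warnings.warn("no positive predictions: FDR undefined", stacklevel=2)
            fdr = float("nan")
        else:
            fdr = 100.0 * c.FP / (c.FP + c.TP)
    elif fdr_mode == "eq27":
        fdr = 100.0 * c.FP / (c.FP + c.TN)
    else:
        raise ValueError("fdr_mode must be 'reported' or 'eq27'")
    return MetricReport(AC=ac, SE=se, SP=sp, F1=f1, FDR=fdr)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineSpec:
    """What happens inside each training fold."""

    classifier: str = "LSVM"
    select: bool = False
    floating: bool = True
    k_inner: int = 10
    min_features: int = 1
    fdr_mode: str = "reported"


@dataclass
class FittedFold:
    """Scaler statistics, selected columns and model fitted on one fold."""

    stats: ZScoreStats
    selected_idx: list[int]
    model: object
    selection: SelectionResult | None = None

    def state_hash(self) -> str:
        """Digest of the training-derived state (for leakage audits)."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.stats.mean).tobytes())
        h.update(np.ascontiguousarray(self.stats.sd).tobytes())
        h.update(np.asarray(self.selected_idx, dtype=np.int64).tobytes())
        return h.hexdigest()


def fit_fold(
    fm: FeatureMatrix,
    train_idx: np.ndarray,
    spec: PipelineSpec = PipelineSpec(),
    seed: int = 0,
) -> FittedFold:
    """Fit scaler, (optional) SBFS and classifier on training rows only."""
    train = fm.rows(train_idx)
    stats = zscore_fit(train)
    z_train = zscore_apply(stats, train.values)
    selection = None
    if spec.select:
        selection = sbfs(
            FeatureMatrix(z_train, fm.feature_names,
                          train.subject_ids, train.labels),
            floating=spec.floating,
            seed=seed,
            k_inner=spec.k_inner,
            min_features=spec.min_features,
        )
        selected_idx = [fm.feature_names.index(n) for n in selection.selected]
    else:
        selected_idx = list(range(len(fm.feature_names)))
    cols = np.asarray(selected_idx)
    model = train_classifier(spec.classifier, z_train[:, cols], train.y, seed)
    return FittedFold(stats=stats, selected_idx=selected_idx,
                      model=model, selection=selection)


def _predict_fold(fold: FittedFold, fm: FeatureMatrix, idx: np.ndarray):
    z = zscore_apply(fold.stats, fm.values[idx])
    return predict(fold.model, z[:, np.asarray(fold.selected_idx)])


@dataclass
class CVResult:
    """Per-fold metric reports plus the fitted-state audit trail."""

    fold_reports: list[MetricReport]
    fold_counts: list[ConfusionCounts]
    fold_test_idx: list[np.ndarray]
    fold_hashes: list[str]
    fold_selected: list[list[str]]

    def summary(self) -> dict[str, tuple[float, float]]:
        """(mean, sample sd) of each metric over folds, NaN-aware."""
        out = {}
        for key in ("AC", "SE", "SP", "F1", "FDR"):
            vals = np.array([r.as_dict()[key] for r in self.fold_reports])
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                out[key] = (float("nan"), float("nan"))
                continue
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            out[key] = (float(vals.mean()), sd)
        return out


def kfold_cv(
    fm: FeatureMatrix,
    k: int = 10,
    spec: PipelineSpec = PipelineSpec(),
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV with fold-internal scaling and selection.

    Every sample is tested exactly once; the scaler and the selected
    subset are refitted from scratch on each training fold.
    """
    y = fm.y
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("cross-validation needs two classes")
    if k < 2 or k > counts.min():
        raise ValueError(
            f"k={k} incompatible with smallest class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports, countses, test_sets, hashes, selected = [], [], [], [], []
    for tr, te in skf.split(np.zeros(y.size), y):
        fold = fit_fold(fm, tr, spec, seed)
        y_pred = _predict_fold(fold, fm, te)
        counts_f = confusion_from_labels(y[te], y_pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports.append(confusion_metrics(counts_f, spec.fdr_mode))
        countses.append(counts_f)
        test_sets.append(te)
        hashes.append(fold.state_hash())
        selected.append([fm.feature_names[i] for i in fold.selected_idx])
    return CVResult(reports, countses, test_sets, hashes, selected)


@dataclass
class LOPOResult:
    counts: ConfusionCounts
    subject_ids: list[str]
    y_true: list[str]
    y_pred: list[str]


def lopo_cv_features(
    fm: FeatureMatrix,
    spec: PipelineSpec = PipelineSpec(),
    seed: int = 0,
) -> LOPOResult:
    """Leave-one-participant-out CV on a one-row-per-subject feature matrix."""
    if len(set(fm.subject_ids)) != fm.n_samples:
        raise ValueError("duplicate subject_ids: need one row per participant")
    y = fm.y
    total = ConfusionCounts(0, 0, 0, 0)
    y_pred_all = []
    for i in range(fm.n_samples):
        train_idx = np.asarray([j for j in range(fm.n_samples) if j != i])
        fold = fit_fold(fm, train_idx, spec, seed)
        y_pred = _predict_fold(fold, fm, np.asarray([i]))
        y_pred_all.append(str(y_pred[0]))
        pos = y[i] == Label.MCI
        hit = y_pred[0] == y[i]
        total = total + ConfusionCounts(
            TP=int(pos and hit),
            FN=int(pos and not hit),
            FP=int(not pos and not hit),
            TN=int(not pos and hit),
        )
    return LOPOResult(
        counts=total,
        subject_ids=list(fm.subject_ids),
        y_true=list(y),
        y_pred=y_pred_all,
    )


def lopo_cv(
    recordings: list[EEGRecording],
    spec: PipelineSpec = PipelineSpec(),
    sets: tuple[str, ...] = FEATURE_SET_ORDER,
    seed: int = 0,
    **extract_kwargs,
) -> LOPOResult:
    """Leave-one-participant-out CV from whole (unsegmented) recordings.

    Features are extracted once per full recording (no segmentation, so no
    subject contributes samples to both sides of any split), then each
    participant is held out in turn.
    """
    ids = [r.subject_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_ids across recordings")
    fm = assemble_features(recordings, sets=sets, **extract_kwargs)
    return lopo_cv_features(fm, spec, seed)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def ttest_features(
    fm: FeatureMatrix,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sample t-test (MCI vs HC) per feature; columns feature, t, p."""
    y = fm.y
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("t-tests need exactly two groups")
    names = features if features is not None else fm.feature_names
    sub = fm.select(list(names))
    a = sub.values[y == classes[0]]
    b = sub.values[y == classes[1]]
    if min(a.shape[0], b.shape[0]) < 2:
        raise ValueError("each group needs at least two samples")
    t, p = sstats.ttest_ind(a, b, axis=0)
    return pd.DataFrame({"feature": list(names), "t": t, "p": p})


def rank_connectivity(ttable: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Top-k rows by ascending p; ties break alphabetically by feature."""
    if ttable.empty:
        raise ValueError("empty t-test table")
    if top_k > len(ttable):
        warnings.warn(
            f"top_k={top_k} exceeds table size {len(ttable)}; returning all",
            stacklevel=2,
        )
        top_k = len(ttable)
    ranked = ttable.sort_values(["p", "feature"], kind="mergesort")
    return ranked.head(top_k).reset_index(drop=True)
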