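"""Random-forest core: normalisation, folds, confidence, tuning, nested CV.

The classifier is a bagged random forest whose prediction confidence is
the fraction of trees voting for the winning class. Hyperparameters are
tuned by Bayesian optimisation (Gaussian-process surrogate, expected-
improvement acquisition, 30 objective evaluations) inside a stratified
nested cross-validation: inner folds select hyperparameters, outer folds
give an unbiased accuracy estimate.

Min-max normalisation is fitted on labelled data only and then applied,
without clipping, to unlabelled and test rows — the normaliser is the
one place data leakage could silently occur, so its fit inputs are kept
explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold
from scipy.stats import norm

from ._seeds import derive, rng_for

__all__ = [
    "HyperParams",
    "SearchSpace",
    "DEFAULT_SPACE",
    "DEFAULT_HP",
    "Normaliser",
    "fit_minmax",
    "apply_minmax",
    "stratified_folds",
    "train_forest",
    "predict_with_confidence",
    "bayes_optimise",
    "maximise_expected_improvement",
    "nested_cv",
    "NestedCVResult",
]


# ---------------------------------------------------------------------------
# hyperparameters and search space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperParams:
    """Random-forest hyperparameters.

    ``max_samples_frac`` is the bootstrap sample size per tree as a
    fraction of the training rows; 1.0 means a full-size bootstrap.
    """

    n_trees: int = 100
    max_depth: int = 16
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    max_features: int = 4
    max_samples_frac: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_trees, self.max_depth, self.min_samples_split,
               self.min_samples_leaf, self.max_features) < 1:
            raise ValueError("hyperparameters must be positive")
        if self.min_samples_leaf > self.min_samples_split:
            raise ValueError("min_samples_leaf must not exceed min_samples_split")
        if not (0 < self.max_samples_frac <= 1):
            raise ValueError("max_samples_frac must lie in (0, 1]")


@dataclass(frozen=True)
class SearchSpace:
    """Inclusive box bounds for hyperparameter search.

    Defaults bracket the library defaults for a 12-feature problem.
    """

    n_trees: tuple[int, int] = (50, 500)
    max_depth: tuple[int, int] = (2, 32)
    min_samples_split: tuple[int, int] = (2, 20)
    min_samples_leaf: tuple[int, int] = (1, 10)
    max_features: tuple[int, int] = (1, 12)
    max_samples_frac: tuple[float, float] = (0.3, 1.0)

    def _dims(self):
        return (
            ("n_trees", *self.n_trees, int),
            ("max_depth", *self.max_depth, int),
            ("min_samples_split", *self.min_samples_split, int),
            ("min_samples_leaf", *self.min_samples_leaf, int),
            ("max_features", *self.max_features, int),
            ("max_samples_frac", *self.max_samples_frac, float),
        )

    def decode(self, u: np.ndarray) -> HyperParams:
        """Map a point in the unit cube to (rounded) hyperparameters."""
        kw = {}
        for (name, lo, hi, typ), ui in zip(self._dims(), u):
            val = lo + float(np.clip(ui, 0, 1)) * (hi - lo)
            kw[name] = int(round(val)) if typ is int else float(val)
        if kw["min_samples_leaf"] > kw["min_samples_split"]:
            kw["min_samples_leaf"] = kw["min_samples_split"]
        return HyperParams(**kw)

    def contains(self, hp: HyperParams) -> bool:
        for name, lo, hi, _ in self._dims():
            v = getattr(hp, name)
            if not (lo <= v <= hi):
                return False
        return True

    @property
    def is_point(self) -> bool:
        return all(lo == hi for _, lo, hi, _ in self._dims())


DEFAULT_SPACE = SearchSpace()
DEFAULT_HP = HyperParams()


# ---------------------------------------------------------------------------
# min-max normalisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Normaliser:
    """Per-feature min-max parameters learned from labelled data.

    Constant features (max == min) are flagged and map to 0.
    """

    mins: np.ndarray
    maxs: np.ndarray
    constant: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        span = np.where(self.constant, 1.0, self.maxs - self.mins)
        out = (X - self.mins) / span
        out[:, self.constant] = 0.0
        return out


def fit_minmax(X: np.ndarray) -> Normaliser:
    """Learn min-max parameters from the labelled feature matrix only."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("expected a non-empty 2-D feature matrix")
    mins, maxs = X.min(axis=0), X.max(axis=0)
    constant = maxs == mins
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); mapped to 0", stacklevel=2
        )
    return Normaliser(mins=mins, maxs=maxs, constant=constant)


def apply_minmax(norm_: Normaliser, X: np.ndarray) -> np.ndarray:
    """Apply saved parameters; unseen rows may fall outside [0, 1] (no clip)."""
    return norm_.transform(np.atleast_2d(X))


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Grade-stratified k-fold partition as (train_idx, test_idx) pairs.

    If the smallest class has fewer than ``k`` members, k is lowered to
    that count (with a warning) so every fold still sees every class.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    smallest = int(min(np.unique(labels, return_counts=True)[1]))
    if smallest < k:
        warnings.warn(
            f"smallest class has {smallest} members; lowering k from {k}",
            stacklevel=2,
        )
        k = max(2, smallest)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=derive(seed, "folds"))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# forest + vote-fraction confidence
# ---------------------------------------------------------------------------

def train_forest(
    X: np.ndarray, y: np.ndarray, hp: HyperParams = DEFAULT_HP, seed: int = 0
) -> RandomForestClassifier:
    """Fit a bagged random forest with the given hyperparameters."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n, p = np.asarray(X).shape
    model = RandomForestClassifier(
        n_estimators=hp.n_trees,
        max_depth=hp.max_depth,
        min_samples_split=hp.min_samples_split,
        min_samples_leaf=hp.min_samples_leaf,
        max_features=min(hp.max_features, p),
        max_samples=None if hp.max_samples_frac >= 1.0 else hp.max_samples_frac,
        bootstrap=True,
        random_state=derive(seed, "forest"),
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def predict_with_confidence(
    model: RandomForestClassifier, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Plurality label and its vote fraction for each row.

    Confidence is the share of trees voting for the winning class, so it
    is always at least 1/n_classes. Vote ties break toward the
    lower-indexed class.
    """
    X = np.atleast_2d(X)
    votes = np.stack([est.predict(X) for est in model.estimators_])  # trees x rows
    votes = votes.astype(int)
    n_classes = len(model.classes_)
    counts = np.apply_along_axis(
        lambda col: np.bincount(col, minlength=n_classes), 0, votes
    )  # classes x rows
    best = counts.argmax(axis=0)
    conf = counts[best, np.arange(X.shape[0])] / votes.shape[0]
    return model.classes_[best], conf


# ---------------------------------------------------------------------------
# Bayesian optimisation (GP surrogate + expected improvement)
# ---------------------------------------------------------------------------

def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    hp: HyperParams,
    plan: list[tuple[np.ndarray, np.ndarray]],
    seed: int,
) -> float:
    accs = []
    for i, (tr, te) in enumerate(plan):
        model = train_forest(X[tr], y[tr], hp, seed=derive(seed, "cvfit", i))
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def maximise_expected_improvement(
    objective,
    ndim: int,
    n_iter: int = 30,
    seed: int = 0,
    n_initial: int = 8,
    n_candidates: int = 256,
) -> tuple[np.ndarray, float]:
    """Maximise a black-box objective over the unit cube by GP + EI.

    Starting points are random; after ``n_initial`` of them a
    Matern-kernel Gaussian process is refitted each step and the next
    evaluation maximises expected improvement over random candidates.
    Exactly ``n_iter`` objective evaluations are spent. Returns the best
    evaluated point and its objective value.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    rng = rng_for(seed, "bayes")
    evaluated: list[np.ndarray] = []
    scores: list[float] = []

    n_initial = min(n_initial, n_iter)
    for _ in range(n_initial):
        u = rng.uniform(size=ndim)
        evaluated.append(u)
        scores.append(float(objective(u)))

    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5, length_scale=np.full(ndim, 0.3)),
        alpha=1e-4,
        normalize_y=True,
        random_state=derive(seed, "gp"),
    )
    for _ in range(n_iter - n_initial):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.array(evaluated), -np.array(scores))  # GP minimises
        cand = rng.uniform(size=(n_candidates, ndim))
        mu, sd = gp.predict(cand, return_std=True)
        best_so_far = -max(scores)
        sd = np.maximum(sd, 1e-9)
        z = (best_so_far - mu) / sd
        ei = (best_so_far - mu) * norm.cdf(z) + sd * norm.pdf(z)
        u = cand[int(np.argmax(ei))]
        evaluated.append(u)
        scores.append(float(objective(u)))

    best = int(np.argmax(scores))
    return evaluated[best], scores[best]


def bayes_optimise(
    X: np.ndarray,
    y: np.ndarray,
    inner_plan: list[tuple[np.ndarray, np.ndarray]] | None = None,
    n_iter: int = 30,
    seed: int = 0,
    space: SearchSpace = DEFAULT_SPACE,
    n_initial: int = 8,
    inner_k: int = 10,
) -> HyperParams:
    """Tune forest hyperparameters by GP-based Bayesian optimisation.

    The objective is mean inner-CV accuracy, maximised with
    :func:`maximise_expected_improvement` over a continuous relaxation
    of the search box; integer hyperparameters are rounded at
    evaluation. A single-point space is evaluated once and returned.
    """
    if inner_plan is None:
        inner_plan = stratified_folds(y, k=inner_k, seed=derive(seed, "inner"))

    if space.is_point:
        hp = space.decode(np.zeros(6))
        _cv_accuracy(X, y, hp, inner_plan, seed)
        return hp

    def objective(u: np.ndarray) -> float:
        return _cv_accuracy(X, y, space.decode(u), inner_plan, seed)

    best_u, _ = maximise_expected_improvement(
        objective, ndim=6, n_iter=n_iter, seed=seed, n_initial=n_initial
    )
    return space.decode(best_u)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class NestedCVResult:
    """Outer-fold accuracies, their mean/std, and the per-fold winners."""

    fold_accuracies: list[float]
    fold_hyperparams: list[HyperParams]
    mean_accuracy: float = field(init=False)
    std_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_accuracy = float(np.mean(self.fold_accuracies))
        self.std_accuracy = float(np.std(self.fold_accuracies))


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    outer_k: int = 10,
    inner_k: int = 10,
    n_iter: int = 30,
    seed: int = 0,
    space: SearchSpace = DEFAULT_SPACE,
) -> NestedCVResult:
    """Stratified nested cross-validation of the tuned forest.

    For each outer fold: normalise on the outer-training rows, tune on
    inner folds of those rows, retrain on all of them with the winning
    hyperparameters, then score once on the withheld fold. The withheld
    fold never influences normalisation or tuning.
    """
    X, y = np.asarray(X, dtype=np.float64), np.asarray(y)
    accs: list[float] = []
    hps: list[HyperParams] = []
    for i, (tr, te) in enumerate(stratified_folds(y, outer_k, derive(seed, "outer"))):
        assert len(np.intersect1d(tr, te)) == 0
        norm_ = fit_minmax(X[tr])
        Xtr, Xte = apply_minmax(norm_, X[tr]), apply_minmax(norm_, X[te])
        inner = stratified_folds(y[tr], inner_k, derive(seed, "inner", i))
        hp = bayes_optimise(
            Xtr, y[tr], inner_plan=inner, n_iter=n_iter,
            seed=derive(seed, "bayes", i), space=space,
        )
        model = train_forest(Xtr, y[tr], hp, seed=derive(seed, "refit", i))
        accs.append(float(np.mean(model.predict(Xte) == y[te])))
        hps.append(hp)
    return NestedCVResult(fold_accuracies=accs, fold_hyperparams=hps)
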