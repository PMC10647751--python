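"""Supervised, self-training and active-learning strategies.

All three strategies share one training core (min-max normalisation
fitted on the labelled pool, optional Bayesian hyperparameter tuning,
random-forest fit) and differ only in how the labelled pool grows:

* supervised — the seed labels are all there is;
* self-training (semi-supervised) — each round, the single most
  confident unlabelled prediction per class is promoted to a label if
  its vote-fraction confidence exceeds the confidence limit; promoted
  rows carry the model's own prediction, not the hidden truth;
* active learning (uncertainty sampling) — each round, the least
  confident unlabelled prediction per class is sent to the expert
  oracle if its confidence falls below the limit; queried rows carry
  the oracle's answer and each query costs labelling time.

Both loops stop when the pool empties or no candidate crosses the
limit. Because plurality vote fractions are never below 1/n_classes, an
active-learning limit at or below 1/n_classes can never trigger a query
and the run collapses exactly onto the supervised baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive, rng_for
from .image_features import FeatureRecord
from .model_core import (
    DEFAULT_HP,
    DEFAULT_SPACE,
    HyperParams,
    Normaliser,
    SearchSpace,
    apply_minmax,
    bayes_optimise,
    fit_minmax,
    predict_with_confidence,
    stratified_folds,
    train_forest,
)
from .synthetic_data import SimulatedOracle, OracleAccount

__all__ = [
    "DatasetSplit",
    "LoopConfig",
    "IterationRecord",
    "LoopTrace",
    "SupervisedResult",
    "LoopResult",
    "make_split",
    "run_supervised",
    "run_ssl",
    "run_active",
    "CONFIDENCE_LIMITS",
]

#: The five preset confidence limits explored in the study design.
CONFIDENCE_LIMITS = (0.10, 0.25, 0.50, 0.75, 0.90)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    """Labelled pool / unlabelled pool / test set over one feature matrix.

    ``y_true`` holds every row's hidden grade; the learner may only read
    it through ``labelled_y`` (and the oracle). ``provenance`` records,
    per labelled row, whether its label came with the seed data, from
    the oracle, or is a model pseudo-label.
    """

    X: np.ndarray
    y_true: np.ndarray
    labelled_idx: np.ndarray
    labelled_y: np.ndarray
    unlabelled_idx: np.ndarray
    test_idx: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        pools = [self.labelled_idx, self.unlabelled_idx, self.test_idx]
        total = sum(len(p) for p in pools)
        union = np.union1d(np.union1d(pools[0], pools[1]), pools[2])
        if len(union) != total:
            raise ValueError("labelled/unlabelled/test pools overlap")
        if len(self.labelled_y) != len(self.labelled_idx):
            raise ValueError("labelled_y out of step with labelled_idx")
        if len(self.provenance) != len(self.labelled_idx):
            raise ValueError("provenance out of step with labelled pool")

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.y_true))

    def copy(self) -> "DatasetSplit":
        return DatasetSplit(
            X=self.X,
            y_true=self.y_true,
            labelled_idx=self.labelled_idx.copy(),
            labelled_y=self.labelled_y.copy(),
            unlabelled_idx=self.unlabelled_idx.copy(),
            test_idx=self.test_idx.copy(),
            provenance=list(self.provenance),
        )


def _apportion(counts: np.ndarray, ratio: float) -> np.ndarray:
    """Largest-remainder split so the labelled total is round(ratio*total)."""
    quota = counts * ratio
    base = np.floor(quota).astype(int)
    short = int(round(counts.sum() * ratio)) - base.sum()
    order = np.argsort(-(quota - base))
    for i in range(abs(short)):
        base[order[i % len(base)]] += 1 if short > 0 else -1
    return np.clip(base, 0, counts)


def make_split(
    records: list[FeatureRecord] | tuple[np.ndarray, np.ndarray],
    seed_ratio: int,
    test: float | np.ndarray = 0.25,
    seed: int = 0,
) -> DatasetSplit:
    """Partition data into test set and labelled/unlabelled training pools.

    ``seed_ratio`` is the labelled percentage of the training partition
    (the study scanned 10..90). ``test`` is either a held-out fraction
    (grade-stratified) or an explicit index array, so several runs can
    share one test plan. Both partitions are stratified by grade; at
    very low ratios a grade can end up with no labelled rows, which is
    warned about but allowed.
    """
    if not (1 <= seed_ratio <= 99):
        raise ValueError("seed_ratio must be a percentage in [1, 99]")
    if isinstance(records, tuple):
        X, y = np.asarray(records[0], float), np.asarray(records[1])
    else:
        X = np.stack([r.values for r in records])
        y = np.array([r.grade for r in records])
        if any(g is None for g in (r.grade for r in records)):
            raise ValueError("all records need a true grade to build a split")
    rng = rng_for(seed, "split")

    if isinstance(test, (float, int)) and not isinstance(test, bool) and np.ndim(test) == 0:
        frac = float(test)
        classes, counts = np.unique(y, return_counts=True)
        n_test = _apportion(counts, frac)
        test_idx = []
        for cls, n_t in zip(classes, n_test):
            members = np.flatnonzero(y == cls)
            test_idx.append(rng.permutation(members)[:n_t])
        test_idx = np.sort(np.concatenate(test_idx))
    else:
        test_idx = np.sort(np.asarray(test, dtype=int))

    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    classes, counts = np.unique(y[train_idx], return_counts=True)
    n_lab = _apportion(counts, seed_ratio / 100.0)
    labelled, unlabelled = [], []
    for cls, n_l in zip(classes, n_lab):
        members = train_idx[y[train_idx] == cls]
        perm = rng.permutation(members)
        labelled.append(perm[:n_l])
        unlabelled.append(perm[n_l:])
        if n_l == 0:
            warnings.warn(
                f"grade {cls} has no labelled rows at ratio {seed_ratio}%",
                stacklevel=2,
            )
    labelled_idx = np.sort(np.concatenate(labelled))
    unlabelled_idx = np.sort(np.concatenate(unlabelled))
    return DatasetSplit(
        X=X,
        y_true=y,
        labelled_idx=labelled_idx,
        labelled_y=y[labelled_idx].copy(),
        unlabelled_idx=unlabelled_idx,
        test_idx=test_idx,
        provenance=["seed"] * len(labelled_idx),
    )


# ---------------------------------------------------------------------------
# loop configuration and traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopConfig:
    """Training configuration shared by the three strategies.

    With ``optimise=False`` the fixed ``hp`` is used throughout (fast
    path); with ``optimise=True`` Bayesian tuning runs before the first
    fit and again every ``reoptimise_every``-th loop iteration, the
    study's per-iteration re-tuning being ``reoptimise_every=1``.
    ``ssl_promote_all=True`` switches self-training from one point per
    class to every point above the limit.
    """

    hp: HyperParams = DEFAULT_HP
    optimise: bool = False
    n_iter: int = 30
    inner_k: int = 10
    reoptimise_every: int = 1
    space: SearchSpace = DEFAULT_SPACE
    seed: int = 0
    ssl_promote_all: bool = False
    record_interim: bool = False


@dataclass
class IterationRecord:
    """One loop iteration: pool size before/after, what moved and why."""

    iteration: int
    n_labelled: int
    moved: int
    cumulative_queries: int
    selected_confidence: dict[int, float]
    interim_accuracy: float | None = None


@dataclass
class LoopTrace:
    iterations: list[IterationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iterations)


@dataclass
class SupervisedResult:
    accuracy: float
    model: object
    normaliser: Normaliser
    hp: HyperParams
    n_labelled_used: int


@dataclass
class LoopResult:
    accuracy: float
    trace: LoopTrace
    model: object
    final_split: DatasetSplit
    n_labelled_used: int
    account: OracleAccount | None = None


# ---------------------------------------------------------------------------
# shared training core
# ---------------------------------------------------------------------------

def _fit_iteration(split: DatasetSplit, config: LoopConfig, it: int, hp: HyperParams):
    """Normalise on the labelled pool, optionally re-tune, fit the forest."""
    X_lab = split.X[split.labelled_idx]
    y_lab = split.labelled_y
    norm_ = fit_minmax(X_lab)
    Xn = apply_minmax(norm_, X_lab)
    if config.optimise and it % config.reoptimise_every == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inner = stratified_folds(
                y_lab, config.inner_k, derive(config.seed, "inner", it)
            )
            hp = bayes_optimise(
                Xn,
                y_lab,
                inner_plan=inner,
                n_iter=config.n_iter,
                seed=derive(config.seed, "bayes", it),
                space=config.space,
            )
    model = train_forest(Xn, y_lab, hp, seed=derive(config.seed, "fit", it))
    return model, norm_, hp


def _test_accuracy(split: DatasetSplit, model, norm_: Normaliser) -> float:
    Xte = apply_minmax(norm_, split.X[split.test_idx])
    return float(np.mean(model.predict(Xte) == split.y_true[split.test_idx]))


def run_supervised(split: DatasetSplit, config: LoopConfig = LoopConfig()) -> SupervisedResult:
    """Train once on the labelled pool and score on the test set.

    The unlabelled pool is never read.
    """
    if len(split.labelled_idx) == 0:
        raise ValueError("labelled pool is empty")
    model, norm_, hp = _fit_iteration(split, config, it=0, hp=config.hp)
    return SupervisedResult(
        accuracy=_test_accuracy(split, model, norm_),
        model=model,
        normaliser=norm_,
        hp=hp,
        n_labelled_used=len(split.labelled_idx),
    )


# ---------------------------------------------------------------------------
# the two loops
# ---------------------------------------------------------------------------

def _select_per_class(
    model, conf: np.ndarray, pred: np.ndarray, lowest: bool
) -> dict[int, int]:
    """Per predicted class, the position of the extreme-confidence row.

    ``lowest=False`` picks the most confident (self-training);
    ``lowest=True`` the least confident (uncertainty sampling). Ties
    break toward the lowest row position, i.e. the lowest original
    index, since pools are kept sorted.
    """
    chosen: dict[int, int] = {}
    for cls in model.classes_:
        rows = np.flatnonzero(pred == cls)
        if len(rows) == 0:
            continue
        c = conf[rows]
        pos = rows[np.argmin(c) if lowest else np.argmax(c)]
        chosen[int(cls)] = int(pos)
    return chosen


def _run_loop(
    split: DatasetSplit,
    confidence_limit: float,
    config: LoopConfig,
    oracle: SimulatedOracle | None,
) -> LoopResult:
    """Shared loop body; oracle=None means self-training."""
    if not (0 < confidence_limit <= 1):
        raise ValueError("confidence limit must lie in (0, 1]")
    work = split.copy()
    total0 = len(work.labelled_idx) + len(work.unlabelled_idx) + len(work.test_idx)
    active = oracle is not None
    trace = LoopTrace()
    max_rounds = len(work.unlabelled_idx) + 1
    model = norm_ = None
    hp = config.hp
    for it in range(max_rounds + 1):
        model, norm_, hp = _fit_iteration(work, config, it, hp)
        if len(work.unlabelled_idx) == 0:
            break
        Xu = apply_minmax(norm_, work.X[work.unlabelled_idx])
        pred, conf = predict_with_confidence(model, Xu)
        chosen = _select_per_class(model, conf, pred, lowest=active)
        move_pos: list[int] = []
        move_lab: list[int] = []
        selected_conf: dict[int, float] = {}
        for cls, pos in sorted(chosen.items()):
            selected_conf[cls] = float(conf[pos])
            if active:
                if conf[pos] < confidence_limit:
                    move_pos.append(pos)
                    move_lab.append(oracle.label(int(work.y_true[work.unlabelled_idx[pos]])))
            else:
                if conf[pos] > confidence_limit:
                    move_pos.append(pos)
                    move_lab.append(int(pred[pos]))
        if not active and config.ssl_promote_all:
            extra = np.flatnonzero(conf > confidence_limit)
            for pos in extra:
                if pos not in move_pos:
                    move_pos.append(int(pos))
                    move_lab.append(int(pred[pos]))
        interim = _test_accuracy(work, model, norm_) if config.record_interim else None
        trace.iterations.append(
            IterationRecord(
                iteration=it,
                n_labelled=len(work.labelled_idx),
                moved=len(move_pos),
                cumulative_queries=oracle.account.queries if active else 0,
                selected_confidence=selected_conf,
                interim_accuracy=interim,
            )
        )
        if not move_pos:
            break
        moved_idx = work.unlabelled_idx[move_pos]
        keep = np.setdiff1d(np.arange(len(work.unlabelled_idx)), move_pos)
        work.unlabelled_idx = work.unlabelled_idx[keep]
        order = np.argsort(np.concatenate([work.labelled_idx, moved_idx]))
        new_idx = np.concatenate([work.labelled_idx, moved_idx])[order]
        new_y = np.concatenate([work.labelled_y, move_lab])[order]
        tag = "oracle" if active else "pseudo"
        new_prov = [
            p for _, p in sorted(
                zip(
                    np.concatenate([work.labelled_idx, moved_idx]),
                    work.provenance + [tag] * len(moved_idx),
                ),
                key=lambda t: t[0],
            )
        ]
        work.labelled_idx, work.labelled_y, work.provenance = new_idx, new_y, new_prov
        work.check()
        assert len(work.labelled_idx) + len(work.unlabelled_idx) + len(work.test_idx) == total0
    return LoopResult(
        accuracy=_test_accuracy(work, model, norm_),
        trace=trace,
        model=model,
        final_split=work,
        n_labelled_used=len(work.labelled_idx),
        account=oracle.account if active else None,
    )


def run_ssl(
    split: DatasetSplit, confidence_limit: float, config: LoopConfig = LoopConfig()
) -> LoopResult:
    """Self-training: promote the most confident prediction per class.

    Promotion requires vote-fraction confidence strictly above the
    limit; promoted rows carry the model's predicted grade, never the
    hidden truth.
    """
    return _run_loop(split, confidence_limit, config, oracle=None)


def run_active(
    split: DatasetSplit,
    oracle: SimulatedOracle,
    confidence_limit: float,
    config: LoopConfig = LoopConfig(),
) -> LoopResult:
    """Uncertainty sampling: query the oracle on the least confident
    prediction per class when its confidence is strictly below the limit.

    Every query is charged to the oracle's time account. Limits at or
    below 1/n_classes can never trigger a query, reproducing the
    supervised baseline exactly.
    """
    return _run_loop(split, confidence_limit, config, oracle=oracle)
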