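"""Dropout-regularized combination classifier.

The development procedure, designed for the p >> n regime of mass-spectral
feature tables:

1. the development set is split many times into stratified training and test
   halves ("realizations");
2. within each realization, many small k-nearest-neighbour "atomic"
   classifiers are built on single attributes and attribute pairs;
3. atomics that cannot classify the training set (per-class leave-one-out
   accuracy below a floor) or that misclassify healthy-donor spectra as
   "Cancer" (the confounder-mitigation constraint) are filtered out;
4. the survivors are combined by dropout-regularized logistic regression:
   the logistic fit is repeated on many random "leave-in" subsets of the
   atomics, and the per-draw coefficients are averaged (atomics absent from
   a draw contribute zero), yielding one "master" classifier per realization;
5. a sample's development-set score is the average of the master outputs over
   exactly those realizations that held the sample out (out-of-bag), and a
   new sample's score is the average over all masters;
6. a threshold chosen on the development out-of-bag scores turns the score
   into the binary "Cancer" / "No Cancer" call, after which the model is
   locked.

Samples with a Poor pre-classifier call or AFP >= 100 ng/mL are assigned
"Cancer" up front and excluded from classifier training.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .afp import parse_afp

__all__ = [
    "TrainConfig",
    "AtomicClassifier",
    "FilterResult",
    "MasterClassifier",
    "CortexModel",
    "DevelopmentResult",
    "ContractError",
    "pre_assign_development",
    "make_realizations",
    "train_atomic",
    "filter_atomic",
    "combine_dropout",
    "oob_scores",
    "ensemble_score",
    "choose_threshold",
    "develop_test",
    "save_model",
    "load_model",
]

_EPS_STD = 1e-12


class ContractError(RuntimeError):
    """A locked-model or estimation contract was violated."""


@dataclass(frozen=True)
class TrainConfig:
    n_realizations: int = 300
    train_fraction: float = 0.5
    k_neighbors: int = 5
    max_subset_size: int = 2
    filter_min_accuracy: float = 0.60
    healthy_min_no_cancer_rate: float = 0.90
    dropout_leave_in: int = 10
    n_dropout_iterations: int = 10_000
    n_keep_features: int = 100
    ridge: float = 1e-4
    max_atomics: int = 6000
    afp_assign_cutoff: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.dropout_leave_in < 1:
            raise ValueError("dropout_leave_in must be >= 1")
        if self.k_neighbors % 2 == 0:
            raise ValueError("k_neighbors must be odd")


# ---------------------------------------------------------------------------
# pre-assignment
# ---------------------------------------------------------------------------

def pre_assign_development(
    samples: pd.DataFrame,
    *,
    afp_column: str = "afp",
    pre_column: str = "pre_label",
    afp_cutoff: float = 100.0,
) -> Tuple[List[str], List[str], List[str]]:
    """Partition the development set by the high-confidence cancer rules.

    Samples with a Poor pre-classifier call or AFP at or above ``afp_cutoff``
    ng/mL (censored ">=10,000" included) are assigned "Cancer" outright; the
    remainder feed classifier training.  Samples missing both the AFP value
    and the pre-classifier result are excluded and logged.

    Returns (assigned_cancer_ids, remaining_ids, excluded_ids).
    """
    assigned, remaining, excluded = [], [], []
    for sid, row in samples.iterrows():
        afp_raw = row.get(afp_column)
        pre = row.get(pre_column)
        have_afp = afp_raw is not None and not (isinstance(afp_raw, float) and math.isnan(afp_raw))
        have_pre = isinstance(pre, str) and pre in ("Good", "Poor")
        if not have_afp and not have_pre:
            excluded.append(str(sid))
            continue
        poor = have_pre and pre == "Poor"
        high_afp = have_afp and parse_afp(afp_raw).geq(afp_cutoff)
        (assigned if poor or high_afp else remaining).append(str(sid))
    return assigned, remaining, excluded


# ---------------------------------------------------------------------------
# realizations
# ---------------------------------------------------------------------------

def make_realizations(
    labels: pd.Series,
    config: TrainConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[List[str], List[str]]]:
    """Stratified train/test splits of the development pool.

    Every sample must land in at least one test set across the realizations;
    the whole batch of splits is redrawn until that holds.
    """
    y = labels.astype(bool)
    ids = np.asarray(y.index.astype(str))
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each class needs at least 2 samples to split")
    rng = rng or np.random.default_rng(config.seed)
    pos = ids[y.values]
    neg = ids[~y.values]
    n_pos_train = max(1, int(round(config.train_fraction * len(pos))))
    n_neg_train = max(1, int(round(config.train_fraction * len(neg))))
    n_pos_train = min(n_pos_train, len(pos) - 1)
    n_neg_train = min(n_neg_train, len(neg) - 1)

    for _ in range(100):
        splits = []
        tested: set = set()
        for _r in range(config.n_realizations):
            p = rng.permutation(pos)
            n = rng.permutation(neg)
            train = sorted(p[:n_pos_train].tolist() + n[:n_neg_train].tolist())
            test = sorted(p[n_pos_train:].tolist() + n[n_neg_train:].tolist())
            splits.append((train, test))
            tested.update(test)
        if tested == set(ids.tolist()):
            return splits
    # coverage can be impossible (e.g. a single realization); out-of-bag
    # scoring will still refuse to score any never-held-out sample
    warnings.warn("not every sample appears in a test set across realizations")
    return splits


# ---------------------------------------------------------------------------
# k-NN machinery (vectorised)
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std < _EPS_STD, 1.0, std)
    return (X - mean) / std, mean, std


def _attr_sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-attribute squared differences; shape (d, len(A), len(B))."""
    return (A.T[:, :, None] - B.T[:, None, :]) ** 2


def _knn_vote_rows(dist: np.ndarray, yf: np.ndarray, k: int) -> np.ndarray:
    """Mean label of the k nearest points for each row of ``dist`` (R, n).

    Ties in distance are broken by training-sample order.  The fast path
    uses ``argpartition``; rows with a distance tie straddling the k-th
    position fall back to a stable sort so the documented tie-break holds
    exactly.
    """
    n = dist.shape[-1]
    if k >= n:
        return np.full(dist.shape[:-1], yf.mean())
    idx = np.argpartition(dist, (k - 1, k), axis=-1)
    boundary = np.take_along_axis(dist, idx[..., k - 1 : k + 1], axis=-1)
    tied = boundary[..., 0] == boundary[..., 1]
    votes = yf[idx[..., :k]].mean(axis=-1)
    if np.any(tied):
        rows = np.nonzero(tied)
        order = np.argsort(dist[rows], axis=-1, kind="stable")[..., :k]
        votes[rows] = yf[order].mean(axis=-1)
    return votes


def _subset_votes(
    attr_d: np.ndarray,
    subsets: np.ndarray,
    y_train: np.ndarray,
    k: int,
    *,
    loo: bool = False,
    chunk: int = 256,
) -> np.ndarray:
    """k-NN Cancer-vote fractions for many attribute subsets at once.

    ``attr_d``: (d, q, n) per-attribute squared distances from q queries to
    n training points; ``subsets``: (S, m) attribute indices padded with -1.
    Distance ties are broken by training-sample order.
    Returns (S, q) vote fractions.
    """
    d, q, n = attr_d.shape
    # pad with a zero layer so -1 indexes contribute nothing
    padded = np.concatenate(
        [attr_d.astype(np.float32, copy=False), np.zeros((1, q, n), dtype=np.float32)],
        axis=0,
    )
    idx = np.where(subsets < 0, d, subsets)
    out = np.empty((len(subsets), q))
    # distances are reduced precision for speed; vote fractions stay exact
    yf = y_train.astype(np.float64)
    diag = np.arange(n)
    for s0 in range(0, len(subsets), chunk):
        sl = idx[s0 : s0 + chunk]
        dist = padded[sl[:, 0]].copy()
        for j in range(1, sl.shape[1]):
            dist += padded[sl[:, j]]
        if loo:
            dist[:, diag, diag] = np.inf
        out[s0 : s0 + chunk] = _knn_vote_rows(dist, yf, k)
    return out



# ---------------------------------------------------------------------------
# public atomic-classifier API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: Tuple[str, ...]
    accuracy_no_cancer: float
    accuracy_cancer: float
    healthy_no_cancer_rate: Optional[float]


@dataclass
class AtomicClassifier:
    """A k-NN classifier on a small attribute subset.

    References are stored standardized (z-scored with training statistics);
    queries are standardized with the same statistics.  Prediction is the
    majority vote of the k nearest references under Euclidean distance, ties
    in distance broken by training-sample order.
    """

    subset: Tuple[str, ...]
    k: int
    mean: np.ndarray
    std: np.ndarray
    refs: np.ndarray          # (n, m) standardized
    ref_labels: np.ndarray    # (n,) bool
    ref_ids: Tuple[str, ...]
    passed_filter: Optional[FilterResult] = None

    def _queries(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.loc[:, list(self.subset)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) / self.std

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of the k nearest references labelled Cancer."""
        Q = self._queries(X)
        d = ((Q[:, None, :] - self.refs[None, :, :]) ** 2).sum(axis=-1)
        order = np.argsort(d, axis=-1, kind="stable")[:, : self.k]
        return self.ref_labels.astype(float)[order].mean(axis=-1)

    def predict(self, X) -> np.ndarray:
        return self.vote_fraction(X) > 0.5

    def loo_vote_fractions(self) -> np.ndarray:
        """Leave-one-out votes on the training references themselves."""
        d = ((self.refs[:, None, :] - self.refs[None, :, :]) ** 2).sum(axis=-1)
        np.fill_diagonal(d, np.inf)
        order = np.argsort(d, axis=-1, kind="stable")[:, : self.k]
        return self.ref_labels.astype(float)[order].mean(axis=-1)


def train_atomic(
    train_data: pd.DataFrame,
    labels: pd.Series,
    subset: Sequence[str],
    k: int,
) -> AtomicClassifier:
    """Build one k-NN atomic classifier on ``subset`` of the attributes."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("attribute subset must be nonempty")
    y = labels.loc[train_data.index].astype(bool).to_numpy()
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    if k > len(train_data):
        raise ValueError(f"k={k} exceeds training size {len(train_data)}")
    X = train_data.loc[:, list(subset)].to_numpy(dtype=float)
    Z, mean, std = _standardize(X)
    return AtomicClassifier(
        subset=subset,
        k=k,
        mean=mean,
        std=std,
        refs=Z,
        ref_labels=y,
        ref_ids=tuple(str(i) for i in train_data.index),
    )


def filter_atomic(
    atomic: AtomicClassifier,
    healthy_data: Optional[pd.DataFrame],
    config: TrainConfig,
) -> FilterResult:
    """Apply the training-performance and healthy-sample filters.

    Pass requires (a) per-class leave-one-out training accuracy at or above
    ``filter_min_accuracy`` for *each* class and (b) at least
    ``healthy_min_no_cancer_rate`` of the healthy-donor spectra classified
    "No Cancer".  Failing is a valid outcome, not an error.
    """
    votes = atomic.loo_vote_fractions()
    pred = votes > 0.5
    y = atomic.ref_labels
    acc1 = float((pred[y] == True).mean())
    acc0 = float((pred[~y] == False).mean())
    reasons: List[str] = []
    if acc0 < config.filter_min_accuracy:
        reasons.append(f"No-Cancer training accuracy {acc0:.2f} below floor")
    if acc1 < config.filter_min_accuracy:
        reasons.append(f"Cancer training accuracy {acc1:.2f} below floor")
    healthy_rate: Optional[float] = None
    if config.healthy_min_no_cancer_rate > 0:
        if healthy_data is None or len(healthy_data) == 0:
            raise ValueError("healthy reference spectra required for filtering")
        healthy_rate = float((~atomic.predict(healthy_data)).mean())
        if healthy_rate < config.healthy_min_no_cancer_rate:
            reasons.append(f"healthy No-Cancer rate {healthy_rate:.2f} below floor")
    result = FilterResult(
        passed=not reasons,
        reasons=tuple(reasons),
        accuracy_no_cancer=acc0,
        accuracy_cancer=acc1,
        healthy_no_cancer_rate=healthy_rate,
    )
    atomic.passed_filter = result
    return result


# ---------------------------------------------------------------------------
# dropout-regularized logistic combination
# ---------------------------------------------------------------------------

def _logistic_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    z = np.einsum("dnm,dm->dn", X, w)
    # log(1 + e^z) - y z, numerically stable
    f = (np.logaddexp(0.0, z) - y[None, :] * z).sum(axis=1)
    return f + 0.5 * ridge * (w[:, 1:] ** 2).sum(axis=1)


def _fit_logistic_batched(
    X: np.ndarray, y: np.ndarray, ridge: float, *, max_iter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    """Damped-Newton logistic fits for a batch of designs.

    ``X``: (draws, n, m) including an intercept column at position 0; the
    intercept is not penalized.  Returns (draws, m) coefficients.
    """
    D, n, m = X.shape
    w = np.zeros((D, m))
    f = _logistic_objective(w, X, y, ridge)
    pen = ridge * np.eye(m)
    pen[0, 0] = 1e-12  # intercept unpenalized; epsilon for conditioning
    for _ in range(max_iter):
        z = np.einsum("dnm,dm->dn", X, w)
        p = 1.0 / (1.0 + np.exp(-z))
        grad = np.einsum("dnm,dn->dm", X, p - y[None, :])
        grad[:, 1:] += ridge * w[:, 1:]
        if np.max(np.abs(grad)) < tol:
            break
        W = np.clip(p * (1.0 - p), 1e-12, None)
        H = np.einsum("dnl,dn,dnm->dlm", X, W, X) + pen[None, :, :]
        delta = np.linalg.solve(H, grad[..., None])[..., 0]
        step = np.ones(D)
        w_new, f_new = w, f
        for _halve in range(25):
            w_new = w - step[:, None] * delta
            f_new = _logistic_objective(w_new, X, y, ridge)
            bad = f_new > f + 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        improved = f_new <= f + 1e-12
        w = np.where(improved[:, None], w_new, w)
        f = np.where(improved, f_new, f)
    return w


def _dropout_average_weights(
    votes: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, float]:
    """Average logistic weights over dropout draws.

    ``votes``: (n_train, P) atomic vote fractions.  Each draw fits a
    logistic regression on ``dropout_leave_in`` atomics sampled without
    replacement; the averaged weight of an atomic counts draws it was absent
    from as zero.  Returns (per-atomic averaged weights, averaged intercept).
    """
    n, P = votes.shape
    L = config.dropout_leave_in
    if L > P:
        warnings.warn(
            f"dropout_leave_in={L} exceeds {P} passing atomics; using all atomics"
        )
        L = P
    D = config.n_dropout_iterations
    if L == P:
        draw_idx = np.tile(np.arange(P), (D, 1))
    else:
        draw_idx = np.argsort(rng.random((D, P)), axis=1)[:, :L]
    Xd = votes[:, draw_idx]               # (n, D, L)
    Xd = np.moveaxis(Xd, 0, 1)            # (D, n, L)
    Xd = np.concatenate([np.ones((D, n, 1)), Xd], axis=2)
    coef = _fit_logistic_batched(Xd, y.astype(float), config.ridge)
    intercept = float(coef[:, 0].mean())
    weights = np.zeros(P)
    np.add.at(weights, draw_idx.ravel(), coef[:, 1:].ravel())
    return weights / D, intercept


# ---------------------------------------------------------------------------
# master classifier
# ---------------------------------------------------------------------------

@dataclass
class MasterClassifier:
    """One realization's classifier: filtered atomics + averaged logistic weights."""

    split_id: int
    attributes: Tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray
    train_X: np.ndarray        # standardized, (n_train, d)
    train_y: np.ndarray        # bool
    train_ids: Tuple[str, ...]
    test_ids: Tuple[str, ...]
    k: int
    subsets: np.ndarray        # (P, max_subset) attr indices, padded -1
    weights: np.ndarray        # (P,)
    intercept: float

    def __post_init__(self) -> None:
        if set(self.test_ids) & set(self.train_ids):
            raise ContractError("train and test ids overlap")
        if not np.all(np.isfinite(self.weights)) or not math.isfinite(self.intercept):
            raise ContractError("master weights must be finite")

    @property
    def n_atomics(self) -> int:
        return len(self.weights)

    def _votes(self, X_raw: np.ndarray) -> np.ndarray:
        Z = (X_raw - self.mean) / self.std
        attr_d = _attr_sq_dists(Z, self.train_X)
        return _subset_votes(attr_d, self.subsets, self.train_y, self.k)

    def predict_proba(self, X) -> np.ndarray:
        """Logistic output for each query row (full reference set)."""
        if isinstance(X, pd.DataFrame):
            X = X.loc[:, list(self.attributes)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.n_atomics == 0:
            z = np.full(len(X), self.intercept)
        else:
            votes = self._votes(X)  # (P, q)
            z = self.intercept + votes.T @ self.weights
        return 1.0 / (1.0 + np.exp(-z))


def combine_dropout(
    atomics: Sequence[AtomicClassifier],
    train_data: pd.DataFrame,
    labels: pd.Series,
    config: TrainConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    split_id: int = 0,
    test_ids: Sequence[str] = (),
) -> MasterClassifier:
    """Combine passing atomics into a master via dropout-regularized logistic
    regression.

    Regressors are the atomics' leave-one-out vote fractions on the training
    samples (a k-NN queried on a point in its own reference set would simply
    return that point's label).
    """
    if not atomics:
        raise ValueError("at least one passing atomic is required")
    rng = rng or np.random.default_rng(config.seed)
    y = labels.loc[train_data.index].astype(bool).to_numpy()
    votes = np.column_stack([a.loo_vote_fractions() for a in atomics])
    weights, intercept = _dropout_average_weights(votes, y, config, rng)

    attrs = tuple(train_data.columns.astype(str))
    attr_index = {a: i for i, a in enumerate(attrs)}
    max_m = max(len(a.subset) for a in atomics)
    subsets = np.full((len(atomics), max_m), -1, dtype=int)
    for i, a in enumerate(atomics):
        for j, name in enumerate(a.subset):
            subsets[i, j] = attr_index[name]
    X = train_data.to_numpy(dtype=float)
    Z, mean, std = _standardize(X)
    return MasterClassifier(
        split_id=split_id,
        attributes=attrs,
        mean=mean,
        std=std,
        train_X=Z,
        train_y=y,
        train_ids=tuple(str(i) for i in train_data.index),
        test_ids=tuple(str(i) for i in test_ids),
        k=atomics[0].k,
        subsets=subsets,
        weights=weights,
        intercept=intercept,
    )


# ---------------------------------------------------------------------------
# ensemble model
# ---------------------------------------------------------------------------

@dataclass
class CortexModel:
    masters: List[MasterClassifier]
    feature_subset: Tuple[str, ...]     # selected MS features + ln_afp
    threshold: float
    locked: bool = False
    config: TrainConfig = field(default_factory=TrainConfig)
    afp_assign_cutoff: float = 100.0
    pre_classifier_id: str = "surrogate"

    def lock(self) -> "CortexModel":
        self.locked = True
        return self


def oob_scores(masters: Sequence[MasterClassifier], dev_samples: pd.DataFrame) -> pd.Series:
    """Out-of-bag score: for each development sample, the mean output of
    exactly those masters that held it out.  Masters trained on the sample
    are never consulted."""
    ids = [str(i) for i in dev_samples.index]
    sums = {i: 0.0 for i in ids}
    counts = {i: 0 for i in ids}
    for m in masters:
        held = [i for i in m.test_ids if i in sums]
        if not held:
            continue
        proba = m.predict_proba(dev_samples.loc[held, list(m.attributes)])
        for i, p in zip(held, proba):
            sums[i] += float(p)
            counts[i] += 1
    missing = [i for i in ids if counts[i] == 0]
    if missing:
        raise ContractError(
            f"{len(missing)} sample(s) never held out; no out-of-bag estimate: {missing[:5]}"
        )
    return pd.Series({i: sums[i] / counts[i] for i in ids}, name="oob_score")


def ensemble_score(model: CortexModel, x) -> np.ndarray:
    """Final score for new samples: mean of all masters' outputs."""
    if isinstance(x, (pd.Series, dict)):
        x = pd.DataFrame([x])
    if isinstance(x, pd.DataFrame):
        missing = [a for a in model.feature_subset if a not in x.columns]
        if missing:
            raise ValueError(f"missing attributes: {missing[:5]}")
        X = x.loc[:, list(model.feature_subset)]
    else:
        X = pd.DataFrame(np.atleast_2d(x), columns=list(model.feature_subset))
    outputs = np.stack([m.predict_proba(X) for m in model.masters])
    return outputs.mean(axis=0)


def choose_threshold(
    scores: Sequence[float],
    labels: Sequence[bool],
    criterion: str = "youden",
    *,
    min_sensitivity: Optional[float] = None,
    min_specificity: Optional[float] = None,
) -> float:
    """Pick the score threshold from development out-of-bag data.

    ``"youden"`` maximizes sensitivity + specificity - 1; ``"balanced"``
    maximizes min(sensitivity, specificity) with their sum as tie-break;
    ``"sensitivity_floor"`` maximizes specificity subject to sensitivity >=
    ``min_sensitivity``; ``"specificity_floor"`` symmetrically.  The
    threshold is placed at the midpoint between adjacent observed scores for
    stability.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes required to choose a threshold")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("degenerate scores: all equal, no threshold exists")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best_cut, best_val = None, -np.inf
    for c in cuts:
        pred = s >= c
        sens = float(pred[y].mean())
        spec = float((~pred[~y]).mean())
        if criterion == "youden":
            val = sens + spec - 1.0
        elif criterion == "balanced":
            val = min(sens, spec) + (sens + spec) / 1e3
        elif criterion == "sensitivity_floor":
            if min_sensitivity is None:
                raise ValueError("min_sensitivity required")
            val = spec if sens >= min_sensitivity else -np.inf
        elif criterion == "specificity_floor":
            if min_specificity is None:
                raise ValueError("min_specificity required")
            val = sens if spec >= min_specificity else -np.inf
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if val > best_val:
            best_val, best_cut = val, float(c)
    if best_cut is None or best_val == -np.inf:
        raise ValueError("no threshold satisfies the requested criterion")
    return best_cut


# ---------------------------------------------------------------------------
# training orchestration (vectorised path)
# ---------------------------------------------------------------------------

def _enumerate_subsets(d: int, max_size: int, cap: int,
                       rng: np.random.Generator) -> np.ndarray:
    singles = [(i, -1) for i in range(d)]
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)] if max_size >= 2 else []
    subsets = np.array(singles + pairs, dtype=int)
    if cap and len(subsets) > cap:
        keep = rng.choice(len(subsets), size=cap, replace=False)
        subsets = subsets[np.sort(keep)]
    return subsets


@dataclass
class RealizationLog:
    split_id: int
    n_atomics: int
    n_passed: int
    fallback: bool


@dataclass
class DevelopmentResult:
    model: CortexModel
    oob: pd.Series
    assigned_cancer: List[str]
    remaining: List[str]
    excluded: List[str]
    feature_subset: Tuple[str, ...]
    logs: List[RealizationLog]


def _train_one_realization(
    split_id: int,
    X: np.ndarray,
    y_all: np.ndarray,
    ids: np.ndarray,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    healthy_X: Optional[np.ndarray],
    attrs: Tuple[str, ...],
    subsets: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> Tuple[MasterClassifier, RealizationLog]:
    pos = {s: i for i, s in enumerate(ids)}
    tr = np.array([pos[s] for s in train_ids])
    Xtr_raw = X[tr]
    ytr = y_all[tr]
    Ztr, mean, std = _standardize(Xtr_raw)

    attr_d_tr = _attr_sq_dists(Ztr, Ztr)
    loo_votes = _subset_votes(attr_d_tr, subsets, ytr, config.k_neighbors, loo=True)
    pred = loo_votes > 0.5
    acc1 = (pred[:, ytr] == True).mean(axis=1)
    acc0 = (pred[:, ~ytr] == False).mean(axis=1)
    passed = (acc0 >= config.filter_min_accuracy) & (acc1 >= config.filter_min_accuracy)

    if config.healthy_min_no_cancer_rate > 0:
        if healthy_X is None or len(healthy_X) == 0:
            raise ValueError("healthy reference spectra required for filtering")
        Zhe = (healthy_X - mean) / std
        attr_d_he = _attr_sq_dists(Zhe, Ztr)
        he_votes = _subset_votes(attr_d_he, subsets, ytr, config.k_neighbors)
        he_rate = (he_votes <= 0.5).mean(axis=1)
        passed &= he_rate >= config.healthy_min_no_cancer_rate

    fallback = not passed.any()
    if fallback:
        # degenerate realization: intercept-only master (prevalence score)
        prev = float(ytr.mean())
        prev = min(max(prev, 1e-6), 1 - 1e-6)
        kept = np.empty((0, subsets.shape[1]), dtype=int)
        weights = np.empty(0)
        intercept = math.log(prev / (1 - prev))
    else:
        kept = subsets[passed]
        votes = loo_votes[passed].T  # (n_train, P)
        weights, intercept = _dropout_average_weights(votes, ytr, config, rng)

    master = MasterClassifier(
        split_id=split_id,
        attributes=attrs,
        mean=mean,
        std=std,
        train_X=Ztr,
        train_y=ytr,
        train_ids=tuple(train_ids),
        test_ids=tuple(test_ids),
        k=config.k_neighbors,
        subsets=kept,
        weights=weights,
        intercept=intercept,
    )
    log = RealizationLog(split_id, len(subsets), int(passed.sum()), fallback)
    return master, log


def develop_test(
    dev_table: pd.DataFrame,
    healthy_table: Optional[pd.DataFrame],
    config: TrainConfig,
    *,
    threshold_criterion: str = "youden",
    feature_subset: Optional[Sequence[str]] = None,
    **threshold_kwargs,
) -> DevelopmentResult:
    """Run the full development procedure and return a locked model.

    ``dev_table``: rows = development samples; columns = MS features +
    ``ln_afp`` + ``label`` (bool) and optionally ``afp`` / ``pre_label`` for
    the pre-assignment rules.  ``healthy_table``: healthy-donor feature rows
    (same feature columns + ``ln_afp``) used by the filtering constraint.
    """
    from .spectral_processing import select_top_features

    rng = np.random.default_rng(config.seed)
    meta_cols = [c for c in ("afp", "pre_label", "label") if c in dev_table.columns]
    assigned, remaining, excluded = ([], list(map(str, dev_table.index)), [])
    if {"afp", "pre_label"} & set(dev_table.columns):
        assigned, remaining, excluded = pre_assign_development(
            dev_table, afp_cutoff=config.afp_assign_cutoff
        )
    pool = dev_table.loc[remaining]
    labels = pool["label"].astype(bool)

    if feature_subset is None:
        ranked = select_top_features(
            pool.drop(columns=[c for c in meta_cols if c != "label"]),
            config.n_keep_features,
        )
        feature_subset = tuple(ranked) + ("ln_afp",)
    attrs = tuple(feature_subset)

    X = pool.loc[:, list(attrs)].to_numpy(dtype=float)
    ids = np.asarray(pool.index.astype(str))
    y_all = labels.to_numpy()
    healthy_X = (
        healthy_table.loc[:, list(attrs)].to_numpy(dtype=float)
        if healthy_table is not None and config.healthy_min_no_cancer_rate > 0
        else None
    )

    splits = make_realizations(labels, config, rng)
    subsets = _enumerate_subsets(len(attrs), config.max_subset_size,
                                 config.max_atomics, rng)

    masters: List[MasterClassifier] = []
    logs: List[RealizationLog] = []
    for split_id, (train_ids, test_ids) in enumerate(splits):
        m, log = _train_one_realization(
            split_id, X, y_all, ids, train_ids, test_ids, healthy_X,
            attrs, subsets, config, rng,
        )
        masters.append(m)
        logs.append(log)

    oob = oob_scores(masters, pool.loc[:, list(attrs)])
    threshold = choose_threshold(
        oob.to_numpy(), labels.loc[oob.index].to_numpy(),
        threshold_criterion, **threshold_kwargs,
    )
    model = CortexModel(
        masters=masters,
        feature_subset=attrs,
        threshold=threshold,
        config=config,
        afp_assign_cutoff=config.afp_assign_cutoff,
    ).lock()
    return DevelopmentResult(model, oob, assigned, remaining, excluded, attrs, logs)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _master_to_dict(m: MasterClassifier) -> dict:
    return {
        "split_id": m.split_id,
        "attributes": list(m.attributes),
        "mean": m.mean.tolist(),
        "std": m.std.tolist(),
        "train_X": m.train_X.tolist(),
        "train_y": m.train_y.astype(int).tolist(),
        "train_ids": list(m.train_ids),
        "test_ids": list(m.test_ids),
        "k": m.k,
        "subsets": m.subsets.tolist(),
        "weights": m.weights.tolist(),
        "intercept": m.intercept,
    }


def _master_from_dict(d: dict) -> MasterClassifier:
    n_sub = len(d["subsets"])
    return MasterClassifier(
        split_id=d["split_id"],
        attributes=tuple(d["attributes"]),
        mean=np.asarray(d["mean"], dtype=float),
        std=np.asarray(d["std"], dtype=float),
        train_X=np.asarray(d["train_X"], dtype=float),
        train_y=np.asarray(d["train_y"], dtype=bool),
        train_ids=tuple(d["train_ids"]),
        test_ids=tuple(d["test_ids"]),
        k=d["k"],
        subsets=np.asarray(d["subsets"], dtype=int).reshape(n_sub, -1),
        weights=np.asarray(d["weights"], dtype=float),
        intercept=float(d["intercept"]),
    )


def save_model(model: CortexModel, path: Path) -> None:
    from dataclasses import asdict

    doc = {
        "format": "hccdetect-cortex-model",
        "version": 1,
        "config": asdict(model.config),
        "feature_subset": list(model.feature_subset),
        "threshold": model.threshold,
        "locked": model.locked,
        "afp_assign_cutoff": model.afp_assign_cutoff,
        "pre_classifier_id": model.pre_classifier_id,
        "masters": [_master_to_dict(m) for m in model.masters],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: Path) -> CortexModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "hccdetect-cortex-model":
        raise ValueError("not an hccdetect model file")
    return CortexModel(
        masters=[_master_from_dict(m) for m in doc["masters"]],
        feature_subset=tuple(doc["feature_subset"]),
        threshold=float(doc["threshold"]),
        locked=bool(doc["locked"]),
        config=TrainConfig(**doc["config"]),
        afp_assign_cutoff=float(doc["afp_assign_cutoff"]),
        pre_classifier_id=doc["pre_classifier_id"],
    )
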