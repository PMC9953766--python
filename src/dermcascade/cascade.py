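"""Cascade generalization for benign-vs-melanoma classification.

A level-0 classifier (a deep network in practice; any object with
``fit(records, labels)`` / ``predict_proba(records)`` here) produces a
melanoma probability per image. Level-1 "conventional" classifiers are then
trained on the 36 hand-crafted mask features concatenated with that
probability (probability last, row length 37).

Data discipline follows the grouped folding strategy:

* a hold-out test set (30% of images) is split off grouping by lesion_id, so
  no lesion appears on both sides;
* the remaining train pool is split into 5 lesion-grouped folds; the level-0
  model for fold f is fitted on the other folds and scores fold f
  out-of-fold, so level-1 training rows never contain a probability produced
  by a model that saw the record;
* each fold's rows get a further grouped 80/20 inner split; the level-1
  model fits on the 80% (out-of-the-box hyperparameters, no tuning — the
  20% is held for diagnostics only), giving five models per classifier kind;
* at test time the fold-f level-0 model feeds the fold-f level-1 model
  (pairing preserved; a shared-probability variant is available) and the
  five outputs are averaged; kinds can be ensemble-averaged on top;
* final decisions threshold the probability at a constant 0.5 (strict >).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, GroupShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._seeds import derive_seed
from .features import FEATURE_NAMES, extract_features_table

__all__ = [
    "CLASSIFIER_KINDS",
    "SplitPlan",
    "CascadeEnsemble",
    "make_grouped_split",
    "make_level1_classifier",
    "level0_cv_probabilities",
    "build_level1_rows",
    "train_level1",
    "cascade_predict",
    "ensemble_average",
    "decide",
    "TinyImageLevel0",
    "CascadeClassifier",
]

CLASSIFIER_KINDS = ("linear_svm", "rbf_svm", "random_forest",
                    "decision_tree", "neural_network")
LEVEL0_COLUMN = "level0_prob"


# ---------------------------------------------------------------------------
# Grouped splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Train-pool/test assignment and fold membership, grouped by lesion_id."""

    test_ids: tuple[str, ...]
    fold_of: dict[str, int]  # image_id -> fold in 1..n_folds (train pool only)
    n_folds: int

    @property
    def trainpool_ids(self) -> tuple[str, ...]:
        return tuple(self.fold_of)

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f == fold]


def make_grouped_split(metadata: pd.DataFrame, test_fraction: float = 0.30,
                       n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Split images into hold-out test + k folds, grouping by lesion_id.

    No lesion_id ever crosses the trainpool/test boundary or spans two
    folds. Achieved fractions drift from the targets by whatever the group
    sizes force. ``metadata`` needs columns ``image`` and ``lesion_id``.
    """
    ids = metadata["image"].to_numpy()
    groups = metadata["lesion_id"].to_numpy()
    n_groups = len(np.unique(groups))
    if n_groups < n_folds + 1:
        raise ValueError(
            f"need more than {n_folds} lesion groups, got {n_groups}")
    gss = GroupShuffleSplit(n_splits=1, test_size=test_fraction,
                            random_state=derive_seed(seed, "holdout"))
    (pool_idx, test_idx), = gss.split(ids, groups=groups)
    fold_of: dict[str, int] = {}
    gkf = GroupKFold(n_splits=n_folds, shuffle=True,
                     random_state=derive_seed(seed, "folds"))
    pool_ids, pool_groups = ids[pool_idx], groups[pool_idx]
    for f, (_, val_idx) in enumerate(
            gkf.split(pool_ids, groups=pool_groups), start=1):
        for i in val_idx:
            fold_of[pool_ids[i]] = f
    return SplitPlan(test_ids=tuple(ids[test_idx]), fold_of=fold_of,
                     n_folds=n_folds)


# ---------------------------------------------------------------------------
# Level-0 out-of-fold probabilities
# ---------------------------------------------------------------------------

def _validate_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("level-0 probabilities must lie in [0, 1]")
    return p


def level0_cv_probabilities(level0_factory, plan: SplitPlan,
                            records) -> tuple[pd.Series, dict]:
    """Out-of-fold level-0 probabilities for every train-pool record.

    For each fold f the factory builds a fresh model, fitted on folds != f
    and evaluated on fold f, so every record is scored by a model that never
    saw it. ``level0_factory`` is called with the fold number.
    Returns (probabilities indexed by image_id, {fold: fitted model}).
    """
    by_id = {r.image_id: r for r in records}
    probs: dict[str, float] = {}
    models: dict[int, object] = {}
    for f in range(1, plan.n_folds + 1):
        train_ids = [i for i, g in plan.fold_of.items() if g != f]
        val_ids = plan.fold_ids(f)
        model = level0_factory(f)
        train_recs = [by_id[i] for i in train_ids]
        model.fit(train_recs, np.array([r.label for r in train_recs]))
        p = _validate_probs(model.predict_proba([by_id[i] for i in val_ids]))
        probs.update(zip(val_ids, p))
        models[f] = model
    return pd.Series(probs, name=LEVEL0_COLUMN), models


# ---------------------------------------------------------------------------
# Level-1 rows and training
# ---------------------------------------------------------------------------

def build_level1_rows(features: pd.DataFrame,
                      probs: pd.Series) -> pd.DataFrame:
    """Concatenate the 36 features with the level-0 probability (last column).

    ``features`` is indexed by image_id and must contain the full feature
    schema; every row must have a probability.
    """
    missing = features.index.difference(probs.index)
    if len(missing):
        raise ValueError(f"missing level-0 probability for {list(missing)[:5]}")
    rows = features[list(FEATURE_NAMES)].copy()
    rows[LEVEL0_COLUMN] = probs.reindex(rows.index)
    return rows


def make_level1_classifier(kind: str, seed: int = 0):
    """Out-of-the-box level-1 classifier (defaults, no tuning).

    Scale-sensitive kinds (SVMs, the neural network) are wrapped with a
    z-score standardizer fitted on their own training split; tree-based
    kinds consume raw features.
    """
    if kind == "linear_svm":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="linear", probability=True,
                                 random_state=seed))
    if kind == "rbf_svm":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="rbf", probability=True,
                                 random_state=seed))
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "neural_network":
        return make_pipeline(StandardScaler(),
                             MLPClassifier(random_state=seed, max_iter=500))
    raise ValueError(f"unknown classifier kind: {kind!r}")


@dataclass
class CascadeEnsemble:
    """Five fitted level-1 models per kind, paired with fold level-0 models."""

    level1: dict[str, dict[int, object]]   # kind -> fold -> fitted model
    level0_models: dict[int, object]       # fold -> fitted level-0 model
    kinds: tuple[str, ...]
    n_folds: int
    inner_reports: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kind, models in self.level1.items():
            if len(models) != self.n_folds:
                raise ValueError(
                    f"kind {kind!r} must have exactly {self.n_folds} models")


def train_level1(fold_rows: dict[int, pd.DataFrame], kinds=CLASSIFIER_KINDS,
                 inner_train_fraction: float = 0.8, seed: int = 0,
                 level0_models: dict | None = None) -> CascadeEnsemble:
    """Fit one level-1 model per (kind, fold) on grouped 80/20 inner splits.

    Each entry of ``fold_rows`` carries the 37 feature columns plus ``label``
    and ``lesion_id``. The 20% inner validation rows are only scored for
    diagnostics (``inner_reports``), never used for tuning.
    """
    level1: dict[str, dict[int, object]] = {k: {} for k in kinds}
    reports: dict[str, dict[int, float]] = {k: {} for k in kinds}
    feat_cols = list(FEATURE_NAMES) + [LEVEL0_COLUMN]
    for f, rows in sorted(fold_rows.items()):
        y = rows["label"].to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError(f"fold {f} contains a single class")
        X = rows[feat_cols].to_numpy()
        groups = rows["lesion_id"].to_numpy()
        gss = GroupShuffleSplit(
            n_splits=1, train_size=inner_train_fraction,
            random_state=derive_seed(seed, f"inner-split/{f}"))
        (tr, va), = gss.split(X, groups=groups)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {f}: inner training split single-class")
        for kind in kinds:
            model = make_level1_classifier(
                kind, derive_seed(seed, f"level1/{kind}/{f}"))
            model.fit(X[tr], y[tr])
            level1[kind][f] = model
            if len(va):
                reports[kind][f] = float(model.score(X[va], y[va]))
    return CascadeEnsemble(level1=level1,
                           level0_models=dict(level0_models or {}),
                           kinds=tuple(kinds),
                           n_folds=len(fold_rows),
                           inner_reports=reports)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def cascade_predict(ensemble: CascadeEnsemble, kind: str, test_records,
                    test_features: pd.DataFrame,
                    pairing: str = "foldwise") -> np.ndarray:
    """Average the five fold models' probabilities on the test records.

    ``pairing='foldwise'`` (default): the fold-f level-0 model's test
    probabilities feed the fold-f level-1 model. ``pairing='shared'``: the
    five level-0 outputs are averaged once and that single probability feeds
    every level-1 model.
    """
    if kind not in ensemble.level1:
        raise ValueError(f"unknown kind {kind!r}; have {ensemble.kinds}")
    if pairing not in ("foldwise", "shared"):
        raise ValueError("pairing must be 'foldwise' or 'shared'")
    feats = test_features[list(FEATURE_NAMES)]
    level0_probs = {
        f: _validate_probs(m.predict_proba(list(test_records)))
        for f, m in ensemble.level0_models.items()}
    if pairing == "shared":
        shared = np.mean(list(level0_probs.values()), axis=0)
        level0_probs = {f: shared for f in level0_probs}
    outs = []
    for f, model in sorted(ensemble.level1[kind].items()):
        X = np.column_stack([feats.to_numpy(), level0_probs[f]])
        outs.append(model.predict_proba(X)[:, 1])
    return np.mean(outs, axis=0)


def ensemble_average(*prob_vectors: np.ndarray) -> np.ndarray:
    """Elementwise mean of equally long probability vectors."""
    if not prob_vectors:
        raise ValueError("need at least one probability vector")
    arrs = [np.asarray(p, dtype=float) for p in prob_vectors]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("probability vectors must have equal length")
    return np.mean(arrs, axis=0)


def decide(probs: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Melanoma iff probability strictly exceeds the constant threshold."""
    return (np.asarray(probs, dtype=float) > t).astype(int)


# ---------------------------------------------------------------------------
# Desk-scale default level-0 and the estimator facade
# ---------------------------------------------------------------------------

class TinyImageLevel0:
    """Logistic regression on 8x8 downsampled grayscale intensities.

    A desk-scale stand-in honoring the level-0 contract; real CNN classifiers
    attach through the same interface.
    """

    def __init__(self, seed: int = 0, size: int = 8):
        self.seed = seed
        self.size = size

    def _featurize(self, records) -> np.ndarray:
        from skimage.transform import resize

        out = np.empty((len(records), self.size * self.size))
        for i, rec in enumerate(records):
            gray = rec.image.astype(float).mean(axis=2) / 255.0
            out[i] = resize(gray, (self.size, self.size),
                            anti_aliasing=True).ravel()
        return out

    def fit(self, records, labels) -> "TinyImageLevel0":
        from sklearn.linear_model import LogisticRegression

        self.model_ = LogisticRegression(max_iter=1000,
                                         random_state=self.seed)
        self.model_.fit(self._featurize(records), np.asarray(labels))
        return self

    def predict_proba(self, records) -> np.ndarray:
        return self.model_.predict_proba(self._featurize(records))[:, 1]


class CascadeClassifier(BaseEstimator, ClassifierMixin):
    """Estimator facade over the full cascade.

    fit() takes the training records (labels travel on the records) and
    optionally their precomputed feature table; it runs the lesion-grouped
    5-fold level-0 cross-validation, builds the level-1 rows, and fits five
    level-1 models per kind. predict_proba() scores new records with the
    fold-paired level-0/level-1 chain and averages.

    Fitted attributes: ``ensemble_``, ``oof_probs_``, ``fold_of_``.
    """

    def __init__(self, level0_factory=None, kinds=CLASSIFIER_KINDS,
                 n_folds: int = 5, inner_train_fraction: float = 0.8,
                 pairing: str = "foldwise", random_state: int = 0):
        self.level0_factory = level0_factory
        self.kinds = kinds
        self.n_folds = n_folds
        self.inner_train_fraction = inner_train_fraction
        self.pairing = pairing
        self.random_state = random_state

    def _factory(self, fold: int):
        if self.level0_factory is None:
            return TinyImageLevel0(
                seed=derive_seed(self.random_state, f"level0/{fold}"))
        return self.level0_factory(fold)

    def fit(self, records, y=None,
            features: pd.DataFrame | None = None) -> "CascadeClassifier":
        records = list(records)
        if features is None:
            features = extract_features_table(records)
        meta = pd.DataFrame({
            "image": [r.image_id for r in records],
            "lesion_id": [r.lesion_id for r in records],
        })
        ids = meta["image"].to_numpy()
        groups = meta["lesion_id"].to_numpy()
        gkf = GroupKFold(n_splits=self.n_folds, shuffle=True,
                         random_state=derive_seed(self.random_state, "folds"))
        fold_of = {}
        for f, (_, val) in enumerate(gkf.split(ids, groups=groups), start=1):
            for i in val:
                fold_of[ids[i]] = f
        plan = SplitPlan(test_ids=(), fold_of=fold_of, n_folds=self.n_folds)
        oof, level0_models = level0_cv_probabilities(
            self._factory, plan, records)
        rows = build_level1_rows(features, oof)
        rows["label"] = features["label"]
        rows["lesion_id"] = features["lesion_id"]
        fold_rows = {f: rows.loc[plan.fold_ids(f)]
                     for f in range(1, self.n_folds + 1)}
        self.ensemble_ = train_level1(
            fold_rows, self.kinds, self.inner_train_fraction,
            seed=self.random_state, level0_models=level0_models)
        self.oof_probs_ = oof
        self.fold_of_ = fold_of
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba_by_kind(self, records,
                              features: pd.DataFrame | None = None) -> dict:
        records = list(records)
        if features is None:
            features = extract_features_table(records)
        features = features.loc[[r.image_id for r in records]]
        return {kind: cascade_predict(self.ensemble_, kind, records,
                                      features, self.pairing)
                for kind in self.ensemble_.kinds}

    def predict_proba(self, records,
                      features: pd.DataFrame | None = None) -> np.ndarray:
        by_kind = self.predict_proba_by_kind(records, features)
        p1 = ensemble_average(*by_kind.values())
        return np.column_stack([1.0 - p1, p1])

    def predict(self, records,
                features: pd.DataFrame | None = None) -> np.ndarray:
        return decide(self.predict_proba(records, features)[:, 1])
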