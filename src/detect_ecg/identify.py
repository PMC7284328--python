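"""One-vs-rest subject identification with random-forest base estimators.

The K-subject identification problem is split into K binary problems: one
random forest per enrolled subject, trained with that subject's feature rows
as positives and every other subject's rows as negatives (no subsampling, no
class weighting).  A probe row is scored by every forest — the positive-class
vote fraction — and assigned to the subject whose forest outputs the greatest
probability; exact ties resolve to the lexicographically first subject label.

Default hyperparameters are the grid-search optimum of the published study
(max_depth 100, min_samples_leaf 3, min_samples_split 10, 120 trees); the
3×3×3×3 search grid itself is available through :func:`grid_search`.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .errors import InvalidArgumentError
from .ioformats import KEY_COLUMNS

#: Hyperparameter grid of the original tuning study (81 combinations).
DEFAULT_GRID = {
    "max_depth": [60, 80, 100],
    "min_samples_leaf": [3, 4, 5],
    "min_samples_split": [8, 10, 12],
    "n_estimators": [80, 100, 120],
}


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    max_depth: int = 100
    min_samples_leaf: int = 3
    min_samples_split: int = 10
    n_estimators: int = 120
    random_state: int = 0
    cv_folds: int = 3
    grid: dict | None = None

    def __post_init__(self):
        for name in ("max_depth", "min_samples_leaf", "min_samples_split",
                     "n_estimators", "cv_folds"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    def forest_params(self) -> dict:
        return dict(max_depth=self.max_depth,
                    min_samples_leaf=self.min_samples_leaf,
                    min_samples_split=self.min_samples_split,
                    n_estimators=self.n_estimators)


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    random_state: int = 0
    stratify_by_subject: bool = True

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise InvalidArgumentError("train_fraction must be in (0, 1)")


@dataclasses.dataclass
class IdentificationModel:
    subjects: list
    estimators: dict
    feature_names: list
    config: ModelConfig


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in KEY_COLUMNS]


def split_dataset(table: pd.DataFrame, spec: SplitSpec = SplitSpec()
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject stratified train/test split.

    Each subject contributes round(train_fraction × n) rows to training
    (clamped so both splits stay non-empty); a subject with fewer than two
    rows cannot be split and raises.
    """
    train_idx, test_idx = [], []
    for sid, group in table.groupby("subject_id", sort=True):
        n = len(group)
        if n < 2:
            raise InvalidArgumentError(
                f"subject {sid!r} has {n} row(s); need at least 2 to split")
        if spec.stratify_by_subject:
            rng = np.random.default_rng(derive_seed(spec.random_state, "split", sid))
        else:
            rng = np.random.default_rng(derive_seed(spec.random_state, "split"))
        order = rng.permutation(n)
        n_train = int(np.clip(round(spec.train_fraction * n), 1, n - 1))
        idx = group.index.to_numpy()
        train_idx.extend(idx[order[:n_train]])
        test_idx.extend(idx[order[n_train:]])
    return table.loc[sorted(train_idx)].copy(), table.loc[sorted(test_idx)].copy()


def _canonical_order(table: pd.DataFrame) -> pd.DataFrame:
    # Forest fitting is row-order sensitive; sort rows canonically so that
    # permuting the input table cannot change the fitted model.
    cols = ["subject_id"] + _feature_cols(table)
    return table.sort_values(cols, kind="mergesort")


def fit_identifier(train: pd.DataFrame, cfg: ModelConfig = ModelConfig()
                   ) -> IdentificationModel:
    """Fit one binary forest per subject (positives vs all other subjects)."""
    subjects = sorted(train["subject_id"].unique())
    if len(subjects) < 2:
        raise InvalidArgumentError("need at least 2 subjects to fit an identifier")
    train = _canonical_order(train)
    feats = _feature_cols(train)
    X = train[feats].to_numpy(dtype=float)
    labels = train["subject_id"].to_numpy()
    estimators = {}
    for sid in subjects:
        y = (labels == sid).astype(int)
        rf = RandomForestClassifier(
            **cfg.forest_params(),
            random_state=derive_seed(cfg.random_state, "forest", sid),
            n_jobs=1)
        rf.fit(X, y)
        estimators[sid] = rf
    return IdentificationModel(subjects, estimators, feats, cfg)


def _probability_matrix(model: IdentificationModel, X: np.ndarray) -> np.ndarray:
    probs = np.zeros((X.shape[0], len(model.subjects)))
    for j, sid in enumerate(model.subjects):
        rf = model.estimators[sid]
        p = rf.predict_proba(X)
        if p.shape[1] == 2:
            probs[:, j] = p[:, list(rf.classes_).index(1)]
        else:  # degenerate single-class training fold
            probs[:, j] = float(rf.classes_[0])
    return probs


def predict_subject(model: IdentificationModel, rows: pd.DataFrame) -> np.ndarray:
    """Assign each row to the subject with the greatest forest probability."""
    feats = _feature_cols(rows)
    missing = [c for c in model.feature_names if c not in feats]
    extra = [c for c in feats if c not in model.feature_names]
    if missing or extra:
        raise InvalidArgumentError(
            f"feature columns mismatch; missing={missing}, extra={extra}")
    X = rows[model.feature_names].to_numpy(dtype=float)
    probs = _probability_matrix(model, X)
    # argmax returns the first maximum: subjects are sorted, so ties resolve
    # to the lexicographically first label
    winners = np.argmax(probs, axis=1)
    return np.asarray([model.subjects[i] for i in winners])


def grid_search(train: pd.DataFrame, cfg: ModelConfig = ModelConfig(grid=DEFAULT_GRID)
                ) -> ModelConfig:
    """Exhaustive search of the hyperparameter grid by cross-validated accuracy.

    Ties resolve to fewer trees, then shallower depth, then the remaining
    parameters in ascending order.
    """
    grid = cfg.grid or DEFAULT_GRID
    keys = sorted(grid)
    combos = [dict(zip(keys, vals))
              for vals in itertools.product(*(grid[k] for k in keys))]
    if not combos:
        raise InvalidArgumentError("empty hyperparameter grid")

    labels = train["subject_id"].to_numpy()
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                          random_state=derive_seed(cfg.random_state, "cv"))
    folds = list(skf.split(np.zeros(len(train)), labels))

    def tiebreak(c):
        return (c.get("n_estimators", 0), c.get("max_depth", 0),
                c.get("min_samples_leaf", 0), c.get("min_samples_split", 0))

    best, best_score = None, -np.inf
    for combo in sorted(combos, key=tiebreak):
        params = dataclasses.replace(cfg, grid=None, **combo)
        scores = []
        for tr, te in folds:
            sub_train, sub_test = train.iloc[tr], train.iloc[te]
            if sub_train["subject_id"].nunique() < 2:
                continue
            model = fit_identifier(sub_train, params)
            pred = predict_subject(model, sub_test)
            scores.append(float(np.mean(pred == sub_test["subject_id"].to_numpy())))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best, best_score = params, score
    return best
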