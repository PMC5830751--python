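"""Bagged ensemble of randomized decision trees.

The classifier is a bagging ensemble of eight binary decision trees.
At every node each tree draws 128 random split candidates — a feature
chosen uniformly among the 44 and a threshold uniform on that feature's
range within the node — and keeps the candidate with the largest Gini
impurity decrease.  Trees grow unbounded until nodes are pure,
range-degenerate, or a child would fall below the one-sample leaf
minimum; leaves store class-frequency vectors and the ensemble
prediction is the argmax of their average (majority vote with
probability ties broken by the fixed class order lying < standing <
walking).

Randomized-threshold splitting keeps per-node cost linear in the node
size (no sorting), which is what makes the method attractive for
embedded deployment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .features import FEATURE_NAMES
from .rng import substream
from .signals import CLASSES

__all__ = [
    "ForestConfig",
    "ForestModel",
    "split_train_test",
    "train_forest",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class ForestConfig:
    """Ensemble hyperparameters (study defaults)."""

    n_trees: int = 8
    random_splits_per_node: int = 128
    min_samples_per_leaf: int = 1
    bagging: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "random_splits_per_node", "min_samples_per_leaf"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")


@dataclass
class ForestModel:
    """A trained forest: nested-dict trees plus training metadata."""

    trees: list[dict]
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    config: ForestConfig
    oob_fractions: list[float] = field(default_factory=list)


def split_train_test(
    table: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test partition of a feature table.

    Per behaviour class, ``round(train_fraction × n_class)`` windows go
    to the training set, so class ratios match the full table within
    one window.  With ``groups`` (e.g. bout ids) whole groups are
    assigned greedily instead, avoiding leakage through overlapping
    windows; this is off by default to mirror the pooled-window design.
    """
    if not 0 < train_fraction < 1:
        raise ConfigError("train_fraction must be in (0, 1)")
    counts = table["label"].value_counts()
    for c in CLASSES:
        if counts.get(c, 0) == 0:
            raise DataError(f"cannot stratify: class {c!r} has 0 windows")
    rng = substream(seed, "split")
    if groups is not None:
        groups = np.asarray(groups)
        uniq = pd.unique(groups)
        order = rng.permutation(len(uniq))
        target = train_fraction * len(table)
        train_groups, size = set(), 0
        for g in uniq[order]:
            if size >= target:
                break
            train_groups.add(g)
            size += int(np.sum(groups == g))
        mask = np.array([g in train_groups for g in groups])
        return table[mask], table[~mask]
    train_idx: list[np.ndarray] = []
    for c in sorted(counts.index):
        idx = table.index[table["label"] == c].to_numpy()
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(train_fraction * len(idx)))
        train_idx.append(idx[:n_train])
    chosen = np.concatenate(train_idx)
    mask = table.index.isin(chosen)
    return table[mask], table[~mask]


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    rng: np.random.Generator,
    config: ForestConfig,
    n_classes: int,
    return_candidates: bool = False,
):
    """Draw the random candidates for one node and keep the best.

    Returns ``(feature, threshold, gain)`` or ``None`` when no
    candidate yields two children of at least ``min_samples_per_leaf``
    samples.  With ``return_candidates`` the full candidate list
    ``(feature, threshold, gain_or_nan)`` is returned too, for
    auditing.
    """
    m = len(idx)
    k = config.random_splits_per_node
    feats = rng.integers(0, X.shape[1], size=k)
    Xn = X[np.ix_(idx, feats)]
    lo, hi = Xn.min(axis=0), Xn.max(axis=0)
    thr = rng.uniform(lo, hi)
    left = Xn <= thr  # m × k boolean partition per candidate
    left_counts = np.empty((n_classes, k))
    yn = y[idx]
    for c in range(n_classes):
        left_counts[c] = left[yn == c].sum(axis=0)
    n_left = left_counts.sum(axis=0)
    n_right = m - n_left
    total = np.bincount(yn, minlength=n_classes).astype(float)
    right_counts = total[:, None] - left_counts
    parent = _gini(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        gini_l = 1.0 - np.sum((left_counts / n_left) ** 2, axis=0)
        gini_r = 1.0 - np.sum((right_counts / n_right) ** 2, axis=0)
    child = np.where(n_left > 0, n_left * np.nan_to_num(gini_l), 0.0)
    child += np.where(n_right > 0, n_right * np.nan_to_num(gini_r), 0.0)
    gains = parent - child / m
    valid = (
        (n_left >= config.min_samples_per_leaf)
        & (n_right >= config.min_samples_per_leaf)
        & (hi > lo)
    )
    gains = np.where(valid, gains, np.nan)
    if not valid.any():
        best = None
    else:
        i = int(np.nanargmax(gains))  # first maximal candidate wins ties
        best = (int(feats[i]), float(thr[i]), float(gains[i]))
    if return_candidates:
        return best, list(zip(feats.tolist(), thr.tolist(), gains.tolist()))
    return best


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    rng: np.random.Generator,
    config: ForestConfig,
    n_classes: int,
) -> dict:
    counts = np.bincount(y[idx], minlength=n_classes).astype(float)
    node_total = counts.sum()
    if np.count_nonzero(counts) <= 1:
        return {"counts": counts.tolist(), "freq": (counts / node_total).tolist()}
    best = _best_split(X, y, idx, rng, config, n_classes)
    if best is None:  # range-degenerate or leaf-minimum exhausted
        return {"counts": counts.tolist(), "freq": (counts / node_total).tolist()}
    feature, threshold, gain = best
    mask = X[idx, feature] <= threshold
    return {
        "feature": feature,
        "threshold": threshold,
        "gain": gain,
        "left": _grow_tree(X, y, idx[mask], rng, config, n_classes),
        "right": _grow_tree(X, y, idx[~mask], rng, config, n_classes),
    }


def _design_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise DataError(f"feature table missing columns {missing[:3]}...")
    X = table[list(FEATURE_NAMES)].to_numpy(float)
    code = {c: i for i, c in enumerate(CLASSES)}
    try:
        y = table["label"].map(code).to_numpy()
    except KeyError as exc:  # pragma: no cover
        raise DataError("feature table has no 'label' column") from exc
    if np.any(pd.isna(y)):
        raise DataError("feature table contains labels outside the ethogram")
    return X, y.astype(np.int64)


def train_forest(train: pd.DataFrame, config: ForestConfig | None = None) -> ForestModel:
    """Fit the bagged randomized-tree ensemble on a feature table."""
    config = config or ForestConfig()
    X, y = _design_matrix(train)
    if len(X) == 0:
        raise DataError("training table is empty")
    n_classes = len(CLASSES)
    if len(np.unique(y)) == 1:
        warnings.warn(
            "training set contains a single class; model is a constant predictor",
            stacklevel=2,
        )
    trees, oob = [], []
    n = len(X)
    for i in range(config.n_trees):
        rng = substream(config.seed, "tree", i)
        if config.bagging:
            bag = rng.integers(0, n, size=n)
            oob.append(1.0 - len(np.unique(bag)) / n)
        else:
            bag = np.arange(n)
            oob.append(0.0)
        trees.append(_grow_tree(X, y, bag, rng, config, n_classes))
    return ForestModel(
        trees=trees,
        classes=CLASSES,
        feature_names=FEATURE_NAMES,
        config=config,
        oob_fractions=oob,
    )


def _tree_proba(tree: dict, x: np.ndarray) -> np.ndarray:
    node = tree
    while "feature" in node:
        node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
    return np.asarray(node["freq"])


def predict(
    model: ForestModel, features: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble prediction: labels and class-probability vectors.

    The probability of a window is the mean of the leaf class-frequency
    vectors over trees; the label is its argmax, ties resolved by the
    fixed class order.
    """
    if tuple(model.feature_names) != tuple(FEATURE_NAMES):
        raise DataError("model was trained with a different feature set")
    X = features[list(model.feature_names)].to_numpy(float)
    proba = np.zeros((len(X), len(model.classes)))
    for tree in model.trees:
        for i, x in enumerate(X):
            proba[i] += _tree_proba(tree, x)
    proba /= len(model.trees)
    labels = np.array([model.classes[int(i)] for i in np.argmax(proba, axis=1)])
    return labels, proba


# ---------------------------------------------------------------------------
# JSON serialization (inspectable, exactly reloadable)


def save_model(model: ForestModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "classes": list(model.classes),
        "feature_names": list(model.feature_names),
        "config": asdict(model.config),
        "oob_fractions": model.oob_fractions,
        "trees": model.trees,
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> ForestModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise DataError(f"unsupported model format {payload.get('format_version')}")
    return ForestModel(
        trees=payload["trees"],
        classes=tuple(payload["classes"]),
        feature_names=tuple(payload["feature_names"]),
        config=ForestConfig(**payload["config"]),
        oob_fractions=list(payload.get("oob_fractions", [])),
    )
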