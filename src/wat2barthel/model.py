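"""Interpretable regression tree for Barthel Index prediction.

The model is a classic CART regression tree: greedy binary recursive
partitioning that, at every node, picks the (feature, threshold) pair
minimising the weighted within-child sum of squared errors. Candidate
thresholds are the midpoints between consecutive distinct sorted feature
values; a split is accepted only when its *weighted* impurity decrease,

    (SSE_node - SSE_left - SSE_right) / n_total,

reaches ``min_impurity_decrease``, both children hold at least
``min_samples_leaf`` rows, and the node holds at least ``min_samples_split``
rows. Leaves predict the mean training target, so predictions always stay
inside the training target range. Ties in split quality are broken towards
the lowest feature index, then the lowest threshold, making fits fully
deterministic.

Hyperparameters are tuned by k-fold cross-validation over a dense grid.
Because the greedy split *choice* at a node never depends on
``min_impurity_decrease`` (the parameter only gates acceptance), the tree
for any value of it is a pruning of the tree fitted with the parameter at
zero; the grid search exploits this to fit one full tree per
(fold, min_samples_leaf, min_samples_split) combination and score all
impurity-decrease values by cheap pruning instead of refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS


# --------------------------------------------------------------------------
# Hyperparameters and split specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Hyperparams:
    """Tree-growing controls, mirroring the usual CART conventions."""

    min_impurity_decrease: float = 0.0
    min_samples_leaf: int = 1
    min_samples_split: int = 2
    max_depth: int | None = None
    seed: int = 0

    def effective(self) -> "Hyperparams":
        """Clamp degenerate values (a binary split needs >= 2 samples)."""
        hp = self
        if hp.min_samples_split < 2:
            warnings.warn(
                f"min_samples_split={hp.min_samples_split} cannot produce a binary "
                "split; clamping to 2",
                stacklevel=2,
            )
            hp = replace(hp, min_samples_split=2)
        if hp.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if hp.min_impurity_decrease < 0:
            raise ValueError("min_impurity_decrease must be >= 0")
        return hp


@dataclass(frozen=True)
class SplitSpec:
    """Group-stratified train/validation split specification."""

    train_fraction: float = 0.7
    group_field: str = "aid_group"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows into train/validation preserving group proportions.

    Within every group the rows are shuffled (seeded) and allocated to the
    training set; per-group training counts are the largest-remainder
    apportionment of ``round(train_fraction * N)`` total training rows, so
    the overall ratio is honoured exactly while each group stays as close to
    the target fraction as integer counts allow. Groups with fewer than two
    rows go entirely to training (with a warning) — they cannot be split.
    """
    if spec.group_field not in table.columns:
        raise KeyError(f"table has no group column {spec.group_field!r}")
    n_total = len(table)
    target_train = int(round(spec.train_fraction * n_total))
    rng = np.random.default_rng(spec.seed)

    groups = []  # (label, shuffled positional indices, exact share)
    forced_train: list[np.ndarray] = []
    for label, idx in table.groupby(spec.group_field, sort=True).indices.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            warnings.warn(
                f"group {label!r} has {len(idx)} row(s); assigning all to training",
                stacklevel=2,
            )
            forced_train.append(idx)
            continue
        groups.append((label, rng.permutation(idx), spec.train_fraction * len(idx)))

    n_forced = sum(len(i) for i in forced_train)
    remaining = max(target_train - n_forced, 0)
    floors = [int(np.floor(share)) for _, _, share in groups]
    # Never take more from a group than leaves at least... allocation may hit
    # group size; cap at group size.
    floors = [min(f, len(idx)) for f, (_, idx, _) in zip(floors, groups)]
    leftover = remaining - sum(floors)
    remainders = sorted(
        range(len(groups)),
        key=lambda i: (-(groups[i][2] - np.floor(groups[i][2])), i),
    )
    take = floors[:]
    j = 0
    while leftover > 0 and j < 10 * max(len(groups), 1):
        i = remainders[j % len(remainders)]
        if take[i] < len(groups[i][1]):
            take[i] += 1
            leftover -= 1
        j += 1

    train_idx = list(forced_train)
    val_idx = []
    for (label, idx, _), k in zip(groups, take):
        train_idx.append(idx[:k])
        val_idx.append(idx[k:])
    train_pos = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], dtype=int)
    val_pos = np.sort(np.concatenate(val_idx)) if val_idx else np.array([], dtype=int)
    return table.iloc[train_pos].copy(), table.iloc[val_pos].copy()


# --------------------------------------------------------------------------
# Tree structure
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    """One node of the fitted tree.

    Internal nodes carry the split (feature index/name, threshold, weighted
    impurity decrease); every node carries its training-sample count, mean
    target (the prediction if reached as a leaf) and within-node squared
    error (the impurity).
    """

    n_samples: int
    value: float
    squared_error: float
    feature_index: int | None = None
    feature_name: str | None = None
    threshold: float | None = None
    weighted_decrease: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "value": self.value,
            "squared_error": self.squared_error,
        }
        if not self.is_leaf:
            d.update(
                feature_index=self.feature_index,
                feature_name=self.feature_name,
                threshold=self.threshold,
                weighted_decrease=self.weighted_decrease,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            n_samples=d["n_samples"], value=d["value"], squared_error=d["squared_error"]
        )
        if "left" in d:
            node.feature_index = d["feature_index"]
            node.feature_name = d["feature_name"]
            node.threshold = d["threshold"]
            node.weighted_decrease = d.get("weighted_decrease")
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class RegressionTreeModel:
    """A fitted CART regression tree plus its training schema."""

    root: TreeNode
    feature_names: list[str]
    hyperparams: Hyperparams
    train_target_range: tuple[float, float]

    # -- prediction --------------------------------------------------------
    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Route rows down the tree; `value <= threshold` goes left."""
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing feature column(s): {missing}")
            X = X.loc[:, self.feature_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature_index] <= node.threshold else node.right
            out[i] = node.value
        return out

    def predict_one(self, features: dict[str, float]) -> float:
        missing = [c for c in self.feature_names if c not in features]
        if missing:
            raise KeyError(f"missing feature(s): {missing}")
        row = np.array([[features[c] for c in self.feature_names]])
        return float(self.predict(row)[0])

    # -- introspection -----------------------------------------------------
    @property
    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    @property
    def n_leaves(self) -> int:
        def c(node: TreeNode) -> int:
            return 1 if node.is_leaf else c(node.left) + c(node.right)

        return c(self.root)

    def first_split_feature(self) -> str | None:
        return None if self.root.is_leaf else self.root.feature_name

    def structure_signature(self) -> list[tuple]:
        """Pre-order (feature_index, threshold, n) tuples; leaves as (None, value, n)."""
        sig: list[tuple] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                sig.append((None, round(node.value, 10), node.n_samples))
            else:
                sig.append((node.feature_index, round(node.threshold, 10), node.n_samples))
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return sig

    def training_mse(self) -> float:
        """Weighted mean of leaf impurities = training MSE."""
        total = self.root.n_samples

        def sse(node: TreeNode) -> float:
            if node.is_leaf:
                return node.squared_error * node.n_samples
            return sse(node.left) + sse(node.right)

        return sse(self.root) / total

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "hyperparams": {
                "min_impurity_decrease": self.hyperparams.min_impurity_decrease,
                "min_samples_leaf": self.hyperparams.min_samples_leaf,
                "min_samples_split": self.hyperparams.min_samples_split,
                "max_depth": self.hyperparams.max_depth,
                "seed": self.hyperparams.seed,
            },
            "train_target_range": list(self.train_target_range),
            "tree": self.root.to_dict(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RegressionTreeModel":
        d = json.loads(text)
        return cls(
            root=TreeNode.from_dict(d["tree"]),
            feature_names=list(d["feature_names"]),
            hyperparams=Hyperparams(**d["hyperparams"]),
            train_target_range=tuple(d["train_target_range"]),
        )

    def to_text(self) -> str:
        """Indented plain-text rendering of the decision paths."""
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(
                    f"{pad}predict {node.value:.2f} "
                    f"(n={node.n_samples}, squared_error={node.squared_error:.2f})"
                )
            else:
                lines.append(
                    f"{pad}{node.feature_name} <= {node.threshold:.3f} "
                    f"(n={node.n_samples}, squared_error={node.squared_error:.2f})"
                )
                walk(node.left, indent + 1)
                lines.append(f"{pad}{node.feature_name} >  {node.threshold:.3f}")
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def _best_split(X: np.ndarray, y: np.ndarray, idx: np.ndarray, min_samples_leaf: int):
    """Exhaustive best (feature, threshold) over midpoint candidates.

    Returns ``(feature, threshold, sse_gain, left_mask)`` for the split
    minimising SSE_left + SSE_right, or ``None`` when no threshold respects
    ``min_samples_leaf``. Ties resolve to the lowest feature index, then the
    lowest threshold. Vectorised via prefix sums per feature.
    """
    n = idx.size
    yv = y[idx]
    best = None  # (gain, feature, threshold)
    sse_parent = float(np.sum((yv - yv.mean()) ** 2))
    # Tie tolerance relative to the node SSE: gains closer than this are
    # treated as equal and resolve to the lowest feature index / threshold,
    # independent of how the SSE happened to be accumulated.
    eps = 1e-9 * max(sse_parent, 1.0)
    for j in range(X.shape[1]):
        xv = X[idx, j]
        order = np.argsort(xv, kind="mergesort")
        xs, ys = xv[order], yv[order]
        # candidate boundaries: positions i where xs[i-1] < xs[i]
        diff = xs[1:] != xs[:-1]
        pos = np.flatnonzero(diff) + 1  # left child size
        if pos.size == 0:
            continue
        ok = (pos >= min_samples_leaf) & (n - pos >= min_samples_leaf)
        pos = pos[ok]
        if pos.size == 0:
            continue
        csum = np.cumsum(ys)
        csq = np.cumsum(ys * ys)
        tot, totsq = csum[-1], csq[-1]
        nl = pos.astype(float)
        sl, sql = csum[pos - 1], csq[pos - 1]
        sse_l = sql - sl * sl / nl
        sse_r = (totsq - sql) - (tot - sl) ** 2 / (n - nl)
        sse_children = sse_l + sse_r
        # first near-minimal candidate => lowest threshold among ties
        k = int(np.argmax(sse_children <= sse_children.min() + eps))
        gain = sse_parent - float(sse_children[k])
        thr = float((xs[pos[k] - 1] + xs[pos[k]]) / 2.0)
        if best is None or gain > best[0] + eps:
            best = (gain, j, thr)
    if best is None:
        return None
    gain, j, thr = best
    left_mask = X[idx, j] <= thr
    return j, thr, gain, left_mask


def fit_tree(
    table: pd.DataFrame | tuple[np.ndarray, np.ndarray],
    hp: Hyperparams = Hyperparams(),
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
) -> RegressionTreeModel:
    """Fit the CART regression tree on a modelling table.

    Accepts either a feature table (with ``barthel_index`` target) or a raw
    ``(X, y)`` pair. Rows tagged ``role == "test"`` are refused outright:
    the production-like hold-out must never leak into training.
    """
    if isinstance(table, pd.DataFrame):
        if "role" in table.columns and (table["role"] == "test").any():
            raise ValueError("table contains rows tagged role='test'; refusing to train on them")
        from .features import feature_matrix

        X, y, names = feature_matrix(table, feature_columns)
    else:
        X, y = table
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])] if X.ndim == 2 else ["x0"]
        X = np.atleast_2d(X.T).T if X.ndim == 1 else X
    if X.shape[0] == 0:
        raise ValueError("cannot fit a tree on an empty table")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    if isinstance(table, pd.DataFrame):
        names = list(feature_columns)
    hp = hp.effective()
    n_total = X.shape[0]

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        yv = y[idx]
        value = float(yv.mean())
        sse = float(np.sum((yv - value) ** 2))
        node = TreeNode(n_samples=idx.size, value=value, squared_error=sse / idx.size)
        if (
            idx.size < hp.min_samples_split
            or idx.size < 2 * hp.min_samples_leaf
            or sse <= 1e-12
            or (hp.max_depth is not None and depth >= hp.max_depth)
        ):
            return node
        found = _best_split(X, y, idx, hp.min_samples_leaf)
        if found is None:
            return node
        j, thr, gain, left_mask = found
        weighted_decrease = gain / n_total
        if weighted_decrease < hp.min_impurity_decrease:
            return node
        node.feature_index = j
        node.feature_name = names[j]
        node.threshold = thr
        node.weighted_decrease = weighted_decrease
        node.left = grow(idx[left_mask], depth + 1)
        node.right = grow(idx[~left_mask], depth + 1)
        return node

    root = grow(np.arange(n_total), 0)
    return RegressionTreeModel(
        root=root,
        feature_names=names,
        hyperparams=hp,
        train_target_range=(float(y.min()), float(y.max())),
    )


def prune_tree(model: RegressionTreeModel, min_impurity_decrease: float) -> RegressionTreeModel:
    """Tree for a larger ``min_impurity_decrease`` by pruning a full fit.

    Valid because the greedy split choice at every node is independent of
    the acceptance threshold: raising the threshold only turns nodes whose
    weighted decrease falls below it into leaves.
    """

    def cut(node: TreeNode) -> TreeNode:
        if node.is_leaf or node.weighted_decrease < min_impurity_decrease:
            return TreeNode(node.n_samples, node.value, node.squared_error)
        out = TreeNode(
            node.n_samples,
            node.value,
            node.squared_error,
            feature_index=node.feature_index,
            feature_name=node.feature_name,
            threshold=node.threshold,
            weighted_decrease=node.weighted_decrease,
        )
        out.left = cut(node.left)
        out.right = cut(node.right)
        return out

    hp = replace(model.hyperparams, min_impurity_decrease=min_impurity_decrease)
    return RegressionTreeModel(
        root=cut(model.root),
        feature_names=model.feature_names,
        hyperparams=hp,
        train_target_range=model.train_target_range,
    )


# --------------------------------------------------------------------------
# Cross-validated grid search
# --------------------------------------------------------------------------

def default_grid() -> dict[str, list]:
    """The dense tuning grid: 101 x 10 x 10 = 10,100 candidates."""
    return {
        "min_impurity_decrease": [round(0.01 * i, 2) for i in range(101)],
        "min_samples_leaf": list(range(1, 11)),
        "min_samples_split": list(range(1, 11)),
    }


def _predictions_by_threshold(
    root: TreeNode, X: np.ndarray, mids: np.ndarray
) -> np.ndarray:
    """Predictions of every ``min_impurity_decrease``-pruning of a full tree.

    ``mids`` must be ascending. For each row, walk its full-tree path
    recording node values and the running minimum of the weighted impurity
    decreases; the pruned prediction at threshold ``mid`` is the value of
    the first path node whose running minimum drops below ``mid`` (no such
    node -> the leaf). Returns an (n_rows, n_mids) array.
    """
    out = np.empty((X.shape[0], mids.size))
    for i, row in enumerate(X):
        values = []
        dec = []
        node = root
        while not node.is_leaf:
            values.append(node.value)
            dec.append(node.weighted_decrease)
            node = node.left if row[node.feature_index] <= node.threshold else node.right
        values.append(node.value)
        if not dec:
            out[i, :] = values[0]
            continue
        cmin = np.minimum.accumulate(np.asarray(dec))
        # cmin is non-increasing; nodes surviving threshold t are the prefix
        # with cmin >= t, so the cut index is the count of cmin >= t.
        idx = cmin.size - np.searchsorted(cmin[::-1], mids, side="left")
        out[i, :] = np.asarray(values)[idx]
    return out


def _score(y_true: np.ndarray, y_pred: np.ndarray, scoring: str) -> float:
    err = y_true - y_pred
    if scoring == "neg_mean_squared_error":
        return -float(np.mean(err**2))
    if scoring == "neg_median_absolute_error":
        return -float(np.median(np.abs(err)))
    if scoring == "neg_mean_absolute_error":
        return -float(np.mean(np.abs(err)))
    raise ValueError(f"unknown scoring {scoring!r}")


def cross_validate(
    table: pd.DataFrame,
    grid: dict[str, list] | None = None,
    k: int = 7,
    scoring: str = "neg_mean_squared_error",
    seed: int = 0,
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
    max_depth: int | None = None,
) -> tuple[Hyperparams, pd.DataFrame]:
    """Grid search by k-fold cross-validation.

    Every grid point is scored by the mean held-out score over ``k``
    seeded shuffled folds; the winner is the argmax, ties broken towards the
    lexicographically smallest (min_impurity_decrease, min_samples_leaf,
    min_samples_split) tuple. Returns the winning hyperparameters and the
    full per-candidate score table.

    min_samples_split = 1 is accepted in the grid but clamps to 2 at fit
    time (a binary split needs two children), so those candidates duplicate
    the value-2 candidates and can only win via the tie-break.
    """
    from .features import feature_matrix

    if "role" in table.columns and (table["role"] == "test").any():
        raise ValueError("table contains rows tagged role='test'; refusing to tune on them")
    grid = grid or default_grid()
    X, y, _names = feature_matrix(table, feature_columns)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} rows")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)

    mids = np.asarray(sorted(grid["min_impurity_decrease"]), dtype=float)
    leaf_vals = sorted(set(grid["min_samples_leaf"]))
    split_vals = sorted(set(grid["min_samples_split"]))

    # scores[(mid, leaf, split)] accumulated over folds
    acc: dict[tuple, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # min_samples_split=1 clamp warning
        for fold_idx in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold_idx] = False
            Xtr, ytr = X[mask], y[mask]
            Xva, yva = X[fold_idx], y[fold_idx]
            for leaf in leaf_vals:
                for split in split_vals:
                    hp = Hyperparams(
                        min_impurity_decrease=0.0,
                        min_samples_leaf=leaf,
                        min_samples_split=split,
                        max_depth=max_depth,
                    )
                    full = fit_tree((Xtr, ytr), hp)
                    # Predictions for every impurity threshold at once: the
                    # pruned-tree prediction of a row is the value of the
                    # first node on its full-tree path whose running-minimum
                    # weighted decrease falls below the threshold.
                    preds = _predictions_by_threshold(full.root, Xva, mids)
                    for m, mid in enumerate(mids):
                        key = (float(mid), leaf, split)
                        s = _score(yva, preds[:, m], scoring)
                        acc[key] = acc.get(key, 0.0) + s / k

    records = [
        {
            "min_impurity_decrease": mid,
            "min_samples_leaf": leaf,
            "min_samples_split": split,
            "mean_score": s,
        }
        for (mid, leaf, split), s in acc.items()
    ]
    scores = pd.DataFrame.from_records(records).sort_values(
        ["min_impurity_decrease", "min_samples_leaf", "min_samples_split"],
        ignore_index=True,
    )
    # argmax with lexicographically-smallest tie-break: the frame is sorted
    # lexicographically, and idxmax returns the first maximal row.
    best_row = scores.loc[scores["mean_score"].idxmax()]
    best = Hyperparams(
        min_impurity_decrease=float(best_row["min_impurity_decrease"]),
        min_samples_leaf=int(best_row["min_samples_leaf"]),
        min_samples_split=int(best_row["min_samples_split"]),
        max_depth=max_depth,
        seed=seed,
    )
    return best, scores


# --------------------------------------------------------------------------
# Permutation importance
# --------------------------------------------------------------------------

def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def permutation_importance(
    model: RegressionTreeModel,
    table: pd.DataFrame,
    n_repeats: int = 50,
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Decrease in R^2 when one feature column is shuffled, per repeat.

    Returns a long-format frame with columns ``feature, repeat, importance``
    (importance = baseline R^2 minus permuted R^2) plus a ``mean_importance``
    column, sorted by descending mean. The full per-repeat distribution is
    retained for violin-style summaries.
    """
    from .features import feature_matrix

    cols = list(feature_columns or model.feature_names)
    X, y, _ = feature_matrix(table, cols)
    baseline = _r2(y, model.predict(X))
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(cols):
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            rows.append(
                {"feature": name, "repeat": r, "importance": baseline - _r2(y, model.predict(Xp))}
            )
    out = pd.DataFrame(rows)
    means = out.groupby("feature")["importance"].mean().rename("mean_importance")
    out = out.merge(means, on="feature")
    return out.sort_values(
        ["mean_importance", "feature", "repeat"], ascending=[False, True, True],
        ignore_index=True,
    )
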