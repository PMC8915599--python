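"""From-scratch Random Forest regression with RSS node splitting, bootstrap
sampling, random descriptor subsetting, out-of-bag validation and
permutation importance.

Each tree recursively splits nodes at the threshold minimizing the residual
sum of squares

    RSS = sum_i (y_i - <y>_L)^2 + sum_j (y_j - <y>_R)^2

over all midpoints between consecutive distinct values of an mtry-sized
random feature subset, stopping when a node holds fewer than 2*nodesize
rows or no split reduces the RSS. Leaf predictions are node means, so the
forest cannot extrapolate: every prediction lies inside the training
response range. Ties in RSS are broken deterministically (lowest feature
index, then lowest threshold). A master seed spawns one independent RNG
stream per tree, so growing more trees never reshuffles earlier ones.

Descriptor importance is OOB permutation importance -- the mean increase in
a tree's out-of-bag MSE when one feature column is shuffled -- rather than
impurity importance, which is biased toward many-valued features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

DEFAULT_NTREE = 500
DEFAULT_NODESIZE = 5


class TreeNode(NamedTuple):
    """View of one node: a split (feature, threshold) or a leaf (value)."""

    feature: int        # -1 for a leaf
    threshold: float
    left: int           # child indices; -1 for a leaf
    right: int
    value: float        # mean response of the node
    count: int


def best_split(x: np.ndarray, y: np.ndarray, min_leaf: int = 1):
    """Best RSS split of one feature; returns ``(threshold, rss)`` or None.

    Thresholds are midpoints between consecutive distinct sorted values of
    ``x``; both sides must keep at least ``min_leaf`` rows. Computed in one
    pass with prefix sums of y and y^2. Ties go to the smallest threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError(f"length mismatch: {n} vs {len(y)}")
    if n < 2 * min_leaf:
        return None
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cs = np.cumsum(ys)
    css = np.cumsum(ys**2)
    total_s, total_ss = cs[-1], css[-1]
    # candidate left sizes k: split between positions k-1 and k
    k = np.arange(1, n)
    valid = (xs[1:] != xs[:-1]) & (k >= min_leaf) & (n - k >= min_leaf)
    if not valid.any():
        return None
    k = k[valid]
    sl, ssl = cs[k - 1], css[k - 1]
    sr, ssr = total_s - sl, total_ss - ssl
    rss = (ssl - sl**2 / k) + (ssr - sr**2 / (n - k))
    rss = np.maximum(rss, 0.0)
    i = int(np.argmin(rss))  # first minimum = smallest threshold (xs ascending)
    thr = 0.5 * (xs[k[i] - 1] + xs[k[i]])
    return float(thr), float(rss[i])


class _TreeBuilder:
    __slots__ = ("feature", "threshold", "left", "right", "value", "count")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []
        self.count: list[int] = []

    def add(self) -> int:
        for a in (self.feature, self.left, self.right):
            a.append(-1)
        self.threshold.append(np.nan)
        self.value.append(np.nan)
        self.count.append(0)
        return len(self.feature) - 1


@dataclass
class Tree:
    """A grown regression tree stored as flat arrays (root = node 0)."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    count: np.ndarray

    def node(self, i: int) -> TreeNode:
        return TreeNode(int(self.feature[i]), float(self.threshold[i]),
                        int(self.left[i]), int(self.right[i]),
                        float(self.value[i]), int(self.count[i]))

    @property
    def n_leaves(self) -> int:
        return int((self.feature == -1).sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        idx = np.zeros(len(X), dtype=np.int64)
        while True:
            feat = self.feature[idx]
            active = feat >= 0
            if not active.any():
                break
            rows = np.nonzero(active)[0]
            f = feat[rows]
            go_left = X[rows, f] < self.threshold[idx[rows]]
            idx[rows] = np.where(go_left, self.left[idx[rows]], self.right[idx[rows]])
        return self.value[idx]

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist()
                for k in ("feature", "threshold", "left", "right", "value", "count")}

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        return cls(
            feature=np.array(d["feature"], dtype=np.int64),
            threshold=np.array(d["threshold"], dtype=float),
            left=np.array(d["left"], dtype=np.int64),
            right=np.array(d["right"], dtype=np.int64),
            value=np.array(d["value"], dtype=float),
            count=np.array(d["count"], dtype=np.int64),
        )


def grow_tree(X: np.ndarray, y: np.ndarray, mtry: int, nodesize: int,
              rng: np.random.Generator) -> Tree:
    """Grow one RSS regression tree.

    At each node an ``mtry``-subset of features is drawn from ``rng``; the
    node becomes a leaf when it holds fewer than ``2*nodesize`` rows or no
    candidate split reduces the RSS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < nodesize:
        raise ValueError(f"need at least nodesize={nodesize} rows, got {n}")
    mtry = max(1, min(mtry, p))
    b = _TreeBuilder()

    def build(rows: np.ndarray) -> int:
        i = b.add()
        yr = y[rows]
        b.value[i] = float(yr.mean())
        b.count[i] = len(rows)
        if len(rows) < 2 * nodesize:
            return i
        node_rss = float(np.sum((yr - yr.mean()) ** 2))
        feats = np.sort(rng.choice(p, size=mtry, replace=False))
        best = None  # (rss, feature, threshold)
        for f in feats:
            cand = best_split(X[rows, f], yr, min_leaf=nodesize)
            if cand is None:
                continue
            thr, rss = cand
            if best is None or rss < best[0] - 1e-12 or (
                abs(rss - best[0]) <= 1e-12 and (f, thr) < best[1:]
            ):
                best = (rss, int(f), thr)
        if best is None or best[0] >= node_rss - 1e-12:
            return i
        _, f, thr = best
        go_left = X[rows, f] < thr
        b.feature[i], b.threshold[i] = f, thr
        b.left[i] = build(rows[go_left])
        b.right[i] = build(rows[~go_left])
        return i

    build(np.arange(n))
    return Tree(
        feature=np.array(b.feature, dtype=np.int64),
        threshold=np.array(b.threshold, dtype=float),
        left=np.array(b.left, dtype=np.int64),
        right=np.array(b.right, dtype=np.int64),
        value=np.array(b.value, dtype=float),
        count=np.array(b.count, dtype=np.int64),
    )


@dataclass
class Forest:
    """A fitted random forest with its OOB diagnostics."""

    trees: list[Tree]
    ntree: int
    mtry: int
    nodesize: int
    seed: int
    feature_names: list[str]
    y_range: tuple[float, float]
    oob_predictions: np.ndarray          # NaN where a row was never OOB
    oob_counts: np.ndarray
    feature_importance: pd.Series        # mean OOB MSE increase per feature
    extra: dict = field(default_factory=dict)

    def predict(self, X, return_sd: bool = False):
        """Mean (and optional per-row SD) over the per-tree predictions."""
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature column(s) {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        preds = np.stack([t.predict(X) for t in self.trees])
        mean = preds.mean(axis=0)
        if return_sd:
            return mean, preds.std(axis=0)
        return mean

    def oob_mse(self, y: np.ndarray) -> float:
        have = self.oob_counts > 0
        return float(np.mean((self.oob_predictions[have] - np.asarray(y)[have]) ** 2))

    def summary(self) -> str:
        top = self.feature_importance.sort_values(ascending=False).head(10)
        lines = [
            f"Random forest: ntree={self.ntree} mtry={self.mtry} "
            f"nodesize={self.nodesize} seed={self.seed}",
            f"features: {len(self.feature_names)}; training response range "
            f"[{self.y_range[0]:.3f}, {self.y_range[1]:.3f}]",
            "top importances (OOB permutation, MSE increase):",
        ]
        lines += [f"  {k:>24} {v:10.4f}" for k, v in top.items()]
        return "\n".join(lines)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "ntree": self.ntree, "mtry": self.mtry, "nodesize": self.nodesize,
                "seed": self.seed, "feature_names": self.feature_names,
                "y_range": list(self.y_range),
                "trees": [t.to_dict() for t in self.trees],
            }, fh)

    @classmethod
    def load(cls, path) -> "Forest":
        with open(path) as fh:
            d = json.load(fh)
        trees = [Tree.from_dict(t) for t in d["trees"]]
        p = len(d["feature_names"])
        return cls(
            trees=trees, ntree=d["ntree"], mtry=d["mtry"], nodesize=d["nodesize"],
            seed=d["seed"], feature_names=d["feature_names"],
            y_range=tuple(d["y_range"]),
            oob_predictions=np.full(0, np.nan), oob_counts=np.zeros(0, dtype=int),
            feature_importance=pd.Series(np.nan, index=d["feature_names"]),
        )


def rfr_fit(
    X, y, ntree: int = DEFAULT_NTREE, mtry: int | None = None,
    nodesize: int = DEFAULT_NODESIZE, seed: int = 0,
    importance: bool = True,
) -> Forest:
    """Fit the forest: ``ntree`` trees, each on a bootstrap (with
    replacement) sample of the rows, with ``mtry`` (default p/3) features
    drawn per node.

    OOB predictions average, per row, the trees whose bootstrap missed that
    row. Permutation importance is the mean over trees of the OOB MSE
    increase on shuffling one feature.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2 * nodesize:
        raise ValueError(f"need at least 2*nodesize={2*nodesize} rows, got {n}")
    if mtry is None:
        mtry = max(1, p // 3)

    streams = np.random.SeedSequence(seed).spawn(ntree)
    trees: list[Tree] = []
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=int)
    imp_sum = np.zeros(p)
    imp_cnt = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        boot = rng.integers(0, n, size=n)
        tree = grow_tree(X[boot], y[boot], mtry=mtry, nodesize=nodesize, rng=rng)
        trees.append(tree)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        if oob.any():
            Xo = X[oob]
            pred = tree.predict(Xo)
            oob_sum[oob] += pred
            oob_cnt[oob] += 1
            if importance:
                base_mse = np.mean((pred - y[oob]) ** 2)
                m = len(Xo)
                for j in range(p):
                    perm = rng.permutation(m)
                    Xp = Xo.copy()
                    Xp[:, j] = Xo[perm, j]
                    imp_sum[j] += np.mean((tree.predict(Xp) - y[oob]) ** 2) - base_mse
                imp_cnt += 1

    oob_pred = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
    fi = pd.Series(imp_sum / imp_cnt if imp_cnt else np.nan, index=feature_names)
    return Forest(
        trees=trees, ntree=ntree, mtry=mtry, nodesize=nodesize, seed=seed,
        feature_names=feature_names, y_range=(float(y.min()), float(y.max())),
        oob_predictions=oob_pred, oob_counts=oob_cnt, feature_importance=fi,
        extra={"never_oob_rows": int((oob_cnt == 0).sum())},
    )


def rfr_predict(forest: Forest, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean and SD over the per-tree predictions."""
    return forest.predict(X_new, return_sd=True)


class RandomForestSolubility:
    """Model facade: construct from data, ``fit()`` returns a :class:`Forest`.

    A ``backend="sklearn"`` option delegates to scikit-learn's forest for
    cross-validation of this implementation; the in-repo forest is the
    reference and the default.
    """

    def __init__(self, X, y, ntree: int = DEFAULT_NTREE, mtry: int | None = None,
                 nodesize: int = DEFAULT_NODESIZE, seed: int = 0,
                 backend: str = "native"):
        if backend not in ("native", "sklearn"):
            raise ValueError(backend)
        self.X, self.y = X, y
        self.ntree, self.mtry, self.nodesize, self.seed = ntree, mtry, nodesize, seed
        self.backend = backend

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y_col: str = "log_s0", **kw):
        X = df.drop(columns=[y_col])
        return cls(X, df[y_col], **kw)

    def fit(self):
        if self.backend == "sklearn":
            from sklearn.ensemble import RandomForestRegressor

            p = self.X.shape[1]
            est = RandomForestRegressor(
                n_estimators=self.ntree,
                max_features=self.mtry or max(1, p // 3),
                min_samples_leaf=self.nodesize,
                oob_score=True, random_state=self.seed, bootstrap=True,
            )
            est.fit(np.asarray(self.X, dtype=float), np.asarray(self.y, dtype=float))
            return est
        return rfr_fit(self.X, self.y, ntree=self.ntree, mtry=self.mtry,
                       nodesize=self.nodesize, seed=self.seed)
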