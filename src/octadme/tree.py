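"""CART regression trees for 12-month visual outcome, plus the published tree.

Greedy binary recursive partitioning minimizing within-node sum of squared
errors (SSE).  Split candidates are midpoints of consecutive sorted unique
predictor values (a 0/1 flag therefore splits at 0.5); the condition
``x >= threshold`` routes to the high branch, matching the closed lower
bounds of the published node labels (CMT >= 373 µm, DCP LAC >= 0.41).
Ties are broken deterministically: predictor declaration order first, then
the smaller threshold.  Model selection across a small hyperparameter grid
uses the training determination coefficient r^2 — the study reports a
training r^2, so no pruning or cross-validation is applied by default
(an overfitting caveat worth keeping in mind; see docs/methods.md).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class UnspecifiedLeafError(ValueError):
    """Prediction routed into a leaf whose value was never published or set."""


class MissingPredictorError(KeyError):
    """A record lacks a variable the tree tests."""


@dataclass
class TreeNode:
    """One node of a binary regression tree.

    Internal nodes carry ``split_var`` and ``threshold`` (``x >=
    threshold`` goes to ``high``); leaves carry neither.  ``value`` is the
    mean outcome at the node (may be ``None`` for published-but-unprinted
    leaves) and ``n`` the training count (``None`` when unknown).
    """

    value: float | None = None
    n: int | None = None
    split_var: str | None = None
    threshold: float | None = None
    low: "TreeNode | None" = None
    high: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.low.leaves() + self.high.leaves()

    def n_leaves(self) -> int:
        return len(self.leaves())

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.low.depth(), self.high.depth())


@dataclass
class RegressionTree:
    """A fitted (or published) tree plus the outcome/predictor metadata."""

    root: TreeNode
    outcome: str = "bcva_final"
    predictors: tuple[str, ...] = ()

    def predict_record(self, record: Mapping) -> float:
        return predict(self, record)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return np.array([predict(self, row) for _, row in table.iterrows()])


DEFAULT_PREDICTORS = (
    "vma", "cmt_baseline", "lac_dcp", "lac_scp", "vpd_dcp", "vpd_scp",
    "bcva_baseline",
)


@dataclass
class TreeFitConfig:
    """Hyperparameter grid for automatic tree generation.

    One tree is fitted per (max_depth, min_leaf_n) grid point and the
    training-r^2 winner kept.  ``min_sse_gain`` is the absolute SSE
    improvement required to accept a split; the near-zero default accepts
    effectively any gain.
    """

    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    max_depth_grid: tuple[int, ...] = (1, 2, 3, 4)
    min_leaf_n_grid: tuple[int, ...] = (5, 10)
    min_sse_gain: float = 1e-9

    def __post_init__(self) -> None:
        if not self.max_depth_grid or not self.min_leaf_n_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if min(self.min_leaf_n_grid) < 2:
            raise ValueError("min_leaf_n must be >= 2")


def _best_split(
    X: dict[str, np.ndarray],
    y: np.ndarray,
    predictors: tuple[str, ...],
    min_leaf_n: int,
) -> tuple[str, float, float] | None:
    """Best (predictor, threshold, sse_gain), or None if no valid split.

    Vectorized over candidate thresholds via prefix sums; deterministic
    tie-break by predictor order then smaller threshold (strict ``>``
    comparisons keep the first best seen).
    """
    n = len(y)
    best: tuple[str, float, float] | None = None
    best_gain = 0.0
    sse_parent_term = y.sum() ** 2 / n
    for name in predictors:
        x = X[name]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        cut = np.nonzero(xs[:-1] < xs[1:])[0]  # split after position i
        if cut.size == 0:
            continue
        n_left = cut + 1
        n_right = n - n_left
        valid = (n_left >= min_leaf_n) & (n_right >= min_leaf_n)
        cut = cut[valid]
        if cut.size == 0:
            continue
        csum = np.cumsum(ys)
        s_left = csum[cut]
        s_right = csum[-1] - s_left
        n_left = cut + 1
        n_right = n - n_left
        gain = s_left**2 / n_left + s_right**2 / n_right - sse_parent_term
        k = int(np.argmax(gain))  # first max -> smallest threshold
        if gain[k] > best_gain:
            best_gain = float(gain[k])
            thr = (xs[cut[k]] + xs[cut[k] + 1]) / 2.0
            best = (name, float(thr), best_gain)
    return best


def fit_regression_tree(
    table: pd.DataFrame,
    outcome: str = "bcva_final",
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    max_depth: int = 3,
    min_leaf_n: int = 5,
    min_sse_gain: float = 1e-9,
) -> RegressionTree:
    """Greedy CART fit at a single hyperparameter point.

    Stops a branch on ``max_depth``, on children smaller than
    ``min_leaf_n``, or when the best achievable SSE reduction falls below
    ``min_sse_gain``.  A constant outcome yields a single-leaf tree with
    a warning.
    """
    predictors = tuple(p for p in predictors if p in table.columns)
    if not predictors:
        raise ValueError("no configured predictor present in the table")
    rows = table[list(predictors) + [outcome]].dropna()
    if len(rows) < 2 * min_leaf_n:
        raise ValueError(
            f"too few rows ({len(rows)}) for min_leaf_n={min_leaf_n}"
        )
    y = rows[outcome].to_numpy(dtype=float)
    X = {p: rows[p].to_numpy(dtype=float) for p in predictors}
    if np.ptp(y) == 0:
        warnings.warn("constant outcome: returning a single-leaf tree")
        root = TreeNode(value=float(y[0]), n=len(y))
        return RegressionTree(root=root, outcome=outcome, predictors=predictors)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node_y = y[idx]
        node = TreeNode(value=float(node_y.mean()), n=len(idx))
        if depth >= max_depth or len(idx) < 2 * min_leaf_n:
            return node
        split = _best_split({p: X[p][idx] for p in predictors}, node_y,
                            predictors, min_leaf_n)
        if split is None or split[2] < min_sse_gain:
            return node
        name, thr, _ = split
        go_high = X[name][idx] >= thr
        node.split_var, node.threshold = name, thr
        node.low = build(idx[~go_high], depth + 1)
        node.high = build(idx[go_high], depth + 1)
        return node

    root = build(np.arange(len(y)), 0)
    return RegressionTree(root=root, outcome=outcome, predictors=predictors)


def predict(tree: RegressionTree, record: Mapping) -> float:
    """Route one record to its leaf value.

    Boundary equality routes high (``x >= threshold``), matching the
    published closed lower bounds.  Raises on a missing tested variable
    or an unset leaf value.
    """
    node = tree.root
    while not node.is_leaf:
        try:
            x = record[node.split_var]
        except (KeyError, IndexError) as exc:
            raise MissingPredictorError(
                f"record lacks tested variable {node.split_var!r}"
            ) from exc
        if x is None or (isinstance(x, float) and np.isnan(x)):
            raise MissingPredictorError(
                f"record has missing value for tested variable {node.split_var!r}"
            )
        node = node.high if float(x) >= node.threshold else node.low
    if node.value is None:
        raise UnspecifiedLeafError(
            "prediction routed into a leaf with no published/overridden value"
        )
    return float(node.value)


def r_squared(tree: RegressionTree, table: pd.DataFrame,
              outcome: str | None = None) -> float:
    """Determination coefficient r^2 = 1 - SSE/SST of tree predictions."""
    outcome = outcome or tree.outcome
    rows = table.dropna(subset=[outcome])
    if len(rows) == 0:
        raise ValueError("empty table")
    y = rows[outcome].to_numpy(dtype=float)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("outcome has zero variance: r^2 undefined")
    yhat = tree.predict_table(rows)
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst


def select_best_tree(
    table: pd.DataFrame,
    config: TreeFitConfig | None = None,
    outcome: str = "bcva_final",
) -> tuple[RegressionTree, float]:
    """Fit one tree per grid point and keep the training-r^2 winner.

    Ties go to the tree with fewer leaves, then to the lower max_depth —
    a deterministic preference for the simpler model.
    """
    config = config or TreeFitConfig()
    best: tuple[RegressionTree, float, int, int] | None = None
    errors = []
    for depth in sorted(config.max_depth_grid):
        for min_leaf in sorted(config.min_leaf_n_grid):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tree = fit_regression_tree(
                        table, outcome=outcome, predictors=config.predictors,
                        max_depth=depth, min_leaf_n=min_leaf,
                        min_sse_gain=config.min_sse_gain,
                    )
                    r2 = r_squared(tree, table)
            except (ValueError, KeyError) as exc:
                errors.append(f"depth={depth}, min_leaf={min_leaf}: {exc}")
                continue
            key = (r2, -tree.root.n_leaves(), -depth)
            if best is None or key > (best[1], -best[2], -best[3]):
                best = (tree, r2, tree.root.n_leaves(), depth)
    if best is None:
        raise ValueError("all grid fits failed: " + "; ".join(errors))
    return best[0], best[1]


# ---------------------------------------------------------------------------
# the published outcome tree
# ---------------------------------------------------------------------------

def published_tree(
    leaf_overrides: Mapping[str, float] | None = None,
) -> RegressionTree:
    """The published regression tree for 12-month BCVA.

    Structure: VMA at the root (present -> worse outcome); VMA-absent
    eyes split on baseline CMT >= 373 µm; the thick-CMT node (value 71
    letters, n = 36) splits on DCP LAC >= 0.41 into leaves 65 letters
    (n = 10) and 73 letters (n = 26).  The VMA-present and thin-CMT leaf
    values were never printed and default to unset: predicting into them
    raises :class:`UnspecifiedLeafError` unless ``leaf_overrides``
    supplies ``"vma_present"`` / ``"cmt_low"`` values.
    """
    ov = dict(leaf_overrides or {})
    unknown = set(ov) - {"vma_present", "cmt_low",
                         "cmt_high_lac_high", "cmt_high_lac_low"}
    if unknown:
        raise ValueError(f"unknown leaf overrides: {sorted(unknown)}")
    lac_high = TreeNode(value=ov.get("cmt_high_lac_high", 65.0), n=10)
    lac_low = TreeNode(value=ov.get("cmt_high_lac_low", 73.0), n=26)
    cmt_high = TreeNode(value=71.0, n=36, split_var="lac_dcp", threshold=0.41,
                        low=lac_low, high=lac_high)
    cmt_low = TreeNode(value=ov.get("cmt_low"), n=None)
    vma_absent = TreeNode(split_var="cmt_baseline", threshold=373.0,
                          low=cmt_low, high=cmt_high)
    vma_present = TreeNode(value=ov.get("vma_present"), n=None)
    root = TreeNode(split_var="vma", threshold=0.5,
                    low=vma_absent, high=vma_present)
    return RegressionTree(root=root, outcome="bcva_final",
                          predictors=("vma", "cmt_baseline", "lac_dcp"))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _node_to_dict(node: TreeNode) -> dict:
    d: dict = {"value": node.value, "n": node.n}
    if not node.is_leaf:
        d.update(
            split_var=node.split_var,
            threshold=node.threshold,
            low=_node_to_dict(node.low),
            high=_node_to_dict(node.high),
        )
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(value=d.get("value"), n=d.get("n"))
    if "split_var" in d:
        node.split_var = d["split_var"]
        node.threshold = float(d["threshold"])
        node.low = _node_from_dict(d["low"])
        node.high = _node_from_dict(d["high"])
    return node


def tree_to_dict(tree: RegressionTree) -> dict:
    return {
        "outcome": tree.outcome,
        "predictors": list(tree.predictors),
        "root": _node_to_dict(tree.root),
    }


def tree_from_dict(d: dict) -> RegressionTree:
    return RegressionTree(
        root=_node_from_dict(d["root"]),
        outcome=d.get("outcome", "bcva_final"),
        predictors=tuple(d.get("predictors", ())),
    )


def save_tree(tree: RegressionTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=2) + "\n")


def load_tree(path: str | Path) -> RegressionTree:
    return tree_from_dict(json.loads(Path(path).read_text()))
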