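"""Binary regression tree with variance-reduction splits.

Recursive partitioning for a continuous outcome (here, logit-transformed
RPD).  At each node the split — a threshold on an ordered predictor or a
category subset on a nominal one — is the one maximizing the reduction
in within-node sum of squared errors,

    dSSE = SSE(parent) - SSE(left) - SSE(right),

computed over the subjects with the candidate variable observed.
Growth stops when a node reaches the maximum depth, its outcome
variance falls below ``minvariance``, or no admissible split (both
children at least ``minleafsize`` observed subjects, dSSE > 0) exists.

Missing values never participate in choosing a split; they are routed
by *surrogate* rules — splits on other variables ranked by how well
they agree with the primary split on subjects where both are observed —
with a final fallback to the branch that received the majority of the
node.  Leaves predict their mean outcome.

Variable importance is each variable's share of the total dSSE over all
primary splits, scaled to sum to 100, with a count of how many times
the variable was split on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .predictors import PredictorTable

__all__ = [
    "Hyperparams",
    "PRESETS",
    "SplitRule",
    "SurrogateRule",
    "TreeNode",
    "Tree",
    "best_split_threshold",
    "best_split_subset",
    "grow_tree",
    "route",
    "predict",
    "predict_frame",
    "variable_importance",
    "export_tree",
    "import_tree",
]

MAX_SURROGATES = 5


@dataclass(frozen=True)
class Hyperparams:
    """Stopping-rule knobs (binary splits are fixed).

    ``minvariance`` is compared against the node's population variance
    of the outcome (SSE/n), a scale-free per-node stopping bound.
    """

    maxdepth: int = 5
    minleafsize: int = 1
    minvariance: float = 1e-8

    def __post_init__(self):
        if self.maxdepth < 1:
            raise ConfigError("maxdepth must be >= 1")
        if self.minleafsize < 1:
            raise ConfigError("minleafsize must be >= 1")
        if self.minvariance < 0:
            raise ConfigError("minvariance must be >= 0")


#: the primary-analysis defaults and the sensitivity-analysis preset
PRESETS = {
    "default": Hyperparams(maxdepth=5, minleafsize=1, minvariance=1e-8),
    "sensitivity": Hyperparams(maxdepth=10, minleafsize=10, minvariance=0.01),
}


@dataclass(frozen=True)
class SurrogateRule:
    """Backup routing rule, scored by agreement with the primary split."""

    variable: str
    kind: str  # "threshold" | "subset"
    agreement: float
    threshold: float | None = None
    left_if_less: bool = True
    left_set: tuple = ()


@dataclass(frozen=True)
class SplitRule:
    variable: str
    kind: str  # "threshold" | "subset"
    sse_reduction: float
    threshold: float | None = None  # value < threshold goes left
    left_set: tuple = ()  # value in left_set goes left
    surrogates: tuple = ()
    majority_branch: str = "left"


@dataclass
class TreeNode:
    id: int
    depth: int
    n: int
    mean: float
    sse: float
    rule: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.rule is None

    def walk(self):
        yield self
        if not self.is_leaf:
            yield from self.left.walk()
            yield from self.right.walk()


@dataclass
class Tree:
    root: TreeNode
    hyperparams: Hyperparams
    columns: list[str]
    kinds: dict[str, str]  # column -> "numeric" | "nominal"
    n: int
    training_ase: float

    def leaves(self):
        return [nd for nd in self.root.walk() if nd.is_leaf]

    @property
    def depth(self) -> int:
        return max(nd.depth for nd in self.root.walk())

    def split_variables(self) -> list[str]:
        return [nd.rule.variable for nd in self.root.walk() if not nd.is_leaf]


# -- split search ---------------------------------------------------------


def _scan_ordered(ys: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """dSSE at every candidate left-count, for mean-centered sorted ys.

    ``boundaries`` are the admissible left-group sizes.  Centering makes
    the identity dSSE = S_l^2/n_l + S_r^2/n_r exact and non-negative.
    """
    n = len(ys)
    cs = np.cumsum(ys)
    total = cs[-1]
    nl = boundaries
    sl = cs[nl - 1]
    sr = total - sl
    return sl * sl / nl + sr * sr / (n - nl)


def best_split_threshold(values, y, minleafsize: int = 1):
    """Best ``x < c`` split of an ordered column, or None.

    Candidate thresholds are midpoints between consecutive distinct
    observed values; rows with ``values`` missing are excluded.  Returns
    ``(threshold, sse_reduction)`` for the dSSE-maximizing admissible
    cut (smallest threshold on ties), or None when no cut leaves
    ``minleafsize`` observed rows on both sides with dSSE > 0.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(values)
    x, yy = values[obs], y[obs]
    n = len(x)
    if n < 2 * minleafsize:
        return None
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], yy[order] - yy.mean()
    i = np.arange(1, n)
    valid = (xs[1:] > xs[:-1]) & (i >= minleafsize) & (i <= n - minleafsize)
    if not valid.any():
        return None
    nl = i[valid]
    delta = _scan_ordered(ys, nl)
    best = int(np.argmax(delta))
    if delta[best] <= 0.0:
        return None
    pos = nl[best]
    threshold = (xs[pos - 1] + xs[pos]) / 2.0
    return float(threshold), float(delta[best])


#: nominal columns with at most this many observed categories are split by
#: exhaustive subset enumeration (2^(k-1)-1 partitions); wider ones use the
#: mean-ordering scan, which is optimal only when minleafsize is 1
EXHAUSTIVE_SUBSET_MAX_K = 10


def best_split_subset(categories, y, minleafsize: int = 1):
    """Best category-subset split of a nominal column, or None.

    For up to ``EXHAUSTIVE_SUBSET_MAX_K`` observed categories every
    binary partition is scored (necessary for exactness: under a
    minleafsize constraint the optimum need not be contiguous in the
    category-mean ordering).  Wider nominals fall back to ordering
    categories by their within-node outcome mean and scanning like an
    ordered variable.  Returns ``(left_set, sse_reduction)`` with
    ``left_set`` a sorted tuple of the categories routed left.
    """
    import itertools

    y = np.asarray(y, dtype=float)
    cats = pd.Series(list(categories))
    obs = cats.notna().to_numpy()
    cc, yy = cats[obs], y[obs]
    n = len(cc)
    if n < 2 * minleafsize:
        return None
    yy = yy - yy.mean()
    groups = pd.DataFrame({"c": cc.to_numpy(), "y": yy}).groupby("c", sort=True)["y"]
    stats = pd.DataFrame({"sum": groups.sum(), "count": groups.size()})
    if len(stats) < 2:
        return None
    k = len(stats)
    labels = list(stats.index)
    counts = stats["count"].to_numpy(dtype=float)
    sums = stats["sum"].to_numpy()
    total = sums.sum()

    def delta_for(nl, sl):
        return sl * sl / nl + (total - sl) ** 2 / (n - nl)

    if k <= EXHAUSTIVE_SUBSET_MAX_K:
        # each partition enumerated once: the left side never holds the
        # last label; combinations() order makes ties deterministic
        best = None
        for r in range(1, k):
            for subset in itertools.combinations(range(k - 1), r):
                nl = counts[list(subset)].sum()
                if nl < minleafsize or n - nl < minleafsize:
                    continue
                d = delta_for(nl, sums[list(subset)].sum())
                if best is None or d > best[0]:
                    best = (d, subset)
        if best is None or best[0] <= 0.0:
            return None
        left_set = tuple(sorted(labels[i] for i in best[1]))
        return left_set, float(best[0])

    order = stats.assign(mean=stats["sum"] / stats["count"]).sort_values(
        ["mean"], kind="stable"
    )
    counts_o = order["count"].to_numpy(dtype=float)
    sums_o = order["sum"].to_numpy()
    nl_group = np.cumsum(counts_o)[:-1]
    valid = (nl_group >= minleafsize) & (nl_group <= n - minleafsize)
    if not valid.any():
        return None
    cum_sums = np.cumsum(sums_o)[:-1]
    delta = delta_for(nl_group[valid], cum_sums[valid])
    best_i = int(np.argmax(delta))
    if delta[best_i] <= 0.0:
        return None
    pos = np.nonzero(valid)[0][best_i] + 1
    left_set = tuple(sorted(order.index[:pos]))
    return left_set, float(delta[best_i])


# -- internal feature container ------------------------------------------


class _Feature:
    """One predictor column pre-converted for fast node-level slicing."""

    __slots__ = ("name", "nominal", "x", "codes", "categories")

    def __init__(self, name: str, series: pd.Series, nominal: bool):
        self.name = name
        self.nominal = nominal
        if nominal:
            cats = pd.Categorical(series.astype(object))
            order = np.argsort([str(c) for c in cats.categories], kind="stable")
            self.categories = [cats.categories[i] for i in order]
            remap = {old: new for new, old in enumerate(order)}
            codes = cats.codes.astype(int)
            self.codes = np.array([remap[c] if c >= 0 else -1 for c in codes])
            self.x = None
        else:
            self.x = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
            self.codes = None
            self.categories = None

    def observed(self, idx: np.ndarray) -> np.ndarray:
        if self.nominal:
            return self.codes[idx] >= 0
        return ~np.isnan(self.x[idx])


def _as_features(X) -> tuple[list[_Feature], list[str], dict[str, str]]:
    if isinstance(X, PredictorTable):
        df, kinds_in = X.data, X.kinds()
        nominal = {c: kinds_in[c] == "nominal" for c in df.columns}
    elif isinstance(X, pd.DataFrame):
        df = X
        nominal = {
            c: not pd.api.types.is_numeric_dtype(df[c].dtype) for c in df.columns
        }
    else:
        raise ContractError("X must be a PredictorTable or a pandas DataFrame")
    feats = [_Feature(c, df[c], nominal[c]) for c in df.columns]
    kinds = {c: ("nominal" if nominal[c] else "numeric") for c in df.columns}
    return feats, list(df.columns), kinds


# -- growth ---------------------------------------------------------------


def _primary_left(feat: _Feature, idx: np.ndarray, rule_threshold, rule_left_set):
    """(observed mask, goes-left mask among observed) for the primary rule."""
    if feat.nominal:
        codes = feat.codes[idx]
        obs = codes >= 0
        left_codes = {feat.categories.index(c) for c in rule_left_set}
        left = np.isin(codes[obs], list(left_codes))
    else:
        x = feat.x[idx]
        obs = ~np.isnan(x)
        left = x[obs] < rule_threshold
    return obs, left


def _surrogates_for(
    feats: list[_Feature],
    idx: np.ndarray,
    primary_col: int,
    obs_primary: np.ndarray,
    left_primary_obs: np.ndarray,
) -> tuple:
    """Rank backup rules by agreement with the primary split.

    Agreement is evaluated on subjects with both the primary and the
    candidate variable observed; only rules beating the go-with-the-
    majority baseline are kept.
    """
    left_full = np.zeros(len(idx), dtype=bool)
    left_full[np.nonzero(obs_primary)[0]] = left_primary_obs
    found = []
    for ci, feat in enumerate(feats):
        if ci == primary_col:
            continue
        obs_v = feat.observed(idx)
        both = obs_primary & obs_v
        m = int(both.sum())
        if m == 0:
            continue
        L = left_full[both]
        baseline = max(L.sum(), m - L.sum()) / m
        if feat.nominal:
            codes = feat.codes[idx][both]
            k = len(feat.categories)
            left_counts = np.bincount(codes, weights=L.astype(float), minlength=k)
            tot_counts = np.bincount(codes, minlength=k)
            present = tot_counts > 0
            go_left = left_counts > (tot_counts - left_counts)
            agree = int(
                left_counts[go_left & present].sum()
                + (tot_counts - left_counts)[~go_left & present].sum()
            )
            agreement = agree / m
            if agreement <= baseline:
                continue
            left_set = tuple(
                sorted(feat.categories[j] for j in range(k) if present[j] and go_left[j])
            )
            found.append(
                (agreement, ci, SurrogateRule(feat.name, "subset", agreement, left_set=left_set))
            )
        else:
            x = feat.x[idx][both]
            order = np.argsort(x, kind="stable")
            xs, Ls = x[order], L[order].astype(int)
            i = np.arange(1, m)
            valid = xs[1:] > xs[:-1]
            if not valid.any():
                continue
            nl = i[valid]
            cum_left = np.cumsum(Ls)
            n_left_total = cum_left[-1]
            # orientation A: x < c -> left
            agree_a = cum_left[nl - 1] + ((m - nl) - (n_left_total - cum_left[nl - 1]))
            # orientation B: x < c -> right
            agree_b = m - agree_a
            best_a, best_b = int(np.argmax(agree_a)), int(np.argmax(agree_b))
            if agree_a[best_a] >= agree_b[best_b]:
                pos, agree, left_if_less = nl[best_a], int(agree_a[best_a]), True
            else:
                pos, agree, left_if_less = nl[best_b], int(agree_b[best_b]), False
            agreement = agree / m
            if agreement <= baseline:
                continue
            thr = float((xs[pos - 1] + xs[pos]) / 2.0)
            found.append(
                (
                    agreement,
                    ci,
                    SurrogateRule(
                        feat.name, "threshold", agreement, threshold=thr, left_if_less=left_if_less
                    ),
                )
            )
    found.sort(key=lambda t: (-t[0], t[1]))
    return tuple(sr for _, _, sr in found[:MAX_SURROGATES])


def _route_missing(
    feats_by_name: dict, idx: np.ndarray, rows: np.ndarray, surrogates, majority: str
) -> np.ndarray:
    """Left/right for node members whose primary value is missing."""
    goes_left = np.full(len(rows), majority == "left")
    decided = np.zeros(len(rows), dtype=bool)
    for sr in surrogates:
        feat = feats_by_name[sr.variable]
        sub = idx[rows]
        if feat.nominal:
            codes = feat.codes[sub]
            obs = codes >= 0
            left_codes = {feat.categories.index(c) for c in sr.left_set}
            sleft = np.isin(codes, list(left_codes))
        else:
            x = feat.x[sub]
            obs = ~np.isnan(x)
            with np.errstate(invalid="ignore"):
                sleft = (x < sr.threshold) == sr.left_if_less
        use = obs & ~decided
        goes_left[use] = sleft[use]
        decided |= obs
        if decided.all():
            break
    return goes_left


def grow_tree(X, y, hp: Hyperparams | None = None) -> Tree:
    """Fit the regression tree.

    ``X`` is a :class:`~rpdtree.predictors.PredictorTable` or a plain
    DataFrame (non-numeric dtypes treated as nominal); ``y`` must be
    numeric with no missing values.  Growth is depth-first and fully
    deterministic: ties between candidate splits go to the earlier
    column, then the smaller threshold / lexicographically smaller
    category subset.
    """
    hp = hp or PRESETS["default"]
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) == 0:
        raise ContractError("y must be a non-empty 1-D numeric array")
    if np.isnan(y).any():
        raise ContractError("y must not contain missing values")
    feats, columns, kinds = _as_features(X)
    if feats and len(feats[0].x if not feats[0].nominal else feats[0].codes) != len(y):
        raise ContractError("X and y lengths differ")
    feats_by_name = {f.name: f for f in feats}

    counter = {"next_id": 0}

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node_id = counter["next_id"]
        counter["next_id"] += 1
        yy = y[idx]
        mean = float(yy.mean())
        sse = float(((yy - mean) ** 2).sum())
        node = TreeNode(id=node_id, depth=depth, n=len(idx), mean=mean, sse=sse)
        if depth >= hp.maxdepth or sse / len(idx) < hp.minvariance:
            return node

        best = None  # (delta, col_index, kind, payload)
        for ci, feat in enumerate(feats):
            if feat.nominal:
                res = best_split_subset(
                    [feat.categories[c] if c >= 0 else None for c in feat.codes[idx]],
                    yy,
                    hp.minleafsize,
                )
                if res is not None:
                    left_set, delta = res
                    if best is None or delta > best[0]:
                        best = (delta, ci, "subset", left_set)
            else:
                res = best_split_threshold(feat.x[idx], yy, hp.minleafsize)
                if res is not None:
                    thr, delta = res
                    if best is None or delta > best[0]:
                        best = (delta, ci, "threshold", thr)
        if best is None:
            return node

        delta, ci, kind, payload = best
        feat = feats[ci]
        thr = payload if kind == "threshold" else None
        left_set = payload if kind == "subset" else ()
        obs, left_obs = _primary_left(feat, idx, thr, left_set)
        majority = "left" if left_obs.sum() * 2 >= left_obs.size else "right"
        has_missing = not obs.all()
        surrogates = (
            _surrogates_for(feats, idx, ci, obs, left_obs) if has_missing else ()
        )
        goes_left = np.zeros(len(idx), dtype=bool)
        goes_left[np.nonzero(obs)[0]] = left_obs
        if has_missing:
            miss_rows = np.nonzero(~obs)[0]
            goes_left[miss_rows] = _route_missing(
                feats_by_name, idx, miss_rows, surrogates, majority
            )
        node.rule = SplitRule(
            variable=feat.name,
            kind=kind,
            sse_reduction=float(delta),
            threshold=thr,
            left_set=left_set,
            surrogates=surrogates,
            majority_branch=majority,
        )
        node.left = build(idx[goes_left], depth + 1)
        node.right = build(idx[~goes_left], depth + 1)
        return node

    root = build(np.arange(len(y)), 0)
    leaf_sse = sum(nd.sse for nd in root.walk() if nd.is_leaf)
    return Tree(
        root=root,
        hyperparams=hp,
        columns=columns,
        kinds=kinds,
        n=len(y),
        training_ase=leaf_sse / len(y),
    )


# -- application ----------------------------------------------------------


def _value_missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(np.isnan(v))
    except TypeError:
        return False


def _rule_side(kind, threshold, left_set, left_if_less, value) -> bool:
    if kind == "threshold":
        return (float(value) < threshold) == left_if_less
    return value in left_set


def route(x_row, node: TreeNode) -> str:
    """One routing step: 'left' or 'right' for this subject at this node.

    Primary rule if its variable is observed; else the best-agreeing
    surrogate with an observed value; else the majority branch.  Total —
    never errors on missing data.
    """
    if node.is_leaf:
        raise ContractError("cannot route at a leaf")
    rule = node.rule
    v = x_row.get(rule.variable)
    if not _value_missing(v):
        left = _rule_side(rule.kind, rule.threshold, rule.left_set, True, v)
        return "left" if left else "right"
    for sr in rule.surrogates:
        sv = x_row.get(sr.variable)
        if not _value_missing(sv):
            left = _rule_side(sr.kind, sr.threshold, sr.left_set, sr.left_if_less, sv)
            return "left" if left else "right"
    return rule.majority_branch


def predict(tree: Tree, x_row) -> float:
    """Predicted outcome: the mean of the leaf the subject is routed to."""
    if hasattr(x_row, "to_dict"):
        x_row = x_row.to_dict()
    node = tree.root
    while not node.is_leaf:
        node = node.left if route(x_row, node) == "left" else node.right
    return node.mean


def predict_frame(tree: Tree, X) -> np.ndarray:
    df = X.data if isinstance(X, PredictorTable) else X
    records = df.to_dict("records")
    return np.array([predict(tree, r) for r in records])


# -- summaries ------------------------------------------------------------


def variable_importance(tree: Tree) -> pd.DataFrame:
    """Importance table: per split variable, its share (sums to 100) and count.

    Raw importance is the summed SSE reduction of the variable's primary
    splits; surrogate use does not contribute.  Variables never split on
    are omitted; a single-leaf tree gives an empty table.
    """
    raw: dict[str, float] = {}
    count: dict[str, int] = {}
    for nd in tree.root.walk():
        if nd.is_leaf:
            continue
        v = nd.rule.variable
        raw[v] = raw.get(v, 0.0) + nd.rule.sse_reduction
        count[v] = count.get(v, 0) + 1
    if not raw:
        return pd.DataFrame(columns=["variable", "importance", "count"])
    total = sum(raw.values())
    df = pd.DataFrame(
        {
            "variable": list(raw),
            "importance": [100.0 * raw[v] / total for v in raw],
            "count": [count[v] for v in raw],
        }
    )
    return df.sort_values(
        ["importance", "variable"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


# -- serialization --------------------------------------------------------


def _rule_to_dict(rule: SplitRule) -> dict:
    return {
        "variable": rule.variable,
        "kind": rule.kind,
        "sse_reduction": rule.sse_reduction,
        "threshold": rule.threshold,
        "left_set": list(rule.left_set),
        "majority_branch": rule.majority_branch,
        "surrogates": [
            {
                "variable": sr.variable,
                "kind": sr.kind,
                "agreement": sr.agreement,
                "threshold": sr.threshold,
                "left_if_less": sr.left_if_less,
                "left_set": list(sr.left_set),
            }
            for sr in rule.surrogates
        ],
    }


def _rule_from_dict(d: dict) -> SplitRule:
    return SplitRule(
        variable=d["variable"],
        kind=d["kind"],
        sse_reduction=d["sse_reduction"],
        threshold=d["threshold"],
        left_set=tuple(d["left_set"]),
        majority_branch=d["majority_branch"],
        surrogates=tuple(
            SurrogateRule(
                variable=s["variable"],
                kind=s["kind"],
                agreement=s["agreement"],
                threshold=s["threshold"],
                left_if_less=s["left_if_less"],
                left_set=tuple(s["left_set"]),
            )
            for s in d["surrogates"]
        ),
    )


def export_tree(tree: Tree, format: str = "json") -> str:
    """Serialize the tree: lossless ``json``, Graphviz ``dot``, or indented ``text``."""
    if format == "json":
        nodes = []
        for nd in tree.root.walk():
            nodes.append(
                {
                    "id": nd.id,
                    "depth": nd.depth,
                    "n": nd.n,
                    "mean": nd.mean,
                    "sse": nd.sse,
                    "rule": None if nd.is_leaf else _rule_to_dict(nd.rule),
                    "children": None if nd.is_leaf else [nd.left.id, nd.right.id],
                }
            )
        doc = {
            "hyperparams": {
                "maxdepth": tree.hyperparams.maxdepth,
                "minleafsize": tree.hyperparams.minleafsize,
                "minvariance": tree.hyperparams.minvariance,
            },
            "columns": tree.columns,
            "kinds": tree.kinds,
            "n": tree.n,
            "training_ase": tree.training_ase,
            "nodes": nodes,
        }
        return json.dumps(doc, indent=1, sort_keys=True)
    if format == "dot":
        lines = ["digraph tree {", '  node [shape=box, fontname="Helvetica"];']
        for nd in tree.root.walk():
            label = f"n={nd.n}\\nmean={nd.mean:.3f}"
            if not nd.is_leaf:
                label = _rule_label(nd.rule) + "\\n" + label
            lines.append(f'  n{nd.id} [label="{label}"];')
        for nd in tree.root.walk():
            if not nd.is_leaf:
                lines.append(f'  n{nd.id} -> n{nd.left.id} [label="yes"];')
                lines.append(f'  n{nd.id} -> n{nd.right.id} [label="no"];')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if format == "text":
        out = []

        def walk(nd, indent):
            pad = "  " * indent
            if nd.is_leaf:
                out.append(f"{pad}leaf #{nd.id}: n={nd.n}, mean={nd.mean:.4f}")
            else:
                out.append(
                    f"{pad}node #{nd.id}: {_rule_label(nd.rule)} "
                    f"(n={nd.n}, mean={nd.mean:.4f}, dSSE={nd.rule.sse_reduction:.4f})"
                )
                walk(nd.left, indent + 1)
                walk(nd.right, indent + 1)

        walk(tree.root, 0)
        return "\n".join(out) + "\n"
    raise ContractError(f"unknown export format {format!r}")


def _rule_label(rule: SplitRule) -> str:
    if rule.kind == "threshold":
        return f"{rule.variable} < {rule.threshold:g}"
    return f"{rule.variable} in {{{', '.join(map(str, rule.left_set))}}}"


def import_tree(serialized: str) -> Tree:
    """Inverse of ``export_tree(..., 'json')``."""
    doc = json.loads(serialized)
    by_id = {}
    for nd in doc["nodes"]:
        by_id[nd["id"]] = TreeNode(
            id=nd["id"],
            depth=nd["depth"],
            n=nd["n"],
            mean=nd["mean"],
            sse=nd["sse"],
            rule=None if nd["rule"] is None else _rule_from_dict(nd["rule"]),
        )
    for nd in doc["nodes"]:
        if nd["children"] is not None:
            by_id[nd["id"]].left = by_id[nd["children"][0]]
            by_id[nd["id"]].right = by_id[nd["children"][1]]
    hp = Hyperparams(**doc["hyperparams"])
    return Tree(
        root=by_id[doc["nodes"][0]["id"]],
        hyperparams=hp,
        columns=doc["columns"],
        kinds=doc["kinds"],
        n=doc["n"],
        training_ase=doc["training_ase"],
    )
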