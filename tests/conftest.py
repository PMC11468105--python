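"""Shared fixtures and independent oracles.

The split oracle here is deliberately naive: it enumerates every
threshold and every category subset and computes sums of squares
directly, so it shares no code path with the tree's optimized scan.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from rpdtree import LifeTable, Subject


@pytest.fixture
def worked_example_table():
    """Two-year toy table realizing annual death probabilities 0.1 then 1/9.

    Along the trajectory of a subject aged 70 in 1979: q(70, 1979) = 0.1
    and q(71, 1980) = 1/9, for both sexes.  Off-trajectory cells are
    filled with an arbitrary valid value.
    """
    q = np.full((2, 2, 2), 0.2)
    q[:, 0, 0] = 0.1
    q[:, 1, 1] = 1.0 / 9.0
    return LifeTable(q, 70, 71, 1979, 1980, period_only=False)


@pytest.fixture
def worked_example_subject():
    return Subject("p1", "f", 70, 1979, 2014, death_year=1980)


def make_subject(sid="s", sex="f", age=70, year=2000, death=None, end=2010):
    return Subject(
        sid, sex, age, year, end, death_year=death, alive_at_end=death is None
    )


# -- independent split oracle --------------------------------------------


def sse(y: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    return float(((y - y.mean()) ** 2).sum()) if len(y) else 0.0


def brute_force_best_delta(df: pd.DataFrame, y: np.ndarray, minleafsize: int = 1):
    """Exhaustive best SSE reduction over all variables, cuts and subsets.

    Returns (best_delta, winners) where winners is the set of variables
    achieving within 1e-9 of the maximum, or (None, set()) when no
    admissible positive-gain split exists anywhere.
    """
    y = np.asarray(y, dtype=float)
    candidates = []
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            obs = s.notna().to_numpy()
            x, yy = s[obs].to_numpy(dtype=float), y[obs]
            parent = sse(yy)
            for c in np.unique(x)[1:]:
                left = x < c
                nl = left.sum()
                if nl < minleafsize or len(x) - nl < minleafsize:
                    continue
                delta = parent - sse(yy[left]) - sse(yy[~left])
                if delta > 0:
                    candidates.append((delta, col))
        else:
            obs = s.notna().to_numpy()
            cc, yy = s[obs].to_numpy(), y[obs]
            parent = sse(yy)
            cats = sorted(set(cc), key=str)
            for r in range(1, len(cats)):
                for subset in itertools.combinations(cats, r):
                    left = np.isin(cc, subset)
                    nl = left.sum()
                    if nl < minleafsize or len(cc) - nl < minleafsize:
                        continue
                    delta = parent - sse(yy[left]) - sse(yy[~left])
                    if delta > 0:
                        candidates.append((delta, col))
    if not candidates:
        return None, set()
    best = max(d for d, _ in candidates)
    winners = {c for d, c in candidates if d >= best - 1e-9 * max(1.0, best)}
    return best, winners


def random_mixed_dataset(rng: np.random.Generator, n=40, missing_rate=0.1):
    """Small dataset with numeric + nominal predictors and light missingness."""
    df = pd.DataFrame(
        {
            "x1": rng.normal(size=n),
            "x2": rng.integers(0, 5, size=n).astype(float),
            "g1": rng.choice(list("abcd"), size=n),
            "g2": rng.choice(["u", "v"], size=n),
        }
    )
    y = (
        1.5 * (df["x1"] > 0)
        + 0.8 * (df["g1"].isin(["a", "b"]))
        + rng.normal(scale=0.7, size=n)
    ).to_numpy()
    for c in df.columns:
        hit = rng.random(n) < missing_rate
        if df[c].dtype == object:
            df.loc[hit, c] = None
        else:
            df.loc[hit, c] = np.nan
    return df, y


def node_membership(tree, df: pd.DataFrame) -> dict:
    """Row indices reaching each node, by replaying the tree's routing."""
    from rpdtree import route

    members = {nd.id: [] for nd in tree.root.walk()}
    for i, row in enumerate(df.to_dict("records")):
        node = tree.root
        members[node.id].append(i)
        while not node.is_leaf:
            node = node.left if route(row, node) == "left" else node.right
            members[node.id].append(i)
    return {k: np.array(v, dtype=int) for k, v in members.items()}
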