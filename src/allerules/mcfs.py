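"""Monte Carlo Feature Selection (MCFS).

Attributes are ranked by *relative importance* (RI) accumulated over a large
ensemble of decision trees, each grown on a random projection of m attributes
and a random train/test split. For attribute g,

    RI_g = sum over all s*t trees of  wAcc^u * sum over nodes splitting on g
           of IG(node) * (n_node / n_tree)^v

where wAcc is the tree's weighted accuracy (mean of per-class recalls) on its
test split and IG is the information gain (bits) of the split. Significance is
assessed against a permutation null: the whole procedure is repeated B times
on label-permuted data; attributes are selected when their observed RI beats
the global maximum null RI of the permutation runs (single-step max-null
adjustment, exact family-wise control by exchangeability), with a smooth
descriptive p-value per attribute from a Gaussian fit to its null RIs.

Trees are grown level-wise with vectorized contingency counting so that the
ensemble sizes used for null calibration stay cheap; `build_tree` materializes
the conventional node/children view of the same tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import stats
from scipy.special import xlogy

from ._seeds import substream
from .dtable import Attribute, DecisionTable, EncodedTable, permute_columns

log = logging.getLogger(__name__)

_LN2 = math.log(2.0)
_IG_TOL = 1e-12


@dataclass
class MCFSParams:
    """Ensemble and significance settings.

    s: number of random attribute projections (default: enough for every
       attribute to appear in ~30 projections in expectation).
    t: train/test splits (trees) per projection.
    m: attributes per projection (default ceil(sqrt(d))).
    train_fraction: fraction of classified objects used to grow each tree
       (stratified; 1.0 means train = test = all objects).
    u, v: exponents on wAcc and on the node-size fraction in RI.
    max_depth: tree depth cap.
    B: label-permutation replicates for the null distribution.
    alpha: family-wise error rate of the max-null permutation selection
       (attainable only when 1/(B+1) <= alpha).
    """

    s: int | None = None
    t: int = 5
    m: int | None = None
    train_fraction: float = 0.66
    u: float = 1.0
    v: float = 1.0
    max_depth: int = 2
    B: int = 50
    alpha: float = 0.05
    seed: int = 0

    def resolved(self, d: int) -> "MCFSParams":
        m = self.m if self.m is not None else max(1, math.ceil(math.sqrt(d)))
        if m > d:
            raise ValueError(f"m={m} exceeds the number of attributes d={d}")
        s = self.s if self.s is not None else max(1, math.ceil(30 * d / m))
        out = replace(self, s=s, m=m)
        if out.s < 1 or out.t < 1 or out.B < 1:
            raise ValueError("s, t and B must all be >= 1")
        if not (0 < out.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if out.u < 0 or out.v < 0:
            raise ValueError("u and v must be non-negative")
        return out


@dataclass
class TreeNode:
    """One node of an information-gain decision tree."""

    split_attribute: str | None  # None at leaves
    n_node: int
    class_counts: tuple[int, int]  # (unaffected, affected)
    ig: float
    children: list["TreeNode"] = field(default_factory=list)


@dataclass
class RIResult:
    """Per-attribute relative importance, with optional permutation p-values."""

    ri: dict[str, float]
    appearances: dict[str, int]
    p_value: dict[str, float] | None = None
    p_adjusted: dict[str, float] | None = None
    significant: set[str] | None = None
    null_mean: dict[str, float] | None = None
    null_sd: dict[str, float] | None = None

    def ranking(self) -> list[str]:
        return sorted(self.ri, key=lambda a: (-self.ri[a], a))


# -- elementary statistics -------------------------------------------------

def weighted_accuracy(confusion) -> float:
    """Mean of per-class recalls from a 2x2 confusion matrix.

    Rows are true classes, columns predicted classes. Raises if a true class
    has no objects (the tree's contribution is then skipped by the caller).
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("confusion must be a non-negative 2x2 matrix")
    row = c.sum(axis=1)
    if (row == 0).any():
        raise ValueError("a true class has no objects in the test split")
    return float(np.mean(np.diag(c) / row))


def _entropy_bits(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (base 2) from class counts along the last axis."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = (xlogy(n, n) - xlogy(counts, counts).sum(axis=-1)) / (n * _LN2)
    return np.where(n > 0, h, 0.0)


def information_gain(parent_counts, children_counts) -> float:
    """Information gain (bits) of a multiway split.

    ``children_counts`` must partition ``parent_counts``.
    """
    parent = np.asarray(parent_counts, dtype=float)
    children = [np.asarray(c, dtype=float) for c in children_counts]
    if not np.allclose(sum(children), parent):
        raise ValueError("children counts must partition the parent counts")
    n = parent.sum()
    weighted = sum(c.sum() / n * _entropy_bits(c) for c in children)
    return max(0.0, float(_entropy_bits(parent) - weighted))


# -- level-wise tree growth ------------------------------------------------

class _FlatTree:
    """Array representation of a grown tree (missing category code = kmax)."""

    __slots__ = ("split", "n", "counts", "ig", "children", "majority", "depth", "kmax")

    def __init__(self, kmax: int):
        self.kmax = kmax
        self.split: list[int] = []
        self.n: list[int] = []
        self.counts: list[tuple[int, int]] = []
        self.ig: list[float] = []
        self.children: list[np.ndarray | None] = []
        self.majority: list[int] = []
        self.depth: list[int] = []

    def add_node(self, counts, depth: int) -> int:
        self.split.append(-1)
        self.counts.append((int(counts[0]), int(counts[1])))
        self.n.append(int(counts[0] + counts[1]))
        self.ig.append(0.0)
        self.children.append(None)
        self.majority.append(-1)
        self.depth.append(depth)
        return len(self.split) - 1


def _grow_tree(Xm: np.ndarray, y: np.ndarray, kmax: int, max_depth: int) -> _FlatTree:
    """Grow a greedy multiway IG tree; missing values follow the majority child.

    ``Xm`` uses category codes 0..kmax-1 with ``kmax`` for missing. Splits are
    chosen by maximal IG; ties break toward the lowest column index, which is
    lexicographic when columns are sorted by attribute name.
    """
    n, m = Xm.shape
    tree = _FlatTree(kmax)
    root_counts = np.bincount(y, minlength=2)
    tree.add_node((root_counts[0], root_counts[1]), 0)
    node_of = np.zeros(n, dtype=np.int64)
    active = np.array([0], dtype=np.int64)
    cols = np.arange(m, dtype=np.int64)

    for level in range(max_depth):
        if active.size == 0:
            break
        remap = np.full(len(tree.split), -1, dtype=np.int64)
        remap[active] = np.arange(active.size)
        loc = remap[node_of]
        sel = np.nonzero(loc >= 0)[0]
        if sel.size == 0:
            break
        l = loc[sel]
        Xs = Xm[sel]
        ys = y[sel]
        A = active.size
        width = kmax + 1
        flat = ((l[:, None] * m + cols[None, :]) * width + Xs) * 2 + ys[:, None]
        C = np.bincount(flat.ravel(), minlength=A * m * width * 2).reshape(A, m, width, 2)

        # merge missing objects into the largest non-missing child (tie: lowest category)
        tot = C.sum(axis=-1)
        jmax = tot[..., :kmax].argmax(axis=-1)  # (A, m)
        jm = jmax[..., None, None]
        merged = np.take_along_axis(C, jm, axis=2) + C[:, :, kmax : kmax + 1, :]
        np.put_along_axis(C, jm, merged, axis=2)
        C[:, :, kmax, :] = 0

        P = C[:, 0, :, :].sum(axis=1)  # (A, 2) parent class counts
        npar = P.sum(axis=1).astype(float)
        h_parent = _entropy_bits(P)
        child_counts = C[:, :, :kmax, :]
        n_child = child_counts.sum(axis=-1).astype(float)  # (A, m, kmax)
        h_child = _entropy_bits(child_counts)
        weighted = (n_child * h_child).sum(axis=-1) / npar[:, None]
        ig = np.clip(h_parent[:, None] - weighted, 0.0, None)  # (A, m)

        best = ig.argmax(axis=1)
        best_ig = ig[np.arange(A), best]
        pure = (P == 0).any(axis=1)
        leaf = pure | (best_ig <= _IG_TOL)

        # route objects and create children
        child_lookup = np.zeros((A, kmax), dtype=np.int64)
        new_active: list[int] = []
        for a_i, node in enumerate(active):
            if leaf[a_i]:
                child_lookup[a_i, :] = node
                continue
            b = int(best[a_i])
            tree.split[node] = b
            tree.ig[node] = float(best_ig[a_i])
            tree.majority[node] = int(jmax[a_i, b])
            ch = np.full(kmax, -1, dtype=np.int64)
            for cat in range(kmax):
                cc = C[a_i, b, cat]
                if cc[0] + cc[1] > 0:
                    cid = tree.add_node(cc, level + 1)
                    ch[cat] = cid
                    new_active.append(cid)
            # categories unseen in training route to the majority child
            ch[ch < 0] = ch[tree.majority[node]]
            tree.children[node] = ch
            child_lookup[a_i, :] = ch
        if not new_active:
            break
        best_of = best[l]
        cats = Xs[np.arange(sel.size), best_of]
        cats = np.where(cats >= kmax, jmax[l, best_of], cats)
        node_of[sel] = child_lookup[l, cats]
        active = np.array(new_active, dtype=np.int64)
    return tree


def _predict(tree: _FlatTree, Xm: np.ndarray, prior_class: int) -> np.ndarray:
    """Route objects to leaves and predict the leaf majority class."""
    split = np.asarray(tree.split)
    majority = np.asarray(tree.majority)
    counts = np.asarray(tree.counts)
    kmax = tree.kmax
    children = np.zeros((len(split), kmax), dtype=np.int64)
    for i, ch in enumerate(tree.children):
        if ch is not None:
            children[i] = ch
    cur = np.zeros(Xm.shape[0], dtype=np.int64)
    while True:
        sp = split[cur]
        act = np.nonzero(sp >= 0)[0]
        if act.size == 0:
            break
        cats = Xm[act, sp[act]]
        cats = np.where(cats >= kmax, majority[cur[act]], cats)
        cur[act] = children[cur[act], cats]
    c = counts[cur]
    pred = np.where(c[:, 1] > c[:, 0], 1, 0)
    pred = np.where(c[:, 1] == c[:, 0], prior_class, pred)
    return pred.astype(np.int8)


def build_tree(table: DecisionTable, params: MCFSParams | None = None) -> TreeNode:
    """Grow a single IG tree on the full (classified) table and return its root."""
    params = (params or MCFSParams()).resolved(len(table.attributes))
    enc = table.encode()
    if len(np.unique(enc.y)) < 2:
        raise ValueError("training data must contain both classes")
    kmax = int(enc.n_categories.max())
    Xm = np.where(enc.X < 0, kmax, enc.X).astype(np.int64)
    flat = _grow_tree(Xm, enc.y.astype(np.int64), kmax, params.max_depth)
    return _materialize(flat, enc.names)


def _materialize(tree: _FlatTree, names: list[str]) -> TreeNode:
    nodes = [
        TreeNode(
            split_attribute=None if s < 0 else names[s],
            n_node=n,
            class_counts=(c[0], c[1]),
            ig=g,
        )
        for s, n, c, g in zip(tree.split, tree.n, tree.counts, tree.ig)
    ]
    for i, ch in enumerate(tree.children):
        if ch is not None:
            seen: list[int] = []
            for cid in ch:
                if cid >= 0 and cid not in seen:
                    seen.append(int(cid))
            nodes[i].children = [nodes[c] for c in seen]
    return nodes[0]


# -- compiled per-tree kernel ----------------------------------------------

@njit(cache=True)
def _tree_ri_kernel(X, y, train, test, kmax, max_depth, u, v, prior_class, ri_out):
    """Grow one IG tree on ``train``, score it on ``test`` and accumulate the
    wAcc-weighted RI contributions into ``ri_out``.

    Mirrors the level-wise numpy builder: greedy multiway splits by maximal
    IG (ties to the lowest column index), missing values (-1) merged into the
    majority child, stop at purity, non-positive IG or the depth cap. Returns
    1 on success, 0 when a test class is empty (contribution skipped).
    """
    n_train = train.shape[0]
    m = X.shape[1]
    cap = 1
    p = 1
    for _ in range(max_depth):
        p *= kmax
        cap += p
        if cap > 2 * n_train + 2:
            cap = 2 * n_train + 2
            break

    split = np.full(cap, -1, np.int64)
    ig_arr = np.zeros(cap, np.float64)
    nn = np.zeros(cap, np.int64)
    c0 = np.zeros(cap, np.int64)
    c1 = np.zeros(cap, np.int64)
    depth = np.zeros(cap, np.int64)
    start = np.zeros(cap, np.int64)
    end = np.zeros(cap, np.int64)
    child = np.full((cap, kmax), -1, np.int64)
    majority = np.zeros(cap, np.int64)

    idx = train.copy()
    a0 = 0
    a1 = 0
    for i in range(n_train):
        if y[idx[i]] == 1:
            a1 += 1
        else:
            a0 += 1
    c0[0] = a0
    c1[0] = a1
    nn[0] = n_train
    end[0] = n_train
    n_nodes = 1

    stack = np.zeros(cap, np.int64)
    stack[0] = 0
    top = 1
    ln2 = 0.6931471805599453
    counts = np.zeros((kmax + 1, 2), np.float64)
    cnt = np.zeros(kmax, np.int64)
    off = np.zeros(kmax + 1, np.int64)
    pos = np.zeros(kmax, np.int64)
    tmp = np.empty(n_train, np.int64)

    while top > 0:
        top -= 1
        node = stack[top]
        if c0[node] == 0 or c1[node] == 0 or depth[node] >= max_depth:
            continue
        s = start[node]
        e = end[node]
        npar = float(e - s)
        hp = 0.0
        for cls in range(2):
            cc = float(c0[node]) if cls == 0 else float(c1[node])
            if cc > 0.0:
                hp -= (cc / npar) * np.log(cc / npar)
        hp /= ln2

        best_a = -1
        best_ig = 0.0
        best_maj = 0
        for a in range(m):
            for k in range(kmax + 1):
                counts[k, 0] = 0.0
                counts[k, 1] = 0.0
            for i in range(s, e):
                o = idx[i]
                vv = X[o, a]
                k = kmax if vv < 0 else vv
                counts[k, y[o]] += 1.0
            maj = 0
            majn = -1.0
            for k in range(kmax):
                tot = counts[k, 0] + counts[k, 1]
                if tot > majn:
                    majn = tot
                    maj = k
            counts[maj, 0] += counts[kmax, 0]
            counts[maj, 1] += counts[kmax, 1]
            w = 0.0
            for k in range(kmax):
                tot = counts[k, 0] + counts[k, 1]
                if tot > 0.0:
                    h = 0.0
                    for cls in range(2):
                        cc = counts[k, cls]
                        if cc > 0.0:
                            h -= (cc / tot) * np.log(cc / tot)
                    w += tot * (h / ln2)
            ig = hp - w / npar
            if ig > best_ig + 1e-12:
                best_ig = ig
                best_a = a
                best_maj = maj
        if best_a < 0 or best_ig <= 1e-12:
            continue

        for k in range(kmax):
            cnt[k] = 0
        for i in range(s, e):
            o = idx[i]
            vv = X[o, best_a]
            k = best_maj if vv < 0 else vv
            cnt[k] += 1
        n_children = 0
        for k in range(kmax):
            if cnt[k] > 0:
                n_children += 1
        if n_nodes + n_children > cap:
            continue  # capacity guard: keep as leaf
        split[node] = best_a
        ig_arr[node] = best_ig
        majority[node] = best_maj
        off[0] = 0
        for k in range(kmax):
            off[k + 1] = off[k] + cnt[k]
            pos[k] = off[k]
        for i in range(s, e):
            o = idx[i]
            vv = X[o, best_a]
            k = best_maj if vv < 0 else vv
            tmp[pos[k]] = o
            pos[k] += 1
        for i in range(e - s):
            idx[s + i] = tmp[i]
        for k in range(kmax):
            if cnt[k] == 0:
                continue
            cid = n_nodes
            n_nodes += 1
            child[node, k] = cid
            start[cid] = s + off[k]
            end[cid] = s + off[k + 1]
            depth[cid] = depth[node] + 1
            b0 = 0
            b1 = 0
            for i in range(start[cid], end[cid]):
                if y[idx[i]] == 1:
                    b1 += 1
                else:
                    b0 += 1
            c0[cid] = b0
            c1[cid] = b1
            nn[cid] = b0 + b1
            stack[top] = cid
            top += 1
        for k in range(kmax):
            if child[node, k] < 0:
                child[node, k] = child[node, majority[node]]

    t00 = 0
    t01 = 0
    t10 = 0
    t11 = 0
    for j in range(test.shape[0]):
        o = test[j]
        node = 0
        while split[node] >= 0:
            a = split[node]
            vv = X[o, a]
            k = majority[node] if (vv < 0 or vv >= kmax) else vv
            nxt = child[node, k]
            if nxt < 0:
                nxt = child[node, majority[node]]
            node = nxt
        if c1[node] > c0[node]:
            pred = 1
        elif c0[node] > c1[node]:
            pred = 0
        else:
            pred = prior_class
        if y[o] == 1:
            if pred == 1:
                t11 += 1
            else:
                t10 += 1
        else:
            if pred == 0:
                t00 += 1
            else:
                t01 += 1
    if t00 + t01 == 0 or t10 + t11 == 0:
        return 0
    wacc = 0.5 * (t00 / float(t00 + t01) + t11 / float(t10 + t11))
    wu = wacc**u
    for node in range(n_nodes):
        if split[node] >= 0:
            ri_out[split[node]] += wu * ig_arr[node] * (nn[node] / float(n_train)) ** v
    return 1


# -- RI over the ensemble --------------------------------------------------

def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    if fraction >= 1.0:
        idx = np.arange(y.size)
        return idx, idx
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for cls in (0, 1):
        ids = np.nonzero(y == cls)[0]
        perm = rng.permutation(ids)
        n_tr = min(ids.size - 1, max(1, int(round(fraction * ids.size))))
        train.append(perm[:n_tr])
        test.append(perm[n_tr:])
    return np.concatenate(train), np.concatenate(test)


def _ri_core(
    enc: EncodedTable,
    y: np.ndarray,
    params: MCFSParams,
    seed: int,
    stream: tuple = ("mcfs",),
    proj_start: int = 0,
    engine: str = "numba",
) -> tuple[np.ndarray, np.ndarray]:
    """RI and appearance counts on an encoded table (attributes name-sorted).

    ``engine`` selects the compiled per-tree kernel (default) or the
    vectorized numpy builder; both implement the same tree semantics and are
    cross-checked in the test suite.
    """
    d = len(enc.attributes)
    kmax = int(enc.n_categories.max())
    y64 = y.astype(np.int64)
    prior_class = 1 if np.count_nonzero(y64 == 1) >= np.count_nonzero(y64 == 0) else 0
    ri = np.zeros(d)
    appearances = np.zeros(d, dtype=np.int64)
    skipped = 0
    X8 = np.ascontiguousarray(enc.X, dtype=np.int8)
    y8 = np.ascontiguousarray(y, dtype=np.int8)
    Xall = None
    if engine != "numba":
        Xall = np.where(enc.X < 0, kmax, enc.X).astype(np.int64)
    for i in range(params.s):
        rng_p = substream(seed, *stream, "proj", proj_start + i)
        cols = np.sort(rng_p.choice(d, size=params.m, replace=False))
        appearances[cols] += 1
        Xp = np.ascontiguousarray(X8[:, cols]) if engine == "numba" else Xall[:, cols]
        for j in range(params.t):
            rng_s = substream(seed, *stream, "split", proj_start + i, j)
            train, test = _stratified_split(y64, params.train_fraction, rng_s)
            if y64[train].min() == y64[train].max():
                skipped += 1
                continue
            if engine == "numba":
                local = np.zeros(params.m)
                ok = _tree_ri_kernel(
                    Xp,
                    y8,
                    train.astype(np.int64),
                    test.astype(np.int64),
                    kmax,
                    params.max_depth,
                    float(params.u),
                    float(params.v),
                    prior_class,
                    local,
                )
                if ok:
                    ri[cols] += local
                else:
                    skipped += 1
                continue
            tree = _grow_tree(Xp[train], y64[train], kmax, params.max_depth)
            yte = y64[test]
            if len(np.unique(yte)) < 2:
                skipped += 1
                continue
            pred = _predict(tree, Xp[test], prior_class)
            conf = np.bincount(yte * 2 + pred, minlength=4).reshape(2, 2)
            wacc = weighted_accuracy(conf)
            split = np.asarray(tree.split)
            internal = split >= 0
            if not internal.any():
                continue
            n_node = np.asarray(tree.n, dtype=float)[internal]
            ig = np.asarray(tree.ig)[internal]
            contrib = ig * (n_node / float(train.size)) ** params.v
            local = np.zeros(params.m)
            np.add.at(local, split[internal], contrib)
            ri[cols] += (wacc ** params.u) * local
    if skipped:
        log.info("skipped %d trees with a one-class split", skipped)
    return ri, appearances


def mcfs_ri(
    table: DecisionTable | EncodedTable,
    params: MCFSParams | None = None,
    proj_start: int = 0,
    engine: str = "numba",
) -> RIResult:
    """Relative importance for every attribute (no p-values).

    ``proj_start`` offsets the projection substream indices so that runs over
    disjoint projection ranges sum exactly to one combined run.
    """
    enc = table.encode() if isinstance(table, DecisionTable) else table
    counts = np.bincount(enc.y, minlength=2)
    if counts.min() < 10:
        raise ValueError("each class needs at least 10 classified objects")
    params = (params or MCFSParams()).resolved(len(enc.attributes))
    ri, app = _ri_core(enc, enc.y, params, params.seed, proj_start=proj_start, engine=engine)
    names = enc.names
    return RIResult(ri=dict(zip(names, ri)), appearances=dict(zip(names, app.tolist())))


def mcfs_significance(
    table: DecisionTable | EncodedTable, params: MCFSParams | None = None
) -> RIResult:
    """RI plus permutation-null p-values and family-wise selection.

    The full ensemble is re-run B times on label-permuted data. Two summaries
    are computed per attribute: a smooth descriptive upper-tail p from the
    Gaussian fit to its B null RIs (evaluated through the fit's Student-t
    predictive distribution, df = B-1); and the family-wise adjusted p used
    for the significance call, the single-step max-null (Westfall-Young)
    probability p_adj = (1 + #{b : max_g RI_null[b,g] >= RI_obs}) / (B + 1).
    Under the global null the observed run is exchangeable with the permuted
    runs, so the selection controls the family-wise error rate at 1/(B+1) <=
    alpha exactly, whatever the shape of the RI null -- a plug-in Gaussian
    tail is badly anti-conservative at the family-wise quantiles this
    selection needs.
    """
    enc = table.encode() if isinstance(table, DecisionTable) else table
    params = (params or MCFSParams()).resolved(len(enc.attributes))
    if params.B < 10:
        raise ValueError("B must be at least 10 for a usable null fit")
    if 1.0 / (params.B + 1) > params.alpha:
        log.warning(
            "B=%d cannot reach alpha=%.3g (smallest attainable adjusted p is %.3g)",
            params.B, params.alpha, 1.0 / (params.B + 1),
        )
    d = len(enc.attributes)
    counts = np.bincount(enc.y, minlength=2)
    if counts.min() < 10:
        raise ValueError("each class needs at least 10 classified objects")
    ri_obs, app = _ri_core(enc, enc.y, params, params.seed)
    null = np.empty((params.B, d))
    for b in range(params.B):
        rng = substream(params.seed, "mcfs-null-perm", b)
        y_perm = rng.permutation(enc.y)
        null[b], _ = _ri_core(enc, y_perm, params, params.seed, stream=("mcfs-null", b))
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    positive = sd[sd > 0]
    sd_floor = 0.5 * positive.min() if positive.size else 1e-12
    if (sd == 0).any():
        log.warning(
            "%d attributes had zero-variance nulls; applying half-width floor %.3g",
            int((sd == 0).sum()),
            sd_floor,
        )
    sd_eff = np.where(sd > 0, sd, sd_floor)
    scale = sd_eff * math.sqrt(1.0 + 1.0 / params.B)
    tstat = (ri_obs - mean) / scale
    p = stats.t.sf(tstat, df=params.B - 1)
    p = np.where((sd == 0) & (ri_obs <= mean), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    max_null = null.max(axis=1)  # (B,) global max RI per permutation run
    p_adj = (1.0 + (max_null[:, None] >= ri_obs[None, :]).sum(axis=0)) / (params.B + 1.0)
    names = enc.names
    return RIResult(
        ri=dict(zip(names, ri_obs)),
        appearances=dict(zip(names, app.tolist())),
        p_value=dict(zip(names, p)),
        p_adjusted=dict(zip(names, p_adj)),
        significant={n for n, q in zip(names, p_adj) if q < params.alpha},
        null_mean=dict(zip(names, mean)),
        null_sd=dict(zip(names, sd)),
    )


def mcfs_null_validation(table: DecisionTable, params: MCFSParams | None = None):
    """Randomization validation: original, randomized-only and combined runs.

    Returns a three-row DataFrame counting significant original and randomized
    attributes in each run. The randomized attributes are column-permuted
    copies of the originals (category counts preserved, labels untouched).
    """
    import pandas as pd

    params = params or MCFSParams()
    randomized = permute_columns(table, params.seed)
    rand_attrs = [replace(a, name=a.name + "__rand") for a in randomized.attributes]
    rand_data = randomized.data.copy()
    rand_data.columns = [a.name for a in rand_attrs]
    combined = DecisionTable(
        table.data.join(rand_data),
        list(table.attributes) + rand_attrs,
        table.decision.copy(),
        table.decision_name,
    )
    rows = []
    for run, tab in (("original", table), ("randomized", randomized), ("combined", combined)):
        use = tab if run != "randomized" else DecisionTable(
            rand_data.copy(), list(rand_attrs), table.decision.copy(), table.decision_name
        )
        res = mcfs_significance(use, params)
        sig = res.significant or set()
        rows.append(
            {
                "run": run,
                "n_attributes": len(use.attributes),
                "n_significant_original": sum(1 for a in sig if not a.endswith("__rand")),
                "n_significant_randomized": sum(1 for a in sig if a.endswith("__rand")),
            }
        )
    return pd.DataFrame(rows)
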