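"""Right-censored survival primitives and the random survival forest.

Everything here is implemented from first principles: Harrell's concordance
index, the Nelson-Aalen cumulative-hazard estimator, the standardized
two-group log-rank statistic used as the node split criterion, log-rank-split
survival trees with Nelson-Aalen leaf estimators, the bootstrap ensemble
(random survival forest, RSF), and permutation importance.

Conventions
-----------
* Outcomes are (time, event) pairs with time > 0 and event in {0, 1}
  (1 = the endpoint occurred, 0 = right-censored at ``time``).
* The forest's risk score is *ensemble mortality*: the ensemble cumulative
  hazard summed over the shared event-time grid. Higher = higher risk.
* All randomness flows through ``numpy.random.Generator`` objects seeded from
  an integer, so identical inputs and seeds reproduce fits bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from . import _kernels

__all__ = [
    "SurvivalOutcomes",
    "RSFParams",
    "CumulativeHazard",
    "RandomSurvivalForest",
    "harrell_c",
    "nelson_aalen",
    "logrank_split_statistic",
    "fit_rsf",
    "predict_risk",
    "permutation_importance",
]


# ---------------------------------------------------------------------------
# outcome container


@dataclass(frozen=True)
class SurvivalOutcomes:
    """Aligned right-censored outcomes for one endpoint (OS or PFS)."""

    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be aligned 1-d arrays")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("survival times must be finite and strictly positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalOutcomes":
        return SurvivalOutcomes(self.time[idx], self.event[idx], self.endpoint)


def _as_time_event(outcomes) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(outcomes, SurvivalOutcomes):
        return outcomes.time, outcomes.event
    time, event = outcomes
    return np.asarray(time, dtype=float), np.asarray(event, dtype=int)


# ---------------------------------------------------------------------------
# Harrell's C


def harrell_c(outcomes, risk) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable when ``time_i < time_j`` and sample i had the
    event; it scores 1 if ``risk_i > risk_j``, 0.5 on a risk tie, else 0.
    Pairs tied on time are never comparable under the strict inequality, which
    matches Harrell's convention of dropping pairs tied on time.

    Raises
    ------
    ValueError
        If no comparable pair exists (e.g. everything censored).
    """
    time, event = _as_time_event(outcomes)
    risk = np.asarray(risk, dtype=float)
    if risk.shape != time.shape:
        raise ValueError("risk scores must align with outcomes")
    # pairwise O(n^2) with broadcasting; n is at most a few thousand here
    comparable = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pair (all samples censored or tied)")
    greater = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    concordant = (comparable & greater).sum() + 0.5 * (comparable & tied).sum()
    return float(concordant / n_comp)


# ---------------------------------------------------------------------------
# Nelson-Aalen


@dataclass(frozen=True)
class CumulativeHazard:
    """A right-continuous non-decreasing step function H(t)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must align")
        if t.size and (np.any(np.diff(t) <= 0) or np.any(np.diff(v) < -1e-12)):
            raise ValueError("times must increase and values be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def at(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate H at each grid point (0 before the first event time)."""
        if self.times.size == 0:
            return np.zeros_like(np.asarray(grid, dtype=float))
        idx = np.searchsorted(self.times, grid, side="right")
        padded = np.concatenate([[0.0], self.values])
        return padded[idx]


def nelson_aalen(outcomes) -> CumulativeHazard:
    """Nelson-Aalen cumulative hazard: H(t) = sum_{t_k <= t} d_k / n_at_risk_k."""
    time, event = _as_time_event(outcomes)
    if time.size == 0:
        raise ValueError("empty outcome list")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return CumulativeHazard(np.array([]), np.array([]))
    # deaths and at-risk counts at each distinct event time
    d = np.array([np.sum((t == et) & (e == 1)) for et in event_times], dtype=float)
    n_at_risk = np.array([np.sum(t >= et) for et in event_times], dtype=float)
    return CumulativeHazard(event_times, np.cumsum(d / n_at_risk))


# ---------------------------------------------------------------------------
# log-rank split statistic


def logrank_split_statistic(outcomes, membership) -> float:
    """Standardized two-group log-rank statistic (O - E)^2 / V.

    ``membership`` is a boolean vector marking the left group. Larger values
    indicate better survival separation; degenerate variance returns 0.
    """
    time, event = _as_time_event(outcomes)
    member = np.asarray(membership, dtype=bool)
    if member.shape != time.shape:
        raise ValueError("membership must align with outcomes")
    if member.all() or (~member).all():
        raise ValueError("both groups must be non-empty")
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return 0.0
    at_risk = time[:, None] >= event_times[None, :]
    deaths = (time[:, None] == event_times[None, :]) & (event[:, None] == 1)
    Y = at_risk.sum(axis=0).astype(float)
    D = deaths.sum(axis=0).astype(float)
    Y1 = at_risk[member].sum(axis=0).astype(float)
    D1 = deaths[member].sum(axis=0).astype(float)
    O_minus_E = float((D1 - Y1 * D / Y).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(Y > 1, (Y1 / Y) * (1 - Y1 / Y) * D * (Y - D) / (Y - 1), 0.0)
    V = float(v.sum())
    if V <= 0:
        return 0.0
    return O_minus_E**2 / V


# ---------------------------------------------------------------------------
# RSF parameters


@dataclass(frozen=True)
class RSFParams:
    """Hyperparameters of the random survival forest.

    max_features may be an integer count or a fraction of the feature count.
    """

    n_estimators: int = 300
    max_features: float | int = "sqrt"  # type: ignore[assignment]
    min_samples_leaf: int = 5
    min_samples_split: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_estimators < 1 or self.min_samples_leaf < 1:
            raise ValueError("n_estimators and min_samples_leaf must be positive")
        if self.min_samples_split < 2 * self.min_samples_leaf:
            raise ValueError("min_samples_split must be >= 2 * min_samples_leaf")
        if isinstance(self.max_features, (int, np.integer)) and self.max_features < 1:
            raise ValueError("max_features must be positive")

    def resolve_max_features(self, n_features: int) -> int:
        mf = self.max_features
        if isinstance(mf, str):
            if mf != "sqrt":
                raise ValueError(f"unknown max_features spec {mf!r}")
            return max(1, int(np.sqrt(n_features)))
        if isinstance(mf, (int, np.integer)):
            return min(int(mf), n_features)
        return max(1, min(n_features, int(np.ceil(mf * n_features))))


# ---------------------------------------------------------------------------
# survival tree


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "chf", "mortality", "n")

    def __init__(self):
        self.feature = -1
        self.threshold = np.nan
        self.left = None
        self.right = None
        self.chf = None  # leaf CHF on the shared grid
        self.mortality = np.nan
        self.n = 0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"n": self.n, "chf": list(map(float, self.chf))}
        return {
            "n": self.n,
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def _best_split_numpy(X, time, event, candidates, min_leaf):
    """Exhaustive log-rank search over (feature, threshold).

    Candidate features are scanned in ascending index order and a new optimum
    must be *strictly* better, so ties resolve to the lowest feature index and
    then the lowest threshold — the deterministic tie-break.

    Returns (feature, threshold, statistic) or None.
    """
    n = time.shape[0]
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return None
    best = None
    best_stat = 0.0
    for f in np.sort(candidates):
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ts = time[order]
        es = event[order]
        # boundaries between distinct values, honoring min_leaf on both sides
        ks = np.arange(1, n)  # left group = first k sorted samples
        valid = (xs[1:] > xs[:-1]) & (ks >= min_leaf) & (n - ks >= min_leaf)
        if not valid.any():
            continue
        at_risk = ts[:, None] >= event_times[None, :]
        deaths = (ts[:, None] == event_times[None, :]) & (es[:, None] == 1)
        Y = at_risk.sum(axis=0).astype(float)
        D = deaths.sum(axis=0).astype(float)
        Y1 = np.cumsum(at_risk, axis=0, dtype=float)[:-1]  # prefix k = 1..n-1
        D1 = np.cumsum(deaths, axis=0, dtype=float)[:-1]
        o_minus_e = D1.sum(axis=1) - (Y1 * (D / Y)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vfac = np.where(Y > 1, D * (Y - D) / (Y - 1), 0.0)
            frac = Y1 / Y
        V = (frac * (1 - frac) * vfac).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            stats = np.where(V > 0, o_minus_e**2 / V, 0.0)
        stats[~valid] = -np.inf
        k_best = int(np.argmax(stats))
        # np.argmax takes the first maximum -> lowest threshold tie-break
        if stats[k_best] > best_stat:
            best_stat = float(stats[k_best])
            k = k_best + 1  # left group = first k sorted samples
            threshold = 0.5 * (xs[k - 1] + xs[k])  # midpoint between distinct values
            best = (int(f), float(threshold), best_stat)
    return best


def _best_split(X, time, event, candidates, min_leaf):
    """Dispatch the split search to the compiled kernel when available."""
    if not _kernels.HAVE_NUMBA:
        return _best_split_numpy(X, time, event, candidates, min_leaf)
    event_times, D = np.unique(time[event == 1], return_counts=True)
    if event_times.size == 0:
        return None
    D = D.astype(float)
    ti = np.searchsorted(event_times, time, side="right") - 1
    di = (event == 1) & (ti >= 0) & (event_times[np.clip(ti, 0, None)] == time)
    # at-risk count at each event time via the sorted time vector
    sorted_times = np.sort(time)
    Y = (time.shape[0] - np.searchsorted(sorted_times, event_times, side="left")
         ).astype(float)
    f, thr, stat = _kernels.best_split_kernel(
        np.ascontiguousarray(X, dtype=float),
        ti.astype(np.int64),
        di,
        Y,
        D,
        np.sort(np.asarray(candidates, dtype=np.int64)),
        int(min_leaf),
    )
    if f < 0 or stat <= 0.0:
        return None
    return int(f), float(thr), float(stat)


def _grow_tree(X, time, event, params, mf, grid, rng):
    """Grow one survival tree on (X, time, event); returns the root node."""
    node = _Node()
    node.n = time.shape[0]
    n_features = X.shape[1]

    def make_leaf(nd, idx_time, idx_event):
        ch = nelson_aalen((idx_time, idx_event))
        nd.chf = ch.at(grid)
        nd.mortality = float(nd.chf.sum())

    def recurse(nd, rows):
        t, e = time[rows], event[rows]
        nd.n = rows.shape[0]
        if nd.n < params.min_samples_split or e.sum() == 0:
            make_leaf(nd, t, e)
            return
        cand = rng.choice(n_features, size=min(mf, n_features), replace=False)
        split = _best_split(X[rows], t, e, cand, params.min_samples_leaf)
        if split is None or split[2] <= 0.0:
            make_leaf(nd, t, e)
            return
        f, thr, _ = split
        go_left = X[rows, f] <= thr
        nd.feature, nd.threshold = f, thr
        nd.left, nd.right = _Node(), _Node()
        recurse(nd.left, rows[go_left])
        recurse(nd.right, rows[~go_left])

    recurse(node, np.arange(time.shape[0]))
    return node


def _tree_features(node, acc):
    if not node.is_leaf:
        acc.add(node.feature)
        _tree_features(node.left, acc)
        _tree_features(node.right, acc)


class _FlatForest:
    """Array-of-nodes forest layout for the compiled routing kernels."""

    __slots__ = ("feat", "thr", "left", "right", "mort", "roots", "tree_features")

    def __init__(self, trees):
        feat, thr, left, right, mort = [], [], [], [], []
        roots = []
        self.tree_features = []

        def add(node):
            idx = len(feat)
            feat.append(node.feature if not node.is_leaf else -1)
            thr.append(node.threshold if not node.is_leaf else 0.0)
            mort.append(node.mortality if node.is_leaf else 0.0)
            left.append(-1)
            right.append(-1)
            if not node.is_leaf:
                left[idx] = add(node.left)
                right[idx] = add(node.right)
            return idx

        for tree in trees:
            roots.append(add(tree))
            fs: set = set()
            _tree_features(tree, fs)
            self.tree_features.append(fs)
        self.feat = np.asarray(feat, dtype=np.int64)
        self.thr = np.asarray(thr, dtype=float)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.mort = np.asarray(mort, dtype=float)
        self.roots = np.asarray(roots, dtype=np.int64)

    def sum_mortality(self, X, sel=None):
        sel = np.arange(self.roots.size, dtype=np.int64) if sel is None else sel
        if _kernels.HAVE_NUMBA:
            return _kernels.tree_sum_mortality(
                X, self.feat, self.thr, self.left, self.right, self.mort,
                self.roots, np.asarray(sel, dtype=np.int64))
        return self.per_tree(X, sel).sum(axis=0)

    def per_tree(self, X, sel=None):
        sel = np.arange(self.roots.size, dtype=np.int64) if sel is None else sel
        sel = np.asarray(sel, dtype=np.int64)
        if _kernels.HAVE_NUMBA:
            return _kernels.per_tree_mortality(
                X, self.feat, self.thr, self.left, self.right, self.mort,
                self.roots, sel)
        out = np.empty((sel.size, X.shape[0]))
        for row, s in enumerate(sel):
            node_out = np.empty(X.shape[0])
            idx = np.full(X.shape[0], self.roots[s])
            alive = np.arange(X.shape[0])
            while alive.size:
                cur = idx[alive]
                leaf = self.feat[cur] < 0
                node_out[alive[leaf]] = self.mort[cur[leaf]]
                rest = alive[~leaf]
                cur = idx[rest]
                go_left = X[rest, self.feat[cur]] <= self.thr[cur]
                idx[rest] = np.where(go_left, self.left[cur], self.right[cur])
                alive = rest
            out[row] = node_out
        return out


@dataclass
class RandomSurvivalForest:
    """A fitted bootstrap ensemble of log-rank-split survival trees."""

    trees: list
    grid: np.ndarray
    oob_membership: np.ndarray  # (n_trees, n_train) True where sample is OOB
    params: RSFParams
    n_features: int

    @property
    def flat(self) -> _FlatForest:
        if not hasattr(self, "_flat") or self._flat is None:
            self._flat = _FlatForest(self.trees)
        return self._flat

    def used_features(self) -> set:
        acc: set = set()
        for tr in self.trees:
            _tree_features(tr, acc)
        return acc

    def predict_risk(self, X) -> np.ndarray:
        return predict_risk(self, X)

    def predict_risk_per_tree(self, X) -> np.ndarray:
        """(n_trees, n_samples) mortality matrix, used for OOB evaluation."""
        X = np.ascontiguousarray(X, dtype=float)
        return self.flat.per_tree(X)

    def oob_risk(self, X) -> np.ndarray:
        """Out-of-bag ensemble mortality; NaN where a sample was never OOB."""
        per_tree = self.predict_risk_per_tree(X)
        mask = self.oob_membership
        counts = mask.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            risk = np.where(counts > 0, (per_tree * mask).sum(axis=0) / counts, np.nan)
        return risk

    def to_json_dict(self) -> dict:
        return {
            "grid": list(map(float, self.grid)),
            "params": {
                "n_estimators": self.params.n_estimators,
                "max_features": self.params.max_features
                if not isinstance(self.params.max_features, str)
                else self.params.max_features,
                "min_samples_leaf": self.params.min_samples_leaf,
                "min_samples_split": self.params.min_samples_split,
                "seed": self.params.seed,
            },
            "trees": [tr.to_dict() for tr in self.trees],
        }


def fit_rsf(X, outcomes, params: RSFParams) -> RandomSurvivalForest:
    """Fit a random survival forest.

    Each tree is grown on a bootstrap resample; at every node
    ``max_features`` candidate features are drawn without replacement and the
    best (feature, threshold) pair by the log-rank statistic is taken. Leaves
    store the Nelson-Aalen cumulative hazard of their bootstrap samples
    evaluated on the shared grid of training event times.
    """
    X = np.asarray(X, dtype=float)
    time, event = _as_time_event(outcomes)
    if X.ndim != 2 or X.shape[0] != time.shape[0]:
        raise ValueError("X rows must align with outcomes")
    if np.isnan(X).any():
        raise ValueError("X must not contain NA; impute first")
    if event.sum() < params.min_samples_leaf:
        raise ValueError("fewer events than min_samples_leaf")
    n, p = X.shape
    mf = params.resolve_max_features(p)
    grid = np.unique(time[event == 1])
    rng = np.random.default_rng(params.seed)
    trees = []
    oob = np.zeros((params.n_estimators, n), dtype=bool)
    for b in range(params.n_estimators):
        idx = rng.integers(0, n, size=n)
        oob[b] = ~np.isin(np.arange(n), idx)
        tree = _grow_tree(X[idx], time[idx], event[idx], params, mf, grid, rng)
        trees.append(tree)
    return RandomSurvivalForest(trees, grid, oob, params, p)


def predict_risk(forest: RandomSurvivalForest, X) -> np.ndarray:
    """Ensemble mortality: mean over trees of the leaf CHF summed over the grid."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != forest.n_features:
        raise ValueError(
            f"X must have {forest.n_features} features, got {X.shape[1] if X.ndim == 2 else 'non-2d'}"
        )
    X = np.ascontiguousarray(X, dtype=float)
    return forest.flat.sum_mortality(X) / len(forest.trees)


def permutation_importance(
    forest: RandomSurvivalForest,
    X,
    outcomes,
    n_repeats: int = 5,
    seed: int = 0,
    use_oob: bool = False,
) -> np.ndarray:
    """Permutation importance against Harrell's C.

    importance(p) = mean over repeats of C(original) - C(column p permuted).
    Features never used in any split have importance exactly 0 (permuting
    them cannot change any tree routing), and are skipped for speed.

    With ``use_oob=True`` the evaluation risk is the out-of-bag ensemble
    mortality on the training matrix; otherwise the full-forest prediction on
    the supplied evaluation set is used.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.ascontiguousarray(X, dtype=float)
    time, event = _as_time_event(outcomes)
    rng = np.random.default_rng(seed)
    flat = forest.flat
    n_trees = len(forest.trees)

    # per-tree base mortality; only trees using the permuted feature need
    # re-routing, which keeps the quadratic feature sweep cheap
    base_per_tree = flat.per_tree(X)
    if use_oob:
        mask = forest.oob_membership
        counts = mask.sum(axis=0)
        keep = counts > 0
        weights = np.where(keep, counts, 1).astype(float)
    else:
        mask = np.ones((n_trees, X.shape[0]), dtype=bool)
        keep = np.ones(X.shape[0], dtype=bool)
        weights = np.full(X.shape[0], float(n_trees))
    base_sum = (base_per_tree * mask).sum(axis=0)
    base_risk = base_sum / weights
    eval_outcomes = (time[keep], event[keep])
    base_c = harrell_c(eval_outcomes, base_risk[keep])

    trees_with = [
        np.asarray([t for t in range(n_trees) if f in flat.tree_features[t]],
                   dtype=np.int64)
        for f in range(forest.n_features)
    ]
    imp = np.zeros(forest.n_features, dtype=float)
    for f in range(forest.n_features):
        sel = trees_with[f]
        if sel.size == 0:
            continue  # never split on -> permuting cannot change routing
        base_contrib = (base_per_tree[sel] * mask[sel]).sum(axis=0)
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, f] = Xp[rng.permutation(X.shape[0]), f]
            new_per_tree = flat.per_tree(Xp, sel)
            new_contrib = (new_per_tree * mask[sel]).sum(axis=0)
            risk = (base_sum - base_contrib + new_contrib) / weights
            drops.append(base_c - harrell_c(eval_outcomes, risk[keep]))
        imp[f] = float(np.mean(drops))
    return imp
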