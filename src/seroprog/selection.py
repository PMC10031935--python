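"""Cascaded marker selection against right-censored survival.

The cascade: (1) residualize each protein on the eight clinical prognostic
covariates by ordinary least squares, so forests rank proteins on signal not
already explained by the clinic; (2) a survival-forest prescreen drops the
25% of proteins with the lowest median permutation importance and passes the
top 20 forward; (3) randomized-grid hyperparameter tuning with repeated
5-fold cross-validation scored by Harrell's C; (4) repeated 10-fold
cross-validation with the tuned parameters; (5) recursive feature
elimination over the importance-ordered top 20, selecting the feature count
with the highest median test C; (6) rank-concordance summaries across
selection models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.model_selection import KFold

from .survival import (
    RSFParams,
    SurvivalOutcomes,
    fit_rsf,
    harrell_c,
    permutation_importance,
    predict_risk,
)

__all__ = [
    "CLINICAL_CATEGORIES",
    "build_clinical_design",
    "residualize",
    "ImportanceTable",
    "ScreenResult",
    "TuningResult",
    "RFEResult",
    "rf_screen",
    "tune_rsf",
    "crossval_rsf",
    "recursive_feature_elimination",
    "rank_concordance",
    "DEFAULT_GRID",
]

# category structure of the eight adjustment covariates; the first level of
# each is the reference in dummy coding
CLINICAL_CATEGORIES = {
    "ecog": ["0", "1", "2"],
    "mfi_years": ["0", "(0,3)", ">=3"],
    "n_metastatic_sites": ["<3", ">=3"],
    "site": ["non-visceral", "visceral"],
    "subtype": ["ER+HER2-", "HER2+", "TNBC"],
    "nhg": ["I-II", "III"],
    "ctc_ge5": ["<5", ">=5"],
}


def build_clinical_design(clinical: pd.DataFrame, intercept: bool = True) -> pd.DataFrame:
    """Dummy-coded design matrix for the eight adjustment covariates.

    Age enters continuously; each categorical covariate is coded against its
    first listed (reference) level. The same builder backs both the
    residualization step and the multivariable Cox models, so the two cannot
    drift apart in coding.
    """
    cols = {}
    if intercept:
        cols["intercept"] = np.ones(clinical.shape[0])
    if "age" not in clinical.columns:
        raise ValueError("clinical table must contain an 'age' column")
    cols["age"] = clinical["age"].to_numpy(float)
    for cov, levels in CLINICAL_CATEGORIES.items():
        if cov not in clinical.columns:
            raise ValueError(f"clinical table must contain {cov!r}")
        vals = clinical[cov].astype(str)
        unknown = set(vals.unique()) - set(levels) - {"nan"}
        if unknown:
            raise ValueError(f"unknown {cov} categories: {sorted(unknown)}")
        for level in levels[1:]:
            safe = level.replace(" ", "")
            ind = (vals == level).to_numpy(float)
            if ind.sum() == 0:
                continue  # level absent in this cohort: no information
            cols[f"{cov}[{safe}]"] = ind
    return pd.DataFrame(cols, index=clinical.index)


def residualize(X: pd.DataFrame, clinical: pd.DataFrame | None = None,
                design: pd.DataFrame | None = None) -> pd.DataFrame:
    """OLS residuals of each protein on the clinical design.

    The design defaults to the eight-covariate builder applied to
    ``clinical``; an explicit ``design`` (with intercept) overrides it.
    Residuals are orthogonal to every design column. Raises when the design
    is rank deficient, naming the collinear columns.
    """
    if X.isna().to_numpy().any():
        raise ValueError("X must be fully observed (impute first)")
    if design is None:
        if clinical is None:
            raise ValueError("provide clinical covariates or an explicit design")
        design = build_clinical_design(clinical.loc[X.index])
    D = design.to_numpy(float)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name a minimal set of columns whose removal restores full rank
        bad = []
        cols = list(design.columns)
        current = D
        while np.linalg.matrix_rank(current) < current.shape[1]:
            for j in range(current.shape[1]):
                reduced = np.delete(current, j, axis=1)
                if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(current):
                    bad.append(cols.pop(j))
                    current = reduced
                    break
        raise ValueError(f"rank-deficient clinical design; collinear columns: {bad}")
    Y = X.to_numpy(float)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    return pd.DataFrame(resid, index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# screening


@dataclass
class ImportanceTable:
    """Per-protein permutation-importance medians across seeded repeats."""

    table: pd.DataFrame  # index protein; columns: median_importance, rank
    repeats: pd.DataFrame  # (protein x repeat) raw importances

    @classmethod
    def from_repeats(cls, repeats: pd.DataFrame) -> "ImportanceTable":
        med = repeats.median(axis=1)
        rank = med.rank(ascending=False, method="first").astype(int)
        table = pd.DataFrame({"median_importance": med, "rank": rank})
        return cls(table.sort_values("rank"), repeats)

    def ordered_proteins(self) -> list:
        return list(self.table.index)


@dataclass
class ScreenResult:
    importance: ImportanceTable
    retained: list
    top20: list
    n_eliminated: int


DEFAULT_SCREEN_PARAMS = dict(n_estimators=500, max_features="sqrt",
                             min_samples_leaf=5, min_samples_split=10)


def rf_screen(
    X: pd.DataFrame,
    outcomes: SurvivalOutcomes,
    n_repeats: int = 5,
    seed: int = 0,
    params: dict | None = None,
    importance_repeats: int = 3,
    top_k: int = 20,
    use_oob: bool = True,
) -> ScreenResult:
    """Untuned survival-forest prescreen.

    Fits ``n_repeats`` seeded forests with fixed default parameters, takes
    per-protein median permutation importance, removes the ceil(25%) proteins
    with the lowest medians, and passes the ``top_k`` highest-median proteins
    among those retained. Screening is done per endpoint; the caller runs it
    once for OS and once for PFS.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if X.shape[1] < top_k + 1:
        raise ValueError(f"need at least {top_k + 1} proteins to screen")
    p = dict(DEFAULT_SCREEN_PARAMS)
    if params:
        p.update(params)
    Xv = X.to_numpy(float)
    cols = []
    for r in range(n_repeats):
        rp = RSFParams(seed=seed * 10_000 + r, **p)
        forest = fit_rsf(Xv, outcomes, rp)
        imp = permutation_importance(forest, Xv, outcomes,
                                     n_repeats=importance_repeats,
                                     seed=seed * 10_000 + r, use_oob=use_oob)
        cols.append(pd.Series(imp, index=X.columns, name=f"repeat{r}"))
    repeats = pd.concat(cols, axis=1)
    imp_table = ImportanceTable.from_repeats(repeats)
    n_prot = X.shape[1]
    n_drop = int(np.ceil(0.25 * n_prot))
    ordered = imp_table.ordered_proteins()
    retained = ordered[: n_prot - n_drop]
    top = retained[:top_k]
    return ScreenResult(imp_table, retained, top, n_drop)


# ---------------------------------------------------------------------------
# tuning and cross-validation

DEFAULT_GRID = {
    "n_estimators": list(range(100, 1001, 100)),
    "max_features": list(range(2, 11)),
    "min_samples_leaf": list(range(3, 16)),
    "min_samples_split": list(range(6, 31)),
}


@dataclass
class TuningResult:
    candidates: list  # RSFParams-like dicts
    cv_scores: list  # per-candidate array of test C values
    best_params: RSFParams
    best_median: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cand, scores in zip(self.candidates, self.cv_scores):
            row = dict(cand)
            row["median_test_c"] = float(np.median(scores))
            rows.append(row)
        return pd.DataFrame(rows)


def _sample_grid(grid: dict, n_candidates: int, rng: np.random.Generator) -> list:
    keys = sorted(grid)
    if any(len(grid[k]) == 0 for k in keys):
        raise ValueError("empty grid")
    out = []
    for _ in range(n_candidates):
        cand = {k: grid[k][rng.integers(len(grid[k]))] for k in keys}
        # keep the split/leaf invariant satisfiable
        cand["min_samples_split"] = max(cand["min_samples_split"],
                                        2 * cand["min_samples_leaf"])
        out.append(cand)
    return out


def _cv_scores(Xv, outcomes, params: RSFParams, n_folds: int, n_repeats: int,
               seed: int, with_train: bool = False):
    """Test (and optionally train) C for all folds x repeats, seeded."""
    time, event = outcomes.time, outcomes.event
    test_c, train_c = [], []
    for rep in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for fold, (tr, te) in enumerate(kf.split(Xv)):
            p = RSFParams(
                n_estimators=params.n_estimators,
                max_features=params.max_features,
                min_samples_leaf=params.min_samples_leaf,
                min_samples_split=params.min_samples_split,
                seed=params.seed + 97 * rep + fold,
            )
            forest = fit_rsf(Xv[tr], outcomes.subset(tr), p)
            risk_te = predict_risk(forest, Xv[te])
            test_c.append(harrell_c((time[te], event[te]), risk_te))
            if with_train:
                risk_tr = predict_risk(forest, Xv[tr])
                train_c.append(harrell_c((time[tr], event[tr]), risk_tr))
    if with_train:
        return np.asarray(train_c), np.asarray(test_c)
    return np.asarray(test_c)


def tune_rsf(
    X: pd.DataFrame,
    outcomes: SurvivalOutcomes,
    grid: dict | None = None,
    n_candidates: int = 25,
    n_folds: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
) -> TuningResult:
    """Randomized grid search with repeated k-fold cross-validation.

    Samples ``n_candidates`` configurations uniformly from the grid; each is
    scored by the test-fold Harrell's C of the forest risk over
    ``n_folds``-fold CV repeated ``n_repeats`` times (fold assignment seeded
    per repeat). Returns the configuration with the maximal median test C
    (ties break toward the earlier-sampled candidate).
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    grid = DEFAULT_GRID if grid is None else grid
    rng = np.random.default_rng(seed)
    candidates = _sample_grid(grid, n_candidates, rng)
    Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    scores = []
    best_idx, best_median = 0, -np.inf
    for i, cand in enumerate(candidates):
        params = RSFParams(seed=seed + 1000 * i, **cand)
        sc = _cv_scores(Xv, outcomes, params, n_folds, n_repeats, seed=seed)
        scores.append(sc)
        med = float(np.median(sc))
        if med > best_median:
            best_median, best_idx = med, i
    best = RSFParams(seed=seed, **candidates[best_idx])
    return TuningResult(candidates, scores, best, best_median)


def crossval_rsf(
    X,
    outcomes: SurvivalOutcomes,
    params: RSFParams,
    n_folds: int = 10,
    n_repeats: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Repeated k-fold train/test C distributions under fixed parameters."""
    Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if n_folds > Xv.shape[0]:
        raise ValueError("n_folds exceeds the number of samples")
    return _cv_scores(Xv, outcomes, params, n_folds, n_repeats, seed, with_train=True)


# ---------------------------------------------------------------------------
# recursive feature elimination


@dataclass
class RFEResult:
    curve: pd.Series  # n_features -> median test C
    selected_set: list
    selected_size: int
    order: list  # proteins by descending median importance
    n_folds: int
    n_repeats: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_features": self.curve.index,
            "median_test_c": self.curve.to_numpy(),
            "selected": [k == self.selected_size for k in self.curve.index],
        })


def recursive_feature_elimination(
    X: pd.DataFrame,
    outcomes: SurvivalOutcomes,
    params: RSFParams,
    importance: pd.Series,
    n_folds: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
) -> RFEResult:
    """Find the feature count that maximizes cross-validated Harrell's C.

    Proteins are ordered by descending median importance; for each k the
    top-k set is evaluated by repeated k-fold CV under ``params``. The
    selected size is the argmax of the median test C, ties broken toward the
    smaller (more parsimonious) k.
    """
    missing = [p for p in X.columns if p not in importance.index]
    if missing:
        raise ValueError(f"importance table missing proteins: {missing}")
    order = list(importance.loc[list(X.columns)]
                 .sort_values(ascending=False, kind="stable").index)
    medians = {}
    for k in range(1, len(order) + 1):
        cols = order[:k]
        sc = _cv_scores(X[cols].to_numpy(float), outcomes, params,
                        n_folds, n_repeats, seed)
        medians[k] = float(np.median(sc))
    curve = pd.Series(medians).sort_index()
    best_k = int(curve.index[np.argmax(curve.to_numpy())])  # first max -> smallest k
    return RFEResult(curve, order[:best_k], best_k, order, n_folds, n_repeats)


# ---------------------------------------------------------------------------
# cross-model rank concordance


def rank_concordance(rankings: dict) -> dict:
    """Cross-model rank table, pairwise Spearman, and top-k set overlaps.

    ``rankings`` maps model name -> pd.Series of per-protein ranks (1 =
    most important). Models must share at least part of a protein universe.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two models")
    names = list(rankings)
    universe = set()
    for s in rankings.values():
        universe |= set(s.index)
    shared = set.intersection(*[set(s.index) for s in rankings.values()])
    if not shared:
        raise ValueError("models have disjoint protein sets")
    table = pd.DataFrame(index=sorted(universe))
    for name in names:
        table[name] = rankings[name].reindex(table.index)
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        common = rankings[a].index.intersection(rankings[b].index)
        r, _ = spearmanr(rankings[a].loc[common], rankings[b].loc[common])
        rho.loc[a, b] = rho.loc[b, a] = float(r)
    overlaps = {}
    for k in (5, 9, 10, 13, 20):
        tops = {n: set(rankings[n].nsmallest(k).index) for n in names}
        inter = set.intersection(*tops.values())
        union = set.union(*tops.values())
        overlaps[k] = {"intersection": len(inter), "union": len(union)}
    return {"table": table, "spearman": rho, "top_k_overlap": overlaps}
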