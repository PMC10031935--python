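"""Median-dichotomized marker vs clinicopathological-feature associations.

Each selected serum protein is split at its median NPX into low/high; the
association between marker-high status and a clinical feature is tested with
Fisher's exact test for two-level features and logistic regression (odds
ratios against the feature's reference level) for features with three or
more levels. This reproduces odds-ratio tables of the form
feature x marker with per-level OR, 95% CI, p, and the test code
(a = Fisher, b = logistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DichotomizedMarker",
    "AssociationResult",
    "dichotomize_at_median",
    "fisher_exact",
    "logistic_or",
    "association_table",
]


@dataclass
class DichotomizedMarker:
    """Low/high labels at the per-protein median; ties at the median go low."""

    protein: str
    cutoff: float
    labels: np.ndarray  # True = high

    @property
    def n_high(self) -> int:
        return int(self.labels.sum())

    @property
    def n_low(self) -> int:
        return int((~self.labels).sum())


def dichotomize_at_median(values, protein: str = "marker") -> DichotomizedMarker:
    """Split at the median; value <= median -> low, > median -> high."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(v).any():
        raise ValueError("values must not contain NA")
    if np.all(v == v[0]):
        raise ValueError(f"all values identical for {protein!r}; no contrast")
    cutoff = float(np.median(v))
    return DichotomizedMarker(protein, cutoff, v > cutoff)


@dataclass
class AssociationResult:
    """One feature-level vs marker-high association."""

    marker: str
    feature: str
    level: str
    n: int
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    test: str  # "fisher" (a) or "logistic" (b); "reference" for OR = 1 rows
    flag: str = ""

    def to_row(self) -> dict:
        return {
            "marker": self.marker, "feature": self.feature, "level": self.level,
            "n": self.n, "OR": self.odds_ratio, "CI95_low": self.ci_low,
            "CI95_high": self.ci_high, "P": self.p, "test": self.test,
            "flag": self.flag,
        }


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (OR, p) with OR the cross-product ratio ad/bc (NaN on a zero
    margin, where p is 1 by convention). The two-sided p sums hypergeometric
    probabilities of all tables, with the observed margins, whose probability
    does not exceed the observed table's.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    a, b = t[0]
    c, d = t[1]
    if min(a + b, c + d, a + c, b + d) == 0:
        return np.nan, 1.0
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds), float(p)


def _fisher_ci(table, level: float = 0.95) -> tuple[float, float]:
    """Wald CI on the log cross-product odds ratio (Woolf, 0.5 correction on
    zero cells) — the standard companion interval for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if (t == 0).any():
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def logistic_or(marker: DichotomizedMarker, feature: pd.Series,
                reference: str | None = None) -> list[AssociationResult]:
    """Logistic regression of marker-high on dummy-coded feature levels.

    Per-level OR = exp(coefficient) against the reference level (first
    category by default), with Wald 95% CI and p. Quasi-separation is
    flagged rather than silently reported.
    """
    y = marker.labels.astype(float)
    f = feature.astype(str)
    levels = list(pd.unique(f))
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not present")
        levels = [reference] + [l for l in levels if l != reference]
    if len(levels) < 2:
        raise ValueError("feature must have at least 2 levels")
    counts = f.value_counts()
    if (counts < 1).any():
        raise ValueError("every level must be non-empty")
    Xcols = {f"{feature.name}[{lv}]": (f == lv).to_numpy(float) for lv in levels[1:]}
    X = pd.DataFrame(Xcols)
    X.insert(0, "intercept", 1.0)
    flag = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X.to_numpy())
        try:
            res = model.fit(disp=0, method="newton", tol=1e-9, maxiter=100)
            params = res.params
            bse = res.bse
            pvals = res.pvalues
            if np.any(np.abs(params[1:]) > 15) or np.any(~np.isfinite(bse)):
                flag = "separation"
        except Exception:
            flag = "separation"
            params = np.zeros(X.shape[1])
            bse = np.full(X.shape[1], np.inf)
            pvals = np.ones(X.shape[1])
    out = [AssociationResult(marker.protein, str(feature.name), levels[0],
                             int((f == levels[0]).sum()), 1.0, None, None, None,
                             "reference")]
    for i, lv in enumerate(levels[1:], start=1):
        beta, se, p = float(params[i]), float(bse[i]), float(pvals[i])
        out.append(AssociationResult(
            marker.protein, str(feature.name), lv, int((f == lv).sum()),
            float(np.exp(beta)),
            float(np.exp(beta - 1.96 * se)) if np.isfinite(se) else 0.0,
            float(np.exp(beta + 1.96 * se)) if np.isfinite(se) else np.inf,
            p, "logistic", flag))
    return out


def association_table(
    markers: pd.DataFrame,
    features: pd.DataFrame,
    references: dict | None = None,
) -> pd.DataFrame:
    """Marker x feature association grid.

    ``markers``: samples x selected proteins (continuous NPX; dichotomized
    here at each protein's median). ``features``: samples x clinical
    features (categorical). Two-level features use Fisher's exact test
    (test code "a"); features with three or more levels use logistic
    regression (test code "b"). Samples missing a feature are dropped for
    that feature and counted in the ``n_missing`` column.
    """
    if not markers.index.equals(features.index):
        raise ValueError("markers and features must be aligned on samples")
    references = references or {}
    rows = []
    for protein in markers.columns:
        marker_all = dichotomize_at_median(markers[protein].to_numpy(float),
                                           str(protein))
        for feat in features.columns:
            fvals = features[feat]
            present = fvals.notna() & (fvals.astype(str) != "nan")
            n_missing = int((~present).sum())
            f = fvals[present].astype(str)
            high = marker_all.labels[present.to_numpy()]
            sub_marker = DichotomizedMarker(str(protein), marker_all.cutoff, high)
            uniq = pd.unique(f)
            ref = references.get(feat, sorted(uniq)[0] if len(uniq) else None)
            if len(uniq) < 2:
                rows.append({"marker": str(protein), "feature": feat,
                             "level": "-", "n": int(present.sum()), "OR": np.nan,
                             "CI95_low": np.nan, "CI95_high": np.nan, "P": np.nan,
                             "test": "skipped", "flag": "single level",
                             "n_missing": n_missing})
                continue
            if len(uniq) == 2:
                lv = sorted(uniq)
                if ref in lv:
                    lv = [ref] + [l for l in lv if l != ref]
                tab = np.array([
                    [np.sum((f == lv[0]).to_numpy() & ~high),
                     np.sum((f == lv[0]).to_numpy() & high)],
                    [np.sum((f == lv[1]).to_numpy() & ~high),
                     np.sum((f == lv[1]).to_numpy() & high)],
                ])
                # OR for level 2 vs reference of being marker-high
                odds, p = fisher_exact(np.array([[tab[1, 1], tab[1, 0]],
                                                 [tab[0, 1], tab[0, 0]]]))
                ci = _fisher_ci(np.array([[tab[1, 1], tab[1, 0]],
                                          [tab[0, 1], tab[0, 0]]]))
                rows.append({"marker": str(protein), "feature": feat,
                             "level": lv[0], "n": int((f == lv[0]).sum()),
                             "OR": 1.0, "CI95_low": np.nan, "CI95_high": np.nan,
                             "P": np.nan, "test": "reference", "flag": "",
                             "n_missing": n_missing})
                rows.append({"marker": str(protein), "feature": feat,
                             "level": lv[1], "n": int((f == lv[1]).sum()),
                             "OR": odds, "CI95_low": ci[0], "CI95_high": ci[1],
                             "P": p, "test": "a", "flag": "",
                             "n_missing": n_missing})
            else:
                results = logistic_or(sub_marker, f.rename(feat), reference=ref)
                for r in results:
                    row = r.to_row()
                    row["test"] = {"fisher": "a", "logistic": "b",
                                   "reference": "reference"}[row["test"]]
                    row["n_missing"] = n_missing
                    rows.append(row)
    return pd.DataFrame(rows)
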