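"""Classical and elastic-net Cox regression with per-doubling hazard ratios.

Because serum protein abundances are expressed in log2 NPX units, the
coefficient of a protein in a Cox model is the log hazard ratio *per
doubling* of protein content; ``exp(beta)`` is the per-doubling HR reported
throughout.

Panel-wide multiple testing uses Benjamini-Hochberg q-values computed with
the full panel size m (92 by default) even when fewer fits converge;
non-converged fits carry p = 1. Evidence is classified with the
two-threshold convention: significant (p < 0.005), suggestive
(0.005 <= p < 0.05), weak otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .survival import SurvivalOutcomes, _as_time_event

__all__ = [
    "CoxFit",
    "PenalizedCoxFit",
    "fit_cox",
    "cox_panel",
    "fit_elastic_net_cox",
    "bh_qvalues",
    "classify_evidence",
    "breslow_partial_loglik",
]


@dataclass
class CoxFit:
    """One Cox regression focused on a single protein term.

    ``beta`` is the log-HR per unit of x; with x in log2 NPX units this is
    the log-HR per doubling, so ``hr = exp(beta)`` is the per-doubling HR.
    """

    protein: str
    endpoint: str
    adjusted: bool
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    converged: bool
    ties: str = "efron"
    summary: pd.DataFrame | None = None

    def to_row(self) -> dict:
        return {
            "protein": self.protein,
            "endpoint": self.endpoint,
            "adjusted": self.adjusted,
            "beta": self.beta,
            "se": self.se,
            "HR": self.hr,
            "CI95_low": self.ci_low,
            "CI95_high": self.ci_high,
            "P": self.p,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
        }


def fit_cox(x, outcomes, adjust: pd.DataFrame | None = None,
            name: str = "protein", endpoint: str | None = None) -> CoxFit:
    """Cox proportional-hazards fit of one protein, optionally adjusted.

    Maximizes the partial likelihood with Efron's tie handling by
    Newton-Raphson (via lifelines). ``adjust`` is the dummy-coded covariate
    design; complete-case rows only — the caller drops missing covariates.
    Non-convergence or a monotone likelihood yields ``converged=False`` with
    p = 1 rather than silent values.
    """
    time, event = _as_time_event(outcomes)
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("x must not contain NA")
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    ep = endpoint or (outcomes.endpoint if isinstance(outcomes, SurvivalOutcomes) else "OS")
    df = pd.DataFrame({name: x, "_time": time, "_event": event})
    if adjust is not None:
        adjust = adjust.reset_index(drop=True)
        for col in adjust.columns:
            df[col] = adjust[col].to_numpy(float)
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event",
                    fit_options={"precision": 1e-9, "max_steps": 100})
        summ = cph.summary
        beta = float(summ.loc[name, "coef"])
        se = float(summ.loc[name, "se(coef)"])
        p = float(summ.loc[name, "p"])
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 50:
            converged = False
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        converged = False
        summ = None
    if not converged:
        beta, se, p = 0.0, np.inf, 1.0
    return CoxFit(
        protein=name,
        endpoint=ep,
        adjusted=adjust is not None,
        beta=beta,
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)) if np.isfinite(se) else 0.0,
        ci_high=float(np.exp(beta + 1.96 * se)) if np.isfinite(se) else np.inf,
        p=p,
        n=int(df.shape[0]),
        n_events=int(event.sum()),
        converged=converged,
        summary=summ,
    )


def cox_panel(X: pd.DataFrame, outcomes, adjust: pd.DataFrame | None = None,
              endpoint: str | None = None) -> pd.DataFrame:
    """Univariable (or covariate-adjusted) Cox fits for every panel protein."""
    rows = []
    for protein in X.columns:
        fit = fit_cox(X[protein].to_numpy(float), outcomes, adjust=adjust,
                      name=str(protein), endpoint=endpoint)
        rows.append(fit.to_row())
    out = pd.DataFrame(rows).set_index("protein")
    return out


# ---------------------------------------------------------------------------
# penalized Cox (elastic net)


def breslow_partial_loglik(beta: np.ndarray, X: np.ndarray, time, event) -> float:
    """Cox partial log-likelihood with Breslow tie handling, used for the
    cross-validated deviance that selects the penalty strength."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    log_cumsum = np.logaddexp.accumulate(eta_o)
    # risk set of sample i (sorted decreasing) = samples 0..i
    ll = 0.0
    i = 0
    n = t_o.shape[0]
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        # all samples with time >= t_o[i] are 0..j-1
        denom = log_cumsum[j - 1]
        for k in range(i, j):
            if e_o[k] == 1:
                ll += eta_o[k] - denom
        i = j
    return float(ll)


@dataclass
class PenalizedCoxFit:
    """An elastic-net Cox path with a cross-validation-selected penalty."""

    alpha: float  # L1/L2 mixing in [0, 1]
    lambdas: np.ndarray
    coef_path: np.ndarray  # (n_features, n_lambdas), standardized scale
    cv_deviance: np.ndarray  # mean CV deviance per lambda
    selected_lambda: float
    selected_index: int
    proteins: list
    all_zero: bool = False

    @property
    def selected_coefs(self) -> pd.Series:
        return pd.Series(self.coef_path[:, self.selected_index], index=self.proteins)

    @property
    def variable_weights(self) -> pd.Series:
        """|standardized coefficient| at the selected penalty, for ranking."""
        return self.selected_coefs.abs().sort_values(ascending=False)

    def rank_table(self) -> pd.Series:
        w = self.selected_coefs.abs()
        return w.rank(ascending=False, method="first").astype(int)


def fit_elastic_net_cox(
    X: pd.DataFrame,
    outcomes,
    alpha: float = 0.5,
    lambdas: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 50,
) -> PenalizedCoxFit:
    """Elastic-net penalized Cox regression over a lambda path.

    Columns are standardized to unit variance internally, so coefficient
    magnitudes are comparable across proteins and serve as variable weights.
    The path is fit by cyclic coordinate descent (glmnet-style, via
    scikit-survival); the penalty is selected by cross-validated partial-
    likelihood deviance. An all-zero selected model is reported as such, not
    as an error.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    time, event = _as_time_event(outcomes)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    proteins = list(X.columns)
    Xs = X.to_numpy(float)
    mu, sd = Xs.mean(axis=0), Xs.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xs - mu) / sd
    # coordinate descent requires a strictly positive L1 share; a pure-ridge
    # request is approximated with a numerically tiny one
    l1_ratio = max(alpha, 1e-4)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    def fit_path(Xa, ya, alphas):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio,
            alphas=alphas,
            normalize=False,
            fit_baseline_model=False,
            tol=1e-9,
            max_iter=200000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xa, ya)
        return model

    if lambdas is None:
        probe = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=n_lambdas,
                                       alpha_min_ratio=0.001, normalize=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe.fit(Xs, y)
        lambdas = np.asarray(probe.alphas_)
    else:
        lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
        lambdas = np.maximum(lambdas, 1e-10)  # the solver needs positive penalties

    # cross-validated deviance: -2 * (pll(beta; fold) ) difference vs null
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    dev = np.zeros((cv_folds, lambdas.size))
    for f, (tr, te) in enumerate(kf.split(Xs)):
        m = fit_path(Xs[tr], y[tr], lambdas)
        coefs = m.coef_  # (p, n_fitted); the solver may stop the path early
        n_fitted = coefs.shape[1]
        for li in range(lambdas.size):
            beta = coefs[:, min(li, n_fitted - 1)]
            pll = breslow_partial_loglik(beta, Xs[te], time[te], event[te])
            dev[f, li] = -2.0 * pll
    mean_dev = dev.mean(axis=0)
    sel = int(np.argmin(mean_dev))

    final = fit_path(Xs, y, lambdas)
    coef_path = np.asarray(final.coef_)
    if coef_path.shape[1] < lambdas.size:  # early-stopped path
        lambdas = lambdas[: coef_path.shape[1]]
        mean_dev = mean_dev[: coef_path.shape[1]]
        sel = min(sel, coef_path.shape[1] - 1)
    fit = PenalizedCoxFit(
        alpha=alpha,
        lambdas=lambdas,
        coef_path=coef_path,
        cv_deviance=mean_dev,
        selected_lambda=float(lambdas[sel]),
        selected_index=sel,
        proteins=proteins,
        all_zero=bool(np.all(coef_path[:, sel] == 0.0)),
    )
    return fit


# ---------------------------------------------------------------------------
# multiple testing and evidence thresholds


def bh_qvalues(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with an explicit panel size m.

    q(i) = min_{j >= i} p(j) * m / j on the sorted scale, mapped back to the
    input order and capped at 1. m defaults to len(pvals) and must be at
    least that large; using the full panel size (92) even when fewer fits
    converged matches adjusting over all assayed proteins.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("panel size m must be >= len(pvals)")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    q_sorted = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def classify_evidence(p: float) -> str:
    """Two-threshold evidence labels: significant (p < 0.005),
    suggestive (0.005 <= p < 0.05), weak otherwise."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    if p < 0.005:
        return "significant"
    if p < 0.05:
        return "suggestive"
    return "weak"


def qvalue_table(panel: pd.DataFrame, m: int = 92) -> pd.DataFrame:
    """Attach q-values and evidence classes to a cox_panel result."""
    out = panel.copy()
    p = out["P"].to_numpy(float)
    p = np.where(out["converged"].to_numpy(bool), p, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out["q"] = bh_qvalues(p, m=max(m, p.size))
    out["evidence"] = [classify_evidence(float(v)) for v in p]
    return out
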