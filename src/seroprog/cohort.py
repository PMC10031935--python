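"""Synthetic metastatic-breast-cancer cohort generator.

Emulates the statistical structure the downstream analysis assumes: a panel
of 92 serum proteins on a log2 NPX scale with correlated blocks and
per-protein limits of detection, the clinical covariates of a first-line MBC
cohort, and proportional-hazards OS/PFS outcomes with planted per-doubling
log hazard ratios, shared frailty between the two endpoints, and independent
right censoring calibrated to a target censored fraction.

The generator is the study-condition oracle for the test suite: planted
effects are recorded in ``truth`` so recovery can be checked end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .preprocess import NPXMatrix

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "write_cohort", "read_cohort"]


# Covariate category frequencies of a first-line MBC cohort (n=136-scale):
# ECOG 0/1/2 ~ 55/27/15%, visceral ~59%, >=3 metastatic sites ~29%,
# subtype ER+HER2-/HER2+/TNBC ~ 70/11/18%, NHG III ~31%, CTC>=5 ~51%,
# metastasis-free interval 0 / (0,3) / >=3 years ~ 21/18/61%.
_COVARIATE_LEVELS = {
    "ecog": (["0", "1", "2"], [0.552, 0.265, 0.154]),
    "mfi_years": (["0", "(0,3)", ">=3"], [0.206, 0.184, 0.610]),
    "n_metastatic_sites": (["<3", ">=3"], [0.706, 0.294]),
    "site": (["non-visceral", "visceral"], [0.412, 0.588]),
    "subtype": (["ER+HER2-", "HER2+", "TNBC"], [0.707, 0.113, 0.180]),
    "nhg": (["I-II", "III"], [0.618, 0.382]),
    "ctc_ge5": (["<5", ">=5"], [0.485, 0.515]),
}

COVARIATE_COLUMNS = ("age", "ecog", "mfi_years", "n_metastatic_sites",
                     "site", "subtype", "nhg", "ctc_ge5")


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort.

    planted_effects maps protein id -> (log-HR per doubling for OS,
    log-HR per doubling for PFS); NPX is log2-scaled so a unit increase is a
    doubling. baseline_hazard is the (shape, scale-in-months) of the Weibull
    OS baseline; the PFS baseline uses the same shape with a shorter scale.
    """

    n_samples: int = 136
    n_proteins: int = 92
    correlation_blocks: tuple = ((8, 0.5), (8, 0.5), (6, 0.3))
    planted_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    protein_covariate_confounding: dict = field(default_factory=dict)
    lod_quantile: float = 0.05
    lod_sd: float = 0.1
    censoring_rate: float = 0.3
    baseline_hazard: tuple = (1.2, 42.0)  # shape, scale: median OS ~ 42*ln2^(1/1.2) ~ 31 mo
    pfs_scale: float = 12.0
    frailty_sd: float = 0.5
    frailty_correlation: float = 0.5
    missing_sample_fraction: float = 0.0
    npx_mean: float = 5.0
    npx_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        for frac, name in [
            (self.lod_quantile, "lod_quantile"),
            (self.censoring_rate, "censoring_rate"),
            (self.missing_sample_fraction, "missing_sample_fraction"),
        ]:
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if sum(b for b, _ in self.correlation_blocks) > self.n_proteins:
            raise ValueError("correlation block sizes must sum to <= n_proteins")
        for _, rho in self.correlation_blocks:
            if not 0.0 <= rho < 1.0:
                raise ValueError("within-block correlation must be in [0, 1)")
        ids = set(self.protein_ids())
        for pid in self.planted_effects:
            if pid not in ids:
                raise ValueError(f"planted effect refers to unknown protein {pid!r}")
        # crude overflow guard on the linear predictor
        total = sum(abs(b_os) + abs(b_pfs) for b_os, b_pfs in self.planted_effects.values())
        if total * (self.npx_mean + 6 * self.npx_sd) > 500:
            raise ValueError("planted effects would overflow the linear predictor")

    def protein_ids(self) -> list[str]:
        return [f"P{i+1:03d}" for i in range(self.n_proteins)]

    def sample_ids(self) -> list[str]:
        return [f"S{i+1:04d}" for i in range(self.n_samples)]


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    npx: NPXMatrix
    npx_true: np.ndarray
    clinical: pd.DataFrame
    os: pd.DataFrame   # columns: time, event
    pfs: pd.DataFrame
    manifest: pd.DataFrame  # sample_id, reason
    truth: dict

    def outcomes(self, endpoint: str):
        from .survival import SurvivalOutcomes

        df = {"OS": self.os, "PFS": self.pfs}[endpoint.upper()]
        return SurvivalOutcomes(df["time"].to_numpy(), df["event"].to_numpy(),
                                endpoint.upper())


def _block_covariance(config: CohortConfig) -> np.ndarray:
    p = config.n_proteins
    cov = np.eye(p)
    start = 0
    for size, rho in config.correlation_blocks:
        cov[start:start + size, start:start + size] = rho
        np.fill_diagonal(cov[start:start + size, start:start + size], 1.0)
        start += size
    return cov * config.npx_sd**2


def _draw_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    cols = {"sample_id": config.sample_ids()}
    # age: roughly 65 (40-90) as in first-line MBC cohorts
    cols["age"] = np.clip(np.round(rng.normal(65, 10, n)), 40, 90).astype(int)
    for name, (levels, probs) in _COVARIATE_LEVELS.items():
        probs = np.asarray(probs) / np.sum(probs)
        cols[name] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(cols).set_index("sample_id")


def _covariate_indicator(clinical: pd.DataFrame, key: str) -> np.ndarray:
    """Indicator/numeric vector for a covariate spec like 'ecog=2' or 'age'."""
    if "=" in key:
        col, level = key.split("=", 1)
        if col not in clinical.columns:
            raise ValueError(f"unknown covariate {col!r}")
        return (clinical[col].astype(str) == level).to_numpy(float)
    if key not in clinical.columns:
        raise ValueError(f"unknown covariate {key!r}")
    return clinical[key].to_numpy(float)


def _weibull_times(lp: np.ndarray, shape: float, scale: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample T from a Weibull proportional-hazards model with linear predictor lp."""
    u = rng.uniform(size=lp.shape[0])
    return scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)


def _censor(times: np.ndarray, target: float, rng: np.random.Generator):
    """Independent exponential censoring with the rate solved so the expected
    censored fraction matches ``target`` for the realized event times."""
    if target <= 0:
        return times.copy(), np.ones(times.shape[0], dtype=int)

    def expected_censored(log_rate):
        return float(np.mean(1.0 - np.exp(-np.exp(log_rate) * times))) - target

    log_rate = brentq(expected_censored, -30.0, 30.0)
    c = rng.exponential(1.0 / np.exp(log_rate), size=times.shape[0])
    observed = np.minimum(times, c)
    event = (times <= c).astype(int)
    return observed, event


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort; identical config + seed reproduces it bit-for-bit."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_proteins
    protein_ids = config.protein_ids()
    pid_index = {pid: j for j, pid in enumerate(protein_ids)}

    clinical = _draw_covariates(config, rng)

    cov = _block_covariance(config)
    chol = np.linalg.cholesky(cov)
    latent = config.npx_mean + rng.standard_normal((n, p)) @ chol.T
    for (pid, covkey), shift in config.protein_covariate_confounding.items():
        latent[:, pid_index[pid]] += shift * _covariate_indicator(clinical, covkey)
    npx_true = latent.copy()

    # linear predictors: per-doubling log-HRs act on centered log2 NPX, plus
    # covariate effects and a shared Gaussian frailty linking OS and PFS
    centered = latent - latent.mean(axis=0, keepdims=True)
    lp_os = np.zeros(n)
    lp_pfs = np.zeros(n)
    for pid, (b_os, b_pfs) in config.planted_effects.items():
        j = pid_index[pid]
        lp_os += b_os * centered[:, j]
        lp_pfs += b_pfs * centered[:, j]
    for covkey, beta in config.covariate_effects.items():
        ind = _covariate_indicator(clinical, covkey)
        ind = ind - ind.mean()
        lp_os += beta * ind
        lp_pfs += beta * ind
    rho = config.frailty_correlation
    z_shared = rng.standard_normal(n)
    z_os = rng.standard_normal(n)
    z_pfs = rng.standard_normal(n)
    if config.frailty_sd > 0:
        lp_os += config.frailty_sd * (np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * z_os)
        lp_pfs += config.frailty_sd * (np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * z_pfs)
    if not (np.all(np.isfinite(np.exp(lp_os))) and np.all(np.isfinite(np.exp(lp_pfs)))):
        raise ValueError("linear predictor overflows; reduce planted effects")

    shape, scale = config.baseline_hazard
    t_os = _weibull_times(lp_os, shape, scale, rng)
    t_pfs = _weibull_times(lp_pfs, shape, config.pfs_scale, rng)
    os_time, os_event = _censor(t_os, config.censoring_rate, rng)
    pfs_time, pfs_event = _censor(t_pfs, config.censoring_rate, rng)
    os_time = np.maximum(os_time, 1e-3)
    pfs_time = np.maximum(pfs_time, 1e-3)

    # per-protein LOD at the requested quantile of the latent marginal, with a
    # reported LOD-estimate SD used by downstream censoring rules
    if config.lod_quantile > 0:
        lod = np.quantile(latent, config.lod_quantile, axis=0)
    else:
        lod = latent.min(axis=0) - 6 * config.npx_sd
    lod_sd = np.full(p, config.lod_sd)
    npx = NPXMatrix(config.sample_ids(), protein_ids, latent.copy(), lod, lod_sd)

    # availability manifest: missing samples split over the three real-world
    # reasons in 14:5:1 proportion (lost sample, QC failure, low volume)
    reasons = np.array(["available"] * n, dtype=object)
    n_missing = int(round(config.missing_sample_fraction * n))
    if n_missing:
        missing_idx = rng.choice(n, size=n_missing, replace=False)
        reason_pool = rng.choice(
            ["no_sample", "qc_fail", "insufficient_material"],
            size=n_missing, p=np.array([14, 5, 1]) / 20,
        )
        reasons[missing_idx] = reason_pool
    manifest = pd.DataFrame({"sample_id": config.sample_ids(), "reason": reasons})

    truth = {
        "planted_effects": {k: list(v) for k, v in config.planted_effects.items()},
        "covariate_effects": dict(config.covariate_effects),
        "baseline_hazard": list(config.baseline_hazard),
        "censoring_rate": config.censoring_rate,
        "seed": config.seed,
    }
    sid = config.sample_ids()
    os_df = pd.DataFrame({"time": os_time, "event": os_event}, index=sid)
    pfs_df = pd.DataFrame({"time": pfs_time, "event": pfs_event}, index=sid)
    return SyntheticCohort(npx, npx_true, clinical, os_df, pfs_df, manifest, truth)


# ---------------------------------------------------------------------------
# round-trip I/O


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as plain-text files; returns the path map.

    Emits an Olink-style long CSV (SampleID, Assay, NPX, LOD, LOD_SD), a wide
    NPX TSV, clinical and outcome TSVs, and the truth JSON. Below-LOD values
    are written as measured — truncation is a downstream preprocessing
    decision — with the LOD column carrying the threshold.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    npx = cohort.npx
    long_rows = pd.DataFrame({
        "SampleID": np.repeat(npx.sample_ids, npx.n_proteins),
        "Assay": np.tile(npx.protein_ids, npx.n_samples),
        "NPX": npx.values.ravel(),
        "LOD": np.tile(npx.lod, npx.n_samples),
        "LOD_SD": np.tile(npx.lod_sd, npx.n_samples),
    })
    paths["npx_long"] = directory / "npx_long.csv"
    long_rows.to_csv(paths["npx_long"], index=False, float_format="%.17g")

    wide = npx.to_frame()
    wide.index.name = "sample_id"
    paths["npx_wide"] = directory / "npx_wide.tsv"
    wide.to_csv(paths["npx_wide"], sep="\t", float_format="%.17g")

    clin = cohort.clinical.copy()
    clin.index.name = "sample_id"
    paths["clinical"] = directory / "clinical.tsv"
    clin.to_csv(paths["clinical"], sep="\t")

    outcomes = pd.DataFrame({
        "sample_id": npx.sample_ids,
        "os_months": cohort.os["time"].to_numpy(),
        "os_event": cohort.os["event"].to_numpy(),
        "pfs_months": cohort.pfs["time"].to_numpy(),
        "pfs_event": cohort.pfs["event"].to_numpy(),
    })
    paths["outcomes"] = directory / "outcomes.tsv"
    outcomes.to_csv(paths["outcomes"], sep="\t", index=False, float_format="%.17g")

    paths["manifest"] = directory / "manifest.tsv"
    cohort.manifest.to_csv(paths["manifest"], sep="\t", index=False)

    paths["truth"] = directory / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
    return paths


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    long_df = pd.read_csv(directory / "npx_long.csv")
    npx = NPXMatrix.from_long_frame(long_df)
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t", dtype={"sample_id": str})
    clinical = clinical.set_index("sample_id")
    for col in clinical.columns:
        if col != "age":
            clinical[col] = clinical[col].astype(str)
    outcomes = pd.read_csv(directory / "outcomes.tsv", sep="\t", dtype={"sample_id": str})
    outcomes = outcomes.set_index("sample_id")
    # align everything to the NPX sample order
    order = npx.sample_ids
    clinical = clinical.loc[order]
    outcomes = outcomes.loc[order]
    os_df = pd.DataFrame({"time": outcomes["os_months"], "event": outcomes["os_event"]})
    pfs_df = pd.DataFrame({"time": outcomes["pfs_months"], "event": outcomes["pfs_event"]})
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t", dtype=str)
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return SyntheticCohort(npx, npx.values.copy(), clinical, os_df, pfs_df, manifest, truth)
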