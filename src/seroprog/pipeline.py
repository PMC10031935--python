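"""End-to-end orchestration of the serum-panel prognostication workflow.

Order of stages per endpoint (OS, PFS):

    exclusions -> NPX preprocessing -> covariate residualization ->
    forest prescreen (drop bottom 25%, keep top 20) -> randomized-grid
    tuning (5-fold CV) -> repeated 10-fold CV -> permutation importance ->
    recursive feature elimination -> classical Cox (UV + MV, per-doubling
    HRs, BH q-values over the panel) -> elastic-net Cox (residualized and
    raw) -> cross-model rank concordance -> marker/clinic associations.

A run is fully reproducible from (config, seed): rerunning writes an
identical bundle byte-for-byte.
"""

from __future__ import annotations

import json
import time as _time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import association_table
from .cohort import CohortConfig, SyntheticCohort, generate_cohort, read_cohort
from .cox import cox_panel, fit_elastic_net_cox, qvalue_table
from .preprocess import NPXMatrix, preprocess_pipeline
from .selection import (
    RFEResult,
    build_clinical_design,
    crossval_rsf,
    rank_concordance,
    recursive_feature_elimination,
    residualize,
    rf_screen,
    tune_rsf,
)
from .survival import fit_rsf, permutation_importance

__all__ = ["RunConfig", "PROFILES", "run_pipeline", "report_overlap", "PipelineResult"]


# repeat/budget profiles: "full" is the documented protocol (randomized grid
# with 5-fold CV x 100, 10-fold CV x 100); "desk" is a reduced profile for
# desk-scale runs and tests
PROFILES = {
    "full": dict(
        screen_repeats=5, screen_trees=500, importance_repeats=5,
        tune_candidates=25, tune_folds=5, tune_repeats=100,
        cv_folds=10, cv_repeats=100,
        rfe_folds=10, rfe_repeats=100,
        enet_cv_folds=5,
    ),
    "desk": dict(
        screen_repeats=2, screen_trees=150, importance_repeats=2,
        tune_candidates=3, tune_folds=5, tune_repeats=1,
        cv_folds=10, cv_repeats=1,
        rfe_folds=3, rfe_repeats=1,
        enet_cv_folds=3,
    ),
}

DESK_GRID = {
    "n_estimators": [50, 100],
    "max_features": [3, 5],
    "min_samples_leaf": [5, 10],
    "min_samples_split": [10, 20],
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_dir`` (a directory holding the cohort file set)
    and ``simulate`` (a CohortConfig) must be given.
    """

    input_dir: str | None = None
    simulate: CohortConfig | None = None
    endpoints: tuple = ("OS", "PFS")
    profile: str = "desk"
    seed: int = 0
    outdir: str | None = None
    max_lod_fraction: float = 0.15
    knn_k: int = 5
    panel_m: int = 92
    enet_alpha: float = 0.5
    grid: dict | None = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir and simulate must be set")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        for ep in self.endpoints:
            if ep.upper() not in ("OS", "PFS"):
                raise ValueError(f"unknown endpoint {ep!r}")
        bad = set(self.overrides) - set(PROFILES[self.profile])
        if bad:
            raise ValueError(f"unknown profile overrides: {sorted(bad)}")

    def settings(self) -> dict:
        s = dict(PROFILES[self.profile])
        s.update(self.overrides)
        if any(v < 1 for v in s.values()):
            raise ValueError("all repeat counts must be >= 1")
        return s

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = CohortConfig(**{k: tuple(v) if isinstance(v, list) and k in
                                  ("correlation_blocks", "baseline_hazard") else v
                                  for k, v in sim.items()})
        if "endpoints" in raw:
            raw["endpoints"] = tuple(raw["endpoints"])
        return cls(simulate=sim, **raw)


@dataclass
class EndpointResult:
    endpoint: str
    screen: object
    tuning: object
    cv_train_c: np.ndarray
    cv_test_c: np.ndarray
    importance: pd.Series
    rfe: RFEResult
    cox_uv: pd.DataFrame
    cox_mv: pd.DataFrame
    enet_regressed: object
    enet_raw: object
    concordance: dict

    @property
    def selected(self) -> list:
        return self.rfe.selected_set

    @property
    def median_train_c(self) -> float:
        return float(np.median(self.cv_train_c))

    @property
    def median_test_c(self) -> float:
        return float(np.median(self.cv_test_c))


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: SyntheticCohort
    npx_processed: NPXMatrix
    residualized: pd.DataFrame
    preprocess_reports: list
    endpoints: dict  # name -> EndpointResult
    overlap: tuple | None
    associations: pd.DataFrame | None
    manifest: dict


def report_overlap(selected_os, selected_pfs) -> tuple[int, int]:
    """Exact intersection/union cardinalities of two marker lists."""
    a, b = list(selected_os), list(selected_pfs)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("marker lists must not contain duplicates")
    return len(set(a) & set(b)), len(set(a) | set(b))


def _stage_seed(base: int, stage: str, endpoint: str = "") -> int:
    # stable small per-stage seeds derived from the global seed; crc32 is
    # process-independent (unlike the builtin hash)
    h = zlib.crc32(f"{stage}|{endpoint}".encode()) % 9973
    return (base * 10007 + h) % (2**31 - 1)


def _run_endpoint(ep, npx_df, resid, outcomes, clinical, config, settings, log):
    seed = config.seed
    t0 = _time.time()
    screen = rf_screen(
        resid, outcomes,
        n_repeats=settings["screen_repeats"],
        seed=_stage_seed(seed, "screen", ep),
        params={"n_estimators": settings["screen_trees"]},
        importance_repeats=settings["importance_repeats"],
    )
    log(ep, "screen", n_proteins_in=resid.shape[1], retained=len(screen.retained),
        top20=len(screen.top20), seconds=round(_time.time() - t0, 2))

    X20 = resid[screen.top20]
    t0 = _time.time()
    tuning = tune_rsf(
        X20, outcomes,
        grid=config.grid or (DESK_GRID if config.profile == "desk" else None),
        n_candidates=settings["tune_candidates"],
        n_folds=settings["tune_folds"],
        n_repeats=settings["tune_repeats"],
        seed=_stage_seed(seed, "tune", ep),
    )
    log(ep, "tune", best=str(asdict(tuning.best_params)),
        median_c=round(tuning.best_median, 4), seconds=round(_time.time() - t0, 2))

    t0 = _time.time()
    train_c, test_c = crossval_rsf(
        X20, outcomes, tuning.best_params,
        n_folds=min(settings["cv_folds"], X20.shape[0]),
        n_repeats=settings["cv_repeats"],
        seed=_stage_seed(seed, "cv", ep),
    )
    log(ep, "crossval", median_train_c=round(float(np.median(train_c)), 4),
        median_test_c=round(float(np.median(test_c)), 4),
        seconds=round(_time.time() - t0, 2))

    t0 = _time.time()
    final_forest = fit_rsf(X20.to_numpy(float), outcomes, tuning.best_params)
    imp_reps = []
    for r in range(settings["importance_repeats"]):
        imp = permutation_importance(
            final_forest, X20.to_numpy(float), outcomes, n_repeats=2,
            seed=_stage_seed(seed, f"imp{r}", ep), use_oob=True)
        imp_reps.append(pd.Series(imp, index=X20.columns))
    importance = pd.concat(imp_reps, axis=1).median(axis=1)
    rfe = recursive_feature_elimination(
        X20, outcomes, tuning.best_params, importance,
        n_folds=settings["rfe_folds"], n_repeats=settings["rfe_repeats"],
        seed=_stage_seed(seed, "rfe", ep),
    )
    log(ep, "rfe", selected_size=rfe.selected_size, seconds=round(_time.time() - t0, 2))

    # classical Cox over the whole processed panel (UV and covariate-adjusted),
    # q-values over the full assayed panel size
    t0 = _time.time()
    design = build_clinical_design(clinical, intercept=False)
    cox_uv = qvalue_table(cox_panel(npx_df, outcomes, endpoint=ep),
                          m=config.panel_m)
    cox_mv = qvalue_table(cox_panel(npx_df, outcomes, adjust=design, endpoint=ep),
                          m=config.panel_m)
    log(ep, "cox", n_uv=cox_uv.shape[0],
        n_nonconverged=int((~cox_uv["converged"]).sum() + (~cox_mv["converged"]).sum()),
        seconds=round(_time.time() - t0, 2))

    t0 = _time.time()
    enet_regressed = fit_elastic_net_cox(
        resid, outcomes, alpha=config.enet_alpha,
        cv_folds=settings["enet_cv_folds"], seed=_stage_seed(seed, "enet_r", ep))
    enet_raw = fit_elastic_net_cox(
        npx_df, outcomes, alpha=config.enet_alpha,
        cv_folds=settings["enet_cv_folds"], seed=_stage_seed(seed, "enet_u", ep))
    log(ep, "elastic_net", selected_lambda=float(enet_regressed.selected_lambda),
        all_zero=enet_regressed.all_zero, seconds=round(_time.time() - t0, 2))

    # cross-model ranks over the screened top-20 universe
    rankings = {
        "RF_screen": screen.importance.table["rank"].loc[
            screen.importance.table.index.intersection(X20.columns)],
        "RSF": importance.rank(ascending=False, method="first").astype(int),
        "Cox": cox_uv.loc[list(X20.columns), "P"].rank(method="first").astype(int),
        "PenalizedCox": enet_regressed.rank_table().loc[list(X20.columns)],
        "PenalizedCox_raw": enet_raw.rank_table().loc[list(X20.columns)],
    }
    concordance = rank_concordance(rankings)

    return EndpointResult(ep, screen, tuning, train_c, test_c, importance, rfe,
                          cox_uv, cox_mv, enet_regressed, enet_raw, concordance)


def run_pipeline(config: RunConfig, cohort: SyntheticCohort | None = None) -> PipelineResult:
    """Execute the full workflow; optionally write the report bundle.

    ``cohort`` overrides the config's input source with an in-memory cohort
    (used by the Model facade).
    """
    settings = config.settings()
    manifest = {
        "version": __version__,
        "profile": config.profile,
        "seed": config.seed,
        "settings": settings,
        "stages": [],
    }

    def log(endpoint, stage, **kv):
        entry = {"endpoint": endpoint, "stage": stage, **kv}
        manifest["stages"].append(entry)

    stage = "load"
    try:
        if cohort is None:
            if config.simulate is not None:
                cohort = generate_cohort(config.simulate)
            else:
                cohort = read_cohort(config.input_dir)
        log("-", "load", n_samples=cohort.npx.n_samples,
            n_proteins=cohort.npx.n_proteins)

        stage = "preprocess"
        npx_proc, reports = preprocess_pipeline(
            cohort.npx, manifest=cohort.manifest,
            max_lod_fraction=config.max_lod_fraction, k=config.knn_k)
        for rep in reports:
            log("-", f"preprocess/{rep.step}", **{
                k: v for k, v in rep.to_dict().items()
                if k.startswith("n_")})
        npx_df = npx_proc.to_frame()
        keep = npx_df.index
        clinical = cohort.clinical.loc[keep]

        stage = "residualize"
        resid = residualize(npx_df, clinical)
        log("-", "residualize", n_samples=resid.shape[0], n_proteins=resid.shape[1])

        endpoint_results = {}
        for ep in [e.upper() for e in config.endpoints]:
            stage = f"endpoint:{ep}"
            full = cohort.outcomes(ep)
            idx = [cohort.npx.sample_ids.index(s) for s in keep]
            outcomes = full.subset(np.asarray(idx))
            endpoint_results[ep] = _run_endpoint(
                ep, npx_df, resid, outcomes, clinical, config, settings, log)

        stage = "overlap"
        overlap = None
        if {"OS", "PFS"} <= set(endpoint_results):
            overlap = report_overlap(endpoint_results["OS"].selected,
                                     endpoint_results["PFS"].selected)
            log("-", "overlap", intersection=overlap[0], union=overlap[1])

        stage = "associations"
        union_markers = sorted({p for r in endpoint_results.values()
                                for p in r.selected})
        associations = None
        if union_markers:
            feats = clinical.drop(columns=["age"])
            from .selection import CLINICAL_CATEGORIES

            refs = {c: CLINICAL_CATEGORIES[c][0] for c in feats.columns
                    if c in CLINICAL_CATEGORIES}
            associations = association_table(npx_df[union_markers], feats,
                                             references=refs)
            log("-", "associations", n_markers=len(union_markers),
                n_rows=associations.shape[0])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(config, cohort, npx_proc, resid, reports,
                            endpoint_results, overlap, associations, manifest)
    if config.outdir:
        write_bundle(result, config.outdir)
    return result


# ---------------------------------------------------------------------------
# report bundle


def write_bundle(result: PipelineResult, outdir) -> dict:
    """Write the tables, curves, and manifest; deterministic byte-for-byte."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, df, index=True):
        p = outdir / name
        df.to_csv(p, sep="\t", index=index, float_format="%.10g")
        paths[name] = p

    for ep, res in result.endpoints.items():
        lo = ep.lower()
        # Table-2-shaped output: UV and MV per-doubling HRs with q and evidence
        uv = res.cox_uv[["HR", "CI95_low", "CI95_high", "P", "q", "evidence"]]
        mv = res.cox_mv[["HR", "CI95_low", "CI95_high", "P", "q", "evidence"]]
        tab2 = uv.join(mv, lsuffix="_uv", rsuffix="_mv")
        tab2_sel = tab2.loc[[p for p in res.selected if p in tab2.index]]
        save(f"cox_panel_{lo}.tsv", tab2)
        save(f"cox_selected_{lo}.tsv", tab2_sel)
        save(f"importance_{lo}.tsv",
             res.importance.rename("median_importance").to_frame())
        save(f"screen_importance_{lo}.tsv", res.screen.importance.table)
        save(f"rfe_curve_{lo}.tsv", res.rfe.to_frame(), index=False)
        save(f"rank_concordance_{lo}.tsv", res.concordance["table"])
        save(f"rank_spearman_{lo}.tsv", res.concordance["spearman"])
        enet = pd.DataFrame({
            "coef_regressed": res.enet_regressed.selected_coefs,
            "coef_raw": res.enet_raw.selected_coefs.reindex(
                res.enet_regressed.selected_coefs.index),
        })
        save(f"elastic_net_{lo}.tsv", enet)
    if result.associations is not None:
        save("associations.tsv", result.associations, index=False)
    summary = {
        "selected": {ep: r.selected for ep, r in result.endpoints.items()},
        "median_train_c": {ep: r.median_train_c for ep, r in result.endpoints.items()},
        "median_test_c": {ep: r.median_test_c for ep, r in result.endpoints.items()},
        "overlap": {"intersection": result.overlap[0], "union": result.overlap[1]}
        if result.overlap else None,
    }
    # wall-clock entries are stripped so reruns are byte-identical
    clean = dict(result.manifest)
    clean["stages"] = [{k: v for k, v in st.items() if k != "seconds"}
                       for st in result.manifest["stages"]]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"summary": summary, "manifest": clean}, fh,
                  indent=2, sort_keys=True, default=str)
    paths["manifest.json"] = outdir / "manifest.json"
    return paths
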