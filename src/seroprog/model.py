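"""Model/Results facade over the selection-and-validation workflow.

`PanelPrognosisModel` is built from cohort data (NPX matrix, clinical
covariates, outcomes); its `fit()` runs the cascade and returns a
`PanelPrognosisResults` carrying selected marker sets, cross-validated
concordance, per-doubling hazard ratios with q-values, and a printable
summary — the familiar model.fit() -> results.summary() idiom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import SyntheticCohort
from .pipeline import PipelineResult, RunConfig, run_pipeline
from .preprocess import NPXMatrix

__all__ = ["PanelPrognosisModel", "PanelPrognosisResults"]


class PanelPrognosisModel:
    """Serum-panel prognostication model for right-censored outcomes.

    Parameters
    ----------
    npx : NPXMatrix
        Raw log2 NPX abundances with LOD metadata.
    clinical : pd.DataFrame
        Eight adjustment covariates indexed by sample id.
    outcomes : dict
        Endpoint name ("OS"/"PFS") -> DataFrame with ``time`` and ``event``
        columns aligned to the NPX samples.
    manifest : pd.DataFrame, optional
        Per-sample availability flags (sample_id, reason).
    """

    def __init__(self, npx: NPXMatrix, clinical: pd.DataFrame, outcomes: dict,
                 manifest: pd.DataFrame | None = None):
        self.npx = npx
        self.clinical = clinical
        self.outcomes = {k.upper(): v for k, v in outcomes.items()}
        if manifest is None:
            manifest = pd.DataFrame({"sample_id": npx.sample_ids,
                                     "reason": "available"})
        self.manifest = manifest

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort) -> "PanelPrognosisModel":
        return cls(cohort.npx, cohort.clinical,
                   {"OS": cohort.os, "PFS": cohort.pfs}, cohort.manifest)

    @classmethod
    def from_files(cls, directory) -> "PanelPrognosisModel":
        from .cohort import read_cohort

        return cls.from_cohort(read_cohort(directory))

    def fit(self, profile: str = "desk", seed: int = 0,
            endpoints=None, **config_kwargs) -> "PanelPrognosisResults":
        """Run the full cascade; returns a results object."""
        endpoints = tuple(self.outcomes) if endpoints is None else tuple(endpoints)
        cohort = SyntheticCohort(
            npx=self.npx,
            npx_true=self.npx.values.copy(),
            clinical=self.clinical,
            os=self.outcomes.get("OS"),
            pfs=self.outcomes.get("PFS"),
            manifest=self.manifest,
            truth={},
        )
        config = RunConfig(simulate=None, input_dir="<in-memory>",
                           endpoints=endpoints, profile=profile, seed=seed,
                           **config_kwargs)
        result = run_pipeline(config, cohort=cohort)
        return PanelPrognosisResults(self, result)


class PanelPrognosisResults:
    """Fitted results: selected markers, concordance, and Cox tables."""

    def __init__(self, model: PanelPrognosisModel, pipeline: PipelineResult):
        self.model = model
        self.pipeline = pipeline

    @property
    def selected(self) -> dict:
        return {ep: r.selected for ep, r in self.pipeline.endpoints.items()}

    @property
    def overlap(self):
        return self.pipeline.overlap

    def concordance(self) -> pd.DataFrame:
        rows = {ep: {"median_train_c": r.median_train_c,
                     "median_test_c": r.median_test_c}
                for ep, r in self.pipeline.endpoints.items()}
        return pd.DataFrame(rows).T

    def cox_table(self, endpoint: str, selected_only: bool = True) -> pd.DataFrame:
        res = self.pipeline.endpoints[endpoint.upper()]
        uv = res.cox_uv[["HR", "CI95_low", "CI95_high", "P", "q", "evidence"]]
        mv = res.cox_mv[["HR", "CI95_low", "CI95_high", "P", "q", "evidence"]]
        tab = uv.join(mv, lsuffix="_uv", rsuffix="_mv")
        if selected_only:
            tab = tab.loc[[p for p in res.selected if p in tab.index]]
        return tab

    def associations(self) -> pd.DataFrame | None:
        return self.pipeline.associations

    def summary(self) -> str:
        lines = ["Serum panel prognostication", "=" * 40]
        npx = self.pipeline.npx_processed
        lines.append(f"samples analyzed: {npx.n_samples}; proteins retained: {npx.n_proteins}")
        for ep, r in self.pipeline.endpoints.items():
            lines.append("")
            lines.append(f"[{ep}] median train C = {r.median_train_c:.3f}, "
                         f"median test C = {r.median_test_c:.3f}")
            lines.append(f"[{ep}] selected markers ({len(r.selected)}): "
                         + ", ".join(r.selected))
            tab = self.cox_table(ep)
            if tab.shape[0]:
                with pd.option_context("display.width", 120,
                                       "display.float_format", "{:.3f}".format):
                    lines.append(tab[["HR_uv", "P_uv", "q_uv",
                                      "HR_mv", "P_mv", "q_mv"]].to_string())
        if self.overlap is not None:
            lines.append("")
            lines.append(f"OS/PFS marker overlap: intersection {self.overlap[0]}, "
                         f"union {self.overlap[1]}")
        return "\n".join(lines)

    def __repr__(self):
        eps = ", ".join(self.pipeline.endpoints)
        return f"<PanelPrognosisResults endpoints=[{eps}]>"
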