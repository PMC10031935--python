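"""Olink-style NPX preprocessing.

Mirrors the serum-panel workflow: sample exclusion accounting, limit-of-
detection (LOD) prevalence filtering, LOD rescaling with NA assignment, and
k-nearest-neighbour imputation. NPX is a relative abundance unit on a log2
scale, so a one-unit change is a doubling of protein content; the LOD is the
per-assay threshold below which a measurement is unreliable.

The pipeline order is fixed: exclusions -> LOD filter (proteins, then
samples, strict > threshold) -> rescale/censor -> impute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NPXMatrix",
    "PreprocessReport",
    "EXCLUSION_REASONS",
    "apply_sample_exclusions",
    "filter_by_lod",
    "rescale_and_censor",
    "impute_knn",
    "preprocess_pipeline",
]

EXCLUSION_REASONS = ("available", "no_sample", "qc_fail", "insufficient_material")


@dataclass
class NPXMatrix:
    """Samples x proteins log2 NPX with per-protein LOD metadata.

    ``values`` may contain NaN (missing); ``below_lod_mask`` flags entries
    measured below the protein's LOD. ``lod_sd`` is the per-protein standard
    deviation of the LOD estimate; when absent it defaults to 0, under which
    every below-LOD value is assigned NA by :func:`rescale_and_censor`.
    """

    sample_ids: list
    protein_ids: list
    values: np.ndarray
    lod: np.ndarray
    lod_sd: np.ndarray | None = None
    below_lod_mask: np.ndarray | None = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.protein_ids = list(self.protein_ids)
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.sample_ids), len(self.protein_ids)
        if self.values.shape != (n, p):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {p})")
        self.lod = np.asarray(self.lod, dtype=float)
        if self.lod.shape != (p,):
            raise ValueError("lod must have one entry per protein")
        if self.lod_sd is None:
            self.lod_sd = np.zeros(p)
        else:
            self.lod_sd = np.asarray(self.lod_sd, dtype=float)
            if self.lod_sd.shape != (p,):
                raise ValueError("lod_sd must have one entry per protein")
        if self.below_lod_mask is None:
            with np.errstate(invalid="ignore"):
                self.below_lod_mask = self.values < self.lod[None, :]
        else:
            self.below_lod_mask = np.asarray(self.below_lod_mask, dtype=bool)
            if self.below_lod_mask.shape != self.values.shape:
                raise ValueError("below_lod_mask must match values shape")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.protein_ids)

    def subset(self, sample_idx=None, protein_idx=None) -> "NPXMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        pi = np.arange(self.n_proteins) if protein_idx is None else np.asarray(protein_idx)
        return NPXMatrix(
            [self.sample_ids[i] for i in si],
            [self.protein_ids[j] for j in pi],
            self.values[np.ix_(si, pi)],
            self.lod[pi],
            self.lod_sd[pi],
            self.below_lod_mask[np.ix_(si, pi)],
        )

    @classmethod
    def from_wide_frame(cls, df: pd.DataFrame, lod, lod_sd=None) -> "NPXMatrix":
        lod = np.asarray(pd.Series(lod).reindex(df.columns), dtype=float)
        if lod_sd is not None:
            lod_sd = np.asarray(pd.Series(lod_sd).reindex(df.columns), dtype=float)
        return cls(list(df.index), list(df.columns), df.to_numpy(float), lod, lod_sd)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "NPXMatrix":
        """Build from Olink-style long data with SampleID/Assay/NPX/LOD columns."""
        required = {"SampleID", "Assay", "NPX", "LOD"}
        if not required.issubset(df.columns):
            raise ValueError(f"long NPX table must have columns {sorted(required)}")
        wide = df.pivot(index="SampleID", columns="Assay", values="NPX")
        lod = df.groupby("Assay")["LOD"].first().reindex(wide.columns)
        lod_sd = None
        if "LOD_SD" in df.columns:
            lod_sd = df.groupby("Assay")["LOD_SD"].first().reindex(wide.columns).to_numpy()
        return cls(list(wide.index), list(wide.columns), wide.to_numpy(float),
                   lod.to_numpy(), lod_sd)


@dataclass
class PreprocessReport:
    """Accounting for one preprocessing step; counts must reconcile."""

    step: str
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_proteins_in: int = 0
    n_proteins_out: int = 0
    removed_samples: list = field(default_factory=list)  # (sample_id, reason/fraction)
    removed_proteins: list = field(default_factory=list)  # (protein_id, fraction)
    n_values_rescaled: int = 0
    n_values_set_na: int = 0
    n_values_imputed: int = 0

    def __post_init__(self):
        self._check()

    def _check(self):
        if self.n_samples_in - len(self.removed_samples) != self.n_samples_out:
            raise ValueError("sample accounting does not reconcile")
        if self.n_proteins_in - len(self.removed_proteins) != self.n_proteins_out:
            raise ValueError("protein accounting does not reconcile")

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_proteins_in": self.n_proteins_in,
            "n_proteins_out": self.n_proteins_out,
            "removed_samples": [list(map(str, r)) for r in self.removed_samples],
            "removed_proteins": [[str(p), float(f)] for p, f in self.removed_proteins],
            "n_values_rescaled": self.n_values_rescaled,
            "n_values_set_na": self.n_values_set_na,
            "n_values_imputed": self.n_values_imputed,
        }


# ---------------------------------------------------------------------------


def apply_sample_exclusions(manifest: pd.DataFrame) -> tuple[list, PreprocessReport]:
    """Retain samples flagged ``available``; itemize exclusions by reason.

    ``manifest`` has columns ``sample_id`` and ``reason``, one row per
    enrolled sample, with reasons drawn from
    available | no_sample | qc_fail | insufficient_material.
    """
    if manifest.shape[0]:
        bad = manifest.loc[~manifest["reason"].isin(EXCLUSION_REASONS)]
        if bad.shape[0]:
            sid = bad["sample_id"].iloc[0]
            raise ValueError(f"unknown exclusion reason {bad['reason'].iloc[0]!r} for sample {sid!r}")
    retained = list(manifest.loc[manifest["reason"] == "available", "sample_id"])
    removed = [
        (row.sample_id, row.reason)
        for row in manifest.itertuples()
        if row.reason != "available"
    ]
    report = PreprocessReport(
        step="sample_exclusions",
        n_samples_in=manifest.shape[0],
        n_samples_out=len(retained),
        removed_samples=removed,
    )
    return retained, report


def filter_by_lod(npx: NPXMatrix, max_fraction: float = 0.15) -> tuple[NPXMatrix, PreprocessReport]:
    """Drop proteins, then samples, with below-LOD prevalence strictly above
    ``max_fraction`` (default 15%).

    The protein pass uses the current samples; the sample pass uses only the
    retained proteins, matching the order the thresholds were stated in.
    """
    mask = npx.below_lod_mask & ~npx.missing_mask
    n, p = npx.values.shape
    prot_frac = mask.sum(axis=0) / max(n, 1)
    keep_prot = prot_frac <= max_fraction
    removed_proteins = [
        (npx.protein_ids[j], float(prot_frac[j])) for j in np.flatnonzero(~keep_prot)
    ]
    if not keep_prot.any():
        raise ValueError("LOD filter removed every protein")
    mask2 = mask[:, keep_prot]
    samp_frac = mask2.sum(axis=1) / keep_prot.sum()
    keep_samp = samp_frac <= max_fraction
    removed_samples = [
        (npx.sample_ids[i], float(samp_frac[i])) for i in np.flatnonzero(~keep_samp)
    ]
    if not keep_samp.any():
        raise ValueError("LOD filter removed every sample")
    out = npx.subset(np.flatnonzero(keep_samp), np.flatnonzero(keep_prot))
    report = PreprocessReport(
        step="lod_filter",
        n_samples_in=n,
        n_samples_out=out.n_samples,
        n_proteins_in=p,
        n_proteins_out=out.n_proteins,
        removed_samples=removed_samples,
        removed_proteins=removed_proteins,
    )
    return out, report


def rescale_and_censor(npx: NPXMatrix) -> tuple[NPXMatrix, PreprocessReport]:
    """Shift each protein to an above-LOD scale and censor deep below-LOD values.

    Every value v becomes v - LOD(protein), except values already below
    LOD(protein) - 2 * lod_sd(protein), which are assigned NA. With the
    default lod_sd = 0 every below-LOD value becomes NA (the conservative
    reading).
    """
    if np.isnan(npx.lod).any():
        j = int(np.flatnonzero(np.isnan(npx.lod))[0])
        raise ValueError(f"missing LOD for protein {npx.protein_ids[j]!r}")
    values = npx.values.copy()
    with np.errstate(invalid="ignore"):
        censor = values < (npx.lod - 2.0 * npx.lod_sd)[None, :]
    censor &= ~np.isnan(values)
    rescale = ~censor & ~np.isnan(values)
    values = values - npx.lod[None, :]
    values[censor] = np.nan
    out = NPXMatrix(
        npx.sample_ids,
        npx.protein_ids,
        values,
        np.zeros_like(npx.lod),  # values are now on the LOD-shifted scale
        npx.lod_sd,
        npx.below_lod_mask,
    )
    report = PreprocessReport(
        step="rescale_censor",
        n_samples_in=npx.n_samples,
        n_samples_out=npx.n_samples,
        n_proteins_in=npx.n_proteins,
        n_proteins_out=npx.n_proteins,
        n_values_rescaled=int(rescale.sum()),
        n_values_set_na=int(censor.sum()),
    )
    return out, report


def _knn_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance over proteins observed in both samples,
    normalized by the number of shared proteins. Infinite when no overlap."""
    obs = ~np.isnan(values)
    filled = np.where(obs, values, 0.0)
    # sum over shared proteins of (x_i - x_j)^2, computed with masked algebra
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = (filled**2 * obs) @ obs.T.astype(float)
    cross = filled @ filled.T
    ssd = sq + sq.T - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(ssd, 0.0) / shared)
    d[shared == 0] = np.inf
    return d


def impute_knn(npx: NPXMatrix, k: int = 5) -> tuple[NPXMatrix, PreprocessReport]:
    """Replace each NA with the unweighted mean of the k nearest samples'
    observed values for that protein.

    Distance between two samples is the Euclidean distance over proteins
    observed in both, normalized by the shared-protein count so sparsely
    observed samples remain comparable. Only samples with the target protein
    observed are eligible neighbours; distance ties break by sample order.
    """
    n = npx.n_samples
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of samples ({n})")
    obs = ~npx.missing_mask
    if (~obs).sum() == 0:
        report = PreprocessReport(
            step="knn_impute",
            n_samples_in=n, n_samples_out=n,
            n_proteins_in=npx.n_proteins, n_proteins_out=npx.n_proteins,
        )
        return npx, report
    if (obs.sum(axis=1) == 0).any():
        i = int(np.flatnonzero(obs.sum(axis=1) == 0)[0])
        raise ValueError(f"sample {npx.sample_ids[i]!r} has no observed value")
    all_na = np.flatnonzero(obs.sum(axis=0) == 0)
    if all_na.size:
        raise ValueError(f"protein {npx.protein_ids[int(all_na[0])]!r} is NA in every sample")
    dist = _knn_distances(npx.values)
    np.fill_diagonal(dist, np.inf)
    values = npx.values.copy()
    n_imputed = 0
    for i, j in zip(*np.nonzero(~obs)):
        donors = np.flatnonzero(obs[:, j])
        donors = donors[donors != i]
        order = np.argsort(dist[i, donors], kind="stable")  # stable -> tie by sample order
        chosen = donors[order[:k]]
        values[i, j] = npx.values[chosen, j].mean()
        n_imputed += 1
    out = NPXMatrix(npx.sample_ids, npx.protein_ids, values, npx.lod, npx.lod_sd,
                    npx.below_lod_mask)
    report = PreprocessReport(
        step="knn_impute",
        n_samples_in=n, n_samples_out=n,
        n_proteins_in=npx.n_proteins, n_proteins_out=npx.n_proteins,
        n_values_imputed=n_imputed,
    )
    return out, report


def preprocess_pipeline(
    npx: NPXMatrix,
    manifest: pd.DataFrame | None = None,
    max_lod_fraction: float = 0.15,
    k: int = 5,
) -> tuple[NPXMatrix, list[PreprocessReport]]:
    """Full fixed-order preprocessing: exclusions -> LOD filter -> rescale -> impute."""
    reports = []
    if manifest is not None:
        retained, rep = apply_sample_exclusions(manifest)
        reports.append(rep)
        keep = [i for i, s in enumerate(npx.sample_ids) if s in set(retained)]
        npx = npx.subset(sample_idx=keep)
    npx, rep = filter_by_lod(npx, max_lod_fraction)
    reports.append(rep)
    npx, rep = rescale_and_censor(npx)
    reports.append(rep)
    npx, rep = impute_knn(npx, k)
    reports.append(rep)
    return npx, reports
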