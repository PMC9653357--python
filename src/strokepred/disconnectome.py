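"""Region-level disconnection summaries and component-score estimation.

The disconnection pattern of a stroke patient is summarised in two steps:
voxelwise disconnection probabilities are averaged within each grey-matter
structure of a parcellation, and the resulting region vector is regressed
(ordinary least squares with intercept) on the columns of a fixed component
basis.  The unstandardised regression coefficients are the patient's
*component scores* — the predictors used everywhere downstream — and the
per-patient adjusted R-squared measures how much of the disconnection
pattern the basis explains.

A classical baseline, the tract lesion load (fraction of a tract mask's
voxels overlapped by the lesion), is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ComponentBasis, DisconnectionDataset, LabeledVolume


class AlignmentError(ValueError):
    """Volumes do not share grid shape / affine, or labels are misordered."""


class AtlasError(ValueError):
    """A requested region code is absent from the atlas."""


class SingularBasisError(np.linalg.LinAlgError):
    """The component basis is rank deficient."""


@dataclass
class ComponentScores:
    """Per-patient component scores (unstandardised OLS betas) + fit quality."""

    betas: np.ndarray  # n_patients x n_components
    intercepts: np.ndarray  # n_patients
    adj_r2: np.ndarray  # n_patients
    patient_ids: list[str]
    component_ids: list[str]

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.adj_r2 = np.asarray(self.adj_r2, dtype=float)
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas contain non-finite values")
        if np.any(self.adj_r2 > 1 + 1e-12):
            raise ValueError("adjusted R-squared cannot exceed 1")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.betas, index=self.patient_ids, columns=self.component_ids)
        df.index.name = "patient_id"
        df["intercept"] = self.intercepts
        df["adj_r2"] = self.adj_r2
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ComponentScores":
        df = pd.read_csv(path, index_col="patient_id")
        comp_ids = [c for c in df.columns if c not in ("intercept", "adj_r2")]
        return cls(
            betas=df[comp_ids].to_numpy(float),
            intercepts=df["intercept"].to_numpy(float),
            adj_r2=df["adj_r2"].to_numpy(float),
            patient_ids=list(df.index.astype(str)),
            component_ids=comp_ids,
        )


def average_by_region(
    volume: np.ndarray,
    atlas: LabeledVolume,
    region_codes,
    volume_affine: np.ndarray | None = None,
) -> np.ndarray:
    """Mean of the probability volume within each atlas label.

    Background (label 0) is excluded; output follows ``region_codes`` order.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != atlas.data.shape:
        raise AlignmentError(
            f"volume grid {volume.shape} != atlas grid {atlas.data.shape}"
        )
    if volume_affine is not None and not np.allclose(volume_affine, atlas.affine):
        raise AlignmentError("volume and atlas affines differ")
    region_codes = np.asarray(list(region_codes), dtype=int)
    labels = atlas.data.ravel()
    vals = volume.ravel()
    counts = np.bincount(labels, minlength=int(labels.max()) + 1)
    sums = np.bincount(labels, weights=vals, minlength=counts.size)
    missing = [int(c) for c in region_codes if c <= 0 or c >= counts.size or counts[c] == 0]
    if missing:
        raise AtlasError(f"region codes absent from atlas: {missing}")
    return sums[region_codes] / counts[region_codes]


def estimate_component_scores(
    dataset: DisconnectionDataset, basis: ComponentBasis
) -> ComponentScores:
    """OLS of each patient's region vector on the basis columns (+ intercept).

    For patient *i* the 372-vector of region disconnection values is the
    response and the basis columns are the predictors; the unstandardised
    coefficients are the component scores and adj R² = 1 - (1-R²)(n-1)/(n-p-1)
    with n = n_regions, p = n_components.
    """
    if list(dataset.region_labels) != list(basis.region_labels):
        raise AlignmentError(
            "dataset region labels do not match basis region order; "
            "reorder the dataset columns to the basis labels"
        )
    n, p = basis.n_regions, basis.n_components
    if n <= p + 1:
        raise ValueError("need n_regions > n_components + 1 for adjusted R-squared")
    sv = np.linalg.svd(basis.loadings, compute_uv=False)
    if sv[-1] <= 1e-10 * sv[0]:
        # name the most collinear columns for the error message
        corr = np.corrcoef(basis.loadings, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        j, k = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise SingularBasisError(
            "rank-deficient basis; most collinear columns: "
            f"{basis.component_ids[j]}, {basis.component_ids[k]}"
        )
    design = np.column_stack([np.ones(n), basis.loadings])
    Y = dataset.values.T  # n_regions x n_patients
    coef, _, _, _ = np.linalg.lstsq(design, Y, rcond=None)
    fitted = design @ coef
    resid = Y - fitted
    rss = (resid**2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 1.0)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return ComponentScores(
        betas=coef[1:].T,
        intercepts=coef[0],
        adj_r2=adj,
        patient_ids=list(dataset.patient_ids),
        component_ids=list(basis.component_ids),
    )


def lesion_load(lesion_mask: LabeledVolume, tract_mask: LabeledVolume) -> float:
    """Fraction of tract voxels intersected by the lesion: |lesion & tract| / |tract|."""
    if lesion_mask.data.shape != tract_mask.data.shape:
        raise AlignmentError("lesion and tract masks are on different grids")
    lesion = lesion_mask.data > 0
    tract = tract_mask.data > 0
    n_tract = int(tract.sum())
    if n_tract == 0:
        raise ZeroDivisionError("tract mask is empty; lesion load undefined")
    return float(np.logical_and(lesion, tract).sum() / n_tract)


def lesion_loads(
    lesion_masks: list[LabeledVolume], tract_mask: LabeledVolume
) -> np.ndarray:
    """Lesion load for each patient's lesion mask against one tract mask."""
    return np.array([lesion_load(m, tract_mask) for m in lesion_masks])
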