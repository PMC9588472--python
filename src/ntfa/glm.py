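"""Univariate GLM baseline: per-trial boxcar regressors and the
experimental-vs-baseline contrast.

Segments of one participant are stacked in trial order into a single
time series; each trial contributes one boxcar regressor covering
exactly its own TRs (no hemodynamic convolution, no nuisance columns —
the simulated data contain neither). Betas are ordinary least squares
per voxel, which for disjoint boxcars reduce exactly to each trial's
temporal mean. The contrast is mean(experimental betas) minus
mean(baseline betas) per participant, averaged across participants, so
the 2-vs-6 trial-count imbalance cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ValidationError
from .grids import BrainGrid
from .simulate import Dataset

BASELINE = "baseline"


@dataclass(frozen=True)
class DesignMatrix:
    """Boxcar design for one participant: (total TRs) x S."""

    X: np.ndarray
    column_labels: tuple      # trial IDs, ascending
    condition_of: dict        # trial_id -> "baseline" | "experimental"


@dataclass(frozen=True)
class GLMResult:
    """Per-trial betas per participant and the averaged contrast map."""

    betas: dict               # participant_id -> (S, V)
    contrast_map: np.ndarray = field(repr=False)  # (V,)
    threshold: float = 0.5


def build_design(dataset: Dataset, participant_id: int) -> DesignMatrix:
    """One boxcar regressor per trial, trials ordered by ID, disjoint blocks."""
    segs = sorted((s for s in dataset.segments
                   if s.participant_id == participant_id),
                  key=lambda s: s.trial_id)
    if not segs:
        raise ValidationError(f"no segments for participant {participant_id}")
    tids = [s.trial_id for s in segs]
    if len(set(tids)) != len(tids):
        raise ValidationError("duplicate trial IDs in design")
    lengths = [s.data.shape[0] for s in segs]
    total = int(np.sum(lengths))
    X = np.zeros((total, len(segs)))
    row = 0
    for j, L in enumerate(lengths):
        X[row:row + L, j] = 1.0
        row += L
    condition_of = {s.trial_id: (BASELINE if s.trial_type == BASELINE
                                 else "experimental") for s in segs}
    return DesignMatrix(X=X, column_labels=tuple(tids), condition_of=condition_of)


def stack_participant(dataset: Dataset, participant_id: int) -> np.ndarray:
    """Stack one participant's segments (trial-ID order) into (total TRs, V)."""
    segs = sorted((s for s in dataset.segments
                   if s.participant_id == participant_id),
                  key=lambda s: s.trial_id)
    return np.vstack([s.data for s in segs])


def fit_glm(Y_stacked: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-voxel ordinary least squares; returns betas of shape (S, V)."""
    Y_stacked = np.asarray(Y_stacked, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y_stacked.shape[0] != X.shape[0]:
        raise ValidationError("row counts of Y and X differ")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank-deficient")
    betas, *_ = np.linalg.lstsq(X, Y_stacked, rcond=None)
    return betas


def contrast_map(betas_by_participant: dict, condition_of_by_participant: dict,
                 column_labels_by_participant: dict) -> np.ndarray:
    """Experimental-minus-baseline condition means, averaged over participants."""
    maps = []
    for pid, betas in betas_by_participant.items():
        cond = condition_of_by_participant[pid]
        labels = column_labels_by_participant[pid]
        exp_rows = [j for j, t in enumerate(labels) if cond[t] != BASELINE]
        base_rows = [j for j, t in enumerate(labels) if cond[t] == BASELINE]
        if not exp_rows or not base_rows:
            raise ValidationError(
                f"participant {pid} lacks a baseline or experimental trial")
        maps.append(betas[exp_rows].mean(axis=0) - betas[base_rows].mean(axis=0))
    return np.mean(maps, axis=0)


def count_active_regions(contrast: np.ndarray, grid: BrainGrid,
                         threshold_fraction: float = 0.5) -> int:
    """Count 6-connected suprathreshold components within the mask.

    The map is binarized at ``threshold_fraction * max(contrast)``; a
    non-positive maximum yields 0.
    """
    contrast = np.asarray(contrast, dtype=float)
    if not np.isfinite(contrast).all():
        raise ValidationError("contrast map must be finite")
    peak = contrast.max(initial=-np.inf)
    if peak <= 0:
        return 0
    vol = grid.embed(contrast >= threshold_fraction * peak)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    _, n = ndimage.label(vol & grid.mask, structure=structure)
    return int(n)


def region_report(contrast: np.ndarray, grid: BrainGrid,
                  threshold_fraction: float = 0.5) -> pd.DataFrame:
    """Connected-component table: ID, size, peak coordinate, peak value."""
    peak = contrast.max(initial=-np.inf)
    rows = []
    if peak > 0:
        vol = grid.embed(contrast >= threshold_fraction * peak)
        labeled, n = ndimage.label(
            vol & grid.mask, structure=ndimage.generate_binary_structure(3, 1))
        cvol = grid.embed(contrast)
        for cid in range(1, n + 1):
            sel = labeled == cid
            vals = cvol[sel]
            imax = np.argmax(vals)
            coords_vox = np.argwhere(sel)[imax]
            mm = (coords_vox - (np.asarray(grid.shape) - 1) / 2.0) * grid.voxel_size_mm
            rows.append([cid, int(sel.sum()), *mm.tolist(), float(vals[imax])])
    return pd.DataFrame(rows, columns=["component_id", "n_voxels",
                                       "peak_x_mm", "peak_y_mm", "peak_z_mm",
                                       "peak_value"])


def run_glm(dataset: Dataset, threshold_fraction: float = 0.5) -> GLMResult:
    """Full baseline analysis: designs, per-voxel OLS, averaged contrast."""
    betas, conds, labels = {}, {}, {}
    for pid in sorted({s.participant_id for s in dataset.segments}):
        design = build_design(dataset, pid)
        betas[pid] = fit_glm(stack_participant(dataset, pid), design.X)
        conds[pid] = design.condition_of
        labels[pid] = design.column_labels
    cmap = contrast_map(betas, conds, labels)
    return GLMResult(betas=betas, contrast_map=cmap,
                     threshold=threshold_fraction)


def write_contrast(result: GLMResult, grid: BrainGrid, path) -> None:
    """Write the averaged contrast as a 3-D NIfTI on the dataset grid."""
    img = nib.Nifti1Image(grid.embed(result.contrast_map.astype(np.float32)),
                          grid.affine)
    img.header["descrip"] = f"threshold_fraction={result.threshold}".encode()
    nib.save(img, Path(path))
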