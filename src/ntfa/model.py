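"""Model / Results interface.

`NTFAModel` wraps the topographic factor model: construct it from a
`Dataset` (or a dataset directory), call :meth:`NTFAModel.fit`, and get
an :class:`NTFAResults` carrying the variational posterior, the trained
networks, the optimization trace, and analysis helpers (reconstructions,
embedding tables, degeneracy report, plots). `TrialGLM` provides the
univariate per-trial baseline the same way.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import embeddings as _emb
from . import glm as _glm
from . import inference as _inf
from .exceptions import ValidationError
from .simulate import Dataset, Segment, read_dataset


def standardize_dataset(dataset: Dataset):
    """Scale all segment data by the global sd; returns (dataset, scale)."""
    scale = float(np.std(np.concatenate(
        [s.data.reshape(-1) for s in dataset.segments])))
    if scale == 0:
        raise ValidationError("dataset has zero variance")
    segs = tuple(
        Segment(s.participant_id, s.trial_id, s.trial_type, s.data / scale)
        for s in dataset.segments)
    return Dataset(grid=dataset.grid, segments=segs), scale


class NTFAModel:
    """Topographic factor model with participant/trial embeddings.

    Parameters
    ----------
    dataset : Dataset
        Labelled segments on a common grid.
    K : int
        Number of radial-basis spatial factors.
    D : int
        Embedding dimension (2 keeps embeddings directly plottable).
    standardize : bool
        Scale the data to unit global variance before fitting, which
        makes the default observation noise sd of 1 meaningful.
    """

    def __init__(self, dataset: Dataset, K: int = 5, D: int = 2,
                 standardize: bool = True, **config_kwargs):
        self.raw_dataset = dataset
        self.scale = 1.0
        if standardize:
            dataset, self.scale = standardize_dataset(dataset)
        self.dataset = dataset
        self.config = _inf.FitConfig(K=K, D=D, **config_kwargs)

    @classmethod
    def from_directory(cls, path, **kwargs) -> "NTFAModel":
        return cls(read_dataset(path), **kwargs)

    def fit(self, callback=None, resume_from=None, checkpoint_path=None,
            **overrides) -> "NTFAResults":
        config = replace(self.config, **overrides) if overrides else self.config
        result = _inf.fit(self.dataset, config, callback=callback,
                          resume_from=resume_from,
                          checkpoint_path=checkpoint_path)
        return NTFAResults(self, result)


class NTFAResults:
    """Fitted posterior plus analysis conveniences."""

    def __init__(self, model: NTFAModel, result: _inf.FitResult):
        self.model = model
        self._result = result

    # -- direct accessors -------------------------------------------------

    @property
    def posterior(self):
        return self._result.posterior

    @property
    def nets(self):
        return self._result.nets

    @property
    def loss_trace(self):
        return self._result.loss_trace

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def epochs_run(self) -> int:
        return self._result.epochs_run

    # -- analysis ----------------------------------------------------------

    def reconstruct(self, segment_index: int) -> np.ndarray:
        """Posterior-mean reconstruction in the original data units."""
        return _inf.reconstruct(self._result, segment_index) * self.model.scale

    def embedding_table(self, space: str = "activation", seed: int = 0):
        return _emb.extract_embeddings(self._result, self.model.dataset,
                                       space=space, seed=seed)

    def degeneracy_report(self, seed: int = 0, k_range=range(2, 7)):
        _, report = _emb.analyze(self._result, self.model.dataset,
                                 seed=seed, k_range=k_range)
        return report

    def plot_embeddings(self, path=None, space: str = "activation", seed: int = 0):
        table = self.embedding_table(space=space, seed=seed)
        return _emb.plot_embeddings(table, path=path)

    def save(self, path) -> None:
        _inf.save_checkpoint(self._result, path)

    def summary(self) -> str:
        r = self._result
        q = r.posterior
        lines = [
            "Topographic factor model — variational fit",
            "=" * 48,
            f"segments: {self.model.dataset.N}   participants: {self.model.dataset.P}"
            f"   trials: {self.model.dataset.S}   TRs: {self.model.dataset.T}",
            f"voxels: {self.model.dataset.grid.n_voxels}   factors K: {r.config.K}"
            f"   embedding dim D: {r.config.D}",
            f"epochs: {r.epochs_run}   converged: {r.converged}",
            f"final ELBO: {r.loss_trace[-1]:.2f}" if r.loss_trace else "final ELBO: n/a",
            "",
            "posterior factor centers (participant 1, mm):",
        ]
        centers = q.mean["x_F"].data[0]
        widths = np.exp(q.mean["rho_F"].data[0])
        for k in range(r.config.K):
            lines.append(
                f"  k={k}: center=({centers[k, 0]:7.1f}, {centers[k, 1]:7.1f},"
                f" {centers[k, 2]:7.1f})  exp(rho)={widths[k]:9.1f} mm^2")
        return "\n".join(lines)


class TrialGLM:
    """Univariate per-trial GLM with an experimental-vs-baseline contrast."""

    def __init__(self, dataset: Dataset, threshold_fraction: float = 0.5):
        self.dataset = dataset
        self.threshold_fraction = float(threshold_fraction)

    @classmethod
    def from_directory(cls, path, **kwargs) -> "TrialGLM":
        return cls(read_dataset(path), **kwargs)

    def fit(self) -> "TrialGLMResults":
        result = _glm.run_glm(self.dataset, self.threshold_fraction)
        return TrialGLMResults(self, result)


class TrialGLMResults:
    def __init__(self, model: TrialGLM, result: _glm.GLMResult):
        self.model = model
        self._result = result

    @property
    def betas(self):
        return self._result.betas

    @property
    def contrast_map(self) -> np.ndarray:
        return self._result.contrast_map

    def count_active_regions(self, threshold_fraction: float | None = None) -> int:
        thr = (self.model.threshold_fraction if threshold_fraction is None
               else threshold_fraction)
        return _glm.count_active_regions(self.contrast_map,
                                         self.model.dataset.grid, thr)

    def region_table(self):
        return _glm.region_report(self.contrast_map, self.model.dataset.grid,
                                  self.model.threshold_fraction)

    def write_contrast(self, path) -> None:
        _glm.write_contrast(self._result, self.model.dataset.grid, path)

    def summary(self) -> str:
        n = self.count_active_regions()
        lines = [
            "Per-trial univariate GLM — experimental vs baseline",
            "=" * 52,
            f"participants: {self.model.dataset.P}   trials: {self.model.dataset.S}",
            f"contrast max: {self.contrast_map.max():.4f}   "
            f"threshold fraction: {self.model.threshold_fraction}",
            f"suprathreshold 6-connected regions: {n}",
        ]
        return "\n".join(lines)
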