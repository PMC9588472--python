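"""Generative model: embeddings -> shared networks -> factors, weights, data.

Each participant p carries a spatial embedding z^PF_p and a weight
embedding z^P_p; each trial s carries an embedding z^S_s; all have a
standard-normal prior. A shared network theta_C combines (z^P_p, z^S_s)
into the activation embedding z^C of the combination; theta_F maps z^PF
to Gaussian parameters of K radial-basis factor centers (mm) and
log-widths; theta_W maps z^C to Gaussian parameters of the K factor
weights, sampled independently over TRs. A segment is then
Y = W F + Gaussian noise with fixed sd sigma_Y, where
F[k, v] = exp(-||coords[v] - x_k||^2 / exp(rho_k)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .autodiff import Tensor
from .exceptions import ValidationError
from .grids import BrainGrid
from .nets import GenerativeNets
from .simulate import Dataset

__all__ = [
    "GenerativeConfig", "EmbeddingSet", "FactorDistributionParams",
    "SpatialFactors", "WeightDistributionParams", "GenerativeState",
    "sample_prior_embeddings", "combine_embeddings", "factor_params",
    "sample_factors", "rbf_factor_matrix", "rbf_tensor", "weight_params",
    "sample_weights", "generate_segment", "log_joint",
]


@dataclass(frozen=True)
class GenerativeConfig:
    """Model-level constants: factor count K, embedding dim D, noise sd."""

    K: int = 5
    D: int = 2
    sigma_Y: float = 1.0
    hidden_units: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if self.sigma_Y <= 0:
            raise ValidationError("sigma_Y must be positive")


@dataclass(frozen=True)
class EmbeddingSet:
    z_P: np.ndarray   # (P, D) participant weight embeddings
    z_PF: np.ndarray  # (P, D) participant spatial embeddings
    z_S: np.ndarray   # (S, D) trial embeddings

    @property
    def D(self) -> int:
        return self.z_P.shape[1]


@dataclass(frozen=True)
class FactorDistributionParams:
    mu_x: np.ndarray      # (K, 3)
    sigma_x: np.ndarray   # (K, 3) > 0
    mu_rho: np.ndarray    # (K,)
    sigma_rho: np.ndarray  # (K,) > 0


@dataclass(frozen=True)
class SpatialFactors:
    centers: np.ndarray     # (K, 3) mm
    log_widths: np.ndarray  # (K,)
    F: np.ndarray = field(repr=False)  # (K, V), entries in (0, 1]


@dataclass(frozen=True)
class WeightDistributionParams:
    mu_W: np.ndarray     # (K,)
    sigma_W: np.ndarray  # (K,) > 0, shared across the segment's TRs


@dataclass(frozen=True)
class GenerativeState:
    """A full assignment of the model's latent variables for a dataset."""

    embeddings: EmbeddingSet
    x_F: np.ndarray    # (P, K, 3)
    rho_F: np.ndarray  # (P, K)
    W: np.ndarray      # (N, T, K)


def sample_prior_embeddings(P: int, S: int, D: int = 2,
                            seed: int = 0) -> EmbeddingSet:
    """i.i.d. standard-normal embedding rows for P participants, S trials."""
    if P < 1 or S < 1:
        raise ValidationError("P and S must be >= 1")
    rng = np.random.default_rng(seed)
    return EmbeddingSet(
        z_P=rng.standard_normal((P, D)),
        z_PF=rng.standard_normal((P, D)),
        z_S=rng.standard_normal((S, D)),
    )


def combine_embeddings(z_P_row: np.ndarray, z_S_row: np.ndarray,
                       nets: GenerativeNets) -> np.ndarray:
    """Deterministic activation embedding z^C = theta_C(z^P, z^S)."""
    z_P_row = np.asarray(z_P_row, dtype=float)
    z_S_row = np.asarray(z_S_row, dtype=float)
    if z_P_row.shape[-1] != nets.D or z_S_row.shape[-1] != nets.D:
        raise ValidationError(f"embedding rows must have dimension D={nets.D}")
    return nets.combine(Tensor(z_P_row), Tensor(z_S_row)).data


def factor_params(z_PF_row: np.ndarray, nets: GenerativeNets) -> FactorDistributionParams:
    """Gaussian parameters of the factor centers/log-widths for one participant."""
    z = np.asarray(z_PF_row, dtype=float)
    if z.shape[-1] != nets.D:
        raise ValidationError(f"embedding row must have dimension D={nets.D}")
    mu_x, sigma_x, mu_rho, sigma_rho = nets.factor_params(Tensor(z))
    return FactorDistributionParams(mu_x.data, sigma_x.data,
                                    mu_rho.data, sigma_rho.data)


def sample_factors(params: FactorDistributionParams, seed: int = 0):
    """Draw (x_F, rho_F) elementwise from the factor parameter Gaussians."""
    rng = np.random.default_rng(seed)
    x_F = rng.normal(params.mu_x, params.sigma_x)
    rho_F = rng.normal(params.mu_rho, params.sigma_rho)
    return x_F, rho_F


def rbf_factor_matrix(x_F: np.ndarray, rho_F: np.ndarray,
                      grid: BrainGrid) -> SpatialFactors:
    """F[k, v] = exp(-||coords[v] - x_F[k]||^2 / exp(rho_F[k]))."""
    x_F = np.atleast_2d(np.asarray(x_F, dtype=float))
    rho_F = np.atleast_1d(np.asarray(rho_F, dtype=float))
    if not (np.isfinite(x_F).all() and np.isfinite(rho_F).all()):
        raise ValidationError("factor centers/log-widths must be finite")
    d2 = ((grid.coords[None, :, :] - x_F[:, None, :]) ** 2).sum(-1)
    F = np.exp(-d2 / np.exp(rho_F)[:, None])
    return SpatialFactors(centers=x_F, log_widths=rho_F, F=F)


def rbf_tensor(x_F: Tensor, rho_F: Tensor, coords: np.ndarray) -> Tensor:
    """Autodiff version of the factor matrix; trailing dims (..., K, V)."""
    K = x_F.shape[-2]
    lead = x_F.shape[:-2]
    diff = x_F.reshape(lead + (K, 1, 3)) - coords[None, :, :]
    d2 = (diff * diff).sum(axis=-1)                     # (..., K, V)
    inv_width = (rho_F.reshape(lead + (K, 1)) * -1.0).exp()
    return (d2 * inv_width * -1.0).exp()


def weight_params(z_C_row: np.ndarray, nets: GenerativeNets) -> WeightDistributionParams:
    """Gaussian parameters of the K factor weights for one combination."""
    z = np.asarray(z_C_row, dtype=float)
    if z.shape[-1] != nets.D:
        raise ValidationError(f"embedding row must have dimension D={nets.D}")
    mu, sigma = nets.weight_params(Tensor(z))
    return WeightDistributionParams(mu.data, sigma.data)


def sample_weights(params: WeightDistributionParams, T: int,
                   seed: int = 0) -> np.ndarray:
    """T i.i.d. rows W_t ~ N(mu_W, diag(sigma_W^2))."""
    if T < 1:
        raise ValidationError("T must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.normal(params.mu_W, params.sigma_W, size=(T, params.mu_W.size))


def generate_segment(W: np.ndarray, F: np.ndarray, sigma_Y: float,
                     seed: int = 0) -> np.ndarray:
    """Y = W F + eps, eps i.i.d. N(0, sigma_Y^2)."""
    W = np.asarray(W, dtype=float)
    F = np.asarray(F, dtype=float)
    Y = W @ F
    if sigma_Y > 0:
        Y = Y + np.random.default_rng(seed).normal(0.0, sigma_Y, size=Y.shape)
    return Y


def log_joint(dataset: Dataset, state: GenerativeState, nets: GenerativeNets,
              config: GenerativeConfig) -> float:
    """Joint log-density of data and latents under the generative model.

    Sums, over segments, the Gaussian data likelihood and the weight
    likelihood given z^C; over participants, the factor center/log-width
    likelihood given z^PF; plus standard-normal log-priors on all
    embedding rows.
    """
    emb = state.embeddings
    arrays = (emb.z_P, emb.z_PF, emb.z_S, state.x_F, state.rho_F, state.W)
    if not all(np.isfinite(a).all() for a in arrays):
        raise ValidationError("latents must be finite")

    total = 0.0
    # embedding priors
    for z in (emb.z_P, emb.z_PF, emb.z_S):
        total += norm.logpdf(z).sum()
    # factors | z_PF
    for p in range(emb.z_P.shape[0]):
        fp = factor_params(emb.z_PF[p], nets)
        total += norm.logpdf(state.x_F[p], fp.mu_x, fp.sigma_x).sum()
        total += norm.logpdf(state.rho_F[p], fp.mu_rho, fp.sigma_rho).sum()
    # weights | z_C and data | W, F
    for n, seg in enumerate(dataset.segments):
        p, s = seg.participant_id - 1, seg.trial_id - 1
        z_C = combine_embeddings(emb.z_P[p], emb.z_S[s], nets)
        wp = weight_params(z_C, nets)
        total += norm.logpdf(state.W[n], wp.mu_W, wp.sigma_W).sum()
        F = rbf_factor_matrix(state.x_F[p], state.rho_F[p], dataset.grid).F
        total += norm.logpdf(seg.data, state.W[n] @ F, config.sigma_Y).sum()
    return float(total)
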