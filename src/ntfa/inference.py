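"""Stochastic variational inference for the topographic factor model.

The posterior over all latents is approximated by a fully factorized
Gaussian family: one block per factor weight W_{n,t}, per trial embedding
z^S_s, per participant block for factor centers x^F_p, log-widths
rho^F_p, and embeddings z^P_p and z^PF_p. The evidence lower bound

    L = E_q[log p(Y | W, x^F, rho^F)] - KL(q || p)

is maximized over the variational parameters and the three shared
network parameter sets with reparameterized single-sample gradients and
an adaptive-step optimizer (Adam by default; vanilla SGD available).
Embedding KL terms are closed-form against the standard-normal prior;
the factor and weight KL terms are closed-form Gaussian KLs evaluated at
a reparameterized draw of the conditioning embedding (their prior
parameters are network outputs, so no unconditional closed form exists).

Initialization follows the topographic-factor-analysis recipes: factor
center/width means from k-means on voxel locations or from greedy
"hotspot" peak picking on the dataset's mean image, and weight means
from an ordinary least squares fit of the initial factors to the mean
image. Embedding blocks start at the standard normal.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.cluster import KMeans

from .autodiff import SGD, Adam, Tensor
from .exceptions import DivergenceError, ValidationError
from .generative import rbf_tensor
from .grids import BrainGrid
from .nets import GenerativeNets
from .simulate import Dataset

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of the variational fit.

    Convergence is declared when the relative change of the
    ``convergence_window``-epoch moving-average ELBO falls below
    ``convergence_tol``.
    """

    K: int = 5
    D: int = 2
    sigma_Y: float = 1.0
    hidden_units: int = 16
    learning_rate: float = 1e-2
    max_epochs: int = 2000
    convergence_tol: float = 1e-4
    convergence_window: int = 50
    mc_samples: int = 1
    init_method: str = "hotspot"
    optimizer: str = "adam"
    learn_sigma_Y: bool = False
    weight_decay: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.D < 1:
            raise ValidationError("K and D must be >= 1")
        if self.learning_rate <= 0 or self.convergence_tol <= 0:
            raise ValidationError("rates and tolerances must be positive")
        if self.mc_samples < 1:
            raise ValidationError("mc_samples must be >= 1")
        if self.init_method not in ("kmeans", "hotspot"):
            raise ValidationError("init_method must be 'kmeans' or 'hotspot'")
        if self.optimizer not in ("adam", "sgd"):
            raise ValidationError("optimizer must be 'adam' or 'sgd'")


# ---------------------------------------------------------------------------
# variational posterior


class VariationalPosterior:
    """Gaussian mean/log-std parameter blocks for every latent family."""

    BLOCKS = ("W", "z_S", "z_P", "z_PF", "x_F", "rho_F")

    def __init__(self, N: int, T: int, P: int, S: int, K: int, D: int):
        self.dims = dict(N=N, T=T, P=P, S=S, K=K, D=D)
        shapes = {
            "W": (N, T, K),
            "z_S": (S, D),
            "z_P": (P, D),
            "z_PF": (P, D),
            "x_F": (P, K, 3),
            "rho_F": (P, K),
        }
        self.mean: dict[str, Tensor] = {}
        self.log_std: dict[str, Tensor] = {}
        for name, shape in shapes.items():
            self.mean[name] = Tensor(np.zeros(shape), requires_grad=True)
            self.log_std[name] = Tensor(np.zeros(shape), requires_grad=True)

    def std(self, name: str) -> np.ndarray:
        return np.exp(self.log_std[name].data)

    @property
    def parameters(self) -> list[Tensor]:
        return [self.mean[b] for b in self.BLOCKS] + \
               [self.log_std[b] for b in self.BLOCKS]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for b in self.BLOCKS:
            out[f"q.{b}.mean"] = self.mean[b].data
            out[f"q.{b}.log_std"] = self.log_std[b].data
        return out

    def load_state_arrays(self, state) -> None:
        for b in self.BLOCKS:
            self.mean[b].data = np.asarray(state[f"q.{b}.mean"], dtype=np.float64)
            self.log_std[b].data = np.asarray(state[f"q.{b}.log_std"], dtype=np.float64)


@dataclass(frozen=True)
class ELBOEstimate:
    """One evaluation of the bound: total = reconstruction - kl."""

    total: float
    reconstruction: float
    kl: float
    n_mc_samples: int


@dataclass
class FitResult:
    """Trained posterior, networks and the optimization trace."""

    posterior: VariationalPosterior
    nets: GenerativeNets
    loss_trace: list
    converged: bool
    epochs_run: int
    config: FitConfig
    dataset: Dataset = field(repr=False)
    sigma_Y: float = 1.0


# ---------------------------------------------------------------------------
# initialization


def _softplus_inverse(y: float) -> float:
    return float(np.log(np.expm1(y)))


def _var_to_log_width(var: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    """Isotropic cluster variance -> log-width of exp(-d^2/exp(rho)).

    The kernel exp(-d^2/exp(rho)) is a Gaussian with variance exp(rho)/2,
    so rho = log(2 var); variances are floored at (voxel/2)^2.
    """
    var = np.maximum(np.asarray(var, dtype=float), (voxel_size_mm / 2.0) ** 2)
    return np.log(2.0 * var)


def kmeans_center_init(grid: BrainGrid, K: int, seed: int = 0):
    """Factor centers from k-means on voxel locations; widths from cluster spread."""
    if K > grid.n_voxels:
        raise ValidationError(f"K={K} exceeds V={grid.n_voxels}")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(grid.coords)
    centers = km.cluster_centers_
    labels = km.labels_
    variances = np.empty(K)
    for k in range(K):
        pts = grid.coords[labels == k]
        variances[k] = pts.var(axis=0).mean() if len(pts) else 0.0
    return centers, _var_to_log_width(variances, grid.voxel_size_mm)


def hotspot_init(mean_image: np.ndarray, grid: BrainGrid, K: int):
    """Greedy peak-pick-and-subtract placement of K factor centers.

    Repeats K times: put a center at the residual image's maximum (ties
    broken by lowest linear voxel index), fit the best isotropic RBF
    log-width by golden-section search for a factor scaled to the
    residual's peak value, and subtract that factor. Scaling to the peak
    (rather than unit amplitude) keeps successive centers from stacking
    on one tall peak when the image is far from unit scale. Works best
    for small K (e.g. simulated data).
    """
    mean_image = np.asarray(mean_image, dtype=float)
    if K < 1:
        raise ValidationError("K must be >= 1")
    if not np.any(mean_image != 0):
        logger.info("all-zero mean image; falling back to k-means centers")
        return kmeans_center_init(grid, K)
    rho_lo = _var_to_log_width(0.0, grid.voxel_size_mm)[()]
    extent = np.ptp(grid.coords, axis=0).max() + grid.voxel_size_mm
    rho_hi = float(np.log(2.0 * extent**2))
    residual = mean_image.copy()
    centers = np.empty((K, 3))
    rhos = np.empty(K)
    for k in range(K):
        v = int(np.argmax(residual))  # first occurrence = lowest linear index
        centers[k] = grid.coords[v]
        amplitude = residual[v]
        d2 = ((grid.coords - centers[k]) ** 2).sum(axis=1)

        def rss(rho):
            return float(((residual - amplitude * np.exp(-d2 / np.exp(rho))) ** 2).sum())

        res = minimize_scalar(rss, bracket=(rho_lo, rho_hi), method="golden",
                              options={"xtol": 1e-3})
        rhos[k] = float(np.clip(res.x, rho_lo, rho_hi))
        residual = residual - amplitude * np.exp(-d2 / np.exp(rhos[k]))
    return centers, rhos


def ols_weight_init(F: np.ndarray, mean_image: np.ndarray) -> np.ndarray:
    """Weights minimizing ||mean_image - w^T F||^2 (ridge fallback if F is rank-deficient)."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    y = np.asarray(mean_image, dtype=float)
    K = F.shape[0]
    G = F @ F.T
    if np.linalg.matrix_rank(F) < K:
        warnings.warn("factor matrix is rank-deficient; using ridge-regularized "
                      "weight initialization", RuntimeWarning, stacklevel=2)
        G = G + 1e-6 * np.trace(G) / K * np.eye(K)
        return np.linalg.solve(G, F @ y)
    return np.linalg.solve(G, F @ y)


def init_variational(dataset: Dataset, config: FitConfig,
                     nets: GenerativeNets | None = None):
    """Build the initialized posterior (and networks, if not supplied).

    Embedding blocks start at mean 0, std 1. Factor center/log-width
    means come from the chosen init method (center stds 1; log-width std
    = spread of the initialized widths, floored). Weight means come from
    an OLS fit of the initial factors to the dataset-wide average image,
    stds 1. The network output biases for the factor and weight heads
    are set so the conditional priors start centered on the same
    initialization.
    """
    from scipy.optimize import linear_sum_assignment

    K, D = config.K, config.D
    N, T, P, S = dataset.N, dataset.T, dataset.P, dataset.S
    if nets is None:
        nets = GenerativeNets(K=K, D=D, hidden=config.hidden_units,
                              seed=config.seed)
    q = VariationalPosterior(N=N, T=T, P=P, S=S, K=K, D=D)

    mean_image = dataset.mean_image()
    if config.init_method == "kmeans":
        ref_centers, ref_rhos = kmeans_center_init(dataset.grid, K,
                                                   seed=config.seed)
        centers = np.broadcast_to(ref_centers, (P, K, 3)).copy()
        rhos = np.broadcast_to(ref_rhos, (P, K)).copy()
    else:
        # factors are per-participant entities, so peaks are picked on
        # each participant's own mean image; factor order is aligned to
        # the dataset-level reference, and centers matching a reference
        # peak snap onto it so the basis is identical across
        # participants wherever their functional anatomy agrees
        ref_centers, ref_rhos = hotspot_init(mean_image, dataset.grid, K)
        snap = 1.5 * dataset.grid.voxel_size_mm
        centers = np.empty((P, K, 3))
        rhos = np.empty((P, K))
        for p in range(P):
            segs = [s.data.mean(axis=0) for s in dataset.segments
                    if s.participant_id == p + 1]
            c_p, r_p = hotspot_init(np.mean(segs, axis=0), dataset.grid, K)
            cost = np.linalg.norm(c_p[:, None, :] - ref_centers[None, :, :],
                                  axis=-1)
            row, col = linear_sum_assignment(cost)
            order = row[np.argsort(col)]
            centers[p] = c_p[order]
            rhos[p] = r_p[order]
            near = np.linalg.norm(centers[p] - ref_centers, axis=1) <= snap
            centers[p][near] = ref_centers[near]
            rhos[p][near] = ref_rhos[near]

    rho_std = max(float(np.std(rhos)), 0.1)
    q.mean["x_F"].data[:] = centers
    q.log_std["x_F"].data[:] = 0.0  # std 1
    q.mean["rho_F"].data[:] = rhos
    q.log_std["rho_F"].data[:] = np.log(rho_std)

    w0_mean = np.zeros(K)
    for p in range(P):
        d2 = ((dataset.grid.coords[None, :, :] - centers[p][:, None, :]) ** 2).sum(-1)
        F0 = np.exp(-d2 / np.exp(rhos[p])[:, None])
        w0 = ols_weight_init(F0, mean_image)
        w0_mean += w0 / P
        for n, seg in enumerate(dataset.segments):
            if seg.participant_id == p + 1:
                q.mean["W"].data[n] = w0
    q.log_std["W"].data[:] = 0.0

    # center the conditional priors on the same initialization
    b2 = nets.theta_F.b2.data
    b2[: 3 * K] = centers.mean(axis=0).reshape(-1)
    b2[3 * K: 6 * K] = _softplus_inverse(1.0)
    b2[6 * K: 7 * K] = rhos.mean(axis=0)
    b2[7 * K: 8 * K] = _softplus_inverse(rho_std)
    bw = nets.theta_W.b2.data
    bw[:K] = w0_mean
    bw[K:] = _softplus_inverse(1.0)
    return q, nets


# ---------------------------------------------------------------------------
# ELBO


def _gaussian_kl(mu_q: Tensor, log_std_q: Tensor, mu_p: Tensor,
                 sigma_p: Tensor) -> Tensor:
    """Elementwise KL(N(mu_q, sigma_q) || N(mu_p, sigma_p)); sigma_q = exp(log_std_q)."""
    var_q = (log_std_q * 2.0).exp()
    diff = mu_q - mu_p
    return (sigma_p.log() - log_std_q
            + (var_q + diff * diff) / (sigma_p * sigma_p * 2.0) - 0.5)


def _std_normal_kl(mu: Tensor, log_std: Tensor) -> Tensor:
    var = (log_std * 2.0).exp()
    return (var + mu * mu) * 0.5 - log_std - 0.5


def _stack_data(dataset: Dataset):
    Y = np.stack([s.data for s in dataset.segments])  # (N, T, V)
    p_idx = np.array([s.participant_id - 1 for s in dataset.segments])
    s_idx = np.array([s.trial_id - 1 for s in dataset.segments])
    return Y, p_idx, s_idx


def elbo(posterior: VariationalPosterior, nets: GenerativeNets,
         dataset: Dataset, config: FitConfig,
         rng: np.random.Generator | int = 0,
         mc_samples: int | None = None,
         log_sigma_Y: Tensor | None = None):
    """Monte-Carlo ELBO with a leading sample axis; returns (Tensor, ELBOEstimate).

    The returned Tensor is the (differentiable) total; the estimate
    carries the reconstruction and KL parts, with total = recon - kl.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    M = int(mc_samples if mc_samples is not None else config.mc_samples)
    for b in posterior.BLOCKS:
        if not np.all(np.isfinite(posterior.log_std[b].data)):
            raise ValidationError(f"non-finite log-std in block {b!r}")
    Y, p_idx, s_idx = _stack_data(dataset)
    N, T, V = Y.shape
    K = config.K

    def draw(name, shape):
        mu, ls = posterior.mean[name], posterior.log_std[name]
        eps = rng.standard_normal((M,) + shape)
        return mu + ls.exp() * eps

    dims = posterior.dims
    z_P = draw("z_P", (dims["P"], dims["D"]))
    z_S = draw("z_S", (dims["S"], dims["D"]))
    z_PF = draw("z_PF", (dims["P"], dims["D"]))
    W = draw("W", (N, T, K))

    # -- KL: embeddings vs standard normal (closed form, no MC) ----------
    kl = Tensor(0.0)
    for b in ("z_P", "z_S", "z_PF"):
        kl = kl + _std_normal_kl(posterior.mean[b], posterior.log_std[b]).sum()

    # -- KL: factor centers / log-widths vs network prior at z_PF draw ---
    mu_x, sigma_x, mu_rho, sigma_rho = nets.factor_params(z_PF)  # (M,P,K,*)
    kl_x = _gaussian_kl(posterior.mean["x_F"], posterior.log_std["x_F"],
                        mu_x, sigma_x)
    kl_rho = _gaussian_kl(posterior.mean["rho_F"], posterior.log_std["rho_F"],
                          mu_rho, sigma_rho)
    kl = kl + kl_x.sum() * (1.0 / M) + kl_rho.sum() * (1.0 / M)

    # -- KL: weights vs network prior at z_C draw ------------------------
    z_C = nets.combine(z_P.take(p_idx, axis=1), z_S.take(s_idx, axis=1))
    mu_W, sigma_W = nets.weight_params(z_C)           # (M, N, K)
    mu_W = mu_W.reshape((M, N, 1, K))
    sigma_W = sigma_W.reshape((M, N, 1, K))
    kl_W = _gaussian_kl(posterior.mean["W"], posterior.log_std["W"],
                        mu_W, sigma_W)
    kl = kl + kl_W.sum() * (1.0 / M)

    # -- reconstruction ---------------------------------------------------
    x_F = draw("x_F", (dims["P"], K, 3))
    rho_F = draw("rho_F", (dims["P"], K))
    F = rbf_tensor(x_F, rho_F, dataset.grid.coords)   # (M, P, K, V)
    F_seg = F.take(p_idx, axis=1)                     # (M, N, K, V)
    Y_hat = W @ F_seg                                 # (M, N, T, V)
    resid = Y_hat - Y[None]
    if log_sigma_Y is not None:
        inv_var = (log_sigma_Y * -2.0).exp()
        recon = ((resid * resid).sum(axis=(1, 2, 3)) * inv_var * (-0.5)
                 - (log_sigma_Y + 0.5 * LOG2PI) * float(N * T * V)).mean()
    else:
        s2 = config.sigma_Y**2
        recon = ((resid * resid).sum(axis=(1, 2, 3)) * (-0.5 / s2)).mean() \
            - 0.5 * (LOG2PI + 2.0 * np.log(config.sigma_Y)) * N * T * V

    total = recon - kl
    est = ELBOEstimate(total=total.item(), reconstruction=float(recon.data),
                       kl=float(kl.data), n_mc_samples=M)
    return total, est


# ---------------------------------------------------------------------------
# fitting


def fit(dataset: Dataset, config: FitConfig,
        callback=None, resume_from=None,
        checkpoint_path=None) -> FitResult:
    """Maximize the ELBO with reparameterized stochastic gradients.

    Stops when the relative change of the moving-average ELBO falls
    below ``config.convergence_tol``, or at ``config.max_epochs``.
    ``resume_from`` restores a checkpoint (parameters, optimizer state
    and loss trace) and continues; ``checkpoint_path`` saves one at the
    end of the run.
    """
    q, nets = init_variational(dataset, config)
    params = q.parameters + nets.parameters
    log_sigma_Y = None
    if config.learn_sigma_Y:
        log_sigma_Y = Tensor(np.log(config.sigma_Y), requires_grad=True)
        params = params + [log_sigma_Y]
    opt_cls = Adam if config.optimizer == "adam" else SGD
    opt = opt_cls(params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7, 1)))
    trace: list[float] = []
    start_epoch = 0
    if resume_from is not None:
        header, arrays = _read_checkpoint(resume_from)
        q.load_state_arrays(arrays)
        nets.load_state_arrays(arrays)
        if header.get("optimizer"):
            opt.load_state_dict({
                "t": header["optimizer"]["t"],
                "m": [arrays[f"opt.m.{i}"] for i in range(len(params))],
                "v": [arrays[f"opt.v.{i}"] for i in range(len(params))],
            } if config.optimizer == "adam" else {})
        trace = list(header["loss_trace"])
        start_epoch = int(header["epoch"])
        rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 7, 1, start_epoch)))
        if log_sigma_Y is not None and "log_sigma_Y" in arrays:
            log_sigma_Y.data = np.asarray(arrays["log_sigma_Y"])

    w = config.convergence_window
    converged = False
    for epoch in range(start_epoch, config.max_epochs):
        opt.zero_grad()
        total, est = elbo(q, nets, dataset, config, rng=rng,
                          log_sigma_Y=log_sigma_Y)
        if not np.isfinite(est.total):
            raise DivergenceError(
                f"non-finite ELBO at epoch {epoch}: {est}")
        loss = total * -1.0
        if config.weight_decay > 0:
            # Occam pressure on the shared maps only (weights, not the
            # biases that anchor the factor/weight initialization): an
            # embedding direction the data do not require decays away
            # instead of persisting as spurious cluster sub-structure.
            penalty = Tensor(0.0)
            for net in (nets.theta_C, nets.theta_F, nets.theta_W):
                penalty = penalty + (net.W1 * net.W1).sum() + (net.W2 * net.W2).sum()
            loss = loss + penalty * config.weight_decay
        loss.backward()
        opt.step()
        trace.append(est.total)
        logger.debug("epoch %d elbo=%.4f recon=%.4f kl=%.4f",
                     epoch, est.total, est.reconstruction, est.kl)
        if callback is not None:
            callback(epoch, est)
        if len(trace) >= 2 * w:
            recent = float(np.mean(trace[-w:]))
            previous = float(np.mean(trace[-2 * w:-w]))
            denom = max(abs(previous), 1.0)
            if abs(recent - previous) / denom < config.convergence_tol:
                converged = True
                break

    sigma_Y = float(np.exp(log_sigma_Y.data)) if log_sigma_Y is not None \
        else config.sigma_Y
    result = FitResult(posterior=q, nets=nets, loss_trace=trace,
                       converged=converged, epochs_run=len(trace),
                       config=config, dataset=dataset, sigma_Y=sigma_Y)
    if checkpoint_path is not None:
        save_checkpoint(result, checkpoint_path, optimizer=opt,
                        log_sigma_Y=log_sigma_Y)
    return result


def reconstruct(result: FitResult, segment_index: int) -> np.ndarray:
    """Posterior-mean reconstruction W_n F_{p_n} for one segment (T x V)."""
    ds = result.dataset
    if not 0 <= segment_index < ds.N:
        raise IndexError(f"segment index {segment_index} out of range")
    seg = ds.segments[segment_index]
    p = seg.participant_id - 1
    q = result.posterior
    centers = q.mean["x_F"].data[p]
    rhos = q.mean["rho_F"].data[p]
    d2 = ((ds.grid.coords[None, :, :] - centers[:, None, :]) ** 2).sum(-1)
    F = np.exp(-d2 / np.exp(rhos)[:, None])
    W = q.mean["W"].data[segment_index]
    return W @ F


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(result: FitResult, path, optimizer=None,
                    log_sigma_Y=None) -> None:
    """Single-archive checkpoint: JSON header + float arrays; resumable."""
    from dataclasses import asdict
    arrays = {}
    arrays.update(result.posterior.state_arrays())
    arrays.update(result.nets.state_arrays())
    if log_sigma_Y is not None:
        arrays["log_sigma_Y"] = np.asarray(log_sigma_Y.data)
    header = {
        "config": asdict(result.config),
        "epoch": result.epochs_run,
        "converged": result.converged,
        "loss_trace": list(map(float, result.loss_trace)),
        "sigma_Y": result.sigma_Y,
        "dims": result.posterior.dims,
        "optimizer": None,
    }
    if optimizer is not None and isinstance(optimizer, Adam):
        header["optimizer"] = {"t": optimizer.t}
        for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
            arrays[f"opt.m.{i}"] = m
            arrays[f"opt.v.{i}"] = v
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def _read_checkpoint(path):
    with np.load(path) as npz:
        try:
            header = json.loads(bytes(npz["__header__"]).decode())
        except KeyError as exc:
            raise ValidationError(f"malformed checkpoint {path}") from exc
        arrays = {k: npz[k] for k in npz.files if k != "__header__"}
    return header, arrays


def load_checkpoint(path, dataset: Dataset) -> FitResult:
    header, arrays = _read_checkpoint(path)
    config = FitConfig(**header["config"])
    q, nets = init_variational(dataset, config)
    q.load_state_arrays(arrays)
    nets.load_state_arrays(arrays)
    return FitResult(posterior=q, nets=nets,
                     loss_trace=header["loss_trace"],
                     converged=bool(header["converged"]),
                     epochs_run=int(header["epoch"]),
                     config=config, dataset=dataset,
                     sigma_Y=float(header.get("sigma_Y", config.sigma_Y)))
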