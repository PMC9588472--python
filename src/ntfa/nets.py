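"""Small fully-connected networks shared across participants and trials.

Three networks drive the generative model:

* ``theta_C`` maps a (participant, trial) embedding pair to the activation
  embedding of their combination (2D -> D),
* ``theta_F`` maps a participant's spatial embedding to the Gaussian
  parameters of the K factor centers and log-widths (D -> K*(3+3+1+1)),
* ``theta_W`` maps an activation embedding to the Gaussian parameters of
  the K factor weights (D -> 2K).

Each is a one-hidden-layer tanh network (16 units by default) — the
smallest genuinely nonlinear choice. Standard-deviation outputs pass
through softplus plus a 1e-3 floor so they are strictly positive.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

SIGMA_FLOOR = 1e-3


class MLP:
    """One-hidden-layer tanh network y = W2 @ tanh(W1 x + b1) + b2."""

    def __init__(self, in_dim: int, out_dim: int, hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.out_dim, self.hidden = in_dim, out_dim, hidden
        s1 = 1.0 / np.sqrt(in_dim)
        s2 = 1.0 / np.sqrt(hidden)
        self.W1 = Tensor(rng.normal(0.0, s1, size=(in_dim, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = Tensor(rng.normal(0.0, s2, size=(hidden, out_dim)), requires_grad=True)
        self.b2 = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = (x @ self.W1 + self.b1).tanh()
        return h @ self.W2 + self.b2

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1.data, "b1": self.b1.data,
                "W2": self.W2.data, "b2": self.b2.data}

    def load_state_arrays(self, state) -> None:
        self.W1.data = np.asarray(state["W1"], dtype=np.float64)
        self.b1.data = np.asarray(state["b1"], dtype=np.float64)
        self.W2.data = np.asarray(state["W2"], dtype=np.float64)
        self.b2.data = np.asarray(state["b2"], dtype=np.float64)


def positive(x: Tensor) -> Tensor:
    """Softplus positivity transform with an absolute floor."""
    return x.softplus() + SIGMA_FLOOR




class GenerativeNets:
    """The three shared networks (theta_C, theta_F, theta_W) and K, D."""

    def __init__(self, K: int, D: int = 2, hidden: int = 16, seed: int = 0):
        self.K, self.D, self.hidden = K, D, hidden
        rng = np.random.default_rng(seed)
        self.theta_C = MLP(2 * D, D, hidden, rng)
        self.theta_F = MLP(D, K * 8, hidden, rng)
        self.theta_W = MLP(D, 2 * K, hidden, rng)

    # -- typed forward passes -------------------------------------------

    def combine(self, z_P: Tensor, z_S: Tensor) -> Tensor:
        """theta_C: activation embedding of a participant-trial combination."""
        if z_P.shape[-1] != self.D or z_S.shape[-1] != self.D:
            raise ValueError(
                f"embedding rows must have dimension D={self.D}, "
                f"got {z_P.shape[-1]} and {z_S.shape[-1]}"
            )
        return self.theta_C(concat([z_P, z_S], axis=-1))

    def factor_params(self, z_PF: Tensor):
        """theta_F: (mu_x (...,K,3), sigma_x (...,K,3), mu_rho (...,K), sigma_rho (...,K))."""
        K = self.K
        raw = self.theta_F(z_PF)
        lead = raw.shape[:-1]
        mu_x = raw[..., : 3 * K].reshape(lead + (K, 3))
        sigma_x = positive(raw[..., 3 * K : 6 * K].reshape(lead + (K, 3)))
        mu_rho = raw[..., 6 * K : 7 * K]
        sigma_rho = positive(raw[..., 7 * K : 8 * K])
        return mu_x, sigma_x, mu_rho, sigma_rho

    def weight_params(self, z_C: Tensor):
        """theta_W: (mu_W (...,K), sigma_W (...,K)) shared across a segment's TRs."""
        K = self.K
        raw = self.theta_W(z_C)
        return raw[..., :K], positive(raw[..., K:])

    @property
    def parameters(self) -> list[Tensor]:
        return (self.theta_C.parameters + self.theta_F.parameters
                + self.theta_W.parameters)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, net in (("C", self.theta_C), ("F", self.theta_F), ("W", self.theta_W)):
            for k, v in net.state_arrays().items():
                out[f"theta_{name}.{k}"] = v
        return out

    def load_state_arrays(self, state) -> None:
        for name, net in (("C", self.theta_C), ("F", self.theta_F), ("W", self.theta_W)):
            net.load_state_arrays(
                {k.split(".", 1)[1]: v for k, v in state.items()
                 if k.startswith(f"theta_{name}.")}
            )
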