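"""Hebbian learning with multiplicative L2 renormalization.

Weight growth is proportional to the product of pre- and postsynaptic rates
(dW_ij/dt = rho * post_i * pre_j), confined to the diluted connectivity
mask. After every update each postsynaptic weight vector is rescaled to
unit L2 norm, which implements synaptic competition: strengthening one
afferent necessarily weakens the others.

Learning rates are per second (``dt`` below is in seconds even though the
network integration grid is in milliseconds). Under continual
renormalization the per-step increment sets an effective forgetting rate,
so the time unit of rho is behaviorally meaningful: per-second rates make
a weight vector integrate pairings over many trials, whereas per-ms rates
would slave it to the last few integration steps of the last trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LearningConfig:
    rho_VC: float = 0.1
    rho_SC: float = 0.1
    rho_CR: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.rho_VC, self.rho_SC, self.rho_CR) < 0:
            raise ValueError("learning rates must be nonnegative")


def hebbian_step(W, mask, pre_rates, post_rates, rho, dt):
    """In-place Hebbian increment W_ij += dt * rho * post_i * pre_j on the
    mask support; off-mask entries are untouched (and stay exactly 0).

    ``dt`` is in seconds (rho is a per-second rate)."""
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    dW = (dt * rho) * np.outer(post_rates, pre_rates)
    dW *= mask
    W += dW
    return W


def normalize_rows(W, mask=None):
    """Scale each row of W to unit L2 norm (direction preserved).

    A zero row signals corrupted initialization (rows start strictly
    positive and Hebbian increments are nonnegative) and raises.
    """
    norms = np.sqrt(np.einsum("ij,ij->i", W, W))
    if np.any(norms == 0.0):
        raise ValueError("weight row with zero norm cannot be normalized")
    W /= norms[:, None]
    return W
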