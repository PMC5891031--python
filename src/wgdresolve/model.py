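"""Four-state Markov model of duplicate-gene resolution after whole-genome duplication.

Every ancestral locus starts as an undifferentiated duplicate pair (state U).
Along each branch of the species tree it may be fixed as a permanent duplicate
(F, e.g. by neo-/sub-functionalization), or return to single copy, retaining
either the copy from parental subgenome 1 (S1) or from subgenome 2 (S2).
F, S1 and S2 are absorbing.

Rates are expressed relative to the base loss rate alpha: the rate of loss
into S1 is fixed to 1, so branch lengths are in alpha*t units.  The
fractionation-bias parameter ``epsilon`` (0 <= eps <= 1) multiplies the loss
rate into S2, making losses of the subgenome-2-destined copy rarer; it equals
the expected ratio of single-copy genes retained from subgenome 2 relative to
subgenome 1.  The relative fixation rate ``gamma`` (>= 0) is the U -> F rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Ordered state labels. Indices are used throughout the package.
STATES = ("U", "F", "S1", "S2")
U, F, S1, S2 = 0, 1, 2, 3
N_STATES = 4


@dataclass(frozen=True)
class LossParams:
    """Global loss-model parameters (branch lengths live on the tree).

    gamma : relative duplicate-fixation rate, 0 <= gamma < inf
    epsilon : fractionation bias, 0 <= epsilon <= 1
    """

    gamma: float
    epsilon: float

    def __post_init__(self) -> None:
        _check_params(self.gamma, self.epsilon)


def _check_params(gamma: float, epsilon: float) -> None:
    if not (gamma >= 0.0 and np.isfinite(gamma)):
        raise ValueError(f"gamma must satisfy 0 <= gamma < inf, got {gamma!r}")
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError(f"epsilon must satisfy 0 <= epsilon <= 1, got {epsilon!r}")


def rate_matrix(gamma: float, epsilon: float) -> np.ndarray:
    """Instantaneous generator of the loss process, in units of the base loss rate.

    Row order (U, F, S1, S2).  The U row is (-(1+eps+gamma), gamma, 1, eps);
    the absorbing rows are identically zero.
    """
    _check_params(gamma, epsilon)
    q = np.zeros((N_STATES, N_STATES))
    q[U, F] = gamma
    q[U, S1] = 1.0
    q[U, S2] = epsilon
    q[U, U] = -(1.0 + epsilon + gamma)
    return q


def transition_probs(gamma: float, epsilon: float, b: float) -> np.ndarray:
    """Transition probability matrix over a branch of length ``b`` (alpha*t units).

    Closed form of expm(b*Q): with total outflow lam = 1 + eps + gamma,
    P[U,U] = exp(-lam*b) and the absorbed mass splits proportionally to the
    rates; absorbing rows are identity.
    """
    _check_params(gamma, epsilon)
    if not (b >= 0.0):
        raise ValueError(f"branch length must be >= 0, got {b!r}")
    lam = 1.0 + epsilon + gamma
    p = np.eye(N_STATES)
    p_uu = np.exp(-lam * b)
    absorbed = (1.0 - p_uu) / lam
    p[U, U] = p_uu
    p[U, S1] = absorbed
    p[U, S2] = epsilon * absorbed
    p[U, F] = gamma * absorbed
    return p
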