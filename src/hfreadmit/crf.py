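"""First-order linear-chain CRF over binary label sequences.

Two potential variants:

- ``unary``    — per-step unary scores plus one static transition
  matrix A of shape 2 x 2 shared across steps;
- ``pairwise`` — input-dependent per-step 2 x 2 transition scores that
  replace A and subsume the unaries for t >= 1; the first step keeps a
  unary term (there is no incoming transition to score it with).

All inference is exact and in log-space (log-sum-exp), stable for
scores up to about +-1e3.  The chain is open at both ends (no
start/stop boundary states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ._autograd import Tensor

N_LABELS = 2
VARIANTS = ("unary", "pairwise")


@dataclass
class ChainPotentials:
    """Log-potentials for one sequence.

    ``unary``: T x 2.  ``pairwise``: 2 x 2 static matrix for the
    ``unary`` variant, or T x 2 x 2 per-step scores for the
    ``pairwise`` variant (entry [t] scores the transition from step
    t-1 to step t; entry [0] is ignored).
    """

    unary: np.ndarray
    pairwise: np.ndarray
    variant: str = "unary"

    def __post_init__(self):
        self.unary = np.asarray(self.unary, dtype=float)
        self.pairwise = np.asarray(self.pairwise, dtype=float)
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.unary.ndim != 2 or self.unary.shape[1] != N_LABELS:
            raise ValueError("unary must be T x 2")
        expected = ((N_LABELS, N_LABELS) if self.variant == "unary"
                    else (self.T, N_LABELS, N_LABELS))
        if self.T > 1 and self.pairwise.shape != expected:
            raise ValueError(f"pairwise must have shape {expected}")
        if not (np.isfinite(self.unary).all()
                and np.isfinite(self.pairwise).all()):
            raise ValueError("potentials must be finite")

    @property
    def T(self) -> int:
        return self.unary.shape[0]

    def _steps(self):
        """(phi0, [M_1 .. M_{T-1}]) — first-step vector and per-step
        transition matrices of the equivalent chain."""
        phi0 = self.unary[0]
        if self.T == 1:
            return phi0, np.zeros((0, N_LABELS, N_LABELS))
        if self.variant == "unary":
            M = (self.pairwise[None, :, :]
                 + self.unary[1:, None, :])
        else:
            M = self.pairwise[1:]
        return phi0, M


def sequence_score(potentials: ChainPotentials, y) -> float:
    """Unnormalized log-score of one labeling."""
    y = np.asarray(y, dtype=int)
    if len(y) != potentials.T:
        raise ValueError("label sequence length mismatch")
    phi0, M = potentials._steps()
    s = float(phi0[y[0]])
    for t in range(1, potentials.T):
        s += float(M[t - 1, y[t - 1], y[t]])
    return s


def _forward(potentials: ChainPotentials) -> np.ndarray:
    phi0, M = potentials._steps()
    alpha = np.empty((potentials.T, N_LABELS))
    alpha[0] = phi0
    for t in range(1, potentials.T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + M[t - 1], axis=0)
    return alpha


def _backward(potentials: ChainPotentials) -> np.ndarray:
    _, M = potentials._steps()
    beta = np.zeros((potentials.T, N_LABELS))
    for t in range(potentials.T - 2, -1, -1):
        beta[t] = logsumexp(M[t] + beta[t + 1][None, :], axis=1)
    return beta


def log_partition(potentials: ChainPotentials) -> float:
    """log sum over all 2^T labelings of exp(score)."""
    return float(logsumexp(_forward(potentials)[-1]))


def nll(potentials: ChainPotentials, y_true) -> float:
    """Negative conditional log-likelihood of ``y_true``; >= 0."""
    return max(log_partition(potentials)
               - sequence_score(potentials, y_true), 0.0)


def marginals(potentials: ChainPotentials) -> np.ndarray:
    """Per-step posterior p(y_t = c | x); rows sum to 1."""
    alpha, beta = _forward(potentials), _backward(potentials)
    logz = logsumexp(alpha[-1])
    return np.exp(alpha + beta - logz)


def pairwise_marginals(potentials: ChainPotentials) -> np.ndarray:
    """p(y_{t-1} = i, y_t = j | x) for t = 1..T-1 (shape T-1 x 2 x 2)."""
    alpha, beta = _forward(potentials), _backward(potentials)
    _, M = potentials._steps()
    logz = logsumexp(alpha[-1])
    out = np.empty((potentials.T - 1, N_LABELS, N_LABELS))
    for t in range(1, potentials.T):
        out[t - 1] = np.exp(alpha[t - 1][:, None] + M[t - 1]
                            + beta[t][None, :] - logz)
    return out


def viterbi(potentials: ChainPotentials) -> np.ndarray:
    """Highest-scoring labeling; ties broken toward label 0 at every
    backtrack step (argmax takes the first maximizer)."""
    phi0, M = potentials._steps()
    T = potentials.T
    delta = np.empty((T, N_LABELS))
    psi = np.zeros((T, N_LABELS), dtype=int)
    delta[0] = phi0
    for t in range(1, T):
        cand = delta[t - 1][:, None] + M[t - 1]
        psi[t] = cand.argmax(axis=0)
        delta[t] = cand.max(axis=0)
    y = np.empty(T, dtype=int)
    y[-1] = int(delta[-1].argmax())
    for t in range(T - 1, 0, -1):
        y[t - 1] = psi[t, y[t]]
    return y


def nll_grad(potentials: ChainPotentials, y_true):
    """Analytic gradient of the NLL w.r.t. the potential arrays.

    Unary gradient is (marginals - one-hot); transition gradient is
    (pairwise marginals - observed transitions), accumulated into the
    static A for the ``unary`` variant.
    """
    y_true = np.asarray(y_true, dtype=int)
    T = potentials.T
    mu = marginals(potentials)
    g_unary = mu.copy()
    g_unary[np.arange(T), y_true] -= 1.0
    if T == 1:
        return g_unary, np.zeros_like(potentials.pairwise)
    mu2 = pairwise_marginals(potentials)
    obs = np.zeros_like(mu2)
    obs[np.arange(T - 1), y_true[:-1], y_true[1:]] = 1.0
    g_pair_steps = mu2 - obs
    if potentials.variant == "unary":
        return g_unary, g_pair_steps.sum(axis=0)
    g_pair = np.zeros_like(potentials.pairwise)
    g_pair[1:] = g_pair_steps
    g_unary_out = np.zeros_like(g_unary)
    g_unary_out[0] = g_unary[0]         # only the first unary is used
    return g_unary_out, g_pair


def readmission_marginal(potentials: ChainPotentials) -> float:
    """p(y_T = 1 | x): the score used to rank readmission risk."""
    return float(marginals(potentials)[-1, 1])


# -- autodiff bridge ---------------------------------------------------


def crf_nll_op(unary: Tensor, pairwise: Tensor, y_true,
               variant: str) -> Tensor:
    """CRF negative log-likelihood as an autodiff node.

    Forward runs the exact numpy inference; backward injects the
    analytic gradient (expected minus observed sufficient statistics).
    """
    pots = ChainPotentials(unary=unary.data, pairwise=pairwise.data,
                           variant=variant)
    value = nll(pots, y_true)
    out = Tensor(value,
                 requires_grad=unary.requires_grad or pairwise.requires_grad,
                 _parents=tuple(p for p in (unary, pairwise)
                                if p.requires_grad))

    def bw(g):
        g = float(g)
        gu, gp = nll_grad(pots, y_true)
        if unary.requires_grad:
            unary._accum(g * gu)
        if pairwise.requires_grad:
            pairwise._accum(g * gp)

    if out.requires_grad:
        out._backward = bw
    return out
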