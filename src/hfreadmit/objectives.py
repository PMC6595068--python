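"""Training objectives for timeline models.

Per-step loss is the (class-weighted) cross-entropy.  Four
sequence-level aggregations are supported:

- ``LastHF``          — loss of the final HF event only;
- ``Uniform_HF``      — uniform average over all HF events;
- ``Convex_HF_lastHF``— alpha * mean-HF + (1 - alpha) * last-HF;
- ``Convex_HF_NonHF`` — alpha * mean-HF + (1 - alpha) * mean-non-HF.

Our orientation of the convex weight: alpha multiplies the HF-average
term, so alpha = 1 recovers Uniform_HF and alpha = 0 recovers LastHF
(for the first convex variant).  The total objective adds an L2
penalty (lambda / 2) * ||theta||^2 over weight matrices, biases
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

LOSS_KINDS = ("LastHF", "Uniform_HF", "Convex_HF_lastHF",
              "Convex_HF_NonHF")
_CONVEX = ("Convex_HF_lastHF", "Convex_HF_NonHF")

_P_FLOOR = 1e-12


@dataclass(frozen=True)
class LossSpec:
    kind: str = "LastHF"
    alpha: float = None
    lam: float = 0.0
    p_dropout: float = 0.0

    def __post_init__(self):
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.kind in _CONVEX:
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ValueError("convex losses require alpha in [0, 1]")
        elif self.alpha is not None:
            raise ValueError(f"{self.kind} does not take alpha")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.p_dropout < 1.0:
            raise ValueError("p_dropout must be in [0, 1)")


def step_loss(y_true: int, y_prob, weight: float = 1.0) -> float:
    """Weighted cross-entropy of one step: -weight * log p(y_true)."""
    y_prob = np.asarray(y_prob, dtype=float)
    if y_prob.shape != (2,):
        raise ValueError("binary outcome: y_prob must have 2 entries")
    if abs(y_prob.sum() - 1.0) > 1e-6 or (y_prob < -1e-12).any():
        raise ValueError("y_prob is not a probability distribution")
    if weight <= 0:
        raise ValueError("weight must be positive")
    return float(-weight * np.log(max(y_prob[int(y_true)], _P_FLOOR)))


def aggregation_weights(is_hf, last_hf_index: int,
                        spec: LossSpec) -> np.ndarray:
    """Per-step weights w_t such that the sequence loss is sum w_t l_t.

    Every loss kind is a fixed convex combination of per-step losses;
    factoring it out keeps the numpy reference path and the autodiff
    training path on the same arithmetic.
    """
    is_hf = np.asarray(is_hf, dtype=bool)
    T = len(is_hf)
    n_hf = int(is_hf.sum())
    if n_hf == 0:
        raise ValueError("sequence has no HF events (impossible after "
                         "truncation)")
    w = np.zeros(T)
    if spec.kind == "LastHF":
        w[last_hf_index] = 1.0
    elif spec.kind == "Uniform_HF":
        w[is_hf] = 1.0 / n_hf
    elif spec.kind == "Convex_HF_lastHF":
        w[is_hf] += spec.alpha / n_hf
        w[last_hf_index] += 1.0 - spec.alpha
    else:                               # Convex_HF_NonHF
        n_non = T - n_hf
        if n_non:
            w[is_hf] += spec.alpha / n_hf
            w[~is_hf] += (1.0 - spec.alpha) / n_non
        else:
            # all-HF timeline: the combination degenerates to the HF
            # average (a single HF event then yields l_T for any alpha)
            logger.info("Convex_HF_NonHF on an all-HF sequence: "
                        "using the HF average alone")
            w[is_hf] += 1.0 / n_hf
    return w


def sequence_loss(seq, probs, spec: LossSpec, weights=None) -> float:
    """Aggregate per-step cross-entropies for one encoded sequence.

    ``probs`` is a T x 2 array of per-step label distributions;
    ``weights`` an optional class-weight mapping applied per step.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape[0] != seq.T:
        raise ValueError("probs length must equal sequence length")
    losses = np.array([
        step_loss(seq.labels[t], probs[t],
                  1.0 if weights is None else weights[int(seq.labels[t])])
        for t in range(seq.T)])
    w = aggregation_weights(seq.is_hf, seq.last_hf_index, spec)
    return float(w @ losses)


def total_objective(losses, params, lam: float) -> float:
    """Mean per-sequence loss plus (lam / 2) * ||theta||^2.

    ``params`` are the penalized weight arrays only (no biases).
    """
    losses = np.asarray(losses, dtype=float)
    if losses.size == 0:
        raise ValueError("need at least one sequence loss")
    penalty = 0.5 * lam * sum(float((np.asarray(p) ** 2).sum())
                              for p in params)
    return float(losses.mean() + penalty)
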