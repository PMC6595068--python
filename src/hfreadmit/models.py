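"""The predictive model zoo, statsmodels-style.

Every family is driven through :class:`ReadmissionModel` (configured,
unfitted) whose ``fit`` returns a :class:`ReadmissionResults` carrying
the learned parameters, the per-epoch training history, and
``predict_proba`` — the probability of 30-day all-cause readmission
for the last HF event of each timeline.

Families
--------
- ``RNN``       — GRU/LSTM sequence labeler; honours all four loss kinds.
- ``RNNSS``     — RNN with scheduled sampling: the previous step's label
  (true with probability epsilon, else sampled from the model) is
  one-hot concatenated to the next input; decays per epoch.  Feedback
  weights start at zero, so at initialization RNNSS coincides with RNN.
- ``CRF_only``  — linear-chain CRF with affine potentials on raw features.
- ``NeuralCRF`` — potentials from a one-hidden-layer nonlinear net.
- ``RNNCRF``    — GRU features feeding CRF potentials.
- ``CNN``       — square 3x3 conv / 2x2 max-pool blocks on the padded
  T_max x d timeline matrix; last-HF loss.
- ``CNN_Wide``  — full-width kernels (heights 2/3/5) with max-over-time
  pooling; last-HF loss.
- ``MLP``       — feed-forward net on the last event only (event view).
- ``LR``        — logistic regression (L1 or L2) on the last event,
  via scikit-learn; the convex baseline.

CRF-family training minimizes the negative conditional log-likelihood;
sequences are weighted by the class weight of their last-event label.
All stochastic choices (init, shuffling, dropout, sampling) flow from
``ModelConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._autograd import Adam, SGD, Tensor, clip_grad_norm, glorot
from .crf import ChainPotentials, nll, nll_grad, readmission_marginal
from .objectives import LossSpec, aggregation_weights

logger = logging.getLogger(__name__)

FAMILIES = ("RNN", "RNNSS", "CRF_only", "NeuralCRF", "RNNCRF", "CNN",
            "CNN_Wide", "MLP", "LR")
_SEQ_LOSS_FAMILIES = ("RNN", "RNNSS")      # honour all four loss kinds
_CRF_FAMILIES = ("CRF_only", "NeuralCRF", "RNNCRF")
SS_SCHEDULES = ("linear", "exponential", "inverse_sigmoid")


class TrainingDivergedError(RuntimeError):
    pass


def ss_probability(schedule: str, k: int, *, rate: float = 0.05,
                   gamma: float = 0.98, c: float = 5.0,
                   eps_min: float = 0.0) -> float:
    """Scheduled-sampling probability of feeding the *true* label.

    ``linear``: max(eps_min, 1 - rate * k); ``exponential``: gamma**k
    with gamma in (0, 1); ``inverse_sigmoid``: c / (c + exp(k / c))
    with c >= 1 (starts at c / (c + 1), the standard form's offset).
    All schedules are non-increasing in k and start at 1 except the
    inverse sigmoid.
    """
    if k < 0:
        raise ValueError("step k must be >= 0")
    if schedule == "linear":
        if rate < 0:
            raise ValueError("linear decay rate must be >= 0")
        return max(eps_min, 1.0 - rate * k)
    if schedule == "exponential":
        if not 0.0 < gamma < 1.0:
            raise ValueError("exponential decay needs gamma in (0, 1)")
        return gamma ** k
    if schedule == "inverse_sigmoid":
        if c < 1.0:
            raise ValueError("inverse sigmoid needs c >= 1")
        return c / (c + np.exp(k / c))
    raise ValueError(f"unknown schedule {schedule!r}")


@dataclass
class ModelConfig:
    """Architecture + optimization settings for one model family."""

    family: str = "RNN"
    hidden_size: int = 32
    n_layers: int = 1
    cell: str = "gru"                   # or "lstm"
    loss: LossSpec = field(default_factory=LossSpec)
    lr: float = 0.1                     # step size eta
    epochs: int = 15
    batch_size: int = 64
    clip_norm: float = 5.0
    optimizer: str = "sgd"              # or "adam"
    momentum: float = 0.0
    ss_schedule: str = "linear"
    ss_rate: float = 0.05
    ss_gamma: float = 0.98
    ss_c: float = 5.0
    ss_eps_min: float = 0.0
    potential_variant: str = "unary"    # or "pairwise"
    cnn_channels: tuple = (8, 16)
    cnn_kernel_heights: tuple = (2, 3, 5)
    cnn_filters: int = 16
    fc_size: int = 32
    t_max: int = None                   # CNN padding length; data-driven
    lr_penalty: str = "l1"              # LR family only
    lr_C: float = 1.0                   # inverse regularization strength
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.lr <= 0:
            raise ValueError("step size eta must be > 0")
        if self.cell not in ("gru", "lstm"):
            raise ValueError("cell must be 'gru' or 'lstm'")
        if self.family == "RNNSS" and self.ss_schedule not in SS_SCHEDULES:
            raise ValueError(f"unknown ss schedule {self.ss_schedule!r}")
        if self.family in _CRF_FAMILIES and \
                self.potential_variant not in ("unary", "pairwise"):
            raise ValueError("potential_variant must be unary|pairwise")
        if self.family == "LR" and self.lr_penalty not in ("l1", "l2"):
            raise ValueError("LR penalty must be 'l1' or 'l2'")
        if self.family in ("CNN", "CNN_Wide", "MLP") and \
                self.loss.kind != "LastHF":
            raise ValueError(f"{self.family} supports the LastHF loss only")


# ----------------------------------------------------------------------
# internal helpers
# ----------------------------------------------------------------------


def _group_by_length(seqs):
    groups = {}
    for i, s in enumerate(seqs):
        groups.setdefault(s.T, []).append(i)
    return groups


def _batch_arrays(seqs, idx):
    X = np.stack([seqs[i].X for i in idx])              # B x T x d
    y = np.stack([seqs[i].labels for i in idx])         # B x T
    hf = np.stack([seqs[i].is_hf for i in idx])
    last = np.array([seqs[i].last_hf_index for i in idx])
    return X, y, hf, last


def _step_weight_matrix(y, hf, last, spec, cw):
    """(B, T) combined aggregation x class weights."""
    B, T = y.shape
    w = np.empty((B, T))
    for b in range(B):
        w[b] = aggregation_weights(hf[b], last[b], spec)
    if cw is not None:
        w = w * np.vectorize(cw.get)(y)
    return w


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _init_linear(rng, d_in, d_out, zero_rows=0):
    """Glorot-initialized linear layer.

    ``zero_rows`` appends that many all-zero input rows *after* the
    random draw, so a model with extra feedback inputs starts from the
    exact same weights (and forward pass) as its feedback-free twin.
    """
    W = glorot(rng, d_in - zero_rows, d_out)
    if zero_rows:
        W = Tensor(np.vstack([W.data, np.zeros((zero_rows, d_out))]),
                   requires_grad=True)
    b = Tensor(np.zeros(d_out), requires_grad=True)
    return W, b


class _GRUCell:
    def __init__(self, rng, d_in, h, zero_rows=0):
        self.Wx, self.bz = _init_linear(rng, d_in, 3 * h, zero_rows)
        self.Wh = glorot(rng, h, 3 * h)
        self.h = h

    def params(self):
        return [self.Wx, self.Wh, self.bz]

    def weights(self):
        return [self.Wx, self.Wh]

    def step(self, x, h):
        gx = x @ self.Wx + self.bz
        gh = h @ self.Wh
        n = self.h
        z = (gx[:, 0:n] + gh[:, 0:n]).sigmoid()
        r = (gx[:, n:2 * n] + gh[:, n:2 * n]).sigmoid()
        hh = (gx[:, 2 * n:] + r * gh[:, 2 * n:]).tanh()
        return (1.0 - z) * h + z * hh


class _LSTMCell:
    def __init__(self, rng, d_in, h, zero_rows=0):
        self.Wx, self.b = _init_linear(rng, d_in, 4 * h, zero_rows)
        self.Wh = glorot(rng, h, 4 * h)
        self.h = h

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def weights(self):
        return [self.Wx, self.Wh]

    def step(self, x, state):
        h, c = state
        g = x @ self.Wx + h @ self.Wh + self.b
        n = self.h
        i = g[:, 0:n].sigmoid()
        f = g[:, n:2 * n].sigmoid()
        o = g[:, 2 * n:3 * n].sigmoid()
        u = g[:, 3 * n:].tanh()
        c = f * c + i * u
        return o * c.tanh(), c


# ----------------------------------------------------------------------
# results object
# ----------------------------------------------------------------------


@dataclass
class ReadmissionResults:
    """Fitted model: parameters, history and prediction interface."""

    config: ModelConfig
    params: dict
    history: pd.DataFrame
    best_epoch: int
    untrained: bool = False
    feature_names: list = None
    input_dim: int = None
    t_max_resolved: int = None
    _predict_fn: callable = None
    _sk_model: object = None

    def predict_proba(self, seqs) -> np.ndarray:
        """p(y_T = 1 | timeline) for each encoded sequence."""
        p = self._predict_fn(seqs)
        if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise RuntimeError("predictions escaped [0, 1]")
        return p

    @property
    def coef_(self):
        """LR coefficients (named), for the importance module."""
        if self._sk_model is None:
            raise AttributeError("coefficients exposed for the LR family")
        return self._sk_model.coef_.ravel()

    def summary(self) -> str:
        lines = [
            "Readmission model results",
            "=" * 40,
            f"family:        {self.config.family}",
            f"loss:          {self.config.loss.kind}"
            + (f" (alpha={self.config.loss.alpha})"
               if self.config.loss.alpha is not None else ""),
            f"n parameters:  {sum(p.data.size for p in self.params.values()) if self.params else 'n/a'}",
            f"best epoch:    {self.best_epoch}",
        ]
        if len(self.history):
            last = self.history.iloc[self.best_epoch]
            lines.append(f"train loss:    {last['train_loss']:.4f}")
            if np.isfinite(last["valid_auc"]):
                lines.append(f"valid AUC:     {last['valid_auc']:.4f}")
        if self.untrained:
            lines.append("WARNING: zero training epochs requested; "
                         "parameters are at initialization")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# the model front-end
# ----------------------------------------------------------------------


class ReadmissionModel:
    """Configured, unfitted readmission model (any family)."""

    def __init__(self, config: ModelConfig):
        self.config = config

    # -- public API ----------------------------------------------------

    def fit(self, train, valid=None, class_weight=None) -> ReadmissionResults:
        """Gradient-based training with best-epoch selection.

        ``train``/``valid`` are lists of EncodedSequences sharing a
        schema.  When a validation set is given, the epoch checkpoint
        with the best validation AUC is returned; otherwise the final
        epoch.  Deterministic given ``config.seed``.
        """
        cfg = self.config
        if not train:
            raise ValueError("empty training set")
        if len({s.labels[s.last_hf_index] for s in train}) < 2:
            raise ValueError("training set must contain both classes")
        if cfg.family == "LR":
            return self._fit_lr(train, valid, class_weight)
        return self._fit_neural(train, valid, class_weight)

    # -- LR ------------------------------------------------------------

    @staticmethod
    def _event_matrix(seqs):
        return np.stack([s.X[s.last_hf_index] for s in seqs])

    def _fit_lr(self, train, valid, class_weight):
        cfg = self.config
        X = self._event_matrix(train)
        y = np.array([s.last_label for s in train])
        sk = LogisticRegression(
            l1_ratio=1.0 if cfg.lr_penalty == "l1" else 0.0,
            C=cfg.lr_C, solver="liblinear",
            class_weight=class_weight, tol=1e-6, max_iter=2000,
            random_state=cfg.seed)
        sk.fit(X, y)
        if sk.n_iter_[0] >= 2000:
            logger.warning("LR did not converge within the iteration "
                           "cap; returning the best iterate")

        def predict(seqs):
            return sk.predict_proba(self._event_matrix(seqs))[:, 1]

        hist = pd.DataFrame({"train_loss": [np.nan],
                             "valid_auc": [np.nan]})
        return ReadmissionResults(config=cfg, params={}, history=hist,
                                  best_epoch=0, input_dim=X.shape[1],
                                  _predict_fn=predict, _sk_model=sk)

    # -- neural families -----------------------------------------------

    def _fit_neural(self, train, valid, class_weight):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        d = train[0].X.shape[1]
        t_max = cfg.t_max
        if cfg.family == "CNN" and t_max is None:
            t_max = max(4, max(s.T for s in train))
        elif cfg.family == "CNN_Wide" and t_max is None:
            t_max = max(max(cfg.cnn_kernel_heights),
                        max(s.T for s in train))
        params, loss_fn, predict_fn = self._build(d, rng, t_max)
        weights = [p for name, p in params.items()
                   if name.startswith("W")]
        opt = (Adam(params.values(), cfg.lr) if cfg.optimizer == "adam"
               else SGD(params.values(), cfg.lr, cfg.momentum))

        def full_predict(seqs):
            return predict_fn(params, seqs)

        history, best_auc, best_state = [], -np.inf, None
        n = len(train)
        order = np.arange(n)
        for epoch in range(cfg.epochs):
            rng.shuffle(order)
            eps = ss_probability(cfg.ss_schedule, epoch, rate=cfg.ss_rate,
                                 gamma=cfg.ss_gamma, c=cfg.ss_c,
                                 eps_min=cfg.ss_eps_min) \
                if cfg.family == "RNNSS" else 1.0
            ep_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss = loss_fn(params, [train[i] for i in idx],
                               class_weight, rng, eps)
                if cfg.loss.lam > 0:
                    pen = None
                    for w in weights:
                        term = (w ** 2).sum()
                        pen = term if pen is None else pen + term
                    loss = loss + pen * (0.5 * cfg.loss.lam)
                val = float(loss.data)
                if not np.isfinite(val):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch} "
                        f"(eta={cfg.lr})")
                opt.zero_grad()
                loss.backward()
                if cfg.clip_norm:
                    clip_grad_norm(params.values(), cfg.clip_norm)
                opt.step()
                ep_loss += val
                n_batches += 1
            if not all(np.isfinite(p.data).all()
                       for p in params.values()):
                raise TrainingDivergedError(
                    f"non-finite parameters after epoch {epoch} "
                    f"(eta={cfg.lr})")
            auc_v = np.nan
            if valid:
                pv = full_predict(valid)
                if not np.all(np.isfinite(pv)):
                    raise TrainingDivergedError(
                        f"non-finite validation predictions at epoch "
                        f"{epoch} (eta={cfg.lr})")
                auc_v = _safe_auc(
                    np.array([s.last_label for s in valid]), pv)
            history.append({"train_loss": ep_loss / max(n_batches, 1),
                            "valid_auc": auc_v})
            if valid and np.isfinite(auc_v) and auc_v > best_auc:
                best_auc = auc_v
                best_state = {k: p.data.copy() for k, p in params.items()}
        best_epoch = cfg.epochs - 1 if cfg.epochs else 0
        if best_state is not None:
            aucs = [h["valid_auc"] for h in history]
            best_epoch = int(np.nanargmax(aucs))
            for k, p in params.items():
                p.data = best_state[k]
        hist = pd.DataFrame(history,
                            columns=["train_loss", "valid_auc"])
        return ReadmissionResults(
            config=cfg, params=params, history=hist,
            best_epoch=best_epoch, untrained=cfg.epochs == 0,
            input_dim=d, t_max_resolved=t_max,
            _predict_fn=full_predict)

    # -- family wiring -------------------------------------------------

    def _build(self, d, rng, t_max):
        fam = self.config.family
        if fam == "MLP":
            return self._build_mlp(d, rng)
        if fam in ("RNN", "RNNSS"):
            return self._build_rnn(d, rng, feedback=(fam == "RNNSS"))
        if fam in _CRF_FAMILIES:
            return self._build_crf(d, rng)
        if fam == "CNN":
            return self._build_cnn(d, rng, t_max)
        if fam == "CNN_Wide":
            return self._build_cnn_wide(d, rng, t_max)
        raise AssertionError(fam)

    # .. MLP ...........................................................

    def _build_mlp(self, d, rng):
        cfg = self.config
        params = {}
        sizes = [d] + [cfg.hidden_size] * cfg.n_layers
        for i, (a, b) in enumerate(zip(sizes, sizes[1:])):
            params[f"W{i}"], params[f"b{i}"] = _init_linear(rng, a, b)
        params["Wout"], params["bout"] = _init_linear(rng, sizes[-1], 2)

        def forward(params, X, drop_rng=None):
            h = Tensor(X)
            for i in range(cfg.n_layers):
                h = (h @ params[f"W{i}"] + params[f"b{i}"]).tanh()
                if drop_rng is not None and cfg.loss.p_dropout > 0:
                    h = h.dropout(cfg.loss.p_dropout, drop_rng)
            return h @ params["Wout"] + params["bout"]

        def loss_fn(params, batch, cw, rng, eps):
            X = self._event_matrix(batch)
            y = np.array([s.last_label for s in batch])
            logits = forward(params, X, drop_rng=rng)
            logp = logits.log_softmax()
            w = np.ones(len(y)) if cw is None \
                else np.array([cw[int(v)] for v in y])
            sel = logp[np.arange(len(y)), y]
            return (sel * Tensor(-w)).sum() * (1.0 / len(y))

        def predict(params, seqs):
            logits = forward(params, self._event_matrix(seqs))
            return _softmax(logits.data)[:, 1]

        return params, loss_fn, predict

    # .. RNN / RNNSS ...................................................

    def _build_rnn(self, d, rng, feedback: bool):
        cfg = self.config
        d_in = d + (2 if feedback else 0)
        Cell = _GRUCell if cfg.cell == "gru" else _LSTMCell
        cell = Cell(rng, d_in, cfg.hidden_size,
                    zero_rows=2 if feedback else 0)
        params = {"Wx_cell": cell.Wx, "Wh_cell": cell.Wh,
                  "b_cell": cell.params()[-1]}
        params["Wout"], params["bout"] = _init_linear(
            rng, cfg.hidden_size, 2)

        def init_state(B):
            h = Tensor(np.zeros((B, cfg.hidden_size)))
            if cfg.cell == "lstm":
                return h, Tensor(np.zeros((B, cfg.hidden_size)))
            return h

        def unroll(params, X, y=None, eps=1.0, samp_rng=None,
                   drop_rng=None):
            """Returns the list of per-step logits tensors."""
            B, T, _ = X.shape
            state = init_state(B)
            prev_label = np.full((B, 2), 0.5)       # neutral start token
            logits_steps = []
            for t in range(T):
                x_np = X[:, t, :]
                if feedback:
                    x_np = np.concatenate([x_np, prev_label], axis=1)
                x = Tensor(x_np)
                state = cell.step(x, state)
                h = state[0] if cfg.cell == "lstm" else state
                hd = h
                if drop_rng is not None and cfg.loss.p_dropout > 0:
                    hd = hd.dropout(cfg.loss.p_dropout, drop_rng)
                logits = hd @ params["Wout"] + params["bout"]
                logits_steps.append(logits)
                if feedback:
                    probs = _softmax(logits.data)
                    if y is not None and samp_rng is not None:
                        use_true = samp_rng.random(B) < eps
                        sampled = (samp_rng.random(B)
                                   < probs[:, 1]).astype(int)
                        lbl = np.where(use_true, y[:, t], sampled)
                    else:                            # decoding: greedy
                        lbl = probs.argmax(axis=1)
                    prev_label = np.eye(2)[lbl]
            return logits_steps

        def loss_fn(params, batch, cw, rng, eps):
            total, n = None, 0
            for T, idx in sorted(_group_by_length(batch).items()):
                X, y, hf, last = _batch_arrays(batch, idx)
                w = _step_weight_matrix(y, hf, last, cfg.loss, cw)
                logits_steps = unroll(params, X, y=y, eps=eps,
                                      samp_rng=rng, drop_rng=rng)
                B = len(idx)
                for t, logits in enumerate(logits_steps):
                    wt = w[:, t]
                    if not wt.any():
                        continue
                    logp = logits.log_softmax()
                    sel = logp[np.arange(B), y[:, t]]
                    term = (sel * Tensor(-wt)).sum()
                    total = term if total is None else total + term
                n += B
            return total * (1.0 / n)

        def predict(params, seqs):
            out = np.empty(len(seqs))
            for T, idx in sorted(_group_by_length(seqs).items()):
                X = np.stack([seqs[i].X for i in idx])
                logits_steps = unroll(params, X)
                p = _softmax(logits_steps[-1].data)[:, 1]
                out[np.array(idx)] = p
            return out

        return params, loss_fn, predict

    # .. CRF families ..................................................

    def _build_crf(self, d, rng):
        cfg = self.config
        fam = cfg.family
        variant = cfg.potential_variant
        params = {}
        h = cfg.hidden_size
        cell = None
        if fam == "RNNCRF":
            Cell = _GRUCell if cfg.cell == "gru" else _LSTMCell
            cell = Cell(rng, d, h)
            params.update({"Wx_cell": cell.Wx, "Wh_cell": cell.Wh,
                           "b_cell": cell.params()[-1]})
            feat_dim = h
        elif fam == "NeuralCRF":
            params["Wfeat"], params["bfeat"] = _init_linear(rng, d, h)
            feat_dim = h
        else:
            feat_dim = d
        params["Wu"], params["bu"] = _init_linear(rng, feat_dim, 2)
        if variant == "unary":
            params["WA"] = Tensor(np.zeros((2, 2)), requires_grad=True)
        else:
            params["Wp"], params["bp"] = _init_linear(rng, feat_dim, 4)

        def features(params, X, drop_rng=None):
            """B x T x feat_dim tensor of per-step features."""
            B, T, _ = X.shape
            if fam == "RNNCRF":
                state = (Tensor(np.zeros((B, h))) if cfg.cell == "gru"
                         else (Tensor(np.zeros((B, h))),
                               Tensor(np.zeros((B, h)))))
                outs = []
                for t in range(T):
                    state = cell.step(Tensor(X[:, t, :]), state)
                    outs.append(state[0] if cfg.cell == "lstm" else state)
                z = Tensor.concat([o.reshape(B, 1, hdim)
                                   for o, hdim in
                                   zip(outs, [h] * T)], axis=1)
            elif fam == "NeuralCRF":
                z = (Tensor(X.reshape(B * T, d)) @ params["Wfeat"]
                     + params["bfeat"]).tanh().reshape(B, T, h)
            else:
                z = Tensor(X)
            if drop_rng is not None and cfg.loss.p_dropout > 0 \
                    and fam != "CRF_only":
                z = z.dropout(cfg.loss.p_dropout, drop_rng)
            return z

        def potentials_np(params, X):
            """Numpy potentials for decoding (no gradients)."""
            z = features(params, X).data
            B, T, _ = z.shape
            unary = z @ params["Wu"].data + params["bu"].data
            if variant == "unary":
                pair = params["WA"].data
                return [ChainPotentials(unary[b], pair, "unary")
                        for b in range(B)]
            pair = (z @ params["Wp"].data
                    + params["bp"].data).reshape(B, T, 2, 2)
            return [ChainPotentials(unary[b], pair[b], "pairwise")
                    for b in range(B)]

        def loss_fn(params, batch, cw, rng, eps):
            total, n = None, 0
            for T, idx in sorted(_group_by_length(batch).items()):
                X, y, hf, last = _batch_arrays(batch, idx)
                B = len(idx)
                z = features(params, X, drop_rng=rng)
                fdim = z.shape[2]
                zf = z.reshape(B * T, fdim)
                unary = (zf @ params["Wu"] + params["bu"]).reshape(B, T, 2)
                if variant == "unary":
                    pair = params["WA"]
                else:
                    pair = (zf @ params["Wp"]
                            + params["bp"]).reshape(B, T, 2, 2)
                w = (np.ones(B) if cw is None else
                     np.array([cw[int(y[b, last[b]])] for b in range(B)]))
                term = _crf_nll_batch(unary, pair, y, variant, w)
                total = term if total is None else total + term
                n += B
            return total * (1.0 / n)

        def predict(params, seqs):
            out = np.empty(len(seqs))
            for T, idx in sorted(_group_by_length(seqs).items()):
                X = np.stack([seqs[i].X for i in idx])
                pots = potentials_np(params, X)
                out[np.array(idx)] = [readmission_marginal(p)
                                      for p in pots]
            return out

        return params, loss_fn, predict

    # .. CNN ...........................................................

    def _pad_batch(self, seqs, t_max):
        return np.stack([s.padded(t_max)[0] for s in seqs])[:, None, :, :]

    def _build_cnn(self, d, rng, t_max):
        cfg = self.config
        c1, c2 = cfg.cnn_channels
        params = {}
        params["Wc1"] = glorot(rng, c1, 1, 3, 3)
        params["bc1"] = Tensor(np.zeros(c1), requires_grad=True)
        params["Wc2"] = glorot(rng, c2, c1, 3, 3)
        params["bc2"] = Tensor(np.zeros(c2), requires_grad=True)
        oh = (t_max // 2) // 2
        ow = (d // 2) // 2
        flat = c2 * max(oh, 1) * max(ow, 1)
        params["Wfc"], params["bfc"] = _init_linear(rng, flat, cfg.fc_size)
        params["Wout"], params["bout"] = _init_linear(rng, cfg.fc_size, 2)

        def forward(params, Xp, drop_rng=None):
            h = Tensor(Xp)
            h = h.conv2d(params["Wc1"], params["bc1"], padding=1).relu()
            h = h.maxpool2d(2)
            h = h.conv2d(params["Wc2"], params["bc2"], padding=1).relu()
            h = h.maxpool2d(2)
            B = Xp.shape[0]
            h = h.reshape(B, -1)
            h = (h @ params["Wfc"] + params["bfc"]).relu()
            if drop_rng is not None and cfg.loss.p_dropout > 0:
                h = h.dropout(cfg.loss.p_dropout, drop_rng)
            return h @ params["Wout"] + params["bout"]

        return self._last_event_wiring(params, forward, t_max)

    def _build_cnn_wide(self, d, rng, t_max):
        cfg = self.config
        params = {}
        for k in cfg.cnn_kernel_heights:
            params[f"Wk{k}"] = glorot(rng, cfg.cnn_filters, 1, k, d)
            params[f"bk{k}"] = Tensor(np.zeros(cfg.cnn_filters),
                                      requires_grad=True)
        concat_dim = cfg.cnn_filters * len(cfg.cnn_kernel_heights)
        params["Wfc"], params["bfc"] = _init_linear(rng, concat_dim,
                                                    cfg.fc_size)
        params["Wout"], params["bout"] = _init_linear(rng, cfg.fc_size, 2)

        def forward(params, Xp, drop_rng=None):
            B = Xp.shape[0]
            pieces = []
            for k in cfg.cnn_kernel_heights:
                fm = Tensor(Xp).conv2d(params[f"Wk{k}"],
                                       params[f"bk{k}"]).relu()
                # fm: B x filters x (T-k+1) x 1 -> max over time
                fm = fm.reshape(B, cfg.cnn_filters, -1)
                pieces.append(fm.max_over_axis(2))
            h = Tensor.concat(pieces, axis=1)
            h = (h @ params["Wfc"] + params["bfc"]).relu()
            if drop_rng is not None and cfg.loss.p_dropout > 0:
                h = h.dropout(cfg.loss.p_dropout, drop_rng)
            return h @ params["Wout"] + params["bout"]

        return self._last_event_wiring(params, forward, t_max)

    def _last_event_wiring(self, params, forward, t_max):
        """Loss/predict plumbing shared by the CNN families (LastHF)."""
        def loss_fn(params, batch, cw, rng, eps):
            Xp = self._pad_batch(batch, t_max)
            y = np.array([s.last_label for s in batch])
            logits = forward(params, Xp, drop_rng=rng)
            logp = logits.log_softmax()
            w = np.ones(len(y)) if cw is None \
                else np.array([cw[int(v)] for v in y])
            sel = logp[np.arange(len(y)), y]
            return (sel * Tensor(-w)).sum() * (1.0 / len(y))

        def predict(params, seqs):
            out = np.empty(len(seqs))
            bs = 256
            for s0 in range(0, len(seqs), bs):
                chunk = seqs[s0:s0 + bs]
                logits = forward(params, self._pad_batch(chunk, t_max))
                out[s0:s0 + len(chunk)] = _softmax(logits.data)[:, 1]
            return out

        return params, loss_fn, predict


# ----------------------------------------------------------------------
# batched CRF NLL autodiff node
# ----------------------------------------------------------------------


def _crf_nll_batch(unary: Tensor, pairwise: Tensor, y, variant,
                   seq_weights) -> Tensor:
    """Sum of per-sequence weighted CRF NLLs as one autodiff node.

    ``unary`` is B x T x 2; ``pairwise`` is a shared 2 x 2 transition
    matrix (``unary`` variant) or B x T x 2 x 2 (``pairwise``
    variant).  Backward injects the analytic gradients.
    """
    B, T, _ = unary.shape
    shared = pairwise.data.ndim == 2
    pots, value = [], 0.0
    for b in range(B):
        pw = pairwise.data if shared else pairwise.data[b]
        p = ChainPotentials(unary.data[b], pw, variant)
        pots.append(p)
        value += seq_weights[b] * nll(p, y[b])
    out = Tensor(value, requires_grad=True, _parents=tuple(
        t for t in (unary, pairwise) if t.requires_grad))

    def bw(g):
        g = float(g)
        gu = np.zeros_like(unary.data)
        gp = np.zeros_like(pairwise.data)
        for b in range(B):
            du, dp = nll_grad(pots[b], y[b])
            gu[b] = seq_weights[b] * du
            if shared:
                gp += seq_weights[b] * dp
            else:
                gp[b] = seq_weights[b] * dp
        if unary.requires_grad:
            unary._accum(g * gu)
        if pairwise.requires_grad:
            pairwise._accum(g * gp)

    out._backward = bw
    return out


def _safe_auc(y, p):
    from sklearn.metrics import roc_auc_score
    if len(np.unique(y)) < 2:
        return np.nan
    return roc_auc_score(y, p)


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------


def save_results(results: ReadmissionResults, path) -> None:
    """Serialize a fitted model (parameters + config) to disk."""
    import pickle
    blob = {
        "config": results.config,
        "params": {k: p.data for k, p in results.params.items()},
        "history": results.history,
        "best_epoch": results.best_epoch,
        "untrained": results.untrained,
        "input_dim": results.input_dim,
        "t_max": results.t_max_resolved,
        "sk_model": results._sk_model,
    }
    with open(path, "wb") as fh:
        pickle.dump(blob, fh)


def load_results(path) -> ReadmissionResults:
    """Rebuild a fitted model saved by :func:`save_results`."""
    import pickle
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    cfg = blob["config"]
    model = ReadmissionModel(cfg)
    if cfg.family == "LR":
        sk = blob["sk_model"]

        def predict(seqs):
            return sk.predict_proba(
                ReadmissionModel._event_matrix(seqs))[:, 1]

        return ReadmissionResults(
            config=cfg, params={}, history=blob["history"],
            best_epoch=blob["best_epoch"], untrained=blob["untrained"],
            input_dim=blob["input_dim"], _predict_fn=predict,
            _sk_model=sk)
    rng = np.random.default_rng(cfg.seed)
    params, _, predict_fn = model._build(blob["input_dim"], rng,
                                         blob["t_max"])
    for k, arr in blob["params"].items():
        params[k].data = arr

    def predict(seqs):
        return predict_fn(params, seqs)

    return ReadmissionResults(
        config=cfg, params=params, history=blob["history"],
        best_epoch=blob["best_epoch"], untrained=blob["untrained"],
        input_dim=blob["input_dim"], t_max_resolved=blob["t_max"],
        _predict_fn=predict)
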