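"""Feature encoding: ClaimEvents -> fixed-length numeric vectors.

Vocabularies and numeric statistics are learned from the *training*
fold only; every categorical block carries an explicit UNK slot for
codes unseen at fit time.  Code sets are multi-hot, single categories
one-hot, numerics z-scored.  Timeline-summary features (prior-event
and prior-HF counts) are appended only when ``summary_features`` is
on — the switch that gives event-view models (MLP, LR) access to
history without changing the sequence models' inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .timelines import PatientTimeline

logger = logging.getLogger(__name__)

UNK = "<UNK>"


class SchemaContractError(ValueError):
    pass


def _vocab(values) -> list:
    return sorted(set(values)) + [UNK]


def _numeric_stats(values) -> tuple:
    # math.fsum keeps the statistics exactly invariant to patient order
    import math
    arr = np.asarray(values, dtype=float)
    mean = math.fsum(arr) / len(arr)
    sd = math.sqrt(max(math.fsum((arr - mean) ** 2) / len(arr), 0.0))
    if sd < 1e-12:
        logger.info("numeric feature constant in training data; "
                    "SD replaced by 1.0")
        sd = 1.0
    return mean, sd


@dataclass
class FeatureSchema:
    """Fitted feature dictionary; ``dim`` is frozen after fit."""

    dx_vocab: list
    proc_vocab: list
    com_vocab: list
    sex_vocab: list
    pay_vocab: list
    numeric_stats: dict                 # name -> (mean, sd)
    summary_features: bool = False
    summary_stats: dict = field(default_factory=dict)

    NUMERIC_FIELDS = ("age_years", "length_of_stay")
    SUMMARY_FIELDS = ("prior_events", "prior_hf_events")

    def __post_init__(self):
        self._dx_idx = {c: i for i, c in enumerate(self.dx_vocab)}
        self._proc_idx = {c: i for i, c in enumerate(self.proc_vocab)}
        self._com_idx = {c: i for i, c in enumerate(self.com_vocab)}
        self._sex_idx = {c: i for i, c in enumerate(self.sex_vocab)}
        self._pay_idx = {c: i for i, c in enumerate(self.pay_vocab)}
        names = []
        names += [f"primary_dx={c}" for c in self.dx_vocab]
        names += [f"secondary_dx={c}" for c in self.dx_vocab]
        names += [f"procedure={c}" for c in self.proc_vocab]
        names += [f"comorbidity={c}" for c in self.com_vocab]
        names += [f"sex={c}" for c in self.sex_vocab]
        names += [f"pay_source={c}" for c in self.pay_vocab]
        names += list(self.NUMERIC_FIELDS)
        if self.summary_features:
            names += list(self.SUMMARY_FIELDS)
        self.feature_names = names
        #: indices of binary (one-/multi-hot) features, for perturbation
        n_binary = (2 * len(self.dx_vocab) + len(self.proc_vocab)
                    + len(self.com_vocab) + len(self.sex_vocab)
                    + len(self.pay_vocab))
        self.binary_mask = np.zeros(len(names), dtype=bool)
        self.binary_mask[:n_binary] = True

    @property
    def dim(self) -> int:
        return len(self.feature_names)

    # -- encoding ------------------------------------------------------

    def _lookup(self, idx_map, code) -> int:
        return idx_map.get(code, idx_map[UNK])

    def encode_event(self, event, prior_events: int = 0,
                     prior_hf: int = 0) -> np.ndarray:
        x = np.zeros(self.dim)
        off = 0
        x[off + self._lookup(self._dx_idx, event.primary_dx)] = 1.0
        off += len(self.dx_vocab)
        for c in event.secondary_dx:
            x[off + self._lookup(self._dx_idx, c)] = 1.0
        off += len(self.dx_vocab)
        for c in event.procedures:
            x[off + self._lookup(self._proc_idx, c)] = 1.0
        off += len(self.proc_vocab)
        for c in event.comorbidities:
            x[off + self._lookup(self._com_idx, c)] = 1.0
        off += len(self.com_vocab)
        x[off + self._lookup(self._sex_idx, event.sex)] = 1.0
        off += len(self.sex_vocab)
        x[off + self._lookup(self._pay_idx, event.pay_source)] = 1.0
        off += len(self.pay_vocab)
        for name in self.NUMERIC_FIELDS:
            mean, sd = self.numeric_stats[name]
            x[off] = (getattr(event, name) - mean) / sd
            off += 1
        if self.summary_features:
            for name, val in zip(self.SUMMARY_FIELDS,
                                 (prior_events, prior_hf)):
                mean, sd = self.summary_stats[name]
                x[off] = (val - mean) / sd
                off += 1
        return x

    # -- persistence ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "dx_vocab": self.dx_vocab, "proc_vocab": self.proc_vocab,
            "com_vocab": self.com_vocab, "sex_vocab": self.sex_vocab,
            "pay_vocab": self.pay_vocab,
            "numeric_stats": self.numeric_stats,
            "summary_features": self.summary_features,
            "summary_stats": self.summary_stats})

    @classmethod
    def from_json(cls, s: str) -> "FeatureSchema":
        d = json.loads(s)
        d["numeric_stats"] = {k: tuple(v)
                              for k, v in d["numeric_stats"].items()}
        d["summary_stats"] = {k: tuple(v)
                              for k, v in d["summary_stats"].items()}
        return cls(**d)


def fit_schema(timelines, summary_features: bool = False) -> FeatureSchema:
    """Learn vocabularies and numeric statistics from training timelines.

    Vocabulary slots are ordered lexicographically (deterministic and
    order-independent in the input).
    """
    if not timelines:
        raise ValueError("cannot fit a schema on an empty training split")
    dx, proc, com, sex, pay = set(), set(), set(), set(), set()
    numerics = {n: [] for n in FeatureSchema.NUMERIC_FIELDS}
    summaries = {n: [] for n in FeatureSchema.SUMMARY_FIELDS}
    for tl in timelines:
        n_hf = 0
        for t, e in enumerate(tl.events):
            dx.add(e.primary_dx)
            dx.update(e.secondary_dx)
            proc.update(e.procedures)
            com.update(e.comorbidities)
            sex.add(e.sex)
            pay.add(e.pay_source)
            for n in FeatureSchema.NUMERIC_FIELDS:
                numerics[n].append(getattr(e, n))
            summaries["prior_events"].append(t)
            summaries["prior_hf_events"].append(n_hf)
            n_hf += int(e.is_hf)
    return FeatureSchema(
        dx_vocab=_vocab(dx), proc_vocab=_vocab(proc), com_vocab=_vocab(com),
        sex_vocab=_vocab(sex), pay_vocab=_vocab(pay),
        numeric_stats={n: _numeric_stats(v) for n, v in numerics.items()},
        summary_features=summary_features,
        summary_stats={n: _numeric_stats(v) for n, v in summaries.items()})


@dataclass
class EncodedSequence:
    """T x d matrix plus labels, HF flags and padding mask.

    ``padded(t_max)`` returns the zero-padded T_max x d matrix used by
    the CNN families; rows beyond T are zero and masked out.
    """

    patient_id: str
    X: np.ndarray                       # T x d
    labels: np.ndarray                  # T
    is_hf: np.ndarray                   # T bool
    last_hf_index: int

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def last_label(self) -> int:
        return int(self.labels[self.last_hf_index])

    def padded(self, t_max: int):
        """Right-aligned zero padding to t_max rows, plus the mask."""
        if self.T >= t_max:
            return self.X[-t_max:], np.ones(t_max, dtype=bool)
        pad = np.zeros((t_max - self.T, self.X.shape[1]))
        mask = np.concatenate([np.ones(self.T, dtype=bool),
                               np.zeros(t_max - self.T, dtype=bool)])
        return np.vstack([self.X, pad]), mask


def encode_timeline(tl: PatientTimeline, schema: FeatureSchema,
                    t_max: int = None) -> EncodedSequence:
    """Encode a timeline; keeps the *most recent* t_max events.

    The final event must be the HF index event (the prediction
    target); anything else is a contract violation.
    """
    if not tl.is_hf[tl.last_hf_index] or tl.last_hf_index != len(tl) - 1:
        raise SchemaContractError("timeline must end at its last HF event")
    start = 0
    if t_max is not None and len(tl) > t_max:
        start = len(tl) - t_max
    rows, n_hf = [], 0
    for t, e in enumerate(tl.events):
        if t >= start:
            rows.append(schema.encode_event(e, prior_events=t,
                                            prior_hf=n_hf))
        n_hf += int(e.is_hf)
    X = np.vstack(rows)
    labels = tl.labels[start:]
    is_hf = tl.is_hf[start:]
    return EncodedSequence(patient_id=tl.patient_id, X=X,
                           labels=np.asarray(labels, dtype=int),
                           is_hf=np.asarray(is_hf, dtype=bool),
                           last_hf_index=len(rows) - 1)


def default_t_max(timelines, cap: int = 20) -> int:
    """95th percentile of training timeline lengths, capped."""
    lengths = np.array([len(tl) for tl in timelines])
    return int(min(max(np.percentile(lengths, 95), 1), cap))


def encode_cohort(timelines, schema: FeatureSchema,
                  t_max: int = None) -> list:
    return [encode_timeline(tl, schema, t_max) for tl in timelines]


def class_weights(labels) -> dict:
    """Inverse-class-frequency weights: w_c = N / (|classes| * N_c).

    The weighted class-frequency average is 1 by construction.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present to weight")
    n = len(labels)
    return {int(c): n / (len(classes) * cnt)
            for c, cnt in zip(classes, counts)}
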