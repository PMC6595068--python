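"""Study orchestration: hyperparameter random search and the full
simulate -> label -> encode -> cross-validate pipeline.

Seeding: one master seed; every stage derives its own stream by
stable hashing of (master, stage name, fold id), so re-running a study
config reproduces every artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import class_weights, encode_cohort, fit_schema
from .evaluation import evaluate_model_cv, make_folds
from .models import ModelConfig, ReadmissionModel
from .simulate import SimConfig, generate_claims, read_claims, write_claims
from .timelines import build_timelines, cohort_summary

logger = logging.getLogger(__name__)


def derive_seed(master: int, *parts) -> int:
    """Stable sub-seed from (master, stage name, fold id, ...)."""
    key = ":".join(str(p) for p in (master,) + parts)
    return zlib.crc32(key.encode()) % (2 ** 31)


class AllTrialsDivergedError(RuntimeError):
    pass


def sample_config(space: dict, base: ModelConfig,
                  rng: np.random.Generator) -> ModelConfig:
    """Uniform draw from a discrete hyperparameter space.

    ``space`` maps ModelConfig field names (or ``loss.<field>``) to
    candidate lists.
    """
    updates, loss_updates = {}, {}
    for key in sorted(space):
        val = space[key][int(rng.integers(0, len(space[key])))]
        if key.startswith("loss."):
            loss_updates[key.split(".", 1)[1]] = val
        else:
            updates[key] = val
    if loss_updates:
        updates["loss"] = dataclasses.replace(base.loss, **loss_updates)
    return replace(base, **updates)


def random_search(space: dict, budget: int, train, valid,
                  base_config: ModelConfig, seed: int,
                  class_weight=None):
    """Uniform random hyperparameter search on one data split.

    Trains ``budget`` sampled configurations and returns
    ``(best_config, trials)`` where ``trials`` logs every draw and its
    validation AUC.  Raises if every trial diverges.
    """
    if budget < 1 or not space:
        raise ValueError("budget >= 1 and a non-empty space required")
    rng = np.random.default_rng(seed)
    from .evaluation import auc as _auc
    y_valid = [s.last_label for s in valid]
    trials = []
    best_cfg, best_auc = None, -np.inf
    for trial in range(budget):
        cfg = sample_config(space, base_config, rng)
        cfg = replace(cfg, seed=derive_seed(seed, "trial", trial))
        try:
            res = ReadmissionModel(cfg).fit(train, valid,
                                            class_weight=class_weight)
            a = _auc(res.predict_proba(valid), y_valid)
        except Exception as err:      # noqa: BLE001 - trial log captures it
            logger.warning("trial %d diverged: %s", trial, err)
            trials.append({"trial": trial, "valid_auc": np.nan,
                           "error": str(err), **_cfg_row(cfg)})
            continue
        trials.append({"trial": trial, "valid_auc": a, "error": "",
                       **_cfg_row(cfg)})
        if a > best_auc:
            best_cfg, best_auc = cfg, a
    trials = pd.DataFrame(trials)
    if best_cfg is None:
        raise AllTrialsDivergedError(
            f"all {budget} trials diverged:\n{trials}")
    return best_cfg, trials


def _cfg_row(cfg: ModelConfig) -> dict:
    return {"family": cfg.family, "hidden_size": cfg.hidden_size,
            "lr": cfg.lr, "loss_kind": cfg.loss.kind,
            "alpha": cfg.loss.alpha, "lam": cfg.loss.lam,
            "optimizer": cfg.optimizer}


def search_split(timelines, plan, frac: float = 0.3,
                 valid_frac: float = 0.1, seed: int = 0):
    """The search protocol's data: one randomly chosen fold, 30% of
    its training set, split 90/10 into search-train and search-valid."""
    rng = np.random.default_rng(seed)
    fold_id = int(rng.integers(0, plan.k))
    tr, _, _ = plan.folds[fold_id]
    sub = rng.choice(tr, size=max(int(frac * len(tr)), 20), replace=False)
    rng.shuffle(sub)
    n_valid = max(int(valid_frac * len(sub)), 5)
    return sub[n_valid:], sub[:n_valid], fold_id


@dataclass
class StudyConfig:
    """End-to-end study definition."""

    sim: SimConfig = field(default_factory=SimConfig)
    claims_path: str = None             # load instead of simulate
    model_configs: dict = field(default_factory=dict)  # name -> ModelConfig
    summary_families: tuple = ("MLP", "LR")   # get timeline summaries
    t_max: int = None
    k_folds: int = 5
    seed: int = 0
    search_space: dict = None
    search_budget: int = 20
    out_dir: str = None

    def __post_init__(self):
        if not self.model_configs:
            raise ValueError("run_study needs at least one model config")
        for name, cfg in self.model_configs.items():
            if not isinstance(cfg, ModelConfig):
                raise ValueError(f"model {name!r} is not a ModelConfig")


def run_study(study: StudyConfig) -> pd.DataFrame:
    """Simulate/load claims, build timelines, cross-validate every
    configured model, and return the comparison table.

    Writes claims, the cohort summary, per-model reports and the
    comparison table under ``out_dir`` when given.  Re-running the
    same config reproduces the table exactly.
    """
    out = Path(study.out_dir) if study.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    if study.claims_path:
        claims = read_claims(study.claims_path)
    else:
        sim = replace(study.sim, seed=derive_seed(study.seed, "simulate"))
        claims = generate_claims(sim)
        if out:
            write_claims(claims, out / "claims.csv")
    timelines = build_timelines(
        claims, window_days=study.sim.observation_window_days)
    if out:
        cohort_summary(timelines).to_csv(out / "cohort_summary.csv")
    labels = [tl.last_label for tl in timelines]
    plan = make_folds(labels, seed=derive_seed(study.seed, "folds"),
                      k=study.k_folds)

    rows = []
    for name, cfg in study.model_configs.items():
        cfg = replace(cfg, seed=derive_seed(study.seed, "train", name))
        summary = cfg.family in study.summary_families
        if study.search_space:
            s_tr, s_va, fold_id = search_split(
                timelines, plan,
                seed=derive_seed(study.seed, "search", name))
            schema = fit_schema([timelines[i] for i in s_tr],
                                summary_features=summary)
            enc_tr = encode_cohort([timelines[i] for i in s_tr], schema,
                                   study.t_max)
            enc_va = encode_cohort([timelines[i] for i in s_va], schema,
                                   study.t_max)
            cw = class_weights([s.last_label for s in enc_tr])
            cfg, trials = random_search(
                study.search_space, study.search_budget, enc_tr, enc_va,
                cfg, seed=derive_seed(study.seed, "searchrng", name),
                class_weight=cw)
            if out:
                trials.to_csv(out / f"search_{name}.csv", index=False)
        report = evaluate_model_cv(timelines, cfg, plan,
                                   summary_features=summary,
                                   t_max=study.t_max)
        if out:
            with open(out / f"report_{name}.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            report.scores.to_csv(out / f"scores_{name}.csv", index=False)
        rows.append({"model": name, "family": cfg.family,
                     "loss": cfg.loss.kind, "auc": report.cv_auc,
                     "ci_low": report.ci_low, "ci_high": report.ci_high,
                     "youden_cutoff": report.youden_mean,
                     "youden_sd": report.youden_sd})
        logger.info("model %s: AUC %.3f (%.3f-%.3f)", name,
                    report.cv_auc, report.ci_low, report.ci_high)
    table = pd.DataFrame(rows)
    if out:
        table.to_csv(out / "comparison.csv", index=False)
        with open(out / "study_config.json", "w") as fh:
            json.dump({"seed": study.seed,
                       "sim": dataclasses.asdict(study.sim)}, fh,
                      indent=2, default=str)
    return table
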