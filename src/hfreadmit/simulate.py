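"""Synthetic hospital-claims generator.

Emulates the statistical structure of an all-payer inpatient claims
cohort for heart-failure (HF) readmission studies: per-patient ordered
hospitalization events (mean timeline length ~1.9), ~67% of admissions
with HF (CCS code 108) as primary diagnosis, a ~23.6% 30-day all-cause
readmission rate among HF events, and a tunable dependence of the
readmission mechanism on timeline history.

The generative mechanism
------------------------
Each patient draws an event count K ~ 1 + Poisson(mean_events - 1).
After every event t a latent readmission indicator r_t is drawn from
Bernoulli(p_t) with

    logit(p_t) = logit(base_readmit_rate)
                 + beta_history * (z_prior_events + z_prior_readmits)
                 + beta_event . (age_z, los_z, comorb_z)

where the history features are standardized with *theoretical* moments
derived from the configuration (so the mechanism is identical across
cohort sizes).  r_t = 1 materializes the next admission with a short
gap (1..30 days after discharge); r_t = 0 with a long gap (31..75
days).  A final HF event with r = 1 materializes one non-HF
continuation admission inside 30 days, so the label that the timeline
module later computes equals r for every HF event: the labeled HF
readmission rate matches ``base_readmit_rate`` by construction when the
betas are zero.

Labels are never stored here: the timeline module is the single source
of truth for the 30-day labeling rule; this module records the drawn
mechanism (``truth`` frame) for test oracles only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import poisson

HF_CODE = "108"

#: Claims-table schema, in column order.  Code-set columns are
#: serialized as ";"-joined tokens (empty string = empty set).
CLAIMS_COLUMNS = [
    "patient_id", "admit_day", "discharge_day", "primary_dx",
    "secondary_dx", "procedures", "comorbidities", "age_years", "sex",
    "pay_source",
]
_SET_COLUMNS = ["secondary_dx", "procedures", "comorbidities"]

PAY_SOURCES = ["Medicare", "Private insurance", "Medicaid", "Self-pay",
               "Other", "No charge"]


class ClaimsSchemaError(ValueError):
    """A claims table violates the documented schema."""


@dataclass
class SimConfig:
    """Configuration of the synthetic claims cohort.

    Defaults target the study conditions of a US HF inpatient cohort:
    mean timeline length 1.9, 67% HF-primary admissions, 23.6% 30-day
    readmission rate among HF events, age 73 (SD 14), 49% female, and
    the all-payer pay-source mix dominated by Medicare.
    """

    n_patients: int = 1000
    mean_events: float = 1.9
    p_hf_primary: float = 0.67
    base_readmit_rate: float = 0.236
    beta_history: float = 0.0
    #: log-odds weights on (age_z, length_of_stay_z, comorbidity_count_z)
    beta_event: tuple = (0.0, 0.0, 0.0)
    n_dx_codes: int = 30
    n_proc_codes: int = 20
    n_comorbidities: int = 10
    age_mean: float = 73.0
    age_sd: float = 14.0
    p_female: float = 0.49
    pay_source_probs: tuple = (0.7643, 0.0923, 0.0919, 0.0255, 0.0231,
                               0.0029)
    mean_los: float = 5.0
    observation_window_days: int = 365
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not np.isfinite(self.beta_history) or self.beta_history < 0:
            raise ValueError("beta_history must be finite and >= 0")
        if not np.all(np.isfinite(self.beta_event)):
            raise ValueError("beta_event must be finite")
        if len(self.beta_event) != 3:
            raise ValueError("beta_event has 3 slots: (age, los, comorb)")
        for name in ("p_hf_primary", "base_readmit_rate", "p_female"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.base_readmit_rate in (0.0, 1.0):
            raise ValueError("base_readmit_rate must be strictly inside "
                             "(0, 1): the logit is undefined at 0 and 1")
        if abs(sum(self.pay_source_probs) - 1.0) > 1e-9:
            raise ValueError("pay_source_probs must sum to 1")
        if self.mean_events < 1.0:
            raise ValueError("mean_events must be >= 1")


def history_standardization(config: SimConfig) -> tuple:
    """Theoretical mean/SD of the two history features.

    Prior-event count: exact moments under K ~ 1 + Poisson(mean_events
    - 1), event-weighted (an event drawn uniformly from a random
    patient's timeline).  Prior-readmission count: compound-binomial
    approximation with per-event rate ``base_readmit_rate``.  Fixed by
    the config alone so the mechanism does not drift with cohort size.
    """
    lam = config.mean_events - 1.0
    ks = np.arange(0, 81)
    pmf = poisson.pmf(ks, lam)
    K = ks + 1.0                                # events per patient
    e_k = float((pmf * K).sum())
    # event-weighted moments of the 0-based index (= prior-event count)
    e_prior = float((pmf * K * (K - 1) / 2).sum()) / e_k
    e_prior2 = float((pmf * (K - 1) * K * (2 * K - 1) / 6).sum()) / e_k
    var_prior = max(e_prior2 - e_prior ** 2, 0.0)
    sd_prior = np.sqrt(var_prior) if var_prior > 1e-12 else 1.0

    p = config.base_readmit_rate
    mean_re = p * e_prior
    var_re = p * (1 - p) * e_prior + p ** 2 * var_prior
    sd_re = np.sqrt(var_re) if var_re > 1e-12 else 1.0
    return e_prior, sd_prior, mean_re, sd_re


def _event_z(age, los, n_comorb, config):
    age_z = (age - config.age_mean) / config.age_sd
    los_sd = max(np.sqrt(config.mean_los - 1.0), 1.0)   # 1 + Poisson
    los_z = (los - config.mean_los) / los_sd
    p_c = 0.25
    comorb_z = (n_comorb - p_c * config.n_comorbidities) / np.sqrt(
        config.n_comorbidities * p_c * (1 - p_c))
    return np.array([age_z, los_z, comorb_z])


def simulate_cohort(config: SimConfig):
    """Generate a claims table plus the ground-truth mechanism frame.

    Returns ``(claims, truth)``; ``truth`` has one row per generated
    event with the short-gap probability ``p_short``, the drawn
    indicator ``readmit_indicator``, the drawn gap (NaN for terminal
    events without a materialized successor) and a continuation flag.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return (pd.DataFrame(columns=CLAIMS_COLUMNS),
                pd.DataFrame(columns=["patient_id", "event_index",
                                      "p_short", "readmit_indicator",
                                      "gap", "is_continuation"]))

    dx_vocab = [str(c) for c in range(100, 100 + config.n_dx_codes)]
    nonhf_vocab = [c for c in dx_vocab if c != HF_CODE]
    proc_vocab = [f"p{c:02d}" for c in range(1, config.n_proc_codes + 1)]
    com_vocab = [f"c{c:02d}" for c in range(1, config.n_comorbidities + 1)]

    ages = np.clip(np.rint(rng.normal(config.age_mean, config.age_sd, n)),
                   18, 100).astype(int)
    sexes = np.where(rng.random(n) < config.p_female, "F", "M")
    pays = rng.choice(PAY_SOURCES, size=n, p=config.pay_source_probs)
    counts = 1 + rng.poisson(config.mean_events - 1.0, n)
    admit0 = rng.integers(0, 46, n)

    mu_pe, sd_pe, mu_re, sd_re = history_standardization(config)
    base_logit = logit(config.base_readmit_rate)
    beta_ev = np.asarray(config.beta_event, dtype=float)
    window_end = config.observation_window_days
    safe_end = window_end - 31
    pad = int(np.ceil(np.log10(max(n, 2))))

    rows, truth_rows = [], []
    for i in range(n):
        pid = f"P{i:0{pad}d}"
        age, sex, pay = int(ages[i]), sexes[i], pays[i]
        admit = int(admit0[i])
        k = int(counts[i])
        n_prior_re = 0
        t = 0
        while t < k:
            los = 1 + min(int(rng.poisson(config.mean_los - 1.0)), 20)
            discharge = admit + los
            is_hf = rng.random() < config.p_hf_primary
            primary = HF_CODE if is_hf else str(rng.choice(nonhf_vocab))
            n_sec = min(int(rng.poisson(2.0)), len(dx_vocab) - 1)
            secondary = tuple(sorted(rng.choice(
                [c for c in dx_vocab if c != primary], size=n_sec,
                replace=False))) if n_sec else ()
            n_proc = min(int(rng.poisson(1.5)), len(proc_vocab))
            procs = tuple(sorted(rng.choice(proc_vocab, size=n_proc,
                                            replace=False))) if n_proc else ()
            com_mask = rng.random(len(com_vocab)) < 0.25
            coms = tuple(c for c, m in zip(com_vocab, com_mask) if m)

            z_hist = ((t - mu_pe) / sd_pe + (n_prior_re - mu_re) / sd_re)
            xz = _event_z(age, los, len(coms), config)
            p_short = float(expit(base_logit
                                  + config.beta_history * z_hist
                                  + beta_ev @ xz))
            r = int(rng.random() < p_short)

            rows.append((pid, admit, discharge, primary, secondary,
                         procs, coms, age, sex, pay))

            terminal = t == k - 1
            gap = np.nan
            if not terminal:
                if r:
                    gap = int(1 + rng.integers(0, 30))          # 1..30
                else:
                    gap = int(31 + rng.integers(0, 45))         # 31..75
                    if discharge + gap > safe_end:
                        gap = 31
                        if discharge + gap > safe_end:
                            # no room for a long-gap successor: the
                            # sequence ends here with r = 0
                            terminal, k, gap = True, t + 1, np.nan
            truth_rows.append((pid, t, p_short, r, gap, False))

            if terminal:
                if r and is_hf:
                    # materialize the readmission that makes the final
                    # HF label observable; all-cause, non-HF primary
                    cgap = int(1 + rng.integers(0, 30))
                    truth_rows[-1] = (pid, t, p_short, r, cgap, False)
                    cadmit = discharge + cgap
                    clos = 1 + min(int(rng.poisson(config.mean_los - 1.0)),
                                   20)
                    csec_n = min(int(rng.poisson(2.0)), len(dx_vocab) - 1)
                    cprimary = str(rng.choice(nonhf_vocab))
                    csec = tuple(sorted(rng.choice(
                        [c for c in dx_vocab if c != cprimary],
                        size=csec_n, replace=False))) if csec_n else ()
                    rows.append((pid, cadmit, cadmit + clos, cprimary,
                                 csec, (), coms, age, sex, pay))
                    truth_rows.append((pid, t + 1, np.nan, np.nan,
                                       np.nan, True))
                break
            admit = discharge + gap
            n_prior_re += r
            t += 1

    claims = pd.DataFrame(rows, columns=CLAIMS_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=[
        "patient_id", "event_index", "p_short", "readmit_indicator",
        "gap", "is_continuation"])
    return claims, truth


def generate_claims(config: SimConfig) -> pd.DataFrame:
    """Generate a synthetic claims table (see :func:`simulate_cohort`)."""
    claims, _ = simulate_cohort(config)
    return claims


# -- I/O ---------------------------------------------------------------


def _serialize_sets(claims: pd.DataFrame) -> pd.DataFrame:
    out = claims.copy()
    for col in _SET_COLUMNS:
        out[col] = out[col].map(lambda s: ";".join(s))
    return out


def write_claims(claims: pd.DataFrame, path) -> None:
    """Write a claims table to CSV; code sets become ";"-joined tokens."""
    missing = [c for c in CLAIMS_COLUMNS if c not in claims.columns]
    if missing:
        raise ClaimsSchemaError(f"missing column(s): {', '.join(missing)}")
    _serialize_sets(claims[CLAIMS_COLUMNS]).to_csv(path, index=False)


def read_claims(path) -> pd.DataFrame:
    """Read a claims CSV, validating schema, day offsets and stay order."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLAIMS_COLUMNS if c not in raw.columns]
    if missing:
        raise ClaimsSchemaError(f"missing column(s): {', '.join(missing)}")
    out = raw[CLAIMS_COLUMNS].copy()
    for col in ("admit_day", "discharge_day", "age_years"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise ClaimsSchemaError(
                f"malformed integer in column '{col}' at row {row}: "
                f"{out[col].iloc[row]!r}")
        out[col] = vals.astype(int)
    bad = out["discharge_day"] < out["admit_day"]
    if bad.any():
        offending = [int(v) for v in np.flatnonzero(bad.values)[:10]]
        raise ClaimsSchemaError(
            f"discharge_day < admit_day at row(s) {offending}")
    for col in _SET_COLUMNS:
        out[col] = out[col].map(
            lambda s: tuple(s.split(";")) if s else ())
    return out


def claims_roundtrip_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """True if two claims tables are identical (including code sets)."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    return _serialize_sets(a).equals(_serialize_sets(b))
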