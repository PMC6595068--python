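"""Feature-importance analyses.

Three complementary views: normalized LASSO coefficients (averaged
across folds), perturbation importance for any fitted model (toggle a
binary feature of the last HF event on/off and average the change in
predicted readmission probability), and top-k Jaccard overlap between
two importance rankings.  A strategy hook allows alternative
perturbation schemes; only the present/absent toggle is built in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def lasso_importance(fold_results, feature_names) -> pd.DataFrame:
    """Fold-averaged, max-abs-normalized LR coefficients.

    Each fold's coefficient vector is divided by its own maximum
    absolute value before averaging; the table is sorted by signed
    value (descending).  An all-zero model yields an empty table.
    """
    rows = []
    for res in fold_results:
        coef = np.asarray(res.coef_, dtype=float)
        m = np.abs(coef).max()
        if m == 0:
            continue
        rows.append(coef / m)
    if not rows:
        import warnings
        warnings.warn("all LASSO coefficients are zero; no importances")
        return pd.DataFrame(columns=["feature", "importance"])
    mean = np.mean(rows, axis=0)
    out = pd.DataFrame({"feature": feature_names, "importance": mean})
    return out.sort_values("importance", ascending=False,
                           ignore_index=True)


def top_features(table: pd.DataFrame, k: int,
                 direction: str = "increase") -> list:
    """Top-k feature names by signed importance, per direction."""
    if direction == "increase":
        sub = table.sort_values("importance", ascending=False)
    else:
        sub = table.sort_values("importance", ascending=True)
    return list(sub["feature"].head(k))


def toggle_perturbation(X_last: np.ndarray, j: int):
    """The present/absent strategy: returns (X with feature j on,
    X with feature j off)."""
    on = X_last.copy()
    off = X_last.copy()
    on[:, j] = 1.0
    off[:, j] = 0.0
    return on, off


def perturb_importance(results, seqs, feature, schema,
                       strategy=toggle_perturbation) -> float:
    """Mean p(readmit | feature on) - p(readmit | feature off).

    The toggle is applied to the *last HF event only*, leaving history
    untouched; ``feature`` must be a binary (one-/multi-hot) feature,
    named or indexed per the schema.
    """
    j = (schema.feature_names.index(feature)
         if isinstance(feature, str) else int(feature))
    if not schema.binary_mask[j]:
        raise ValueError(
            f"feature {schema.feature_names[j]!r} is numeric; the "
            "present/absent toggle applies to binary features only")
    diffs = []
    for s in seqs:
        on_row, off_row = strategy(s.X[None, s.last_hf_index], j)
        import copy
        s_on = copy.copy(s)
        s_off = copy.copy(s)
        X_on = s.X.copy()
        X_on[s.last_hf_index] = on_row[0]
        X_off = s.X.copy()
        X_off[s.last_hf_index] = off_row[0]
        s_on.X, s_off.X = X_on, X_off
        diffs.append((s_on, s_off))
    p_on = results.predict_proba([a for a, _ in diffs])
    p_off = results.predict_proba([b for _, b in diffs])
    return float(np.mean(p_on - p_off))


def topk_overlap(ranking_a, ranking_b, k: int) -> float:
    """Jaccard similarity |A & B| / |A | B| of the two top-k sets."""
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k > len(ranking_a) or k > len(ranking_b):
        raise ValueError("k exceeds a ranking length")
    a, b = set(list(ranking_a)[:k]), set(list(ranking_b)[:k])
    return len(a & b) / len(a | b)
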