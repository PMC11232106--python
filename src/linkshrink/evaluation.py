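"""Estimator evaluation: coefficient rMSE, prediction MSEp, FDR-sensitivity.

The three criteria compare an estimator over B replicate training sets
against a known truth:

* per-coefficient root mean squared error,
  ``rMSE = sqrt( (1/B) sum_b (bhat^(b) - beta)^2 )``;
* prediction error against the *true linear predictor* on a test design,
  ``MSEp^(b) = || X_test bhat^(b) - X_test beta ||^2`` (noise-free, so it
  compares fits rather than forecasts);
* sensitivity at fixed empirical FDR, sweeping a per-coefficient selection
  score against truth labels (positive / negative / indeterminate), with
  indeterminate coefficients excluded from both FDR and sensitivity.

An OLS fit on the full interaction design serves as the unshrunken
reference estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rmse", "msep", "sensitivity_at_fdr", "ols_baseline"]

TRUTH_LABELS = ("positive", "negative", "indeterminate")


def rmse(estimates_over_B, beta_true) -> np.ndarray:
    """Per-coefficient root mean squared error over B replicate estimates."""
    est = np.atleast_2d(np.asarray(estimates_over_B, dtype=float))
    beta = np.asarray(beta_true, dtype=float)
    if est.shape[1] != beta.shape[0]:
        raise ValueError("estimate and truth dimensions differ")
    return np.sqrt(np.mean((est - beta[None, :]) ** 2, axis=0))


def msep(estimates_over_B, beta_true, X_test) -> np.ndarray:
    """Per-replicate squared distance between fitted and true linear predictor.

    ``X_test`` must contain every column the coefficients refer to (all main
    and two-way interaction terms). Returns one value per replicate; average
    for the summary criterion.
    """
    est = np.atleast_2d(np.asarray(estimates_over_B, dtype=float))
    beta = np.asarray(beta_true, dtype=float)
    X = np.asarray(X_test, dtype=float)
    if X.shape[1] != beta.shape[0] or est.shape[1] != beta.shape[0]:
        raise ValueError("design/coefficient dimension mismatch")
    diff = X @ (est - beta[None, :]).T  # (n_test, B)
    return np.sum(diff**2, axis=0)


def sensitivity_at_fdr(selection_scores, truth_labels, fdr_levels) -> pd.DataFrame:
    """Sensitivity of score-threshold selection at prescribed empirical FDRs.

    Coefficients are ranked by score (descending; ties broken by index) and
    the selection grown one coefficient at a time. At each selection size the
    empirical FDR is FP/(FP+TP) and the sensitivity TP/#positives, counted
    over labelled (non-indeterminate) coefficients only. For each requested
    level the reported sensitivity belongs to the largest selection whose
    FDR does not exceed that level.
    """
    scores = np.asarray(selection_scores, dtype=float)
    labels = np.asarray(truth_labels, dtype=object)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    unknown = set(labels) - set(TRUTH_LABELS)
    if unknown:
        raise ValueError(f"unknown truth labels: {sorted(unknown)}")
    keep = labels != "indeterminate"
    scores, labels = scores[keep], labels[keep]
    n_pos = int(np.sum(labels == "positive"))
    if n_pos == 0:
        raise ValueError("no positive coefficients in truth labels")

    order = np.lexsort((np.arange(scores.size), -scores))
    is_pos = (labels[order] == "positive").astype(int)
    tp = np.cumsum(is_pos)
    fp = np.cumsum(1 - is_pos)
    fdr_path = fp / np.maximum(fp + tp, 1)
    sens_path = tp / n_pos

    rows = []
    for level in np.atleast_1d(fdr_levels):
        ok = np.flatnonzero(fdr_path <= level)
        if ok.size:
            i = ok[-1]
            rows.append(
                {
                    "fdr_level": float(level),
                    "sensitivity": float(sens_path[i]),
                    "realized_fdr": float(fdr_path[i]),
                    "n_selected": int(i + 1),
                    "score_threshold": float(scores[order][i]),
                }
            )
        else:
            rows.append(
                {
                    "fdr_level": float(level),
                    "sensitivity": 0.0,
                    "realized_fdr": 0.0,
                    "n_selected": 0,
                    "score_threshold": np.inf,
                }
            )
    return pd.DataFrame(rows)


def ols_baseline(y, design) -> pd.Series:
    """OLS on the full main + interaction design (no shrinkage reference).

    Requires ``n > 1 + p_enc + q`` and a full-rank design; rank deficiency
    raises rather than silently pseudo-inverting.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.hstack([np.ones((design.n, 1)), design.full_matrix()])
    if design.n <= X.shape[1] - 1:
        raise ValueError(
            f"OLS needs n > p_enc + q (+1); got n={design.n}, columns={X.shape[1]}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient; OLS undefined")
    res = sm.OLS(y, X).fit()
    names = ["alpha"] + list(design.column_names) + design.interaction_names()
    return pd.Series(res.params, index=names, name="ols")
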