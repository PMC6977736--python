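"""Evaluation metrics for cluster-number estimates.

All metrics are computed at a *cluster delta* tolerance: an estimate is a
hit when it lies within ``delta`` of the true count.  In the single-truth
scenario (every instance has the same intrinsic count) recall at delta is
simply the hit fraction (accuracy).  For mixed truths, per-count binary F1
scores are averaged into a macro F1.  The hit-based Jaccard index of a
comparator can be normalized by that of a reference model so that 1 means
parity.  Uncertainty is quantified with a percentile bootstrap over
resampled test cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "hits_at_delta",
    "recall_at_delta",
    "jaccard_scores",
    "f1_scores",
    "bootstrap_recall_ci",
    "EvalReport",
    "evaluation_report",
]


def _check_inputs(estimates, truths):
    Y = np.asarray(estimates, dtype=float).reshape(-1)
    T = np.asarray(truths, dtype=float).reshape(-1)
    if Y.shape[0] == 0:
        raise ValueError("empty input")
    if Y.shape != T.shape:
        raise ValueError(f"length mismatch: {Y.shape[0]} vs {T.shape[0]}")
    if np.any(T < 1):
        raise ValueError("true cluster counts must be >= 1")
    return Y, T


def hits_at_delta(estimates, truths, delta: int) -> np.ndarray:
    """Boolean hit vector: |Y - Y_true| <= delta."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    Y, T = _check_inputs(estimates, truths)
    return np.abs(Y - T) <= delta


def recall_at_delta(estimates, truths, delta: int) -> float:
    """Fraction of instances whose estimate is within delta of the truth.

    With all-positive test cases (a single intrinsic cluster number) this
    equals TP / (TP + FN) and is synonymous with accuracy.
    """
    return float(hits_at_delta(estimates, truths, delta).mean())


def jaccard_scores(estimates, ref_estimates, truths, delta: int):
    """Hit-based Jaccard index and its value normalized by a reference model.

    The hit vector is intersected/united with the all-positive indicator, so
    the Jaccard index reduces to ``hits / N`` and the normalized score to the
    hit-count ratio ``hits_model / hits_ref``; 1 means parity with the
    reference (normally the linkage-regression model itself).

    Returns
    -------
    (j_model, j_normalized) : (float, float or None)
        ``j_normalized`` is None (undefined) when the reference has no hits.
    """
    h_model = hits_at_delta(estimates, truths, delta)
    h_ref = hits_at_delta(ref_estimates, truths, delta)
    if h_model.shape != h_ref.shape:
        raise ValueError("model and reference inputs must have equal length")
    n = h_model.shape[0]
    j_model = float(h_model.sum() / n)
    if h_ref.sum() == 0:
        return j_model, None
    return j_model, float(h_model.sum() / h_ref.sum())


def f1_scores(estimates, truths, delta: int, y_max: int | None = None):
    """Per-cluster-number binary F1 scores and their unweighted (macro) mean.

    For each intrinsic count ``c`` in ``1..y_max``:

    - TP: truth == c and the estimate is within delta of the truth;
    - FN: truth == c and the estimate misses;
    - FP: the rounded estimate is within delta of c but the truth is not.

    F1 is zero when precision + recall is zero.  With ``y_max = 1`` and
    all-positive truths this reduces to the binary F1.

    Returns
    -------
    (per_count, macro) : (list of float, float)
    """
    Y, T = _check_inputs(estimates, truths)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if y_max is None:
        y_max = int(T.max())
    if y_max < int(T.max()):
        raise ValueError(f"y_max={y_max} is below the largest truth {int(T.max())}")
    Yr = np.round(Y)
    per_count = []
    for c in range(1, y_max + 1):
        is_c = T == c
        hit = np.abs(Y - T) <= delta
        claimed = np.abs(Yr - c) <= delta
        truth_near = np.abs(T - c) <= delta
        tp = int(np.sum(is_c & hit))
        fn = int(np.sum(is_c & ~hit))
        fp = int(np.sum(claimed & ~truth_near))
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 0.0 if precision + recall == 0 else \
            2 * precision * recall / (precision + recall)
        per_count.append(f1)
    return per_count, float(np.mean(per_count))


def bootstrap_recall_ci(estimates, truths, deltas=range(6), n_cases: int = 200,
                        case_size: int = 200, level: float = 0.95,
                        seed: int | None = None) -> pd.DataFrame:
    """Percentile-bootstrap confidence intervals for recall at each delta.

    ``n_cases`` test cases of ``case_size`` samples are drawn with
    replacement; for each delta, the CI is the pair of empirical
    ``(1 - level)/2`` and ``1 - (1 - level)/2`` quantiles of recall over the
    resampled cases.  Defaults: 200 cases of 200 samples, 95% level.
    """
    Y, T = _check_inputs(estimates, truths)
    if Y.shape[0] < 2:
        raise ValueError("bootstrap needs at least 2 samples")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, Y.shape[0], size=(n_cases, case_size))
    err = np.abs(Y[idx] - T[idx])  # (n_cases, case_size)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for d in deltas:
        rec = (err <= d).mean(axis=1)
        rows.append({"delta": int(d),
                     "recall": recall_at_delta(Y, T, int(d)),
                     "lower": float(np.quantile(rec, lo_q)),
                     "upper": float(np.quantile(rec, hi_q)),
                     "level": level})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Delta-indexed metric table plus bootstrap CIs.

    ``table`` has one row per delta with recall, TP/FN counts, Jaccard
    (and normalized Jaccard when a reference was supplied), macro F1, and
    the bootstrap CI bounds.
    """

    table: pd.DataFrame
    y_max: int
    n: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        doc = {"n": self.n, "y_max": self.y_max,
               "per_delta": self.table.to_dict(orient="records")}
        if path is None:
            return doc
        Path(path).write_text(json.dumps(doc, indent=2))

    def __repr__(self):
        return (f"EvalReport(n={self.n}, y_max={self.y_max})\n"
                + self.table.to_string(index=False))


def evaluation_report(estimates, truths, ref_estimates=None, deltas=range(6),
                      y_max: int | None = None, n_cases: int = 200,
                      case_size: int = 200, level: float = 0.95,
                      seed: int | None = None) -> EvalReport:
    """Full evaluation at every delta, with percentile-bootstrap recall CIs."""
    Y, T = _check_inputs(estimates, truths)
    if y_max is None:
        y_max = int(T.max())
    ci = bootstrap_recall_ci(Y, T, deltas=deltas, n_cases=n_cases,
                             case_size=case_size, level=level, seed=seed)
    rows = []
    for d in deltas:
        d = int(d)
        hit = hits_at_delta(Y, T, d)
        _, macro = f1_scores(Y, T, d, y_max=y_max)
        row = {"delta": d,
               "recall": float(hit.mean()),
               "tp": int(hit.sum()),
               "fn": int((~hit).sum()),
               "jaccard": float(hit.mean()),
               "macro_f1": macro}
        if ref_estimates is not None:
            j, jn = jaccard_scores(Y, ref_estimates, T, d)
            row["jaccard_normalized"] = jn
        rows.append(row)
    table = pd.DataFrame(rows).merge(ci[["delta", "lower", "upper", "level"]],
                                     on="delta")
    return EvalReport(table=table, y_max=y_max, n=Y.shape[0])
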