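"""Biometric evaluation: per-subject confusion counts and FAR/FRR/P/R/F1.

For each enrolled subject s the multi-class predictions are re-read as a
binary accept/reject decision, giving the one-vs-rest confusion counts

    TP = #(true = s and pred = s)      FN = #(true = s and pred != s)
    FP = #(true != s and pred = s)     TN = #(true != s and pred != s)

and the five derived metrics

    FAR = FP / (FP + TN)           (false acceptance rate)
    FRR = FN / (TP + FN)           (false rejection rate)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1 = 2 * precision * recall / (precision + recall)

A ratio whose denominator is zero is reported as absent (NaN) and excluded
from macro means, rather than coerced to 0 — coercion would silently inflate
the averages for subjects without test rows.  Macro summaries are per-subject
mean ± sd (sample sd, ddof=1); micro aggregates over pooled counts are also
emitted, and micro recall equals plain multi-class accuracy by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

#: Precision histogram bin edges (fractions): <=60%, then decade bins to 100%.
HISTOGRAM_EDGES = [0.0, 0.6, 0.7, 0.8, 0.9, 1.0]

METRIC_COLUMNS = ["far", "frr", "precision", "recall", "f1"]


def confusion_per_subject(y_true, y_pred) -> pd.DataFrame:
    """One-vs-rest confusion counts per subject (rows indexed by subject)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidArgumentError(
            f"label length mismatch: {y_true.shape} vs {y_pred.shape}")
    n = y_true.size
    subjects = sorted(set(y_true) | set(y_pred))
    rows = []
    for s in subjects:
        tp = int(np.sum((y_true == s) & (y_pred == s)))
        fp = int(np.sum((y_true != s) & (y_pred == s)))
        fn = int(np.sum((y_true == s) & (y_pred != s)))
        rows.append({"subject_id": s, "tp": tp, "fp": fp, "fn": fn,
                     "tn": n - tp - fp - fn})
    return pd.DataFrame(rows).set_index("subject_id")


def _ratio(num, den):
    return num / den if den > 0 else np.nan


def compute_metrics(counts: pd.DataFrame) -> pd.DataFrame:
    """FAR/FRR/precision/recall/F1 per subject; NaN where undefined."""
    if (counts[["tp", "fp", "fn", "tn"]] < 0).any().any():
        raise InvalidArgumentError("confusion counts must be non-negative")
    out = counts.copy()
    far, frr, prec, rec, f1 = [], [], [], [], []
    for _, c in counts.iterrows():
        p = _ratio(c.tp, c.tp + c.fp)
        r = _ratio(c.tp, c.tp + c.fn)
        far.append(_ratio(c.fp, c.fp + c.tn))
        frr.append(_ratio(c.fn, c.tp + c.fn))
        prec.append(p)
        rec.append(r)
        f1.append(2 * p * r / (p + r) if np.isfinite(p) and np.isfinite(r)
                  and (p + r) > 0 else np.nan)
    out["far"], out["frr"] = far, frr
    out["precision"], out["recall"], out["f1"] = prec, rec, f1
    return out


def macro_summary(metrics: pd.DataFrame) -> dict:
    """Per-subject mean/sd of each metric plus pooled (micro) aggregates."""
    summary = {}
    for m in METRIC_COLUMNS:
        vals = metrics[m].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        summary[f"{m}_mean"] = float(vals.mean()) if vals.size else np.nan
        summary[f"{m}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
    tp, fp, fn, tn = (int(metrics[c].sum()) for c in ("tp", "fp", "fn", "tn"))
    summary["micro_accuracy"] = _ratio(tp, tp + fn)
    summary["micro_far"] = _ratio(fp, fp + tn)
    summary["n_test"] = int(metrics.iloc[0][["tp", "fp", "fn", "tn"]].sum()) \
        if len(metrics) else 0
    return summary


def precision_histogram(metrics: pd.DataFrame) -> dict:
    """Subject counts per precision bin: <=60%, 60-70, 70-80, 80-90, 90-100."""
    vals = metrics["precision"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    counts, _ = np.histogram(vals, bins=HISTOGRAM_EDGES)
    # np.histogram's last bin is closed on the right, matching 90-100 incl. 100
    labels = ["<=60%", "60-70%", "70-80%", "80-90%", "90-100%"]
    return dict(zip(labels, (int(c) for c in counts)))


def evaluation_report(y_true, y_pred) -> dict:
    """Full report: per-subject table, macro summary, precision histogram."""
    counts = confusion_per_subject(y_true, y_pred)
    metrics = compute_metrics(counts)
    return {
        "per_subject": metrics.reset_index().to_dict(orient="records"),
        "macro": macro_summary(metrics),
        "precision_histogram": precision_histogram(metrics),
    }


def summarize_scenarios(reports: dict) -> pd.DataFrame:
    """One comparison row per scenario from reports keyed by scenario name.

    All reports must cover the same subject set (same cohort definition).
    """
    subject_sets = {name: frozenset(r["per_subject"][i]["subject_id"]
                                    for i in range(len(r["per_subject"])))
                    for name, r in reports.items()}
    if len(set(subject_sets.values())) > 1:
        raise InvalidArgumentError(
            "scenario reports evaluated on different cohorts: "
            + str({k: len(v) for k, v in subject_sets.items()}))
    rows = []
    for name, rep in reports.items():
        row = {"scenario": name}
        row.update({k: rep["macro"][k] for k in rep["macro"]})
        row.update({f"hist_{k}": v for k, v in rep["precision_histogram"].items()})
        rows.append(row)
    return pd.DataFrame(rows)
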