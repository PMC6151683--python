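"""Performance metrics and paired comparison statistics.

Detection performance for referable DR is summarised by

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

plus the area under the ROC curve.  Two input representations evaluated on
the same test images form a paired design, compared with:

* a Pearson chi-square test (1 df, no continuity correction) on the 2×2
  correct/incorrect × method table for accuracy;
* McNemar's test on the discordant pairs, run separately within the
  truth-positive images (sensitivity) and truth-negative images
  (specificity); the continuity-corrected chi-square approximation is used
  when b + c >= 26 and the exact two-sided binomial otherwise;
* DeLong's paired test for the AUC difference (a seeded paired bootstrap is
  available as an alternative).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .cnn_referable import PredictionSet

MCNEMAR_EXACT_MAX = 25  # b + c above this uses the corrected chi-square


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def correct(self) -> int:
        return self.tp + self.tn


def confusion(preds: PredictionSet, truth: dict[str, int]) -> ConfusionCounts:
    """Exact confusion counts of binary calls against binary truth."""
    if not preds.ids:
        raise ValueError("empty prediction set")
    missing = [i for i in preds.ids if i not in truth]
    if missing or len(truth) != len(preds.ids):
        raise ValueError(
            f"prediction/truth id mismatch (missing {missing[:3]}, "
            f"{len(truth)} truth vs {len(preds.ids)} predictions)")
    tp = tn = fp = fn = 0
    for i, call in zip(preds.ids, preds.calls):
        t = truth[i]
        if t == 1:
            tp += call == 1
            fn += call == 0
        else:
            tn += call == 0
            fp += call == 1
    return ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity and specificity; None where undefined."""
    out: dict[str, float | None] = {}
    out["accuracy"] = c.correct / c.total if c.total else None
    out["sensitivity"] = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    out["specificity"] = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    return out


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> dict:
    """ROC sweep and AUC (ties counted one half, Mann-Whitney formulation)."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.int64)
    if truth.min() == truth.max():
        raise ValueError("ROC needs both classes present in truth")
    fpr, tpr, thresholds = roc_curve(truth, scores)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    # Mann-Whitney U via midranks: exact pairwise concordance with half-ties
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) \
        / (len(pos) * len(neg))
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds,
            "auc": float(auc)}


# ---------------------------------------------------------------------------
# paired tests


@dataclass(frozen=True)
class PairedOutcomes:
    """Per-image truth and the binary calls of two methods on the same set."""

    ids: list[str]
    truth: np.ndarray
    calls_a: np.ndarray
    calls_b: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.truth) == len(self.calls_a) == len(self.calls_b) == n):
            raise ValueError("paired outcome arrays must share one image set")


def paired_outcomes(preds_a: PredictionSet, preds_b: PredictionSet,
                    truth: dict[str, int]) -> PairedOutcomes:
    if preds_a.ids != preds_b.ids:
        order = {i: k for k, i in enumerate(preds_a.ids)}
        if set(preds_a.ids) != set(preds_b.ids):
            raise ValueError("paired predictions must cover the same images")
        perm = np.array([order[i] for i in preds_b.ids]).argsort()
        preds_b = PredictionSet(ids=[preds_b.ids[i] for i in perm],
                                scores=preds_b.scores[perm],
                                calls=preds_b.calls[perm],
                                threshold=preds_b.threshold)
    t = np.array([truth[i] for i in preds_a.ids], dtype=np.int64)
    return PairedOutcomes(ids=list(preds_a.ids), truth=t,
                          calls_a=np.asarray(preds_a.calls),
                          calls_b=np.asarray(preds_b.calls))


def mcnemar(paired: PairedOutcomes, metric_subset: str) -> dict:
    """McNemar's test on discordant pairs within one truth stratum.

    ``metric_subset``: "sensitivity" restricts to truth-positive images,
    "specificity" to truth-negatives.  b counts images method A got right and
    B wrong, c the reverse.  b+c > 25 uses the continuity-corrected
    chi-square (|b-c|-1)²/(b+c) on 1 df, smaller discordance uses the exact
    two-sided binomial; b+c = 0 returns p = 1 with a note.
    """
    if metric_subset == "sensitivity":
        sel = paired.truth == 1
    elif metric_subset == "specificity":
        sel = paired.truth == 0
    else:
        raise ValueError(f"unknown metric_subset {metric_subset!r}")
    correct_a = paired.calls_a[sel] == paired.truth[sel]
    correct_b = paired.calls_b[sel] == paired.truth[sel]
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        return {"b": b, "c": c, "statistic": 0.0, "p_value": 1.0,
                "method": "degenerate", "note": "no discordant pairs"}
    if b + c > MCNEMAR_EXACT_MAX:
        statistic = (abs(b - c) - 1) ** 2 / (b + c)
        p = float(stats.chi2.sf(statistic, df=1))
        return {"b": b, "c": c, "statistic": float(statistic), "p_value": p,
                "method": "chi-square, continuity corrected"}
    p = float(stats.binomtest(min(b, c), n=b + c, p=0.5,
                              alternative="two-sided").pvalue)
    return {"b": b, "c": c, "statistic": float(min(b, c)),
            "p_value": min(1.0, p), "method": "exact binomial"}


def chisq_accuracy(c_a: ConfusionCounts, c_b: ConfusionCounts) -> dict:
    """Pearson chi-square (1 df, uncorrected) on correct/incorrect × method."""
    if c_a.total == 0 or c_b.total == 0:
        raise ValueError("empty confusion counts")
    table = np.array([[c_a.correct, c_a.total - c_a.correct],
                      [c_b.correct, c_b.total - c_b.correct]], dtype=np.float64)
    if table[:, 1].sum() == 0 or table[:, 0].sum() == 0:
        # degenerate margin: identical all-correct or all-wrong columns
        return {"statistic": 0.0, "p_value": 1.0, "warning": "degenerate margin"}
    statistic, p, _, expected = stats.chi2_contingency(table, correction=False)
    out = {"statistic": float(statistic), "p_value": float(p)}
    if (expected < 1).any():
        out["warning"] = "expected cell count below 1"
    return out


# ---------------------------------------------------------------------------
# AUC comparison


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_paired(scores_a: np.ndarray, scores_b: np.ndarray,
                  truth: np.ndarray) -> dict:
    """DeLong's paired test for the difference of two correlated AUCs.

    Uses the structural-component (midrank) formulation; returns both AUCs,
    the z statistic and the two-sided normal p-value.  With zero variance of
    the difference (e.g. identical scores) the difference is reported with
    p = 1 when it is 0.
    """
    truth = np.asarray(truth, dtype=np.int64)
    if truth.min() == truth.max():
        raise ValueError("AUC comparison needs both classes")
    order = np.argsort(-truth, kind="stable")  # positives first
    m = int(truth.sum())
    n = len(truth) - m
    aucs = []
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for k, s in enumerate((scores_a, scores_b)):
        s = np.asarray(s, dtype=np.float64)[order]
        pos, neg = s[:m], s[m:]
        tx = _midrank(pos)
        ty = _midrank(neg)
        tz = _midrank(s)
        auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        aucs.append(float(auc))
        v10[k] = (tz[:m] - tx) / n
        v01[k] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": aucs[0], "auc_b": aucs[1], "difference": diff,
            "z": float(z), "p_value": p, "method": "DeLong paired"}


def bootstrap_auc_compare(scores_a: np.ndarray, scores_b: np.ndarray,
                          truth: np.ndarray, n_resamples: int = 2000,
                          seed: int = 0) -> dict:
    """Seeded paired-bootstrap test of the AUC difference (two-sided)."""
    truth = np.asarray(truth, dtype=np.int64)
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    auc_a = roc_auc(scores_a, truth)["auc"]
    auc_b = roc_auc(scores_b, truth)["auc"]
    observed = auc_a - auc_b
    rng = np.random.default_rng(seed)
    n = len(truth)
    diffs = np.empty(n_resamples)
    k = 0
    while k < n_resamples:
        idx = rng.integers(0, n, size=n)
        t = truth[idx]
        if t.min() == t.max():
            continue
        diffs[k] = roc_auc(scores_a[idx], t)["auc"] \
            - roc_auc(scores_b[idx], t)["auc"]
        k += 1
    # two-sided p from the bootstrap null of zero shift
    shifted = diffs - diffs.mean()
    p = float((np.abs(shifted) >= abs(observed)).mean())
    return {"auc_a": auc_a, "auc_b": auc_b, "difference": observed,
            "p_value": max(p, 1.0 / n_resamples), "method": "paired bootstrap",
            "n_resamples": n_resamples}


def auc_compare(scores_a: np.ndarray, scores_b: np.ndarray,
                truth: np.ndarray, method: str = "delong",
                seed: int = 0) -> dict:
    if method == "delong":
        return delong_paired(scores_a, scores_b, truth)
    if method == "bootstrap":
        return bootstrap_auc_compare(scores_a, scores_b, truth, seed=seed)
    raise ValueError(f"unknown AUC comparison method {method!r}")


# ---------------------------------------------------------------------------
# the comparison report


@dataclass
class ComparisonReport:
    """Side-by-side evaluation of two input representations."""

    label_a: str
    label_b: str
    metrics_a: dict
    metrics_b: dict
    auc_a: float
    auc_b: float
    p_accuracy: float
    p_sensitivity: float
    p_specificity: float
    p_auc: float
    details: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("accuracy", "sensitivity", "specificity"):
            rows.append({
                "metric": name,
                self.label_a: self.metrics_a[name],
                self.label_b: self.metrics_b[name],
                "p_value": getattr(self, f"p_{name}"),
            })
        rows.append({"metric": "auc", self.label_a: self.auc_a,
                     self.label_b: self.auc_b, "p_value": self.p_auc})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, default=_jsonable)

    def save(self, csv_path, json_path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        with open(json_path, "w") as fh:
            fh.write(self.to_json())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def report(preds_a: PredictionSet, preds_b: PredictionSet,
           truth: dict[str, int], label_a: str = "original",
           label_b: str = "entropy", auc_method: str = "delong",
           seed: int = 0) -> ComparisonReport:
    """Full paired comparison of two runs on one test manifest."""
    if set(preds_a.ids) != set(preds_b.ids):
        raise ValueError("runs were not evaluated on the same test set")
    c_a = confusion(preds_a, truth)
    c_b = confusion(preds_b, truth)
    paired = paired_outcomes(preds_a, preds_b, truth)
    order = {i: k for k, i in enumerate(preds_a.ids)}
    perm = np.array([order[i] for i in preds_b.ids]).argsort() \
        if preds_a.ids != preds_b.ids else np.arange(len(preds_a.ids))
    scores_b = preds_b.scores[perm] if preds_a.ids != preds_b.ids \
        else preds_b.scores
    truth_vec = paired.truth
    mcn_sens = mcnemar(paired, "sensitivity")
    mcn_spec = mcnemar(paired, "specificity")
    chi = chisq_accuracy(c_a, c_b)
    auc_cmp = auc_compare(preds_a.scores, scores_b, truth_vec,
                          method=auc_method, seed=seed)
    return ComparisonReport(
        label_a=label_a, label_b=label_b,
        metrics_a=metrics(c_a), metrics_b=metrics(c_b),
        auc_a=auc_cmp["auc_a"], auc_b=auc_cmp["auc_b"],
        p_accuracy=chi["p_value"],
        p_sensitivity=mcn_sens["p_value"],
        p_specificity=mcn_spec["p_value"],
        p_auc=auc_cmp["p_value"],
        details={"confusion_a": asdict(c_a), "confusion_b": asdict(c_b),
                 "chi_square": chi, "mcnemar_sensitivity": mcn_sens,
                 "mcnemar_specificity": mcn_spec, "auc_test": auc_cmp},
    )
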