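"""Posterior draws -> screening outputs.

Per-compound posterior-predictive probabilities for the three key events and
the adverse outcome, 95% credible intervals (equal-tailed by default — the
interval defined by the 2.5th/97.5th percentiles — with a true highest
density interval available by flag), two-threshold low/medium/high hazard
classes, and confusion-matrix performance metrics against observed labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import NODES, PosteriorSamples

__all__ = [
    "PredictionReport",
    "ConfusionMetrics",
    "predictive_probabilities",
    "credible_interval",
    "derive_thresholds",
    "classify_levels",
    "build_report",
    "performance_metrics",
]

LEVELS = ("low", "medium", "high")


def predictive_probabilities(ps: PosteriorSamples) -> dict[str, np.ndarray]:
    """Per-node posterior probability draws, (chain, draw, n_compounds).

    Probabilities are inv_logit of the theta draws (already materialized on
    the PosteriorSamples), including compounds whose inputs were imputed.
    """
    return {node: ps.prob[..., k] for k, node in enumerate(NODES)}


def credible_interval(
    draws: np.ndarray, level: float = 0.95, method: str = "equal_tailed"
) -> tuple[float, float]:
    """Credible interval of a draw vector.

    ``equal_tailed``: the ((1-level)/2, (1+level)/2) quantiles — for level
    0.95 the 2.5th and 97.5th percentiles.  ``hdi``: the narrowest interval
    containing ``level`` posterior mass.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 20:
        raise ValueError("need at least 20 draws for a credible interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if method == "equal_tailed":
        lo, hi = np.quantile(draws, [(1 - level) / 2, (1 + level) / 2])
    elif method == "hdi":
        sorted_ = np.sort(draws)
        n = sorted_.size
        m = max(int(np.floor(level * n)), 1)
        widths = sorted_[m:] - sorted_[: n - m]
        i = int(np.argmin(widths))
        lo, hi = sorted_[i], sorted_[i + m]
    else:
        raise ValueError(f"unknown interval method '{method}'")
    return float(lo), float(hi)


def derive_thresholds(
    dnt_means: np.ndarray, method: str = "tertiles", fixed: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Two classification thresholds from the predicted probability means.

    Default: empirical 1/3 and 2/3 quantiles of the per-compound means.
    ``fixed`` (t_low, t_high) is returned verbatim.  All-equal means are
    degenerate — an error advises fixed thresholds.
    """
    if fixed is not None:
        t_low, t_high = float(fixed[0]), float(fixed[1])
        if not t_low < t_high:
            raise ValueError("need t_low < t_high")
        return t_low, t_high
    means = np.asarray(dnt_means, dtype=float)
    if means.size < 3:
        raise ValueError("need at least 3 compounds to derive thresholds")
    if method != "tertiles":
        raise ValueError(f"unknown threshold method '{method}'")
    t_low, t_high = np.quantile(means, [1.0 / 3.0, 2.0 / 3.0])
    if not t_low < t_high:
        raise ValueError(
            "degenerate predicted means (all equal); supply fixed thresholds"
        )
    return float(t_low), float(t_high)


def classify_levels(mean: float, thresholds: tuple[float, float]) -> str:
    """low if mean < t_low; medium if t_low <= mean < t_high; high if
    mean >= t_high (thresholds inclusive on the upper class side)."""
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError("need t_low < t_high")
    if mean >= t_high:
        return "high"
    if mean >= t_low:
        return "medium"
    return "low"


@dataclass
class PredictionReport:
    """Per compound x node summary: mean probability, interval, hazard class.

    ``table`` columns: compound, node, mean, lo, hi, interval_method, level.
    Rows are ordered by increasing DNT probability within each node group.
    """

    table: pd.DataFrame
    thresholds: dict[str, tuple[float, float]]  # per node
    level: float
    interval_method: str

    def node_frame(self, node: str) -> pd.DataFrame:
        return self.table[self.table["node"] == node].reset_index(drop=True)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    def to_json_summary(self) -> str:
        counts = (
            self.table.groupby(["node", "level"], sort=False)["compound"]
            .count()
            .to_dict()
        )
        return json.dumps(
            {
                "interval_level": self.level,
                "interval_method": self.interval_method,
                "thresholds": {k: list(v) for k, v in self.thresholds.items()},
                "class_counts": {f"{n}:{l}": int(c) for (n, l), c in counts.items()},
            },
            indent=1,
        )


def build_report(
    ps: PosteriorSamples,
    level: float = 0.95,
    interval_method: str = "equal_tailed",
    thresholds: tuple[float, float] | None = None,
) -> PredictionReport:
    """Summarize probability draws into the screening report.

    Thresholds are derived per node from the tertiles of that node's
    predicted means unless fixed ones are given.  Compounds are listed in
    order of increasing DNT probability.
    """
    prob = ps.prob  # (chain, draw, n, 4)
    n = prob.shape[2]
    names = list(ps.compound_names) or [f"compound_{i + 1}" for i in range(n)]
    means = prob.mean(axis=(0, 1))  # (n, 4)
    order = np.argsort(means[:, NODES.index("dnt")], kind="stable")
    rows = []
    thr: dict[str, tuple[float, float]] = {}
    for k, node in enumerate(NODES):
        thr[node] = derive_thresholds(means[:, k], fixed=thresholds)
        for i in order:
            draws = prob[:, :, i, k].ravel()
            lo, hi = credible_interval(draws, level=level, method=interval_method)
            m = float(means[i, k])
            rows.append(
                {
                    "compound": names[i],
                    "node": node,
                    "mean": m,
                    "lo": lo,
                    "hi": hi,
                    "interval_method": interval_method,
                    "level": classify_levels(m, thr[node]),
                }
            )
    return PredictionReport(
        table=pd.DataFrame(rows),
        thresholds=thr,
        level=level,
        interval_method=interval_method,
    )


@dataclass
class ConfusionMetrics:
    """Confusion counts and the four performance metrics.

    ``sensitivity``/``specificity`` are None (undefined) when there are no
    observed positives/negatives, never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_evaluable: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    balanced_accuracy: float | None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n_evaluable": self.n_evaluable,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


def performance_metrics(
    predicted_means: np.ndarray,
    labels: np.ndarray,
    label_missing: np.ndarray | None = None,
    decision_cutoff: float = 0.5,
) -> ConfusionMetrics:
    """Binarize predicted means at ``decision_cutoff`` (positive iff mean >=
    cutoff) and evaluate against observed labels.

    Compounds with missing labels are excluded; sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), accuracy = (TP+TN)/all, balanced accuracy =
    (sensitivity+specificity)/2.
    """
    predicted_means = np.asarray(predicted_means, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predicted_means.shape != labels.shape:
        raise ValueError("predicted means and labels must have equal length")
    if label_missing is None:
        keep = ~np.isnan(labels)
    else:
        keep = np.asarray(label_missing) == 0
    pred = predicted_means[keep] >= decision_cutoff
    act = labels[keep].astype(int)
    if act.size == 0:
        raise ValueError("no observed labels to evaluate")
    tp = int(np.sum(pred & (act == 1)))
    fn = int(np.sum(~pred & (act == 1)))
    tn = int(np.sum(~pred & (act == 0)))
    fp = int(np.sum(pred & (act == 0)))
    n_eval = tp + fn + tn + fp
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    acc = (tp + tn) / n_eval
    bal = (sens + spec) / 2 if (sens is not None and spec is not None) else None
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_evaluable=n_eval,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=bal,
    )
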