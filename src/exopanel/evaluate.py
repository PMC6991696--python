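"""ROC, confusion and stability evaluation of fitted biomarker panels.

The AUC is the Mann-Whitney statistic P(score_pos > score_neg) + 0.5 P(tie).
ROC curves are built from the at-most-(k+1) distinct score thresholds without
smoothing — an honest representation for a coded risk score that takes only a
handful of integer values — and the area is computed by the trapezoidal rule
on exact integer TP/FP counts with a single final division, so it equals the
pair-counting statistic to the last bit. Scores are never direction-flipped:
a variant that orders cases below controls reports its sub-0.5 AUC as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .quant import RelExprMatrix, _ann_index
from .risk import RiskModel, code_samples, combine_with_afp, risk_scores
from .screen import Contrast


class LeakageError(ValueError):
    """Raised when evaluation samples overlap the model's fitting samples."""


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending; starts at +inf (predict nothing)
    tp_counts: np.ndarray
    fp_counts: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def tpr(self) -> np.ndarray:
        return self.tp_counts / self.n_pos

    @property
    def fpr(self) -> np.ndarray:
        return self.fp_counts / self.n_neg

    @property
    def auc(self) -> float:
        # trapezoid on integer counts; exact up to one final division
        twice_area = int(
            np.sum(
                np.diff(self.fp_counts) * (self.tp_counts[1:] + self.tp_counts[:-1])
            )
        )
        return twice_area / (2 * self.n_pos * self.n_neg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc(scores, labels) -> ROCCurve:
    """ROC curve and Mann-Whitney AUC for the rule ``score >= t -> positive``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # last index of each tie block of distinct score values
    block_end = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[block_end]
    fps = block_end + 1 - tps
    return ROCCurve(
        thresholds=np.r_[np.inf, s_sorted[block_end]],
        tp_counts=np.r_[0, tps],
        fp_counts=np.r_[0, fps],
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return self._rate(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def confusion(pred_class, labels) -> ConfusionSummary:
    pred = np.asarray(pred_class, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if pred.shape != labels.shape:
        raise ValueError("pred_class and labels must be aligned")
    return ConfusionSummary(
        tp=int((pred & labels).sum()),
        fp=int((pred & ~labels).sum()),
        tn=int((~pred & ~labels).sum()),
        fn=int((~pred & labels).sum()),
    )


def _contrast_samples(
    ann: pd.DataFrame, contrast: Contrast, split: str | None
) -> tuple[list[str], pd.Series]:
    a = _ann_index(ann)
    mask = a["group"].isin(contrast.low + contrast.high)
    if split is not None:
        mask &= a["split"] == split
    ids = list(a.index[mask])
    labels = a.loc[ids, "group"].isin(contrast.high)
    return ids, labels


def evaluate_contrast(
    model: RiskModel,
    expr: RelExprMatrix,
    ann: pd.DataFrame,
    contrast: Contrast,
    split: str = "valid",
) -> pd.DataFrame:
    """One ROC (+ confusion where a cut-off applies) per score variant.

    Variants: each single panel marker (continuous expression as the score),
    AFP alone (continuous), the coded panel RSF, and the AFP-extended RSF.
    Confusion metrics use the frozen training cut-offs and are reported only
    for the two coded variants. On any split other than the fitting split the
    model must be frozen and must share no samples with the evaluation set.
    """
    ids, labels = _contrast_samples(ann, contrast, split)
    if not ids:
        raise ValueError(f"no samples for contrast {contrast.name!r} in split {split!r}")
    overlap = set(ids) & set(model.fit_sample_ids)
    if split != "train":
        if not model.frozen:
            raise ValueError("model must be frozen before out-of-split evaluation")
        if overlap:
            raise LeakageError(
                f"evaluation split {split!r} shares samples with the fitting set: "
                f"{sorted(overlap)[:5]}"
            )
    sub = expr.subset(ids)
    y = labels.to_numpy()
    afp = _ann_index(ann)["afp"].reindex(ids)
    s = code_samples(sub, list(model.marker_ids), pd.Series(model.theta))
    weights = pd.Series(model.weights)
    rsf = risk_scores(s, weights)

    rows = []

    def add(variant: str, marker: str, scores: pd.Series, cutoff: float | None):
        curve = roc(scores.to_numpy(), y)
        row = {
            "variant": variant,
            "marker_id": marker,
            "auc": curve.auc,
            "n_pos": curve.n_pos,
            "n_neg": curve.n_neg,
            "n_censored": int(
                sub.censored.loc[marker].sum() if marker else sub.censored.sum().sum()
            ),
            "cutoff": cutoff if cutoff is not None else float("nan"),
        }
        if cutoff is not None:
            cs = confusion(scores.to_numpy() >= cutoff, y)
            row.update(cs.as_dict())
        rows.append(row)

    for m in model.marker_ids:
        add("single_marker", m, sub.expr.loc[m], None)
    add("afp_only", "", afp, None)
    add("panel", "", rsf, model.cutoff)
    if model.afp_theta is not None and model.cutoff_with_afp is not None:
        ext = combine_with_afp(s, weights, afp, model.afp_theta)
        add("panel_plus_afp", "", ext, model.cutoff_with_afp)
    out = pd.DataFrame(rows)
    out.insert(0, "split", split)
    out.insert(0, "contrast", contrast.name)
    return out


def blind_accuracy(
    model: RiskModel,
    expr: RelExprMatrix,
    ann: pd.DataFrame,
    contrast: Contrast,
    with_afp: bool = False,
) -> tuple[float, ConfusionSummary]:
    """Frozen-model classification accuracy on the double-blind split.

    Group labels are consulted only to adjudicate the predictions afterwards.
    """
    if not model.frozen:
        raise ValueError("model must be frozen before blind evaluation")
    ids, labels = _contrast_samples(ann, contrast, "blind")
    if not ids:
        raise ValueError(f"no blind samples for contrast {contrast.name!r}")
    overlap = set(ids) & set(model.fit_sample_ids)
    if overlap:
        raise LeakageError(f"blind split overlaps fitting set: {sorted(overlap)[:5]}")
    sub = expr.subset(ids)
    s = code_samples(sub, list(model.marker_ids), pd.Series(model.theta))
    weights = pd.Series(model.weights)
    if with_afp:
        if model.afp_theta is None:
            raise ValueError("model has no AFP threshold")
        scores = combine_with_afp(
            s, weights, _ann_index(ann)["afp"].reindex(ids), model.afp_theta
        )
    else:
        scores = risk_scores(s, weights)
    pred = model.classify(scores, with_afp=with_afp)
    cs = confusion(pred.to_numpy(), labels.to_numpy())
    return cs.accuracy, cs


def stability_compare(
    expr_by_condition: Mapping[str, pd.DataFrame], baseline: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired comparison of marker expression across handling conditions.

    *expr_by_condition* maps condition name -> expression matrix (markers x
    samples) with identical marker and sample labels (paired aliquots of the
    same donors). Each non-baseline condition is tested per marker against the
    baseline with a two-sided paired t test on log2 expression; the reported
    effect is the mean log2 ratio. Returns ``(summary, per_condition)``:
    per-marker min p, worst-case |log2 ratio| and a ``stable`` flag
    (no condition significant at *alpha*), plus the per-condition detail.
    Significance alone is weak evidence of equivalence, hence the magnitude
    is always reported alongside.
    """
    if baseline not in expr_by_condition:
        raise ValueError(f"baseline condition {baseline!r} missing")
    if len(expr_by_condition) < 2:
        raise ValueError("need at least two conditions")
    base = expr_by_condition[baseline]
    detail_rows = []
    for cond, mat in expr_by_condition.items():
        if cond == baseline:
            continue
        if not mat.index.equals(base.index) or not mat.columns.equals(base.columns):
            raise ValueError(
                f"condition {cond!r} is not paired with baseline "
                "(marker/sample labels differ)"
            )
        diffs = np.log2(mat.to_numpy()) - np.log2(base.to_numpy())
        mean_ratio = diffs.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pval = stats.ttest_rel(
                np.log2(mat.to_numpy()), np.log2(base.to_numpy()), axis=1
            )
        # identical replicates: zero variance of zero diffs -> no evidence
        degenerate = np.all(diffs == 0, axis=1)
        pval = np.where(degenerate, 1.0, pval)
        for m, p, r in zip(base.index, pval, mean_ratio):
            detail_rows.append(
                {
                    "assay_id": m,
                    "condition": cond,
                    "p_value": float(p),
                    "mean_log2_ratio": float(r),
                    "n_pairs": base.shape[1],
                }
            )
    detail = pd.DataFrame(detail_rows)
    grouped = detail.groupby("assay_id", sort=False)
    summary = pd.DataFrame(
        {
            "min_p": grouped["p_value"].min(),
            "max_abs_log2_ratio": grouped["mean_log2_ratio"].apply(
                lambda x: float(np.max(np.abs(x)))
            ),
        }
    )
    summary["stable"] = summary["min_p"] > alpha
    return summary, detail
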