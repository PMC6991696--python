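"""Binary-coded weighted risk score with control-derived thresholds.

The classifier follows the risk-score-function (RSF) tradition of circulating
biomarker fingerprint studies:

* per-marker threshold theta_j = upper limit of the controls' 95% reference
  interval (one-sided 95th percentile of control relative expression),
* per-sample coding s_ij = 1 when expression strictly exceeds theta_j
  (censored nondetect cells always code 0),
* rsf_i = sum_j W_j * s_ij with unit weights by default, so the score is the
  number of positive markers,
* decision cut-off c chosen on the training samples to maximise
  sensitivity + specificity, classification rule rsf >= c -> high risk.

AFP can be appended as one extra coded marker (its own control-derived
threshold, weight 1). Fitted models are frozen: applying them to validation
or blind samples never re-estimates theta, weights or the cut-off.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .quant import RelExprMatrix, _ann_index

VARIANTS = ("panel_only", "panel_plus_afp", "single_marker", "afp_only")


@dataclass(frozen=True)
class RiskModel:
    """A frozen fitted risk-score model for one diagnostic comparison."""

    marker_ids: tuple[str, ...]
    theta: dict[str, float]
    weights: dict[str, float]
    cutoff: float | None = None
    cutoff_with_afp: float | None = None
    afp_theta: float | None = None
    variant: str = "panel_only"
    contrast_name: str | None = None
    fit_sample_ids: tuple[str, ...] = ()
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if set(self.theta) != set(self.marker_ids) or set(self.weights) != set(
            self.marker_ids
        ):
            raise ValueError("theta/weights must cover exactly the panel markers")
        if any(v <= 0 for v in self.theta.values()):
            raise ValueError("thresholds must be > 0")

    def freeze(self) -> "RiskModel":
        return dataclasses.replace(self, frozen=True)

    def classify(self, rsf: pd.Series, with_afp: bool = False) -> pd.Series:
        c = self.cutoff_with_afp if with_afp else self.cutoff
        if c is None:
            raise ValueError("cutoff not fitted")
        return rsf >= c

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["marker_ids"] = list(self.marker_ids)
        d["fit_sample_ids"] = list(self.fit_sample_ids)
        Path(path).write_text(json.dumps(d, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        d["marker_ids"] = tuple(d["marker_ids"])
        d["fit_sample_ids"] = tuple(d["fit_sample_ids"])
        return cls(**d)


def fit_thresholds(
    expr: RelExprMatrix,
    ann: pd.DataFrame,
    control_group: str,
    panel: Sequence[str],
    method: str = "quantile",
) -> pd.Series:
    """Per-marker coding threshold from the control group's expression.

    ``method="quantile"`` (default): empirical 95th percentile with the
    linear-interpolation convention (sample maximum at p=1).
    ``method="parametric"``: exp(mean + 1.645 * SD) of log expression.
    """
    groups = _ann_index(ann)["group"]
    ctrl = [s for s in expr.sample_ids if groups.get(s) == control_group]
    if not ctrl:
        raise ValueError(f"control group {control_group!r} has no samples")
    if len(ctrl) < 5:
        raise ValueError(
            f"need >=5 control samples to set a reference interval, got {len(ctrl)}"
        )
    missing = set(panel) - set(expr.marker_ids)
    if missing:
        raise KeyError(f"panel markers absent from expression: {sorted(missing)}")
    vals = expr.expr.loc[list(panel), ctrl]
    if method == "quantile":
        theta = vals.quantile(0.95, axis=1, interpolation="linear")
    elif method == "parametric":
        logs = np.log(vals)
        theta = np.exp(logs.mean(axis=1) + 1.645 * logs.std(axis=1, ddof=1))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    theta.name = "theta"
    return theta


def fit_afp_threshold(
    ann: pd.DataFrame, control_group: str, sample_ids: Sequence[str] | None = None
) -> float:
    """Control-derived 95th-percentile threshold for AFP (ng/mL)."""
    a = _ann_index(ann)
    ids = list(sample_ids) if sample_ids is not None else list(a.index)
    ctrl = [s for s in ids if a["group"].get(s) == control_group]
    if len(ctrl) < 5:
        raise ValueError(f"need >=5 control samples for AFP threshold, got {len(ctrl)}")
    afp = a.loc[ctrl, "afp"]
    if afp.isna().any():
        raise ValueError(f"missing AFP for samples: {list(afp.index[afp.isna()])}")
    return float(np.quantile(afp.to_numpy(), 0.95))


def code_samples(
    expr: RelExprMatrix, panel: Sequence[str], theta: pd.Series
) -> pd.DataFrame:
    """0/1 marker coding: s_ij = 1 iff expr_ij > theta_j and not censored."""
    missing = set(panel) - set(expr.marker_ids)
    if missing:
        raise KeyError(f"panel markers absent from expression: {sorted(missing)}")
    th = theta.reindex(list(panel))
    if th.isna().any():
        raise KeyError(f"thresholds missing for: {list(th.index[th.isna()])}")
    over = expr.expr.loc[list(panel)].gt(th, axis=0)
    s = (over & ~expr.censored.loc[list(panel)]).astype(int)
    return s


def risk_scores(
    s: pd.DataFrame, weights: pd.Series, allow_negative: bool = False
) -> pd.Series:
    """rsf_i = sum_j W_j * s_ij over the panel markers (rows of *s*)."""
    w = weights.reindex(s.index)
    if w.isna().any():
        raise KeyError(f"weights missing for: {list(w.index[w.isna()])}")
    if not allow_negative and (w < 0).any():
        raise ValueError("negative weights rejected (set allow_negative to override)")
    bad = ~s.isin([0, 1]).all(axis=None)
    if bad:
        raise ValueError("codes must be 0/1")
    rsf = s.mul(w, axis=0).sum(axis=0)
    rsf.name = "rsf"
    return rsf


def _sens_spec(rsf: np.ndarray, labels: np.ndarray, c: float) -> tuple[float, float]:
    pred = rsf >= c
    sens = float(pred[labels].mean())
    spec = float((~pred[~labels]).mean())
    return sens, spec


def fit_cutoff(rsf, labels, rule: str = "max_sens_spec") -> float:
    """Training cut-off for the rule ``rsf >= c -> high risk``.

    ``max_sens_spec`` scans the midpoints between adjacent distinct scores
    plus +/-inf and keeps the candidate maximising sensitivity + specificity;
    ties break toward higher specificity, then toward smaller c.
    ``median`` returns the median training score.
    """
    rsf = np.asarray(rsf, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if rsf.shape != labels.shape:
        raise ValueError("rsf and labels must be aligned")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to fit a cutoff")
    if rule == "median":
        return float(np.median(rsf))
    if rule != "max_sens_spec":
        raise ValueError(f"unknown cutoff rule {rule!r}")
    values = np.unique(rsf)
    candidates = np.concatenate(
        [[-np.inf], (values[:-1] + values[1:]) / 2.0, [np.inf]]
    )
    best: tuple[float, float, float] | None = None  # (J, spec, c)
    for c in candidates:
        sens, spec = _sens_spec(rsf, labels, c)
        j = sens + spec
        if best is None or (j, spec, -c) > (best[0], best[1], -best[2]):
            best = (j, spec, float(c))
    assert best is not None
    return best[2]


def combine_with_afp(
    s: pd.DataFrame, weights: pd.Series, afp: pd.Series, afp_theta: float
) -> pd.Series:
    """Extended RSF with AFP appended as a (J+1)-th coded marker, weight 1."""
    afp = afp.reindex(s.columns)
    if afp.isna().any():
        raise ValueError(f"missing AFP for samples: {list(afp.index[afp.isna()])}")
    rsf = risk_scores(s, weights)
    ext = rsf + (afp > afp_theta).astype(int)
    ext.name = "rsf_with_afp"
    return ext


def fit_risk_model(
    expr: RelExprMatrix,
    ann: pd.DataFrame,
    panel: Sequence[str],
    contrast,
    *,
    control_group: str = "NC",
    weights_mode: str = "unit",
    log2_fc: pd.Series | None = None,
    quantile_method: str = "quantile",
    cutoff_rule: str = "max_sens_spec",
    with_afp: bool = True,
) -> RiskModel:
    """Fit theta, W and the cut-off(s) on one training split and freeze.

    *expr* must already be restricted to the training samples; theta comes
    from its control samples, the cut-off from the contrast's two sides.
    ``weights_mode="log2fc"`` uses |log2 fold change| (pass *log2_fc*) instead
    of unit weights.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("cannot fit a risk model on an empty panel")
    theta = fit_thresholds(expr, ann, control_group, panel, method=quantile_method)
    if weights_mode == "unit":
        weights = pd.Series(1.0, index=panel)
    elif weights_mode == "log2fc":
        if log2_fc is None:
            raise ValueError("weights_mode='log2fc' requires log2_fc")
        weights = log2_fc.reindex(panel).abs()
        if weights.isna().any():
            raise KeyError("log2_fc missing for some panel markers")
    else:
        raise ValueError(f"unknown weights_mode {weights_mode!r}")

    low_ids, high_ids = contrast.side_ids(ann, expr.sample_ids)
    fit_ids = low_ids + high_ids
    sub = expr.subset(fit_ids)
    s = code_samples(sub, panel, theta)
    rsf = risk_scores(s, weights)
    labels = np.array([sid in set(high_ids) for sid in fit_ids])
    cutoff = fit_cutoff(rsf.to_numpy(), labels, rule=cutoff_rule)

    afp_theta = None
    cutoff_afp = None
    if with_afp:
        afp_theta = fit_afp_threshold(ann, control_group, expr.sample_ids)
        afp = _ann_index(ann)["afp"]
        ext = combine_with_afp(s, weights, afp.reindex(fit_ids), afp_theta)
        cutoff_afp = fit_cutoff(ext.to_numpy(), labels, rule=cutoff_rule)

    groups = _ann_index(ann)["group"]
    ctrl_ids = [s_ for s_ in expr.sample_ids if groups.get(s_) == control_group]
    model = RiskModel(
        marker_ids=tuple(panel),
        theta={m: float(theta[m]) for m in panel},
        weights={m: float(weights[m]) for m in panel},
        cutoff=cutoff,
        cutoff_with_afp=cutoff_afp,
        afp_theta=afp_theta,
        variant="panel_plus_afp" if with_afp else "panel_only",
        contrast_name=contrast.name,
        fit_sample_ids=tuple(sorted(set(fit_ids) | set(ctrl_ids))),
    )
    return model.freeze()
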