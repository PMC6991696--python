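"""Differential screening of markers per group contrast and Venn selection.

Each contrast compares a lower disease stage against a higher one. A marker
passes a contrast when, on that contrast's samples:

* two-sample Student t test on log2 relative expression gives p < alpha,
* it is up-regulated (positive log2 fold change, higher group over lower),
* mean raw Ct in the higher-expression group is below ``ct_max``
  (the marker is actually measurable where it matters), and
* the detection rate exceeds ``det_min`` in both compared groups.

Candidates are the intersection of the per-contrast pass sets (the Venn
step), ranked by combined evidence (sum of -log10 p over contrasts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CtMatrix, GROUPS
from .quant import RelExprMatrix, _ann_index


def _as_groups(side) -> tuple[str, ...]:
    groups = (side,) if isinstance(side, str) else tuple(side)
    unknown = set(groups) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}; expected {GROUPS}")
    return groups


@dataclass(frozen=True)
class Contrast:
    """An ordered two-sided comparison; each side may pool several groups."""

    name: str
    low: tuple[str, ...]
    high: tuple[str, ...]

    def __init__(self, name: str, low, high):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "low", _as_groups(low))
        object.__setattr__(self, "high", _as_groups(high))
        if set(self.low) & set(self.high):
            raise ValueError(f"contrast {name!r}: sides share groups")

    def side_ids(self, ann: pd.DataFrame, sample_ids) -> tuple[list[str], list[str]]:
        groups = _ann_index(ann)["group"]
        low = [s for s in sample_ids if groups.get(s) in self.low]
        high = [s for s in sample_ids if groups.get(s) in self.high]
        return low, high

    def to_dict(self) -> dict:
        return {"name": self.name, "low": list(self.low), "high": list(self.high)}

    @classmethod
    def from_dict(cls, d: dict) -> "Contrast":
        return cls(d["name"], d["low"], d["high"])


#: adjacent-stage screening comparisons of the multiphase design
SCREENING_CONTRASTS: tuple[Contrast, ...] = (
    Contrast("CH_vs_NC", "NC", "CH"),
    Contrast("HCCN_vs_CH", "CH", "HCC-N"),
    Contrast("HCCM_vs_HCCN", "HCC-N", "HCC-M"),
)

#: diagnostic comparisons the risk model is evaluated on
EVAL_CONTRASTS: tuple[Contrast, ...] = (
    Contrast("HCC_vs_NC", "NC", ("HCC-N", "HCC-M")),
    Contrast("HCC_vs_CH", "CH", ("HCC-N", "HCC-M")),
    Contrast("HCCM_vs_HCCN", "HCC-N", "HCC-M"),
)


@dataclass
class ScreenResult:
    contrast: Contrast
    table: pd.DataFrame  # indexed by marker id

    @property
    def pass_set(self) -> set[str]:
        return set(self.table.index[self.table["pass"]])

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, sep="\t")


@dataclass
class CandidatePanel:
    assay_ids: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.assay_ids)) != len(self.assay_ids):
            raise ValueError("panel assay ids must be unique")

    def __len__(self) -> int:
        return len(self.assay_ids)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"assay_ids": self.assay_ids, "provenance": self.provenance},
                indent=1,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CandidatePanel":
        d = json.loads(Path(path).read_text())
        return cls(assay_ids=d["assay_ids"], provenance=d["provenance"])


def _det_rate(matrix: CtMatrix, ids: Sequence[str]) -> pd.Series:
    return (~matrix.nondetect.loc[matrix.marker_ids, list(ids)]).mean(axis=1)


def screen_contrast(
    expr: RelExprMatrix,
    ct: CtMatrix,
    ann: pd.DataFrame,
    contrast: Contrast,
    alpha: float = 0.05,
    ct_max: float = 35.0,
    det_min: float = 0.75,
    min_abs_log2_fc: float = 0.0,
    multitest: str | None = None,
) -> ScreenResult:
    """Apply the per-contrast screening filters to every marker.

    ``multitest="fdr_bh"`` optionally replaces the raw-p gate with a
    Benjamini-Hochberg adjusted one (off by default).
    """
    low_ids, high_ids = contrast.side_ids(ann, expr.sample_ids)
    if len(low_ids) < 2 or len(high_ids) < 2:
        raise ValueError(
            f"contrast {contrast.name!r} needs >=2 samples per side "
            f"(got {len(low_ids)} low, {len(high_ids)} high)"
        )
    log2e = expr.log2()
    lo = log2e[low_ids].to_numpy()
    hi = log2e[high_ids].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(hi, lo, axis=1, equal_var=True)
    log2_fc = hi.mean(axis=1) - lo.mean(axis=1)

    det_low = _det_rate(ct, low_ids).reindex(expr.marker_ids)
    det_high = _det_rate(ct, high_ids).reindex(expr.marker_ids)
    mean_ct_high = ct.ct.loc[expr.marker_ids, high_ids].mean(axis=1)

    p_gate = pval.copy()
    if multitest == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        finite = np.isfinite(pval)
        adj = np.full_like(pval, np.nan)
        if finite.any():
            adj[finite] = multipletests(pval[finite], method="fdr_bh")[1]
        p_gate = adj
    elif multitest is not None:
        raise ValueError(f"unknown multitest method {multitest!r}")

    direction = np.where(log2_fc > 0, "up", np.where(log2_fc < 0, "down", "flat"))
    passed = (
        (p_gate < alpha)
        & (direction == "up")
        & (np.abs(log2_fc) >= min_abs_log2_fc)
        & (mean_ct_high.to_numpy() < ct_max)
        & (det_low.to_numpy() > det_min)
        & (det_high.to_numpy() > det_min)
    )
    passed = np.where(np.isfinite(p_gate), passed, False).astype(bool)

    n_cens_low = expr.censored[low_ids].sum(axis=1)
    n_cens_high = expr.censored[high_ids].sum(axis=1)
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": pval,
            "det_rate_low": det_low.to_numpy(),
            "det_rate_high": det_high.to_numpy(),
            "mean_ct_high": mean_ct_high.to_numpy(),
            "n_censored_low": n_cens_low.to_numpy(),
            "n_censored_high": n_cens_high.to_numpy(),
            "direction": direction,
            "pass": passed,
        },
        index=pd.Index(expr.marker_ids, name="assay_id"),
    )
    return ScreenResult(contrast=contrast, table=table)


def venn_candidates(results: Sequence[ScreenResult]) -> CandidatePanel:
    """Markers up-regulated in EVERY supplied contrast, by set intersection.

    Ranked by combined evidence: descending sum of -log10 p over the supplied
    contrasts, ties broken by assay id.
    """
    if len(results) < 2:
        raise ValueError("need at least two screen results to intersect")
    roster = list(results[0].table.index)
    for r in results[1:]:
        if list(r.table.index) != roster:
            raise ValueError("screen results cover inconsistent assay rosters")
    common = set(roster)
    for r in results:
        common &= r.pass_set
    with np.errstate(divide="ignore"):
        evidence = {
            m: sum(-np.log10(r.table.loc[m, "p_value"]) for r in results)
            for m in common
        }
    ordered = sorted(common, key=lambda m: (-evidence[m], m))
    return CandidatePanel(
        assay_ids=ordered, provenance=[r.contrast.name for r in results]
    )


def confirm_in_set(
    expr: RelExprMatrix,
    ann: pd.DataFrame,
    panel: CandidatePanel,
    contrast: Contrast,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-test panel markers only, in a new sample split.

    Confirmed means up-regulated with p < alpha on the provided samples.
    """
    missing = set(panel.assay_ids) - set(expr.marker_ids)
    if missing:
        raise KeyError(f"panel markers absent from expression: {sorted(missing)}")
    cols = ["log2_fc", "p_value", "confirmed"]
    if not panel.assay_ids:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="assay_id"))
    low_ids, high_ids = contrast.side_ids(ann, expr.sample_ids)
    if len(low_ids) < 2 or len(high_ids) < 2:
        raise ValueError(f"contrast {contrast.name!r} needs >=2 samples per side")
    log2e = expr.log2().loc[panel.assay_ids]
    lo = log2e[low_ids].to_numpy()
    hi = log2e[high_ids].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pval = stats.ttest_ind(hi, lo, axis=1, equal_var=True)
    log2_fc = hi.mean(axis=1) - lo.mean(axis=1)
    confirmed = (log2_fc > 0) & np.where(np.isfinite(pval), pval < alpha, False)
    return pd.DataFrame(
        {"log2_fc": log2_fc, "p_value": pval, "confirmed": confirmed},
        index=pd.Index(panel.assay_ids, name="assay_id"),
    )
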