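"""Comparative-Ct relative quantification against a spike-in reference.

dCt[j, i] = Ct[j, i] - Ct[ref, i] removes per-sample technical scale via the
exogenous spike-in; ddCt subtracts the per-marker mean dCt of a designated
baseline group (healthy controls by default), and relative expression is
2^-ddCt, so one qPCR cycle equals a two-fold change and the baseline group
has per-marker geometric-mean expression exactly 1.

Nondetect cells are imputed at the censoring limit before subtraction — the
lowest expression consistent with the observation — and the censoring flag is
carried on every downstream container rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CtMatrix, GROUPS


@dataclass
class RelExprMatrix:
    """Relative expression 2^-ddCt (markers x samples) plus censoring mask."""

    expr: pd.DataFrame
    censored: pd.DataFrame
    baseline_group: str
    n_baseline: int

    def __post_init__(self) -> None:
        if self.expr.shape != self.censored.shape:
            raise ValueError("expr and censored shapes differ")
        if np.any(self.expr.to_numpy() <= 0):
            raise ValueError("relative expression must be > 0")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)

    def subset(self, sample_ids) -> "RelExprMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.expr.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)[:5]}")
        return RelExprMatrix(
            expr=self.expr[ids],
            censored=self.censored[ids],
            baseline_group=self.baseline_group,
            n_baseline=self.n_baseline,
        )

    def log2(self) -> pd.DataFrame:
        """log2 relative expression (= -ddCt); the scale tests operate on."""
        return np.log2(self.expr)


def _ann_index(ann: pd.DataFrame) -> pd.DataFrame:
    return ann.set_index("sample_id", drop=False)


def delta_ct(matrix: CtMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample dCt of every marker against the spike-in reference.

    Returns ``(dct, censored)`` with the reference row removed. Raises if the
    reference is nondetect in any sample (the sample is named).
    """
    ref = matrix.nondetect.loc[matrix.reference_assay_id]
    if bool(ref.any()):
        bad = list(matrix.nondetect.columns[ref])
        raise ValueError(f"reference assay nondetect in samples: {bad}")
    markers = matrix.marker_ids
    ref_ct = matrix.ct.loc[matrix.reference_assay_id]
    dct = matrix.ct.loc[markers].sub(ref_ct, axis=1)
    return dct, matrix.nondetect.loc[markers].copy()


def rel_expression(
    matrix: CtMatrix, ann: pd.DataFrame, baseline_group: str = "NC"
) -> RelExprMatrix:
    """Comparative 2^-ddCt relative expression against *baseline_group*.

    The baseline statistic is the arithmetic mean dCt over the baseline
    samples present in the matrix, making their geometric-mean expression 1.
    """
    dct, censored = delta_ct(matrix)
    groups = _ann_index(ann)["group"]
    base_ids = [s for s in matrix.sample_ids if groups.get(s) == baseline_group]
    if not base_ids:
        raise ValueError(f"baseline group {baseline_group!r} has no samples")
    ddct = dct.sub(dct[base_ids].mean(axis=1), axis=0)
    return RelExprMatrix(
        expr=np.exp2(-ddct),
        censored=censored,
        baseline_group=baseline_group,
        n_baseline=len(base_ids),
    )


def detection_rate(matrix: CtMatrix, ann: pd.DataFrame, group: str) -> pd.Series:
    """Per-marker fraction of *group* samples with detected (non-ND) signal."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    groups = _ann_index(ann)["group"]
    ids = [s for s in matrix.sample_ids if groups.get(s) == group]
    if not ids:
        raise ValueError(f"group {group!r} has no samples in matrix")
    detected = ~matrix.nondetect.loc[matrix.marker_ids, ids]
    return detected.mean(axis=1)
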