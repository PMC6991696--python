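from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from exopanel import CtMatrix, RelExprMatrix, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_per_group_screen=4,
        n_per_group_train=10,
        n_per_group_valid=20,
        n_blind=12,
        n_markers_total=30,
        planted_marker_ids=("LNC-0001", "LNC-0002", "LNC-0003"),
        delta_dct_per_stage=2.0,
        sigma_dct=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_ct_matrix(ct_values, sample_ids=None, marker_ids=None, nondetect=None,
                   ref_ct=20.0, limit=35.0) -> CtMatrix:
    """Hand-rolled CtMatrix with an appended constant-Ct reference row."""
    ct_values = np.asarray(ct_values, dtype=float)
    n_markers, n_samples = ct_values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(1, n_samples + 1)]
    marker_ids = marker_ids or [f"M{i}" for i in range(1, n_markers + 1)]
    nd = np.zeros_like(ct_values, dtype=bool) if nondetect is None else np.asarray(nondetect)
    ct_values = np.where(nd, limit, ct_values)
    ct = pd.DataFrame(
        np.vstack([ct_values, np.full((1, n_samples), ref_ct)]),
        index=pd.Index(marker_ids + ["cel-miR-39"], name="assay_id"),
        columns=sample_ids,
    )
    mask = pd.DataFrame(
        np.vstack([nd, np.zeros((1, n_samples), dtype=bool)]),
        index=ct.index, columns=ct.columns,
    )
    return CtMatrix(ct=ct, nondetect=mask, nondetect_limit=limit)


def make_ann(sample_ids, groups, split="screen", afp=None) -> pd.DataFrame:
    afp = afp if afp is not None else np.full(len(sample_ids), 10.0)
    return pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "afp": afp,
         "split": [split] * len(sample_ids) if isinstance(split, str) else split}
    )


def make_expr(values, sample_ids=None, marker_ids=None, censored=None) -> RelExprMatrix:
    values = np.asarray(values, dtype=float)
    n_markers, n_samples = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(1, n_samples + 1)]
    marker_ids = marker_ids or [f"M{i}" for i in range(1, n_markers + 1)]
    expr = pd.DataFrame(values, index=pd.Index(marker_ids, name="assay_id"),
                        columns=sample_ids)
    cens = (
        pd.DataFrame(np.zeros_like(values, dtype=bool), index=expr.index,
                     columns=expr.columns)
        if censored is None
        else pd.DataFrame(np.asarray(censored, dtype=bool), index=expr.index,
                          columns=expr.columns)
    )
    return RelExprMatrix(expr=expr, censored=cens, baseline_group="NC", n_baseline=1)
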