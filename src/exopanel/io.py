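"""Plain-text serialization of cohorts and expression matrices.

Ct matrices travel as TSV (rows = assays, first column ``assay_id``, one
column per sample) with nondetects written as the sentinel token ``ND`` —
never as a fake numeric Ct. A sidecar ``meta.json`` records the reference
assay id and the censoring limit so a round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CtMatrix

ND_SENTINEL = "ND"

CT_FILE = "ct.tsv"
ANN_FILE = "annotation.tsv"
META_FILE = "meta.json"


def write_cohort(matrix: CtMatrix, ann: pd.DataFrame, out_dir: str | Path) -> dict:
    """Write ``ct.tsv``, ``annotation.tsv`` and ``meta.json`` under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if list(matrix.sample_ids) != list(ann["sample_id"]):
        raise ValueError("matrix and annotation sample ids differ (order matters)")

    body = matrix.ct.astype(object).copy()
    body = body.mask(matrix.nondetect, ND_SENTINEL)
    ct_path = out / CT_FILE
    body.to_csv(ct_path, sep="\t")

    ann_path = out / ANN_FILE
    ann.to_csv(ann_path, sep="\t", index=False)

    meta = {
        "reference_assay_id": matrix.reference_assay_id,
        "nondetect_limit": matrix.nondetect_limit,
    }
    meta_path = out / META_FILE
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return {"ct": ct_path, "annotation": ann_path, "meta": meta_path}


def read_cohort(in_dir: str | Path) -> tuple[CtMatrix, pd.DataFrame]:
    """Inverse of :func:`write_cohort`."""
    src = Path(in_dir)
    meta = json.loads((src / META_FILE).read_text())
    raw = pd.read_csv(src / CT_FILE, sep="\t", index_col=0, dtype=str)
    nondetect = raw == ND_SENTINEL
    ct = raw.mask(nondetect, str(meta["nondetect_limit"])).astype(float)
    matrix = CtMatrix(
        ct=ct,
        nondetect=nondetect.astype(bool),
        reference_assay_id=meta["reference_assay_id"],
        nondetect_limit=float(meta["nondetect_limit"]),
    )
    ann = pd.read_csv(
        src / ANN_FILE,
        sep="\t",
        dtype={"sample_id": str, "group": str, "split": str},
    )
    return matrix, ann


def write_expression(expr: pd.DataFrame, censored: pd.DataFrame, prefix: str | Path) -> dict:
    """Write an expression matrix and its parallel censoring mask.

    Produces ``<prefix>.tsv`` and ``<prefix>.censored.tsv``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    expr_path = prefix.with_suffix(".tsv")
    mask_path = prefix.with_name(prefix.name + ".censored.tsv")
    expr.to_csv(expr_path, sep="\t")
    censored.astype(int).to_csv(mask_path, sep="\t")
    return {"expr": expr_path, "censored": mask_path}


def read_expression(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    expr = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col=0)
    mask = pd.read_csv(
        prefix.with_name(prefix.name + ".censored.tsv"), sep="\t", index_col=0
    ).astype(bool)
    return expr, mask
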