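"""Synthetic multiphase case-control cohorts of circulating-biomarker qPCR data.

The generator emulates the data layout of a plasma exosomal lncRNA study: a
Ct matrix (assays x samples) that includes one exogenous spike-in reference
assay (cel-miR-39 style), and a per-sample annotation table with a four-level
ordered disease group (NC < CH < HCC-N < HCC-M), a serum AFP covariate, and a
fixed assignment to the study phases (screen / train / valid / blind).

Expression acts on the dCt scale (dCt = Ct_marker - Ct_reference): planted
marker dCt decreases by a fixed step per disease stage (lower Ct = higher
abundance), null markers share one group-independent dCt distribution, and
non-detection arises by right-censoring simulated Ct at the assay's
quantification limit (default Ct 35).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

GROUPS: tuple[str, ...] = ("NC", "CH", "HCC-N", "HCC-M")
GROUP_STAGE: dict[str, int] = {g: i for i, g in enumerate(GROUPS)}
SPLITS: tuple[str, ...] = ("screen", "train", "valid", "blind")

DEFAULT_REFERENCE_ID = "cel-miR-39"


class SimConfig(BaseModel):
    """Parameters of the synthetic cohort.

    The split sizes default to the multiphase design of the study family this
    package targets: a 3-per-group pilot screen, a 20-per-group training set,
    a 180-per-group validation set and 100 double-blind samples.
    """

    n_per_group_screen: int = Field(default=3, ge=1)
    n_per_group_train: int = Field(default=20, ge=1)
    n_per_group_valid: int = Field(default=180, ge=1)
    n_blind: int = Field(default=100, ge=1)
    n_markers_total: int = Field(default=200, ge=1)
    planted_marker_ids: tuple[str, ...] = ("LNC-0001", "LNC-0002", "LNC-0003")
    #: decrease in dCt per disease stage NC -> CH -> HCC-N -> HCC-M (planted only)
    delta_dct_per_stage: float = 1.0
    #: within-group SD of dCt, in Ct units
    sigma_dct: float = Field(default=1.0, gt=0.0)
    nondetect_limit: float = Field(default=35.0, gt=0.0)
    #: group-independent mean dCt of null markers
    dct_mean_null: float = 12.0
    #: mean dCt of planted markers in the NC group
    dct_mean_planted_base: float = 12.0
    reference_assay_id: str = DEFAULT_REFERENCE_ID
    reference_ct_mean: float = 20.0
    reference_ct_sd: float = Field(default=0.25, gt=0.0)
    afp_log_mean_by_group: dict[str, float] = Field(
        default_factory=lambda: {"NC": 2.0, "CH": 2.3, "HCC-N": 2.6, "HCC-M": 2.9}
    )
    afp_log_sd: float = Field(default=1.8, gt=0.0)
    seed: int = 0

    @property
    def marker_ids(self) -> list[str]:
        return [f"LNC-{i:04d}" for i in range(1, self.n_markers_total + 1)]

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        roster = set(self.marker_ids)
        missing = [m for m in self.planted_marker_ids if m not in roster]
        if missing:
            raise ValueError(f"planted marker ids not in assay roster: {missing}")
        if len(set(self.planted_marker_ids)) != len(self.planted_marker_ids):
            raise ValueError("planted marker ids must be unique")
        if self.reference_assay_id in roster:
            raise ValueError("reference assay id collides with a marker id")
        extra = set(self.afp_log_mean_by_group) - set(GROUPS)
        if extra or set(GROUPS) - set(self.afp_log_mean_by_group):
            raise ValueError(f"afp_log_mean_by_group must cover exactly {GROUPS}")
        if self.nondetect_limit <= self.reference_ct_mean + 8 * self.reference_ct_sd:
            raise ValueError(
                "nondetect_limit must sit clearly above the reference spike-in Ct"
            )
        return self


@dataclass
class CtMatrix:
    """Raw Ct values (assays x samples) with a nondetect mask.

    ``ct`` includes the reference assay row. Cells flagged in ``nondetect``
    hold the censoring limit as their numeric value (the lowest expression
    consistent with the observation); the reference row is never censored.
    """

    ct: pd.DataFrame
    nondetect: pd.DataFrame
    reference_assay_id: str = DEFAULT_REFERENCE_ID
    nondetect_limit: float = 35.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.ct.shape != self.nondetect.shape:
            raise ValueError("ct and nondetect shapes differ")
        if not self.ct.index.equals(self.nondetect.index) or not self.ct.columns.equals(
            self.nondetect.columns
        ):
            raise ValueError("ct and nondetect must share assay/sample labels")
        if self.reference_assay_id not in self.ct.index:
            raise ValueError(f"reference assay {self.reference_assay_id!r} missing")
        if bool(self.nondetect.loc[self.reference_assay_id].any()):
            bad = self.nondetect.columns[self.nondetect.loc[self.reference_assay_id]]
            raise ValueError(
                f"reference assay nondetect in samples: {list(bad[:5])}"
            )
        vals = self.ct.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("all Ct values must be finite and > 0")

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def marker_ids(self) -> list[str]:
        return [a for a in self.ct.index if a != self.reference_assay_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    def subset(self, sample_ids) -> "CtMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.ct.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)[:5]}")
        return CtMatrix(
            ct=self.ct[ids].copy(),
            nondetect=self.nondetect[ids].copy(),
            reference_assay_id=self.reference_assay_id,
            nondetect_limit=self.nondetect_limit,
        )


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows: list[tuple[str, str]] = []  # (group, split)
    for split, n_per_group in (
        ("screen", config.n_per_group_screen),
        ("train", config.n_per_group_train),
        ("valid", config.n_per_group_valid),
    ):
        for g in GROUPS:
            rows.extend([(g, split)] * n_per_group)
    # blind samples spread across the four groups, remainder to earlier groups
    base, rem = divmod(config.n_blind, len(GROUPS))
    for i, g in enumerate(GROUPS):
        rows.extend([(g, "blind")] * (base + (1 if i < rem else 0)))
    ann = pd.DataFrame(rows, columns=["group", "split"])
    ann.insert(0, "sample_id", [f"S{i:05d}" for i in range(1, len(ann) + 1)])
    return ann


def generate_cohort(config: SimConfig) -> tuple[CtMatrix, pd.DataFrame]:
    """Simulate one cohort: Ct matrix (markers + reference) and annotations.

    Deterministic given ``config.seed``; all draws flow from a single
    ``numpy.random.default_rng`` stream in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    ann = _sample_table(config)
    n_samples = len(ann)
    markers = config.marker_ids
    planted = set(config.planted_marker_ids)
    stages = ann["group"].map(GROUP_STAGE).to_numpy()

    ref_ct = rng.normal(config.reference_ct_mean, config.reference_ct_sd, n_samples)

    mean_dct = np.empty((len(markers), n_samples))
    for j, m in enumerate(markers):
        if m in planted:
            mean_dct[j] = (
                config.dct_mean_planted_base - config.delta_dct_per_stage * stages
            )
        else:
            mean_dct[j] = config.dct_mean_null
    dct = rng.normal(mean_dct, config.sigma_dct)

    ct_markers = ref_ct[None, :] + dct
    nondetect = ct_markers >= config.nondetect_limit
    ct_markers = np.where(nondetect, config.nondetect_limit, ct_markers)

    afp_mu = ann["group"].map(config.afp_log_mean_by_group).to_numpy(dtype=float)
    afp = np.exp(rng.normal(afp_mu, config.afp_log_sd))
    ann = ann.assign(afp=afp)[["sample_id", "group", "afp", "split"]]

    sample_ids = ann["sample_id"].tolist()
    index = pd.Index(markers + [config.reference_assay_id], name="assay_id")
    ct = pd.DataFrame(
        np.vstack([ct_markers, ref_ct[None, :]]), index=index, columns=sample_ids
    )
    nd = pd.DataFrame(
        np.vstack([nondetect, np.zeros((1, n_samples), dtype=bool)]),
        index=index,
        columns=sample_ids,
    )
    matrix = CtMatrix(
        ct=ct,
        nondetect=nd,
        reference_assay_id=config.reference_assay_id,
        nondetect_limit=config.nondetect_limit,
    )
    return matrix, ann
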