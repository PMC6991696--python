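"""End-to-end orchestration of the multiphase case-control design.

simulate (or load) -> screen on the pilot split -> Venn candidate panel ->
confirm in the training split -> fit the frozen risk model on training ->
evaluate on the validation split -> classify the double-blind split.

Splits are fixed in the annotation table and never re-randomized inside a
stage; all stochastic behaviour flows from the single root seed in the
configuration. Re-running the same configuration reproduces byte-identical
artifacts, every one stamped with the configuration hash and seed, and the
run log records every filter decision count so the screening funnel can be
audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as _io
from .cohort import CtMatrix, SimConfig, generate_cohort
from .quant import RelExprMatrix, rel_expression, _ann_index
from .risk import RiskModel, fit_risk_model
from .screen import (
    EVAL_CONTRASTS,
    SCREENING_CONTRASTS,
    CandidatePanel,
    Contrast,
    ScreenResult,
    confirm_in_set,
    screen_contrast,
    venn_candidates,
)
from .evaluate import blind_accuracy, evaluate_contrast


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class PipelineConfig(BaseModel):
    """Full configuration of one pipeline run (JSON-serializable)."""

    sim: SimConfig | None = None
    ct_path: str | None = None
    ann_path: str | None = None  # unused when ct/ann live in one directory
    data_dir: str | None = None
    baseline_group: str = "NC"
    control_group: str = "NC"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    ct_max: float = 35.0
    det_min: float = Field(default=0.75, ge=0, lt=1)
    min_abs_log2_fc: float = 0.0
    multitest: str | None = None
    weights_mode: str = "unit"
    quantile_method: str = "quantile"
    cutoff_rule: str = "max_sens_spec"
    with_afp: bool = True
    screen_split: str = "screen"
    confirm_split: str = "train"
    fit_split: str = "train"
    eval_split: str = "valid"
    screening_contrasts: list[dict] | None = None
    eval_contrasts: list[dict] | None = None
    seed: int | None = None

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        if (self.sim is None) == (self.data_dir is None):
            raise ValueError("supply exactly one of sim | data_dir")
        return self

    def resolved_sim(self) -> SimConfig | None:
        if self.sim is None:
            return None
        if self.seed is not None and self.seed != self.sim.seed:
            return self.sim.model_copy(update={"seed": self.seed})
        return self.sim

    def contrasts(self) -> tuple[list[Contrast], list[Contrast]]:
        screen = (
            [Contrast.from_dict(d) for d in self.screening_contrasts]
            if self.screening_contrasts
            else list(SCREENING_CONTRASTS)
        )
        ev = (
            [Contrast.from_dict(d) for d in self.eval_contrasts]
            if self.eval_contrasts
            else list(EVAL_CONTRASTS)
        )
        return screen, ev

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    status: str
    out_dir: Path
    panel: CandidatePanel | None = None
    confirmed_panel: CandidatePanel | None = None
    screen_results: dict[str, ScreenResult] = field(default_factory=dict)
    models: dict[str, RiskModel] = field(default_factory=dict)
    eval_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    blind: dict[str, dict] = field(default_factory=dict)


def _split_ids(ann: pd.DataFrame, split: str) -> list[str]:
    a = _ann_index(ann)
    return list(a.index[a["split"] == split])


def _funnel(result: ScreenResult, alpha, ct_max, det_min) -> dict:
    t = result.table
    return {
        "assays_in": int(len(t)),
        "pass_p": int((t["p_value"] < alpha).sum()),
        "pass_up": int((t["direction"] == "up").sum()),
        "pass_ct": int((t["mean_ct_high"] < ct_max).sum()),
        "pass_det": int(
            ((t["det_rate_low"] > det_min) & (t["det_rate_high"] > det_min)).sum()
        ),
        "pass_all": int(t["pass"].sum()),
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run every stage of the multiphase design, writing artifacts to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    log_fh = open(log_path, "w")
    stamp = {"config_hash": config.config_hash(), "seed": None}

    def log(stage: str, event: str, **extra) -> None:
        log_fh.write(json.dumps({"stage": stage, "event": event, **extra}) + "\n")

    def tsv_stamp() -> str:
        return f"config_hash={stamp['config_hash']} seed={stamp['seed']}"

    result = PipelineResult(status="ok", out_dir=out)
    try:
        # ---- data ------------------------------------------------------
        sim = config.resolved_sim()
        try:
            if sim is not None:
                stamp["seed"] = sim.seed
                matrix, ann = generate_cohort(sim)
                _io.write_cohort(matrix, ann, out / "cohort")
                log("data", "simulated", n_samples=len(ann), n_markers=len(matrix.marker_ids))
            else:
                matrix, ann = _io.read_cohort(config.data_dir)
                stamp["seed"] = config.seed
                log("data", "loaded", n_samples=len(ann), n_markers=len(matrix.marker_ids))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("data", str(exc)) from exc

        screening, evaluating = config.contrasts()

        # ---- quantification --------------------------------------------
        try:
            expr = rel_expression(matrix, ann, config.baseline_group)
        except Exception as exc:
            raise PipelineError("quant", str(exc)) from exc

        # ---- screening on the pilot split ------------------------------
        try:
            ids = _split_ids(ann, config.screen_split)
            expr_screen = expr.subset(ids)
            ct_screen = matrix.subset(ids)
            for c in screening:
                r = screen_contrast(
                    expr_screen,
                    ct_screen,
                    ann,
                    c,
                    alpha=config.alpha,
                    ct_max=config.ct_max,
                    det_min=config.det_min,
                    min_abs_log2_fc=config.min_abs_log2_fc,
                    multitest=config.multitest,
                )
                result.screen_results[c.name] = r
                r.to_tsv(out / f"screen_{c.name}.tsv", header_comment=tsv_stamp())
                log("screen", "contrast", contrast=c.name,
                    **_funnel(r, config.alpha, config.ct_max, config.det_min))
        except Exception as exc:
            raise PipelineError("screen", str(exc)) from exc

        # ---- Venn candidate panel --------------------------------------
        try:
            panel = venn_candidates(list(result.screen_results.values()))
            result.panel = panel
            panel.to_json(out / "panel.json")
            log("venn", "panel", size=len(panel), assay_ids=panel.assay_ids)
        except Exception as exc:
            raise PipelineError("venn", str(exc)) from exc
        if not panel.assay_ids:
            result.status = "no_candidates"
            (out / "status.json").write_text(
                json.dumps({"status": result.status, **stamp}) + "\n"
            )
            log("pipeline", "stopped", status=result.status)
            return result

        # ---- training-set confirmation ---------------------------------
        try:
            ids = _split_ids(ann, config.confirm_split)
            expr_confirm = expr.subset(ids)
            confirmed = set(panel.assay_ids)
            tables = []
            for c in screening:
                t = confirm_in_set(expr_confirm, ann, panel, c, alpha=config.alpha)
                t = t.assign(contrast=c.name)
                tables.append(t)
                confirmed &= set(t.index[t["confirmed"]])
                log("confirm", "contrast", contrast=c.name,
                    n_confirmed=int(t["confirmed"].sum()))
            confirm_table = pd.concat(tables)
            with open(out / "confirm.tsv", "w") as fh:
                fh.write(f"# {tsv_stamp()}\n")
                confirm_table.to_csv(fh, sep="\t")
            confirmed_panel = CandidatePanel(
                assay_ids=[m for m in panel.assay_ids if m in confirmed],
                provenance=panel.provenance + [f"confirm:{config.confirm_split}"],
            )
            result.confirmed_panel = confirmed_panel
            confirmed_panel.to_json(out / "confirmed_panel.json")
            log("confirm", "panel", size=len(confirmed_panel),
                assay_ids=confirmed_panel.assay_ids)
        except Exception as exc:
            raise PipelineError("confirm", str(exc)) from exc
        if not confirmed_panel.assay_ids:
            result.status = "no_confirmed"
            (out / "status.json").write_text(
                json.dumps({"status": result.status, **stamp}) + "\n"
            )
            log("pipeline", "stopped", status=result.status)
            return result

        # ---- risk model fitting (training split, then frozen) ----------
        try:
            train_ids = _split_ids(ann, config.fit_split)
            expr_train = expr.subset(train_ids)
            for c in evaluating:
                model = fit_risk_model(
                    expr_train,
                    ann,
                    confirmed_panel.assay_ids,
                    c,
                    control_group=config.control_group,
                    weights_mode=config.weights_mode,
                    log2_fc=confirm_table.groupby(level=0)["log2_fc"].mean()
                    if config.weights_mode == "log2fc"
                    else None,
                    quantile_method=config.quantile_method,
                    cutoff_rule=config.cutoff_rule,
                    with_afp=config.with_afp,
                )
                result.models[c.name] = model
                model.to_json(out / f"model_{c.name}.json")
                log("fit", "model", contrast=c.name, cutoff=model.cutoff,
                    cutoff_with_afp=model.cutoff_with_afp)
        except Exception as exc:
            raise PipelineError("fit", str(exc)) from exc

        # ---- validation evaluation -------------------------------------
        try:
            for c in evaluating:
                table = evaluate_contrast(
                    result.models[c.name], expr, ann, c, split=config.eval_split
                )
                result.eval_tables[c.name] = table
                path = out / f"eval_{config.eval_split}_{c.name}.tsv"
                with open(path, "w") as fh:
                    fh.write(f"# {tsv_stamp()}\n")
                    table.to_csv(fh, sep="\t", index=False)
                log("evaluate", "contrast", contrast=c.name, split=config.eval_split,
                    panel_auc=float(table.loc[table["variant"] == "panel", "auc"].iloc[0]))
        except Exception as exc:
            raise PipelineError("evaluate", str(exc)) from exc

        # ---- double-blind classification -------------------------------
        try:
            blind = {}
            for c in evaluating:
                acc, cs = blind_accuracy(result.models[c.name], expr, ann, c)
                entry = {"accuracy": acc, **cs.as_dict()}
                if config.with_afp:
                    acc2, cs2 = blind_accuracy(
                        result.models[c.name], expr, ann, c, with_afp=True
                    )
                    entry["with_afp"] = {"accuracy": acc2, **cs2.as_dict()}
                blind[c.name] = entry
                log("blind", "contrast", contrast=c.name, accuracy=acc)
            result.blind = blind
            (out / "blind.json").write_text(json.dumps({**stamp, "blind": blind}, indent=1) + "\n")
        except Exception as exc:
            raise PipelineError("blind", str(exc)) from exc

        (out / "status.json").write_text(
            json.dumps({"status": result.status, **stamp}) + "\n"
        )
        manifest = {
            **stamp,
            "status": result.status,
            "panel": panel.assay_ids,
            "confirmed_panel": confirmed_panel.assay_ids,
            "contrasts": [c.name for c in evaluating],
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        log("pipeline", "done", status=result.status)
        return result
    finally:
        log_fh.close()
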