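"""ROC/AUC, confusion identities, contrast evaluation, blind set, stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exopanel import (
    Contrast,
    LeakageError,
    SimConfig,
    blind_accuracy,
    confusion,
    evaluate_contrast,
    fit_risk_model,
    generate_cohort,
    rel_expression,
    roc,
    stability_compare,
)
from exopanel.risk import RiskModel

from helpers import auc_pair_oracle, trapezoid_auc_exact

HCC_VS_NC = Contrast("HCC_vs_NC", "NC", ("HCC-N", "HCC-M"))


def test_auc_examples():
    assert roc([3, 1, 2, 0], [True, True, False, False]).auc == 0.75
    assert roc([1.0] * 6, [True] * 3 + [False] * 3).auc == 0.5
    assert roc([5, 6, 1, 2], [True, True, False, False]).auc == 1.0
    with pytest.raises(ValueError, match="both classes"):
        roc([1, 2], [True, True])


def test_roc_curve_shape_invariants():
    rng = np.random.default_rng(20)
    scores = rng.integers(0, 4, 30).astype(float)
    labels = rng.random(30) < 0.5
    curve = roc(scores, labels)
    assert curve.tpr[0] == 0 and curve.fpr[0] == 0
    assert curve.tpr[-1] == 1 and curve.fpr[-1] == 1
    assert (np.diff(curve.tpr) >= 0).all() and (np.diff(curve.fpr) >= 0).all()
    assert (np.diff(curve.thresholds) < 0).all()


@settings(max_examples=300, derandomize=True)
@given(
    scores=st.lists(st.integers(0, 5), min_size=2, max_size=12),
    draw=st.integers(0, 2**30),
)
def test_auc_equals_pair_counting_exactly(scores, draw):
    """Trapezoidal AUC over the stored curve equals the Mann-Whitney
    pair-counting oracle exactly on every small instance, ties included."""
    rng = np.random.default_rng(draw)
    labels = rng.random(len(scores)) < 0.5
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    curve = roc(np.array(scores, dtype=float), labels)
    oracle = auc_pair_oracle(scores, labels)
    assert trapezoid_auc_exact(curve) == oracle
    assert curve.auc == float(oracle)


def test_auc_matches_sklearn_on_random_floats():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(21)
    for _ in range(20):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        if labels.all() or not labels.any():
            continue
        assert roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


def test_auc_reflection_and_monotone_invariance():
    rng = np.random.default_rng(22)
    scores = rng.normal(size=40)  # tie-free almost surely
    labels = rng.random(40) < 0.5
    a = roc(scores, labels).auc
    assert a + roc(-scores, labels).auc == pytest.approx(1.0)
    assert roc(np.exp(scores), labels).auc == pytest.approx(a)


def test_confusion_identities():
    pred = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    labels = np.r_[np.ones(9, bool), np.zeros(1, bool),
                   np.ones(1, bool), np.zeros(9, bool)]
    cs = confusion(pred, labels)
    assert (cs.tp, cs.fp, cs.tn, cs.fn) == (9, 1, 9, 1)
    assert cs.ppv == cs.npv == cs.accuracy == 0.9
    all_right = confusion(labels, labels)
    assert all_right.sensitivity == all_right.specificity == all_right.accuracy == 1.0


def test_confusion_random_tally_oracle():
    rng = np.random.default_rng(23)
    for _ in range(30):
        pred = rng.random(40) < 0.5
        labels = rng.random(40) < 0.5
        cs = confusion(pred, labels)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, y in zip(pred, labels):
            tally["tp" if p and y else "fp" if p else "fn" if y else "tn"] += 1
        assert (cs.tp, cs.fp, cs.tn, cs.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"])
        total = sum(tally.values())
        assert cs.accuracy == pytest.approx((cs.tp + cs.tn) / total)


def test_prevalence_rebalancing_moves_ppv_not_sens_spec():
    """Duplicating every positive sample leaves sensitivity/specificity
    untouched but raises PPV and lowers NPV, as Bayes' rule predicts."""
    pred = np.array([True] * 8 + [False] * 2 + [True] * 3 + [False] * 7)
    labels = np.array([True] * 10 + [False] * 10)
    base = confusion(pred, labels)
    pred2 = np.r_[pred, pred[:10], pred[:10]]
    labels2 = np.r_[labels, labels[:10], labels[:10]]
    up = confusion(pred2, labels2)
    assert up.sensitivity == base.sensitivity
    assert up.specificity == base.specificity
    assert up.ppv > base.ppv
    assert up.npv < base.npv


def _fitted_setup(seed=0, delta=1.0, n_markers=10):
    # training and validation sizes follow the multiphase study design
    cfg = SimConfig(
        n_per_group_screen=2, n_per_group_train=20, n_per_group_valid=180,
        n_blind=40, n_markers_total=n_markers, delta_dct_per_stage=delta,
        seed=seed,
    )
    matrix, ann = generate_cohort(cfg)
    expr = rel_expression(matrix, ann, "NC")
    train_ids = ann.loc[ann.split == "train", "sample_id"].tolist()
    model = fit_risk_model(
        expr.subset(train_ids), ann, ["LNC-0001", "LNC-0002", "LNC-0003"],
        HCC_VS_NC,
    )
    return model, expr, ann


def test_training_split_confusion_attains_fitted_optimum():
    model, expr, ann = _fitted_setup()
    table = evaluate_contrast(model, expr, ann, HCC_VS_NC, split="train")
    row = table[table["variant"] == "panel"].iloc[0]
    from helpers import cutoff_oracle
    a = ann.set_index("sample_id")
    ids = a.index[(a.split == "train") & a.group.isin(["NC", "HCC-N", "HCC-M"])]
    # by construction no candidate threshold can beat the fitted cut-off
    assert row["sensitivity"] + row["specificity"] == pytest.approx(
        cutoff_oracle(
            *_training_scores(model, expr, ann, ids)
        )[0]
    )


def _training_scores(model, expr, ann, ids):
    from exopanel.risk import code_samples, risk_scores

    sub = expr.subset(list(ids))
    s = code_samples(sub, list(model.marker_ids), pd.Series(model.theta))
    rsf = risk_scores(s, pd.Series(model.weights))
    labels = ann.set_index("sample_id").loc[list(ids), "group"].isin(
        ["HCC-N", "HCC-M"]).to_numpy()
    return rsf.to_numpy(), labels


def test_panel_beats_single_markers_in_most_seeds():
    """With planted effects, the coded panel's validation AUC beats every
    single coded-marker input in at least 90% of seeds."""
    wins = 0
    n_seeds = 50
    for seed in range(n_seeds):
        model, expr, ann = _fitted_setup(seed=seed)
        table = evaluate_contrast(model, expr, ann, HCC_VS_NC, split="valid")
        panel_auc = table.loc[table["variant"] == "panel", "auc"].iloc[0]
        singles = table.loc[table["variant"] == "single_marker", "auc"]
        wins += bool((panel_auc >= singles).all())
    assert wins >= int(0.9 * n_seeds)


def test_permuted_labels_give_null_aucs():
    model, expr, ann = _fitted_setup(seed=3)
    rng = np.random.default_rng(24)
    a = ann.copy()
    perm_groups = a["group"].to_numpy().copy()
    rng.shuffle(perm_groups)
    a["group"] = perm_groups
    aucs = []
    for seed in range(10):
        table = evaluate_contrast(model, expr, a, HCC_VS_NC, split="valid")
        aucs.extend(table["auc"].tolist())
        rng.shuffle(perm_groups)
        a["group"] = perm_groups
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_leakage_between_fit_and_eval_is_refused():
    model, expr, ann = _fitted_setup()
    leaky = ann.copy()
    # relabel one fitting sample into the validation split
    victim = model.fit_sample_ids[0]
    leaky.loc[leaky.sample_id == victim, "split"] = "valid"
    with pytest.raises(LeakageError):
        evaluate_contrast(model, expr, leaky, HCC_VS_NC, split="valid")


def test_unfrozen_model_cannot_evaluate_out_of_split():
    model, expr, ann = _fitted_setup()
    thawed = RiskModel(**{**model.__dict__, "frozen": False})
    with pytest.raises(ValueError, match="frozen"):
        evaluate_contrast(thawed, expr, ann, HCC_VS_NC, split="valid")


def test_blind_accuracy_everything_high_risk_is_prevalence():
    model, expr, ann = _fitted_setup()
    always_high = RiskModel(**{**model.__dict__, "cutoff": float("-inf")})
    acc, cs = blind_accuracy(always_high, expr, ann, HCC_VS_NC)
    a = ann.set_index("sample_id")
    blind = a[(a.split == "blind") & a.group.isin(["NC", "HCC-N", "HCC-M"])]
    assert acc == pytest.approx(blind.group.isin(["HCC-N", "HCC-M"]).mean())
    assert cs.sensitivity == 1.0 and cs.specificity == 0.0


def test_blind_accuracy_tracks_training_accuracy():
    model, expr, ann = _fitted_setup(seed=6, delta=2.0)
    acc, _ = blind_accuracy(model, expr, ann, HCC_VS_NC)
    table = evaluate_contrast(model, expr, ann, HCC_VS_NC, split="train")
    train_acc = table.loc[table["variant"] == "panel", "accuracy"].iloc[0]
    assert abs(acc - train_acc) < 0.25  # generalization within wide MC bounds
    assert acc > 0.8


def _paired_mats(rng, n_markers=6, n=10, shift=0.0):
    base = np.exp(rng.normal(0, 1, size=(n_markers, n)))
    cond = base * np.exp2(rng.normal(shift, 0.3, size=(n_markers, n)))
    idx = pd.Index([f"M{i}" for i in range(n_markers)], name="assay_id")
    cols = [f"S{i}" for i in range(n)]
    return (pd.DataFrame(base, index=idx, columns=cols),
            pd.DataFrame(cond, index=idx, columns=cols))


def test_stability_identical_replicates():
    rng = np.random.default_rng(25)
    base, _ = _paired_mats(rng)
    summary, detail = stability_compare(
        {"fresh": base, "12h": base.copy()}, baseline="fresh")
    assert (summary["min_p"] == 1.0).all()
    assert (summary["max_abs_log2_ratio"] == 0.0).all()
    assert summary["stable"].all()


def test_stability_detects_three_sigma_shift():
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        base, cond = _paired_mats(rng, n_markers=1, n=10, shift=0.9)  # 3x sd 0.3
        summary, _ = stability_compare({"fresh": base, "24h": cond}, "fresh")
        hits += int(not summary["stable"].iloc[0])
    assert hits >= int(0.99 * n_seeds)


def test_stability_null_calibration():
    flat = 0
    total = 0
    for seed in range(40):
        rng = np.random.default_rng(1000 + seed)
        base, c1 = _paired_mats(rng, n_markers=10, n=8, shift=0.0)
        _, c2 = _paired_mats(rng, n_markers=10, n=8, shift=0.0)
        c2 = base * np.exp2(rng.normal(0, 0.3, size=base.shape))
        _, detail = stability_compare(
            {"fresh": base, "12h": c1, "24h": c2}, "fresh")
        flat += (detail["p_value"] > 0.05).sum()
        total += len(detail)
    rate = flat / total
    half = 2.576 * np.sqrt(0.95 * 0.05 / total)
    assert abs(rate - 0.95) < max(half, 0.02)


def test_stability_rejects_unpaired_inputs():
    rng = np.random.default_rng(26)
    base, cond = _paired_mats(rng)
    with pytest.raises(ValueError, match="paired"):
        stability_compare({"fresh": base, "24h": cond.iloc[:, :-1]}, "fresh")
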