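"""Independent brute-force oracles used to check the implementation paths."""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def auc_pair_oracle(scores, labels) -> Fraction:
    """Mann-Whitney AUC by exhaustive pair counting, in exact rationals."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    num = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                num += 1
            elif p == n:
                num += Fraction(1, 2)
    return num / (len(pos) * len(neg))


def trapezoid_auc_exact(curve) -> Fraction:
    """Trapezoidal area of a stored ROC curve, in exact rationals."""
    area = Fraction(0)
    for i in range(1, len(curve.tp_counts)):
        dfp = int(curve.fp_counts[i] - curve.fp_counts[i - 1])
        area += Fraction(dfp * int(curve.tp_counts[i] + curve.tp_counts[i - 1]), 2)
    return area / (curve.n_pos * curve.n_neg)


def cutoff_oracle(rsf, labels):
    """Exhaustive search over midpoints plus +/-inf for max sens+spec.

    Returns (best_J, best_candidates) where best_candidates lists every
    threshold achieving the maximum, as (J, spec, c) tuples.
    """
    rsf = np.asarray(rsf, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    values = np.unique(rsf)
    candidates = np.concatenate([[-np.inf], (values[:-1] + values[1:]) / 2, [np.inf]])
    scored = []
    for c in candidates:
        pred = rsf >= c
        sens = pred[labels].mean()
        spec = (~pred[~labels]).mean()
        scored.append((sens + spec, spec, float(c)))
    best_j = max(s[0] for s in scored)
    return best_j, [s for s in scored if s[0] == best_j]


def venn_oracle(pass_sets):
    """Triple-nested-loop intersection of pass sets."""
    out = []
    for m in sorted(set.union(*map(set, pass_sets))):
        keep = True
        for ps in pass_sets:
            found = False
            for x in ps:
                if x == m:
                    found = True
            if not found:
                keep = False
        if keep:
            out.append(m)
    return out
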