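"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the library code paths they check: pair counting
for ROC-AUC, threshold enumeration for AP, and scalar step-by-step greedy
selection for the diversity picker.
"""

import itertools

from vscreen.fingerprints import tanimoto_distance


def auc_pair_counting(scores, labels):
    """Fraction of (active, inactive) pairs ranked correctly, ties as 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def ap_enumeration(scores, labels):
    """Step-wise AP by explicit enumeration of distinct score thresholds."""
    thresholds = sorted(set(scores), reverse=True)
    n_pos = sum(labels)
    points = []
    for t in thresholds:
        sel = [y for s, y in zip(scores, labels) if s >= t]
        tp = sum(sel)
        points.append((tp / len(sel), tp / n_pos))  # (precision, recall)
    ap, prev_r = 0.0, 0.0
    for p, r in points:
        ap += (r - prev_r) * p
        prev_r = r
    return ap


def greedy_maxmin_stepwise(candidates, n):
    """Scalar step-by-step max-min greedy pick over Candidate objects."""
    remaining = {c.id: c for c in candidates}
    fp_of = {c.id: c.fingerprint for c in candidates}
    first = sorted(candidates, key=lambda c: (-c.score, c.id))[0]
    picks = [first.id]
    del remaining[first.id]
    while remaining and len(picks) < min(n, len(candidates)):
        best = None
        for c in remaining.values():
            dmin = min(tanimoto_distance(c.fingerprint, fp_of[p]) for p in picks)
            key = (-dmin, -c.score, c.id)
            if best is None or key < best[0]:
                best = (key, c.id)
        picks.append(best[1])
        del remaining[best[1]]
    return picks
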