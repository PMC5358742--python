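"""Continuous severity index on [0, 100] from (B%, Y%).

Severity is a clipped weighted sum ``clip(w1 * B% + w2 * Y%, 0, 100)``
with ``w1 >= w2 >= 0``: necrosis (brown) marks more advanced stress
than chlorosis (yellow), so it never receives the smaller weight.  The
anchors are structural — (0, 0) maps to 0 (no symptoms) and a fully
necrotic canopy with ``w1 = 1`` maps to 100.

Weights are fitted by minimising the misclassification of ordinal
labels when the severity axis is cut into five bands: ``w1`` is fixed
at 1.0 (the scale anchor), ``w2 / w1`` is searched on a grid, and for
each candidate the optimal four cutpoints are found by an exact
dynamic program over the sorted severity values (equivalent to
exhaustive search over adjacent midpoints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SeverityModel", "fit_severity", "score_severity"]


@dataclass(frozen=True)
class SeverityModel:
    """Weights and score-band cutpoints of the fitted severity map."""

    w1: float  # weight on B% (necrosis)
    w2: float  # weight on Y% (chlorosis)
    cutpoints: tuple  # 4 increasing thresholds splitting [0,100] into 5 bands
    train_misclassification: float = float("nan")

    def __post_init__(self):
        if not (self.w1 >= self.w2 >= 0.0):
            raise ValueError("weights must satisfy w1 >= w2 >= 0")
        cp = self.cutpoints
        if len(cp) != 4 or any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be 4 strictly increasing values")

    def severity(self, brown_pct, yellow_pct):
        """clip(w1*B% + w2*Y%, 0, 100); accepts scalars or arrays."""
        s = self.w1 * np.asarray(brown_pct, dtype=float) + self.w2 * np.asarray(
            yellow_pct, dtype=float
        )
        return np.clip(s, 0.0, 100.0)

    def band_score(self, severity_value):
        """Ordinal score 1-5 obtained by reading severity against cutpoints."""
        return np.searchsorted(np.asarray(self.cutpoints),
                               np.asarray(severity_value, dtype=float),
                               side="right") + 1

    def summary(self) -> str:
        cps = ", ".join(f"{c:.3f}" for c in self.cutpoints)
        return (
            "Severity model: clip(w1*B% + w2*Y%, 0, 100)\n"
            f"  w1 (necrosis weight):  {self.w1:.3f}\n"
            f"  w2 (chlorosis weight): {self.w2:.3f}\n"
            f"  score-band cutpoints:  [{cps}]\n"
            f"  training misclassification: {self.train_misclassification:.4f}"
        )


def _optimal_cutpoints(sev: np.ndarray, labels: np.ndarray):
    """Best 4 monotone cutpoints for ordinal labels 1..5 on a severity axis.

    Exact DP on the sorted values: cost of assigning a sorted segment to
    score c is the count of labels != c there; each layer reduces to a
    prefix minimum, so the whole solve is O(n) per score.
    Returns (cutpoints, misclassification_count).
    """
    order = np.argsort(sev, kind="stable")
    s = sev[order]
    lab = labels[order]
    n = s.size
    # pref[c, i] = number of labels == c+1 among the first i sorted rows
    pref = np.zeros((5, n + 1), dtype=np.int64)
    for c in range(5):
        pref[c, 1:] = np.cumsum(lab == c + 1)
    idx = np.arange(n + 1)
    dp = idx - pref[0]  # boundary after j rows, all assigned score 1
    bounds = []  # argmin tables for backtracking
    for c in range(1, 5):
        a = dp - idx + pref[c]
        # prefix minimum of a with earliest-index ties
        amin = np.minimum.accumulate(a)
        arg = np.zeros(n + 1, dtype=np.int64)
        best = a[0]
        bi = 0
        for j in range(1, n + 1):
            if a[j] < best:
                best, bi = a[j], j
            arg[j] = bi
        dp = amin + idx - pref[c]
        bounds.append(arg)
    err = int(dp[n])
    # backtrack boundary row-indices b1 <= b2 <= b3 <= b4
    cut_idx = [0] * 4
    j = n
    for c in range(3, -1, -1):
        j = int(bounds[c][j])
        cut_idx[c] = j
    # convert boundary indices to numeric cutpoints (midpoints), forcing
    # strict increase even when a band is empty
    eps = 1e-9
    cuts = []
    lo_anchor = 0.0
    for b in cut_idx:
        if b == 0:
            c = lo_anchor + eps if cuts else max(s[0] / 2.0, eps)
        elif b == n:
            c = max(s[-1] + 1.0, (cuts[-1] if cuts else 0.0) + eps)
        else:
            c = 0.5 * (s[b - 1] + s[b])
        if cuts and c <= cuts[-1]:
            c = cuts[-1] + eps
        cuts.append(float(min(c, 100.0 - eps)))
        lo_anchor = cuts[-1]
    # final monotonicity repair near the upper bound
    for k in range(1, 4):
        if cuts[k] <= cuts[k - 1]:
            cuts[k] = cuts[k - 1] + eps
    return tuple(cuts), err


def fit_severity(brown_pct, yellow_pct, labels,
                 grid_step: float = 0.01) -> SeverityModel:
    """Fit (w1, w2) and cutpoints by minimising band misclassification.

    ``w1`` anchors the scale at 1.0; ``w2`` is searched over
    [0, 1] in steps of ``grid_step``.  Ties in misclassification go to
    the smallest ``w2`` so refits are deterministic and invariant to
    row order.
    """
    b = np.asarray(brown_pct, dtype=float)
    y = np.asarray(yellow_pct, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if b.shape != y.shape or b.shape != lab.shape:
        raise ValueError("brown_pct, yellow_pct and labels must align")
    if np.unique(lab).size < 2:
        raise ValueError("need >= 2 distinct labels to fit severity bands")
    if not np.isin(lab, [1, 2, 3, 4, 5]).all():
        raise ValueError("labels must be integers in 1..5")
    best = None
    for w2 in np.arange(0.0, 1.0 + 1e-12, grid_step):
        sev = np.clip(1.0 * b + w2 * y, 0.0, 100.0)
        cuts, err = _optimal_cutpoints(sev, lab)
        if best is None or err < best[0]:
            best = (err, w2, cuts)
    err, w2, cuts = best
    return SeverityModel(w1=1.0, w2=round(float(w2), 10), cutpoints=cuts,
                         train_misclassification=err / b.size)


def score_severity(model: SeverityModel, brown_pct, yellow_pct):
    """Severity value(s) of (B%, Y%) under a fitted model."""
    return model.severity(brown_pct, yellow_pct)
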