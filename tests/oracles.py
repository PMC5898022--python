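"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: recursion and O(n^2) loops, no shared code with the
package. Only usable at tiny problem sizes.
"""

from functools import lru_cache


def brute_force_local_alignment(x: str, y: str, match: float, mismatch: float, gap: float) -> float:
    """Best local alignment score by enumerating all substring pairs.

    For every pair of substrings the best gapped global alignment is found
    by plain recursion; the empty alignment contributes 0.
    """

    @lru_cache(maxsize=None)
    def global_best(a: str, b: str) -> float:
        if not a and not b:
            return 0.0
        options = []
        if a and b:
            sub = match if a[0] == b[0] else mismatch
            options.append(sub + global_best(a[1:], b[1:]))
        if a:
            options.append(gap + global_best(a[1:], b))
        if b:
            options.append(gap + global_best(a, b[1:]))
        return max(options)

    best = 0.0
    for i1 in range(len(x) + 1):
        for i2 in range(i1, len(x) + 1):
            for j1 in range(len(y) + 1):
                for j2 in range(j1, len(y) + 1):
                    best = max(best, global_best(x[i1:i2], y[j1:j2]))
    return best


def brute_force_non_dominated(rows: list[tuple]) -> set[int]:
    """Indices of rows not dominated by any other row (>= everywhere, > somewhere)."""
    n = len(rows)
    keep = set()
    for i in range(n):
        dominated = False
        for j in range(n):
            if j == i:
                continue
            ge = all(rows[j][f] >= rows[i][f] for f in range(len(rows[i])))
            gt = any(rows[j][f] > rows[i][f] for f in range(len(rows[i])))
            if ge and gt:
                dominated = True
                break
        if not dominated:
            keep.add(i)
    return keep


def brute_force_auc_roc(scores: list[float], labels: list[int]) -> float:
    """Pair counting: P(positive outranks negative), ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def threshold_sweep_auc_pr(scores: list[float], labels: list[int]) -> float:
    """PR area by sweeping every distinct score as a threshold (trapezoid)."""
    n_pos = sum(labels)
    points = []
    for thr in sorted(set(scores), reverse=True):
        picked = [l for s, l in zip(scores, labels) if s >= thr]
        tp = sum(picked)
        points.append((tp / n_pos, tp / len(picked)))
    area = 0.0
    prev_r, prev_p = 0.0, points[0][1]
    for r, p in points:
        area += (r - prev_r) * (p + prev_p) / 2.0
        prev_r, prev_p = r, p
    return area
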