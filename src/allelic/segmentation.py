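"""Circular binary segmentation (CBS) of per-marker log R ratios.

Recursive change-point detection on an ordered marker sequence. Each candidate
split is the arc (i, j] maximising the two-sample t statistic between the arc
and the rest of the segment (the circular statistic: an arc and its complement
score identically, so only non-wrapping arcs are scanned). Split significance
is assessed by a permutation test on the marker values; because permutation
preserves the value multiset, the pooled-variance factor cancels and the
scan can use the scale-free score

    score(i, j) = |S_j - S_i - k * mean| / sqrt(k (n - k) / n),   k = j - i,

whose maximiser equals the max-t maximiser. Accepted splits are applied
(up to two boundaries for an interior arc) and the pieces re-tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


@dataclass
class CbsParams:
    alpha: float = 0.01        # permutation significance for accepting a split
    min_markers: int = 10      # minimum markers per emitted segment
    n_perm: int = 1000         # permutations per split test
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")


def _max_arc_score(x: np.ndarray, min_markers: int):
    """Best arc (i, j] and its score; arcs keep both sides >= min_markers."""
    n = len(x)
    s = np.concatenate(([0.0], np.cumsum(x)))
    total = s[-1]
    best = (-1.0, 0, 0)
    for k in range(min_markers, n - min_markers + 1):
        arc = s[k:] - s[:-k]                      # arc sums starting at i=0..n-k
        scores = np.abs(arc - k * total / n) / np.sqrt(k * (n - k) / n)
        i = int(np.argmax(scores))
        if scores[i] > best[0]:
            best = (float(scores[i]), i, i + k)
    return best


def _max_scores_batch(xs: np.ndarray, min_markers: int) -> np.ndarray:
    """Max arc score per row of a (b, n) matrix of permuted sequences."""
    b, n = xs.shape
    s = np.concatenate([np.zeros((b, 1)), np.cumsum(xs, axis=1)], axis=1)
    total = s[:, -1:]
    best = np.zeros(b)
    for k in range(min_markers, n - min_markers + 1):
        arc = s[:, k:] - s[:, :-k]
        scores = np.abs(arc - k * total / n) / np.sqrt(k * (n - k) / n)
        np.maximum(best, scores.max(axis=1), out=best)
    return best


def _split_pvalue(x, obs_score, params: CbsParams, rng) -> float:
    """Permutation p-value of the observed max arc score, with early stop.

    Permutations proceed in blocks; once the exceedance count guarantees
    p > alpha the test stops early (the split can no longer be accepted).
    """
    n_perm = params.n_perm
    give_up = params.alpha * n_perm
    exceed = 0
    done = 0
    block = 100
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        stats = _max_scores_batch(perms, params.min_markers)
        exceed += int((stats >= obs_score - _EPS).sum())
        done += b
        if exceed > give_up:
            break
    return (exceed + 1) / (done + 1)


def segment_sequence(x: np.ndarray, params: CbsParams | None = None,
                     rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
    """Segment a 1-D marker sequence; returns [(start, end)) index pairs.

    The pairs tile [0, len(x)). A sequence shorter than 2 * min_markers is
    returned as a single segment.
    """
    params = params or CbsParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return []
    boundaries = []

    def recurse(lo: int, hi: int):
        seg = x[lo:hi]
        m = hi - lo
        if m < 2 * params.min_markers or np.ptp(seg) < _EPS:
            return
        score, i, j = _max_arc_score(seg, params.min_markers)
        if score <= 0:
            return
        p = _split_pvalue(seg, score, params, rng)
        if p > params.alpha:
            return
        # drop an arc edge that hugs the segment boundary: edge arcs are
        # single change points, interior arcs contribute two
        cuts = [c for c in (i, j) if params.min_markers <= c <= m - params.min_markers]
        if not cuts:
            return
        pieces = [lo] + [lo + c for c in cuts] + [hi]
        boundaries.extend(pieces[1:-1])
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, n)
    edges = [0] + sorted(set(boundaries)) + [n]
    return list(zip(edges[:-1], edges[1:]))


def best_single_change_point(x: np.ndarray, min_markers: int = 1):
    """Exhaustive single change-point t-scan (independent oracle).

    Scans every simple split point c and returns (c, t) maximising the
    two-sample |t| between x[:c] and x[c:]. Brute force, for validating the
    arc-scan segmentation on simulated steps.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    best_c, best_t = -1, -1.0
    for c in range(min_markers, n - min_markers + 1):
        a, b = x[:c], x[c:]
        va = a.var(ddof=1) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) if len(b) > 1 else 0.0
        pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / max(n - 2, 1)
        denom = np.sqrt(max(pooled, _EPS) * (1 / len(a) + 1 / len(b)))
        t = abs(a.mean() - b.mean()) / denom
        if t > best_t:
            best_c, best_t = c, t
    return best_c, best_t
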