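"""Independent brute-force oracles used by the test suite.

Deliberately simple implementations that share no code with the package:
an exhaustive recursive local aligner, a quadratic fixpoint interval
merger, and a direct (start, period) tandem-repeat window scan.
"""

from functools import lru_cache
from itertools import accumulate
from math import ceil


def brute_force_local_align(a: str, b: str, match=1, mismatch=-2, gap=-3):
    """Best local alignment score and identity by exhaustive recursion
    (linear gap penalty ``gap``; only suitable for very short strings)."""

    @lru_cache(maxsize=None)
    def ext(i, j):
        # best (score, matches, columns) of an alignment ending at (i, j)
        best = (0, 0, 0)
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            ps, pm, pc = ext(i - 1, j - 1)
            cand = (ps + s, pm + (1 if a[i - 1] == b[j - 1] else 0), pc + 1)
            if cand[0] > best[0]:
                best = cand
        if i > 0:
            ps, pm, pc = ext(i - 1, j)
            if ps + gap > best[0]:
                best = (ps + gap, pm, pc + 1)
        if j > 0:
            ps, pm, pc = ext(i, j - 1)
            if ps + gap > best[0]:
                best = (ps + gap, pm, pc + 1)
        return best

    top = (0, 0, 0)
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            cand = ext(i, j)
            if cand[0] > top[0] or (
                cand[0] == top[0] and cand[2] > top[2]
            ):
                top = cand
    score, matches, columns = top
    identity = 100.0 * matches / columns if columns else 0.0
    return score, matches, columns, identity


def merge_intervals_fixpoint(intervals, max_gap, min_len):
    """Quadratic all-pairs merge to fixpoint, then length filter."""
    ivs = [tuple(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        out = []
        used = [False] * len(ivs)
        for i in range(len(ivs)):
            if used[i]:
                continue
            s, e = ivs[i]
            for j in range(len(ivs)):
                if j == i or used[j]:
                    continue
                s2, e2 = ivs[j]
                gap = max(s, s2) - min(e, e2)
                if gap <= max_gap:
                    s, e = min(s, s2), max(e, e2)
                    used[j] = True
                    changed = True
            used[i] = True
            out.append((s, e))
        ivs = out
    return sorted((s, e) for s, e in ivs if e - s >= min_len)


def tandem_coverage_scan(seq, max_period=100, min_copies=3.0, min_array=24,
                         max_mismatch_frac=0.10):
    """Per-base tandem coverage by scanning every (start, period) window with
    prefix sums (pure Python; independent of the package's detector)."""
    n = len(seq)
    covered = [False] * n
    for p in range(1, min(max_period, n - 1) + 1):
        w = max(min_array, ceil(min_copies * p))
        if w > n or w <= p:
            continue
        neq = [1 if seq[i] != seq[i - p] else 0 for i in range(p, n)]
        cs = [0] + list(accumulate(neq))
        ncmp = w - p
        limit = max_mismatch_frac * ncmp
        for start in range(0, n - w + 1):
            if cs[start + ncmp] - cs[start] <= limit:
                for k in range(start, start + w):
                    covered[k] = True
    return covered
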