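"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately uses a different algorithm from the code path it
verifies: innermost-pair elimination instead of a stack parser, exhaustive
pair enumeration instead of directed scans, and zoomed grid search instead
of the closed-form maximum-likelihood fit.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def match_brackets_by_elimination(db: str) -> dict[int, int]:
    """Dot-bracket matching by repeatedly deleting innermost '(...)' spans.

    Returns {1-based position: partner}. Raises ValueError on unbalanced
    input.  O(n^2), independent of the stack parser under test.
    """
    chars = list(db)
    pairs: dict[int, int] = {}
    changed = True
    while changed:
        changed = False
        open_pos = None
        for i, ch in enumerate(chars):
            if ch == "(":
                open_pos = i
            elif ch == ")":
                if open_pos is None:
                    raise ValueError("unbalanced ')'")
                pairs[open_pos + 1] = i + 1
                pairs[i + 1] = open_pos + 1
                chars[open_pos] = chars[i] = "."
                changed = True
                break
    if "(" in chars or ")" in chars:
        raise ValueError("unbalanced at end")
    return pairs


def brute_duplex_bounds(pairing, five_span, three_span):
    """(a, c) = outermost/innermost 5'-mature positions paired into the 3'
    mature, by exhaustive enumeration of all position pairs; None if no such
    pair exists."""
    s5, e5 = five_span
    s3, e3 = three_span
    joining = [
        p
        for p in range(s5, e5 + 1)
        for q in range(s3, e3 + 1)
        if pairing[p - 1] == q
    ]
    if not joining:
        return None
    return min(joining), max(joining)


def brute_end_distance(pairing, mature_span, end_kind):
    """Signed end-to-loop distance by examining every position explicitly.

    Mirrors the definition: outside candidates are unpaired positions
    strictly outside the mature on the outward side, inside candidates are
    unpaired positions within the mature; d_out = gap size, d_in = -cut
    size; smaller magnitude wins, ties go outside.  Returns None when the
    terminal nucleotide is unpaired or no candidate exists.
    """
    s, e = mature_span
    n = len(pairing)
    if end_kind.endswith("_start"):
        t, outward = s, -1
    else:
        t, outward = e, +1
    if pairing[t - 1] == 0:
        return None
    if outward == -1:
        outside = [u for u in range(1, t) if pairing[u - 1] == 0]
        inside = [u for u in range(s, e + 1) if pairing[u - 1] == 0 and u > t]
    else:
        outside = [u for u in range(t + 1, n + 1) if pairing[u - 1] == 0]
        inside = [u for u in range(s, e + 1) if pairing[u - 1] == 0 and u < t]
    d_out = min(abs(u - t) for u in outside) - 1 if outside else None
    d_in = -min(abs(u - t) for u in inside) if inside else None
    if d_out is None and d_in is None:
        return None
    if d_in is None:
        return d_out
    if d_out is None:
        return d_in
    return d_out if abs(d_out) <= abs(d_in) else d_in


def grid_search_independence(counts: np.ndarray, resolution: float = 1e-4):
    """Maximum-likelihood (p_short, p_long) by zoomed grid search.

    Three refinement stages ending at the requested resolution; the
    likelihood is evaluated directly from the product model at every grid
    point, with no use of the closed form under test.
    """
    counts = np.asarray(counts, dtype=float)

    def loglik(ps: float, pl: float) -> float:
        pc = 1 - ps - pl
        if min(ps, pl, pc) <= 0:
            return -np.inf
        q = np.array([ps, pc, pl])
        with np.errstate(divide="ignore"):
            return float((counts * np.log(np.outer(q, q))).sum())

    lo_s, hi_s, lo_l, hi_l = 0.0, 1.0, 0.0, 1.0
    step = 1e-2
    best = (0.3, 0.3)
    while True:
        ss = np.arange(lo_s, hi_s + step / 2, step)
        ls = np.arange(lo_l, hi_l + step / 2, step)
        best = max(
            ((ps, pl) for ps in ss for pl in ls),
            key=lambda t: loglik(*t),
        )
        if step <= resolution:
            return best
        lo_s, hi_s = best[0] - 2 * step, best[0] + 2 * step
        lo_l, hi_l = best[1] - 2 * step, best[1] + 2 * step
        step /= 10


def exact_spearman_permutation_p(x, y) -> float:
    """Two-sided permutation p-value by full enumeration of all n! orderings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_obs = abs(stats.spearmanr(x, y).statistic)
    n = len(y)
    count = sum(
        abs(stats.spearmanr(x, np.asarray(perm)).statistic) >= rho_obs - 1e-12
        for perm in itertools.permutations(y)
    )
    return count / math.factorial(n)
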