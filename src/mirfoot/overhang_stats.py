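"""Joint overhang statistics: coherence test and the independence null model.

Drosha and Dicer are believed to cleave independently; the joint
distribution of basal (Drosha/splice-side) and apical (Dicer-side) overhang
lengths tests that belief.  Two tools are provided:

* a rank-correlation test (Spearman, asymptotic or permutation p-value)
  over observed (basal, apical) pairs, and
* a 2-parameter null model of independent overhang lengths restricted to
  near-canonical lengths {1, 2, 3} nt = {short, canonical, long}: both
  sites share one marginal q = (p_short, 1 - p_short - p_long, p_long) and
  P(i, j) = q_i * q_j.  Coherent processing shows up as observed/expected
  ratios above 1 in the short/short and long/long cells.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .duplex import OverhangPair
from .ingest import FIVE_PRIME, THREE_PRIME, HairpinRecord

#: near-canonical overhang lengths and their class labels
LENGTH_CLASSES = (1, 2, 3)
CLASS_NAMES = ("short", "canonical", "long")


# ---------------------------------------------------------------------------
# joint table
# ---------------------------------------------------------------------------

@dataclass
class JointOverhangTable:
    """Exact joint counts of (basal, apical) overhang lengths."""

    counts: dict[tuple[int, int], int]
    n_total: int
    n_suspect: int = 0

    def basal_margin(self) -> Counter:
        m: Counter = Counter()
        for (b, _), c in self.counts.items():
            m[b] += c
        return m

    def apical_margin(self) -> Counter:
        m: Counter = Counter()
        for (_, a), c in self.counts.items():
            m[a] += c
        return m

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"basal": b, "apical": a, "count": c}
            for (b, a), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["basal", "apical", "count"])


def _as_pair(item) -> tuple[int, int, bool]:
    if isinstance(item, OverhangPair):
        return item.basal, item.apical, item.suspect
    b, a = item
    return int(b), int(a), False


def joint_overhang_table(pairs: Iterable) -> JointOverhangTable:
    """Count (basal, apical) pairs; suspect-flagged pairs included but tallied."""
    counts: Counter = Counter()
    n_suspect = 0
    n = 0
    for item in pairs:
        b, a, suspect = _as_pair(item)
        counts[(b, a)] += 1
        n += 1
        n_suspect += suspect
    return JointOverhangTable(dict(counts), n_total=n, n_suspect=n_suspect)


def restrict_near_canonical(pairs: Iterable) -> tuple[list, float]:
    """Keep pairs with both overhangs in {1, 2, 3} nt; report retained fraction.

    Restricting to canonical overhangs and their minimal 1-nt deviations
    removes the pathologies that inflate the full-table correlation (large
    bulge loops, mispredicted terminal loops, G-avoidance shifts).
    """
    all_pairs = list(pairs)
    subset = [
        item for item in all_pairs
        if _as_pair(item)[0] in LENGTH_CLASSES and _as_pair(item)[1] in LENGTH_CLASSES
    ]
    fraction = len(subset) / len(all_pairs) if all_pairs else float("nan")
    return subset, fraction


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def rank_correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rank correlation with midrank ties.

    ``method="asymptotic"`` uses the large-sample approximation.
    ``method="permutation"`` shuffles the pairing of x and y; when n! does
    not exceed ``n_permutations`` every ordering is enumerated, making the
    two-sided p-value exact (the observed ordering is one of the n!, so the
    p-value is strictly positive).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")

    rho_s, p_asym = stats.spearmanr(x, y)
    rho = float(rho_s)
    if method == "asymptotic":
        return CorrelationResult(rho, float(p_asym), len(x), "asymptotic")
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = _rank_rho(rx, ry)
    eps = 1e-12
    n = len(x)
    if math.factorial(n) <= n_permutations:
        import itertools

        count = sum(
            abs(_rank_rho(rx, np.asarray(perm))) >= abs(rho_obs) - eps
            for perm in itertools.permutations(ry)
        )
        p = count / math.factorial(n)
        return CorrelationResult(rho, p, n, "permutation(exact)")

    rng = np.random.default_rng(seed)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc @ rxc) * (ryc @ ryc))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ryc)
        if abs(rxc @ perm / denom) >= abs(rho_obs) - eps:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return CorrelationResult(rho, p, n, "permutation")


def overhang_correlation(
    pairs: Iterable,
    method: str = "asymptotic",
    exclude_suspect: bool = False,
    suspect_threshold: int = 15,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Rank correlation between basal and apical overhang lengths.

    By default all pairs enter, matching how the full-table correlation is
    computed; ``exclude_suspect`` drops overhang magnitudes above the
    threshold.
    """
    tuples = [_as_pair(item) for item in pairs]
    if exclude_suspect:
        tuples = [
            t for t in tuples
            if max(abs(t[0]), abs(t[1])) <= suspect_threshold
        ]
    basal = [t[0] for t in tuples]
    apical = [t[1] for t in tuples]
    return rank_correlation(
        basal, apical, method=method, n_permutations=n_permutations, seed=seed
    )


# ---------------------------------------------------------------------------
# 2-parameter independence model
# ---------------------------------------------------------------------------

@dataclass
class IndependenceFit:
    """Fit of the independent-overhang null over length classes {1, 2, 3}.

    ``q`` is the shared marginal (p_short, p_canonical, p_long).  For the
    per-site variant (``shared=False``) ``q_basal``/``q_apical`` hold the
    two marginals and ``q`` their average (informational only).
    """

    p_short: float
    p_long: float
    q: tuple[float, float, float]
    expected: np.ndarray
    obs_over_exp: np.ndarray
    log_likelihood: float
    gof_stat: float
    gof_df: int
    gof_p: float
    n_total: int
    method: str = "ml"
    shared: bool = True
    boundary: bool = False
    q_basal: tuple[float, float, float] | None = None
    q_apical: tuple[float, float, float] | None = None

    @property
    def p_canonical(self) -> float:
        return self.q[1]

    def depletion_factors(self) -> tuple[float, float]:
        """(canonical/short, canonical/long) marginal ratios under the fit."""
        return self.q[1] / self.q[0], self.q[1] / self.q[2]


def class_counts(table: JointOverhangTable | Mapping[tuple[int, int], int]) -> np.ndarray:
    """3x3 count matrix over near-canonical classes, rows = basal 1,2,3."""
    counts = table.counts if isinstance(table, JointOverhangTable) else table
    mat = np.zeros((3, 3), dtype=float)
    for (b, a), c in counts.items():
        if b in LENGTH_CLASSES and a in LENGTH_CLASSES:
            mat[b - 1, a - 1] += c
    return mat


def _fit_metrics(counts: np.ndarray, expected: np.ndarray) -> tuple[float, float]:
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.where(counts > 0, counts * np.log(expected / counts.sum()), 0.0).sum())
        g = 2.0 * float(
            np.where(counts > 0, counts * np.log(counts / expected), 0.0).sum()
        )
    return ll, g


def fit_independence_model(
    counts,
    method: str = "ml",
    shared: bool = True,
) -> IndependenceFit:
    """Fit P(i, j) = q_i * q_j over the 3x3 near-canonical count table.

    With a shared marginal the maximum-likelihood solution is closed-form:
    the log-likelihood collapses to a multinomial over row+column margins,
    so q_i = (row_i + col_i) / (2 n).  ``method="ls"`` instead minimizes
    the squared frequency residuals numerically.  ``shared=False`` fits a
    per-site marginal to each axis (4 free parameters).

    The goodness of fit is the likelihood-ratio statistic against the
    saturated multinomial, with 9 - 1 minus the number of free parameters
    degrees of freedom.
    """
    mat = counts if isinstance(counts, np.ndarray) else class_counts(counts)
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (3, 3):
        raise ValueError("expected a 3x3 count table")
    n = mat.sum()
    if n <= 0:
        raise ValueError("empty count table")

    if not shared:
        q_b = mat.sum(axis=1) / n
        q_a = mat.sum(axis=0) / n
        expected = n * np.outer(q_b, q_a)
        ll, g = _fit_metrics(mat, expected)
        df = 8 - 4
        q_avg = tuple((q_b + q_a) / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(expected > 0, mat / expected, np.nan)
        return IndependenceFit(
            p_short=float(q_avg[0]), p_long=float(q_avg[2]), q=q_avg,
            expected=expected, obs_over_exp=ratio, log_likelihood=ll,
            gof_stat=g, gof_df=df, gof_p=float(stats.chi2.sf(g, df)),
            n_total=int(n), method=method, shared=False,
            boundary=bool(np.any(q_b <= 0) or np.any(q_a <= 0)),
            q_basal=tuple(q_b), q_apical=tuple(q_a),
        )

    if method == "ml":
        margins = mat.sum(axis=1) + mat.sum(axis=0)
        q = margins / (2 * n)
    elif method == "ls":
        freq = mat / n

        def objective(params: np.ndarray) -> float:
            ps, pl = params
            if ps < 0 or pl < 0 or ps + pl > 1:
                return 1e6 + abs(ps) + abs(pl)
            qv = np.array([ps, 1 - ps - pl, pl])
            return float(((freq - np.outer(qv, qv)) ** 2).sum())

        margins = mat.sum(axis=1) + mat.sum(axis=0)
        x0 = (margins / (2 * n))[[0, 2]]
        res = optimize.minimize(objective, x0, method="Nelder-Mead")
        ps, pl = np.clip(res.x, 0, 1)
        q = np.array([ps, 1 - ps - pl, pl])
    else:
        raise ValueError(f"unknown fit method {method!r}")

    expected = n * np.outer(q, q)
    ll, g = _fit_metrics(mat, expected)
    df = 8 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, mat / expected, np.nan)
    return IndependenceFit(
        p_short=float(q[0]), p_long=float(q[2]), q=tuple(float(v) for v in q),
        expected=expected, obs_over_exp=ratio, log_likelihood=ll,
        gof_stat=g, gof_df=df, gof_p=float(stats.chi2.sf(g, df)),
        n_total=int(n), method=method, shared=True,
        boundary=bool(np.any(q <= 0) or np.any(q >= 1)),
    )


# ---------------------------------------------------------------------------
# boundary base composition
# ---------------------------------------------------------------------------

def boundary_base_frequencies(
    records: Iterable[HairpinRecord],
    end_kind: str,
    offsets: Sequence[int] = (-1, 0, 1),
) -> pd.DataFrame:
    """Base frequencies at and around one mature boundary across a dataset.

    Rows A/C/G/U, one column per offset relative to the chosen end position
    (offset 0 = the terminal mature nucleotide itself).  Offsets falling
    outside a hairpin are dropped from that record's denominator.  Used for
    the guanine-avoidance check at cleavage boundaries.
    """
    arm = FIVE_PRIME if end_kind.startswith("5p") else THREE_PRIME
    use_start = end_kind.endswith("_start")
    counts = {off: Counter() for off in offsets}
    denom = {off: 0 for off in offsets}
    for rec in records:
        m = rec.mature(arm)
        if m is None:
            continue
        t = m.start if use_start else m.end
        for off in offsets:
            pos = t + off
            if 1 <= pos <= rec.length:
                counts[off][rec.sequence[pos - 1]] += 1
                denom[off] += 1
    data = {
        off: {
            base: (counts[off][base] / denom[off] if denom[off] else float("nan"))
            for base in "ACGU"
        }
        for off in offsets
    }
    return pd.DataFrame(data).loc[list("ACGU")]
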