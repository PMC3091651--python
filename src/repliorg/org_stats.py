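"""Rank statistics for genome-organisation gradients.

Spearman rank correlations and Mann-Whitney rank-sum tests, with exact
enumeration p-values on small tie-free samples and standard approximations
otherwise, plus the expression-stratified confound analysis: genes are split
into equally sized expression bins and core vs non-core origin distances are
compared within each bin, so that a core-gene distance effect can be
separated from the expression gradient itself.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedCorrelationError
from .genome_model import GeneRecord
from .window_tracks import WindowTrack


@dataclass(frozen=True)
class StatResult:
    """Outcome of one rank test: statistic, two-sided p, n, method tag."""

    statistic: float
    p_two_sided: float
    n: int | tuple[int, int]
    method: str


def _clamp_p(p: float) -> float:
    """Keep p in the half-open interval (0, 1]."""
    return float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


# ---------------------------------------------------------------------------
# Spearman rank correlation


def _spearman_null_devs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of |4*S - n(n+1)^2| over all rank permutations.

    S = sum_i i * pi(i) for ranks 1..n is an integer monotone in rho, so the
    two-sided exact p reduces to counting permutations whose integer
    deviation from the mean is at least the observed one. Cached per n.
    """
    cache = _spearman_null_devs._cache
    if n not in cache:
        base = np.arange(1, n + 1, dtype=np.int64)
        centre = n * (n + 1) ** 2
        counts: dict[int, int] = {}
        it = itertools.permutations(range(1, n + 1))
        while True:
            block = list(itertools.islice(it, 200_000))
            if not block:
                break
            arr = np.asarray(block, dtype=np.int64)
            dev = np.abs(4 * (arr @ base) - centre)
            vals, cnts = np.unique(dev, return_counts=True)
            for v, c in zip(vals.tolist(), cnts.tolist()):
                counts[v] = counts.get(v, 0) + c
        devs = np.array(sorted(counts), dtype=np.int64)
        tail = np.cumsum([counts[int(v)] for v in devs][::-1])[::-1]
        cache[n] = (devs, tail.astype(np.int64))
    return cache[n]


_spearman_null_devs._cache = {}

#: Largest n for which the exact permutation null is enumerated.
SPEARMAN_EXACT_MAX_N = 10


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).
    For tie-free samples of n <= 10 the p-value is exact, from full
    enumeration of the n! rank permutations; otherwise the usual
    t-approximation ``t = rho*sqrt((n-2)/(1-rho^2))`` on n-2 df is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("zero rank variance; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if tie_free and n <= SPEARMAN_EXACT_MAX_N:
        # S depends only on the relative permutation of tie-free ranks
        s_obs = int(round(float(rx @ ry)))
        dev_obs = abs(4 * s_obs - n * (n + 1) ** 2)
        devs, tail = _spearman_null_devs(n)
        idx = np.searchsorted(devs, dev_obs, side="left")
        count = int(tail[idx]) if idx < len(devs) else 0
        p = count / math.factorial(n)
        return StatResult(rho, _clamp_p(p), n, "spearman_exact")

    if abs(rho) >= 1.0:
        return StatResult(rho, _clamp_p(0.0), n, "spearman_t_approx")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return StatResult(rho, _clamp_p(p), n, "spearman_t_approx")


# ---------------------------------------------------------------------------
# Mann-Whitney U


#: Exact enumeration is used when the smaller group has at most this many obs.
MANNWHITNEY_EXACT_MAX_N = 8
#: ... and the number of group assignments to enumerate stays below this
#: (covers every shape up to 8 vs 8; keeps a very small group paired with a
#: very large one on the normal approximation instead of a C(n, n1) blow-up).
MANNWHITNEY_EXACT_MAX_COMB = 100_000


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Mann-Whitney U test (two-sided) for two independent samples.

    U counts pairs ``(a_i, b_j)`` with ``a_i > b_j``, ties credited 0.5.
    When the smaller sample has at most 8 observations and the pooled data
    are tie-free, the p-value is exact by enumeration of all
    ``C(n1+n2, n1)`` group assignments; otherwise the normal approximation
    with tie correction and a 0.5 continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0  # U for group a, 0.5 credit on ties
    mu = n1 * n2 / 2.0

    tie_free = len(np.unique(pooled)) == n1 + n2
    total = math.comb(n1 + n2, n1)
    if (
        tie_free
        and min(n1, n2) <= MANNWHITNEY_EXACT_MAX_N
        and total <= MANNWHITNEY_EXACT_MAX_COMB
    ):
        # integer deviations: |2U' - n1*n2| over all assignments of ranks
        dev_obs = abs(int(round(2 * u)) - n1 * n2)
        count = 0
        rank_base = n1 * (n1 + 1)
        for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
            dev = abs(2 * sum(combo) - rank_base - n1 * n2)
            if dev >= dev_obs:
                count += 1
        return StatResult(u, _clamp_p(count / total), (n1, n2), "mw_exact")

    nt = n1 + n2
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((t_counts**3 - t_counts).sum())) / (nt * (nt - 1))
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term)
    if var <= 0:
        return StatResult(u, 1.0, (n1, n2), "mw_normal")
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return StatResult(u, _clamp_p(p), (n1, n2), "mw_normal")


# ---------------------------------------------------------------------------
# Expression bins and the confound analysis


def expression_bins(expression: Sequence[float], n_bins: int = 12) -> np.ndarray:
    """Assign genes to ``n_bins`` contiguous, equally sized expression bins.

    Genes are ranked ascending by expression (ties broken by input order,
    stable) and split so bin sizes differ by at most 1, earlier bins taking
    the remainder. Returns the bin index (0-based) per input gene.
    """
    expr = np.asarray(expression, dtype=float)
    n = len(expr)
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} genes, got {n}")
    order = np.argsort(expr, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    labels = np.repeat(np.arange(n_bins), sizes)
    out = np.empty(n, dtype=int)
    out[order] = labels
    return out


@dataclass
class BinReport:
    """Per-expression-bin core vs non-core comparison.

    ``rows`` has one record per bin: group sizes, the Mann-Whitney p for the
    within-bin expression difference (confound check) and for the origin
    distance difference, whether the bin held both categories, and the
    direction of the distance difference (by group medians).
    """

    n_bins: int
    alpha: float
    rows: pd.DataFrame
    n_usable: int
    n_significant_distance: int
    n_significant_expression: int

    def summary(self) -> str:
        return (
            f"{self.n_usable}/{self.n_bins} bins held both core and non-core genes; "
            f"origin distance differed (P < {self.alpha:g}) in "
            f"{self.n_significant_distance} of them "
            f"(expression differed in {self.n_significant_expression})."
        )


def bin_confound_analysis(
    expression: Sequence[float],
    is_core: Sequence[bool],
    distance: Sequence[float],
    n_bins: int = 12,
    alpha: float = 0.05,
) -> BinReport:
    """Test whether core genes sit nearer origins independently of expression.

    Genes are binned into ``n_bins`` equally sized expression bins; within
    each bin holding both categories, Mann-Whitney tests compare core vs
    non-core expression (should be null if the binning is fine enough) and
    core vs non-core origin distance. Bins significant for distance at
    ``alpha`` are counted, with the direction of the median difference.
    """
    expr = np.asarray(expression, dtype=float)
    core = np.asarray(is_core, dtype=bool)
    dist = np.asarray(distance, dtype=float)
    if not (len(expr) == len(core) == len(dist)):
        raise ValueError("expression, is_core and distance must align")
    bins = expression_bins(expr, n_bins)
    records = []
    for b in range(n_bins):
        m = bins == b
        nc, nn = int((m & core).sum()), int((m & ~core).sum())
        rec = {
            "bin": b,
            "n_core": nc,
            "n_noncore": nn,
            "usable": nc > 0 and nn > 0,
            "p_expression": np.nan,
            "p_distance": np.nan,
            "direction": "",
        }
        if rec["usable"]:
            rec["p_expression"] = mann_whitney(expr[m & core], expr[m & ~core]).p_two_sided
            rec["p_distance"] = mann_whitney(dist[m & core], dist[m & ~core]).p_two_sided
            mc, mn = np.median(dist[m & core]), np.median(dist[m & ~core])
            rec["direction"] = (
                "core_shorter" if mc < mn else "core_longer" if mc > mn else "tied"
            )
        records.append(rec)
    rows = pd.DataFrame.from_records(records)
    usable = rows["usable"]
    n_sig_d = int((usable & (rows["p_distance"] < alpha)).sum())
    n_sig_e = int((usable & (rows["p_expression"] < alpha)).sum())
    return BinReport(n_bins, alpha, rows, int(usable.sum()), n_sig_d, n_sig_e)


# ---------------------------------------------------------------------------
# Gene-subset and window-track correlations


def correlate_subset(
    genes: Sequence[GeneRecord],
    value_a: Callable[[GeneRecord], float | None],
    value_b: Callable[[GeneRecord], float | None],
    include: Callable[[GeneRecord], bool] = lambda g: True,
) -> StatResult:
    """Spearman correlation over the genes passing ``include``.

    ``value_a``/``value_b`` extract the two quantities per gene (``None``
    drops the gene); category predicates express the restrictions used in
    the analysis, e.g. core-only, non-core-only, or excluding transcription
    and translation genes.
    """
    xs, ys = [], []
    for g in genes:
        if not include(g):
            continue
        va, vb = value_a(g), value_b(g)
        if va is None or vb is None:
            continue
        xs.append(float(va))
        ys.append(float(vb))
    if len(xs) < 3:
        raise ValueError(f"fewer than 3 genes pass the predicate (got {len(xs)})")
    return spearman(xs, ys)


def category_predicate(
    exclude: Sequence[str] = (), require: Sequence[str] = ()
) -> Callable[[GeneRecord], bool]:
    """Predicate keeping genes with all of ``require`` and none of ``exclude``."""
    exc, req = frozenset(exclude), frozenset(require)

    def pred(g: GeneRecord) -> bool:
        return req <= g.categories and not (exc & g.categories)

    return pred


def track_correlation_matrix(tracks: Mapping[str, WindowTrack]) -> pd.DataFrame:
    """All pairwise Spearman correlations among window feature tracks.

    Tracks must share one window set (typically non-overlapping windows so
    that windows are independent observations); for each pair, windows where
    either value is missing are dropped. Returns a tidy frame with one row
    per unordered feature pair.
    """
    names = list(tracks)
    n_windows = {len(tracks[k].values) for k in names}
    if len(n_windows) != 1:
        raise ValueError("all tracks must share the same window set")
    rows = []
    for i, fa in enumerate(names):
        for fb in names[i + 1 :]:
            va = np.asarray(tracks[fa].values, dtype=float)
            vb = np.asarray(tracks[fb].values, dtype=float)
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete window pairs for {fa} vs {fb}"
                )
            res = spearman(va[ok], vb[ok])
            rows.append(
                {
                    "feature_a": fa,
                    "feature_b": fb,
                    "rho": res.statistic,
                    "p": res.p_two_sided,
                    "n": res.n,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
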