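"""Hypothesis tests used throughout the analyses.

* Peacock-style two-sample 2D Kolmogorov-Smirnov test with a permutation
  null (plus the Fasano-Franceschini sample-point variant),
* two-tailed Mann-Whitney with exact enumeration at small sample sizes,
* exact two-tailed binomial test (minimum-likelihood convention, log-space),
* aligned-rank-transform (ART) two-factor ANOVA for skewed responses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, f as f_dist, norm, rankdata

__all__ = [
    "StatTestResult",
    "peacock_ks2d",
    "ks2d_statistic",
    "mann_whitney_two_tailed",
    "binomial_two_tailed",
    "art_anova_two_factor",
]


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    p_value: float
    method: str
    n_perm: int | None = None
    seed: int | None = None
    ties_present: bool = False


# ---------------------------------------------------------------------------
# 2D two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------


def _quadrant_d(cum1: np.ndarray, cum2: np.ndarray, n1: int, n2: int) -> float:
    """Max quadrant discrepancy from the two cumulative count matrices.

    ``cum[i, j]`` counts points with x <= xs[i] and y <= ys[j]; the four
    quadrants at each origin are derived from it, which covers all
    closed/open orientation combinations once origins run over the full
    pooled coordinate grid.
    """
    F1, F2 = cum1 / n1, cum2 / n2
    row1, row2 = cum1[-1, :] / n1, cum2[-1, :] / n2  # P(y <= ys[j])
    col1, col2 = cum1[:, -1] / n1, cum2[:, -1] / n2  # P(x <= xs[i])
    d_ll = np.abs(F1 - F2)
    d_lr = np.abs((col1[:, None] - F1) - (col2[:, None] - F2))
    d_ul = np.abs((row1[None, :] - F1) - (row2[None, :] - F2))
    d_uu = np.abs((1 - col1[:, None] - row1[None, :] + F1)
                  - (1 - col2[:, None] - row2[None, :] + F2))
    return float(max(d_ll.max(), d_lr.max(), d_ul.max(), d_uu.max()))


def _cumcounts(ix: np.ndarray, iy: np.ndarray, nx: int, ny: int) -> np.ndarray:
    c = np.zeros((nx, ny))
    np.add.at(c, (ix, iy), 1.0)
    return c.cumsum(axis=0).cumsum(axis=1)


def ks2d_statistic(sample1, sample2, variant: str = "peacock") -> float:
    """Two-sample 2D KS statistic D in [0, 1].

    ``peacock``: quadrant origins run over the full grid of pooled unique
    x-coordinates times pooled unique y-coordinates.  ``ff``
    (Fasano-Franceschini): origins restricted to observed data points.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both samples must be nonempty lists of (x, y) pairs")
    xs = np.unique(np.concatenate([a[:, 0], b[:, 0]]))
    ys = np.unique(np.concatenate([a[:, 1], b[:, 1]]))
    ix_a = np.searchsorted(xs, a[:, 0])
    iy_a = np.searchsorted(ys, a[:, 1])
    ix_b = np.searchsorted(xs, b[:, 0])
    iy_b = np.searchsorted(ys, b[:, 1])
    cum1 = _cumcounts(ix_a, iy_a, xs.size, ys.size)
    cum2 = _cumcounts(ix_b, iy_b, xs.size, ys.size)
    if variant == "peacock":
        return _quadrant_d(cum1, cum2, a.shape[0], b.shape[0])
    if variant == "ff":
        # restrict origins to observed points
        F1, F2 = cum1 / a.shape[0], cum2 / b.shape[0]
        row1, row2 = cum1[-1, :] / a.shape[0], cum2[-1, :] / b.shape[0]
        col1, col2 = cum1[:, -1] / a.shape[0], cum2[:, -1] / b.shape[0]
        pts_i = np.concatenate([ix_a, ix_b])
        pts_j = np.concatenate([iy_a, iy_b])
        d = 0.0
        for dmat in (
            np.abs(F1 - F2),
            np.abs((col1[:, None] - F1) - (col2[:, None] - F2)),
            np.abs((row1[None, :] - F1) - (row2[None, :] - F2)),
            np.abs((1 - col1[:, None] - row1[None, :] + F1)
                   - (1 - col2[:, None] - row2[None, :] + F2)),
        ):
            d = max(d, float(dmat[pts_i, pts_j].max()))
        return d
    raise ValueError(f"unknown variant {variant!r}; expected 'peacock' or 'ff'")


def peacock_ks2d(sample1, sample2, n_perm: int = 9999, seed: int | None = None,
                 variant: str = "peacock") -> StatTestResult:
    """Two-sample 2D KS test with a label-permutation p-value.

    The p-value is ``(1 + #{D_perm >= D_obs}) / (1 + n_perm)`` so it is never
    zero and is reproducible from the seed.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both samples must be nonempty lists of (x, y) pairs")
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99 for an interpretable p, got {n_perm}")
    d_obs = ks2d_statistic(a, b, variant=variant)

    pooled = np.concatenate([a, b])
    n1 = a.shape[0]
    xs = np.unique(pooled[:, 0])
    ys = np.unique(pooled[:, 1])
    ix = np.searchsorted(xs, pooled[:, 0])
    iy = np.searchsorted(ys, pooled[:, 1])
    rng = np.random.default_rng(seed)
    order = np.arange(pooled.shape[0])
    count = 0
    for _ in range(n_perm):
        rng.shuffle(order)
        first = order[:n1]
        second = order[n1:]
        if variant == "peacock":
            cum1 = _cumcounts(ix[first], iy[first], xs.size, ys.size)
            cum2 = _cumcounts(ix[second], iy[second], xs.size, ys.size)
            d = _quadrant_d(cum1, cum2, n1, pooled.shape[0] - n1)
        else:
            d = ks2d_statistic(pooled[first], pooled[second], variant=variant)
        if d >= d_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    ties = (np.unique(pooled, axis=0).shape[0] < pooled.shape[0])
    return StatTestResult(statistic=d_obs, p_value=p, method=f"ks2d_{variant}_perm",
                         n_perm=n_perm, seed=seed, ties_present=bool(ties))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 8


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney_two_tailed(x, y) -> StatTestResult:
    """Two-tailed Mann-Whitney U test with mid-ranks for ties.

    Exact enumeration over all pooled splits when both samples have at most
    8 observations (valid under ties); otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return StatTestResult(statistic=x.size * y.size / 2.0, p_value=1.0,
                              method="mann_whitney_degenerate", ties_present=True)
    u_obs = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    ties = np.unique(pooled).size < pooled.size

    if n1 <= _EXACT_LIMIT and n2 <= _EXACT_LIMIT:
        ranks = rankdata(pooled)
        lo = hi = 0
        total = 0
        offset = n1 * (n1 + 1) / 2.0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - offset
            total += 1
            if u <= u_obs + 1e-9:
                lo += 1
            if u >= u_obs - 1e-9:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return StatTestResult(statistic=u_obs, p_value=p, method="mann_whitney_exact",
                              ties_present=bool(ties))

    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return StatTestResult(statistic=u_obs, p_value=1.0,
                              method="mann_whitney_degenerate", ties_present=True)
    z = (abs(u_obs - mean) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
    return StatTestResult(statistic=u_obs, p_value=p, method="mann_whitney_normal",
                          ties_present=bool(ties))


# ---------------------------------------------------------------------------
# binomial
# ---------------------------------------------------------------------------


def binomial_two_tailed(k: int, n: int, p0: float, slack: float = 1e-7) -> float:
    """Exact two-tailed binomial p-value, minimum-likelihood convention.

    Sums P(X = x) over every x whose point probability is at most
    ``P(X = k) * (1 + slack)``, evaluated in log space so tail values down to
    ~1e-300 do not underflow.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < p0 < 1):
        raise ValueError(f"need 0 < p0 < 1, got {p0}")
    x = np.arange(n + 1)
    logpmf = (gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
              + x * math.log(p0) + (n - x) * math.log1p(-p0))
    thresh = logpmf[k] + math.log1p(slack)
    sel = logpmf <= thresh
    return float(min(1.0, math.exp(logsumexp(logpmf[sel]))))


# ---------------------------------------------------------------------------
# aligned-rank-transform two-factor ANOVA
# ---------------------------------------------------------------------------


def _effects_design(a_codes: np.ndarray, b_codes: np.ndarray,
                    n_a: int, n_b: int) -> dict[str, np.ndarray]:
    """Sum-to-zero (effects) coded columns for a full two-way layout."""
    n = a_codes.size

    def code(codes, n_lev):
        cols = np.zeros((n, n_lev - 1))
        for lev in range(n_lev - 1):
            cols[codes == lev, lev] = 1.0
            cols[codes == n_lev - 1, lev] = -1.0
        return cols

    xa = code(a_codes, n_a)
    xb = code(b_codes, n_b)
    xab = np.concatenate([xa[:, i:i + 1] * xb[:, j:j + 1]
                          for i in range(n_a - 1) for j in range(n_b - 1)], axis=1)
    return {"intercept": np.ones((n, 1)), "A": xa, "B": xb, "A:B": xab}


def _anova_f(ranks: np.ndarray, blocks: dict[str, np.ndarray], effect: str):
    """Type-III F for one effect in the full two-way fixed-effects model."""
    full = np.concatenate(list(blocks.values()), axis=1)
    reduced = np.concatenate([v for k, v in blocks.items() if k != effect], axis=1)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, ranks, rcond=None)
        resid = ranks - X @ beta
        return float(resid @ resid)

    rss_full = rss(full)
    rss_red = rss(reduced)
    df1 = blocks[effect].shape[1]
    df2 = ranks.size - np.linalg.matrix_rank(full)
    ss_eff = max(0.0, rss_red - rss_full)
    if rss_full <= 1e-10 * max(1.0, float(ranks @ ranks)):
        if ss_eff <= 1e-10:
            return 0.0, df1, df2, 1.0, True  # degenerate: constant aligned ranks
        return float("inf"), df1, df2, 0.0, False
    f_val = (ss_eff / df1) / (rss_full / df2)
    p = float(f_dist.sf(f_val, df1, df2))
    return f_val, df1, df2, p, False


def art_anova_two_factor(response, factor_a, factor_b) -> list[dict]:
    """Aligned-rank-transform ANOVA for a two-factor fixed-effects design.

    For each effect (A, B, A:B) the response is aligned — residual from the
    cell means plus that effect's estimate from (unweighted) cell/marginal/
    grand means — mid-ranked, and a full two-way ANOVA is run on the ranks;
    only the aligned effect's F and p are reported, giving three separate
    alignments.

    Returns a list of dicts ``{effect, F, df1, df2, p, ties}``.
    """
    y = np.asarray(response, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (y.size == a.size == b.size):
        raise ValueError("response and factors must have equal length")
    a_levels, a_codes = np.unique(a, return_inverse=True)
    b_levels, b_codes = np.unique(b, return_inverse=True)
    n_a, n_b = a_levels.size, b_levels.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each factor needs at least 2 levels")

    cell_sum = np.zeros((n_a, n_b))
    cell_n = np.zeros((n_a, n_b))
    np.add.at(cell_sum, (a_codes, b_codes), y)
    np.add.at(cell_n, (a_codes, b_codes), 1.0)
    if (cell_n == 0).any():
        i, j = np.argwhere(cell_n == 0)[0]
        raise ValueError(f"empty design cell: A={a_levels[i]!r}, B={b_levels[j]!r}")
    cell_mean = cell_sum / cell_n
    # unweighted marginal/grand means of cell means (robust to unbalance)
    mean_a = cell_mean.mean(axis=1)
    mean_b = cell_mean.mean(axis=0)
    grand = cell_mean.mean()

    resid = y - cell_mean[a_codes, b_codes]
    estimates = {
        "A": mean_a[a_codes] - grand,
        "B": mean_b[b_codes] - grand,
        "A:B": (cell_mean[a_codes, b_codes] - mean_a[a_codes]
                - mean_b[b_codes] + grand),
    }
    blocks = _effects_design(a_codes, b_codes, n_a, n_b)

    out = []
    for effect, est in estimates.items():
        aligned = resid + est
        ranks = rankdata(aligned)
        f_val, df1, df2, p, degenerate = _anova_f(ranks, blocks, effect)
        ties = degenerate or (np.unique(aligned).size < aligned.size)
        out.append({"effect": effect, "F": f_val, "df1": df1, "df2": df2,
                    "p": p, "ties": bool(ties)})
    return out


def lr_pvalue(lr_statistic: float, df: int = 1) -> float:
    """Chi-squared tail p-value for a likelihood-ratio statistic."""
    return float(chi2.sf(max(lr_statistic, 0.0), df))
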