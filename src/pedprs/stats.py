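"""Rank-based inference: correlations, group tests, post-hoc and interaction.

All procedures operate on ranks (average ranks for ties) and report two-sided
p-values. The toolbox covers what a nonparametric cross-sectional analysis of
a skewed pediatric outcome needs:

- Spearman correlation, plain and covariate-adjusted (partial) via rank
  residualization;
- Wilcoxon rank-sum (exact enumeration for small pooled samples,
  tie-corrected normal approximation otherwise);
- Kruskal–Wallis with tie correction;
- Dunn's pairwise z comparisons on joint ranks, valid for unequal group
  sizes, with Bonferroni (default) or Holm adjustment;
- Jonckheere–Terpstra trend test for ordered groups (exact for tiny N);
- Scheirer–Ray–Hare rank two-way interaction;
- Pearson chi-square for contingency tables;
- rank R² (the share of outcome rank variance explained by a predictor's
  ranks; identical to the squared Spearman coefficient).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    """One inference step: statistic, p-value and group summaries."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    label: str | None = None
    groups: list[dict] | None = None
    adjusted: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "label": self.label,
            "adjusted": self.adjusted,
        }
        if self.groups is not None:
            d["groups"] = self.groups
        d.update(self.extra)
        return d

    def tsv_row(self) -> str:
        d = self.to_dict()
        keys = ["method", "label", "statistic", "p_value", "df", "adjusted"]
        return "\t".join("" if d.get(k) is None else str(d.get(k)) for k in keys)


def group_summary(name, values) -> dict:
    """n, median and quartiles (linear interpolation) of one group."""
    v = np.asarray(values, dtype=float)
    return {
        "group": str(name),
        "n": int(v.size),
        "median": float(np.median(v)) if v.size else np.nan,
        "p25": float(np.percentile(v, 25)) if v.size else np.nan,
        "p75": float(np.percentile(v, 75)) if v.size else np.nan,
    }


def _as_1d(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.isnan(x).any():
        raise ValueError(f"{name} contains missing values; pass complete cases")
    return x


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with the t-approximation p-value (n-2 df)."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero rank variance")
    rs, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rs), float(p), df=n - 2, extra={"n": n})


def partial_spearman(x, y, covariates=None) -> TestResult:
    """Covariate-adjusted Spearman via rank residualization.

    Ranks x, y and every covariate column, residualizes the ranked x and y on
    the ranked covariate matrix by least squares (with intercept), and
    correlates the residuals. The p-value uses the t reference with
    n - 2 - k df, k the number of covariate columns. Categorical covariates
    must be indicator-coded by the caller.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    n = x.size
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        res = spearman(x, y)
        return TestResult(
            "partial_spearman", res.statistic, res.p_value, df=res.df, extra={"n": n, "k": 0}
        )
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValueError("covariate rows must match x/y length")
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rz = np.column_stack([np.ones(n)] + [sps.rankdata(Z[:, j]) for j in range(k)])
    if np.linalg.matrix_rank(rz) < rz.shape[1]:
        warnings.warn("collinear covariates: using least-norm projection", stacklevel=2)
    coef_x, *_ = np.linalg.lstsq(rz, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(rz, ry, rcond=None)
    ex = rx - rz @ coef_x
    ey = ry - rz @ coef_y
    sx, sy = ex.std(), ey.std()
    # ranks fully explained by the covariates: the partial association is zero
    # (comparing against the rank scale guards lstsq round-off)
    rank_scale = max(rx.std(), ry.std(), 1.0)
    if sx <= 1e-9 * rank_scale or sy <= 1e-9 * rank_scale:
        return TestResult(
            "partial_spearman", 0.0, 1.0, df=n - 2 - k, extra={"n": n, "k": k}
        )
    r = float(np.dot(ex - ex.mean(), ey - ey.mean()) / (n * sx * sy))
    dfree = n - 2 - k
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dfree / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), dfree))
    return TestResult("partial_spearman", r, p, df=dfree, extra={"n": n, "k": k})


def _tie_term(values: np.ndarray) -> float:
    """Sum of t³ - t over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    return float((counts**3 - counts).sum())


def wilcoxon_ranksum(a, b, exact_max_n: int = 12) -> TestResult:
    """Two-sample Wilcoxon rank-sum test, two-sided.

    Exact enumeration over all C(N, n_a) rank assignments when the pooled
    size is at most ``exact_max_n``; otherwise the tie-corrected normal
    approximation (no continuity correction). The statistic reported is the
    rank sum of the first sample.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    N = pooled.size
    na = a.size
    ranks = sps.rankdata(pooled)
    W = float(ranks[:na].sum())
    mean_W = na * (N + 1) / 2.0
    if N <= exact_max_n:
        # W is symmetric about its mean conditional on the pooled ranks
        dist = np.array(
            [ranks[list(c)].sum() for c in itertools.combinations(range(N), na)]
        )
        p = float(np.mean(np.abs(dist - mean_W) >= abs(W - mean_W) - 1e-12))
        z = np.nan
        method = "wilcoxon_ranksum_exact"
    else:
        nb = b.size
        var_W = na * nb / 12.0 * ((N + 1) - _tie_term(pooled) / (N * (N - 1)))
        if var_W <= 0:
            z, p = 0.0, 1.0
        else:
            z = (W - mean_W) / np.sqrt(var_W)
            p = float(2.0 * sps.norm.sf(abs(z)))
        method = "wilcoxon_ranksum"
    return TestResult(
        method,
        W,
        min(p, 1.0),
        groups=[group_summary("a", a), group_summary("b", b)],
        extra={"z": float(z) if np.isfinite(z) else None, "n": N},
    )


def kruskal_wallis(groups, labels=None) -> TestResult:
    """Kruskal–Wallis H with tie correction; chi-square reference, k-1 df."""
    groups = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    summaries = [group_summary(lab, g) for lab, g in zip(labels, groups)]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal_wallis", 0.0, 1.0, df=len(groups) - 1, groups=summaries)
    H, p = sps.kruskal(*groups)
    return TestResult(
        "kruskal_wallis", float(H), float(p), df=len(groups) - 1, groups=summaries
    )


def dunn_multiple(groups, labels=None, adjust: str = "bonferroni") -> list[TestResult]:
    """Dunn's joint-rank pairwise comparisons for unequal sample sizes.

    For each pair (i, j):

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    with T the tie term sum(t³ - t) over pooled tie groups. Unadjusted
    two-sided normal p-values are adjusted per ``adjust`` ("bonferroni",
    "holm" or "none").
    """
    groups = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group in Dunn comparison")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if adjust not in ("bonferroni", "holm", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    var_base = N * (N + 1) / 12.0
    if N > 1:
        var_base -= _tie_term(pooled) / (12.0 * (N - 1))

    pairs = list(itertools.combinations(range(len(groups)), 2))
    zs, ps = [], []
    for i, j in pairs:
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    ps = np.asarray(ps)
    m = len(pairs)
    if adjust == "bonferroni":
        adj = np.minimum(ps * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(ps)
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * ps[idx])
            adj[idx] = min(running, 1.0)
    else:
        adj = ps
    results = []
    for (i, j), z, p_raw, p_adj in zip(pairs, zs, ps, adj):
        results.append(
            TestResult(
                "dunn",
                float(z),
                float(p_adj),
                label=f"{labels[i]} vs {labels[j]}",
                groups=[group_summary(labels[i], groups[i]), group_summary(labels[j], groups[j])],
                adjusted=adjust != "none",
                extra={"p_unadjusted": float(p_raw), "adjust": adjust},
            )
        )
    return results


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for gi, gj in itertools.combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        jt += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(jt)


def trend_test(groups, labels=None, exact_max_n: int = 10) -> TestResult:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    JT counts cross-group pairs concordant with the group order (ties half).
    Exact enumeration over all group assignments of the pooled values when
    N <= ``exact_max_n``; otherwise the tie-corrected normal approximation.
    Two-sided p as twice the smaller tail (point included), capped at 1.
    """
    groups = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(groups) < 3:
        raise ValueError("trend test needs >= 3 ordered groups; use wilcoxon_ranksum for 2")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group in trend test")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    summaries = [group_summary(lab, g) for lab, g in zip(labels, groups)]
    jt = _jt_statistic(groups)
    sizes = np.array([g.size for g in groups])
    N = int(sizes.sum())
    E = (N * N - (sizes**2).sum()) / 4.0

    if N <= exact_max_n:
        pooled = np.concatenate(groups)
        stats_all = []
        idx = list(range(N))

        def recurse(remaining: list[int], assigned: list[np.ndarray]) -> None:
            gi = len(assigned)
            if gi == len(sizes) - 1:
                stats_all.append(_jt_statistic(assigned + [pooled[remaining]]))
                return
            for comb in itertools.combinations(remaining, int(sizes[gi])):
                rest = [r for r in remaining if r not in comb]
                recurse(rest, assigned + [pooled[list(comb)]])

        recurse(idx, [])
        dist = np.asarray(stats_all)
        lo = np.mean(dist <= jt + 1e-12)
        hi = np.mean(dist >= jt - 1e-12)
        p = min(1.0, 2.0 * min(lo, hi))
        z = np.nan
        method = "jonckheere_terpstra_exact"
    else:
        pooled = np.concatenate(groups)
        _, t = np.unique(pooled, return_counts=True)
        n_i = sizes.astype(float)
        A = N * (N - 1) * (2 * N + 5) - (n_i * (n_i - 1) * (2 * n_i + 5)).sum() - (
            t * (t - 1) * (2 * t + 5)
        ).sum()
        B = (n_i * (n_i - 1) * (n_i - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
        C = (n_i * (n_i - 1)).sum() * (t * (t - 1)).sum()
        var = A / 72.0 + B / (36.0 * N * (N - 1) * (N - 2)) + C / (8.0 * N * (N - 1))
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (jt - E) / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(abs(z)))
        method = "jonckheere_terpstra"
    return TestResult(
        method,
        jt,
        p,
        groups=summaries,
        extra={"z": float(z) if np.isfinite(z) else None, "expected": E, "n": N},
    )


def rank_interaction(outcome, factor_a, factor_b) -> TestResult:
    """Scheirer–Ray–Hare rank test for a two-factor interaction.

    Ranks the outcome jointly, computes the interaction sum of squares as
    SSE(additive model) - SSE(full cell-means model) on the ranks, and refers
    H = SS_interaction / MS_total to chi-square with (a-1)(b-1) df, where
    MS_total = SS_total / (N-1).
    """
    y = _as_1d(outcome, "outcome")
    fa = np.asarray(factor_a, dtype=object)
    fb = np.asarray(factor_b, dtype=object)
    if not (len(fa) == len(fb) == y.size):
        raise ValueError("outcome and factors must be aligned")
    levels_a = sorted(set(fa), key=str)
    levels_b = sorted(set(fb), key=str)
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("both factors need at least two levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((fa == la) & (fb == lb)):
                raise ValueError(f"empty design cell ({la!r}, {lb!r})")
    df_int = (len(levels_a) - 1) * (len(levels_b) - 1)
    r = sps.rankdata(y)
    ss_total = float(((r - r.mean()) ** 2).sum())
    if ss_total == 0:
        return TestResult("scheirer_ray_hare", 0.0, 1.0, df=df_int)
    A = np.column_stack([(fa == la).astype(float) for la in levels_a[1:]])
    B = np.column_stack([(fb == lb).astype(float) for lb in levels_b[1:]])
    ones = np.ones((y.size, 1))
    X_add = np.hstack([ones, A, B])
    inter = [
        (A[:, i] * B[:, j])[:, None] for i in range(A.shape[1]) for j in range(B.shape[1])
    ]
    X_full = np.hstack([X_add] + inter)

    def sse(X: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(X, r, rcond=None)
        e = r - X @ coef
        return float(e @ e)

    ss_int = max(sse(X_add) - sse(X_full), 0.0)
    ms_total = ss_total / (y.size - 1)
    H = ss_int / ms_total
    p = float(sps.chi2.sf(H, df_int))
    return TestResult("scheirer_ray_hare", H, p, df=df_int, extra={"n": y.size})


def chi_square_table(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r×c count table.

    Rows/columns with zero marginals are dropped with a warning; expected
    counts below 5 trigger a small-cell warning. If fewer than two rows or
    columns remain, the statistic is 0 with p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() < 1:
        raise ValueError("table total must be at least 1")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-marginal rows/columns", stacklevel=2)
        t = t[keep_r][:, keep_c]
    r, c = t.shape
    if r < 2 or c < 2:
        return TestResult("chi_square", 0.0, 1.0, df=0, extra={"n": float(t.sum())})
    res = sps.chi2_contingency(t, correction=correction)
    if (res.expected_freq < 5).any():
        warnings.warn("expected cell counts below 5; chi-square approximation is weak", stacklevel=2)
        log.warning("chi-square table has expected counts < 5")
    return TestResult(
        "chi_square", float(res.statistic), float(res.pvalue), df=float(res.dof),
        extra={"n": float(t.sum())},
    )


def rank_r_squared(x, y) -> float:
    """Share of rank variance of y explained by ranks of x (= Spearman r²)."""
    res = spearman(x, y)
    return float(res.statistic**2)
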