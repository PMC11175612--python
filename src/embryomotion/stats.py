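"""Group-comparison battery for phase sums and related measurements.

The decision logic mirrors common practice in behavioural datasets:

* a normality gate — a sample counts as normal only if **all four** of
  D'Agostino & Pearson, Anderson-Darling, Shapiro-Wilk and
  Kolmogorov-Smirnov (Lilliefors, since mean and sd are estimated) fail to
  reject at alpha = 0.05; a single rejection routes the comparison to the
  nonparametric branch;
* two groups — Welch's t when both pass the gate, otherwise Mann-Whitney U
  (exact enumeration when min(n) <= 8 with no ties, tie-corrected normal
  approximation otherwise), with Bonferroni adjustment across the number of
  planned comparisons (e.g. the two movement phases);
* three or more groups — Brown-Forsythe and Welch ANOVA followed by pairwise
  Dunnett T3 when all groups pass the gate, otherwise Kruskal-Wallis followed
  by Dunn's pairwise test with Bonferroni adjustment.

Tests are two-sided unless a direction is configured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupData",
    "NormalityReport",
    "TestReport",
    "normality_gate",
    "compare_two",
    "compare_many",
    "welch_anova",
    "brown_forsythe_anova",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupData:
    """Labelled numeric observations, one entry per group."""

    groups: tuple[tuple[str, np.ndarray], ...]

    def __post_init__(self) -> None:
        clean = []
        for label, obs in self.groups:
            arr = np.asarray(obs, dtype=float)
            if arr.size < 1:
                raise ValueError(f"group {label!r} is empty")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {label!r} contains non-finite observations")
            clean.append((str(label), arr))
        object.__setattr__(self, "groups", tuple(clean))

    @classmethod
    def from_dict(cls, d: dict) -> "GroupData":
        return cls(groups=tuple((k, np.asarray(v, dtype=float)) for k, v in d.items()))

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]


@dataclass
class NormalityReport:
    verdict: str                       # "normal" | "non-normal" | "indeterminate"
    detail: dict = field(default_factory=dict)  # test name -> (statistic, p or crit, reject)
    note: str = ""


@dataclass
class TestReport:
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment: str
    n_per_group: dict
    normality: dict
    comparison: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_adjusted):
            if not (0.0 <= p <= 1.0 or np.isnan(p)):
                raise ValueError(f"p-value outside [0, 1]: {p}")


def normality_gate(obs, alpha: float = ALPHA) -> NormalityReport:
    """Unanimity gate over the four standard normality tests.

    Returns "normal" only if none of D'Agostino & Pearson, Anderson-Darling,
    Shapiro-Wilk, Lilliefors rejects at ``alpha``; "indeterminate" for n < 8
    where the omnibus tests are undefined.
    """
    x = np.asarray(obs, dtype=float)
    if x.size < 8:
        return NormalityReport(
            verdict="indeterminate",
            note=f"n={x.size} < 8: omnibus normality tests undefined; "
                 "treated as non-normal downstream")
    if np.ptp(x) == 0:
        return NormalityReport(verdict="non-normal",
                               note="zero variance: degenerate sample")
    detail = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # kurtosistest warns for n < 20
        k2, p_dp = sps.normaltest(x)
        detail["dagostino_pearson"] = (float(k2), float(p_dp), p_dp < alpha)
        ad = sps.anderson(x, dist="norm")
        crit = float(ad.critical_values[list(ad.significance_level).index(5.0)])
        detail["anderson_darling"] = (float(ad.statistic), crit, ad.statistic > crit)
        w, p_sw = sps.shapiro(x)
        detail["shapiro_wilk"] = (float(w), float(p_sw), p_sw < alpha)
        d, p_ks = lilliefors(x, dist="norm")
        detail["kolmogorov_smirnov_lilliefors"] = (float(d), float(p_ks), p_ks < alpha)
    rejected = any(rej for _, _, rej in detail.values())
    return NormalityReport(verdict="non-normal" if rejected else "normal", detail=detail)


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * max(int(m), 1))


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if min(a.size, b.size) <= 8 and not ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "mann_whitney_exact"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue), "mann_whitney_asymptotic"


def compare_two(groups: GroupData, n_comparisons: int = 1,
                alpha: float = ALPHA) -> TestReport:
    """Welch's t if both groups pass the normality gate, else Mann-Whitney U,
    Bonferroni-adjusted over ``n_comparisons`` planned comparisons."""
    if len(groups.groups) != 2:
        raise ValueError("compare_two needs exactly 2 groups")
    (la, a), (lb, b) = groups.groups
    gates = {la: normality_gate(a, alpha), lb: normality_gate(b, alpha)}
    both_normal = all(g.verdict == "normal" for g in gates.values())
    if both_normal:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        test, stat = "welch_t", float(t)
        p = float(p)
    else:
        stat, p, test = _mannwhitney(a, b)
    return TestReport(
        test=test, statistic=stat, p_raw=p,
        p_adjusted=_bonferroni(p, n_comparisons),
        adjustment=f"bonferroni(m={n_comparisons})",
        n_per_group={la: a.size, lb: b.size},
        normality={k: v.verdict for k, v in gates.items()},
        comparison=(la, lb),
    )


def welch_anova(groups: GroupData) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA: (F, df1, df2, p)."""
    data = [arr for _, arr in groups.groups]
    k = len(data)
    ns = np.array([a.size for a in data], dtype=float)
    if np.any(ns < 2):
        raise ValueError("Welch ANOVA needs n >= 2 in every group")
    means = np.array([a.mean() for a in data])
    vars_ = np.array([a.var(ddof=1) for a in data])
    if np.any(vars_ == 0):
        raise ValueError("Welch ANOVA undefined for zero-variance groups")
    w = ns / vars_
    W = w.sum()
    mstar = (w * means).sum() / W
    A = (w * (means - mstar) ** 2).sum() / (k - 1)
    lam = ((1 - w / W) ** 2 / (ns - 1)).sum()
    B = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    F = A / B
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * lam)
    return float(F), float(df1), float(df2), float(sps.f.sf(F, df1, df2))


def brown_forsythe_anova(groups: GroupData) -> tuple[float, float, float, float]:
    """Brown-Forsythe F* ANOVA (group means, variance-weighted denominator):
    (F*, df1, df2, p) with Satterthwaite denominator df."""
    data = [arr for _, arr in groups.groups]
    k = len(data)
    ns = np.array([a.size for a in data], dtype=float)
    if np.any(ns < 2):
        raise ValueError("Brown-Forsythe ANOVA needs n >= 2 in every group")
    N = ns.sum()
    means = np.array([a.mean() for a in data])
    vars_ = np.array([a.var(ddof=1) for a in data])
    grand = np.concatenate(data).mean()
    num = (ns * (means - grand) ** 2).sum()
    denom_terms = (1 - ns / N) * vars_
    denom = denom_terms.sum()
    if denom == 0:
        raise ValueError("Brown-Forsythe ANOVA undefined for zero-variance groups")
    F = num / denom
    c = denom_terms / denom
    df2 = 1.0 / (c**2 / (ns - 1)).sum()
    df1 = k - 1
    return float(F), float(df1), float(df2), float(sps.f.sf(F, df1, df2))


def _dunnett_t3_pairs(groups: GroupData) -> list[TestReport]:
    """Pairwise Welch-type t with studentized-maximum-modulus family adjustment.

    The SMM tail is evaluated via the independence bound
    ``p_adj = 1 - P(|T_nu| < t)^m`` with Welch degrees of freedom per pair —
    the standard approximation when the proprietary reference tables are not
    reproducible.
    """
    pairs = list(combinations(groups.groups, 2))
    m = len(pairs)
    out = []
    for (la, a), (lb, b) in pairs:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se = np.sqrt(va + vb)
        t = (a.mean() - b.mean()) / se
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_raw = 2 * sps.t.sf(abs(t), df)
        central = 2 * sps.t.cdf(abs(t), df) - 1
        p_adj = float(np.clip(1 - central**m, 0, 1))
        out.append(TestReport(
            test="dunnett_t3", statistic=float(t), p_raw=float(p_raw),
            p_adjusted=max(p_adj, float(p_raw)),
            adjustment=f"studentized_maximum_modulus(m={m})",
            n_per_group={la: a.size, lb: b.size},
            normality={}, comparison=(la, lb)))
    return out


def _dunn_pairs(groups: GroupData) -> list[TestReport]:
    """Dunn's rank-based pairwise z tests with tie correction and Bonferroni
    family adjustment."""
    data = [arr for _, arr in groups.groups]
    labels = groups.labels
    pooled = np.concatenate(data)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    i0 = 0
    for arr in data:
        mean_ranks.append(ranks[i0:i0 + arr.size].mean())
        i0 += arr.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    pairs = list(combinations(range(len(data)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / data[i].size + 1.0 / data[j].size))
        if se == 0:   # every observation tied
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2 * sps.norm.sf(abs(z))
        out.append(TestReport(
            test="dunn", statistic=float(z), p_raw=float(p_raw),
            p_adjusted=_bonferroni(p_raw, m), adjustment=f"bonferroni(m={m})",
            n_per_group={labels[i]: data[i].size, labels[j]: data[j].size},
            normality={}, comparison=(labels[i], labels[j])))
    return out


def compare_many(groups: GroupData, alpha: float = ALPHA) -> list[TestReport]:
    """Omnibus + pairwise battery for >= 3 groups.

    All groups normal (unanimous gate) -> Welch and Brown-Forsythe ANOVA, then
    pairwise Dunnett T3.  Otherwise -> Kruskal-Wallis (tie-corrected), then
    Dunn's pairwise tests.  Returns the omnibus report(s) followed by the
    pairwise reports.
    """
    if len(groups.groups) < 3:
        raise ValueError("compare_many needs >= 3 groups")
    gates = {label: normality_gate(arr, alpha) for label, arr in groups.groups}
    verdicts = {k: v.verdict for k, v in gates.items()}
    all_normal = all(v == "normal" for v in verdicts.values())
    ns = {label: arr.size for label, arr in groups.groups}
    reports: list[TestReport] = []
    if all_normal:
        F_w, _, _, p_w = welch_anova(groups)
        F_bf, _, _, p_bf = brown_forsythe_anova(groups)
        reports.append(TestReport(test="welch_anova", statistic=F_w, p_raw=p_w,
                                  p_adjusted=p_w, adjustment="none",
                                  n_per_group=ns, normality=verdicts))
        reports.append(TestReport(test="brown_forsythe_anova", statistic=F_bf,
                                  p_raw=p_bf, p_adjusted=p_bf, adjustment="none",
                                  n_per_group=ns, normality=verdicts))
        reports.extend(_dunnett_t3_pairs(groups))
    else:
        data = [arr for _, arr in groups.groups]
        if np.ptp(np.concatenate(data)) == 0:
            h, p = 0.0, 1.0   # every observation tied: no evidence of any difference
        else:
            h, p = sps.kruskal(*data)
        reports.append(TestReport(test="kruskal_wallis", statistic=float(h),
                                  p_raw=float(p), p_adjusted=float(p),
                                  adjustment="none", n_per_group=ns,
                                  normality=verdicts))
        reports.extend(_dunn_pairs(groups))
    return reports
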