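"""Group-level statistics: t-tests, 2×2 mixed ANOVA, correlations, power.

Covers the inferential layer of the two-group dot-probe analysis:

* independent-samples t-tests (from raw vectors or from printed summary
  statistics) with pooled-SD Cohen's d and a 95% CI on the mean difference;
* the 2 (group, between) × 2 (condition, within) mixed-design ANOVA with
  partial eta squared; for a two-level within factor every effect is an
  exact F(1, N−2) and the Greenhouse–Geisser epsilon is identically 1;
* Pearson correlations with t-based two-sided p-values;
* Bonferroni adjustment;
* the repeated-measures-ANOVA sample-size search based on the noncentral F
  distribution with noncentrality λ = f²·N·m·ε/(1−ρ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "TTestResult",
    "AnovaEffect",
    "AnovaResult",
    "PowerSpec",
    "t_independent_from_summary",
    "t_independent",
    "mixed_anova_2x2",
    "pearson_r",
    "bonferroni_adjust",
    "rm_anova_power",
    "rm_anova_sample_size",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD and n of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def of(cls, x: np.ndarray) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    d: float                      # pooled-SD Cohen's d
    ci95: tuple[float, float]     # CI on the mean difference
    variance_rule: str = "pooled"


@dataclass
class AnovaEffect:
    F: float
    df: tuple[float, float]
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    group: AnovaEffect
    condition: AnovaEffect
    interaction: AnovaEffect
    gg_epsilon: float = 1.0

    def effects(self) -> dict[str, AnovaEffect]:
        return {"group": self.group, "condition": self.condition,
                "interaction": self.interaction}


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the repeated-measures ANOVA power computation."""

    f: float                      # Cohen's f effect size
    alpha: float = 0.05
    target_power: float = 0.80
    n_groups: int = 2
    n_measurements: int = 2
    rho: float = 0.5              # correlation among repeated measures
    epsilon: float = 1.0          # nonsphericity correction

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("effect size f must be > 0")
        for name in ("alpha", "target_power", "rho"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must be in (0, 1]")


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def t_independent_from_summary(g1: SummaryStats, g2: SummaryStats,
                               variance_rule: str = "pooled") -> TTestResult:
    """Independent-samples t-test from group summary statistics.

    Pooled rule: s_p² = ((n1−1)s1² + (n2−1)s2²)/(n1+n2−2),
    t = (m1−m2)/(s_p √(1/n1+1/n2)), df = n1+n2−2. Cohen's d is (m1−m2)/s_p
    under either rule; the Welch rule changes only t's SE and df.
    """
    diff = g1.mean - g2.mean
    sp2 = ((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2) / (g1.n + g2.n - 2)
    sp = math.sqrt(sp2)
    if variance_rule == "pooled":
        se = sp * math.sqrt(1.0 / g1.n + 1.0 / g2.n)
        df = g1.n + g2.n - 2
    elif variance_rule == "welch":
        v1, v2 = g1.sd ** 2 / g1.n, g2.sd ** 2 / g2.n
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1)) \
            if (v1 + v2) > 0 else g1.n + g2.n - 2
    else:
        raise ValueError(f"unknown variance rule {variance_rule!r}")

    if se == 0.0:
        # zero variance: infinite t unless the means agree too
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
        d = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        return TTestResult(t=t, df=df, p=p, d=d, ci95=(diff, diff),
                           variance_rule=variance_rule)

    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    d = diff / sp if sp > 0 else math.copysign(math.inf, diff)
    tc = stats.t.ppf(0.975, df)
    return TTestResult(t=t, df=df, p=float(p), d=d,
                       ci95=(diff - tc * se, diff + tc * se),
                       variance_rule=variance_rule)


def t_independent(x: np.ndarray, y: np.ndarray,
                  variance_rule: str = "pooled") -> TTestResult:
    """Independent-samples t-test on raw vectors (via their summaries)."""
    return t_independent_from_summary(SummaryStats.of(x), SummaryStats.of(y),
                                      variance_rule)


# ---------------------------------------------------------------------------
# 2 x 2 mixed ANOVA
# ---------------------------------------------------------------------------

def mixed_anova_2x2(data: pd.DataFrame,
                    group_col: str = "group",
                    within_cols: tuple[str, str] = ("congruent", "incongruent"),
                    ) -> AnovaResult:
    """Mixed-design ANOVA: 2 groups (between) × 2 conditions (within).

    ``data`` holds one row per subject with the group label and both
    condition values (wide format). With a two-level within factor the
    design collapses exactly onto subject means and difference scores:

    * group effect   — pooled t² on per-subject condition means;
    * condition      — t² of the unweighted mean of the two groups'
      difference-score means against 0 (Type-III convention, robust to
      unequal group sizes);
    * interaction    — pooled t² comparing difference scores between groups.

    All three effects have df = (1, N−2); partial η² = F/(F + df₂);
    Greenhouse–Geisser ε ≡ 1 (two within levels).
    """
    groups = data[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    c1, c2 = within_cols
    if data[[c1, c2]].isna().any().any():
        raise ValueError("every subject needs both condition values")

    g1 = data[data[group_col] == groups[0]]
    g2 = data[data[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    n1, n2 = len(g1), len(g2)
    df2 = n1 + n2 - 2

    def _f_effect(t: float) -> AnovaEffect:
        F = t * t
        if math.isinf(F):       # zero error variance, nonzero effect
            return AnovaEffect(F=F, df=(1, df2), p=0.0, partial_eta_sq=1.0)
        p = stats.f.sf(F, 1, df2)
        return AnovaEffect(F=F, df=(1, df2), p=float(p),
                           partial_eta_sq=F / (F + df2))

    def _t_ratio(num: float, se: float) -> float:
        if se > 0:
            return num / se
        return 0.0 if num == 0 else math.copysign(math.inf, num)

    # between: subject means across conditions
    s1 = (g1[c1].to_numpy() + g1[c2].to_numpy()) / 2.0
    s2 = (g2[c1].to_numpy() + g2[c2].to_numpy()) / 2.0
    pooled = lambda a, b: math.sqrt(((len(a) - 1) * a.var(ddof=1)
                                     + (len(b) - 1) * b.var(ddof=1)) / df2)
    inv_n = 1.0 / n1 + 1.0 / n2
    sp_s = pooled(s1, s2)
    t_group = _t_ratio(s1.mean() - s2.mean(), sp_s * math.sqrt(inv_n))

    # within + interaction: difference scores
    d1 = g1[c2].to_numpy() - g1[c1].to_numpy()
    d2 = g2[c2].to_numpy() - g2[c1].to_numpy()
    sp_d = pooled(d1, d2)
    grand_d = (d1.mean() + d2.mean()) / 2.0           # unweighted (Type III)
    t_cond = _t_ratio(grand_d, sp_d * math.sqrt(inv_n) / 2.0)
    t_int = _t_ratio(d1.mean() - d2.mean(), sp_d * math.sqrt(inv_n))

    return AnovaResult(group=_f_effect(t_group),
                       condition=_f_effect(t_cond),
                       interaction=_f_effect(t_int),
                       gg_epsilon=1.0)


# ---------------------------------------------------------------------------
# correlations and multiplicity
# ---------------------------------------------------------------------------

def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(pvals) -> np.ndarray:
    """p_adj = min(1, m·p); order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return np.minimum(1.0, p * p.size)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA power / sample size
# ---------------------------------------------------------------------------

def rm_anova_power(spec: PowerSpec, n_total: int) -> float:
    """Analytic power of the within/interaction F-test at total N.

    Noncentral-F formulation: df1 = (m−1)ε, df2 = (N−k)(m−1)ε and
    λ = f²·N·m·ε/(1−ρ), where k groups, m repeated measurements, ρ the
    correlation among repeated measures and ε the nonsphericity correction.
    """
    k, m = spec.n_groups, spec.n_measurements
    if n_total <= k:
        return 0.0
    df1 = (m - 1) * spec.epsilon
    df2 = (n_total - k) * (m - 1) * spec.epsilon
    lam = spec.f ** 2 * n_total * m * spec.epsilon / (1.0 - spec.rho)
    f_crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def rm_anova_sample_size(spec: PowerSpec, n_cap: int = 100_000) -> int:
    """Smallest total N whose analytic power reaches ``spec.target_power``.

    N is meant to be split as evenly as possible across the groups. Raises
    ``ValueError`` if the target power is not reached by ``n_cap``.
    """
    for n_total in range(spec.n_groups + 1, n_cap + 1):
        if rm_anova_power(spec, n_total) >= spec.target_power:
            return n_total
    raise ValueError(f"target power {spec.target_power} not reachable "
                     f"with N <= {n_cap}")
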