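"""Group-level statistics over per-image summary values.

The unit of replication is the image: each round (condition folder)
contributes one value per image for the chosen parameter (count, mean area,
mean intensity, or density). On top of these the layer offers a classical
one-way ANOVA with Tukey-Kramer post hoc comparisons (valid for unequal group
sizes), a two-tailed equal-variance t test, and a one-sample K-S normality
check against a normal with the sample's own moments (Lilliefors-style
composite null; estimating the moments from the sample makes the asymptotic
p value conservative toward normality, so a parametric-bootstrap p is offered
as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError


@dataclass
class GroupedMeasurements:
    """Ordered (round_name, values) groups for one parameter."""

    groups: list[tuple[str, np.ndarray]]
    parameter: str = "count"

    def __post_init__(self) -> None:
        if not self.groups:
            raise DegenerateDataError("need at least one group")
        clean = []
        for name, vals in self.groups:
            arr = np.asarray(vals, dtype=np.float64)
            if arr.size < 1 or not np.all(np.isfinite(arr)):
                raise DegenerateDataError(f"group {name!r} must hold >=1 finite values")
            clean.append((name, arr))
        self.groups = clean

    def arrays(self) -> list[np.ndarray]:
        return [vals for _, vals in self.groups]

    def names(self) -> list[str]:
        return [name for name, _ in self.groups]


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    group_sems: dict[str, float]
    ms_within: float


@dataclass
class TukeyTable:
    """All-pairs comparisons: (group_i, group_j, mean difference, 95% CI, p)."""

    rows: list[tuple[str, str, float, float, float, float]]


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def one_way_anova(data: GroupedMeasurements) -> AnovaResult:
    """Classical one-way ANOVA decomposition with per-group mean +/- SEM."""
    arrays = data.arrays()
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    if k < 2 or n_total <= k:
        raise DegenerateDataError("ANOVA needs >=2 groups and total N > k")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        raise DegenerateDataError("all observations identical: ANOVA undefined")
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = float("inf")
        p = 0.0
    else:
        f = (ss_between / df_b) / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means={name: float(vals.mean()) for name, vals in data.groups},
        group_sems={name: _sem(vals) for name, vals in data.groups},
        ms_within=float(ms_w),
    )


def tukey_kramer(data: GroupedMeasurements, alpha: float = 0.05) -> TukeyTable:
    """Tukey-Kramer all-pairs comparisons after a one-way ANOVA.

    For groups i, j the CI half-width is
    q(1-alpha; k, df_within) / sqrt(2) * sqrt(MSW * (1/n_i + 1/n_j)) and the
    adjusted p comes from the studentized-range distribution; with unequal
    group sizes this is the Kramer extension.
    """
    anova = one_way_anova(data)
    k = len(data.groups)
    df_w = anova.df_within
    msw = anova.ms_within
    q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df_w))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            name_i, a = data.groups[i]
            name_j, b = data.groups[j]
            diff = float(a.mean() - b.mean())
            se = np.sqrt(msw * (1 / a.size + 1 / b.size))
            half = q_crit / np.sqrt(2) * se
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q_obs = abs(diff) / (se / np.sqrt(2))
                p = float(np.clip(sps.studentized_range.sf(q_obs, k, df_w), 0.0, 1.0))
            rows.append((name_i, name_j, diff, diff - half, diff + half, p))
    return TukeyTable(rows=rows)


def t_test_two_tailed(a, b) -> tuple[float, float]:
    """Two-sample pooled-variance (equal-variance) t test, two-tailed."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each sample needs >=2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateDataError("both samples constant but different: t undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def ks_normality(sample, n_bootstrap: int = 0, seed: int | None = None) -> tuple[float, float]:
    """One-sample K-S test against a normal with the sample's mean and SD.

    With ``n_bootstrap > 0`` the p value is instead calibrated by parametric
    bootstrap (resampling normal samples of the same size and re-estimating
    moments each time), which corrects the composite-null bias of the
    asymptotic p.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 5:
        raise DegenerateDataError("K-S normality needs >=5 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant sample: K-S normality undefined")
    d, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_bootstrap):
            sim = rng.standard_normal(x.size)
            d_sim, _ = sps.kstest(sim, "norm", args=(sim.mean(), sim.std(ddof=1)))
            count += d_sim >= d
        p = (count + 1) / (n_bootstrap + 1)
    return float(d), float(p)


__all__ = [
    "GroupedMeasurements", "AnovaResult", "TukeyTable",
    "one_way_anova", "tukey_kramer", "t_test_two_tailed", "ks_normality",
]
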