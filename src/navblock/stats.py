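"""Summary statistics, group comparisons, and synthetic cohorts.

Reporting follows the conventions of the quantification pipeline being
reproduced: values are summarized as mean ± SEM when a Shapiro-Wilk test
does not reject normality at alpha = 0.05 and as median (IQR) otherwise;
two groups are compared with Student's t or Mann-Whitney, three or more
with one-way ANOVA or Kruskal-Wallis followed by Dunn's multiple
comparison test; significance stars use the *p<0.05 ** p<0.01 ***p<0.001
****p<0.0001 convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStat",
    "TestResult",
    "summarize",
    "compare_groups",
    "dunn_posthoc",
    "significance_stars",
    "synthetic_cohort",
]

ALPHA = 0.05


@dataclass
class SummaryStat:
    n: int
    mean: float
    sem: float
    median: float
    iqr: tuple[float, float]
    normality_p: float
    descriptor: str              # "mean±SEM" | "median"
    degenerate: bool = False

    def __str__(self) -> str:
        if self.descriptor == "mean±SEM":
            return f"{self.mean:.3g} ± {self.sem:.3g} (n={self.n})"
        return f"median {self.median:.3g} [{self.iqr[0]:.3g}, {self.iqr[1]:.3g}] (n={self.n})"


def summarize(values: Sequence[float]) -> SummaryStat:
    """Shapiro-Wilk-gated descriptive summary of one group."""
    x = np.asarray(values, float)
    if len(x) < 3:
        raise ValueError("need n >= 3 to summarize")
    degenerate = bool(np.ptp(x) == 0)
    if degenerate:
        p_norm = 0.0       # Shapiro is undefined on constant data
    else:
        p_norm = float(sps.shapiro(x).pvalue)
    descriptor = "mean±SEM" if (p_norm >= ALPHA and not degenerate) else "median"
    q1, q3 = np.percentile(x, [25, 75])
    return SummaryStat(
        n=len(x), mean=float(np.mean(x)), sem=float(sps.sem(x)) if len(x) > 1 else 0.0,
        median=float(np.median(x)), iqr=(float(q1), float(q3)),
        normality_p=p_norm, descriptor=descriptor, degenerate=degenerate,
    )


def significance_stars(p: float) -> str:
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return mark
    return "ns"


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    group_sizes: list[int]
    stars: str = "ns"
    posthoc: Optional[pd.DataFrame] = None


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Dunn's rank-based multiple comparison after Kruskal-Wallis.

    Pairwise z statistics on mean ranks of the pooled sample with tie
    correction; two-sided p values are Bonferroni-adjusted over the
    number of pairs.
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    idx = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(k)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))
    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt((N * (N + 1) / 12.0 - tie_term)
                       * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs)
        rows.append(dict(group_a=labels[i], group_b=labels[j], z=z,
                         p_adjusted=p, stars=significance_stars(p)))
    return pd.DataFrame(rows)


def compare_groups(groups: Sequence[Sequence[float]], paired: bool = False,
                   labels: Sequence[str] | None = None,
                   force: str | None = None) -> TestResult:
    """Normality-gated comparison of two or more groups.

    Two groups: Student's t (or paired t) when every group passes
    Shapiro-Wilk at alpha = 0.05, otherwise Mann-Whitney (or Wilcoxon).
    Three or more: one-way ANOVA or Kruskal-Wallis, the latter followed
    by Dunn's post hoc.  ``force`` overrides the normality gate with
    "parametric" or "nonparametric".
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if len(g) == 0:
            raise ValueError("empty group")
    if force is None:
        parametric = all(
            len(g) >= 3 and np.ptp(g) > 0 and sps.shapiro(g).pvalue >= ALPHA
            for g in gs
        )
    elif force in ("parametric", "nonparametric"):
        parametric = force == "parametric"
    else:
        raise ValueError("force must be 'parametric' or 'nonparametric'")
    posthoc = None
    if len(gs) == 2:
        a, b = gs
        if parametric:
            if paired:
                res = sps.ttest_rel(a, b)
                name = "paired t"
            else:
                res = sps.ttest_ind(a, b)
                name = "Student t"
        else:
            if paired:
                res = sps.wilcoxon(a, b)
                name = "Wilcoxon"
            else:
                method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
                res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
                name = "Mann-Whitney"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if paired:
            raise ValueError("paired comparison supports exactly 2 groups")
        if parametric:
            res = sps.f_oneway(*gs)
            name = "one-way ANOVA"
        else:
            res = sps.kruskal(*gs)
            name = "Kruskal-Wallis"
            posthoc = dunn_posthoc(gs, labels)
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(test=name, statistic=stat, p=p,
                      group_sizes=[len(g) for g in gs],
                      stars=significance_stars(p), posthoc=posthoc)


# ---------------------------------------------------------------------------
# synthetic cohorts


def synthetic_cohort(scenario, n_cells: int, between_cell_cv: float, seed: int,
                     metrics: Sequence[str] = ("plateau_block", "tau_s", "i1_i2")):
    """Per-cell metric table with lognormal between-cell variability.

    Each synthetic cell multiplies ``k_mod``, ``g_max`` and (when
    nonzero) ``p_resistant`` by independent lognormal factors of
    coefficient of variation ``between_cell_cv``; metrics are then
    evaluated from the closed-form block envelope of the perturbed
    scenario, which is what the diary fit recovers for these quantities.
    """
    from .channel import analytic_block_time_course, steady_state_gates

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if between_cell_cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + between_cell_cv ** 2))
    rows = []
    for cell in range(n_cells):
        fac = rng.lognormal(-0.5 * sigma ** 2, sigma, size=3) if sigma > 0 else np.ones(3)
        cp = scenario.coupling.model_copy(update=dict(
            k_mod=scenario.coupling.k_mod * float(fac[0]),
            p_resistant=min(1.0, scenario.coupling.p_resistant * float(fac[2])),
        ))
        gp = scenario.gating.model_copy(update=dict(
            g_max=scenario.gating.g_max * float(fac[1])))
        A, B, tau = analytic_block_time_course(cp, scenario.holding_mV, gp,
                                               scenario.modified,
                                               scenario.drug_conc_uM)
        row = dict(cell=cell, k_mod=cp.k_mod, g_max=gp.g_max,
                   p_resistant=cp.p_resistant)
        if "plateau_block" in metrics:
            row["plateau_block"] = A / (A + B)
        if "tau_s" in metrics:
            row["tau_s"] = tau
        if "i1_i2" in metrics:
            # silent-incubation block read from the envelope at the
            # configured incubation time; the 1-s hyperpolarization
            # restores the full current (I2), so I1/I2 is the residual
            inc_s = getattr(scenario, "incubation_s", 583.0)
            # silent drive: no cycling contribution to D
            gn = steady_state_gates(scenario.holding_mV, gp, "normal")
            from .channel import inactivation_drive
            D = inactivation_drive(gn.h_inf, gn.s_inf, cp)
            rate = cp.k_mod * cp.ramp_rate * cp.eta(scenario.drug_conc_uM) * D
            f_n = math.exp(-0.5 * rate * inc_s ** 2)
            row["i1_i2"] = B + (1.0 - B) * f_n
        rows.append(row)
    return pd.DataFrame(rows)
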