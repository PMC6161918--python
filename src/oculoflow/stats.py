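"""Inferential layer: paired t with Bonferroni and d_z, JZS default Bayes
factors, two-factor repeated-measures ANOVA with generalized eta squared,
and exact noncentral-t power / sample-size calculations.

The JZS (Jeffreys-Zellner-Siow) Bayes factor for the paired/one-sample t
test compares the point null against a Cauchy prior with scale r (default
0.707) on the standardized effect size delta:

    BF10 = [ integral T_df(t; delta * sqrt(n)) Cauchy(delta; 0, r) ddelta ]
           / T_df(t; 0)

where T_df(t; ncp) is the noncentral-t density of the observed statistic.
The integral is evaluated by adaptive quadrature after the substitution
delta = r tan(theta), which maps the real line to a finite interval and
absorbs the Cauchy weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate, stats

from .config import BayesConfig


class DegenerateDataError(ValueError):
    """Raised for inputs on which the statistic is undefined."""


@dataclass
class TTestResult:
    t: float
    df: int
    p_raw: float
    p_corrected: float
    d_z: float
    bf10: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    @property
    def n(self) -> int:
        return self.df + 1


def paired_t(diffs: Sequence[float], k_corrections: int = 1,
             bayes: Optional[BayesConfig] = None) -> TTestResult:
    """Paired t test on per-participant differences.

    Two-sided p, Bonferroni-corrected across ``k_corrections`` tests
    (capped at 1), Cohen's d_z = t / sqrt(n), and the JZS Bayes factor.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2 or not np.all(np.isfinite(diffs)):
        raise DegenerateDataError("need >= 2 finite differences")
    if np.std(diffs, ddof=1) == 0:
        raise DegenerateDataError("zero-variance differences")
    n = diffs.size
    res = stats.ttest_1samp(diffs, 0.0)
    t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(
        t=t, df=n - 1, p_raw=p,
        p_corrected=min(1.0, k_corrections * p),
        d_z=t / math.sqrt(n),
        bf10=jzs_bf_ttest(t, n, bayes))


def jzs_bf_ttest(t: float, n: int,
                 config: Optional[BayesConfig] = None) -> float:
    """JZS default Bayes factor BF10 for a paired/one-sample t statistic.

    Cauchy prior with scale ``config.prior_scale`` (default 0.707) on the
    standardized effect; invariant to the sign of t. Raises on integration
    failure.
    """
    config = config or BayesConfig()
    if n < 2:
        raise DegenerateDataError("n must be >= 2")
    if not math.isfinite(t):
        raise DegenerateDataError("t must be finite")
    r = config.prior_scale
    df = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(theta: float) -> float:
        delta = r * math.tan(theta)
        return stats.nct.pdf(t, df, delta * sqrt_n) / math.pi

    marginal_alt, err = integrate.quad(
        integrand, -math.pi / 2, math.pi / 2,
        epsabs=0.0, epsrel=config.rel_tol, limit=400)
    if not (math.isfinite(marginal_alt) and marginal_alt > 0):
        raise ArithmeticError(
            f"JZS integration failed: value={marginal_alt}, abserr={err}")
    if err / marginal_alt > 100 * config.rel_tol:
        raise ArithmeticError(
            f"JZS integration did not converge: rel err {err / marginal_alt:g}")
    null_density = stats.t.pdf(t, df)
    return float(marginal_alt / null_density)


@dataclass
class AnovaResult:
    """Within-subjects two-way ANOVA effects table."""

    table: pd.DataFrame  # columns: effect, F, df_num, df_den, p, eta_sq

    def effect(self, name: str) -> pd.Series:
        match = self.table[self.table["effect"] == name]
        if match.empty:
            raise KeyError(name)
        return match.iloc[0]


def rm_anova_2way(data: pd.DataFrame, dv: str = "value",
                  within: Sequence[str] = ("condition", "time"),
                  subject: str = "participant",
                  gg_correction: bool = False) -> AnovaResult:
    """Two-factor repeated-measures ANOVA with generalized eta squared.

    Participants with incomplete cells are removed listwise before
    fitting. Degrees of freedom follow the uncorrected
    within-subjects design: (a-1, (a-1)(n-1)) per main effect and
    ((a-1)(b-1), (a-1)(b-1)(n-1)) for the interaction; with
    ``gg_correction`` the Greenhouse-Geisser corrected p is reported
    instead.
    """
    a, b = within
    counts = data.groupby(subject)[dv].count()
    n_cells = data[a].nunique() * data[b].nunique()
    complete = counts[counts == n_cells].index
    clean = data[data[subject].isin(complete)
                 & np.isfinite(data[dv].to_numpy(float))]
    counts2 = clean.groupby(subject)[dv].count()
    clean = clean[clean[subject].isin(counts2[counts2 == n_cells].index)]
    if clean[subject].nunique() < 2:
        raise DegenerateDataError("need >= 2 complete participants")
    import warnings
    with warnings.catch_warnings():
        # sphericity epsilons are not used unless gg_correction is requested;
        # they are undefined (0/0) for zero-variance factors
        warnings.filterwarnings("ignore", message="Epsilon values might be")
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                module="pingouin")
        res = pg.rm_anova(data=clean, dv=dv, within=list(within),
                          subject=subject, detailed=True, effsize="ng2")
    rows = []
    for _, row in res.iterrows():
        name = row["Source"].replace(" * ", ":")
        p = row["p_GG_corr"] if gg_correction and "p_GG_corr" in row.index \
            and np.isfinite(row.get("p_GG_corr", np.nan)) else row["p_unc"]
        rows.append({"effect": name, "F": row["F"],
                     "df_num": int(row["ddof1"]), "df_den": int(row["ddof2"]),
                     "p": p, "eta_sq": row["ng2"]})
    return AnovaResult(pd.DataFrame(rows))


def power_paired_t(n: int, d_z: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided paired t test.

    Under effect d_z the t statistic is noncentral t with df = n - 1 and
    noncentrality d_z * sqrt(n); power is the probability it exceeds the
    two-sided critical value at ``alpha``. At d_z = 0 this returns alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    ncp = d_z * math.sqrt(n)
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(t_crit, df, ncp)
                 + stats.nct.cdf(-t_crit, df, ncp))


def sample_size_paired_t(target_power: float, d_z: float,
                         alpha: float = 0.05, n_max: int = 100000) -> int:
    """Smallest n with power_paired_t(n, d_z, alpha) >= target_power."""
    if not alpha < target_power < 1:
        raise ValueError("target_power must be in (alpha, 1)")
    if d_z == 0:
        raise ValueError("power beyond alpha is unreachable at d_z = 0")
    for n in range(2, n_max + 1):
        if power_paired_t(n, d_z, alpha) >= target_power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")


def compare_conditions(cells: pd.DataFrame, cond_a: str, cond_b: str,
                       k_corrections: int = 4,
                       bayes: Optional[BayesConfig] = None) -> pd.DataFrame:
    """Paired comparisons of two conditions per parameter and bin.

    ``cells`` is the per-participant condition-cell table from
    :func:`oculoflow.trials.assemble_conditions`. Returns one row per
    parameter x bin with t, df, raw and Bonferroni-corrected p (k tests
    per parameter), d_z, BF10 and BF01. Participants missing either
    condition cell are dropped pairwise per parameter x bin.
    """
    rows = []
    for (param, b), grp in cells.groupby(["parameter", "bin"]):
        wide = grp.pivot_table(index="participant", columns="condition",
                               values="corrected")
        if cond_a not in wide.columns or cond_b not in wide.columns:
            continue
        wide = wide[[cond_a, cond_b]].dropna()
        diffs = (wide[cond_b] - wide[cond_a]).to_numpy()
        try:
            res = paired_t(diffs, k_corrections, bayes)
        except DegenerateDataError:
            continue
        rows.append({"parameter": param, "bin": b, "n": len(diffs),
                     "mean_a": wide[cond_a].mean(), "sd_a": wide[cond_a].std(),
                     "mean_b": wide[cond_b].mean(), "sd_b": wide[cond_b].std(),
                     "t": res.t, "df": res.df, "p_raw": res.p_raw,
                     "p_corrected": res.p_corrected, "d_z": res.d_z,
                     "bf10": res.bf10, "bf01": res.bf01})
    return pd.DataFrame(rows)


def performance_ttests(summary: pd.DataFrame,
                       bayes: Optional[BayesConfig] = None) -> pd.DataFrame:
    """Paired t tests of the block-level performance measures.

    One row per measure (percent correct/incorrect/forgot, median RT, SD of
    RT) comparing the no-distractor and distractor blocks across
    participants.
    """
    measures = ["pct_correct", "pct_incorrect", "pct_forgot",
                "median_rt_s", "sd_rt_s"]
    rows = []
    for measure in measures:
        wide = summary.pivot_table(index="participant", columns="block",
                                   values=measure)
        if not {"no_distractor", "distractor"} <= set(wide.columns):
            continue
        wide = wide[["no_distractor", "distractor"]].dropna()
        diffs = (wide["distractor"] - wide["no_distractor"]).to_numpy()
        try:
            res = paired_t(diffs, 1, bayes)
        except DegenerateDataError:
            continue
        rows.append({"measure": measure, "n": len(diffs),
                     "mean_no_distractor": wide["no_distractor"].mean(),
                     "mean_distractor": wide["distractor"].mean(),
                     "t": res.t, "df": res.df, "p_raw": res.p_raw,
                     "d_z": res.d_z, "bf10": res.bf10, "bf01": res.bf01})
    return pd.DataFrame(rows)
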