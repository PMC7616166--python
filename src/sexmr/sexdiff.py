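"""Woman-vs-man differences in causal estimates via a two-group Cochran's Q test.

With per-sex log-odds estimates ``b_w`` (SE ``s_w``) and ``b_m`` (SE
``s_m``) and inverse-variance weights, the two-group Cochran's Q statistic
reduces algebraically to the squared z-statistic

    Q = (b_w - b_m)² / (s_w² + s_m²),

tested against the chi-square distribution with one degree of freedom.

Because published Mendelian randomization results are usually printed as
odds ratios with 95% confidence intervals, this module also provides the
back-conversion ``OR, (L, U) -> beta = ln(OR), se = (ln U - ln L)/(2 z)``
so the test can be applied directly to forest-plot numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import Z975, MREstimate

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class SexDifferenceResult:
    """Two-group Cochran's Q test of equality of sex-specific estimates."""

    beta_women: float
    se_women: float
    beta_men: float
    se_men: float
    q_stat: float
    df: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.q_stat < 0:
            raise ValueError("Q must be non-negative")
        if self.df != 1:
            raise ValueError("two-group comparison has df = 1")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError("pvalue outside (0, 1]")

    @property
    def flagged(self) -> bool:
        return self.pvalue <= SIGNIFICANCE_LEVEL


def ci_to_log(or_: float, lcl: float, ucl: float) -> tuple[float, float]:
    """Back-convert an odds ratio with 95% CI to ``(beta, se)`` on log scale.

    ``beta = ln(OR)``; ``se = (ln(ucl) - ln(lcl)) / (2 z)`` with ``z`` the
    97.5% normal quantile.  Requires ``0 < lcl <= or_ <= ucl``.
    """
    if not (0.0 < lcl <= or_ <= ucl):
        raise ValueError(
            f"CI ordering violated: need 0 < lcl <= OR <= ucl, got ({or_}, {lcl}, {ucl})"
        )
    return math.log(or_), (math.log(ucl) - math.log(lcl)) / (2.0 * Z975)


def sex_difference(
    est_w: tuple[float, float], est_m: tuple[float, float]
) -> SexDifferenceResult:
    """Two-group Cochran's Q test for a (women, men) pair of ``(beta, se)``."""
    b_w, s_w = est_w
    b_m, s_m = est_m
    if not (s_w > 0 and s_m > 0):
        raise ValueError("both standard errors must be > 0")
    b = np.array([b_w, b_m])
    w = np.array([1.0 / s_w**2, 1.0 / s_m**2])
    pooled = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - pooled) ** 2))
    p = float(max(sps.chi2.sf(q, 1), 1e-300))
    return SexDifferenceResult(
        beta_women=b_w, se_women=s_w, beta_men=b_m, se_men=s_m, q_stat=q, df=1, pvalue=p
    )


def sex_difference_from_cis(
    or_w: float, lcl_w: float, ucl_w: float, or_m: float, lcl_m: float, ucl_m: float
) -> SexDifferenceResult:
    """Convenience: back-convert both printed ORs, then test."""
    return sex_difference(ci_to_log(or_w, lcl_w, ucl_w), ci_to_log(or_m, lcl_m, ucl_m))


def sexdiff_table(estimates: pd.DataFrame, methods: list[str] | None = None) -> pd.DataFrame:
    """Pair woman/man estimates and test each pair.

    ``estimates`` needs columns ``exposure outcome method sex beta se`` with
    ``sex`` in {female, male}.  Returns one row per (exposure, outcome,
    method) with the Q statistic, p-value and a ``flagged`` column at
    p <= 0.05.  A pair missing one sex raises a ``ValueError`` naming it.
    """
    required = {"exposure", "outcome", "method", "sex", "beta", "se"}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates table missing columns: {sorted(missing)}")
    df = estimates
    if methods is not None:
        df = df[df["method"].isin(methods)]
    rows = []
    for (exp_, out_, meth), grp in df.groupby(["exposure", "outcome", "method"], sort=False):
        sexes = dict(zip(grp["sex"], grp.index))
        for needed in ("female", "male"):
            if needed not in sexes:
                raise ValueError(
                    f"{exp_} -> {out_} [{meth}]: missing {needed} estimate for sex pairing"
                )
        gw = grp.loc[sexes["female"]]
        gm = grp.loc[sexes["male"]]
        res = sex_difference((gw["beta"], gw["se"]), (gm["beta"], gm["se"]))
        rows.append(
            {
                "exposure": exp_,
                "outcome": out_,
                "method": meth,
                "beta_women": res.beta_women,
                "se_women": res.se_women,
                "beta_men": res.beta_men,
                "se_men": res.se_men,
                "q_stat": res.q_stat,
                "df": res.df,
                "pvalue": res.pvalue,
                "flagged": res.flagged,
            }
        )
    return pd.DataFrame(rows)


def sexdiff_from_cis_table(table: pd.DataFrame) -> pd.DataFrame:
    """Back-conversion path for published forest-plot numbers.

    Input columns: ``exposure outcome sex or ci_low ci_high`` with one
    female and one male row per (exposure, outcome).  Output adds ``beta se``
    per sex plus ``q pvalue flagged`` per pair.
    """
    required = {"exposure", "outcome", "sex", "or", "ci_low", "ci_high"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"input table missing columns: {sorted(missing)}")
    work = table.copy()
    logs = [ci_to_log(r["or"], r["ci_low"], r["ci_high"]) for _, r in work.iterrows()]
    work["beta"] = [b for b, _ in logs]
    work["se"] = [s for _, s in logs]
    rows = []
    for (exp_, out_), grp in work.groupby(["exposure", "outcome"], sort=False):
        sexes = dict(zip(grp["sex"], grp.index))
        for needed in ("female", "male"):
            if needed not in sexes:
                raise ValueError(f"{exp_} -> {out_}: missing {needed} row")
        gw, gm = grp.loc[sexes["female"]], grp.loc[sexes["male"]]
        res = sex_difference((gw["beta"], gw["se"]), (gm["beta"], gm["se"]))
        for _, row in grp.iterrows():
            rows.append(
                dict(row)
                | {"q": res.q_stat, "pvalue": res.pvalue, "flagged": res.flagged}
            )
    return pd.DataFrame(rows)


def from_estimates(
    pairs: list[tuple[str, str, MREstimate, MREstimate]]
) -> pd.DataFrame:
    """Build a sexdiff table from (exposure, outcome, women est, men est) tuples."""
    records = []
    for exp_, out_, est_w, est_m in pairs:
        if est_w.method != est_m.method:
            raise ValueError(f"{exp_} -> {out_}: methods differ between sexes")
        for sex, est in (("female", est_w), ("male", est_m)):
            records.append(
                {
                    "exposure": exp_,
                    "outcome": out_,
                    "method": est.method,
                    "sex": sex,
                    "beta": est.beta,
                    "se": est.se,
                }
            )
    return sexdiff_table(pd.DataFrame(records))
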