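"""Causal-effect estimators for summary-data Mendelian randomization.

Given harmonized per-SNP exposure effects ``beta_x`` (SE ``se_x``) and
outcome effects ``beta_y`` (SE ``se_y``), the estimators are

* **IVW** (primary): weighted regression of ``beta_y`` on ``beta_x``
  through the origin with weights ``1/se_y²``.  Under the default
  multiplicative random-effects model, the fixed-effect standard error is
  inflated by ``max(1, sqrt(Q/(J-1)))`` where Q is Cochran's heterogeneity
  statistic — over-dispersion widens the interval, under-dispersion never
  narrows it.
* **MR-Egger**: the same weighted regression with a free intercept after
  orienting every SNP to a non-negative exposure effect; a non-zero
  intercept is evidence of directional pleiotropy.
* **Simple / weighted median**: the median of the per-SNP Wald ratios
  ``beta_y/beta_x`` under equal or inverse-variance weights, consistent
  when at least half the weight comes from valid instruments.  Standard
  errors come from a seeded parametric bootstrap.

All causal estimates are reported on the log-odds scale per exposure unit
and exponentiated to odds ratios with 95% confidence intervals.  P-values
for slopes use the standard normal, the summary-data MR convention.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .io import HarmonizedInstruments

logger = logging.getLogger(__name__)

#: 97.5% standard-normal quantile, carried at full double precision
Z975 = float(sps.norm.ppf(0.975))

METHODS = ("ivw", "egger", "simple_median", "weighted_median")

_TINY_P = 1e-300


class EggerUnidentifiedError(ValueError):
    """All oriented exposure effects identical; the Egger slope is undefined."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds scale.

    ``or_`` is ``exp(beta)`` exactly; the CI is on the odds-ratio scale.
    ``q_stat``/``q_df``/``q_pvalue`` carry Cochran's Q for IVW; the
    ``egger_*`` fields carry the directional-pleiotropy intercept test for
    MR-Egger.  Unused fields are ``None``.
    """

    method: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.se >= 0:
            raise ValueError("se must be non-negative")
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError("pvalue outside (0, 1]")


def _two_sided_p(z: float) -> float:
    return float(min(1.0, max(2.0 * sps.norm.sf(abs(z)), _TINY_P)))


def _finish(method: str, beta: float, se: float, n_snps: int, **extra) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        or_=math.exp(beta),
        ci_low=math.exp(beta - Z975 * se),
        ci_high=math.exp(beta + Z975 * se),
        pvalue=_two_sided_p(beta / se) if se > 0 else (1.0 if beta == 0 else _TINY_P),
        n_snps=int(n_snps),
        **extra,
    )


class RatioEstimates(NamedTuple):
    """Per-SNP Wald ratios with first-order (delta-method) standard errors."""

    rsids: list[str]
    ratio: np.ndarray
    se: np.ndarray


def ratio_estimates(h: HarmonizedInstruments) -> RatioEstimates:
    """Per-SNP ratio ``beta_y/beta_x`` with SE ``se_y/|beta_x|``.

    SNPs with ``beta_x == 0`` have an undefined ratio and are excluded with
    a warning.
    """
    bx, by, sy = h.beta_x, h.beta_y, h.se_y
    mask = bx != 0.0
    if not mask.all():
        excluded = [r for r, ok in zip(h.rsids, mask) if not ok]
        warnings.warn(
            f"excluded {len(excluded)} SNP(s) with beta_x = 0 from ratio estimates: "
            f"{excluded[:5]}",
            stacklevel=2,
        )
    rsids = [r for r, ok in zip(h.rsids, mask) if ok]
    return RatioEstimates(rsids=rsids, ratio=by[mask] / bx[mask], se=sy[mask] / np.abs(bx[mask]))


def cochran_q(h: HarmonizedInstruments, beta: float) -> tuple[float, int, float]:
    """Cochran's Q of the outcome effects around ``beta * beta_x``.

    Returns ``(Q, df, p)`` with ``df = J - 1`` and the p-value from the
    chi-square upper tail.
    """
    if h.n_snps < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    w = 1.0 / h.se_y**2
    q = float(np.sum(w * (h.beta_y - beta * h.beta_x) ** 2))
    df = h.n_snps - 1
    return q, df, float(sps.chi2.sf(q, df))


def ivw(h: HarmonizedInstruments, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate (the primary analysis).

    ``model="fixed"`` uses the fixed-effect SE; the default
    ``"multiplicative_random"`` inflates it by ``max(1, sqrt(Q/(J-1)))``.
    A single-SNP set falls back to the fixed model with a warning.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = h.n_snps
    if j < 1:
        raise ValueError("IVW requires at least 1 SNP")
    x, y = h.beta_x, h.beta_y
    w = 1.0 / h.se_y**2
    sxx = float(np.sum(w * x * x))
    if sxx == 0.0:
        raise ValueError("all exposure effects are zero; IVW slope undefined")
    beta = float(np.sum(w * x * y)) / sxx
    se = sxx**-0.5
    q = float(np.sum(w * (y - beta * x) ** 2))
    q_df = j - 1
    q_p = float(sps.chi2.sf(q, q_df)) if j >= 2 else None
    if model == "multiplicative_random":
        if j == 1:
            warnings.warn(
                "single-SNP instrument: multiplicative random effects undefined, "
                "falling back to the fixed-effect model",
                stacklevel=2,
            )
        else:
            se *= max(1.0, math.sqrt(q / q_df))
    return _finish("ivw", beta, se, j, q_stat=q, q_df=q_df, q_pvalue=q_p)


def egger(h: HarmonizedInstruments) -> MREstimate:
    """MR-Egger regression with the directional-pleiotropy intercept test.

    SNPs are oriented to non-negative exposure effects, then ``beta_y`` is
    regressed on ``beta_x`` with weights ``1/se_y²`` and a free intercept.
    Standard errors carry the multiplicative residual inflation
    ``max(1, sqrt(Q/(J-2)))``.
    """
    j = h.n_snps
    if j < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    sign = np.where(h.beta_x < 0, -1.0, 1.0)
    x = h.beta_x * sign
    y = h.beta_y * sign
    if np.ptp(x) == 0.0:
        raise EggerUnidentifiedError(
            "Egger unidentified: no spread in oriented exposure effects"
        )
    w = 1.0 / h.se_y**2
    sw = float(np.sum(w))
    swx = float(np.sum(w * x))
    swx2 = float(np.sum(w * x * x))
    swy = float(np.sum(w * y))
    swxy = float(np.sum(w * x * y))
    denom = sw * swx2 - swx**2
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    inflate = max(1.0, math.sqrt(q / (j - 2)))
    slope_se = math.sqrt(sw / denom) * inflate
    int_se = math.sqrt(swx2 / denom) * inflate
    return _finish(
        "egger",
        slope,
        slope_se,
        j,
        egger_intercept=float(intercept),
        egger_intercept_se=float(int_se),
        egger_intercept_p=_two_sided_p(intercept / int_se),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-midpoint weighted median with linear interpolation."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    wn = weights[order] / weights.sum()
    s = np.cumsum(wn) - 0.5 * wn
    return float(np.interp(0.5, s, r))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (n_boot, J) bootstrap matrices."""
    order = np.argsort(ratios, axis=1, kind="stable")
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    wn = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(wn, axis=1) - 0.5 * wn
    # first column where the cumulative midpoint reaches 0.5
    hit = s >= 0.5
    idx = np.argmax(hit, axis=1)
    idx[~hit.any(axis=1)] = r.shape[1] - 1
    rows = np.arange(r.shape[0])
    out = r[rows, idx]
    interior = idx > 0
    i1 = idx[interior]
    i0 = i1 - 1
    s0 = s[rows[interior], i0]
    s1 = s[rows[interior], i1]
    r0 = r[rows[interior], i0]
    r1 = r[rows[interior], i1]
    frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
    out[interior] = r0 + frac * (r1 - r0)
    return out


def _median_estimate(
    h: HarmonizedInstruments, weighted: bool, n_boot: int, seed: int, method: str
) -> MREstimate:
    if h.n_snps < 3:
        raise ValueError(f"{method} requires at least 3 SNPs")
    if seed is None:
        raise ValueError("an explicit bootstrap seed is mandatory")
    if n_boot < 100:
        warnings.warn(
            f"n_boot = {n_boot} < 100 gives an unreliable bootstrap SE", stacklevel=3
        )
    rsids = set(ratio_estimates(h).rsids)
    keep = [i for i, r in enumerate(h.rsids) if r in rsids]
    hh = h.subset(keep)
    # canonical orientation (beta_x >= 0) leaves every ratio unchanged but
    # makes the bootstrap exactly invariant to per-SNP allele negation
    sign = np.where(hh.beta_x < 0, -1.0, 1.0)
    bx0, by0 = hh.beta_x * sign, hh.beta_y * sign
    ratios, ratio_se = by0 / bx0, hh.se_y / np.abs(bx0)
    weights = 1.0 / ratio_se**2 if weighted else np.ones_like(ratios)
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx = rng.normal(bx0, hh.se_x, size=(n_boot, hh.n_snps))
    by = rng.normal(by0, hh.se_y, size=(n_boot, hh.n_snps))
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = by / bx
        wb = (bx / hh.se_y) ** 2 if weighted else np.ones_like(rb)
    if not (np.isfinite(rb).all() and np.isfinite(wb).all()):
        raise ValueError("non-finite bootstrap draws (a resampled beta_x hit zero)")
    boots = _weighted_median_rows(rb, wb)
    se = float(np.std(boots, ddof=1))
    return _finish(method, beta, se, hh.n_snps)


def simple_median(h: HarmonizedInstruments, n_boot: int = 10_000, seed: int = None) -> MREstimate:
    """Simple median of the per-SNP ratios (equal weights), bootstrap SE."""
    return _median_estimate(h, weighted=False, n_boot=n_boot, seed=seed, method="simple_median")


def weighted_median(
    h: HarmonizedInstruments, n_boot: int = 10_000, seed: int = None
) -> MREstimate:
    """Inverse-variance weighted median of the per-SNP ratios, bootstrap SE."""
    return _median_estimate(h, weighted=True, n_boot=n_boot, seed=seed, method="weighted_median")


def all_estimates(
    h: HarmonizedInstruments, n_boot: int = 10_000, seed: int = 0
) -> list[MREstimate]:
    """IVW plus the three sensitivity estimators (where J permits them)."""
    out = [ivw(h)]
    if h.n_snps >= 3:
        out.append(egger(h))
        out.append(simple_median(h, n_boot=n_boot, seed=seed))
        out.append(weighted_median(h, n_boot=n_boot, seed=seed + 1))
    return out
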