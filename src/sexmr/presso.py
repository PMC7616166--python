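"""MR-PRESSO: simulation-based detection of pleiotropic outlier SNPs.

The global test compares the observed residual sum of squares around
leave-one-out IVW fits with its parametric null distribution: for every SNP
*j* the IVW slope is re-fitted without it, the squared residual
``(beta_y_j - theta_-j * beta_x_j)²`` is accumulated, and the same statistic
is recomputed on Monte-Carlo replicates drawn from the no-pleiotropy model
``beta_x* ~ N(beta_x, se_x)``, ``beta_y* ~ N(theta_-j * beta_x, se_y)``.
Per-SNP p-values flag individual outliers (Bonferroni-corrected), and the
distortion test asks whether removing the flagged SNPs changes the IVW
estimate more than removing equally many randomly chosen clean SNPs would.

All Monte-Carlo p-values use the ``(b + 1) / (n_sim + 1)`` correction and
are therefore never exactly zero.  Results are bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import ivw
from .io import HarmonizedInstruments

logger = logging.getLogger(__name__)


class PressoError(ValueError):
    """Raised when the MR-PRESSO test is undefined for the given input."""


@dataclass(frozen=True)
class DistortionResult:
    """Distortion of the IVW estimate caused by removing flagged outliers.

    ``coef`` is the percent change ``100 * (beta_raw - beta_corrected) /
    |beta_corrected|``; ``applicable`` is False when there were no outliers
    to remove (then ``coef`` and ``pvalue`` are NaN).
    """

    coef: float
    pvalue: float
    applicable: bool = True

    @classmethod
    def not_applicable(cls) -> "DistortionResult":
        return cls(coef=float("nan"), pvalue=float("nan"), applicable=False)


@dataclass
class PressoResult:
    """Outcome of the MR-PRESSO global, outlier and distortion tests."""

    rss_obs: float
    global_p: float
    outlier_table: pd.DataFrame  # rsid, raw_p, corrected_p, flagged
    outliers: list[tuple[str, float]]  # (rsid, corrected p) for flagged SNPs
    beta_raw: float
    beta_corrected: float | None
    distortion_coef: float | None
    distortion_p: float | None
    n_sim: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.global_p <= 1.0:
            raise PressoError("global_p outside (0, 1]")
        if self.distortion_p is not None and not 0.0 < self.distortion_p <= 1.0:
            raise PressoError("distortion_p outside (0, 1]")


def _require(h: HarmonizedInstruments, n_sim: int) -> None:
    if h.n_snps < 4:
        raise PressoError(
            f"MR-PRESSO is undefined for {h.n_snps} SNPs (at least 4 required)"
        )
    if n_sim < 1000:
        raise PressoError(f"n_sim must be at least 1000, got {n_sim}")


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, one per SNP."""
    sxy = float(np.sum(w * x * y))
    sxx = float(np.sum(w * x * x))
    return (sxy - w * x * y) / (sxx - w * x * x)


def _simulate(
    h: HarmonizedInstruments, n_sim: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Observed per-SNP squared residuals and their (n_sim, J) null draws."""
    x, y = h.beta_x, h.beta_y
    sx, sy = h.se_x, h.se_y
    w = 1.0 / sy**2
    theta_loo = _loo_slopes(x, y, w)
    res_obs = (y - theta_loo * x) ** 2

    rng = np.random.default_rng(seed)
    xs = rng.normal(x, sx, size=(n_sim, x.size))
    ys = rng.normal(theta_loo * x, sy, size=(n_sim, x.size))
    sxy = np.sum(w * xs * ys, axis=1, keepdims=True)
    sxx = np.sum(w * xs * xs, axis=1, keepdims=True)
    theta_star = (sxy - w * xs * ys) / (sxx - w * xs * xs)
    res_star = (ys - theta_star * xs) ** 2
    return res_obs, res_star


def presso_global(h: HarmonizedInstruments, n_sim: int = 5000, seed: int = 0) -> PressoResult:
    """Global pleiotropy test; outlier and distortion fields left empty."""
    _require(h, n_sim)
    res_obs, res_star = _simulate(h, n_sim, seed)
    rss_obs = float(res_obs.sum())
    b = int(np.sum(res_star.sum(axis=1) >= rss_obs))
    return PressoResult(
        rss_obs=rss_obs,
        global_p=(b + 1) / (n_sim + 1),
        outlier_table=pd.DataFrame(columns=["rsid", "raw_p", "corrected_p", "flagged"]),
        outliers=[],
        beta_raw=ivw(h, model="fixed").beta,
        beta_corrected=None,
        distortion_coef=None,
        distortion_p=None,
        n_sim=n_sim,
        seed=seed,
    )


def presso_outliers(
    h: HarmonizedInstruments, n_sim: int = 5000, seed: int = 0, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-SNP outlier test (identical draws to the global test for the seed).

    Raw Monte-Carlo p-values are Bonferroni-multiplied by J and capped at 1;
    SNPs with corrected p < ``alpha`` are flagged.
    """
    _require(h, n_sim)
    res_obs, res_star = _simulate(h, n_sim, seed)
    j = h.n_snps
    raw = (np.sum(res_star >= res_obs, axis=0) + 1) / (n_sim + 1)
    corrected = np.minimum(1.0, raw * j)
    return pd.DataFrame(
        {
            "rsid": h.rsids,
            "raw_p": raw,
            "corrected_p": corrected,
            "flagged": corrected < alpha,
        }
    )


def presso_distortion(
    h: HarmonizedInstruments,
    outlier_rsids: list[str],
    n_sim: int = 5000,
    seed: int = 0,
) -> DistortionResult:
    """Distortion test for the flagged outliers.

    The null distribution removes ``len(outlier_rsids)`` SNPs sampled with
    replacement from the non-outlier set and recomputes the percent change
    of the IVW estimate each time.
    """
    if not outlier_rsids:
        return DistortionResult.not_applicable()
    index = {r: i for i, r in enumerate(h.rsids)}
    out_idx = np.array(sorted(index[r] for r in outlier_rsids))
    keep_idx = np.array([i for i in range(h.n_snps) if i not in set(out_idx)])
    if keep_idx.size == 0:
        raise PressoError("no reference set: every SNP was flagged as an outlier")

    x, y = h.beta_x, h.beta_y
    w = 1.0 / h.se_y**2
    sxy_all = float(np.sum(w * x * y))
    sxx_all = float(np.sum(w * x * x))
    beta_raw = sxy_all / sxx_all
    beta_corr = float(
        np.sum((w * x * y)[keep_idx]) / np.sum((w * x * x)[keep_idx])
    )
    coef_obs = 100.0 * (beta_raw - beta_corr) / abs(beta_corr)

    rng = np.random.default_rng(seed)
    k = out_idx.size
    wxy = w * x * y
    wxx = w * x * x
    coefs = np.empty(n_sim)
    for s in range(n_sim):
        drop = np.unique(rng.choice(keep_idx, size=k, replace=True))
        beta_s = (sxy_all - wxy[drop].sum()) / (sxx_all - wxx[drop].sum())
        coefs[s] = 100.0 * (beta_raw - beta_s) / abs(beta_s)
    b_hi = int(np.sum(coefs >= coef_obs))
    b_lo = int(np.sum(coefs <= coef_obs))
    p = min(1.0, 2.0 * (min(b_hi, b_lo) + 1) / (n_sim + 1))
    return DistortionResult(coef=float(coef_obs), pvalue=float(p))


def presso(
    h: HarmonizedInstruments, n_sim: int = 5000, seed: int = 0, alpha: float = 0.05
) -> PressoResult:
    """Full MR-PRESSO pass: global test, outlier identification, distortion."""
    _require(h, n_sim)
    res_obs, res_star = _simulate(h, n_sim, seed)
    rss_obs = float(res_obs.sum())
    b = int(np.sum(res_star.sum(axis=1) >= rss_obs))
    global_p = (b + 1) / (n_sim + 1)

    j = h.n_snps
    raw = (np.sum(res_star >= res_obs, axis=0) + 1) / (n_sim + 1)
    corrected = np.minimum(1.0, raw * j)
    flagged = corrected < alpha
    table = pd.DataFrame(
        {"rsid": h.rsids, "raw_p": raw, "corrected_p": corrected, "flagged": flagged}
    )
    outliers = [(r, float(p)) for r, p, f in zip(h.rsids, corrected, flagged) if f]

    beta_raw = ivw(h, model="fixed").beta
    if flagged.any() and not flagged.all():
        keep = np.flatnonzero(~flagged)
        beta_corrected = ivw(h.subset(keep), model="fixed").beta
        dist = presso_distortion(h, [r for r, _ in outliers], n_sim=n_sim, seed=seed + 1)
        dist_coef, dist_p = dist.coef, dist.pvalue
    elif flagged.all():
        raise PressoError("no reference set: every SNP was flagged as an outlier")
    else:
        beta_corrected = None
        dist_coef = dist_p = None
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_table=table,
        outliers=outliers,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        distortion_coef=dist_coef,
        distortion_p=dist_p,
        n_sim=n_sim,
        seed=seed,
    )
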