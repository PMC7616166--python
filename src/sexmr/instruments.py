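"""Instrument selection: greedy LD clumping and instrument-strength summaries.

Instruments for Mendelian randomization must be approximately independent.
Starting from the genome-wide-significant candidates, clumping repeatedly
takes the remaining SNP with the smallest p-value as an index SNP and
discards every remaining candidate whose squared correlation with it exceeds
the r² threshold.  Pairwise correlations come from an external LD reference
panel supplied as a SNP x SNP correlation matrix.

Instrument strength is summarised by the mean per-SNP F-statistic
(beta/se)²; a mean F of 10 or less is the conventional weak-instrument
warning level (Staiger-Stock rule of thumb).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SummaryStats, filter_maf, filter_pvalue

logger = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


class LdPanelError(ValueError):
    """Raised for malformed LD reference panels."""


class NoInstrumentsError(RuntimeError):
    """Raised when no candidate instruments survive the significance filter."""

    def __init__(self, trait: str, sex: str, detail: str = "") -> None:
        self.trait = trait
        self.sex = sex
        msg = f"no instruments for exposure {trait!r} ({sex})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


@dataclass
class LdPanel:
    """SNP x SNP correlation matrix with its rsid labels.

    The matrix is validated to be symmetric within 1e-8 with unit diagonal,
    then symmetrized exactly.
    """

    rsids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.rsids = list(self.rsids)
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.rsids)
        if self.r.shape != (k, k):
            raise LdPanelError(f"matrix shape {self.r.shape} does not match {k} rsids")
        if len(set(self.rsids)) != k:
            raise LdPanelError("duplicate rsids in LD panel")
        if not np.allclose(self.r, self.r.T, atol=1e-8, rtol=0.0):
            raise LdPanelError("correlation matrix is not symmetric within 1e-8")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8, rtol=0.0):
            raise LdPanelError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise LdPanelError("correlations must lie in [-1, 1]")
        self.r = np.clip((self.r + self.r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.r, 1.0)
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def submatrix(self, rsids: list[str]) -> np.ndarray:
        idx = [self._index[r] for r in rsids]
        return self.r[np.ix_(idx, idx)]

    @classmethod
    def identity(cls, rsids: list[str]) -> "LdPanel":
        return cls(rsids=list(rsids), r=np.eye(len(rsids)))


def read_ld_panel(path: str | Path) -> LdPanel:
    """Read a square correlation matrix whose first row and column are rsids."""
    path = Path(path)
    with open(path) as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise LdPanelError(f"{path.name}: row and column rsids differ")
    return LdPanel(rsids=[str(r) for r in df.index], r=df.to_numpy(dtype=float))


def write_ld_panel(panel: LdPanel, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(panel.r, index=panel.rsids, columns=panel.rsids).to_csv(path, sep=sep)


def clump(
    stats: SummaryStats,
    panel: LdPanel,
    r2_threshold: float = 0.001,
    p_threshold: float = 5e-8,
    *,
    absent: str = "drop",
) -> SummaryStats:
    """Greedy LD clumping on p-value order.

    Candidates are the records with ``pvalue <= p_threshold``.  SNPs absent
    from the panel are dropped with a warning (``absent="drop"``) or treated
    as uncorrelated (``absent="independent"``).  Ties in p-value are broken
    by ascending rsid, making the output invariant to input row order.
    Every retained pair satisfies r² <= ``r2_threshold``.
    """
    if not 0.0 < r2_threshold < 1.0:
        raise ValueError(f"r2_threshold must be in (0, 1), got {r2_threshold}")
    if absent not in ("drop", "independent"):
        raise ValueError("absent must be 'drop' or 'independent'")
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    cands = stats.df if p_threshold >= 1.0 else filter_pvalue(stats, p_threshold).df
    if cands.empty:
        raise NoInstrumentsError(stats.trait, stats.sex, f"no SNP at p <= {p_threshold:g}")

    known = cands["rsid"].map(lambda r: r in panel)
    if not known.all():
        missing = cands["rsid"][~known].tolist()
        if absent == "drop":
            warnings.warn(
                f"{stats.trait} ({stats.sex}): {len(missing)} candidate SNP(s) absent "
                f"from the LD panel were dropped before clumping: {missing[:5]}...",
                stacklevel=2,
            )
            cands = cands[known]
            if cands.empty:
                raise NoInstrumentsError(
                    stats.trait, stats.sex, "all significant SNPs absent from LD panel"
                )
        else:
            logger.info(
                "%s (%s): %d SNP(s) absent from panel treated as uncorrelated",
                stats.trait,
                stats.sex,
                len(missing),
            )

    ordered = cands.sort_values(["pvalue", "rsid"], kind="mergesort")
    rsids = ordered["rsid"].tolist()
    in_panel = np.array([r in panel for r in rsids])
    r2 = np.zeros((len(rsids), len(rsids)))
    if in_panel.any():
        sub = panel.submatrix([r for r, ok in zip(rsids, in_panel) if ok]) ** 2
        r2[np.ix_(in_panel, in_panel)] = sub

    alive = np.ones(len(rsids), dtype=bool)
    kept: list[int] = []
    for i in range(len(rsids)):
        if not alive[i]:
            continue
        kept.append(i)
        alive &= r2[i] <= r2_threshold
        alive[i] = False
    kept_rsids = [rsids[i] for i in kept]
    out = ordered[ordered["rsid"].isin(kept_rsids)]
    return stats.with_df(out)


def f_statistics(stats: SummaryStats) -> np.ndarray:
    """Per-SNP F-statistics, (beta/se)²."""
    if stats.n_snps == 0:
        raise ValueError("cannot compute F-statistics on an empty instrument set")
    beta = stats.df["beta"].to_numpy(dtype=float)
    se = stats.df["se"].to_numpy(dtype=float)
    return (beta / se) ** 2


def mean_f_statistic(stats: SummaryStats) -> float:
    """Mean over SNPs of the per-SNP F-statistic (beta/se)²."""
    return float(np.mean(f_statistics(stats)))


@dataclass
class InstrumentSet:
    """A clumped instrument set with its strength summary."""

    stats: SummaryStats
    mean_f: float
    n_snps: int

    def __post_init__(self) -> None:
        if self.n_snps != self.stats.n_snps:
            raise ValueError("n_snps does not match the instrument table")
        if not self.mean_f > 0:
            raise ValueError("mean F must be positive")

    @property
    def is_weak(self) -> bool:
        return self.mean_f <= WEAK_F_THRESHOLD


def select_instruments(
    stats: SummaryStats,
    panel: LdPanel,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    min_maf: float = 0.05,
    *,
    absent: str = "drop",
) -> InstrumentSet:
    """Full instrument-selection pass: MAF filter, significance filter, clump.

    Emits a warning when the resulting mean F-statistic is at or below the
    weak-instrument level of 10.
    """
    filtered = filter_maf(stats, min_maf)
    if filtered.n_snps == 0:
        raise NoInstrumentsError(stats.trait, stats.sex, f"no SNP with MAF >= {min_maf:g}")
    clumped = clump(filtered, panel, r2_threshold, p_threshold, absent=absent)
    mean_f = mean_f_statistic(clumped)
    if mean_f <= WEAK_F_THRESHOLD:
        warnings.warn(
            f"{stats.trait} ({stats.sex}): weak instruments, mean F = {mean_f:.1f} <= 10",
            stacklevel=2,
        )
    return InstrumentSet(stats=clumped, mean_f=mean_f, n_snps=clumped.n_snps)
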