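"""Synthetic sex-specific two-sample GWAS summary statistics with known truth.

The generator works at the level the analysis consumes: per-SNP summary
effects with sampling noise, not individual genotypes.  For each variant

* a true per-allele exposure effect ``b_j ~ N(0, beta_x_sd²)`` is drawn
  (shared between the sexes: the same variants instrument both strata);
* the observed exposure effect is ``beta_x_j ~ N(b_j, se_x_j²)`` with the
  standard GWAS precision ``se_x_j = (2 p_j (1-p_j) n_exposure)^{-1/2}``
  for allele frequency ``p_j``;
* the observed outcome effect is
  ``beta_y_j ~ N(theta_sex * b_j + s_j * alpha_j, se_y_j²)`` where
  ``alpha_j`` is a pleiotropic effect (zero, balanced, or directional) and
  ``s_j = sign(b_j)`` attaches it to the exposure-increasing allele — the
  orientation convention under which directional pleiotropy is defined for
  MR-Egger;
* decoy null SNPs (``b = 0``) are appended, and allele labels are then
  corrupted at configurable rates (effect/other swaps, strand flips,
  palindromic variants) to exercise harmonization.

Binary-outcome effects are generated directly on the log-odds scale with
independent normal noise; two-sample MR only ever sees these summary
quantities.  Exposure and outcome noise are independent (no sample
overlap), matching a design that excludes overlapping cohorts from the
outcome GWAS.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CANONICAL_COLUMNS, HarmonizedInstruments, SummaryStats
from .instruments import LdPanel

_SEX_CODE = {"female": 1, "male": 2, "combined": 3}

# ordered allele pairs: complement pairs are palindromic, the rest are not
_NONPALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth generative parameters for one simulated exposure-outcome pair.

    Defaults emulate a large-consortium exposure GWAS instrumenting a rarer
    binary outcome: 150 causal variants, 300k exposure / 50k outcome
    samples, effect spread chosen so the mean instrument F-statistic lands
    around 100, inside the 37-245 range typical of published sex-specific
    instruments for cardiometabolic traits.
    """

    n_snps: int = 150
    theta_women: float = 0.0
    theta_men: float = 0.0
    n_exposure: int = 300_000
    n_outcome: int = 50_000
    eaf_range: tuple[float, float] = (0.10, 0.90)
    beta_x_sd: float = 0.03
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    n_null_snps: int = 0
    strand_flip_rate: float = 0.0
    allele_swap_rate: float = 0.0
    palindrome_rate: float = 0.0
    seed: int = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eaf_range must be an interval inside (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        for name in ("strand_flip_rate", "allele_swap_rate", "palindrome_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("sample sizes must be at least 2")
        if self.ld_blocks is not None:
            object.__setattr__(
                self, "ld_blocks", tuple((int(m), float(r)) for m, r in self.ld_blocks)
            )
            total = sum(m for m, _ in self.ld_blocks)
            if total > self.n_snps + self.n_null_snps:
                raise ValueError(
                    f"ld_blocks cover {total} SNPs but only "
                    f"{self.n_snps + self.n_null_snps} are generated"
                )

    @property
    def total_snps(self) -> int:
        return self.n_snps + self.n_null_snps

    def theta(self, sex: str) -> float:
        if sex == "female":
            return self.theta_women
        if sex == "male":
            return self.theta_men
        return 0.5 * (self.theta_women + self.theta_men)


@dataclass(frozen=True)
class TruthRecord:
    """Every generative quantity for one simulated pair, for recovery tests."""

    sex: str
    theta: float
    table: pd.DataFrame


def _rsid(i: int) -> str:
    return f"rs{i + 1:07d}"


def _shared_rng(config: SynthConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 101])


def _block_ids(config: SynthConfig) -> np.ndarray:
    """Block label per SNP; -1 for SNPs outside any LD block."""
    ids = np.full(config.total_snps, -1, dtype=int)
    if config.ld_blocks:
        pos = 0
        for b, (m, _) in enumerate(config.ld_blocks):
            ids[pos : pos + m] = b
            pos += m
    return ids


def generate_pair(config: SynthConfig, sex: str) -> tuple[SummaryStats, SummaryStats, TruthRecord]:
    """Generate one (exposure, outcome) summary-statistics pair for one sex.

    Deterministic in ``(config, sex)``.  Frequencies, true effects and
    allele labels are shared between the sexes; observation noise is not.
    """
    if sex not in _SEX_CODE:
        raise ValueError(f"sex must be one of {tuple(_SEX_CODE)}, got {sex!r}")
    jt = config.total_snps
    jc = config.n_snps
    shared = _shared_rng(config)

    eaf = shared.uniform(*config.eaf_range, size=jt)
    b = np.zeros(jt)
    b[:jc] = shared.normal(0.0, config.beta_x_sd, size=jc)
    # LD-tagged effects: non-index block members carry r * the index effect
    blocks = _block_ids(config)
    if config.ld_blocks:
        pos = 0
        for m, r in config.ld_blocks:
            b[pos + 1 : pos + m] = r * b[pos]
            pos += m

    palin = shared.uniform(size=jt) < config.palindrome_rate
    pair_choice = shared.integers(0, 8, size=jt)
    pal_choice = shared.integers(0, 4, size=jt)
    ea = np.where(
        palin,
        [_PALINDROMIC[c][0] for c in pal_choice],
        [_NONPALINDROMIC[c][0] for c in pair_choice],
    )
    oa = np.where(
        palin,
        [_PALINDROMIC[c][1] for c in pal_choice],
        [_NONPALINDROMIC[c][1] for c in pair_choice],
    )

    code = _SEX_CODE[sex]
    rng_x = np.random.default_rng([config.seed, code, 1])
    rng_y = np.random.default_rng([config.seed, code, 2])
    rng_c = np.random.default_rng([config.seed, code, 3])

    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure)
    beta_x = rng_x.normal(b, se_x)

    theta = config.theta(sex)
    alpha = np.zeros(jt)
    if config.pleiotropy_mode == "balanced":
        alpha = rng_y.normal(0.0, config.pleiotropy_sd, size=jt)
    elif config.pleiotropy_mode == "directional":
        alpha = rng_y.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=jt)
    s = np.where(b >= 0, 1.0, -1.0)  # exposure-increasing-allele orientation
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_outcome)
    beta_y_clean = rng_y.normal(theta * b + s * alpha, se_y)

    def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
        from scipy import stats as sps

        return np.maximum(2.0 * sps.norm.sf(np.abs(beta / se)), 1e-300)

    rsids = [_rsid(i) for i in range(jt)]
    exposure_df = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": "1",
            "pos": np.arange(1, jt + 1) * 10_000,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta_x,
            "se": se_x,
            "pvalue": _pvals(beta_x, se_x),
            "n": config.n_exposure,
        }
    )[CANONICAL_COLUMNS]

    swap = rng_c.uniform(size=jt) < config.allele_swap_rate
    flipstrand = rng_c.uniform(size=jt) < config.strand_flip_rate
    ea_y, oa_y = ea.copy(), oa.copy()
    beta_y = beta_y_clean.copy()
    eaf_y = eaf.copy()
    # effect/other swap: report the association for the opposite allele
    ea_y[swap], oa_y[swap] = oa[swap], ea[swap]
    beta_y[swap] = -beta_y[swap]
    eaf_y[swap] = 1.0 - eaf_y[swap]
    # strand flip: same physical allele named from the other strand
    ea_y[flipstrand] = [_COMP[a] for a in ea_y[flipstrand]]
    oa_y[flipstrand] = [_COMP[a] for a in oa_y[flipstrand]]

    outcome_df = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": "1",
            "pos": np.arange(1, jt + 1) * 10_000,
            "effect_allele": ea_y,
            "other_allele": oa_y,
            "eaf": eaf_y,
            "beta": beta_y,
            "se": se_y,
            "pvalue": _pvals(beta_y, se_y),
            "n": config.n_outcome,
        }
    )[CANONICAL_COLUMNS]

    truth = TruthRecord(
        sex=sex,
        theta=theta,
        table=pd.DataFrame(
            {
                "rsid": rsids,
                "eaf": eaf,
                "b_true": b,
                "alpha": s * alpha,
                "se_x": se_x,
                "se_y": se_y,
                "beta_y_clean": beta_y_clean,
                "is_null": np.arange(jt) >= jc,
                "block": blocks,
                "is_palindromic": palin,
                "swapped": swap,
                "strand_flipped": flipstrand,
            }
        ),
    )
    exposure = SummaryStats(
        trait="sim_exposure", unit="SD", sex=sex, df=exposure_df, ancestry="EUR"
    )
    outcome = SummaryStats(
        trait="sim_outcome", unit="log-odds", sex=sex, df=outcome_df, ancestry="EUR"
    )
    return exposure, outcome, truth


def generate_ld_panel(config: SynthConfig) -> LdPanel:
    """Block-diagonal LD panel matching :func:`generate_pair`'s rsids.

    Each configured block is compound-symmetric with its within-block
    correlation; SNPs outside the blocks are uncorrelated.  Correlations
    must keep every block positive definite
    (``-1/(m-1) < r < 1`` for block size m).
    """
    jt = config.total_snps
    r = np.eye(jt)
    if config.ld_blocks:
        pos = 0
        for m, rho in config.ld_blocks:
            if m > 1 and not (-1.0 / (m - 1) < rho < 1.0):
                raise ValueError(
                    f"block correlation {rho} with size {m} is not positive definite"
                )
            r[pos : pos + m, pos : pos + m] = rho
            pos += m
        np.fill_diagonal(r, 1.0)
    return LdPanel(rsids=[_rsid(i) for i in range(jt)], r=r)


def plant_outlier(
    h: HarmonizedInstruments, index: int, n_se: float = 10.0
) -> HarmonizedInstruments:
    """Add a pleiotropic offset of ``n_se`` outcome SEs to one SNP."""
    table = h.table.copy()
    table.loc[table.index[index], "beta_y"] += n_se * table.iloc[index]["se_y"]
    return HarmonizedInstruments(table=table)


def write_truth(truth: TruthRecord, path, sep: str = "\t") -> None:
    out = truth.table.copy()
    out.insert(0, "theta", truth.theta)
    out.insert(0, "sex", truth.sex)
    out.to_csv(path, sep=sep, index=False)
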