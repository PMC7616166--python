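"""GWAS summary-statistics I/O, validation, filtering and allele harmonization.

Two-sample Mendelian randomization operates entirely on per-variant
association tables: for every SNP an effect allele, the other allele, the
effect-allele frequency, an effect estimate (beta) with its standard error,
a p-value and the contributing sample size.  This module reads such tables
from delimited text, validates them row by row, applies the instrument
pre-filters (genome-wide significance, minor-allele frequency), and
reconciles allele coding between an exposure study and an outcome study so
that both betas refer to the same allele on the same strand.

Harmonization rules
-------------------
For each variant shared between the two studies:

* identical allele pair  -> keep as is;
* swapped alleles        -> negate the outcome beta, flip its frequency;
* strand complement      -> relabel, then apply the two rules above;
* palindromic (A/T, G/C) -> orientation cannot be read off the alleles, so
  it is inferred from allele frequency; variants whose minor-allele
  frequency is too close to 0.5 in either study are dropped as ambiguous;
* anything else          -> dropped as an allele mismatch.

Exposure betas are never altered; the exposure study defines the reference
orientation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of a summary-statistics table
CANONICAL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_FLOAT_COLUMNS = ("eaf", "beta", "se", "pvalue")
_INT_COLUMNS = ("pos", "n")

SEXES = ("female", "male", "combined")

#: reasons recorded for variants removed during harmonization
REASON_AMBIGUOUS = "ambiguous palindrome"
REASON_MISMATCH = "allele mismatch"


class SumstatsError(ValueError):
    """Raised for malformed or internally inconsistent summary statistics."""


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect in the trait's stated unit
    (log-odds per allele for binary traits).
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SumstatsError(
                f"{self.rsid}: alleles must be single bases in A/C/G/T, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.rsid}: effect and other allele are identical")
        if not 0.0 <= self.eaf <= 1.0:
            raise SumstatsError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if not self.se > 0:
            raise SumstatsError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not 0.0 < self.pvalue <= 1.0:
            raise SumstatsError(f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]")
        if self.pos <= 0:
            raise SumstatsError(f"{self.rsid}: position must be positive")
        if self.n <= 0:
            raise SumstatsError(f"{self.rsid}: sample size must be positive")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummaryStats:
    """A validated set of SNP associations for one trait in one sex stratum.

    The records live in ``df`` (canonical columns, one row per SNP, unique
    rsid, order preserved); ``records`` materialises them as
    :class:`SnpAssociation` objects.  ``sex`` and ``unit`` are mandatory
    metadata echoed into every downstream result.
    """

    trait: str
    unit: str
    sex: str
    df: pd.DataFrame
    ancestry: str = "EUR"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SumstatsError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.unit:
            raise SumstatsError("unit metadata is mandatory")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing canonical columns: {missing}")
        self.df = self.df.loc[:, CANONICAL_COLUMNS].reset_index(drop=True)
        dup = self.df["rsid"][self.df["rsid"].duplicated()]
        if not dup.empty:
            raise SumstatsError(f"duplicate rsid(s): {sorted(set(dup))}")

    @classmethod
    def from_records(
        cls,
        trait: str,
        unit: str,
        sex: str,
        records: Iterable[SnpAssociation],
        ancestry: str = "EUR",
    ) -> "SummaryStats":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return cls(trait=trait, unit=unit, sex=sex, df=df, ancestry=ancestry)

    @property
    def records(self) -> list[SnpAssociation]:
        return [SnpAssociation(**row) for row in self.df.to_dict("records")]

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame) -> "SummaryStats":
        return dataclasses.replace(self, df=df.reset_index(drop=True))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.df)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait: str | None = None,
    unit: str = "unknown",
    sex: str = "combined",
    ancestry: str = "EUR",
) -> SummaryStats:
    """Read and validate a delimited summary-statistics table.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    column_map
        Optional mapping from the file's headers to canonical field names
        (e.g. ``{"hm_rsid": "rsid", "hm_beta": "beta"}``).
    trait, unit, sex, ancestry
        Trait metadata; ``trait`` defaults to the file stem.

    Raises
    ------
    SumstatsError
        On a missing mandatory column, an unparsable numeric cell (reported
        with its line number, header = line 1), a validation failure
        (reported per row), or duplicate rsids.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsError(f"{path.name}: missing mandatory column(s): {missing}")
    raw = raw.loc[:, CANONICAL_COLUMNS]

    df = pd.DataFrame({"rsid": raw["rsid"].str.strip(), "chrom": raw["chrom"].str.strip()})
    errors: list[str] = []

    def _line(i: int) -> str:
        # data row i sits on file line i+2 (header is line 1)
        return f"row {i + 1} (line {i + 2})"

    for col in _FLOAT_COLUMNS + _INT_COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna()
        for i in raw.index[bad]:
            errors.append(f"{_line(i)}: unparsable {col} value {raw.at[i, col]!r}")
        if col in _INT_COLUMNS:
            nonint = ~bad & (vals != np.floor(vals))
            for i in raw.index[nonint]:
                errors.append(f"{_line(i)}: {col} must be an integer, got {raw.at[i, col]!r}")
            vals = vals.fillna(0)
        df[col] = vals
    if errors:
        raise SumstatsError(f"{path.name}: " + "; ".join(errors))
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(np.int64)

    for col in ("effect_allele", "other_allele"):
        alleles = raw[col].str.strip().str.upper()
        bad = ~alleles.isin(list(VALID_ALLELES))
        for i in raw.index[bad]:
            errors.append(
                f"{_line(i)}: {col} {raw.at[i, col]!r} is not a single base in A/C/G/T "
                "(indels and multi-allelic variants are rejected)"
            )
        df[col] = alleles

    checks = [
        (df["effect_allele"] == df["other_allele"], "effect and other allele identical"),
        (~df["eaf"].between(0.0, 1.0), "eaf outside [0, 1]"),
        (df["se"] <= 0, "se must be > 0"),
        (~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue outside (0, 1]"),
        (df["pos"] <= 0, "pos must be positive"),
        (df["n"] <= 0, "n must be positive"),
    ]
    for mask, msg in checks:
        for i in df.index[mask]:
            errors.append(f"{_line(i)} ({df.at[i, 'rsid']}): {msg}")
    if errors:
        raise SumstatsError(f"{path.name}: " + "; ".join(errors))

    dup = df["rsid"][df["rsid"].duplicated()]
    if not dup.empty:
        raise SumstatsError(f"{path.name}: duplicate rsid(s): {sorted(set(dup))}")

    return SummaryStats(
        trait=trait if trait is not None else path.stem,
        unit=unit,
        sex=sex,
        df=df.loc[:, CANONICAL_COLUMNS],
        ancestry=ancestry,
    )


def write_sumstats(stats: SummaryStats, path: str | Path, sep: str = "\t") -> None:
    """Write a summary-statistics table; floats round-trip bit-exactly."""
    stats.df.to_csv(path, sep=sep, index=False)


def filter_pvalue(stats: SummaryStats, threshold: float) -> SummaryStats:
    """Keep records with ``pvalue <= threshold`` (inclusive), order preserved."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return stats.with_df(stats.df[stats.df["pvalue"] <= threshold])


def filter_maf(stats: SummaryStats, min_maf: float) -> SummaryStats:
    """Keep records whose minor-allele frequency ``min(eaf, 1-eaf) >= min_maf``."""
    if not 0.0 < min_maf < 0.5:
        raise ValueError(f"min_maf must be in (0, 0.5), got {min_maf}")
    maf = np.minimum(stats.df["eaf"], 1.0 - stats.df["eaf"])
    return stats.with_df(stats.df[maf >= min_maf])


@dataclass
class HarmonizedInstruments:
    """Per-SNP aligned exposure and outcome effects after allele reconciliation.

    ``table`` carries one row per retained SNP with the exposure's allele
    orientation (columns ``rsid chrom pos effect_allele other_allele eaf_x
    beta_x se_x eaf_y beta_y se_y``); ``dropped`` records the shared SNPs
    removed during reconciliation as ``(rsid, reason)`` rows.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"])
    )

    def __post_init__(self) -> None:
        required = {"rsid", "beta_x", "se_x", "beta_y", "se_y"}
        missing = required - set(self.table.columns)
        if missing:
            raise SumstatsError(f"harmonized table missing columns: {sorted(missing)}")
        if (self.table["se_x"] <= 0).any() or (self.table["se_y"] <= 0).any():
            raise SumstatsError("all standard errors must be > 0")
        dup = self.table["rsid"][self.table["rsid"].duplicated()]
        if not dup.empty:
            raise SumstatsError(f"duplicate rsid(s) in harmonized table: {sorted(set(dup))}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        rsids: Sequence[str],
        beta_x: Sequence[float],
        se_x: Sequence[float],
        beta_y: Sequence[float],
        se_y: Sequence[float],
    ) -> "HarmonizedInstruments":
        return cls(
            table=pd.DataFrame(
                {
                    "rsid": list(rsids),
                    "beta_x": np.asarray(beta_x, dtype=float),
                    "se_x": np.asarray(se_x, dtype=float),
                    "beta_y": np.asarray(beta_y, dtype=float),
                    "se_y": np.asarray(se_y, dtype=float),
                }
            )
        )

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    @property
    def beta_x(self) -> np.ndarray:
        return self.table["beta_x"].to_numpy(dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return self.table["se_x"].to_numpy(dtype=float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.table["beta_y"].to_numpy(dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_y"].to_numpy(dtype=float)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def subset(self, index: Sequence[int] | np.ndarray) -> "HarmonizedInstruments":
        """Positional subset, e.g. after outlier removal."""
        return HarmonizedInstruments(table=self.table.iloc[list(index)].copy())


def write_dropped_report(h: HarmonizedInstruments, path: str | Path, sep: str = "\t") -> None:
    h.dropped.to_csv(path, sep=sep, index=False)


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedInstruments:
    """Align outcome effects to the exposure's allele orientation.

    Palindromic variants (A/T or G/C) are oriented by allele frequency and
    dropped as ``"ambiguous palindrome"`` when the minor-allele frequency in
    either study exceeds ``0.5 - palindrome_eaf_window``.  Exposure betas are
    never altered.  Every shared rsid ends up either in the harmonized table
    or in the ``dropped`` report.
    """
    if not 0.0 <= palindrome_eaf_window < 0.5:
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")
    m = exposure.df.merge(outcome.df, on="rsid", how="inner", suffixes=("_x", "_y"))
    if m.empty:
        raise SumstatsError(
            f"no shared variants between {exposure.trait} ({exposure.sex}) "
            f"and {outcome.trait} ({outcome.sex})"
        )

    def _comp(col: pd.Series) -> pd.Series:
        return col.map(COMPLEMENT)

    ea_x, oa_x = m["effect_allele_x"], m["other_allele_x"]
    ea_y, oa_y = m["effect_allele_y"], m["other_allele_y"]

    is_palin = (_comp(ea_x) == oa_x).to_numpy()
    same = ((ea_y == ea_x) & (oa_y == oa_x)).to_numpy()
    swap = ((ea_y == oa_x) & (oa_y == ea_x)).to_numpy()
    comp_same = ((_comp(ea_y) == ea_x) & (_comp(oa_y) == oa_x)).to_numpy()
    comp_swap = ((_comp(ea_y) == oa_x) & (_comp(oa_y) == ea_x)).to_numpy()
    reconcilable = same | swap | comp_same | comp_swap

    eaf_x = m["eaf_x"].to_numpy(dtype=float)
    eaf_y = m["eaf_y"].to_numpy(dtype=float)
    maf_x = np.minimum(eaf_x, 1.0 - eaf_x)
    maf_y = np.minimum(eaf_y, 1.0 - eaf_y)

    reason = np.full(len(m), "", dtype=object)
    reason[~reconcilable] = REASON_MISMATCH
    ambiguous = (
        is_palin
        & reconcilable
        & ((maf_x > 0.5 - palindrome_eaf_window) | (maf_y > 0.5 - palindrome_eaf_window))
    )
    reason[ambiguous] = REASON_AMBIGUOUS

    # For palindromes the allele labels cannot distinguish a swap from a
    # strand flip; frequency decides.  For everything else the labels decide.
    palin_flip = is_palin & reconcilable & ~ambiguous & ((eaf_x - 0.5) * (eaf_y - 0.5) < 0)
    plain_flip = ~is_palin & (swap | comp_swap)
    flip = palin_flip | plain_flip

    keep = reconcilable & (reason == "")
    beta_y = m["beta_y"].to_numpy(dtype=float).copy()
    beta_y[flip] = -beta_y[flip]
    eaf_y_out = eaf_y.copy()
    eaf_y_out[flip] = 1.0 - eaf_y_out[flip]

    table = pd.DataFrame(
        {
            "rsid": m["rsid"],
            "chrom": m["chrom_x"],
            "pos": m["pos_x"],
            "effect_allele": ea_x,
            "other_allele": oa_x,
            "eaf_x": eaf_x,
            "beta_x": m["beta_x"].to_numpy(dtype=float),
            "se_x": m["se_x"].to_numpy(dtype=float),
            "n_x": m["n_x"],
            "eaf_y": eaf_y_out,
            "beta_y": beta_y,
            "se_y": m["se_y"].to_numpy(dtype=float),
            "n_y": m["n_y"],
        }
    )[keep]
    dropped = pd.DataFrame({"rsid": m["rsid"][~keep], "reason": reason[~keep]})
    if len(dropped):
        logger.info(
            "harmonize(%s~%s, %s): dropped %d of %d shared SNPs (%s)",
            exposure.trait,
            outcome.trait,
            outcome.sex,
            len(dropped),
            len(m),
            dropped["reason"].value_counts().to_dict(),
        )
    return HarmonizedInstruments(
        table=table.reset_index(drop=True), dropped=dropped.reset_index(drop=True)
    )
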