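"""Full study orchestration: per exposure x outcome x sex, select
instruments, harmonize, estimate, run MR-PRESSO, then pair the sexes for
the Cochran's Q difference test, emitting tidy figure-ready tables.

The analysis plan is a YAML file listing exposures (with per-sex or
sex-combined summary-statistics files), outcomes (per-sex files), an LD
panel, and thresholds.  A sex-combined exposure instrument is applied
identically against both sexes' outcome data, mirroring the handling of
traits for which no sex-specific GWAS exists.  Everything is validated
before any computation runs (fail-fast), and the whole run is
deterministic given the plan plus its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import estimators, presso as presso_mod
from .instruments import (
    LdPanel,
    NoInstrumentsError,
    mean_f_statistic,
    read_ld_panel,
    select_instruments,
)
from .io import SummaryStats, SumstatsError, filter_maf, harmonize, read_sumstats
from .sexdiff import sexdiff_table

logger = logging.getLogger(__name__)

ANALYSIS_SEXES = ("female", "male")

ESTIMATE_COLUMNS = [
    "exposure",
    "outcome",
    "sex",
    "method",
    "n_snps",
    "beta",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "pvalue",
    "q_stat",
    "egger_intercept",
    "egger_intercept_p",
]


class PlanError(ValueError):
    """Raised when the analysis plan fails fail-fast validation."""


@dataclass
class ExposureSpec:
    trait: str
    unit: str
    files: dict[str, str]  # sex (or "combined") -> path

    @property
    def sex_specific(self) -> bool:
        return "combined" not in self.files

    def path_for(self, sex: str) -> str:
        return self.files[sex] if self.sex_specific else self.files["combined"]


@dataclass
class OutcomeSpec:
    trait: str
    files: dict[str, str]  # sex -> path


@dataclass
class AnalysisPlan:
    """Validated description of a full sex-stratified MR study."""

    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    ld_panel: str
    seed: int = 0
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    min_maf: float = 0.05
    palindrome_eaf_window: float = 0.08
    presso_enabled: bool = True
    presso_n_sim: int = 5000
    presso_alpha: float = 0.05
    n_boot: int = 2000
    source_text: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisPlan":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text)
        thresholds = raw.get("thresholds", {})
        presso_cfg = raw.get("presso", {})
        try:
            exposures = [
                ExposureSpec(
                    trait=e["trait"],
                    unit=e.get("unit", "unknown"),
                    files={k: str(Path(path.parent, v)) for k, v in e["files"].items()},
                )
                for e in raw["exposures"]
            ]
            outcomes = [
                OutcomeSpec(
                    trait=o["trait"],
                    files={k: str(Path(path.parent, v)) for k, v in o["files"].items()},
                )
                for o in raw["outcomes"]
            ]
            return cls(
                exposures=exposures,
                outcomes=outcomes,
                ld_panel=str(Path(path.parent, raw["ld_panel"])),
                seed=int(raw.get("seed", 0)),
                p_threshold=float(thresholds.get("p_value", 5e-8)),
                r2_threshold=float(thresholds.get("r2", 0.001)),
                min_maf=float(thresholds.get("min_maf", 0.05)),
                palindrome_eaf_window=float(thresholds.get("palindrome_eaf_window", 0.08)),
                presso_enabled=bool(presso_cfg.get("enabled", True)),
                presso_n_sim=int(presso_cfg.get("n_sim", 5000)),
                presso_alpha=float(presso_cfg.get("alpha", 0.05)),
                n_boot=int(raw.get("median", {}).get("n_boot", 2000)),
                source_text=text,
            )
        except KeyError as exc:
            raise PlanError(f"{path.name}: missing plan key {exc}") from exc

    def config_hash(self) -> str:
        basis = self.source_text or repr(
            dataclasses.asdict(self)
        )
        return hashlib.sha256(basis.encode()).hexdigest()[:16]


@dataclass
class StudyResults:
    """Tidy result tables for a full study run."""

    estimates: pd.DataFrame
    sexdiffs: pd.DataFrame
    instrument_summary: pd.DataFrame
    presso: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _unit_seed(plan_seed: int, *key: str) -> int:
    """Deterministic sub-seed for one analysis unit, independent of ordering."""
    h = zlib.crc32("|".join(key).encode())
    return (plan_seed * 1_000_003 + h) % (2**31)


def _validate_plan(plan: AnalysisPlan) -> tuple[dict, dict, LdPanel]:
    """Fail-fast pass: every referenced file must exist and parse."""
    exposures: dict[tuple[str, str], SummaryStats] = {}
    outcomes: dict[tuple[str, str], SummaryStats] = {}
    problems: list[str] = []
    for spec in plan.exposures:
        for key, fpath in spec.files.items():
            try:
                exposures[(spec.trait, key)] = read_sumstats(
                    fpath, trait=spec.trait, unit=spec.unit, sex=key
                )
            except (OSError, ValueError) as exc:
                problems.append(f"exposure {spec.trait}/{key}: {exc}")
    for spec in plan.outcomes:
        for key, fpath in spec.files.items():
            try:
                outcomes[(spec.trait, key)] = read_sumstats(
                    fpath, trait=spec.trait, unit="log-odds", sex=key
                )
            except (OSError, ValueError) as exc:
                problems.append(f"outcome {spec.trait}/{key}: {exc}")
        for sex in ANALYSIS_SEXES:
            if sex not in spec.files:
                problems.append(f"outcome {spec.trait}: missing {sex} file")
    try:
        panel = read_ld_panel(plan.ld_panel)
    except (OSError, ValueError) as exc:
        problems.append(f"LD panel: {exc}")
        panel = None
    if problems:
        raise PlanError("plan validation failed: " + "; ".join(problems))
    return exposures, outcomes, panel


def run_analysis(plan: AnalysisPlan) -> StudyResults:
    """Execute the full stage sequence for every exposure x outcome x sex."""
    exposures, outcomes, panel = _validate_plan(plan)

    est_rows: list[dict] = []
    inst_rows: list[dict] = []
    presso_rows: list[dict] = []

    for espec in plan.exposures:
        for ospec in plan.outcomes:
            for sex in ANALYSIS_SEXES:
                unit_key = (espec.trait, ospec.trait, sex)
                exp_stats = exposures[(espec.trait, sex if espec.sex_specific else "combined")]
                out_stats = outcomes[(ospec.trait, sex)]
                try:
                    iset = select_instruments(
                        exp_stats,
                        panel,
                        p_threshold=plan.p_threshold,
                        r2_threshold=plan.r2_threshold,
                        min_maf=plan.min_maf,
                    )
                except NoInstrumentsError as exc:
                    logger.warning("unit %s failed: %s", unit_key, exc)
                    inst_rows.append(
                        {
                            "exposure": espec.trait,
                            "outcome": ospec.trait,
                            "sex": sex,
                            "n_snps": 0,
                            "mean_f": float("nan"),
                            "status": "failed: no instruments",
                        }
                    )
                    continue
                try:
                    h = harmonize(
                        iset.stats,
                        filter_maf(out_stats, plan.min_maf),
                        palindrome_eaf_window=plan.palindrome_eaf_window,
                    )
                except SumstatsError as exc:
                    logger.warning("unit %s failed: %s", unit_key, exc)
                    inst_rows.append(
                        {
                            "exposure": espec.trait,
                            "outcome": ospec.trait,
                            "sex": sex,
                            "n_snps": 0,
                            "mean_f": float("nan"),
                            "status": "failed: no shared variants",
                        }
                    )
                    continue
                # instrument strength on the SNPs actually analysed
                kept = iset.stats.with_df(
                    iset.stats.df[iset.stats.df["rsid"].isin(set(h.rsids))]
                )
                mean_f = mean_f_statistic(kept) if kept.n_snps else float("nan")
                if mean_f <= 10:
                    logger.warning("unit %s: weak instruments, mean F %.1f", unit_key, mean_f)
                if len(h.dropped):
                    logger.info(
                        "unit %s: %d SNP(s) dropped in harmonization", unit_key, len(h.dropped)
                    )
                inst_rows.append(
                    {
                        "exposure": espec.trait,
                        "outcome": ospec.trait,
                        "sex": sex,
                        "n_snps": h.n_snps,
                        "mean_f": mean_f,
                        "status": "ok",
                    }
                )

                seed = _unit_seed(plan.seed, espec.trait, ospec.trait, sex)
                ests = estimators.all_estimates(h, n_boot=plan.n_boot, seed=seed)
                for est in ests:
                    if est.method == "egger" and est.egger_intercept_p is not None:
                        if est.egger_intercept_p <= 0.05:
                            logger.warning(
                                "unit %s: Egger intercept p = %.3g suggests directional "
                                "pleiotropy",
                                unit_key,
                                est.egger_intercept_p,
                            )
                    est_rows.append(
                        {
                            "exposure": espec.trait,
                            "outcome": ospec.trait,
                            "sex": sex,
                            "method": est.method,
                            "n_snps": est.n_snps,
                            "beta": est.beta,
                            "se": est.se,
                            "or": est.or_,
                            "ci_low": est.ci_low,
                            "ci_high": est.ci_high,
                            "pvalue": est.pvalue,
                            "q_stat": est.q_stat,
                            "egger_intercept": est.egger_intercept,
                            "egger_intercept_p": est.egger_intercept_p,
                        }
                    )

                if plan.presso_enabled and h.n_snps >= 4:
                    try:
                        pres = presso_mod.presso(
                            h,
                            n_sim=plan.presso_n_sim,
                            seed=_unit_seed(plan.seed, *unit_key, "presso"),
                            alpha=plan.presso_alpha,
                        )
                        presso_rows.append(
                            {
                                "exposure": espec.trait,
                                "outcome": ospec.trait,
                                "sex": sex,
                                "rss_obs": pres.rss_obs,
                                "global_p": pres.global_p,
                                "n_outliers": len(pres.outliers),
                                "outlier_rsids": ",".join(r for r, _ in pres.outliers),
                                "beta_raw": pres.beta_raw,
                                "beta_corrected": pres.beta_corrected,
                                "distortion_coef": pres.distortion_coef,
                                "distortion_p": pres.distortion_p,
                            }
                        )
                    except presso_mod.PressoError as exc:
                        logger.warning("unit %s: MR-PRESSO failed: %s", unit_key, exc)

    estimates = pd.DataFrame(est_rows, columns=ESTIMATE_COLUMNS)
    if len(estimates):
        pairable = estimates.rename(columns={"or": "or_"})
        counts = pairable.groupby(["exposure", "outcome", "method"])["sex"].nunique()
        complete = counts[counts == 2].index
        mask = pairable.set_index(["exposure", "outcome", "method"]).index.isin(complete)
        sexdiffs = (
            sexdiff_table(estimates[mask]) if mask.any() else pd.DataFrame()
        )
    else:
        sexdiffs = pd.DataFrame()

    n_tests = len(sexdiffs[sexdiffs["method"] == "ivw"]) if len(sexdiffs) else 0
    provenance = {
        "config_hash": plan.config_hash(),
        "seed": plan.seed,
        "n_sexdiff_tests_ivw": n_tests,
    }
    logger.info("run complete: %d estimate rows, %d sex-difference tests", len(estimates), n_tests)
    return StudyResults(
        estimates=estimates,
        sexdiffs=sexdiffs,
        instrument_summary=pd.DataFrame(
            inst_rows, columns=["exposure", "outcome", "sex", "n_snps", "mean_f", "status"]
        ),
        presso=pd.DataFrame(
            presso_rows,
            columns=[
                "exposure",
                "outcome",
                "sex",
                "rss_obs",
                "global_p",
                "n_outliers",
                "outlier_rsids",
                "beta_raw",
                "beta_corrected",
                "distortion_coef",
                "distortion_p",
            ],
        ),
        provenance=provenance,
    )


def _round_half_away(x: float, ndigits: int) -> Decimal:
    q = Decimal(1).scaleb(-ndigits)
    return Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)


def format_number(x: float, ndigits: int) -> str:
    """Fixed-precision rendering, ties rounded away from zero."""
    return str(_round_half_away(x, ndigits))


def format_pvalue(p: float, ndigits: int = 3) -> str:
    if p < 10 ** (-ndigits):
        return "<" + str(Decimal(1).scaleb(-ndigits))
    return format_number(p, ndigits)


def write_forest_table(results: StudyResults, path: str | Path) -> None:
    """One row per (outcome, exposure, sex): the numeric content of a forest plot.

    ORs and CI bounds are printed to 2 decimals and p-values to 3 (half
    away from zero; p < 0.001 renders "<0.001"), with the paired
    sex-difference p in the last column (blank when the pair is missing).
    """
    est = results.estimates
    if est.empty:
        raise ValueError("no estimates to write")
    ivw_rows = est[est["method"] == "ivw"]
    diffs = results.sexdiffs
    if len(diffs):
        diffs = diffs[diffs["method"] == "ivw"].set_index(["exposure", "outcome"])
    rows = []
    for _, r in ivw_rows.iterrows():
        key = (r["exposure"], r["outcome"])
        diff_p = ""
        if len(diffs) and key in diffs.index:
            diff_p = format_pvalue(float(diffs.loc[key, "pvalue"]))
        rows.append(
            {
                "outcome": r["outcome"],
                "exposure": r["exposure"],
                "sex": r["sex"],
                "n_snps": int(r["n_snps"]),
                "or": format_number(r["or"], 2),
                "ci_low": format_number(r["ci_low"], 2),
                "ci_high": format_number(r["ci_high"], 2),
                "pvalue": format_pvalue(r["pvalue"]),
                "sexdiff_p": diff_p,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_results(results: StudyResults, out_dir: str | Path) -> list[Path]:
    """Write every result table under ``out_dir``; returns the paths written.

    Output files carry no timestamps, so identical plan + seed reproduce
    byte-identical tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    meta = pd.DataFrame([results.provenance])
    for name, df in [
        ("estimates.tsv", results.estimates),
        ("sexdiff.tsv", results.sexdiffs),
        ("instruments.tsv", results.instrument_summary),
        ("presso.tsv", results.presso),
        ("provenance.tsv", meta),
    ]:
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    forest = out_dir / "forest.tsv"
    if len(results.estimates):
        write_forest_table(results, forest)
        written.append(forest)
    return written
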