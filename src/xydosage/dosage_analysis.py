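"""Y/X and Xmale/2Xfemale dosage statistics, tests, and the full pipeline.

Per detected contig two ratios summarize degeneration and compensation:

* Y/X — male Y-allele expression over male X-allele expression; values below
  1 indicate Y-expression degeneration.
* Xmale/2Xfemale — the single male X's expression over the combined output of
  both female X copies; 0.5 is expected without dosage compensation, 1 under
  full compensation of the male X.

Contigs are binned by Y/X ratio, contigs with Y/X > 1.5 or Xmale/2Xfemale > 2
(male-biased expression, candidate sexually antagonistic genes) are flagged
excluded, Wilcoxon signed-rank tests assess Y reduction and departure of
Xmale/2Xfemale from 0.5, and a dosage profile reports per-bin pooled medians
of RPKM-normalized expression with percentile-bootstrap confidence intervals.
A null-simulation driver estimates the false-positive rate of the detector on
autosomal-only data.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from . import __version__
from .data_model import (
    Individual,
    read_contig_lengths,
    read_individuals,
    read_library_composition,
    write_frame,
    write_report,
)
from .expression_quant import (
    expression_table,
    normalized_library_size,
    per_sex_summary,
)
from .sexlink_detection import (
    ContigClassification,
    DetectionParams,
    DetectionResult,
    detect_from_vcf,
)
from .synthetic_data import SimulationConfig, simulate_autosomal_null

logger = logging.getLogger(__name__)

YX_BIN_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, math.inf)
YX_BIN_LABELS = ("[0,0.25)", "[0.25,0.5)", "[0.5,0.75)", "[0.75,1)", "[1,1.5)", "[1.5,inf)")
PROFILE_CLASSES = ("XX_females", "X_males", "Y_males", "XY_males")


def yx_bin(ratio: float) -> str:
    """Half-open Y/X ratio bin; every finite nonnegative ratio falls in
    exactly one bin, non-finite ratios go to the top bin."""
    if not math.isfinite(ratio):
        return YX_BIN_LABELS[-1]
    if ratio < 0:
        raise ValueError("expression ratios are nonnegative")
    for lo, hi, label in zip(YX_BIN_EDGES[:-1], YX_BIN_EDGES[1:], YX_BIN_LABELS):
        if lo <= ratio < hi:
            return label
    raise AssertionError("unreachable: bins partition [0, inf)")


@dataclass
class DosageRecord:
    contig_id: str
    n_sexlinked_snps: int
    passes_strict: bool
    x_polymorphic: bool
    yx_ratio: float
    xm2xf_ratio: float
    yx_bin: str
    excluded_high_yx: bool
    excluded_high_xm2xf: bool


def compute_dosage_records(
    summary: pd.DataFrame,
    classifications: list[ContigClassification],
) -> list[DosageRecord]:
    """Per-contig ratios from per-sex summaries (ratio of summaries).

    A male X summary of 0 cannot arise for detected contigs when the male
    heterozygote rule requires read support on both alleles, but is handled
    defensively: the contig goes to the top Y/X bin and is flagged excluded.
    Exclusion thresholds are strict: ratios exactly at the boundary are kept.
    """
    wide = summary.pivot(index="contig_id", columns="allele_class", values="summary")
    by_id = {c.contig_id: c for c in classifications}
    records = []
    for contig_id, row in wide.iterrows():
        x_m = float(row.get("X_male", np.nan))
        y_m = float(row.get("Y_male", np.nan))
        xx_f = float(row.get("X_female_both", np.nan))
        yx = y_m / x_m if x_m > 0 else math.inf
        xm2xf = x_m / xx_f if xx_f > 0 else math.inf
        cls = by_id.get(contig_id)
        records.append(
            DosageRecord(
                contig_id=contig_id,
                n_sexlinked_snps=cls.n_sexlinked_snps if cls else 0,
                passes_strict=cls.passes_strict if cls else False,
                x_polymorphic=cls.x_polymorphic if cls else False,
                yx_ratio=yx,
                xm2xf_ratio=xm2xf,
                yx_bin=yx_bin(yx),
                excluded_high_yx=(yx > 1.5) or not math.isfinite(yx),
                excluded_high_xm2xf=(xm2xf > 2.0),
            )
        )
    return records


def records_frame(records: list[DosageRecord]) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(DosageRecord)]
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------


@dataclass
class TestOutcome:
    statistic: float
    p_value: float
    direction: str  # "reduced", "elevated", "none"
    n: int


def _paired_wilcoxon(diffs: np.ndarray, alternative: str) -> tuple[float, float]:
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 0.0, 1.0  # degenerate: no information against the null
    res = stats.wilcoxon(nonzero, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def test_y_reduction(
    x_values: np.ndarray, y_values: np.ndarray, alternative: str = "two-sided"
) -> TestOutcome:
    """Wilcoxon signed-rank test pairing male X and Y expression per contig."""
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)
    if x_values.size != y_values.size:
        raise ValueError("paired samples must have equal length")
    if x_values.size < 2:
        raise ValueError("need at least two contigs")
    diffs = y_values - x_values
    statistic, p = _paired_wilcoxon(diffs, alternative)
    med = float(np.median(diffs))
    direction = "reduced" if med < 0 else ("elevated" if med > 0 else "none")
    return TestOutcome(statistic=statistic, p_value=p, direction=direction, n=int(diffs.size))


def test_xm2xf_departure(
    ratios: np.ndarray, reference: float = 0.5, alternative: str = "two-sided"
) -> TestOutcome:
    """One-sample Wilcoxon signed-rank of Xmale/2Xfemale ratios vs a reference."""
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size < 2:
        raise ValueError("need at least two contigs")
    diffs = ratios - reference
    statistic, p = _paired_wilcoxon(diffs, alternative)
    med = float(np.median(diffs))
    direction = "elevated" if med > 0 else ("reduced" if med < 0 else "none")
    return TestOutcome(statistic=statistic, p_value=p, direction=direction, n=int(ratios.size))


# ---------------------------------------------------------------------------
# dosage profile
# ---------------------------------------------------------------------------


def _pooled_class_values(
    expr: pd.DataFrame, contig_ids: list[str]
) -> dict[str, dict[str, np.ndarray]]:
    """Per profile class, per contig: the pooled individual-level values."""
    sub = expr[expr["contig_id"].isin(contig_ids)]
    males = sub[sub["sex"] == "male"]
    females = sub[sub["sex"] == "female"]
    xy = (
        males.pivot_table(
            index=["contig_id", "individual_id"], columns="allele_class", values="value"
        )
        .reset_index()
    )
    out: dict[str, dict[str, np.ndarray]] = {c: {} for c in PROFILE_CLASSES}
    for cid, g in females.groupby("contig_id"):
        out["XX_females"][cid] = g.loc[g["allele_class"] == "X_female_both", "value"].to_numpy()
    for cid, g in males.groupby("contig_id"):
        out["X_males"][cid] = g.loc[g["allele_class"] == "X_male", "value"].to_numpy()
        out["Y_males"][cid] = g.loc[g["allele_class"] == "Y_male", "value"].to_numpy()
    for cid, g in xy.groupby("contig_id"):
        out["XY_males"][cid] = (g["X_male"] + g["Y_male"]).to_numpy()
    return out


def build_dosage_profile(
    records: list[DosageRecord],
    expr: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    value: str = "rpkm",
) -> pd.DataFrame:
    """Per-bin pooled medians of the four allele classes, rescaled by females.

    Contigs flagged excluded (Y/X > 1.5 or Xmale/2Xfemale > 2) are removed
    first. Within each Y/X bin, expression values (RPKM by default) are pooled
    over contigs and same-sex individuals; the four medians (XX females,
    X males, Y males, XY males = X + Y per male) are rescaled by the female
    median so females sit at 1. Confidence intervals are a percentile
    bootstrap over contigs (n_boot resamples; none when n_boot == 0).
    """
    rng = np.random.default_rng(seed)
    kept = [r for r in records if not (r.excluded_high_yx or r.excluded_high_xm2xf)]
    expr = expr.rename(columns={value: "value"})[
        ["contig_id", "individual_id", "sex", "allele_class", "value"]
    ]
    rows = []
    for label in YX_BIN_LABELS:
        bin_contigs = [r.contig_id for r in kept if r.yx_bin == label]
        if not bin_contigs:
            for cls in PROFILE_CLASSES:
                rows.append(
                    {
                        "yx_bin": label,
                        "allele_class": cls,
                        "n_contigs": 0,
                        "median_raw": np.nan,
                        "median_rescaled": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                    }
                )
            continue
        pooled = _pooled_class_values(expr, bin_contigs)

        def class_medians(contig_sample: list[str]) -> dict[str, float]:
            meds = {}
            for cls in PROFILE_CLASSES:
                vals = np.concatenate(
                    [pooled[cls][cid] for cid in contig_sample if cid in pooled[cls]]
                )
                meds[cls] = float(np.median(vals))
            return meds

        point = class_medians(bin_contigs)
        female_med = point["XX_females"]
        boots: dict[str, list[float]] = {c: [] for c in PROFILE_CLASSES}
        for _ in range(n_boot):
            sample = list(rng.choice(bin_contigs, size=len(bin_contigs), replace=True))
            meds = class_medians(sample)
            f = meds["XX_females"]
            for cls in PROFILE_CLASSES:
                boots[cls].append(meds[cls] / f if f > 0 else np.nan)
        for cls in PROFILE_CLASSES:
            rescaled = point[cls] / female_med if female_med > 0 else np.nan
            if n_boot > 0:
                lo, hi = np.nanpercentile(boots[cls], [2.5, 97.5])
            else:
                lo = hi = np.nan
            rows.append(
                {
                    "yx_bin": label,
                    "allele_class": cls,
                    "n_contigs": len(bin_contigs),
                    "median_raw": point[cls],
                    "median_rescaled": rescaled,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heterozygosity comparison
# ---------------------------------------------------------------------------


@dataclass
class HeterozygosityComparison:
    n_compensated: int
    n_uncompensated: int
    poly_compensated: int
    poly_uncompensated: int
    prop_compensated: float
    prop_uncompensated: float
    odds_ratio: float
    p_value: float


def heterozygosity_comparison(
    records: list[DosageRecord],
    yx_threshold: float = 0.5,
    xm2xf_threshold: float = 0.75,
) -> HeterozygosityComparison:
    """Compare X-linked polymorphism between compensated and other contigs.

    The compensated stratum is Y/X < yx_threshold AND Xmale/2Xfemale >=
    xm2xf_threshold (reduced Y, male X raised toward the female level); the
    complement is everything else. Fisher's exact test on the 2x2 table of
    stratum x X-polymorphism. Empty strata are reported with NaN proportions
    rather than raising.
    """
    def is_comp(r: DosageRecord) -> bool:
        return r.yx_ratio < yx_threshold and r.xm2xf_ratio >= xm2xf_threshold

    comp = [r for r in records if is_comp(r)]
    other = [r for r in records if not is_comp(r)]
    pc = sum(1 for r in comp if r.x_polymorphic)
    po = sum(1 for r in other if r.x_polymorphic)
    table = [[pc, len(comp) - pc], [po, len(other) - po]]
    if len(comp) and len(other):
        odds, p = stats.fisher_exact(table)
    else:
        odds, p = math.nan, math.nan
    return HeterozygosityComparison(
        n_compensated=len(comp),
        n_uncompensated=len(other),
        poly_compensated=pc,
        poly_uncompensated=po,
        prop_compensated=pc / len(comp) if comp else math.nan,
        prop_uncompensated=po / len(other) if other else math.nan,
        odds_ratio=float(odds) if odds == odds else math.nan,
        p_value=float(p) if p == p else math.nan,
    )


# ---------------------------------------------------------------------------
# false-positive validation
# ---------------------------------------------------------------------------


@dataclass
class FalsePositiveEstimate:
    n_reps: int
    n_contigs_total: int
    n_false_any: int
    n_false_strict: int
    rate_any: float
    rate_strict: float
    rate_any_ci: tuple[float, float]
    rate_strict_ci: tuple[float, float]
    expected_count_any: float
    expected_count_strict: float


def estimate_false_positive_rate(
    null_config: SimulationConfig,
    detector_params: DetectionParams = DetectionParams(),
    n_reps: int = 5,
    scale_to: int = 1346,
    workdir: str | Path | None = None,
) -> FalsePositiveEstimate:
    """Rate of autosomal contigs falsely classified sex-linked under the null.

    Runs ``simulate_autosomal_null`` -> detection ``n_reps`` times (seeds
    derived from the config seed), pooling counts for contigs with >= 1 and
    >= 2 diagnostic SNPs. Clopper-Pearson 95% intervals; expected counts are
    the rates scaled to ``scale_to`` reference contigs.
    """
    n_total = 0
    n_any = 0
    n_strict = 0
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="xydosage_null_"))
    for rep in range(n_reps):
        cfg = dataclasses.replace(null_config, seed=(null_config.seed + 7919 * rep) % (2**31))
        ds = simulate_autosomal_null(cfg, base / f"rep{rep}")
        result = detect_from_vcf(ds.vcf, ds.individuals, detector_params)
        n_total += len(result.classifications)
        n_any += sum(1 for c in result.classifications if c.is_sex_linked)
        n_strict += sum(1 for c in result.classifications if c.passes_strict)
    ci_any = proportion_confint(n_any, n_total, alpha=0.05, method="beta")
    ci_strict = proportion_confint(n_strict, n_total, alpha=0.05, method="beta")
    return FalsePositiveEstimate(
        n_reps=n_reps,
        n_contigs_total=n_total,
        n_false_any=n_any,
        n_false_strict=n_strict,
        rate_any=n_any / n_total,
        rate_strict=n_strict / n_total,
        rate_any_ci=(float(ci_any[0]), float(ci_any[1])),
        rate_strict_ci=(float(ci_strict[0]), float(ci_strict[1])),
        expected_count_any=scale_to * n_any / n_total,
        expected_count_strict=scale_to * n_strict / n_total,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    vcf: str | Path,
    samples: str | Path,
    library: str | Path,
    outdir: str | Path,
    contig_lengths: str | Path | None = None,
    detector_params: DetectionParams = DetectionParams(),
    stat: str = "mean",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """detect -> quantify -> dosage -> reports, with a JSON run log.

    Writes sites.tsv, contigs.tsv, expression.tsv, dosage.tsv, profile.tsv
    and run_log.json under ``outdir``; returns the run log as a dict.
    Re-running with identical inputs and seed reproduces the reports
    byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, p in (("VCF", vcf), ("sample sheet", samples), ("library composition", library)):
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")

    individuals = read_individuals(samples)
    comps = read_library_composition(library)
    lib_sizes = {c.individual_id: normalized_library_size(c) for c in comps}
    lengths = None
    if contig_lengths is not None:
        lengths = {c.contig_id: c.length_bp for c in read_contig_lengths(contig_lengths)}

    result = detect_from_vcf(vcf, individuals, detector_params)

    site_rows = []
    for contig_id, calls in result.calls_by_contig.items():
        for call in calls:
            site_rows.append(
                {
                    "contig_id": contig_id,
                    "position": call.site.position,
                    "x_allele": call.x_allele,
                    "y_allele": call.y_allele,
                    "x_depth_males": ",".join(str(call.x_depths[k]) for k in sorted(call.x_depths)),
                    "y_depth_males": ",".join(str(call.y_depths[k]) for k in sorted(call.y_depths)),
                    "x_depth_females": ",".join(
                        str(call.female_x_totals[k]) for k in sorted(call.female_x_totals)
                    ),
                }
            )
    write_frame(
        pd.DataFrame(
            site_rows,
            columns=[
                "contig_id",
                "position",
                "x_allele",
                "y_allele",
                "x_depth_males",
                "y_depth_males",
                "x_depth_females",
            ],
        ),
        outdir / "sites.tsv",
    )
    write_report(result.classifications, outdir / "contigs.tsv")

    expr = expression_table(result.calls_by_contig, individuals, lib_sizes, lengths)
    write_frame(expr, outdir / "expression.tsv")

    log: dict = {
        "version": __version__,
        "seed": seed,
        "stat": stat,
        "detector_params": dataclasses.asdict(detector_params),
        "n_contigs_seen": len(result.classifications),
        "n_sex_linked": len(result.calls_by_contig),
        "n_strict": sum(1 for c in result.classifications if c.passes_strict),
        "expression_value_for_profile": "rpkm" if lengths else "E",
    }

    if result.calls_by_contig:
        summary = per_sex_summary(expr, stat=stat, value="E")
        records = compute_dosage_records(summary, result.classifications)
        write_report(records, outdir / "dosage.tsv")
        yx = np.array([r.yx_ratio for r in records if math.isfinite(r.yx_ratio)])
        xm = np.array([r.xm2xf_ratio for r in records if math.isfinite(r.xm2xf_ratio)])
        log["yx_median"] = float(np.median(yx)) if yx.size else None
        log["yx_mean"] = float(np.mean(yx)) if yx.size else None
        log["xm2xf_median"] = float(np.median(xm)) if xm.size else None
        if len(records) >= 2:
            wide = summary.pivot(index="contig_id", columns="allele_class", values="summary")
            yred = test_y_reduction(wide["X_male"].to_numpy(), wide["Y_male"].to_numpy())
            xtest = test_xm2xf_departure(xm)
            log["y_reduction_test"] = dataclasses.asdict(yred)
            log["xm2xf_vs_0.5_test"] = dataclasses.asdict(xtest)
        profile_value = "rpkm" if lengths else "E"
        profile = build_dosage_profile(records, expr, n_boot=n_boot, seed=seed, value=profile_value)
        write_frame(profile, outdir / "profile.tsv")
        het = heterozygosity_comparison(records)
        log["heterozygosity_comparison"] = dataclasses.asdict(het)
    else:
        write_report([], outdir / "dosage.tsv")
        write_frame(pd.DataFrame(), outdir / "profile.tsv")

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return log
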