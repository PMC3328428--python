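"""Ratios, bins, exclusion filters, Wilcoxon tests, profile, FP validation."""
import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from xydosage.dosage_analysis import (
    DosageRecord,
    YX_BIN_LABELS,
    build_dosage_profile,
    compute_dosage_records,
    estimate_false_positive_rate,
    heterozygosity_comparison,
    run_pipeline,
    test_xm2xf_departure as wilcoxon_xm2xf_departure,
    test_y_reduction as wilcoxon_y_reduction,
    yx_bin,
)
from xydosage.sexlink_detection import ContigClassification
from xydosage.synthetic_data import DistSpec, SimulationConfig, simulate_dataset


def make_record(contig_id="c1", yx=0.8, xm2xf=0.5, poly=False, n=2):
    return DosageRecord(
        contig_id=contig_id,
        n_sexlinked_snps=n,
        passes_strict=n >= 2,
        x_polymorphic=poly,
        yx_ratio=yx,
        xm2xf_ratio=xm2xf,
        yx_bin=yx_bin(yx),
        excluded_high_yx=yx > 1.5,
        excluded_high_xm2xf=xm2xf > 2.0,
    )


class TestBins:
    @pytest.mark.parametrize(
        "ratio,label",
        [(0.0, "[0,0.25)"), (0.25, "[0.25,0.5)"), (0.8, "[0.75,1)"), (1.0, "[1,1.5)"),
         (1.5, "[1.5,inf)"), (7.3, "[1.5,inf)")],
    )
    def test_half_open_bin_convention(self, ratio, label):
        assert yx_bin(ratio) == label

    def test_bins_partition_the_nonnegative_line(self):
        rng = np.random.default_rng(0)
        for ratio in np.concatenate([rng.uniform(0, 5, 500), [0, 0.25, 0.5, 0.75, 1, 1.5]]):
            assert yx_bin(float(ratio)) in YX_BIN_LABELS

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            yx_bin(-0.1)


class TestDosageRecords:
    def make_summary(self, x_m, y_m, xx_f, contig="c1"):
        return pd.DataFrame(
            {
                "contig_id": [contig] * 3,
                "allele_class": ["X_male", "Y_male", "X_female_both"],
                "summary": [x_m, y_m, xx_f],
            }
        )

    def classification(self, contig="c1", n=2):
        return ContigClassification(contig, n, n >= 1, n >= 2, False)

    def test_halved_male_x_gives_ratio_one_half(self):
        recs = compute_dosage_records(self.make_summary(5.0, 4.0, 10.0), [self.classification()])
        assert recs[0].xm2xf_ratio == pytest.approx(0.5)

    def test_bin_assignment_from_ratio(self):
        recs = compute_dosage_records(self.make_summary(10.0, 8.0, 10.0), [self.classification()])
        assert recs[0].yx_ratio == pytest.approx(0.8)
        assert recs[0].yx_bin == "[0.75,1)"

    def test_exclusions_are_strict_inequalities(self):
        at_boundary = make_record(yx=1.5, xm2xf=2.0)
        assert not at_boundary.excluded_high_yx and not at_boundary.excluded_high_xm2xf
        above = make_record(yx=1.51, xm2xf=2.01)
        assert above.excluded_high_yx and above.excluded_high_xm2xf

    def test_zero_male_x_summary_goes_to_top_bin_and_is_excluded(self):
        recs = compute_dosage_records(self.make_summary(0.0, 0.0, 10.0), [self.classification()])
        assert recs[0].yx_bin == "[1.5,inf)"
        assert recs[0].excluded_high_yx


class TestWilcoxon:
    def test_equal_x_and_y_is_degenerate_null(self):
        x = np.full(50, 3.0)
        out = wilcoxon_y_reduction(x, x.copy())
        assert out.p_value == 1.0 and out.direction == "none"

    def test_halved_y_dominates(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(5, 2, size=100)
        out = wilcoxon_y_reduction(x, x / 2)
        assert out.p_value < 1e-10
        assert out.direction == "reduced"

    def test_xm2xf_at_reference_not_significant(self):
        out = wilcoxon_xm2xf_departure(np.full(50, 0.5))
        assert out.p_value == 1.0

    def test_xm2xf_at_one_significant_and_elevated(self):
        rng = np.random.default_rng(2)
        out = wilcoxon_xm2xf_departure(1.0 + rng.normal(0, 0.01, size=100))
        assert out.p_value < 1e-10
        assert out.direction == "elevated"

    def test_type_i_error_rate_under_uncompensated_null(self):
        """Ratios symmetric around 0.5: rejections at alpha=0.01 stay near
        the nominal level across replicates."""
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 200
        for _ in range(reps):
            ratios = 0.5 + rng.normal(0, 0.1, size=60)  # symmetric around 0.5
            if wilcoxon_xm2xf_departure(ratios).p_value < 0.01:
                rejections += 1
        assert rejections / reps < 0.05

    def test_too_few_contigs_is_an_error(self):
        with pytest.raises(ValueError):
            wilcoxon_y_reduction(np.array([1.0]), np.array([0.5]))


class TestProfile:
    def make_inputs(self):
        rng = np.random.default_rng(4)
        records, expr_rows = [], []
        for i in range(30):
            cid = f"c{i:03d}"
            yx = rng.uniform(0.05, 1.4)
            records.append(make_record(cid, yx=yx, xm2xf=0.6))
            for j in range(3):
                x = rng.gamma(20, 1)
                y = yx * x
                expr_rows += [
                    dict(contig_id=cid, individual_id=f"M{j}", sex="male",
                         allele_class="X_male", rpkm=x),
                    dict(contig_id=cid, individual_id=f"M{j}", sex="male",
                         allele_class="Y_male", rpkm=y),
                    dict(contig_id=cid, individual_id=f"F{j}", sex="female",
                         allele_class="X_female_both", rpkm=rng.gamma(40, 1)),
                ]
        return records, pd.DataFrame(expr_rows)

    def test_female_level_rescaled_to_one_and_xy_is_sum(self):
        records, expr = self.make_inputs()
        profile = build_dosage_profile(records, expr, n_boot=0)
        filled = profile.dropna(subset=["median_raw"])
        for _, grp in filled.groupby("yx_bin"):
            by_class = grp.set_index("allele_class")["median_rescaled"]
            assert by_class["XX_females"] == pytest.approx(1.0)

    def test_xy_equals_x_plus_y_before_rescaling_per_male(self):
        """XY is formed per male as X + Y before pooling; verified exactly on
        a single-contig bin where medians reduce to the middle male."""
        records = [make_record("c1", yx=0.5, xm2xf=0.6)]
        rows = []
        for j, (x, y, f) in enumerate([(10, 5, 30), (12, 6, 32), (14, 7, 34)]):
            rows += [
                dict(contig_id="c1", individual_id=f"M{j}", sex="male",
                     allele_class="X_male", rpkm=x),
                dict(contig_id="c1", individual_id=f"M{j}", sex="male",
                     allele_class="Y_male", rpkm=y),
                dict(contig_id="c1", individual_id=f"F{j}", sex="female",
                     allele_class="X_female_both", rpkm=f),
            ]
        profile = build_dosage_profile(records, pd.DataFrame(rows), n_boot=0)
        grp = profile[profile.yx_bin == "[0.5,0.75)"].set_index("allele_class")
        assert grp.loc["XY_males", "median_raw"] == pytest.approx(
            grp.loc["X_males", "median_raw"] + grp.loc["Y_males", "median_raw"]
        )

    def test_excluded_contigs_do_not_enter_the_profile(self):
        records, expr = self.make_inputs()
        records.append(make_record("bad", yx=3.0, xm2xf=0.6))
        profile = build_dosage_profile(records, expr, n_boot=0)
        top = profile[profile.yx_bin == "[1.5,inf)"]
        assert (top["n_contigs"] == 0).all()

    def test_no_bootstrap_means_no_intervals(self):
        records, expr = self.make_inputs()
        profile = build_dosage_profile(records, expr, n_boot=0)
        assert profile["ci_low"].isna().all()

    def test_bootstrap_intervals_cover_the_point_estimate(self):
        records, expr = self.make_inputs()
        profile = build_dosage_profile(records, expr, n_boot=200, seed=1)
        filled = profile.dropna(subset=["ci_low"])
        assert len(filled) > 0
        assert (filled["ci_low"] <= filled["median_rescaled"] + 1e-9).all()
        assert (filled["ci_high"] >= filled["median_rescaled"] - 1e-9).all()


class TestHeterozygosityComparison:
    def test_identical_proportions_show_no_difference(self):
        records = []
        for i in range(40):
            comp = i < 20
            records.append(
                make_record(f"c{i}", yx=0.3 if comp else 1.2,
                            xm2xf=0.9 if comp else 0.5, poly=(i % 4 == 0))
            )
        out = heterozygosity_comparison(records)
        assert out.n_compensated == 20 and out.n_uncompensated == 20
        assert out.prop_compensated == out.prop_uncompensated
        assert out.p_value == pytest.approx(1.0)

    def test_monoallelic_compensated_stratum_is_depleted(self):
        """If compensated contigs never show X polymorphism (as under
        X-inactivation-like monoallelic expression) the association is
        detected."""
        records = []
        for i in range(60):
            comp = i < 30
            records.append(
                make_record(f"c{i}", yx=0.3 if comp else 1.2,
                            xm2xf=0.9 if comp else 0.5,
                            poly=(not comp) and (i % 2 == 0))
            )
        out = heterozygosity_comparison(records)
        assert out.prop_compensated == 0.0
        assert out.p_value < 0.01

    def test_degenerate_all_nonpolymorphic_table(self):
        records = [make_record(f"c{i}", yx=0.3, xm2xf=0.9) for i in range(5)]
        out = heterozygosity_comparison(records)
        assert out.n_uncompensated == 0
        assert math.isnan(out.p_value)


class TestFalsePositives:
    def test_clean_null_rate_is_exactly_zero(self, tmp_path):
        config = SimulationConfig(
            n_sexlinked_contigs=0,
            n_autosomal_contigs=500,
            residual_heterozygosity_h=0.0,
            base_error_rate_e=0.0,
            seed=59,
        )
        est = estimate_false_positive_rate(config, n_reps=2, workdir=tmp_path)
        assert est.rate_any == 0.0 and est.rate_strict == 0.0

    def test_strict_rate_never_exceeds_any_rate(self, tmp_path):
        config = SimulationConfig(
            n_sexlinked_contigs=0,
            n_autosomal_contigs=2000,
            residual_heterozygosity_h=0.1,
            base_error_rate_e=0.005,
            seed=61,
        )
        est = estimate_false_positive_rate(config, n_reps=2, workdir=tmp_path)
        assert est.rate_strict <= est.rate_any
        assert est.rate_any_ci[0] <= est.rate_any <= est.rate_any_ci[1]

    def test_rate_is_monotone_in_heterozygosity(self, tmp_path):
        rates = []
        for k, h in enumerate((0.0, 0.05, 0.3)):
            config = SimulationConfig(
                n_sexlinked_contigs=0,
                n_autosomal_contigs=3000,
                residual_heterozygosity_h=h,
                base_error_rate_e=0.0,
                seed=67,
            )
            est = estimate_false_positive_rate(config, n_reps=1, workdir=tmp_path / str(k))
            rates.append(est.rate_any)
        assert rates == sorted(rates)


class TestPipeline:
    def test_end_to_end_smoke_and_determinism(self, small_dataset, tmp_path):
        out1 = tmp_path / "run1"
        out2 = tmp_path / "run2"
        for out in (out1, out2):
            log = run_pipeline(
                vcf=small_dataset.vcf,
                samples=small_dataset.samples,
                library=small_dataset.library,
                outdir=out,
                contig_lengths=small_dataset.contig_lengths,
                n_boot=50,
                seed=5,
            )
        for name in ("sites.tsv", "contigs.tsv", "expression.tsv", "dosage.tsv",
                     "profile.tsv", "run_log.json"):
            assert (out1 / name).exists()
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name
        assert log["n_sex_linked"] >= 45  # nearly all 50 true contigs detected

    def test_missing_library_file_is_a_named_error(self, small_dataset, tmp_path):
        with pytest.raises(FileNotFoundError, match="library"):
            run_pipeline(
                vcf=small_dataset.vcf,
                samples=small_dataset.samples,
                library=tmp_path / "nope.tsv",
                outdir=tmp_path / "out",
            )


def test_degeneration_recovery_rank_correlation(tmp_path):
    """Per-contig simulated d is recovered by the measured Y/X ratio with
    rank correlation > 0.9 at depth >= 50."""
    from scipy import stats as sps

    from xydosage.data_model import read_library_composition
    from xydosage.expression_quant import (
        expression_table,
        normalized_library_size,
        per_sex_summary,
    )
    from xydosage.sexlink_detection import detect_from_vcf

    config = SimulationConfig(
        n_sexlinked_contigs=400,
        n_autosomal_contigs=0,
        degeneration_d=DistSpec("uniform", 0.1, 1.5),
        seed=71,
    )
    ds = simulate_dataset(config, tmp_path)
    result = detect_from_vcf(ds.vcf, ds.individuals)
    lib = {c.individual_id: normalized_library_size(c)
           for c in read_library_composition(ds.library)}
    expr = expression_table(result.calls_by_contig, ds.individuals, lib)
    summary = per_sex_summary(expr, stat="mean")
    records = compute_dosage_records(summary, result.classifications)
    rec = pd.DataFrame({"contig_id": [r.contig_id for r in records],
                        "yx": [r.yx_ratio for r in records]})
    merged = rec.merge(ds.truth_contigs[["contig_id", "true_d"]], on="contig_id")
    rho = sps.spearmanr(merged["yx"], merged["true_d"]).statistic
    assert rho > 0.9
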