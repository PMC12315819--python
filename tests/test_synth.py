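"""Synthetic-data generator: construction guarantees and statistical laws."""

import numpy as np
import pytest

from coagg import (
    KineticParams,
    ParameterError,
    SynthFieldParams,
    SyntheticCohortParams,
    generate_field,
    simulate_sensorgram,
)
from coagg.synth import (
    cohort_sample_summary,
    generate_cohort,
    generate_dilution_series,
)


class TestGenerateField:
    def test_invalid_params_name_the_offending_field(self):
        with pytest.raises(ParameterError, match="psf_sigma_px"):
            SynthFieldParams(psf_sigma_px=-1.0)
        with pytest.raises(ParameterError, match="lambda_pair"):
            SynthFieldParams(lambda_pair=-2)
        with pytest.raises(ParameterError, match="width_px"):
            SynthFieldParams(width_px=16)

    def test_no_pairs_requested_gives_empty_pair_index(self):
        _, truth = generate_field(SynthFieldParams(lambda_pair=0, seed=1))
        assert truth.pair_index == []
        assert truth.coloc_fraction == 0.0

    def test_pairs_only_gives_coloc_fraction_one(self):
        _, truth = generate_field(SynthFieldParams(
            lambda_pair=20, lambda_red_only=0, lambda_blue_only=0, seed=2))
        assert len(truth.red_centers) >= 1
        assert truth.coloc_fraction == 1.0
        # every red spot has exactly one blue partner
        assert len(truth.pair_index) == len(truth.red_centers)
        assert len(truth.blue_centers) == len(truth.pair_index)

    def test_blue_count_conservation(self):
        for seed in range(5):
            _, truth = generate_field(SynthFieldParams(seed=seed))
            n_blue_only = len(truth.blue_centers) - len(truth.pair_index)
            assert n_blue_only >= 0
            assert len(truth.blue_centers) == len(truth.pair_index) + n_blue_only

    def test_poisson_mean_red_count(self):
        # mean red count over 200 small fields ~ lambda_pair + lambda_red_only
        lam = 30.0
        counts = [len(generate_field(SynthFieldParams(
            width_px=64, height_px=64, lambda_pair=20, lambda_red_only=10,
            lambda_blue_only=0, seed=s))[1].red_centers) for s in range(200)]
        tol = 3.0 * np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) <= tol

    def test_centers_respect_border_margin(self):
        p = SynthFieldParams(seed=4)
        _, truth = generate_field(p)
        m = 3 * p.psf_sigma_px
        for x, y in truth.red_centers + truth.blue_centers:
            assert m <= x <= p.width_px - 1 - m
            assert m <= y <= p.height_px - 1 - m

    def test_same_seed_bit_identical(self):
        p = SynthFieldParams(seed=9)
        f1, t1 = generate_field(p)
        f2, t2 = generate_field(p)
        assert np.array_equal(f1.red_image, f2.red_image)
        assert np.array_equal(f1.blue_image, f2.blue_image)
        assert t1.red_centers == t2.red_centers

    def test_images_are_uint16(self, default_field):
        fld, _ = default_field
        assert fld.red_image.dtype == np.uint16
        assert fld.blue_image.dtype == np.uint16


class TestDilutionSeries:
    def test_rates_scale_geometrically(self):
        base = SynthFieldParams(width_px=64, height_px=64, lambda_pair=20,
                                lambda_red_only=5, lambda_blue_only=0, seed=1)
        # expected total rate at step 2 is 1/25 of step 0: check empirically
        tot = np.zeros(3)
        n_rep = 100
        for rep in range(n_rep):
            b = SynthFieldParams(**{**base.__dict__, "seed": rep})
            series = generate_dilution_series(b, fold=5, steps=3)
            tot += [len(t.red_centers) for _, t in series]
        means = tot / n_rep
        assert abs(means[0] - 25) < 3 * np.sqrt(25 / n_rep)
        assert abs(means[2] - 1.0) < 3 * np.sqrt(1.0 / n_rep)
        # monotone decrease of the empirical means
        assert means[0] > means[1] > means[2]

    def test_single_step_request_is_an_error(self):
        with pytest.raises(ParameterError, match="steps"):
            generate_dilution_series(SynthFieldParams(seed=0), steps=1)

    def test_fold_at_most_one_is_an_error(self):
        with pytest.raises(ParameterError, match="fold"):
            generate_dilution_series(SynthFieldParams(seed=0), fold=1.0)

    def test_reproducible_per_step_seeds(self):
        base = SynthFieldParams(width_px=64, height_px=64, seed=5)
        s1 = generate_dilution_series(base, steps=3)
        s2 = generate_dilution_series(base, steps=3)
        for (f1, _), (f2, _) in zip(s1, s2):
            assert np.array_equal(f1.red_image, f2.red_image)


class TestCohort:
    def test_row_counts_and_determinism(self):
        p = SyntheticCohortParams(n_per_group=2, dispersion=1.0, seed=3)
        df = generate_cohort(p)
        # 2 samples/group x 2 groups x 2 replicates x 6 readouts
        assert len(df) == 2 * 2 * 2 * 6
        samples = cohort_sample_summary(df)
        assert (samples.groupby("group").size() == 2).all()
        df2 = generate_cohort(p)
        assert df.equals(df2)

    def test_both_count_columns_present_with_scaled_alpha_syn(self):
        p = SyntheticCohortParams(
            n_per_group=200, group_means={"HC": 10.0},
            alpha_syn_mean_factor=2.0, seed=5)
        s = cohort_sample_summary(generate_cohort(p))
        ratio = s.alpha_syn_count.mean() / s.coagg_count.mean()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_cohort_record_validates_enumerations(self):
        from coagg import CohortRecord
        rec = CohortRecord("s1", "PD", "L1EV", 10.0, 4.0,
                           {"HbA1c_pct": 6.1})
        assert rec.covariates["HbA1c_pct"] == 6.1
        with pytest.raises(ParameterError, match="group"):
            CohortRecord("s1", "XX", "L1EV", 1.0, 1.0)
        with pytest.raises(ParameterError, match="analyte"):
            CohortRecord("s1", "PD", "plasma", 1.0, 1.0)

    def test_invalid_rank_corr_rejected(self):
        with pytest.raises(ParameterError, match="covariate_rank_corr"):
            SyntheticCohortParams(covariate_rank_corr=1.5)

    def test_zero_rank_corr_is_near_zero(self):
        from scipy import stats
        p = SyntheticCohortParams(
            n_per_group=500, group_means={"HC": 10.0, "PD": 10.0},
            covariate_rank_corr=0.0, seed=7)
        s = cohort_sample_summary(generate_cohort(p), covariate="HbA1c_pct")
        rho = stats.spearmanr(s.coagg_count, s.HbA1c_pct).statistic
        assert abs(rho) <= 0.1

    def test_target_rank_corr_recovered(self):
        from scipy import stats
        p = SyntheticCohortParams(
            n_per_group=500, group_means={"HC": 10.0, "PD": 10.0},
            covariate_rank_corr=0.55, seed=8)
        s = cohort_sample_summary(generate_cohort(p), covariate="HbA1c_pct")
        rho = stats.spearmanr(s.coagg_count, s.HbA1c_pct).statistic
        assert abs(rho - 0.55) <= 0.1


class TestSensorgram:
    KP = KineticParams(ka=1e4, kd=1e-3, Rmax=100.0)

    def test_association_plateau_matches_closed_form(self):
        c = 5 * self.KP.KD
        sg = simulate_sensorgram(self.KP, c, t_assoc=50000, t_dissoc=10,
                                 noise_sd=0.0)
        plateau = self.KP.Rmax * c / (c + self.KP.KD)
        assoc_end = sg.response[sg.t <= sg.t_assoc][-1]
        assert assoc_end == pytest.approx(plateau, rel=1e-6)

    def test_zero_kd_dissociation_is_constant(self):
        kp = KineticParams(ka=1e4, kd=0.0, Rmax=100.0)
        sg = simulate_sensorgram(kp, 1e-6, t_assoc=100, t_dissoc=200,
                                 noise_sd=0.0)
        dis = sg.response[sg.t > sg.t_assoc]
        assert np.allclose(dis, dis[0])

    def test_characteristic_time_point(self):
        # R at t = 1/(ka*C + kd) equals (1 - 1/e) of the plateau
        c = 2e-7
        kobs = self.KP.ka * c + self.KP.kd
        sg = simulate_sensorgram(self.KP, c, t_assoc=10000, t_dissoc=10,
                                 noise_sd=0.0, dt=1.0 / kobs)
        plateau = self.KP.Rmax * c / (c + self.KP.KD)
        idx = np.argmin(np.abs(sg.t - 1.0 / kobs))
        assert sg.response[idx] == pytest.approx(
            plateau * (1 - np.exp(-1)), rel=1e-6)

    def test_nonpositive_conc_rejected(self):
        with pytest.raises(ParameterError, match="conc"):
            simulate_sensorgram(self.KP, 0.0, 10, 10)
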