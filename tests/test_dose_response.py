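import numpy as np
import pytest
from scipy import stats

from pelletox.dose_response import (
    CONTROL,
    BioassayDataset,
    ProbitFit,
    Vial,
    check_control_acceptability,
    compute_size_increase,
    derive_noec_loec,
    dunnett_t3_test,
    dunnett_test,
    estimate_ecx,
    fit_probit,
    normalize_to_control,
    read_bioassays,
    toxic_units,
)
from pelletox.pipeline import bioassays_to_frames
from pelletox.synthetic import BioassaySimSpec, simulate_bioassay

DILUTIONS = (1.0, 1 / 3, 1 / 10, 1 / 30)


class TestSizeIncrease:
    def test_subtracts_mean_egg_size(self):
        v = Vial("v", 1.0, [400.0, 420.0])
        assert compute_size_increase(v, 100.0).tolist() == [300.0, 320.0]

    def test_all_equal_gives_zeros(self):
        v = Vial("v", 1.0, [100.0, 100.0])
        assert compute_size_increase(v, 100.0).tolist() == [0.0, 0.0]

    def test_negative_increase_retained_with_warning(self):
        v = Vial("v", 1.0, [90.0, 150.0])
        with pytest.warns(UserWarning):
            inc = compute_size_increase(v, 100.0)
        assert inc.tolist() == [-10.0, 50.0]

    def test_empty_vial_rejected(self):
        with pytest.raises(ValueError):
            Vial("v", 1.0, [])


class TestAcceptability:
    def _assay(self, fert, increase):
        vials = [Vial("c1", CONTROL, [100.0 + increase] * 3),
                 Vial("c2", CONTROL, [100.0 + increase] * 3),
                 Vial("t1", 1.0, [300.0] * 3), Vial("t2", 1.0, [300.0] * 3)]
        return BioassayDataset("s", 100.0, fert, vials)

    def test_passing_assay(self):
        acc = check_control_acceptability(self._assay(96.0, 260.0))
        assert acc.passed and acc.reasons == []

    def test_fertilization_threshold_is_strict(self):
        acc = check_control_acceptability(self._assay(95.0, 260.0))
        assert not acc.passed
        assert any("fertilization" in r for r in acc.reasons)

    def test_growth_threshold_is_strict(self):
        acc = check_control_acceptability(self._assay(98.0, 253.0))
        assert not acc.passed
        assert any("size increase" in r for r in acc.reasons)


class TestNormalization:
    def test_control_vials_average_to_one(self):
        ds = simulate_bioassay(BioassaySimSpec(seed=5))
        norm = normalize_to_control(ds)
        ctrl_r = norm[norm["treatment"] == CONTROL]["r"]
        assert ctrl_r.mean() == pytest.approx(1.0, abs=1e-12)

    def test_vial_at_control_mean_has_r_one(self):
        vials = [Vial("c", CONTROL, [350.0] * 4), Vial("c2", CONTROL, [350.0] * 4),
                 Vial("t", 1.0, [350.0] * 4)]
        ds = BioassayDataset("s", 50.0, 98.0, vials)
        norm = normalize_to_control(ds)
        assert norm[norm["treatment"] == 1.0]["r"].iloc[0] == pytest.approx(1.0)


class TestProbitFit:
    def test_noiseless_recovery_of_generating_parameters(self):
        # b0 = 0, b1 = 1 corresponds to EC50 = 1 in the simulator's form.
        ds = simulate_bioassay(BioassaySimSpec(ec50=1.0, slope_b1=1.0, sigma_um=0.0))
        fit = fit_probit(ds)
        assert fit.converged
        assert fit.b0 == pytest.approx(0.0, abs=1e-6)
        assert fit.b1 == pytest.approx(1.0, abs=1e-6)

    def test_flat_responses_do_not_converge(self):
        vials = [Vial(f"c{i}", CONTROL, [400.0] * 5) for i in range(2)]
        for d in DILUTIONS:
            vials += [Vial(f"d{d:g}_{i}", d, [400.0] * 5) for i in range(2)]
        ds = BioassayDataset("flat", 100.0, 98.0, vials)
        fit = fit_probit(ds)
        assert not fit.converged
        assert not estimate_ecx(fit, 50).calculable

    def test_single_dilution_rejected(self):
        vials = [Vial("c", CONTROL, [400.0] * 5), Vial("c2", CONTROL, [401.0] * 5),
                 Vial("t", 1.0, [300.0] * 5), Vial("t2", 1.0, [301.0] * 5)]
        with pytest.raises(ValueError):
            fit_probit(BioassayDataset("s", 100.0, 98.0, vials))

    def test_noisy_recovery_is_unbiased(self):
        # Oracle is the generating model; scaled-down replicate check.
        errs = []
        for seed in range(50):
            ds = simulate_bioassay(BioassaySimSpec(ec50=0.33, sigma_um=40.0,
                                                   control_mean_um=300.0, seed=seed))
            ec50 = estimate_ecx(fit_probit(ds), 50)
            errs.append(abs(np.log10(ec50.estimate / 0.33)))
        assert np.median(errs) < 0.05


class TestEstimateEcx:
    def _fit(self, b0, b1, cov=None, df=14):
        cov = np.zeros((2, 2)) if cov is None else cov
        return ProbitFit(b0, b1, cov, df, True)

    def test_ec50_closed_form(self):
        assert estimate_ecx(self._fit(0.0, 2.0), 50).estimate == pytest.approx(1.0)

    def test_ec20_closed_form(self):
        # Frozen oracle: 10 ** (norm.ppf(0.2) / 2) = 10 ** (-0.8416 / 2)
        e = estimate_ecx(self._fit(0.0, 2.0), 20)
        assert e.estimate == pytest.approx(0.3794, abs=1e-3)

    def test_estimate_above_undiluted_not_calculable(self):
        e = estimate_ecx(self._fit(-2.0, 1.0), 50)
        assert e.estimate == pytest.approx(100.0)
        assert not e.calculable

    def test_negative_slope_not_calculable(self):
        assert not estimate_ecx(self._fit(0.0, -1.0), 50).calculable

    def test_ecx_strictly_increasing_in_effect_level(self):
        fit = self._fit(0.5, 1.5)
        estimates = [estimate_ecx(fit, x).estimate for x in (10, 20, 50, 80)]
        assert all(b > a for a, b in zip(estimates, estimates[1:]))

    def test_ci_brackets_estimate(self):
        ds = simulate_bioassay(BioassaySimSpec(seed=3))
        e = estimate_ecx(fit_probit(ds), 50)
        assert e.ci_low <= e.estimate <= e.ci_high


class TestToxicUnits:
    def test_reciprocal(self):
        from pelletox.dose_response import ECx

        assert toxic_units(ECx(20, 0.5, 0.4, 0.6, True)) == pytest.approx(2.0)

    def test_definition_consistency(self):
        # TU 1.9 corresponds to EC20 = 1/1.9.
        from pelletox.dose_response import ECx

        assert toxic_units(ECx(20, 1 / 1.9, 0.4, 0.7, True)) == pytest.approx(1.9)

    def test_not_calculable_gives_none(self):
        from pelletox.dose_response import ECx

        assert toxic_units(ECx(20, np.nan, np.nan, np.nan, False)) is None

    def test_tu_times_ec20_is_one(self):
        ds = simulate_bioassay(BioassaySimSpec(seed=11))
        ec20 = estimate_ecx(fit_probit(ds), 20)
        assert ec20.calculable
        assert toxic_units(ec20) * ec20.estimate == pytest.approx(1.0, abs=1e-12)


class TestDunnett:
    def test_single_treatment_reduces_to_pooled_t(self):
        rng = np.random.default_rng(4)
        a, c = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        p = dunnett_test([a], c, seed=0).pvalue[0]
        assert p == pytest.approx(stats.ttest_ind(a, c).pvalue, abs=0.005)

    def test_identical_groups_give_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = dunnett_test([g.copy(), g.copy()], g.copy(), seed=0)
        assert np.all(res.pvalue > 0.99)

    def test_matches_brute_force_multivariate_t_oracle(self):
        # Independent oracle: Monte Carlo of the max-|T| null distribution
        # of the simultaneous comparisons (shared-control correlation).
        rng = np.random.default_rng(21)
        groups = [rng.normal(0.8, 1, 5), rng.normal(0.2, 1, 4), rng.normal(0, 1, 6)]
        control = rng.normal(0, 1, 5)
        res = dunnett_test(groups, control, seed=1)

        ns = np.array([len(g) for g in groups])
        n0 = len(control)
        df = int(ns.sum() + n0 - len(groups) - 1)
        rho = np.sqrt(np.outer(ns, ns) / np.outer(ns + n0, ns + n0))
        np.fill_diagonal(rho, 1.0)
        orng = np.random.default_rng(77)
        z = orng.multivariate_normal(np.zeros(len(groups)), rho, size=200_000,
                                     method="cholesky")
        s = np.sqrt(orng.chisquare(df, size=200_000) / df)
        max_abs_t = np.max(np.abs(z), axis=1) / s
        for t_i, p_i in zip(res.statistic, res.pvalue):
            p_mc = np.mean(max_abs_t >= abs(t_i))
            assert p_i == pytest.approx(p_mc, abs=0.005)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            dunnett_test([np.array([1.0])], np.array([1.0, 2.0]))


class TestDunnettT3:
    def test_single_treatment_reduces_to_welch_t(self):
        rng = np.random.default_rng(8)
        a, c = rng.normal(0, 3, 5), rng.normal(1, 1, 7)
        p = dunnett_t3_test([a], c).pvalue[0]
        assert p == pytest.approx(stats.ttest_ind(a, c, equal_var=False).pvalue,
                                  abs=0.005)

    def test_identical_groups_give_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        res = dunnett_t3_test([g.copy(), g.copy()], g.copy())
        assert np.all(res.pvalue > 0.99)

    def test_familywise_error_under_heteroscedastic_null(self):
        # Variance ratio 9 between treatments and control; T3 should hold
        # the familywise error at or below ~nominal.
        rng = np.random.default_rng(99)
        reps, rejections = 2000, 0
        for _ in range(reps):
            groups = [rng.normal(0, 3, 4) for _ in range(4)]
            control = rng.normal(0, 1, 4)
            if (dunnett_t3_test(groups, control).pvalue < 0.05).any():
                rejections += 1
        assert rejections / reps <= 0.07

    def test_p_values_not_below_welch(self):
        # The maximum-modulus adjustment can only increase each p-value.
        rng = np.random.default_rng(13)
        groups = [rng.normal(0.5, 2, 5) for _ in range(3)]
        control = rng.normal(0, 1, 5)
        res = dunnett_t3_test(groups, control)
        for g, p_adj in zip(groups, res.pvalue):
            p_welch = stats.ttest_ind(g, control, equal_var=False).pvalue
            assert p_adj >= p_welch - 1e-12


class TestNoecLoec:
    def test_effect_only_at_undiluted(self, assay_from_shifts):
        ds = assay_from_shifts({1.0: -10, 1 / 3: 0, 1 / 10: 0, 1 / 30: 0})
        nl = derive_noec_loec(ds, seed=0)
        assert nl.loec == pytest.approx(1.0)
        assert nl.noec == pytest.approx(1 / 3)

    def test_null_assay_has_no_loec(self, assay_from_shifts):
        ds = assay_from_shifts({d: 0 for d in DILUTIONS})
        nl = derive_noec_loec(ds, seed=0)
        assert nl.loec is None and nl.loec_label == "n.c."
        assert nl.noec == pytest.approx(1.0)

    def test_effect_at_all_dilutions(self, assay_from_shifts):
        ds = assay_from_shifts({d: -10 for d in DILUTIONS})
        nl = derive_noec_loec(ds, seed=0)
        assert nl.loec == pytest.approx(1 / 30)
        assert nl.noec is None and nl.noec_label.startswith("<")

    def test_noec_below_loec_when_both_defined(self, assay_from_shifts):
        ds = assay_from_shifts({1.0: -10, 1 / 3: -8, 1 / 10: 0, 1 / 30: 0})
        nl = derive_noec_loec(ds, seed=0)
        assert nl.noec is not None and nl.loec is not None
        assert nl.noec < nl.loec

    def test_standard_gating_uses_t3_under_heteroscedasticity(self):
        rng = np.random.default_rng(31)
        vials = [Vial(f"c{i}", CONTROL, 400 + rng.normal(0, 2, 20)) for i in range(4)]
        for d in DILUTIONS:
            for i in range(4):
                # Strongly unequal between-vial spread in treatments.
                vials.append(Vial(f"d{d:g}_{i}", d,
                                  400 + rng.normal(0, 2, 20) + rng.normal(0, 60)))
        ds = BioassayDataset("het", 100.0, 98.0, vials)
        assert derive_noec_loec(ds, gating="standard").method == "dunnett_t3"
        assert derive_noec_loec(ds, gating="literal").method == "dunnett"

    def test_unreplicated_design_rejected(self):
        vials = [Vial("c1", CONTROL, [400.0] * 5), Vial("c2", CONTROL, [390.0] * 5),
                 Vial("t", 1.0, [300.0] * 5)]
        with pytest.raises(ValueError):
            derive_noec_loec(BioassayDataset("s", 100.0, 98.0, vials))


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        ds = simulate_bioassay(BioassaySimSpec(seed=2), sample_id="S1")
        data_df, meta_df = bioassays_to_frames([ds])
        data_path, meta_path = tmp_path / "b.csv", tmp_path / "m.csv"
        data_df.to_csv(data_path, index=False)
        meta_df.to_csv(meta_path, index=False)
        back = read_bioassays(data_path, meta_path)[0]
        assert back.sample_id == "S1"
        assert sorted(back.dilutions) == sorted(ds.dilutions)
        f1, f2 = fit_probit(ds), fit_probit(back)
        assert f2.b0 == pytest.approx(f1.b0, abs=1e-9)
        assert f2.b1 == pytest.approx(f1.b1, abs=1e-9)

    def test_missing_metadata_rejected(self, tmp_path):
        ds = simulate_bioassay(BioassaySimSpec(seed=2), sample_id="S1")
        data_df, meta_df = bioassays_to_frames([ds])
        meta_df["sample_id"] = "OTHER"
        data_path, meta_path = tmp_path / "b.csv", tmp_path / "m.csv"
        data_df.to_csv(data_path, index=False)
        meta_df.to_csv(meta_path, index=False)
        with pytest.raises(ValueError):
            read_bioassays(data_path, meta_path)
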