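"""Fitting workflow: objective, lethality, HRF, and scavenging-factor fits."""

import math

import numpy as np
import pytest

from dsbsurv import (
    GeneratorSpec,
    LethalityParams,
    NucleusModel,
    ScavengerModel,
    SurvivalDataset,
    SurvivalRecord,
    analytic_mean_survival,
    f_dmso,
    fit_fdmso_curve,
    fit_fdmso_points,
    fit_hrf,
    fit_lethality,
    generate_dataset,
    n_loops,
    objective,
)

CHO = LethalityParams(5.56e-3, 0.765)


def _rec(dose, s, conc=0.0, oxygen="normoxic", unc=None):
    return SurvivalRecord("X", dose, conc, oxygen, s, unc)


class TestObjective:
    def test_perfect_prediction_scores_zero(self):
        ds = SurvivalDataset((_rec(2, 0.5), _rec(4, 0.1)))
        assert objective([0.5, 0.1], ds) == 0.0

    def test_e_fold_error_scores_one(self):
        ds = SurvivalDataset((_rec(2, 0.2),))
        assert objective([0.2 * math.e], ds) == pytest.approx(1.0)

    def test_weighting_changes_nonuniform_uncertainty_case(self):
        # same residuals, different error bars: weighting must matter
        unweighted = SurvivalDataset((_rec(2, 0.5), _rec(4, 0.1)))
        weighted = SurvivalDataset(
            (_rec(2, 0.5, unc=0.05), _rec(4, 0.1, unc=0.001))
        )
        pred = [0.45, 0.12]
        assert objective(pred, weighted) != pytest.approx(objective(pred, unweighted))
        # hand value: sum ((ln ratio) / (unc/S))^2
        expected = (math.log(0.45 / 0.5) / 0.1) ** 2 + (math.log(0.12 / 0.1) / 0.01) ** 2
        assert objective(pred, weighted) == pytest.approx(expected)

    def test_record_validation(self):
        with pytest.raises(ValueError, match="surviving_fraction"):
            _rec(2, 0.0)
        with pytest.raises(ValueError, match="oxygen"):
            SurvivalRecord("X", 1, 0, "anoxic", 0.5)


def _noise_free_curve(lethality, hrf=None, doses=tuple(range(1, 11))):
    return generate_dataset(
        GeneratorSpec(
            lethality=lethality, hrf=hrf, doses=doses, dmso_concs=(0.0,),
            noise_sigma_ln=0.0,
        )
    )


class TestFitLethality:
    def test_zero_noise_round_trip(self):
        ds = _noise_free_curve(CHO).filter(oxygen="normoxic")
        res = fit_lethality(ds)
        assert res.converged
        assert res.params["k_idsb"] == pytest.approx(CHO.k_idsb, rel=1e-3)
        assert res.params["k_cdsb"] == pytest.approx(CHO.k_cdsb, rel=1e-3)
        # closed-form predictor: repeated fits are bit-identical
        res2 = fit_lethality(ds)
        assert res2.params == res.params

    def test_all_survivors_degenerates_to_zero_lethality(self):
        ds = SurvivalDataset(tuple(_rec(d, 1.0) for d in (1.0, 2.0, 3.0)))
        res = fit_lethality(ds)
        assert res.params["k_idsb"] == pytest.approx(0.0, abs=1e-6)
        assert res.params["k_cdsb"] == pytest.approx(0.0, abs=1e-6)
        assert res.at_boundary

    def test_too_few_doses_rejected(self):
        ds = SurvivalDataset((_rec(2, 0.5), _rec(2, 0.52), _rec(4, 0.1)))
        with pytest.raises(ValueError, match="3 distinct doses"):
            fit_lethality(ds)

    def test_hypoxic_or_dmso_records_rejected(self):
        with pytest.raises(ValueError, match="normoxic"):
            fit_lethality(
                SurvivalDataset(tuple(_rec(d, 0.5, oxygen="hypoxic") for d in (1, 2, 3)))
            )
        with pytest.raises(ValueError, match="zero-DMSO"):
            fit_lethality(
                SurvivalDataset(tuple(_rec(d, 0.5, conc=0.5) for d in (1, 2, 3)))
            )


class TestFitHrf:
    def test_zero_noise_round_trip(self):
        ds = _noise_free_curve(CHO, hrf=2.90).filter(oxygen="hypoxic")
        res = fit_hrf(ds, CHO)
        assert res.converged
        assert res.params["hrf"] == pytest.approx(2.90, rel=1e-3)

    def test_normoxia_like_data_pins_hrf_at_unity(self):
        nuc = NucleusModel()
        ngl = n_loops(nuc)
        records = tuple(
            SurvivalRecord(
                "X", d, 0.0, "hypoxic",
                analytic_mean_survival(nuc.alpha_dsb * d * nuc.dna_content, ngl, CHO),
            )
            for d in (2.0, 4.0, 8.0)
        )
        res = fit_hrf(SurvivalDataset(records), CHO)
        assert res.at_boundary
        assert res.params["hrf"] == pytest.approx(1.0, abs=1e-4)

    def test_dmso_records_rejected(self):
        ds = SurvivalDataset((_rec(2, 0.5, conc=0.5, oxygen="hypoxic"),))
        with pytest.raises(ValueError, match="zero-DMSO"):
            fit_hrf(ds, CHO)


class TestFitFdmsoPoints:
    def test_recovers_injected_scaling_factor(self):
        # survival generated with an explicit f = 0.5 in the split yield
        nuc = NucleusModel()
        ngl = n_loops(nuc)
        sc = ScavengerModel()
        f_true = 0.5
        records = []
        for d in (2.0, 4.0, 8.0):
            base = nuc.alpha_dsb * d * nuc.dna_content
            y = sc.fr_dir * base + (1 - sc.fr_dir) * base * f_true
            records.append(
                SurvivalRecord("X", d, 0.3, "normoxic",
                               analytic_mean_survival(y, ngl, CHO))
            )
        points = fit_fdmso_points(SurvivalDataset(tuple(records)), CHO)
        assert len(points) == 1
        assert points[0][0] == 0.3
        assert points[0][1] == pytest.approx(f_true, abs=1e-3)

    def test_zero_concentration_yields_unit_factor(self):
        ds = _noise_free_curve(CHO, doses=(2.0, 4.0, 8.0))
        points = fit_fdmso_points(ds, CHO)
        assert points[0] == (0.0, pytest.approx(1.0, abs=1e-4))

    def test_estimates_bounded_even_for_inconsistent_data(self):
        # survival far above any achievable prediction drives f to its bound
        ds = SurvivalDataset((_rec(8.0, 1.0, conc=2.0),))
        points = fit_fdmso_points(ds, CHO)
        assert 0.0 <= points[0][1] <= 1.0

    def test_hypoxic_records_need_hrf(self):
        ds = SurvivalDataset((_rec(4, 0.5, conc=0.5, oxygen="hypoxic"),))
        with pytest.raises(ValueError, match="hrf"):
            fit_fdmso_points(ds, CHO)

    def test_round_trip_through_parametrized_factor(self):
        spec = GeneratorSpec(
            lethality=CHO, doses=(2.0, 4.0, 8.0),
            dmso_concs=(0.05, 0.1, 0.25, 0.5, 1.0, 2.0), noise_sigma_ln=0.0,
        )
        points = fit_fdmso_points(generate_dataset(spec), CHO)
        for conc, f_hat in points:
            assert f_hat == pytest.approx(f_dmso(conc), rel=1e-3)


class TestFitFdmsoCurve:
    def test_exact_points_recover_parametrization(self):
        concs = (0.05, 0.1, 0.25, 0.5, 1.0, 2.0)
        points = [(c, f_dmso(c)) for c in concs]
        res = fit_fdmso_curve(points)
        assert res.converged
        assert res.params["a_dmso"] == pytest.approx(0.9065, rel=1e-3)
        assert res.params["b_dmso"] == pytest.approx(0.4172, rel=1e-3)

    def test_flat_unity_points_flag_zero_scavenging(self):
        res = fit_fdmso_curve([(0.1, 1.0), (0.5, 1.0), (1.0, 1.0)])
        assert res.at_boundary
        assert res.params["a_dmso"] == pytest.approx(0.0, abs=1e-6)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError, match="2 distinct positive"):
            fit_fdmso_curve([(0.5, 0.5), (0.5, 0.51), (0.0, 1.0)])


class TestNoisyRecovery:
    def test_median_relative_error_under_noise(self):
        # CHO-like curves, 8 doses x 3 replicates, sigma_ln = 0.05
        true_hrf = 2.90
        errs = []
        for i in range(20):
            ds = generate_dataset(
                GeneratorSpec(
                    lethality=CHO, hrf=true_hrf, doses=tuple(np.linspace(1, 10, 8)),
                    dmso_concs=(0.0,), replicates=3, noise_sigma_ln=0.05,
                    seed=1000 + i,
                )
            )
            res = fit_lethality(ds.filter(oxygen="normoxic"))
            leth_hat = LethalityParams(res.params["k_idsb"], res.params["k_cdsb"])
            res_h = fit_hrf(ds.filter(oxygen="hypoxic"), leth_hat)
            errs.append(
                [
                    abs(res.params["k_idsb"] / CHO.k_idsb - 1),
                    abs(res.params["k_cdsb"] / CHO.k_cdsb - 1),
                    abs(res_h.params["hrf"] / true_hrf - 1),
                ]
            )
        assert np.all(np.median(errs, axis=0) <= 0.10)
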