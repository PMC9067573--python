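import math

import numpy as np
import pytest

from uniquacmc import (Dataset, ObservationRecord, PriorSpec, evaluate,
                       fit_map, fit_per_system_baseline, fit_vi, log_joint,
                       predict_records, select_hyperparameters,
                       split_by_system)
from uniquacmc.core import check_delta_consistency
from uniquacmc.constants import R_GAS
from uniquacmc.factorization import LatentFeatures
from uniquacmc.inference import (LN_SQRT_2PI, _Objective,
                                 read_observation_table, system_key,
                                 write_observation_table)
from uniquacmc.synthetic import (GeneratorConfig, generate_observations,
                                 generate_truth)


def _toy_record(**kw):
    defaults = dict(id_i="a", id_j="b", T=300.0, x_i=0.5,
                    ln_gamma_obs=0.2, record_type="finite")
    defaults.update(kw)
    return ObservationRecord(**defaults)


class TestRecordsAndSplits:
    def test_record_type_composition_coupling(self):
        with pytest.raises(ValueError):
            _toy_record(record_type="infinite_dilution", x_i=0.3)
        with pytest.raises(ValueError):
            _toy_record(record_type="finite", x_i=0.0)
        rec = _toy_record(record_type="infinite_dilution", x_i=0.0)
        assert rec.system_key == system_key("b", "a")

    def test_split_sizes_exact_fractions(self):
        records = [_toy_record(id_i=f"c{k}", id_j=f"d{k}") for k in range(10)]
        ds = split_by_system(Dataset(records), (0.8, 0.1, 0.1), seed=3)
        labels = list(ds.split_labels.values())
        assert labels.count("train") == 8
        assert labels.count("validation") == 1
        assert labels.count("test") == 1

    def test_split_deterministic(self):
        records = [_toy_record(id_i=f"c{k}", id_j=f"d{k}") for k in range(12)]
        a = split_by_system(Dataset(records), seed=7).split_labels
        b = split_by_system(Dataset(records), seed=7).split_labels
        assert a == b

    def test_no_system_straddles_partitions(self):
        records = []
        for k in range(9):
            for _ in range(3):
                records.append(_toy_record(id_i=f"c{k}", id_j=f"d{k}"))
        for seed in range(100):
            ds = split_by_system(Dataset(records), seed=seed)
            for split in ("train", "validation", "test"):
                sub = ds.subset(split)
                for rec in sub.records:
                    assert ds.label_of(rec.system_key) == split

    def test_observation_table_round_trip(self, tmp_path):
        records = [_toy_record(), _toy_record(id_i="b", id_j="a", x_i=0.0,
                                              record_type="infinite_dilution")]
        path = tmp_path / "obs.csv"
        write_observation_table(Dataset(records), path)
        back = read_observation_table(path)
        assert [r.record_type for r in back.records] == \
               ["finite", "infinite_dilution"]
        assert back.records[0].ln_gamma_obs == records[0].ln_gamma_obs


class TestLogJoint:
    def _features_and_geometries(self, dense_clean):
        truth, _ = dense_clean
        return truth.features, truth.geometries

    def test_prior_only_maximum_at_prior_mode(self, dense_clean):
        truth, _ = dense_clean
        priors = PriorSpec()
        K = truth.features.K
        n = len(truth.component_ids)
        mode = LatentFeatures(truth.component_ids,
                              np.zeros((n, K)), np.zeros((n, K)),
                              np.full(n, priors.like_energy_loc))
        got = log_joint(mode, Dataset([]), priors, truth.geometries)
        expected = (-2 * n * K * (math.log(priors.feature_scale) + LN_SQRT_2PI)
                    - n * (math.log(priors.like_energy_scale / R_GAS)
                           + LN_SQRT_2PI))
        assert got == pytest.approx(expected, rel=1e-12)
        # any perturbation decreases the prior density
        other = LatentFeatures(truth.component_ids,
                               np.full((n, K), 5.0), np.zeros((n, K)),
                               np.full(n, priors.like_energy_loc))
        assert log_joint(other, Dataset([]), priors, truth.geometries) < got

    def test_exactly_predicted_record_contributes_gaussian_mode(self, dense_clean):
        truth, _ = dense_clean
        priors = PriorSpec()
        f = truth.features
        rec = ObservationRecord(id_i=truth.component_ids[0],
                                id_j=truth.component_ids[1],
                                T=320.0, x_i=0.4, ln_gamma_obs=0.0)
        pred = predict_records(f, truth.geometries, [rec])[0]
        exact = ObservationRecord(id_i=rec.id_i, id_j=rec.id_j, T=rec.T,
                                  x_i=rec.x_i, ln_gamma_obs=float(pred))
        with_rec = log_joint(f, Dataset([exact]), priors, truth.geometries)
        without = log_joint(f, Dataset([]), priors, truth.geometries)
        assert with_rec - without == pytest.approx(
            -math.log(priors.likelihood_scale) - LN_SQRT_2PI, rel=1e-10)

    def test_analytic_gradient_matches_finite_differences(self, dense_clean):
        truth, dataset = dense_clean
        obj = _Objective(dataset.records[:40], truth.component_ids,
                         truth.geometries, PriorSpec(), K=2)
        rng = np.random.default_rng(17)
        p = rng.normal(0, 0.5, obj.dim)
        _, grad = obj.value_and_grad(p)
        h = 1e-6
        for k in rng.choice(obj.dim, size=20, replace=False):
            e = np.zeros(obj.dim)
            e[k] = h
            fd = (obj.value_and_grad(p + e)[0]
                  - obj.value_and_grad(p - e)[0]) / (2 * h)
            # abs floor covers the cancellation noise of the central
            # difference, ~eps * |f| / h
            assert grad[k] == pytest.approx(fd, rel=1e-4, abs=3e-5)

    def test_unknown_component_rejected(self, dense_clean):
        truth, _ = dense_clean
        rec = ObservationRecord(id_i="nope", id_j=truth.component_ids[0],
                                T=300.0, x_i=0.5, ln_gamma_obs=0.0)
        with pytest.raises(KeyError):
            log_joint(truth.features, Dataset([rec]), PriorSpec(),
                      truth.geometries)


class TestFitMap:
    def test_interpolates_noise_free_data(self, dense_clean_map_fit):
        truth, dataset, summary = dense_clean_map_fit
        metrics = evaluate(summary, dataset, truth.geometries, "train")
        assert metrics["MAE"] < 0.01

    def test_deterministic_given_seed(self, dense_clean_map_fit):
        truth, dataset, summary = dense_clean_map_fit
        again = fit_map(dataset, PriorSpec(), truth.geometries,
                        truth.config.K_true, seed=4)
        np.testing.assert_array_equal(summary.U_mean, again.U_mean)

    def test_test_records_do_not_influence_fit(self, dense_clean_map_fit):
        truth, dataset, summary = dense_clean_map_fit
        tampered = []
        for rec in dataset.records:
            if dataset.label_of(rec.system_key) == "test":
                tampered.append(ObservationRecord(
                    id_i=rec.id_i, id_j=rec.id_j, T=rec.T, x_i=rec.x_i,
                    ln_gamma_obs=rec.ln_gamma_obs + 50.0,
                    record_type=rec.record_type))
            else:
                tampered.append(rec)
        refit = fit_map(Dataset(tampered, dataset.split_labels), PriorSpec(),
                        truth.geometries, truth.config.K_true, seed=4,
                        roster=dataset.component_ids())
        np.testing.assert_array_equal(summary.U_mean, refit.U_mean)

    def test_weaker_likelihood_does_not_improve_fit(self, dense_clean_map_fit):
        truth, dataset, summary = dense_clean_map_fit
        loose = fit_map(dataset, PriorSpec(likelihood_scale=0.3),
                        truth.geometries, truth.config.K_true, seed=4)
        tight_mae = evaluate(summary, dataset, truth.geometries, "train")["MAE"]
        loose_mae = evaluate(loose, dataset, truth.geometries, "train")["MAE"]
        assert loose_mae >= tight_mae - 1e-9

    def test_map_summary_reports_zero_sd(self, dense_clean_map_fit):
        _, _, summary = dense_clean_map_fit
        assert np.all(summary.U_sd == 0.0)
        assert np.all(summary.like_sd == 0.0)


@pytest.fixture(scope="module")
def vi_setup(dense_clean_map_fit):
    truth, dataset, map_summary = dense_clean_map_fit
    vi_summary = fit_vi(dataset, PriorSpec(), truth.geometries,
                        truth.config.K_true, seed=4, n_iter=3000,
                        n_samples=8, learning_rate=0.005,
                        init_summary=map_summary)
    return truth, dataset, map_summary, vi_summary


class TestFitVI:

    def test_vi_means_agree_with_map_within_2sd(self, vi_setup):
        truth, dataset, map_summary, vi = vi_setup
        n = len(vi.component_ids)
        agree = total = 0
        for a in range(n):
            for b in range(a + 1, n):
                total += 1
                sd = max(vi.U_sd[a, b], 1e-6)
                if abs(vi.U_mean[a, b] - map_summary.U_mean[a, b]) <= 2 * sd:
                    agree += 1
        assert agree / total >= 0.95

    def test_observed_pairs_have_smaller_sd_than_unobserved(self):
        config = GeneratorConfig(N_components=10, K_true=2,
                                 observed_system_fraction=0.55,
                                 records_per_system=12, noise_scale=0.05,
                                 seed=19)
        truth = generate_truth(config)
        dataset = split_by_system(generate_observations(truth),
                                  (0.8, 0.1, 0.1), seed=2)
        vi = fit_vi(dataset, PriorSpec(), truth.geometries, 2, seed=3,
                    n_iter=1500, roster=truth.component_ids)
        ids = vi.component_ids
        observed = set(dataset.system_keys())
        sd_obs, sd_unobs = [], []
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                target = (sd_obs if system_key(ids[a], ids[b]) in observed
                          else sd_unobs)
                target.append(vi.U_sd[a, b])
        assert np.median(sd_obs) < np.median(sd_unobs)

    def test_priors_only_recovers_prior_moments(self, dense_clean):
        truth, _ = dense_clean
        priors = PriorSpec()
        vi = fit_vi(Dataset([]), priors, truth.geometries, 2, seed=5,
                    roster=truth.component_ids, n_iter=800)
        # prior means are zero for features and like energies
        assert np.abs(vi.mean.theta).max() < 0.25 * np.median(vi.theta_sd)
        assert np.abs(vi.mean.like_energies).max() < \
            0.25 * np.median(vi.like_sd)
        # and the variational sd approaches the prior sd
        assert np.median(vi.like_sd) == pytest.approx(
            priors.like_energy_scale, rel=0.25)


class TestBaselines:
    def test_noise_free_symmetric_truth_fits_exactly(self, dense_clean):
        truth, dataset = dense_clean
        for mode in ("U", "deltaU"):
            fit = fit_per_system_baseline(dataset, truth.geometries, mode)
            assert fit.train_mae < 1e-4, mode

    def test_asymmetric_baseline_at_least_as_flexible(self, noisy_small):
        truth, dataset = noisy_small
        fit_u = fit_per_system_baseline(dataset, truth.geometries, "U")
        fit_d = fit_per_system_baseline(dataset, truth.geometries, "deltaU")
        assert fit_d.train_mse <= fit_u.train_mse + 1e-12

    def test_parameter_counts_by_mode(self, noisy_small):
        truth, dataset = noisy_small
        fit_u = fit_per_system_baseline(dataset, truth.geometries, "U")
        fit_d = fit_per_system_baseline(dataset, truth.geometries, "deltaU")
        n_sys = len({r.system_key for r in dataset.subset("train").records})
        n_comp = len({c for key in
                      {r.system_key for r in dataset.subset("train").records}
                      for c in key.split("|")})
        assert fit_d.n_parameters() == 2 * n_sys
        assert fit_u.n_parameters() == n_sys + n_comp

    def test_independent_delta_fits_break_symmetry_consistency(self):
        """Fitting two difference parameters per system independently on
        noisy data yields values that cannot come from any single
        symmetric energy matrix."""
        config = GeneratorConfig(N_components=3, K_true=2,
                                 observed_system_fraction=1.0,
                                 records_per_system=30, noise_scale=0.1,
                                 seed=29)
        truth = generate_truth(config)
        dataset = Dataset(generate_observations(truth).records)  # all train
        fit = fit_per_system_baseline(dataset, truth.geometries, "deltaU")
        report = check_delta_consistency(fit.to_asymmetric_set())
        assert not report.consistent

    def test_baseline_cannot_predict_unfitted_system(self, noisy_small):
        truth, dataset = noisy_small
        fit = fit_per_system_baseline(dataset, truth.geometries, "deltaU")
        test_records = dataset.subset("test").records
        with pytest.raises(KeyError):
            predict_records(fit, truth.geometries, test_records)


class TestEvaluate:
    def test_perfect_predictions_give_zero_error(self, dense_clean):
        truth, dataset = dense_clean
        metrics = evaluate(truth.features, dataset, truth.geometries)
        # noise-free data generated from these exact parameters
        assert metrics["MAE"] == pytest.approx(0.0, abs=1e-10)
        assert metrics["MSE"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_closed_form(self, dense_clean):
        truth, dataset = dense_clean
        delta = 0.37
        shifted = Dataset([ObservationRecord(
            id_i=r.id_i, id_j=r.id_j, T=r.T, x_i=r.x_i,
            ln_gamma_obs=r.ln_gamma_obs + delta, record_type=r.record_type)
            for r in dataset.records])
        metrics = evaluate(truth.features, shifted, truth.geometries)
        assert metrics["MAE"] == pytest.approx(delta, abs=1e-9)
        assert metrics["MSE"] == pytest.approx(delta ** 2, abs=1e-9)

    def test_mae_bounded_by_rms(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            err = rng.normal(0, rng.uniform(0.1, 5.0), size=100)
            mae = np.abs(err).mean()
            mse = (err ** 2).mean()
            assert mae <= math.sqrt(mse) + 1e-12

    def test_empty_split_rejected(self, dense_clean):
        truth, dataset = dense_clean
        no_labels = Dataset(dataset.records, {})
        with pytest.raises(ValueError):
            evaluate(truth.features, no_labels, truth.geometries, "test")


class TestHyperparameterSelection:
    def test_single_point_grid_returned(self, dense_clean):
        truth, dataset = dense_clean
        best, results = select_hyperparameters(
            dataset, truth.geometries, [{"K": 2}], seed=4)
        assert best == {"K": 2}
        assert len(results) == 1

    def test_argmin_contract(self, dense_clean):
        truth, dataset = dense_clean
        best, results = select_hyperparameters(
            dataset, truth.geometries,
            [{"K": 1}, {"K": 2}], seed=4)
        best_mae = min(r["validation_MAE"] for r in results)
        chosen = next(r for r in results if r["config"] == best)
        assert chosen["validation_MAE"] == best_mae

    def test_empty_validation_rejected(self, dense_clean):
        truth, dataset = dense_clean
        no_val = Dataset(dataset.records,
                         {k: "train" for k in dataset.split_labels})
        with pytest.raises(ValueError):
            select_hyperparameters(no_val, truth.geometries, [{"K": 2}],
                                   seed=1)
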