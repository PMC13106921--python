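import numpy as np
import pandas as pd
import pytest

from ucepi.alignments import LocusAlignment
from ucepi.errors import NoDataError, ParameterError
from ucepi.estimators import (
    UCEDiversityEstimator,
    build_stacked_profile,
    fit_concatenated,
    fit_stacked,
    subsample_individuals,
    subsample_loci,
)
from ucepi.models import GompertzParams, gompertz_eval
from ucepi.simulate import SimConfig, simulate_dataset
from ucepi.sites import dataset_site_stats, locus_site_stats

STD = GompertzParams(0.005, 10.0, 0.009)


def profile_from_curve(params=STD, flank=750):
    """Noise-free stacked profile sampled exactly from the curve."""
    from ucepi.estimators import StackedProfile

    i = np.arange(-flank, flank + 1)
    return StackedProfile(
        positions=i,
        mean_pi=gompertz_eval(i, params),
        n=np.full(i.shape, 1000),
        k=np.full(i.shape, 100),
    )


class TestBuildStackedProfile:
    def test_single_locus_equals_its_profile(self, small_loci):
        stats = locus_site_stats(small_loci[0])
        prof = build_stacked_profile(stats)
        merged = pd.DataFrame({"position": prof.positions, "mean_pi": prof.mean_pi})
        joined = stats.merge(merged, on="position")
        np.testing.assert_allclose(joined["pi"], joined["mean_pi"])

    def test_positionwise_mean_adjusts_for_missing_loci(self):
        # locus b has an all-gap column at position +1: the mean there must
        # divide by 1 (locus a only), not 2
        a = LocusAlignment("a", ["x", "y"], np.array([[b"A", b"C", b"C"], [b"A", b"C", b"T"]]))
        b = LocusAlignment("b", ["x", "y"], np.array([[b"A", b"C", b"-"], [b"A", b"C", b"-"]]))
        prof = build_stacked_profile(dataset_site_stats([a, b]))
        at1 = prof.mean_pi[prof.positions == 1][0]
        assert at1 == 1.0  # not 0.5
        assert prof.k[prof.positions == 1][0] == 1

    def test_mean_matches_brute_force_recount(self, messy_loci):
        stats = dataset_site_stats(messy_loci)
        prof = build_stacked_profile(stats)
        by_pos = {}
        for _, row in stats.iterrows():
            by_pos.setdefault(row.position, []).append(row.pi)
        for pos, mean, n_loci in zip(prof.positions, prof.mean_pi, prof.k):
            vals = by_pos[pos]
            assert len(vals) == n_loci
            assert mean == pytest.approx(np.mean(vals), rel=1e-12)

    def test_delta_excludes_positions(self, messy_loci):
        stats = dataset_site_stats(messy_loci)
        full = build_stacked_profile(stats, delta=0)
        cut = build_stacked_profile(stats, delta=int(np.median(full.n)))
        assert set(cut.positions) <= set(full.positions)
        assert cut.n.min() >= int(np.median(full.n))

    def test_all_excluded_raises(self, small_loci):
        with pytest.raises(NoDataError):
            build_stacked_profile(dataset_site_stats(small_loci), delta=10**9)


class TestFitStacked:
    def test_noise_free_exact_recovery(self):
        fit = fit_stacked(profile_from_curve())
        assert fit.theta_hat == pytest.approx(STD.theta, rel=1e-4)
        assert fit.params["beta"] == pytest.approx(STD.beta, rel=1e-4)
        assert fit.params["gamma"] == pytest.approx(STD.gamma, rel=1e-4)

    def test_all_zero_profile_pins_theta_at_lower_bound(self):
        prof = profile_from_curve()
        prof.mean_pi = np.zeros_like(prof.mean_pi)
        fit = fit_stacked(prof)
        assert fit.theta_hat == pytest.approx(0.0, abs=1e-5)

    def test_too_few_positions(self):
        prof = profile_from_curve(flank=3)
        with pytest.raises(NoDataError):
            fit_stacked(prof)

    def test_parameter_recovery_across_seeds(self):
        # moderate-size generator runs: theta recovered within 10%
        for seed in range(3):
            loci = simulate_dataset(SimConfig(k=300, n=10, flank=750, seed=seed))
            fit = fit_stacked(build_stacked_profile(dataset_site_stats(loci)))
            assert abs(fit.theta_hat - 0.005) / 0.005 <= 0.10


class TestFitConcatenated:
    def test_duplicated_locus_gives_same_fit(self, small_loci):
        one = dataset_site_stats(small_loci[:1])
        k = 5
        dup = pd.concat(
            [one.assign(locus_id=f"copy{j}") for j in range(k)], ignore_index=True
        )
        f1 = fit_concatenated(one)
        fk = fit_concatenated(dup)
        assert fk.theta_hat == pytest.approx(f1.theta_hat, rel=1e-6)
        # objective scales by the duplication factor
        assert fk.objective == pytest.approx(k * f1.objective, rel=1e-6)

    def test_descent_from_initial_point(self, messy_loci):
        from ucepi.models import GompertzRegressor

        stats = dataset_site_stats(messy_loci)
        reg = GompertzRegressor().fit(
            stats["position"].to_numpy(float),
            stats["pi"].to_numpy(float),
            sample_weight=stats["weight"].to_numpy(float),
        )
        assert reg.objective_ <= reg.initial_objective_

    def test_agrees_with_stacked_on_complete_data(self, small_loci):
        stats = dataset_site_stats(small_loci)
        s = fit_stacked(build_stacked_profile(stats))
        c = fit_concatenated(stats)
        assert abs(c.theta_hat - s.theta_hat) / s.theta_hat <= 0.05


class TestUCEDiversityEstimator:
    def test_pipeline_stacked(self, messy_loci):
        est = UCEDiversityEstimator(mode="stacked").fit(messy_loci)
        assert est.theta_ > est.uncorrected_pi_
        assert est.result_.mode == "stacked"
        assert est.n_loci_ <= len(messy_loci)

    def test_predict_evaluates_fitted_curve(self, small_loci):
        est = UCEDiversityEstimator().fit(small_loci)
        far = est.predict([10**6])[0]
        assert far == pytest.approx(est.theta_, rel=1e-9)

    def test_flank_trim_reduces_sites(self, small_loci):
        full = UCEDiversityEstimator(delta=0).fit(small_loci)
        trimmed = UCEDiversityEstimator(delta=0, flank=100).fit(small_loci)
        assert trimmed.n_sites_ < full.n_sites_
        assert trimmed.n_sites_ <= 2 * 100 + 1

    def test_unknown_mode_rejected(self, small_loci):
        with pytest.raises(ParameterError):
            UCEDiversityEstimator(mode="mixed").fit(small_loci)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = UCEDiversityEstimator(mode="concatenated", model="plf", delta=5)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_deterministic(self, small_loci):
        t1 = UCEDiversityEstimator().fit(small_loci).theta_
        t2 = UCEDiversityEstimator().fit(small_loci).theta_
        assert t1 == t2


class TestSubsampling:
    def test_full_size_identical_to_unsubsampled(self, small_loci):
        table = subsample_loci(small_loci, [len(small_loci)], replicates=2, seed=4)
        direct = fit_stacked(
            build_stacked_profile(dataset_site_stats(small_loci))
        ).theta_hat
        assert set(table["theta_hat"]) == {direct}

    def test_same_seed_reproducible(self, small_loci):
        t1 = subsample_loci(small_loci, [10, 20], replicates=3, seed=7)
        t2 = subsample_loci(small_loci, [10, 20], replicates=3, seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_oversized_subset_rejected(self, small_loci):
        with pytest.raises(ParameterError):
            subsample_loci(small_loci, [len(small_loci) + 1])

    def test_individual_subsets(self, small_loci):
        table = subsample_individuals(small_loci, [4, 8], replicates=2, seed=1)
        assert set(table["size"]) == {4, 8}
        assert np.isfinite(table["theta_hat"]).all()
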