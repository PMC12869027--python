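import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patquant import (FluenceVolume, LesionFeature, PhantomSpec, PressureMap,
                      build_phantom, classify_lesions, cluster_cross_sections,
                      forward_pressure, rank_compensators,
                      simulate_lesion_cohort, thb_ratio, uniformity_std)
from patquant.errors import ConfigurationError
from patquant.unmix import HB_PAIR

from conftest import make_synthetic_eigenspectra


class TestClusterCrossSections:
    def _disk_map(self, grid, centers, nz=40, nx=40, amp=1.0):
        images = np.zeros((len(grid), nz, nx))
        yy, xx = np.mgrid[:nz, :nx]
        for (cz, cx) in centers:
            images[:, (yy - cz) ** 2 + (xx - cx) ** 2 <= 9] = amp
        return PressureMap(grid, images, 0.5)

    def test_two_disks_two_clusters(self, phantom_grid):
        m = self._disk_map(phantom_grid, [(10, 10), (30, 30)])
        cs = cluster_cross_sections(m, amplitude_threshold=0.5)
        assert len(cs) == 2

    def test_threshold_above_maximum_gives_empty_set(self, phantom_grid):
        m = self._disk_map(phantom_grid, [(10, 10)])
        cs = cluster_cross_sections(m, amplitude_threshold=2.0)
        assert len(cs) == 0

    def test_fifteen_rendered_cross_sections_recovered(self, table, phantom_grid):
        """Forward map of the 15-tube phantom under a constructed uniform
        fluence: clustering recovers exactly the rendered cross-sections."""
        spec = PhantomSpec.tube()
        phantom, truth = build_phantom(spec, table, phantom_grid)
        fl = FluenceVolume(phantom_grid, np.ones_like(phantom.mu_a),
                           phantom.voxel_size_mm, 1000, 0)
        m = forward_pressure(phantom, fl, noise_snr_db=40.0, seed=1)
        cs = cluster_cross_sections(m, amplitude_threshold_quantile=0.97,
                                    min_pixels=8)
        assert len(cs) == len(truth.table) == 15

    def test_cluster_mean_depth_and_spectrum(self, phantom_grid):
        m = self._disk_map(phantom_grid, [(20, 20)], amp=2.5)
        cs = cluster_cross_sections(m, amplitude_threshold=1.0)
        cl = cs.clusters[0]
        assert cl.mean_depth_cm == pytest.approx(20 * 0.05, abs=0.01)
        np.testing.assert_allclose(cl.mean_spectrum.amplitudes, 2.5)


class TestUniformityStd:
    def test_exact_values(self):
        assert uniformity_std([5.0, 5.0, 5.0]) == 0.0
        assert uniformity_std([1.0, 3.0]) == 1.0  # divisor n, not n-1
        assert uniformity_std([2.0, 4.0, 6.0, 8.0]) == pytest.approx(np.sqrt(5))

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            uniformity_std([1.0])

    @settings(deadline=None, derandomize=True)
    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
    def test_translation_invariance_and_linear_scaling(self, shift, scale):
        v = np.array([0.3, 1.2, 0.8, 2.0])
        base = uniformity_std(v)
        assert uniformity_std(v + shift) == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert uniformity_std(scale * v) == pytest.approx(scale * base, rel=1e-9)


class TestThbRatio:
    def test_exact_values(self):
        assert thb_ratio([2.0], [2.0]) == 1.0
        assert thb_ratio([4.0, 2.0], [2.0, 1.0]) == 2.0

    def test_domain(self):
        with pytest.raises(ValueError):
            thb_ratio([], [1.0])
        with pytest.raises(ValueError):
            thb_ratio([1.0], [0.0])

    def test_cohort_round_trip_recovers_designed_ratio(self):
        """The cohort generator plants a malignant/benign THb ratio of 1.9 in
        the compensated view; the mean recovered ratio over 20 seeded cohorts
        stays within 10%."""
        ratios = []
        for seed in range(20):
            cohort = simulate_lesion_cohort(seed)["isdc"]
            mal = [f.mean_thb_rel for f in cohort if f.class_label == "malignant"]
            ben = [f.mean_thb_rel for f in cohort if f.class_label == "benign"]
            ratios.append(thb_ratio(mal, ben))
        assert np.mean(ratios) == pytest.approx(1.9, rel=0.10)


class TestRankCompensators:
    def _study(self, table, grid, slopes, fluences_from=0):
        eig = make_synthetic_eigenspectra(grid, slopes=slopes)
        truths = [20.0, 50.0, 80.0]
        fluences = [eig.spectra[fluences_from]]
        return eig, rank_compensators(eig, table, HB_PAIR, truths, fluences)

    def test_perfect_compensator_ranks_first_everywhere(self, table, phantom_grid):
        eig, report = self._study(table, phantom_grid,
                                  slopes=(-0.002, 0.0008), fluences_from=0)
        row = report.table[report.table["name"] == "phi_1"].iloc[0]
        assert row["mae"] == pytest.approx(0.0, abs=1e-9)
        for metric in ("mae", "rmse", "robustness", "consistency", "composite"):
            assert report.rank_of("phi_1", metric) == 1

    def test_dominated_candidate_ranks_last(self, table, phantom_grid):
        eig, report = self._study(table, phantom_grid,
                                  slopes=(-0.003, -0.0029), fluences_from=0)
        # the exact compensator dominates every metric; the rest follow in a
        # strict ordering
        assert report.rank_of("phi_1", "composite") == 1
        assert (report.table["rank_composite"].sort_values().to_numpy()
                == np.arange(1, 4)).all()

    def test_ranks_are_a_permutation(self, table, phantom_grid, synthetic_eig):
        from patquant.pipeline import in_cone_fluences
        fluences = in_cone_fluences(synthetic_eig, 5, seed=3)
        report = rank_compensators(synthetic_eig, table, HB_PAIR,
                                   [10.0, 50.0, 90.0], fluences)
        n = len(report.table)
        for metric in ("mae", "rmse", "robustness", "consistency", "composite"):
            assert sorted(report.table[f"rank_{metric}"]) == list(range(1, n + 1))

    def test_permutation_equivariance(self, table, phantom_grid):
        """Relabeling the candidate spectra permutes the metrics with them."""
        from patquant import EigenspectraSet
        eig = make_synthetic_eigenspectra(phantom_grid,
                                          slopes=(-0.002, -0.0005, 0.001))
        rev = EigenspectraSet(list(reversed(eig.spectra)), eig.phi_ave,
                              eig.reference_wavelength)
        truths = [20.0, 60.0, 90.0]
        fl = [eig.spectra[0], eig.spectra[2]]
        a = rank_compensators(eig, table, HB_PAIR, truths, fl).table
        b = rank_compensators(rev, table, HB_PAIR, truths, fl).table
        for i in range(3):
            ra = a[a["name"] == f"phi_{i + 1}"].iloc[0]
            rb = b[b["name"] == f"phi_{3 - i}"].iloc[0]
            assert ra["mae"] == pytest.approx(rb["mae"], abs=1e-12)
            assert ra["rmse"] == pytest.approx(rb["rmse"], abs=1e-12)

    def test_single_truth_rejected(self, table, phantom_grid, synthetic_eig):
        with pytest.raises(ConfigurationError):
            rank_compensators(synthetic_eig, table, HB_PAIR, [50.0],
                              [synthetic_eig.spectra[0]])


def cohort_features(sep, n=40, seed=0):
    rng = np.random.default_rng(seed)
    feats = []
    for i in range(n):
        malignant = i < n // 3
        so2 = rng.normal(60 - sep * malignant, 5)
        thb = rng.normal(1 + 0.5 * malignant, 0.2)
        feats.append(LesionFeature(f"l{i}", float(np.clip(so2, 0, 100)),
                                   float(max(thb, 0.01)),
                                   "malignant" if malignant else "benign"))
    return feats


class TestClassifyLesions:
    def test_perfect_separation_auc_one(self):
        feats = [LesionFeature(f"a{i}", 90.0, 1.0, "benign") for i in range(8)] \
            + [LesionFeature(f"b{i}", 40.0, 1.0, "malignant") for i in range(8)]
        assert classify_lesions(feats, "so2")["auc"] == 1.0

    def test_uninformative_feature_auc_half(self):
        feats = [LesionFeature(f"a{i}", 70.0, 1.0,
                               "benign" if i % 2 else "malignant")
                 for i in range(20)]
        assert classify_lesions(feats, "both")["auc"] == pytest.approx(0.5)

    def test_auc_equals_rank_statistic(self):
        """Dual-route check: the reported AUC equals the Mann-Whitney
        probability computed directly from the fitted scores."""
        feats = cohort_features(sep=12)
        res = classify_lesions(feats, "both")
        coefs = np.array(res["coefficients"]["coef"])
        mu = np.array(res["coefficients"]["standardize_mean"])
        sd = np.array(res["coefficients"]["standardize_std"])
        x = np.array([[f.mean_so2_pct, f.mean_thb_rel] for f in feats])
        scores = ((x - mu) / sd) @ coefs
        y = np.array([f.class_label == "malignant" for f in feats])
        pos, neg = scores[y], scores[~y]
        mw = (np.mean(pos[:, None] > neg[None, :])
              + 0.5 * np.mean(pos[:, None] == neg[None, :]))
        assert res["auc"] == pytest.approx(mw, abs=1e-12)

    def test_roc_is_monotone_staircase(self):
        res = classify_lesions(cohort_features(sep=8), "both")
        roc = res["roc_points"]
        assert np.all(np.diff(roc["fpr"]) >= 0)
        assert np.all(np.diff(roc["tpr"]) >= 0)
        assert roc["fpr"].iloc[-1] == 1.0 and roc["tpr"].iloc[-1] == 1.0

    def test_contract_violations(self):
        few = cohort_features(sep=10)[:5]
        with pytest.raises(ValueError):
            classify_lesions(few)
        single = [LesionFeature(f"x{i}", 50.0, 1.0, "benign") for i in range(12)]
        with pytest.raises(ValueError):
            classify_lesions(single)

    def test_paired_views_preserve_lesion_ids(self):
        cohort = simulate_lesion_cohort(0)
        ids_i = [f.lesion_id for f in cohort["isdc"]]
        ids_l = [f.lesion_id for f in cohort["lu"]]
        assert ids_i == ids_l
        assert sum(f.class_label == "malignant" for f in cohort["isdc"]) == 15
        assert sum(f.class_label == "benign" for f in cohort["isdc"]) == 67
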