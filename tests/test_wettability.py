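import numpy as np
import pytest
from scipy import stats as sps

import clearwing as cw
from clearwing.errors import FitError, NoContactError, ValidationError
from clearwing.wettability import DropletContour, read_contour_csv


def cap_contour(theta, radius=500.0, n=100, seed=0, noise_frac=0.0):
    return cw.synth_droplet_contour(theta, radius, n, cw.GeneratorConfig(seed=seed), noise_frac)


class TestContactAngle:
    def test_semicircle_gives_90_degrees(self):
        res = cw.contact_angle(cap_contour(90.0))
        assert res.theta_left_deg == pytest.approx(90.0, abs=1e-6)
        assert res.theta_right_deg == pytest.approx(90.0, abs=1e-6)

    def test_center_at_half_radius_gives_120(self):
        # circle center at height r/2 above the baseline: closed-form 120 deg
        res = cw.contact_angle(cap_contour(120.0))
        assert res.theta_mean_deg == pytest.approx(120.0, abs=1e-6)

    @pytest.mark.parametrize("theta", [60.0, 90.0, 114.0, 145.0, 170.0])
    def test_noiseless_recovery_sweep(self, theta):
        res = cw.contact_angle(cap_contour(theta))
        assert res.theta_mean_deg == pytest.approx(theta, abs=0.1)

    @pytest.mark.parametrize("theta", [60.0, 90.0, 114.0, 145.0, 170.0])
    def test_noisy_recovery_within_one_degree(self, theta):
        res = cw.contact_angle(cap_contour(theta, n=200, seed=11, noise_frac=0.005))
        assert res.theta_mean_deg == pytest.approx(theta, abs=1.0)

    def test_scale_and_translation_invariance(self):
        base = cap_contour(145.0, n=150, seed=5, noise_frac=0.003)
        theta0 = cw.contact_angle(base).theta_mean_deg
        moved = DropletContour(base.points * 3.7 + np.array([120.0, 48.0]),
                               baseline=3.7 * base.baseline + 48.0)
        assert cw.contact_angle(moved).theta_mean_deg == pytest.approx(theta0, abs=1e-9)

    def test_mean_is_average_of_left_and_right(self):
        res = cw.contact_angle(cap_contour(114.0))
        assert res.theta_mean_deg == pytest.approx(
            0.5 * (res.theta_left_deg + res.theta_right_deg), abs=1e-12
        )

    def test_floating_circle_raises_no_contact(self):
        phi = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts = np.column_stack([100 * np.cos(phi), 1000.0 + 100 * np.sin(phi)])
        with pytest.raises(NoContactError):
            cw.contact_angle(DropletContour(pts, baseline=0.0))

    def test_collinear_points_raise_fit_error(self):
        pts = np.column_stack([np.linspace(0, 100, 30), np.full(30, 50.0)])
        with pytest.raises(FitError):
            cw.contact_angle(DropletContour(pts, baseline=0.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            DropletContour(np.random.default_rng(0).uniform(0, 1, (6, 2)), baseline=0.0)


class TestCompareGroups:
    def test_symmetric_differences_give_p_one(self):
        b = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        a = b + np.array([-1.0, 1.0, -2.0, 2.0, 0.0])
        res = cw.compare_groups(a, b, paired=True)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_worked_example_against_distribution_oracle(self):
        # paired differences (1,2,3,4,5): t = 3 / (sqrt(2.5)/sqrt(5)) = 4.2426
        b = np.zeros(5)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = cw.compare_groups(a, b, paired=True)
        assert res.t == pytest.approx(4.2426, abs=1e-4)
        assert res.df == 4
        assert res.p == pytest.approx(0.0132, abs=1e-3)
        # independent oracle: scipy's own paired t-test
        oracle = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(oracle.statistic, abs=1e-12)
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_five_paired_droplets_have_four_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        res = cw.compare_groups(rng.normal(145, 3, 5), rng.normal(114, 7, 5), paired=True)
        assert res.df == 4

    def test_unpaired_pooled_variance_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(145, 3, 5), rng.normal(114, 7, 6)
        res = cw.compare_groups(a, b, paired=False)
        oracle = sps.ttest_ind(a, b, equal_var=True)
        assert res.df == 9
        assert res.t == pytest.approx(oracle.statistic, abs=1e-12)
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_degenerate_zero_variance(self):
        same = np.full(5, 100.0)
        assert cw.compare_groups(same, same, paired=True).p == 1.0
        with pytest.raises(ValidationError):
            cw.compare_groups(same, same + 5.0, paired=True)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValidationError):
            cw.compare_groups([1.0], [2.0])


class TestClassification:
    @pytest.mark.parametrize(
        "theta,label",
        [
            (93.0, "hydrophobic"),
            (145.0, "hydrophobic"),
            (150.0, "hydrophobic"),
            (150.01, "superhydrophobic"),
            (90.0, "hydrophilic"),
            (45.0, "hydrophilic"),
        ],
    )
    def test_thresholds(self, theta, label):
        assert cw.classify_wettability(theta) == label

    def test_out_of_range_rejected(self):
        for theta in (0.0, 180.0, -10.0):
            with pytest.raises(ValidationError):
                cw.classify_wettability(theta)


class TestGroupOrdering:
    def test_printed_group_ordering_is_stable_across_seeds(self):
        """black > transparent > scale-removed for synthetic groups at the
        printed means/sds (145/3.2, 114/6.9, 93/11.1; n = 5)."""
        ok = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            means = {}
            for region, (mu, sd) in (
                ("black", (145.0, 3.2)),
                ("transparent", (114.0, 6.9)),
                ("scale_removed", (93.0, 11.1)),
            ):
                thetas = rng.normal(mu, sd, 5)
                fitted = [
                    cw.contact_angle(cap_contour(t, n=120, seed=seed * 10 + i, noise_frac=0.005)).theta_mean_deg
                    for i, t in enumerate(thetas)
                ]
                means[region] = np.mean(fitted)
            if means["black"] > means["transparent"] > means["scale_removed"]:
                ok += 1
        assert ok / n_seeds >= 0.98


def test_contour_csv_round_trip(tmp_path):
    contour = cap_contour(114.0, n=80, seed=4, noise_frac=0.002)
    path = tmp_path / "c.csv"
    import pandas as pd

    with open(path, "w", newline="") as fh:
        fh.write("# baseline: 0.0\n")
        pd.DataFrame(contour.points, columns=["x", "y"]).to_csv(fh, index=False)
    back = read_contour_csv(path)
    assert cw.contact_angle(back).theta_mean_deg == pytest.approx(
        cw.contact_angle(contour).theta_mean_deg, abs=1e-5
    )
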