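"""Information metrics and the four signed scoring functions."""

import numpy as np
import pytest

from oracles import brute_force_scores
from siren import (
    CliqueSpec,
    DiscretizationConfig,
    JointDistribution,
    ScoreConfig,
    build_rescaling_matrix,
    joint_distribution,
    make_insilico_clique,
    membership_matrix,
    mutual_information,
    npmi_grid,
    pearson_sign_score,
    pmi_grid,
    score_s1,
    score_s2,
    score_s3,
    score_s4,
    siren_score,
)


def jd_from_grid(joint):
    return JointDistribution(joint=np.asarray(joint, dtype=float), n_samples=100)


def random_jd(rng, config):
    mx = membership_matrix(rng.normal(size=50), config)
    my = membership_matrix(rng.normal(size=50), config)
    return joint_distribution(mx, my)


@pytest.fixture
def toy_jd():
    joint = np.array([[0.25, 0.05, 0.0], [0.05, 0.3, 0.05], [0.0, 0.05, 0.25]])
    return jd_from_grid(joint)


class TestPmiNpmi:
    def test_independence_gives_zero_everywhere(self):
        b = 4
        jd = jd_from_grid(np.full((b, b), 1 / b**2))
        np.testing.assert_allclose(pmi_grid(jd, 2), 0.0, atol=1e-12)
        np.testing.assert_allclose(npmi_grid(jd, 2), 0.0, atol=1e-12)

    def test_diagonal_joint_gives_log_b(self):
        b = 8
        jd = jd_from_grid(np.eye(b) / b)
        diag = np.diag(pmi_grid(jd, 2))
        np.testing.assert_allclose(diag, np.log2(b), atol=1e-12)

    def test_perfect_association_npmi_is_one(self):
        jd = jd_from_grid(np.diag([0.2, 0.5, 0.3]))
        diag = np.diag(npmi_grid(jd, 2))
        np.testing.assert_allclose(diag, 1.0, atol=1e-12)

    def test_all_mass_single_cell_npmi_is_one(self):
        joint = np.zeros((3, 3))
        joint[1, 1] = 1.0
        grid = npmi_grid(jd_from_grid(joint), 10)
        assert grid[1, 1] == 1.0

    def test_toy_grid_matches_hand_computation(self, toy_jd):
        grid = pmi_grid(toy_jd, 2)
        # cell (0,0): p=0.25, px=0.3, py=0.3
        assert grid[0, 0] == pytest.approx(np.log2(0.25 / 0.09))
        # zero-mass cell zeroed by convention
        assert grid[0, 2] == 0.0
        ngrid = npmi_grid(toy_jd, 2)
        assert ngrid[1, 1] == pytest.approx(
            np.log2(0.3 / (0.4 * 0.4)) / -np.log2(0.3)
        )


class TestMutualInformation:
    def test_independent_joint_is_zero(self):
        jd = jd_from_grid(np.outer([0.2, 0.8], [0.5, 0.5]))
        assert mutual_information(jd, 2) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_dependence_is_log_b(self):
        config = DiscretizationConfig(num_bins=5, spline_order=1)
        mm = membership_matrix(np.array([0.0, 1, 2, 3, 4]), config)
        jd = joint_distribution(mm, mm)
        assert mutual_information(jd, 2) == pytest.approx(np.log2(5))

    def test_non_negative_on_estimated_joints(self, rng, default_disc):
        for _ in range(20):
            jd = random_jd(rng, default_disc)
            assert mutual_information(jd, 2) >= -1e-9


class TestScoringFunctions:
    def test_s1_with_unit_weights_equals_mi(self, rng, default_disc):
        jd = random_jd(rng, default_disc)
        ones = np.ones((10, 10))
        assert score_s1(jd, ones, 2) == pytest.approx(
            mutual_information(jd, 2), abs=1e-12
        )

    def test_zero_weights_give_zero(self, toy_jd):
        zeros = np.zeros((3, 3))
        assert score_s1(toy_jd, zeros, 2) == 0.0
        assert score_s2(toy_jd, zeros, 2) == 0.0
        assert score_s3(toy_jd, zeros) == 0.0

    def test_s4_perfect_dependence_unit_weights_is_one(self):
        jd = jd_from_grid(np.diag([0.2, 0.5, 0.3]))
        assert score_s4(jd, np.ones((3, 3)), 2) == pytest.approx(1.0)

    def test_s4_independence_unit_weights_is_zero(self):
        jd = jd_from_grid(np.outer([0.3, 0.7], [0.6, 0.4]))
        assert score_s4(jd, np.ones((2, 2)), 2) == pytest.approx(0.0, abs=1e-12)

    def test_s3_corner_mass_extremes(self):
        w = build_rescaling_matrix("M3")
        for cell, expected in [((0, 0), 1.0), ((0, 9), -1.0)]:
            joint = np.zeros((10, 10))
            joint[cell] = 1.0
            assert score_s3(jd_from_grid(joint), w) == pytest.approx(expected)

    def test_s3_uniform_joint_m3_is_zero(self):
        w = build_rescaling_matrix("M3")
        jd = jd_from_grid(np.full((10, 10), 0.01))
        assert score_s3(jd, w) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("base", [2, 10])
    def test_all_four_match_brute_force(self, rng, default_disc, base):
        w = build_rescaling_matrix("M3").weights
        for _ in range(5):
            jd = random_jd(rng, default_disc)
            e1, e2, e3, e4 = brute_force_scores(jd.joint, w, base)
            assert score_s1(jd, w, base) == pytest.approx(e1, abs=1e-10)
            assert score_s2(jd, w, base) == pytest.approx(e2, abs=1e-10)
            assert score_s3(jd, w) == pytest.approx(e3, abs=1e-10)
            assert score_s4(jd, w, base) == pytest.approx(e4, abs=1e-10)


class TestSirenScore:
    def test_symmetric_in_arguments(self, rng):
        for fn in ("S1", "S2", "S3", "S4"):
            config = ScoreConfig(scoring_function=fn)
            x, y = rng.normal(size=60), rng.normal(size=60)
            assert siren_score(x, y, config).score == pytest.approx(
                siren_score(y, x, config).score, abs=1e-10
            )

    def test_mirror_antisymmetry_s1_s2_s3(self, rng):
        for fn in ("S1", "S2", "S3"):
            config = ScoreConfig(scoring_function=fn)
            x, y = rng.normal(size=60), rng.normal(size=60)
            mirrored = y.max() + y.min() - y
            assert siren_score(x, mirrored, config).score == pytest.approx(
                -siren_score(x, y, config).score, abs=1e-10
            )

    def test_mirror_invariance_s4(self, rng):
        """S4's numerator and denominator both flip sign under mirroring,
        so the ratio is invariant rather than antisymmetric."""
        config = ScoreConfig(scoring_function="S4")
        x, y = rng.normal(size=60), rng.normal(size=60)
        mirrored = y.max() + y.min() - y
        assert siren_score(x, mirrored, config).score == pytest.approx(
            siren_score(x, y, config).score, abs=1e-10
        )

    def test_monotone_pairs_have_correct_sign(self):
        x = np.linspace(0, 1, 100)
        for fn in ("S1", "S2", "S3"):
            config = ScoreConfig(scoring_function=fn)
            assert siren_score(x, 2 * x + 1, config).score > 0
            assert siren_score(x, -x, config).score < 0

    def test_metric_grid_sums_to_score(self, rng):
        for fn in ("S1", "S2", "S3", "S4"):
            config = ScoreConfig(scoring_function=fn)
            ps = siren_score(
                rng.normal(size=40), rng.normal(size=40), config,
                materialize_grid=True,
            )
            assert ps.metric_grid.shape == (10, 10)
            assert ps.metric_grid.sum() == pytest.approx(ps.score, abs=1e-9)

    def test_s1_wider_range_than_s2_on_clique(self):
        expr, grn = make_insilico_clique(CliqueSpec(seed=3))
        scores = {}
        for fn in ("S1", "S2"):
            config = ScoreConfig(scoring_function=fn)
            vals = [
                siren_score(
                    expr.loc[e.gene_a].to_numpy(),
                    expr.loc[e.gene_b].to_numpy(),
                    config,
                ).score
                for e in grn.edges
            ]
            scores[fn] = np.ptp(vals)
        assert scores["S1"] > scores["S2"]


class TestPearsonBaseline:
    def test_reference_values(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson_sign_score(x, x) == pytest.approx(1.0)
        assert pearson_sign_score(x, -x) == pytest.approx(-1.0)
        y = np.array([2.0, 1, 4, 3, 5])
        # textbook formula: cov / (sd_x * sd_y)
        expected = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert pearson_sign_score(x, y) == pytest.approx(expected)
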