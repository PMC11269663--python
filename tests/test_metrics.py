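"""Fréchet distance and kernel-MMD scores: closed forms, oracles, orderings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virtstain.errors import ConfigurationError, InputError
from virtstain.fixtures import SyntheticTissueSpec, apply_stain_oracle, generate_unstained_image
from virtstain.metrics import (
    COVARIANCE_JITTER,
    FeatureDistribution,
    ToyFeatureExtractor,
    evaluate_sets,
    extract_features,
    frechet_distance,
    get_extractor,
    kid,
    polynomial_kernel,
)
from virtstain.utils import save_image


def gaussian_dist(mean, cov, extractor_id="test"):
    return FeatureDistribution(mean=np.asarray(mean, float),
                               covariance=np.asarray(cov, float), n=1000,
                               extractor_id=extractor_id)


class TestToyExtractor:
    def test_one_row_per_image(self):
        ex = ToyFeatureExtractor(dim=16)
        imgs = [np.random.default_rng(i).integers(0, 255, (32, 32, 3), np.uint8)
                for i in range(10)]
        feats = extract_features(imgs, ex)
        assert feats.shape == (10, 16)

    def test_bit_reproducible(self):
        ex1, ex2 = ToyFeatureExtractor(), ToyFeatureExtractor()
        img = np.random.default_rng(0).integers(0, 255, (48, 48, 3), np.uint8)
        np.testing.assert_array_equal(ex1(img), ex2(img))

    def test_inception_path_errors_actionably(self):
        with pytest.raises(ConfigurationError, match="toy"):
            get_extractor("inception_pool3")

    def test_unknown_extractor_rejected(self):
        with pytest.raises(ConfigurationError):
            get_extractor("resnet")


class TestFrechetDistance:
    def test_self_distance_is_zero(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((200, 8))
        d = FeatureDistribution.from_features(a, "t")
        assert frechet_distance(d, d) == pytest.approx(0.0, abs=1e-6)

    def test_equal_covariance_reduces_to_mean_distance(self):
        d = 8
        mu_b = np.zeros(d)
        mu_b[0] = 2.0
        da = gaussian_dist(np.zeros(d), np.eye(d))
        db = gaussian_dist(mu_b, np.eye(d))
        assert frechet_distance(da, db) == pytest.approx(4.0, abs=1e-6)

    def test_diagonal_case_matches_analytic_form(self):
        rng = np.random.default_rng(1)
        d = 6
        sa = rng.uniform(0.5, 2.0, d)
        sb = rng.uniform(0.5, 2.0, d)
        mu_a, mu_b = rng.standard_normal(d), rng.standard_normal(d)
        got = frechet_distance(gaussian_dist(mu_a, np.diag(sa)),
                               gaussian_dist(mu_b, np.diag(sb)))
        ja, jb = sa + COVARIANCE_JITTER, sb + COVARIANCE_JITTER
        want = float(((mu_a - mu_b) ** 2).sum() + ((np.sqrt(ja) - np.sqrt(jb)) ** 2).sum())
        assert got == pytest.approx(want, abs=1e-8)

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        a = FeatureDistribution.from_features(rng.standard_normal((100, 5)), "t")
        b = FeatureDistribution.from_features(rng.standard_normal((100, 5)) + 1.0, "t")
        assert frechet_distance(a, b) == pytest.approx(frechet_distance(b, a), rel=1e-9)

    def test_extractor_mismatch_rejected(self):
        a = gaussian_dist(np.zeros(3), np.eye(3), "x")
        b = gaussian_dist(np.zeros(3), np.eye(3), "y")
        with pytest.raises(InputError):
            frechet_distance(a, b)

    @given(t=st.floats(0.1, 1.0))
    @settings(deadline=None, max_examples=15, derandomize=True)
    def test_decreases_as_means_interpolate(self, t):
        d = 4
        mu_b = np.full(d, 3.0)
        da = gaussian_dist(np.zeros(d), np.eye(d))
        closer = gaussian_dist((1 - t) * mu_b, np.eye(d))
        far = gaussian_dist(mu_b, np.eye(d))
        assert frechet_distance(da, closer) <= frechet_distance(da, far) + 1e-9


class TestKID:
    def test_matches_double_loop_oracle_tiny(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 3))
        y = rng.standard_normal((4, 3))
        got_mean, got_std = kid(x, y, subset_size=4, n_subsets=1, seed=0)

        def k(a, b):
            return (a @ b / 3 + 1) ** 3

        m = n = 4
        sxx = sum(k(x[i], x[j]) for i in range(m) for j in range(m) if i != j) / (m * (m - 1))
        syy = sum(k(y[i], y[j]) for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
        sxy = sum(k(x[i], y[j]) for i in range(m) for j in range(n)) / (m * n)
        assert got_mean == pytest.approx(sxx + syy - 2 * sxy, abs=1e-10)
        assert got_std == 0.0

    def test_null_behavior_same_distribution(self):
        """Two independent n=1000 draws from one 16-d Gaussian score ~0.

        Large subsets keep the estimator's Monte-Carlo noise well below the
        0.01 band being checked.
        """
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1000, 16))
        y = rng.standard_normal((1000, 16))
        kid_mean, _ = kid(x, y, subset_size=500, n_subsets=20, seed=1)
        assert abs(kid_mean) < 0.01

    def test_kernel_at_origin_is_one(self):
        z = np.zeros((1, 5))
        assert polynomial_kernel(z, z)[0, 0] == 1.0

    def test_subset_size_bounds(self):
        x = np.zeros((10, 2))
        with pytest.raises(ConfigurationError):
            kid(x, x, subset_size=1)
        with pytest.raises(ConfigurationError):
            kid(x, x, subset_size=50)


@pytest.fixture(scope="module")
def image_dirs(tmp_path_factory, oracle):
    root = tmp_path_factory.mktemp("sets")
    half1, half2, unst = root / "h1", root / "h2", root / "u"
    for d in (half1, half2, unst):
        d.mkdir()
    n = 0
    for s in range(24):
        spec = SyntheticTissueSpec(height=64, width=64, seed=500 + s,
                                   cytoplasm_fraction=0.5)
        u, lab = generate_unstained_image(spec)
        st_img = apply_stain_oracle(u, lab, oracle)
        target = half1 if s % 2 == 0 else half2
        save_image(st_img, target / f"s{n:03d}.png")
        save_image(u, unst / f"u{n:03d}.png")
        n += 1
    return half1, half2, unst


class TestEvaluateSets:
    def test_same_distribution_halves_closer_than_cross_domain(self, image_dirs):
        """FID between two stained halves is far below stained-vs-unstained,
        mirroring the expected ordering of virtual-staining evaluations."""
        half1, half2, unst = image_dirs
        same = evaluate_sets(half1, half2, subset_size=8, n_subsets=5)
        cross = evaluate_sets(half1, unst, subset_size=8, n_subsets=5)
        assert same.fid < cross.fid
        assert same.kid_mean < cross.kid_mean

    def test_report_echoes_counts_and_extractor(self, image_dirs, tmp_path):
        half1, half2, _ = image_dirs
        report = evaluate_sets(half1, half2, subset_size=8, n_subsets=3,
                               report_path=tmp_path / "r.json")
        assert report.n_a == 12 and report.n_b == 12
        assert report.extractor_id.startswith("toy")
        assert (tmp_path / "r.json").exists()
        assert report.kid_std >= 0.0
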