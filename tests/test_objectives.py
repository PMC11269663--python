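"""Loss-function semantics: contrastive, adversarial, identity, collective.

The contrastive losses are checked against independent brute-force oracles
that exponentiate the similarity ratios directly, and against closed forms
where one exists.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virtstain.autodiff import Tensor
from virtstain.errors import ConfigurationError, InputError, NumericError
from virtstain.networks import EmbeddingStack
from virtstain.objectives import (
    LossComponents,
    LossWeights,
    NCEBatch,
    adversarial_losses,
    cosine_similarity,
    identity_loss,
    nce_cross_entropy,
    patchnce_loss,
    total_objective,
)


def naive_nce(v, vp, negs, tau):
    """Direct-exponentiation oracle for the (N+1)-way contrastive loss."""
    def sim(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    num = np.exp(sim(v, vp) / tau)
    den = num + sum(np.exp(sim(v, n) / tau) for n in negs)
    return -np.log(num / den)


def unit(rng, k):
    v = rng.standard_normal(k)
    return v / np.linalg.norm(v)


class TestCosineSimilarity:
    def test_self_similarity_is_one(self):
        assert cosine_similarity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 5.0]) == pytest.approx(0.0)

    def test_antiparallel_is_minus_one(self):
        assert cosine_similarity([1.0, 0.0], [-1.0, 0.0]) == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(InputError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestNCECrossEntropy:
    def test_no_negatives_and_identical_pair_gives_zero(self):
        v = np.array([0.6, 0.8])
        loss = nce_cross_entropy(NCEBatch(v, v, np.empty((0, 2)), temperature=1.0))
        assert float(loss) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_single_orthogonal_negative(self):
        # v = v+, one orthogonal negative, tau = 1  ->  log(1 + e^-1)
        v = np.array([1.0, 0.0])
        neg = np.array([[0.0, 1.0]])
        loss = nce_cross_entropy(NCEBatch(v, v, neg, temperature=1.0))
        assert float(loss) == pytest.approx(np.log(1 + np.exp(-1.0)), abs=1e-9)

    def test_matches_brute_force_oracle_on_random_batches(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            v, vp = unit(rng, 8), unit(rng, 8)
            negs = np.stack([unit(rng, 8) for _ in range(7)])
            got = float(nce_cross_entropy(NCEBatch(v, vp, negs, temperature=0.07)))
            want = naive_nce(v, vp, negs, 0.07)
            assert got == pytest.approx(want, abs=1e-6)

    def test_positive_whenever_negatives_exist(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            v, vp = unit(rng, 4), unit(rng, 4)
            negs = np.stack([unit(rng, 4)])
            assert float(nce_cross_entropy(NCEBatch(v, vp, negs, temperature=0.5))) > 0

    def test_finite_at_low_temperature(self):
        rng = np.random.default_rng(8)
        v, vp = unit(rng, 8), unit(rng, 8)
        negs = np.stack([unit(rng, 8) for _ in range(5)])
        loss = float(nce_cross_entropy(NCEBatch(v, vp, negs, temperature=0.01)))
        assert np.isfinite(loss)

    def test_nonpositive_temperature_rejected(self):
        v = np.array([1.0, 0.0])
        with pytest.raises(ConfigurationError):
            nce_cross_entropy(NCEBatch(v, v, np.empty((0, 2)), temperature=0.0))

    @given(delta=st.floats(0.01, 0.5))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_raising_positive_similarity_lowers_the_loss(self, delta):
        base = np.array([1.0, 0.0])
        neg = np.array([[0.0, 1.0]])
        angle = np.pi / 3
        closer = np.array([np.cos(angle - delta), np.sin(angle - delta)])
        farther = np.array([np.cos(angle), np.sin(angle)])
        lo = float(nce_cross_entropy(NCEBatch(base, closer, neg, temperature=0.2)))
        hi = float(nce_cross_entropy(NCEBatch(base, farther, neg, temperature=0.2)))
        assert lo < hi

    @given(delta=st.floats(0.01, 0.5))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_raising_negative_similarity_raises_the_loss(self, delta):
        base = np.array([1.0, 0.0])
        pos = np.array([np.cos(0.3), np.sin(0.3)])
        angle = np.pi / 2
        near_neg = np.array([[np.cos(angle - delta), np.sin(angle - delta)]])
        far_neg = np.array([[np.cos(angle), np.sin(angle)]])
        hi = float(nce_cross_entropy(NCEBatch(base, pos, near_neg, temperature=0.2)))
        lo = float(nce_cross_entropy(NCEBatch(base, pos, far_neg, temperature=0.2)))
        assert hi > lo


def make_stack(rng, n_layers=2, s=8, k=6, copy_of=None):
    """Random unit-vector embedding stack (float64) for oracle comparisons."""
    vectors, locations = [], []
    for li in range(n_layers):
        if copy_of is not None:
            vecs = copy_of.vectors[li].data.copy()
            ids = copy_of.locations[li].copy()
        else:
            vecs = np.stack([unit(rng, k) for _ in range(s)])
            ids = np.arange(s)
        vectors.append(Tensor(vecs))
        locations.append(ids)
    return EmbeddingStack(layer_ids=tuple(range(n_layers)), locations=locations,
                          vectors=vectors, channel_dims=[k] * n_layers)


class TestPatchNCE:
    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(99)
        inp = make_stack(rng, n_layers=2, s=8)
        out = make_stack(rng, n_layers=2, s=8)
        out.locations = [ids.copy() for ids in inp.locations]
        tau = 0.07
        got = float(patchnce_loss(inp, out, temperature=tau))
        per_layer = []
        for li in range(2):
            z = inp.vectors[li].data
            zhat = out.vectors[li].data
            losses = [
                naive_nce(zhat[s], z[s], np.delete(z, s, axis=0), tau)
                for s in range(z.shape[0])
            ]
            per_layer.append(np.mean(losses))
        assert got == pytest.approx(float(np.mean(per_layer)), abs=1e-6)

    def test_identical_stacks_single_location_is_zero(self):
        rng = np.random.default_rng(5)
        inp = make_stack(rng, n_layers=1, s=1)
        out = make_stack(rng, copy_of=inp, n_layers=1, s=1)
        assert float(patchnce_loss(inp, out, temperature=1.0)) == pytest.approx(0.0, abs=1e-12)

    def test_consistent_permutation_leaves_loss_unchanged(self):
        rng = np.random.default_rng(6)
        inp = make_stack(rng, n_layers=1, s=6)
        out = make_stack(rng, n_layers=1, s=6)
        out.locations = [ids.copy() for ids in inp.locations]
        base = float(patchnce_loss(inp, out, temperature=0.3))
        perm = rng.permutation(6)
        inp2 = make_stack(rng, copy_of=inp, n_layers=1, s=6)
        out2 = make_stack(rng, copy_of=out, n_layers=1, s=6)
        inp2.vectors[0] = Tensor(inp.vectors[0].data[perm])
        out2.vectors[0] = Tensor(out.vectors[0].data[perm])
        assert float(patchnce_loss(inp2, out2, temperature=0.3)) == pytest.approx(base, rel=1e-12)

    def test_mismatched_locations_rejected(self):
        rng = np.random.default_rng(7)
        inp = make_stack(rng, n_layers=1, s=4)
        out = make_stack(rng, n_layers=1, s=4)
        out.locations = [inp.locations[0] + 1]
        with pytest.raises(InputError):
            patchnce_loss(inp, out)


class TestAdversarial:
    def test_perfect_discriminator_log_form(self):
        d_loss, _ = adversarial_losses(np.ones((2, 3, 3, 1)), np.zeros((2, 3, 3, 1)), "log")
        assert float(d_loss) == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_discriminator_gives_log2(self):
        half = np.full((2, 3, 3, 1), 0.5)
        d_loss, g_loss = adversarial_losses(half, half, "log")
        assert float(d_loss) == pytest.approx(np.log(2), abs=1e-9)
        assert float(g_loss) == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_discriminator_least_squares(self):
        d_loss, _ = adversarial_losses(np.ones((4,)), np.zeros((4,)), "lsgan")
        assert float(d_loss) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_form_rejected(self):
        with pytest.raises(ConfigurationError):
            adversarial_losses(np.ones(3), np.zeros(3), "wasserstein")


class TestIdentity:
    def test_identity_generators_give_zero(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-1, 1, (1, 4, 4, 3))
        b = rng.uniform(-1, 1, (1, 4, 4, 3))
        assert float(identity_loss(lambda x: x, lambda x: x, a, b)) == 0.0

    def test_constant_shift_measured_exactly(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-0.5, 0.5, (1, 4, 4, 3))
        b = rng.uniform(-0.5, 0.5, (1, 4, 4, 3))
        loss = identity_loss(lambda x: x, lambda x: Tensor(x.data + 0.1), a, b)
        assert float(loss) == pytest.approx(0.1, abs=1e-12)

    def test_symmetric_under_joint_channel_permutation(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-1, 1, (1, 4, 4, 3))
        b = rng.uniform(-1, 1, (1, 4, 4, 3))
        g2 = lambda x: Tensor(x.data * 0.9)
        base = float(identity_loss(lambda x: x, g2, a, b))
        perm = [2, 0, 1]
        permuted = float(identity_loss(lambda x: x, g2, a[..., perm], b[..., perm]))
        assert permuted == pytest.approx(base, rel=1e-12)


class TestTotalObjective:
    def test_printed_weights_example(self):
        comps = LossComponents(gan_1=0.6, gan_2=0.4, nce_a=0.3, nce_b=0.2, identity=0.5)
        assert float(total_objective(comps, LossWeights())) == 2.5

    def test_all_zero_components(self):
        comps = LossComponents(0.0, 0.0, 0.0, 0.0, 0.0)
        assert float(total_objective(comps)) == 0.0

    def test_nce_weight_scales_only_nce_terms(self):
        comps = LossComponents(gan_1=0.6, gan_2=0.4, nce_a=0.3, nce_b=0.2, identity=0.5)
        base = float(total_objective(comps, LossWeights(lambda_nce=2.0)))
        doubled = float(total_objective(comps, LossWeights(lambda_nce=4.0)))
        assert doubled - base == pytest.approx(2.0 * (0.3 + 0.2), rel=1e-12)

    def test_nonfinite_component_rejected_by_name(self):
        comps = LossComponents(gan_1=np.nan, gan_2=0.0, nce_a=0.0, nce_b=0.0, identity=0.0)
        with pytest.raises(NumericError, match="gan_1"):
            total_objective(comps)
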