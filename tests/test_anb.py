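"""Streaming chunked moments, chunk combination and Gaussian likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from harf.anb import (
    ChunkStats,
    VARIANCE_FLOOR,
    chunk_update,
    combine_chunks,
    gaussian_log_likelihood,
    train_class,
)

from .conftest import make_fv


def batch_stats(data):
    """Independent oracle: direct batch mean / mean-square / variance."""
    data = np.asarray(data, dtype=float)
    return data.mean(), (data ** 2).mean(), data.var()


def feed(data, stats=None):
    stats = stats or ChunkStats()
    for x in data:
        stats = chunk_update(stats, x)
    return stats


class TestChunkStats:
    def test_single_sample(self):
        s = chunk_update(ChunkStats(), 5.0)
        assert (s.n, s.mu, s.v) == (1, 5.0, 25.0)
        assert s.sigma2 == 0.0

    def test_three_samples_match_batch_oracle(self):
        s = feed([1.0, 2.0, 3.0])
        mu, v, var = batch_stats([1, 2, 3])
        assert s.n == 3
        assert s.mu == pytest.approx(mu)  # 2
        assert s.v == pytest.approx(v)  # 14/3
        assert s.sigma2 == pytest.approx(var)  # 2/3

    def test_order_invariance_forward_vs_reversed(self, rng):
        data = rng.normal(3.0, 2.0, size=57)
        a, b = feed(data), feed(data[::-1])
        assert a.n == b.n
        assert a.mu == pytest.approx(b.mu, rel=1e-12)
        assert a.v == pytest.approx(b.v, rel=1e-12)

    def test_non_finite_sample_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            chunk_update(ChunkStats(), float("nan"))

    def test_functional_update_leaves_input_untouched(self):
        s0 = ChunkStats()
        chunk_update(s0, 1.0)
        assert s0.n == 0

    def test_empty_chunk_cannot_finalize(self):
        with pytest.raises(ValueError):
            ChunkStats().finalized()

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=200))
    @settings(max_examples=100, derandomize=True)
    def test_variance_nonnegative_on_all_reachable_states(self, data):
        s = ChunkStats()
        for x in data:
            s = chunk_update(s, x)
            assert s.sigma2 >= -1e-6  # fp tolerance
        mu, sig, n = s.finalized()
        assert sig >= 0.0


class TestCombineChunks:
    def test_single_chunk_identity_both_modes(self):
        for mode in ("adaptive", "pooled"):
            mu, var = combine_chunks([(2.0, 0.5, 10)], mode=mode)
            assert (mu, var) == (2.0, 0.5)
        mu, var = combine_chunks([(2.0, 0.0, 10)])
        assert var == VARIANCE_FLOOR  # degenerate variance clamped

    def test_two_constant_chunks_vs_batch_oracle(self):
        # chunks [0,0] and [2,2]; concatenated batch is [0,0,2,2]
        chunks = [feed([0.0, 0.0]).finalized(), feed([2.0, 2.0]).finalized()]
        mu_a, var_a = combine_chunks(chunks, mode="adaptive")
        assert mu_a == 1.0 and var_a == VARIANCE_FLOOR  # 0 clamped to floor
        mu_p, var_p = combine_chunks(chunks, mode="pooled")
        bmu, _, bvar = batch_stats([0, 0, 2, 2])
        assert mu_p == pytest.approx(bmu) and var_p == pytest.approx(bvar)  # (1, 1)

    def test_empty_or_zero_count_chunks_rejected(self):
        with pytest.raises(ValueError):
            combine_chunks([])
        with pytest.raises(ValueError):
            combine_chunks([(0.0, 0.0, 0)])

    def test_vector_chunks_supported(self, rng):
        data = rng.normal(size=(30, 4))
        chunks = []
        for block in np.split(data, [10, 18]):
            chunks.append((block.mean(axis=0), block.var(axis=0), block.shape[0]))
        mu, var = combine_chunks(chunks, mode="pooled")
        np.testing.assert_allclose(mu, data.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(var, data.var(axis=0), rtol=1e-9)

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=120),
        st.data(),
    )
    @settings(max_examples=150, derandomize=True)
    def test_pooled_equals_batch_for_any_chunking(self, data, draw):
        cuts = draw.draw(
            st.lists(st.integers(1, len(data) - 1), max_size=6, unique=True)
        )
        bounds = [0] + sorted(cuts) + [len(data)]
        chunks = [
            feed(data[a:b]).finalized() for a, b in zip(bounds, bounds[1:]) if b > a
        ]
        mu, var = combine_chunks(chunks, mode="pooled", variance_floor=0.0)
        bmu, _, bvar = batch_stats(data)
        assert mu == pytest.approx(bmu, rel=1e-9, abs=1e-9)
        assert var == pytest.approx(bvar, rel=1e-9, abs=1e-9)

    def test_adaptive_approaches_pooled_for_stationary_chunks(self):
        # equal-size chunks of one stationary distribution: the between-chunk
        # mean spread the adaptive rule drops is O(sigma^2 / n_chunk)
        rng = np.random.default_rng(42)
        n, j, sigma2 = 10_000, 8, 4.0
        chunks = [
            feed(rng.normal(1.0, math.sqrt(sigma2), size=n)).finalized()
            for _ in range(j)
        ]
        mu_a, var_a = combine_chunks(chunks, mode="adaptive")
        mu_p, var_p = combine_chunks(chunks, mode="pooled")
        assert abs(var_a - var_p) < 10 * sigma2 / n  # CLT-scale tolerance
        assert mu_a == pytest.approx(mu_p, abs=1e-12)

    def test_adaptive_equals_pooled_on_identical_equal_chunks(self, rng):
        base = feed(rng.integers(-50, 50, size=64).astype(float)).finalized()
        for j in (2, 4, 8):  # dyadic replica counts keep the arithmetic exact
            mu_a, var_a = combine_chunks([base] * j, mode="adaptive")
            mu_p, var_p = combine_chunks([base] * j, mode="pooled")
            assert mu_a == mu_p and var_a == var_p


class TestGaussianLogLikelihood:
    def test_value_at_mode_unit_variance(self):
        assert gaussian_log_likelihood(0.0, 0.0, 1.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi)  # -0.918939
        )

    def test_symmetry_about_mean(self):
        assert gaussian_log_likelihood(3.7, 3.0, 0.5) == pytest.approx(
            gaussian_log_likelihood(2.3, 3.0, 0.5)
        )

    def test_monotone_decay_from_mode(self):
        assert gaussian_log_likelihood(1.0, 0.0, 1.0) > gaussian_log_likelihood(
            2.0, 0.0, 1.0
        )

    def test_variance_below_floor_is_contract_violation(self):
        with pytest.raises(ValueError, match="floor"):
            gaussian_log_likelihood(0.0, 0.0, 1e-9)

    def test_agrees_with_scipy_normal(self, rng):
        from scipy.stats import norm

        v, mu, var = rng.normal(size=3) * 2.0, 0.3, 1.7
        np.testing.assert_allclose(
            gaussian_log_likelihood(v, mu, var),
            norm.logpdf(v, loc=mu, scale=math.sqrt(var)),
            rtol=1e-12,
        )


class TestTrainClass:
    def test_single_chunk_equals_batch_both_modes(self, rng):
        data = rng.normal(3.0, 2.0, size=(100, 1))
        for mode in ("adaptive", "pooled"):
            m = train_class([make_fv(row) for row in data], chunk_size=100, mode=mode)
            assert m.chunk_count == 1
            assert m.mu_m[0] == pytest.approx(data.mean(), rel=1e-12)
            assert m.mu_v[0] == pytest.approx(data.var(), rel=1e-9)

    def test_pooled_chunked_equals_batch_oracle(self):
        rng = np.random.default_rng(123)
        data = rng.normal(3.0, 2.0, size=100)
        m = train_class([make_fv([x]) for x in data], chunk_size=25, mode="pooled")
        assert m.chunk_count == 4
        assert abs(m.mu_m[0] - data.mean()) < 1e-9
        assert abs(m.mu_v[0] - data.var()) < 1e-9

    def test_partial_final_chunk_counts_as_chunk(self, rng):
        data = rng.normal(size=(53, 2))
        m = train_class([make_fv(r) for r in data], chunk_size=25)
        assert m.chunk_count == 3
        assert m.n_samples == 53

    def test_adaptive_mode_sensitive_to_chunk_boundaries_on_drift(self):
        # drifting sequence: chunk means differ, so the unweighted rule's
        # variance depends on where the chunk boundaries fall
        drift = np.linspace(0.0, 10.0, 100)
        a = train_class([make_fv([x]) for x in drift], chunk_size=50, mode="adaptive")
        b = train_class([make_fv([x]) for x in drift], chunk_size=25, mode="adaptive")
        p1 = train_class([make_fv([x]) for x in drift], chunk_size=50, mode="pooled")
        p2 = train_class([make_fv([x]) for x in drift], chunk_size=25, mode="pooled")
        assert a.mu_v[0] != b.mu_v[0]
        assert p1.mu_v[0] == pytest.approx(p2.mu_v[0], rel=1e-9)

    def test_inconsistent_vector_length_names_index(self):
        stream = [make_fv([1.0, 2.0]), make_fv([1.0, 2.0]), make_fv([1.0])]
        with pytest.raises(ValueError, match="vector 2"):
            train_class(stream)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            train_class([])

    def test_consumes_a_one_shot_stream_and_keeps_no_samples(self, rng):
        # bounded-memory contract: the trainer reads a generator once and the
        # resulting model retains only O(features) state (no audit by default)
        n = 5000
        gen = (make_fv(rng.normal(size=3)) for _ in range(n))
        m = train_class(gen, chunk_size=50)
        assert m.n_samples == n and m.chunks is None
        assert m.mu_m.size == m.mu_v.size == 3

    def test_audit_chunks_match_combine_chunks(self, rng):
        data = rng.normal(size=(40, 2))
        m = train_class(
            [make_fv(r) for r in data], chunk_size=16, mode="pooled",
            retain_chunks=True,
        )
        mu, var = combine_chunks(m.chunks, mode="pooled")
        np.testing.assert_allclose(m.mu_m, mu, rtol=1e-12)
        np.testing.assert_allclose(m.mu_v, var, rtol=1e-12)

    def test_parameter_recovery_from_simulator_truth(self):
        from harf.simulator import generate_feature_dataset

        n = 10_000
        params = {
            "standing": (np.array([0.0, 9.81, 0.2]), np.array([0.04, 0.09, 0.01])),
            "walking": (np.array([1.0, 9.81, 2.0]), np.array([0.25, 0.5, 0.2])),
        }
        ds = generate_feature_dataset(params, n_per_class=n, seed=77)
        for label, (mu_true, var_true) in ds.class_params.items():
            rows = ds.X[[i for i, y in enumerate(ds.y) if y == label]]
            m = train_class([make_fv(r, ds.feature_names) for r in rows], chunk_size=500)
            bound = 4.0 * np.sqrt(var_true / n)
            assert np.all(np.abs(m.mu_m - mu_true) < bound)
            assert np.all(np.abs(m.mu_v - var_true) / var_true < 0.10)

    def test_prior_validation(self):
        with pytest.raises(ValueError, match="prior"):
            train_class([make_fv([1.0])], prior=0.0)
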