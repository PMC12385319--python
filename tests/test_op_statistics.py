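"""Entropy and magnitude-variability statistics, checked against hand values
and an independent brute-force implementation."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import opvar as ov


def dist_from(probs, D, m=10_000):
    counts = np.round(np.asarray(probs) * m).astype(int)
    return ov.OPDistribution(counts=counts, D=D)


def brute_force_variability(vectors, symbols, D):
    """Direct per-pattern groupby evaluation of the weighted log2-sigma means.

    Groups the embedded vectors by symbol explicitly, computes the sample
    standard deviation of each component with the statistics module, and
    evaluates the weighted sums term by term, renormalising over patterns
    with defined positive spread.
    """
    n_pat = math.factorial(D)
    m = len(symbols)
    groups = {a: [v for v, s in zip(vectors, symbols) if s == a] for a in range(1, n_pat + 1)}
    included, weights, logs = [], [], []
    for a in range(1, n_pat + 1):
        g = groups[a]
        if len(g) < 2:
            continue
        sigmas = [statistics.stdev([v[j] for v in g]) for j in range(D)]
        if any(s <= 0 for s in sigmas):
            continue
        included.append(a)
        weights.append(len(g) / m)
        logs.append([math.log2(s) for s in sigmas])
    wsum = sum(weights)
    mean_log = [
        sum(w * row[j] for w, row in zip(weights, logs)) / wsum for j in range(D)
    ]
    return mean_log, sum(mean_log) / D


class TestDistribution:
    def test_direct_counting(self):
        symbols = ov.SymbolSequence(np.array([1, 1, 2, 2]), ov.EmbeddingConfig(2))
        d = ov.distribution(symbols)
        np.testing.assert_allclose(d.probabilities, [0.5, 0.5])
        assert d.m == 4

    def test_point_mass(self):
        symbols = ov.SymbolSequence(np.array([3] * 10), ov.EmbeddingConfig(3))
        d = ov.distribution(symbols)
        assert d.probabilities[2] == 1.0
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_iid_signal_is_equidistributed(self, rng):
        """Exchangeability makes every ordering of an i.i.d. signal equally likely."""
        s = ov.Signal(rng.uniform(0, 1, 1_000_000))
        d = ov.distribution(ov.encode(s, ov.EmbeddingConfig(3))[0])
        p = 1.0 / 6.0
        se = math.sqrt(p * (1 - p) / d.m)
        np.testing.assert_allclose(d.probabilities, p, atol=3 * se)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ov.distribution(ov.SymbolSequence(np.array([], dtype=int), ov.EmbeddingConfig(2)))


class TestEntropies:
    def test_uniform_reaches_max_entropy(self):
        d = dist_from([1 / 6] * 6, D=3, m=6000)
        assert ov.permutation_entropy(d) == pytest.approx(math.log2(6))
        assert ov.min_entropy(d) == pytest.approx(math.log2(6))

    def test_point_mass_entropies_vanish(self):
        d = dist_from([1, 0, 0, 0, 0, 0], D=3)
        assert ov.permutation_entropy(d) == 0.0
        assert ov.min_entropy(d) == 0.0

    def test_hand_evaluated_values(self):
        d = dist_from([0.5, 0.25, 0.25, 0, 0, 0], D=3)
        assert ov.permutation_entropy(d) == pytest.approx(1.5)
        assert ov.min_entropy(d) == pytest.approx(1.0)

    def test_collision_entropy_by_hand(self):
        d = dist_from([0.5, 0.5, 0, 0, 0, 0], D=3)
        assert ov.renyi_entropy(d, 2) == pytest.approx(1.0)

    def test_renyi_limits(self):
        d = dist_from([0.4, 0.3, 0.2, 0.1, 0, 0], D=3)
        assert ov.renyi_entropy(d, 1.0001) == pytest.approx(ov.permutation_entropy(d), abs=1e-3)
        # finite-q gap to the min-entropy closes as ~H_inf/(q-1)
        assert ov.renyi_entropy(d, 400) == pytest.approx(ov.min_entropy(d), abs=0.01)
        assert ov.renyi_entropy(d, math.inf) == ov.min_entropy(d)

    @pytest.mark.parametrize("q", [0.0, -1.0, 1.0])
    def test_invalid_orders_rejected(self, q):
        with pytest.raises(ValueError):
            ov.renyi_entropy(dist_from([0.5, 0.5, 0, 0, 0, 0], D=3), q)

    @given(
        counts=st.lists(st.integers(0, 1000), min_size=6, max_size=6).filter(
            lambda c: sum(c) > 0
        ),
        q=st.floats(1.1, 50),
    )
    def test_sandwich_bound(self, counts, q):
        """H_inf <= H_q <= H <= Hmax on arbitrary distributions."""
        d = ov.OPDistribution(counts=np.array(counts), D=3)
        h_inf, h_q, h = ov.min_entropy(d), ov.renyi_entropy(d, q), ov.permutation_entropy(d)
        tol = 1e-9
        assert h_inf <= h_q + tol
        assert h_q <= h + tol
        assert h <= math.log2(6) + tol


class TestMagnitudeVariability:
    def test_translated_copies_give_constant_spread(self, rng):
        """Vectors of one pattern that are exact translates: sigma_j = s, avg = log2 s."""
        base = np.array([0.0, 2.0, 1.0])
        offsets = np.array([0.0, 10.0, 20.0, 30.0])  # spread s over 4 copies
        vectors = base[None, :] + offsets[:, None]
        cfg = ov.EmbeddingConfig(3)
        vset = ov.EmbeddedVectorSet(vectors=vectors, start_indices=np.arange(4) * 2, config=cfg)
        symbols = ov.SymbolSequence(symbols=ov.rank_patterns(vectors), config=cfg)
        panel = ov.magnitude_variability(vset, symbols)
        s = np.std(offsets, ddof=1)
        np.testing.assert_allclose(panel.sigma[symbols.symbols[0] - 1], s)
        assert panel.avg == pytest.approx(math.log2(s))
        np.testing.assert_allclose(panel.dispersion, 0.0, atol=1e-12)

    @pytest.mark.parametrize("T", [20, 35, 50])
    def test_matches_brute_force_oracle(self, rng, T):
        s = ov.Signal(rng.uniform(0, 1, T))
        cfg = ov.EmbeddingConfig(3)
        symbols, vset = ov.encode(s, cfg)
        panel = ov.magnitude_variability(vset, symbols)
        mean_log, avg = brute_force_variability(
            vset.vectors.tolist(), symbols.symbols.tolist(), 3
        )
        np.testing.assert_allclose(panel.mean_log_sigma, mean_log, atol=1e-12)
        assert panel.avg == pytest.approx(avg, abs=1e-12)

    def test_avg_is_exact_mean_of_components(self, rng):
        s = ov.Signal(rng.normal(0, 1, 500))
        symbols, vset = ov.encode(s, ov.EmbeddingConfig(4))
        panel = ov.magnitude_variability(vset, symbols)
        assert panel.avg == np.mean(panel.mean_log_sigma)

    def test_doubling_shifts_avg_by_one_bit(self, rng):
        s = ov.Signal(rng.uniform(0, 1, 2000))
        cfg = ov.EmbeddingConfig(3)
        r1 = ov.summarize(s, cfg)
        r2 = ov.summarize(ov.Signal(2 * s.values), cfg)
        assert r2.variability.avg - r1.variability.avg == pytest.approx(1.0, abs=1e-9)
        assert r2.entropy.H == r1.entropy.H
        assert r2.entropy.H_inf == r1.entropy.H_inf

    def test_label_permutation_invariance(self, rng):
        """Relabelling the OP symbols leaves H, H_inf and avg unchanged."""
        s = ov.Signal(rng.uniform(0, 1, 3000))
        cfg = ov.EmbeddingConfig(3)
        symbols, vset = ov.encode(s, cfg)
        perm = rng.permutation(6) + 1
        relabelled = ov.SymbolSequence(perm[symbols.symbols - 1], cfg)
        d1, d2 = ov.distribution(symbols), ov.distribution(relabelled)
        assert ov.permutation_entropy(d1) == pytest.approx(ov.permutation_entropy(d2))
        assert ov.min_entropy(d1) == pytest.approx(ov.min_entropy(d2))
        p1 = ov.magnitude_variability(vset, symbols)
        p2 = ov.magnitude_variability(vset, relabelled)
        assert p1.avg == pytest.approx(p2.avg, abs=1e-12)

    def test_insufficient_data_raises(self):
        cfg = ov.EmbeddingConfig(3)
        vectors = np.array([[1.0, 2.0, 3.0]])
        vset = ov.EmbeddedVectorSet(vectors, np.array([0]), cfg)
        symbols = ov.SymbolSequence(np.array([1]), cfg)
        with pytest.raises(ValueError, match="insufficient data"):
            ov.magnitude_variability(vset, symbols)

    def test_iqr_estimator(self, rng):
        s = ov.Signal(rng.uniform(0, 1, 2000))
        symbols, vset = ov.encode(s, ov.EmbeddingConfig(3))
        panel = ov.magnitude_variability(vset, symbols, estimator="iqr")
        assert panel.estimator == "iqr"
        a = symbols.symbols[0] - 1
        mask = symbols.symbols == symbols.symbols[0]
        expected = np.subtract(*np.percentile(vset.vectors[mask, 0], [75, 25]))
        assert panel.sigma[a, 0] == pytest.approx(expected)


class TestSummarize:
    def test_point_mass_symbol_stream(self):
        res = ov.summarize(ov.Signal(np.arange(30.0)), ov.EmbeddingConfig(3))
        assert res.entropy.H == 0.0
        assert res.entropy.H_inf == 0.0
        assert res.entropy.H_max == pytest.approx(math.log2(6))

    def test_provenance_recorded(self, rng):
        s = ov.Signal(rng.uniform(0, 1, 500))
        res = ov.summarize(s, ov.EmbeddingConfig(3, 2))
        prov = res.provenance
        assert prov["D"] == 3 and prov["tau"] == 2 and prov["T"] == 500
        assert prov["m"] == res.distribution.m
        assert prov["tie_fraction"] == 0.0
        assert 0.0 <= prov["excluded_op_mass"] < 1.0

    def test_split_half_min_entropy_stability(self, logistic_38):
        """H_inf on each half of a long chaotic trajectory agrees within 0.02 bits."""
        cfg = ov.EmbeddingConfig(4)
        half = logistic_38.T // 2
        h1 = ov.summarize(ov.Signal(logistic_38.values[:half]), cfg).entropy.H_inf
        h2 = ov.summarize(ov.Signal(logistic_38.values[half:]), cfg).entropy.H_inf
        assert abs(h1 - h2) < 0.02

    @pytest.mark.parametrize("fixture", ["logistic_38", "logistic_36"])
    def test_component_homogeneity_on_long_trajectories(self, fixture, request):
        """Per-component log2-sigma means vary by less than twice the panel dispersion."""
        signal = request.getfixturevalue(fixture)
        panel = ov.summarize(signal, ov.EmbeddingConfig(4)).variability
        spread = panel.mean_log_sigma.max() - panel.mean_log_sigma.min()
        assert spread <= 2.0 * panel.dispersion.max()
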