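"""Generative model: log-scores, couplings, fields, enumeration, sampling."""

import itertools

import numpy as np
import pytest

import hpdca
from hpdca import EncodedMSA
from hpdca.hopfield_model import (
    build_couplings,
    enumerate_distribution,
    fit_fields,
    gibbs_sample,
    interaction_likelihood_ratio,
    load_model,
    log_score,
    save_model,
)
from hpdca.msa_io import ALPHABET
from hpdca.preprocessing import compute_frequencies
from hpdca.spectral_patterns import likelihood_contribution

from conftest import make_two_site_pattern


class TestLogScore:
    """The worked XOR examples: a two-site pattern with components at
    (i, A) and (j, B) scores each of the four presence combinations."""

    @pytest.mark.parametrize(
        "has_a,has_b,expected",
        [(False, False, 0.0), (True, False, 1.0), (False, True, 1.0), (True, True, 0.0)],
    )
    def test_opposite_sign_pattern_is_xor(self, has_a, has_b, expected):
        pat = make_two_site_pattern(3, 3, 1, 2, 2, 3, opposite=True)
        seq = np.array([2 if has_a else 1, 3 if has_b else 1, 1])
        assert log_score(seq, pat) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "has_a,has_b,expected",
        [(False, False, 0.0), (True, False, 1.0), (False, True, 1.0), (True, True, 4.0)],
    )
    def test_equal_sign_pattern_rewards_copresence(self, has_a, has_b, expected):
        pat = make_two_site_pattern(3, 3, 1, 2, 2, 3, opposite=False)
        seq = np.array([2 if has_a else 1, 3 if has_b else 1, 1])
        assert log_score(seq, pat) == pytest.approx(expected)

    def test_global_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        xi = rng.normal(size=(4, 3))
        p1 = hpdca.Pattern(xi=xi, sign="attractive", eigenvalue=2.0)
        p2 = hpdca.Pattern(xi=-xi, sign="attractive", eigenvalue=2.0)
        seq = np.array([1, 3, 2, 2])
        assert log_score(seq, p1) == pytest.approx(log_score(seq, p2))

    def test_length_mismatch(self):
        pat = make_two_site_pattern(3, 3, 1, 2, 2, 3)
        with pytest.raises(ValueError):
            log_score(np.array([1, 2]), pat)


class TestBuildCouplings:
    def test_empty_set_gives_zero_couplings(self):
        model = build_couplings([], L=4, q=3)
        assert not np.any(model.e)
        assert model.rank == 0

    def test_single_pattern_support(self):
        pat = make_two_site_pattern(5, 3, 2, 4, 1, 2)
        model = build_couplings([pat])
        nonzero = {(i, j) for i in range(5) for j in range(5) if np.any(model.e[i, j])}
        assert nonzero == {(1, 3), (3, 1)}
        assert model.e[1, 3, 0, 1] == pytest.approx(-(-1.0))  # repulsive: −(+1·−1)

    def test_symmetry_and_gauge(self, random_spectrum):
        ps = hpdca.select_patterns(random_spectrum, 6)
        model = build_couplings(ps)
        np.testing.assert_allclose(model.e, model.e.transpose(1, 0, 3, 2), atol=1e-12)
        np.testing.assert_array_equal(model.e[:, :, -1, :], 0.0)
        np.testing.assert_array_equal(model.e[:, :, :, -1], 0.0)

    def test_full_rank_matches_inverse_covariance(self, random_msa):
        """At p=(q−1)L the couplings equal −C⁻¹ off the diagonal blocks:
        the mean-field direct coupling analysis solution."""
        spectrum, _, _ = hpdca.pearson_spectrum(random_msa)
        L, q = random_msa.L, random_msa.q
        r = q - 1
        model = build_couplings(hpdca.select_patterns(spectrum, r * L))
        Cinv = np.linalg.inv(spectrum.C)
        for i in range(L):
            for j in range(L):
                if i == j:
                    continue
                np.testing.assert_allclose(
                    model.e[i, j, :r, :r],
                    -Cinv[i * r:(i + 1) * r, j * r:(j + 1) * r],
                    atol=1e-8,
                )

    def test_basis_independence_in_degenerate_subspace(self):
        """Couplings built from a degenerate eigen-pair do not depend on the
        orthonormal basis chosen inside the subspace."""
        v1 = np.array([1.0, 0.0, 0.0, 0.0])
        v2 = np.array([0.0, 0.0, 1.0, 0.0])
        c, s = np.cos(0.7), np.sin(0.7)
        w1, w2 = c * v1 + s * v2, -s * v1 + c * v2
        lam = 1.8

        def model_from(vecs):
            pats = [
                hpdca.Pattern(
                    xi=np.hstack([np.sqrt(1 - 1 / lam) * v.reshape(2, 2),
                                  np.zeros((2, 1))]),
                    sign="attractive", eigenvalue=lam)
                for v in vecs
            ]
            return build_couplings(pats)

        m_a = model_from([v1, v2])
        m_b = model_from([w1, w2])
        np.testing.assert_allclose(m_a.e, m_b.e, atol=1e-12)


class TestFields:
    def test_zero_couplings_give_pssm_fields(self):
        msa = EncodedMSA(np.array([[1, 2], [2, 2], [1, 1]]), alphabet=ALPHABET[:3])
        freqs = compute_frequencies(msa, None, 0.3)
        model = fit_fields(freqs, build_couplings([], L=2, q=3))
        expected = np.log(freqs.f1[:, :2] / freqs.f1[:, 2:])
        np.testing.assert_allclose(model.h[:, :2], expected, atol=1e-12)
        np.testing.assert_array_equal(model.h[:, -1], 0.0)

    def test_weak_coupling_marginals_via_enumeration(self):
        """L=2, q=2: mean-field fields reproduce the exact single-site
        marginals within 5% for weak couplings."""
        L, q = 2, 2
        f1 = np.array([[0.7, 0.3], [0.4, 0.6]])
        e = np.zeros((L, L, q, q))
        e[0, 1, 0, 0] = e[1, 0, 0, 0] = 0.1
        freqs = hpdca.FrequencyModel(
            f1=f1,
            f2=np.einsum("ia,jb->ijab", f1, f1),
            pseudocount_fraction=0.0, M_eff=1.0,
        )
        for i in range(L):
            freqs.f2[i, i] = np.diag(f1[i])
        model = fit_fields(freqs, hpdca.CouplingModel(e=e, h=np.zeros((L, q)), rank=1))
        _, _, f1_exact, _ = enumerate_distribution(model)
        np.testing.assert_allclose(f1_exact, f1, rtol=0.05)

    def test_zero_frequency_rejected(self):
        freqs = hpdca.FrequencyModel(
            f1=np.array([[1.0, 0.0], [0.5, 0.5]]),
            f2=np.zeros((2, 2, 2, 2)), pseudocount_fraction=0.0, M_eff=1.0)
        with pytest.raises(ValueError):
            fit_fields(freqs, build_couplings([], L=2, q=2))


class TestEnumeration:
    def test_probabilities_normalize(self):
        pat = make_two_site_pattern(3, 3, 1, 3, 1, 2)
        model = build_couplings([pat])
        P, Z, f1, f2 = enumerate_distribution(model)
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(f1.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_couplings_factorize(self):
        L, q = 3, 3
        rng = np.random.default_rng(4)
        h = rng.normal(size=(L, q))
        model = hpdca.CouplingModel(e=np.zeros((L, L, q, q)), h=h, rank=0)
        P, _, f1, f2 = enumerate_distribution(model)
        for i, j in itertools.combinations(range(L), 2):
            np.testing.assert_allclose(f2[i, j], np.outer(f1[i], f1[j]), atol=1e-12)

    def test_repulsive_pattern_suppresses_xor_configs(self):
        """With an opposite-sign repulsive pattern, configurations carrying
        exactly one favored state are depleted below independence."""
        L, q = 2, 3
        pat = make_two_site_pattern(L, q, 1, 2, 2, 3, c=1.2, opposite=True)
        model = build_couplings([pat])
        _, _, f1, f2 = enumerate_distribution(model)
        p_joint = f2[0, 1, 1, 2]           # both favored states
        p_indep = f1[0, 1] * f1[1, 2]
        assert p_joint > p_indep
        p_xor = f2[0, 1, 1, 0]             # A at i, B absent at j
        assert p_xor < f1[0, 1] * f1[1, 0]

    def test_attractive_pattern_favors_copresence(self):
        pat = make_two_site_pattern(2, 3, 1, 2, 2, 3, c=0.9, opposite=False,
                                    sign="attractive")
        model = build_couplings([pat])
        _, _, f1, f2 = enumerate_distribution(model)
        assert f2[0, 1, 1, 2] > f1[0, 1] * f1[1, 2]

    def test_state_space_guard(self):
        model = hpdca.CouplingModel(
            e=np.zeros((10, 10, 21, 21)), h=np.zeros((10, 21)), rank=0)
        with pytest.raises(ValueError, match="gibbs_sample"):
            enumerate_distribution(model)


class TestGibbsSampler:
    def test_deterministic_for_fixed_seed(self):
        pat = make_two_site_pattern(3, 3, 1, 3, 1, 2)
        model = build_couplings([pat])
        a = gibbs_sample(model, 50, seed=11, burn_in=20, thin=2)
        b = gibbs_sample(model, 50, seed=11, burn_in=20, thin=2)
        np.testing.assert_array_equal(a.data, b.data)
        c = gibbs_sample(model, 50, seed=12, burn_in=20, thin=2)
        assert not np.array_equal(a.data, c.data)

    def test_zero_coupling_marginals_match_pssm(self):
        L, q, n = 3, 3, 20000
        rng = np.random.default_rng(6)
        h = rng.normal(scale=0.5, size=(L, q))
        h[:, -1] = 0.0
        model = hpdca.CouplingModel(e=np.zeros((L, L, q, q)), h=h, rank=0)
        exact = np.exp(h) / np.exp(h).sum(axis=1, keepdims=True)
        msa = gibbs_sample(model, n, seed=9, burn_in=100, thin=1)
        freqs = compute_frequencies(msa, None, 0.0)
        se = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(freqs.f1 - exact) <= 3 * np.maximum(se, 1e-12))

    def test_two_site_marginals_match_enumeration(self):
        """Sampled pair statistics agree with the exact distribution of a
        planted-pattern model within Monte-Carlo error."""
        L, q, n = 4, 3, 30000
        pat = make_two_site_pattern(L, q, 1, 4, 2, 3, c=1.0)
        model = build_couplings([pat])
        _, _, f1_exact, f2_exact = enumerate_distribution(model)
        msa = gibbs_sample(model, n, seed=13, burn_in=200, thin=3)
        freqs = compute_frequencies(msa, None, 0.0)
        se = np.sqrt(f2_exact * (1 - f2_exact) / n)
        off = ~np.eye(L, dtype=bool)
        dev = np.abs(freqs.f2 - f2_exact)[off]
        assert np.all(dev <= 3.0 * np.maximum(se[off], 1e-12))


class TestLikelihoodRatio:
    def test_endpoints(self, random_spectrum):
        n = len(random_spectrum.eigvals)
        assert interaction_likelihood_ratio(random_spectrum, 0) == 0.0
        assert interaction_likelihood_ratio(random_spectrum, n) == pytest.approx(1.0)

    def test_monotone_non_decreasing(self, random_spectrum):
        n = len(random_spectrum.eigvals)
        vals = [interaction_likelihood_ratio(random_spectrum, p) for p in range(n + 1)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_four_mode_closed_form(self):
        from test_spectral_patterns import make_spectrum
        spec = make_spectrum([4.0, 1.2, 1.0, 0.1], L=2, q=3)
        s = {lam: likelihood_contribution(lam) for lam in (4.0, 1.2, 1.0, 0.1)}
        expected = (s[0.1] + s[4.0]) / sum(s.values())
        assert interaction_likelihood_ratio(spec, 2) == pytest.approx(expected)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, random_spectrum):
        ps = hpdca.select_patterns(random_spectrum, 4)
        model = build_couplings(ps)
        model.h[:] = np.random.default_rng(0).normal(size=model.h.shape)
        model.h[:, -1] = 0.0
        path = tmp_path / "model.txt"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.e, model.e)
        np.testing.assert_array_equal(back.h, model.h)
        assert back.rank == model.rank
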