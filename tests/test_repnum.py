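import numpy as np
import pytest

from virodyn import (
    DepletionChainSpec,
    DiscretePMF,
    ModelParams,
    burst_pmf,
    derive,
    hellinger,
    mean_repnum,
    repnum_pmf_case1,
    repnum_pmf_case2,
    secondary_infection_kernel,
)
from virodyn.params import beta_for_theta


class TestCase1:
    def test_equals_burst_pmf_with_thinned_rate(self, small):
        d = derive(small)
        direct = burst_pmf(small, "budding", p_eff=d.theta * small.p)
        via = repnum_pmf_case1(small, "budding")
        np.testing.assert_allclose(via.probs, direct.probs, atol=1e-15)

    def test_zero_theta_gives_point_mass(self, small):
        pmf = repnum_pmf_case1(small.replace(beta=0.0), "bursting")
        assert pmf.probs.tolist() == [1.0]

    def test_unit_theta_recovers_burst_pmf(self, small):
        pmf = repnum_pmf_case1(small, "budding", theta=1.0)
        ref = burst_pmf(small, "budding")
        np.testing.assert_allclose(pmf.probs, ref.probs, atol=1e-15)

    def test_mean_matches_closed_form(self, table3, small):
        for params in (table3, small, table3.replace(nu_I=1.6)):
            for model in ("budding", "bursting"):
                pmf = repnum_pmf_case1(params, model)
                assert pmf.mean() == pytest.approx(
                    mean_repnum(params, model), rel=1e-6
                )


class TestDepletionKernel:
    def test_no_virions_no_infections(self, small):
        chain = DepletionChainSpec.from_params(small)
        np.testing.assert_array_equal(secondary_infection_kernel(0, chain), [1.0])

    def test_single_target_two_virions_enumerated(self):
        # T0=1, beta*T0 = c: xi_0 = 1/2; P(no infection) = (1/2)^2
        p = ModelParams(p=1, tau_I=1, n_I=1, beta=7.0, c=7.0, T0=1)
        chain = DepletionChainSpec.from_params(p)
        np.testing.assert_allclose(
            secondary_infection_kernel(2, chain), [0.25, 0.75]
        )

    def test_exhaustive_enumeration_small_chain(self):
        # T0=2, b=3: compare against brute-force path enumeration
        p = ModelParams(p=1, tau_I=1, n_I=1, beta=0.02, c=7.0, T0=2)
        xi = [0.02 * 2 / (0.02 * 2 + 7), 0.02 * 1 / (0.02 * 1 + 7)]
        probs = np.zeros(3)
        for path in range(2**3):  # each virion: infect-attempt sequencing
            prob, state = 1.0, 0
            for step in range(3):
                infect = (path >> step) & 1
                if state >= 2:
                    ok = infect == 0
                    prob *= 1.0 if ok else 0.0
                    continue
                prob *= xi[state] if infect else 1 - xi[state]
                state += infect
            probs[state] += prob
        chain = DepletionChainSpec.from_params(p)
        np.testing.assert_allclose(secondary_infection_kernel(3, chain), probs, atol=1e-15)

    def test_constant_xi_matches_binomial(self):
        # with all xi_i pinned to theta the kernel is binomial(b, theta)
        theta = 0.3
        chain = DepletionChainSpec(T0=10**9, xi=np.full(50, theta))
        from scipy.stats import binom

        got = secondary_infection_kernel(12, chain)
        np.testing.assert_allclose(got, binom.pmf(np.arange(13), 12, theta), atol=1e-12)

    def test_kernel_sums_to_one(self, small):
        chain = DepletionChainSpec.from_params(small)
        for b in (1, 5, 40, 300):
            assert secondary_infection_kernel(b, chain).sum() == pytest.approx(1.0)


class TestCase2:
    def test_support_bounded_by_target_cells(self, small):
        p = small.replace(T0=7, beta=1.0)
        pmf = repnum_pmf_case2(p, "budding")
        assert pmf.max_value <= 7

    def test_single_target_matches_pgf_identity(self, small):
        # T0=1: P(R=0) = E[(1-xi_0)^B], the burst p.g.f. at 1-xi_0
        p = small.replace(T0=1, beta=2.0)
        xi0 = 2.0 / (2.0 + p.c)
        burst = burst_pmf(p, "bursting")
        expected = burst.pgf(1.0 - xi0)
        pmf = repnum_pmf_case2(p, "bursting")
        assert pmf.p0() == pytest.approx(expected, abs=1e-10)

    def test_mean_never_exceeds_case1(self, small, table3):
        for params in (small, small.replace(T0=20, beta=0.05), table3.replace(nu_I=1.0)):
            m1 = repnum_pmf_case1(params, "budding").mean()
            m2 = repnum_pmf_case2(params, "budding").mean()
            assert m2 <= m1 + 1e-9

    def test_converges_to_case1_along_T0_ladder(self, small):
        # fixed theta, growing pool: Hellinger distance must shrink
        theta = 0.2
        dists = []
        for T0 in (30, 300, 3000):
            params = small.replace(T0=T0, beta=beta_for_theta(theta, T0, small.c))
            p1 = repnum_pmf_case1(params, "budding")
            p2 = repnum_pmf_case2(params, "budding")
            dists.append(hellinger(p1, p2))
        assert dists[0] > dists[1] > dists[2]
        assert dists[2] < 0.01


class TestHellinger:
    def test_identical_distributions(self, small):
        pmf = repnum_pmf_case1(small, "budding")
        assert hellinger(pmf, pmf) == 0.0

    def test_disjoint_point_masses(self):
        assert hellinger(
            DiscretePMF.point_mass(0), DiscretePMF.point_mass(3)
        ) == pytest.approx(1.0)

    def test_half_half_versus_point_mass(self):
        p = DiscretePMF(np.array([0.5, 0.5]))
        q = DiscretePMF(np.array([1.0, 0.0]))
        assert hellinger(p, q) == pytest.approx(np.sqrt(1 - np.sqrt(0.5)), rel=1e-12)

    def test_rejects_heavy_tails(self):
        p = DiscretePMF(np.array([0.9]), tail_mass=0.1)
        with pytest.raises(ValueError, match="tail"):
            hellinger(p, p)


class TestMeanRepnum:
    def test_models_agree_without_killing(self, table3):
        assert mean_repnum(table3, "budding") == pytest.approx(
            mean_repnum(table3, "bursting")
        )
        assert mean_repnum(table3, "budding") == pytest.approx(10 / 17 * 1250)

    @pytest.mark.parametrize(
        "model,nu_I,expected",
        [
            ("budding", 0.0, 735), ("budding", 0.25, 623), ("budding", 0.5, 535),
            ("budding", 1.0, 407), ("budding", 1.6, 308),
            ("bursting", 0.25, 524), ("bursting", 0.5, 377),
            ("bursting", 1.0, 201), ("bursting", 1.6, 99),
        ],
    )
    def test_rounded_means_at_baseline(self, table3, model, nu_I, expected):
        got = mean_repnum(table3.replace(nu_I=nu_I), model)
        assert round(got) == expected
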