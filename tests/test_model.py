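import numpy as np
import pytest

from hgtlv.errors import InvariantError, ParameterError
from hgtlv.model import (
    CommunityModel,
    CommunityState,
    classic_rhs,
    convert_empirical_rate,
    effective_growth_rates,
    hgt_rhs,
)

from conftest import random_hgt_model, random_valid_state


def two_species_rhs_oracle(s1, s2, p1, p2, mu1, mu2, lam1, lam2,
                           gamma1, gamma2, eta, kappa, D):
    """Independent transcription of the four two-species ODEs.

    p1 is the subpopulation of species 1 carrying species 2's element and
    vice versa; the donor pools are (s2 + p1) and (s1 + p2).
    """
    comp1 = 1 - s1 - gamma2 * s2
    comp2 = 1 - s2 - gamma1 * s1
    mu1e = mu1 * (1 + lam2 * p1 / s1)
    mu2e = mu2 * (1 + lam1 * p2 / s2)
    ds1 = mu1e * s1 * comp1 - D * s1
    ds2 = mu2e * s2 * comp2 - D * s2
    dp1 = mu1 * (1 + lam2) * p1 * comp1 + eta * (s2 + p1) * (s1 - p1) - (D + kappa) * p1
    dp2 = mu2 * (1 + lam1) * p2 * comp2 + eta * (s1 + p2) * (s2 - p2) - (D + kappa) * p2
    return ds1, ds2, dp1, dp2


class TestClassicRhs:
    @pytest.mark.parametrize(
        "mu, gamma, s, expected",
        [
            # single species at its dilution-corrected equilibrium (mu-D)/mu
            ([0.5], 0.0, [0.6], [0.0]),
            # extinction is absorbing
            ([0.5, 0.5], 0.9, [0.0, 0.0], [0.0, 0.0]),
            # symmetric interior fixed point 0.06/0.19
            ([0.5, 0.5], 0.9, [0.06 / 0.19, 0.06 / 0.19], [0.0, 0.0]),
        ],
    )
    def test_fixed_points(self, mu, gamma, s, expected):
        model = CommunityModel.from_growth_rates(mu, gamma=gamma, D=0.2)
        np.testing.assert_allclose(
            classic_rhs(np.array(s), model), expected, atol=1e-12
        )

    def test_shape_mismatch_raises(self):
        model = CommunityModel.from_growth_rates([0.5, 0.5])
        with pytest.raises(ParameterError):
            classic_rhs(np.array([0.5, 0.5, 0.5]), model)


class TestHgtRhs:
    def test_hand_evaluated_example(self):
        # mu=(0.5,0.4), mu0=0.5 => lam=(0,-0.2); worked through the four
        # two-species equations by hand at s=(0.5,0.5), p=(0.1,0.1)
        model = CommunityModel.from_growth_rates(
            [0.5, 0.4], mu0=0.5, gamma=0.9, eta=0.1, kappa=0.005, D=0.2
        )
        state = CommunityState(s=[0.5, 0.5], p=[[0.5, 0.1], [0.1, 0.5]])
        ds, dp = hgt_rhs(state, model)
        np.testing.assert_allclose(ds, [-0.088, -0.09], atol=1e-12)
        np.testing.assert_allclose([dp[0, 1], dp[1, 0]], [0.0055, 0.0055], atol=1e-12)

    def test_matches_two_species_oracle_at_random_states(self, rng):
        for _ in range(50):
            mu = rng.uniform(0.25, 0.95, 2)
            lam = mu / 0.5 - 1.0
            s = rng.uniform(0.05, 0.7, 2)
            p = rng.uniform(0.0, 0.999, 2) * s
            model = CommunityModel.from_growth_rates(
                mu, mu0=0.5, gamma=0.9, eta=0.1, kappa=0.005, D=0.2
            )
            state = CommunityState(s=s, p=[[s[0], p[0]], [p[1], s[1]]])
            ds, dp = hgt_rhs(state, model)
            ds1, ds2, dp1, dp2 = two_species_rhs_oracle(
                s[0], s[1], p[0], p[1], mu[0], mu[1], lam[0], lam[1],
                0.9, 0.9, 0.1, 0.005, 0.2,
            )
            np.testing.assert_allclose(ds, [ds1, ds2], rtol=1e-12)
            np.testing.assert_allclose([dp[0, 1], dp[1, 0]], [dp1, dp2], rtol=1e-12)

    def test_reduces_to_classic_without_transfer(self, rng):
        for _ in range(10):
            model = random_hgt_model(rng, m=4, eta_max=0.0)
            s = rng.uniform(0.05, 0.5, 4)
            state = CommunityState(s=s)  # no transconjugants
            ds, dp = hgt_rhs(state, model)
            np.testing.assert_allclose(ds, classic_rhs(s, model), rtol=1e-12)
            assert np.all(dp == 0)

    def test_saturation_boundary(self, rng):
        # at p_ij = s_i the transfer term vanishes; with kappa = 0 every
        # subpopulation derivative must exactly track its species
        model = CommunityModel.from_growth_rates(
            rng.uniform(0.4, 0.6, 3), gamma=0.9, eta=0.2, kappa=0.0, D=0.2
        )
        s = rng.uniform(0.1, 0.5, 3)
        state = CommunityState(s=s, p=np.tile(s[:, None], (1, 3)))
        ds, dp = hgt_rhs(state, model)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(
            dp[off], np.tile(ds[:, None], (1, 3))[off], rtol=1e-12
        )

    def test_two_species_bookkeeping_identity(self, rng):
        # species growth is the exact sum of its subpopulations' growth:
        # mu_e * s = (s - p) * mu + p * mu * (1 + lam_other)
        for _ in range(25):
            mu = rng.uniform(0.3, 0.9, 2)
            model = CommunityModel.from_growth_rates(mu, mu0=0.5, eta=0.05)
            s = rng.uniform(0.05, 0.7, 2)
            p = rng.uniform(0.0, 1.0, 2) * s
            state = CommunityState(s=s, p=[[s[0], p[0]], [p[1], s[1]]])
            mu_e = effective_growth_rates(state, model)
            lam = mu / 0.5 - 1.0
            expected = (s - p) * mu + p * mu * (1 + lam[::-1])
            np.testing.assert_allclose(mu_e * s, expected, rtol=1e-12)

    def test_permutation_equivariance(self, rng):
        m = 5
        model = random_hgt_model(rng, m=m)
        state = random_valid_state(rng, m)
        perm = rng.permutation(m)
        ds, dp = hgt_rhs(state, model)
        perm_model = CommunityModel(
            m=m, mu0=model.mu0[perm], mu=model.mu[perm],
            lam=model.lam[np.ix_(perm, perm)], gamma=model.gamma[np.ix_(perm, perm)],
            eta=model.eta[np.ix_(perm, perm, perm)], kappa=model.kappa[np.ix_(perm, perm)],
            D=model.D,
        )
        perm_state = CommunityState(s=state.s[perm], p=state.p[np.ix_(perm, perm)])
        ds_p, dp_p = hgt_rhs(perm_state, perm_model)
        np.testing.assert_allclose(ds_p, ds[perm], rtol=1e-12)
        np.testing.assert_allclose(dp_p, dp[np.ix_(perm, perm)], rtol=1e-12)

    def test_nonnegativity_guard(self, rng):
        # s_i = 0 pins ds_i at 0; p_ij = 0 cannot be driven negative
        for _ in range(20):
            m = 4
            model = random_hgt_model(rng, m=m)
            state = random_valid_state(rng, m)
            state.s[0] = 0.0
            state.p[0, :] = 0.0
            state.p[2, 3] = 0.0
            state = CommunityState(s=state.s, p=state.p)
            ds, dp = hgt_rhs(state, model)
            assert ds[0] == 0.0
            assert dp[2, 3] >= 0.0
            assert np.all(dp[0, 1:] >= 0.0)

    def test_eta_constructor_forms_agree(self, rng):
        m = 3
        mu = rng.uniform(0.4, 0.6, m)
        state = random_valid_state(rng, m)
        by_scalar = CommunityModel.from_growth_rates(mu, eta=0.15)
        by_matrix = CommunityModel.from_growth_rates(mu, eta=np.full((m, m), 0.15))
        by_tensor = CommunityModel.from_growth_rates(mu, eta=np.full((m, m, m), 0.15))
        ref = hgt_rhs(state, by_scalar)
        for other in (by_matrix, by_tensor):
            alt = hgt_rhs(state, other)
            np.testing.assert_allclose(alt[0], ref[0], rtol=1e-12)
            np.testing.assert_allclose(alt[1], ref[1], rtol=1e-12)


class TestEffectiveGrowthRates:
    def test_neutral_elements(self, rng):
        model = CommunityModel.from_growth_rates([0.5, 0.5, 0.5], mu0=0.5)  # lam = 0
        state = random_valid_state(rng, 3)
        np.testing.assert_allclose(effective_growth_rates(state, model), model.mu)

    def test_half_penetrance_example(self):
        # mu1 = 0.5, lam2 = -0.2, p1/s1 = 0.5 -> mu1_e = 0.5 * 0.9 = 0.45
        model = CommunityModel.from_growth_rates([0.5, 0.4], mu0=0.5)
        state = CommunityState(s=[0.4, 0.4], p=[[0.4, 0.2], [0.0, 0.4]])
        mu_e = effective_growth_rates(state, model)
        assert mu_e[0] == pytest.approx(0.45)
        assert mu_e[1] == pytest.approx(0.4)

    def test_full_penetrance_product(self, rng):
        mu = rng.uniform(0.4, 0.6, 4)
        model = CommunityModel.from_growth_rates(mu, mu0=0.5)
        s = rng.uniform(0.1, 0.5, 4)
        state = CommunityState(s=s, p=np.tile(s[:, None], (1, 4)))
        lam = mu / 0.5 - 1.0
        expected = np.array(
            [mu[i] * np.prod([1 + lam[j] for j in range(4) if j != i]) for i in range(4)]
        )
        np.testing.assert_allclose(effective_growth_rates(state, model), expected, rtol=1e-12)

    def test_extinct_species_gets_static_rate(self):
        model = CommunityModel.from_growth_rates([0.5, 0.4], mu0=0.5)
        state = CommunityState(s=[0.0, 0.4], p=np.zeros((2, 2)))
        assert effective_growth_rates(state, model)[0] == pytest.approx(0.5)


class TestAdditiveComposition:
    def test_lambda_derivation_and_effective_rate(self):
        model = CommunityModel.from_growth_rates(
            [0.6, 0.45], mu0=0.5, composition="additive"
        )
        np.testing.assert_allclose(model.lam[:, 0], 0.1)
        np.testing.assert_allclose(model.lam[:, 1], -0.05)
        state = CommunityState(s=[0.5, 0.5], p=[[0.5, 0.25], [0.1, 0.5]])
        mu_e = effective_growth_rates(state, model)
        # additive: mu_e = mu + sum_j lam_ij p_ij/s_i
        assert mu_e[0] == pytest.approx(0.6 + (-0.05) * 0.5)
        assert mu_e[1] == pytest.approx(0.45 + 0.1 * 0.2)


class TestValidation:
    def test_inconsistent_mu_lam_rejected(self):
        with pytest.raises(ParameterError, match="inconsistent"):
            CommunityModel(
                m=2, mu0=[0.5, 0.5], mu=[0.6, 0.6], lam=np.zeros((2, 2)),
                gamma=0.9, eta=0.0, kappa=0.005, D=0.2,
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"D": -0.1},
            {"eta": -0.05},
            {"kappa": -1e-3},
        ],
    )
    def test_negative_rates_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            CommunityModel.from_growth_rates([0.5, 0.5], **kwargs)

    def test_bad_eta_shape_rejected(self):
        with pytest.raises(ParameterError, match="eta"):
            CommunityModel.from_growth_rates([0.5, 0.5], eta=np.zeros((3, 3)))

    def test_state_invariant_check(self):
        state = CommunityState(s=[0.2, 0.2], p=[[0.2, 0.5], [0.0, 0.2]])
        with pytest.raises(InvariantError):
            state.validate()

    def test_flat_roundtrip_and_diagonal_alias(self, rng):
        state = random_valid_state(rng, 4)
        back = CommunityState.from_flat(state.to_flat(), 4)
        np.testing.assert_array_equal(back.s, state.s)
        np.testing.assert_array_equal(back.p, state.p)
        np.testing.assert_array_equal(np.diag(state.p), state.s)


class TestConvertEmpiricalRate:
    @pytest.mark.parametrize(
        "eta_c, N_m, expected",
        [(0.0, 1e9, 0.0), (2e-10, 1e9, 0.2), (1e-12, 1e5, 1e-7)],
    )
    def test_conversion(self, eta_c, N_m, expected):
        assert convert_empirical_rate(eta_c, N_m) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            convert_empirical_rate(-1e-10, 1e9)
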