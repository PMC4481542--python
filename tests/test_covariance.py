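import warnings

import numpy as np
import pytest

from monma import (
    Model1Params,
    Model2Params,
    delta_block,
    omega_block_model2,
    rho_limits,
    sigma_block_model1,
    verify_half_rho_identity,
)
from monma.covariance import CovarianceError, omega_patterns
from monma.network import ContrastBlock, ContrastRow

from conftest import random_three_arm_block


def _block_2arm(s_R=0.5, s_D=0.4, y=(0.1, -0.2)):
    rows = [ContrastRow("A", "B", "R"), ContrastRow("A", "B", "D")]
    sigma1 = np.diag([s_R**2, s_D**2])
    sigma2 = np.array([[0.0, s_R * s_D], [s_R * s_D, 0.0]])
    return ContrastBlock("S", rows, np.array(y), sigma1, sigma2, 2)


def _block_3arm(sd=(1.0, 1.0, 1.0, 1.0), kappa=0.5):
    rows = [
        ContrastRow("A", "B", "R"), ContrastRow("A", "B", "D"),
        ContrastRow("A", "C", "R"), ContrastRow("A", "C", "D"),
    ]
    sd = np.asarray(sd, dtype=float)
    sigma1 = np.diag(sd**2)
    sigma1[0, 2] = sigma1[2, 0] = kappa       # shared-arm, outcome R
    sigma1[1, 3] = sigma1[3, 1] = kappa       # shared-arm, outcome D
    sigma2 = np.zeros((4, 4))
    sigma2[0, 1] = sigma2[1, 0] = sd[0] * sd[1]
    sigma2[2, 3] = sigma2[3, 2] = sd[2] * sd[3]
    sigma2[0, 3] = sigma2[3, 0] = 0.5 * sd[0] * sd[3]
    sigma2[1, 2] = sigma2[2, 1] = 0.5 * sd[1] * sd[2]
    return ContrastBlock("S3", rows, np.zeros(4), sigma1, sigma2, 3)


class TestDeltaBlock:
    def test_zero_heterogeneity_gives_zero_matrix(self):
        p = Model1Params(0.0, 0.0, -0.5)
        np.testing.assert_array_equal(delta_block(p, 2), np.zeros((2, 2)))

    def test_two_arm_numeric(self):
        p = Model1Params(0.3, 0.4, -0.5)
        np.testing.assert_allclose(
            delta_block(p, 2),
            [[0.09, -0.06], [-0.06, 0.16]],
            atol=1e-15,
        )

    def test_three_arm_shared_arm_covariance_is_half_tau2(self):
        p = Model1Params(1.0, 0.7, 0.0)
        D = delta_block(p, 3)
        assert D[0, 2] == pytest.approx(0.5)  # cov(delta_ABR, delta_ACR)

    def test_three_arm_pattern_decomposition(self):
        """4x4 block equals tauR^2 P1 + tauD^2 P2 + rho tauR tauD P3 entrywise."""
        P1 = np.array([
            [1, 0, 0.5, 0], [0, 0, 0, 0], [0.5, 0, 1, 0], [0, 0, 0, 0],
        ])
        P2 = np.array([
            [0, 0, 0, 0], [0, 1, 0, 0.5], [0, 0, 0, 0], [0, 0.5, 0, 1],
        ])
        P3 = np.array([
            [0, 1, 0, 0.5], [1, 0, 0.5, 0], [0, 0.5, 0, 1], [0.5, 0, 1, 0],
        ])
        tr, td, rt = 0.31, 0.47, -0.63
        expected = tr**2 * P1 + td**2 * P2 + rt * tr * td * P3
        np.testing.assert_allclose(
            delta_block(Model1Params(tr, td, rt), 3), expected, atol=1e-15
        )

    def test_single_outcome_subset(self):
        p = Model1Params(0.5, 0.9, -0.4)
        D = delta_block(p, 3, outcomes_present=("R",))
        np.testing.assert_allclose(D, [[0.25, 0.125], [0.125, 0.25]], atol=1e-15)

    def test_more_than_three_arms_refused(self):
        with pytest.raises(CovarianceError, match="unsupported"):
            delta_block(Model1Params(0.1, 0.1, 0.0), 4)

    @pytest.mark.parametrize("rho_tau", [-0.99, -0.5, 0.0, 0.5, 0.99])
    @pytest.mark.parametrize("n_arms", [2, 3])
    def test_symmetric_psd(self, rho_tau, n_arms):
        D = delta_block(Model1Params(0.3, 0.6, rho_tau), n_arms)
        np.testing.assert_allclose(D, D.T, atol=1e-15)
        assert np.all(np.linalg.eigvalsh(D) > -1e-12)


class TestSigmaBlockModel1:
    def test_two_arm_cross_outcome_entry(self):
        b = _block_2arm(s_R=0.5, s_D=0.4)
        S = sigma_block_model1(b, -0.6)
        assert S[0, 1] == pytest.approx(-0.6 * 0.5 * 0.4, abs=1e-15)

    def test_rho_zero_returns_sigma1_with_kappa(self):
        b = _block_3arm(kappa=0.3)
        S = sigma_block_model1(b, 0.0)
        np.testing.assert_array_equal(S, b.sigma1)
        assert S[0, 2] == 0.3

    def test_three_arm_cross_entries_halved(self):
        b = _block_3arm(sd=(0.6, 0.7, 0.8, 0.9), kappa=0.1)
        rho = -0.5
        S = sigma_block_model1(b, rho)
        assert S[0, 3] == pytest.approx(rho / 2 * 0.6 * 0.9, abs=1e-15)
        assert S[1, 2] == pytest.approx(rho / 2 * 0.7 * 0.8, abs=1e-15)
        assert S[0, 1] == pytest.approx(rho * 0.6 * 0.7, abs=1e-15)

    def test_rho_outside_limits_rejected(self):
        b = _block_3arm(kappa=0.9)  # tight PD interval
        lim = rho_limits(b)
        with pytest.raises(CovarianceError, match="limits"):
            sigma_block_model1(b, lim.u + 0.05)


def _grid_limits(block, step=1e-3):
    """Brute-force eigen-scan oracle for the PD interval around 0."""
    grid = np.arange(-1.0, 1.0 + step, step)
    V = block.sigma1[None] + grid[:, None, None] * block.sigma2[None]
    lam = np.linalg.eigvalsh(V)[:, 0]
    ok = lam > 0.0
    i0 = np.argmin(np.abs(grid))
    lo = i0
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(grid) - 1 and ok[hi + 1]:
        hi += 1
    return grid[lo], grid[hi]


class TestRhoLimits:
    def test_two_arm_full_interval(self):
        lim = rho_limits(_block_2arm())
        assert lim.l == pytest.approx(-1.0, abs=2e-6)
        assert lim.u == pytest.approx(1.0, abs=2e-6)

    def test_single_outcome_block_constant_in_rho(self):
        rows = [ContrastRow("A", "B", "R"), ContrastRow("A", "C", "R")]
        b = ContrastBlock(
            "S", rows, np.zeros(2), np.array([[0.2, 0.05], [0.05, 0.3]]),
            np.zeros((2, 2)), 3,
        )
        lim = rho_limits(b)
        assert (lim.l, lim.u) == (-1.0, 1.0)

    def test_balanced_block_matches_grid_oracle(self):
        b = _block_3arm(sd=(1.0, 1.0, 1.0, 1.0), kappa=0.5)
        lim = rho_limits(b)
        glo, ghi = _grid_limits(b)
        assert lim.l == pytest.approx(glo, abs=2e-3)
        assert lim.u == pytest.approx(ghi, abs=2e-3)

    def test_random_blocks_match_grid_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            b = random_three_arm_block(rng)
            lim = rho_limits(b)
            glo, ghi = _grid_limits(b)
            assert lim.l == pytest.approx(glo, abs=2e-3)
            assert lim.u == pytest.approx(ghi, abs=2e-3)

    def test_boundary_eigenvalue_near_zero(self):
        b = _block_3arm(kappa=0.5)
        lim = rho_limits(b)
        for r in (lim.l, lim.u):
            if -1.0 < r < 1.0:
                lam = np.linalg.eigvalsh(b.sigma(r))[0]
                assert abs(lam) < 1e-4

    def test_non_pd_sigma1_rejected(self):
        b = _block_3arm(kappa=1.5)  # kappa > variances: sigma1 indefinite
        with pytest.raises(CovarianceError, match="not positive definite"):
            rho_limits(b)

    def test_interior_of_interval_is_pd(self):
        rng = np.random.default_rng(7)
        b = random_three_arm_block(rng)
        lim = rho_limits(b)
        for r in np.linspace(lim.l + 1e-4, lim.u - 1e-4, 9):
            np.linalg.cholesky(b.sigma(r))  # raises if not PD


class TestOmegaBlockModel2:
    def test_two_arm_numeric(self):
        b = _block_2arm(s_R=0.2, s_D=0.3)  # variances 0.04, 0.09
        om = omega_block_model2(b, Model2Params(np.sqrt(0.05), np.sqrt(0.07), -0.5))
        # zeta_R = 0.09, zeta_D = 0.16
        np.testing.assert_allclose(np.diag(om), [0.09, 0.16], atol=1e-15)
        assert om[0, 1] == pytest.approx(-0.5 * 0.3 * 0.4, abs=1e-12)

    def test_psi_zero_reduces_to_within_study_form(self):
        b = _block_2arm(s_R=0.5, s_D=0.4)
        om = omega_block_model2(b, Model2Params(0.0, 0.0, -0.6))
        np.testing.assert_allclose(om, sigma_block_model1(b, -0.6), atol=1e-14)

    def test_three_arm_same_outcome_half_coefficient(self):
        b = _block_3arm(sd=(0.5, 0.6, 0.7, 0.8), kappa=0.1)
        p = Model2Params(0.3, 0.2, -0.4)
        om = omega_block_model2(b, p)
        z = np.diag(b.sigma1) + np.array([0.09, 0.04, 0.09, 0.04])
        assert om[0, 2] == pytest.approx(0.5 * np.sqrt(z[0] * z[2]), abs=1e-12)
        assert om[1, 3] == pytest.approx(0.5 * np.sqrt(z[1] * z[3]), abs=1e-12)
        assert om[0, 3] == pytest.approx(-0.2 * np.sqrt(z[0] * z[3]), abs=1e-12)
        assert om[0, 1] == pytest.approx(-0.4 * np.sqrt(z[0] * z[1]), abs=1e-12)

    def test_model2_with_psi0_matches_model1_with_half_kappa(self):
        """With kappa replaced by sigma*sigma/2 the two structures coincide."""
        sd = (0.5, 0.6, 0.7, 0.8)
        rho = -0.45
        b2 = _block_3arm(sd=sd)
        # model 1 block whose kappas follow the balanced-arm value
        s1 = b2.sigma1.copy()
        s1[0, 2] = s1[2, 0] = 0.5 * sd[0] * sd[2]
        s1[1, 3] = s1[3, 1] = 0.5 * sd[1] * sd[3]
        b1 = ContrastBlock("S3", b2.rows, b2.y, s1, b2.sigma2, 3)
        np.testing.assert_allclose(
            omega_block_model2(b1, Model2Params(0.0, 0.0, rho)),
            sigma_block_model1(b1, rho),
            atol=1e-14,
        )

    @pytest.mark.parametrize("rho_h", [-0.95, -0.4, 0.0, 0.6, 0.95])
    def test_always_pd_inside_open_interval(self, rho_h):
        rng = np.random.default_rng(3)
        for _ in range(5):
            b = random_three_arm_block(rng)
            om = omega_block_model2(b, Model2Params(0.3, 0.2, rho_h))
            np.testing.assert_allclose(om, om.T, atol=1e-14)
            np.linalg.cholesky(om)

    def test_omega_patterns_cover_all_cells(self):
        rows = [
            ContrastRow("A", "B", "R"), ContrastRow("A", "B", "D"),
            ContrastRow("A", "C", "R"), ContrastRow("A", "C", "D"),
        ]
        C0, C1 = omega_patterns(rows)
        # each off-diagonal cell is in exactly one pattern
        off = ~np.eye(4, dtype=bool)
        assert np.all((C0[off] != 0) ^ (C1[off] != 0))


class TestHalfRhoIdentity:
    def test_zero_latent_correlation_gives_near_zero(self):
        res = verify_half_rho_identity(
            n_per_arm=100, latent_rho=0.0, n_sim=20_000, seed=1
        )
        assert abs(res.rho_same) < 0.03
        assert abs(res.rho_cross) < 0.03

    def test_unbalanced_design_warns_and_deviates(self):
        with pytest.warns(UserWarning, match="unbalanced"):
            res = verify_half_rho_identity(
                n_per_arm=(30, 300, 3000), latent_rho=-0.7, n_sim=30_000, seed=2
            )
        # with strongly unbalanced arms the 1/2 ratio no longer holds
        assert abs(res.ratio - 0.5) > 0.05

    def test_ratio_sign_follows_latent_correlation(self):
        res = verify_half_rho_identity(
            n_per_arm=150, latent_rho=-0.5, n_sim=20_000, seed=3
        )
        assert res.rho_same < -0.2
        assert res.rho_cross < 0.0
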