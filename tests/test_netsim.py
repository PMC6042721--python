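"""Solution networks, covariance construction, sampling and the study runner."""

import numpy as np
import pytest
import yaml

from mnlnet import netsim
from mnlnet.comparators import score_network


class TestGenerateSolutionNetwork:
    def test_pure_band_link_count(self):
        S = netsim.generate_solution_network(68, p_extra=0.0, seed=0)
        assert S.sum() / 2 == (68 - 1) + (68 - 2) == 133

    def test_total_potential_pairs_at_68_rois(self):
        K = 68
        S = netsim.generate_solution_network(K, 0.1, seed=0)
        assert K * (K - 1) // 2 == 2278
        iu = np.triu_indices(K, 1)
        assert len(iu[0]) == 2278 and S.shape == (K, K)

    def test_band_always_present(self):
        S = netsim.generate_solution_network(20, 0.5, seed=1)
        for off in (1, 2):
            assert np.all(np.diag(S, k=off) == 1)

    def test_extra_link_rate_matches_binomial(self):
        extra_pairs = 2278 - 133
        counts = [
            netsim.generate_solution_network(68, 0.1, seed=s).sum() / 2 - 133
            for s in range(500)
        ]
        expected = 0.1 * extra_pairs
        se = np.sqrt(extra_pairs * 0.1 * 0.9 / 500)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            netsim.generate_solution_network(2, 0.1)


class TestNetworkToCovariance:
    def test_empty_network_gives_diagonal(self):
        S = np.zeros((6, 6))
        Omega = netsim.network_to_covariance(S, 0.7)
        assert np.allclose(Omega, np.eye(6))  # lambda_min(0) = 0 -> diag = 1

    def test_chain_matches_eigendecomposition_oracle(self):
        """K=3 chain: diagonal from an independent eigendecomposition of S."""
        S = np.zeros((3, 3))
        S[0, 1] = S[1, 0] = S[1, 2] = S[2, 1] = 1.0
        lam_min = np.linalg.eigvalsh(S)[0]
        assert lam_min == pytest.approx(-np.sqrt(2))
        Omega = netsim.network_to_covariance(S, 0.3)
        expected_diag = 0.3 * np.sqrt(2) + 1.0
        assert np.allclose(np.diag(Omega), expected_diag)
        assert Omega[0, 1] == 0.3 and Omega[0, 2] == 0.0
        assert np.linalg.eigvalsh(Omega)[0] > 0

    def test_support_matches_network(self):
        S = netsim.generate_solution_network(15, 0.2, seed=2)
        Omega = netsim.network_to_covariance(S, 1.3)
        off = ~np.eye(15, dtype=bool)
        assert np.array_equal(Omega[off] != 0, S[off] == 1)

    def test_pd_for_random_networks(self):
        for seed in range(25):
            S = netsim.generate_solution_network(30, 0.3, seed=seed)
            Omega = netsim.network_to_covariance(S, 5.0)
            assert np.linalg.eigvalsh(Omega)[0] > 0

    def test_bad_user_diagonal_reports_eigenvalue(self):
        S = netsim.generate_solution_network(10, 0.3, seed=3)
        with pytest.raises(ValueError, match="eigenvalue"):
            netsim.network_to_covariance(S, 1.0, diag_const=0.05)


class TestSampleData:
    def test_reproducible(self):
        Omega = np.eye(4)
        assert np.array_equal(
            netsim.sample_data(Omega, 50, seed=7), netsim.sample_data(Omega, 50, seed=7)
        )

    def test_sample_covariance_converges(self):
        S = np.zeros((5, 5))
        S[0, 1] = S[1, 0] = 1.0
        Omega = netsim.network_to_covariance(S, 0.5)
        B = netsim.sample_data(Omega, 100_000, seed=8)
        emp = B.T @ B / B.shape[0]
        # elementwise CLT bound: se of each entry ~ sqrt((o_ij^2 + o_ii o_jj)/N)
        se = np.sqrt((Omega**2 + np.outer(np.diag(Omega), np.diag(Omega))) / B.shape[0])
        assert np.all(np.abs(emp - Omega) < 5 * se)

    def test_identity_covariance_uncorrelated(self):
        B = netsim.sample_data(np.eye(6), 10_000, seed=9)
        R = np.corrcoef(B, rowvar=False)
        off = R[np.triu_indices(6, 1)]
        assert abs(off.mean()) < 3 / np.sqrt(10_000)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            netsim.sample_data(np.array([[1.0, 2.0], [2.0, 1.0]]), 10)


class TestStudyRunner:
    def test_pipeline_identity_and_schema(self):
        """Tiny smoke run: schema complete, scores well-formed, truth scores 1."""
        study = netsim.StudyConfig(
            K=10,
            sample_sizes=(100,),
            replicates=1,
            networks=(netsim.NetworkSpec("S1", 0.1, 3.0),),
            mnl={"restarts": 2},
            ppc_grid=(0.2,),
            seed=5,
        )
        df = netsim.run_simulation_study(study)
        assert set(df.columns) >= {
            "network", "N", "replicate", "method", "tuning",
            "tp", "fp", "tn", "fn", "sensitivity", "specificity", "error",
        }
        assert set(df["method"]) == {"mnl", "ppc"}
        assert (df["tp"] + df["fp"] + df["tn"] + df["fn"] == 45).all()
        truth = netsim.generate_solution_network(10, 0.1, seed=[5, 0, 100, 0, 0])
        s = score_network(truth, truth)
        assert s.sensitivity == 1.0 and s.specificity == 1.0

    def test_failed_evaluation_recorded_not_dropped(self):
        study = netsim.StudyConfig(
            K=8,
            sample_sizes=(50,),
            replicates=1,
            networks=(netsim.NetworkSpec("S1", 0.1, 3.0),),
            mnl=None,
            glasso_grid=(-1.0,),  # invalid penalty -> recorded failure row
            seed=6,
        )
        df = netsim.run_simulation_study(study)
        assert len(df) == 1
        assert df.loc[0, "error"].startswith("ValueError")
        assert np.isnan(df.loc[0, "sensitivity"])

    def test_mnl_consistency_small_scale(self):
        """Sensitivity improves with sample size on a scaled-down study."""
        study = netsim.StudyConfig(
            K=20,
            sample_sizes=(100, 500),
            replicates=2,
            networks=(netsim.NetworkSpec("S1", 0.1, 6.0),),
            mnl={"restarts": 5},
            seed=7,
        )
        df = netsim.run_simulation_study(study)
        g = df[df["method"] == "mnl"].groupby("N")["sensitivity"].mean()
        assert g[500] >= g[100] - 0.05

    def test_config_validation_and_yaml_roundtrip(self, tmp_path):
        with pytest.raises(ValueError):
            netsim.StudyConfig(replicates=0)
        with pytest.raises(ValueError):
            netsim.StudyConfig(sample_sizes=(1,))
        cfg = {
            "K": 12,
            "sample_sizes": [50],
            "replicates": 1,
            "networks": [{"name": "S2", "p_extra": 0.05, "offdiag_const": 2.0}],
            "ppc_grid": [0.1, 0.5],
            "seed": 3,
        }
        path = tmp_path / "study.yaml"
        path.write_text(yaml.safe_dump(cfg))
        study = netsim.StudyConfig.from_yaml(path)
        assert study.K == 12 and study.networks[0].offdiag_const == 2.0
        assert study.ppc_grid == (0.1, 0.5)


class TestSimulateCohort:
    def test_shapes_and_alignment(self):
        roi, cov, W = netsim.simulate_cohort(n_subjects=40, K=12, seed=1)
        assert roi.shape == (40, 13) and cov.shape == (40, 4)
        assert (roi["participant_id"] == cov["participant_id"]).all()
        assert W.shape == (12, 12)

    def test_residualised_cohort_recovers_noise_correlation(self):
        """Residualising on the true covariates recovers the CAR field's
        correlation structure (covariates independent of the noise)."""
        from mnlnet.car import build_precision
        from mnlnet.preprocess import residualize

        roi, cov, W = netsim.simulate_cohort(n_subjects=4000, K=10, seed=2)
        B = residualize(roi, cov).drop(columns="participant_id").to_numpy()
        target = np.linalg.inv(build_precision(W, 0.9))
        d = np.sqrt(np.diag(target))
        target_corr = target / np.outer(d, d)
        emp = np.corrcoef(B, rowvar=False)
        assert np.max(np.abs(emp - target_corr)) < 0.08
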