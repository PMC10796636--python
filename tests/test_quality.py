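"""Waveform feature space and spike-sorting quality metrics, checked
against brute-force geometric oracles."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from sternwm.quality import (isolation_distance, projection_distance,
                             quality_frame, snr_metrics, unit_quality_metrics,
                             waveform_features)
from sternwm.synth import (GeneratorConfig, generate_sternberg_session,
                           make_gaussian_feature_clouds, simulate_waveforms,
                           waveform_template)


class TestWaveformFeatures:
    def test_feature_columns_are_named_set(self, rng):
        # three scalar shape features plus the first five PCs
        wf = rng.normal(size=(20, 48))
        fm = waveform_features(wf)
        assert fm.features.shape == (20, len(fm.column_names))
        assert fm.column_names[:3] == ("energy", "peak_amplitude",
                                       "total_area")

    def test_impulse_waveform_features(self):
        wf = np.zeros((6, 32))
        wf[:, 5] = [3.0, -4.0, 2.0, 1.0, -1.0, 5.0]
        fm = waveform_features(wf)
        np.testing.assert_allclose(fm.features[:, 0], np.array([9, 16, 4, 1, 1, 25.0]))
        np.testing.assert_allclose(fm.features[:, 1], wf[:, 5])  # signed peak
        np.testing.assert_allclose(fm.features[:, 2], np.abs(wf[:, 5]))

    def test_pca_basis_orthonormal_and_matches_eigen_oracle(self, rng):
        wf = simulate_waveforms(200, 0, 50.0, 8.0, 40, rng)
        fm = waveform_features(wf)
        gram = fm.pca_basis.T @ fm.pca_basis
        assert np.allclose(gram, np.eye(5), atol=1e-9)
        assert np.all(np.diff(fm.explained_variance) <= 1e-9)
        # independent eigendecomposition of the normalized covariance
        energy = np.sum(wf ** 2, axis=1)
        X = wf / np.sqrt(energy)[:, None]
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(Xc, rowvar=False))
        top = evals[::-1][:5]
        assert np.allclose(fm.explained_variance, top, rtol=1e-8)
        for j in range(5):
            v = evecs[:, ::-1][:, j]
            dot = abs(v @ fm.pca_basis[:, j])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_too_few_spikes_rejected(self, rng):
        with pytest.raises(ValueError):
            waveform_features(rng.normal(size=(5, 16)))

    def test_degenerate_rows_flagged(self, rng):
        wf = rng.normal(size=(8, 16))
        wf[2] = 0.0
        fm = waveform_features(wf)
        assert fm.degenerate[2] and not fm.degenerate[0]


def brute_isolation_distance(cluster, noise):
    mu = cluster.mean(axis=0)
    cov_inv = np.linalg.inv(np.cov(cluster, rowvar=False))
    d2 = sorted(float((x - mu) @ cov_inv @ (x - mu)) for x in noise)
    return d2[len(cluster) - 1]


class TestIsolationDistance:
    def test_noise_at_cluster_mean_gives_zero(self, rng):
        cluster = rng.normal(size=(50, 3))
        noise = np.tile(cluster.mean(axis=0), (60, 1))
        assert isolation_distance(cluster, noise) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_radius_recovered(self, rng):
        """Noise placed so the n-th closest point sits at squared
        Mahalanobis radius 25."""
        cluster = rng.normal(size=(40, 2))
        mu = cluster.mean(axis=0)
        cov = np.cov(cluster, rowvar=False)
        L = np.linalg.cholesky(cov)
        directions = rng.normal(size=(60, 2))
        directions /= np.linalg.norm(directions, axis=1)[:, None]
        # 39 inside radius 5, the 40th at exactly 5, the rest outside
        radii = np.concatenate([np.linspace(0.5, 4.5, 39), [5.0],
                                np.linspace(6.0, 9.0, 20)])
        noise = mu + (directions * radii[:, None]) @ L.T
        assert isolation_distance(cluster, noise) == pytest.approx(25.0, rel=1e-9)

    def test_fewer_noise_than_cluster_is_undefined(self, rng):
        cluster = rng.normal(size=(30, 3))
        assert isolation_distance(cluster, rng.normal(size=(29, 3))) is None

    def test_singular_covariance_is_undefined(self):
        cluster = np.zeros((20, 3))
        cluster[:, 0] = np.arange(20)  # rank 1
        noise = np.random.default_rng(0).normal(size=(30, 3))
        assert isolation_distance(cluster, noise) is None

    @pytest.mark.parametrize("dim", [2, 10])
    def test_matches_brute_force_oracle(self, dim, rng):
        cluster, noise = make_gaussian_feature_clouds(
            200, 300, dim, np.full(dim, 2.0), (1.0, 2.0), seed=rng)
        assert isolation_distance(cluster, noise) == pytest.approx(
            brute_isolation_distance(cluster, noise), abs=1e-9)

    def test_monotone_in_noise_translation(self, rng):
        cluster = rng.normal(size=(80, 4))
        noise = rng.normal(size=(120, 4))
        direction = np.array([1.0, 0.0, 0.0, 0.0])
        values = [isolation_distance(cluster, noise + s * direction)
                  for s in (0.0, 1.0, 2.0, 4.0, 8.0)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestProjectionDistance:
    def test_known_separation_over_injected_sd(self, rng):
        d, s = 8.0, 0.5
        a = np.zeros((4000, 3))
        b = np.zeros((4000, 3))
        b[:, 0] = d
        a[:, 0] += rng.normal(0, s, 4000)
        b[:, 0] += rng.normal(0, s, 4000)
        assert projection_distance(a, b) == pytest.approx(d / s, rel=0.05)

    def test_identical_distributions_near_zero(self, rng):
        a = rng.normal(size=(2000, 4))
        b = rng.normal(size=(2000, 4))
        assert projection_distance(a, b) < 0.2

    def test_symmetric_and_rotation_invariant(self, rng):
        a = rng.normal(size=(100, 5)) + 3.0
        b = rng.normal(size=(120, 5))
        base = projection_distance(a, b)
        assert projection_distance(b, a) == pytest.approx(base, rel=1e-12)
        R = ortho_group.rvs(5, random_state=7)
        assert projection_distance(a @ R, b @ R) == pytest.approx(base, rel=1e-9)
        shift = rng.normal(size=5)
        assert projection_distance(a + shift, b + shift) == pytest.approx(
            base, rel=1e-9)

    def test_coincident_means_give_zero(self):
        pts = np.ones((10, 2))
        assert projection_distance(pts, pts) == 0.0


class TestSnr:
    def test_peak_over_noise_sd(self, rng):
        template = np.zeros(32)
        template[10] = 60.0
        wf = template + rng.normal(0, 10.0, size=(5000, 32))
        out = snr_metrics(wf)
        assert out["snr_peak"] == pytest.approx(6.0, rel=0.05)

    def test_template_amplitude_doubling_doubles_both(self, rng):
        # doubled signal amplitude at fixed noise level doubles the SNRs
        wf = simulate_waveforms(500, 0, 40.0, 5.0, 32,
                                np.random.default_rng(3))
        wf2 = simulate_waveforms(500, 0, 80.0, 5.0, 32,
                                 np.random.default_rng(3))
        a, b = snr_metrics(wf), snr_metrics(wf2)
        # identical noise draws, so only the residual noise mean (~0.2 uV)
        # keeps this from being exact
        assert b["snr_peak"] == pytest.approx(2 * a["snr_peak"], rel=0.02)
        assert b["snr_mean"] == pytest.approx(2 * a["snr_mean"], rel=0.05)

    def test_generator_ground_truth_recovered(self, rng):
        amplitude, noise_sd = 80.0, 12.5
        wf = simulate_waveforms(4000, 1, amplitude, noise_sd, 48, rng)
        out = snr_metrics(wf)
        peak = np.max(np.abs(amplitude * waveform_template(1, 48)))
        assert out["snr_peak"] == pytest.approx(peak / noise_sd, rel=0.05)


class TestSessionQuality:
    def test_lone_unit_has_no_isolation_distance(self):
        cfg = GeneratorConfig(seed=71, n_trials=10, n_concept=1,
                              n_maintenance=0, n_probe=0, n_null=0,
                              units_per_electrode=1, n_samples=32)
        s = generate_sternberg_session(cfg)
        metrics = unit_quality_metrics(s)
        assert metrics[0].isolation_distance is None
        assert metrics[0].pairwise_projection_distances == []

    def test_shared_electrode_metrics_defined(self, sternberg_session):
        metrics = unit_quality_metrics(sternberg_session)
        df = quality_frame(metrics)
        assert len(df) == len(sternberg_session.units)
        # paired units have projection distances, and each pair yields at
        # least one defined isolation distance (the smaller cluster's)
        assert df["mean_projection_distance"].notna().all()
        assert df["isolation_distance"].notna().sum() >= len(df) // 2
        assert (df["pct_isi_below"] == 0.0).all()  # 3 ms dead time planted
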