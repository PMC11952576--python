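"""Regularized Tikhonov inversion, chromophore unmixing, image metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import optarray as oa
from optarray.optics import extinction_matrix
from optarray.recon import (ReconConfig, build_regularized_system,
                            center_of_mass, hrf_to_od, image_timecourse,
                            localization_error, reconstruct, resolution_metric,
                            unmix_vertices)


def dense_tikhonov(A, y, alpha_spatial=1e-3, alpha_meas=1e-3):
    """Brute-force closed-form evaluation of the regularized inverse."""
    col = np.diag(A.T @ A)
    lam_sp = alpha_spatial * col.max()
    L = np.sqrt(col + lam_sp)
    Ah = A / L[None, :]
    AAt = Ah @ Ah.T
    lam = alpha_meas * np.max(np.diag(AAt))
    return np.diag(1.0 / L) @ Ah.T @ np.linalg.inv(AAt + lam * np.eye(
        A.shape[0])) @ y


class TestRegularizedSystem:
    def test_identity_limit(self):
        """A = I with alpha_spatial -> 0 gives L = I and A_hat = A."""
        A = np.eye(2)
        sysm = build_regularized_system(A, ReconConfig(alpha_spatial=1e-15))
        np.testing.assert_allclose(sysm.L_diag, 1.0, rtol=1e-7)
        np.testing.assert_allclose(sysm.A_hat, A, rtol=1e-7)

    def test_column_norms_bounded(self):
        """After rescaling, every column norm of A_hat is <= 1."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = np.abs(rng.standard_normal((5, 8)))
            sysm = build_regularized_system(A)
            norms = np.linalg.norm(sysm.A_hat, axis=0)
            assert np.all(norms <= 1.0 + 1e-12)

    def test_alpha_spatial_monotone_in_L(self):
        rng = np.random.default_rng(1)
        A = np.abs(rng.standard_normal((4, 6)))
        L1 = build_regularized_system(A, ReconConfig(alpha_spatial=1e-3)).L_diag
        L2 = build_regularized_system(A, ReconConfig(alpha_spatial=1e-2)).L_diag
        assert np.all(L2 > L1)

    def test_invalid_alphas(self):
        with pytest.raises(ValueError):
            ReconConfig(alpha_spatial=0.0)


class TestReconstruct:
    def test_zero_measurement_zero_image(self):
        A = np.abs(np.random.default_rng(2).standard_normal((3, 7)))
        sysm = build_regularized_system(A)
        assert np.allclose(reconstruct(np.zeros(3), sysm), 0.0)

    def test_toy_system_matches_closed_form(self):
        """2-channel x 3-vertex system against explicit matrix arithmetic."""
        A = np.array([[1.0, 0.5, 0.2], [0.1, 0.8, 0.4]])
        y = np.array([0.3, -0.2])
        sysm = build_regularized_system(A)
        np.testing.assert_allclose(reconstruct(y, sysm),
                                   dense_tikhonov(A, y), atol=1e-10)

    def test_oracle_equivalence_many_random_systems(self):
        """Matches the dense closed form to 1e-8 relative on 100 random
        systems up to 50 channels x 200 vertices."""
        rng = np.random.default_rng(12345)
        worst = 0.0
        for _ in range(100):
            m = rng.integers(2, 51)
            n = rng.integers(m, 201)
            A = np.abs(rng.standard_normal((m, n)))
            y = rng.standard_normal(m)
            x = reconstruct(y, build_regularized_system(A))
            x_ref = dense_tikhonov(A, y)
            worst = max(worst, np.linalg.norm(x - x_ref)
                        / np.linalg.norm(x_ref))
        assert worst < 1e-8

    def test_shrinkage_with_lambda(self):
        """||x|| decreases monotonically as alpha_meas grows."""
        rng = np.random.default_rng(3)
        A = np.abs(rng.standard_normal((6, 20)))
        y = rng.standard_normal(6)
        norms = []
        for am in (1e-4, 1e-2, 1.0, 100.0):
            sysm = build_regularized_system(A, ReconConfig(alpha_meas=am))
            norms.append(np.linalg.norm(reconstruct(y, sysm)))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_linearity_superposition(self):
        rng = np.random.default_rng(4)
        A = np.abs(rng.standard_normal((5, 15)))
        sysm = build_regularized_system(A)
        y1, y2 = rng.standard_normal(5), rng.standard_normal(5)
        np.testing.assert_allclose(
            reconstruct(y1 + 2 * y2, sysm),
            reconstruct(y1, sysm) + 2 * reconstruct(y2, sysm), atol=1e-10)

    def test_brain_only_mode_drops_scalp(self, arrays):
        probes, mesh, sens = arrays
        A = sens["sparse"][0]
        rows = probes["sparse"].long_channels
        sysm = build_regularized_system(A, ReconConfig(mode="brain_only"),
                                        channel_rows=rows)
        assert sysm.n_vertices == mesh.n_brain

    def test_scalp_perturbation_attribution(self, arrays):
        """A scalp-only perturbation lands mostly on scalp vertices in
        brain-and-scalp mode; brain-only mode is forced to explain it with
        brain vertices (higher brain energy fraction)."""
        probes, mesh, sens = arrays
        A = sens["sparse"][0]
        rows = probes["sparse"].long_channels
        x_true = np.zeros(A.values.shape[1])
        scalp_idx = mesh.n_brain + np.arange(mesh.n_scalp)
        x_true[scalp_idx] = 1.0
        y = A.values[rows] @ x_true
        both = reconstruct(y, build_regularized_system(
            A, ReconConfig(), channel_rows=rows))
        brain_only = reconstruct(y, build_regularized_system(
            A, ReconConfig(mode="brain_only"), channel_rows=rows))
        frac_both = np.sum(both[:mesh.n_brain] ** 2) / np.sum(both ** 2)
        frac_brain_only = 1.0  # by construction: no scalp columns exist
        assert np.sum(brain_only ** 2) > 0  # brain-only must use brain
        assert frac_both < 0.95 < frac_brain_only


class TestUnmixing:
    def test_zero_images(self):
        hb = unmix_vertices([np.zeros(5), np.zeros(5)])
        assert np.allclose(hb, 0.0)

    def test_roundtrip_through_extinction(self):
        rng = np.random.default_rng(5)
        hb_true = rng.standard_normal((12, 2))
        E = extinction_matrix((760.0, 850.0))
        mua = hb_true @ E.T
        hb = unmix_vertices([mua[:, 0], mua[:, 1]])
        np.testing.assert_allclose(hb, hb_true, atol=1e-12)

    def test_hbo_increase_dominates_850(self):
        """Pure HbO increase produces more absorption at 850 than 760 nm
        (the extinction table ordering)."""
        E = extinction_matrix((760.0, 850.0))
        mua = np.array([[1.0, 0.0]]) @ E.T
        assert mua[0, 1] > mua[0, 0]


class TestHrfToOD:
    def test_inverse_pair_with_conc(self, sparse_probe):
        rng = np.random.default_rng(6)
        hrf = rng.standard_normal((30, sparse_probe.n_channels, 2))
        od = hrf_to_od(hrf, sparse_probe)
        odts = oa.ODTimeSeries(od=od, sample_rate_hz=10.0,
                               channel_mask=np.ones(sparse_probe.n_channels,
                                                    bool),
                               events=[], probe=sparse_probe)
        back = oa.od_to_conc(odts)
        np.testing.assert_allclose(back.conc[:, :, :2], hrf, atol=1e-10)

    def test_zero_and_linearity(self, sparse_probe):
        z = hrf_to_od(np.zeros((4, sparse_probe.n_channels, 2)), sparse_probe)
        assert np.allclose(z, 0.0)
        rng = np.random.default_rng(7)
        h = rng.standard_normal((4, sparse_probe.n_channels, 2))
        np.testing.assert_allclose(hrf_to_od(2 * h, sparse_probe),
                                   2 * hrf_to_od(h, sparse_probe))


class TestImageTimecourse:
    def _setup(self, arrays):
        probes, mesh, sens = arrays
        probe = probes["sparse"]
        rows = probe.long_channels
        systems = tuple(build_regularized_system(s, ReconConfig(),
                                                 channel_rows=rows)
                        for s in sens["sparse"])
        return probe, rows, systems, mesh

    def test_zero_hrf_zero_series(self, arrays):
        probe, rows, systems, mesh = self._setup(arrays)
        fs = 24.4
        n_win = int(round(25 * fs)) + 1
        hrf = np.zeros((n_win, probe.n_channels, 2))
        time_s = -2 + np.arange(n_win) / fs
        steps, stack, roi = image_timecourse(hrf, time_s, systems, probe,
                                             channel_rows=rows,
                                             roi_vertices=[5])
        assert np.allclose(stack, 0.0) and np.allclose(roi, 0.0)

    def test_stack_has_26_steps(self, arrays):
        """-2..23 s at 1 s steps reconstructs 26 images."""
        probe, rows, systems, mesh = self._setup(arrays)
        fs = 24.4
        n_win = int(round(25 * fs)) + 1
        hrf = np.zeros((n_win, probe.n_channels, 2))
        time_s = -2 + np.arange(n_win) / fs
        steps, stack, _ = image_timecourse(hrf, time_s, systems, probe,
                                           channel_rows=rows)
        assert steps.size == 26 and stack.shape[0] == 26

    def test_single_vertex_roi_tracks_vertex(self, arrays):
        probe, rows, systems, mesh = self._setup(arrays)
        fs = 24.4
        n_win = int(round(25 * fs)) + 1
        rng = np.random.default_rng(8)
        hrf = 0.1 * rng.standard_normal((n_win, probe.n_channels, 2))
        time_s = -2 + np.arange(n_win) / fs
        steps, stack, roi = image_timecourse(hrf, time_s, systems, probe,
                                             channel_rows=rows,
                                             roi_vertices=[17])
        np.testing.assert_allclose(roi, stack[:, 17, :])

    def test_empty_roi_raises(self, arrays):
        probe, rows, systems, mesh = self._setup(arrays)
        with pytest.raises(ValueError):
            image_timecourse(np.zeros((10, probe.n_channels, 2)),
                             np.linspace(-2, 23, 10), systems, probe,
                             channel_rows=rows, roi_vertices=[])


class TestImageMetrics:
    def test_single_vertex(self):
        pos = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        vals = np.array([0.0, 2.5])
        np.testing.assert_allclose(center_of_mass(vals, pos), pos[1])
        assert resolution_metric(vals, pos) == 0.0

    def test_two_equal_vertices(self):
        pos = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        vals = np.array([1.0, 1.0])
        np.testing.assert_allclose(center_of_mass(vals, pos), [5.0, 0, 0])
        assert np.isclose(resolution_metric(vals, pos), 5.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_weighted_sums(self, seed):
        """Random 10-vertex images match the direct formula to 1e-12."""
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-50, 50, (10, 3))
        vals = rng.standard_normal(10)
        I = np.abs(vals)
        cm_ref = sum(I[i] * pos[i] for i in range(10)) / I.sum()
        np.testing.assert_allclose(center_of_mass(vals, pos), cm_ref,
                                   atol=1e-12)
        res_ref = sum(I[i] * np.linalg.norm(pos[i] - cm_ref)
                      for i in range(10)) / I.sum()
        assert abs(resolution_metric(vals, pos) - res_ref) < 1e-12

    def test_localization_error_345(self):
        """A center of mass offset by (3, 4, 0) mm gives 5 mm error."""
        pos = np.array([[3.0, 4.0, 0.0]])
        vals = np.array([1.0])
        assert np.isclose(localization_error(vals, pos, np.zeros(3)), 5.0)

    def test_all_zero_image_raises(self):
        with pytest.raises(ValueError):
            center_of_mass(np.zeros(4), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            resolution_metric(np.zeros(4), np.zeros((4, 3)))
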