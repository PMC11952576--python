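"""Synthetic data generator: paradigm, forward projection, noise, cohort."""

import numpy as np
import pytest

import optarray as oa
from optarray.optics import extinction_matrix
from optarray.simulate import (CohortSpec, _patch_pattern,
                               add_noise_and_artifacts, generate_group,
                               generate_paradigm)


class TestParadigm:
    def test_default_block_structure(self):
        """18 events, 9 per condition, each 18 s long."""
        events = generate_paradigm(oa.ParadigmSpec(), 0)
        assert len(events) == 18
        by_cond = {}
        for e in events:
            by_cond[e.condition] = by_cond.get(e.condition, 0) + 1
            assert e.duration_s == 18.0
        assert by_cond == {"congruent": 9, "incongruent": 9}

    def test_fixed_isi_onsets_deterministic(self):
        """ISI fixed at 10 s gives onsets 20, 48, 76, ... s."""
        spec = oa.ParadigmSpec(isi_range_s=(10.0, 10.0))
        events = generate_paradigm(spec, 5)
        onsets = [e.onset_s for e in events]
        np.testing.assert_allclose(onsets, 20.0 + 28.0 * np.arange(18))

    def test_total_duration_bounds(self):
        """Total run duration lies within the jitter sum bounds."""
        lo = 20 + 18 * 18 + 17 * 10
        hi = 20 + 18 * 18 + 17 * 15
        for seed in range(10):
            events = generate_paradigm(oa.ParadigmSpec(), seed)
            end = events[-1].onset_s + events[-1].duration_s
            assert lo <= end <= hi

    def test_mean_isi_matches_uniform(self):
        """Over many seeded paradigms the mean ISI is 12.5 +- 0.2 s."""
        spec = oa.ParadigmSpec()
        isis = []
        for seed in range(1000):
            events = generate_paradigm(spec, seed)
            on = np.array([e.onset_s for e in events])
            isis.extend(np.diff(on) - 18.0)
        assert abs(np.mean(isis) - 12.5) < 0.2

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            oa.ParadigmSpec(n_blocks=18, n_per_condition=8)


class TestVertexTimecourses:
    def test_zero_amplitudes_zero_brain(self, mesh):
        truth = oa.GroundTruth(activation_patches=[
            ("dlPFC_left", "incongruent", 0.0, 0.0, 40.0)])
        events = generate_paradigm(oa.ParadigmSpec(), 0)
        vt = oa.simulate_vertex_timecourses(truth, mesh, events, 5.0, seed=0)
        hbo = vt.hbo_dense()
        assert np.allclose(hbo[:, :mesh.n_brain], 0.0)

    def test_amplitude_linearity(self, mesh):
        events = generate_paradigm(oa.ParadigmSpec(), 0)
        t1 = oa.GroundTruth()
        vt1 = oa.simulate_vertex_timecourses(t1, mesh, events, 5.0, seed=2)
        doubled = vt1.scaled(2.0)
        np.testing.assert_allclose(doubled.hbo_dense(), 2 * vt1.hbo_dense())

    def test_block_peak_within_window(self, mesh):
        """A single block's vertex response peaks after onset and before
        offset + 10 s (numeric convolution oracle)."""
        spec = oa.ParadigmSpec(n_blocks=2, n_per_condition=1,
                               isi_range_s=(60.0, 60.0))
        events = generate_paradigm(spec, 0)
        truth = oa.GroundTruth()
        truth.systemic = oa.SystemicSpec(cardiac_amp_uM=0,
                                         respiration_amp_uM=0,
                                         mayer_amp_uM=0, drift_amp_uM=0)
        vt = oa.simulate_vertex_timecourses(truth, mesh, events, 10.0, seed=0)
        centroid = mesh.region_centroid("dlPFC_left")
        idx = mesh.region_vertices("dlPFC_left")
        v = idx[np.argmin(np.linalg.norm(
            mesh.brain_vertices[idx] - centroid, axis=1))]
        hbo = vt.hbo_dense()[:, v]
        t_peak = np.argmax(hbo) / 10.0
        assert any(e.onset_s < t_peak < e.onset_s + e.duration_s + 10.0
                   for e in events)

    def test_scalp_carries_systemic_only(self, mesh):
        truth = oa.GroundTruth()
        events = generate_paradigm(oa.ParadigmSpec(), 0)
        vt = oa.simulate_vertex_timecourses(truth, mesh, events, 5.0, seed=1)
        brain_rows = vt.spatial[:, :mesh.n_brain]
        scalp_rows = vt.spatial[:, mesh.n_brain:]
        # every component is either pure brain or pure scalp
        for k in range(vt.spatial.shape[0]):
            assert (brain_rows[k].any() != scalp_rows[k].any())


class TestForwardProject:
    def test_zero_series_constant_intensity(self, arrays):
        probes, mesh, sens = arrays
        events = generate_paradigm(oa.ParadigmSpec(), 0)
        truth = oa.GroundTruth(activation_patches=[],
                               systemic=oa.SystemicSpec(
                                   cardiac_amp_uM=0, respiration_amp_uM=0,
                                   mayer_amp_uM=0, drift_amp_uM=0))
        vt = oa.simulate_vertex_timecourses(truth, mesh, events, 5.0, seed=0)
        rec = oa.forward_project(vt, sens["sparse"], events, seed=1)
        assert np.allclose(rec.intensity, rec.intensity[0][None], atol=0)

    def test_od_roundtrip_to_machine_precision(self, noisefree_recording,
                                               arrays):
        """OD computed by the preprocessing chain equals the injected
        channel OD up to the per-channel baseline constant."""
        probes, mesh, sens = arrays
        rec = noisefree_recording
        truth = rec.ground_truth
        events = rec.events
        vt = oa.simulate_vertex_timecourses(truth, mesh, events, 24.4, seed=3)
        od = oa.intensity_to_od(rec)
        E = extinction_matrix(rec.wavelengths_nm)
        injected = np.zeros_like(od.od)
        for w, A in enumerate(sens["sparse"]):
            weights = vt.spatial @ A.values.T
            coef = E[w, 0] * vt.hbo_scale + E[w, 1] * vt.hbr_scale
            injected[:, :, w] = vt.temporal @ (weights * coef[:, None])
        diff = od.od - injected
        diff -= diff.mean(axis=0, keepdims=True)
        assert np.abs(diff).max() < 1e-10

    def test_mismatched_mesh_raises(self, arrays, mesh):
        probes, _mesh, sens = arrays
        events = generate_paradigm(oa.ParadigmSpec(), 0)
        truth = oa.GroundTruth()
        vt = oa.simulate_vertex_timecourses(truth, mesh, events, 5.0, seed=0)
        bad = oa.simulate_vertex_timecourses(truth, mesh, events, 5.0, seed=0)
        bad.spatial = bad.spatial[:, :100]
        with pytest.raises(ValueError):
            oa.forward_project(bad, sens["sparse"], events)


class TestNoise:
    def test_zero_noise_is_identity(self, noisefree_recording):
        truth = oa.GroundTruth(noise=oa.NoiseSpec(
            white_noise_density={}, pink_sd={}, spike_rate_per_min=0,
            shift_rate_per_min=0))
        out = add_noise_and_artifacts(noisefree_recording, truth, seed=0)
        np.testing.assert_array_equal(out.intensity,
                                      noisefree_recording.intensity)

    def test_deterministic_under_seed(self, noisefree_recording):
        truth = oa.GroundTruth()
        a = add_noise_and_artifacts(noisefree_recording, truth, seed=42)
        b = add_noise_and_artifacts(noisefree_recording, truth, seed=42)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_forced_dead_channels_prune_downstream(self, noisefree_recording):
        """Exactly the forced-dead channels fall below the 0.001 pruning
        threshold."""
        truth = oa.GroundTruth(noise=oa.NoiseSpec(
            white_noise_density={}, pink_sd={}, spike_rate_per_min=0,
            shift_rate_per_min=0, forced_dead_channels=(2, 7, 11)))
        out = add_noise_and_artifacts(noisefree_recording, truth, seed=0)
        prune = oa.prune_channels(out)
        assert sorted(np.flatnonzero(~prune.mask)) == [2, 7, 11]


class TestGroup:
    def test_cohort_structure_and_pairing(self, arrays):
        probes, mesh, sens = arrays
        cohort = CohortSpec(n_subjects=3)
        recs = generate_group(sens, mesh, cohort=cohort, seed=11)
        assert len(recs) == 6
        subjects = sorted({r.subject_id for r in recs})
        assert len(subjects) == 3
        by_subject = {}
        for r in recs:
            by_subject.setdefault(r.subject_id, []).append(r)
        for subj, pair in by_subject.items():
            assert sorted(r.array_id for r in pair) == ["hd", "sparse"]
            ev_a, ev_b = pair[0].events, pair[1].events
            assert [(e.condition, e.onset_s) for e in ev_a] == \
                [(e.condition, e.onset_s) for e in ev_b]
            amp_a = pair[0].ground_truth.activation_patches[0][2]
            amp_b = pair[1].ground_truth.activation_patches[0][2]
            assert amp_a == amp_b

    def test_determinism(self, arrays):
        probes, mesh, sens = arrays
        a = generate_group(sens, mesh, cohort=CohortSpec(n_subjects=2), seed=5)
        b = generate_group(sens, mesh, cohort=CohortSpec(n_subjects=2), seed=5)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.intensity, rb.intensity)

    def test_zero_jitter_shares_truth(self, arrays):
        probes, mesh, sens = arrays
        cohort = CohortSpec(n_subjects=2, amplitude_jitter_sd=0.0,
                            cardiac_jitter_sd_hz=0.0)
        recs = generate_group(sens, mesh, cohort=cohort, seed=5)
        amps = {r.ground_truth.activation_patches[0][2] for r in recs}
        assert len(amps) == 1

    def test_seventeen_subjects_thirtyfour_recordings(self, arrays):
        probes, mesh, sens = arrays
        recs = generate_group(sens, mesh, cohort=CohortSpec(n_subjects=17),
                              seed=1)
        assert len(recs) == 34
        assert len({r.subject_id for r in recs}) == 17
        assert {r.array_id for r in recs} == {"sparse", "hd"}
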