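"""Preprocessing chain: pruning, OD, motion correction, filtering, MBLL."""

import numpy as np
import pytest

import optarray as oa
from optarray.optics import extinction_matrix, hb_to_od
from optarray.preprocess import (AllChannelsPrunedError, block_windows,
                                 splinesg_correct)
from optarray.simulate import StimulusEvent

from conftest import make_short_recording


def _recording_from_intensity(intensity, fs=10.0):
    events = [StimulusEvent("congruent", 5.0, 5.0)]
    return oa.RawRecording(intensity=intensity, sample_rate_hz=fs,
                           events=events, subject_id="T", array_id="t")


class TestPruning:
    def test_low_intensity_pruned(self):
        """A constant channel at 0.0005 V fails the 0.001 intensity floor."""
        I = np.ones((100, 3, 2))
        I[:, 1, :] = 0.0005
        prune = oa.prune_channels(_recording_from_intensity(I))
        assert list(prune.mask) == [True, False, True]

    def test_snr_rule(self):
        """SNR 10 passes, SNR 4 fails the threshold of 5."""
        rng = np.random.default_rng(0)
        I = np.ones((20000, 3, 2))
        I[:, 1, :] = 1.0 + 0.1 * rng.standard_normal((20000, 2))   # SNR ~10
        I[:, 2, :] = 1.0 + 0.25 * rng.standard_normal((20000, 2))  # SNR ~4
        I = np.abs(I) + 1e-6
        prune = oa.prune_channels(_recording_from_intensity(I))
        assert list(prune.mask) == [True, True, False]

    def test_all_pruned_raises(self):
        I = np.full((100, 2, 2), 1e-5)
        with pytest.raises(AllChannelsPrunedError):
            oa.prune_channels(_recording_from_intensity(I))


class TestOD:
    def test_constant_channel_zero_od(self):
        I = np.full((50, 2, 2), 0.7)
        od = oa.intensity_to_od(_recording_from_intensity(I))
        assert np.allclose(od.od, 0.0)

    def test_od_definition(self):
        """An intensity dip by e^-0.2 raises OD by exactly 0.2 there."""
        I = np.ones((100, 1, 2))
        I[40, 0, 0] = np.exp(-0.2)
        od = oa.intensity_to_od(_recording_from_intensity(I)).od[:, 0, 0]
        assert np.isclose(od[40] - od[41], 0.2)
        # and OD is -ln(I / temporal mean) exactly
        np.testing.assert_allclose(od, -np.log(I[:, 0, 0] / I[:, 0, 0].mean()))

    def test_nonpositive_raises(self):
        I = np.ones((50, 1, 2))
        I[3, 0, 1] = -1.0
        with pytest.raises(ValueError):
            oa.intensity_to_od(_recording_from_intensity(I))


class TestSplineSG:
    def _wrap(self, x, fs):
        od = np.zeros((x.size, 1, 2))
        od[:, 0, 0] = x
        od[:, 0, 1] = x
        return oa.ODTimeSeries(od=od, sample_rate_hz=fs,
                               channel_mask=np.ones(1, bool), events=[])

    def test_clean_sinusoid_passthrough(self):
        """Artifact-free oscillation passes through within 2% RMS."""
        fs = 10.0
        t = np.arange(0, 120, 1 / fs)
        x = 0.01 * np.sin(2 * np.pi * 0.08 * t)
        out = splinesg_correct(self._wrap(x, fs))
        rms_in = np.sqrt(np.mean(x ** 2))
        err = np.sqrt(np.mean((out.od[:, 0, 0] - x) ** 2))
        assert err < 0.02 * rms_in

    def test_step_correction(self):
        """A baseline step on an otherwise flat noisy signal is leveled
        by >= 90%."""
        fs = 10.0
        rng = np.random.default_rng(1)
        n = 1200
        x = 0.001 * rng.standard_normal(n)
        x[n // 2:] += 0.5
        out = splinesg_correct(self._wrap(x, fs)).od[:, 0, 0]
        gap_before = abs(x[n // 2:].mean() - x[:n // 2].mean())
        gap_after = abs(out[n // 2:].mean() - out[:n // 2].mean())
        assert gap_after < 0.1 * gap_before

    def test_spike_suppression(self):
        """An isolated large spike is attenuated by >= 80%."""
        fs = 10.0
        rng = np.random.default_rng(2)
        n = 1200
        x = 0.001 * rng.standard_normal(n)
        x[600] += 0.05
        out = splinesg_correct(self._wrap(x, fs)).od[:, 0, 0]
        assert abs(out[600]) < 0.2 * 0.05

    def test_short_frame_raises(self):
        fs = 10.0
        x = np.zeros(100)
        with pytest.raises(ValueError):
            splinesg_correct(self._wrap(x, fs), frame_s=0.2)


class TestLowpass:
    def _wrap(self, x, fs):
        od = np.tile(x[:, None, None], (1, 1, 2))
        return oa.ODTimeSeries(od=od, sample_rate_hz=fs,
                               channel_mask=np.ones(1, bool), events=[])

    def test_dc_preserved(self):
        out = oa.lowpass(self._wrap(np.full(500, 0.3), 17.5))
        assert np.allclose(out.od, 0.3, atol=1e-9)

    @pytest.mark.parametrize("freq,check", [
        (1.2, lambda gain: gain < 0.1),     # cardiac-band attenuation
        (0.05, lambda gain: abs(gain - 1.0) < 0.02),  # hemodynamics pass
    ])
    def test_frequency_response(self, freq, check):
        fs = 17.5
        t = np.arange(0, 200, 1 / fs)
        x = np.sin(2 * np.pi * freq * t)
        out = oa.lowpass(self._wrap(x, fs)).od[:, 0, 0]
        core = slice(200, -200)
        gain = out[core].std() / x[core].std()
        assert check(gain)

    def test_cutoff_above_nyquist_raises(self):
        with pytest.raises(ValueError):
            oa.lowpass(self._wrap(np.zeros(100), 5.0), cutoff_hz=3.0)


class TestBeerLambert:
    def test_known_concentration_roundtrip(self, sparse_probe):
        """OD built from known (dHbO, dHbR) is inverted exactly."""
        rng = np.random.default_rng(3)
        n_ch = sparse_probe.n_channels
        hb = rng.standard_normal((50, n_ch, 2))
        L = sparse_probe.nominal_separations()
        od = hb_to_od(hb, L)
        odts = oa.ODTimeSeries(od=od, sample_rate_hz=10.0,
                               channel_mask=np.ones(n_ch, bool), events=[],
                               probe=sparse_probe)
        conc = oa.od_to_conc(odts)
        np.testing.assert_allclose(conc.conc[:, :, :2], hb, atol=1e-10)
        np.testing.assert_allclose(conc.conc[:, :, 2], hb.sum(axis=2),
                                   atol=1e-10)

    def test_zero_od_zero_conc(self, sparse_probe):
        odts = oa.ODTimeSeries(od=np.zeros((10, 60, 2)), sample_rate_hz=10.0,
                               channel_mask=np.ones(60, bool), events=[],
                               probe=sparse_probe)
        conc = oa.od_to_conc(odts)
        assert np.allclose(conc.conc, 0.0)

    def test_linearity(self, sparse_probe):
        rng = np.random.default_rng(4)
        od = rng.standard_normal((20, 60, 2)) * 1e-3
        mk = lambda o: oa.od_to_conc(oa.ODTimeSeries(
            od=o, sample_rate_hz=10.0, channel_mask=np.ones(60, bool),
            events=[], probe=sparse_probe))
        np.testing.assert_allclose(mk(2 * od).conc, 2 * mk(od).conc)


class TestBlockRejection:
    def _conc(self, fs=10.0, n_ch=5, excursion_block=None, amp=30.0):
        spec = oa.ParadigmSpec(initial_rest_s=10.0, n_blocks=6,
                               n_per_condition=3, isi_range_s=(5.0, 5.0),
                               block_duration_s=18.0, trials_per_block=6)
        events = oa.generate_paradigm(spec, 0)
        nt = int((events[-1].onset_s + 30) * fs)
        conc = np.zeros((nt, n_ch, 3))
        if excursion_block is not None:
            cond_events = [e for e in events
                           if e.condition == "incongruent"]
            e = cond_events[excursion_block]
            a = int(e.onset_s * fs)
            conc[a + 5:a + 15, :3, 0] = amp   # 60% of channels
        return oa.ConcTimeSeries(conc=conc, sample_rate_hz=fs,
                                 channel_mask=np.ones(n_ch, bool),
                                 events=events)

    def test_clean_run_keeps_all_blocks(self):
        conc = self._conc()
        rejected = oa.reject_blocks(conc)
        assert all(len(v) == 0 for v in rejected.values())

    def test_forced_excursion_rejects_that_block(self):
        conc = self._conc(excursion_block=1)
        rejected = oa.reject_blocks(conc, amp_threshold_uM=15.0,
                                    channel_fraction=0.5)
        assert rejected["incongruent"] == [1]
        assert rejected["congruent"] == []

    def test_infinite_threshold_rejects_nothing(self):
        conc = self._conc(excursion_block=1)
        rejected = oa.reject_blocks(conc, amp_threshold_uM=np.inf)
        assert all(len(v) == 0 for v in rejected.values())


class TestSubjectExclusion:
    @pytest.mark.parametrize("n_rejected,expected", [
        (0, False),   # 9/9 remaining -> keep
        (5, True),    # 4 remaining -> exclude
        (4, False),   # 5 remaining -> keep (rule boundary)
    ])
    def test_exclusion_rule(self, n_rejected, expected):
        events = oa.generate_paradigm(oa.ParadigmSpec(), 0)
        conc = oa.ConcTimeSeries(conc=np.zeros((10, 2, 3)),
                                 sample_rate_hz=10.0,
                                 channel_mask=np.ones(2, bool),
                                 events=events,
                                 rejected_blocks={
                                     "congruent": list(range(n_rejected))})
        assert oa.exclude_subject(conc) is expected


def test_chain_linearity_without_motion_correction(arrays):
    """With motion correction off, the OD -> concentration chain is linear:
    pipeline(a x) = a pipeline(x)."""
    probes, mesh, sens = arrays
    rec = make_short_recording(probe=None)
    rng = np.random.default_rng(0)
    base = 1.0 + 0.0 * rec.intensity
    od_sig = 1e-3 * rng.standard_normal(rec.intensity.shape)

    def run(alpha):
        intensity = base * np.exp(-alpha * od_sig)
        r = oa.RawRecording(intensity=intensity,
                            sample_rate_hz=rec.sample_rate_hz,
                            events=rec.events, subject_id="T",
                            array_id="t")
        od = oa.intensity_to_od(r)
        od = oa.lowpass(od)
        # the OD convention fixes each channel's baseline constant; the
        # fluctuations around it are what scale linearly
        return od.od - od.od.mean(axis=0, keepdims=True)

    np.testing.assert_allclose(run(2.0), 2.0 * run(1.0), atol=1e-12)
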