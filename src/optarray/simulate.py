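"""Synthetic group-level fNIRS recordings with known ground truth.

Emulates the study conditions of a two-array prefrontal block-design
experiment: 17 subjects x 2 arrays x 1 run; runs of 20 s initial rest then
18 blocks of 18 s (9 per condition) with 10-15 s jittered inter-block rest;
sampling 24.4 Hz (sparse) / 17.5 Hz (HD); lateral-PFC activation and
medial-PFC deactivation with a stronger response in the more demanding
(incongruent) condition; superficial systemic physiology common to
scalp-sensitive channels; motion spikes and baseline shifts; and
separation-dependent measurement noise.

Vertex time courses are kept in a low-rank (spatial pattern x temporal
course) representation so that forward projection through the sensitivity
matrices never materializes a time x vertex array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import SensitivityMatrix
from .headmodel import HeadMesh
from .hrf import block_response
from .optics import DEFAULT_WAVELENGTHS_NM, extinction_matrix

CONDITIONS = ("congruent", "incongruent")


@dataclass(frozen=True)
class StimulusEvent:
    condition: str
    onset_s: float
    duration_s: float


@dataclass
class ParadigmSpec:
    """Block-design timing: initial rest, then jittered task blocks."""

    initial_rest_s: float = 20.0
    block_duration_s: float = 18.0
    n_blocks: int = 18
    n_per_condition: int = 9
    isi_range_s: tuple = (10.0, 15.0)
    trial_duration_s: float = 3.0
    trials_per_block: int = 6

    def __post_init__(self):
        if self.n_per_condition * 2 != self.n_blocks:
            raise ValueError("n_per_condition x 2 must equal n_blocks")
        if abs(self.trials_per_block * self.trial_duration_s
               - self.block_duration_s) > 1e-9:
            raise ValueError("trials_per_block x trial_duration must equal "
                             "block_duration")
        if self.isi_range_s[0] > self.isi_range_s[1]:
            raise ValueError("invalid ISI range")


def generate_paradigm(spec: ParadigmSpec, seed) -> list:
    """Draw a randomized block order and jittered inter-stimulus intervals.

    Returns a sorted list of StimulusEvent; the first onset is at the end of
    the initial rest.
    """
    rng = np.random.default_rng(seed)
    order = [CONDITIONS[0]] * spec.n_per_condition \
        + [CONDITIONS[1]] * spec.n_per_condition
    order = [order[i] for i in rng.permutation(spec.n_blocks)]
    events = []
    t = spec.initial_rest_s
    for k, cond in enumerate(order):
        events.append(StimulusEvent(cond, t, spec.block_duration_s))
        t += spec.block_duration_s
        if k < spec.n_blocks - 1:
            t += rng.uniform(*spec.isi_range_s)
    return events


def run_duration_s(events, tail_s: float = 25.0) -> float:
    last = events[-1]
    return last.onset_s + last.duration_s + tail_s


@dataclass
class SystemicSpec:
    """Superficial (scalp) physiology common to scalp-sensitive channels."""

    cardiac_hz: float = 1.1
    respiration_hz: float = 0.25
    mayer_hz: float = 0.1
    cardiac_amp_uM: float = 0.15
    respiration_amp_uM: float = 0.10
    mayer_amp_uM: float = 0.25
    drift_amp_uM: float = 0.4
    hbr_fraction: float = 0.25  # systemic HbR co-varies at this fraction of HbO


@dataclass
class NoiseSpec:
    """Measurement noise and motion artifacts, in OD units.

    White noise is specified as a spectral density (OD per sqrt(Hz)) and
    scaled by sqrt(fs/2) at generation time: the two arrays use the same
    detector hardware, so their noise floors share a density, not a
    per-sample amplitude. Densities grow with separation (light level falls
    off with source-detector distance).
    """

    white_noise_density: dict = field(default_factory=lambda: {
        "short": 0.0015, "second_nn": 0.004, "third_nn": 0.007,
        "grid30": 0.0065})
    pink_sd: dict = field(default_factory=lambda: {
        "short": 0.0015, "second_nn": 0.004, "third_nn": 0.007,
        "grid30": 0.0065})
    spike_rate_per_min: float = 0.3
    spike_amp_od: float = 0.25
    shift_rate_per_min: float = 0.15
    shift_amp_od: float = 0.08
    artifact_channel_fraction: float = 0.4
    forced_dead_channels: tuple = ()
    dead_intensity: float = 5e-4
    i0_range: tuple = (0.8, 1.2)


@dataclass
class GroundTruth:
    """Activation patches plus nuisance structure for one simulated subject.

    Patches are (region_label, condition, hbo_amplitude_uM, hbr_amplitude_uM,
    patch_radius_mm): top-hat concentration changes around the region
    centroid whose block time course is the 18 s boxcar convolved with the
    canonical kernel (peak-normalized, so amplitudes read as peak uM).
    """

    activation_patches: list = field(default_factory=lambda: [
        ("dlPFC_left", "incongruent", 1.0, -0.3, 40.0),
        ("dlPFC_left", "congruent", 0.5, -0.15, 40.0),
        ("dlPFC_right", "incongruent", 1.0, -0.3, 40.0),
        ("dlPFC_right", "congruent", 0.5, -0.15, 40.0),
        ("mPFC", "incongruent", -0.5, 0.15, 25.0),
        ("mPFC", "congruent", -0.25, 0.075, 25.0),
    ])
    systemic: SystemicSpec = field(default_factory=SystemicSpec)
    hrf_shape: dict = field(default_factory=dict)  # double_gamma overrides
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def validate(self) -> None:
        lateral = {}
        for region, cond, hbo, hbr, _radius in self.activation_patches:
            if hbo != 0 and not (np.sign(hbr) == -np.sign(hbo)
                                 and abs(hbr) < abs(hbo)):
                raise ValueError(
                    f"patch {region}/{cond}: HbR must oppose HbO and be smaller")
            if region.startswith("dlPFC"):
                lateral[(region, cond)] = hbo
        for region in ("dlPFC_left", "dlPFC_right"):
            inc = lateral.get((region, "incongruent"))
            con = lateral.get((region, "congruent"))
            if inc is not None and con is not None and not inc > con:
                raise ValueError(f"{region}: incongruent amplitude must exceed "
                                 "congruent")


@dataclass
class RawRecording:
    """Two-wavelength intensity time series with stimulus metadata."""

    intensity: np.ndarray        # (n_times, n_channels, 2), positive
    sample_rate_hz: float
    events: list                 # of StimulusEvent, sorted
    subject_id: str
    array_id: str
    probe: object = None         # ProbeGeometry
    wavelengths_nm: tuple = DEFAULT_WAVELENGTHS_NM

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sample_rate_hz

    def validate(self) -> None:
        assert np.all(self.intensity > 0), "intensities must be positive"
        onsets = [e.onset_s for e in self.events]
        assert onsets == sorted(onsets), "events must be sorted by onset"
        for a, b in zip(self.events, self.events[1:]):
            assert a.onset_s + a.duration_s <= b.onset_s + 1e-9, \
                "events must not overlap"


@dataclass
class VertexTimecourses:
    """Low-rank vertex HbO/HbR series: sum of spatial x temporal components."""

    spatial: np.ndarray      # (n_components, n_vertices)
    temporal: np.ndarray     # (n_times, n_components)
    hbo_scale: np.ndarray    # (n_components,)
    hbr_scale: np.ndarray
    sample_rate_hz: float
    vertex_split: int        # brain/scalp boundary

    @property
    def n_times(self) -> int:
        return self.temporal.shape[0]

    def hbo_dense(self) -> np.ndarray:
        return self.temporal @ (self.spatial * self.hbo_scale[:, None])

    def hbr_dense(self) -> np.ndarray:
        return self.temporal @ (self.spatial * self.hbr_scale[:, None])

    def scaled(self, factor: float) -> "VertexTimecourses":
        return replace(self, hbo_scale=self.hbo_scale * factor,
                       hbr_scale=self.hbr_scale * factor)


def _patch_pattern(mesh: HeadMesh, region: str, radius_mm: float) -> np.ndarray:
    """Top-hat spatial pattern around a region centroid, brain vertices only."""
    n_all = mesh.n_brain + mesh.n_scalp
    center = mesh.region_centroid(region)
    center = center / np.linalg.norm(center) * mesh.config.brain_radius_mm
    d = np.linalg.norm(mesh.brain_vertices - center, axis=1)
    pattern = np.zeros(n_all)
    pattern[:mesh.n_brain] = (d <= radius_mm).astype(float)
    return pattern


def simulate_vertex_timecourses(truth: GroundTruth, mesh: HeadMesh, events,
                                sample_rate_hz: float,
                                duration_s: float | None = None,
                                seed=0) -> VertexTimecourses:
    """Build brain activation and scalp physiology vertex time courses.

    Brain vertices carry, per condition, amplitude x top-hat pattern x
    (boxcar convolved with the canonical kernel); scalp vertices carry the
    shared systemic oscillations and a slow drift only.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = run_duration_s(events)
    dt = 1.0 / sample_rate_hz
    nt = int(round(duration_s * sample_rate_hz))
    t = np.arange(nt) * dt
    n_all = mesh.n_brain + mesh.n_scalp

    spatial, temporal, hbo_s, hbr_s = [], [], [], []

    # condition responses: one temporal course per condition, one spatial
    # pattern per patch
    cond_course = {}
    for cond in CONDITIONS:
        onsets = [e.onset_s for e in events if e.condition == cond]
        durs = [e.duration_s for e in events if e.condition == cond]
        course = np.zeros(nt)
        for onset, dur in zip(onsets, durs):
            course += block_response(t - onset, dur, dt, **truth.hrf_shape)
        cond_course[cond] = course

    for region, cond, hbo, hbr, radius in truth.activation_patches:
        if cond not in cond_course:
            raise ValueError(f"patch condition {cond!r} not in events")
        spatial.append(_patch_pattern(mesh, region, radius))
        temporal.append(cond_course[cond])
        hbo_s.append(hbo)
        hbr_s.append(hbr)

    # systemic physiology: common course over the scalp with mild per-vertex
    # gain variation
    sysm = truth.systemic
    scalp_gain = np.zeros(n_all)
    scalp_gain[mesh.n_brain:] = 1.0 + 0.2 * rng.standard_normal(mesh.n_scalp)
    for freq, amp in ((sysm.cardiac_hz, sysm.cardiac_amp_uM),
                      (sysm.respiration_hz, sysm.respiration_amp_uM),
                      (sysm.mayer_hz, sysm.mayer_amp_uM)):
        if amp == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        spatial.append(scalp_gain)
        temporal.append(np.sin(2 * np.pi * freq * t + phase))
        hbo_s.append(amp)
        hbr_s.append(-amp * sysm.hbr_fraction)

    if sysm.drift_amp_uM:
        phase = rng.uniform(0, 2 * np.pi)
        slow = np.sin(2 * np.pi * 0.008 * t + phase) + (t / t[-1] - 0.5)
        spatial.append(scalp_gain)
        temporal.append(slow)
        hbo_s.append(sysm.drift_amp_uM)
        hbr_s.append(sysm.drift_amp_uM * sysm.hbr_fraction)

    return VertexTimecourses(
        spatial=(np.asarray(spatial) if spatial
                 else np.zeros((0, n_all))),
        temporal=np.column_stack(temporal) if temporal else np.zeros((nt, 0)),
        hbo_scale=np.asarray(hbo_s, dtype=float),
        hbr_scale=np.asarray(hbr_s, dtype=float),
        sample_rate_hz=sample_rate_hz,
        vertex_split=mesh.n_brain,
    )


def forward_project(vertex_tc: VertexTimecourses, sensitivities, events,
                    subject_id: str = "S01", array_id: str = "array",
                    i0=None, seed=0) -> RawRecording:
    """Project vertex chromophore series to channel intensities (y = A x).

    For each wavelength, vertex concentrations are mixed to absorption
    changes through the extinction table, projected through that
    wavelength's sensitivity matrix to optical density, and exponentiated
    around a per-channel baseline intensity I0.
    """
    wavelengths = tuple(s.wavelength_nm for s in sensitivities)
    E = extinction_matrix(wavelengths)
    n_ch = sensitivities[0].n_channels
    for s in sensitivities:
        if s.values.shape[1] != vertex_tc.spatial.shape[1]:
            raise ValueError("sensitivity columns do not match mesh vertices")
        if s.n_channels != n_ch:
            raise ValueError("sensitivity matrices must share channel ordering")

    rng = np.random.default_rng(seed)
    if i0 is None:
        lo, hi = 0.8, 1.2
        i0 = rng.uniform(lo, hi, size=(n_ch, len(wavelengths)))
    i0 = np.broadcast_to(np.asarray(i0, dtype=float), (n_ch, len(wavelengths)))

    nt = vertex_tc.n_times
    od = np.zeros((nt, n_ch, len(wavelengths)))
    for w, sens in enumerate(sensitivities):
        # channel weight per component: A @ spatial pattern
        w_comp = vertex_tc.spatial @ sens.values.T  # (n_comp, n_ch)
        coef = (E[w, 0] * vertex_tc.hbo_scale
                + E[w, 1] * vertex_tc.hbr_scale)    # (n_comp,)
        od[:, :, w] = vertex_tc.temporal @ (w_comp * coef[:, None])

    intensity = i0[None, :, :] * np.exp(-od)
    rec = RawRecording(intensity=intensity,
                       sample_rate_hz=vertex_tc.sample_rate_hz,
                       events=list(events), subject_id=subject_id,
                       array_id=array_id,
                       probe=sensitivities[0].probe,
                       wavelengths_nm=wavelengths)
    rec.validate()
    return rec


def _pink_noise(rng, shape, sd):
    """1/f-shaped noise along axis 0, unit-free (OD units via sd)."""
    nt = shape[0]
    white = rng.standard_normal(shape)
    f = np.fft.rfftfreq(nt, d=1.0)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec = np.fft.rfft(white, axis=0) * scale.reshape(-1, *([1] * (len(shape) - 1)))
    pink = np.fft.irfft(spec, n=nt, axis=0)
    rms = pink.std(axis=0, keepdims=True)
    rms[rms == 0] = 1.0
    return pink / rms * sd


def add_noise_and_artifacts(recording: RawRecording, truth: GroundTruth,
                            seed) -> RawRecording:
    """Add measurement noise, motion artifacts and dead channels.

    Separation-class-scaled white and 1/f noise, Poisson-timed spike
    transients (1-3 s) and step baseline shifts on random channel subsets,
    all applied multiplicatively in OD units; optionally forces configured
    channels to near-zero intensity to exercise pruning. Deterministic for a
    fixed seed; a zero-rate, zero-sd spec returns the recording unchanged.
    """
    ns = truth.noise
    rng = np.random.default_rng(seed)
    probe = recording.probe
    nt, n_ch, n_wl = recording.intensity.shape
    fs = recording.sample_rate_hz
    duration_min = nt / fs / 60.0

    classes = [c[2] for c in probe.channels] if probe is not None else None

    od_noise = np.zeros((nt, n_ch, n_wl))
    bw = np.sqrt(fs / 2.0)  # noise bandwidth of the sampling rate
    white = bw * np.array([ns.white_noise_density.get(cls, 0.0)
                           for cls in classes]) \
        if classes is not None else np.zeros(n_ch)
    pink = np.array([ns.pink_sd.get(cls, 0.0) for cls in classes]) \
        if classes is not None else np.zeros(n_ch)
    if np.any(white > 0):
        od_noise += rng.standard_normal((nt, n_ch, n_wl)) * white[None, :, None]
    if np.any(pink > 0):
        od_noise += _pink_noise(rng, (nt, n_ch, n_wl), 1.0) * pink[None, :, None]

    n_spikes = rng.poisson(ns.spike_rate_per_min * duration_min) \
        if ns.spike_rate_per_min > 0 else 0
    for _ in range(n_spikes):
        t0 = rng.uniform(0, nt / fs)
        dur = rng.uniform(1.0, 3.0)
        chans = rng.random(n_ch) < ns.artifact_channel_fraction
        amp = ns.spike_amp_od * rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
        tt = np.arange(nt) / fs
        shape = np.exp(-np.abs(tt - t0) / (dur / 4.0))
        shape[np.abs(tt - t0) > dur] = 0.0
        od_noise[:, chans, :] += amp * shape[:, None, None]

    n_shifts = rng.poisson(ns.shift_rate_per_min * duration_min) \
        if ns.shift_rate_per_min > 0 else 0
    for _ in range(n_shifts):
        k0 = rng.integers(0, nt)
        chans = rng.random(n_ch) < ns.artifact_channel_fraction
        amp = ns.shift_amp_od * rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
        od_noise[k0:, chans, :] += amp

    intensity = recording.intensity
    if np.any(od_noise):
        intensity = intensity * np.exp(-od_noise)

    if len(ns.forced_dead_channels):
        intensity = intensity.copy()
        dead = np.asarray(ns.forced_dead_channels, dtype=int)
        jitter = 1.0 + 0.01 * rng.standard_normal((nt, dead.size, n_wl))
        intensity[:, dead, :] = ns.dead_intensity * np.abs(jitter)

    return replace(recording, intensity=intensity)


def peripheral_channels(probe, fraction: float = 0.3) -> np.ndarray:
    """Channels in the superior portion of the array (the hair-prone edge)."""
    z = probe.channel_midpoints()[:, 2]
    cut = np.quantile(z, 1.0 - fraction)
    return np.flatnonzero(z >= cut)


@dataclass
class CohortSpec:
    """Study conditions for the simulated group."""

    n_subjects: int = 17
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    amplitude_jitter_sd: float = 0.25     # per-subject multiplicative gain
    cardiac_jitter_sd_hz: float = 0.1
    hd_dead_channel_mean: float = 8.0     # Poisson mean, peripheral HD channels
    sparse_dead_channel_mean: float = 0.3
    sample_rates_hz: dict = field(default_factory=lambda: {
        "sparse": 24.4, "hd": 17.5})


def generate_group(sensitivities_by_array: dict, mesh: HeadMesh,
                   truth_template: GroundTruth | None = None,
                   cohort: CohortSpec | None = None,
                   seed: int = 0) -> list:
    """Simulate the paired cohort: one recording per subject per array.

    Each subject draws one shared ground truth (jittered amplitudes and
    cardiac rate) and one event sequence applied through both arrays'
    forward models; measurement noise is independent between arrays. All
    randomness derives deterministically from the master seed.
    """
    cohort = cohort or CohortSpec()
    truth_template = truth_template or GroundTruth()
    if cohort.n_subjects < 2:
        raise ValueError("need at least 2 subjects")

    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(cohort.n_subjects)
    recordings = []
    for s_idx, sseq in enumerate(subject_seeds):
        subject_id = f"S{s_idx + 1:02d}"
        seeds = [s.generate_state(1)[0] % (2 ** 31) for s in sseq.spawn(8)]
        rng = np.random.default_rng(seeds[0])

        gain = max(0.3, 1.0 + cohort.amplitude_jitter_sd * rng.standard_normal())
        patches = [(r, c, hbo * gain, hbr * gain, rad)
                   for r, c, hbo, hbr, rad in truth_template.activation_patches]
        systemic = replace(
            truth_template.systemic,
            cardiac_hz=max(0.6, truth_template.systemic.cardiac_hz
                           + cohort.cardiac_jitter_sd_hz * rng.standard_normal()))
        events = generate_paradigm(cohort.paradigm, seeds[1])

        for a_idx, (array_id, sens_pair) in \
                enumerate(sorted(sensitivities_by_array.items())):
            probe = sens_pair[0].probe
            n_dead_mean = (cohort.hd_dead_channel_mean if array_id == "hd"
                           else cohort.sparse_dead_channel_mean)
            n_dead = rng.poisson(n_dead_mean)
            candidates = peripheral_channels(probe)
            dead = tuple(rng.choice(candidates,
                                    size=min(n_dead, candidates.size),
                                    replace=False).tolist())
            truth = GroundTruth(
                activation_patches=patches,
                systemic=systemic,
                hrf_shape=dict(truth_template.hrf_shape),
                noise=replace(truth_template.noise,
                              forced_dead_channels=dead))
            fs = cohort.sample_rates_hz.get(array_id, 17.5)
            vt = simulate_vertex_timecourses(truth, mesh, events, fs,
                                             seed=seeds[2])
            rec = forward_project(vt, sens_pair, events,
                                  subject_id=subject_id, array_id=array_id,
                                  seed=seeds[3 + a_idx])
            rec = add_noise_and_artifacts(rec, truth, seeds[5 + a_idx])
            rec.ground_truth = truth
            recordings.append(rec)
    return recordings
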