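"""Shared fixtures: default geometries and a processed synthetic cohort.

Expensive objects (probes, mesh, sensitivities, the 17-subject pipeline
run) are session-scoped so the whole suite builds them once.
"""

import warnings

import numpy as np
import pytest

import optarray as oa


@pytest.fixture(scope="session")
def mesh():
    return oa.build_head_mesh()


@pytest.fixture(scope="session")
def sparse_probe():
    return oa.build_sparse_probe()


@pytest.fixture(scope="session")
def hd_probe():
    return oa.build_hd_probe()


@pytest.fixture(scope="session")
def arrays():
    """(probes, mesh, sensitivities) at the default configuration."""
    return oa.build_arrays(oa.PipelineConfig())


@pytest.fixture(scope="session")
def noisefree_recording(arrays):
    """Single noise-free, systemic-free sparse-array recording."""
    probes, mesh, sens = arrays
    events = oa.generate_paradigm(oa.ParadigmSpec(), 1)
    truth = oa.GroundTruth()
    truth.systemic = oa.SystemicSpec(cardiac_amp_uM=0, respiration_amp_uM=0,
                                     mayer_amp_uM=0, drift_amp_uM=0)
    vt = oa.simulate_vertex_timecourses(truth, mesh, events, 24.4, seed=3)
    rec = oa.forward_project(vt, sens["sparse"], events, seed=4)
    rec.ground_truth = truth
    return rec


@pytest.fixture(scope="session")
def pipeline17():
    """Full paired 17-subject cohort analysis under the default conditions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return oa.run_pipeline(oa.PipelineConfig(seed=7), keep_hrfs=True)


def make_short_recording(fs=10.0, n_blocks=4, seed=0, n_channels=3,
                         probe=None):
    """Small constructed recording for fast preprocessing/GLM unit tests."""
    spec = oa.ParadigmSpec(initial_rest_s=10.0, n_blocks=n_blocks,
                           n_per_condition=n_blocks // 2,
                           isi_range_s=(8.0, 8.0))
    events = oa.generate_paradigm(spec, seed)
    nt = int(round((events[-1].onset_s + 40) * fs))
    rng = np.random.default_rng(seed)
    intensity = 1.0 + 0.01 * rng.standard_normal((nt, n_channels, 2))
    rec = oa.RawRecording(intensity=np.abs(intensity) + 0.1,
                          sample_rate_hz=fs, events=events,
                          subject_id="T01", array_id="test", probe=probe)
    return rec
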