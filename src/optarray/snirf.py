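"""Minimal SNIRF (HDF5) interchange for raw two-wavelength recordings.

Implements the subset of the SNIRF layout the pipeline needs: continuous-
wave intensity (dataType 1) with a measurement list, 3D probe geometry,
stimulus blocks and basic metadata. Files written here round-trip through
:func:`read_snirf` with bit-identical numeric payloads.
"""

from __future__ import annotations

import numpy as np

from .probes import NOMINAL_SEPARATION_MM, ProbeGeometry, SEPARATION_TOL_MM
from .simulate import RawRecording, StimulusEvent

FORMAT_VERSION = "1.0"


def _write_str(group, name, value):
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(recording: RawRecording, path, probe: ProbeGeometry | None = None):
    """Write a raw recording to a SNIRF-layout HDF5 file."""
    import h5py

    probe = probe if probe is not None else recording.probe
    if probe is None:
        raise ValueError("a probe geometry is required to write SNIRF")
    nt, n_ch, n_wl = recording.intensity.shape
    with h5py.File(path, "w") as f:
        _write_str(f, "formatVersion", FORMAT_VERSION)
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        _write_str(meta, "SubjectID", recording.subject_id)
        _write_str(meta, "MeasurementDate", "unknown")
        _write_str(meta, "MeasurementTime", "unknown")
        _write_str(meta, "LengthUnit", "mm")
        _write_str(meta, "TimeUnit", "s")
        _write_str(meta, "FrequencyUnit", "Hz")
        _write_str(meta, "ArrayID", recording.array_id)

        data = nirs.create_group("data1")
        flat = recording.intensity.reshape(nt, n_ch * n_wl, order="F")
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=recording.times())
        m = 0
        for w in range(n_wl):
            for c, (si, di, _cls) in enumerate(probe.channels):
                ml = data.create_group(f"measurementList{m + 1}")
                ml.create_dataset("sourceIndex", data=si + 1)
                ml.create_dataset("detectorIndex", data=di + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                m += 1

        pg = nirs.create_group("probe")
        pg.create_dataset("wavelengths",
                          data=np.asarray(recording.wavelengths_nm, float))
        pg.create_dataset("sourcePos3D", data=probe.source_positions)
        pg.create_dataset("detectorPos3D", data=probe.detector_positions)
        names = list(probe.landmark_anchors)
        pg.create_dataset("landmarkLabels",
                          data=np.array([np.bytes_(n) for n in names]))
        pg.create_dataset(
            "landmarkPos3D",
            data=np.vstack([probe.landmark_anchors[n] for n in names]))

        conditions = sorted({e.condition for e in recording.events})
        for k, cond in enumerate(conditions):
            st = nirs.create_group(f"stim{k + 1}")
            _write_str(st, "name", cond)
            rows = [(e.onset_s, e.duration_s, 1.0)
                    for e in recording.events if e.condition == cond]
            st.create_dataset("data", data=np.asarray(rows, float))


def _classify_channels(src_pos, det_pos, pairs):
    channels = []
    for si, di in pairs:
        d = float(np.linalg.norm(src_pos[si] - det_pos[di]))
        cls = None
        for name, nominal in NOMINAL_SEPARATION_MM.items():
            if abs(d - nominal) <= SEPARATION_TOL_MM:
                cls = name
                break
        if cls is None:
            raise ValueError(
                f"channel separation {d:.1f} mm matches no separation class")
        channels.append((si, di, cls))
    return channels


def read_snirf(path) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible).

    Requires a two-wavelength continuous-wave measurement list; probe
    geometry is rebuilt from the stored optode positions with separation
    classes inferred from source-detector distances.
    """
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs1"] if "nirs1" in f else f["nirs"]
        data = nirs["data1"]
        flat = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        ml_names = sorted((k for k in data.keys()
                           if k.startswith("measurementList")),
                          key=lambda s: int(s[len("measurementList"):]))
        if not ml_names:
            raise ValueError("missing measurement list")
        src_i, det_i, wl_i = [], [], []
        for name in ml_names:
            ml = data[name]
            src_i.append(int(ml["sourceIndex"][()]) - 1)
            det_i.append(int(ml["detectorIndex"][()]) - 1)
            wl_i.append(int(ml["wavelengthIndex"][()]) - 1)
        wl_i = np.asarray(wl_i)
        n_wl = wl_i.max() + 1
        if n_wl != 2:
            raise ValueError(
                f"two wavelengths required, file has {n_wl}")

        probe_g = nirs["probe"]
        wavelengths = tuple(np.asarray(probe_g["wavelengths"]).tolist())
        src_pos = np.asarray(probe_g["sourcePos3D"])
        det_pos = np.asarray(probe_g["detectorPos3D"])

        # channel order: measurements of wavelength 1, matching pair order
        first = np.flatnonzero(wl_i == 0)
        pairs = [(src_i[m], det_i[m]) for m in first]
        n_ch = len(pairs)
        intensity = np.empty((flat.shape[0], n_ch, n_wl))
        for w in range(n_wl):
            cols = np.flatnonzero(wl_i == w)
            order = {(src_i[m], det_i[m]): m for m in cols}
            for c, pair in enumerate(pairs):
                intensity[:, c, w] = flat[:, order[pair]]

        channels = _classify_channels(src_pos, det_pos, pairs)
        landmarks = {}
        if "landmarkLabels" in probe_g:
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in np.asarray(probe_g["landmarkLabels"])]
            pos = np.asarray(probe_g["landmarkPos3D"])
            landmarks = {lab: pos[i] for i, lab in enumerate(labels)}
        scalp_r = float(np.linalg.norm(src_pos, axis=1).mean())
        probe = ProbeGeometry(name="from_snirf", source_positions=src_pos,
                              detector_positions=det_pos, channels=channels,
                              landmark_anchors=landmarks,
                              scalp_radius_mm=scalp_r)

        events = []
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            st = nirs[k]
            name = st["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            for onset, dur, _amp in np.atleast_2d(np.asarray(st["data"])):
                events.append(StimulusEvent(name, float(onset), float(dur)))
        events.sort(key=lambda e: e.onset_s)

        meta = nirs["metaDataTags"]

        def _read_str(name, default=""):
            if name not in meta:
                return default
            v = meta[name][()]
            return v.decode() if isinstance(v, bytes) else str(v)

        fs = 1.0 / np.median(np.diff(time)) if time.size > 1 else 1.0
        return RawRecording(intensity=intensity, sample_rate_hz=float(fs),
                            events=events, subject_id=_read_str("SubjectID"),
                            array_id=_read_str("ArrayID"), probe=probe,
                            wavelengths_nm=wavelengths)
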