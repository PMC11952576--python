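"""Channel pruning, OD conversion, motion correction, filtering and QC.

The standard chain up to the GLM: channels with low raw signal or low SNR
are pruned; intensity is converted to optical density (natural log around
the temporal mean); baseline shifts and spikes are corrected by a
spline-plus-Savitzky-Golay scheme; a zero-phase low-pass removes cardiac
oscillations; and the two-wavelength OD is converted to hemoglobin
concentrations through the modified Beer-Lambert law. Blocks contaminated
by residual artifacts are rejected by an automated amplitude criterion, and
subjects with too few surviving blocks are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .optics import od_to_hb
from .simulate import RawRecording

CHROMOPHORES = ("HbO", "HbR", "HbT")


class AllChannelsPrunedError(RuntimeError):
    """Every channel failed the pruning criteria."""


@dataclass
class PruneResult:
    mask: np.ndarray            # (n_channels,) True = kept
    n_pruned: int
    fraction_pruned: float
    snr: np.ndarray             # (n_channels, n_wavelengths)
    mean_level: np.ndarray
    per_class_pruned: dict = field(default_factory=dict)


@dataclass
class ODTimeSeries:
    od: np.ndarray              # (n_times, n_channels, 2), natural log
    sample_rate_hz: float
    channel_mask: np.ndarray    # (n_channels,) bool, False = pruned
    events: list
    probe: object = None
    subject_id: str = ""
    array_id: str = ""

    def times(self) -> np.ndarray:
        return np.arange(self.od.shape[0]) / self.sample_rate_hz


@dataclass
class ConcTimeSeries:
    conc: np.ndarray            # (n_times, n_channels, 3) HbO/HbR/HbT, uM
    sample_rate_hz: float
    channel_mask: np.ndarray
    events: list
    rejected_blocks: dict = field(default_factory=dict)  # cond -> [block idx]
    probe: object = None
    subject_id: str = ""
    array_id: str = ""

    def times(self) -> np.ndarray:
        return np.arange(self.conc.shape[0]) / self.sample_rate_hz


def prune_channels(raw: RawRecording, intensity_min: float = 0.001,
                   snr_min: float = 5.0) -> PruneResult:
    """Prune channels with raw level below threshold or SNR below threshold.

    SNR is mean/sd of the raw intensity per channel-wavelength; a channel is
    pruned when either wavelength fails either rule.
    """
    I = raw.intensity
    mean = I.mean(axis=0)                       # (n_ch, n_wl)
    sd = I.std(axis=0)
    with np.errstate(divide="ignore"):
        snr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    ok = (mean >= intensity_min) & (snr >= snr_min)
    mask = ok.all(axis=1)
    if not mask.any():
        raise AllChannelsPrunedError(
            "all channels failed the pruning criteria")
    per_class = {}
    if raw.probe is not None:
        for i, (_, _, cls) in enumerate(raw.probe.channels):
            if not mask[i]:
                per_class[cls] = per_class.get(cls, 0) + 1
    return PruneResult(mask=mask, n_pruned=int((~mask).sum()),
                       fraction_pruned=float((~mask).mean()),
                       snr=snr, mean_level=mean, per_class_pruned=per_class)


def intensity_to_od(raw: RawRecording,
                    channel_mask: np.ndarray | None = None) -> ODTimeSeries:
    """OD = -ln(I / temporal mean of I), per channel and wavelength."""
    mask = (np.ones(raw.n_channels, bool) if channel_mask is None
            else np.asarray(channel_mask, bool))
    I = raw.intensity
    if np.any(I[:, mask, :] <= 0):
        raise ValueError("non-positive intensity on an unpruned channel")
    mean = I.mean(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        od = -np.log(I / mean)
    od[:, ~mask, :] = 0.0
    return ODTimeSeries(od=od, sample_rate_hz=raw.sample_rate_hz,
                        channel_mask=mask, events=raw.events, probe=raw.probe,
                        subject_id=raw.subject_id, array_id=raw.array_id)


def _moving_std(x: np.ndarray, win: int) -> np.ndarray:
    m = uniform_filter1d(x, win, axis=0, mode="nearest")
    m2 = uniform_filter1d(x * x, win, axis=0, mode="nearest")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def _segments_from_flags(flags: np.ndarray):
    """Contiguous (start, stop, is_motion) runs from a boolean vector."""
    edges = np.flatnonzero(np.diff(flags.astype(int))) + 1
    bounds = np.concatenate([[0], edges, [flags.size]])
    return [(int(a), int(b), bool(flags[a]))
            for a, b in zip(bounds[:-1], bounds[1:])]


def _motion_flags(od_channel: np.ndarray, k: float, window: int) -> np.ndarray:
    """Joint motion flags for one channel from both wavelengths.

    Motion is achromatic: a segment flagged at either wavelength is treated
    as motion at both, so the correction never introduces differential
    (wavelength-unbalanced) baseline errors that would masquerade as huge
    concentration steps.
    """
    flags = np.zeros(od_channel.shape[0], dtype=bool)
    for w in range(od_channel.shape[1]):
        mstd = _moving_std(od_channel[:, w], window)
        med = np.median(mstd)
        if med <= 0:
            med = np.finfo(float).eps
        flags |= mstd > k * med
    # dilate flags by half a window so segments cover the transition
    return uniform_filter1d(flags.astype(float), window,
                            mode="nearest") > 1e-12


def _splinesg_one(x: np.ndarray, flags: np.ndarray, fs: float, p: float,
                  frame: int) -> np.ndarray:
    """SplineSG correction of a single OD series; see splinesg_correct."""
    anchor_n = max(int(round(fs)), 2)
    out = np.empty_like(x)
    segments = _segments_from_flags(flags)
    level = None
    for a, b, is_motion in segments:
        seg = x[a:b]
        if is_motion and b - a >= 4:
            tt = np.arange(a, b) / fs
            lam = (1.0 - p) / p
            spline = make_smoothing_spline(tt, seg, lam=lam)(tt)
            corrected = seg - spline
        else:
            corrected = seg.copy()
        head = corrected[:min(anchor_n, corrected.size)].mean()
        if level is None:
            offset = 0.0
        else:
            offset = level - head
        corrected = corrected + offset
        out[a:b] = corrected
        level = corrected[-min(anchor_n, corrected.size):].mean()

    # Savitzky-Golay residual despiking: replace samples that deviate
    # strongly from the smooth baseline
    if frame >= 5:
        frame_odd = frame if frame % 2 == 1 else frame + 1
        if frame_odd < out.size:
            base = savgol_filter(out, frame_odd, 3)
            resid = out - base
            sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if sd > 0:
                spikes = np.abs(resid) > 4.0 * sd
                out[spikes] = base[spikes]
    return out


def splinesg_correct(odts: ODTimeSeries, p: float = 0.99,
                     frame_s: float = 10.0, k: float = 3.0,
                     motion_window_s: float = 0.5) -> ODTimeSeries:
    """Spline baseline-shift correction plus Savitzky-Golay despiking.

    Motion segments are flagged, jointly over the two wavelengths of a
    channel, where a short moving-window standard deviation exceeds ``k``
    times its median; within flagged segments a smoothing spline (smoothing
    parameter ``p``, csaps convention) is subtracted and segment levels are
    re-anchored sequentially to the neighboring clean baseline. A
    Savitzky-Golay filter (order 3, window ``frame_s``) then replaces
    residual fast spikes with the local smooth baseline. Clean data passes
    through unchanged up to the (identity) re-anchoring.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    fs = odts.sample_rate_hz
    frame = int(round(frame_s * fs))
    if frame < 5:
        raise ValueError("frame_s shorter than 5 samples")
    window = max(int(round(motion_window_s * fs)), 3)
    od = odts.od.copy()
    for c in np.flatnonzero(odts.channel_mask):
        flags = _motion_flags(od[:, c, :], k, window)
        for w in range(od.shape[2]):
            od[:, c, w] = _splinesg_one(od[:, c, w], flags, fs, p, frame)
    return replace(odts, od=od)


def lowpass(odts: ODTimeSeries, cutoff_hz: float = 0.5,
            order: int = 3) -> ODTimeSeries:
    """Zero-phase Butterworth low-pass (forward-backward)."""
    nyq = odts.sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = butter(order, cutoff_hz / nyq, btype="low", output="sos")
    od = sosfiltfilt(sos, odts.od, axis=0)
    return replace(odts, od=od)


def od_to_conc(odts: ODTimeSeries, probe=None, ppf: float = 1.0,
               wavelengths=None) -> ConcTimeSeries:
    """Modified Beer-Lambert conversion to HbO/HbR/HbT concentrations (uM).

    Effective pathlength per channel is its nominal separation times the
    partial pathlength factor ``ppf``.
    """
    probe = probe if probe is not None else odts.probe
    if probe is None:
        raise ValueError("probe geometry required for pathlengths")
    wavelengths = wavelengths or (760.0, 850.0)
    L = probe.nominal_separations() * ppf
    hb = od_to_hb(odts.od, L, wavelengths)       # (nt, nch, 2)
    conc = np.concatenate([hb, hb.sum(axis=2, keepdims=True)], axis=2)
    return ConcTimeSeries(conc=conc, sample_rate_hz=odts.sample_rate_hz,
                          channel_mask=odts.channel_mask, events=odts.events,
                          probe=probe, subject_id=odts.subject_id,
                          array_id=odts.array_id)


def block_windows(events, sample_rate_hz, n_times, pre_s=0.0, post_s=0.0):
    """Per-condition sample windows [onset-pre, onset+duration+post)."""
    out = {}
    for e in events:
        a = int(round((e.onset_s - pre_s) * sample_rate_hz))
        b = int(round((e.onset_s + e.duration_s + post_s) * sample_rate_hz))
        out.setdefault(e.condition, []).append((max(a, 0), min(b, n_times)))
    return out


def reject_blocks(conc: ConcTimeSeries, amp_threshold_uM: float = 15.0,
                  channel_fraction: float = 0.5) -> dict:
    """Automated surrogate for manual artifact-block rejection.

    A block is rejected when the within-block peak-to-peak HbO excursion
    exceeds ``amp_threshold_uM`` on more than ``channel_fraction`` of the
    unpruned channels. Updates ``conc.rejected_blocks`` and returns it.
    """
    rejected = {}
    kept = np.flatnonzero(conc.channel_mask)
    wins = block_windows(conc.events, conc.sample_rate_hz, conc.conc.shape[0])
    for cond, windows in wins.items():
        bad = []
        for b_idx, (a, b) in enumerate(windows):
            if b <= a or kept.size == 0:
                continue
            seg = conc.conc[a:b, kept, 0]
            p2p = seg.max(axis=0) - seg.min(axis=0)
            if np.mean(p2p > amp_threshold_uM) > channel_fraction:
                bad.append(b_idx)
        rejected[cond] = bad
    conc.rejected_blocks = rejected
    return rejected


def exclude_subject(conc: ConcTimeSeries, min_blocks: int = 5) -> bool:
    """True when fewer than ``min_blocks`` blocks survive for any condition.

    The default reproduces the exclusion rule "four or fewer blocks
    remaining for either condition".
    """
    counts = {}
    for e in conc.events:
        counts[e.condition] = counts.get(e.condition, 0) + 1
    for cond, total in counts.items():
        remaining = total - len(conc.rejected_blocks.get(cond, []))
        if remaining < min_blocks:
            return True
    return False


def preprocess_recording(raw: RawRecording, intensity_min: float = 0.001,
                         snr_min: float = 5.0, motion_correction: bool = True,
                         spline_p: float = 0.99, frame_s: float = 10.0,
                         cutoff_hz: float = 0.5, ppf: float = 1.0,
                         reject_amp_uM: float = 15.0) -> ConcTimeSeries:
    """Run the full preprocessing chain on one recording."""
    prune = prune_channels(raw, intensity_min, snr_min)
    od = intensity_to_od(raw, prune.mask)
    if motion_correction:
        od = splinesg_correct(od, p=spline_p, frame_s=frame_s)
    od = lowpass(od, cutoff_hz)
    conc = od_to_conc(od, ppf=ppf, wavelengths=raw.wavelengths_nm)
    reject_blocks(conc, amp_threshold_uM=reject_amp_uM)
    conc.prune_stats = prune
    return conc
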