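"""Block-delta t-statistics, ROI selection and the paired array comparison.

Per block, a delta concentration is the mean over the active window (7-18 s
after onset) minus the mean over the baseline window (-2-0 s); the mean
delta across blocks divided by its standard error is the per-channel (or
per-vertex) t-statistic. Group statistics aggregate subject block-average
deltas. Array performance is compared by a paired Student's t-test on the
per-subject ROI-extreme statistics (highest t for HbO, lowest for HbR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .preprocess import ConcTimeSeries


@dataclass
class BlockStats:
    deltas: np.ndarray          # (n_blocks, n_features) uM
    t: np.ndarray               # (n_features,), NaN where undefined
    n_blocks: int
    condition: str
    chromophore: str
    subject_id: str = ""
    array_id: str = ""


@dataclass
class ROISpec:
    """Channel ROIs per array and shared image-space vertex sets."""

    channel_sets: dict = field(default_factory=dict)  # (array, side) -> [ch]
    vertex_sets: dict = field(default_factory=dict)   # side -> [vertex]

    def validate(self) -> None:
        for array in {a for a, _ in self.channel_sets}:
            left = set(self.channel_sets.get((array, "left"), []))
            right = set(self.channel_sets.get((array, "right"), []))
            assert not (left & right), f"{array}: left/right ROIs overlap"


@dataclass
class ComparisonResult:
    """Paired array comparison for one condition/chromophore/ROI."""

    subject_ids: list
    sparse_values: np.ndarray
    hd_values: np.ndarray
    t: float
    p: float
    mean_sparse: float
    mean_hd: float
    se_sparse: float
    se_hd: float
    zero_variance: bool = False


def block_delta(conc: ConcTimeSeries, condition: str,
                chromophore: str = "HbO",
                active_window=(7.0, 18.0),
                baseline_window=(-2.0, 0.0)) -> BlockStats:
    """Per-block active-minus-baseline window means for all channels.

    Rejected blocks are excluded; blocks whose windows exceed the recording
    bounds are skipped with a warning.
    """
    wi = {"HbO": 0, "HbR": 1, "HbT": 2}[chromophore]
    fs = conc.sample_rate_hz
    nt = conc.conc.shape[0]
    rejected = set(conc.rejected_blocks.get(condition, []))
    onsets = [e.onset_s for e in conc.events if e.condition == condition]
    deltas = []
    for b_idx, onset in enumerate(onsets):
        if b_idx in rejected:
            continue
        a0 = int(round((onset + baseline_window[0]) * fs))
        a1 = int(round((onset + baseline_window[1]) * fs))
        b0 = int(round((onset + active_window[0]) * fs))
        b1 = int(round((onset + active_window[1]) * fs))
        if a0 < 0 or b1 > nt:
            warnings.warn(f"block at {onset:.1f}s exceeds recording bounds; "
                          "skipped")
            continue
        active = conc.conc[b0:b1, :, wi].mean(axis=0)
        base = conc.conc[a0:a1, :, wi].mean(axis=0)
        deltas.append(active - base)
    deltas = np.asarray(deltas)
    t = tstat(deltas) if deltas.shape[0] >= 2 else np.full(conc.conc.shape[1],
                                                           np.nan)
    t = np.where(conc.channel_mask, t, np.nan)
    return BlockStats(deltas=deltas, t=t, n_blocks=deltas.shape[0],
                      condition=condition, chromophore=chromophore,
                      subject_id=conc.subject_id, array_id=conc.array_id)


def tstat(deltas: np.ndarray) -> np.ndarray:
    """t = mean / (sd / sqrt(n)) across axis 0; NaN where SE is zero."""
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.shape[0]
    if n < 2:
        raise ValueError("need at least 2 blocks for a t-statistic")
    mean = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), np.nan)
    return t


def group_tstat(subject_means: np.ndarray,
                min_contributors: int = 2):
    """Across-subject t per feature from subject block-average deltas.

    ``subject_means``: (n_subjects, n_features), NaN where a subject does
    not contribute (pruned). Returns (t, n_contributing); features with
    fewer than ``min_contributors`` or zero SE are NaN-masked.
    """
    sm = np.asarray(subject_means, dtype=float)
    n = np.sum(~np.isnan(sm), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(sm, axis=0)
        sd = np.nanstd(sm, axis=0, ddof=1)
    se = sd / np.sqrt(np.maximum(n, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((n >= min_contributors) & (se > 0),
                     mean / np.where(se > 0, se, 1.0), np.nan)
    return t, n


def critical_t(n: int, alpha: float = 0.05) -> float:
    """Two-tailed Student t critical value with df = n - 1."""
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.t.ppf(1.0 - alpha / 2.0, n - 1))


def roi_vertices_from_sensitivity(A_hd, roi_channels, threshold: float = 0.01,
                                  brain_only: bool = True) -> np.ndarray:
    """Image-space ROI: vertices sensitive to the HD ROI channels.

    Stage 1 keeps vertices whose summed ROI-channel sensitivity exceeds
    ``threshold`` x maximum; stage 2 keeps those at or above the stage-1
    mean. Both arrays share this HD-defined vertex set by construction.
    """
    from .forward import SensitivityMatrix

    if isinstance(A_hd, SensitivityMatrix):
        values = A_hd.brain if brain_only else A_hd.values
    else:
        values = np.asarray(A_hd)
    summed = values[np.asarray(roi_channels, dtype=int)].sum(axis=0)
    stage1 = np.flatnonzero(summed > threshold * summed.max())
    if stage1.size == 0:
        raise ValueError("no vertices above the sensitivity threshold")
    stage2 = stage1[summed[stage1] >= summed[stage1].mean()]
    if stage2.size == 0:
        raise ValueError("no vertices above the ROI mean sensitivity")
    return stage2


def select_roi_extreme(t_values: np.ndarray, roi_channels,
                       chromophore: str = "HbO"):
    """ROI channel with the highest t (HbO) or lowest t (HbR).

    Returns (channel_id, value); NaN entries (pruned) are ignored; ties are
    broken by lowest channel index. Returns (None, nan) when every ROI
    channel is unavailable.
    """
    roi = np.asarray(sorted(roi_channels), dtype=int)
    vals = np.asarray(t_values, dtype=float)[roi]
    ok = ~np.isnan(vals)
    if not ok.any():
        return None, float("nan")
    roi, vals = roi[ok], vals[ok]
    pick = np.argmin(vals) if chromophore == "HbR" else np.argmax(vals)
    return int(roi[pick]), float(vals[pick])


def select_top_vertices(stat_values: np.ndarray, vertex_set, k: int = 25,
                        chromophore: str = "HbO") -> float:
    """Mean statistic over the k most extreme vertices of a vertex set."""
    vs = np.asarray(sorted(vertex_set), dtype=int)
    vals = np.asarray(stat_values, dtype=float)[vs]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    if vals.size < k:
        warnings.warn(f"vertex set smaller than k={k}; using all "
                      f"{vals.size} vertices")
        k = vals.size
    ordered = np.sort(vals)
    picked = ordered[:k] if chromophore == "HbR" else ordered[-k:]
    return float(picked.mean())


def paired_compare(selected_sparse: dict, selected_hd: dict) -> ComparisonResult:
    """Paired Student's t-test on per-subject (HD - sparse) selected values.

    Inputs map subject_id -> value; subjects missing from either side are
    excluded with a warning. Degenerate zero-variance differences are
    flagged rather than reported as infinite t.
    """
    common = sorted(set(selected_sparse) & set(selected_hd))
    dropped = (set(selected_sparse) | set(selected_hd)) - set(common)
    if dropped:
        warnings.warn(f"unpaired subjects excluded: {sorted(dropped)}")
    sp = np.array([selected_sparse[s] for s in common], dtype=float)
    hd = np.array([selected_hd[s] for s in common], dtype=float)
    ok = ~(np.isnan(sp) | np.isnan(hd))
    sp, hd = sp[ok], hd[ok]
    common = [s for s, o in zip(common, ok) if o]
    if len(common) < 2:
        raise ValueError("need at least 2 complete subject pairs")
    diff = hd - sp
    zero_var = bool(np.allclose(diff.std(ddof=1), 0.0))
    if zero_var:
        t = 0.0 if np.allclose(diff, 0.0) else float("nan")
        p = 1.0 if np.allclose(diff, 0.0) else float("nan")
    else:
        t, p = sps.ttest_rel(hd, sp)
    n = len(common)
    return ComparisonResult(
        subject_ids=common, sparse_values=sp, hd_values=hd,
        t=float(t), p=float(p),
        mean_sparse=float(sp.mean()), mean_hd=float(hd.mean()),
        se_sparse=float(sp.std(ddof=1) / np.sqrt(n)),
        se_hd=float(hd.std(ddof=1) / np.sqrt(n)),
        zero_variance=zero_var)


def paired_condition_contrast(values_a: dict, values_b: dict):
    """Paired t-test between two conditions within one array.

    Inputs map subject_id -> selected statistic for each condition; returns
    (t, p, n).
    """
    common = sorted(set(values_a) & set(values_b))
    a = np.array([values_a[s] for s in common], dtype=float)
    b = np.array([values_b[s] for s in common], dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need at least 2 complete subject pairs")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p), int(a.size)


def roi_channels_from_labels(probe, mesh, long_only: bool = True) -> dict:
    """Channel ROIs by the region label nearest each channel midpoint.

    Returns {"left": [...], "right": [...]} of channel indices whose
    midpoint projects radially onto a dlPFC-labeled brain vertex.
    """
    mids = probe.channel_midpoints()
    proj = mids / np.linalg.norm(mids, axis=1, keepdims=True) \
        * mesh.config.brain_radius_mm
    d = np.linalg.norm(proj[:, None, :] - mesh.brain_vertices[None], axis=-1)
    nearest = np.argmin(d, axis=1)
    labels = mesh.region_labels[nearest]
    sets = {"left": [], "right": []}
    for c_idx, lab in enumerate(labels):
        if long_only and probe.channels[c_idx][2] == "short":
            continue
        if lab == "dlPFC_left":
            sets["left"].append(c_idx)
        elif lab == "dlPFC_right":
            sets["right"].append(c_idx)
    return sets
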