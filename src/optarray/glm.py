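"""Per-channel HRF estimation: OLS GLM with Gaussian temporal bases.

The hemodynamic response of each long channel is modeled, per condition, as
a linear combination of Gaussian bumps stepped at 1 s across the -2..23 s
peristimulus window; nuisance structure is captured by the best-correlated
short-separation channel (superficial physiology) and Legendre drift
polynomials. Estimation is ordinary least squares, solved per group of
channels sharing a short-separation regressor with a single multi-RHS
factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ConcTimeSeries


@dataclass
class DesignMatrix:
    matrix: np.ndarray            # (n_times, n_columns) shared columns
    column_groups: dict           # name -> index array into matrix columns
    conditions: tuple
    basis_centers_s: np.ndarray   # Gaussian centers relative to onset
    basis_width_s: float
    trange: tuple
    sample_rate_hz: float

    @property
    def n_basis(self) -> int:
        return self.basis_centers_s.size


@dataclass
class HRFEstimate:
    """Estimated per-channel, per-condition HRFs on the peristimulus grid."""

    hrf: np.ndarray               # (n_cond, n_ch, 2 chromophores, n_window)
    time_s: np.ndarray            # (n_window,), -2..23 s at the sample rate
    conditions: tuple
    channel_mask: np.ndarray
    coefficients: dict            # chromophore -> (n_ch, n_columns[+1])
    residual_variance: np.ndarray  # (n_ch, 2)
    dof: int
    ss_choice: np.ndarray         # (n_ch, 2) chosen SS channel or -1
    clean_conc: np.ndarray | None = None  # conc minus SS + drift fits

    def peak(self, condition: str, chromophore: str = "HbO") -> np.ndarray:
        ci = self.conditions.index(condition)
        wi = {"HbO": 0, "HbR": 1}[chromophore]
        return self.hrf[ci, :, wi, :].max(axis=-1)


def build_design(events, sample_rate_hz: float, n_times: int,
                 trange=(-2.0, 23.0), basis_width_s: float = 1.0,
                 basis_step_s: float = 1.0,
                 drift_order: int = 3) -> DesignMatrix:
    """Assemble condition Gaussian-basis columns plus Legendre drift.

    Per condition, one column per Gaussian center (centers stepped
    ``basis_step_s`` across the inclusive window), each column the sum over
    that condition's onsets of a Gaussian placed relative to onset.
    """
    events = list(events)
    if not events:
        raise ValueError("no events to build a design from")
    conditions = tuple(sorted({e.condition for e in events}))
    t = np.arange(n_times) / sample_rate_hz
    centers = np.arange(trange[0], trange[1] + 1e-9, basis_step_s)
    sigma = basis_width_s

    cols, groups = [], {}
    n_cols = 0
    run_end = t[-1]
    for cond in conditions:
        onsets = [e.onset_s for e in events if e.condition == cond]
        block = np.zeros((n_times, centers.size))
        for onset in onsets:
            if onset + trange[1] > run_end:
                warnings.warn(
                    f"window for onset {onset:.1f}s extends past recording "
                    "end; contribution truncated")
            rel = t - onset
            block += np.exp(-0.5 * ((rel[:, None] - centers[None, :])
                                    / sigma) ** 2)
        groups[f"condition:{cond}"] = np.arange(n_cols, n_cols + centers.size)
        cols.append(block)
        n_cols += centers.size

    # Legendre drift polynomials on [-1, 1] for conditioning
    x = np.linspace(-1.0, 1.0, n_times)
    drift = np.polynomial.legendre.legvander(x, drift_order)
    groups["drift"] = np.arange(n_cols, n_cols + drift.shape[1])
    cols.append(drift)

    return DesignMatrix(matrix=np.hstack(cols), column_groups=groups,
                        conditions=conditions, basis_centers_s=centers,
                        basis_width_s=sigma, trange=tuple(trange),
                        sample_rate_hz=sample_rate_hz)


def pick_ss_regressor(conc: ConcTimeSeries, channel: int, ss_channels,
                      chromophore: str = "HbO") -> int:
    """Short-separation channel with greatest Pearson correlation.

    Ties are broken by lowest channel index. Raises if no unpruned short
    channel is available.
    """
    wi = {"HbO": 0, "HbR": 1}[chromophore]
    ss = [s for s in np.atleast_1d(ss_channels) if conc.channel_mask[s]]
    if not ss:
        raise ValueError("no unpruned short-separation channel")
    y = conc.conc[:, channel, wi]
    best, best_r = ss[0], -np.inf
    for s in sorted(ss):
        r = _pearson(y, conc.conc[:, s, wi])
        if r > best_r + 1e-12:
            best, best_r = s, r
    return int(best)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _ss_choices(conc: ConcTimeSeries, targets, ss_list, wi) -> np.ndarray:
    """Vectorized best-correlated SS channel per target (ties: lowest index)."""
    X = conc.conc[:, ss_list, wi]
    Y = conc.conc[:, targets, wi]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Xn = np.linalg.norm(Xc, axis=0)
    Yn = np.linalg.norm(Yc, axis=0)
    Xn[Xn == 0] = 1.0
    Yn[Yn == 0] = 1.0
    corr = (Xc / Xn).T @ (Yc / Yn)            # (n_ss, n_targets)
    order = np.argsort(ss_list)               # lowest index wins ties
    corr = corr[order]
    best = np.argmax(np.round(corr, 12), axis=0)
    return np.asarray(ss_list)[order][best]


def fit_glm(conc: ConcTimeSeries, design: DesignMatrix,
            ss_channels=None, keep_clean: bool = True) -> HRFEstimate:
    """OLS fit of the Gaussian-basis GLM for every unpruned long channel.

    The HRF per condition is reconstructed as the basis expansion over the
    peristimulus grid; short-separation and drift contributions are excluded
    from the HRF. When ``keep_clean`` is set, the concentration time series
    with the fitted nuisance (SS + drift) removed is retained for
    block-level statistics.
    """
    X0 = design.matrix
    nt, n_ch = conc.conc.shape[:2]
    fs = conc.sample_rate_hz
    probe = conc.probe
    if ss_channels is None and probe is not None:
        ss_channels = probe.short_channels
    ss_list = [int(s) for s in np.atleast_1d(
        ss_channels if ss_channels is not None else [])
        if conc.channel_mask[s]]

    targets_all = [c for c in range(n_ch) if conc.channel_mask[c]]
    if probe is not None:
        long_set = set(probe.long_channels.tolist())
        targets_all = [c for c in targets_all if c in long_set]
    if not targets_all:
        raise ValueError("no unpruned long channels to fit")

    t0, t1 = design.trange
    n_win = int(round((t1 - t0) * fs)) + 1
    tgrid = t0 + np.arange(n_win) / fs
    basis_eval = np.exp(-0.5 * ((tgrid[:, None] - design.basis_centers_s[None, :])
                                / design.basis_width_s) ** 2)

    n_cond = len(design.conditions)
    hrf = np.full((n_cond, n_ch, 2, n_win), np.nan)
    resid_var = np.full((n_ch, 2), np.nan)
    ss_choice = np.full((n_ch, 2), -1, dtype=int)
    coefficients = {}
    clean = conc.conc[:, :, :2].copy() if keep_clean else None
    dof = nt - (X0.shape[1] + (1 if ss_list else 0))

    for wi, chrom in enumerate(("HbO", "HbR")):
        betas = np.zeros((n_ch, X0.shape[1] + (1 if ss_list else 0)))
        if ss_list:
            choice = _ss_choices(conc, targets_all, ss_list, wi)
        else:
            choice = np.full(len(targets_all), -1)
            warnings.warn("no unpruned short-separation channel; GLM "
                          "proceeds without superficial regression")
        for s_val in np.unique(choice):
            members = [t for t, s in zip(targets_all, choice) if s == s_val]
            if s_val >= 0:
                X = np.column_stack([X0, conc.conc[:, s_val, wi]])
            else:
                X = X0
            Y = conc.conc[:, members, wi]
            B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
            if rank < X.shape[1]:
                warnings.warn("rank-deficient design; minimum-norm solution")
            resid = Y - X @ B
            resid_var[members, wi] = (resid ** 2).sum(axis=0) / max(nt - rank, 1)
            betas[members, :X.shape[1]] = B.T
            ss_choice[members, wi] = s_val
            if keep_clean:
                nuis_idx = list(design.column_groups["drift"])
                Xn = X[:, nuis_idx]
                Bn = B[nuis_idx]
                fitted_nuis = Xn @ Bn
                if s_val >= 0:
                    fitted_nuis = fitted_nuis + np.outer(
                        X[:, -1], np.ones(len(members))) * B[-1]
                clean[:, members, wi] -= fitted_nuis
        coefficients[chrom] = betas

        for ci, cond in enumerate(design.conditions):
            idx = design.column_groups[f"condition:{cond}"]
            hrf[ci, targets_all, wi, :] = betas[targets_all][:, idx] @ basis_eval.T

    return HRFEstimate(hrf=hrf, time_s=tgrid, conditions=design.conditions,
                       channel_mask=conc.channel_mask,
                       coefficients=coefficients,
                       residual_variance=resid_var, dof=dof,
                       ss_choice=ss_choice, clean_conc=clean)
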