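"""Temporal cleaning of BOLD runs.

Fixed step order (all per-run until concatenation): discard initial volumes
-> spike interpolation -> high-pass (2000 s) -> dynamic band-stop -> nuisance
regression (WM/CSF means + PCs, Volterra-expanded B0 parameters) -> low-pass
(10 s) -> per-run demean -> run concatenation -> group-PCA reduction.

All filters are zero-phase (forward-backward Butterworth).  A high-pass whose
cutoff period is not representable at the run length degrades gracefully to
linear+quadratic detrending, with a logged warning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.stats import median_abs_deviation

from .core import ConfoundRecord, TimeSeriesRun

log = logging.getLogger(__name__)

__all__ = [
    "NuisanceDesign",
    "CleaningParams",
    "discard_initial_volumes",
    "despike_interpolate",
    "highpass_filter",
    "dynamic_bandstop",
    "build_nuisance_design",
    "regress_confounds",
    "lowpass_filter",
    "demean_and_concatenate",
    "group_pca_reduce",
    "clean_run",
]


@dataclass
class NuisanceDesign:
    columns: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.shape[1] != len(self.column_labels):
            raise ValueError("column count does not match labels")
        norms = np.abs(self.columns).max(axis=0)
        if np.any(norms == 0):
            dead = [self.column_labels[i] for i in np.flatnonzero(norms == 0)]
            raise ValueError(f"all-zero nuisance column(s): {dead}")


def discard_initial_volumes(run: TimeSeriesRun, n: int = 5) -> TimeSeriesRun:
    """Drop the first ``n`` volumes (pre-steady-state RF excitation)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if run.n_volumes <= n:
        raise ValueError(f"run has {run.n_volumes} volumes, cannot discard {n}")
    return run.with_data(run.data[n:])


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = median_abs_deviation(x, scale="normal")
    if mad == 0:
        return np.zeros_like(x)
    return (x - med) / mad


def despike_interpolate(
    run: TimeSeriesRun, z_threshold: float = 5.0, max_spike_len: int = 10
) -> tuple[TimeSeriesRun, np.ndarray]:
    """Flag spike volumes on the robust z of the first-differenced mean
    signal and replace them by linear interpolation between clean neighbours.

    A large difference entering a spike is paired with the next large
    difference of opposite sign leaving it (within ``max_spike_len``
    volumes); the volumes in between are flagged.  An unpaired jump flags a
    single volume.  Endpoints take the nearest clean value.
    """
    if run.n_volumes < 3:
        raise ValueError("need at least 3 volumes to despike")
    mean_sig = run.data.mean(axis=1)
    d = np.diff(mean_sig)
    z = _robust_z(d)
    big = np.flatnonzero(np.abs(z) > z_threshold)
    flagged: set[int] = set()
    used: set[int] = set()
    for i in big:
        if i in used:
            continue
        partner = None
        for j in big:
            if i < j <= i + max_spike_len and np.sign(z[j]) == -np.sign(z[i]):
                partner = j
                break
        if partner is None:
            flagged.add(i + 1)  # diff at i implicates volume i+1
            used.add(i)
        else:
            flagged.update(range(i + 1, partner + 1))
            used.update((i, partner))
    idx = np.array(sorted(flagged), dtype=int)
    if idx.size == 0:
        return run, idx
    clean = np.setdiff1d(np.arange(run.n_volumes), idx)
    if clean.size == 0:
        raise ValueError("every volume flagged as a spike; data unusable")
    data = run.data.copy()
    for p in range(run.n_points):
        data[idx, p] = np.interp(idx, clean, data[clean, p])
    log.info("despike: interpolated %d volume(s) %s", idx.size, idx.tolist())
    return run.with_data(data), idx


def _apply_zero_phase(data: np.ndarray, fs: float, sos: np.ndarray) -> np.ndarray:
    """Apply the squared Butterworth magnitude response in the frequency
    domain: exactly zero-phase and exactly symmetric under time reversal
    (the squared gain mirrors a forward-backward IIR pass without its edge
    transients)."""
    n = data.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
    gain = np.abs(h) ** 2
    return np.fft.irfft(np.fft.rfft(data, axis=0) * gain[:, None], n=n, axis=0)


def highpass_filter(run: TimeSeriesRun, cutoff_seconds: float = 2000.0) -> TimeSeriesRun:
    """Zero-phase high-pass at ``1/cutoff_seconds`` Hz (Butterworth order 2,
    squared magnitude).  The mean and linear trend sit below any admissible
    cutoff and are removed outright before filtering.

    When the run is shorter than twice the cutoff period the filter is not
    representable; the step falls back to removing a fitted linear+quadratic
    trend (plus the mean), logged as such.
    """
    if cutoff_seconds <= 2 * run.tr_seconds:
        raise ValueError("cutoff must exceed twice the sampling interval")
    duration = run.n_volumes * run.tr_seconds
    t = np.linspace(-1.0, 1.0, run.n_volumes)
    if duration < 2 * cutoff_seconds:
        log.warning(
            "high-pass cutoff %.0f s not representable on a %.0f s run; "
            "falling back to quadratic detrend", cutoff_seconds, duration,
        )
        basis = np.column_stack([np.ones_like(t), t, t**2])
    else:
        basis = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(basis, run.data, rcond=None)
    detrended = run.data - basis @ beta
    if duration < 2 * cutoff_seconds:
        return run.with_data(detrended)
    sos = sps.butter(2, 1.0 / cutoff_seconds, btype="highpass",
                     fs=1.0 / run.tr_seconds, output="sos")
    return run.with_data(_apply_zero_phase(detrended, 1.0 / run.tr_seconds, sos))


def lowpass_filter(run: TimeSeriesRun, cutoff_seconds: float = 10.0) -> TimeSeriesRun:
    """Zero-phase low-pass at ``1/cutoff_seconds`` Hz (Butterworth order 2,
    squared magnitude)."""
    if cutoff_seconds <= 2 * run.tr_seconds:
        raise ValueError("cutoff must exceed twice the sampling interval")
    sos = sps.butter(2, 1.0 / cutoff_seconds, btype="lowpass",
                     fs=1.0 / run.tr_seconds, output="sos")
    return run.with_data(_apply_zero_phase(run.data, 1.0 / run.tr_seconds, sos))


def dynamic_bandstop(
    run: TimeSeriesRun,
    search_band: tuple[float, float] | None = None,
    k_mad: float = 6.0,
    notch_halfwidth_hz: float = 0.01,
    nperseg: int = 256,
) -> tuple[TimeSeriesRun, list[float]]:
    """Notch cyclic noise peaks found in the cross-point mean power spectrum.

    Peaks are local maxima of the Welch log-power (averaged over points)
    exceeding ``median + k_mad * MAD`` (MAD on the Gaussian-sigma scale)
    within ``search_band``; each is removed with a zero-phase Butterworth
    band-stop of the given half-width.  Defaults never trigger on white
    noise at typical run lengths.
    """
    fs = 1.0 / run.tr_seconds
    nyq = fs / 2.0
    lo, hi = search_band if search_band is not None else (0.1, nyq)
    if not (0.0 <= lo < hi <= nyq + 1e-12):
        raise ValueError(f"search band [{lo}, {hi}] invalid for Nyquist {nyq}")
    nperseg = min(nperseg, run.n_volumes)
    freqs, psd = sps.welch(run.data, fs=fs, nperseg=nperseg, axis=0)
    mean_psd = psd.mean(axis=1)
    band = (freqs >= lo) & (freqs <= hi)
    if band.sum() < 5:
        raise ValueError("search band contains too few frequency bins")
    logp = np.log(mean_psd[band] + np.finfo(float).tiny)
    thresh = np.median(logp) + k_mad * median_abs_deviation(logp, scale="normal")
    peaks, _ = sps.find_peaks(logp)
    # a peak at the band edge (monotone into the band) also counts
    edge = [i for i in (0, logp.size - 1) if logp[i] > thresh]
    cand = sorted(set(peaks.tolist()) | set(edge))
    notch_freqs = [float(freqs[band][i]) for i in cand if logp[i] > thresh]
    data = run.data
    applied: list[float] = []
    for f0 in notch_freqs:
        f_lo = max(f0 - notch_halfwidth_hz, 1e-4)
        f_hi = min(f0 + notch_halfwidth_hz, nyq * 0.999)
        if f_lo >= f_hi:
            continue
        sos = sps.butter(2, [f_lo, f_hi], btype="bandstop", fs=fs, output="sos")
        data = _apply_zero_phase(data, fs, sos)
        applied.append(f0)
        log.info("band-stop: notched %.4f Hz (half-width %.3f Hz)", f0, notch_halfwidth_hz)
    if applied:
        return run.with_data(data), applied
    return run, applied


def _leading_pcs(x: np.ndarray, n: int) -> np.ndarray:
    """Unit-norm time courses of the first ``n`` principal components of the
    column-demeaned signal matrix (fewer if rank-limited)."""
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    keep = min(n, int(np.sum(s > s[0] * 1e-10))) if s.size and s[0] > 0 else 0
    return u[:, :keep]


def build_nuisance_design(
    confounds: ConfoundRecord, include_cross_terms: bool = False
) -> NuisanceDesign:
    """Nuisance design: WM/CSF mean + first two PCs each, and the B0 traces
    expanded as a second-degree Volterra series.

    Per B0 trace x(t) the expansion is {x(t), x(t-1), x(t)^2, x(t-1)^2}
    (one-sample lag, edge-replicated), on the raw traces: a constant trace
    yields constant columns, whose collinearity with the intercept the
    pseudoinverse absorbs.  With ``include_cross_terms`` the products
    x(t)*x(t-1) are added.  An intercept column closes the design.
    Compartments with fewer than 3 signals fall back to the available PCs
    with a logged warning.
    """
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for name, sigs in (("wm", confounds.wm_signals), ("csf", confounds.csf_signals)):
        if sigs.shape[1] < 3:
            log.warning("%s compartment has only %d signal(s); using available PCs",
                        name, sigs.shape[1])
        cols.append(sigs.mean(axis=1))
        labels.append(f"{name}_mean")
        pcs = _leading_pcs(sigs, 2)
        for i in range(pcs.shape[1]):
            cols.append(pcs[:, i])
            labels.append(f"{name}_pc{i + 1}")
    b0 = confounds.b0_params
    for j in range(b0.shape[1]):
        x = b0[:, j]
        xlag = np.concatenate([[x[0]], x[:-1]])
        cols += [x, xlag, x**2, xlag**2]
        labels += [f"b0_{j + 1}", f"b0_{j + 1}_lag", f"b0_{j + 1}_sq", f"b0_{j + 1}_lag_sq"]
        if include_cross_terms:
            cols.append(x * xlag)
            labels.append(f"b0_{j + 1}_x_lag")
    cols.append(np.ones(confounds.n_volumes))
    labels.append("intercept")
    return NuisanceDesign(np.column_stack(cols), labels)


def regress_confounds(run: TimeSeriesRun, design: NuisanceDesign) -> TimeSeriesRun:
    """OLS residuals of every point's series against the nuisance design
    (pseudoinverse, so rank deficiency is harmless)."""
    if design.columns.shape[0] != run.n_volumes:
        raise ValueError("design rows do not match run length")
    beta = np.linalg.pinv(design.columns) @ run.data
    return run.with_data(run.data - design.columns @ beta)


def demean_and_concatenate(runs: Sequence[TimeSeriesRun]) -> np.ndarray:
    """Demean each run per point and stack in run order (time x points)."""
    if not runs:
        raise ValueError("no runs to concatenate")
    n_points = runs[0].n_points
    if any(r.n_points != n_points for r in runs):
        raise ValueError("runs disagree on point count")
    return np.vstack([r.data - r.data.mean(axis=0, keepdims=True) for r in runs])


def group_pca_reduce(subject_series: Sequence[np.ndarray], n_components: int) -> np.ndarray:
    """Group-PCA reduction of temporally stacked subject series.

    Returns an (n_components x points) representation S_n V_n^T from the SVD
    of the stack; its point-space covariance equals the stack's covariance
    restricted to the top-n principal subspace, and at full rank the
    reconstruction is lossless.
    """
    stack = np.vstack(list(subject_series))
    if n_components < 1 or n_components > min(stack.shape):
        raise ValueError(
            f"n_components must lie in [1, {min(stack.shape)}] for a "
            f"{stack.shape[0]} x {stack.shape[1]} stack"
        )
    _, s, vt = np.linalg.svd(stack, full_matrices=False)
    return s[:n_components, None] * vt[:n_components]


@dataclass(frozen=True)
class CleaningParams:
    """Tunable parameters of the per-run cleaning chain."""

    n_discard: int = 5
    spike_z: float = 5.0
    highpass_seconds: float = 2000.0
    lowpass_seconds: float = 10.0
    bandstop_band: tuple[float, float] | None = None
    bandstop_k_mad: float = 6.0
    notch_halfwidth_hz: float = 0.01
    truncate_last: int = 0  # drop this many trailing volumes before anything else


def clean_run(
    run: TimeSeriesRun,
    confounds: ConfoundRecord,
    params: CleaningParams | None = None,
) -> TimeSeriesRun:
    """Apply the full per-run cleaning chain in the fixed order."""
    p = params if params is not None else CleaningParams()
    if p.truncate_last > 0:
        run = run.with_data(run.data[: -p.truncate_last])
        confounds = confounds.trimmed(0, run.n_volumes)
    run = discard_initial_volumes(run, p.n_discard)
    confounds = confounds.trimmed(p.n_discard)
    run, _ = despike_interpolate(run, p.spike_z)
    run = highpass_filter(run, p.highpass_seconds)
    run, _ = dynamic_bandstop(run, p.bandstop_band, p.bandstop_k_mad, p.notch_halfwidth_hz)
    design = build_nuisance_design(confounds)
    run = regress_confounds(run, design)
    run = lowpass_filter(run, p.lowpass_seconds)
    return run.with_data(run.data - run.data.mean(axis=0, keepdims=True))
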