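"""Signal cleaning: Butterworth bandpass, EMD power-line removal, Hilbert spectrum.

EMG and ECG channels are zero-phase bandpass filtered (4th-order Butterworth,
forward-backward), then decomposed into intrinsic mode functions by empirical
mode decomposition so that the mode carrying power-line interference can be
dropped before reconstruction.  The Hilbert spectrum — time-frequency energy
built from the analytic signal of each retained IMF — feeds the
degree-of-stationarity features.  Skin conductance is only segmented (its
information lives well below any filter band used here).

No EMD library is assumed: the decomposition below is the standard sifting
algorithm with cubic-spline envelopes, mirrored boundary extrema, and a
Cauchy-type stopping criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numba
import numpy as np
from scipy import signal as sps

logger = logging.getLogger("painmap")


@dataclass
class PreprocessConfig:
    emg_band: tuple[float, float] = (20.0, 250.0)
    ecg_low: float = 0.1
    ecg_high: float = 250.0            # clipped to 0.45*fs at run time
    filter_order: int = 4
    line_freq: float = 50.0
    line_tol: float = 5.0              # IMF dominant-frequency match band, Hz
    remove_line: bool = True
    emd_max_imfs: int = 10
    emd_sift_tol: float = 0.2          # Cauchy stopping criterion
    emd_max_sifts: int = 12
    n_freq_bins: int = 64
    time_decim: int = 16

    def for_fs(self, fs: float) -> "PreprocessConfig":
        """Clip band edges below the Nyquist frequency for a given rate."""
        hi = 0.45 * fs
        cfg = PreprocessConfig(**self.__dict__)
        cfg.emg_band = (self.emg_band[0], min(self.emg_band[1], hi))
        cfg.ecg_high = min(self.ecg_high, hi)
        return cfg


@dataclass
class CleanWindow:
    """A cleaned, segmented single-channel window."""

    samples: np.ndarray
    sampling_rate: float
    modality: str
    provenance: list[str] = field(default_factory=list)


@dataclass
class HilbertSpectrum:
    """Time-frequency energy H(t, f); rows are time bins, columns frequency bins."""

    time_bins: np.ndarray
    freq_bins: np.ndarray
    energy: np.ndarray  # (n_time, n_freq), non-negative


# ---------------------------------------------------------------------------
# Filtering and segmentation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _design_sos(order: int, low: float, high: float, fs: float):
    if low == 0:
        return sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
    return sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    x: np.ndarray, fs: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward, no phase shift)."""
    if not (0 <= low < high < fs / 2):
        raise ValueError(f"band [{low}, {high}] Hz outside (0, fs/2) for fs={fs}")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = _design_sos(int(order), float(low), float(high), float(fs))
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def response_window(
    x: np.ndarray, fs: float, onset: float, duration: float
) -> np.ndarray:
    """Samples in [onset, onset + duration): a pure half-open slice."""
    if onset < 0:
        raise ValueError("onset must be >= 0")
    i0 = round(onset * fs)
    n = round(duration * fs)
    if i0 + n > len(x):
        raise ValueError("response window exceeds recording length")
    return np.asarray(x)[i0 : i0 + n]


# ---------------------------------------------------------------------------
# Empirical mode decomposition
# ---------------------------------------------------------------------------

def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mid = x[1:-1]
    maxi = np.nonzero((mid > x[:-2]) & (mid >= x[2:]))[0] + 1
    mini = np.nonzero((mid < x[:-2]) & (mid <= x[2:]))[0] + 1
    return maxi, mini


@numba.njit(cache=True)
def _natural_spline_eval(xi: np.ndarray, yi: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through (xi, yi) evaluated at 0..n-1 (xi sorted)."""
    k = xi.shape[0]
    m2 = np.zeros(k)  # second derivatives; natural boundary: ends stay 0
    if k > 2:
        # Thomas algorithm on the tridiagonal system for interior knots
        a = np.empty(k - 2)
        b = np.empty(k - 2)
        c = np.empty(k - 2)
        d = np.empty(k - 2)
        for i in range(1, k - 1):
            h0 = xi[i] - xi[i - 1]
            h1 = xi[i + 1] - xi[i]
            a[i - 1] = h0
            b[i - 1] = 2.0 * (h0 + h1)
            c[i - 1] = h1
            d[i - 1] = 6.0 * ((yi[i + 1] - yi[i]) / h1 - (yi[i] - yi[i - 1]) / h0)
        for i in range(1, k - 2):
            w = a[i] / b[i - 1]
            b[i] -= w * c[i - 1]
            d[i] -= w * d[i - 1]
        m2[k - 2] = d[k - 3] / b[k - 3]
        for i in range(k - 4, -1, -1):
            m2[i + 1] = (d[i] - c[i] * m2[i + 2]) / b[i]
    out = np.empty(n)
    seg = 0
    for t in range(n):
        tt = float(t)
        while seg < k - 2 and tt > xi[seg + 1]:
            seg += 1
        h = xi[seg + 1] - xi[seg]
        u = (xi[seg + 1] - tt) / h
        v = (tt - xi[seg]) / h
        out[t] = (
            u * yi[seg]
            + v * yi[seg + 1]
            + ((u**3 - u) * m2[seg] + (v**3 - v) * m2[seg + 1]) * h * h / 6.0
        )
    return out


def _envelope(idx: np.ndarray, x: np.ndarray, n: int) -> np.ndarray | None:
    """Cubic-spline envelope through extrema, with extrema mirrored past the ends."""
    if len(idx) < 2:
        return None
    # mirror up to two extrema about each end to tame spline end swings
    k = min(2, len(idx))
    left_i = -idx[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    xi = np.concatenate([left_i, idx, right_i])
    yi = np.concatenate([x[idx[:k]][::-1], x[idx], x[idx[-k:]][::-1]])
    xi, keep = np.unique(xi, return_index=True)
    yi = yi[keep]
    if len(xi) < 2:
        return None
    if len(xi) < 4:
        return np.interp(np.arange(n), xi, yi)
    return _natural_spline_eval(xi.astype(np.float64), yi.astype(np.float64), n)


def emd(
    x: np.ndarray,
    max_imfs: int = 10,
    sift_tol: float = 0.2,
    max_sifts: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose ``x`` into intrinsic mode functions.

    Returns ``(imfs, residual)`` with ``imfs`` of shape (n_imfs, n);
    ``imfs.sum(axis=0) + residual`` reconstructs the input exactly.
    Sifting stops per mode when the normalized squared change between
    successive siftings drops below ``sift_tol`` (Cauchy criterion).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    imfs: list[np.ndarray] = []
    r = x.copy()
    for _ in range(max_imfs):
        maxi, mini = _extrema(r)
        if len(maxi) + len(mini) < 3:
            break
        h = r.copy()
        for _ in range(max_sifts):
            maxi, mini = _extrema(h)
            upper = _envelope(maxi, h, n)
            lower = _envelope(mini, h, n)
            if upper is None or lower is None:
                break
            m = 0.5 * (upper + lower)
            h_new = h - m
            denom = float(np.sum(h * h))
            sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sift_tol:
                break
        imfs.append(h)
        r = r - h
    return (np.asarray(imfs) if imfs else np.empty((0, n))), r


def imf_dominant_frequency(imf: np.ndarray, fs: float) -> float:
    """Frequency of the spectral peak of one IMF (Hz)."""
    spec = np.abs(np.fft.rfft(imf))
    freqs = np.fft.rfftfreq(len(imf), d=1.0 / fs)
    if spec.sum() == 0:
        return 0.0
    return float(freqs[int(np.argmax(spec))])


def _line_concentration(imf: np.ndarray, fs: float, line_freq: float, tol: float) -> float:
    """Fraction of an IMF's spectral power within ±tol Hz of the line frequency."""
    spec = np.abs(np.fft.rfft(imf)) ** 2
    freqs = np.fft.rfftfreq(len(imf), d=1.0 / fs)
    tot = spec.sum()
    if tot == 0:
        return 0.0
    return float(spec[np.abs(freqs - line_freq) <= tol].sum() / tot)


def remove_powerline(
    x: np.ndarray,
    fs: float,
    line_freq: float = 50.0,
    tol: float = 5.0,
    emd_kwargs: dict | None = None,
    return_decomposition: bool = False,
    min_concentration: float = 0.5,
):
    """Drop the IMF carrying the power-line interference.

    A candidate mode must have its dominant (spectral-peak) frequency within
    ±tol of ``line_freq`` AND be tone-like — at least ``min_concentration`` of
    its spectral power inside that band.  The concentration gate prevents the
    removal of broadband signal modes that merely peak near the line frequency
    (e.g. wideband EMG whose passband contains the mains frequency), where
    dropping the mode would delete signal rather than interference.

    If no IMF qualifies the input is returned unchanged (logged).  With
    ``return_decomposition`` the retained IMFs and residual are also returned,
    so downstream Hilbert-spectrum computation can reuse the decomposition.
    """
    if line_freq >= fs / 2:
        raise ValueError("line_freq must be below Nyquist")
    imfs, res = emd(x, **(emd_kwargs or {}))
    removed = None
    if len(imfs):
        doms = np.array([imf_dominant_frequency(m, fs) for m in imfs])
        conc = np.array(
            [_line_concentration(m, fs, line_freq, tol) for m in imfs]
        )
        close = (np.abs(doms - line_freq) <= tol) & (conc >= min_concentration)
        if close.any():
            removed = int(np.argmin(np.where(close, np.abs(doms - line_freq), np.inf)))
    if removed is None:
        logger.debug("no IMF matched %.0f Hz within +/-%.0f Hz; signal unchanged", line_freq, tol)
        clean = np.asarray(x, dtype=float)
        kept = imfs
    else:
        kept = np.delete(imfs, removed, axis=0)
        clean = kept.sum(axis=0) + res if len(kept) else res.copy()
    if return_decomposition:
        return clean, kept, res, removed
    return clean


# ---------------------------------------------------------------------------
# Hilbert spectrum
# ---------------------------------------------------------------------------

def hilbert_spectrum_from_imfs(
    imfs: np.ndarray, fs: float, n_freq_bins: int = 64, time_decim: int = 16
) -> HilbertSpectrum:
    """Bin per-IMF instantaneous energy over a (time, frequency) grid.

    The grid total equals the summed squared instantaneous amplitudes of the
    IMFs exactly (every sample lands in exactly one cell).
    """
    n = imfs.shape[1] if len(imfs) else 0
    n_t = max(1, int(np.ceil(n / time_decim))) if n else 1
    f_edges = np.linspace(0.0, fs / 2, n_freq_bins + 1)
    energy = np.zeros((n_t, n_freq_bins))
    t_idx = np.minimum(np.arange(n) // time_decim, n_t - 1) if n else np.empty(0, int)
    for imf in imfs:
        analytic = sps.hilbert(imf)
        amp2 = np.abs(analytic) ** 2
        phase = np.unwrap(np.angle(analytic))
        if n > 1:
            inst_f = np.diff(phase) * fs / (2 * np.pi)
            inst_f = np.append(inst_f, inst_f[-1])
        else:
            inst_f = np.zeros(n)
        f_idx = np.clip(
            np.digitize(np.clip(inst_f, 0.0, fs / 2), f_edges) - 1, 0, n_freq_bins - 1
        )
        np.add.at(energy, (t_idx, f_idx), amp2)
    time_bins = (np.arange(n_t) * time_decim + time_decim / 2) / fs
    f_centers = 0.5 * (f_edges[:-1] + f_edges[1:])
    return HilbertSpectrum(time_bins, f_centers, energy)


def hilbert_spectrum(
    x: np.ndarray,
    fs: float,
    n_freq_bins: int = 64,
    time_decim: int = 16,
    emd_kwargs: dict | None = None,
) -> HilbertSpectrum:
    """EMD → analytic signal per IMF → binned time-frequency energy."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        n_t = max(1, int(np.ceil(len(x) / time_decim)))
        f_edges = np.linspace(0.0, fs / 2, n_freq_bins + 1)
        return HilbertSpectrum(
            (np.arange(n_t) * time_decim + time_decim / 2) / fs,
            0.5 * (f_edges[:-1] + f_edges[1:]),
            np.zeros((n_t, n_freq_bins)),
        )
    imfs, _ = emd(x, **(emd_kwargs or {}))
    return hilbert_spectrum_from_imfs(imfs, fs, n_freq_bins, time_decim)


# ---------------------------------------------------------------------------
# Per-trial pipeline
# ---------------------------------------------------------------------------

def preprocess_trial(trial, config: PreprocessConfig | None = None):
    """Clean all five channels of a trial.

    Returns ``(windows, spectra)``: modality → CleanWindow, and modality →
    HilbertSpectrum for the modalities whose stationarity features need one
    (the three EMG sites and SCL).  Spectra are built from the IMFs retained
    after power-line removal, so each channel is decomposed once.
    """
    cfg = (config or PreprocessConfig()).for_fs(trial.sampling_rate)
    fs = trial.sampling_rate
    emd_kwargs = dict(
        max_imfs=cfg.emd_max_imfs, sift_tol=cfg.emd_sift_tol, max_sifts=cfg.emd_max_sifts
    )
    windows: dict[str, CleanWindow] = {}
    spectra: dict[str, HilbertSpectrum] = {}

    def seg(x):
        return response_window(x, fs, trial.stimulus_onset, trial.duration - trial.stimulus_onset)

    for ch in ("zEMG", "cEMG", "tEMG"):
        y = bandpass_filter(seg(trial.channels[ch]), fs, *cfg.emg_band, cfg.filter_order)
        prov = [f"window", f"bandpass {cfg.emg_band[0]:g}-{cfg.emg_band[1]:g} Hz"]
        if cfg.remove_line:
            y, kept, res, removed = remove_powerline(
                y, fs, cfg.line_freq, cfg.line_tol, emd_kwargs, return_decomposition=True
            )
            prov.append(f"emd line removal (imf {removed})")
        else:
            kept, res = emd(y, **emd_kwargs)
        windows[ch] = CleanWindow(y, fs, ch, prov)
        spectra[ch] = hilbert_spectrum_from_imfs(kept, fs, cfg.n_freq_bins, cfg.time_decim)

    y = bandpass_filter(seg(trial.channels["ECG"]), fs, cfg.ecg_low, cfg.ecg_high, cfg.filter_order)
    prov = ["window", f"bandpass {cfg.ecg_low:g}-{cfg.ecg_high:g} Hz"]
    if cfg.remove_line:
        y, _, _, removed = remove_powerline(
            y, fs, cfg.line_freq, cfg.line_tol, emd_kwargs, return_decomposition=True
        )
        prov.append(f"emd line removal (imf {removed})")
    windows["ECG"] = CleanWindow(y, fs, "ECG", prov)

    y = seg(trial.channels["SCL"]).astype(float)
    windows["SCL"] = CleanWindow(y, fs, "SCL", ["window"])
    kept, _ = emd(y, **emd_kwargs)
    spectra["SCL"] = hilbert_spectrum_from_imfs(kept, fs, cfg.n_freq_bins, cfg.time_decim)

    return windows, spectra
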