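"""The 155-feature bank.

Each EMG site (zygomaticus ``z``, corrugator ``c``, trapezius ``t``) is
characterized by 39 features (#1–#39), skin conductance ``s`` by 35 (#1–#35),
and ECG ``h`` (heart) by 3 heart-rate-variability features (#40–#42), for a
total of 3×39 + 35 + 3 = 155 modality-prefixed feature names (e.g. ``cP2P``,
``sSDSD``, ``hslopeRR``).  The features fall into seven theoretical groups:
amplitude, variability, stationarity, entropy, linearity, similarity, and
frequency.

Similarity features compare the measurement window against the same channel of
a dedicated pain-free baseline recording of the same subject.  Stationarity's
degree-of-stationarity family is computed from the Hilbert spectrum produced
by :mod:`painmap.preprocess`.

Degenerate inputs (constant signals, zero variance, too few heartbeats) map to
documented zero conventions: no NaN or Inf ever leaves ``extract_features``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numba
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d

from .preprocess import (
    HilbertSpectrum,
    PreprocessConfig,
    bandpass_filter,
    preprocess_trial,
)

# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

# (number, base name, theoretical group) in canonical (numeric) order
FEATURE_TABLE: list[tuple[int, str, str]] = [
    (1, "HOMAV1", "Amplitude"),
    (2, "HOMAV1n", "Amplitude"),
    (3, "HOMAV2", "Amplitude"),
    (4, "HOMAV2n", "Amplitude"),
    (5, "MAV", "Amplitude"),
    (6, "P2P", "Amplitude"),
    (7, "PK", "Amplitude"),
    (8, "RMS", "Amplitude"),
    (9, "TMNP", "Amplitude"),
    (10, "TMNV", "Amplitude"),
    (11, "IQR", "Variability"),
    (12, "R", "Variability"),
    (13, "SD", "Variability"),
    (14, "VAR", "Variability"),
    (15, "IDS", "Stationarity"),
    (16, "MD", "Stationarity"),
    (17, "MIDS", "Stationarity"),
    (18, "MMNDS", "Stationarity"),
    (19, "SDMN", "Stationarity"),
    (20, "SDSD", "Stationarity"),
    (21, "ApEn", "Entropy"),
    (22, "FuzzyEn", "Entropy"),
    (23, "SampEn", "Entropy"),
    (24, "ShannonEn", "Entropy"),
    (25, "SpectralEn", "Entropy"),
    (26, "LDF", "Linearity"),
    (27, "PLDF", "Linearity"),
    (28, "CC", "Similarity"),
    (29, "MDCOH", "Similarity"),
    (30, "MI", "Similarity"),
    (31, "MICOH", "Similarity"),
    (32, "MNCOH", "Similarity"),
    (33, "MMNCOH", "Similarity"),
    (34, "BW", "Frequency"),
    (35, "CF", "Frequency"),
    (36, "MDF", "Frequency"),
    (37, "MNF", "Frequency"),
    (38, "MOF", "Frequency"),
    (39, "ZC", "Frequency"),
    (40, "MNRR", "Variability"),
    (41, "RMSSD", "Variability"),
    (42, "slopeRR", "Variability"),
]

MODALITY_PREFIX = {"zEMG": "z", "cEMG": "c", "tEMG": "t", "SCL": "s", "ECG": "h"}
PREFIX_MODALITY = {v: k for k, v in MODALITY_PREFIX.items()}
# feature numbers applicable per modality: EMG #1-39, SCL #1-35, ECG #40-42
MODALITY_NUMBERS = {
    "zEMG": range(1, 40),
    "cEMG": range(1, 40),
    "tEMG": range(1, 40),
    "SCL": range(1, 36),
    "ECG": range(40, 43),
}


@dataclass(frozen=True)
class RegistryEntry:
    name: str       # modality-prefixed, e.g. "cP2P"
    base: str       # e.g. "P2P"
    group: str
    modality: str
    number: int


def build_registry() -> list[RegistryEntry]:
    """Canonical ordered list of the 155 instantiated feature names."""
    by_number = {num: (base, grp) for num, base, grp in FEATURE_TABLE}
    entries = []
    for modality in ("zEMG", "cEMG", "tEMG", "SCL", "ECG"):
        p = MODALITY_PREFIX[modality]
        for num in MODALITY_NUMBERS[modality]:
            base, grp = by_number[num]
            entries.append(RegistryEntry(p + base, base, grp, modality, num))
    return entries


REGISTRY: list[RegistryEntry] = build_registry()
FEATURE_NAMES: list[str] = [e.name for e in REGISTRY]
META_COLUMNS = ("subject", "trial", "level")


@dataclass
class FeatureConfig:
    """Feature-extraction parameters (entropy template length m, tolerance
    fraction r of SD, histogram bins, stationarity sub-windows, dependence
    lags, per-modality coherence summary bands)."""

    m: int = 2
    r_frac: float = 0.2
    n_bins: int = 16
    n_segments: int = 10
    max_lag: int = 32
    linearity_bins: int = 8
    emg_coh_band: tuple[float, float] = (20.0, 250.0)
    scl_coh_band: tuple[float, float] = (0.0, 2.0)

    def coh_band(self, modality: str, fs: float) -> tuple[float, float]:
        if modality == "SCL":
            return self.scl_coh_band
        lo, hi = self.emg_coh_band
        return (lo, min(hi, 0.5 * fs))


@dataclass
class FeatureMatrix:
    """Trials × 155 features with per-row metadata (subject, trial, level)."""

    values: pd.DataFrame
    meta: pd.DataFrame
    normalization: str = "raw"

    def __post_init__(self):
        if len(self.values) != len(self.meta):
            raise ValueError("values and metadata row counts differ")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_trials(self) -> int:
        return len(self.values)

    def rows_for_levels(self, levels) -> np.ndarray:
        names = {lv if isinstance(lv, str) else lv.name for lv in levels}
        return np.nonzero(self.meta["level"].isin(names).to_numpy())[0]


# ---------------------------------------------------------------------------
# Group operations
# ---------------------------------------------------------------------------

def amplitude_features(x: np.ndarray) -> dict[str, float]:
    """MAV/RMS/PK/P2P, higher-order MAVs of the 1st/2nd difference (plus
    MAV-normalized variants), and mean relative times of peaks/valleys."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("amplitude features need at least 3 samples")
    mav = float(np.mean(np.abs(x)))
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    homav1 = float(np.mean(np.abs(d1)))
    homav2 = float(np.mean(np.abs(d2)))
    maxi, mini = _strict_extrema(x)
    tmnp = float(np.mean(maxi / (n - 1))) if len(maxi) else 0.0
    tmnv = float(np.mean(mini / (n - 1))) if len(mini) else 0.0
    return {
        "MAV": mav,
        "RMS": float(np.sqrt(np.mean(x**2))),
        "PK": float(np.max(np.abs(x))),
        "P2P": float(np.max(x) - np.min(x)),
        "HOMAV1": homav1,
        "HOMAV1n": homav1 / mav if mav > 0 else 0.0,
        "HOMAV2": homav2,
        "HOMAV2n": homav2 / mav if mav > 0 else 0.0,
        "TMNP": tmnp,
        "TMNV": tmnv,
    }


def _strict_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # local extrema by strict sign change of the first difference
    d = np.sign(np.diff(x))
    nz = d != 0
    if not nz.any():
        return np.empty(0, int), np.empty(0, int)
    idx = np.arange(len(d))
    # carry forward the last nonzero slope sign across plateaus
    acc = np.maximum.accumulate(np.where(nz, idx, -1))
    filled = np.where(acc >= 0, d[np.maximum(acc, 0)], 0.0)
    change = np.nonzero((filled[:-1] != filled[1:]) & (filled[:-1] != 0) & (filled[1:] != 0))[0] + 1
    maxi = change[filled[change] < 0]
    mini = change[filled[change] > 0]
    return maxi, mini


def variability_features(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("variability features need at least 2 samples")
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "VAR": float(np.var(x, ddof=1)),
        "SD": float(np.std(x, ddof=1)),
        "R": float(np.max(x) - np.min(x)),
        "IQR": float(q3 - q1),
    }


def stationarity_features(
    x: np.ndarray, fs: float, hs: HilbertSpectrum, n_segments: int = 10
) -> dict[str, float]:
    """Median, sub-window mean/SD dispersion, and the degree-of-stationarity
    family from the Hilbert spectrum.

    DS(f) = mean over time of (1 − H(t,f)/H̄(f))², where H̄(f) is the time
    average of the spectrum at frequency f.  IDS integrates DS over frequency;
    the modified variants weight DS by the marginal spectral energy:
    MIDS = ∫ DS·w df and MMNDS = Σ DS·w with w(f) = E(f)/ΣE.
    """
    x = np.asarray(x, dtype=float)
    if n_segments < 2 or n_segments > len(x):
        raise ValueError("n_segments must be in [2, len(x)]")
    seg_len = len(x) // n_segments
    segs = x[: seg_len * n_segments].reshape(n_segments, seg_len)
    sdmn = float(np.std(segs.mean(axis=1), ddof=1))
    sdsd = float(np.std(segs.std(axis=1, ddof=1), ddof=1))
    H = hs.energy  # (time, freq)
    hbar = H.mean(axis=0)
    ok = hbar > 0
    ds = np.zeros_like(hbar)
    if ok.any():
        ds[ok] = np.mean((1.0 - H[:, ok] / hbar[ok]) ** 2, axis=0)
    marg = H.sum(axis=0)
    w = marg / marg.sum() if marg.sum() > 0 else np.zeros_like(marg)
    return {
        "MD": float(np.median(x)),
        "SDMN": sdmn,
        "SDSD": sdsd,
        "IDS": float(np.trapezoid(ds, hs.freq_bins)),
        "MIDS": float(np.trapezoid(ds * w, hs.freq_bins)),
        "MMNDS": float(np.sum(ds * w)),
    }


@numba.njit(cache=True, fastmath=True)
def _template_pair_stats(x: np.ndarray, m: int, r: float):
    """Fused pass over template pairs for ApEn / SampEn / FuzzyEn.

    Chebyshev distances between length-m (and m+1) templates are accumulated
    pairwise: per-template match counts including self (ApEn), pair match
    counts over the first n−m start points excluding self (SampEn), and soft
    Gaussian membership sums exp(−(d/r)²) over the same pairs (FuzzyEn).
    Memberships below exp(−25) are skipped — beyond double reporting
    precision relative to the accumulated sums.
    """
    n = x.shape[0]
    nm = n - m + 1          # length-m template count (ApEn)
    q = n - m               # common template count for SampEn / FuzzyEn
    cm = np.ones(nm)        # self-matches included
    cm1 = np.ones(q)
    b_pairs = 0
    a_pairs = 0
    s_m = 0.0
    s_m1 = 0.0
    inv_r2 = 1.0 / (r * r)
    for i in range(nm):
        for j in range(i + 1, nm):
            d = 0.0
            for k in range(m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
            if d <= r:
                cm[i] += 1.0
                cm[j] += 1.0
            if j < q:  # both templates inside the common range
                if d <= r:
                    b_pairs += 1
                z = d * d * inv_r2
                if z < 25.0:
                    s_m += np.exp(-z)
                dk = abs(x[i + m] - x[j + m])
                d1 = dk if dk > d else d
                if d1 <= r:
                    a_pairs += 1
                    cm1[i] += 1.0
                    cm1[j] += 1.0
                z1 = d1 * d1 * inv_r2
                if z1 < 25.0:
                    s_m1 += np.exp(-z1)
    return cm, cm1, b_pairs, a_pairs, s_m, s_m1


def entropy_features(
    x: np.ndarray, m: int = 2, r_frac: float = 0.2, n_bins: int = 16
) -> dict[str, float]:
    """Approximate, sample, fuzzy, Shannon (amplitude histogram), and spectral
    entropy.  A constant signal returns all zeros by convention."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 50:
        raise ValueError("entropy features need at least 50 samples")
    sd = np.std(x)
    if sd == 0:
        return {k: 0.0 for k in ("ApEn", "SampEn", "FuzzyEn", "ShannonEn", "SpectralEn")}
    r = r_frac * sd
    q = n - m
    cm, cm1, B, A, s_m, s_m1 = _template_pair_stats(x, m, r)

    # ApEn: phi(m) − phi(m+1), self-matches included
    apen = float(np.mean(np.log(cm / (n - m + 1))) - np.mean(np.log(cm1 / q)))

    # SampEn: −ln(A/B) over matched pairs, self-matches excluded
    sampen = float(-np.log(A / B)) if A > 0 and B > 0 else 0.0

    # FuzzyEn: soft template matching with Gaussian membership exp(-(d/r)^2)
    phi_m = s_m / (q * (q - 1) / 2.0)
    phi_m1 = s_m1 / (q * (q - 1) / 2.0)
    fuzzyen = float(np.log(phi_m / phi_m1)) if phi_m > 0 and phi_m1 > 0 else 0.0

    # Shannon entropy of the amplitude histogram (bits)
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / n
    shannon = float(-np.sum(p * np.log2(p)))

    # Spectral entropy of the normalized Welch spectrum, in [0, 1]
    _, psd = _welch_psd(x, 1.0, min(256, n))
    tot = psd.sum()
    if tot > 0 and len(psd) > 1:
        ps = psd[psd > 0] / tot
        spectral = float(-np.sum(ps * np.log2(ps)) / np.log2(len(psd)))
    else:
        spectral = 0.0
    return {
        "ApEn": apen,
        "SampEn": sampen,
        "FuzzyEn": fuzzyen,
        "ShannonEn": shannon,
        "SpectralEn": spectral,
    }


def _hist_mi(a: np.ndarray, b: np.ndarray, bins: int, correct: bool = False) -> float:
    """Histogram mutual information in nats (optionally Miller–Madow corrected)."""
    counts, _, _ = np.histogram2d(a, b, bins=bins)
    return _mi_from_counts(counts, correct)


def _mi_from_counts(counts: np.ndarray, correct: bool = False) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    if correct:
        kx = int((px > 0).sum())
        ky = int((py > 0).sum())
        mi -= (kx - 1) * (ky - 1) / (2.0 * n)
        mi = max(mi, 0.0)
    return mi


def linearity_features(
    x: np.ndarray, max_lag: int = 32, n_bins: int = 8
) -> dict[str, float]:
    """Lag dependence function: excess of total over linear lag dependence.

    For each lag τ the linear dependence is the squared Pearson autocorrelation
    ρ(τ)² and the total dependence g(τ) = 1 − exp(−2·MI(τ)) from a
    Miller–Madow-corrected histogram MI.  LDF averages max(g − ρ², 0) over
    lags; PLDF computes the same statistic once on the pooled lag-pair
    population.
    """
    x = np.asarray(x, dtype=float)
    if not (1 <= max_lag < len(x) / 4):
        raise ValueError("max_lag must satisfy 1 <= max_lag < len(x)/4")
    n = len(x)
    if np.std(x) == 0:
        return {"LDF": 0.0, "PLDF": 0.0}
    # all lagged cross sums at once: FFT autocorrelation + prefix sums
    nfft = 2 * n
    X = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(X * np.conj(X), nfft)[: max_lag + 1]  # Σ_t x_t x_{t+τ}
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    taus = np.arange(1, max_lag + 1)
    cnt = n - taus
    sum_a = c1[n - taus]                      # Σ x[0:n-τ]
    sum_b = c1[n] - c1[taus]                  # Σ x[τ:n]
    sq_a = c2[n - taus]
    sq_b = c2[n] - c2[taus]
    cov = ac[1:] / cnt - sum_a * sum_b / cnt**2
    va = sq_a / cnt - (sum_a / cnt) ** 2
    vb = sq_b / cnt - (sum_b / cnt) ** 2
    ok = (va > 0) & (vb > 0)
    rho2 = np.zeros(max_lag)
    rho2[ok] = cov[ok] ** 2 / (va[ok] * vb[ok])
    # bin each sample once (bins span the full signal range), then per-lag
    # joint histograms reduce to a single bincount over combined indices
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    ix = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    excesses = []
    pooled = np.zeros(n_bins * n_bins)
    for i, tau in enumerate(taus):
        counts = np.bincount(ix[:-tau] * n_bins + ix[tau:], minlength=n_bins * n_bins)
        g = 1.0 - np.exp(-2.0 * _mi_from_counts(counts.reshape(n_bins, n_bins), correct=True))
        excesses.append(max(g - rho2[i], 0.0))
        pooled += counts
    n_pooled = int(cnt.sum())
    va_p = sq_a.sum() / n_pooled - (sum_a.sum() / n_pooled) ** 2
    vb_p = sq_b.sum() / n_pooled - (sum_b.sum() / n_pooled) ** 2
    cov_p = ac[1:].sum() / n_pooled - sum_a.sum() * sum_b.sum() / n_pooled**2
    rho2_p = cov_p**2 / (va_p * vb_p) if va_p > 0 and vb_p > 0 else 0.0
    g_p = 1.0 - np.exp(-2.0 * _mi_from_counts(pooled.reshape(n_bins, n_bins), correct=True))
    return {"LDF": float(np.mean(excesses)), "PLDF": float(max(g_p - rho2_p, 0.0))}


# Welch periodogram averaging (Hann window, 50% overlap, constant detrend,
# one-sided density scaling — the standard convention; agreement with
# scipy.signal.welch/csd is asserted in the test suite).  Implemented directly
# on a strided segment matrix because the per-call overhead of the generic
# scipy path dominates extraction time at these short window lengths.

@lru_cache(maxsize=32)
def _hann(nperseg: int) -> np.ndarray:
    return sps.get_window("hann", nperseg)


def _segments(x: np.ndarray, nperseg: int) -> np.ndarray:
    step = nperseg - nperseg // 2
    nseg = (len(x) - nperseg) // step + 1
    idx = np.arange(nperseg)[None, :] + step * np.arange(nseg)[:, None]
    return x[idx]


def _welch_fft(x: np.ndarray, nperseg: int) -> np.ndarray:
    seg = _segments(x, nperseg)
    seg = seg - seg.mean(axis=1, keepdims=True)
    return np.fft.rfft(seg * _hann(nperseg), axis=1)


def _onesided_scale(nperseg: int, fs: float) -> np.ndarray:
    w = _hann(nperseg)
    scale = np.full(nperseg // 2 + 1, 2.0 / (fs * float(w @ w)))
    scale[0] /= 2.0
    if nperseg % 2 == 0:
        scale[-1] /= 2.0
    return scale


def _welch_psd(x: np.ndarray, fs: float, nperseg: int):
    nperseg = min(nperseg, len(x))
    X = _welch_fft(x, nperseg)
    psd = (X.real**2 + X.imag**2).mean(axis=0) * _onesided_scale(nperseg, fs)
    return np.fft.rfftfreq(nperseg, 1.0 / fs), psd


def _welch_coherence(x: np.ndarray, y: np.ndarray, fs: float, nperseg: int):
    nperseg = min(nperseg, len(x))
    X = _welch_fft(x, nperseg)
    Y = _welch_fft(y, nperseg)
    pxx = (X.real**2 + X.imag**2).mean(axis=0)
    pyy = (Y.real**2 + Y.imag**2).mean(axis=0)
    pxy = (np.conj(X) * Y).mean(axis=0)
    denom = pxx * pyy
    coh = np.zeros_like(pxx)
    ok = denom > 0
    coh[ok] = np.abs(pxy[ok]) ** 2 / denom[ok]
    return np.fft.rfftfreq(nperseg, 1.0 / fs), coh


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def similarity_features(
    x: np.ndarray,
    ref: np.ndarray,
    fs: float,
    band: tuple[float, float],
    n_bins: int = 16,
) -> dict[str, float]:
    """Similarity of the measurement window to the subject's pain-free
    baseline on the same channel: Pearson correlation, histogram mutual
    information (nats), and Welch magnitude-squared coherence summaries over
    the modality band (mean, median, trapezoidal integral, and the mean
    restricted to coherence > 0.5)."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(x) != len(ref):
        raise ValueError("window and baseline reference must have equal length")
    cc = _corr(x, ref)
    mi = _hist_mi(x, ref, n_bins)
    nper = min(len(x), max(8, int(round(fs / 2))))
    f, coh = _welch_coherence(x, ref, fs, nper)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        mask = np.ones_like(f, bool)
    cb, fb = coh[mask], f[mask]
    above = cb > 0.5
    return {
        "CC": cc,
        "MI": mi,
        "MNCOH": float(cb.mean()),
        "MDCOH": float(np.median(cb)),
        "MICOH": float(np.trapezoid(cb, fb)),
        "MMNCOH": float(cb[above].mean()) if above.any() else 0.0,
    }


def frequency_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Welch-spectrum moments (mean/median/mode/center frequency, bandwidth)
    and the time-domain zero-crossing count."""
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise ValueError("frequency features need at least 64 samples")
    f, psd = _welch_psd(x, fs, min(256, len(x)))
    tot = psd.sum()
    signs = np.sign(x)
    signs = signs[signs != 0]
    zc = int(np.sum(signs[:-1] != signs[1:]))
    if tot == 0:
        return {"MNF": 0.0, "MDF": 0.0, "MOF": 0.0, "BW": 0.0, "CF": 0.0, "ZC": 0.0}
    p = psd / tot
    mnf = float(np.sum(f * p))
    cum = np.cumsum(psd)
    half = tot / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        mdf = float(f[0])
    else:
        frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
        mdf = float(f[i - 1] + frac * (f[i] - f[i - 1]))
    return {
        "MNF": mnf,
        "MDF": mdf,
        "MOF": float(f[int(np.argmax(psd))]),
        "CF": float(np.sqrt(np.sum(f**2 * p))),
        "BW": float(np.sqrt(np.sum((f - mnf) ** 2 * p))),
        "ZC": float(zc),
    }


# ---------------------------------------------------------------------------
# ECG heart-rate variability
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak sample indices: 5–30 Hz bandpass → squaring → peaks above half
    the rolling maximum, with a 250 ms refractory period."""
    ecg = np.asarray(ecg, dtype=float)
    hi = min(30.0, 0.45 * fs)
    y = bandpass_filter(ecg, fs, 5.0, hi, order=2)
    sq = y**2
    win = max(3, int(round(2.0 * fs)))
    thr = 0.5 * maximum_filter1d(sq, size=win, mode="nearest")
    peaks, _ = sps.find_peaks(sq, distance=max(1, int(round(0.25 * fs))))
    return peaks[sq[peaks] >= thr[peaks]]


def hrv_from_rr(rr_ms: np.ndarray) -> dict[str, float]:
    """HRV statistics from a sequence of RR intervals in milliseconds."""
    rr = np.asarray(rr_ms, dtype=float)
    if len(rr) < 1:
        return {"MNRR": 0.0, "RMSSD": 0.0, "slopeRR": 0.0}
    d = np.diff(rr)
    slope = float(np.polyfit(np.arange(len(rr)), rr, 1)[0]) if len(rr) > 1 else 0.0
    return {
        "MNRR": float(np.mean(rr)),
        "RMSSD": float(np.sqrt(np.mean(d**2))) if len(d) else 0.0,
        "slopeRR": slope,
    }


def hrv_features(ecg: np.ndarray, fs: float) -> dict[str, float]:
    """Mean RR interval (ms), RMSSD (ms), and the least-squares slope of RR
    versus beat index (ms/beat).  Fewer than 3 detected beats → zeros."""
    peaks = detect_r_peaks(ecg, fs)
    if len(peaks) < 3:
        return {"MNRR": 0.0, "RMSSD": 0.0, "slopeRR": 0.0}
    return hrv_from_rr(np.diff(peaks) / fs * 1000.0)


# ---------------------------------------------------------------------------
# Per-trial extraction and matrix assembly
# ---------------------------------------------------------------------------

def extract_features(
    trial,
    baseline_ref,
    pre_config: PreprocessConfig | None = None,
    feat_config: FeatureConfig | None = None,
    _baseline_windows: dict | None = None,
) -> dict[str, float]:
    """All 155 features of one trial (name → value).

    ``baseline_ref`` is the subject's dedicated pain-free recording; its
    cleaned windows can be passed via ``_baseline_windows`` to amortize
    preprocessing across a subject's trials.
    """
    if baseline_ref is not None and trial.subject_id != baseline_ref.subject_id:
        raise ValueError("trial and baseline reference belong to different subjects")
    if baseline_ref is not None and trial.sampling_rate != baseline_ref.sampling_rate:
        raise ValueError("trial and baseline reference sampling rates differ")
    fcfg = feat_config or FeatureConfig()
    windows, spectra = preprocess_trial(trial, pre_config)
    if _baseline_windows is None:
        _baseline_windows, _ = preprocess_trial(baseline_ref, pre_config)
    out: dict[str, float] = {}
    fs = trial.sampling_rate
    for modality in ("zEMG", "cEMG", "tEMG", "SCL"):
        p = MODALITY_PREFIX[modality]
        x = windows[modality].samples
        vals: dict[str, float] = {}
        vals.update(amplitude_features(x))
        vals.update(variability_features(x))
        vals.update(stationarity_features(x, fs, spectra[modality], fcfg.n_segments))
        vals.update(entropy_features(x, fcfg.m, fcfg.r_frac, fcfg.n_bins))
        vals.update(linearity_features(x, min(fcfg.max_lag, len(x) // 4 - 1), fcfg.linearity_bins))
        vals.update(
            similarity_features(
                x,
                _baseline_windows[modality].samples,
                fs,
                fcfg.coh_band(modality, fs),
                fcfg.n_bins,
            )
        )
        if modality != "SCL":
            vals.update(frequency_features(x, fs))
        else:
            fv = frequency_features(x, fs)
            vals.update({k: fv[k] for k in ("BW", "CF")})
        for num in MODALITY_NUMBERS[modality]:
            base = FEATURE_TABLE[num - 1][1]
            out[p + base] = vals[base]
    hv = hrv_features(windows["ECG"].samples, fs)
    for base, v in hv.items():
        out["h" + base] = v
    # degenerate-input conventions guarantee finiteness
    for k, v in out.items():
        if not np.isfinite(v):
            out[k] = 0.0
    return out


def build_feature_matrix(
    roster,
    gen_config=None,
    pre_config: PreprocessConfig | None = None,
    feat_config: FeatureConfig | None = None,
    progress: bool = False,
) -> FeatureMatrix:
    """Generate the roster's trials and extract the full feature matrix.

    Streams trial-by-trial (nothing but the matrix is kept); each subject's
    baseline recording is preprocessed once and reused.
    """
    from .synthgen import generate_dataset, synth_baseline

    rows, meta = [], []
    base_windows: dict[str, dict] = {}
    baselines = {}
    for si, prof in enumerate(roster.subjects):
        baselines[prof.subject_id] = (si, None)
    it = generate_dataset(roster, gen_config)
    for count, trial in enumerate(it):
        si, bw = baselines[trial.subject_id]
        if bw is None:
            bref = synth_baseline(roster, si, gen_config)
            bw, _ = preprocess_trial(bref, pre_config)
            baselines[trial.subject_id] = (si, bw)
        vec = extract_features(trial, None, pre_config, feat_config, _baseline_windows=bw)
        rows.append([vec[name] for name in FEATURE_NAMES])
        meta.append((trial.subject_id, trial.trial_id, trial.pain_level.name))
        if progress and (count + 1) % 500 == 0:
            print(f"  extracted {count + 1} trials", flush=True)
    values = pd.DataFrame(np.asarray(rows), columns=FEATURE_NAMES)
    meta_df = pd.DataFrame(meta, columns=list(META_COLUMNS))
    return FeatureMatrix(values=values, meta=meta_df, normalization="raw")


def zscore_normalize(matrix: FeatureMatrix, fit_rows=None) -> FeatureMatrix:
    """Column-wise z-score with statistics estimated on ``fit_rows`` only
    (defaults to all rows) and applied everywhere; constant columns map to 0."""
    if matrix.normalization != "raw":
        raise ValueError("matrix is already normalized")
    if fit_rows is None:
        fit_rows = np.arange(matrix.n_trials)
    fit_rows = np.asarray(fit_rows)
    if len(fit_rows) == 0:
        raise ValueError("fit_rows must be non-empty")
    sub = matrix.values.iloc[fit_rows]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    z = (matrix.values - mu) / sd.replace(0.0, np.inf)
    z = z.fillna(0.0).replace([np.inf, -np.inf], 0.0)
    return FeatureMatrix(values=z, meta=matrix.meta.copy(), normalization="zscored")
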