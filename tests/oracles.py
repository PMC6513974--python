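"""Independent brute-force oracles for feature computations.

Everything here is written directly from the definitions — plain loops and
library reference routines (scipy.stats / scipy.signal) — deliberately not
sharing code with the package implementation.
"""

import math

import numpy as np
from scipy import signal as sps


def amplitude(x):
    x = np.asarray(x, float)
    n = len(x)
    mav = sum(abs(v) for v in x) / n
    d1 = [x[i + 1] - x[i] for i in range(n - 1)]
    d2 = [d1[i + 1] - d1[i] for i in range(n - 2)]
    homav1 = sum(abs(v) for v in d1) / len(d1)
    homav2 = sum(abs(v) for v in d2) / len(d2)
    peaks, valleys = [], []
    for i in range(1, n - 1):
        left = x[i] - x[i - 1]
        right = x[i + 1] - x[i]
        if left > 0 and right < 0:
            peaks.append(i)
        if left < 0 and right > 0:
            valleys.append(i)
    return {
        "MAV": mav,
        "RMS": math.sqrt(sum(v * v for v in x) / n),
        "PK": max(abs(v) for v in x),
        "P2P": max(x) - min(x),
        "HOMAV1": homav1,
        "HOMAV1n": homav1 / mav if mav else 0.0,
        "HOMAV2": homav2,
        "HOMAV2n": homav2 / mav if mav else 0.0,
        "TMNP": sum(p / (n - 1) for p in peaks) / len(peaks) if peaks else 0.0,
        "TMNV": sum(v / (n - 1) for v in valleys) / len(valleys) if valleys else 0.0,
    }


def variability(x):
    x = np.asarray(x, float)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    s = np.sort(x)

    def quantile(q):
        h = (n - 1) * q
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    return {
        "VAR": var,
        "SD": math.sqrt(var),
        "R": max(x) - min(x),
        "IQR": quantile(0.75) - quantile(0.25),
    }


def entropy(x, m=2, r_frac=0.2):
    """Naive template-counting ApEn / SampEn / FuzzyEn (Chebyshev distance)."""
    x = np.asarray(x, float)
    n = len(x)
    r = r_frac * float(np.std(x))

    def dist(i, j, k):
        return max(abs(x[i + u] - x[j + u]) for u in range(k))

    nm, q = n - m + 1, n - m
    cm = [sum(1 for j in range(nm) if dist(i, j, m) <= r) / nm for i in range(nm)]
    cm1 = [sum(1 for j in range(q) if dist(i, j, m + 1) <= r) / q for i in range(q)]
    apen = np.mean([math.log(c) for c in cm]) - np.mean([math.log(c) for c in cm1])
    B = sum(1 for i in range(q) for j in range(i + 1, q) if dist(i, j, m) <= r)
    A = sum(1 for i in range(q) for j in range(i + 1, q) if dist(i, j, m + 1) <= r)
    sampen = -math.log(A / B) if A and B else 0.0
    sm = sum(math.exp(-((dist(i, j, m) / r) ** 2)) for i in range(q) for j in range(i + 1, q))
    sm1 = sum(math.exp(-((dist(i, j, m + 1) / r) ** 2)) for i in range(q) for j in range(i + 1, q))
    fuzzyen = math.log(sm / sm1) if sm and sm1 else 0.0
    return {"ApEn": float(apen), "SampEn": sampen, "FuzzyEn": fuzzyen}


def shannon(x, n_bins=16):
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts / counts.sum()
    return float(-sum(pi * math.log2(pi) for pi in p if pi > 0))


def hist_mi(a, b, bins, full_range_of=None, correct=False):
    if full_range_of is not None:
        edges = np.linspace(full_range_of.min(), full_range_of.max(), bins + 1)
        ia = np.clip(np.digitize(a, edges) - 1, 0, bins - 1)
        ib = np.clip(np.digitize(b, edges) - 1, 0, bins - 1)
        counts, _, _ = np.histogram2d(ia, ib, bins=[np.arange(bins + 1)] * 2)
    else:
        counts, _, _ = np.histogram2d(a, b, bins=bins)
    n = counts.sum()
    pxy = counts / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mi = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if pxy[i, j] > 0:
                mi += pxy[i, j] * math.log(pxy[i, j] / (px[i] * py[j]))
    if correct:
        kx = int((px > 0).sum())
        ky = int((py > 0).sum())
        mi = max(mi - (kx - 1) * (ky - 1) / (2.0 * n), 0.0)
    return mi


def linearity(x, max_lag=32, n_bins=8):
    x = np.asarray(x, float)
    ex = []
    pa, pb = [], []
    for tau in range(1, max_lag + 1):
        a, b = x[:-tau], x[tau:]
        rho = np.corrcoef(a, b)[0, 1]
        g = 1 - math.exp(-2 * hist_mi(a, b, n_bins, full_range_of=x, correct=True))
        ex.append(max(g - rho**2, 0.0))
        pa.append(a)
        pb.append(b)
    pa, pb = np.concatenate(pa), np.concatenate(pb)
    rho_p = np.corrcoef(pa, pb)[0, 1]
    # pooled joint histogram = sum of the per-lag histograms (same bins)
    counts = np.zeros((n_bins, n_bins))
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    ia = np.clip(np.digitize(pa, edges) - 1, 0, n_bins - 1)
    ib = np.clip(np.digitize(pb, edges) - 1, 0, n_bins - 1)
    for i, j in zip(ia, ib):
        counts[i, j] += 1
    n = counts.sum()
    pxy = counts / n
    px, py = pxy.sum(axis=1), pxy.sum(axis=0)
    mi = sum(
        pxy[i, j] * math.log(pxy[i, j] / (px[i] * py[j]))
        for i in range(n_bins)
        for j in range(n_bins)
        if pxy[i, j] > 0
    )
    kx, ky = int((px > 0).sum()), int((py > 0).sum())
    mi = max(mi - (kx - 1) * (ky - 1) / (2 * n), 0.0)
    g_p = 1 - math.exp(-2 * mi)
    return {"LDF": float(np.mean(ex)), "PLDF": float(max(g_p - rho_p**2, 0.0))}


def similarity(x, ref, fs, band, n_bins=16):
    cc = float(np.corrcoef(x, ref)[0, 1])
    mi = hist_mi(x, ref, n_bins)
    nper = min(len(x), max(8, int(round(fs / 2))))
    f, coh = sps.coherence(x, ref, fs=fs, nperseg=nper, noverlap=nper // 2)
    mask = (f >= band[0]) & (f <= band[1])
    cb, fb = coh[mask], f[mask]
    above = cb[cb > 0.5]
    return {
        "CC": cc,
        "MI": mi,
        "MNCOH": float(cb.mean()),
        "MDCOH": float(np.median(cb)),
        "MICOH": float(np.trapezoid(cb, fb)),
        "MMNCOH": float(above.mean()) if len(above) else 0.0,
    }


def frequency(x, fs):
    f, psd = sps.welch(x, fs=fs, nperseg=min(256, len(x)))
    tot = psd.sum()
    p = psd / tot
    mnf = float((f * p).sum())
    cum = np.cumsum(psd)
    half = tot / 2
    i = int(np.searchsorted(cum, half))
    if i == 0:
        mdf = float(f[0])
    else:
        mdf = float(f[i - 1] + (half - cum[i - 1]) / (cum[i] - cum[i - 1]) * (f[i] - f[i - 1]))
    signs = [1 if v > 0 else -1 for v in x if v != 0]
    zc = sum(1 for i in range(len(signs) - 1) if signs[i] != signs[i + 1])
    return {
        "MNF": mnf,
        "MDF": mdf,
        "MOF": float(f[int(np.argmax(psd))]),
        "CF": float(math.sqrt((f**2 * p).sum())),
        "BW": float(math.sqrt(((f - mnf) ** 2 * p).sum())),
        "ZC": float(zc),
    }


def stationarity_subwindows(x, n_segments=10):
    x = np.asarray(x, float)
    seg_len = len(x) // n_segments
    means, sds = [], []
    for i in range(n_segments):
        seg = x[i * seg_len : (i + 1) * seg_len]
        means.append(np.mean(seg))
        sds.append(np.std(seg, ddof=1))
    return {
        "MD": float(np.median(x)),
        "SDMN": float(np.std(means, ddof=1)),
        "SDSD": float(np.std(sds, ddof=1)),
    }


def ds_family(hs):
    """Degree-of-stationarity family recomputed from a Hilbert spectrum."""
    H = hs.energy
    nt, nf = H.shape
    ds = np.zeros(nf)
    for j in range(nf):
        hbar = np.mean(H[:, j])
        if hbar > 0:
            ds[j] = np.mean([(1 - H[t, j] / hbar) ** 2 for t in range(nt)])
    marg = H.sum(axis=0)
    w = marg / marg.sum() if marg.sum() > 0 else np.zeros(nf)
    return {
        "IDS": float(np.trapezoid(ds, hs.freq_bins)),
        "MIDS": float(np.trapezoid(ds * w, hs.freq_bins)),
        "MMNDS": float((ds * w).sum()),
    }


def knn_lens(points, k):
    n = len(points)
    out = np.empty(n)
    for i in range(n):
        d = sorted(
            math.dist(points[i], points[j]) for j in range(n) if j != i
        )
        out[i] = d[k - 1]
    return out


def pairwise_dist(points):
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = math.dist(points[i], points[j])
    return d
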