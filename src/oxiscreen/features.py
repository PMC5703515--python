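"""The 16 oximetric features characterizing an overnight SpO2 profile.

Four complementary subsets are computed from a preprocessed 1-Hz series:

* time-domain statistics — 1st- to 4th-order moments (mean ``M1t``, variance
  ``M2t``, skewness ``M3t``, kurtosis ``M4t``) of the saturation histogram;
* frequency-domain statistics — the same four moments (``M1f``..``M4f``) of
  the normalized power spectral density amplitude distribution, plus median
  frequency ``MF`` and spectral entropy ``SE``;
* conventional spectral measures — total power ``PT``, and peak amplitude
  ``PA`` and relative power ``PR`` in the 0.014-0.033 Hz band where
  recurrent apneic desaturations concentrate their power;
* nonlinear measures — sample entropy ``SampEn`` (irregularity), central
  tendency measure ``CTM`` (variability) and Lempel-Ziv complexity ``LZC``
  (complexity).

Time-domain and nonlinear measures are applied to non-overlapping 512-sample
segments and averaged; spectral measures come from the whole-recording Welch
periodogram (512-sample Hann window, 50 % overlap, 1024-point FFT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, fields

import numpy as np
from scipy import signal as sps
from scipy import stats as sct

__all__ = [
    "FeatureVector",
    "SpectralEstimate",
    "FEATURE_NAMES",
    "APNEA_BAND",
    "segment_signal",
    "time_moments",
    "welch_psd",
    "freq_moments",
    "median_frequency",
    "spectral_entropy",
    "band_powers",
    "sample_entropy",
    "central_tendency_measure",
    "lempel_ziv_complexity",
    "extract_features",
]

#: frequency band of interest for adult sleep apnea, Hz
APNEA_BAND = (0.014, 0.033)
SEGMENT_LEN = 512

FEATURE_NAMES = (
    "M1t", "M2t", "M3t", "M4t",
    "M1f", "M2f", "M3f", "M4f", "MF", "SE",
    "PT", "PA", "PR",
    "SampEn", "CTM", "LZC",
)


@dataclass
class FeatureVector:
    M1t: float
    M2t: float
    M3t: float
    M4t: float
    M1f: float
    M2f: float
    M3f: float
    M4f: float
    MF: float
    SE: float
    PT: float
    PA: float
    PR: float
    SampEn: float
    CTM: float
    LZC: float

    def to_array(self, names: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
        d = asdict(self)
        return np.array([d[n] for n in names], dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpectralEstimate:
    frequencies: np.ndarray
    psd: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def segment_signal(x: np.ndarray, length: int = SEGMENT_LEN) -> list[np.ndarray]:
    """Cut the series into non-overlapping segments; trailing remainder dropped."""
    x = np.asarray(x, float)
    n_seg = len(x) // length
    if n_seg < 1:
        raise ValueError(
            f"recording too short for segmental features ({len(x)} < {length} samples)")
    return [x[i * length : (i + 1) * length] for i in range(n_seg)]


def _moments(v: np.ndarray) -> tuple[float, float, float, float]:
    """Population moments: mean, variance, skewness, kurtosis (Gaussian -> 3).

    Degenerate (constant) input yields skewness/kurtosis 0.
    """
    m1 = float(np.mean(v))
    m2 = float(np.var(v))
    if m2 == 0:
        return m1, 0.0, 0.0, 0.0
    m3 = float(sct.skew(v, bias=True))
    m4 = float(sct.kurtosis(v, fisher=False, bias=True))
    return m1, m2, m3, m4


def time_moments(x: np.ndarray, segment_len: int = SEGMENT_LEN
                 ) -> tuple[float, float, float, float]:
    """Per-segment time-domain moments, averaged over all segments."""
    segs = segment_signal(x, segment_len)
    vals = np.array([_moments(s) for s in segs])
    return tuple(vals.mean(axis=0))


def welch_psd(x: np.ndarray, sample_rate: float = 1.0, nperseg: int = 512,
              nfft: int = 1024) -> SpectralEstimate:
    """One-sided Welch periodogram (Hann window, 50 % overlap).

    Windows are mean-detrended so that Parseval's identity against the
    signal variance is meaningful.
    """
    if len(x) < nperseg:
        raise ValueError(
            f"recording too short for spectral features ({len(x)} < {nperseg})")
    f, p = sps.welch(x, fs=sample_rate, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, nfft=nfft, detrend="constant",
                     scaling="density")
    return SpectralEstimate(f, p)


def _normalized(psd: SpectralEstimate) -> np.ndarray:
    tot = psd.psd.sum()
    if tot <= 0:
        raise ValueError("empty spectrum")
    return psd.psd / tot


def freq_moments(psd: SpectralEstimate) -> tuple[float, float, float, float]:
    """Moments of the normalized PSD amplitude distribution over bins."""
    return _moments(_normalized(psd))


def freq_moments_weighted(psd: SpectralEstimate) -> tuple[float, float, float, float]:
    """Alternative reading: spectral moments of frequency weighted by power."""
    p = _normalized(psd)
    f = psd.frequencies
    m1 = float(np.sum(f * p))
    m2 = float(np.sum((f - m1) ** 2 * p))
    if m2 == 0:
        return m1, 0.0, 0.0, 0.0
    m3 = float(np.sum((f - m1) ** 3 * p) / m2 ** 1.5)
    m4 = float(np.sum((f - m1) ** 4 * p) / m2 ** 2)
    return m1, m2, m3, m4


def median_frequency(psd: SpectralEstimate) -> float:
    """Smallest frequency at which cumulative power reaches half the total."""
    p = _normalized(psd)
    idx = int(np.searchsorted(np.cumsum(p), 0.5))
    return float(psd.frequencies[min(idx, len(p) - 1)])


def spectral_entropy(psd: SpectralEstimate) -> float:
    """Shannon entropy of the sum-normalized PSD, scaled to [0, 1]."""
    p = _normalized(psd)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(p)))


def band_powers(psd: SpectralEstimate, band: tuple[float, float] = APNEA_BAND
                ) -> tuple[float, float, float]:
    """Total power PT, in-band peak amplitude PA, relative band power PR."""
    df = psd.resolution
    pt = float(psd.psd.sum() * df)
    if pt <= 0:
        raise ValueError("empty spectrum")
    in_band = (psd.frequencies >= band[0]) & (psd.frequencies <= band[1])
    pa = float(psd.psd[in_band].max()) if in_band.any() else 0.0
    pr = float(psd.psd[in_band].sum() * df / pt)
    return pt, pa, pr


def sample_entropy(x: np.ndarray, m: int = 1, r: float = 0.25,
                   sd: float | None = None) -> float:
    """Sample entropy: -ln(A/B) for template length m and tolerance r*SD.

    ``r`` is a fraction of the signal standard deviation; ``sd`` overrides
    the SD used for the tolerance (e.g. a whole-recording SD applied to a
    segment). Self-matches are excluded. An over-regular signal with no
    (m+1)-matches (or no m-matches) yields 0 with a warning.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n <= m + 1:
        raise ValueError("series too short for sample entropy")
    tol = r * (np.std(x) if sd is None else sd)
    if tol == 0:
        warnings.warn("constant signal: sample entropy set to 0")
        return 0.0

    def count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distance between all template pairs, i < j
        total = 0
        for i in range(len(templ) - 1):
            d = np.abs(templ[i + 1 :] - templ[i]).max(axis=1)
            total += int(np.count_nonzero(d <= tol))
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        warnings.warn("over-regular signal: sample entropy set to 0")
        return 0.0
    return float(-np.log(a / b))


def central_tendency_measure(x: np.ndarray, rho: float = 0.25) -> float:
    """Fraction of second-order difference points inside the radius-rho circle.

    The scatter plot of (x[t+1]-x[t], x[t+2]-x[t+1]) characterizes
    sample-to-sample variability; a quiet trace concentrates near the origin.
    """
    x = np.asarray(x, float)
    if len(x) < 3:
        raise ValueError("series too short for CTM")
    d = np.diff(x)
    radii = np.hypot(d[1:], d[:-1])
    return float(np.mean(radii < rho))


def lz76_phrase_count(bits: np.ndarray) -> int:
    """Number of distinct phrases in the LZ76 parsing of a binary sequence."""
    s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    c, i = 0, 0
    # exhaustive-history parsing: a phrase grows while it can be copied from
    # the text seen so far (everything before its last character)
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def lempel_ziv_complexity(x: np.ndarray, threshold: float | None = None) -> float:
    """Normalized Lempel-Ziv complexity of the median-binarized series.

    The series is binarized at its median (or a given threshold); the LZ76
    phrase count c(n) is normalized by n / log2(n), so random sequences tend
    to 1 and constant sequences to ~2 log2(n)/n.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2:
        raise ValueError("series too short for LZC")
    thr = np.median(x) if threshold is None else threshold
    bits = x > thr
    c = lz76_phrase_count(bits)
    return float(c * np.log2(n) / n)


def extract_features(
    x: np.ndarray,
    sample_rate: float = 1.0,
    segment_len: int = SEGMENT_LEN,
    sampen_m: int = 1,
    sampen_r: float = 0.25,
    ctm_rho: float = 0.25,
    band: tuple[float, float] = APNEA_BAND,
    freq_moment_basis: str = "amplitude",
) -> FeatureVector:
    """Compute the full 16-feature vector from a preprocessed series.

    ``freq_moment_basis`` selects the reading of the frequency-domain
    moments: ``"amplitude"`` (moments of the normalized PSD amplitude
    histogram, the default) or ``"frequency"`` (power-weighted spectral
    moments).
    """
    x = np.asarray(x, float)
    segs = segment_signal(x, segment_len)

    m1t, m2t, m3t, m4t = time_moments(x, segment_len)

    psd = welch_psd(x, sample_rate, nperseg=segment_len, nfft=2 * segment_len)
    fm = freq_moments(psd) if freq_moment_basis == "amplitude" else \
        freq_moments_weighted(psd)
    mf = median_frequency(psd)
    se = spectral_entropy(psd)
    pt, pa, pr = band_powers(psd, band)

    whole_sd = float(np.std(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampen = float(np.mean([
            sample_entropy(s, m=sampen_m, r=sampen_r, sd=whole_sd) for s in segs]))
    ctm = float(np.mean([central_tendency_measure(s, ctm_rho) for s in segs]))
    lzc = float(np.mean([lempel_ziv_complexity(s) for s in segs]))

    return FeatureVector(m1t, m2t, m3t, m4t, *fm, mf, se, pt, pa, pr,
                         sampen, ctm, lzc)


def feature_matrix(vectors: list[FeatureVector],
                   names: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
    """Stack feature vectors into an (n_recordings, n_features) matrix."""
    return np.vstack([v.to_array(names) for v in vectors])
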