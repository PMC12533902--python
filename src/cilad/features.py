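"""Multi-feature extraction: ECG time/frequency descriptors, image
morphology and texture (GLCM, LBP), and statistical moments.

Every extractor returns plain floats; :func:`extract_all` assembles them
into a :class:`~cilad.datatypes.FeatureTable` with deterministic column
names per modality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, periodogram
from skimage.feature import graycomatrix
from skimage.measure import perimeter as _sk_perimeter

from .datatypes import BeatTable, FeatureTable, ImageSet, RecordTable


class UndefinedQRSError(ValueError):
    """The beat has no usable dominant peak (e.g. a flat signal)."""


# --------------------------------------------------------------------------
# ECG descriptors
# --------------------------------------------------------------------------

def hrv_sdnn(nn_intervals) -> float:
    """SDNN: population standard deviation of normal-to-normal intervals (ms)."""
    v = np.asarray(nn_intervals, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 intervals")
    return float(np.std(v))


def qrs_duration(beat, fs: float, theta: float = 0.2) -> float:
    """QRS duration in ms: width of the contiguous region around the global
    absolute-amplitude peak whose amplitude exceeds ``theta`` of the peak.

    Duration counts samples in the region, so an ideal rectangular pulse of
    ``k`` samples yields ``k * 1000 / fs`` ms.
    """
    x = np.asarray(beat, dtype=float)
    if x.size == 0 or not np.isfinite(x).all():
        raise UndefinedQRSError("beat is empty or non-finite")
    a = np.abs(x)
    peak = int(np.argmax(a))
    if a[peak] == 0:
        raise UndefinedQRSError("flat beat: no dominant peak")
    thr = theta * a[peak]
    lo = peak
    while lo > 0 and a[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(a) - 1 and a[hi + 1] >= thr:
        hi += 1
    return (hi - lo + 1) * 1000.0 / fs


def psd_periodogram(signal, fs: float, squared: bool = True):
    """One-sided periodogram power spectral density.

    The default is the standard squared-magnitude estimator |DFT|^2 scaled so
    that the two-sided power integrates to the mean signal power;
    ``squared=False`` yields the plain-magnitude variant for comparison.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal too short")
    freqs, power = periodogram(x, fs=fs, window="boxcar", detrend=False)
    if not squared:
        power = np.sqrt(power * fs * len(x)) / (fs * len(x))
    return freqs, power


def band_powers(freqs, power, bands) -> dict[str, float]:
    """Integrate a spectrum over half-open frequency bands [lo, hi)."""
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    out = {}
    for lo, hi in bands:
        sel = (freqs >= lo) & (freqs < hi)
        out[f"bp_{lo:g}_{hi:g}"] = float(power[sel].sum() * df)
    return out


# --------------------------------------------------------------------------
# Image morphology
# --------------------------------------------------------------------------

def shape_features(mask) -> dict[str, float]:
    """Circularity 4*pi*A/p^2, bounding-box aspect ratio, and moment-ellipse
    eccentricity of a binary mask."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2 or not m.any():
        raise ValueError("mask must be a non-empty 2-D binary matrix")
    area = float(m.sum())
    p = float(_sk_perimeter(m, neighborhood=4))
    circularity = 4.0 * np.pi * area / p ** 2 if p > 0 else 0.0
    rows, cols = np.nonzero(m)
    width = cols.max() - cols.min() + 1
    height = rows.max() - rows.min() + 1
    aspect_ratio = width / height
    # second central moments -> ellipse axes
    y = rows - rows.mean()
    x = cols - cols.mean()
    cov = np.array([[np.mean(x * x), np.mean(x * y)],
                    [np.mean(x * y), np.mean(y * y)]])
    evals = np.linalg.eigvalsh(cov)
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_major <= 0:
        ecc = 0.0
    else:
        ecc = float(np.sqrt(max(0.0, 1.0 - lam_minor / lam_major)))
    return {"circularity": circularity, "aspect_ratio": float(aspect_ratio),
            "eccentricity": ecc}


# --------------------------------------------------------------------------
# Texture: GLCM and LBP
# --------------------------------------------------------------------------

@dataclass
class GLCMSpec:
    """Gray-level co-occurrence configuration: offset distance, the four
    standard angles, quantization levels, symmetrization and normalization."""

    distance: int = 1
    angles: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    levels: int = 16
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


def _quantize(image, levels: int) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def _glcm_stats(P: np.ndarray) -> dict[str, float]:
    """Texture statistics of one normalized co-occurrence matrix."""
    levels = P.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float((P * (i - j) ** 2).sum())
    energy = float((P ** 2).sum())  # angular second moment / uniformity
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    if var_i > 0 and var_j > 0:
        correlation = float((P * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    else:
        correlation = 1.0  # degenerate: a single gray level is perfectly dependent
    return {"contrast": contrast, "correlation": correlation, "energy": energy,
            "homogeneity": homogeneity, "entropy": entropy}


def glcm_features(image, spec: GLCMSpec | None = None) -> dict[str, float]:
    """Co-occurrence statistics averaged over the configured angles.

    The image is uniformly quantized to ``spec.levels`` bins over its
    intensity range; each angle's matrix is symmetrized / normalized per the
    spec before the statistics are averaged.
    """
    spec = spec or GLCMSpec()
    q = _quantize(image, spec.levels)
    glcm = graycomatrix(q, distances=[spec.distance], angles=list(spec.angles),
                        levels=spec.levels, symmetric=spec.symmetric, normed=False)
    stats: dict[str, float] = {}
    for a in range(glcm.shape[3]):
        P = glcm[:, :, 0, a].astype(float)
        total = P.sum()
        if spec.normalized and total > 0:
            P = P / total
        for k, v in _glcm_stats(P).items():
            stats[k] = stats.get(k, 0.0) + v / glcm.shape[3]
    return stats


def lbp_codes(image, radius: int = 1, points: int = 8) -> np.ndarray:
    """Per-pixel local binary pattern codes over interior pixels.

    Neighbors sit on integer-rounded circle offsets starting east and going
    counter-clockwise; bit i is set when neighbor i >= center (s(0) = 1).
    Border pixels (margin = radius) are excluded.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(img.shape) <= 2 * radius:
        raise ValueError("image too small for the requested radius")
    r = radius
    center = img[r:-r, r:-r]
    codes = np.zeros(center.shape, dtype=np.int64)
    h, w = center.shape
    for i in range(points):
        ang = 2.0 * np.pi * i / points
        dx = int(round(r * np.cos(ang)))
        dy = -int(round(r * np.sin(ang)))
        neigh = img[r + dy:r + dy + h, r + dx:r + dx + w]
        codes |= (neigh >= center).astype(np.int64) << i
    return codes


def lbp_histogram(image, radius: int = 1, points: int = 8) -> np.ndarray:
    """Normalized histogram of LBP codes (2**points bins, sums to 1)."""
    codes = lbp_codes(image, radius, points)
    hist = np.bincount(codes.ravel(), minlength=2 ** points).astype(float)
    return hist / hist.sum()


# --------------------------------------------------------------------------
# Statistical moments
# --------------------------------------------------------------------------

def stat_moments(values) -> dict[str, float]:
    """Population mean, median, sd, skewness and excess kurtosis.

    All moments use divisor n; kurtosis subtracts 3 so a normal population
    scores 0.  A constant sequence has skewness and kurtosis defined as 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sequence")
    m = float(np.mean(v))
    md = float(np.median(v))
    sd = float(np.std(v))
    if sd == 0:
        sk = kr = 0.0
    else:
        z = (v - m) / sd
        sk = float(np.mean(z ** 3))
        kr = float(np.mean(z ** 4) - 3.0)
    return {"mean": m, "median": md, "sd": sd, "skewness": sk, "kurtosis": kr}


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

ECG_BANDS = ((0.5, 4.0), (4.0, 15.0), (15.0, 40.0), (40.0, 60.0))


def _ecg_row(beat: np.ndarray, fs: float) -> dict[str, float]:
    feats = {f"beat_{k}": v for k, v in stat_moments(beat).items()}
    try:
        feats["qrs_ms"] = qrs_duration(beat, fs)
    except UndefinedQRSError:
        feats["qrs_ms"] = 0.0
    # Within-beat peak-interval spread: a per-beat stand-in for SDNN, since a
    # single-beat row carries no true NN interval sequence.
    prom = 0.2 * (beat.max() - beat.min())
    peaks, _ = find_peaks(beat, prominence=max(prom, 1e-12))
    if len(peaks) >= 3:
        intervals = np.diff(peaks) * 1000.0 / fs
        feats["sdnn_proxy_ms"] = hrv_sdnn(intervals)
    else:
        feats["sdnn_proxy_ms"] = 0.0
    freqs, power = psd_periodogram(beat, fs)
    feats.update(band_powers(freqs, power, ECG_BANDS))
    return feats


def _image_row(image: np.ndarray, mask: np.ndarray | None) -> dict[str, float]:
    if mask is None:
        mask = np.asarray(image) > np.mean(image)
    feats = shape_features(mask)
    feats.update(glcm_features(image))
    hist = lbp_histogram(image)
    nz = hist[hist > 0]
    feats["lbp_energy"] = float((hist ** 2).sum())
    feats["lbp_entropy"] = float(-(nz * np.log(nz)).sum())
    return feats


def _tabular_rows(table: RecordTable) -> tuple[list[str], np.ndarray]:
    frame = table.frame
    if frame.isna().any().any():
        raise ValueError("table contains missing values; impute first")
    vals = frame.to_numpy(dtype=float)
    moments = np.empty((len(frame), 5))
    for i, row in enumerate(vals):
        m = stat_moments(row)
        moments[i] = [m["mean"], m["median"], m["sd"], m["skewness"], m["kurtosis"]]
    names = list(frame.columns) + ["row_mean", "row_median", "row_sd",
                                   "row_skewness", "row_kurtosis"]
    return names, np.hstack([vals, moments])


def extract_all(modality: str, data) -> FeatureTable:
    """Extract the documented feature schema for one modality.

    - ``ecg``: per-beat moments, QRS duration, peak-interval SDNN proxy and
      four band powers (11 features).
    - ``image``: shape descriptors, GLCM statistics and pooled LBP
      energy/entropy (10 features).
    - ``tabular`` / ``metadata``: raw predictors plus row-wise moment
      augmentation.
    """
    if modality == "ecg":
        if not isinstance(data, BeatTable):
            raise TypeError("ecg modality expects a BeatTable")
        rows = [_ecg_row(b, data.fs) for b in data.signals]
        names = list(rows[0]) if rows else []
        values = np.array([[r[k] for k in names] for r in rows]).reshape(len(rows), -1)
        return FeatureTable(names, values, data.labels)
    if modality == "image":
        if not isinstance(data, ImageSet):
            raise TypeError("image modality expects an ImageSet")
        masks = data.masks or [None] * len(data)
        rows = [_image_row(img, msk) for img, msk in zip(data.images, masks)]
        names = list(rows[0]) if rows else []
        values = np.array([[r[k] for k in names] for r in rows]).reshape(len(rows), -1)
        return FeatureTable(names, values, data.labels)
    if modality in ("tabular", "metadata"):
        if not isinstance(data, RecordTable):
            raise TypeError(f"{modality} modality expects a RecordTable")
        names, values = _tabular_rows(data)
        return FeatureTable(names, values, data.target)
    raise ValueError(f"unknown modality {modality!r}")
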