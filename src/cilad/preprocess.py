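"""Per-modality cleaning: wavelet denoising, normalization, equalization,
resizing, imputation, outlier handling and metadata cleaning.

Normalization and encoding transforms are expressed as fit/apply pairs so
statistics learned on a training split can be replayed on held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from skimage.transform import resize as _sk_resize

from .datatypes import RecordTable


class DegenerateRangeWarning(UserWarning):
    """Raised (as a warning) when min-max normalization sees max == min."""


@dataclass
class DenoiseSpec:
    """Discrete wavelet shrinkage configuration.

    ``db4`` at level 3 with universal-threshold hard shrinkage is the default:
    on short single-beat signals the soft rule's constant shrinkage visibly
    over-smooths the QRS complex, so hard thresholding (keep-or-kill) is the
    better default; ``universal-soft`` remains available.
    """

    wavelet: str = "db4"
    level: int = 3
    threshold_rule: str = "universal-hard"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.threshold_rule not in ("universal-soft", "universal-hard"):
            raise ValueError("threshold_rule must be universal-soft or universal-hard")


@dataclass
class NormalizationSpec:
    """Replayable min-max transform: [observed_min, observed_max] -> [lo, hi]."""

    lo: float = 0.0
    hi: float = 1.0
    observed_min: float = 0.0
    observed_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("lo must be < hi")
        if self.observed_min > self.observed_max:
            raise ValueError("observed_min must be <= observed_max")

    @classmethod
    def fit(cls, values, lo: float = 0.0, hi: float = 1.0) -> "NormalizationSpec":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("cannot fit on empty data")
        return cls(lo, hi, float(np.nanmin(v)), float(np.nanmax(v)))

    def apply(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        rng = self.observed_max - self.observed_min
        if rng == 0:
            warnings.warn("degenerate min-max range (max == min); mapping to lo",
                          DegenerateRangeWarning)
            return np.full_like(v, self.lo)
        return self.lo + (v - self.observed_min) * (self.hi - self.lo) / rng


def wavelet_denoise(signal, spec: DenoiseSpec | None = None) -> np.ndarray:
    """Denoise a 1-D signal by wavelet decomposition and detail-coefficient
    shrinkage at the universal threshold sigma * sqrt(2 log n).

    The noise scale sigma is estimated from the finest detail band by the
    standard median-absolute-deviation rule.
    """
    spec = spec or DenoiseSpec()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < 2 ** spec.level:
        raise ValueError(f"signal of length {len(x)} too short for level {spec.level}")
    coeffs = pywt.wavedec(x, spec.wavelet, level=spec.level)
    detail = coeffs[-1]
    sigma = np.median(np.abs(detail)) / 0.6745 if detail.size else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    mode = "soft" if spec.threshold_rule == "universal-soft" else "hard"
    coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode=mode) for c in coeffs[1:]]
    out = pywt.waverec(coeffs, spec.wavelet)
    return out[: len(x)]


def minmax_normalize(values, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Affine rescale so the observed min maps to ``lo`` and max to ``hi``.

    A constant input degenerates to all-``lo`` with a warning rather than an
    error so constant columns cannot abort a pipeline run.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty sequence")
    return NormalizationSpec.fit(v, lo, hi).apply(v)


def hist_equalize(image, levels: int = 256) -> np.ndarray:
    """Histogram equalization: e = round(cdf(i) * (levels - 1)).

    The CDF is the empirical cumulative distribution of pixel intensities
    over the whole image; shape is preserved and relative intensity order is
    non-strictly preserved.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if np.any(img < 0) or np.any(img >= levels):
        raise ValueError(f"intensities must lie in [0, {levels})")
    flat = np.sort(img.ravel())
    # cdf(v) = P(X <= v)
    cdf = np.searchsorted(flat, img.ravel(), side="right") / img.size
    out = np.rint(cdf * (levels - 1)).astype(int).reshape(img.shape)
    return out


def resize_bilinear(image, w: int, h: int) -> np.ndarray:
    """Bilinear resize to h x w; constant images stay constant."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if w <= 0 or h <= 0:
        raise ValueError("target size must be positive")
    if img.shape == (h, w):
        return img.copy()
    return _sk_resize(img, (h, w), order=1, mode="edge", anti_aliasing=False,
                      preserve_range=True)


def impute_mean(table: RecordTable) -> RecordTable:
    """Replace each missing numeric cell by its column mean over non-missing
    entries; column means are unchanged and the operation is idempotent."""
    out = table.copy()
    for col in out.frame.columns:
        series = out.frame[col]
        if not pd.api.types.is_numeric_dtype(series):
            continue
        if series.isna().all():
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if series.isna().any():
            out.frame[col] = series.fillna(series.mean())
    return out


def zscore_outliers(values, threshold: float = 3.0) -> np.ndarray:
    """Flag entries with |(v - mean) / sd| > threshold (population sd).

    A constant sequence (sd = 0) yields no flags.
    """
    v = np.asarray(values, dtype=float)
    mu = np.nanmean(v)
    sd = np.nanstd(v)
    if sd == 0 or np.isnan(sd):
        return np.zeros(v.shape, dtype=bool)
    return np.abs((v - mu) / sd) > threshold


def winsorize_outliers(values, threshold: float = 3.0) -> np.ndarray:
    """Clip flagged outliers to mean +/- threshold * sd (the configurable
    'deal with outliers' policy; the alternative is report-only)."""
    v = np.asarray(values, dtype=float).copy()
    flags = zscore_outliers(v, threshold)
    if flags.any():
        mu, sd = np.nanmean(v), np.nanstd(v)
        v[flags] = np.clip(v[flags], mu - threshold * sd, mu + threshold * sd)
    return v


def clean_metadata(table: RecordTable, lo: float = 0.0, hi: float = 1.0) -> RecordTable:
    """Clean wearable metadata: drop exact-duplicate rows (keep first), map
    categorical columns to first-appearance integer codes, and min-max
    normalize numeric columns.

    The categorical encodings and per-column normalization specs are recorded
    in ``meta['encodings']`` / ``meta['norm_specs']`` so the transform can be
    replayed.
    """
    frame = table.frame.reset_index(drop=True)
    keep = ~frame.duplicated(keep="first")
    frame = frame.loc[keep].reset_index(drop=True)
    target = np.asarray(table.target)[keep.to_numpy()]

    encodings: dict[str, dict] = {}
    norm_specs: dict[str, NormalizationSpec] = {}
    out = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        series = frame[col]
        if pd.api.types.is_numeric_dtype(series):
            spec = NormalizationSpec.fit(series.to_numpy(), lo, hi)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateRangeWarning)
                out[col] = spec.apply(series.to_numpy())
            norm_specs[col] = spec
        else:
            codes, uniques = pd.factorize(series)  # first-appearance order
            encodings[col] = {str(u): int(i) for i, u in enumerate(uniques)}
            out[col] = codes
    cleaned = RecordTable(out, target, dict(table.provenance))
    cleaned.meta = {**table.meta, "encodings": encodings, "norm_specs": norm_specs,
                    "n_dropped_duplicates": int((~keep).sum())}
    return cleaned
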