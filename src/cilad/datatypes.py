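"""Core record containers shared by every pipeline stage.

The pipeline moves data through four modalities (ECG beats, cardiac images,
tabular patient records, wearable metadata) and two recommendation-side
structures (food items and patient profiles).  Each container is a plain
dataclass over NumPy arrays / pandas frames so stages stay composable and
serializable to text formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

NUTRIENTS = ("sodium_mg", "satfat_g", "fiber_g", "calories_kcal", "cholesterol_mg")
"""Nutrient dimensions used throughout the nutrition MDP (d = 5)."""


@dataclass
class BeatTable:
    """Fixed-length ECG beats, one beat per row, with integer class labels."""

    signals: np.ndarray  # (n_beats, beat_len) amplitudes
    labels: np.ndarray   # (n_beats,) int class in [0, n_classes)
    fs: float = 125.0    # sampling frequency, Hz

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (n_beats, beat_len) array")
        if self.signals.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match number of beats")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def n_beats(self) -> int:
        return self.signals.shape[0]

    @property
    def beat_len(self) -> int:
        return self.signals.shape[1]

    def subset(self, idx: np.ndarray) -> "BeatTable":
        return BeatTable(self.signals[idx], self.labels[idx], self.fs)


@dataclass
class ImageSet:
    """Grayscale images with labels and optional binary foreground masks."""

    images: list[np.ndarray]
    labels: np.ndarray
    masks: list[np.ndarray] | None = None
    levels: int = 256

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("labels length must match number of images")
        if self.masks is not None and len(self.masks) != len(self.images):
            raise ValueError("masks length must match number of images")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class RecordTable:
    """Named tabular records plus a label vector and a provenance map.

    ``provenance`` tags every feature column as ``"signal"`` (used by the
    generative model of the target) or ``"noise"`` so planted-truth selection
    experiments can score recovery.
    """

    frame: pd.DataFrame
    target: np.ndarray
    provenance: Mapping[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target)
        if len(self.frame) != len(self.target):
            raise ValueError("target length must match number of rows")
        if self.provenance:
            missing = set(self.frame.columns) - set(self.provenance)
            if missing:
                raise ValueError(f"provenance missing for columns: {sorted(missing)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def copy(self) -> "RecordTable":
        return RecordTable(self.frame.copy(), self.target.copy(),
                           dict(self.provenance), dict(self.meta))


@dataclass
class FeatureTable:
    """The common currency after feature extraction: named columns + labels."""

    names: list[str]
    values: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names length must equal number of feature columns")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match number of samples")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df["label"] = self.labels
        return df

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(list(self.names), self.values[idx], self.labels[idx])


@dataclass(frozen=True)
class FoodItem:
    """A single discrete dietary action: one serving of one menu item."""

    id: str
    nutrients: tuple[float, ...]  # aligned with NUTRIENTS
    cost: float
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.nutrients):
            raise ValueError(f"nutrients must be nonnegative for {self.id}")
        if self.cost < 0:
            raise ValueError(f"cost must be nonnegative for {self.id}")

    @property
    def nutrient_array(self) -> np.ndarray:
        return np.asarray(self.nutrients, dtype=float)


@dataclass
class PatientProfile:
    """Patient-side parameters of the nutrition MDP.

    Bounds, targets and tolerances are per-nutrient vectors aligned with
    :data:`NUTRIENTS`.  ``risk`` is the disease-risk score produced by the
    classifier (in [0, 1]); ``risk_weights`` up-weights nutrients tied to the
    detected condition (e.g. sodium under hypertension).
    """

    name: str
    age: float
    bmi: float
    risk: float
    required_tags: frozenset[str] = frozenset()
    forbidden_tags: frozenset[str] = frozenset()
    exclusions: frozenset[str] = frozenset()
    lower: np.ndarray = field(default_factory=lambda: np.zeros(len(NUTRIENTS)))
    upper: np.ndarray = field(default_factory=lambda: np.full(len(NUTRIENTS), np.inf))
    targets: np.ndarray = field(default_factory=lambda: np.zeros(len(NUTRIENTS)))
    tolerance: np.ndarray = field(default_factory=lambda: np.zeros(len(NUTRIENTS)))
    hard_max: np.ndarray = field(default_factory=lambda: np.full(len(NUTRIENTS), np.inf))
    risk_weights: np.ndarray = field(default_factory=lambda: np.ones(len(NUTRIENTS)))

    def __post_init__(self) -> None:
        for attr in ("lower", "upper", "targets", "tolerance", "hard_max", "risk_weights"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if np.any(self.lower > self.upper):
            raise ValueError("lower bounds must not exceed upper bounds")
        if np.any(self.tolerance < 0):
            raise ValueError("tolerances must be nonnegative")
        if np.any((self.targets < self.lower) | (self.targets > self.upper)):
            raise ValueError("targets must lie within [lower, upper]")
        if np.any(self.risk_weights < 0):
            raise ValueError("risk weights must be nonnegative")
        if not 0.0 <= self.risk <= 1.0:
            raise ValueError("risk must lie in [0, 1]")


def clone_profile(profile: PatientProfile, **changes) -> PatientProfile:
    """Return a copy of ``profile`` with selected fields replaced."""
    return replace(profile, **changes)
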