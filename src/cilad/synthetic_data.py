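"""Synthetic generators for every input modality the pipeline consumes.

All generators are pure functions of their arguments (including ``seed``), so
every experiment in the package is reproducible without downloads.  Each
generator plants known ground truth — class-dependent beat morphology,
wall-thickness/eccentricity phantom geometry, logistic signal features,
guideline bounds — so tests can score recovery against the truth.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datatypes import (
    NUTRIENTS,
    BeatTable,
    FoodItem,
    ImageSet,
    PatientProfile,
    RecordTable,
)

# --------------------------------------------------------------------------
# ECG beats
# --------------------------------------------------------------------------

#: Above-threshold QRS width (ms) per beat class at theta = 0.2 of peak height.
QRS_WIDTH_MS = (80.0, 64.0, 120.0, 96.0, 48.0)

# Each bump: (center as fraction of beat, amplitude, above-0.2-threshold
# width in ms for the R bump / plain sd fraction otherwise).
_THETA = 0.2
_WIDTH_FACTOR = 2.0 * math.sqrt(2.0 * math.log(1.0 / _THETA))  # width = factor * sd


def _class_bumps(cls: int, beat_len: int, fs: float) -> list[tuple[float, float, float]]:
    """Gaussian bump parameters (center_sample, amplitude, sd_samples) for a class.

    Class templates loosely emulate the five canonical beat morphologies
    (normal, supraventricular, ventricular, fusion, unclassifiable): they vary
    QRS width and amplitude, P-wave presence and T-wave polarity.
    """
    qrs_ms = QRS_WIDTH_MS[cls % len(QRS_WIDTH_MS)]
    qrs_sd = (qrs_ms / 1000.0 * fs) / _WIDTH_FACTOR  # samples
    base = {
        "p_amp": 0.15, "p_pos": 0.18, "p_sd": 0.020,
        "q_amp": -0.12, "q_pos": 0.365, "q_sd": 0.008,
        "r_amp": 1.0, "r_pos": 0.40,
        "s_amp": -0.22, "s_pos": 0.435, "s_sd": 0.008,
        "t_amp": 0.30, "t_pos": 0.62, "t_sd": 0.045,
    }
    per_class = [
        {},  # class 0: the reference morphology
        {"p_amp": 0.02, "r_pos": 0.36, "t_amp": 0.42, "t_pos": 0.58},
        {"r_amp": 0.85, "s_amp": -0.55, "t_amp": -0.35, "p_amp": 0.0},
        {"r_amp": 0.92, "p_amp": 0.08, "t_amp": 0.18, "t_pos": 0.66},
        {"r_amp": 0.60, "p_amp": 0.0, "q_amp": 0.0, "s_amp": -0.08, "t_amp": 0.10},
    ]
    params = dict(base)
    params.update(per_class[cls % len(per_class)])
    L = beat_len
    return [
        (params["p_pos"] * L, params["p_amp"], params["p_sd"] * L),
        (params["q_pos"] * L, params["q_amp"], params["q_sd"] * L),
        (params["r_pos"] * L, params["r_amp"], qrs_sd),
        (params["s_pos"] * L, params["s_amp"], params["s_sd"] * L),
        (params["t_pos"] * L, params["t_amp"], params["t_sd"] * L),
    ]


def class_template(cls: int, beat_len: int, fs: float = 125.0,
                   separation: float = 1.0) -> np.ndarray:
    """Noise-free beat template for ``cls``.

    ``separation`` in [0, 1] interpolates every class template toward the
    class-0 template; 1.0 gives the full between-class morphology contrast.
    """
    t = np.arange(beat_len, dtype=float)
    bumps0 = _class_bumps(0, beat_len, fs)
    bumps = _class_bumps(cls, beat_len, fs)
    beat = np.zeros(beat_len)
    for (c0, a0, s0), (c1, a1, s1) in zip(bumps0, bumps):
        c = c0 + separation * (c1 - c0)
        a = a0 + separation * (a1 - a0)
        s = s0 + separation * (s1 - s0)
        if abs(a) > 0 and s > 0:
            beat += a * np.exp(-0.5 * ((t - c) / s) ** 2)
    return beat


def qrs_truth_ms(cls: int, separation: float = 1.0) -> float:
    """Configured R-bump width (ms) planted in the class template.

    Exact as an above-threshold width only for classes whose R bump is
    isolated (0, 1, 4); the wide-QRS classes overlap deep S deflections by
    design, which narrows the contiguous above-threshold region.
    """
    w = QRS_WIDTH_MS[cls % len(QRS_WIDTH_MS)]
    return QRS_WIDTH_MS[0] + separation * (w - QRS_WIDTH_MS[0])


def gen_ecg_beats(n_per_class: int, n_classes: int, beat_len: int = 187,
                  noise_sd: float = 0.05, seed: int = 0, fs: float = 125.0,
                  separation: float = 1.0,
                  baseline_amp: float | None = None) -> BeatTable:
    """Generate class-structured synthetic ECG beats.

    Beats are sums of Gaussian bumps (P, QRS, T) whose amplitudes, widths and
    positions are class-dependent, plus white noise of sd ``noise_sd`` and a
    low-frequency sinusoidal baseline wander of amplitude ``baseline_amp``
    (defaults to ``noise_sd`` so zero-noise tables are exactly the templates).
    """
    if n_per_class <= 0 or n_classes <= 0 or beat_len <= 0:
        raise ValueError("counts must be positive")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if beat_len < 32:
        raise ValueError("beat_len must be at least 32")
    if baseline_amp is None:
        baseline_amp = float(noise_sd)
    rng = np.random.default_rng(seed)
    t = np.arange(beat_len) / fs
    signals = np.empty((n_per_class * n_classes, beat_len))
    labels = np.empty(n_per_class * n_classes, dtype=int)
    row = 0
    for cls in range(n_classes):
        template = class_template(cls, beat_len, fs, separation)
        for _ in range(n_per_class):
            beat = template.copy()
            if noise_sd > 0:
                beat = beat + rng.normal(0.0, noise_sd, beat_len)
            if baseline_amp > 0:
                f_w = rng.uniform(0.3, 1.0)       # Hz, respiration-scale drift
                phase = rng.uniform(0, 2 * np.pi)
                beat = beat + baseline_amp * np.sin(2 * np.pi * f_w * t + phase)
            signals[row] = beat
            labels[row] = cls
            row += 1
    return BeatTable(signals, labels, fs)


# --------------------------------------------------------------------------
# Cardiac image phantoms
# --------------------------------------------------------------------------

#: (myocardial wall thickness as a fraction of the outer radius,
#:  cavity-ellipse eccentricity) per phantom class.
PHANTOM_CLASSES = (
    (0.18, 0.30),  # healthy
    (0.34, 0.45),  # hypertrophy: thick wall
    (0.10, 0.62),  # heart failure: thin wall, remodelled cavity
    (0.12, 0.70),  # heart failure with infarction
)


def phantom_eccentricity(cls: int) -> float:
    """Configured cavity eccentricity for a phantom class."""
    return PHANTOM_CLASSES[cls % len(PHANTOM_CLASSES)][1]


def gen_cardiac_images(n_per_class: int, size: int = 64, seed: int = 0,
                       n_classes: int = 3, levels: int = 256) -> ImageSet:
    """Generate annular short-axis "myocardium" phantoms.

    Each image holds a bright elliptical annulus (the wall) around a darker
    cavity; class controls wall thickness and cavity eccentricity.  Texture
    is smoothed noise.  Masks mark the annulus.
    """
    if n_per_class <= 0 or n_classes <= 0:
        raise ValueError("counts must be positive")
    if size < 32:
        raise ValueError("size must be at least 32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    images: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    labels = np.empty(n_per_class * n_classes, dtype=int)
    row = 0
    for cls in range(n_classes):
        wall_frac, ecc = PHANTOM_CLASSES[cls % len(PHANTOM_CLASSES)]
        for _ in range(n_per_class):
            r_out = size * 0.40 * rng.uniform(0.92, 1.0)
            a_in = r_out * (1.0 - wall_frac)           # cavity semi-major axis
            b_in = a_in * math.sqrt(1.0 - ecc ** 2)    # semi-minor axis
            theta = rng.uniform(0, np.pi)              # cavity orientation
            dy, dx = yy - cy, xx - cx
            u = dx * math.cos(theta) + dy * math.sin(theta)
            v = -dx * math.sin(theta) + dy * math.cos(theta)
            outer = dx ** 2 + dy ** 2 <= r_out ** 2
            cavity = (u / a_in) ** 2 + (v / b_in) ** 2 <= 1.0
            annulus = outer & ~cavity
            texture = gaussian_filter(rng.normal(0, 1, (size, size)), sigma=2.0)
            img = 0.20 + 0.55 * annulus + 0.10 * cavity + 0.12 * texture
            img = np.clip(img, 0.0, 1.0 - 1e-9)
            images.append(np.floor(img * levels).astype(int))
            masks.append(annulus)
            labels[row] = cls
            row += 1
    return ImageSet(images, labels, masks, levels=levels)


# --------------------------------------------------------------------------
# Tabular patient records and wearable metadata
# --------------------------------------------------------------------------

UCI_FEATURES = ("age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
                "thalach", "exang", "oldpeak", "slope", "ca", "thal")

#: Display scales (mean, sd) so synthetic columns look like the UCI schema.
_UCI_SCALES = {
    "age": (54, 9), "sex": (0.7, 0.46), "cp": (1.0, 1.0), "trestbps": (131, 17),
    "chol": (246, 51), "fbs": (0.15, 0.36), "restecg": (0.5, 0.5),
    "thalach": (149, 22), "exang": (0.33, 0.47), "oldpeak": (1.0, 1.2),
    "slope": (1.4, 0.6), "ca": (0.7, 1.0), "thal": (2.3, 0.6),
}


def _logistic_table(n: int, names: list[str], signal_names: list[str],
                    rng: np.random.Generator, scales: dict | None = None,
                    coef_scale: float = 1.2) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Latent standard-normal features; target from a logistic model on the
    signal subset.  Returns (frame, target, meta with coefficients)."""
    z = rng.normal(0, 1, (n, len(names)))
    coefs = {}
    logit = np.zeros(n)
    for name in signal_names:
        j = names.index(name)
        beta = coef_scale * rng.uniform(0.8, 1.5) * rng.choice([-1.0, 1.0])
        coefs[name] = float(beta)
        logit += beta * z[:, j]
    p = 1.0 / (1.0 + np.exp(-logit))
    target = (rng.uniform(0, 1, n) < p).astype(int)
    cols = {}
    for j, name in enumerate(names):
        mu, sd = (scales or {}).get(name, (0.0, 1.0))
        cols[name] = mu + sd * z[:, j]
    return pd.DataFrame(cols), target, {"coefficients": coefs}


def gen_patient_records(n: int, n_signal: int = 5, n_noise: int = 8,
                        missing_frac: float = 0.0, outlier_frac: float = 0.0,
                        seed: int = 0) -> RecordTable:
    """Generate UCI-style patient records with planted informative features.

    The binary target follows a logistic model over ``n_signal`` features
    only; the remaining ``n_noise`` features are independent of the target.
    ``missing_frac`` of cells are blanked and ``outlier_frac`` are replaced
    by mean +/- 6 sd (guaranteed to trip the z-score rule at threshold 3 for
    small fractions).
    """
    if n < 0 or n_signal < 1 or n_noise < 0:
        raise ValueError("counts out of range")
    if not (0 <= missing_frac < 0.5) or not (0 <= outlier_frac < 0.5):
        raise ValueError("fractions must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    total = n_signal + n_noise
    names = list(UCI_FEATURES[:total])
    names += [f"f{j}" for j in range(len(names), total)]
    signal_names = list(rng.choice(names, size=n_signal, replace=False))
    frame, target, meta = _logistic_table(n, names, signal_names, rng, _UCI_SCALES)

    outlier_mask = np.zeros((n, total), dtype=bool)
    if outlier_frac > 0 and n > 0:
        k = int(round(outlier_frac * n * total))
        flat = rng.choice(n * total, size=k, replace=False)
        outlier_mask.flat[flat] = True
        mu = frame.to_numpy().mean(axis=0)
        sd = frame.to_numpy().std(axis=0)
        vals = frame.to_numpy()
        signs = rng.choice([-1.0, 1.0], size=k)
        rows, cols = np.unravel_index(flat, (n, total))
        vals[rows, cols] = mu[cols] + signs * 6.0 * sd[cols]
        frame = pd.DataFrame(vals, columns=names)
    missing_mask = np.zeros((n, total), dtype=bool)
    if missing_frac > 0 and n > 0:
        candidates = np.flatnonzero(~outlier_mask.ravel())
        k = int(round(missing_frac * n * total))
        flat = rng.choice(candidates, size=min(k, len(candidates)), replace=False)
        missing_mask.flat[flat] = True
        vals = frame.to_numpy()
        vals[missing_mask] = np.nan
        frame = pd.DataFrame(vals, columns=names)

    provenance = {name: ("signal" if name in signal_names else "noise") for name in names}
    table = RecordTable(frame, target, provenance)
    table.meta = {**meta, "outlier_mask": outlier_mask, "missing_mask": missing_mask}
    return table


METADATA_FEATURES = ("resting_hr", "hrv_rmssd", "steps_per_day", "sleep_hours",
                     "activity_minutes")
_METADATA_SCALES = {
    "resting_hr": (68, 9), "hrv_rmssd": (42, 15), "steps_per_day": (7500, 2800),
    "sleep_hours": (7.0, 1.1), "activity_minutes": (35, 18),
}
_METADATA_SIGNAL = ("resting_hr", "hrv_rmssd", "activity_minutes")


def gen_metadata(n: int, seed: int = 0, duplicate_frac: float = 0.05,
                 missing_frac: float = 0.0) -> RecordTable:
    """Generate wearable-style metadata records with injected duplicate rows.

    ``duplicate_frac`` of the rows are exact copies of earlier rows so the
    cleaning stage's deduplication can be verified to remove exactly
    ``floor(duplicate_frac * n)`` rows.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not (0 <= duplicate_frac < 0.5) or not (0 <= missing_frac < 0.5):
        raise ValueError("fractions must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    names = list(METADATA_FEATURES)
    n_dup = int(math.floor(duplicate_frac * n))
    n_base = n - n_dup
    frame, target, meta = _logistic_table(n_base, names, list(_METADATA_SIGNAL),
                                          rng, _METADATA_SCALES)
    if n_dup > 0:
        src = np.arange(n_dup) % max(n_base, 1)
        frame = pd.concat([frame, frame.iloc[src]], ignore_index=True)
        target = np.concatenate([target, target[src]])
    if missing_frac > 0 and n > 0:
        mask = rng.uniform(0, 1, frame.shape) < missing_frac
        vals = frame.to_numpy()
        vals[mask] = np.nan
        frame = pd.DataFrame(vals, columns=names)
    provenance = {name: ("signal" if name in _METADATA_SIGNAL else "noise")
                  for name in names}
    table = RecordTable(frame, target, provenance)
    table.meta = {**meta, "n_duplicates": n_dup}
    return table


# --------------------------------------------------------------------------
# Food database and patient profiles
# --------------------------------------------------------------------------

# (name, sodium mg, sat fat g, fiber g, kcal, cholesterol mg, cost, tags)
_FOOD_ARCHETYPES = (
    ("oatmeal_berries",   120, 1.0, 7.0, 320, 0,   1.2, ("vegetarian", "breakfast")),
    ("grilled_salmon",    340, 2.5, 0.5, 420, 70,  4.5, ("fish",)),
    ("garden_salad",       95, 0.8, 5.5, 180, 0,   2.0, ("vegetarian", "vegan")),
    ("lentil_soup",       380, 0.6, 8.5, 310, 0,   1.8, ("vegetarian", "vegan")),
    ("brown_rice_bowl",   300, 1.5, 6.0, 450, 25,  2.6, ("vegetarian",)),
    ("fruit_plate",         5, 0.2, 4.5, 160, 0,   1.5, ("vegetarian", "vegan")),
    ("greek_yogurt",       65, 2.2, 0.0, 150, 12,  1.1, ("vegetarian",)),
    ("mixed_nuts",          2, 2.0, 3.5, 260, 0,   1.4, ("vegetarian", "vegan", "nut")),
    ("grilled_chicken",   320, 1.8, 0.0, 380, 85,  3.2, ()),
    ("fried_snack",       520, 5.5, 1.5, 420, 15,  1.0, ("fried",)),
    ("beef_burger",       780, 9.0, 1.5, 650, 95,  3.0, ("fried",)),
    ("pizza_slice",       640, 5.0, 2.0, 480, 30,  2.2, ("vegetarian",)),
    ("green_smoothie",     60, 0.4, 5.0, 210, 0,   2.4, ("vegetarian", "vegan")),
    ("veg_curry",         410, 3.0, 7.5, 390, 0,   2.5, ("vegetarian", "vegan")),
    ("wholegrain_bread",  210, 0.5, 4.0, 180, 0,   0.8, ("vegetarian", "vegan")),
    ("boiled_eggs",       125, 3.0, 0.0, 155, 370, 0.9, ("vegetarian",)),
    ("tomato_soup",       290, 1.0, 3.0, 160, 5,   1.3, ("vegetarian",)),
    ("pasta_marinara",    430, 1.2, 5.0, 470, 10,  2.1, ("vegetarian",)),
    ("steamed_veg",        45, 0.3, 6.5, 120, 0,   1.6, ("vegetarian", "vegan")),
    ("bean_chili",        360, 1.1, 9.5, 340, 0,   1.9, ("vegetarian", "vegan")),
)


def gen_food_db(n_items: int = 20, seed: int = 0, jitter: float = 0.08) -> list[FoodItem]:
    """Generate a toy per-serving food database.

    Items cycle through realistic archetypes with multiplicative nutrient and
    cost jitter; ids are stable and deterministic per seed.
    """
    if n_items <= 0:
        raise ValueError("n_items must be positive")
    rng = np.random.default_rng(seed)
    items: list[FoodItem] = []
    for i in range(n_items):
        name, *nutr, cost, tags = _FOOD_ARCHETYPES[i % len(_FOOD_ARCHETYPES)]
        nutr = np.asarray(nutr, dtype=float)
        scale = rng.uniform(1 - jitter, 1 + jitter, nutr.shape)
        nutr = np.maximum(nutr * scale, 0.0)
        cost = max(float(cost) * rng.uniform(1 - jitter, 1 + jitter), 0.0)
        suffix = "" if i < len(_FOOD_ARCHETYPES) else f"_{i // len(_FOOD_ARCHETYPES)}"
        items.append(FoodItem(id=name + suffix, nutrients=tuple(nutr),
                              cost=round(cost, 2), tags=frozenset(tags)))
    return items


#: Daily guideline scaffold: lower bound l, upper bound u per nutrient
#: (sodium mg, sat fat g, fiber g, calories kcal, cholesterol mg).
GUIDELINE_LOWER = np.array([0.0, 0.0, 25.0, 1800.0, 0.0])
GUIDELINE_UPPER = np.array([2300.0, 13.0, 60.0, 2200.0, 300.0])

_PROFILE_KINDS = {
    # kind: (age, bmi, risk, targets g, risk weights w, forbidden tags, exclusions)
    "hypertension": (63, 29.0, 0.80,
                     np.array([1500.0, 10.0, 28.0, 2000.0, 180.0]),
                     np.array([2.5, 0.8, 0.0, 0.3, 0.8]),
                     ("fried",), ()),
    "dyslipidemia": (58, 28.0, 0.70,
                     np.array([2000.0, 8.0, 30.0, 2000.0, 150.0]),
                     np.array([0.8, 2.0, 0.0, 0.3, 2.5]),
                     ("fried",), ("boiled_eggs",)),
    "healthy":      (45, 23.0, 0.10,
                     np.array([2000.0, 11.0, 28.0, 2000.0, 200.0]),
                     np.array([0.5, 0.5, 0.0, 0.3, 0.5]),
                     (), ()),
}


def gen_patient_profile(kind: str = "hypertension", seed: int = 0) -> PatientProfile:
    """Generate a patient profile with guideline bounds, targets and risk weights.

    ``kind`` selects the risk emphasis: hypertension up-weights sodium,
    dyslipidemia up-weights cholesterol and saturated fat.  Bound and target
    defaults follow the daily-intake scaffold in :data:`GUIDELINE_LOWER` /
    :data:`GUIDELINE_UPPER` (one day, about five eating occasions).
    """
    if kind not in _PROFILE_KINDS:
        raise ValueError(f"unknown profile kind {kind!r}; choose from {sorted(_PROFILE_KINDS)}")
    rng = np.random.default_rng(seed)
    age, bmi, risk, targets, weights, forbidden, exclusions = _PROFILE_KINDS[kind]
    age = age + rng.integers(-4, 5)
    bmi = bmi + rng.uniform(-1.0, 1.0)
    return PatientProfile(
        name=kind,
        age=float(age),
        bmi=round(float(bmi), 1),
        risk=risk,
        forbidden_tags=frozenset(forbidden),
        exclusions=frozenset(exclusions),
        lower=GUIDELINE_LOWER.copy(),
        upper=GUIDELINE_UPPER.copy(),
        targets=targets.copy(),
        tolerance=0.15 * targets,
        hard_max=GUIDELINE_UPPER.copy(),
        risk_weights=weights.copy(),
    )


def nutrient_names() -> tuple[str, ...]:
    return NUTRIENTS
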