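"""Readers and writers for every table/record type the pipeline moves.

Formats are plain text: beat tables as headerless CSV with the label in the
last column, record/feature tables as CSV with header, image sets as PNG
files plus a labels CSV, food databases and patient profiles as JSON, and
configurations as YAML.  ``write`` then ``read`` round-trips losslessly
(bit-exact for integers, 1e-12 for floats).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .datatypes import (NUTRIENTS, BeatTable, FeatureTable, FoodItem, ImageSet,
                        PatientProfile, RecordTable)


class MalformedFileError(ValueError):
    """A text input failed to parse; the message names the offending line."""


# -- BeatTable: headerless CSV, one beat per row, integer label last --------

def write_beats_csv(table: BeatTable, path) -> None:
    data = np.hstack([table.signals, table.labels[:, None].astype(float)])
    fmt = ["%.17g"] * table.beat_len + ["%d"]
    np.savetxt(path, data, delimiter=",", fmt=fmt)


def read_beats_csv(path, fs: float = 125.0) -> BeatTable:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise MalformedFileError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {width}")
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise MalformedFileError(f"{path}: line {lineno}: {exc}") from None
            label = values[-1]
            if label != int(label):
                raise MalformedFileError(
                    f"{path}: line {lineno}: label column must be an integer")
            rows.append(values)
    if not rows:
        raise MalformedFileError(f"{path}: no data rows")
    arr = np.asarray(rows)
    return BeatTable(arr[:, :-1], arr[:, -1].astype(int), fs=fs)


# -- RecordTable / FeatureTable: CSV with header ----------------------------

def write_records_csv(table: RecordTable, path) -> None:
    df = table.frame.copy()
    df["target"] = table.target
    df.to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".provenance.json")
    if table.provenance:
        sidecar.write_text(json.dumps(dict(table.provenance), indent=2))


def read_records_csv(path) -> RecordTable:
    df = pd.read_csv(path)
    if "target" not in df.columns:
        raise MalformedFileError(f"{path}: missing 'target' column")
    target = df.pop("target").to_numpy()
    sidecar = Path(path).with_suffix(".provenance.json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return RecordTable(df, target, provenance)


def write_features_csv(table: FeatureTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_features_csv(path) -> FeatureTable:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise MalformedFileError(f"{path}: missing 'label' column")
    labels = df.pop("label").to_numpy()
    return FeatureTable(list(df.columns), df.to_numpy(dtype=float), labels)


# -- ImageSet: PNG files + labels CSV ---------------------------------------

def write_imageset(images: ImageSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(zip(images.images, images.labels)):
        name = f"img_{i:04d}.png"
        iio.imwrite(directory / name, np.asarray(img, dtype=np.uint8))
        row = {"file": name, "label": int(label)}
        if images.masks is not None:
            mask_name = f"mask_{i:04d}.png"
            iio.imwrite(directory / mask_name,
                        (np.asarray(images.masks[i], dtype=np.uint8) * 255))
            row["mask"] = mask_name
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)


def read_imageset(directory, levels: int = 256) -> ImageSet:
    directory = Path(directory)
    index = pd.read_csv(directory / "labels.csv")
    images, masks, labels = [], [], []
    has_masks = "mask" in index.columns
    for _, row in index.iterrows():
        images.append(np.asarray(iio.imread(directory / row["file"]), dtype=int))
        labels.append(int(row["label"]))
        if has_masks:
            masks.append(np.asarray(iio.imread(directory / row["mask"])) > 127)
    return ImageSet(images, np.asarray(labels), masks if has_masks else None,
                    levels=levels)


# -- Food database and patient profiles: JSON -------------------------------

def write_food_db(items: list[FoodItem], path) -> None:
    payload = [{"id": f.id, "nutrients": dict(zip(NUTRIENTS, f.nutrients)),
                "cost": f.cost, "tags": sorted(f.tags)} for f in items]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_food_db(path) -> list[FoodItem]:
    payload = json.loads(Path(path).read_text())
    items = []
    for entry in payload:
        nutrients = tuple(float(entry["nutrients"][n]) for n in NUTRIENTS)
        items.append(FoodItem(id=entry["id"], nutrients=nutrients,
                              cost=float(entry["cost"]),
                              tags=frozenset(entry.get("tags", ()))))
    return items


def write_profile(profile: PatientProfile, path) -> None:
    d = dataclasses.asdict(profile)
    for key, value in d.items():
        if isinstance(value, np.ndarray):
            d[key] = value.tolist()
        elif isinstance(value, frozenset):
            d[key] = sorted(value)
    Path(path).write_text(json.dumps(d, indent=2))


def read_profile(path) -> PatientProfile:
    d = json.loads(Path(path).read_text())
    for key in ("required_tags", "forbidden_tags", "exclusions"):
        d[key] = frozenset(d.get(key, ()))
    return PatientProfile(**d)


# -- Reports and configs ----------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
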