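"""File formats: label TIFFs, PNG renders, CSV tables, JSON/YAML models.

Masks and compiled label rasters are stored as single-channel 16-bit
TIFFs (one file per class, or one combined signed label file); renders as
PNG; feature tables as CSV with the canonical column names; fitted
models as JSON for exact reload.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .maskops import STRUCTURE_CLASSES, ClassMaskSet
from .morphometry import FEATURE_COLUMNS
from .multivariate import ClusterModel, IndexModel


class SchemaError(ValueError):
    pass


# --- rasters ---------------------------------------------------------------


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label raster (class ids, may include -1) as 16-bit TIFF."""
    tifffile.imwrite(str(path), labels.astype(np.int16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_mask_set(dirpath: str | Path, mask_set: ClassMaskSet, prefix: str = "") -> dict:
    """One 16-bit binary TIFF per structure class, plus a sidecar with pixel size."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, mask in mask_set.masks.items():
        fn = dirpath / f"{prefix}{name}.tif"
        tifffile.imwrite(str(fn), mask.astype(np.uint16))
        files[name] = fn.name
    meta = {"pixel_size_um": mask_set.pixel_size_um, "files": files}
    (dirpath / f"{prefix}masks.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta


def read_mask_set(dirpath: str | Path, prefix: str = "") -> ClassMaskSet:
    dirpath = Path(dirpath)
    meta = json.loads((dirpath / f"{prefix}masks.json").read_text())
    masks = {
        name: tifffile.imread(str(dirpath / fn)).astype(bool)
        for name, fn in meta["files"].items()
    }
    return ClassMaskSet(masks=masks, pixel_size_um=float(meta["pixel_size_um"]))


def write_png(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(str(path), rgb)


def read_png(path: str | Path) -> np.ndarray:
    return iio.imread(str(path))


# --- tables ----------------------------------------------------------------


def validate_feature_table(df: pd.DataFrame) -> None:
    """Check the canonical feature-table schema; raise listing missing columns."""
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")


def write_feature_table(path: str | Path, df: pd.DataFrame) -> None:
    validate_feature_table(df)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_feature_table(df)
    return df


# --- models ----------------------------------------------------------------


def write_index_model(path: str | Path, model: IndexModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))


def read_index_model(path: str | Path) -> IndexModel:
    return IndexModel.from_dict(json.loads(Path(path).read_text()))


def write_cluster_model(path: str | Path, model: ClusterModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))


def read_cluster_model(path: str | Path) -> ClusterModel:
    return ClusterModel.from_dict(json.loads(Path(path).read_text()))


# --- manifests / configs ----------------------------------------------------


def write_yaml(path: str | Path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def assert_known_classes(names) -> None:
    unknown = sorted(set(names) - set(STRUCTURE_CLASSES))
    if unknown:
        raise SchemaError(f"unknown structure classes: {unknown}")
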