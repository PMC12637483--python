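"""File I/O: CSV tables, 16-bit TIFF images, YAML configs."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a single-channel image as 16-bit TIFF (values clipped)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)
    return path


def load_config_file(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
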