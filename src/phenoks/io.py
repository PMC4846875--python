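"""File output helpers: CSV tables and TIFF images/labels."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_plate_map(plate_map: pd.DataFrame, path) -> Path:
    path = Path(path)
    plate_map.to_csv(path, index=False)
    return path


def write_feature_tables(features: pd.DataFrame, out_dir,
                         by: str = "batch_id") -> list:
    """One CSV per batch, named after the batch id."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for batch, sub in features.groupby(by, sort=True):
        p = out_dir / f"features_{batch}.csv"
        sub.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_feature_tables(paths) -> pd.DataFrame:
    return pd.concat([pd.read_csv(p) for p in paths], ignore_index=True)


def write_z_matrix(z_matrix: pd.DataFrame, path) -> Path:
    """Rows = compounds, columns = descriptor@time."""
    path = Path(path)
    out = z_matrix.copy()
    out.columns = ["@".join(str(part) for part in
                            (c if isinstance(c, tuple) else (c,)))
                   for c in out.columns]
    out.to_csv(path)
    return path


def read_z_matrix(path) -> pd.DataFrame:
    raw = pd.read_csv(path, index_col=0)
    cols = []
    for c in raw.columns:
        d, _, t = c.partition("@")
        cols.append((d, int(float(t))))
    raw.columns = pd.MultiIndex.from_tuples(cols,
                                            names=["descriptor", "time_min"])
    return raw


def write_image(image, path) -> Path:
    """Write a SyntheticCellImage's channels as one multi-channel TIFF."""
    path = Path(path)
    stack = np.stack([image.channels[k] for k in sorted(image.channels)])
    tifffile.imwrite(path, stack.astype(np.float32),
                     photometric="minisblack")
    return path


def write_labels(label_image: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(label_image).astype(np.uint16))
    return path


def read_image(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def region_area_table(labels) -> pd.DataFrame:
    """Per-cell pixel areas of every segmented region."""
    regions = {
        "nucleus": labels.nucleus_labels,
        "cell": labels.cell_labels,
        "cytoplasm": labels.cytoplasm_labels,
        "perinuclear": labels.perinuclear_labels,
        "PM": labels.pm_labels,
    }
    ids = labels.cell_ids()
    n = int(labels.cell_labels.max())
    out = {"cell": ids}
    for name, img in regions.items():
        if img is None:
            continue
        areas = np.bincount(img.ravel(), minlength=n + 1)[1:n + 1]
        out[f"{name}_area"] = areas[ids - 1]
    return pd.DataFrame(out)


def write_region_areas(labels, path) -> Path:
    path = Path(path)
    region_area_table(labels).to_csv(path, index=False)
    return path
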