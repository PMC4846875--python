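"""Per-cell descriptor extraction.

A *descriptor* is one quantitative image feature per cell: a region x
channel x statistic combination (e.g. integrated pERK intensity over the
nucleus region, transferrin-positive endosome count in the PM ring, the
perinuclear/PM intensity ratio). This module computes the per-cell
descriptor table from segmentation labels and intensity channels, the
endosome colocalization counts, and the per-batch cross-cell regression
slope of perinuclear on PM intensity used as a trafficking read-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .segmentation import EndosomeObjects, SegmentationLabels

__all__ = [
    "DescriptorDef",
    "default_catalogue",
    "compute_cell_features",
    "coloc_count",
    "perinuclear_pm_slope",
]

REGIONS = ("nucleus", "cell", "cytoplasm", "perinuclear", "PM")
STATISTICS = ("integrated", "mean", "object_count", "coloc_count",
              "ratio_perinuclear_PM")


@dataclass(frozen=True)
class DescriptorDef:
    """Definition of one descriptor.

    ``region`` is one of REGIONS (for ratio descriptors the two regions are
    implied: perinuclear and PM). ``channels`` holds one channel name, or
    two for colocalization counts.
    """

    name: str
    region: str
    channels: tuple
    statistic: str
    min_overlap_frac: float = 0.5

    def __post_init__(self):
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.statistic == "coloc_count" and len(self.channels) != 2:
            raise ValueError("coloc descriptors reference exactly two channels")
        if self.statistic != "coloc_count" and len(self.channels) != 1:
            raise ValueError(f"{self.name}: exactly one channel expected")
        if self.statistic != "ratio_perinuclear_PM" and self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


def default_catalogue(channels, spot_channels=()) -> list:
    """Build the default descriptor catalogue.

    Cross of the five regions x channels x {integrated, mean}, plus
    endosome counts per ring region and a perinuclear/PM ratio for each
    spot-forming channel. The catalogue is configurable; it is a documented
    working set, not a reconstruction of any particular instrument's list.
    """
    cat = []
    for ch in channels:
        for region in REGIONS:
            cat.append(DescriptorDef(f"{region}_{ch}_integrated", region,
                                     (ch,), "integrated"))
            cat.append(DescriptorDef(f"{region}_{ch}_mean", region, (ch,),
                                     "mean"))
    for ch in spot_channels:
        for region in ("perinuclear", "PM", "cytoplasm"):
            cat.append(DescriptorDef(f"{region}_{ch}_endosome_count", region,
                                     (ch,), "object_count"))
        cat.append(DescriptorDef(f"ratio_perinuclear_PM_{ch}", "perinuclear",
                                 (ch,), "ratio_perinuclear_PM"))
    if len(spot_channels) >= 2:
        a, b = spot_channels[0], spot_channels[1]
        for region in ("perinuclear", "PM"):
            cat.append(DescriptorDef(f"{region}_endosome_{a}_{b}_coloc_count",
                                     region, (a, b), "coloc_count"))
    names = [d.name for d in cat]
    if len(names) != len(set(names)):
        raise ValueError("descriptor names must be unique")
    return cat


def _region_label_image(labels: SegmentationLabels, region: str) -> np.ndarray:
    img = {
        "nucleus": labels.nucleus_labels,
        "cell": labels.cell_labels,
        "cytoplasm": labels.cytoplasm_labels,
        "perinuclear": labels.perinuclear_labels,
        "PM": labels.pm_labels,
    }[region]
    if img is None:
        raise ValueError(f"region {region!r} not derived; run derive_regions")
    return img


def _region_sums(label_img, channel, n_cells):
    sums = np.bincount(label_img.ravel(), weights=channel.ravel(),
                       minlength=n_cells + 1)[1:n_cells + 1]
    areas = np.bincount(label_img.ravel(), minlength=n_cells + 1)[1:n_cells + 1]
    return sums, areas


def compute_cell_features(
    labels: SegmentationLabels,
    channels: dict,
    endosomes: dict | None,
    catalogue: list,
) -> pd.DataFrame:
    """One row per cell, one column per descriptor.

    Integrated intensity is the pixel sum of the channel over the region;
    mean is sum/area (missing when the region has zero area, in which case
    the value is NaN and logged by the caller); object counts come from the
    EndosomeObjects tables keyed by channel; colocalization counts from
    :func:`coloc_count`.
    """
    ids = labels.cell_ids()
    n = int(labels.cell_labels.max())
    out = pd.DataFrame(index=pd.Index(ids, name="cell"))
    cache = {}
    for d in catalogue:
        if d.statistic in ("integrated", "mean"):
            key = (d.region, d.channels[0])
            if key not in cache:
                cache[key] = _region_sums(
                    _region_label_image(labels, d.region),
                    np.asarray(channels[d.channels[0]], float), n)
            sums, areas = cache[key]
            if d.statistic == "integrated":
                out[d.name] = sums[ids - 1]
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    means = np.where(areas > 0, sums / np.maximum(areas, 1),
                                     np.nan)
                out[d.name] = means[ids - 1]
        elif d.statistic == "object_count":
            objs = (endosomes or {}).get(d.channels[0])
            counts = pd.Series(0, index=out.index, dtype=int)
            if objs is not None and len(objs.table):
                sub = objs.table[(objs.table["region"] == d.region)
                                 & (objs.table["cell"] > 0)]
                got = sub.groupby("cell").size()
                counts.loc[counts.index.intersection(got.index)] = got
            out[d.name] = counts
        elif d.statistic == "coloc_count":
            a = (endosomes or {}).get(d.channels[0])
            b = (endosomes or {}).get(d.channels[1])
            if a is None or b is None:
                out[d.name] = 0
            else:
                cc = coloc_count(a, b, min_overlap_frac=d.min_overlap_frac,
                                 region=d.region)
                out[d.name] = cc.reindex(out.index, fill_value=0)
        elif d.statistic == "ratio_perinuclear_PM":
            for region in ("perinuclear", "PM"):
                key = (region, d.channels[0])
                if key not in cache:
                    cache[key] = _region_sums(
                        _region_label_image(labels, region),
                        np.asarray(channels[d.channels[0]], float), n)
            peri_sums, _ = cache[("perinuclear", d.channels[0])]
            pm_sums, _ = cache[("PM", d.channels[0])]
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(pm_sums > 0, peri_sums / np.maximum(pm_sums, 1e-300),
                                 np.nan)
            out[d.name] = ratio[ids - 1]
    return out.reset_index()


def coloc_count(objects_a: EndosomeObjects, objects_b: EndosomeObjects,
                min_overlap_frac: float = 0.5,
                region: str | None = None) -> pd.Series:
    """Per-cell count of A-objects colocalizing with B-objects.

    An A-object colocalizes when its pixel overlap with the union of all
    B-objects, as a fraction of the A-object's area, reaches
    ``min_overlap_frac``. Optionally restricted to A-objects whose centroid
    lies in ``region``. Empty object sets give zero counts.
    """
    counts: dict = {}
    if len(objects_a.table) == 0:
        return pd.Series(counts, dtype=int)
    b_mask = objects_b.labels > 0
    tab = objects_a.table
    if region is not None:
        tab = tab[tab["region"] == region]
    for _, row in tab.iterrows():
        rows, cols = objects_a.pixel_sets[row["object"]]
        overlap = b_mask[rows, cols].sum() / len(rows)
        if overlap >= min_overlap_frac:
            cell = int(row["cell"])
            if cell > 0:
                counts[cell] = counts.get(cell, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def perinuclear_pm_slope(table: pd.DataFrame, perinuclear_col: str,
                         pm_col: str, by: str | None = "batch_id") -> pd.Series:
    """OLS slope of perinuclear intensity on PM intensity across cells.

    Fitted with an intercept, per batch. Batches with fewer than 3 cells
    carrying both values, or with zero variance in the PM intensity, give
    NaN (flagged missing).
    """
    def _slope(df: pd.DataFrame) -> float:
        sub = df[[pm_col, perinuclear_col]].dropna()
        x = sub[pm_col].to_numpy(float)
        y = sub[perinuclear_col].to_numpy(float)
        if len(x) < 3 or np.ptp(x) == 0:
            return np.nan
        return float(sps.linregress(x, y).slope)

    if by is None:
        return pd.Series({"all": _slope(table)})
    return table.groupby(by, sort=True).apply(_slope, include_groups=False)
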