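"""Sphere-voxel density maps and atlas aggregation of 3-D cell centroids.

Detected cell centroids (micrometer coordinates in the atlas frame) are
summarized two ways:

* **voxel density** — the count of cells within an analysis sphere
  (100 um diameter by default, inclusive boundary) centered on each node of
  a regular grid; with the default 50 um center spacing the spheres overlap,
  so one cell can contribute to several neighboring voxels;
* **region counts** — each cell is assigned the label of its containing
  atlas voxel (half-open intervals, floor convention), yielding the
  animals x regions matrix consumed by the regional screen.

``voxel_screen`` runs the paired negative-binomial sequential-G test at
every voxel of a set of per-animal density maps and BH-adjusts across all
voxels, producing a q-value map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .regionstats import PairDesign, _screen_counts, bh_fdr
from .simulate import LabelAtlas

__all__ = [
    "VoxelGrid",
    "voxel_density",
    "region_counts",
    "voxel_screen",
    "read_nrrd",
    "write_nrrd",
    "read_centroids",
    "write_centroids",
]

BACKGROUND = "__background__"
OUTSIDE = "__outside__"


@dataclass(frozen=True)
class VoxelGrid:
    """Regular grid of overlapping analysis spheres.

    Centers sit at ``origin + k * spacing`` for every k with the center
    inside ``origin + extent``.  Spacing at or below the sphere diameter
    makes neighboring spheres overlap.
    """

    extent: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: tuple[float, float, float] = (50.0, 50.0, 50.0)
    sphere_diameter: float = 100.0

    def __post_init__(self) -> None:
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if any(e <= 0 for e in self.extent):
            raise ValueError("grid extent must be positive along every axis")

    @classmethod
    def for_atlas(cls, atlas: LabelAtlas, sphere_diameter: float = 100.0,
                  spacing: tuple[float, float, float] | None = None) -> "VoxelGrid":
        if spacing is None:
            spacing = (sphere_diameter / 2,) * 3
        return cls(extent=atlas.extent_um, spacing=spacing, sphere_diameter=sphere_diameter)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(np.floor(e / s)) + 1 for e, s in zip(self.extent, self.spacing))

    def centers(self) -> np.ndarray:
        """All sphere centers as an (n_voxels, 3) array in index order."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d]) for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def _points_array(cloud) -> np.ndarray:
    if isinstance(cloud, pd.DataFrame):
        pts = cloud[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(cloud, dtype=float).reshape(-1, 3)
    if pts.size and not np.isfinite(pts).all():
        raise ValueError("centroid coordinates must be finite")
    return pts


def voxel_density(cloud, grid: VoxelGrid) -> np.ndarray:
    """Count cells within each analysis sphere (boundary inclusive).

    Returns an integer array of the grid's shape.  Cells may be counted by
    several overlapping spheres; cells outside every sphere contribute
    nowhere.
    """
    pts = _points_array(cloud)
    shape = grid.shape
    counts = np.zeros(shape, dtype=np.int64)
    if len(pts) == 0:
        return counts
    tree = cKDTree(pts)
    hits = tree.query_ball_point(grid.centers(), r=grid.sphere_diameter / 2.0)
    counts = np.fromiter((len(h) for h in hits), dtype=np.int64, count=len(hits))
    return counts.reshape(shape)


def region_counts(cloud, atlas: LabelAtlas) -> pd.Series:
    """Tally cells per atlas region (plus background and out-of-volume bins).

    A cell at coordinate x belongs to atlas voxel ``floor(x / spacing)``
    (half-open voxel intervals).  The returned Series covers every atlas
    label (by name when the atlas has one) plus ``__background__`` and
    ``__outside__``; its sum equals the cloud size.
    """
    pts = _points_array(cloud)
    labels = atlas.labels
    names = [atlas.names.get(int(lb), str(int(lb))) for lb in labels]
    tall = pd.Series(0, index=names + [BACKGROUND, OUTSIDE], dtype=np.int64)
    if len(pts) == 0:
        return tall
    idx = np.floor(pts / np.asarray(atlas.spacing)).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.asarray(atlas.volume.shape)), axis=1)
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} centroid(s) fall outside the atlas volume")
        tall[OUTSIDE] = n_out
    lab = atlas.volume[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    binc = np.bincount(lab, minlength=int(labels.max(initial=0)) + 1)
    tall[BACKGROUND] = int(binc[0])
    for lb, name in zip(labels, names):
        tall[name] = int(binc[int(lb)])
    return tall


def region_count_matrix(clouds: dict[str, pd.DataFrame], atlas: LabelAtlas) -> pd.DataFrame:
    """Animals x regions count matrix from per-animal clouds (no background bins)."""
    rows = {aid: region_counts(cloud, atlas) for aid, cloud in clouds.items()}
    mat = pd.DataFrame(rows).T.drop(columns=[BACKGROUND, OUTSIDE])
    mat.index.name = "animal_id"
    return mat


def voxel_screen(
    maps: dict[str, np.ndarray], design: PairDesign, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Paired NB sequential-G test at every voxel, BH-adjusted over voxels.

    ``maps`` holds one density map per animal (identical shapes, in the
    design's animal order by key lookup).  Returns ``(q_map, p_map)`` float
    arrays of the shared grid shape; voxels that are constant across
    animals (e.g. empty everywhere) get p = q = 1.
    """
    shapes = {m.shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValueError("all density maps must share one grid shape")
    try:
        stack = np.stack([maps[a] for a in design.animals])
    except KeyError as e:
        raise ValueError(f"density map missing for animal {e.args[0]!r}") from None
    shape = stack.shape[1:]
    Y = stack.reshape(len(design.animals), -1)
    res = _screen_counts(Y, design)
    p = np.where(np.isnan(res["p_value"]), 1.0, res["p_value"])
    q = bh_fdr(p)
    return q.reshape(shape), p.reshape(shape)


# ---------------------------------------------------------------------------
# volume / centroid I/O


def write_nrrd(path, array: np.ndarray, spacing: tuple[float, float, float]) -> None:
    """Write a 3-D array (x, y, z indexed) as NRRD with spacing metadata (um)."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))


def read_nrrd(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an NRRD volume; returns ((x, y, z) array, spacing)."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing())


def write_centroids(path, cloud: pd.DataFrame) -> None:
    cloud[["x_um", "y_um", "z_um"]].to_csv(path, sep="\t", index=False)


def read_centroids(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"x_um", "y_um", "z_um"} - set(df.columns)
    if missing:
        raise ValueError(f"centroid table {path} lacks columns {sorted(missing)}")
    return df
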