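"""Volumetric label atlas built from sparse per-slice annotations.

Anatomical regions are drawn manually on a subset of planes (e.g. 50
horizontal slices, plus coronal slices for cortical subdivisions); the dense
3D atlas is reconstructed by shape-based interpolation: per-region signed
distance maps on each annotated plane, linearly interpolated between
consecutive annotated planes along the annotation axis. A voxel takes the
region with the most negative interpolated distance if any is negative,
else 0 (outside brain). Annotation groups on different axes are merged with
later groups overriding earlier ones inside their annotated extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["Atlas", "SliceAnnotation", "interpolate_atlas", "region_fraction_table"]

#: signed distance assigned to a region absent from a plane ("infinitely outside")
_FAR = 1.0e6


@dataclass
class Atlas:
    """Dense integer label volume plus a region table.

    Label 0 is reserved for outside-brain; every nonzero label in ``labels``
    must appear in ``regions`` (columns ``id`` >= 1 and ``name``). Regions
    partition the in-brain volume: each voxel carries exactly one label.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    spacing_um: tuple[float, float, float] = (3.5, 5.0, 5.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D integer volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        present = set(np.unique(self.labels)) - {0}
        known = set(int(i) for i in self.regions["id"])
        if not present <= known:
            raise ValueError(f"labels {sorted(present - known)} missing from region table")
        if (self.regions["id"] < 1).any():
            raise ValueError("region ids must be >= 1 (0 is outside-brain)")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_name(self, region_id: int) -> str:
        row = self.regions.loc[self.regions["id"] == region_id, "name"]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return str(row.iloc[0])


@dataclass
class SliceAnnotation:
    """One annotated plane: a 2D label image at ``plane_index`` along ``axis``."""

    axis: int
    plane_index: int
    label_image: np.ndarray

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label_image must be 2D")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance of a 2D mask: negative inside, positive outside."""
    if not mask.any():
        return np.full(mask.shape, _FAR, dtype=np.float32)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return (outside - inside).astype(np.float32)


def _interp_group(
    annotations: list[SliceAnnotation],
    out_shape: tuple[int, int, int],
    region_ids: np.ndarray,
) -> tuple[np.ndarray, int, int]:
    """Dense labels for one axis-group; returns (labels, first_plane, last_plane).

    Labels are only defined on planes within [first, last]; elsewhere 0.
    """
    axis = annotations[0].axis
    ann = sorted(annotations, key=lambda a: a.plane_index)
    idx = [a.plane_index for a in ann]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate annotated planes (plane gap of size 0)")
    plane_shape = tuple(s for i, s in enumerate(out_shape) if i != axis)
    for a in ann:
        if a.label_image.shape != plane_shape:
            raise ValueError(
                f"annotation plane shape {a.label_image.shape} does not match "
                f"volume cross-section {plane_shape}"
            )
        if not (0 <= a.plane_index < out_shape[axis]):
            raise ValueError(f"plane_index {a.plane_index} outside volume")
    # per-plane signed distances, one stack per region
    sd = {
        rid: [_signed_distance(a.label_image == rid) for a in ann] for rid in region_ids
    }
    labels = np.zeros(out_shape, dtype=np.int32)
    nreg = len(region_ids)
    for plane in range(idx[0], idx[-1] + 1):
        k = np.searchsorted(idx, plane, side="right") - 1
        if idx[k] == plane:
            dists = np.stack([sd[rid][k] for rid in region_ids])
        else:
            w = (plane - idx[k]) / (idx[k + 1] - idx[k])
            dists = np.stack(
                [(1 - w) * sd[rid][k] + w * sd[rid][k + 1] for rid in region_ids]
            )
        best = np.argmin(dists, axis=0)
        best_d = np.take_along_axis(dists, best[None], axis=0)[0]
        plane_labels = np.where(best_d < 0, region_ids[best], 0).astype(np.int32)
        sl = [slice(None)] * 3
        sl[axis] = plane
        labels[tuple(sl)] = plane_labels
    return labels, idx[0], idx[-1]


def interpolate_atlas(
    annotations: list[SliceAnnotation],
    out_shape: tuple[int, int, int],
    regions: pd.DataFrame,
    spacing_um: tuple[float, float, float] = (3.5, 5.0, 5.0),
) -> Atlas:
    """Reconstruct a dense atlas from sparse per-slice annotations.

    Annotations are grouped by axis, preserving first-appearance order;
    each group needs >= 2 planes. Within a group, per-region signed distances
    are linearly interpolated between consecutive annotated planes; ties
    between regions break toward the lower region id (np.argmin convention).
    Later-listed axis groups override earlier ones inside their annotated
    extent (where they assign a nonzero label or lie between their first and
    last plane).
    """
    if not annotations:
        raise ValueError("no annotations given")
    region_ids = np.asarray(sorted(int(i) for i in regions["id"]), dtype=np.int32)
    axes_order: list[int] = []
    groups: dict[int, list[SliceAnnotation]] = {}
    for a in annotations:
        if a.axis not in groups:
            groups[a.axis] = []
            axes_order.append(a.axis)
        groups[a.axis].append(a)
    labels = np.zeros(out_shape, dtype=np.int32)
    for gi, axis in enumerate(axes_order):
        group = groups[axis]
        if len(group) < 2:
            raise ValueError(f"axis {axis}: need >= 2 annotated planes, got {len(group)}")
        glabels, first, last = _interp_group(group, out_shape, region_ids)
        sl = [slice(None)] * 3
        sl[axis] = slice(first, last + 1)
        sl = tuple(sl)
        if gi == 0:
            labels[sl] = glabels[sl]
        else:
            # override only inside the group's extent, and only where the
            # later group actually assigns a region (e.g. coronal cortex
            # subdivisions refine, not erase, the horizontal base atlas)
            sub = labels[sl]
            labels[sl] = np.where(glabels[sl] != 0, glabels[sl], sub)
    return Atlas(labels=labels, regions=regions.reset_index(drop=True), spacing_um=spacing_um)


def region_fraction_table(atlas: Atlas) -> pd.DataFrame:
    """Voxel counts per region: columns (id, name, voxel_count).

    Regions absent from the volume are omitted; the counts over ids >= 1 sum
    to the in-brain voxel count.
    """
    counts = np.bincount(atlas.labels.ravel())
    rows = []
    for rid in sorted(int(i) for i in atlas.regions["id"]):
        n = int(counts[rid]) if rid < len(counts) else 0
        if n > 0:
            rows.append({"id": rid, "name": atlas.region_name(rid), "voxel_count": n})
    return pd.DataFrame(rows, columns=["id", "name", "voxel_count"])
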