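"""Volume sculpting and slice-wise manual segmentation.

Sculpting removes extracerebral structures (cranium, dura) the way the
workstation does: the operator outlines a region on the current 2D
projection and every voxel whose orthographic projection along the viewing
direction falls strictly inside that outline is cut away, regardless of
depth.  Rotating the volume and repeating the cut peels the head "like an
apple" until the cortex is exposed.

Slice-wise segmentation is the fallback for difficult cases (veins abutting
contrast-enhancing tumour): per-slice 2D masks either keep only the marked
voxels (stamping-tool marking of veins) or remove them, leaving unmarked
slices untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .projection import StandardView, project_points
from .volumes import Volume3D

__all__ = ["SculptStep", "SliceMaskSet", "sculpt_cut", "apply_slice_masks"]

BACKGROUND = 0.0

_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class SculptStep:
    """One cut: a viewing direction and a closed polygon in view-plane mm."""

    view: StandardView
    polygon: np.ndarray  # (n, 2), closed implicitly

    def __post_init__(self) -> None:
        if not isinstance(self.view, StandardView):
            # arbitrary viewing direction: build an orthonormal frame around it
            d = np.asarray(self.view, dtype=float)
            d = d / np.linalg.norm(d)
            helper = np.array([0.0, 0.0, 1.0])
            if abs(d @ helper) > 0.99:
                helper = np.array([0.0, 1.0, 0.0])
            up = helper - (helper @ d) * d
            up /= np.linalg.norm(up)
            self.view = StandardView(id=0, direction=tuple(d), up=tuple(up))
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or self.polygon.shape[0] < 3:
            raise ValueError("cut polygon needs >= 3 2D vertices")
        poly = shapely.Polygon(self.polygon)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("cut polygon is degenerate or self-intersecting")


@dataclass
class SliceMaskSet:
    """Per-slice 2D boolean masks along one anatomical axis."""

    axis: str
    masks: dict[int, np.ndarray]
    mode: str = "keep"

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {sorted(_AXES)}, got {self.axis!r}")
        if self.mode not in ("keep", "remove"):
            raise ValueError(f"mode must be 'keep' or 'remove', got {self.mode!r}")
        self.masks = {int(k): np.asarray(v, dtype=bool) for k, v in self.masks.items()}


def sculpt_cut(volume: Volume3D, step: SculptStep) -> Volume3D:
    """Cut away all voxels projecting strictly inside the marked polygon.

    The cut is orthographic and depth-unbounded (perpendicular to the
    viewing plane); voxel centres landing exactly on the polygon boundary
    are kept.  Returns a new volume; the input is not modified.
    """
    uv = project_points(volume.grid.all_voxel_centers(), step.view)
    poly = shapely.Polygon(step.polygon)
    # strict interior: shapely `contains` excludes the boundary
    inside = shapely.contains_xy(poly, uv[:, 0], uv[:, 1])
    out = volume.copy()
    out.values = out.values.astype(float)
    out.values.reshape(-1)[inside] = BACKGROUND
    return out


def apply_slice_masks(volume: Volume3D, masks: SliceMaskSet) -> Volume3D:
    """Apply per-slice keep/remove masks; unmarked slices stay untouched."""
    axis = _AXES[masks.axis]
    n_slices = volume.grid.shape[axis]
    slice_shape = tuple(s for i, s in enumerate(volume.grid.shape) if i != axis)
    out = volume.copy()
    out.values = out.values.astype(float)
    for k, m in masks.masks.items():
        if not (0 <= k < n_slices):
            raise ValueError(f"slice index {k} out of bounds for axis {masks.axis}")
        if m.shape != slice_shape:
            raise ValueError(f"slice mask shape {m.shape} != slice shape {slice_shape}")
        sl = [slice(None)] * 3
        sl[axis] = k
        plane = out.values[tuple(sl)]
        if masks.mode == "keep":
            plane[~m] = BACKGROUND
        else:
            plane[m] = BACKGROUND
    return out
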