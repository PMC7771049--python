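"""Standardized views, orthographic projection, and 2D photo alignment.

Six fixed viewing directions are used for reading anatomy off the
reconstructions: a perpendicular cranial view and its 40-degree frontal and
occipital tilts (views 1-3, used for bridging-vein counts and confluence
angles), and a lateral view with cranial and frontal/occipital tilts of 30
degrees (views 4-6, used for the anastomotic veins).  All rendering is
orthographic: an angle or length read in the projection plane is exactly the
projected 3D quantity, with no perspective correction needed.

The in-plane frame of a view is (right, up) with right = direction x up; a
3D point p maps to (p . right, p . up) in mm.

A surgical photograph taken from (approximately) the same viewing direction
differs from the rendered projection by an unknown 2D similarity (rotation,
scale, translation); :func:`fit_similarity` recovers it from matched
landmarks by the closed-form least-squares (Umeyama/Procrustes) solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.transform import SimilarityTransform

__all__ = [
    "StandardView",
    "ProjectionImage",
    "Similarity2D",
    "standard_view",
    "mip",
    "project_points",
    "project_polylines",
    "fit_similarity",
    "save_image",
]


@dataclass(frozen=True)
class StandardView:
    """Orthographic view: unit viewing direction (toward the brain) + up."""

    id: int
    direction: tuple[float, float, float]
    up: tuple[float, float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        u = np.asarray(self.up, float)
        if not (np.isclose(np.linalg.norm(d), 1.0) and np.isclose(np.linalg.norm(u), 1.0)):
            raise ValueError("direction and up must be unit vectors")
        if not np.isclose(d @ u, 0.0, atol=1e-9):
            raise ValueError("direction and up must be orthogonal")
        object.__setattr__(self, "direction", tuple(float(x) for x in d))
        object.__setattr__(self, "up", tuple(float(x) for x in u))

    @property
    def right(self) -> np.ndarray:
        """In-plane horizontal axis, direction x up."""
        return np.cross(self.direction, self.up)

    def frame(self) -> np.ndarray:
        """2x3 matrix mapping 3D mm points to (u, v) plane mm coordinates."""
        return np.stack([self.right, np.asarray(self.up)])


@dataclass
class ProjectionImage:
    """Orthographic scalar rendering with its mm pixel grid."""

    pixels: np.ndarray
    pixel_size: float
    view: StandardView
    origin2d: tuple[float, float]

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")


@dataclass(frozen=True)
class Similarity2D:
    """2D similarity: rotate by ``rotation`` degrees, scale, then translate."""

    scale: float
    rotation: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("similarity scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        th = np.deg2rad(self.rotation)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        p = np.atleast_2d(np.asarray(points, float))
        out = self.scale * (p @ R.T) + np.asarray(self.translation)
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "Similarity2D":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        t = -inv_scale * Similarity2D(1.0, inv_rot, (0.0, 0.0)).apply(
            np.asarray(self.translation)
        )
        return Similarity2D(inv_scale, inv_rot, (float(t[0]), float(t[1])))


def _rot(axis, degrees: float) -> Rotation:
    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(np.deg2rad(degrees) * axis / np.linalg.norm(axis))


def _cranial_tilt(d: np.ndarray, up: np.ndarray, degrees: float):
    """Raise the camera by rotating about the horizontal axis z x direction."""
    axis = np.cross([0.0, 0.0, 1.0], d)
    r = _rot(axis, degrees)
    return r.apply(d), r.apply(up)


def standard_view(id: int) -> StandardView:
    """Return one of the six fixed anatomical views (RAS frame).

    View 1 looks straight down (direction -z, up = anterior); views 2/3 tilt
    it 40 degrees toward frontal (+y) / occipital (-y).  View 4 is the left
    lateral view (direction -x, up = superior) tilted 30 degrees cranially;
    views 5/6 tilt the lateral view 30 degrees toward frontal/occipital
    first, then 30 degrees cranially.
    """
    if id not in range(1, 7):
        raise ValueError(f"view id must be in 1..6, got {id}")
    if id in (1, 2, 3):
        d = np.array([0.0, 0.0, -1.0])
        up = np.array([0.0, 1.0, 0.0])
        if id != 1:
            tilt = 40.0 if id == 2 else -40.0
            r = _rot([1.0, 0.0, 0.0], tilt)
            d, up = r.apply(d), r.apply(up)
    else:
        d = np.array([-1.0, 0.0, 0.0])
        up = np.array([0.0, 0.0, 1.0])
        if id in (5, 6):
            # sagittal-plane tilt first: swing camera 30 deg to frontal/occipital
            tilt = -30.0 if id == 5 else 30.0
            r = _rot([0.0, 0.0, 1.0], tilt)
            d, up = r.apply(d), r.apply(up)
        d, up = _cranial_tilt(d, up, 30.0)
    return StandardView(id=id, direction=tuple(d), up=tuple(up))


def project_points(points: np.ndarray, view: StandardView) -> np.ndarray:
    """Orthographic (u, v) mm coordinates of (n, 3) world points."""
    p = np.atleast_2d(np.asarray(points, float))
    out = p @ view.frame().T
    return out[0] if np.asarray(points).ndim == 1 else out


def project_polylines(tree, view: StandardView) -> list[np.ndarray]:
    """Project 3D polylines into the view plane, preserving connectivity.

    ``tree`` may be a ``VeinTree`` (its branches are projected) or any
    iterable of (n, 3) point arrays.
    """
    if hasattr(tree, "branches"):
        polys = [np.asarray(b.points, float) for b in tree.branches]
    else:
        polys = [np.asarray(p, float) for p in tree]
    return [project_points(p, view) for p in polys]


def mip(volume, view: StandardView, pixel_size: float) -> ProjectionImage:
    """Orthographic maximum-intensity projection along the view direction.

    Every voxel centre is binned into the (right, up) pixel grid; each pixel
    takes the maximum value over the voxels it receives, independent of
    traversal order.
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    uv = project_points(volume.grid.all_voxel_centers(), view)
    vals = volume.values.reshape(-1)
    u0, v0 = uv.min(axis=0)
    iu = np.floor((uv[:, 0] - u0) / pixel_size).astype(int)
    iv = np.floor((uv[:, 1] - v0) / pixel_size).astype(int)
    nx, ny = iu.max() + 1, iv.max() + 1
    pixels = np.full((ny, nx), -np.inf)
    np.maximum.at(pixels, (iv, iu), vals)
    pixels[~np.isfinite(pixels)] = 0.0
    # row 0 at the top of the image = largest v
    pixels = pixels[::-1]
    return ProjectionImage(
        pixels=pixels, pixel_size=float(pixel_size), view=view,
        origin2d=(float(u0), float(v0)),
    )


def save_image(image: ProjectionImage | np.ndarray, path, view_id: int | None = None,
               pixel_size: float | None = None) -> None:
    """Write a projection (or any 2D scalar array) as 8-bit PNG + JSON sidecar.

    Pixel values are linearly rescaled to 0..255; the sidecar records the
    mm pixel size, view id and 2D origin so geometry survives the export.
    """
    import json
    from pathlib import Path
    from PIL import Image

    if isinstance(image, ProjectionImage):
        pixels, meta = image.pixels, {
            "pixel_size_mm": image.pixel_size,
            "view_id": image.view.id,
            "origin2d_mm": list(image.origin2d),
        }
    else:
        pixels = np.asarray(image, float)
        meta = {"pixel_size_mm": pixel_size, "view_id": view_id}
    lo, hi = float(pixels.min()), float(pixels.max())
    scaled = np.zeros_like(pixels) if hi == lo else (pixels - lo) / (hi - lo) * 255.0
    Image.fromarray(scaled.astype(np.uint8), mode="L").save(str(path))
    Path(str(path)).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def fit_similarity(landmarks_src: np.ndarray, landmarks_dst: np.ndarray) -> Similarity2D:
    """Least-squares 2D similarity mapping ``src`` landmarks onto ``dst``.

    Closed-form orthogonal-Procrustes-with-scale solution (no reflection);
    needs at least two non-coincident matched pairs.
    """
    src = np.atleast_2d(np.asarray(landmarks_src, float))
    dst = np.atleast_2d(np.asarray(landmarks_dst, float))
    if src.shape != dst.shape or src.shape[0] < 2 or src.shape[1] != 2:
        raise ValueError("need >= 2 matched 2D landmark pairs of equal count")
    if np.allclose(src, src[0]) or np.allclose(dst, dst[0]):
        raise ValueError("landmarks are all coincident")
    tf = SimilarityTransform.from_estimate(src, dst)
    if not tf:
        raise ValueError("similarity estimation failed (degenerate landmarks)")
    return Similarity2D(
        scale=float(tf.scale),
        rotation=float(np.rad2deg(tf.rotation)),
        translation=(float(tf.translation[0]), float(tf.translation[1])),
    )
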