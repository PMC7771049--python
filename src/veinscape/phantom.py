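"""Synthetic phantom generator: every input the pipeline consumes.

No patient data are distributed with this package, so a configurable
phantom stands in for them: a smooth head ellipsoid with a cortical shell
(structural volume), a midline superior-sagittal-sinus arc with bridging
veins rasterized as bright tubes into a TOF-like angiographic volume, and a
simulated, annotated surgical photograph.  The generator's defaults encode
the study conditions the measurements target:

* per-group confluence angles drawn from truncated normals with the
  reported group means and MADs (sigma = MAD * sqrt(pi/2) under normality),
  truncated to the per-group plausible ranges;
* per-(side, third) bridging-vein counts Poisson with means
  4.3/4.4/2.3 (left) and 4.1/4.5/2.0 (right);
* hemispheric drainage types with frequencies 9:3:3:3:1 (types I..V) among
  assessable hemispheres, with a 19/23 assessability probability;
* photographs with vein dropout, extra photo-only veins, artery
  confounders, occlusions and a 2D similarity misalignment, each mechanism
  mapping onto one validation category.

Veins are built so that the angle read in the perpendicular cranial view
(view 1) equals the sampled angle by construction: the terminal segment is
laid in the axial plane at the sampled angle to the projected sinus
tangent.  Ground truth is recorded alongside, so every downstream
measurement can be closed-loop tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .anatomy import (
    GROUPS,
    THIRDS,
    ANASTOMOTIC,
    BridgingJunction,
    SinusModel,
    VeinBranch,
    VeinTree,
)
from .projection import Similarity2D, StandardView, project_points, standard_view
from .registration import RigidParams, TrialSet
from .veinmatch import VeinMarkSet, SectionRecord, classify_sections
from .volumes import BinaryMask, Volume3D, VoxelGrid

__all__ = [
    "PhantomConfig",
    "PhotoConfig",
    "Phantom",
    "PhotoSample",
    "generate_phantom",
    "generate_registration_trials",
    "generate_photo",
    "align_photo_marks",
    "closed_loop_validate",
    "group_truncated_mean",
    "make_shell_mask",
]

# per-group angle means and MADs (degrees) and plausible ranges; the six
# positional groups run anterior -> posterior along the sinus
DEFAULT_ANGLE_MEANS = {
    "anterior frontal": 103.5,
    "medial frontal": 85.2,
    "posterior frontal": 69.5,
    "anterior parietal": 61.1,
    "posterior parietal": 47.0,
    "occipital": 39.3,
}
DEFAULT_ANGLE_MADS = {
    "anterior frontal": 14.5,
    "medial frontal": 10.3,
    "posterior frontal": 15.3,
    "anterior parietal": 11.9,
    "posterior parietal": 11.2,
    "occipital": 7.9,
}
DEFAULT_ANGLE_RANGES = {
    "anterior frontal": (55.0, 155.0),
    "medial frontal": (20.0, 160.0),
    "posterior frontal": (15.0, 105.0),
    "anterior parietal": (10.0, 95.0),
    "posterior parietal": (0.0, 90.0),
    "occipital": (0.0, 45.0),
}
# mean bridging-vein counts per (side, sinus third)
DEFAULT_COUNT_MEANS = {"L": (4.3, 4.4, 2.3), "R": (4.1, 4.5, 2.0)}
# drainage-type frequencies among assessable hemispheres
DEFAULT_DRAINAGE_FREQ = {"I": 9, "II": 3, "III": 3, "IV": 3, "V": 1}
DEFAULT_ASSESSABLE_PROB = 19.0 / 23.0

MAD_TO_SIGMA = float(np.sqrt(np.pi / 2.0))


@dataclass
class PhotoConfig:
    """Confounder mix for the simulated annotated photograph."""

    jitter_mm: float = 0.5          # tracing jitter on reconstruction marks
    dropout_rate: float = 0.15      # photo vein missing -> Category 2 truth
    n_extra_veins: int = 3          # photo-only veins -> Category 1 truth
    n_arteries: int = 2             # artery confounders -> Category 3 truth
    n_occlusions: int = 1           # occluded sections -> Category 4 truth
    artery_offset_mm: float = 0.6
    occlusion_pad_mm: float = 2.0
    n_landmarks: int = 8
    misalignment: Similarity2D = field(
        default_factory=lambda: Similarity2D(scale=1.1, rotation=5.0, translation=(4.0, -3.0))
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout rate must be in [0, 1]")
        if self.jitter_mm < 0:
            raise ValueError("jitter must be non-negative")


@dataclass
class PhantomConfig:
    """Geometry, intensity and distribution parameters of the phantom."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    head_radii_mm: tuple[float, float, float] = (60.0, 75.0, 60.0)
    shell_thickness_mm: float = 4.0
    sinus_radius_mm: float = 3.0
    vessel_radius_range_mm: tuple[float, float] = (0.8, 2.0)
    vessel_intensity: float = 100.0
    head_intensity: float = 60.0
    shell_intensity: float = 80.0
    noise_sigma: float = 5.0
    recommended_threshold: float = 50.0
    angle_means: dict = field(default_factory=lambda: dict(DEFAULT_ANGLE_MEANS))
    angle_mads: dict = field(default_factory=lambda: dict(DEFAULT_ANGLE_MADS))
    angle_ranges: dict = field(default_factory=lambda: dict(DEFAULT_ANGLE_RANGES))
    count_means: dict = field(default_factory=lambda: dict(DEFAULT_COUNT_MEANS))
    fixed_counts: dict | None = None  # {"L": (n,n,n), "R": (n,n,n)} overrides Poisson
    drainage_freq: dict = field(default_factory=lambda: dict(DEFAULT_DRAINAGE_FREQ))
    assessable_prob: float = DEFAULT_ASSESSABLE_PROB
    photo: PhotoConfig = field(default_factory=PhotoConfig)
    rasterize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.assessable_prob <= 1.0):
            raise ValueError("assessable probability must be in [0, 1]")
        for g in GROUPS:
            lo, hi = self.angle_ranges[g]
            if not (lo < hi):
                raise ValueError(f"empty angle range for group {g!r}")
            if self.angle_means[g] <= 0 or self.angle_mads[g] < 0:
                raise ValueError(f"invalid angle mean/MAD for group {g!r}")
        for side in ("L", "R"):
            if any(m < 0 for m in self.count_means[side]):
                raise ValueError("count means must be non-negative")

    def grid(self) -> VoxelGrid:
        shape = self.grid_shape
        spacing = self.spacing_mm
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return VoxelGrid(shape=shape, spacing=spacing, origin=origin)


@dataclass
class PhantomTruth:
    """Ground truth recorded by the generator, for closed-loop testing."""

    angle_records: list  # (group, angle_deg, side)
    counts: dict         # {"L": (f, m, o), "R": (f, m, o)}
    drainage: dict       # hemisphere -> type str or None (unassessable)
    gold_registration: RigidParams
    recommended_threshold: float


@dataclass
class Phantom:
    structural: Volume3D | None
    angiographic: Volume3D | None
    cortex_mask: BinaryMask | None
    sinus: SinusModel
    tree: VeinTree
    truth: PhantomTruth
    config: PhantomConfig


@dataclass
class PhotoSample:
    """Simulated annotated photograph plus the matching reconstruction marks."""

    photo_image: np.ndarray
    recon_marks: VeinMarkSet     # reconstruction frame (view plane, mm)
    photo_marks: VeinMarkSet     # photo frame (misaligned)
    landmarks_recon: np.ndarray  # (k, 2) matched landmark pairs
    landmarks_photo: np.ndarray
    truth_categories: list[SectionRecord]
    misalignment: Similarity2D
    view: StandardView


def load_config(path) -> PhantomConfig:
    """Load a :class:`PhantomConfig` from a YAML or JSON file.

    Top-level keys mirror the dataclass fields; a nested ``photo`` mapping
    populates :class:`PhotoConfig`, whose ``misalignment`` may be given as
    ``{scale, rotation, translation}``.
    """
    import json
    from pathlib import Path

    import yaml

    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if "photo" in data:
        photo = dict(data["photo"])
        if "misalignment" in photo:
            m = photo["misalignment"]
            photo["misalignment"] = Similarity2D(
                scale=m["scale"], rotation=m["rotation"],
                translation=tuple(m["translation"]),
            )
        data["photo"] = PhotoConfig(**photo)
    for key in ("grid_shape", "spacing_mm", "head_radii_mm", "vessel_radius_range_mm"):
        if key in data:
            data[key] = tuple(data[key])
    return PhantomConfig(**data)


def group_truncated_mean(config: PhantomConfig, group: str) -> float:
    """Analytic mean of the group's truncated-normal angle distribution."""
    mu = config.angle_means[group]
    sigma = config.angle_mads[group] * MAD_TO_SIGMA
    lo, hi = config.angle_ranges[group]
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return float(stats.truncnorm.mean(a, b, loc=mu, scale=sigma))


def make_shell_mask(
    grid: VoxelGrid,
    radii_mm: tuple[float, float, float] = (60.0, 75.0, 60.0),
    thickness_mm: float = 4.0,
) -> BinaryMask:
    """Ellipsoidal-shell cortex mask (the PET-derived cortex stand-in)."""
    centers = grid.all_voxel_centers()
    r = np.asarray(radii_mm)
    rho = np.linalg.norm(centers / r, axis=1)
    inner = 1.0 - thickness_mm / float(np.min(r))
    included = (rho <= 1.0) & (rho >= inner)
    return BinaryMask(grid, included.reshape(grid.shape))


def _sinus_centerline(config: PhantomConfig, n_points: int = 80) -> np.ndarray:
    """Midline sagittal arc just beneath the head surface, anterior -> posterior."""
    _, ry, rz = config.head_radii_mm
    inset = config.sinus_radius_mm + 1.0
    theta = np.linspace(np.deg2rad(25.0), np.deg2rad(155.0), n_points)
    y = (ry - inset) * np.cos(theta)   # +y anterior at theta=25 deg
    z = (rz - inset) * np.sin(theta)
    return np.column_stack([np.zeros_like(y), y, z])


def _group_of_fraction(frac: float) -> str:
    return GROUPS[min(int(frac * 6.0), 5)]


def _make_vein_branch(
    sinus: SinusModel,
    arc_pos: float,
    angle_deg: float,
    side: str,
    rng: np.random.Generator,
) -> VeinBranch:
    """Vein whose view-1 projected confluence angle equals ``angle_deg``.

    The terminal segment lies in the axial (view-1) plane, at the sampled
    angle to the axially projected posterior sinus tangent, pointing to the
    vein's hemisphere; a second, descending segment drapes the vein over
    the cortex laterally.
    """
    p0 = sinus.point_at(arc_pos)
    t = sinus.tangent_at(arc_pos)
    t2 = np.array([t[0], t[1]])  # axial projection (x, y)
    t2 = t2 / np.linalg.norm(t2)
    n2 = np.array([-t2[1], t2[0]])
    if (side == "L" and n2[0] > 0) or (side == "R" and n2[0] < 0):
        n2 = -n2
    a = np.deg2rad(angle_deg)
    d2 = np.cos(a) * t2 + np.sin(a) * n2
    d3 = np.array([d2[0], d2[1], 0.0])
    l1 = 10.0
    p1 = p0 + l1 * d3
    drop = np.array([d3[0], d3[1], -0.75])
    drop /= np.linalg.norm(drop)
    l2 = rng.uniform(8.0, 20.0)
    p2 = p1 + l2 * drop
    return VeinBranch(points=np.array([p0, p1, p2]))


def _sample_calibers(dtype: str, rng: np.random.Generator) -> dict[str, float]:
    """Anastomotic calibers (mm) realizing one drainage type."""
    base = rng.uniform(2.0, 3.0)
    if dtype == "I":
        c = base * rng.uniform(0.9, 1.1, size=3)
    elif dtype in ("II", "III", "IV"):
        c = base * rng.uniform(0.8, 1.0, size=3)
        c[("II", "III", "IV").index(dtype)] = base * rng.uniform(1.6, 2.2)
    else:  # V: one vein absent, the other two co-dominant
        c = base * rng.uniform(0.9, 1.1, size=3)
        c[rng.integers(0, 3)] = rng.uniform(0.0, 0.25)
    return {name: float(v) for name, v in zip(ANASTOMOTIC, c)}


def _rasterize_tube(
    values: np.ndarray, grid: VoxelGrid, polyline: np.ndarray,
    radius_mm: float, intensity: float,
) -> None:
    """Stamp a tube of the given radius along a polyline into ``values``."""
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    # dense enough that every voxel the centreline passes through is stamped,
    # even for sub-voxel vessel radii
    step = float(spacing.min()) / 4.0
    # resample the centreline densely
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(arc[-1] / step)) + 1, 2)
    s = np.linspace(0.0, arc[-1], n)
    pts = np.column_stack([np.interp(s, arc, polyline[:, i]) for i in range(3)])
    # ball stamp in voxel offsets
    r_vox = np.ceil(radius_mm / spacing).astype(int)
    offs = np.mgrid[-r_vox[0]:r_vox[0] + 1,
                    -r_vox[1]:r_vox[1] + 1,
                    -r_vox[2]:r_vox[2] + 1].reshape(3, -1).T
    keep = np.linalg.norm(offs * spacing, axis=1) <= radius_mm
    offs = offs[keep]
    idx = np.rint((pts - origin) / spacing).astype(int)
    all_idx = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    shape = np.asarray(grid.shape)
    ok = np.all((all_idx >= 0) & (all_idx < shape), axis=1)
    all_idx = all_idx[ok]
    values[all_idx[:, 0], all_idx[:, 1], all_idx[:, 2]] = intensity


def generate_phantom(config: PhantomConfig | None = None, seed: int | None = None) -> Phantom:
    """Generate a full phantom; deterministic given the config seed.

    With ``config.rasterize`` false only the geometry (sinus, vein tree,
    truth) is built, which is orders of magnitude faster and sufficient for
    the anatomy measurements.
    """
    config = config or PhantomConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    sinus = SinusModel(_sinus_centerline(config))
    L = sinus.arc_length
    bounds = (0.0, L / 3.0, 2.0 * L / 3.0, L)

    branches: list[VeinBranch] = []
    junctions: list[BridgingJunction] = []
    angle_records = []
    counts = {}
    radius_lo, radius_hi = config.vessel_radius_range_mm
    for side in ("L", "R"):
        side_counts = []
        for k, third in enumerate(THIRDS):
            if config.fixed_counts is not None:
                n = int(config.fixed_counts[side][k])
            else:
                n = int(rng.poisson(config.count_means[side][k]))
            side_counts.append(n)
            for _ in range(n):
                arc = rng.uniform(bounds[k], bounds[k + 1])
                group = _group_of_fraction(arc / L)
                mu = config.angle_means[group]
                sigma = config.angle_mads[group] * MAD_TO_SIGMA
                lo, hi = config.angle_ranges[group]
                angle = float(stats.truncnorm.rvs(
                    (lo - mu) / sigma, (hi - mu) / sigma,
                    loc=mu, scale=sigma, random_state=rng,
                ))
                branch = _make_vein_branch(sinus, arc, angle, side, rng)
                branch.radius_mm = float(rng.uniform(radius_lo, radius_hi))
                junctions.append(BridgingJunction(
                    branch_index=len(branches), arc_position_mm=arc,
                    side=side, group=group,
                ))
                branches.append(branch)
                angle_records.append((group, angle, side))
        counts[side] = tuple(side_counts)

    drainage: dict[str, str | None] = {}
    calibers: dict[str, dict[str, float]] = {}
    type_names = list(config.drainage_freq)
    type_p = np.array([config.drainage_freq[t] for t in type_names], float)
    type_p /= type_p.sum()
    for side in ("L", "R"):
        if rng.uniform() < config.assessable_prob:
            dtype = type_names[rng.choice(len(type_names), p=type_p)]
            drainage[side] = dtype
            calibers[side] = _sample_calibers(dtype, rng)
        else:
            drainage[side] = None

    tree = VeinTree(branches=branches, junctions=junctions, anastomotic_calibers=calibers)
    truth = PhantomTruth(
        angle_records=angle_records,
        counts=counts,
        drainage=drainage,
        gold_registration=RigidParams(),
        recommended_threshold=config.recommended_threshold,
    )

    structural = angiographic = cortex_mask = None
    if config.rasterize:
        centers = grid.all_voxel_centers()
        r = np.asarray(config.head_radii_mm)
        rho = np.linalg.norm(centers / r, axis=1).reshape(grid.shape)
        inner = 1.0 - config.shell_thickness_mm / float(r.min())
        svals = np.zeros(grid.shape)
        svals[rho <= 1.0] = config.head_intensity
        shell = (rho <= 1.0) & (rho >= inner)
        svals[shell] = config.shell_intensity
        svals += rng.normal(0.0, config.noise_sigma, grid.shape)
        structural = Volume3D(grid, svals, modality="structural")
        cortex_mask = BinaryMask(grid, shell)

        avals = np.zeros(grid.shape)
        _rasterize_tube(avals, grid, sinus.centerline,
                        config.sinus_radius_mm, config.vessel_intensity)
        for b in branches:
            _rasterize_tube(avals, grid, b.points, b.radius_mm, config.vessel_intensity)
        avals += rng.normal(0.0, config.noise_sigma, grid.shape)
        angiographic = Volume3D(grid, avals, modality="angiographic")

    return Phantom(
        structural=structural, angiographic=angiographic, cortex_mask=cortex_mask,
        sinus=sinus, tree=tree, truth=truth, config=config,
    )


def generate_registration_trials(
    gold: RigidParams,
    sigma_t: float,
    sigma_r: float,
    n: int = 10,
    seed: int = 0,
    label: str = "phantom",
) -> TrialSet:
    """i.i.d. Gaussian perturbations of the gold pose (repeated registrations)."""
    if sigma_t < 0 or sigma_r < 0:
        raise ValueError("perturbation sigmas must be non-negative")
    if n < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    g = gold.as_array()
    trials = []
    for _ in range(n):
        p = g.copy()
        p[:3] += rng.normal(0.0, sigma_t, 3)
        p[3:] += rng.normal(0.0, sigma_r, 3)
        trials.append(RigidParams.from_array(p))
    return TrialSet(label=label, trials=trials)


def _offset_polyline(poly: np.ndarray, offset_mm: float, rng: np.random.Generator) -> np.ndarray:
    d = np.diff(poly, axis=0).mean(axis=0)
    n = np.array([-d[1], d[0]])
    norm = np.linalg.norm(n)
    if norm == 0:
        n = np.array([1.0, 0.0])
        norm = 1.0
    sign = 1.0 if rng.uniform() < 0.5 else -1.0
    return poly + sign * offset_mm * n / norm


def _occlusion_polygon(poly: np.ndarray, pad_mm: float) -> np.ndarray:
    import shapely

    line = shapely.LineString(poly)
    return np.asarray(shapely.Polygon(line.buffer(pad_mm).exterior).exterior.coords)


def _render_marks(sections: list[np.ndarray], pixel_size: float = 0.5) -> np.ndarray:
    """Simple grayscale rendering of traces (dark on light), for the PNG."""
    if not sections:
        return np.full((16, 16), 200.0)
    allpts = np.vstack(sections)
    lo = allpts.min(axis=0) - 5.0
    hi = allpts.max(axis=0) + 5.0
    nx = int(np.ceil((hi[0] - lo[0]) / pixel_size)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / pixel_size)) + 1
    img = np.full((ny, nx), 200.0)
    from .veinmatch import resample_polyline

    for s in sections:
        pts = resample_polyline(s, pixel_size / 2.0)
        ix = np.floor((pts[:, 0] - lo[0]) / pixel_size).astype(int)
        iy = np.floor((pts[:, 1] - lo[1]) / pixel_size).astype(int)
        img[ny - 1 - iy, ix] = 50.0
    return img


def generate_photo(
    phantom: Phantom,
    view: StandardView | int = 1,
    config: PhotoConfig | None = None,
    seed: int = 0,
) -> PhotoSample:
    """Simulate an annotated surgical photograph for one view.

    Reconstruction marks are the projected vein polylines plus i.i.d.
    Gaussian vertex jitter.  Photo marks start from the exact projections;
    confounders then remove a dropout fraction (truth Category 2 for the
    reconstruction counterparts), add photo-only veins (Category 1),
    replace some veins by nearby artery traces (Category 3), and occlude
    others (Category 4); everything photo-side is finally mapped through
    the configured misalignment similarity.  Matched landmark pairs are
    emitted for re-alignment, and a ground-truth category per section.
    """
    if isinstance(view, int):
        view = standard_view(view)
    config = config or phantom.config.photo
    rng = np.random.default_rng(seed)

    base = [project_points(b.points, view) for b in phantom.tree.branches]
    n = len(base)
    recon_sections = [
        p + rng.normal(0.0, config.jitter_mm, p.shape) for p in base
    ]

    order = rng.permutation(n)
    artery_idx = set(order[: config.n_arteries])
    occl_idx = set(order[config.n_arteries: config.n_arteries + config.n_occlusions])
    rest = [i for i in order[config.n_arteries + config.n_occlusions:]]
    drop_idx = {i for i in rest if rng.uniform() < config.dropout_rate}

    photo_sections: list[np.ndarray] = []
    photo_kinds: list[str] = []
    occlusions: list[np.ndarray] = []
    truth: list[SectionRecord] = []
    for i in range(n):
        if i in artery_idx:
            photo_sections.append(_offset_polyline(base[i], config.artery_offset_mm, rng))
            photo_kinds.append("artery")
            truth.append(SectionRecord(category=3, recon_index=i))
        elif i in occl_idx:
            occlusions.append(_occlusion_polygon(base[i], config.occlusion_pad_mm))
            truth.append(SectionRecord(category=4, recon_index=i))
        elif i in drop_idx:
            truth.append(SectionRecord(category=2, recon_index=i))
        else:
            truth.append(SectionRecord(category=0, recon_index=i,
                                       photo_index=len(photo_sections)))
            photo_sections.append(base[i].copy())
            photo_kinds.append("vein")

    # photo-only veins, placed outside the projected head footprint
    if n:
        allpts = np.vstack(base)
        u_max, v_min = allpts[:, 0].max(), allpts[:, 1].min()
    else:
        u_max, v_min = 0.0, 0.0
    for k in range(config.n_extra_veins):
        u = u_max + 15.0 + 8.0 * k
        extra = np.array([[u, v_min], [u + 2.0, v_min + 18.0]])
        truth.append(SectionRecord(category=1, photo_index=len(photo_sections)))
        photo_sections.append(extra)
        photo_kinds.append("vein")

    # matched landmarks from the endpoints of unconfounded veins
    clean = [r.recon_index for r in truth if r.category == 0][: max(config.n_landmarks // 2, 2)]
    lm = []
    for i in clean:
        lm.append(base[i][0])
        lm.append(base[i][-1])
    landmarks_recon = np.array(lm) if lm else np.zeros((0, 2))

    mis = config.misalignment
    photo_sections = [mis.apply(s) for s in photo_sections]
    occlusions = [mis.apply(o) for o in occlusions]
    landmarks_photo = mis.apply(landmarks_recon) if len(landmarks_recon) else landmarks_recon

    recon_marks = VeinMarkSet(source="reconstruction", sections=recon_sections)
    photo_marks = VeinMarkSet(
        source="photo", sections=photo_sections, kinds=photo_kinds,
        occluded_regions=occlusions,
    )
    image = _render_marks(photo_sections)
    return PhotoSample(
        photo_image=image, recon_marks=recon_marks, photo_marks=photo_marks,
        landmarks_recon=landmarks_recon, landmarks_photo=landmarks_photo,
        truth_categories=truth, misalignment=mis, view=view,
    )


def align_photo_marks(sample: PhotoSample) -> VeinMarkSet:
    """Map the photo marks into the reconstruction frame.

    Fits the 2D similarity from the matched landmarks (the rotate-and-scale
    alignment step) and applies it to the photo traces and occlusion
    polygons.
    """
    from .projection import fit_similarity

    sim = fit_similarity(sample.landmarks_photo, sample.landmarks_recon)
    return VeinMarkSet(
        source="photo",
        sections=[sim.apply(s) for s in sample.photo_marks.sections],
        kinds=list(sample.photo_marks.kinds),
        occluded_regions=[sim.apply(p) for p in sample.photo_marks.occluded_regions],
    )


def closed_loop_validate(sample: PhotoSample, tol: float) -> tuple[list[SectionRecord], float]:
    """Run the category pipeline on a photo sample and score it against truth.

    Returns the classifier's section records and the fraction of
    ground-truth sections that received their true category.
    """
    aligned = align_photo_marks(sample) if len(sample.landmarks_recon) else sample.photo_marks
    records = classify_sections(sample.recon_marks, aligned, tol=tol)
    by_recon = {r.recon_index: r.category for r in records if r.recon_index is not None}
    by_photo = {r.photo_index: r.category for r in records if r.photo_index is not None
                and r.recon_index is None}
    hits = 0
    for t in sample.truth_categories:
        if t.category == 1:
            got = by_photo.get(t.photo_index)
        else:
            got = by_recon.get(t.recon_index)
        hits += int(got == t.category)
    return records, hits / len(sample.truth_categories)
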