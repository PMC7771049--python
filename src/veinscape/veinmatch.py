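"""Five-category validation of the vein reconstruction against a photograph.

Every marked vein section — a short 2D polyline traced either on the
rendered reconstruction or on the (aligned) surgical-site photograph — is
assigned one of five categories:

========  =====================================================
Category  Meaning
========  =====================================================
0         vein in photo and reconstruction correspond (true positive)
1         vein in photo only (false negative)
2         vein in reconstruction only (false positive)
3         reconstruction "vein" is an artery in the photo (false positive)
4         reconstruction vein not assessable in the photo (covered/occluded)
========  =====================================================

Correspondence is decided by the mean symmetric polyline distance (both
traces resampled at 0.5 mm arc-length steps, directed mean nearest-point
distances averaged both ways), with greedy one-to-one matching in ascending
distance; a matched pair counts once, as a single Category-0 section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree

__all__ = [
    "VeinMarkSet",
    "CategorySummary",
    "SectionRecord",
    "resample_polyline",
    "polyline_distance",
    "classify_sections",
    "summarize",
]

RESAMPLE_STEP_MM = 0.5
DEFAULT_TOL_MM = 3.0


@dataclass
class VeinMarkSet:
    """Marked 2D vein (and artery) sections in the common aligned frame."""

    source: str  # "reconstruction" or "photo"
    sections: list[np.ndarray]  # each (n >= 2, 2) polyline, mm
    kinds: list[str] | None = None  # per-section "vein" / "artery"
    occluded_regions: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source not in ("reconstruction", "photo"):
            raise ValueError(f"unknown mark source {self.source!r}")
        self.sections = [np.asarray(s, dtype=float) for s in self.sections]
        for s in self.sections:
            if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 2:
                raise ValueError("each section must be an (n>=2, 2) polyline")
        if self.kinds is None:
            self.kinds = ["vein"] * len(self.sections)
        if len(self.kinds) != len(self.sections):
            raise ValueError("kinds must match sections one-to-one")
        if self.source == "reconstruction" and any(k == "artery" for k in self.kinds):
            raise ValueError("artery marks are only allowed in photo sets")
        self.occluded_regions = [np.asarray(p, dtype=float) for p in self.occluded_regions]

    def vein_indices(self) -> list[int]:
        return [i for i, k in enumerate(self.kinds) if k == "vein"]

    def artery_indices(self) -> list[int]:
        return [i for i, k in enumerate(self.kinds) if k == "artery"]


@dataclass(frozen=True)
class SectionRecord:
    """Category assignment of one validated section."""

    category: int
    recon_index: int | None = None
    photo_index: int | None = None


@dataclass
class CategorySummary:
    """Counts and one-decimal percentages per category, plus derived totals."""

    n0: int
    n1: int
    n2: int
    n3: int
    n4: int
    total: int = field(init=False)
    percentages: tuple[float, ...] = field(init=False)
    photo_visible: int = field(init=False)
    recon_visible: int = field(init=False)

    def __post_init__(self) -> None:
        counts = (self.n0, self.n1, self.n2, self.n3, self.n4)
        self.total = int(sum(counts))
        if self.total == 0:
            raise ValueError("cannot summarize zero sections")
        self.percentages = tuple(round(100.0 * c / self.total, 1) for c in counts)
        self.photo_visible = self.n0 + self.n1
        self.recon_visible = self.n0 + self.n2 + self.n3 + self.n4

    def as_dict(self) -> dict:
        return {
            "counts": [self.n0, self.n1, self.n2, self.n3, self.n4],
            "percentages": list(self.percentages),
            "total": self.total,
            "photo_visible": self.photo_visible,
            "recon_visible": self.recon_visible,
        }


def resample_polyline(poly: np.ndarray, step: float = RESAMPLE_STEP_MM) -> np.ndarray:
    """Resample a polyline at fixed arc-length steps (endpoints included)."""
    poly = np.asarray(poly, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return poly[:1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, arc, poly[:, 0])
    y = np.interp(s, arc, poly[:, 1])
    return np.column_stack([x, y])


def polyline_distance(a: np.ndarray, b: np.ndarray, step: float = RESAMPLE_STEP_MM) -> float:
    """Mean symmetric distance between two polylines (mm).

    Average of the two directed mean nearest-point distances over the
    resampled traces; exactly zero for coincident traces.
    """
    pa = resample_polyline(a, step)
    pb = resample_polyline(b, step)
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float(0.5 * (d_ab + d_ba))


def _occluded_fraction(section: np.ndarray, regions: list[np.ndarray]) -> float:
    if not regions:
        return 0.0
    pts = resample_polyline(section)
    polys = shapely.MultiPolygon([shapely.Polygon(r) for r in regions])
    inside = shapely.contains_xy(polys, pts[:, 0], pts[:, 1])
    return float(np.mean(inside))


def classify_sections(
    recon: VeinMarkSet,
    photo: VeinMarkSet,
    tol: float = DEFAULT_TOL_MM,
) -> list[SectionRecord]:
    """Assign every marked section to one of Categories 0-4.

    Both mark sets must already live in the common aligned frame (the
    photograph mapped through the fitted similarity).  Matching is greedy
    one-to-one over recon-vein x photo-vein pairs in ascending mean
    symmetric distance, ties broken by lower section index; only pairs with
    distance <= ``tol`` are accepted (Category 0, counted once).  Leftover
    photo veins are Category 1.  Leftover reconstruction sections are
    Category 3 if within ``tol`` of a photo artery trace, Category 4 if at
    least half their arc length lies inside an occluded region of the photo,
    and Category 2 otherwise.
    """
    if tol <= 0:
        raise ValueError("matching tolerance must be positive")
    r_idx = recon.vein_indices()
    p_idx = photo.vein_indices()
    pairs = []
    for i in r_idx:
        for j in p_idx:
            d = polyline_distance(recon.sections[i], photo.sections[j])
            if d <= tol:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    records: list[SectionRecord] = []
    used_r: set[int] = set()
    used_p: set[int] = set()
    for d, i, j in pairs:
        if i in used_r or j in used_p:
            continue
        used_r.add(i)
        used_p.add(j)
        records.append(SectionRecord(category=0, recon_index=i, photo_index=j))

    for j in p_idx:
        if j not in used_p:
            records.append(SectionRecord(category=1, photo_index=j))

    artery_idx = photo.artery_indices()
    for i in r_idx:
        if i in used_r:
            continue
        if any(
            polyline_distance(recon.sections[i], photo.sections[j]) <= tol
            for j in artery_idx
        ):
            records.append(SectionRecord(category=3, recon_index=i))
        elif _occluded_fraction(recon.sections[i], photo.occluded_regions) >= 0.5:
            records.append(SectionRecord(category=4, recon_index=i))
        else:
            records.append(SectionRecord(category=2, recon_index=i))
    return records


def summarize(categories=None, *, counts=None) -> CategorySummary:
    """Counts and percentages over categorized sections.

    Pass either ``categories`` (a list of :class:`SectionRecord` or raw
    category integers, one per validated section) or ``counts`` (the five
    per-category totals directly).
    """
    if (categories is None) == (counts is None):
        raise ValueError("pass exactly one of categories or counts")
    if counts is not None:
        counts = [int(c) for c in counts]
        if len(counts) != 5 or any(c < 0 for c in counts):
            raise ValueError("counts must be five non-negative integers")
        return CategorySummary(*counts)
    cats = list(categories)
    if len(cats) == 0:
        raise ValueError("cannot summarize an empty category list")
    values = [c.category if isinstance(c, SectionRecord) else int(c) for c in cats]
    if any(v not in range(5) for v in values):
        raise ValueError("categories must be integers 0..4")
    return CategorySummary(*[values.count(k) for k in range(5)])
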