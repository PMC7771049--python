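"""Bridging-vein anatomy measurements on a vein tree + sinus model.

The superior sagittal sinus (SSS) is modelled as an ordered anterior ->
posterior centreline polyline; bridging veins are polyline branches whose
first node sits at their junction with the sinus, each carrying a caliber,
a side (left/right hemisphere) and a positional group tag.  Three families
of measurements are produced:

* bridging-vein counts per sinus third (frontal / middle / occipital) and
  side, with half-open arc-length intervals [0, L/3), [L/3, 2L/3), [2L/3, L];
* confluence angles: the planar angle, in one of the cranial projection
  views, between the vein's terminal direction (pointing from the junction
  away from the sinus, along the vein) and the posteriorly oriented local
  sinus tangent — obtuse for frontopolar veins (~110 deg), acute for
  occipital ones (~10-40 deg); summarised per positional group by mean and
  mean absolute deviation (MAD);
* a drainage type per hemisphere from the caliber ranking of the three
  large anastomotic veins (Trolard, Labbe, superficial Sylvian).  The
  type I-V rule table used here is an explicit parameterized stand-in for
  the published classification, not a reproduction of it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import StandardView, project_points

__all__ = [
    "GROUPS",
    "THIRDS",
    "ANASTOMOTIC",
    "SinusModel",
    "VeinBranch",
    "BridgingJunction",
    "VeinTree",
    "GroupStats",
    "DrainageProfile",
    "count_bridging_veins",
    "terminal_direction",
    "confluence_angle",
    "confluence_angle_3d",
    "measure_confluence_angles",
    "group_angle_stats",
    "classify_drainage",
    "save_tree",
    "load_tree",
]

GROUPS = (
    "anterior frontal",
    "medial frontal",
    "posterior frontal",
    "anterior parietal",
    "posterior parietal",
    "occipital",
)
THIRDS = ("frontal", "middle", "occipital")
ANASTOMOTIC = ("trolard", "labbe", "sylvian")

TERMINAL_WINDOW_MM = 5.0


@dataclass
class SinusModel:
    """SSS centreline, anterior -> posterior, with arc-length thirds."""

    centerline: np.ndarray  # (m >= 2, 3) mm

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape != (self.centerline.shape[0], 3) \
                or self.centerline.shape[0] < 2:
            raise ValueError("sinus centreline needs >= 2 3D points")
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        self._arc = np.concatenate([[0.0], np.cumsum(seg)])
        if self._arc[-1] <= 0:
            raise ValueError("sinus centreline has zero length")

    @property
    def arc_length(self) -> float:
        return float(self._arc[-1])

    @property
    def third_boundaries(self) -> tuple[float, float]:
        L = self.arc_length
        return (L / 3.0, 2.0 * L / 3.0)

    def point_at(self, s: float) -> np.ndarray:
        """Centreline point at arc-length position ``s`` (mm)."""
        s = float(np.clip(s, 0.0, self.arc_length))
        return np.array([np.interp(s, self._arc, self.centerline[:, i]) for i in range(3)])

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent at arc position ``s``, oriented posteriorly."""
        eps = min(1.0, 0.25 * self.arc_length)
        a = self.point_at(max(0.0, s - eps))
        b = self.point_at(min(self.arc_length, s + eps))
        t = b - a
        norm = np.linalg.norm(t)
        if norm == 0:
            raise ValueError("degenerate sinus tangent")
        return t / norm

    def third_of(self, s: float) -> str:
        """Sinus third of an arc position, half-open boundary rule."""
        if not (0.0 <= s <= self.arc_length):
            raise ValueError(f"arc position {s} outside [0, {self.arc_length}]")
        b1, b2 = self.third_boundaries
        if s < b1:
            return "frontal"
        if s < b2:
            return "middle"
        return "occipital"


@dataclass
class VeinBranch:
    """One vein centreline; ``points[0]`` is the sinus-junction end."""

    points: np.ndarray  # (n >= 2, 3) mm
    radius_mm: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or self.points.shape[0] < 2:
            raise ValueError("vein branch needs >= 2 3D points")
        if self.radius_mm <= 0:
            raise ValueError("vein radius must be positive")


@dataclass(frozen=True)
class BridgingJunction:
    """Junction of one bridging vein with the sinus."""

    branch_index: int
    arc_position_mm: float
    side: str  # "L" / "R"
    group: str

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class VeinTree:
    """Bridging-vein branches plus per-hemisphere anastomotic calibers."""

    branches: list[VeinBranch]
    junctions: list[BridgingJunction] = field(default_factory=list)
    anastomotic_calibers: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for j in self.junctions:
            if not (0 <= j.branch_index < len(self.branches)):
                raise ValueError(f"junction branch index {j.branch_index} out of range")


@dataclass(frozen=True)
class GroupStats:
    """Per-group confluence-angle summary: n, mean, MAD (degrees)."""

    group: str
    n: int
    mean_deg: float
    mad_deg: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group stats need n >= 1")
        if self.mad_deg < 0:
            raise ValueError("MAD cannot be negative")


@dataclass(frozen=True)
class DrainageProfile:
    hemisphere: str
    assessable: bool
    type: str | None = None  # "I".."V" when assessable

    def __post_init__(self) -> None:
        if self.assessable and self.type not in ("I", "II", "III", "IV", "V"):
            raise ValueError("assessable profile needs a type I..V")
        if not self.assessable and self.type is not None:
            raise ValueError("unassessable profile cannot carry a type")


def count_bridging_veins(tree: VeinTree, sinus: SinusModel) -> pd.DataFrame:
    """2x3 bridging-vein count table (side x sinus third) with totals.

    Each junction is assigned by its arc-length position with the half-open
    interval rule; the ``total`` column is the row sum by construction.
    """
    counts = {side: {third: 0 for third in THIRDS} for side in ("L", "R")}
    for j in tree.junctions:
        counts[j.side][sinus.third_of(j.arc_position_mm)] += 1
    df = pd.DataFrame(counts).T.loc[["L", "R"], list(THIRDS)]
    df["total"] = df.sum(axis=1)
    return df


def terminal_direction(branch: VeinBranch, window_mm: float = TERMINAL_WINDOW_MM) -> np.ndarray:
    """Unit direction from the junction into the vein (away from the sinus).

    Estimated from the first ``window_mm`` of arc length of the branch
    centreline to damp tracing noise.
    """
    pts = branch.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    k = int(np.searchsorted(arc, window_mm))
    k = min(max(k, 1), len(pts) - 1)
    d = pts[k] - pts[0]
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("degenerate vein terminal segment")
    return d / norm


def _planar_angle(a2: np.ndarray, b2: np.ndarray) -> float:
    na, nb = np.linalg.norm(a2), np.linalg.norm(b2)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("direction projects to a point in this view")
    cosang = np.clip((a2 @ b2) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def confluence_angle(
    tree: VeinTree,
    junction: BridgingJunction,
    sinus: SinusModel,
    view: StandardView,
) -> float:
    """Projected confluence angle (degrees, [0, 180]) in a cranial view.

    Angle between the vein's terminal direction and the posteriorly oriented
    sinus tangent, both projected orthographically into the view plane.
    """
    vein_dir = terminal_direction(tree.branches[junction.branch_index])
    tangent = sinus.tangent_at(junction.arc_position_mm)
    return _planar_angle(project_points(vein_dir, view), project_points(tangent, view))


def confluence_angle_3d(
    tree: VeinTree, junction: BridgingJunction, sinus: SinusModel
) -> float:
    """Unprojected 3D confluence angle (degrees), for comparison."""
    vein_dir = terminal_direction(tree.branches[junction.branch_index])
    tangent = sinus.tangent_at(junction.arc_position_mm)
    cosang = np.clip(vein_dir @ tangent, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def measure_confluence_angles(
    tree: VeinTree,
    sinus: SinusModel,
    view: StandardView,
    max_per_group: int | None = 2,
) -> list[tuple[str, float]]:
    """(group, angle) records, keeping up to the 2 largest-caliber veins per group.

    Mirrors the sampling rule of measuring (where possible) two veins per
    positional group per subject; pass ``max_per_group=None`` to measure all.
    """
    by_group: dict[str, list[tuple[float, BridgingJunction]]] = {g: [] for g in GROUPS}
    for j in tree.junctions:
        by_group[j.group].append((tree.branches[j.branch_index].radius_mm, j))
    records = []
    for g in GROUPS:
        cand = sorted(by_group[g], key=lambda t: -t[0])
        if max_per_group is not None:
            cand = cand[:max_per_group]
        for _, j in cand:
            records.append((g, confluence_angle(tree, j, sinus, view)))
    return records


def group_angle_stats(records: list[tuple[str, float]]) -> dict[str, GroupStats]:
    """Mean and MAD of confluence angles per positional group.

    MAD is the mean absolute deviation (1/n) sum |x_i - mean|.  Groups with
    no records are excluded with a warning.
    """
    out: dict[str, GroupStats] = {}
    for g in GROUPS:
        vals = np.array([a for grp, a in records if grp == g], dtype=float)
        if vals.size == 0:
            warnings.warn(f"no confluence-angle records for group {g!r}", stacklevel=2)
            continue
        mean = float(vals.mean())
        out[g] = GroupStats(
            group=g, n=int(vals.size), mean_deg=mean,
            mad_deg=float(np.abs(vals - mean).mean()),
        )
    return out


def angle_table(stats: dict[str, GroupStats]) -> pd.DataFrame:
    """Per-group n/mean/MAD table plus the total record count."""
    df = pd.DataFrame(
        [(s.group, s.n, s.mean_deg, s.mad_deg) for s in stats.values()],
        columns=["group", "n", "mean_deg", "mad_deg"],
    )
    return df


def classify_drainage(
    tree: VeinTree,
    hemisphere: str,
    balance_ratio: float = 1.5,
    absent_mm: float = 0.3,
) -> DrainageProfile:
    """Drainage type I-V from anastomotic-vein caliber ranking.

    Deterministic stand-in rule table (configurable, and explicitly not the
    published classification): with calibers of Trolard, Labbe and the
    superficial Sylvian vein,

    * Type V  — one vein absent (< ``absent_mm``) and the remaining two
      co-dominant (ratio < ``balance_ratio``);
    * Type I  — all three present and balanced (max/min < ``balance_ratio``);
    * Type II/III/IV — Trolard / Labbe / Sylvian dominant (largest caliber).

    A hemisphere without recorded calibers is reported as not assessable
    (as happens when the angiography slab does not cover the anastomoses).
    """
    cal = tree.anastomotic_calibers.get(hemisphere)
    if not cal or any(v not in cal for v in ANASTOMOTIC):
        return DrainageProfile(hemisphere=hemisphere, assessable=False)
    c = np.array([cal[v] for v in ANASTOMOTIC], dtype=float)
    present = c >= absent_mm
    if present.sum() == 2:
        a, b = c[present]
        if max(a, b) / min(a, b) < balance_ratio:
            return DrainageProfile(hemisphere=hemisphere, assessable=True, type="V")
    if present.all() and c.max() / c.min() < balance_ratio:
        return DrainageProfile(hemisphere=hemisphere, assessable=True, type="I")
    dominant = int(np.argmax(c))
    return DrainageProfile(
        hemisphere=hemisphere, assessable=True,
        type=("II", "III", "IV")[dominant],
    )


def save_tree(tree: VeinTree, sinus: SinusModel, path: str | Path) -> None:
    """Serialize a vein tree and sinus model as JSON."""
    payload = {
        "sinus_centerline": sinus.centerline.tolist(),
        "branches": [
            {"points": b.points.tolist(), "radius_mm": b.radius_mm}
            for b in tree.branches
        ],
        "junctions": [
            {
                "branch_index": j.branch_index,
                "arc_position_mm": j.arc_position_mm,
                "side": j.side,
                "group": j.group,
            }
            for j in tree.junctions
        ],
        "anastomotic_calibers": tree.anastomotic_calibers,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_tree(path: str | Path) -> tuple[VeinTree, SinusModel]:
    """Load a vein tree and sinus model from :func:`save_tree` JSON."""
    payload = json.loads(Path(path).read_text())
    sinus = SinusModel(np.asarray(payload["sinus_centerline"], dtype=float))
    branches = [
        VeinBranch(points=np.asarray(b["points"], dtype=float), radius_mm=b["radius_mm"])
        for b in payload["branches"]
    ]
    junctions = [BridgingJunction(**j) for j in payload["junctions"]]
    tree = VeinTree(
        branches=branches, junctions=junctions,
        anastomotic_calibers=payload.get("anastomotic_calibers", {}),
    )
    return tree, sinus
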