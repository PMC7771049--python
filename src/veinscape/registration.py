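"""Rigid-body pose parameterization and the repeated-registration gold standard.

Interactive co-registration on the workstation is a sequence of in-plane
displacements and rotations about the volume axes; a completed registration
is summarised by six parameters (three translations in mm, three rotations
in degrees).  The convention here is fixed and documented rather than
reverse-engineered: rotations are applied in the order Rx then Ry then Rz
about the world axes at the world origin (extrinsic, right-handed), then the
translation.  Averaging repeated registrations ("the geometric centre") is
done component-wise in parameter space, adequate for the sub-degree spreads
this pipeline quantifies.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidParams",
    "RigidTransform",
    "TrialSet",
    "params_to_transform",
    "geometric_center",
    "load_trials",
    "save_trials",
]

PARAM_NAMES = ("tx", "ty", "tz", "rx", "ry", "rz")


@dataclass(frozen=True)
class RigidParams:
    """Six-parameter rigid pose: translations in mm, rotations in degrees."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("rigid parameters must be finite")
        for name in ("rx", "ry", "rz"):
            a = getattr(self, name)
            if not (-180.0 < a <= 180.0):
                raise ValueError(f"{name}={a} outside (-180, 180] degrees")

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz], float)

    @classmethod
    def from_array(cls, arr) -> "RigidParams":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid transform (proper rotation + translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform matrix must be 4x4")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation block determinant must be +1")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last row must be (0, 0, 0, 1)")
        object.__setattr__(self, "matrix", m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform (n, 3) or (3,) world-mm points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        R = self.matrix[:3, :3]
        t = self.matrix[:3, 3]
        inv = np.eye(4)
        inv[:3, :3] = R.T
        inv[:3, 3] = -R.T @ t
        return RigidTransform(inv)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (other applied first)."""
        return RigidTransform(self.matrix @ other.matrix)


@dataclass
class TrialSet:
    """Ordered list of repeated registrations of one unit (patient or user)."""

    label: str
    trials: list[RigidParams]

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("a trial set needs at least one trial")


def params_to_transform(p: RigidParams) -> RigidTransform:
    """Homogeneous matrix Translate(t) ∘ Rz ∘ Ry ∘ Rx about the world origin."""
    # extrinsic x-y-z Euler == Rz(rz) @ Ry(ry) @ Rx(rx) on column vectors
    R = Rotation.from_euler("xyz", [p.rx, p.ry, p.rz], degrees=True).as_matrix()
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = [p.tx, p.ty, p.tz]
    return RigidTransform(m)


def geometric_center(trials: TrialSet | list[RigidParams]) -> RigidParams:
    """Component-wise mean pose over repeated registration trials.

    This is the "geometric centre" used as the gold standard against which
    each individual registration attempt is scored.
    """
    params = trials.trials if isinstance(trials, TrialSet) else list(trials)
    if len(params) == 0:
        raise ValueError("cannot take the geometric centre of zero trials")
    stack = np.stack([p.as_array() for p in params])
    return RigidParams.from_array(stack.mean(axis=0))


def save_trials(trials: TrialSet, path: str | Path) -> None:
    """Write a trial set as JSON (``.json``) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"label": trials.label, "trials": [asdict(t) for t in trials.trials]}
        path.write_text(json.dumps(payload, indent=2))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=PARAM_NAMES)
            writer.writeheader()
            for t in trials.trials:
                writer.writerow(asdict(t))


def load_trials(path: str | Path, label: str | None = None) -> TrialSet:
    """Read a trial set from JSON or CSV with columns tx,ty,tz,rx,ry,rz."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return TrialSet(
            label=label or payload.get("label", path.stem),
            trials=[RigidParams(**{k: float(v) for k, v in t.items()})
                    for t in payload["trials"]],
        )
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return TrialSet(
        label=label or path.stem,
        trials=[RigidParams(**{k: float(row[k]) for k in PARAM_NAMES}) for row in rows],
    )
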