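"""Monte-Carlo estimation of the spatial co-registration error.

The error of one registration attempt relative to the gold standard is the
mean, over the cortex of interest, of the distance between where the attempt
and the gold standard place the same material point.  The cortex of interest
is delimited by a 3D binary mask (in the original study derived from an
FDG-PET cortex image); the mean is estimated by Monte-Carlo sampling of
voxel centres inside that mask — 5,000 points by default, which keeps the
estimator's repeatability below 0.01 mm for error magnitudes near 1 mm.

Intra- and interobserver variability are plain unweighted grand means of the
per-unit (per-patient or per-user) mean errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registration import RigidParams, params_to_transform
from .volumes import BinaryMask, sample_mask_points

__all__ = [
    "ErrorReport",
    "VariabilitySummary",
    "mc_spatial_error",
    "exhaustive_spatial_error",
    "mc_convergence",
    "observer_variability",
]


@dataclass
class ErrorReport:
    """Per-trial spatial errors (mm) for one unit, plus their mean."""

    label: str
    per_trial_mm: list[float]
    n_points: int
    seed: int
    unit_mean_mm: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.per_trial_mm) == 0:
            raise ValueError("error report needs at least one trial value")
        if any(v < 0 for v in self.per_trial_mm):
            raise ValueError("spatial errors cannot be negative")
        self.unit_mean_mm = float(np.mean(self.per_trial_mm))


@dataclass
class VariabilitySummary:
    """Grand mean of per-unit mean errors (intra- or interobserver)."""

    unit_means_mm: dict[str, float]
    kind: str
    grand_mean_mm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in ("intraobserver", "interobserver"):
            raise ValueError(f"unknown variability kind {self.kind!r}")
        if len(self.unit_means_mm) == 0:
            raise ValueError("variability summary needs at least one unit")
        self.grand_mean_mm = float(np.mean(list(self.unit_means_mm.values())))

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form (full precision is kept on the instance)."""
        return {
            "kind": self.kind,
            "unit_means_mm": {k: round(v, ndigits) for k, v in self.unit_means_mm.items()},
            "grand_mean_mm": round(self.grand_mean_mm, ndigits),
        }


def _displacement_norms(trial: RigidParams, gold: RigidParams, points: np.ndarray) -> np.ndarray:
    t_trial = params_to_transform(trial)
    t_gold = params_to_transform(gold)
    return np.linalg.norm(t_trial.apply(points) - t_gold.apply(points), axis=1)


def mc_spatial_error(
    trial: RigidParams,
    gold: RigidParams,
    mask: BinaryMask,
    n_points: int = 5000,
    seed: int = 0,
) -> float:
    """Monte-Carlo mean spatial error (mm) of ``trial`` against ``gold``.

    Samples ``n_points`` voxel centres uniformly from the mask and returns
    the mean Euclidean distance between the trial and gold images of each
    point.  Deterministic given ``seed``; symmetric in trial and gold.
    """
    points = sample_mask_points(mask, n_points, seed)
    return float(_displacement_norms(trial, gold, points).mean())


def exhaustive_spatial_error(
    trial: RigidParams, gold: RigidParams, mask: BinaryMask
) -> float:
    """Exact mean spatial error over *every* voxel centre in the mask.

    The brute-force reference for the Monte-Carlo estimator; practical for
    masks up to a few hundred thousand voxels.
    """
    idx = np.argwhere(mask.included)
    if idx.shape[0] == 0:
        raise ValueError("mask is empty")
    points = mask.grid.voxel_centers(idx)
    return float(_displacement_norms(trial, gold, points).mean())


def mc_convergence(
    trial: RigidParams,
    gold: RigidParams,
    mask: BinaryMask,
    n_points: int = 5000,
    n_repeats: int = 20,
    seed: int = 0,
) -> float:
    """Spread (sample SD, mm) of repeated independent Monte-Carlo estimates.

    Quantifies the repeatability of the point-sampled estimator; with 5,000
    points and ~1 mm errors the spread stays below 0.01 mm.
    """
    if n_repeats < 2:
        raise ValueError("need at least two repeats to measure spread")
    seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    estimates = [
        mc_spatial_error(trial, gold, mask, n_points=n_points,
                         seed=int(s.generate_state(1)[0] % (2**31)))
        for s in seeds
    ]
    return float(np.std(estimates, ddof=1))


def observer_variability(groups: list[ErrorReport], kind: str) -> VariabilitySummary:
    """Aggregate unit mean errors into an unweighted grand mean.

    ``kind`` is ``"intraobserver"`` (units are patients registered repeatedly
    by one operator) or ``"interobserver"`` (units are operators).
    """
    if len(groups) == 0:
        raise ValueError("observer variability needs at least one unit")
    return VariabilitySummary(
        unit_means_mm={g.label: g.unit_mean_mm for g in groups}, kind=kind
    )
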