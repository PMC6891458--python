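"""Exact hypervolume indicator for minimisation fronts.

Computed by a recursive dimension-sweep (inclusion-exclusion on each point's
box minus the hypervolume of the clipped remainder), exact in any dimension
and adequate for desk-scale fronts (hundreds of points in 4-D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .moo.core import OptimisationResult, nondominated_filter

__all__ = ["HVConfig", "hypervolume", "choose_reference_point", "hv_trajectory"]


@dataclass(frozen=True)
class HVConfig:
    """A fixed reference point (one value per objective, minimisation)."""

    reference_point: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_point, dtype=np.float64)
        if ref.ndim != 1 or not np.all(np.isfinite(ref)):
            raise ValueError("reference point must be a finite 1-D vector")
        object.__setattr__(self, "reference_point", ref)


def _exact_hv(points: np.ndarray, ref: np.ndarray) -> float:
    """Hypervolume of a mutually nondominated point set, all <= ref."""
    n = points.shape[0]
    if n == 0:
        return 0.0
    if n == 1:
        return float(np.prod(ref - points[0]))
    # sort by first objective descending: clipped remainders shrink fastest
    order = np.argsort(-points[:, 0], kind="stable")
    points = points[order]
    total = 0.0
    for i in range(n):
        p = points[i]
        inclusive = float(np.prod(ref - p))
        rest = points[i + 1 :]
        if rest.size:
            limited = np.maximum(rest, p)
            limited = limited[nondominated_filter(limited)]
            inclusive -= _exact_hv(limited, ref)
        total += inclusive
    return total


def hypervolume(points: np.ndarray, ref: HVConfig | np.ndarray) -> float:
    """Lebesgue measure of the region dominated by `points`, bounded by `ref`.

    Points not componentwise <= the reference are dropped with a warning;
    an empty (or emptied) set yields 0.
    """
    ref_vec = ref.reference_point if isinstance(ref, HVConfig) else np.asarray(ref, float)
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        warnings.warn("hypervolume of an empty set is 0", stacklevel=2)
        return 0.0
    pts = np.atleast_2d(pts)
    if pts.shape[1] != ref_vec.size:
        raise ValueError("points and reference point disagree on dimension")
    valid = np.all(pts <= ref_vec, axis=1)
    if not valid.all():
        warnings.warn(
            f"dropping {int((~valid).sum())} point(s) beyond the reference point",
            stacklevel=2,
        )
        pts = pts[valid]
    if pts.shape[0] == 0:
        return 0.0
    pts = pts[nondominated_filter(pts)]
    return _exact_hv(pts, ref_vec)


def monte_carlo_hypervolume(
    points: np.ndarray,
    ref: HVConfig | np.ndarray,
    n_samples: int = 1_000_000,
    seed: int = 0,
    chunk: int = 200_000,
) -> tuple[float, float]:
    """Monte-Carlo estimate (value, standard error); test oracle for the exact HV.

    Samples uniformly in the box [min(points), ref] and scales the dominated
    fraction by the box volume.
    """
    ref_vec = ref.reference_point if isinstance(ref, HVConfig) else np.asarray(ref, float)
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    lo = pts.min(axis=0)
    box = float(np.prod(ref_vec - lo))
    if box == 0.0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        sample = rng.uniform(lo, ref_vec, size=(m, ref_vec.size))
        dominated = np.zeros(m, dtype=bool)
        for p in pts:
            dominated |= np.all(sample >= p, axis=1)
            if dominated.all():
                break
        hits += int(dominated.sum())
        done += m
    frac = hits / n_samples
    se = box * np.sqrt(max(frac * (1.0 - frac), 1e-12) / n_samples)
    return box * frac, float(se)


def choose_reference_point(fronts: list[np.ndarray]) -> HVConfig:
    """Componentwise max over all fronts, scaled by 1.1 (+0.1 where max is 0)."""
    arrays = [np.atleast_2d(np.asarray(f, dtype=np.float64)) for f in fronts if len(f)]
    if not arrays:
        raise ValueError("need at least one nonempty front")
    union = np.vstack(arrays)
    top = union.max(axis=0)
    ref = np.where(top > 0, 1.1 * top, top + 0.1)
    return HVConfig(ref)


def hv_trajectory(result: OptimisationResult, ref: HVConfig) -> np.ndarray:
    """Per-generation hypervolume of each snapshot's nondominated set."""
    if not result.snapshots:
        raise ValueError("result has no snapshots")
    values = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for snap in result.snapshots:
            values.append(hypervolume(snap.front_objectives(), ref))
    traj = np.asarray(values)
    result.hv_trajectory = traj
    return traj
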