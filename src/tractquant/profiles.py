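"""Tract profiles: build, summarize, recode and combine.

The along-tract representation follows the automated fiber quantification
(AFQ) convention: every streamline of a bundle is resampled to ``n_nodes``
equally spaced arc-length nodes (default 100), per-node scalars (FA, MD)
are averaged over streamlines, a node-wise volume is derived from voxel
occupancy, and the streamline count (Fib) is kept as a single global
number.  Profiles are then summarized into a global mean and 5 segment
means of 20 consecutive nodes each, relabeled ipsilateral/contralateral to
the ictal onset zone for patients, and the two control hemispheres are
combined into a single reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import (ALL_VARIABLES, MIDLINE_TRACT, N_NODES, N_SEGMENTS,
                        SCALAR_VARIABLES, TRACTS)
from .errors import (ConfigurationError, DataError, DegenerateFiberError,
                     ExcludedProfileError)
from .subjects import SubjectRecord


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class Fiber:
    """One streamline: ordered 3D points (mm) with paired FA/MD samples."""

    points: np.ndarray   # (n, 3)
    fa: np.ndarray       # (n,)
    md: np.ndarray       # (n,)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        fa = np.asarray(self.fa, dtype=float)
        md = np.asarray(self.md, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "fa", fa)
        object.__setattr__(self, "md", md)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise DataError("a fiber needs >= 2 three-dimensional points")
        if fa.shape != (len(pts),) or md.shape != (len(pts),):
            raise DataError("FA/MD samples must pair one-to-one with points")
        if np.any(fa < 0) or np.any(fa > 1):
            raise DataError("FA samples must lie in [0, 1]")
        if np.any(md <= 0):
            raise DataError("MD samples must be positive")


@dataclass(frozen=True)
class FiberBundle:
    """All streamlines of one tract for one subject and timepoint."""

    subject_id: str
    timepoint: str
    tract: str
    side: str            # left | right | midline
    fibers: tuple[Fiber, ...]
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fibers", tuple(self.fibers))
        if self.tract not in TRACTS:
            raise DataError(f"unknown tract {self.tract!r}")
        if self.tract == MIDLINE_TRACT and self.side != "midline":
            raise DataError(f"{MIDLINE_TRACT} must have side='midline'")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")


@dataclass(frozen=True)
class TractProfile:
    """Node-wise FA/MD/Vol plus global fiber count for one tract instance.

    ``valid=False`` marks a discarded tract (too few streamlines, simulated
    dropout, ...); invalid profiles are excluded from all downstream
    statistics but still travel through serialization.
    """

    subject_id: str
    timepoint: str
    tract: str
    side: str
    fa_nodes: np.ndarray
    md_nodes: np.ndarray
    vol_nodes: np.ndarray
    fib: int
    valid: bool = True
    n_nodes: int = N_NODES

    def __post_init__(self) -> None:
        for name in ("fa_nodes", "md_nodes", "vol_nodes"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (self.n_nodes,):
                raise DataError(
                    f"{self.subject_id}/{self.tract}: {name} must have "
                    f"length {self.n_nodes}, got {arr.shape}")


@dataclass(frozen=True)
class ProfileSummary:
    """Analysis-ready global and segment means for one tract instance.

    ``laterality`` is ``None`` straight after summarization and becomes
    ipsi/contra/midline for patients (:func:`recode_laterality`) or
    pooled-control/midline for controls (:func:`combine_control_sides`).
    Fib appears only among the global means.
    """

    subject_id: str
    timepoint: str
    tract: str
    side: str
    global_means: dict[str, float]                 # FA, MD, Vol, Fib
    segment_means: dict[tuple[str, int], float]    # (var, segment 1..5)
    laterality: str | None = None
    n_segments: int = N_SEGMENTS


# ---------------------------------------------------------------------------
# geometry

def resample_fiber(points: Sequence | np.ndarray, n_nodes: int) -> np.ndarray:
    """Resample a polyline at ``n_nodes`` equal arc-length positions.

    The output points lie exactly on the piecewise-linear input curve, with
    both endpoints preserved.  Raises :class:`DegenerateFiberError` for a
    zero-length input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise DataError("need >= 2 three-dimensional points")
    if n_nodes < 2:
        raise ConfigurationError("n_nodes must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    total = cum[-1]
    if total == 0.0:
        raise DegenerateFiberError("fiber has zero total arc length")
    targets = np.linspace(0.0, total, n_nodes)
    out = np.column_stack([np.interp(targets, cum, pts[:, d])
                           for d in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def _resample_scalars(points: np.ndarray, scalars: np.ndarray,
                      n_nodes: int) -> np.ndarray:
    """Linearly interpolate per-point scalars at the resampled nodes."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    if cum[-1] == 0.0:
        raise DegenerateFiberError("fiber has zero total arc length")
    targets = np.linspace(0.0, cum[-1], n_nodes)
    return np.interp(targets, cum, np.asarray(scalars, dtype=float))


def profile_bundle(bundle: FiberBundle, n_nodes: int = N_NODES,
                   min_fibers: int = 5) -> TractProfile:
    """Collapse a fiber bundle into a node-wise tract profile.

    FA/MD at node k are the unweighted means over streamlines of the scalar
    interpolated at each streamline's k-th arc-length node.  Vol at node k
    is the number of distinct voxel cells (edge ``bundle.voxel_size``)
    containing any streamline's k-th node, times the voxel volume.  A
    bundle with fewer than ``min_fibers`` streamlines yields a profile
    flagged ``valid=False`` rather than an exception.
    """
    n_fib = len(bundle.fibers)
    if n_fib == 0:
        nan = np.full(n_nodes, np.nan)
        return TractProfile(bundle.subject_id, bundle.timepoint, bundle.tract,
                            bundle.side, nan, nan, np.zeros(n_nodes), 0,
                            valid=False, n_nodes=n_nodes)
    node_pts = np.empty((n_fib, n_nodes, 3))
    fa = np.empty((n_fib, n_nodes))
    md = np.empty((n_fib, n_nodes))
    for i, fiber in enumerate(bundle.fibers):
        node_pts[i] = resample_fiber(fiber.points, n_nodes)
        fa[i] = _resample_scalars(fiber.points, fiber.fa, n_nodes)
        md[i] = _resample_scalars(fiber.points, fiber.md, n_nodes)
    vox = np.floor(node_pts / bundle.voxel_size).astype(np.int64)
    vol = np.empty(n_nodes)
    voxel_volume = bundle.voxel_size ** 3
    for k in range(n_nodes):
        vol[k] = len(np.unique(vox[:, k, :], axis=0)) * voxel_volume
    return TractProfile(bundle.subject_id, bundle.timepoint, bundle.tract,
                        bundle.side, fa.mean(axis=0), md.mean(axis=0), vol,
                        fib=n_fib, valid=n_fib >= min_fibers,
                        n_nodes=n_nodes)


# ---------------------------------------------------------------------------
# summarization

def summarize_profile(profile: TractProfile,
                      n_segments: int = N_SEGMENTS) -> ProfileSummary:
    """Global and segment means of a valid profile.

    Segment s covers nodes (s-1)*w+1 .. s*w (1-based, w = n_nodes /
    n_segments).  Global FA/MD/Vol means are computed as the mean of the
    equal-size segment means, which is algebraically identical to the
    whole-profile mean and makes the aggregation identity hold bitwise.
    Fib is copied through as a global-only variable.
    """
    if not profile.valid:
        raise ExcludedProfileError(
            f"{profile.subject_id}/{profile.tract}/{profile.side}: profile "
            "is flagged invalid and must be excluded")
    if profile.n_nodes % n_segments:
        raise ConfigurationError(
            f"n_nodes={profile.n_nodes} not divisible by "
            f"n_segments={n_segments}")
    width = profile.n_nodes // n_segments
    arrays = {"FA": profile.fa_nodes, "MD": profile.md_nodes,
              "Vol": profile.vol_nodes}
    segment_means: dict[tuple[str, int], float] = {}
    global_means: dict[str, float] = {}
    for var in SCALAR_VARIABLES:
        seg_means = arrays[var].reshape(n_segments, width).mean(axis=1)
        for s in range(n_segments):
            segment_means[(var, s + 1)] = float(seg_means[s])
        global_means[var] = float(seg_means.mean())
    global_means["Fib"] = float(profile.fib)
    return ProfileSummary(profile.subject_id, profile.timepoint,
                          profile.tract, profile.side, global_means,
                          segment_means, n_segments=n_segments)


# ---------------------------------------------------------------------------
# laterality

def recode_laterality(summaries: Iterable[ProfileSummary],
                      subjects: Iterable[SubjectRecord],
                      ) -> list[ProfileSummary]:
    """Relabel patient tract sides relative to the ictal onset zone.

    A side equal to the patient's IOZ side becomes ``ipsi``, the opposite
    side ``contra``; the midline CFMe is always ``midline``.  Control
    summaries pass through unchanged (they are combined separately).  Pure
    relabeling: no numeric field changes, and re-applying is idempotent.
    """
    by_id = {s.subject_id: s for s in subjects}
    out: list[ProfileSummary] = []
    for summ in summaries:
        try:
            rec = by_id[summ.subject_id]
        except KeyError:
            raise DataError(f"unknown subject {summ.subject_id!r}") from None
        if not rec.is_patient:
            out.append(summ)
            continue
        if rec.ioz_side not in ("left", "right"):
            raise DataError(
                f"{rec.subject_id}: patient without an IOZ side cannot be "
                "laterality-recoded")
        if summ.tract == MIDLINE_TRACT:
            lat = "midline"
        elif summ.side == rec.ioz_side:
            lat = "ipsi"
        elif summ.side in ("left", "right"):
            lat = "contra"
        else:
            raise DataError(
                f"{summ.subject_id}/{summ.tract}: bad side {summ.side!r}")
        out.append(replace(summ, laterality=lat))
    return out


def combine_control_sides(summaries: Iterable[ProfileSummary],
                          policy: str = "pool",
                          subjects: Iterable[SubjectRecord] | None = None,
                          ) -> list[ProfileSummary]:
    """Combine left and right control hemispheres into one reference sample.

    ``pool``: each hemisphere enters as a separate observation labeled
    ``pooled-control`` (a bilateral tract contributes two observations per
    control).  ``subject-mean``: one observation per subject per tract with
    every variable averaged over sides.  The midline CFMe passes through
    once per subject under either policy.

    If ``subjects`` is given, any patient summary raises
    :class:`DataError`; otherwise a summary already recoded to
    ipsi/contra is rejected on the same grounds.
    """
    if policy not in ("pool", "subject-mean"):
        raise ConfigurationError(f"unknown control policy {policy!r}")
    patients = (set()
                if subjects is None
                else {s.subject_id for s in subjects if s.is_patient})
    summaries = list(summaries)
    for summ in summaries:
        if summ.subject_id in patients or summ.laterality in ("ipsi",
                                                              "contra"):
            raise DataError(
                f"{summ.subject_id}: patient summary passed to "
                "combine_control_sides")
    out: list[ProfileSummary] = []
    if policy == "pool":
        for summ in summaries:
            lat = "midline" if summ.tract == MIDLINE_TRACT else "pooled-control"
            out.append(replace(summ, laterality=lat))
        return out
    # subject-mean
    grouped: dict[tuple[str, str, str], list[ProfileSummary]] = {}
    for summ in summaries:
        grouped.setdefault(
            (summ.subject_id, summ.timepoint, summ.tract), []).append(summ)
    for (sid, tp, tract), members in grouped.items():
        if tract == MIDLINE_TRACT:
            for summ in members:
                out.append(replace(summ, laterality="midline"))
            continue
        g = {var: float(np.mean([m.global_means[var] for m in members]))
             for var in ALL_VARIABLES}
        seg = {key: float(np.mean([m.segment_means[key] for m in members]))
               for key in members[0].segment_means}
        out.append(ProfileSummary(sid, tp, tract, "both", g, seg,
                                  laterality="pooled-control",
                                  n_segments=members[0].n_segments))
    return out
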