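"""Seeded synthetic cohorts with planted along-tract effects.

The clinical DWI data behind this kind of study are not deposited, so the
package ships a generator that emulates the study design end to end:
controls plus frontal-lobe (FLE) and temporal-lobe (TLE) epilepsy patients,
pre- and post-surgical timepoints, 1-year Engel outcomes, and 11 tract
instances per subject and timepoint (5 bilateral families x 2 sides plus
the midline CFMe).  Group effects are planted additively, either along the
whole tract (global) or confined to one 20-node segment, with the effect
directions the disease is expected to show (MD up; FA, Vol, Fib down in
patients).

Node-wise noise is Gaussian with an exponential correlation over node
index (profiles are smooth, so i.i.d. node noise would be unrealistic),
on top of a per-tract-instance between-subject offset.  Fiber counts are
negative-binomially distributed (overdispersed counts).  Randomness flows
from a single seed through one `numpy` SeedSequence substream per subject,
so cohorts are bit-identical for equal (spec, seed) and reproducible under
any generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .constants import (BILATERAL_TRACTS, MIDLINE_TRACT, N_NODES, N_SEGMENTS,
                        SCALAR_VARIABLES, TRACTS, segment_slice)
from .errors import ConfigurationError
from .profiles import Fiber, FiberBundle, TractProfile
from .subjects import SubjectRecord

# ---------------------------------------------------------------------------
# specification

#: Baseline magnitudes: plausible white-matter values, freely configurable.
DEFAULT_BASELINES = {"FA": 0.45, "MD": 0.80, "Vol": 15.0}
#: Amplitude of the smooth per-tract archetype variation along the profile.
DEFAULT_WAVINESS = {"FA": 0.05, "MD": 0.05, "Vol": 2.0}
DEFAULT_BETWEEN_SD = {"FA": 0.02, "MD": 0.02, "Vol": 0.75}
DEFAULT_NODE_SD = {"FA": 0.04, "MD": 0.04, "Vol": 1.5}


@dataclass(frozen=True)
class EffectSpec:
    """One planted group effect.

    ``effect_size`` is signed and in the variable's units; positive means
    the targeted patients sit above the control baseline.  ``scope`` is
    ``"global"`` or a 1-based segment index.  Fib, being a global-only
    count, accepts only global scope; the midline CFMe only ``midline``
    laterality.
    """

    tract: str
    variable: str                   # FA | MD | Vol | Fib
    effect_size: float
    scope: str | int = "global"     # "global" or segment 1..n_segments
    target_group: str = "both"      # FLE | TLE | both
    timepoint: str = "both"         # pre | post | both
    outcome_restriction: str = "any"  # any | seizure-free | recurrence
    laterality: str = "ipsi"        # ipsi | contra | midline

    def __post_init__(self) -> None:
        if self.tract not in TRACTS:
            raise ConfigurationError(f"EffectSpec.tract: {self.tract!r}")
        if self.variable not in ("FA", "MD", "Vol", "Fib"):
            raise ConfigurationError(f"EffectSpec.variable: {self.variable!r}")
        if self.tract == MIDLINE_TRACT and self.laterality != "midline":
            raise ConfigurationError(
                "EffectSpec.laterality: CFMe effects must be midline")
        if self.tract != MIDLINE_TRACT and self.laterality == "midline":
            raise ConfigurationError(
                "EffectSpec.laterality: midline only valid for CFMe")
        if self.variable == "Fib" and self.scope != "global":
            raise ConfigurationError(
                "EffectSpec.scope: Fib is global-only")
        if self.target_group not in ("FLE", "TLE", "both"):
            raise ConfigurationError(
                f"EffectSpec.target_group: {self.target_group!r}")
        if self.timepoint not in ("pre", "post", "both"):
            raise ConfigurationError(
                f"EffectSpec.timepoint: {self.timepoint!r}")
        if self.outcome_restriction not in ("any", "seizure-free",
                                            "recurrence"):
            raise ConfigurationError(
                f"EffectSpec.outcome_restriction: {self.outcome_restriction!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes per variable (units of the variable itself)."""

    between_subject_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SD))
    node_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NODE_SD))
    node_correlation_length: float = 10.0   # nodes; 0 = independent nodes

    def __post_init__(self) -> None:
        for name in ("between_subject_sd", "node_noise_sd"):
            d = getattr(self, name)
            for var in SCALAR_VARIABLES:
                if var not in d:
                    raise ConfigurationError(f"NoiseSpec.{name}: missing {var}")
                if d[var] < 0:
                    raise ConfigurationError(
                        f"NoiseSpec.{name}[{var}] must be >= 0")
        if self.node_correlation_length < 0:
            raise ConfigurationError(
                "NoiseSpec.node_correlation_length must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults reproduce the study design this package targets: 19 controls,
    8 FLE and 12 TLE patients; 7/8 FLE and 10/12 TLE operated; 1/7 FLE and
    6/10 TLE seizure-free one year after surgery; group ages and epilepsy
    durations matching the published cohort means.  Operated and
    seizure-free counts are ``round(fraction * n)`` so the printed cohort
    percentages are deterministic; which subjects fall in each class is
    randomized.
    """

    n_controls: int = 19
    n_fle: int = 8
    n_tle: int = 12
    operated_fraction: dict[str, float] = field(
        default_factory=lambda: {"FLE": 7 / 8, "TLE": 10 / 12})
    seizure_free_fraction: dict[str, float] = field(
        default_factory=lambda: {"FLE": 1 / 7, "TLE": 6 / 10})
    ioz_side_policy: str = "random"      # all-left | all-right | random
    age_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (34.2, 11.9),
                                 "FLE": (22.0, 5.0),
                                 "TLE": (33.6, 13.8)})
    duration_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"FLE": (13.4, 8.3), "TLE": (17.6, 9.7)})
    female_fraction: dict[str, float] = field(
        default_factory=lambda: {"control": 14 / 19, "FLE": 0.5, "TLE": 0.5})
    effects: tuple[EffectSpec, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    #: (mean, dispersion) of the negative-binomial fiber count;
    #: dispersion ``None`` makes the count deterministic (= round(mean)).
    fibers_per_tract: tuple[float, float | None] = (80.0, 20.0)
    voxel_size: float = 2.0
    n_nodes: int = N_NODES
    n_segments: int = N_SEGMENTS
    dropout_probability: float = 0.0
    baselines: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES))
    waviness: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WAVINESS))
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        for name in ("n_controls", "n_fle", "n_tle"):
            if getattr(self, name) < 2:
                raise ConfigurationError(
                    f"CohortSpec.{name}: every compared group needs >= 2 "
                    "subjects")
        for name in ("operated_fraction", "seizure_free_fraction",
                     "female_fraction"):
            for key, val in getattr(self, name).items():
                if not 0.0 <= val <= 1.0:
                    raise ConfigurationError(
                        f"CohortSpec.{name}[{key}] must be in [0, 1]")
        if self.ioz_side_policy not in ("all-left", "all-right", "random"):
            raise ConfigurationError(
                f"CohortSpec.ioz_side_policy: {self.ioz_side_policy!r}")
        if not 0.0 <= self.dropout_probability <= 1.0:
            raise ConfigurationError(
                "CohortSpec.dropout_probability must be in [0, 1]")
        if self.fibers_per_tract[0] <= 0:
            raise ConfigurationError(
                "CohortSpec.fibers_per_tract mean must be positive")
        if self.n_nodes % self.n_segments:
            raise ConfigurationError(
                "CohortSpec.n_nodes must be divisible by n_segments")
        if self.voxel_size <= 0:
            raise ConfigurationError("CohortSpec.voxel_size must be positive")


# ---------------------------------------------------------------------------
# effect planting

def plant_effect(base_curve: np.ndarray, effect: EffectSpec,
                 n_segments: int = N_SEGMENTS) -> np.ndarray:
    """Apply one additive effect to a node-value curve.

    Global scope shifts every node by ``effect_size``; a segment scope
    shifts only that segment's nodes, leaving all others bit-identical.
    """
    curve = np.asarray(base_curve, dtype=float)
    out = curve.copy()
    if effect.effect_size == 0.0:
        return out
    if effect.scope == "global":
        out += effect.effect_size
    else:
        seg = int(effect.scope)
        out[segment_slice(seg, len(curve), n_segments)] += effect.effect_size
    return out


def _effect_applies(effect: EffectSpec, subject: SubjectRecord,
                    timepoint: str, tract: str, side: str) -> bool:
    if not subject.is_patient:
        return False
    if effect.tract != tract:
        return False
    if effect.target_group not in ("both", subject.group):
        return False
    if effect.timepoint not in ("both", timepoint):
        return False
    if effect.outcome_restriction == "seizure-free" and not subject.seizure_free:
        return False
    if (effect.outcome_restriction == "recurrence"
            and not subject.seizure_recurrence):
        return False
    if tract == MIDLINE_TRACT:
        return effect.laterality == "midline"
    if effect.laterality == "ipsi":
        return side == subject.ioz_side
    if effect.laterality == "contra":
        return side != subject.ioz_side
    return False


# ---------------------------------------------------------------------------
# noise machinery

@lru_cache(maxsize=8)
def _correlation_cholesky(n_nodes: int, corr_length: float) -> np.ndarray:
    """Cholesky factor of the exp(-|i-j|/L) node correlation matrix."""
    if corr_length == 0.0:
        return np.eye(n_nodes)
    idx = np.arange(n_nodes)
    corr = np.exp(-np.abs(idx[:, None] - idx[None, :]) / corr_length)
    # tiny jitter guards against numerically semi-definite matrices
    return np.linalg.cholesky(corr + 1e-12 * np.eye(n_nodes))


def _smooth_archetype(rng: np.random.Generator, n_nodes: int) -> np.ndarray:
    """Smooth mean-curve shape in [-1, 1]: three low-frequency harmonics."""
    x = np.linspace(0.0, 1.0, n_nodes)
    curve = np.zeros(n_nodes)
    for h in (1, 2, 3):
        amp = rng.normal(0.0, 1.0 / h)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        curve += amp * np.sin(2.0 * math.pi * h * x + phase)
    peak = np.max(np.abs(curve))
    return curve / peak if peak > 0 else curve


def _tract_instances_sides() -> list[tuple[str, str]]:
    out = []
    for tract in TRACTS:
        if tract == MIDLINE_TRACT:
            out.append((tract, "midline"))
        else:
            out.append((tract, "left"))
            out.append((tract, "right"))
    return out


# ---------------------------------------------------------------------------
# cohort assembly

def _draw_subjects(spec: CohortSpec,
                   rng: np.random.Generator) -> list[SubjectRecord]:
    subjects: list[SubjectRecord] = []
    roster = ([("control", f"C{i + 1:02d}") for i in range(spec.n_controls)]
              + [("FLE", f"F{i + 1:02d}") for i in range(spec.n_fle)]
              + [("TLE", f"T{i + 1:02d}") for i in range(spec.n_tle)])
    # per-group operated / seizure-free assignment with deterministic counts
    flags: dict[str, tuple[bool, str]] = {}
    for group, n in (("FLE", spec.n_fle), ("TLE", spec.n_tle)):
        ids = [sid for g, sid in roster if g == group]
        n_operated = round(spec.operated_fraction[group] * n)
        operated = list(rng.choice(ids, size=n_operated, replace=False))
        n_free = round(spec.seizure_free_fraction[group] * n_operated)
        free = set(rng.choice(operated, size=n_free, replace=False)
                   ) if n_operated else set()
        for sid in ids:
            if sid not in operated:
                flags[sid] = (False, "none")
            elif sid in free:
                flags[sid] = (True, "I")
            else:
                flags[sid] = (True, str(rng.choice(["II", "III", "IV"])))
    for group, sid in roster:
        age_mu, age_sd = spec.age_distributions[group]
        age = float(max(12.0, rng.normal(age_mu, age_sd)))
        sex = "F" if rng.random() < spec.female_fraction[group] else "M"
        if group == "control":
            subjects.append(SubjectRecord(sid, group, age=age, sex=sex))
            continue
        operated, engel = flags[sid]
        if spec.ioz_side_policy == "all-left":
            ioz = "left"
        elif spec.ioz_side_policy == "all-right":
            ioz = "right"
        else:
            ioz = "left" if rng.random() < 0.5 else "right"
        dur_mu, dur_sd = spec.duration_distributions[group]
        duration = float(max(1.0, rng.normal(dur_mu, dur_sd)))
        tps = frozenset({"pre", "post"}) if operated else frozenset({"pre"})
        subjects.append(SubjectRecord(sid, group, operated=operated,
                                      ioz_side=ioz, engel_class=engel,
                                      age=age, sex=sex,
                                      epilepsy_duration=duration,
                                      timepoints_present=tps))
    return subjects


def _subject_profiles(spec: CohortSpec, subject: SubjectRecord,
                      rng: np.random.Generator,
                      archetypes: dict[tuple[str, str], np.ndarray],
                      chol: np.ndarray) -> list[TractProfile]:
    mean_fib, dispersion = spec.fibers_per_tract
    profiles: list[TractProfile] = []
    for timepoint in ("pre", "post"):
        if timepoint not in subject.timepoints_present:
            continue
        for tract, side in _tract_instances_sides():
            dropped = (spec.dropout_probability > 0
                       and rng.random() < spec.dropout_probability)
            curves: dict[str, np.ndarray] = {}
            for var in SCALAR_VARIABLES:
                offset = rng.normal(0.0, spec.noise.between_subject_sd[var])
                white = rng.standard_normal(spec.n_nodes)
                noise = spec.noise.node_noise_sd[var] * (chol @ white)
                curve = archetypes[(tract, var)] + offset + noise
                for eff in spec.effects:
                    if (eff.variable == var
                            and _effect_applies(eff, subject, timepoint,
                                                tract, side)):
                        curve = plant_effect(curve, eff, spec.n_segments)
                curves[var] = curve
            fib_mean = mean_fib
            for eff in spec.effects:
                if (eff.variable == "Fib"
                        and _effect_applies(eff, subject, timepoint,
                                            tract, side)):
                    fib_mean += eff.effect_size
            fib_mean = max(fib_mean, 1.0)
            if dispersion is None:
                fib = int(round(fib_mean))
            else:
                p = dispersion / (dispersion + fib_mean)
                fib = int(rng.negative_binomial(dispersion, p))
            profiles.append(TractProfile(
                subject.subject_id, timepoint, tract, side,
                np.clip(curves["FA"], 0.0, 1.0),
                np.maximum(curves["MD"], 1e-6),
                np.maximum(curves["Vol"], 0.0),
                fib=fib, valid=not dropped, n_nodes=spec.n_nodes))
    return profiles


def simulate_cohort(spec: CohortSpec, output: str = "profiles",
                    ) -> tuple[list[SubjectRecord],
                               list[TractProfile] | list[FiberBundle]]:
    """Generate a full synthetic cohort.

    ``output="profiles"`` returns ready-made :class:`TractProfile` tables
    (the fast path used by the statistical experiments);
    ``output="bundles"`` returns raw :class:`FiberBundle` streamline sets
    whose scalar samples embed the same subject node curves, for exercising
    the geometry pipeline.  Identical ``(spec, seed)`` give bit-identical
    output.
    """
    if output not in ("profiles", "bundles"):
        raise ConfigurationError(f"simulate_cohort.output: {output!r}")
    n_total = spec.n_controls + spec.n_fle + spec.n_tle
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(1 + n_total)
    cohort_rng = np.random.default_rng(streams[0])
    archetypes = {
        (tract, var): (spec.baselines[var]
                       + spec.waviness[var]
                       * _smooth_archetype(cohort_rng, spec.n_nodes))
        for tract in TRACTS for var in SCALAR_VARIABLES}
    subjects = _draw_subjects(spec, cohort_rng)
    chol = _correlation_cholesky(spec.n_nodes,
                                 spec.noise.node_correlation_length)
    data: list = []
    for subject, stream in zip(subjects, streams[1:]):
        rng = np.random.default_rng(stream)
        profiles = _subject_profiles(spec, subject, rng, archetypes, chol)
        if output == "profiles":
            data.extend(profiles)
        else:
            bundle_rng = np.random.default_rng(stream.spawn(1)[0])
            for prof in profiles:
                data.append(_profile_to_bundle(prof, spec, bundle_rng))
    return subjects, data


# ---------------------------------------------------------------------------
# streamline rendering (bundle output mode)

def _centerline(tract: str, side: str, s: np.ndarray) -> np.ndarray:
    """Deterministic smooth 3D centerline per tract instance, in mm."""
    t = TRACTS.index(tract)
    lateral = {"left": -30.0, "right": 30.0, "midline": 0.0}[side]
    x = lateral + 8.0 * np.sin(math.pi * s + 0.7 * t)
    y = 120.0 * s - 60.0
    z = 10.0 * np.cos(math.pi * s * (1.0 + 0.1 * t)) + 4.0 * t
    return np.column_stack([x, y, z])


def _profile_to_bundle(profile: TractProfile, spec: CohortSpec,
                       rng: np.random.Generator,
                       n_points: int = 64) -> FiberBundle:
    """Render a profile as streamlines whose scalars track its node curves."""
    s = np.linspace(0.0, 1.0, n_points)
    center = _centerline(profile.tract, profile.side, s)
    node_x = np.linspace(0.0, 1.0, profile.n_nodes)
    n_fibers = max(profile.fib, 2)
    fibers = []
    for _ in range(n_fibers):
        offset = rng.normal(0.0, 2.0, size=3)
        wobble = rng.normal(0.0, 0.3, size=(n_points, 3))
        pts = center + offset + np.cumsum(wobble, axis=0) * 0.1
        fa = np.interp(s, node_x, profile.fa_nodes) + rng.normal(
            0.0, 0.005, size=n_points)
        md = np.interp(s, node_x, profile.md_nodes) + rng.normal(
            0.0, 0.005, size=n_points)
        fibers.append(Fiber(pts, np.clip(fa, 0.0, 1.0),
                            np.maximum(md, 1e-6)))
    return FiberBundle(profile.subject_id, profile.timepoint, profile.tract,
                       profile.side, tuple(fibers),
                       voxel_size=spec.voxel_size)
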