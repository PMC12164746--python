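"""Monte-Carlo calibration and planted-effect recovery experiments.

These experiments close the loop on the whole pipeline: simulate a cohort,
summarize profiles, run the comparison grid, classify abnormalities, and
measure either the type-I error under the null (no planted effects) or the
recovery of a known planted abnormality by the correct taxonomy category.

Because contrasts within one simulated cohort share data (scope cells of a
variable overlap; subject offsets shift every scope at once), replicates --
not individual contrasts -- are the independent Monte-Carlo unit.  The
result objects therefore expose both the pooled rejection rate and the
per-contrast-cell rates across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .profiles import summarize_profile
from .simulate import CohortSpec, EffectSpec, NoiseSpec, simulate_cohort
from .stats import AnalysisConfig, comparison_grid
from .taxonomy import classify_comparisons

#: The tract instance used for planted-effect experiments.
RECOVERY_TRACT = "CH"
RECOVERY_LATERALITY = "ipsi"
RECOVERY_SEGMENT = 3


def _grid_summaries(spec: CohortSpec):
    subjects, profiles = simulate_cohort(spec)
    summaries = [summarize_profile(p, spec.n_segments)
                 for p in profiles if p.valid]
    return subjects, summaries


@dataclass(frozen=True)
class CalibrationResult:
    """Null-cohort rejection rates at a fixed alpha."""

    overall_rate: float                 # pooled over replicates x contrasts
    per_cell_rates: np.ndarray          # one rate per contrast cell
    per_replicate_rates: np.ndarray     # one rate per simulated cohort
    n_replicates: int
    n_cells: int
    alpha: float


def null_rejection_rate(n_replicates: int, seed: int,
                        spec: CohortSpec | None = None,
                        alpha: float = 0.05) -> CalibrationResult:
    """Type-I error of the full pipeline on effect-free cohorts.

    Simulates ``n_replicates`` null cohorts (study-sized by default),
    runs the combined 3-level presurgical grid and counts, per contrast
    cell, how often the patient-vs-control LSD p falls below ``alpha``.
    """
    base = spec or CohortSpec()
    config = AnalysisConfig(alpha=alpha, multiplicity="none")
    rejections = None
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    for i in range(n_replicates):
        rep_spec = replace(base, effects=(), seed=int(seeds[i] % 2**31))
        subjects, summaries = _grid_summaries(rep_spec)
        grid = comparison_grid(summaries, subjects, timepoint="pre",
                               config=config)
        flags = np.array([r.significant for r in grid if not r.skipped],
                         dtype=float)
        if rejections is None:
            rejections = np.zeros((n_replicates, flags.size))
        rejections[i] = flags
    assert rejections is not None
    return CalibrationResult(
        overall_rate=float(rejections.mean()),
        per_cell_rates=rejections.mean(axis=0),
        per_replicate_rates=rejections.mean(axis=1),
        n_replicates=n_replicates, n_cells=rejections.shape[1], alpha=alpha)


# ---------------------------------------------------------------------------
# planted-effect recovery

def _recovery_spec(mode: str, seed: int, zero_noise: bool,
                   effect_multiplier: float = 2.0) -> CohortSpec:
    """Cohort with a planted abnormality on the ipsilateral CH in TLE.

    ``mode="global"`` plants the disease-direction triple (MD up, FA down,
    Vol down) along the whole tract -- the pattern the consistent-global
    rule (3-4 variables) is meant to catch.  ``mode="segment"`` plants MD
    up and FA down confined to segment 3 -- the 2-variable pattern the
    consistent-segmental rule is meant to catch, deliberately below the
    3-variable global threshold.  Effects are sized ``effect_multiplier``
    times each variable's node-noise sd (the defaults, even when the run
    itself is noise-free).
    """
    noise = NoiseSpec()
    sds = noise.node_noise_sd
    if mode == "global":
        planted = [("MD", +1.0, "global"), ("FA", -1.0, "global"),
                   ("Vol", -1.0, "global")]
    elif mode == "segment":
        planted = [("MD", +1.0, RECOVERY_SEGMENT),
                   ("FA", -1.0, RECOVERY_SEGMENT)]
    else:
        raise ValueError(f"unknown recovery mode {mode!r}")
    effects = tuple(
        EffectSpec(tract=RECOVERY_TRACT, variable=var,
                   effect_size=sign * effect_multiplier * sds[var],
                   scope=scope, target_group="TLE", timepoint="pre",
                   laterality=RECOVERY_LATERALITY)
        for var, sign, scope in planted)
    if zero_noise:
        noise = NoiseSpec(
            between_subject_sd={v: 0.0 for v in sds},
            node_noise_sd={v: 0.0 for v in sds},
            node_correlation_length=0.0)
    return CohortSpec(n_controls=19, n_fle=2, n_tle=12,
                      ioz_side_policy="all-left", effects=effects,
                      noise=noise,
                      fibers_per_tract=(80.0, None if zero_noise else 20.0),
                      seed=seed)


@dataclass(frozen=True)
class RecoveryResult:
    mode: str
    n_replicates: int
    correct_rate: float     # replicates recovering the planted category
    wrong_rate: float       # replicates emitting the opposite category
    segment_hit_rate: float  # segmental labels that flag the planted segment


def effect_recovery(mode: str, n_replicates: int, seed: int,
                    zero_noise: bool = False,
                    alpha: float = 0.05) -> RecoveryResult:
    """Fraction of replicates whose planted effect lands in the correct
    taxonomy category (consistent-global vs consistent-segmental)."""
    config = AnalysisConfig(alpha=alpha)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    correct = wrong = seg_hit = 0
    for i in range(n_replicates):
        spec = _recovery_spec(mode, int(seeds[i] % 2**31), zero_noise)
        subjects, summaries = _grid_summaries(spec)
        grid = comparison_grid(summaries, subjects, timepoint="pre",
                               config=config, restrict_to="TLE")
        labels, _ = classify_comparisons(grid, cohort_scope="TLE-only")
        inst = [lab for lab in labels
                if (lab.tract, lab.laterality) == (RECOVERY_TRACT,
                                                   RECOVERY_LATERALITY)]
        has_global = any(lab.category == "consistent-global"
                         for lab in inst)
        seg_labels = [lab for lab in inst
                      if lab.category == "consistent-segmental"]
        if mode == "global":
            correct += has_global
            wrong += bool(seg_labels)
        else:
            good = any(RECOVERY_SEGMENT in lab.segments_involved
                       for lab in seg_labels)
            correct += good
            seg_hit += good
            wrong += has_global
    return RecoveryResult(mode, n_replicates,
                          correct_rate=correct / n_replicates,
                          wrong_rate=wrong / n_replicates,
                          segment_hit_rate=seg_hit / n_replicates)
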