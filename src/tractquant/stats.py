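"""Group statistics: Kruskal-Wallis, ANOVA/ANCOVA with Fisher-LSD contrasts,
and the full tract x variable x scope comparison grid.

Demographic contrasts use the tie-corrected Kruskal-Wallis rank test.
Quantitative tract variables are compared with a general linear model:
one-way ANOVA (optionally ANCOVA with age/sex entered linearly) followed by
Fisher's least-significant-difference (LSD) pairwise contrasts -- two-sided
t statistics built on the pooled error mean square and its degrees of
freedom, with no multiplicity adjustment unless configured.  Significance
is raw p < alpha (default 0.05), matching the convention of the small-cohort
studies this pipeline targets; Benjamini-Hochberg adjustment is available
for modern use.

The grid covers 11 tract instances ({ipsi, contra} x 5 bilateral families
plus the midline CFMe) x 19 scopes (global for FA/MD/Vol/Fib plus segments
1-5 for FA/MD/Vol) per group pair: 209 rows per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .constants import SCALAR_VARIABLES, tract_instances
from .errors import (ConfigurationError, DataError, DegenerateVarianceError)
from .profiles import ProfileSummary, combine_control_sides, recode_laterality
from .subjects import SubjectRecord

#: Column layout of a tract-instance value matrix: 19 (variable, scope)
#: pairs -- global + segments 1..5 for each node-wise scalar, then Fib.
SCOPE_COLUMNS: tuple[tuple[str, str | int], ...] = tuple(
    [(var, scope) for var in SCALAR_VARIABLES
     for scope in ("global", 1, 2, 3, 4, 5)]
    + [("Fib", "global")])


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    covariates: tuple[str, ...] = ()            # subset of {age, sex}
    control_policy: str = "pool"                # pool | subject-mean
    n_nodes: int = 100
    n_segments: int = 5
    multiplicity: str = "none"                  # none | benjamini-hochberg

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("AnalysisConfig.alpha must be in (0, 1)")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        for cov in self.covariates:
            if cov not in ("age", "sex"):
                raise ConfigurationError(
                    f"AnalysisConfig.covariates: unknown covariate {cov!r}")
        if self.control_policy not in ("pool", "subject-mean"):
            raise ConfigurationError(
                f"AnalysisConfig.control_policy: {self.control_policy!r}")
        if self.multiplicity not in ("none", "benjamini-hochberg"):
            raise ConfigurationError(
                f"AnalysisConfig.multiplicity: {self.multiplicity!r}")


@dataclass(frozen=True)
class ComparisonResult:
    """One statistical contrast of the grid.

    ``direction`` is the sign of (mean_a - mean_b), group ``a`` being the
    patient (or seizure-free) group, so +1 on MD reads "patients above
    controls".  ``skipped`` rows mark tract instances that could not be
    evaluated (invalid profile in a compared group); they carry NaN
    statistics but are never silently dropped.
    """

    tract: str
    laterality: str                 # ipsi | contra | midline
    timepoint: str
    variable: str
    scope: str | int                # "global" or segment 1..5
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    p_value: float
    direction: int
    significant: bool
    skipped: bool = False
    note: str = ""


@dataclass(frozen=True)
class LsdContrast:
    mean_diff: float
    t_stat: float
    p_value: float


@dataclass(frozen=True)
class LsdAnovaResult:
    f_stat: float
    omnibus_p: float
    df_error: float
    mse: float
    pairwise: dict[tuple[str, str], LsdContrast] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# univariate tests

def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]],
                   ) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    With every observation identical the statistic is defined as H = 0,
    p = 1 (no evidence of a difference).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise DataError("kruskal_wallis needs >= 2 groups")
    for label, vals in zip(values_by_group, groups):
        if vals.size == 0:
            raise DataError(f"kruskal_wallis: group {label!r} is empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _design_matrix(values_by_group: Mapping[str, np.ndarray],
                   covariates: Mapping[str, np.ndarray] | None,
                   ) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    labels = list(values_by_group)
    y = np.concatenate([values_by_group[g] for g in labels])
    n = len(y)
    g = len(labels)
    # intercept + (g-1) treatment dummies, first group as reference
    X = np.ones((n, g))
    start = 0
    for j, lab in enumerate(labels):
        m = len(values_by_group[lab])
        if j > 0:
            X[:, j] = 0.0
            X[start:start + m, j] = 1.0
        start += m
    n_cov = 0
    if covariates:
        cols = []
        for name, vals in covariates.items():
            arr = np.concatenate([np.asarray(vals[lab], dtype=float)
                                  for lab in labels]) if isinstance(
                vals, Mapping) else np.asarray(vals, dtype=float)
            if arr.shape != (n,):
                raise DataError(
                    f"covariate {name!r}: need one value per observation")
            cols.append(arr)
        X = np.column_stack([X] + cols)
        n_cov = len(cols)
    return X, y, labels, n_cov


def lsd_anova(values_by_group: Mapping[str, Sequence[float]],
              covariates: Mapping[str, Mapping[str, Sequence[float]] | Sequence[float]] | None = None,
              ) -> LsdAnovaResult:
    """One-way ANOVA (or ANCOVA) with Fisher-LSD pairwise contrasts.

    Fit as a general linear model: intercept + group dummies (+ covariates
    entered linearly).  The omnibus p compares the full model against the
    covariates-only model; pairwise contrasts are two-sided t tests on the
    (adjusted) group-mean differences using the pooled error mean square
    and its degrees of freedom, with no multiplicity correction -- Fisher's
    LSD.  With no covariates this reduces exactly to classic one-way
    ANOVA, and for two groups the LSD p equals the pooled-variance
    two-sample t-test p.

    Raises :class:`DegenerateVarianceError` when the residual variance is
    exactly zero (the F statistic is undefined).
    """
    groups = {str(k): np.asarray(v, dtype=float)
              for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise DataError("lsd_anova needs >= 2 groups")
    for lab, vals in groups.items():
        if len(vals) < 2:
            raise DataError(f"lsd_anova: group {lab!r} needs n >= 2")
    cov_arrays = None
    if covariates:
        cov_arrays = {name: (np.concatenate(
            [np.asarray(vals[lab], dtype=float) for lab in groups])
            if isinstance(vals, Mapping) else np.asarray(vals, dtype=float))
            for name, vals in covariates.items()}
    X, y, labels, n_cov = _design_matrix(groups, cov_arrays)
    n, p_full = len(y), X.shape[1]
    g = len(labels)
    df_error = n - p_full
    if df_error < 1:
        raise DataError("lsd_anova: error degrees of freedom < 1")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse_full = float(resid @ resid)
    # reduced model: drop the group dummies
    keep = [0] + list(range(g, p_full))
    X_red = X[:, keep]
    beta_red, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    resid_red = y - X_red @ beta_red
    sse_red = float(resid_red @ resid_red)
    mse = sse_full / df_error
    # constant-within-groups data leave only accumulation error in the
    # residual; judge "zero variance" relative to the data's magnitude
    if mse <= 1e-20 * max(float(np.mean(y ** 2)), 1e-300):
        raise DegenerateVarianceError(
            "zero within-group variance everywhere; F undefined")
    f_stat = ((sse_red - sse_full) / (g - 1)) / mse
    f_stat = max(f_stat, 0.0)
    omnibus_p = float(sps.f.sf(f_stat, g - 1, df_error))
    xtx_inv = np.linalg.pinv(X.T @ X)
    cov_beta = mse * xtx_inv
    # group effect of label j relative to the reference is beta[j] (j>=1);
    # the reference group's effect is 0 with zero variance contribution.
    pairwise: dict[tuple[str, str], LsdContrast] = {}
    for i in range(g):
        for j in range(i + 1, g):
            ci = np.zeros(p_full)
            if i > 0:
                ci[i] = 1.0
            if j > 0:
                ci[j] -= 1.0
            diff = float(ci @ beta)
            var = float(ci @ cov_beta @ ci)
            if var <= 0.0:
                t_stat = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
            else:
                t_stat = diff / np.sqrt(var)
            p_val = float(2.0 * sps.t.sf(abs(t_stat), df_error))
            pairwise[(labels[i], labels[j])] = LsdContrast(diff,
                                                           float(t_stat),
                                                           p_val)
    return LsdAnovaResult(float(f_stat), omnibus_p, float(df_error),
                          float(mse), pairwise)


# ---------------------------------------------------------------------------
# vectorized grid engine (no covariates)

def _anova_lsd_columns(groups: Sequence[tuple[str, np.ndarray]],
                       pairs: Sequence[tuple[str, str]],
                       ) -> dict[tuple[str, str],
                                 tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Column-wise one-way ANOVA + LSD over matrices of shape (n_i, m).

    Returns per pair (p_values, mean_diffs, degenerate_mask).  Columns with
    zero pooled within-group variance use the exact-comparison convention:
    p = 0 where the pair means differ, p = 1 where they are equal (flagged
    in the mask) -- the degenerate case a zero-noise simulation produces.
    """
    labels = [lab for lab, _ in groups]
    mats = [np.asarray(x, dtype=float) for _, x in groups]
    ns = np.array([len(x) for x in mats])
    if np.any(ns < 2):
        raise DataError("every compared group needs n >= 2")
    means = np.vstack([x.mean(axis=0) for x in mats])          # (g, m)
    ssw = sum(((x - mu) ** 2).sum(axis=0)
              for x, mu in zip(mats, means))                   # (m,)
    df_error = int(ns.sum() - len(mats))
    mse = ssw / df_error
    # columns whose data are constant within every group have SSW that is
    # zero up to accumulation error; compare against the data's magnitude
    msq = sum((x ** 2).sum(axis=0) for x in mats) / ns.sum()
    degenerate = mse <= 1e-20 * np.maximum(msq, 1e-300)
    diff_tol = 1e-9 * np.sqrt(np.maximum(msq, 0.0))
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    idx = {lab: k for k, lab in enumerate(labels)}
    for a, b in pairs:
        diff = means[idx[a]] - means[idx[b]]
        se = np.sqrt(np.where(degenerate, 1.0, mse)
                     * (1.0 / ns[idx[a]] + 1.0 / ns[idx[b]]))
        t = diff / se
        p = 2.0 * sps.t.sf(np.abs(t), df_error)
        p = np.where(degenerate,
                     np.where(np.abs(diff) > diff_tol, 0.0, 1.0), p)
        out[(a, b)] = (p, diff, degenerate)
    return out


# ---------------------------------------------------------------------------
# the comparison grid

def _summary_vector(summ: ProfileSummary) -> list[float]:
    return [summ.global_means[var] if scope == "global"
            else summ.segment_means[(var, scope)]
            for var, scope in SCOPE_COLUMNS]


def _prepare_summaries(summaries: Iterable[ProfileSummary],
                       subjects: Sequence[SubjectRecord],
                       config: AnalysisConfig) -> list[ProfileSummary]:
    """Recode patient sides and combine control hemispheres if needed."""
    by_id = {s.subject_id: s for s in subjects}
    raw_patients, raw_controls, ready = [], [], []
    for summ in summaries:
        rec = by_id.get(summ.subject_id)
        if rec is None:
            raise DataError(f"unknown subject {summ.subject_id!r}")
        if summ.laterality is not None:
            ready.append(summ)
        elif rec.is_patient:
            raw_patients.append(summ)
        else:
            raw_controls.append(summ)
    ready += recode_laterality(raw_patients, subjects)
    ready += combine_control_sides(raw_controls, config.control_policy)
    return ready


def comparison_grid(summaries: Iterable[ProfileSummary],
                    subjects: Sequence[SubjectRecord],
                    grouping: str = "diagnosis-vs-control",
                    timepoint: str = "pre",
                    config: AnalysisConfig | None = None,
                    restrict_to: str | None = None,
                    ) -> list[ComparisonResult]:
    """Run every contrast of the tract x variable x scope grid.

    ``grouping="diagnosis-vs-control"`` fits a 3-level model (control, FLE,
    TLE) and reads patient-vs-control significance from the LSD pairwise
    contrasts; ``restrict_to="FLE"``/``"TLE"`` analyzes one diagnosis group
    independently against controls (2-level model).
    ``grouping="outcome"`` compares operated patients with seizure freedom
    (Engel I) against seizure recurrence (Engel II-IV).

    Patients contribute their ``timepoint`` summaries (patients lacking the
    timepoint -- e.g. not yet operated at "post" -- are excluded); controls
    always contribute their single presurgical scan.  Tract instances with
    a missing or invalid profile in a compared group, or a compared group
    smaller than 2, are emitted with ``skipped=True`` rather than dropped,
    so the grid is always complete: 11 tract instances x 19 scopes per
    group pair (209 rows per pair).
    """
    config = config or AnalysisConfig()
    if grouping not in ("diagnosis-vs-control", "outcome"):
        raise ConfigurationError(f"comparison_grid.grouping: {grouping!r}")
    if restrict_to not in (None, "FLE", "TLE"):
        raise ConfigurationError(
            f"comparison_grid.restrict_to: {restrict_to!r}")
    prepared = _prepare_summaries(summaries, subjects, config)
    by_id = {s.subject_id: s for s in subjects}

    def membership(rec: SubjectRecord) -> str | None:
        if grouping == "diagnosis-vs-control":
            if rec.group == "control":
                return "control"
            if restrict_to and rec.group != restrict_to:
                return None
            return rec.group
        # outcome grouping: operated patients only
        if not rec.is_patient or not rec.operated:
            return None
        if restrict_to and rec.group != restrict_to:
            return None
        if rec.seizure_free:
            return "seizure-free"
        if rec.seizure_recurrence:
            return "recurrence"
        return None

    if grouping == "diagnosis-vs-control":
        group_order = (["control", restrict_to] if restrict_to
                       else ["control", "FLE", "TLE"])
        pairs = [(g, "control") for g in group_order if g != "control"]
    else:
        group_order = ["recurrence", "seizure-free"]
        pairs = [("seizure-free", "recurrence")]
        counts = {g: 0 for g in group_order}
        for rec in by_id.values():
            m = membership(rec)
            if m in counts:
                counts[m] += 1
        for g, c in counts.items():
            if c == 0:
                raise DataError(
                    f"outcome grouping: no operated subjects in class {g!r}")

    def control_timepoint(rec: SubjectRecord) -> str:
        return ("pre" if "pre" in rec.timepoints_present
                else sorted(rec.timepoints_present)[0])

    # expected observations per analysis group per tract instance kind
    expected: dict[str, dict[str, int]] = {g: {"bilateral": 0, "midline": 0}
                                           for g in group_order}
    for rec in by_id.values():
        m = membership(rec)
        if m is None:
            continue
        if rec.is_patient and timepoint not in rec.timepoints_present:
            continue
        if m == "control" and config.control_policy == "pool":
            expected[m]["bilateral"] += 2
        else:
            expected[m]["bilateral"] += 1
        expected[m]["midline"] += 1

    # collect (value vector, subject id) per (tract, laterality, group)
    cells: dict[tuple[str, str, str],
                list[tuple[list[float], str]]] = {}
    for summ in prepared:
        rec = by_id[summ.subject_id]
        m = membership(rec)
        if m is None:
            continue
        want_tp = (timepoint if rec.is_patient else control_timepoint(rec))
        if summ.timepoint != want_tp:
            continue
        lat = summ.laterality
        if lat == "pooled-control":
            # the combined control sample serves both instances of a tract
            for inst_lat in ("ipsi", "contra"):
                cells.setdefault((summ.tract, inst_lat, m), []).append(
                    (_summary_vector(summ), summ.subject_id))
        elif lat in ("ipsi", "contra", "midline"):
            cells.setdefault((summ.tract, lat, m), []).append(
                (_summary_vector(summ), summ.subject_id))

    results: list[ComparisonResult] = []
    for tract, lat in tract_instances():
        kind = "midline" if lat == "midline" else "bilateral"
        groups: list[tuple[str, np.ndarray]] = []
        group_sids: dict[str, list[str]] = {}
        complete = True
        for g in group_order:
            rows = cells.get((tract, lat, g), [])
            if len(rows) < expected[g][kind] or len(rows) < 2:
                complete = False
            groups.append((g, np.asarray([v for v, _ in rows], dtype=float)
                           if rows else np.empty((0, len(SCOPE_COLUMNS)))))
            group_sids[g] = [sid for _, sid in rows]
        if not complete:
            for a, b in pairs:
                for var, scope in SCOPE_COLUMNS:
                    results.append(ComparisonResult(
                        tract, lat, timepoint, var, scope, a, b,
                        n_a=0, n_b=0, mean_a=float("nan"),
                        mean_b=float("nan"), p_value=float("nan"),
                        direction=0, significant=False, skipped=True,
                        note="invalid or missing profiles in a compared "
                             "group"))
            continue
        if config.covariates:
            stats_by_pair = _ancova_columns(groups, pairs, group_sids,
                                            by_id, config.covariates)
        else:
            stats_by_pair = _anova_lsd_columns(groups, pairs)
        sizes = {g: len(x) for g, x in groups}
        means = {g: x.mean(axis=0) for g, x in groups}
        for a, b in pairs:
            p, diff, degenerate = stats_by_pair[(a, b)]
            for col, (var, scope) in enumerate(SCOPE_COLUMNS):
                d = float(diff[col])
                results.append(ComparisonResult(
                    tract, lat, timepoint, var, scope, a, b,
                    n_a=sizes[a], n_b=sizes[b],
                    mean_a=float(means[a][col]),
                    mean_b=float(means[b][col]),
                    p_value=float(p[col]),
                    direction=int(np.sign(d)) if d == d else 0,
                    significant=False,
                    note=("degenerate variance; exact comparison"
                          if degenerate[col] else "")))
    _apply_significance(results, config)
    return results


def _covariate_values(sid: str, by_id: Mapping[str, SubjectRecord],
                      name: str) -> float:
    rec = by_id[sid]
    if name == "age":
        return float(rec.age)
    if name == "sex":
        return 1.0 if rec.sex == "F" else 0.0
    raise ConfigurationError(f"unknown covariate {name!r}")


def _ancova_columns(groups: Sequence[tuple[str, np.ndarray]],
                    pairs: Sequence[tuple[str, str]],
                    group_sids: Mapping[str, list[str]],
                    by_id: Mapping[str, SubjectRecord],
                    covariates: Sequence[str],
                    ) -> dict[tuple[str, str],
                              tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Column-wise ANCOVA via :func:`lsd_anova` (used when covariates are
    configured; slower than the closed-form path but exercised rarely)."""
    m = groups[0][1].shape[1]
    cov = {name: {g: [_covariate_values(sid, by_id, name)
                      for sid in group_sids[g]] for g, _ in groups}
           for name in covariates}
    out = {pair: (np.empty(m), np.empty(m), np.zeros(m, dtype=bool))
           for pair in pairs}
    labels = [g for g, _ in groups]
    for col in range(m):
        values = {g: x[:, col] for g, x in groups}
        try:
            res = lsd_anova(values, covariates=cov)
        except DegenerateVarianceError:
            col_means = {g: float(x[:, col].mean()) for g, x in groups}
            for a, b in pairs:
                d = col_means[a] - col_means[b]
                out[(a, b)][0][col] = 0.0 if d != 0.0 else 1.0
                out[(a, b)][1][col] = d
                out[(a, b)][2][col] = True
            continue
        for a, b in pairs:
            contrast = res.pairwise.get((a, b)) or res.pairwise[(b, a)]
            sign = 1.0 if (a, b) in res.pairwise else -1.0
            out[(a, b)][0][col] = contrast.p_value
            out[(a, b)][1][col] = sign * contrast.mean_diff
            out[(a, b)][2][col] = False
    return out


def _apply_significance(results: list[ComparisonResult],
                        config: AnalysisConfig) -> None:
    """Set the significant flag, with optional Benjamini-Hochberg control."""
    live = [i for i, r in enumerate(results) if not r.skipped]
    if not live:
        return
    pvals = np.array([results[i].p_value for i in live])
    if config.multiplicity == "benjamini-hochberg":
        pvals = sps.false_discovery_control(pvals, method="bh")
    for i, p in zip(live, pvals):
        r = results[i]
        object.__setattr__(r, "significant", bool(p < config.alpha))
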