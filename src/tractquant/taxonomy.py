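"""Rule-based abnormality taxonomy over the comparison grid.

A tract instance (tract x laterality) is labeled, per timepoint and cohort
scope, by counting which contrasts against controls are significant:

* **consistent global abnormality** -- 3 or 4 of the 4 variables (FA, MD,
  Vol, Fib) significant along the tract's entire length;
* **consistent segmental abnormality** -- at least 2 of the 3 node-wise
  variables (FA, MD, Vol) significant within a segment, in 1 to 4 of the 5
  segments.  A tract abnormal in all 5 segments is not "segmental": it is
  reported through :func:`whole_length_segments` instead, since a
  five-of-five pattern spans the entire length.

Longitudinal categories compare the pre- and postsurgical grids:

* **de novo** -- the rule is met postsurgically by variables (or
  segment-variable pairs) that were *not* significant presurgically;
* **reinforced** -- variables (or pairs) significant at both timepoints
  with the same direction, again meeting the counting rule.

Direction agreement is required for reinforcement (the abnormality
"persisted") but not for de novo emergence.  A tract discarded at either
timepoint is excluded from longitudinal categories and reported as
not-evaluable rather than treated as normal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constants import ALL_VARIABLES, SCALAR_VARIABLES, tract_instances
from .errors import IncompleteGridError
from .stats import ComparisonResult

GLOBAL_CATEGORY_BAND = (3, 4)     # variables significant along full length
SEGMENT_VARIABLE_BAND = (2, 3)    # co-significant variables per segment
MAX_ABNORMAL_SEGMENTS = 4         # "up to four out of ... five segments"

CATEGORIES = ("consistent-global", "consistent-segmental",
              "de-novo-global", "de-novo-segmental",
              "reinforced-global", "reinforced-segmental")


@dataclass(frozen=True)
class AbnormalityLabel:
    tract: str
    laterality: str
    cohort_scope: str              # e.g. combined | FLE-only | TLE-only
    category: str
    timepoint: str                 # pre | post
    variables_involved: frozenset[str]
    segments_involved: frozenset[int] = frozenset()
    directions: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# grid indexing helpers

def _global_rows(results: Iterable[ComparisonResult]
                 ) -> dict[str, ComparisonResult]:
    rows = {r.variable: r for r in results if r.scope == "global"}
    missing = set(ALL_VARIABLES) - set(rows)
    if missing:
        raise IncompleteGridError(
            f"missing global rows for {sorted(missing)}")
    return rows


def _segment_rows(results: Iterable[ComparisonResult]
                  ) -> dict[tuple[str, int], ComparisonResult]:
    rows = {(r.variable, r.scope): r for r in results
            if isinstance(r.scope, int)}
    want = {(v, s) for v in SCALAR_VARIABLES for s in range(1, 6)}
    missing = want - set(rows)
    if missing:
        raise IncompleteGridError(
            f"missing segmental rows for {sorted(missing)}")
    return rows


def _context(results: Sequence[ComparisonResult],
             cohort_scope: str | None) -> tuple[str, str, str, str]:
    r = results[0]
    scope = cohort_scope if cohort_scope is not None else r.group_a
    return r.tract, r.laterality, r.timepoint, scope


# ---------------------------------------------------------------------------
# single-timepoint rules

def classify_global(results: Sequence[ComparisonResult],
                    cohort_scope: str | None = None,
                    ) -> AbnormalityLabel | None:
    """Consistent global abnormality: 3-4 significant global variables."""
    rows = _global_rows(results)
    sig = [v for v in ALL_VARIABLES if rows[v].significant]
    lo, hi = GLOBAL_CATEGORY_BAND
    if not lo <= len(sig) <= hi:
        return None
    tract, lat, tp, scope = _context(results, cohort_scope)
    return AbnormalityLabel(
        tract, lat, scope, "consistent-global", tp,
        frozenset(sig), directions={v: rows[v].direction for v in sig})


def _abnormal_segments(seg_sig: Mapping[tuple[str, int], bool]
                       ) -> dict[int, list[str]]:
    """Segments where >= 2 of the 3 node-wise variables are significant."""
    out: dict[int, list[str]] = {}
    for s in range(1, 6):
        vars_sig = [v for v in SCALAR_VARIABLES if seg_sig[(v, s)]]
        if len(vars_sig) >= SEGMENT_VARIABLE_BAND[0]:
            out[s] = vars_sig
    return out


def classify_segmental(results: Sequence[ComparisonResult],
                       cohort_scope: str | None = None,
                       ) -> AbnormalityLabel | None:
    """Consistent segmental abnormality: 2-3 co-significant variables in
    1-4 of 5 segments.  Returns None for 0 or all-5 abnormal segments."""
    rows = _segment_rows(results)
    abnormal = _abnormal_segments(
        {key: row.significant for key, row in rows.items()})
    if not 1 <= len(abnormal) <= MAX_ABNORMAL_SEGMENTS:
        return None
    variables = frozenset(v for vs in abnormal.values() for v in vs)
    directions: dict[str, int] = {}
    for s, vs in sorted(abnormal.items()):
        for v in vs:
            directions.setdefault(v, rows[(v, s)].direction)
    tract, lat, tp, scope = _context(results, cohort_scope)
    return AbnormalityLabel(
        tract, lat, scope, "consistent-segmental", tp, variables,
        frozenset(abnormal), directions)


def whole_length_segments(results: Sequence[ComparisonResult]) -> bool:
    """True when all 5 segments are abnormal (the pattern that exceeds the
    segmental category and spans the tract's entire length)."""
    rows = _segment_rows(results)
    return len(_abnormal_segments(
        {key: row.significant for key, row in rows.items()})) == 5


# ---------------------------------------------------------------------------
# longitudinal rules

def classify_longitudinal(pre_results: Sequence[ComparisonResult],
                          post_results: Sequence[ComparisonResult],
                          cohort_scope: str | None = None,
                          ) -> list[AbnormalityLabel]:
    """De novo and reinforced labels for one tract instance.

    De novo: the counting rule met postsurgically by variables (or
    segment-variable pairs) not significant presurgically.  Reinforced:
    variables (pairs) significant at both timepoints with the same
    direction.  A tract may earn both labels on disjoint variable sets.
    """
    pre_g, post_g = _global_rows(pre_results), _global_rows(post_results)
    pre_s, post_s = _segment_rows(pre_results), _segment_rows(post_results)
    tract, lat, _, scope = _context(post_results, cohort_scope)
    labels: list[AbnormalityLabel] = []
    lo, hi = GLOBAL_CATEGORY_BAND

    de_novo = [v for v in ALL_VARIABLES
               if post_g[v].significant and not pre_g[v].significant]
    if lo <= len(de_novo) <= hi:
        labels.append(AbnormalityLabel(
            tract, lat, scope, "de-novo-global", "post",
            frozenset(de_novo),
            directions={v: post_g[v].direction for v in de_novo}))

    reinforced = [v for v in ALL_VARIABLES
                  if pre_g[v].significant and post_g[v].significant
                  and pre_g[v].direction == post_g[v].direction]
    if lo <= len(reinforced) <= hi:
        labels.append(AbnormalityLabel(
            tract, lat, scope, "reinforced-global", "post",
            frozenset(reinforced),
            directions={v: post_g[v].direction for v in reinforced}))

    new_pairs = {key: (post_s[key].significant
                       and not pre_s[key].significant)
                 for key in post_s}
    abnormal_new = _abnormal_segments(new_pairs)
    if 1 <= len(abnormal_new) <= MAX_ABNORMAL_SEGMENTS:
        variables = frozenset(v for vs in abnormal_new.values() for v in vs)
        directions: dict[str, int] = {}
        for s, vs in sorted(abnormal_new.items()):
            for v in vs:
                directions.setdefault(v, post_s[(v, s)].direction)
        labels.append(AbnormalityLabel(
            tract, lat, scope, "de-novo-segmental", "post", variables,
            frozenset(abnormal_new), directions))

    persist_pairs = {key: (pre_s[key].significant
                           and post_s[key].significant
                           and pre_s[key].direction == post_s[key].direction)
                     for key in post_s}
    abnormal_persist = _abnormal_segments(persist_pairs)
    if 1 <= len(abnormal_persist) <= MAX_ABNORMAL_SEGMENTS:
        variables = frozenset(v for vs in abnormal_persist.values()
                              for v in vs)
        directions = {}
        for s, vs in sorted(abnormal_persist.items()):
            for v in vs:
                directions.setdefault(v, post_s[(v, s)].direction)
        labels.append(AbnormalityLabel(
            tract, lat, scope, "reinforced-segmental", "post", variables,
            frozenset(abnormal_persist), directions))
    return labels


# ---------------------------------------------------------------------------
# whole-grid driver

def _split_instances(results: Iterable[ComparisonResult]
                     ) -> dict[tuple[str, str], list[ComparisonResult]]:
    grouped: dict[tuple[str, str], list[ComparisonResult]] = {}
    for r in results:
        grouped.setdefault((r.tract, r.laterality), []).append(r)
    return grouped


def intersect_pairs(results_a: Sequence[ComparisonResult],
                    results_b: Sequence[ComparisonResult],
                    ) -> list[ComparisonResult]:
    """Synthesize a "significant in both groups" grid.

    For the combined cohort scope, a contrast counts as significant only
    when both patient groups differ from controls in the same direction.
    The returned rows carry max(p) of the two contrasts and are marked
    skipped if either input row is.
    """
    index_b = {(r.tract, r.laterality, r.variable, r.scope): r
               for r in results_b}
    out: list[ComparisonResult] = []
    for ra in results_a:
        rb = index_b.get((ra.tract, ra.laterality, ra.variable, ra.scope))
        if rb is None:
            raise IncompleteGridError(
                f"no matching row for {ra.tract}/{ra.laterality}/"
                f"{ra.variable}/{ra.scope}")
        both = (ra.significant and rb.significant
                and ra.direction == rb.direction)
        out.append(replace(
            ra, group_a="patients", p_value=max(ra.p_value, rb.p_value),
            significant=both and not (ra.skipped or rb.skipped),
            skipped=ra.skipped or rb.skipped,
            direction=ra.direction if both else 0))
    return out


def classify_comparisons(pre_results: Sequence[ComparisonResult],
                         post_results: Sequence[ComparisonResult] | None = None,
                         cohort_scope: str | None = None,
                         ) -> tuple[list[AbnormalityLabel],
                                    list[tuple[str, str]]]:
    """Classify every tract instance of a (pre, optional post) grid.

    Returns the labels plus a not-evaluable list of (tract, laterality)
    instances whose grid rows were skipped at any required timepoint.
    """
    pre_by_inst = _split_instances(pre_results)
    post_by_inst = (_split_instances(post_results)
                    if post_results is not None else {})
    labels: list[AbnormalityLabel] = []
    not_evaluable: list[tuple[str, str]] = []
    for inst in tract_instances():
        pre_rows = pre_by_inst.get(inst, [])
        post_rows = post_by_inst.get(inst, [])
        pre_ok = pre_rows and not any(r.skipped for r in pre_rows)
        post_ok = post_rows and not any(r.skipped for r in post_rows)
        if pre_ok:
            for label in (classify_global(pre_rows, cohort_scope),
                          classify_segmental(pre_rows, cohort_scope)):
                if label:
                    labels.append(label)
        if post_ok:
            for label in (classify_global(post_rows, cohort_scope),
                          classify_segmental(post_rows, cohort_scope)):
                if label:
                    labels.append(label)
        if post_results is not None:
            if pre_ok and post_ok:
                labels.extend(classify_longitudinal(pre_rows, post_rows,
                                                    cohort_scope))
            elif not (pre_ok and post_ok):
                not_evaluable.append(inst)
        elif not pre_ok:
            not_evaluable.append(inst)
    return labels, not_evaluable


def taxonomy_report(labels: Iterable[AbnormalityLabel]) -> pd.DataFrame:
    """Deterministic count table: category x cohort scope x laterality x
    variable.  Empty input yields an all-zero table over the categories."""
    counter: Counter = Counter()
    for label in labels:
        for var in sorted(label.variables_involved):
            counter[(label.category, label.cohort_scope,
                     label.laterality, var)] += 1
    if not counter:
        rows = [{"category": cat, "cohort_scope": "", "laterality": "",
                 "variable": "", "count": 0} for cat in CATEGORIES]
        return pd.DataFrame(rows)
    rows = [{"category": cat, "cohort_scope": scope, "laterality": lat,
             "variable": var, "count": n}
            for (cat, scope, lat, var), n in sorted(counter.items())]
    return pd.DataFrame(rows)
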