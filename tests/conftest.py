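import numpy as np
import pytest

from tractquant import (AnalysisConfig, CohortSpec, ComparisonResult,
                        SubjectRecord, TractProfile)
from tractquant.constants import ALL_VARIABLES, SCALAR_VARIABLES


@pytest.fixture
def tiny_spec() -> CohortSpec:
    """A small but complete cohort: fast enough for per-test simulation."""
    return CohortSpec(n_controls=6, n_fle=3, n_tle=4, seed=123)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_subject(sid="P01", group="TLE", ioz="left", operated=True,
                 engel="I", **kw) -> SubjectRecord:
    if group == "control":
        return SubjectRecord(sid, "control", **kw)
    tps = frozenset({"pre", "post"}) if operated else frozenset({"pre"})
    return SubjectRecord(sid, group, operated=operated, ioz_side=ioz,
                         engel_class=engel if operated else "none",
                         timepoints_present=tps, **kw)


def make_profile(sid="P01", timepoint="pre", tract="CH", side="left",
                 fa=0.5, md=0.8, vol=15.0, fib=80, n_nodes=100,
                 valid=True) -> TractProfile:
    def arr(v):
        return np.full(n_nodes, float(v)) if np.isscalar(v) else np.asarray(v)
    return TractProfile(sid, timepoint, tract, side, arr(fa), arr(md),
                        arr(vol), fib=fib, valid=valid, n_nodes=n_nodes)


def make_result(var, scope, significant, tract="CH", lat="ipsi",
                timepoint="pre", direction=1, group_a="TLE",
                group_b="control", skipped=False) -> ComparisonResult:
    p = 0.01 if significant else 0.5
    return ComparisonResult(tract, lat, timepoint, var, scope, group_a,
                            group_b, n_a=12, n_b=19, mean_a=1.0 + direction,
                            mean_b=1.0, p_value=p, direction=direction,
                            significant=significant, skipped=skipped)


def grid_rows(global_sig=(), seg_sig=(), directions=None, **kw):
    """A complete 19-row tract-instance grid with chosen significant cells.

    ``global_sig``: variables significant at global scope; ``seg_sig``:
    (variable, segment) pairs significant segmentally; ``directions`` maps
    variable -> sign (default +1).
    """
    directions = directions or {}
    rows = []
    for var in ALL_VARIABLES:
        rows.append(make_result(var, "global", var in global_sig,
                                direction=directions.get(var, 1), **kw))
    for var in SCALAR_VARIABLES:
        for seg in range(1, 6):
            rows.append(make_result(var, seg, (var, seg) in seg_sig,
                                    direction=directions.get(var, 1), **kw))
    return rows
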