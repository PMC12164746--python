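"""Statistical machinery against independent brute-force oracles."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from tractquant import (AnalysisConfig, CohortSpec, DataError,
                        DegenerateVarianceError, EffectSpec, comparison_grid,
                        kruskal_wallis, lsd_anova, simulate_cohort,
                        summarize_profile)
from tractquant.stats import SCOPE_COLUMNS

from conftest import make_profile, make_subject


# ---------------------------------------------------------------------------
# brute-force oracles (independent code paths)

def kw_oracle(groups):
    """Classic rank-sum Kruskal-Wallis with explicit tie correction."""
    pooled = np.concatenate(list(groups.values()))
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start, h = 0, 0.0
    for vals in groups.values():
        r = ranks[start:start + len(vals)]
        h += r.sum() ** 2 / len(vals)
        start += len(vals)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    h /= correction
    p = sps.chi2.sf(h, len(groups) - 1)
    return h, p


def anova_lsd_oracle(groups):
    """Explicit sums-of-squares decomposition plus pooled-variance LSD t."""
    labels = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    all_y = np.concatenate(list(data.values()))
    grand = all_y.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    g, n = len(labels), len(all_y)
    df_e = n - g
    msw = ssw / df_e
    f = (ssb / (g - 1)) / msw
    omnibus_p = sps.f.sf(f, g - 1, df_e)
    pairwise = {}
    for i in range(g):
        for j in range(i + 1, g):
            a, b = data[labels[i]], data[labels[j]]
            diff = a.mean() - b.mean()
            t = diff / np.sqrt(msw * (1 / len(a) + 1 / len(b)))
            pairwise[(labels[i], labels[j])] = (
                diff, 2 * sps.t.sf(abs(t), df_e))
    return f, omnibus_p, pairwise


# ---------------------------------------------------------------------------
# Kruskal-Wallis

class TestKruskalWallis:
    def test_hand_computed_two_group_instance(self):
        h, p = kruskal_wallis({"A": [1, 2, 3], "B": [4, 5, 6]})
        assert h == pytest.approx(3.857, abs=5e-4)

    def test_identical_multisets_give_zero(self):
        h, p = kruskal_wallis({"A": [1, 2, 3], "B": [1, 2, 3]})
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_values_identical(self):
        h, p = kruskal_wallis({"A": [2, 2], "B": [2, 2, 2]})
        assert (h, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            kruskal_wallis({"A": [1.0], "B": []})

    def test_matches_tie_corrected_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            g = rng.integers(2, 4)
            groups = {f"g{i}": rng.integers(0, 6, rng.integers(3, 12))
                      .astype(float) for i in range(g)}
            if len(np.unique(np.concatenate(list(groups.values())))) < 2:
                continue
            h, p = kruskal_wallis(groups)
            h0, p0 = kw_oracle(groups)
            assert h == pytest.approx(h0, rel=1e-10)
            assert p == pytest.approx(p0, rel=1e-10)


# ---------------------------------------------------------------------------
# ANOVA / LSD

class TestLsdAnova:
    def test_three_identical_groups(self):
        res = lsd_anova({"a": [0, 1, 2], "b": [0, 1, 2], "c": [0, 1, 2]})
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert all(c.p_value == pytest.approx(1.0)
                   for c in res.pairwise.values())

    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 13)
        res = lsd_anova({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.pairwise[("a", "b")].p_value == pytest.approx(p,
                                                                 rel=1e-10)
        assert res.omnibus_p == pytest.approx(p, rel=1e-10)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            g = rng.integers(2, 5)
            groups = {f"g{i}": rng.normal(rng.normal(), 1.0,
                                          rng.integers(2, 10))
                      for i in range(g)}
            if sum(len(v) for v in groups.values()) - g < 1:
                continue
            res = lsd_anova(groups)
            f0, p0, pw0 = anova_lsd_oracle(groups)
            assert res.f_stat == pytest.approx(f0, rel=1e-10, abs=1e-12)
            assert res.omnibus_p == pytest.approx(p0, rel=1e-10)
            for pair, (diff0, p_pair0) in pw0.items():
                c = res.pairwise[pair]
                assert c.mean_diff == pytest.approx(diff0, rel=1e-10,
                                                    abs=1e-12)
                assert c.p_value == pytest.approx(p_pair0, rel=1e-10)

    def test_label_permutation_flips_direction_keeps_p(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        fwd = lsd_anova({"a": a, "b": b}).pairwise[("a", "b")]
        rev = lsd_anova({"b": b, "a": a}).pairwise[("b", "a")]
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff, rel=1e-12)

    def test_zero_variance_everywhere_raises(self):
        with pytest.raises(DegenerateVarianceError):
            lsd_anova({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0]})

    def test_ancova_with_no_covariates_reduces_to_anova(self):
        rng = np.random.default_rng(11)
        groups = {k: rng.normal(0, 1, 7) for k in "abc"}
        plain = lsd_anova(groups)
        empty = lsd_anova(groups, covariates={})
        assert empty.f_stat == pytest.approx(plain.f_stat, rel=1e-12)
        for pair in plain.pairwise:
            assert (empty.pairwise[pair].p_value
                    == pytest.approx(plain.pairwise[pair].p_value,
                                     rel=1e-12))

    def test_ancova_matches_statsmodels_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(21)
        groups = {"ctl": rng.normal(0.0, 1.0, 12),
                  "pat": rng.normal(0.6, 1.0, 10)}
        age = {"ctl": rng.uniform(20, 60, 12), "pat": rng.uniform(20, 60, 10)}
        res = lsd_anova(groups, covariates={"age": age})
        y = np.concatenate([groups["ctl"], groups["pat"]])
        dummy = np.concatenate([np.zeros(12), np.ones(10)])
        x = sm.add_constant(np.column_stack(
            [dummy, np.concatenate([age["ctl"], age["pat"]])]))
        fit = sm.OLS(y, x).fit()
        assert res.pairwise[("ctl", "pat")].p_value == pytest.approx(
            fit.pvalues[1], rel=1e-8)
        assert res.pairwise[("ctl", "pat")].mean_diff == pytest.approx(
            -fit.params[1], rel=1e-8)


# ---------------------------------------------------------------------------
# the comparison grid

def _cohort(seed=31, effects=(), **kw):
    spec = CohortSpec(n_controls=6, n_fle=3, n_tle=4,
                      ioz_side_policy="all-left", effects=effects,
                      seed=seed, **kw)
    subjects, profiles = simulate_cohort(spec)
    summaries = [summarize_profile(p) for p in profiles if p.valid]
    return spec, subjects, profiles, summaries


class TestComparisonGrid:
    def test_scope_arithmetic_209_rows_per_pair(self):
        _, subjects, _, summaries = _cohort()
        grid = comparison_grid(summaries, subjects, timepoint="pre")
        per_pair = {}
        for r in grid:
            per_pair[(r.group_a, r.group_b)] = per_pair.get(
                (r.group_a, r.group_b), 0) + 1
        assert per_pair == {("FLE", "control"): 209,
                            ("TLE", "control"): 209}
        # 19 scopes per tract instance: 4 global + 3 x 5 segmental
        assert len(SCOPE_COLUMNS) == 19

    def test_planted_md_increase_detected_with_positive_direction(self):
        eff = EffectSpec("CH", "MD", +0.4, target_group="TLE",
                         laterality="ipsi")
        _, subjects, _, summaries = _cohort(effects=(eff,))
        grid = comparison_grid(summaries, subjects, restrict_to="TLE")
        cell = [r for r in grid if r.tract == "CH" and r.laterality == "ipsi"
                and r.variable == "MD" and r.scope == "global"][0]
        assert cell.significant and cell.direction == +1

    def test_invalid_profile_marks_instance_skipped_not_dropped(self):
        _, subjects, profiles, _ = _cohort()
        # invalidate one control's left CH
        broken = [dataclasses.replace(p, valid=False)
                  if (p.tract == "CH" and p.side == "left"
                      and p.subject_id == "C01") else p
                  for p in profiles]
        summaries = [summarize_profile(p) for p in broken if p.valid]
        grid = comparison_grid(summaries, subjects, timepoint="pre")
        ch_rows = [r for r in grid if r.tract == "CH"
                   and r.laterality in ("ipsi", "contra")]
        assert len(ch_rows) == 2 * 19 * 2          # both pairs, both sides
        assert all(r.skipped for r in ch_rows)      # pooled controls short
        other = [r for r in grid if r.tract != "CH"]
        assert not any(r.skipped for r in other)
        assert len(grid) == 418

    def test_outcome_grouping_compares_engel_classes(self):
        _, subjects, _, summaries = _cohort()
        grid = comparison_grid(summaries, subjects, grouping="outcome",
                               timepoint="post")
        assert {(r.group_a, r.group_b) for r in grid} == {
            ("seizure-free", "recurrence")}
        assert len(grid) == 209

    def test_outcome_with_empty_class_rejected(self):
        subjects = [make_subject(f"P{i}", engel="I") for i in range(4)]
        subjects += [make_subject(f"C{i}", group="control")
                     for i in range(4)]
        summaries = [summarize_profile(make_profile(sid=s.subject_id))
                     for s in subjects]
        with pytest.raises(DataError):
            comparison_grid(summaries, subjects, grouping="outcome")

    def test_grid_cell_p_matches_scalar_lsd_anova(self):
        # the vectorized grid engine and the regression-based scalar op
        # are independent code paths; they must agree
        _, subjects, _, summaries = _cohort()
        grid = comparison_grid(summaries, subjects, timepoint="pre")
        cell = [r for r in grid if r.tract == "ILF"
                and r.laterality == "ipsi" and r.variable == "FA"
                and r.scope == "global"][0]
        groups = {"control": [], "FLE": [], "TLE": []}
        by_id = {s.subject_id: s for s in subjects}
        from tractquant import combine_control_sides, recode_laterality
        pats = recode_laterality(
            [s for s in summaries if by_id[s.subject_id].is_patient],
            subjects)
        ctls = combine_control_sides(
            [s for s in summaries if not by_id[s.subject_id].is_patient])
        for s in pats + ctls:
            if s.tract != "ILF" or s.timepoint != "pre":
                continue
            if s.laterality == "ipsi":
                groups[by_id[s.subject_id].group].append(
                    s.global_means["FA"])
            elif s.laterality == "pooled-control":
                groups["control"].append(s.global_means["FA"])
        res = lsd_anova(groups)
        want = res.pairwise[(cell.group_b, cell.group_a)].p_value
        assert cell.p_value == pytest.approx(want, rel=1e-9)

    def test_benjamini_hochberg_never_adds_significance(self):
        eff = EffectSpec("CH", "MD", +0.4, target_group="TLE",
                         laterality="ipsi")
        _, subjects, _, summaries = _cohort(effects=(eff,))
        raw = comparison_grid(summaries, subjects)
        adj = comparison_grid(summaries, subjects,
                              config=AnalysisConfig(
                                  multiplicity="benjamini-hochberg"))
        sig_raw = {i for i, r in enumerate(raw) if r.significant}
        sig_adj = {i for i, r in enumerate(adj) if r.significant}
        assert sig_adj <= sig_raw
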