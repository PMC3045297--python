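"""Propensity fits, greedy caliper matching vs an exhaustive replay oracle,
three-step cohort construction, balance diagnostics and placebo poolability."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from psbridge import propensity_matching as pm
from psbridge import synthetic_trials as st
from psbridge import trial_data as td
from psbridge.propensity_matching import (
    MatchingError, fit_propensity, greedy_caliper_match,
    build_matched_population, balance_table, placebo_poolability,
    standardized_mean_difference,
)

from conftest import make_subject, make_visit


# ---------------------------------------------------------------------------
# independent oracle: literal replay of the pass rules with explicit lists

def oracle_match(cases, controls, caliper):
    """Brute-force hierarchical matching: repeat passes over cases in
    ascending id order; each case takes the closest free control within the
    caliper, ties to the lower control id; stop when a pass adds nothing."""
    free = dict(controls)
    pairs = []
    while True:
        added = False
        for cid in sorted(dict(cases)):
            cscore = dict(cases)[cid]
            candidates = [(abs(cscore - s), kid) for kid, s in free.items()
                          if abs(cscore - s) <= caliper]
            if candidates:
                d, kid = min(candidates)
                pairs.append((cid, kid))
                del free[kid]
                added = True
        if not added:
            break
    return pairs


class TestGreedyCaliperMatch:
    def test_exact_score_match_pairs_at_distance_zero(self):
        res = greedy_caliper_match({"A": 0.50}, {"X": 0.50}, 0.05)
        assert len(res.pairs) == 1
        p = res.pairs[0]
        assert (p.case_id, p.control_id, p.distance) == ("A", "X", 0.0)

    def test_control_outside_caliper_is_not_matched(self):
        res = greedy_caliper_match({"A": 0.50}, {"X": 0.60}, 0.05)
        assert res.pairs == []
        assert res.unmatched_cases == ["A"]
        assert res.unmatched_controls == ["X"]

    def test_empty_inputs_yield_empty_result(self):
        res = greedy_caliper_match({}, {"X": 0.5}, 0.05)
        assert res.pairs == [] and res.unmatched_controls == ["X"]
        res = greedy_caliper_match({"A": 0.5}, {}, 0.05)
        assert res.pairs == [] and res.unmatched_cases == ["A"]

    def test_one_to_many_growth_across_passes(self):
        # one case, three reachable controls: one claim per pass
        res = greedy_caliper_match({"A": 0.50},
                                   {"X": 0.50, "Y": 0.52, "Z": 0.48}, 0.05)
        assert [p.pass_index for p in res.pairs] == [1, 2, 3]
        # Y and Z are equidistant from A: the lower control id wins pass 2
        assert [p.control_id for p in res.pairs] == ["X", "Y", "Z"]

    def test_max_ratio_caps_controls_per_case(self):
        res = greedy_caliper_match({"A": 0.50},
                                   {"X": 0.50, "Y": 0.52}, 0.05, max_ratio=1)
        assert len(res.pairs) == 1

    def test_equidistant_tie_goes_to_lower_control_id(self):
        res = greedy_caliper_match({"A": 0.50}, {"Y": 0.52, "X": 0.48}, 0.05)
        assert res.pairs[0].control_id == "X"

    def test_invalid_caliper_and_scores_rejected(self):
        with pytest.raises(ValueError, match="caliper"):
            greedy_caliper_match({"A": 0.5}, {"X": 0.5}, 0.0)
        with pytest.raises(ValueError, match="strictly"):
            greedy_caliper_match({"A": 1.0}, {"X": 0.5}, 0.05)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(hst.data())
    def test_matches_exhaustive_replay_oracle(self, data):
        """On every instance up to 6 cases x 8 controls the implementation
        emits exactly the oracle's pair set in the oracle's order."""
        ncase = data.draw(hst.integers(1, 6))
        nctrl = data.draw(hst.integers(1, 8))
        score = hst.floats(0.01, 0.99, allow_nan=False)
        cases = {f"c{i}": data.draw(score) for i in range(ncase)}
        controls = {f"k{i}": data.draw(score) for i in range(nctrl)}
        caliper = data.draw(hst.sampled_from([0.01, 0.05, 0.2, 1.0]))
        res = greedy_caliper_match(cases, controls, caliper)
        assert [(p.case_id, p.control_id) for p in res.pairs] == \
            oracle_match(cases, controls, caliper)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.data())
    def test_structural_invariants(self, data):
        """No pair violates the caliper; each control used at most once;
        pass indices are non-decreasing; relabeling controls permutes ids
        but preserves the matched score multiset."""
        score = hst.floats(0.01, 0.99, allow_nan=False)
        cases = {f"c{i}": data.draw(score) for i in range(data.draw(hst.integers(1, 5)))}
        controls = {f"k{i}": data.draw(score) for i in range(data.draw(hst.integers(1, 7)))}
        res = greedy_caliper_match(cases, controls, 0.05)
        assert all(p.distance <= 0.05 for p in res.pairs)
        used = [p.control_id for p in res.pairs]
        assert len(used) == len(set(used))
        assert all(a.pass_index <= b.pass_index
                   for a, b in zip(res.pairs, res.pairs[1:])
                   if a.case_id == b.case_id)
        relabeled = {f"z{i}": s for i, (_, s) in enumerate(sorted(controls.items()))}
        res2 = greedy_caliper_match(cases, relabeled, 0.05)
        assert sorted(p.control_score for p in res2.pairs) == \
            sorted(p.control_score for p in res.pairs)


# ---------------------------------------------------------------------------
# propensity model

def two_group_subjects(n_per_group=20, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    subs, indicator = [], {}
    for g, (program, dose, trial, group) in enumerate(
            (("PALI", 9.0, "PALI-SCH-303", "PALI_6_12"),
             ("RIS", 3.0, "RIS-INT-3", "RIS_2_4"))):
        for i in range(n_per_group):
            sid = f"{program}{i:03d}"
            subs.append(make_subject(
                sid, trial_id=trial, compound_program=program,
                modal_dose_mg=dose, treatment_group=group,
                age=float(np.clip(rng.normal(36 + g * shift, 8), 18, 65)),
                sex="female" if rng.random() < 0.3 else "male",
                race="white" if rng.random() < 0.7 else "other",
                bmi=float(np.clip(rng.normal(25, 3), 16, 45)),
                baseline_panss_total=int(np.clip(rng.normal(90, 10), 70, 120)),
                baseline_cgi_s=int(np.clip(round(rng.normal(4.7, 0.7)), 1, 7))))
            indicator[sid] = 1 - g
    return subs, indicator


class TestFitPropensity:
    def test_constant_covariates_give_prevalence_scores(self):
        subs = [make_subject(f"A{i}") for i in range(4)] + \
            [make_subject(f"B{i}", trial_id="RIS-INT-3", compound_program="RIS",
                          modal_dose_mg=3.0, treatment_group="RIS_2_4")
             for i in range(8)]
        indicator = {s.subject_id: int(s.compound_program == "PALI") for s in subs}
        model = fit_propensity(subs, indicator)
        assert np.allclose(model.scores, 4 / 12, atol=1e-8)
        assert len(model.dropped_covariates) == 6  # all constant

    def test_single_binary_covariate_matches_2x2_log_odds(self):
        # sex is the only varying covariate; cells (group x female) all nonzero
        subs, indicator = [], {}
        layout = [(1, "female", 3), (1, "male", 2), (0, "female", 1), (0, "male", 4)]
        k = 0
        for y, sex, count in layout:
            for _ in range(count):
                sid = f"S{k}"; k += 1
                subs.append(make_subject(sid, sex=sex))
                indicator[sid] = y
        model = fit_propensity(subs, indicator, covariates=("sex",))
        odds_ratio = (3 * 4) / (2 * 1)
        assert model.params["female"] == pytest.approx(math.log(odds_ratio), abs=1e-6)

    def test_duplicated_rows_leave_scores_unchanged(self):
        subs, indicator = two_group_subjects(15, seed=3)
        model1 = fit_propensity(subs, indicator)
        doubled = subs + [dataclasses.replace(s, subject_id=s.subject_id + "dup")
                          for s in subs]
        ind2 = dict(indicator)
        ind2.update({s.subject_id + "dup": indicator[s.subject_id] for s in subs})
        model2 = fit_propensity(doubled, ind2)
        for s in subs:
            assert model2.scores[s.subject_id] == \
                pytest.approx(model1.scores[s.subject_id], abs=1e-8)

    def test_refit_reproduces_coefficients(self):
        subs, indicator = two_group_subjects(25, seed=4)
        a = fit_propensity(subs, indicator)
        b = fit_propensity(subs, indicator)
        assert np.allclose(a.params, b.params, atol=1e-10)
        assert a.scores.between(0, 1, inclusive="neither").all()

    def test_perfect_separation_raises_with_advice(self):
        subs, indicator = [], {}
        for i in range(10):
            sid = f"S{i}"
            subs.append(make_subject(sid, age=25.0 if i < 5 else 55.0))
            indicator[sid] = int(i < 5)
        with pytest.raises(MatchingError, match="separation"):
            fit_propensity(subs, indicator, covariates=("age",))

    def test_too_few_subjects_raises(self):
        subs, indicator = two_group_subjects(2, seed=0)
        with pytest.raises(MatchingError, match="too few|at least"):
            fit_propensity(subs[:4], {k: indicator[k]
                                      for k in list(indicator)[:4]})


# ---------------------------------------------------------------------------
# matched population

class TestBuildMatchedPopulation:
    def test_wide_caliper_retains_everyone(self):
        subs, _, _ = st.generate_cohort(st.default_suite(), seed=2)
        mp = build_matched_population(subs, caliper=1.0)
        members = td.group_members(subs)
        for g in ("PALI_6_12", "RIS_2_4", "RIS_4_6"):
            assert sorted(mp.groups[g]) == sorted(members[g])

    def test_default_suite_group_sizes_track_published_counts(self):
        """Across seeds the mean retained sizes stay within 15% of the
        published matched-population counts (179, 113, 129, 95, 122)."""
        targets = {"PALI_6_12": 179, "RIS_2_4": 113, "RIS_4_6": 129,
                   "PLACEBO_PALI": 95, "PLACEBO_RIS": 122}
        sizes = {g: [] for g in targets}
        for seed in range(6):
            subs, _, _ = st.generate_cohort(st.default_suite(), seed=seed)
            mp = build_matched_population(subs)
            for g, n in mp.group_sizes().items():
                sizes[g].append(n)
        for g, t in targets.items():
            assert abs(np.mean(sizes[g]) - t) <= 0.15 * t

    def test_disjoint_score_supports_raise_named_step(self):
        subs, _, _ = st.generate_cohort(st.default_suite(), seed=0)
        # force cross-compound disjointness through an extreme age gap
        forced = [dataclasses.replace(s, age=20.0 if s.compound_program == "PALI"
                                      else 64.0) for s in subs]
        with pytest.raises(MatchingError):
            build_matched_population(forced, caliper=0.01)

    def test_dual_membership_preserved_in_final_groups(self):
        subs, _, _ = st.generate_cohort(st.default_suite(), seed=1)
        mp = build_matched_population(subs)
        by_id = {s.subject_id: s for s in subs}
        dual = [i for i in mp.groups["RIS_2_4"]
                if by_id[i].modal_dose_mg == 4.0]
        assert dual and all(i in mp.groups["RIS_4_6"] for i in dual)


# ---------------------------------------------------------------------------
# balance diagnostics

class TestBalance:
    def test_group_compared_with_itself_is_perfectly_balanced(self):
        subs, _ = two_group_subjects(15, seed=5)
        ids = [s.subject_id for s in subs[:15]]
        bal = balance_table(subs, {"A": ids, "B": ids})
        assert (bal.smd[[c for c, _ in pm._BALANCE_COVARIATES]].to_numpy()
                == 0.0).all()

    def test_equal_means_unequal_sds_give_zero_smd(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.0, 2.0, 4.0])
        assert standardized_mean_difference(x, y) == 0.0

    def test_matching_shrinks_imbalance_on_confounded_assignment(self):
        """With a deliberately shifted paliperidone population, matching
        reduces the cross-compound standardized differences for most
        covariates (at least covariates-1 of them) in the median run."""
        covs = [c for c, _ in pm._BALANCE_COVARIATES]
        improved_counts = []
        for seed in range(10):
            suite = st.with_covariate_shift(st.default_suite(), "PALI",
                                            age_shift=4.0, bmi_shift=1.5,
                                            panss_shift=4.0)
            subs, _, _ = st.generate_cohort(suite, seed=seed)
            members = td.group_members(subs)
            pali = members["PALI_6_12"]
            ris = sorted(set(members["RIS_2_4"]) | set(members["RIS_4_6"]))
            pre = balance_table(subs, {"PALI": pali, "RIS": ris}).smd.iloc[0]
            mp = build_matched_population(subs)
            post_pali = mp.groups["PALI_6_12"]
            post_ris = sorted(set(mp.groups["RIS_2_4"]) | set(mp.groups["RIS_4_6"]))
            post = balance_table(subs, {"PALI": post_pali, "RIS": post_ris}).smd.iloc[0]
            improved_counts.append(sum(post[c] <= pre[c] + 1e-12 for c in covs))
        assert np.median(improved_counts) >= len(covs) - 1


# ---------------------------------------------------------------------------
# placebo poolability

def placebo_pair_cohort(effect_a=-6.5, effect_b=-5.4, n=95, seed=0):
    suite = st.default_suite()
    arms = []
    for arm in suite.arms:
        if arm.modal_dose_mg is None:
            eff = effect_a if arm.compound_program == "PALI" else effect_b
            arms.append(dataclasses.replace(arm, endpoint_effect=eff))
    return st.generate_cohort(
        dataclasses.replace(suite, arms=tuple(arms)), seed=seed)


class TestPlaceboPoolability:
    def test_published_scale_difference_usually_pools(self):
        """Placebo endpoint effects of -6.5 vs -5.4 at the published group
        sizes are indistinguishable in most replicates (published analogue
        p = 0.768)."""
        pooled = 0
        for seed in range(12):
            subs, vis, _ = placebo_pair_cohort(seed=seed)
            res = placebo_poolability(subs, vis)
            pooled += res.pool
        assert pooled >= 8

    def test_fifteen_point_difference_blocks_pooling(self):
        """A 15-point PANSS gap at these sample sizes is essentially always
        detected, so the groups are not pooled."""
        blocked = 0
        for seed in range(5):
            subs, vis, _ = placebo_pair_cohort(effect_b=-21.5, seed=seed)
            res = placebo_poolability(subs, vis)
            blocked += not res.pool
        assert blocked >= 4

    def test_evidence_table_contains_baseline_and_endpoint_rows(self):
        subs, vis, _ = placebo_pair_cohort(seed=1)
        res = placebo_poolability(subs, vis)
        kinds = set(res.evidence["kind"])
        assert kinds == {"baseline", "endpoint_change"}

    def test_one_empty_group_raises(self):
        subs, vis, _ = placebo_pair_cohort(seed=0)
        only_pali = [s for s in subs if s.treatment_group != "PLACEBO_RIS"]
        with pytest.raises(MatchingError):
            placebo_poolability(only_pali, vis)
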