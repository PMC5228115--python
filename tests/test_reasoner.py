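"""Reasoning engine: tag resolution, rule evaluation, classification, metarules."""

import pytest
from hypothesis import given, settings, strategies as st

from patheval.guideline import CombiningRule, ThresholdTerm
from patheval.reasoner import (EvidenceTag, StrengthProfile, TagValidationError,
                               classify, classify_profile, evaluate_rule,
                               parse_tag_list, parse_tag_token, resolve_tags,
                               strength_profile)
from patheval.testkit import TagSetSpec, enumerate_profiles, random_tagset


class TestTagParsing:
    @pytest.mark.parametrize("token, code, strength", [
        ("PS1", "PS1", None),
        ("ps1", "PS1", None),
        ("PVS1_Strong", "PVS1", "strong"),
        ("pvs1-strong", "PVS1", "strong"),
        ("PP1_Very_Strong", "PP1", "very_strong"),
        ("PP1_Very-Strong", "PP1", "very_strong"),
        ("BA1_Supporting", "BA1", "supporting"),
    ])
    def test_token_grammar(self, acmg, token, code, strength):
        tag = parse_tag_token(token, acmg)
        assert (tag.code, tag.strength) == (code, strength)

    def test_unknown_code_named(self, acmg):
        with pytest.raises(TagValidationError, match="PX9"):
            parse_tag_token("PX9", acmg)

    def test_unknown_level_named(self, acmg):
        with pytest.raises(TagValidationError, match="mega"):
            parse_tag_token("PS1_mega", acmg)

    def test_list_collects_every_problem(self, acmg):
        with pytest.raises(TagValidationError) as err:
            parse_tag_list("PS1,PX9,BQ2", acmg)
        assert "PX9" in str(err.value) and "BQ2" in str(err.value)

    def test_direction_change_rejected(self, acmg):
        # a pathogenic code may change strength, never direction
        with pytest.raises(TagValidationError, match="stand_alone"):
            resolve_tags([EvidenceTag(code="PS1", strength="stand_alone")], acmg)


class TestStrengthProfile:
    def test_reweighted_tag_counts_at_applied_strength(self, acmg):
        p = strength_profile(parse_tag_list("PVS1_Strong,PS1", acmg), acmg)
        assert p.counts == {("pathogenic", "strong"): 2}

    def test_empty(self, acmg):
        assert strength_profile([], acmg).counts == {}

    def test_duplicate_code_rejected(self, acmg):
        with pytest.raises(TagValidationError, match="PS3"):
            strength_profile([EvidenceTag(code="PS3"), EvidenceTag(code="ps3")], acmg)

    def test_display_names(self, acmg):
        tags = resolve_tags(parse_tag_list("PVS1_Strong,PS1", acmg), acmg)
        assert sorted(rt.display_name for rt in tags) == ["PS1", "PVS1_Strong"]

    @given(st.lists(st.sampled_from(
        ["PVS1", "PS1", "PS2", "PM1", "PM2", "PP1", "BA1", "BS1", "BP1"]),
        unique=True, max_size=9))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_counts_sum_to_tag_count(self, acmg, codes):
        p = strength_profile([EvidenceTag(code=c) for c in codes], acmg)
        assert p.total == len(codes)


class TestEvaluateRule:
    two_strong = CombiningRule(
        rule_id="r", conclusion="Pathogenic",
        terms=(ThresholdTerm(direction="pathogenic", strength="strong", min_count=2),))

    def test_satisfied(self):
        account = evaluate_rule(self.two_strong,
                                StrengthProfile({("pathogenic", "strong"): 2}))
        assert account.satisfied

    def test_unsatisfied_shows_required_vs_observed(self):
        account = evaluate_rule(self.two_strong,
                                StrengthProfile({("pathogenic", "strong"): 1}))
        assert not account.satisfied
        assert (account.terms[0].observed, account.terms[0].required_min) == (1, 2)

    def test_bounded_range_exceeded(self):
        rule = CombiningRule(
            rule_id="r", conclusion="Likely Pathogenic",
            terms=(ThresholdTerm(direction="pathogenic", strength="moderate",
                                 min_count=1, max_count=2),
                   ThresholdTerm(direction="pathogenic", strength="supporting",
                                 min_count=2)))
        profile = StrengthProfile({("pathogenic", "moderate"): 3,
                                   ("pathogenic", "supporting"): 2})
        account = evaluate_rule(rule, profile)
        assert not account.satisfied
        assert account.terms[0].observed == 3 and account.terms[0].required_max == 2


class TestClassify:
    @pytest.mark.parametrize("tags, conclusion, flavor", [
        ("PS1,PS2,PM1,PM2,PM3", "Pathogenic", "not_applicable"),
        ("BS1,BS2,BP1", "Benign", "not_applicable"),
        ("", "Uncertain Significance", "insufficient_evidence"),
        ("PS1,PS2,BS1,BS2", "Uncertain Significance", "conflicting_evidence"),
        ("PVS1", "Uncertain Significance", "insufficient_evidence"),
        ("PVS1_Strong,PS1", "Pathogenic", "not_applicable"),
        ("PVS1,PM1", "Likely Pathogenic", "not_applicable"),
        ("BP1,BP2", "Likely Benign", "not_applicable"),
        ("PP1,BP1", "Uncertain Significance", "insufficient_evidence"),
    ])
    def test_worked_examples(self, acmg, tags, conclusion, flavor):
        result = classify(parse_tag_list(tags, acmg), acmg)
        assert (result.conclusion, result.vus_flavor) == (conclusion, flavor)

    def test_precedence_records_both_conclusions(self, acmg):
        result = classify(parse_tag_list("PS1,PS2,PM1,PM2,PM3", acmg), acmg)
        assert set(result.candidate_conclusions) == {"Pathogenic", "Likely Pathogenic"}
        assert result.metarule == "precedence"

    def test_lone_benign_supporting_does_not_force_conflict(self, acmg):
        # conflict is rule-level: a stray BP tag beside a satisfied Pathogenic
        # rule must not drag the call down to uncertain significance
        result = classify(parse_tag_list("PS1,PS2,BP1", acmg), acmg)
        assert result.conclusion == "Pathogenic"

    def test_tag_scope_policy_option(self, guideline_dict):
        from patheval.guideline import Guideline
        guideline_dict["metarules"]["conflict_scope"] = "tag"
        g = Guideline.model_validate(guideline_dict)
        result = classify(parse_tag_list("PS1,PS2,BP1", g), g)
        assert result.vus_flavor == "conflicting_evidence"

    def test_conflict_provenance_names_the_vus_rule(self, acmg):
        result = classify(parse_tag_list("PS1,PS2,BS1,BS2", acmg), acmg)
        assert result.fired_rule_id == "vus_conflicting"
        assert classify([], acmg).fired_rule_id == "vus_insufficient"

    @given(st.permutations(["PS1", "PS2", "PM1", "BP1", "PVS1_Strong"]))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_order_invariance(self, acmg, order):
        result = classify(parse_tag_list(",".join(order), acmg), acmg)
        baseline = classify(parse_tag_list("PS1,PS2,PM1,BP1,PVS1_Strong", acmg), acmg)
        assert result == baseline


PATH_RANK = {"Pathogenic": 2, "Likely Pathogenic": 1}
BENIGN_RANK = {"Benign": 2, "Likely Benign": 1}


def _dir_profiles(g, direction, max_count):
    cells = [(lv.direction, lv.level_id) for lv in g.levels_for(direction)]
    from itertools import product
    for combo in product(range(max_count + 1), repeat=len(cells)):
        yield StrengthProfile({c: n for c, n in zip(cells, combo) if n})


class TestOrderingProperties:
    @pytest.mark.parametrize("direction, rank", [("pathogenic", PATH_RANK),
                                                 ("benign", BENIGN_RANK)])
    def test_adding_same_direction_tag_is_monotone(self, acmg, direction, rank):
        """More same-direction evidence never weakens a one-sided conclusion."""
        for profile in _dir_profiles(acmg, direction, 3):
            before = rank.get(classify_profile(profile, acmg).conclusion, 0)
            for lv in acmg.levels_for(direction):
                counts = dict(profile.counts)
                cell = (direction, lv.level_id)
                counts[cell] = counts.get(cell, 0) + 1
                after = rank.get(classify_profile(StrengthProfile(counts), acmg).conclusion, 0)
                assert after >= before, (profile.counts, cell)

    def test_lowering_applied_strength_never_strengthens(self, acmg):
        """Re-weighting one tag downward cannot strengthen the conclusion.

        Checked over profiles with at most one very-strong tag: the published
        combining table assumes a single very-strong criterion, so a second
        very-strong tag contributes nothing until down-weighted — outside that
        domain the monotonicity deliberately does not hold.
        """
        for direction, rank in (("pathogenic", PATH_RANK), ("benign", BENIGN_RANK)):
            levels = acmg.levels_for(direction)  # strongest first
            for profile in _dir_profiles(acmg, direction, 3):
                if profile.count("pathogenic", "very_strong") > 1:
                    continue
                before = rank.get(classify_profile(profile, acmg).conclusion, 0)
                for i, src in enumerate(levels):
                    if not profile.count(direction, src.level_id):
                        continue
                    for dst in levels[i + 1:]:
                        counts = dict(profile.counts)
                        counts[(direction, src.level_id)] -= 1
                        if not counts[(direction, src.level_id)]:
                            del counts[(direction, src.level_id)]
                        cell = (direction, dst.level_id)
                        counts[cell] = counts.get(cell, 0) + 1
                        after = rank.get(
                            classify_profile(StrengthProfile(counts), acmg).conclusion, 0)
                        assert after <= before, (profile.counts, src.level_id, dst.level_id)


class TestProvenanceCompleteness:
    @pytest.mark.parametrize("seed", range(30))
    def test_conclusion_recomputable_from_satisfied_rules(self, acmg, seed):
        """satisfied_rules + the metarule policy alone reproduce the conclusion."""
        tags = random_tagset(TagSetSpec(seed=seed), acmg)
        result = classify(tags, acmg)
        directions = {r.direction for r in result.satisfied_rules}
        policy = acmg.metarules
        if {"pathogenic", "benign"} <= directions:
            expected = policy.conflict_conclusion
        elif result.satisfied_rules:
            reached = {r.conclusion for r in result.satisfied_rules}
            expected = next(t for t in policy.precedence if t in reached)
        else:
            expected = policy.insufficient_conclusion
        assert result.conclusion == expected
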