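"""Context paths, uniqueness validation, tree building, rule configs."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depot.context import (ContextTreeRule, InMemoryGraph, build_tree,
                           context_path, load_rules, validate_uniqueness)
from depot.errors import (CollisionError, MissingAttributeError,
                          RuleConfigError, RuleNotApplicableError)

SWC_ATTRS = {"FORMAT": "SWC", "LABOR_STATE": "forager", "REGION": "left_DL",
             "HONEYBEE_ID": "HB130427", "SIGEN_PARAMETERS": "D20V05C01S01"}


def graph_with(*units):
    g = InMemoryGraph()
    for uid, attrs, members in units:
        g.add_unit(uid, attrs, members)
    return g


class TestContextPath:
    def test_morphology_view_golden_path(self, alpha_rule):
        g = graph_with(("u1", SWC_ATTRS, ["seg.swc"]))
        cp = context_path("u1", alpha_rule, g)
        assert cp.as_posix() == "forager/left_DL/HB130427/D20V05C01S01/morphology.swc"

    def test_imaging_view_member_leaves(self, beta_rule):
        g = graph_with(("u2", {"FORMAT": "TIFF_STACK", "HONEYBEE_ID": "HB130427",
                               "REGION": "left-DL"},
                        ["s_001.tiff", "s_002.tiff"]))
        cp = context_path("u2", beta_rule, g)
        assert cp.segments == ("HB130427", "left-DL")
        tree = build_tree(beta_rule, g)
        assert [f.relative_path for f in tree.files] == [
            "HB130427/left-DL/s_001.tiff", "HB130427/left-DL/s_002.tiff"]

    def test_grouping_order_defines_hierarchy(self):
        attrs = {"HONEYBEE": "HB123", "NEURON": "NRN-1", "STAGE": "segmentation"}
        g = graph_with(("u", attrs, ["data.swc"]))
        r1 = ContextTreeRule.make("r1", grouping=["HONEYBEE", "NEURON", "STAGE"],
                                  leaf_template="data.swc")
        r2 = ContextTreeRule.make("r2", grouping=["STAGE", "HONEYBEE", "NEURON"],
                                  leaf_template="data.swc")
        assert context_path("u", r1, g).segments == ("HB123", "NRN-1", "segmentation")
        assert context_path("u", r2, g).segments == ("segmentation", "HB123", "NRN-1")

    def test_empty_grouping_places_leaf_at_root(self):
        g = graph_with(("u", {"K": "v"}, ["only.dat"]))
        rule = ContextTreeRule.make("flat", grouping=[])
        cp = context_path("u", rule, g)
        assert cp.segments == ()
        tree = build_tree(rule, g)
        assert [f.relative_path for f in tree.files] == ["only.dat"]

    def test_filter_mismatch_signals_not_applicable(self, alpha_rule):
        g = graph_with(("u", {"FORMAT": "TIFF_STACK"}, ["x"]))
        with pytest.raises(RuleNotApplicableError):
            context_path("u", alpha_rule, g)

    def test_missing_attribute_policies(self):
        g = graph_with(("u", {"FORMAT": "SWC"}, ["x.swc"]))
        bucket = ContextTreeRule.make("b", grouping=["REGION"],
                                      leaf_template="x.swc", on_missing="unassigned")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cp = context_path("u", bucket, g)
        assert cp.segments == ("UNASSIGNED",)
        assert any("REGION" in str(w.message) for w in caught)
        strict = ContextTreeRule.make("s", grouping=["REGION"],
                                      leaf_template="x.swc", on_missing="fail")
        with pytest.raises(MissingAttributeError):
            context_path("u", strict, g)

    def test_skip_policy_excludes_unit_from_tree(self):
        g = graph_with(("ok", {"REGION": "L"}, ["a"]),
                       ("gap", {"OTHER": "x"}, ["b"]))
        rule = ContextTreeRule.make("r", grouping=["REGION"], on_missing="skip")
        tree = build_tree(rule, g)
        assert tree.unit_ids == {"ok"}
        assert tree.skipped == ["gap"]

    def test_unit_id8_placeholder(self):
        g = graph_with(("abcdef1234567890", {"K": "v"}, ["f.dat"]))
        rule = ContextTreeRule.make("r", grouping=["K"],
                                    leaf_template="unit_{UNIT_ID8}.dat")
        cp = context_path("abcdef1234567890", rule, g)
        assert cp.leaf_name == "unit_abcdef12.dat"


class TestUniqueness:
    def test_distinct_animals_do_not_collide(self, alpha_rule):
        g = graph_with(
            *((f"u{i}", {**SWC_ATTRS, "HONEYBEE_ID": f"HB{i}"}, ["m.swc"])
              for i in range(5)))
        assert validate_uniqueness(alpha_rule, g) == []

    def test_same_bucket_same_leaf_is_one_group_of_two(self, alpha_rule):
        g = graph_with(("u1", SWC_ATTRS, ["m.swc"]),
                       ("u2", dict(SWC_ATTRS), ["m.swc"]))
        assert validate_uniqueness(alpha_rule, g) == [["u1", "u2"]]

    def test_constant_leaf_empty_grouping_groups_everything(self):
        g = graph_with(*((f"u{i}", {"K": "v"}, ["f"]) for i in range(4)))
        rule = ContextTreeRule.make("r", grouping=[], leaf_template="same.dat")
        groups = validate_uniqueness(rule, g)
        assert groups == [[f"u{i}" for i in range(4)]]

    def test_matches_bruteforce_grouping_on_random_graphs(self, rng):
        for _ in range(30):
            g = InMemoryGraph()
            n = rng.randint(2, 8)
            for i in range(n):
                g.add_unit(f"u{i:02d}",
                           {"A": str(rng.randint(0, 2)), "B": str(rng.randint(0, 2))},
                           [f"f{rng.randint(0, 1)}.dat"])
            rule = ContextTreeRule.make("r", grouping=["A"],
                                        leaf_template="{MEMBER_NAME}")
            # oracle: group computed (segments, member-leaf) keys naively
            claims = {}
            for uid in sorted(g.query_units({})):
                attrs = g.get_attributes(uid)
                for m in g.get_unit(uid).member_names:
                    claims.setdefault((attrs["A"], m), set()).add(uid)
            expect_pairs = {frozenset(v) for v in claims.values() if len(v) > 1}
            got = validate_uniqueness(rule, g)
            # every oracle clash must be inside one reported group
            for pair in expect_pairs:
                assert any(pair <= set(group) for group in got)
            # and every reported group must be justified by >=1 oracle clash
            for group in got:
                assert any(pair <= set(group) for pair in expect_pairs)


class TestBuildTree:
    def test_balanced_cohort_counts(self, alpha_rule):
        g = InMemoryGraph()
        uid = 0
        for state in ("forager", "nurse"):
            for region in ("left_DL", "right_DL"):
                for bee in range(5):
                    g.add_unit(f"u{uid:02d}",
                               {**SWC_ATTRS, "LABOR_STATE": state,
                                "REGION": region,
                                "HONEYBEE_ID": f"HB{state[0]}{region[0]}{bee}"},
                               ["m.swc"])
                    uid += 1
        tree = build_tree(alpha_rule, g)
        assert tree.n_leaves == 20
        assert all(len(f.segments) == 4 for f in tree.files)
        assert list(tree.root.children) == ["forager", "nurse"]

    def test_single_unit_tree_is_one_path(self, alpha_rule):
        g = graph_with(("u", SWC_ATTRS, ["m.swc"]))
        tree = build_tree(alpha_rule, g)
        assert tree.n_leaves == 1 and tree.n_files == 1

    def test_empty_filter_match_gives_empty_tree(self, alpha_rule):
        g = graph_with(("u", {"FORMAT": "TIFF_STACK"}, ["x"]))
        tree = build_tree(alpha_rule, g)
        assert tree.n_leaves == 0 and tree.files == []

    def test_leaf_conservation(self, alpha_rule, rng):
        g = InMemoryGraph()
        for i in range(12):
            attrs = dict(SWC_ATTRS)
            attrs["HONEYBEE_ID"] = f"HB{i}"
            if rng.random() < 0.4:
                attrs["FORMAT"] = "TRACE"
            g.add_unit(f"u{i}", attrs, ["m.swc"])
        tree = build_tree(alpha_rule, g)
        assert tree.n_leaves == len(g.query_units({"FORMAT": "SWC"}))

    def test_collision_policy_fail_names_rule_and_groups(self, alpha_rule):
        g = graph_with(("u1", SWC_ATTRS, ["m.swc"]),
                       ("u2", dict(SWC_ATTRS), ["m.swc"]))
        with pytest.raises(CollisionError) as exc:
            build_tree(alpha_rule, g)
        assert "morphology" in str(exc.value)
        assert exc.value.groups == [["u1", "u2"]]

    def test_collision_policy_suffix_disambiguates(self):
        g = graph_with(("u1" * 8, SWC_ATTRS, ["m.swc"]),
                       ("u2" * 8, dict(SWC_ATTRS), ["m.swc"]))
        rule = ContextTreeRule.make(
            "m", filter={"FORMAT": "SWC"}, grouping=["HONEYBEE_ID"],
            leaf_template="morphology.swc", on_collision="suffix")
        tree = build_tree(rule, g)
        names = sorted(f.leaf_path for f in tree.files)
        assert names == [f"morphology.swc_{'u1' * 4}", f"morphology.swc_{'u2' * 4}"]

    @settings(derandomize=True, max_examples=40)
    @given(st.permutations(["A", "B", "C"]))
    def test_grouping_permutation_permutes_segments(self, order):
        attrs = {"A": "a1", "B": "b1", "C": "c1"}
        g = graph_with(("u", attrs, ["f"]))
        rule = ContextTreeRule.make("r", grouping=order, leaf_template="f")
        cp = context_path("u", rule, g)
        assert cp.segments == tuple(attrs[k] for k in order)


class TestLoadRules:
    GOOD = """
rules:
  - name: morphology
    filter: {FORMAT: SWC}
    grouping: [LABOR_STATE, REGION, HONEYBEE_ID, SIGEN_PARAMETERS]
    leaf_template: morphology.swc
  - name: imaging
    filter: {FORMAT: TIFF_STACK}
    grouping: [HONEYBEE_ID, REGION]
    leaf_template: "{MEMBER_NAME}"
"""

    def test_two_view_config_parses(self):
        rules = load_rules(self.GOOD)
        assert [r.name for r in rules] == ["morphology", "imaging"]
        assert rules[0].grouping == ("LABOR_STATE", "REGION", "HONEYBEE_ID",
                                     "SIGEN_PARAMETERS")
        assert rules[1].grouping == ("HONEYBEE_ID", "REGION")
        assert rules[1].leaf_template == "{MEMBER_NAME}"

    def test_repeated_grouping_key_is_schema_error(self):
        bad = "rules:\n  - name: r\n    grouping: [REGION, REGION]\n"
        with pytest.raises(RuleConfigError, match="repeated grouping"):
            load_rules(bad)

    def test_unknown_top_level_field_named(self):
        with pytest.raises(RuleConfigError) as exc:
            load_rules("rules: []\nbogus_section: 1\n")
        assert "bogus_section" in str(exc.value)
        assert exc.value.field_path == "bogus_section"

    def test_unknown_rule_field_has_path(self):
        bad = "rules:\n  - name: r\n    grouping: [A]\n    surprise: 1\n"
        with pytest.raises(RuleConfigError) as exc:
            load_rules(bad)
        assert exc.value.field_path == "rules[0].surprise"

    def test_duplicate_rule_names_rejected(self):
        bad = "rules:\n  - name: r\n    grouping: [A]\n  - name: r\n    grouping: [B]\n"
        with pytest.raises(RuleConfigError, match="duplicate"):
            load_rules(bad)

    def test_key_in_filter_and_grouping_rejected(self):
        bad = "rules:\n  - name: r\n    filter: {REGION: L}\n    grouping: [REGION]\n"
        with pytest.raises(RuleConfigError):
            load_rules(bad)
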