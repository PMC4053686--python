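"""Materialized link hierarchies: layout, idempotence, minimal diffs."""

import os
import stat

import pytest

from depot._sanitize import sanitize_component, sanitize_components
from depot.context import build_tree
from depot.errors import ProjectionError
from depot.projection import (MANIFEST_NAME, ProjectionManifest,
                              enforce_read_only, materialize, refresh)

SWC_TEXT = b"1 1 0 0 0 1 -1\n"


def make_swc_unit(unit_factory, bee, state="forager", region="left_DL",
                  params="D20V05C01S01"):
    return unit_factory(
        {f"{bee}.swc": SWC_TEXT + bee.encode()},
        attrs={"FORMAT": "SWC", "LABOR_STATE": state, "REGION": region,
               "HONEYBEE_ID": bee, "SIGEN_PARAMETERS": params})


def walk_files(root):
    out = {}
    for dirpath, _dirs, files in os.walk(root):
        for f in files:
            p = os.path.join(dirpath, f)
            rel = os.path.relpath(p, root)
            if rel != MANIFEST_NAME:
                out[rel.replace(os.sep, "/")] = open(p, "rb").read()
    return out


def snapshot(root):
    """(mtime_ns, inode) per file — to prove entries were untouched."""
    out = {}
    for dirpath, _dirs, files in os.walk(root):
        for f in files:
            p = os.path.join(dirpath, f)
            st_ = os.lstat(p)
            out[os.path.relpath(p, root)] = (st_.st_mtime_ns, st_.st_ino)
    return out


class TestMaterialize:
    def test_golden_path_resolves_to_stored_bytes(self, store, unit_factory,
                                                  alpha_rule, tmp_path):
        make_swc_unit(unit_factory, "HB130427")
        tree = build_tree(alpha_rule, store)
        target = tmp_path / "view"
        manifest = materialize(tree, store, target)
        leaf = target / "forager/left_DL/HB130427/D20V05C01S01/morphology.swc"
        assert leaf.is_symlink()
        assert leaf.read_bytes() == SWC_TEXT + b"HB130427"
        assert len(manifest.entries) == 1

    def test_empty_tree_leaves_only_manifest(self, store, alpha_rule, tmp_path):
        tree = build_tree(alpha_rule, store)
        target = tmp_path / "view"
        materialize(tree, store, target)
        assert [p.name for p in target.iterdir()] == [MANIFEST_NAME]

    def test_manifest_matches_independent_walk(self, store, unit_factory,
                                               alpha_rule, tmp_path):
        for i in range(6):
            make_swc_unit(unit_factory, f"HB13{i:02d}")
        tree = build_tree(alpha_rule, store)
        target = tmp_path / "view"
        manifest = materialize(tree, store, target)
        assert sorted(e.path for e in manifest.entries) == sorted(walk_files(target))

    def test_foreign_target_refused(self, store, alpha_rule, tmp_path):
        target = tmp_path / "busy"
        target.mkdir()
        (target / "keep.txt").write_text("mine")
        tree = build_tree(alpha_rule, store)
        with pytest.raises(ProjectionError):
            materialize(tree, store, target)

    def test_target_of_other_rule_refused(self, store, unit_factory, alpha_rule,
                                          beta_rule, tmp_path):
        make_swc_unit(unit_factory, "HB1")
        target = tmp_path / "view"
        materialize(build_tree(alpha_rule, store), store, target)
        with pytest.raises(ProjectionError, match="belongs to rule"):
            materialize(build_tree(beta_rule, store), store, target)

    def test_link_modes_equivalent_content(self, store, unit_factory,
                                           alpha_rule, tmp_path):
        make_swc_unit(unit_factory, "HB7")
        tree = build_tree(alpha_rule, store)
        contents = {}
        for mode in ("symlink", "hardlink", "copy"):
            target = tmp_path / mode
            manifest = materialize(tree, store, target, link_mode=mode)
            assert {e.kind for e in manifest.entries} == {mode}
            contents[mode] = walk_files(target)
        assert contents["symlink"] == contents["hardlink"] == contents["copy"]

    def test_symlink_failure_falls_back(self, store, unit_factory, alpha_rule,
                                        tmp_path, monkeypatch):
        make_swc_unit(unit_factory, "HB8")
        monkeypatch.setattr(os, "symlink",
                            lambda *a, **k: (_ for _ in ()).throw(OSError("no")))
        manifest = materialize(build_tree(alpha_rule, store), store,
                               tmp_path / "view", link_mode="symlink")
        assert {e.kind for e in manifest.entries} == {"hardlink"}


class TestRefresh:
    def test_unchanged_inputs_are_byte_level_noop(self, store, unit_factory,
                                                  alpha_rule, tmp_path):
        for i in range(4):
            make_swc_unit(unit_factory, f"HB2{i}")
        target = tmp_path / "view"
        refresh(alpha_rule, store, store, target)
        before = snapshot(target)
        manifest2 = refresh(alpha_rule, store, store, target)
        assert manifest2.ops == []
        assert snapshot(target) == before

    def test_attribute_edit_moves_only_affected_entries(self, store, unit_factory,
                                                        alpha_rule, tmp_path):
        units = [make_swc_unit(unit_factory, f"HB3{i}") for i in range(5)]
        target = tmp_path / "view"
        refresh(alpha_rule, store, store, target)
        before = snapshot(target)
        store.assign_metadata(units[2].unit_id, {"HONEYBEE_ID": "HB3X"})
        manifest = refresh(alpha_rule, store, store, target)
        moved = {p for op, p in manifest.ops if op in ("link", "unlink")}
        assert moved == {"forager/left_DL/HB32/D20V05C01S01/morphology.swc",
                         "forager/left_DL/HB3X/D20V05C01S01/morphology.swc"}
        after = snapshot(target)
        untouched = set(before) & set(after) - {MANIFEST_NAME}
        assert all(before[p] == after[p] for p in untouched)
        assert not (target / "forager/left_DL/HB32").exists()

    def test_metadata_removal_drops_leaf_keeps_store(self, store, unit_factory,
                                                     alpha_rule, tmp_path):
        unit = make_swc_unit(unit_factory, "HB40")
        target = tmp_path / "view"
        refresh(alpha_rule, store, store, target)
        store.assign_metadata(unit.unit_id, {"FORMAT": "TRACE"})  # leaves filter
        refresh(alpha_rule, store, store, target)
        assert walk_files(target) == {}
        assert store.member_path(unit.unit_id, "HB40.swc").is_file()
        assert store.verify().is_clean

    def test_foreign_files_warned_never_deleted(self, store, unit_factory,
                                                alpha_rule, tmp_path):
        make_swc_unit(unit_factory, "HB40")
        target = tmp_path / "view"
        refresh(alpha_rule, store, store, target)
        stray = target / "forager" / "notes.txt"
        stray.write_text("human note")
        store.assign_metadata(make_swc_unit(unit_factory, "HB41").unit_id,
                              {"AGE": "9"})
        manifest = refresh(alpha_rule, store, store, target)
        assert "forager/notes.txt" in manifest.warnings
        assert stray.read_text() == "human note"

    def test_materialize_then_refresh_equals_materialize(self, store, unit_factory,
                                                         alpha_rule, tmp_path):
        for i in range(3):
            make_swc_unit(unit_factory, f"HB5{i}")
        fresh = tmp_path / "fresh"
        incr = tmp_path / "incr"
        materialize(build_tree(alpha_rule, store), store, fresh, graph=store)
        materialize(build_tree(alpha_rule, store), store, incr, graph=store)
        make_swc_unit(unit_factory, "HB59")
        refresh(alpha_rule, store, store, incr)
        fresh2 = tmp_path / "fresh2"
        materialize(build_tree(alpha_rule, store), store, fresh2, graph=store)
        assert walk_files(incr) == walk_files(fresh2)
        m_incr = ProjectionManifest.load(incr)
        m_fresh = ProjectionManifest.load(fresh2)
        assert [(e.path, e.unit_id, e.member) for e in m_incr.entries] == \
            [(e.path, e.unit_id, e.member) for e in m_fresh.entries]

    def test_projection_never_touches_store(self, store, unit_factory,
                                            alpha_rule, tmp_path):
        make_swc_unit(unit_factory, "HB60")
        assert store.verify().is_clean
        refresh(alpha_rule, store, store, tmp_path / "v")
        assert store.verify().is_clean


class TestReadOnly:
    def test_write_permission_bits_removed(self, store, unit_factory,
                                           alpha_rule, tmp_path):
        make_swc_unit(unit_factory, "HB70")
        target = tmp_path / "view"
        manifest = materialize(build_tree(alpha_rule, store), store, target,
                               link_mode="copy")
        enforce_read_only(target)
        for entry in manifest.entries:
            mode = (target / entry.path).stat().st_mode
            assert not mode & (stat.S_IWUSR | stat.S_IWGRP | stat.S_IWOTH)
        for sub in target.rglob("*"):
            if sub.is_dir():
                assert not sub.stat().st_mode & stat.S_IWUSR

    def test_store_edit_after_enforcement_caught_by_verify(self, store,
                                                           unit_factory,
                                                           alpha_rule, tmp_path):
        unit = make_swc_unit(unit_factory, "HB71")
        target = tmp_path / "view"
        materialize(build_tree(alpha_rule, store), store, target)
        enforce_read_only(target)
        member = store.member_path(unit.unit_id, "HB71.swc")
        member.chmod(0o644)
        member.write_bytes(b"tampered")
        report = store.verify()
        assert {f.subject for f in report.by_kind("corrupted")} == {unit.unit_id}

    def test_rematerialize_after_enforcement(self, store, unit_factory,
                                             alpha_rule, tmp_path):
        make_swc_unit(unit_factory, "HB72")
        target = tmp_path / "view"
        materialize(build_tree(alpha_rule, store), store, target)
        enforce_read_only(target)
        make_swc_unit(unit_factory, "HB73")
        manifest = refresh(alpha_rule, store, store, target)
        assert len(manifest.entries) == 2


class TestSanitize:
    @pytest.mark.parametrize("value,expected", [
        ("left_DL", "left_DL"),
        ("left-DL", "left-DL"),
        ("a/b", "a_b"),
        ("", "_EMPTY_"),
        ("a\\b", "a_b"),
    ])
    def test_single_values(self, value, expected):
        assert sanitize_component(value) == expected

    def test_colliding_pair_stays_distinct(self):
        mapping = sanitize_components({"a/b", "a_b"})
        assert mapping["a_b"] == "a_b"
        assert mapping["a/b"].startswith("a_b_") and len(mapping["a/b"]) == 12
        assert mapping["a/b"] != mapping["a_b"]

    def test_mapping_is_order_independent(self):
        values = ["x/y", "x_y", "x:y", "plain"]
        assert sanitize_components(values) == sanitize_components(values[::-1])
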