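"""Persistence, audit history and role-gated sample information."""

import sqlite3
from datetime import datetime

import pytest

from mitoprofile.core import Profile, Role, substitution
from mitoprofile.errors import AccessDeniedError, StoreError
from mitoprofile.store import Store, UserAccount

FROZEN = lambda: datetime(2009, 10, 17, 16, 12)


class TestProjects:
    def test_create_and_type(self, frozen_store):
        frozen_store.create_project("Burma1", "population")
        assert frozen_store.project_type("Burma1").value == "population"

    def test_duplicate_name_rejected(self, frozen_store):
        frozen_store.create_project("Burma1", "population")
        with pytest.raises(StoreError):
            frozen_store.create_project("Burma1", "tumour")

    def test_tumour_project_requires_numeric_sample_ids(self, frozen_store):
        frozen_store.create_project("T1", "tumour")
        with pytest.raises(StoreError, match="numeric"):
            frozen_store.add_sample("T1", "Burma01", tissue="benign")
        frozen_store.add_sample("T1", "17", tissue="tumour")

    def test_tissue_outside_tumour_project_rejected(self, frozen_store):
        frozen_store.create_project("P", "population")
        with pytest.raises(StoreError):
            frozen_store.add_sample("P", "s1", tissue="benign")


class TestHaplogroup:
    def test_initial_set_logs_null_to_value(self, frozen_store):
        frozen_store.create_project("PopTest", "population")
        frozen_store.add_sample("PopTest", "Sample17")
        frozen_store.set_haplogroup("PopTest", "Sample17", "F1a1c", employee="Hansi")
        entry = frozen_store.query_history(project="PopTest", employee="Hansi")[-1]
        assert entry.location == "MTDNA haplogr.: Sample17"
        assert (entry.old_value, entry.new_value) == ("null", "F1a1c")

    def test_update_logs_old_and_new(self, frozen_store):
        frozen_store.create_project("Burma2", "population")
        frozen_store.add_sample("Burma2", "Sample17")
        frozen_store.set_haplogroup("Burma2", "Sample17", "F1a1c", employee="Hansi")
        frozen_store.set_haplogroup("Burma2", "Sample17", "F1a1", employee="Anita")
        entry = frozen_store.query_history(project="Burma2", employee="Anita")[-1]
        assert (entry.old_value, entry.new_value) == ("F1a1c", "F1a1")

    def test_setting_same_value_writes_no_history(self, frozen_store):
        frozen_store.create_project("P", "population")
        frozen_store.add_sample("P", "s1")
        frozen_store.set_haplogroup("P", "s1", "H", employee="A")
        n = frozen_store.history_length()
        frozen_store.set_haplogroup("P", "s1", "H", employee="A")
        assert frozen_store.history_length() == n

    def test_unknown_sample_is_error(self, frozen_store):
        frozen_store.create_project("P", "population")
        with pytest.raises(StoreError):
            frozen_store.set_haplogroup("P", "ghost", "H", employee="A")


class TestHistory:
    def test_export_event_row_shape(self, frozen_store):
        frozen_store.create_project("Burma1", "population", employee="Sebastian")
        frozen_store.log_export(
            "Burma1", "Sebastian", "xls", r"\home\sebastian\1.xls"
        )
        entry = frozen_store.query_history(project="Burma1")[-1]
        assert entry.location == r"Export XLS:\home\sebastian\1.xls"
        assert entry.as_row()[0] == "Burma1"

    def test_query_filters_by_employee(self, frozen_store):
        frozen_store.create_project("P", "population")
        frozen_store.record_history("P", "Anita", "thing one")
        frozen_store.record_history("P", "Gunther", "thing two")
        frozen_store.record_history("P", "Anita", "thing three")
        rows = frozen_store.query_history(project="P", employee="Anita")
        assert [e.location for e in rows] == ["thing one", "thing three"]

    def test_history_is_append_only_at_the_sql_level(self, frozen_store):
        frozen_store.create_project("P", "population")
        with pytest.raises(sqlite3.DatabaseError):
            frozen_store._conn.execute("UPDATE history SET employee = 'x'")
        with pytest.raises(sqlite3.DatabaseError):
            frozen_store._conn.execute("DELETE FROM history")

    def test_replay_under_frozen_clock_is_identical(self):
        def workflow(store):
            store.create_project("P", "population", employee="A")
            store.add_sample("P", "s1", employee="A")
            store.store_validated_profile(
                "P", "s1", Profile("s1", variants=(substitution(73, "G"),)),
                employee="A",
            )
            store.set_haplogroup("P", "s1", "H2a", employee="B")
            return [e.as_row() for e in store.query_history()]

        runs = []
        for _ in range(2):
            store = Store(":memory:", clock=FROZEN)
            runs.append(workflow(store))
            store.close()
        assert runs[0] == runs[1]

    def test_every_mutating_operation_writes_history(self, frozen_store):
        """Each state change adds at least one audit row."""
        counts = [frozen_store.history_length()]

        frozen_store.create_project("P", "association")
        counts.append(frozen_store.history_length())
        frozen_store.add_sample("P", "100")
        counts.append(frozen_store.history_length())
        frozen_store.store_validated_profile(
            "P", "100", Profile("100", variants=(substitution(73, "G"),)),
            employee="A",
        )
        counts.append(frozen_store.history_length())
        frozen_store.set_haplogroup("P", "100", "U5", employee="A")
        counts.append(frozen_store.history_length())
        frozen_store.store_phenotypes("P", {"100": {"BMI": "24.1"}}, employee="A")
        counts.append(frozen_store.history_length())
        frozen_store.delete_phenotype("P", "BMI", UserAccount("root", Role.ADMIN))
        counts.append(frozen_store.history_length())
        frozen_store.log_export("P", "A", "empop", "x.txt")
        counts.append(frozen_store.history_length())

        assert all(b > a for a, b in zip(counts, counts[1:]))


class TestProfiles:
    def test_stored_profile_round_trips_canonically(self, frozen_store):
        frozen_store.create_project("P", "population")
        profile = Profile(
            "s1",
            evaluator="AB",
            variants=(substitution(263, "G"), substitution(73, "G")),
            sequenced_ranges=((16024, 16569), (1, 576)),
        )
        frozen_store.store_validated_profile("P", "s1", profile, employee="A")
        back = frozen_store.get_validated_profile("P", "s1")
        assert back.tokens() == ("73G", "263G")
        assert back.sequenced_ranges == ((16024, 16569), (1, 576))

    def test_double_store_without_force_is_error(self, frozen_store):
        frozen_store.create_project("P", "population")
        profile = Profile("s1", variants=(substitution(73, "G"),))
        frozen_store.store_validated_profile("P", "s1", profile, employee="A")
        with pytest.raises(StoreError):
            frozen_store.store_validated_profile("P", "s1", profile, employee="A")

    def test_tumour_tissues_stored_separately(self, frozen_store):
        frozen_store.create_project("T", "tumour")
        frozen_store.store_validated_profile(
            "T", "100", Profile("100", variants=(substitution(73, "G"),)),
            employee="A", tissue="benign",
        )
        frozen_store.store_validated_profile(
            "T", "100", Profile("100", variants=(substitution(73, "G"),
                                                 substitution(263, "G"))),
            employee="A", tissue="tumour",
        )
        assert frozen_store.get_validated_profile("T", "100", "benign").tokens() == ("73G",)
        assert len(frozen_store.get_validated_profile("T", "100", "tumour").tokens()) == 2


class TestSampleInfoGuard:
    def _setup(self, store):
        store.create_project("P", "association")
        store.add_sample("P", "100")
        store.store_phenotypes(
            "P", {"100": {"BMI": "24.1", "name": "Jane"}},
            sample_specific_columns=["name"], employee="A",
        )

    def test_viewer_denied_flagged_column_and_logged(self, frozen_store):
        self._setup(frozen_store)
        viewer = UserAccount("v", Role.VIEWER)
        permitted = frozen_store.guard_sample_info(viewer, "P", ["BMI", "name"])
        assert permitted == ["BMI"]
        denials = [
            e for e in frozen_store.query_history(project="P", employee="v")
            if e.location == "Access denied: name"
        ]
        assert len(denials) == 1

    def test_admin_sees_everything(self, frozen_store):
        self._setup(frozen_store)
        admin = UserAccount("root", Role.ADMIN)
        assert frozen_store.guard_sample_info(admin, "P", ["BMI", "name"]) == [
            "BMI", "name",
        ]

    def test_unflagged_columns_open_to_all_roles(self, frozen_store):
        frozen_store.create_project("P", "association")
        frozen_store.add_sample("P", "100")
        frozen_store.store_phenotypes("P", {"100": {"BMI": "24.1"}}, employee="A")
        viewer = UserAccount("v", Role.VIEWER)
        assert frozen_store.guard_sample_info(viewer, "P", ["BMI"]) == ["BMI"]

    def test_phenotype_deletion_requires_admin(self, frozen_store):
        self._setup(frozen_store)
        with pytest.raises(AccessDeniedError):
            frozen_store.delete_phenotype("P", "BMI", UserAccount("e", Role.EDITOR))
        frozen_store.delete_phenotype("P", "BMI", UserAccount("root", Role.ADMIN))
        entry = frozen_store.query_history(project="P")[-1]
        assert entry.location == "Deleted: Phenotype BMI"
        assert (entry.old_value or "", entry.new_value or "") == ("", "")
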