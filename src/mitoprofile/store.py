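"""Embedded relational persistence with an append-only audit history.

A single-file sqlite database replaces the server backends a multi-user
deployment would use.  Every mutation of stored data writes exactly one
history row shaped like the audit table users see:

    project | employee | date & time | location | old value | new value

History rows are append-only: the store exposes no update or delete for
them, and triggers reject direct SQL tampering.  Timestamps come from an
injectable clock so replayed workflows are reproducible.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .core import (
    Profile,
    ProjectType,
    Role,
    SourceProgram,
    Tissue,
    format_ranges,
    parse_ranges,
    parse_variant_token,
)
from .errors import AccessDeniedError, StoreError

__all__ = ["HistoryEntry", "UserAccount", "Store"]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS projects (
    name TEXT PRIMARY KEY,
    project_type TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS samples (
    project TEXT NOT NULL REFERENCES projects(name),
    sample_id TEXT NOT NULL,
    tissue TEXT NOT NULL DEFAULT '',
    haplogroup TEXT,
    PRIMARY KEY (project, sample_id, tissue)
);
CREATE TABLE IF NOT EXISTS profiles (
    project TEXT NOT NULL,
    sample_id TEXT NOT NULL,
    tissue TEXT NOT NULL DEFAULT '',
    evaluator TEXT NOT NULL,
    source_program TEXT,
    variants TEXT NOT NULL,         -- space-joined canonical tokens
    ranges TEXT,                    -- ';'-joined 'a-b' intervals
    source_file TEXT,
    provenance TEXT,
    PRIMARY KEY (project, sample_id, tissue)
);
CREATE TABLE IF NOT EXISTS history (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    project TEXT NOT NULL,
    employee TEXT NOT NULL,
    timestamp TEXT NOT NULL,
    location TEXT NOT NULL,
    old_value TEXT,
    new_value TEXT
);
CREATE TABLE IF NOT EXISTS pheno_columns (
    project TEXT NOT NULL,
    column_name TEXT NOT NULL,
    sample_specific INTEGER NOT NULL DEFAULT 0,
    PRIMARY KEY (project, column_name)
);
CREATE TABLE IF NOT EXISTS phenotypes (
    project TEXT NOT NULL,
    sample_id TEXT NOT NULL,
    column_name TEXT NOT NULL,
    value TEXT,
    PRIMARY KEY (project, sample_id, column_name)
);
CREATE TRIGGER IF NOT EXISTS history_no_update
    BEFORE UPDATE ON history
    BEGIN SELECT RAISE(ABORT, 'history is append-only'); END;
CREATE TRIGGER IF NOT EXISTS history_no_delete
    BEFORE DELETE ON history
    BEGIN SELECT RAISE(ABORT, 'history is append-only'); END;
"""


@dataclass(frozen=True)
class HistoryEntry:
    """One append-only audit record."""

    project: str
    employee: str
    timestamp: str
    location: str
    old_value: str | None = None
    new_value: str | None = None

    def as_row(self) -> tuple[str, str, str, str, str, str]:
        return (
            self.project,
            self.employee,
            self.timestamp,
            self.location,
            self.old_value or "",
            self.new_value or "",
        )


@dataclass(frozen=True)
class UserAccount:
    name: str
    role: Role = Role.EDITOR


@dataclass(frozen=True)
class ValidatedSample:
    """Read-model row used by the exporters."""

    sample_id: str
    tissue: str
    haplogroup: str | None
    profile: Profile


class Store:
    """Project, sample, profile, phenotype and history persistence."""

    def __init__(
        self,
        path: str | Path = ":memory:",
        clock: Callable[[], datetime] | None = None,
    ) -> None:
        self.path = str(path)
        self._clock = clock or datetime.now
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- history ----------------------------------------------------------

    def _now(self) -> str:
        return self._clock().strftime("%Y-%m-%d %H:%M")

    def record_history(
        self,
        project: str,
        employee: str,
        location: str,
        old_value: str | None = None,
        new_value: str | None = None,
    ) -> HistoryEntry:
        entry = HistoryEntry(
            project=project,
            employee=employee,
            timestamp=self._now(),
            location=location,
            old_value=old_value,
            new_value=new_value,
        )
        self._conn.execute(
            "INSERT INTO history (project, employee, timestamp, location,"
            " old_value, new_value) VALUES (?,?,?,?,?,?)",
            (entry.project, entry.employee, entry.timestamp, entry.location,
             entry.old_value, entry.new_value),
        )
        self._conn.commit()
        return entry

    def query_history(
        self,
        project: str | None = None,
        employee: str | None = None,
        since: str | None = None,
        until: str | None = None,
    ) -> list[HistoryEntry]:
        """Filter audit rows; ordered by timestamp then insertion order."""
        clauses, params = [], []
        for col, val in (("project", project), ("employee", employee)):
            if val is not None:
                clauses.append(f"{col} = ?")
                params.append(val)
        if since is not None:
            clauses.append("timestamp >= ?")
            params.append(since)
        if until is not None:
            clauses.append("timestamp <= ?")
            params.append(until)
        where = (" WHERE " + " AND ".join(clauses)) if clauses else ""
        rows = self._conn.execute(
            "SELECT project, employee, timestamp, location, old_value, new_value"
            f" FROM history{where} ORDER BY timestamp, id",
            params,
        ).fetchall()
        return [HistoryEntry(*row) for row in rows]

    def history_length(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM history").fetchone()[0]

    # -- projects and samples ---------------------------------------------

    def create_project(
        self, name: str, project_type: ProjectType | str, employee: str = "system"
    ) -> None:
        project_type = ProjectType(project_type)
        try:
            self._conn.execute(
                "INSERT INTO projects (name, project_type) VALUES (?, ?)",
                (name, project_type.value),
            )
        except sqlite3.IntegrityError:
            raise StoreError(f"project {name!r} already exists") from None
        self._conn.commit()
        self.record_history(
            name, employee, "Created project", new_value=project_type.value
        )

    def project_type(self, name: str) -> ProjectType:
        row = self._conn.execute(
            "SELECT project_type FROM projects WHERE name = ?", (name,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown project {name!r}")
        return ProjectType(row[0])

    def list_projects(self) -> list[tuple[str, str]]:
        return self._conn.execute(
            "SELECT name, project_type FROM projects ORDER BY name"
        ).fetchall()

    def _check_sample_id(self, project: str, sample_id: str) -> None:
        if self.project_type(project).requires_numeric_ids and not sample_id.isdigit():
            raise StoreError(
                f"sample ID {sample_id!r} must be numeric in project {project!r}"
            )

    def add_sample(
        self,
        project: str,
        sample_id: str,
        tissue: Tissue | str | None = None,
        employee: str = "system",
    ) -> None:
        self._check_sample_id(project, sample_id)
        tissue_val = Tissue(tissue).value if tissue else ""
        if tissue_val and self.project_type(project) is not ProjectType.TUMOUR:
            raise StoreError("tissue labels apply to tumour projects only")
        cur = self._conn.execute(
            "INSERT OR IGNORE INTO samples (project, sample_id, tissue) VALUES (?,?,?)",
            (project, sample_id, tissue_val),
        )
        self._conn.commit()
        if cur.rowcount:
            self.record_history(
                project, employee, f"Added sample: {sample_id}",
                new_value=tissue_val or None,
            )

    def list_samples(self, project: str) -> list[tuple[str, str, str | None]]:
        self.project_type(project)
        return self._conn.execute(
            "SELECT sample_id, tissue, haplogroup FROM samples WHERE project = ?"
            " ORDER BY sample_id, tissue",
            (project,),
        ).fetchall()

    def set_haplogroup(
        self, project: str, sample_id: str, value: str | None, employee: str
    ) -> None:
        """Set or update a sample's haplogroup annotation, logging old and new.

        Setting the value it already has is a no-op and writes no history.
        """
        rows = self._conn.execute(
            "SELECT tissue, haplogroup FROM samples WHERE project = ? AND sample_id = ?",
            (project, sample_id),
        ).fetchall()
        if not rows:
            raise StoreError(f"unknown sample {sample_id!r} in project {project!r}")
        old = rows[0][1]
        if old == value:
            return
        self._conn.execute(
            "UPDATE samples SET haplogroup = ? WHERE project = ? AND sample_id = ?",
            (value, project, sample_id),
        )
        self._conn.commit()
        self.record_history(
            project, employee, f"MTDNA haplogr.: {sample_id}",
            old_value=old if old is not None else "null",
            new_value=value,
        )

    # -- profiles -----------------------------------------------------------

    def store_validated_profile(
        self,
        project: str,
        sample_id: str,
        profile: Profile,
        *,
        employee: str,
        tissue: Tissue | str | None = None,
        source_file: str | None = None,
        provenance: str | None = None,
        force: bool = False,
    ) -> None:
        self._check_sample_id(project, sample_id)
        tissue_val = Tissue(tissue).value if tissue else ""
        if tissue_val and self.project_type(project) is not ProjectType.TUMOUR:
            raise StoreError("tissue labels apply to tumour projects only")
        existing = self.get_validated_profile(project, sample_id, tissue=tissue_val or None)
        if existing is not None and not force:
            raise StoreError(
                f"sample {sample_id!r} already has a validated profile"
            )
        self.add_sample(project, sample_id, tissue=tissue_val or None, employee=employee)
        tokens = " ".join(profile.tokens())
        ranges = (
            format_ranges(profile.sequenced_ranges)
            if profile.sequenced_ranges
            else None
        )
        self._conn.execute(
            "INSERT OR REPLACE INTO profiles (project, sample_id, tissue, evaluator,"
            " source_program, variants, ranges, source_file, provenance)"
            " VALUES (?,?,?,?,?,?,?,?,?)",
            (
                project, sample_id, tissue_val, profile.evaluator,
                profile.source_program.value if profile.source_program else None,
                tokens, ranges, source_file, provenance,
            ),
        )
        self._conn.commit()
        label = f"Validated profile: {sample_id}" + (
            f" [{tissue_val}]" if tissue_val else ""
        )
        self.record_history(
            project, employee, label,
            old_value=" ".join(existing.tokens()) if existing else None,
            new_value=tokens,
        )

    def get_validated_profile(
        self, project: str, sample_id: str, tissue: Tissue | str | None = None
    ) -> Profile | None:
        tissue_val = Tissue(tissue).value if tissue else ""
        row = self._conn.execute(
            "SELECT evaluator, source_program, variants, ranges FROM profiles"
            " WHERE project = ? AND sample_id = ? AND tissue = ?",
            (project, sample_id, tissue_val),
        ).fetchone()
        if row is None:
            return None
        evaluator, program, tokens, ranges = row
        return Profile(
            sample_id=sample_id,
            evaluator=evaluator,
            source_program=SourceProgram(program) if program else None,
            variants=tuple(parse_variant_token(t) for t in tokens.split()),
            sequenced_ranges=parse_ranges(ranges) if ranges else None,
        )

    def validated_samples(
        self, project: str, tissue: Tissue | str | None = None
    ) -> list[ValidatedSample]:
        """All validated profiles of a project, joined with haplogroups.

        For tumour projects, ``tissue`` restricts to one tissue;
        otherwise every stored tissue row is returned.
        """
        self.project_type(project)
        query = (
            "SELECT p.sample_id, p.tissue, s.haplogroup, p.evaluator,"
            " p.source_program, p.variants, p.ranges"
            " FROM profiles p LEFT JOIN samples s"
            " ON s.project = p.project AND s.sample_id = p.sample_id"
            " AND s.tissue = p.tissue WHERE p.project = ?"
        )
        params: list = [project]
        if tissue is not None:
            query += " AND p.tissue = ?"
            params.append(Tissue(tissue).value if tissue else "")
        query += " ORDER BY p.sample_id, p.tissue"
        out = []
        for sample_id, tis, hg, evaluator, program, tokens, ranges in self._conn.execute(
            query, params
        ):
            out.append(
                ValidatedSample(
                    sample_id=sample_id,
                    tissue=tis,
                    haplogroup=hg,
                    profile=Profile(
                        sample_id=sample_id,
                        evaluator=evaluator,
                        source_program=SourceProgram(program) if program else None,
                        variants=tuple(
                            parse_variant_token(t) for t in tokens.split()
                        ),
                        sequenced_ranges=parse_ranges(ranges) if ranges else None,
                    ),
                )
            )
        return out

    # -- phenotypes ----------------------------------------------------------

    def store_phenotypes(
        self,
        project: str,
        rows: dict[str, dict[str, str]],
        sample_specific_columns: Iterable[str] = (),
        employee: str = "system",
    ) -> list[tuple[str, str, str | None, str]]:
        """Insert/update phenotype values; returns (sample, column, old, new) changes."""
        self.project_type(project)
        flagged = set(sample_specific_columns)
        changes: list[tuple[str, str, str | None, str]] = []
        columns = {c for row in rows.values() for c in row}
        for col in sorted(columns):
            self._conn.execute(
                "INSERT OR REPLACE INTO pheno_columns (project, column_name,"
                " sample_specific) VALUES (?,?,?)",
                (project, col, int(col in flagged)),
            )
        for sample_id in sorted(rows):
            for col, value in rows[sample_id].items():
                old = self._conn.execute(
                    "SELECT value FROM phenotypes WHERE project = ? AND"
                    " sample_id = ? AND column_name = ?",
                    (project, sample_id, col),
                ).fetchone()
                old_val = old[0] if old else None
                new_val = str(value)
                if old_val == new_val:
                    continue
                self._conn.execute(
                    "INSERT OR REPLACE INTO phenotypes (project, sample_id,"
                    " column_name, value) VALUES (?,?,?,?)",
                    (project, sample_id, col, new_val),
                )
                changes.append((sample_id, col, old_val, new_val))
        self._conn.commit()
        for sample_id, col, old_val, new_val in changes:
            self.record_history(
                project, employee, f"Phenotype {col}: {sample_id}",
                old_value=old_val, new_value=new_val,
            )
        return changes

    def phenotype_columns(self, project: str) -> dict[str, bool]:
        return {
            name: bool(flag)
            for name, flag in self._conn.execute(
                "SELECT column_name, sample_specific FROM pheno_columns"
                " WHERE project = ? ORDER BY column_name",
                (project,),
            )
        }

    def phenotype_rows(self, project: str, columns: Sequence[str]) -> dict[str, dict[str, str]]:
        rows: dict[str, dict[str, str]] = {}
        for sample_id, col, value in self._conn.execute(
            "SELECT sample_id, column_name, value FROM phenotypes WHERE project = ?",
            (project,),
        ):
            if col in columns:
                rows.setdefault(sample_id, {})[col] = value
        return rows

    def delete_phenotype(
        self, project: str, column: str, user: UserAccount
    ) -> None:
        """Drop a phenotype column; admin-only, logged with empty old/new."""
        if not user.role.at_least(Role.ADMIN):
            raise AccessDeniedError(
                f"user {user.name!r} ({user.role.value}) may not delete phenotypes"
            )
        known = self.phenotype_columns(project)
        if column not in known:
            raise StoreError(f"unknown phenotype column {column!r}")
        self._conn.execute(
            "DELETE FROM phenotypes WHERE project = ? AND column_name = ?",
            (project, column),
        )
        self._conn.execute(
            "DELETE FROM pheno_columns WHERE project = ? AND column_name = ?",
            (project, column),
        )
        self._conn.commit()
        self.record_history(project, user.name, f"Deleted: Phenotype {column}")

    def guard_sample_info(
        self,
        user: UserAccount,
        project: str,
        requested_columns: Sequence[str],
    ) -> list[str]:
        """Withhold sample-specific columns from under-privileged users.

        Columns flagged sample-specific at phenotype import need role >=
        validator; denied requests are logged.
        """
        flags = self.phenotype_columns(project)
        permitted: list[str] = []
        for col in requested_columns:
            if flags.get(col, False) and not user.role.at_least(Role.VALIDATOR):
                self.record_history(
                    project, user.name, f"Access denied: {col}",
                )
                continue
            permitted.append(col)
        return permitted

    def log_export(
        self, project: str, employee: str, fmt: str, destination: str
    ) -> None:
        self.record_history(
            project, employee, f"Export {fmt.upper()}:{destination}"
        )
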