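"""Persistent study store: registration, import queue, cascading delete.

A single-file SQLite database holds subjects' studies (one per subject ×
modality × date), a synchronous FIFO import-job queue, staging rows (the
raw file lines as received), associated record rows (typed records keyed
by resolved gene identity), and user gene groups.  ``process_next``
drains the queue one job at a time: parse via the ingest module into
staging, associate via the identifier graph, and mark the study
imported (or failed, with the ImportReport attached and staging rows
retained for inspection).  ``cascade_delete`` removes every row of a
study or of a whole subject across all tables, leaving no orphans.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import sqlite3
from pathlib import Path
from typing import Sequence, Union

from . import ingest
from .idmap import GeneIdentity, GenomicLocus, IdGraph
from .integrate import GeneGroup, ModalityDataset, associate
from .report import ImportReport

Source = Union[str, Path]

MODALITY_PARSERS = {
    "wes": "variants",
    "rnaseq_gene": "cuffdiff_genes",
    "rnaseq_isoform": "cuffdiff_isoforms",
    "microarray": "probes",
}

_SCHEMA = """
CREATE TABLE IF NOT EXISTS studies (
    study_id INTEGER PRIMARY KEY,
    subject TEXT NOT NULL,
    modality TEXT NOT NULL,
    study_date TEXT NOT NULL,
    status TEXT NOT NULL DEFAULT 'queued',
    row_count INTEGER,
    report TEXT,
    UNIQUE (subject, modality, study_date)
);
CREATE TABLE IF NOT EXISTS jobs (
    job_id INTEGER PRIMARY KEY AUTOINCREMENT,
    study_id INTEGER NOT NULL REFERENCES studies(study_id),
    paths TEXT NOT NULL,
    enqueue_time TEXT NOT NULL,
    done INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS staging (
    row_id INTEGER PRIMARY KEY,
    study_id INTEGER NOT NULL REFERENCES studies(study_id),
    line_no INTEGER NOT NULL,
    line TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS records (
    record_id INTEGER PRIMARY KEY,
    study_id INTEGER NOT NULL REFERENCES studies(study_id),
    gene_key TEXT,
    resolved INTEGER NOT NULL,
    payload TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS groups (
    group_id INTEGER PRIMARY KEY,
    owner TEXT NOT NULL,
    name TEXT NOT NULL,
    UNIQUE (owner, name)
);
CREATE TABLE IF NOT EXISTS group_members (
    group_id INTEGER NOT NULL REFERENCES groups(group_id),
    member TEXT NOT NULL
);
"""

#: Tables carrying per-study rows, in cascade-delete order.
_STUDY_TABLES = ("records", "staging", "jobs")


# ---------------------------------------------------------------------------
# record (de)serialization
# ---------------------------------------------------------------------------


def _json_default(value):
    if isinstance(value, frozenset):
        return sorted(value)
    raise TypeError(f"not JSON serializable: {type(value)}")


def record_to_payload(record) -> str:
    payload = dataclasses.asdict(record)
    payload["__type__"] = type(record).__name__
    return json.dumps(payload, default=_json_default)


def _locus_from(payload) -> GenomicLocus | None:
    if payload is None:
        return None
    return GenomicLocus(**payload)


def _identity_from(payload) -> GeneIdentity:
    payload = dict(payload)
    payload["genbank_accessions"] = frozenset(payload.get("genbank_accessions", ()))
    payload["affy_probesets"] = frozenset(payload.get("affy_probesets", ()))
    payload["locus"] = _locus_from(payload.get("locus"))
    return GeneIdentity(**payload)


def record_from_payload(text: str):
    payload = json.loads(text)
    kind = payload.pop("__type__")
    if kind == "VariantRecord":
        payload["locus"] = _locus_from(payload["locus"])
        payload["gene"] = _identity_from(payload["gene"])
        return ingest.VariantRecord(**payload)
    if kind == "ExpressionDiffRecord":
        payload["locus"] = _locus_from(payload["locus"])
        payload["gene"] = _identity_from(payload["gene"])
        return ingest.ExpressionDiffRecord(**payload)
    if kind == "IsoformRecord":
        payload["gene"] = _identity_from(payload["gene"])
        return ingest.IsoformRecord(**payload)
    if kind == "ProbeMeasurement":
        return ingest.ProbeMeasurement(**payload)
    raise ValueError(f"unknown record type {kind!r}")


# ---------------------------------------------------------------------------
# the store
# ---------------------------------------------------------------------------


class Store:
    """Single-file relational study store with a synchronous job queue."""

    def __init__(self, db_path: Source, graph: IdGraph | None = None):
        self.db_path = str(db_path)
        self._conn = sqlite3.connect(self.db_path)
        self._conn.row_factory = sqlite3.Row
        self._conn.executescript(_SCHEMA)
        self.graph = graph or IdGraph()
        self._clock = 0  # monotonic enqueue counter (deterministic FIFO)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- studies and queue --------------------------------------------

    def register_study(
        self, subject: str, modality: str, study_date: str
    ) -> int:
        if modality not in MODALITY_PARSERS:
            raise ValueError(
                f"unknown modality {modality!r}; expected one of "
                f"{sorted(MODALITY_PARSERS)}"
            )
        try:
            cursor = self._conn.execute(
                "INSERT INTO studies (subject, modality, study_date) VALUES (?,?,?)",
                (subject, modality, study_date),
            )
        except sqlite3.IntegrityError as exc:
            raise ValueError(
                f"study ({subject}, {modality}, {study_date}) already exists"
            ) from exc
        self._conn.commit()
        return int(cursor.lastrowid)

    def enqueue_import(self, study_id: int, paths: Sequence[Source]) -> int:
        """Append an import job; the study moves to 'queued'."""
        row = self._conn.execute(
            "SELECT study_id FROM studies WHERE study_id=?", (study_id,)
        ).fetchone()
        if row is None:
            raise ValueError(f"study {study_id} is not registered")
        resolved_paths = [str(Path(p)) for p in paths]
        for path in resolved_paths:
            if not Path(path).exists():
                raise FileNotFoundError(path)
        self._clock += 1
        cursor = self._conn.execute(
            "INSERT INTO jobs (study_id, paths, enqueue_time) VALUES (?,?,?)",
            (study_id, json.dumps(resolved_paths), f"{self._clock:012d}"),
        )
        self._conn.execute(
            "UPDATE studies SET status='queued' WHERE study_id=?", (study_id,)
        )
        self._conn.commit()
        return int(cursor.lastrowid)

    def process_next(self) -> dict | None:
        """Process the oldest queued job; None when the queue is empty."""
        job = self._conn.execute(
            "SELECT * FROM jobs WHERE done=0 ORDER BY enqueue_time, job_id LIMIT 1"
        ).fetchone()
        if job is None:
            return None
        study = self._conn.execute(
            "SELECT * FROM studies WHERE study_id=?", (job["study_id"],)
        ).fetchone()
        paths = json.loads(job["paths"])
        self._conn.execute(
            "UPDATE studies SET status='importing' WHERE study_id=?",
            (study["study_id"],),
        )
        outcome = self._import_study(study, paths)
        self._conn.execute("UPDATE jobs SET done=1 WHERE job_id=?", (job["job_id"],))
        self._conn.commit()
        return outcome

    def run_queue(self) -> list[dict]:
        outcomes = []
        while (outcome := self.process_next()) is not None:
            outcomes.append(outcome)
        return outcomes

    def _import_study(self, study, paths: list[str]) -> dict:
        study_id = study["study_id"]
        modality = study["modality"]
        # staging first: the raw lines exactly as received
        for path in paths:
            with open(path, errors="replace") as handle:
                for line_no, line in enumerate(handle, start=1):
                    self._conn.execute(
                        "INSERT INTO staging (study_id, line_no, line) VALUES (?,?,?)",
                        (study_id, line_no, line.rstrip("\n")),
                    )
        try:
            records, report = self._parse(modality, paths)
        except Exception as exc:  # file-level failure: staging retained
            self._finish(study_id, "failed", None, {"error": str(exc)})
            return {"study_id": study_id, "status": "failed", "error": str(exc)}
        if report.rows_read > 0 and report.rows_accepted == 0:
            summary = _report_dict(report)
            self._finish(study_id, "failed", None, summary)
            return {"study_id": study_id, "status": "failed", "report": summary}
        dataset = associate(records, self.graph, modality)
        for key, recs in dataset.records.items():
            for record in recs:
                self._conn.execute(
                    "INSERT INTO records (study_id, gene_key, resolved, payload) "
                    "VALUES (?,?,1,?)",
                    (study_id, key, record_to_payload(record)),
                )
        for key, recs in dataset.unresolved.items():
            for record in recs:
                self._conn.execute(
                    "INSERT INTO records (study_id, gene_key, resolved, payload) "
                    "VALUES (?,?,0,?)",
                    (study_id, key, record_to_payload(record)),
                )
        summary = _report_dict(report)
        self._finish(study_id, "imported", report.rows_accepted, summary)
        return {
            "study_id": study_id,
            "status": "imported",
            "row_count": report.rows_accepted,
            "report": summary,
        }

    def _parse(self, modality: str, paths: list[str]):
        records: list = []
        report = ImportReport()
        for path in paths:
            if modality == "wes":
                recs, rep = ingest.parse_variants(path, self.graph)
            elif modality == "rnaseq_gene":
                recs, rep = ingest.parse_cuffdiff_genes(path)
            elif modality == "rnaseq_isoform":
                recs, rep = ingest.parse_cuffdiff_isoforms(path)
            elif modality == "microarray":
                recs, rep = ingest.parse_probe_table(path)
            else:  # pragma: no cover - register_study guards this
                raise ValueError(f"unknown modality {modality!r}")
            records.extend(recs)
            report.rows_read += rep.rows_read
            report.rows_accepted += rep.rows_accepted
            report.rejections.extend(rep.rejections)
            report.notes.extend(rep.notes)
        return records, report

    def _finish(self, study_id: int, status: str, row_count, report: dict) -> None:
        self._conn.execute(
            "UPDATE studies SET status=?, row_count=?, report=? WHERE study_id=?",
            (status, row_count, json.dumps(report), study_id),
        )
        self._conn.commit()

    # -- retrieval ----------------------------------------------------

    def studies(self) -> list[sqlite3.Row]:
        return list(
            self._conn.execute(
                "SELECT * FROM studies ORDER BY subject, study_date, modality"
            )
        )

    def _study_ids(self, subject: str, modality: str | None, study_date: str | None):
        query = "SELECT study_id FROM studies WHERE subject=?"
        params: list = [subject]
        if modality is not None:
            query += " AND modality=?"
            params.append(modality)
        if study_date is not None:
            query += " AND study_date=?"
            params.append(study_date)
        return [row["study_id"] for row in self._conn.execute(query, params)]

    def load_dataset(
        self,
        subject: str,
        modality: str,
        study_date: str | None = None,
    ) -> ModalityDataset:
        """Reconstruct one study's records and re-associate them."""
        ids = self._study_ids(subject, modality, study_date)
        if not ids:
            raise ValueError(
                f"no imported {modality} study for subject {subject!r}"
            )
        records = []
        for study_id in ids:
            for row in self._conn.execute(
                "SELECT payload FROM records WHERE study_id=? ORDER BY record_id",
                (study_id,),
            ):
                records.append(record_from_payload(row["payload"]))
        return associate(records, self.graph, modality)

    def console_summary(self) -> list[dict]:
        """One aggregate line per study, deterministically ordered."""
        return [
            {
                "subject": row["subject"],
                "modality": row["modality"],
                "study_date": row["study_date"],
                "status": row["status"],
                "row_count": row["row_count"],
            }
            for row in self.studies()
        ]

    # -- cascading delete ---------------------------------------------

    def cascade_delete(
        self,
        subject: str,
        modality: str | None = None,
        study_date: str | None = None,
    ) -> dict[str, int]:
        """Delete a study (or an entire subject); per-table removal counts."""
        ids = self._study_ids(subject, modality, study_date)
        if not ids:
            raise ValueError(f"no study matches subject={subject!r} "
                             f"modality={modality!r} date={study_date!r}")
        marks = ",".join("?" for _ in ids)
        summary: dict[str, int] = {}
        for table in _STUDY_TABLES:
            cursor = self._conn.execute(
                f"DELETE FROM {table} WHERE study_id IN ({marks})", ids
            )
            summary[table] = cursor.rowcount
        cursor = self._conn.execute(
            f"DELETE FROM studies WHERE study_id IN ({marks})", ids
        )
        summary["studies"] = cursor.rowcount
        self._conn.commit()
        return summary

    def orphan_rows(self) -> dict[str, int]:
        """Referential scan: rows whose study no longer exists (0 after delete)."""
        counts = {}
        for table in _STUDY_TABLES:
            row = self._conn.execute(
                f"SELECT COUNT(*) AS n FROM {table} WHERE study_id NOT IN "
                "(SELECT study_id FROM studies)"
            ).fetchone()
            counts[table] = row["n"]
        return counts

    # -- gene groups ----------------------------------------------------

    def create_group(
        self, name: str, members: Sequence[str], owner: str = "default"
    ) -> GeneGroup:
        if not members:
            raise ValueError("a gene group needs at least one member")
        try:
            cursor = self._conn.execute(
                "INSERT INTO groups (owner, name) VALUES (?,?)", (owner, name)
            )
        except sqlite3.IntegrityError as exc:
            raise ValueError(f"group {name!r} already exists for {owner!r}") from exc
        group_id = cursor.lastrowid
        for member in members:
            self._conn.execute(
                "INSERT INTO group_members (group_id, member) VALUES (?,?)",
                (group_id, member),
            )
        self._conn.commit()
        return GeneGroup(name=name, owner=owner, members=frozenset(members))

    def add_to_group(
        self, name: str, members: Sequence[str], owner: str = "default"
    ) -> GeneGroup:
        row = self._conn.execute(
            "SELECT group_id FROM groups WHERE owner=? AND name=?", (owner, name)
        ).fetchone()
        if row is None:
            raise ValueError(f"no group {name!r} for owner {owner!r}")
        for member in members:
            self._conn.execute(
                "INSERT INTO group_members (group_id, member) VALUES (?,?)",
                (row["group_id"], member),
            )
        self._conn.commit()
        return self.get_group(name, owner)

    def get_group(self, name: str, owner: str = "default") -> GeneGroup:
        row = self._conn.execute(
            "SELECT group_id FROM groups WHERE owner=? AND name=?", (owner, name)
        ).fetchone()
        if row is None:
            raise ValueError(f"no group {name!r} for owner {owner!r}")
        members = [
            r["member"]
            for r in self._conn.execute(
                "SELECT member FROM group_members WHERE group_id=?",
                (row["group_id"],),
            )
        ]
        return GeneGroup(name=name, owner=owner, members=frozenset(members))

    def list_groups(self, owner: str | None = None) -> list[GeneGroup]:
        query = "SELECT owner, name FROM groups"
        params: tuple = ()
        if owner is not None:
            query += " WHERE owner=?"
            params = (owner,)
        query += " ORDER BY owner, name"
        return [
            self.get_group(row["name"], row["owner"])
            for row in self._conn.execute(query, params)
        ]


def _report_dict(report: ImportReport) -> dict:
    return {
        "rows_read": report.rows_read,
        "rows_accepted": report.rows_accepted,
        "rows_rejected": report.rows_rejected,
        "rejections": report.rejections[:50],
        "notes": report.notes,
    }
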