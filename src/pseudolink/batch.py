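"""CSV bulk import/export with asynchronous job semantics.

``batch_import`` runs every CSV row through the full pipeline
(normalize -> block -> score -> classify -> create / match / queue) and
produces a job with per-row outcomes and summary counters.  Jobs can be
queued and polled (``BatchQueue``) to model the asynchronous bulk API;
the synchronous path is the same code and is what the tests use.
``batch_export`` writes one row per visible patient (tenant-filtered,
MAIN identity only) with only the columns the caller's role grants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import AuthorizationError, BatchError
from .linkage import Decision, LinkageConfig, ingest_identity
from .model import PatientStore
from .normalize import DEFAULT_FIELDS
from .service import Role


class JobState(str, Enum):
    PENDING = "PENDING"
    RUNNING = "RUNNING"
    DONE = "DONE"
    FAILED = "FAILED"


@dataclass
class RowOutcome:
    row: int
    decision: Optional[str]
    created: bool
    pseudonyms: dict[str, str]
    error: Optional[str] = None


@dataclass
class BatchJob:
    job_id: int
    state: JobState = JobState.PENDING
    rows_read: int = 0
    patients_created: int = 0
    matched: int = 0
    tentative: int = 0
    rejected: int = 0
    failed_rows: int = 0
    outcomes: list[RowOutcome] = field(default_factory=list)

    def counters(self) -> dict[str, int]:
        return {
            "rows_read": self.rows_read,
            "patients_created": self.patients_created,
            "matched": self.matched,
            "tentative": self.tentative,
            "rejected": self.rejected,
            "failed_rows": self.failed_rows,
        }

    def outcome_frame(self) -> pd.DataFrame:
        rows = []
        for oc in self.outcomes:
            row = {"row": oc.row, "decision": oc.decision, "created": oc.created,
                   "error": oc.error}
            row.update(oc.pseudonyms)
            rows.append(row)
        return pd.DataFrame(rows)


_job_ids = itertools.count(1)


def _load_frame(csv, mapping: Optional[Mapping[str, str]]) -> pd.DataFrame:
    frame = csv if isinstance(csv, pd.DataFrame) else pd.read_csv(csv, dtype=str)
    if mapping:
        frame = frame.rename(columns=dict(mapping))
    unknown = [c for c in frame.columns if c not in DEFAULT_FIELDS and not c.endswith("_id")]
    usable = [c for c in frame.columns if c in DEFAULT_FIELDS]
    if not usable:
        raise BatchError(f"no CSV column maps onto a schema field (columns: {list(frame.columns)})")
    return frame


def run_import(
    csv,
    store: PatientStore,
    config: LinkageConfig,
    mapping: Optional[Mapping[str, str]] = None,
    block_index=None,
    tenant: Optional[str] = None,
    id_types: Sequence[str] = (),
) -> BatchJob:
    """Synchronous core of the batch import; rows are processed in order and
    may match earlier rows of the same batch."""
    job = BatchJob(job_id=next(_job_ids), state=JobState.RUNNING)
    frame = _load_frame(csv, mapping)
    schema_cols = [c for c in frame.columns if c in DEFAULT_FIELDS]
    for row_idx, row in enumerate(frame.itertuples(index=False)):
        job.rows_read += 1
        fields = {col: getattr(row, col) for col in schema_cols}
        try:
            outcome = ingest_identity(store, fields, config, block_index, tenant=tenant)
        except Exception as exc:  # malformed row: record and continue
            job.failed_rows += 1
            job.outcomes.append(RowOutcome(row_idx, None, False, {}, error=str(exc)))
            continue
        pseudonyms: dict[str, str] = {}
        if outcome.patient is not None:
            for type_name in id_types:
                values = outcome.patient.pseudonym_values(type_name)
                if values:
                    pseudonyms[type_name] = values[0]
        if outcome.rejected_tentative:
            job.rejected += 1
        elif outcome.created:
            job.patients_created += 1
            if outcome.decision is Decision.TENTATIVE:
                job.tentative += 1
        else:
            job.matched += 1
        job.outcomes.append(
            RowOutcome(row_idx, outcome.decision.value, outcome.created, pseudonyms)
        )
    job.state = JobState.DONE
    return job


def batch_export(
    store: PatientStore,
    tenant: Optional[str],
    columns: Sequence[str],
    role: Optional[Role] = None,
) -> pd.DataFrame:
    """One row per visible patient; MAIN identity only, alias identities never
    leave the store.  Requested columns are id types or schema fields and must
    each be covered by the role's grants when a role is supplied."""
    if role is not None:
        for column in columns:
            action = "read-field" if column in store.schema else "read-idtype"
            if not any(g.matches(action, column) for g in role.grants):
                raise AuthorizationError(f"role {role.name!r} may not export column {column!r}")
        if tenant is not None and tenant not in role.tenant_names() and "*" not in role.tenant_names():
            raise AuthorizationError(f"role {role.name!r} is not a member of tenant {tenant!r}")
    rows = []
    for patient in sorted(store.active_patients(), key=lambda p: p.internal_key):
        if tenant is not None and tenant not in patient.tenants:
            continue
        main = patient.main_identity
        row = {}
        for column in columns:
            if column in store.schema:
                row[column] = main.field_values.get(column) if main else None
            else:
                values = patient.pseudonym_values(column)
                row[column] = values[0] if values else None
        rows.append(row)
    return pd.DataFrame(rows, columns=list(columns))


class BatchQueue:
    """Minimal polling job queue modeling the asynchronous bulk API."""

    def __init__(self) -> None:
        self._pending: list[tuple[BatchJob, tuple, dict]] = []
        self.jobs: dict[int, BatchJob] = {}

    def submit(self, csv, store, config, **kwargs) -> BatchJob:
        job = BatchJob(job_id=next(_job_ids))
        self.jobs[job.job_id] = job
        self._pending.append((job, (csv, store, config), kwargs))
        return job

    def status(self, job_id: int) -> JobState:
        return self.jobs[job_id].state

    def run_pending(self) -> None:
        while self._pending:
            job, (csv, store, config), kwargs = self._pending.pop(0)
            try:
                done = run_import(csv, store, config, **kwargs)
            except Exception:
                job.state = JobState.FAILED
                continue
            done.job_id = job.job_id
            self.jobs[job.job_id] = done


# Alias matching the bulk-API vocabulary.
batch_import = run_import
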