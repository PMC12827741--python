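"""Patient / identity / pseudonym data model.

A *patient* is a real person tracked over time.  Their identifying data
may change (marriage, relocation, typo fixes), so the store never
overwrites PII: every snapshot is kept as an *identity*, exactly one of
which is the MAIN identity shown to users, while the rest are ALIAS
identities that still participate in record linkage and lookups.

Pseudonyms are the only handles exposed outside the store.  Internally
generated pseudonyms are minted once and immutable; externally supplied
pseudonyms mirror a source system and may be edited.  Duplicate records
discovered later are resolved by merging (the absorbed record points at
the survivor and its identities become aliases of the survivor) or by
splitting (the pair is recorded as a definitive non-match that the
matcher must never re-propose).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from typing import Callable, Iterable, Mapping, Optional

import pandas as pd

from . import normalize
from .errors import (
    DuplicatePseudonymError,
    EmptyIdentityError,
    ImmutablePseudonymError,
    MergeError,
    SchemaError,
    TentativePairError,
    UnknownPseudonymTypeError,
)


def _utcnow() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


class IdentityKind(str, Enum):
    MAIN = "MAIN"
    ALIAS = "ALIAS"


class PseudonymOrigin(str, Enum):
    INTERNAL = "INTERNAL"
    EXTERNAL = "EXTERNAL"


@dataclass
class Identity:
    """One snapshot of a person's identifying fields (normalized)."""

    field_values: dict[str, Optional[str]]
    kind: IdentityKind = IdentityKind.MAIN
    created_at: str = field(default_factory=_utcnow)

    @classmethod
    def from_raw(cls, fields: Mapping[str, object], kind: IdentityKind = IdentityKind.MAIN) -> "Identity":
        return cls(normalize.normalize_record(fields), kind=kind)

    def non_missing(self) -> dict[str, str]:
        return {k: v for k, v in self.field_values.items() if v is not None}

    def same_values(self, other: "Identity") -> bool:
        return self.non_missing() == other.non_missing()


@dataclass(frozen=True)
class Pseudonym:
    type_name: str
    value: str
    origin: PseudonymOrigin


@dataclass(frozen=True)
class PseudonymTypeDef:
    """Configuration of one pseudonym type.

    ``generator`` (counter -> value) marks an internally generated type;
    ``multi`` allows several values of this type per patient (biosample
    IDs); ``tenant`` binds the type to a domain as its project pseudonym.
    """

    name: str
    generator: Optional[Callable[[int], str]] = None
    multi: bool = False
    tenant: Optional[str] = None

    @property
    def origin(self) -> PseudonymOrigin:
        return PseudonymOrigin.INTERNAL if self.generator else PseudonymOrigin.EXTERNAL


@dataclass
class Patient:
    internal_key: int
    identities: list[Identity] = field(default_factory=list)
    pseudonyms: list[Pseudonym] = field(default_factory=list)
    tenants: set[str] = field(default_factory=set)
    duplicate_of: Optional[int] = None
    tentative_flag: bool = False

    @property
    def main_identity(self) -> Optional[Identity]:
        for ident in self.identities:
            if ident.kind is IdentityKind.MAIN:
                return ident
        return None

    def pseudonym_values(self, type_name: str) -> list[str]:
        return [p.value for p in self.pseudonyms if p.type_name == type_name]


class PatientStore:
    """In-memory patient list with pseudonym index and conflict bookkeeping."""

    def __init__(
        self,
        schema: Iterable[str] = normalize.DEFAULT_FIELDS,
        pseudonym_types: Iterable[PseudonymTypeDef] = (),
    ) -> None:
        self.schema: tuple[str, ...] = tuple(schema)
        self.pseudonym_types: dict[str, PseudonymTypeDef] = {t.name: t for t in pseudonym_types}
        self.patients: dict[int, Patient] = {}
        self.tentative_pairs: dict[frozenset[int], float] = {}
        self.exclusions: set[frozenset[int]] = set()
        self.audit_log: list[dict] = []
        self._keys = itertools.count(1)
        self._counters: dict[str, itertools.count] = {}
        self._pseudonym_index: dict[tuple[str, str], int] = {}

    # -- configuration ----------------------------------------------------

    def register_pseudonym_type(self, type_def: PseudonymTypeDef) -> None:
        self.pseudonym_types[type_def.name] = type_def

    def tenant_id_type(self, tenant: str) -> Optional[PseudonymTypeDef]:
        for type_def in self.pseudonym_types.values():
            if type_def.tenant == tenant:
                return type_def
        return None

    # -- validation -------------------------------------------------------

    def _check_identity(self, identity: Identity) -> None:
        unknown = set(identity.field_values) - set(self.schema)
        if unknown:
            raise SchemaError(f"unknown field name(s): {sorted(unknown)}")
        if not identity.non_missing():
            raise EmptyIdentityError("identity has no non-missing field value")

    # -- patients and identities -------------------------------------------

    def new_patient(self, identity: Identity | None = None, tenant: str | None = None) -> Patient:
        patient = Patient(internal_key=next(self._keys))
        self.patients[patient.internal_key] = patient
        if identity is not None:
            self.add_identity(patient, identity, as_main=True)
        self._mint_internal_defaults(patient)
        if tenant:
            self.enroll(patient, tenant)
        return patient

    def _mint_internal_defaults(self, patient: Patient) -> None:
        for type_def in self.pseudonym_types.values():
            if type_def.generator is not None and type_def.tenant is None:
                if not patient.pseudonym_values(type_def.name):
                    self.mint_pseudonym(patient, type_def.name)

    def enroll(self, patient: Patient, tenant: str) -> Optional[Pseudonym]:
        """Enroll the patient into a tenant; mints the project pseudonym."""
        patient.tenants.add(tenant)
        type_def = self.tenant_id_type(tenant)
        if type_def is not None and (type_def.multi or not patient.pseudonym_values(type_def.name)):
            return self.mint_pseudonym(patient, type_def.name)
        return None

    def add_identity(self, patient: Patient, identity: Identity, as_main: bool = False) -> Patient:
        if patient.duplicate_of is not None:
            raise MergeError("cannot add an identity to an absorbed patient record")
        self._check_identity(identity)
        if as_main or patient.main_identity is None:
            for ident in patient.identities:
                if ident.kind is IdentityKind.MAIN:
                    ident.kind = IdentityKind.ALIAS
            identity.kind = IdentityKind.MAIN
        else:
            identity.kind = IdentityKind.ALIAS
        patient.identities.append(identity)
        return patient

    # -- pseudonyms ---------------------------------------------------------

    def _type_def(self, type_name: str) -> PseudonymTypeDef:
        try:
            return self.pseudonym_types[type_name]
        except KeyError as exc:
            raise UnknownPseudonymTypeError(f"pseudonym type {type_name!r} not configured") from exc

    def mint_pseudonym(self, patient: Patient, type_name: str) -> Pseudonym:
        type_def = self._type_def(type_name)
        if type_def.generator is None:
            raise ImmutablePseudonymError(f"type {type_name!r} is external; values must be supplied")
        counter = self._counters.setdefault(type_name, itertools.count())
        value = type_def.generator(next(counter))
        return self._attach(patient, type_def, value, PseudonymOrigin.INTERNAL)

    def assign_external_pseudonym(self, patient: Patient, type_name: str, value: str) -> Pseudonym:
        type_def = self._type_def(type_name)
        return self._attach(patient, type_def, value, PseudonymOrigin.EXTERNAL)

    def _attach(
        self, patient: Patient, type_def: PseudonymTypeDef, value: str, origin: PseudonymOrigin
    ) -> Pseudonym:
        key = (type_def.name, value)
        if key in self._pseudonym_index:
            raise DuplicatePseudonymError(f"{key} already assigned")
        if not type_def.multi and patient.pseudonym_values(type_def.name):
            raise DuplicatePseudonymError(
                f"patient already holds a pseudonym of non-multi type {type_def.name!r}"
            )
        pseudonym = Pseudonym(type_def.name, value, origin)
        patient.pseudonyms.append(pseudonym)
        self._pseudonym_index[key] = patient.internal_key
        return pseudonym

    def edit_external_pseudonym(
        self, patient: Patient, type_name: str, old_value: str, new_value: str
    ) -> Patient:
        self._type_def(type_name)
        target = next(
            (p for p in patient.pseudonyms if p.type_name == type_name and p.value == old_value),
            None,
        )
        if target is None:
            raise UnknownPseudonymTypeError(f"patient holds no {type_name!r} = {old_value!r}")
        if target.origin is PseudonymOrigin.INTERNAL:
            raise ImmutablePseudonymError("internally generated pseudonyms are immutable")
        if (type_name, new_value) in self._pseudonym_index:
            raise DuplicatePseudonymError(f"({type_name!r}, {new_value!r}) already assigned")
        patient.pseudonyms[patient.pseudonyms.index(target)] = Pseudonym(
            type_name, new_value, PseudonymOrigin.EXTERNAL
        )
        del self._pseudonym_index[(type_name, old_value)]
        self._pseudonym_index[(type_name, new_value)] = patient.internal_key
        return patient

    # -- lookup -------------------------------------------------------------

    def resolve(self, patient: Patient) -> Patient:
        """Follow duplicate_of links to the surviving record (acyclic by construction)."""
        seen = set()
        current = patient
        while current.duplicate_of is not None:
            if current.internal_key in seen:  # pragma: no cover - guarded by merge checks
                raise MergeError("cyclic duplicate_of chain")
            seen.add(current.internal_key)
            current = self.patients[current.duplicate_of]
        return current

    def lookup_by_pseudonym(self, type_name: str, value: str) -> Optional[Patient]:
        self._type_def(type_name)
        key = self._pseudonym_index.get((type_name, value))
        if key is None:
            return None
        return self.resolve(self.patients[key])

    def active_patients(self) -> list[Patient]:
        return [p for p in self.patients.values() if p.duplicate_of is None]

    # -- conflict resolution -------------------------------------------------

    def record_tentative(self, a: Patient, b: Patient, score: float) -> None:
        pair = frozenset((a.internal_key, b.internal_key))
        if len(pair) < 2 or pair in self.exclusions:
            return
        self.tentative_pairs[pair] = score
        a.tentative_flag = b.tentative_flag = True

    def list_tentative_pairs(self) -> list[tuple[Patient, Patient, float]]:
        out = []
        for pair, score in self.tentative_pairs.items():
            low, high = sorted(pair)
            out.append((self.patients[low], self.patients[high], score))
        out.sort(key=lambda item: (item[0].internal_key, item[1].internal_key))
        return out

    def _clear_tentative_flag(self, patient: Patient) -> None:
        if not any(patient.internal_key in pair for pair in self.tentative_pairs):
            patient.tentative_flag = False

    def merge_patients(self, survivor: Patient, absorbed: Patient, actor: str | None = None) -> Patient:
        if survivor.internal_key == absorbed.internal_key:
            raise MergeError("cannot merge a patient with itself")
        if survivor.duplicate_of is not None or absorbed.duplicate_of is not None:
            raise MergeError("cannot merge an already-absorbed record")
        absorbed.duplicate_of = survivor.internal_key
        for ident in absorbed.identities:
            survivor.identities.append(
                Identity(dict(ident.field_values), kind=IdentityKind.ALIAS, created_at=ident.created_at)
            )
        survivor.tenants |= absorbed.tenants
        # Retarget or drop tentative pairs touching either record.
        for pair in list(self.tentative_pairs):
            if absorbed.internal_key in pair or (
                survivor.internal_key in pair and absorbed.internal_key in pair
            ):
                score = self.tentative_pairs.pop(pair)
                others = pair - {absorbed.internal_key, survivor.internal_key}
                if others and absorbed.internal_key in pair:
                    other = self.patients[next(iter(others))]
                    self.record_tentative(survivor, other, score)
        self.tentative_pairs.pop(frozenset((survivor.internal_key, absorbed.internal_key)), None)
        survivor.tentative_flag = False
        absorbed.tentative_flag = False
        self._clear_tentative_flag(survivor)
        self.audit_log.append(
            {
                "timestamp": _utcnow(),
                "operation": "merge",
                "survivor": survivor.internal_key,
                "absorbed": absorbed.internal_key,
                "actor": actor,
            }
        )
        return survivor

    def split_patients(self, a: Patient, b: Patient, actor: str | None = None) -> tuple[Patient, Patient]:
        pair = frozenset((a.internal_key, b.internal_key))
        if pair not in self.tentative_pairs:
            raise TentativePairError("pair is not a recorded tentative match")
        del self.tentative_pairs[pair]
        self.exclusions.add(pair)
        self._clear_tentative_flag(a)
        self._clear_tentative_flag(b)
        self.audit_log.append(
            {
                "timestamp": _utcnow(),
                "operation": "split",
                "pair": sorted(pair),
                "actor": actor,
            }
        )
        return a, b

    def is_excluded(self, a: Patient, b: Patient) -> bool:
        return frozenset((a.internal_key, b.internal_key)) in self.exclusions

    # -- deletion (token-gated at the service layer) ---------------------------

    def delete_patient(self, patient: Patient) -> None:
        for pseudonym in patient.pseudonyms:
            self._pseudonym_index.pop((pseudonym.type_name, pseudonym.value), None)
        for pair in list(self.tentative_pairs):
            if patient.internal_key in pair:
                del self.tentative_pairs[pair]
        self.patients.pop(patient.internal_key, None)

    # -- export -----------------------------------------------------------------

    def export_identities(self) -> pd.DataFrame:
        """One row per (patient, identity); internal keys stay internal — rows are
        labelled by the patient's pseudonyms instead."""
        rows = []
        for patient in self.active_patients():
            pseudonyms = ";".join(f"{p.type_name}={p.value}" for p in patient.pseudonyms)
            for ident in patient.identities:
                row = {"pseudonyms": pseudonyms, "identity_kind": ident.kind.value,
                       "created_at": ident.created_at}
                for name in self.schema:
                    row[name] = ident.field_values.get(name)
                rows.append(row)
        columns = ["pseudonyms", "identity_kind", "created_at", *self.schema]
        return pd.DataFrame(rows, columns=columns)

    def export_identities_csv(self, path) -> None:
        self.export_identities().to_csv(path, index=False)
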