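"""Modular informed-consent management.

A *template* models a consent form: an ordered list of modules (one per
checkbox), each granting one or more data-usage policies, some of them
required.  A *consent record* stores one patient's choices against a
template version, with monotone versioning, full or partial withdrawal,
an optional validity period, and an optional scanned paper document.

``check_policy`` answers the operational question "may we do X to this
patient's data today?" with PERMIT / DENY / UNKNOWN.  The semantics are
fail-safe: an expired or withdrawn consent denies; UNKNOWN is reserved
for "never asked", so callers can distinguish absence from refusal.

Digital and scanned consents serialize to a simplified, structurally
FHIR-conformant Bundle: a Consent resource with one provision per
module, a DocumentReference carrying the Base64-encoded scan, and a
Provenance resource linking the two.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass
from datetime import date, timedelta
from enum import Enum
from typing import Mapping, Optional

from .errors import ConsentError

_ALLOWED_SCAN_TYPES = {"application/pdf", "image/png"}


class Choice(str, Enum):
    PERMIT = "PERMIT"
    DENY = "DENY"


class ConsentStatus(str, Enum):
    ACTIVE = "ACTIVE"
    WITHDRAWN = "WITHDRAWN"
    SUPERSEDED = "SUPERSEDED"


class PolicyOutcome(str, Enum):
    PERMIT = "PERMIT"
    DENY = "DENY"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ConsentModule:
    module_id: str
    policy_ids: tuple[str, ...]
    text_ref: str = ""
    required: bool = False

    def __post_init__(self) -> None:
        if not self.policy_ids:
            raise ConsentError(f"module {self.module_id!r} must grant at least one policy")


@dataclass(frozen=True)
class ConsentTemplate:
    template_id: str
    version: str
    modules: tuple[ConsentModule, ...]
    validity_days: Optional[int] = None

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(ids) != len(set(ids)):
            raise ConsentError("module_ids must be unique within a template")

    def module(self, module_id: str) -> ConsentModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise ConsentError(f"unknown module {module_id!r}")


@dataclass(frozen=True)
class Scan:
    content: bytes
    media_type: str

    def __post_init__(self) -> None:
        if self.media_type not in _ALLOWED_SCAN_TYPES:
            raise ConsentError(f"unsupported scan media type {self.media_type!r}")


@dataclass
class ConsentRecord:
    patient_ref: str
    template_id: str
    template_version: str
    choices: dict[str, Choice]
    signed_date: date
    version: int
    status: ConsentStatus = ConsentStatus.ACTIVE
    scan: Optional[Scan] = None
    withdrawal_date: Optional[date] = None


@dataclass(frozen=True)
class PolicyDecision:
    outcome: PolicyOutcome
    source: Optional[ConsentRecord]
    evaluated_at: date

    def __post_init__(self) -> None:
        assert (self.source is None) == (self.outcome is PolicyOutcome.UNKNOWN)


class ConsentStore:
    """Append-only store of templates and consent records."""

    def __init__(self) -> None:
        self.templates: dict[tuple[str, str], ConsentTemplate] = {}
        self.records: list[ConsentRecord] = []

    def register_template(self, template: ConsentTemplate) -> None:
        self.templates[(template.template_id, template.version)] = template

    def _template(self, template_id: str, version: str) -> ConsentTemplate:
        try:
            return self.templates[(template_id, version)]
        except KeyError as exc:
            raise ConsentError(f"unknown template {template_id!r} v{version!r}") from exc

    def _records_for(self, patient_ref: str, template_id: str) -> list[ConsentRecord]:
        return [
            r for r in self.records if r.patient_ref == patient_ref and r.template_id == template_id
        ]

    # -- recording ---------------------------------------------------------

    def record_consent(
        self,
        patient_ref: str,
        template_id: str,
        template_version: str,
        choices: Mapping[str, Choice | str],
        signed_date: date,
        scan: Optional[Scan] = None,
    ) -> ConsentRecord:
        template = self._template(template_id, template_version)
        parsed = {mid: Choice(c) for mid, c in choices.items()}
        for mid in parsed:
            template.module(mid)  # raises on unknown module
        missing = [m.module_id for m in template.modules if m.required and m.module_id not in parsed]
        if missing:
            raise ConsentError(f"missing choice(s) for required module(s): {missing}")
        prior = self._records_for(patient_ref, template_id)
        for rec in prior:
            if rec.status is ConsentStatus.ACTIVE:
                rec.status = ConsentStatus.SUPERSEDED
        record = ConsentRecord(
            patient_ref=patient_ref,
            template_id=template_id,
            template_version=template_version,
            choices=parsed,
            signed_date=signed_date,
            version=max((r.version for r in prior), default=0) + 1,
            scan=scan,
        )
        self.records.append(record)
        return record

    def withdraw_consent(
        self,
        patient_ref: str,
        template_id: str,
        withdrawal_date: date,
        modules: Optional[list[str]] = None,
    ) -> ConsentRecord:
        """Full withdrawal flips the ACTIVE record to WITHDRAWN; partial
        withdrawal records a successor version with the named modules DENY."""
        active = [
            r for r in self._records_for(patient_ref, template_id)
            if r.status is ConsentStatus.ACTIVE
        ]
        if not active:
            raise ConsentError("no active consent to withdraw")
        current = active[0]
        if modules is None:
            current.status = ConsentStatus.WITHDRAWN
            current.withdrawal_date = withdrawal_date
            return current
        template = self._template(template_id, current.template_version)
        for mid in modules:
            template.module(mid)
        choices = dict(current.choices)
        for mid in modules:
            choices[mid] = Choice.DENY
        return self.record_consent(
            patient_ref, template_id, current.template_version, choices, withdrawal_date
        )

    # -- evaluation ---------------------------------------------------------

    def check_policy(self, patient_ref: str, policy_id: str, at_date: date) -> PolicyDecision:
        best: Optional[ConsentRecord] = None
        best_outcome = PolicyOutcome.UNKNOWN
        for template in {r.template_id for r in self.records if r.patient_ref == patient_ref}:
            applicable = [
                r for r in self._records_for(patient_ref, template) if r.signed_date <= at_date
            ]
            if not applicable:
                continue
            record = max(applicable, key=lambda r: r.version)
            tmpl = self._template(record.template_id, record.template_version)
            covering = [m for m in tmpl.modules if policy_id in m.policy_ids]
            if not covering:
                continue
            outcome = self._evaluate(record, tmpl, covering, at_date)
            # Fail-safe combination across templates: any DENY wins over PERMIT.
            if best is None or outcome is PolicyOutcome.DENY:
                best, best_outcome = record, outcome
        if best is None:
            return PolicyDecision(PolicyOutcome.UNKNOWN, None, at_date)
        return PolicyDecision(best_outcome, best, at_date)

    @staticmethod
    def _evaluate(
        record: ConsentRecord,
        template: ConsentTemplate,
        covering: list[ConsentModule],
        at_date: date,
    ) -> PolicyOutcome:
        if record.withdrawal_date is not None and at_date >= record.withdrawal_date:
            return PolicyOutcome.DENY
        if template.validity_days is not None:
            if at_date > record.signed_date + timedelta(days=template.validity_days):
                return PolicyOutcome.DENY
        permits = [record.choices.get(m.module_id) for m in covering]
        if any(c is Choice.PERMIT for c in permits):
            return PolicyOutcome.PERMIT
        return PolicyOutcome.DENY


# ---------------------------------------------------------------------------
# FHIR serialization (simplified, structurally conformant)
# ---------------------------------------------------------------------------

_STATUS_TO_FHIR = {
    ConsentStatus.ACTIVE: "active",
    ConsentStatus.WITHDRAWN: "inactive",
    ConsentStatus.SUPERSEDED: "inactive",
}
_FHIR_TO_STATUS = {"active": ConsentStatus.ACTIVE, "inactive": ConsentStatus.WITHDRAWN}


def consent_to_fhir(record: ConsentRecord) -> dict:
    """Serialize to a FHIR Bundle: Consent (+ DocumentReference + Provenance if scanned)."""
    consent_id = f"consent-{record.patient_ref}-{record.template_id}-v{record.version}"
    consent = {
        "resourceType": "Consent",
        "id": consent_id,
        "status": _STATUS_TO_FHIR[record.status],
        "scope": {"coding": [{"system": "http://terminology.hl7.org/CodeSystem/consentscope",
                              "code": "research"}]},
        "category": [{"coding": [{"code": "research"}]}],
        "patient": {"reference": f"Patient/{record.patient_ref}"},
        "dateTime": record.signed_date.isoformat(),
        "policy": [{"uri": f"urn:consent-template:{record.template_id}:{record.template_version}"}],
        "meta": {"versionId": str(record.version)},
        "provision": {
            "type": "deny",
            "provision": [
                {
                    "type": "permit" if choice is Choice.PERMIT else "deny",
                    "code": [{"coding": [{"code": module_id}]}],
                }
                for module_id, choice in record.choices.items()
            ],
        },
    }
    if record.withdrawal_date is not None:
        consent["extension"] = [
            {"url": "urn:pseudolink:withdrawal-date",
             "valueDate": record.withdrawal_date.isoformat()}
        ]
    entries = [{"resource": consent}]
    if record.scan is not None:
        doc_id = f"{consent_id}-scan"
        entries.append(
            {
                "resource": {
                    "resourceType": "DocumentReference",
                    "id": doc_id,
                    "status": "current",
                    "subject": {"reference": f"Patient/{record.patient_ref}"},
                    "content": [
                        {
                            "attachment": {
                                "contentType": record.scan.media_type,
                                "data": base64.b64encode(record.scan.content).decode("ascii"),
                            }
                        }
                    ],
                }
            }
        )
        entries.append(
            {
                "resource": {
                    "resourceType": "Provenance",
                    "id": f"{consent_id}-provenance",
                    "target": [
                        {"reference": f"Consent/{consent_id}"},
                        {"reference": f"DocumentReference/{doc_id}"},
                    ],
                    "recorded": record.signed_date.isoformat(),
                }
            }
        )
    return {"resourceType": "Bundle", "type": "collection", "entry": entries}


def consent_from_fhir(bundle: Mapping) -> ConsentRecord:
    """Reconstruct a ConsentRecord from a Bundle produced by consent_to_fhir."""
    if bundle.get("resourceType") != "Bundle":
        raise ConsentError("not a FHIR Bundle")
    resources = {}
    for entry in bundle.get("entry", []):
        res = entry.get("resource", {})
        resources.setdefault(res.get("resourceType"), []).append(res)
    consents = resources.get("Consent", [])
    if len(consents) != 1:
        raise ConsentError("bundle must contain exactly one Consent resource")
    consent = consents[0]
    try:
        policy_uri = consent["policy"][0]["uri"]
        _, _, template_id, template_version = policy_uri.split(":")
        patient_ref = consent["patient"]["reference"].split("/", 1)[1]
        choices = {}
        for provision in consent["provision"]["provision"]:
            ptype = provision["type"]
            if ptype not in ("permit", "deny"):
                raise ConsentError(f"unknown provision type {ptype!r}")
            module_id = provision["code"][0]["coding"][0]["code"]
            choices[module_id] = Choice.PERMIT if ptype == "permit" else Choice.DENY
        status = _FHIR_TO_STATUS.get(consent["status"])
        if status is None:
            raise ConsentError(f"unknown Consent status {consent['status']!r}")
        signed = date.fromisoformat(consent["dateTime"])
        version = int(consent.get("meta", {}).get("versionId", "1"))
    except (KeyError, IndexError, ValueError) as exc:
        raise ConsentError(f"malformed Consent resource: {exc}") from exc
    withdrawal = None
    for ext in consent.get("extension", []):
        if ext.get("url") == "urn:pseudolink:withdrawal-date":
            withdrawal = date.fromisoformat(ext["valueDate"])
    scan = None
    for doc in resources.get("DocumentReference", []):
        attachment = doc["content"][0]["attachment"]
        scan = Scan(base64.b64decode(attachment["data"]), attachment["contentType"])
    return ConsentRecord(
        patient_ref=patient_ref,
        template_id=template_id,
        template_version=template_version,
        choices=choices,
        signed_date=signed,
        version=version,
        status=status,
        scan=scan,
        withdrawal_date=withdrawal,
    )
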