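"""Session / token delegation engine with multi-tenant RBAC and audit trail.

A client authenticates with a pre-shared API key and opens a *session*;
within it, *tokens* are minted, each authorizing exactly one operation
class (add / read / edit / delete patient).  Another party — typically
the end user's browser — redeems the token without ever holding the API
key.  Redemption validates the token, executes exactly the authorized
operation, optionally delivers selected pseudonyms to a pre-registered
callback URL (so the redeemer and the callback receiver can be shown
*different* pseudonyms), and appends an audit record.  Permissions are
deny-by-default, tenant-scoped, and can be gated on a consent policy.

The engine is in-process and transport-agnostic: callback delivery goes
through an injectable transport callable, and time through an
injectable clock, so the full authorization logic is testable without
networking.
"""

from __future__ import annotations

import hmac
import json
import secrets
import time
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Callable, Mapping, Optional

from .consent import ConsentStore, PolicyOutcome
from .errors import AuthenticationError, AuthorizationError, TokenError
from .linkage import LinkageConfig, ingest_identity
from .model import Patient, PatientStore


class TokenType(str, Enum):
    ADD_PATIENT = "ADD_PATIENT"
    READ_PATIENT = "READ_PATIENT"
    EDIT_PATIENT = "EDIT_PATIENT"
    DELETE_PATIENT = "DELETE_PATIENT"


class TokenState(str, Enum):
    ISSUED = "ISSUED"
    REDEEMED = "REDEEMED"
    INVALID = "INVALID"


@dataclass
class Session:
    session_id: str
    owner: str
    role: str
    created_at: float
    expires_at: float
    tokens: set[str] = field(default_factory=set)
    invalidated: bool = False


@dataclass
class Token:
    token_id: str
    token_type: TokenType
    session_id: str
    payload: dict
    callback: Optional[dict] = None
    audit_reason: Optional[str] = None
    single_use: bool = True
    state: TokenState = TokenState.ISSUED


@dataclass(frozen=True)
class AuditRecord:
    timestamp: float
    client: str
    role: str
    token_id: str
    token_type: TokenType
    reason: Optional[str]
    operation: str
    affected_pseudonyms: tuple[str, ...]
    outcome: str


@dataclass(frozen=True)
class Grant:
    """Parsed grant string ``action[:qualifier][|requires-policy:<id>]``."""

    action: str
    qualifier: Optional[str] = None
    requires_policy: Optional[str] = None

    @classmethod
    def parse(cls, text: str) -> "Grant":
        policy = None
        if "|requires-policy:" in text:
            text, policy = text.split("|requires-policy:", 1)
        if ":" in text:
            action, qualifier = text.split(":", 1)
        else:
            action, qualifier = text, None
        return cls(action, qualifier, policy)

    def matches(self, action: str, qualifier: Optional[str]) -> bool:
        if self.action not in ("*", action):
            return False
        if self.qualifier is None:
            return qualifier is None
        return self.qualifier == "*" or self.qualifier == qualifier


@dataclass(frozen=True)
class Role:
    name: str
    grants: tuple[Grant, ...]

    @classmethod
    def from_strings(cls, name: str, grants) -> "Role":
        return cls(name, tuple(Grant.parse(g) for g in grants))

    def tenant_names(self) -> set[str]:
        return {g.qualifier for g in self.grants if g.action == "tenant" and g.qualifier}


@dataclass(frozen=True)
class ClientConfig:
    client_id: str
    api_key: str
    role: str


@dataclass
class ServiceConfig:
    clients: tuple[ClientConfig, ...]
    roles: tuple[Role, ...]
    callback_allowlist: tuple[str, ...] = ()
    audit_reason_required: bool = True
    session_ttl_seconds: float = 600.0
    callback_secret: bytes = b"pseudolink-callback"
    callback_max_retries: int = 3

    def client_for_key(self, api_key: str) -> ClientConfig:
        for client in self.clients:
            if hmac.compare_digest(client.api_key, api_key):
                return client
        raise AuthenticationError("unknown API key")

    def role_named(self, name: str) -> Optional[Role]:
        for role in self.roles:
            if role.name == name:
                return role
        return None


class PseudonymizationService:
    """In-process engine owning sessions, tokens, permissions, and the audit trail."""

    def __init__(
        self,
        store: PatientStore,
        linkage_config: LinkageConfig,
        config: ServiceConfig,
        block_index=None,
        consent_store: Optional[ConsentStore] = None,
        callback_transport: Optional[Callable[[str, dict], bool]] = None,
        clock: Callable[[], float] = time.monotonic,
    ) -> None:
        self.store = store
        self.linkage_config = linkage_config
        self.config = config
        self.block_index = block_index
        self.consent_store = consent_store
        self.callback_transport = callback_transport
        self.clock = clock
        self.sessions: dict[str, Session] = {}
        self.tokens: dict[str, Token] = {}
        self.audit_trail: list[AuditRecord] = []
        self.auth_log: list[str] = []

    # -- sessions ----------------------------------------------------------

    def create_session(self, api_key: str) -> Session:
        client = self.config.client_for_key(api_key)
        now = self.clock()
        session = Session(
            session_id=secrets.token_urlsafe(24),  # >= 128 bits of randomness
            owner=client.client_id,
            role=client.role,
            created_at=now,
            expires_at=now + self.config.session_ttl_seconds,
        )
        self.sessions[session.session_id] = session
        self.auth_log.append(f"session created for {client.client_id}")
        return session

    def _live_session(self, session_id: str) -> Session:
        session = self.sessions.get(session_id)
        if session is None or session.invalidated:
            raise TokenError("unknown or invalidated session")
        if self.clock() >= session.expires_at:
            raise TokenError("session expired")
        return session

    def invalidate_session(self, session_id: str) -> None:
        session = self.sessions.get(session_id)
        if session is None:
            self.auth_log.append(f"invalidate of unknown session {session_id!r} (no-op)")
            return
        session.invalidated = True
        for token_id in session.tokens:
            token = self.tokens.get(token_id)
            if token is not None and token.state is TokenState.ISSUED:
                token.state = TokenState.INVALID

    # -- permissions -------------------------------------------------------

    def check_permission(
        self,
        role_name: str,
        action: str,
        qualifier: Optional[str] = None,
        patient: Optional[Patient] = None,
        at_date: Optional[date] = None,
    ) -> bool:
        """Deny-by-default grant evaluation with tenant and consent gating."""
        role = self.config.role_named(role_name)
        if role is None:
            self.auth_log.append(f"deny {action}:{qualifier} — unknown role {role_name!r}")
            return False
        grant = next((g for g in role.grants if g.matches(action, qualifier)), None)
        if grant is None:
            self.auth_log.append(f"deny {action}:{qualifier} for role {role_name}")
            return False
        if patient is not None and patient.tenants:
            tenants = role.tenant_names()
            if "*" not in tenants and not (tenants & patient.tenants):
                self.auth_log.append(f"deny {action}:{qualifier} — tenant isolation")
                return False
        if grant.requires_policy is not None:
            if self.consent_store is None or patient is None:
                return False
            decision = self.consent_store.check_policy(
                str(patient.internal_key), grant.requires_policy, at_date or date.today()
            )
            if decision.outcome is not PolicyOutcome.PERMIT:
                self.auth_log.append(
                    f"deny {action}:{qualifier} — consent policy {grant.requires_policy} "
                    f"is {decision.outcome.value}"
                )
                return False
        self.auth_log.append(f"allow {action}:{qualifier} for role {role_name}")
        return True

    # -- tokens ------------------------------------------------------------

    def create_token(
        self,
        session_id: str,
        token_type: TokenType,
        payload: Optional[Mapping] = None,
        callback: Optional[Mapping] = None,
        reason: Optional[str] = None,
    ) -> Token:
        session = self._live_session(session_id)
        token_type = TokenType(token_type)
        if not self.check_permission(session.role, "create-token", token_type.value):
            raise AuthorizationError(f"role {session.role!r} may not create {token_type.value} tokens")
        if self.config.audit_reason_required and not reason:
            raise AuthorizationError("audit trail enabled: a reason must be supplied")
        if callback is not None:
            url = callback.get("url", "")
            if not any(url.startswith(prefix) for prefix in self.config.callback_allowlist):
                raise AuthorizationError(f"callback URL {url!r} is not allow-listed")
        token = Token(
            token_id=secrets.token_urlsafe(24),
            token_type=token_type,
            session_id=session_id,
            payload=dict(payload or {}),
            callback=dict(callback) if callback else None,
            audit_reason=reason,
        )
        self.tokens[token.token_id] = token
        session.tokens.add(token.token_id)
        return token

    def redeem_token(self, token_id: str, request_data: Optional[Mapping] = None) -> dict:
        """Validate, atomically consume, execute, fire callback, audit."""
        request_data = dict(request_data or {})
        token = self.tokens.get(token_id)
        if token is None:
            raise TokenError("unknown token")
        if token.state is not TokenState.ISSUED:
            raise TokenError(f"token is {token.state.value}, not redeemable")
        session = self._live_session(token.session_id)  # raises on expiry/invalidation
        requested_type = request_data.get("operation", token.token_type.value)
        if TokenType(requested_type) is not token.token_type:
            raise TokenError("request does not match the token's operation class")
        # Validation passed: check-and-set so a single-use token can never run twice.
        if token.single_use:
            token.state = TokenState.REDEEMED
        outcome = "ok"
        affected: tuple[str, ...] = ()
        try:
            handler = {
                TokenType.ADD_PATIENT: self._op_add_patient,
                TokenType.READ_PATIENT: self._op_read_patient,
                TokenType.EDIT_PATIENT: self._op_edit_patient,
                TokenType.DELETE_PATIENT: self._op_delete_patient,
            }[token.token_type]
            result, affected = handler(session, token, request_data)
        except Exception:
            outcome = "error"
            raise
        finally:
            self.audit_trail.append(
                AuditRecord(
                    timestamp=self.clock(),
                    client=session.owner,
                    role=session.role,
                    token_id=token.token_id,
                    token_type=token.token_type,
                    reason=token.audit_reason,
                    operation=token.token_type.value,
                    affected_pseudonyms=affected,
                    outcome=outcome,
                )
            )
        return result

    # -- operation handlers --------------------------------------------------

    def _visible_pseudonyms(self, patient: Patient, id_types) -> dict[str, str]:
        out = {}
        for type_name in id_types:
            values = patient.pseudonym_values(type_name)
            if values:
                out[type_name] = values[0] if len(values) == 1 else values
        return out

    def _op_add_patient(self, session: Session, token: Token, request: Mapping):
        fields = request.get("fields")
        if not fields:
            raise TokenError("ADD_PATIENT redemption requires 'fields'")
        tenant = token.payload.get("tenant")
        outcome = ingest_identity(
            self.store, fields, self.linkage_config, self.block_index, tenant=tenant
        )
        if outcome.rejected_tentative:
            return (
                {"decision": "NON_MATCH", "rejected_tentative": True, "pseudonyms": {}},
                (),
            )
        patient = outcome.patient
        for type_name, value in token.payload.get("external_pseudonyms", {}).items():
            if not patient.pseudonym_values(type_name):
                self.store.assign_external_pseudonym(patient, type_name, value)
        visible_types = token.payload.get("id_types", [])
        visible = self._visible_pseudonyms(patient, visible_types)
        affected = tuple(
            f"{t}={v}" for t, v in self._visible_pseudonyms(
                patient, [p.type_name for p in patient.pseudonyms]
            ).items()
        )
        if token.callback:
            callback_types = token.callback.get("id_types", [])
            self._deliver_callback(
                token.callback["url"],
                {"pseudonyms": self._visible_pseudonyms(patient, callback_types)},
            )
        return (
            {
                "decision": outcome.decision.value,
                "created": outcome.created,
                "pseudonyms": visible,
            },
            affected,
        )

    def _require_patient(self, session: Session, request: Mapping) -> Patient:
        id_type, value = request.get("id_type"), request.get("value")
        if not id_type or value is None:
            raise TokenError("request requires 'id_type' and 'value'")
        if not self.check_permission(session.role, "read-idtype", id_type):
            raise AuthorizationError(f"role {session.role!r} may not use id type {id_type!r}")
        patient = self.store.lookup_by_pseudonym(id_type, value)
        if patient is None:
            raise TokenError("no patient under that pseudonym")
        if not self.check_permission(session.role, "read-patient", None, patient=patient):
            raise AuthorizationError("tenant isolation: patient not visible to this role")
        return patient

    def _op_read_patient(self, session: Session, token: Token, request: Mapping):
        patient = self._require_patient(session, request)
        main = patient.main_identity
        readable = [
            p.type_name
            for p in patient.pseudonyms
            if self.check_permission(session.role, "read-idtype", p.type_name, patient=patient)
        ]
        visible = self._visible_pseudonyms(patient, readable)
        return (
            {"fields": dict(main.field_values) if main else {}, "pseudonyms": visible},
            tuple(f"{t}={v}" for t, v in visible.items()),
        )

    def _op_edit_patient(self, session: Session, token: Token, request: Mapping):
        patient = self._require_patient(session, request)
        fields = request.get("fields")
        if not fields:
            raise TokenError("EDIT_PATIENT redemption requires 'fields'")
        from .model import Identity

        self.store.add_identity(patient, Identity.from_raw(fields), as_main=True)
        if self.block_index is not None:
            self.block_index.add_identity(patient.internal_key, patient.main_identity)
        return ({"edited": True}, ())

    def _op_delete_patient(self, session: Session, token: Token, request: Mapping):
        patient = self._require_patient(session, request)
        affected = tuple(f"{p.type_name}={p.value}" for p in patient.pseudonyms)
        self.store.delete_patient(patient)
        return ({"deleted": True}, affected)

    # -- callbacks ------------------------------------------------------------

    def _deliver_callback(self, url: str, body: dict) -> None:
        """At-least-once delivery with bounded retries; failures never block the
        redeemer's response.  The payload is signed with the service secret."""
        if self.callback_transport is None:
            return
        payload = dict(body)
        serialized = json.dumps(body, sort_keys=True).encode()
        payload["signature"] = hmac.digest(self.config.callback_secret, serialized, "sha256").hex()
        for _ in range(self.config.callback_max_retries):
            try:
                if self.callback_transport(url, payload):
                    return
            except Exception:
                continue
        self.auth_log.append(f"callback delivery to {url} failed after retries")
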