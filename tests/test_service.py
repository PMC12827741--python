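"""Sessions, tokens, redemption, RBAC, tenant isolation, audit trail."""

from datetime import date

import numpy as np
import pytest

import pseudolink as pl
from pseudolink.errors import AuthenticationError, AuthorizationError, TokenError
from pseudolink.service import TokenState, TokenType


class FakeClock:
    def __init__(self):
        self.now = 0.0

    def __call__(self):
        return self.now


def make_service(store=None, clock=None, consent_store=None, callbacks=None,
                 audit_reason_required=True):
    store = store or pl.default_store(b"service-test-key")
    store.register_pseudonym_type(
        pl.PseudonymTypeDef(
            "study_a_id",
            generator=lambda n: f"STUDY-A-{n:06d}",
            tenant="study_a",
        )
    )
    store.register_pseudonym_type(
        pl.PseudonymTypeDef(
            "study_b_id",
            generator=lambda n: f"STUDY-B-{n:06d}",
            tenant="study_b",
        )
    )
    config = pl.ServiceConfig(
        clients=(
            pl.ClientConfig("edc-a", "key-edc-a", "study_a_user"),
            pl.ClientConfig("edc-b", "key-edc-b", "study_b_user"),
            pl.ClientConfig("admin", "key-admin", "admin"),
        ),
        roles=(
            pl.Role.from_strings("study_a_user", [
                "create-token:ADD_PATIENT", "create-token:READ_PATIENT",
                "read-idtype:study_a_id", "read-patient", "tenant:study_a",
            ]),
            pl.Role.from_strings("study_b_user", [
                "create-token:ADD_PATIENT", "create-token:READ_PATIENT",
                "read-idtype:study_b_id", "read-patient", "tenant:study_b",
            ]),
            pl.Role.from_strings("admin", [
                "create-token:*", "read-idtype:*", "read-patient", "tenant:*",
            ]),
        ),
        callback_allowlist=("https://edc.example.org/",),
    )
    return pl.PseudonymizationService(
        store,
        pl.default_linkage_config(),
        config,
        consent_store=consent_store,
        callback_transport=callbacks,
        clock=clock or FakeClock(),
    )


class TestSessions:
    def test_valid_key_issues_session(self):
        service = make_service()
        session = service.create_session("key-edc-a")
        assert session.owner == "edc-a" and session.session_id

    def test_bad_key_rejected(self):
        with pytest.raises(AuthenticationError):
            make_service().create_session("wrong")

    def test_session_ids_unguessable_and_distinct(self):
        service = make_service()
        ids = {service.create_session("key-edc-a").session_id for _ in range(20)}
        assert len(ids) == 20

    def test_expired_session_refuses_tokens(self):
        clock = FakeClock()
        service = make_service(clock=clock)
        session = service.create_session("key-edc-a")
        clock.now = 601.0
        with pytest.raises(TokenError):
            service.create_token(session.session_id, TokenType.ADD_PATIENT, reason="r")

    def test_invalidate_cascades_and_is_idempotent(self, anna):
        service = make_service()
        session = service.create_session("key-edc-a")
        token = service.create_token(session.session_id, TokenType.ADD_PATIENT, reason="r")
        other = service.create_session("key-edc-a")
        other_token = service.create_token(other.session_id, TokenType.ADD_PATIENT, reason="r")
        service.invalidate_session(session.session_id)
        assert token.state is TokenState.INVALID
        with pytest.raises(TokenError):
            service.redeem_token(token.token_id, {"fields": anna})
        service.invalidate_session(session.session_id)  # no-op
        # other sessions unaffected
        service.redeem_token(other_token.token_id, {"fields": anna})


class TestTokens:
    def test_role_without_grant_cannot_create(self):
        service = make_service()
        session = service.create_session("key-edc-a")
        with pytest.raises(AuthorizationError):
            service.create_token(session.session_id, TokenType.DELETE_PATIENT, reason="r")

    def test_reason_required_when_audit_on(self):
        service = make_service()
        session = service.create_session("key-edc-a")
        with pytest.raises(AuthorizationError):
            service.create_token(session.session_id, TokenType.ADD_PATIENT)

    def test_callback_must_be_allowlisted(self):
        service = make_service()
        session = service.create_session("key-edc-a")
        with pytest.raises(AuthorizationError):
            service.create_token(
                session.session_id, TokenType.ADD_PATIENT,
                callback={"url": "https://evil.example.net/x", "id_types": ["pid"]},
                reason="r",
            )

    def test_external_pseudonym_carried_in_payload(self, anna):
        service = make_service()
        service.store.register_pseudonym_type(pl.PseudonymTypeDef("lab_id"))
        session = service.create_session("key-edc-a")
        token = service.create_token(
            session.session_id, TokenType.ADD_PATIENT,
            payload={"external_pseudonyms": {"lab_id": "LAB-9"}, "id_types": ["lab_id"]},
            reason="enrolment",
        )
        result = service.redeem_token(token.token_id, {"fields": anna})
        assert result["pseudonyms"]["lab_id"] == "LAB-9"


class TestRedemption:
    def test_caller_sees_study_id_callback_gets_pid(self, anna):
        """The redeemer is shown only the study pseudonym; the internal pid
        travels solely through the pre-registered callback."""
        delivered = []
        service = make_service(callbacks=lambda url, body: delivered.append((url, body)) or True)
        session = service.create_session("key-edc-a")
        token = service.create_token(
            session.session_id, TokenType.ADD_PATIENT,
            payload={"tenant": "study_a", "id_types": ["study_a_id"]},
            callback={"url": "https://edc.example.org/cb", "id_types": ["pid"]},
            reason="registration",
        )
        result = service.redeem_token(token.token_id, {"fields": anna})
        assert set(result["pseudonyms"]) == {"study_a_id"}
        assert len(delivered) == 1
        url, body = delivered[0]
        assert url == "https://edc.example.org/cb"
        assert set(body["pseudonyms"]) == {"pid"}
        assert "signature" in body

    def test_single_use_token_redeems_exactly_once(self, anna, boris):
        service = make_service()
        session = service.create_session("key-edc-a")
        token = service.create_token(session.session_id, TokenType.ADD_PATIENT, reason="r")
        service.redeem_token(token.token_id, {"fields": anna})
        before = len(service.store.active_patients())
        with pytest.raises(TokenError):
            service.redeem_token(token.token_id, {"fields": boris})
        assert len(service.store.active_patients()) == before

    def test_type_mismatch_does_not_consume(self, anna):
        service = make_service()
        session = service.create_session("key-edc-a")
        token = service.create_token(session.session_id, TokenType.ADD_PATIENT, reason="r")
        with pytest.raises(TokenError):
            service.redeem_token(token.token_id, {"operation": "READ_PATIENT"})
        assert token.state is TokenState.ISSUED
        service.redeem_token(token.token_id, {"fields": anna})  # still usable

    def test_every_redemption_writes_one_audit_record(self, anna, boris):
        service = make_service()
        session = service.create_session("key-edc-a")
        for fields in (anna, boris):
            token = service.create_token(session.session_id, TokenType.ADD_PATIENT,
                                         reason="registration")
            service.redeem_token(token.token_id, {"fields": fields})
        assert len(service.audit_trail) == 2
        assert all(r.reason == "registration" for r in service.audit_trail)
        assert all(r.token_type is TokenType.ADD_PATIENT for r in service.audit_trail)

    def test_tenant_enrollment_mints_project_pseudonym(self, anna):
        service = make_service()
        session = service.create_session("key-edc-a")
        token = service.create_token(
            session.session_id, TokenType.ADD_PATIENT,
            payload={"tenant": "study_a", "id_types": ["study_a_id"]}, reason="r",
        )
        result = service.redeem_token(token.token_id, {"fields": anna})
        assert result["pseudonyms"]["study_a_id"].startswith("STUDY-A-")


class TestPermissions:
    def _patient_in_a(self, service, fields):
        session = service.create_session("key-edc-a")
        token = service.create_token(
            session.session_id, TokenType.ADD_PATIENT,
            payload={"tenant": "study_a", "id_types": ["study_a_id"]}, reason="r",
        )
        return service.redeem_token(token.token_id, {"fields": fields})["pseudonyms"]["study_a_id"]

    def test_idtype_restriction(self):
        service = make_service()
        assert service.check_permission("study_a_user", "read-idtype", "study_a_id")
        assert not service.check_permission("study_a_user", "read-idtype", "pid")

    def test_unknown_role_denied(self):
        assert not make_service().check_permission("ghost", "read-idtype", "pid")

    def test_cross_tenant_read_denied(self, anna):
        service = make_service()
        study_a_id = self._patient_in_a(service, anna)
        session_b = service.create_session("key-edc-b")
        token = service.create_token(session_b.session_id, TokenType.READ_PATIENT, reason="r")
        with pytest.raises(AuthorizationError):
            service.redeem_token(token.token_id, {"id_type": "study_a_id", "value": study_a_id})

    def test_same_tenant_read_allowed(self, anna):
        service = make_service()
        study_a_id = self._patient_in_a(service, anna)
        session = service.create_session("key-edc-a")
        token = service.create_token(session.session_id, TokenType.READ_PATIENT, reason="r")
        result = service.redeem_token(token.token_id, {"id_type": "study_a_id", "value": study_a_id})
        assert result["fields"]["last_name"] == "MEIER"
        assert set(result["pseudonyms"]) == {"study_a_id"}  # pid not readable by this role

    def test_consent_gated_grant(self, anna):
        consents = pl.ConsentStore()
        consents.register_template(pl.ConsentTemplate(
            "broad", "1", (pl.ConsentModule("sharing", ("export",)),),
        ))
        service = make_service(consent_store=consents)
        service.config.roles = service.config.roles + (
            pl.Role.from_strings("exporter", ["export:study_a_id|requires-policy:export",
                                              "tenant:study_a"]),
        )
        study_a_id = self._patient_in_a(service, anna)
        patient = service.store.lookup_by_pseudonym("study_a_id", study_a_id)
        ref = str(patient.internal_key)
        at = date(2024, 6, 1)
        # no consent -> deny
        assert not service.check_permission("exporter", "export", "study_a_id",
                                            patient=patient, at_date=at)
        consents.record_consent(ref, "broad", "1", {"sharing": "PERMIT"}, date(2024, 1, 1))
        assert service.check_permission("exporter", "export", "study_a_id",
                                        patient=patient, at_date=at)
        consents.withdraw_consent(ref, "broad", date(2024, 5, 1))
        assert not service.check_permission("exporter", "export", "study_a_id",
                                            patient=patient, at_date=at)


class TestFuzzNoBypass:
    def test_random_action_sequences_never_bypass_tokens(self):
        """10,000 random service actions: the store only ever changes through a
        valid token redemption, and every consumed token leaves exactly one
        audit record."""
        rng = np.random.default_rng(4242)
        service = make_service()
        store = service.store
        sessions, tokens = [], []
        successful_adds = 0
        for step in range(10_000):
            action = rng.integers(6)
            fields = {"first_name": f"F{step}", "last_name": f"L{step}",
                      "birth_year": 1950 + step % 60}
            try:
                if action == 0:
                    key = ["key-edc-a", "key-edc-b", "bogus"][int(rng.integers(3))]
                    sessions.append(service.create_session(key))
                elif action == 1 and sessions:
                    s = sessions[int(rng.integers(len(sessions)))]
                    ttype = [TokenType.ADD_PATIENT, TokenType.READ_PATIENT,
                             TokenType.DELETE_PATIENT][int(rng.integers(3))]
                    reason = "r" if rng.random() < 0.8 else None
                    tokens.append(service.create_token(s.session_id, ttype, reason=reason))
                elif action == 2 and tokens:
                    t = tokens[int(rng.integers(len(tokens)))]
                    could_run = (
                        t.state is TokenState.ISSUED
                        and not service.sessions[t.session_id].invalidated
                        and t.token_type is TokenType.ADD_PATIENT
                    )
                    service.redeem_token(t.token_id, {"fields": fields})
                    successful_adds += 1
                    assert could_run
                elif action == 3 and sessions and rng.random() < 0.05:
                    service.invalidate_session(
                        sessions[int(rng.integers(len(sessions)))].session_id)
                elif action == 4:
                    # forged token id: must never execute anything
                    service.redeem_token(f"forged-{step}", {"fields": fields})
                    raise AssertionError("forged token accepted")
                elif action == 5 and tokens:
                    t = tokens[int(rng.integers(len(tokens)))]
                    if t.state is TokenState.REDEEMED:
                        service.redeem_token(t.token_id, {"fields": fields})
                        raise AssertionError("replayed token accepted")
            except (AuthenticationError, AuthorizationError, TokenError):
                continue
        assert len(store.active_patients()) == successful_adds
        # exactly one audit record per consumed token, whatever its outcome
        consumed = sum(1 for t in tokens if t.state is TokenState.REDEEMED)
        assert len(service.audit_trail) == consumed
        assert successful_adds > 100  # the fuzz actually exercised the path
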