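"""Session/token delegation: the data-capture system never sees PII, the
user never sees the internal pseudonym.

An EDC system authenticates with its API key, opens a session and mints
a single-use ADD_PATIENT token carrying a callback.  The user's browser
redeems the token with the PII; the response shows the user only the
study pseudonym, while the internal pid travels to the EDC system's
callback.  Every redemption lands in the audit trail with its reason.
"""

import pseudolink as pl
from pseudolink.service import TokenType

store = pl.default_store(b"example-mixing-key")
store.register_pseudonym_type(pl.PseudonymTypeDef(
    "study_a_id", generator=lambda n: f"STUDY-A-{n:06d}", tenant="study_a"))

delivered = []
service = pl.PseudonymizationService(
    store,
    pl.default_linkage_config(),
    pl.ServiceConfig(
        clients=(pl.ClientConfig("edc-system", "edc-api-key", "study_a_user"),),
        roles=(pl.Role.from_strings("study_a_user", [
            "create-token:ADD_PATIENT", "read-idtype:study_a_id",
            "read-patient", "tenant:study_a"]),),
        callback_allowlist=("https://edc.example.org/",),
    ),
    callback_transport=lambda url, body: delivered.append((url, body)) or True,
)

session = service.create_session("edc-api-key")
token = service.create_token(
    session.session_id, TokenType.ADD_PATIENT,
    payload={"tenant": "study_a", "id_types": ["study_a_id"]},
    callback={"url": "https://edc.example.org/callback", "id_types": ["pid"]},
    reason="enrolment visit 1",
)

result = service.redeem_token(token.token_id, {"fields": {
    "first_name": "Anna", "last_name": "Meier", "birth_day": 4,
    "birth_month": 7, "birth_year": 1981, "city": "Mainz"}})

print(f"user sees:      {result['pseudonyms']}")
url, body = delivered[0]
print(f"callback to {url} carries: {list(body['pseudonyms'])} (signed)")

try:
    service.redeem_token(token.token_id, {"fields": {"first_name": "Eve"}})
except Exception as exc:
    print(f"second redemption refused: {exc}")

entry = service.audit_trail[0]
print(f"audit: {entry.operation} by {entry.client} because {entry.reason!r}, "
      f"affected {entry.affected_pseudonyms}")
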