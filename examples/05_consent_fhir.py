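"""Modular consent: record, check, withdraw, serialize to FHIR.

A template models the consent form (one module per checkbox, each
granting policies); a patient's choices are recorded against it, policy
checks answer operational questions date-dependently, and the record
round-trips through a FHIR Bundle with the scanned paper form attached.
"""

import json
from datetime import date

import pseudolink as pl

consents = pl.ConsentStore()
consents.register_template(pl.ConsentTemplate(
    template_id="broad-consent", version="1.0",
    modules=(
        pl.ConsentModule("data-storage", ("store-pii",), required=True),
        pl.ConsentModule("data-sharing", ("share-third-party",)),
        pl.ConsentModule("recontact", ("recontact-findings",)),
    ),
    validity_days=5 * 365,
))

record = consents.record_consent(
    "patient-0001", "broad-consent", "1.0",
    {"data-storage": "PERMIT", "data-sharing": "PERMIT", "recontact": "DENY"},
    signed_date=date(2024, 1, 10),
    scan=pl.Scan(b"%PDF-1.4 signed paper form", "application/pdf"),
)
print(f"recorded consent v{record.version}, status {record.status.value}")

for policy in ("share-third-party", "recontact-findings", "never-asked"):
    decision = consents.check_policy("patient-0001", policy, date(2024, 6, 1))
    print(f"  may we '{policy}' on 2024-06-01?  {decision.outcome.value}")

consents.withdraw_consent("patient-0001", "broad-consent", date(2024, 8, 1))
after = consents.check_policy("patient-0001", "share-third-party", date(2024, 9, 1))
print(f"after full withdrawal: share-third-party -> {after.outcome.value}")

bundle = pl.consent_to_fhir(record)
print("FHIR bundle resources:",
      [e["resource"]["resourceType"] for e in bundle["entry"]])
restored = pl.consent_from_fhir(bundle)
print("roundtrip preserves choices:", restored.choices == record.choices)
print(json.dumps(bundle["entry"][0]["resource"]["provision"], indent=2)[:300], "...")
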