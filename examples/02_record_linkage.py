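"""Error-tolerant record linkage with two thresholds and conflict resolution.

Ingests a patient, then a mistyped re-registration, and shows the three
decision zones: exact re-entry matches, a slightly corrupted entry lands
in the tentative zone and is queued for a human merge/split decision.
"""

import pseudolink as pl

store = pl.default_store(b"example-mixing-key")
config = pl.default_linkage_config()  # thresholds: non-match < 0.80 <= tentative < 0.95 <= match

anna = {"first_name": "Anna", "last_name": "Meier", "birth_day": 4,
        "birth_month": 7, "birth_year": 1981, "city": "Mainz"}

first = pl.ingest_identity(store, anna, config)
print(f"first registration  -> {first.decision.value}, new patient, "
      f"pid {first.patient.pseudonym_values('pid')[0]}")

again = pl.ingest_identity(store, dict(anna, last_name="MEIER "), config)
print(f"exact re-entry      -> {again.decision.value} (score {again.score:.3f}), "
      f"same patient: {again.patient is first.patient}")

typo = pl.ingest_identity(store, dict(anna, birth_month=8), config)
print(f"wrong birth month   -> {typo.decision.value} (score {typo.score:.3f}), "
      f"queued for review")

for a, b, score in pl.list_tentative_pairs(store):
    print(f"tentative pair at score {score:.3f}; a trustee now merges them")
    pl.resolve_conflict(store, (a, b), pl.ConflictDecision.MERGE, actor="trustee")

print(f"patients after merge: {len(store.active_patients())}")
# The score is a weighted average of per-field similarities; rare, reliable
# fields (last name) weigh more than fields that agree by chance (birth month).
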